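"""Group comparisons as used throughout the analysis: one-way ANOVA with
Bonferroni post hoc pairwise tests, the unpaired two-sample t-test, and
mean +/- s.e.m. summaries.

Sums of squares and test statistics are computed from their defining
formulas; tail probabilities come from the regularized incomplete beta
function.  The pairwise tests are pooled-variance by default (a Welch
option exists) to match the classic ANOVA + Bonferroni workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc

from .errors import ParameterError


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float
    degenerate: bool = False


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def _groups_to_arrays(groups: Mapping[str, Sequence[float]],
                      min_n: int = 2) -> dict[str, np.ndarray]:
    out = {name: np.asarray(vals, dtype=float) for name, vals in groups.items()}
    for name, vals in out.items():
        if vals.ndim != 1 or vals.size < min_n:
            raise ParameterError(
                f"group {name!r} needs >= {min_n} one-dimensional values")
    return out


def f_sf(F: float, d1: int, d2: int) -> float:
    """Upper-tail probability of the F distribution via the regularized
    incomplete beta function: P(F' > F) = I_{d2/(d2 + d1 F)}(d2/2, d1/2)."""
    if F <= 0:
        return 1.0
    x = d2 / (d2 + d1 * F)
    return float(betainc(d2 / 2.0, d1 / 2.0, x))


def t_sf_two_sided(t: float, df: int) -> float:
    """Two-sided tail probability of Student's t:
    P(|T| > |t|) = I_{df/(df + t^2)}(df/2, 1/2)."""
    if t == 0:
        return 1.0
    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classic between/within sum-of-squares decomposition."""
    arrs = _groups_to_arrays(groups)
    if len(arrs) < 2:
        raise ParameterError("ANOVA needs at least two groups")
    all_vals = np.concatenate(list(arrs.values()))
    grand = all_vals.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in arrs.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in arrs.values())
    dfb = len(arrs) - 1
    dfw = all_vals.size - len(arrs)
    if ssw == 0.0:
        # zero within-group variance: F is 0/0 or infinite -- flag it
        if ssb == 0.0:
            return AnovaResult(np.nan, dfb, dfw, np.nan, 0.0, 0.0,
                               degenerate=True)
        return AnovaResult(np.inf, dfb, dfw, 0.0, float(ssb), 0.0,
                           degenerate=True)
    F = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(float(F), dfb, dfw, f_sf(F, dfb, dfw),
                       float(ssb), float(ssw))


def unpaired_t(a: Sequence[float], b: Sequence[float],
               welch: bool = False) -> TTestResult:
    """Two-sample t-test, pooled-variance by default."""
    arrs = _groups_to_arrays({"a": a, "b": b})
    x, y = arrs["a"], arrs["b"]
    na, nb = x.size, y.size
    va, vb = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0.0:
            return TTestResult(np.nan if diff == 0 else np.inf, na + nb - 2,
                               np.nan if diff == 0 else 0.0, degenerate=True)
        t = diff / np.sqrt(se2)
        df = int(np.floor(se2 ** 2 / ((va / na) ** 2 / (na - 1)
                                      + (vb / nb) ** 2 / (nb - 1))))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        df = na + nb - 2
        if sp2 == 0.0:
            return TTestResult(np.nan if diff == 0 else np.inf, df,
                               np.nan if diff == 0 else 0.0, degenerate=True)
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return TTestResult(float(t), df, t_sf_two_sided(float(t), df))


def bonferroni_pairwise(groups: Mapping[str, Sequence[float]],
                        alpha: float = 0.05,
                        welch: bool = False) -> pd.DataFrame:
    """All pairwise t comparisons with Bonferroni-adjusted p-values.

    p is multiplied by the number of comparisons k(k-1)/2 and capped at 1;
    the ``significant`` flag applies ``alpha`` (default 0.05) to the
    adjusted value.
    """
    arrs = _groups_to_arrays(groups)
    names = list(arrs)
    if len(names) < 2:
        return pd.DataFrame(columns=["group_a", "group_b", "t", "df",
                                     "p_raw", "p_adjusted", "significant"])
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    k = len(pairs)
    rows = []
    for a, b in pairs:
        res = unpaired_t(arrs[a], arrs[b], welch=welch)
        p_adj = min(1.0, res.p * k) if np.isfinite(res.p) else res.p
        rows.append({"group_a": a, "group_b": b, "t": res.t, "df": res.df,
                     "p_raw": res.p, "p_adjusted": p_adj,
                     "significant": bool(p_adj < alpha)
                     if np.isfinite(p_adj) else False})
    return pd.DataFrame(rows)


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error of the mean (sample sd / sqrt(n))."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ParameterError("mean_sem needs at least one value")
    mean = float(v.mean())
    if v.size < 2:
        return mean, float("nan")
    return mean, float(v.std(ddof=1) / np.sqrt(v.size))
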