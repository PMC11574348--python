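"""Trial-level analysis and cohort-level orchestration.

``analyze_trial`` runs the full per-trial chain: likelihood conditioning,
two-view alignment, Hanning smoothing, the centered 500-frame window, the
six angles, mirror normalization to a canonical (right) tail side, the
angular-momentum model, balance metrics, step-cycle segmentation and
cycle statistics.  ``run_analyze`` maps it over a manifest with per-trial
exclusion logging, pools step-cycle momentum epochs into per-width
cross-correlograms (unperturbed trials only), and builds the group
statistics tables.  ``run_report`` renders summary tables and figures.

Momentum sign convention: platform rotations toward the animal's left are
positive; compensation ratios are reported relative to the *opposing*
perturbation momentum, so a tail swing that counters the tilt yields a
positive fraction.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import balance, biomech, coupling, gait, kinematics, stats
from .errors import TailBalanceError
from .io import (AlignedTrial, CentroidTrace, KeypointTable, TrialMeta,
                 align_on_visibility, apply_likelihood_cutoff,
                 extract_centered_window, hanning_smooth, read_centroid_trace,
                 read_keypoint_table, read_manifest, read_trial_meta)


@dataclass
class RunConfig:
    """Analysis parameters; the defaults are the study's stated values."""

    cutoff: float = 0.9                 # likelihood cutoff
    smoothing_window: int = 10          # frames (33 ms at 300 fps)
    centered_window: int = 500          # frames of the analysis window
    stop_threshold: float = 1.0         # mm/s immobility threshold
    response_window: float = 0.5        # s after tilt onset
    perturbation_variant: str = "cylinder_plus_parallel_axis"
    percentile: float = 5.0             # hotspot/coldspot tails
    epoch_halfwidth: int = 75           # frames; one 4 Hz stride period
    expected_stride_frames: float = 75.0
    integration_mode: str = "signed"
    conditioning_mode: str = "interpolate"
    model: biomech.BodyModel = field(default_factory=biomech.BodyModel)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class TrialResult:
    """Per-trial scalars plus the epoch stacks needed for pooling."""

    row: dict
    tail_momentum_epochs: np.ndarray | None = None
    body_momentum_epochs: np.ndarray | None = None
    momentum_traces: dict | None = None


@dataclass
class ResultsBundle:
    trials: pd.DataFrame
    exclusions: pd.DataFrame
    correlograms: dict            # width -> dict(correlogram, hotspot, coldspot)
    stats_tables: dict            # metric -> dict(anova, pairwise)
    config: RunConfig
    log: list[dict] = field(default_factory=list)


def _smooth_table(table: KeypointTable, window: int) -> KeypointTable:
    df = table.data.copy()
    for col in df.columns:
        if col[-1] in ("x", "y"):
            df[col] = hanning_smooth(df[col].to_numpy(dtype=float), window)
    from dataclasses import replace
    return replace(table, data=df)


def _smooth_centroid(tr: CentroidTrace, window: int) -> CentroidTrace:
    return CentroidTrace(hanning_smooth(tr.x, window),
                         hanning_smooth(tr.y, window),
                         tr.visibility, tr.frame_rate)


def analyze_trial(top: KeypointTable, rear: KeypointTable,
                  centroid: CentroidTrace, meta: TrialMeta,
                  config: RunConfig | None = None,
                  slip_count: int | None = None) -> TrialResult:
    """Run the complete single-trial analysis (see module docstring).

    Raises :class:`~tailbalance.errors.TailBalanceError` subclasses for the
    enumerated exclusion conditions (unusable bodypart, no visibility,
    too-short trial, unclassifiable laterality).
    """
    cfg = config or RunConfig()
    top, rep_top = apply_likelihood_cutoff(top, cfg.cutoff,
                                           cfg.conditioning_mode)
    rear, rep_rear = apply_likelihood_cutoff(rear, cfg.cutoff,
                                             cfg.conditioning_mode)
    aligned: AlignedTrial = align_on_visibility(top, rear, centroid)
    top_s = _smooth_table(aligned.top, cfg.smoothing_window)
    rear_s = _smooth_table(aligned.rear, cfg.smoothing_window)
    cen_s = _smooth_centroid(aligned.centroid, cfg.smoothing_window)

    # angles and momenta are computed on the full aligned stream; the
    # centered window is used for trial-level posture and balance metrics
    idx = np.arange(top_s.n_frames)
    _, w0 = extract_centered_window(idx, cfg.centered_window,
                                    return_start=True)
    w1 = w0 + cfg.centered_window
    cen_w = cen_s.crop(w0, w1)
    fr = top_s.frame_rate

    angles = kinematics.compute_angles(
        rear_s, top_s, np.column_stack([cen_s.x, cen_s.y]))

    # ---- laterality -----------------------------------------------------
    onset: int | None = None  # tilt onset on the aligned frame index
    if meta.tilt_present:
        onset = int(meta.tilt_onset - aligned.start_frame)
        if not 0 <= onset < top_s.n_frames:
            raise TailBalanceError("tilt onset outside the aligned trial")
        lat = kinematics.classify_laterality(
            angles["roll_tail"].values[onset], meta.tilt_direction)
        tail_side, label = lat.tail_side, lat.label
    else:
        mean_roll = float(np.mean(angles["roll_tail"].values))
        tail_side = "left" if 0.0 < mean_roll % 360.0 < 180.0 else "right"
        label = None
    canon = kinematics.mirror_normalize(angles, tail_side)
    # side-normalized roll in display convention (tail side in (0, 180))
    roll_side = kinematics.mirror_roll(canon["roll_tail"].values)

    # ---- angular velocities and momenta ---------------------------------
    def smoothed_velocity(trace):
        return hanning_smooth(kinematics.angular_velocity(trace),
                              cfg.smoothing_window)

    omega_tail_deg = smoothed_velocity(angles["roll_tail"])
    omega_body_deg = smoothed_velocity(angles["hip"])
    tail_L = biomech.tail_momentum(np.radians(omega_tail_deg), cfg.model, fr)
    body_L = biomech.body_momentum(np.radians(omega_body_deg), cfg.model, fr)
    sum_L = biomech.sum_momentum(tail_L, body_L)

    row = {
        "animal_id": meta.animal_id,
        "ridge_width": meta.ridge_width,
        "tilt_present": meta.tilt_present,
        "laterality": label,
        "tail_side": tail_side,
        "n_frames_analyzed": cfg.centered_window,
        "dropout_replaced_rear": int(sum(rep_rear.values())),
        "dropout_replaced_top": int(sum(rep_top.values())),
    }

    # mean posture through the centered window (side-normalized convention)
    row["tail_mean_roll"] = float(np.mean(roll_side[w0:w1]))
    # baseline posture: before tilt onset on tilt trials, whole window else
    base_stop = min(onset, w1) if onset is not None else w1
    row["tail_baseline_roll"] = (float(np.mean(roll_side[w0:base_stop]))
                                 if base_stop > w0
                                 else float(np.mean(roll_side[:onset])))
    row["hip_mean"] = float(np.mean(angles["hip"].values[w0:w1]))
    row["tail_on_body_mean"] = float(np.mean(np.abs(
        canon["tail_on_body"].values[w0:w1])))

    # ---- tilt-response metrics ------------------------------------------
    traces = {"tail": tail_L, "body": body_L, "sum": sum_L}
    if meta.tilt_present:
        n_full = top_s.n_frames
        tilt = biomech.TiltProfile(meta.tilt_amplitude, meta.tilt_duration,
                                   meta.tilt_direction, onset)
        pert_L = biomech.perturbation_momentum(
            tilt, cfg.model, n_full, fr, cfg.perturbation_variant)
        traces["perturbation"] = pert_L
        t0 = onset / fr
        t1 = min(t0 + cfg.response_window, (n_full - 1) / fr)
        sl = slice(onset, onset + int(round(cfg.response_window * fr)))

        # swing speed: peak and mean |roll velocity| in the response window
        speed = np.abs(omega_tail_deg[sl]) / 360.0  # rotations/s
        row["tail_peak_speed_rps"] = float(speed.max())
        roll_unwrapped = np.unwrap(angles["roll_tail"].values, period=360.0)
        peak_frame = int(np.argmax(
            np.abs(roll_unwrapped[sl] - roll_unwrapped[onset])))
        row["tail_time_to_peak"] = peak_frame / fr
        row["tail_mean_speed_rps"] = float(
            speed[:peak_frame + 1].mean()) if peak_frame > 0 else float(speed.mean())
        body_peak_frame = int(np.argmax(
            np.abs(angles["hip"].values[sl] - angles["hip"].values[onset])))
        row["body_time_to_peak"] = body_peak_frame / fr

        totals = {}
        for name, tr in traces.items():
            totals[name] = biomech.integrate_momentum(
                tr, (t0, t1), cfg.integration_mode)
            phases = biomech.split_phases(tr, tilt, cfg.response_window,
                                          cfg.integration_mode)
            row[f"momentum_{name}_early"] = phases["early"]
            row[f"momentum_{name}_late"] = phases["late"]
            row[f"momentum_{name}_total"] = totals[name]
        # compensation fraction: relative to the opposing platform momentum
        rel = biomech.relative_momentum(totals["tail"], totals["body"],
                                        -totals["perturbation"])
        if rel is not None:
            row["relative_momentum_tail"] = rel["tail"]
            row["relative_momentum_body"] = rel["body"]
            row["relative_momentum_sum"] = rel["sum"]
        rel_early = biomech.relative_momentum(
            row["momentum_tail_early"], row["momentum_body_early"],
            -row["momentum_perturbation_early"])
        if rel_early is not None:
            row["relative_momentum_sum_early"] = rel_early["sum"]

    # ---- balance metrics -------------------------------------------------
    rep = balance.balance_report(cen_w, meta, cfg.stop_threshold,
                                 cfg.smoothing_window, slip_count)
    row.update({
        "traversing_speed": rep.traversing_speed,
        "traversing_speed_moving": rep.traversing_speed_moving,
        "stop_count": rep.stop_count,
        "stop_duration": rep.stop_duration,
        "time_outside_bos": rep.time_outside_bos,
        "lateral_movement": rep.lateral_movement,
        "centrality": rep.centrality,
        "slip_count": slip_count,
    })

    # ---- step cycles (detected on the full aligned stream) ---------------
    contra = "paw_right" if tail_side == "left" else "paw_left"
    events = gait.detect_step_peaks(
        rear_s.x(contra), expected_stride_frames=cfg.expected_stride_frames,
        paw=contra)
    row["n_step_events"] = events.n_events
    row["stride_period_frames"] = events.stride_period_frames
    row["stride_frequency"] = (fr / events.stride_period_frames
                               if np.isfinite(events.stride_period_frames)
                               else np.nan)
    result = TrialResult(row=row, momentum_traces=traces)
    if events.n_events:
        h = cfg.epoch_halfwidth
        tail_cycles = gait.align_epochs(roll_side, events, h, fr)
        hip_cycles = gait.align_epochs(angles["hip"].values, events, h, fr)
        if tail_cycles.n_epochs:
            _, tail_summary = gait.cycle_stats(tail_cycles)
            _, hip_summary = gait.cycle_stats(hip_cycles)
            row["tail_cycle_mean"] = tail_summary["mean_position"]
            row["tail_cycle_range"] = tail_summary["range"]
            row["hip_cycle_mean"] = hip_summary["mean_position"]
            row["hip_cycle_range"] = hip_summary["range"]
        tl = gait.align_epochs(tail_L.values, events, h, fr)
        bl = gait.align_epochs(body_L.values, events, h, fr)
        if tl.n_epochs:
            result.tail_momentum_epochs = tl.epochs
            result.body_momentum_epochs = bl.epochs
    return result


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

_CYCLE_METRICS = ("traversing_speed", "centrality", "lateral_movement",
                  "time_outside_bos", "tail_cycle_mean", "tail_cycle_range",
                  "hip_cycle_mean", "hip_cycle_range")


def _load_record(record: dict, base: Path | None):
    if "objects" in record:
        o = record["objects"]
        return o["top"], o["rear"], o["centroid"], o["meta"]
    files = record["files"]
    root = base if base is not None else Path(".")
    top = read_keypoint_table(root / files["top"], "top")
    rear = read_keypoint_table(root / files["rear"], "rear")
    centroid = read_centroid_trace(root / files["centroid"])
    meta = read_trial_meta(root / files["meta"])
    return top, rear, centroid, meta


def run_analyze(manifest, config: RunConfig | None = None,
                outdir: str | Path | None = None,
                manifest_base: str | Path | None = None,
                slip_labels: dict | None = None) -> ResultsBundle:
    """Analyze every trial in a manifest; failures become logged exclusions.

    ``manifest`` is a path to a manifest YAML or a list of records (each
    with either ``files`` paths or in-memory ``objects``).  Per-width
    cross-correlograms pool momentum epochs from unperturbed trials.
    """
    cfg = config or RunConfig()
    if isinstance(manifest, (str, Path)):
        if manifest_base is None:
            manifest_base = Path(manifest).parent
        records = read_manifest(manifest)
    else:
        records = list(manifest)
    base = Path(manifest_base) if manifest_base is not None else None

    log: list[dict] = []
    rows, excl = [], []
    epochs_by_width: dict[float, list] = {}
    for record in records:
        tid = record.get("trial_id", "?")
        entry = {"trial_id": tid, "time": time.time()}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                top, rear, centroid, meta = _load_record(record, base)
                slip = (slip_labels or {}).get(tid)
                res = analyze_trial(top, rear, centroid, meta, cfg, slip)
        except FileNotFoundError as exc:
            excl.append({"trial_id": tid, "reason": "missing-file",
                         "detail": str(exc)})
            entry["status"] = "excluded:missing-file"
            log.append(entry)
            continue
        except TailBalanceError as exc:
            reason = _exclusion_reason(exc)
            excl.append({"trial_id": tid, "reason": reason,
                         "detail": str(exc)})
            entry["status"] = f"excluded:{reason}"
            log.append(entry)
            continue
        res.row["trial_id"] = tid
        rows.append(res.row)
        entry["status"] = "ok"
        log.append(entry)
        if (res.tail_momentum_epochs is not None
                and not res.row["tilt_present"]):
            epochs_by_width.setdefault(res.row["ridge_width"], []).append(
                (res.tail_momentum_epochs, res.body_momentum_epochs))

    trials = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excl, columns=["trial_id", "reason", "detail"])

    correlograms: dict = {}
    for width, stacks in sorted(epochs_by_width.items()):
        te = np.vstack([s[0] for s in stacks])
        be = np.vstack([s[1] for s in stacks])
        if te.shape[0] < 3:
            continue
        h = cfg.epoch_halfwidth
        tail_set = gait.StepCycleSet(te, h, np.zeros(te.shape[0], dtype=int))
        body_set = gait.StepCycleSet(be, h, np.zeros(be.shape[0], dtype=int))
        C = coupling.build_correlogram(tail_set, body_set)
        hot, cold = coupling.find_extreme_regions(C, cfg.percentile)
        correlograms[width] = {"correlogram": C, "hotspot": hot,
                               "coldspot": cold}

    stats_tables = _group_statistics(trials)
    bundle = ResultsBundle(trials=trials, exclusions=exclusions,
                           correlograms=correlograms,
                           stats_tables=stats_tables, config=cfg, log=log)
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _exclusion_reason(exc: TailBalanceError) -> str:
    from . import errors
    if isinstance(exc, errors.UnusableBodypartError):
        return "unusable-bodypart"
    if isinstance(exc, errors.WindowError):
        return "too-short"
    if isinstance(exc, errors.AlignmentError):
        return "no-visibility"
    if isinstance(exc, errors.UndefinedAngleError):
        return "unclassifiable-laterality"
    return "analysis-error"


def _group_statistics(trials: pd.DataFrame) -> dict:
    """Per-metric one-way ANOVA across ridge widths on per-animal means
    (unperturbed trials), with Bonferroni pairwise comparisons."""
    out: dict = {}
    if trials.empty:
        return out
    base = trials[~trials["tilt_present"]] if "tilt_present" in trials else trials
    for metric in _CYCLE_METRICS:
        if metric not in base:
            continue
        per_animal = (base.dropna(subset=[metric])
                      .groupby(["ridge_width", "animal_id"])[metric]
                      .mean().reset_index())
        groups = {f"{w:g}mm": sub[metric].to_numpy()
                  for w, sub in per_animal.groupby("ridge_width")
                  if len(sub) >= 2}
        if len(groups) < 2:
            continue
        anova = stats.one_way_anova(groups)
        pairwise = stats.bonferroni_pairwise(groups)
        summary = pd.DataFrame(
            [{"group": name, "n": len(v),
              "mean": stats.mean_sem(v)[0], "sem": stats.mean_sem(v)[1]}
             for name, v in groups.items()])
        out[metric] = {"anova": anova, "pairwise": pairwise,
                       "summary": summary}
    return out


def _write_bundle(bundle: ResultsBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.trials.to_csv(outdir / "trials.csv", index=False)
    bundle.exclusions.to_csv(outdir / "exclusions.csv", index=False)
    with open(outdir / "run_log.jsonl", "w") as fh:
        fh.write(json.dumps({"config": bundle.config.to_dict()}) + "\n")
        for entry in bundle.log:
            fh.write(json.dumps(entry) + "\n")
    stats_rows = []
    for metric, tables in bundle.stats_tables.items():
        a = tables["anova"]
        stats_rows.append({"metric": metric, "comparison": "ANOVA",
                           "statistic": a.F, "df": f"({a.df_between},{a.df_within})",
                           "p_raw": a.p, "p_adjusted": np.nan,
                           "significant": bool(a.p < 0.05)
                           if np.isfinite(a.p) else False})
        for _, r in tables["pairwise"].iterrows():
            stats_rows.append({"metric": metric,
                               "comparison": f"{r.group_a} vs {r.group_b}",
                               "statistic": r.t, "df": str(r.df),
                               "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
                               "significant": r.significant})
    pd.DataFrame(stats_rows).to_csv(outdir / "statistics.csv", index=False)
    for width, entry in bundle.correlograms.items():
        C = entry["correlogram"]
        np.savetxt(outdir / f"correlogram_w{width:g}mm.csv", C.matrix,
                   delimiter=",")
        sidecar = {
            "ridge_width": width, "n_trials": C.n_trials,
            "bin_times": C.bin_times.tolist(),
            "hotspot": sorted([int(i), int(j)] for i, j in entry["hotspot"].cells)
            if entry["hotspot"] else [],
            "coldspot": sorted([int(i), int(j)] for i, j in entry["coldspot"].cells)
            if entry["coldspot"] else [],
        }
        with open(outdir / f"correlogram_w{width:g}mm.json", "w") as fh:
            json.dump(sidecar, fh)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def run_report(bundle: ResultsBundle, outdir: str | Path) -> list[Path]:
    """Summary tables and figures from a results bundle.

    Writes a per-width summary CSV, momentum time-course and width-vs-metric
    figures, and one correlogram heatmap per width.  Returns the paths
    written.  An empty bundle raises.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if bundle.trials.empty:
        raise TailBalanceError("cannot report on an empty results bundle")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    trials = bundle.trials
    base = trials[~trials["tilt_present"]]
    agg_metrics = [m for m in _CYCLE_METRICS if m in trials]
    summary = (base.groupby("ridge_width")[agg_metrics]
               .agg(["mean", "sem"]) if not base.empty else pd.DataFrame())
    p = outdir / "width_summary.csv"
    summary.to_csv(p)
    written.append(p)

    if not base.empty and agg_metrics:
        fig, axes = plt.subplots(2, 4, figsize=(14, 6))
        for ax, metric in zip(axes.ravel(), agg_metrics):
            g = base.groupby("ridge_width")[metric]
            m, s = g.mean(), g.sem()
            ax.errorbar(m.index, m.values, yerr=s.values, marker="o")
            ax.set_xlabel("ridge width (mm)")
            ax.set_title(metric.replace("_", " "))
        fig.tight_layout()
        p = outdir / "width_vs_metrics.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    tilt = trials[trials["tilt_present"] & (trials["laterality"] == "IL")]
    if not tilt.empty and "relative_momentum_sum" in tilt:
        fig, ax = plt.subplots(figsize=(5, 4))
        for col, label in [("relative_momentum_tail", "tail"),
                           ("relative_momentum_body", "body"),
                           ("relative_momentum_sum", "tail+body")]:
            if col in tilt:
                mean, sem = stats.mean_sem(tilt[col].dropna().to_numpy())
                ax.bar(label, mean, yerr=sem)
        ax.axhline(1.0, ls="--", c="k", lw=0.8)
        ax.set_ylabel("momentum / opposing perturbation momentum")
        ax.set_title("compensation during IL tilts")
        fig.tight_layout()
        p = outdir / "relative_momentum.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    for width, entry in bundle.correlograms.items():
        C = entry["correlogram"]
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(C.matrix, vmin=-0.3, vmax=0.3, cmap="RdBu_r",
                       origin="lower",
                       extent=[C.bin_times[0], C.bin_times[-1],
                               C.bin_times[0], C.bin_times[-1]])
        for key, color in (("hotspot", "k"), ("coldspot", "b")):
            region = entry[key]
            if region:
                ii = np.array(sorted(region.cells))
                ax.plot(C.bin_times[ii[:, 1]], C.bin_times[ii[:, 0]],
                        ".", ms=2, color=color)
        ax.set_xlabel("body momentum time (s from swing peak)")
        ax.set_ylabel("tail momentum time (s)")
        ax.set_title(f"tail-body coupling, {width:g} mm ridge "
                     f"(n={C.n_trials} cycles)")
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.tight_layout()
        p = outdir / f"correlogram_heatmap_w{width:g}mm.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)
    return written
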