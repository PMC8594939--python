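"""Reference experiments on synthetic data at the study's conditions.

Each function regenerates its inputs from a seed, runs the relevant slice
of the pipeline, and returns the measured quantities. The default
parameters are the life-cycle constants the study reports (fermentation
doubling 84 min, diauxic shift 5.5-13.9 h, respiration doubling 307 min,
stationary phase from 31.6 h, 12% early-crash cells, initial pH 7.7, gel
point pH 6) — they define the conditions, not tunables.
"""

from __future__ import annotations

import numpy as np

from .calibration import PhCalibration, make_calibration_points
from .config import PipelineConfig, SimulationConfig
from .fate import FateClassifier, R_MINUS, R_PLUS, couple_ph_mobility, inheritance_index
from .lineage import simulate_counts
from .ph import PhDropFitter, measure_cell_ph_series
from .phases import detect_phases, single_cell_growth
from .pipeline import (build_movie, match_tracks_to_truth, mobility_events,
                       foci_records_from_stack, segment_and_track)

__all__ = [
    "random_assignment_inheritance_index", "pure_colony_inheritance_index",
    "phase_recovery", "fate_fraction_recovery", "ph_roundtrip",
    "gel_threshold_recovery",
]


# ---------------------------------------------------------------------------
# inheritance-index endpoints
# ---------------------------------------------------------------------------

def random_assignment_inheritance_index(seed: int, n_colonies: int = 100,
                                        colony_size: int = 15,
                                        p: float = 0.12,
                                        n_seeds: int = 3) -> float:
    """Mean inheritance index when fates are i.i.d. Bernoulli(p) per cell."""
    vals = []
    for child in np.random.SeedSequence(seed).spawn(n_seeds):
        rng = np.random.default_rng(child)
        fates = (rng.random((n_colonies, colony_size)) < p).astype(float).ravel()
        colonies = np.repeat(np.arange(n_colonies), colony_size)
        vals.append(inheritance_index(fates, colonies))
    return float(np.mean(vals))


def pure_colony_inheritance_index(n_colonies: int = 20,
                                  colony_size: int = 10) -> float:
    """Inheritance index of internally homogeneous colonies (half all-0,
    half all-1, mixed across colonies)."""
    fates = np.repeat(np.arange(n_colonies) % 2, colony_size).astype(float)
    colonies = np.repeat(np.arange(n_colonies), colony_size)
    return inheritance_index(fates, colonies)


# ---------------------------------------------------------------------------
# population growth phases
# ---------------------------------------------------------------------------

def phase_recovery(seed: int, noise: float = 0.05,
                   config: SimulationConfig | None = None) -> dict:
    """Recover phase transitions and doubling times from noisy counts.

    Simulates four-phase colony counts over the full life cycle at 15-min
    sampling with multiplicative noise, then fits a 3-breakpoint
    piecewise-linear model to the log counts.
    """
    cfg = config or SimulationConfig(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    t, counts = simulate_counts(cfg, rng, noise=noise)
    seg = detect_phases(t, counts, n_breakpoints=3)
    return {
        "breakpoints_h": [float(b) for b in seg.breakpoints],
        "doubling_time_f_min": float(seg.doubling_times_min[0]),
        "doubling_time_r_min": float(seg.doubling_times_min[2]),
        "true_breakpoints_h": list(cfg.phase_times),
        "segmentation": seg,
    }


# ---------------------------------------------------------------------------
# end-to-end rendered populations
# ---------------------------------------------------------------------------

def _population_config(seed: int, n_cells: int, frame_interval: float,
                       t_end: float = 48.0,
                       phase_times: tuple[float, float, float] = (5.5, 13.9, 31.6),
                       ) -> PipelineConfig:
    """Division-free population of ``n_cells`` founders on a grid sized to
    fit them (trapped-cell layout)."""
    # grid pitch after R-phase growth: 2 * r * sqrt(2) + 4 px
    pitch = 2 * 5.0 * np.sqrt(2.0) + 4.0
    margin = 5.0 * np.sqrt(2.0) + 2.0
    per_row = int(np.ceil(np.sqrt(n_cells)))
    side = int(np.ceil(2 * (margin + 2) + (per_row - 1) * pitch))
    sim = SimulationConfig(n_founders=n_cells, divisions_enabled=False,
                           t_end=t_end, frame_interval=frame_interval,
                           phase_times=phase_times,
                           image_height=side, image_width=side, seed=seed)
    cfg = PipelineConfig(simulation=sim, seed=seed)
    return cfg


def _analyse_population(cfg: PipelineConfig):
    """Shared segmentation -> tracking -> pH -> drops -> fates chain."""
    lineage, series, stack = build_movie(cfg)
    masks, tracks, features = segment_and_track(stack, cfg)

    ss = np.random.SeedSequence(cfg.seed).spawn(8)
    curve = PhCalibration().fit(*make_calibration_points(
        noise=cfg.calibration_noise, rng=np.random.default_rng(ss[5])))
    trajectories = measure_cell_ph_series(features, curve,
                                          smooth_window=cfg.smooth_window)

    t_counts, counts = simulate_counts(cfg.simulation,
                                       np.random.default_rng(ss[6]), noise=0.05)
    segmentation = detect_phases(t_counts, counts, cfg.n_breakpoints)

    drops = {}
    for tid, sub in trajectories.groupby("track_id", sort=True):
        valid = sub.dropna(subset=["ph"])
        if len(valid) >= 6:
            drops[tid] = PhDropFitter(
                min_amplitude=cfg.drop_min_amplitude,
                alpha=cfg.drop_alpha).fit(valid["time"], valid["ph"]).result()

    _, growth = single_cell_growth(features, segmentation)
    r_fold = dict(zip(growth["track_id"], growth["r_phase_fold"]))
    clf = FateClassifier(ds_margin=cfg.ds_margin,
                         growth_fold_threshold=cfg.growth_fold_threshold)
    end_times = tracks.groupby("track_id")["time"].max()
    fates = {tid: clf.classify(drops.get(tid), segmentation,
                               r_phase_fold=r_fold.get(tid),
                               track_end_time=float(end_times[tid]),
                               track_id=tid).fate
             for tid in tracks["track_id"].unique()}
    return dict(lineage=lineage, series=series, stack=stack, masks=masks,
                tracks=tracks, features=features, curve=curve,
                trajectories=trajectories, segmentation=segmentation,
                drops=drops, fates=fates)


def fate_fraction_recovery(seed: int, n_cells: int = 466,
                           frame_interval: float = 30.0) -> dict:
    """Render a population with the study's early-crash fraction and
    recover the R- percentage through the full pipeline."""
    cfg = _population_config(seed, n_cells, frame_interval)
    res = _analyse_population(cfg)
    fates = res["fates"]
    n_minus = sum(f == R_MINUS for f in fates.values())
    n_plus = sum(f == R_PLUS for f in fates.values())
    truth = dict(zip(res["lineage"]["cell_id"], res["lineage"]["fate"]))
    tm = match_tracks_to_truth(res["tracks"], res["masks"], res["stack"].labels)
    matched = [(fates[t], truth[tm[t]]) for t in fates
               if t in tm and fates[t] in (R_PLUS, R_MINUS)]
    acc = float(np.mean([p == g for p, g in matched])) if matched else float("nan")
    return {
        "fraction_r_minus_pct": 100.0 * n_minus / max(n_minus + n_plus, 1),
        "true_fraction_pct": 100.0 * float(
            (res["lineage"]["fate"] == R_MINUS).mean()),
        "n_classified": n_minus + n_plus,
        "n_cells": len(res["lineage"]),
        "accuracy_vs_truth": acc,
    }


def ph_roundtrip(seed: int, n_cells: int = 50) -> dict:
    """Mean pipeline-measured pH of cells rendered at the initial pH.

    A short movie at the very start of the life cycle (frame 1 at t = 0,
    where every cell sits at the initial pH plus small per-cell jitter) is
    rendered at default noise, segmented, tracked, and converted to pH via
    a calibration fitted from 7 synthetic buffer points spanning pH 5-8.
    """
    cfg = _population_config(seed, n_cells, frame_interval=15.0,
                             t_end=2.0, phase_times=(0.5, 1.0, 1.5))
    cfg.smooth_window = 0  # no temporal smoothing: frame 1 is measured as-is
    lineage, series, stack = build_movie(cfg)
    masks, tracks, features = segment_and_track(stack, cfg)
    curve = PhCalibration().fit(*make_calibration_points(
        n=7, noise=cfg.calibration_noise,
        rng=np.random.default_rng(np.random.SeedSequence(seed).spawn(6)[5])))
    traj = measure_cell_ph_series(features, curve, smooth_window=0)
    first = traj[traj["frame"] == 0].dropna(subset=["ph"])
    return {
        "mean_ph_frame1": float(first["ph"].mean()),
        "true_ph": cfg.simulation.ph_init,
        "n_cells": int(len(first)),
    }


def gel_threshold_recovery(seed: int, n_cells: int = 100,
                           frame_interval: float = 15.0) -> dict:
    """Median pH at the detected lipid-droplet mobility-loss time.

    Full pipeline: rendered population, LD tracking on the inverted phase
    channel, changepoint mobility-loss detection, pH interpolation at the
    loss time. The generator's gel transition sits at the default pH 6.
    """
    cfg = _population_config(seed, n_cells, frame_interval)
    res = _analyse_population(cfg)
    ld_records = foci_records_from_stack(res["stack"], res["masks"],
                                         res["tracks"], channel="phase",
                                         invert=True, k=cfg.foci_k,
                                         marker_name="LD")
    t_gate = cfg.simulation.phase_times[0] + cfg.mobility_gate_hours
    _, events = mobility_events(ld_records, t_min=t_gate)
    records, summary = couple_ph_mobility(res["drops"], events,
                                          res["trajectories"], res["fates"])
    out = {
        "median_ph_at_loss": summary.get("pooled", {}).get("median_ph_at_loss",
                                                           float("nan")),
        "n_events": summary.get("pooled", {}).get("n", 0),
        "true_gel_ph": cfg.simulation.ph_gel,
        "by_fate": {f: v["median_ph_at_loss"]
                    for f, v in summary.get("by_fate", {}).items()},
    }
    return out
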