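"""End-to-end orchestration: simulate, render, segment, track, quantify.

`run_pipeline` chains every stage on a synthetic movie (or a user-supplied
stack) and produces a machine-readable summary: phase breakpoints and
doubling times, per-cell pH trajectories and drop fits, foci records,
mobility-loss events, fate fractions, the inheritance index and the
pH-at-mobility-loss statistics. Deterministic given the config seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import io as qio
from .calibration import PhCalibration, make_calibration_points
from .config import PipelineConfig
from .fate import R_MINUS, R_PLUS, FateClassifier, couple_ph_mobility, inheritance_index
from .foci import (MobilityChangepointDetector, MobilityLossEvent, detect_foci,
                   focus_centroid, frame_displacement, globularization_score,
                   aggregate_foci_fraction)
from .lineage import counts_from_lineage, simulate_counts, simulate_lineage
from .ph import PhDropFitter, measure_cell_ph_series
from .phases import detect_phases, single_cell_growth
from .render import ImageStack, render_timelapse
from .segmentation import WatershedSegmenter
from .states import simulate_marker_states, simulate_ph_trajectories
from .tracking import CostLinker, extract_track_features

logger = logging.getLogger("quiescell")

__all__ = ["run_pipeline", "build_movie", "segment_and_track",
           "foci_records_from_stack", "mobility_events", "match_tracks_to_truth"]


def build_movie(config: PipelineConfig):
    """Simulate lineage + states and render the stack, deterministically."""
    sim = config.simulation
    ss = np.random.SeedSequence(config.seed)
    r_lin, r_ph, r_marker, r_render = [np.random.default_rng(s)
                                       for s in ss.spawn(4)]
    lineage = simulate_lineage(sim, r_lin)
    series = simulate_ph_trajectories(lineage, sim, r_ph)
    series = simulate_marker_states(series, sim, r_marker)
    stack = render_timelapse(lineage, series, sim, r_render)
    logger.info("simulated %d cells over %d frames", len(lineage), stack.n_frames)
    return lineage, series, stack


def segment_and_track(stack: ImageStack, config: PipelineConfig):
    """Watershed-segment every frame and link the regions into tracks."""
    seg = WatershedSegmenter(min_area=config.min_area,
                             smoothing_sigma=config.smoothing_sigma,
                             min_distance=max(int(config.simulation.cell_radius_px) - 1, 3))
    masks = [seg.segment(stack.channel("phase")[f])
             for f in range(stack.n_frames)]
    linker = CostLinker(lambda_area=config.lambda_area, gate=config.gate)
    tracks = linker.link(masks, stack.times)
    features = extract_track_features(tracks, stack, masks)
    logger.info("tracked %d regions into %d tracks",
                len(tracks), tracks["track_id"].nunique())
    return masks, tracks, features


def _eroded_region(mask: np.ndarray, label: int, iterations: int = 2):
    sel = mask == label
    er = ndi.binary_erosion(sel, iterations=iterations)
    return er if er.sum() >= 6 else sel


def foci_records_from_stack(stack: ImageStack, masks, tracks: pd.DataFrame,
                            channel: str = "marker", invert: bool = False,
                            k: float = 4.0, marker_name: str | None = None
                            ) -> pd.DataFrame:
    """Globularization score, foci call and top-5 centroid per (track, frame).

    With ``invert=True`` the channel is negated first, which turns the dark
    lipid droplets of the phase-contrast image into bright foci for the same
    top-5-pixel machinery. Masks are eroded by 2 px so rim pixels straddling
    the cell boundary cannot pose as foci.
    """
    rows = []
    for f, sub in tracks.groupby("frame", sort=True):
        img = stack.channel(channel)[f].astype(float)
        if invert:
            img = -img
        mask = np.asarray(masks[f])
        for row in sub.itertuples(index=False):
            sel = _eroded_region(mask, row.label)
            px = img[sel]
            if px.size < 6:
                continue
            ys, xs = np.nonzero(sel)
            score = globularization_score(px)
            cx, cy = focus_centroid(px, np.column_stack([xs, ys]))
            rows.append({
                "track_id": row.track_id, "frame": f, "time": row.time,
                "marker": marker_name or channel,
                "globularization_score": score,
                "has_foci": detect_foci(px, k),
                "focus_x": cx, "focus_y": cy,
            })
    return pd.DataFrame(rows, columns=["track_id", "frame", "time", "marker",
                                       "globularization_score", "has_foci",
                                       "focus_x", "focus_y"])


def mobility_events(records: pd.DataFrame, t_min: float | None = None,
                    drop_ratio: float = 0.5, min_points: int = 6
                    ) -> tuple[pd.DataFrame, dict[int, MobilityLossEvent]]:
    """Per-track displacement series and mobility-loss changepoints.

    ``records`` is a foci-record table (one marker). Displacements before
    ``t_min`` (e.g. before foci appear) are excluded from the changepoint
    fit.
    """
    events: dict[int, MobilityLossEvent] = {}
    disp_rows = []
    for tid, sub in records.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        cent = sub[["focus_x", "focus_y"]].to_numpy()
        disp = frame_displacement(cent)
        # a displacement sample describes motion over the interval that
        # STARTS at its timestamp, so a detected changepoint dates the first
        # arrested interval rather than its end
        t = sub["time"].to_numpy()[:-1]
        consecutive = np.diff(sub["frame"].to_numpy()) == 1
        disp = np.where(consecutive, disp, np.nan)
        for ti, di in zip(t, disp):
            disp_rows.append({"track_id": tid, "time": ti, "displacement": di})
        keep = np.isfinite(disp)
        if t_min is not None:
            keep &= t >= t_min
        if keep.sum() < min_points:
            events[tid] = MobilityLossEvent(tid, None, "changepoint", 0.0)
            continue
        det = MobilityChangepointDetector(drop_ratio=drop_ratio,
                                          min_points=min_points)
        det.fit(t[keep], disp[keep])
        events[tid] = MobilityLossEvent(tid, det.t_loss_, "changepoint",
                                        det.confidence_)
    return pd.DataFrame(disp_rows, columns=["track_id", "time", "displacement"]), events


def match_tracks_to_truth(tracks: pd.DataFrame, masks, labels: np.ndarray
                          ) -> dict[int, int]:
    """Map each track to the ground-truth cell id it overlaps most, judged
    at the track's first frame."""
    out: dict[int, int] = {}
    firsts = tracks.sort_values("frame").groupby("track_id", sort=True).first()
    for tid, row in firsts.iterrows():
        f = int(row["frame"])
        sel = np.asarray(masks[f]) == row["label"]
        overlap = labels[f][sel]
        overlap = overlap[overlap > 0]
        if overlap.size:
            out[int(tid)] = int(np.bincount(overlap).argmax())
    return out


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full synthetic pipeline and return the summary dictionary."""
    config.validate()
    sim = config.simulation
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    lineage, series, stack = build_movie(config)

    # ----- population growth phases -----------------------------------
    counts = counts_from_lineage(lineage, stack.times)
    if counts.max() < 4 * counts.min():
        # the rendered colony does not proliferate enough to date the
        # transitions; use the co-cultured population counts instead
        rng_counts = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
        t_pop, counts_pop = simulate_counts(sim, rng_counts, noise=0.05)
        segmentation = detect_phases(t_pop, counts_pop, config.n_breakpoints)
    else:
        segmentation = detect_phases(stack.times, counts, config.n_breakpoints)
    logger.info("phase breakpoints at %s h", np.round(segmentation.breakpoints, 2))

    # ----- segmentation, tracking, intensities -------------------------
    masks, tracks, features = segment_and_track(stack, config)

    # ----- calibration and pH trajectories -----------------------------
    rng_cal = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    cal_ph, cal_ratio = make_calibration_points(noise=config.calibration_noise,
                                                rng=rng_cal)
    curve = PhCalibration().fit(cal_ph, cal_ratio)
    trajectories = measure_cell_ph_series(features, curve,
                                          smooth_window=config.smooth_window)

    # ----- pH drop fits -------------------------------------------------
    drops = {}
    fitter_params = dict(min_amplitude=config.drop_min_amplitude,
                         alpha=config.drop_alpha)
    for tid, sub in trajectories.groupby("track_id", sort=True):
        valid = sub.dropna(subset=["ph"])
        if len(valid) < 6:
            continue
        fitter = PhDropFitter(**fitter_params)
        drops[tid] = fitter.fit(valid["time"], valid["ph"]).result()

    # ----- growth folds -------------------------------------------------
    fold_series, growth_summary = single_cell_growth(features, segmentation)
    r_fold = dict(zip(growth_summary["track_id"], growth_summary["r_phase_fold"]))

    # ----- fate calls ---------------------------------------------------
    clf = FateClassifier(ds_margin=config.ds_margin,
                         growth_fold_threshold=config.growth_fold_threshold)
    end_times = tracks.groupby("track_id")["time"].max()
    calls = {}
    for tid in tracks["track_id"].unique():
        calls[tid] = clf.classify(drops.get(tid), segmentation,
                                  r_phase_fold=r_fold.get(tid),
                                  track_end_time=float(end_times[tid]),
                                  track_id=tid)
    fates = {tid: c.fate for tid, c in calls.items()}
    n_plus = sum(f == R_PLUS for f in fates.values())
    n_minus = sum(f == R_MINUS for f in fates.values())
    n_uncl = len(fates) - n_plus - n_minus
    frac_minus = n_minus / max(n_plus + n_minus, 1)

    # ----- foci and mobility -------------------------------------------
    marker_records = foci_records_from_stack(stack, masks, tracks,
                                             channel="marker", k=config.foci_k,
                                             marker_name=sim.render_marker)
    ld_records = foci_records_from_stack(stack, masks, tracks, channel="phase",
                                         invert=True, k=config.foci_k,
                                         marker_name="LD")
    t_gate = sim.phase_times[0] + config.mobility_gate_hours
    displacement, events = mobility_events(ld_records, t_min=t_gate)

    marker_records["fate"] = marker_records["track_id"].map(fates)
    foci_curve = aggregate_foci_fraction(marker_records, segmentation)

    # ----- inheritance index (needs ground-truth colony membership) ----
    truth_map = match_tracks_to_truth(tracks, masks, stack.labels)
    colony = dict(zip(lineage["cell_id"], lineage["microcolony_id"]))
    inh_tracks = [tid for tid, f in fates.items()
                  if f in (R_PLUS, R_MINUS) and tid in truth_map]
    inh = None
    if inh_tracks:
        vals = np.array([1.0 if fates[t] == R_MINUS else 0.0 for t in inh_tracks])
        cols = np.array([colony[truth_map[t]] for t in inh_tracks])
        sizes = pd.Series(cols).value_counts()
        if (sizes >= 2).sum() >= 2 and 0 < vals.mean() < 1:
            try:
                inh = inheritance_index(vals, cols)
            except ValueError:
                inh = None

    # ----- pH / mobility coupling --------------------------------------
    coupling, coupling_summary = couple_ph_mobility(drops, events,
                                                    trajectories, fates)

    summary = {
        "seed": config.seed,
        "n_cells_simulated": int(len(lineage)),
        "n_tracks": int(tracks["track_id"].nunique()),
        "phases": {
            "breakpoints_h": [float(b) for b in segmentation.breakpoints],
            "slopes_per_h": [float(s) for s in segmentation.slopes],
            "doubling_times_min": [None if not np.isfinite(d) else float(d)
                                   for d in segmentation.doubling_times_min],
            "n_segments": segmentation.n_segments,
        },
        "fate": {
            "n_R_plus": int(n_plus),
            "n_R_minus": int(n_minus),
            "n_unclassified": int(n_uncl),
            "fraction_R_minus": float(frac_minus),
        },
        "inheritance_index": None if inh is None else float(inh),
        "ph_at_mobility_loss": coupling_summary,
        "foci_fraction_curve": foci_curve.to_dict(orient="records"),
    }

    if out is not None:
        qio.save_stack(stack, out / "images")
        lineage.to_csv(out / "lineage.csv", index=False)
        series.to_csv(out / "states.csv", index=False)
        qio.save_masks(masks, out / "masks.tif")
        tracks.to_csv(out / "tracks.csv", index=False)
        features.to_csv(out / "features.csv", index=False)
        trajectories.to_csv(out / "trajectories.csv", index=False)
        pd.DataFrame([{"track_id": tid, **vars(d)} for tid, d in drops.items()]
                     ).to_csv(out / "drops.csv", index=False)
        marker_records.to_csv(out / "foci.csv", index=False)
        ld_records.to_csv(out / "ld_foci.csv", index=False)
        displacement.to_csv(out / "displacement.csv", index=False)
        pd.DataFrame([vars(e) for e in events.values()]
                     ).to_csv(out / "mobility_events.csv", index=False)
        pd.DataFrame([vars(c) for c in calls.values()]
                     ).to_csv(out / "fates.csv", index=False)
        coupling.to_csv(out / "coupling.csv", index=False)
        fold_series.to_csv(out / "growth_folds.csv", index=False)
        sim.to_yaml(out / "config.yaml")
        qio.write_json(summary, out / "summary.json")

    return summary
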