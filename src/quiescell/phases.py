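"""Population growth-phase segmentation by continuous piecewise-linear fits.

The total cell count over time is fitted on a natural-log scale with a
continuous piecewise-linear function (equivalently, piecewise-exponential
counts). Breakpoints — the intersections of adjacent line pieces — mark the
transitions between metabolic phases: fermentation, diauxic shift,
respiration, stationary phase. Each positive segment slope converts to a
doubling time ln 2 / slope.

For a fixed breakpoint placement the fit is linear least squares on a hinge
basis [1, t, (t - b_1)_+, ..., (t - b_K)_+]; breakpoints are restricted to
the sample times and optimised by exhaustive enumeration when the number of
placements is modest, otherwise by a deterministic coarse-to-fine grid
search refined to a stride-1 local optimum.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["PhaseSegmentation", "GrowthPhaseSegmenter", "detect_phases",
           "doubling_time_from_segment", "single_cell_growth"]


@dataclass
class PhaseSegmentation:
    """Breakpoints and per-segment growth rates of a count series."""

    breakpoints: np.ndarray          # h, strictly increasing, interior
    slopes: np.ndarray               # 1/h on ln(counts), one per segment
    doubling_times_min: np.ndarray   # min; NaN where slope <= 0
    sse: float
    t_range: tuple[float, float]

    @property
    def n_segments(self) -> int:
        return len(self.slopes)

    def segment_bounds(self, index: int) -> tuple[float, float]:
        edges = [self.t_range[0], *self.breakpoints, self.t_range[1]]
        if not 0 <= index < self.n_segments:
            raise IndexError(f"segment index {index} out of range "
                             f"(0..{self.n_segments - 1})")
        return edges[index], edges[index + 1]


def _hinge_design(t: np.ndarray, bp_times: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(t), t]
    for b in bp_times:
        cols.append(np.maximum(t - b, 0.0))
    return np.column_stack(cols)


def _fit_fixed(t: np.ndarray, y: np.ndarray, bp_times: np.ndarray
               ) -> tuple[float, np.ndarray]:
    X = _hinge_design(t, bp_times)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


class GrowthPhaseSegmenter(BaseEstimator):
    """Continuous piecewise-linear fit to ln(counts) with K breakpoints.

    Parameters
    ----------
    n_breakpoints : int
        Number of phase transitions (3 for a full life cycle).
    min_separation : int
        Minimum number of samples between breakpoints and to either end.
    max_exhaustive : int
        Placement-count ceiling below which enumeration is exhaustive;
        larger problems use a coarse grid refined to a stride-1 local
        optimum (deterministic).
    """

    def __init__(self, n_breakpoints: int = 3, min_separation: int = 3,
                 max_exhaustive: int = 100_000):
        self.n_breakpoints = n_breakpoints
        self.min_separation = min_separation
        self.max_exhaustive = max_exhaustive

    # ------------------------------------------------------------------
    def fit(self, times, counts) -> "GrowthPhaseSegmenter":
        t = np.asarray(times, dtype=float)
        c = np.asarray(counts, dtype=float)
        if self.n_breakpoints < 0:
            raise ValueError("n_breakpoints must be >= 0")
        if t.size != c.size:
            raise ValueError("times and counts must have equal length")
        if np.any(c <= 0):
            raise ValueError("counts must be positive")
        if t.size < 3 * (self.n_breakpoints + 1):
            raise ValueError(
                f"need at least {3 * (self.n_breakpoints + 1)} points for "
                f"{self.n_breakpoints} breakpoints, got {t.size}")
        order = np.argsort(t, kind="stable")
        t, c = t[order], c[order]
        y = np.log(c)

        k = self.n_breakpoints
        if k == 0:
            sse, coef = _fit_fixed(t, y, np.empty(0))
            self._finalize(t, np.empty(0, dtype=int), coef, sse)
            return self

        sep = self.min_separation
        lo, hi = sep, t.size - 1 - sep  # candidate index range (inclusive)
        if hi < lo:
            raise ValueError("series too short for the separation constraint")

        n_cand = hi - lo + 1
        n_comb = math.comb(max(n_cand - (k - 1) * (sep - 1), 0), k) if sep > 1 \
            else math.comb(n_cand, k)
        if n_comb and n_comb <= self.max_exhaustive:
            best = self._enumerate(t, y, range(lo, hi + 1), sep, k)
        else:
            best = self._coarse_to_fine(t, y, lo, hi, sep, k)

        sse, idx, coef = best
        self._finalize(t, np.asarray(idx, dtype=int), coef, sse)
        return self

    # ------------------------------------------------------------------
    def _enumerate(self, t, y, candidates, sep, k):
        best = None
        for combo in itertools.combinations(candidates, k):
            if any(combo[i + 1] - combo[i] < sep for i in range(k - 1)):
                continue
            sse, coef = _fit_fixed(t, y, t[list(combo)])
            if best is None or sse < best[0]:
                best = (sse, combo, coef)
        if best is None:
            raise ValueError("no admissible breakpoint placement")
        return best

    def _coarse_to_fine(self, t, y, lo, hi, sep, k):
        stride = 1
        while True:
            n_cand = (hi - lo) // stride + 1
            if math.comb(n_cand, k) <= self.max_exhaustive:
                break
            stride += 1
        best = self._enumerate(t, y, range(lo, hi + 1, stride), sep, k)
        # refine to a stride-1 local optimum: re-enumerate the neighbourhood
        # of the current best placement until it stops moving
        for _ in range(20):
            sse0, combo0, _ = best
            neighbourhoods = [
                [j for j in range(max(lo, i - stride), min(hi, i + stride) + 1)]
                for i in combo0
            ]
            improved = None
            for combo in itertools.product(*neighbourhoods):
                if any(combo[m + 1] - combo[m] < sep for m in range(k - 1)):
                    continue
                sse, coef = _fit_fixed(t, y, t[list(combo)])
                if sse < best[0] - 1e-12:
                    improved = (sse, combo, coef)
                    best = improved
            if improved is None:
                break
        return best

    # ------------------------------------------------------------------
    def _finalize(self, t, idx, coef, sse):
        bp_times = t[idx] if idx.size else np.empty(0)
        slopes = np.cumsum(coef[1:]) if coef.size > 1 else np.array([coef[-1]])
        self.breakpoint_indices_ = idx
        self.breakpoints_ = np.asarray(bp_times, dtype=float)
        self.slopes_ = np.asarray(slopes, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            dt = np.where(self.slopes_ > 1e-12,
                          math.log(2.0) / self.slopes_ * 60.0, np.nan)
        self.doubling_times_min_ = dt
        self.coef_ = coef
        self.sse_ = float(sse)
        self.t_range_ = (float(t[0]), float(t[-1]))

    def result(self) -> PhaseSegmentation:
        return PhaseSegmentation(self.breakpoints_, self.slopes_,
                                 self.doubling_times_min_, self.sse_,
                                 self.t_range_)

    def predict(self, times) -> np.ndarray:
        """Fitted ln(count) at the given times."""
        t = np.asarray(times, dtype=float)
        return _hinge_design(t, self.breakpoints_) @ self.coef_


def detect_phases(times, counts, n_breakpoints: int = 3,
                  min_separation: int = 3) -> PhaseSegmentation:
    """Segment a population count series into growth phases."""
    seg = GrowthPhaseSegmenter(n_breakpoints=n_breakpoints,
                               min_separation=min_separation)
    return seg.fit(times, counts).result()


def doubling_time_from_segment(segmentation: PhaseSegmentation,
                               segment_index: int) -> float:
    """Doubling time (minutes) of one segment; NaN when the slope is <= 0."""
    if not 0 <= segment_index < segmentation.n_segments:
        raise IndexError(f"segment index {segment_index} out of range "
                         f"(0..{segmentation.n_segments - 1})")
    return float(segmentation.doubling_times_min[segment_index])


def single_cell_growth(features: pd.DataFrame,
                       segmentation: PhaseSegmentation,
                       ds_end_segment: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold area increase of single cells, normalised at the end of the DS.

    ``features`` needs columns ``track_id, frame, time, area_total``.
    Returns ``(fold_series, summary)``: the per-(track, frame) fold series,
    and a per-track summary with the fold increase over the respiration
    segment (area at the segment's end over area at its start). Tracks
    absent at the normalisation time are excluded.
    """
    if segmentation.n_segments < ds_end_segment + 2:
        raise ValueError("segmentation has no respiration segment")
    _, t_ds_end = segmentation.segment_bounds(ds_end_segment)
    _, t_r_end = segmentation.segment_bounds(ds_end_segment + 1)

    times = np.sort(features["time"].unique())
    max_gap = np.median(np.diff(times)) * 1.5 if times.size > 1 else np.inf

    series_parts = []
    summary_rows = []
    for tid, sub in features.groupby("track_id", sort=True):
        sub = sub.sort_values("time")
        tt = sub["time"].to_numpy()
        aa = sub["area_total"].to_numpy(dtype=float)
        i_norm = int(np.argmin(np.abs(tt - t_ds_end)))
        if (tt[0] > t_ds_end or abs(tt[i_norm] - t_ds_end) > max_gap
                or aa[i_norm] <= 0):
            # excluded: the track does not reach back to the normalisation
            # frame at the end of the DS, so fold increases are undefined
            continue
        fold = aa / aa[i_norm]
        part = sub[["track_id", "frame", "time"]].copy()
        part["fold_area"] = fold
        series_parts.append(part)

        i_r_end = int(np.argmin(np.abs(tt - t_r_end)))
        r_fold = (aa[i_r_end] / aa[i_norm]
                  if abs(tt[i_r_end] - t_r_end) <= max_gap else np.nan)
        summary_rows.append({"track_id": tid, "r_phase_fold": r_fold})

    fold_series = (pd.concat(series_parts, ignore_index=True)
                   if series_parts else
                   pd.DataFrame(columns=["track_id", "frame", "time", "fold_area"]))
    summary = pd.DataFrame(summary_rows, columns=["track_id", "r_phase_fold"])
    return fold_series, summary
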