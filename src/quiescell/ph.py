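"""Single-cell pH trajectories and piecewise-linear pH-drop fits.

A trajectory is the per-frame ratio of background-subtracted mean in-mask
intensities ex390/ex475 converted to absolute pH through a fitted
calibration curve. A pH drop is modelled as a continuous three-segment
curve — flat at a high level, linear decline, flat at a low level — fitted
by exhaustive search over the two interior breakpoints (each constrained to
frame times) with closed-form least squares for the two levels. The half
time is where the fitted decline crosses the midpoint between the levels,
i.e. the midpoint of the two breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .calibration import PhCalibration

__all__ = ["PhDropFit", "PhDropFitter", "fit_ph_drop", "measure_cell_ph_series"]


@dataclass
class PhDropFit:
    """Fitted three-segment pH drop for one cell."""

    t_start: float
    t_end: float
    t_half: float
    ph_before: float
    ph_after: float
    drop_detected: bool
    sse: float
    pvalue: float


class PhDropFitter(BaseEstimator):
    """Three-segment (flat / linear decline / flat) least-squares drop fit.

    A drop is reported only when the fitted amplitude reaches
    ``min_amplitude`` (pH units) and the three-segment model beats a flat
    fit in an F-ratio test at level ``alpha``.
    """

    def __init__(self, min_amplitude: float = 0.3, alpha: float = 0.01,
                 min_points: int = 6):
        self.min_amplitude = min_amplitude
        self.alpha = alpha
        self.min_points = min_points

    def fit(self, t, y) -> "PhDropFitter":
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(y) & np.isfinite(t)
        t, y = t[ok], y[ok]
        n = t.size
        if n < self.min_points:
            raise ValueError(f"trajectory has {n} valid points; "
                             f"need at least {self.min_points}")
        order = np.argsort(t, kind="stable")
        t, y = t[order], y[order]

        best = None  # (sse, i, j, b, a)
        for i in range(n - 1):
            ts = t[i]
            te = t[i + 1:]
            # u in [0, 1]: fraction of the decline completed at each time
            u = np.clip((t[None, :] - ts) / (te[:, None] - ts), 0.0, 1.0)
            v = 1.0 - u
            s_vv = (v * v).sum(axis=1)
            s_uu = (u * u).sum(axis=1)
            s_uv = (u * v).sum(axis=1)
            s_vy = v @ y
            s_uy = u @ y
            det = s_vv * s_uu - s_uv ** 2
            det = np.where(det <= 1e-12, np.nan, det)
            b = (s_vy * s_uu - s_uy * s_uv) / det     # level before
            a = (s_uy * s_vv - s_vy * s_uv) / det     # level after
            pred_sq = (b ** 2 * s_vv + a ** 2 * s_uu + 2 * a * b * s_uv)
            sse = float(y @ y) - 2 * (b * s_vy + a * s_uy) + pred_sq
            if np.all(~np.isfinite(sse)):
                continue
            with np.errstate(invalid="ignore"):
                k = int(np.nanargmin(sse))
            if np.isfinite(sse[k]) and (best is None or sse[k] < best[0]):
                best = (float(sse[k]), i, i + 1 + k, float(b[k]), float(a[k]))

        sse, i, j, b, a = best
        sse = max(sse, 0.0)
        sse0 = float(np.sum((y - y.mean()) ** 2))
        df1, df2 = 3, n - 4  # model has 4 parameters vs 1 for the flat fit
        if df2 > 0 and sse > 0:
            f_stat = ((sse0 - sse) / df1) / (sse / df2)
            pvalue = float(stats.f.sf(f_stat, df1, df2))
        else:
            pvalue = 0.0 if sse0 > sse else 1.0

        self.t_start_ = float(t[i])
        self.t_end_ = float(t[j])
        self.t_half_ = 0.5 * (self.t_start_ + self.t_end_)
        self.ph_before_ = b
        self.ph_after_ = a
        self.sse_ = sse
        self.pvalue_ = pvalue
        self.amplitude_ = b - a
        self.drop_detected_ = bool(self.amplitude_ >= self.min_amplitude
                                   and pvalue < self.alpha)
        return self

    def result(self) -> PhDropFit:
        return PhDropFit(self.t_start_, self.t_end_, self.t_half_,
                         self.ph_before_, self.ph_after_,
                         self.drop_detected_, self.sse_, self.pvalue_)


def fit_ph_drop(t, ph, min_amplitude: float = 0.3, alpha: float = 0.01) -> PhDropFit:
    """Fit the pH drop of one trajectory; see :class:`PhDropFitter`."""
    return PhDropFitter(min_amplitude=min_amplitude, alpha=alpha).fit(t, ph).result()


def measure_cell_ph_series(features: pd.DataFrame, curve: PhCalibration,
                           smooth_window: int = 3) -> pd.DataFrame:
    """Per-track pH time series from tracked intensity features.

    ``features`` must carry background-subtracted ``mean_ex390`` and
    ``mean_ex475`` columns (see
    :func:`quiescell.tracking.extract_track_features`). Frames whose ex475
    signal is non-positive after background subtraction are flagged missing
    rather than dropped. pH is optionally smoothed with a centred moving
    median (window 3 by default; pass 0 or 1 to disable).
    """
    needed = {"track_id", "frame", "time", "mean_ex390", "mean_ex475"}
    missing_cols = needed - set(features.columns)
    if missing_cols:
        raise ValueError(f"features table lacks columns {sorted(missing_cols)}")

    out = features.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    num = out["mean_ex390"].to_numpy(dtype=float)
    den = out["mean_ex475"].to_numpy(dtype=float)
    valid = (den > 0) & (num > 0)
    ratio = np.full(len(out), np.nan)
    ratio[valid] = num[valid] / den[valid]

    ph = np.full(len(out), np.nan)
    clipped = np.zeros(len(out), dtype=bool)
    if valid.any():
        ph_v, cl_v = curve.inverse(ratio[valid], with_flags=True)
        ph[valid] = ph_v
        clipped[valid] = cl_v

    traj = out[["track_id", "frame", "time"]].copy()
    traj["ratio"] = ratio
    traj["ph"] = ph
    traj["clipped"] = clipped
    traj["missing"] = ~valid
    if smooth_window and smooth_window > 1:
        traj["ph"] = (traj.groupby("track_id")["ph"]
                      .transform(lambda s: s.rolling(smooth_window, center=True,
                                                     min_periods=1).median()))
    return traj
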