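"""Ratiometric pH calibration.

The two-excitation pHluorin ratio R = I_ex390 / I_ex475 increases
monotonically with cytosolic pH. Calibration maps buffer pH to measured
ratio with a 4-parameter logistic

    R(pH) = R_min + (R_max - R_min) / (1 + exp(-k (pH - pH_mid))),

fitted by least squares to buffer measurements spanning pH 5-8; absolute pH
is then read off by numerical inversion (bisection) of the fitted curve.
The logistic is one convenient strictly monotone, bounded choice — the
analysis never assumes the rendering model and the fitted curve agree in
functional form.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

__all__ = [
    "logistic4",
    "logistic4_inverse",
    "DEFAULT_FORWARD_PARAMS",
    "forward_ratio",
    "make_calibration_points",
    "PhCalibration",
    "fit_calibration",
    "ratio_to_ph",
]

PH_DOMAIN = (5.0, 8.0)

#: forward-model parameters used by the synthetic renderer:
#: (R_min, R_max, pH_mid, k)
DEFAULT_FORWARD_PARAMS = (0.3, 3.0, 6.6, 1.1)


def logistic4(ph, r_min: float, r_max: float, ph_mid: float, k: float):
    ph = np.asarray(ph, dtype=float)
    return r_min + (r_max - r_min) / (1.0 + np.exp(-k * (ph - ph_mid)))


def logistic4_inverse(ratio, r_min: float, r_max: float, ph_mid: float, k: float):
    """Closed-form inverse of :func:`logistic4` (used as a test oracle for
    the numerical inversion)."""
    ratio = np.asarray(ratio, dtype=float)
    frac = (ratio - r_min) / (r_max - r_min)
    return ph_mid - np.log(1.0 / frac - 1.0) / k


def forward_ratio(ph, params: tuple[float, float, float, float] = DEFAULT_FORWARD_PARAMS):
    """Ground-truth pH -> ratio map used when rendering synthetic images."""
    return logistic4(ph, *params)


def make_calibration_points(n: int = 7,
                            ph_range: tuple[float, float] = PH_DOMAIN,
                            noise: float = 0.01,
                            rng: np.random.Generator | None = None,
                            params: tuple[float, float, float, float] = DEFAULT_FORWARD_PARAMS,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic buffer-calibration measurements.

    Ratios carry multiplicative Gaussian noise of relative sd ``noise``
    (default 1%: each buffer ratio is an average over many imaged cells).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ph = np.linspace(ph_range[0], ph_range[1], n)
    ratio = forward_ratio(ph, params)
    if noise > 0:
        ratio = ratio * (1.0 + rng.normal(0.0, noise, size=n))
    return ph, ratio


class PhCalibration(BaseEstimator):
    """Strictly monotone pH -> ratio calibration curve (4-parameter logistic).

    Parameters
    ----------
    domain : (low, high)
        pH domain on which the curve is defined and inverted; ratios mapping
        outside it are clipped to the endpoints and flagged.
    monotone_tol : float
        Minimum Spearman correlation between pH and ratio required of the
        calibration points (guards against an inverted or scrambled table).
    """

    def __init__(self, domain: tuple[float, float] = PH_DOMAIN,
                 monotone_tol: float = 0.8):
        self.domain = domain
        self.monotone_tol = monotone_tol

    # ------------------------------------------------------------------
    def fit(self, ph, ratio=None) -> "PhCalibration":
        if ratio is None:  # allow an (n, 2) point array
            pts = np.asarray(ph, dtype=float)
            ph, ratio = pts[:, 0], pts[:, 1]
        ph = np.asarray(ph, dtype=float)
        ratio = np.asarray(ratio, dtype=float)
        if ph.size < 4:
            raise ValueError(f"need >= 4 calibration points, got {ph.size}")
        if ph.max() - ph.min() < 2.0:
            raise ValueError("calibration points must span at least 2 pH units")
        if np.any(ratio <= 0):
            raise ValueError("calibration ratios must be positive")
        from scipy.stats import spearmanr

        rho = spearmanr(ph, ratio).statistic
        if not rho >= self.monotone_tol:
            raise ValueError(
                f"calibration points are not monotone in pH (spearman={rho:.3f}); "
                "check the ratio orientation (expected R = I_ex390 / I_ex475, "
                "increasing with pH)")

        r_lo, r_hi = ratio.min(), ratio.max()
        x0 = np.array([max(r_lo - 0.1 * (r_hi - r_lo), 1e-6),
                       r_hi + 0.1 * (r_hi - r_lo),
                       float(np.median(ph)), 1.0])

        def resid(p):
            return logistic4(ph, *p) - ratio

        res = optimize.least_squares(
            resid, x0,
            bounds=([0.0, 0.0, ph.min() - 5.0, 1e-3],
                    [np.inf, np.inf, ph.max() + 5.0, 50.0]),
            xtol=1e-12, ftol=1e-12)
        self.params_ = tuple(float(v) for v in res.x)
        self.residuals_ = resid(res.x)
        self.sse_ = float(np.sum(self.residuals_ ** 2))
        # verify strict monotonicity on a grid over the domain
        grid = np.linspace(self.domain[0], self.domain[1], 201)
        vals = logistic4(grid, *self.params_)
        if not np.all(np.diff(vals) > 0):
            raise ValueError("fitted calibration curve is not strictly "
                             "monotone on the pH domain")
        return self

    # ------------------------------------------------------------------
    def predict(self, ph) -> np.ndarray:
        """Forward map pH -> ratio."""
        self._check_fitted()
        return logistic4(ph, *self.params_)

    def inverse(self, ratio, with_flags: bool = False):
        """Invert ratio -> pH by bisection on the fitted curve.

        Ratios outside the calibrated range map to the domain endpoints and
        are flagged when ``with_flags`` is true.
        """
        self._check_fitted()
        arr = np.atleast_1d(np.asarray(ratio, dtype=float))
        if np.any(arr <= 0):
            raise ValueError("ratio must be positive")
        lo, hi = self.domain
        r_lo = float(logistic4(lo, *self.params_))
        r_hi = float(logistic4(hi, *self.params_))
        ph = np.empty(arr.shape)
        clipped = np.zeros(arr.shape, dtype=bool)
        for i, r in np.ndenumerate(arr):
            if r <= r_lo:
                ph[i], clipped[i] = lo, r < r_lo
            elif r >= r_hi:
                ph[i], clipped[i] = hi, r > r_hi
            else:
                ph[i] = optimize.brentq(
                    lambda p: float(logistic4(p, *self.params_)) - r,
                    lo, hi, xtol=1e-9)
        if np.isscalar(ratio) or np.asarray(ratio).ndim == 0:
            return (float(ph[0]), bool(clipped[0])) if with_flags else float(ph[0])
        return (ph, clipped) if with_flags else ph

    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("calibration curve is not fitted")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__repr__()
        if hasattr(self, "params_"):
            p = ", ".join(f"{v:.4g}" for v in self.params_)
            return f"{base[:-1]}, params_=({p}))" if base.endswith(")") else base
        return base


def fit_calibration(points) -> PhCalibration:
    """Fit a calibration curve from an iterable of (pH, ratio) pairs."""
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=float)
    return PhCalibration().fit(pts)


def ratio_to_ph(curve: PhCalibration, ratio, with_flags: bool = False):
    """Absolute pH for a measured ratio under a fitted calibration curve."""
    return curve.inverse(ratio, with_flags=with_flags)
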