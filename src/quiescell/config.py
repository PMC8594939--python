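"""Configuration objects for the synthetic life-cycle generator and pipeline.

Defaults encode the unperturbed batch-culture life cycle of budding yeast:
a fermentation phase (FP) with fast doublings, a diauxic shift (DS) growth
arrest when glucose runs out, a slow respiration phase (RP) on ethanol, and
a final stationary phase (SP). Cytosolic pH starts near 7.7, declines during
fermentation, and diverges at the DS: a minority of respiration-deficient
(R-) cells crash to ~5.8 immediately, while respiration-competent (R+) cells
plateau near 6.9, rebound to ~7.2 while respiring, and drop to ~5.8 at
heterogeneous times in stationary phase. Cytoplasmic mobility is lost (a
gel-like transition) when pH first reaches ~6.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = ["SimulationConfig", "PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration field is missing, non-finite or out of range."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"invalid configuration field '{field_name}': {message}")


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(name, msg)


def _finite(value: float, name: str) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(float(value))):
        raise ConfigError(name, f"must be a finite number, got {value!r}")


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic quiescence-entry time lapse.

    Times are hours unless the name says otherwise; doubling times are in
    minutes; diffusion coefficients are px^2/frame; pH values are absolute
    pH units and must lie inside the calibration domain [5, 8].
    """

    # --- time base -------------------------------------------------------
    t_end: float = 48.0                # h, total simulated time
    frame_interval: float = 15.0       # min, between rendered frames
    # (t_DS_start, t_DS_end, t_SP_start): fermentation ends / respiration
    # starts / stationary phase starts.
    phase_times: tuple[float, float, float] = (5.5, 13.9, 31.6)

    # --- population growth ----------------------------------------------
    doubling_time_f: float = 84.0      # min, fermentation
    doubling_time_r: float = 307.0     # min, respiration (R+ cells only)
    n_founders: int = 2
    divisions_enabled: bool = True
    division_jitter: float = 0.1       # lognormal sigma on per-division times

    # --- fate structure --------------------------------------------------
    fraction_r_minus: float = 0.12
    inheritance_strength: float = 0.9  # P(daughter copies mother's fate)
    rho_minus_given_r_minus: float = 0.19  # preexisting mtDNA defects
    survival_p: dict[str, float] = field(
        default_factory=lambda: {"R_plus": 0.8, "R_minus": 0.3}
    )

    # --- cytosolic pH program -------------------------------------------
    # (pH_init, pH_plateau, pH_peak_R, pH_terminal, pH_gel)
    ph_params: tuple[float, float, float, float, float] = (7.7, 6.9, 7.2, 5.8, 6.0)
    sp_drop_time_distribution: tuple[float, float] = (12.0, 6.0)  # h after SP onset
    sp_drop_duration: float = 2.0      # h, duration of the terminal drop
    ds_drop_completion: float = 0.6    # R- drop completes this far into the DS
    ph_jitter_sd: float = 0.05         # per-cell additive offset, pH units
    r_minus_fluorescence_decay: bool = False

    # --- superassemblies and mobility ------------------------------------
    foci_thresholds: dict[str, float] = field(
        default_factory=lambda: {"Dhh1": 7.0, "Cdc28": 6.0}
    )
    foci_hysteresis: float = 0.1       # pH units above threshold to dissolve
    ld_diffusion: tuple[float, float] = (0.5, 0.01)  # (D_free, D_arrested)

    # --- rendering --------------------------------------------------------
    image_height: int = 320
    image_width: int = 320
    pixel_size: float = 0.2            # um/px, metadata only
    cell_radius_px: float = 5.0
    noise_sd: float = 30.0             # Gaussian read noise, counts
    background_level: float = 200.0    # counts
    ex475_amplitude: float = 1200.0    # in-cell signal in the ex475 channel
    marker_diffuse_level: float = 800.0
    foci_contrast: float = 2000.0      # focus amplitude above diffuse level
    ld_depth: float = 0.7              # fraction of cell signal removed at LD
    render_marker: str = "Dhh1"

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check invariants; raise :class:`ConfigError` naming the bad field."""
        for name in ("t_end", "frame_interval", "doubling_time_f",
                     "doubling_time_r", "fraction_r_minus",
                     "inheritance_strength", "ph_jitter_sd", "noise_sd",
                     "background_level", "cell_radius_px"):
            _finite(getattr(self, name), name)
        t_ds_start, t_ds_end, t_sp_start = self.phase_times
        for v in self.phase_times:
            _finite(v, "phase_times")
        _require(0 < t_ds_start < t_ds_end < t_sp_start < self.t_end,
                 "phase_times",
                 "need 0 < t_DS_start < t_DS_end < t_SP_start < t_end, got "
                 f"{self.phase_times} with t_end={self.t_end}")
        _require(self.t_end > 0, "t_end", "must be positive")
        _require(self.frame_interval > 0, "frame_interval", "must be positive")
        _require(self.doubling_time_f > 0, "doubling_time_f", "must be positive")
        _require(self.doubling_time_r > 0, "doubling_time_r", "must be positive")
        _require(0 <= self.fraction_r_minus <= 1, "fraction_r_minus",
                 "must lie in [0, 1]")
        _require(0 <= self.inheritance_strength <= 1, "inheritance_strength",
                 "must lie in [0, 1]")
        _require(self.n_founders >= 1, "n_founders", "need at least one founder")
        for v in self.ph_params:
            _finite(v, "ph_params")
            _require(5.0 <= v <= 8.0, "ph_params",
                     f"pH value {v} outside the calibration domain [5, 8]")
        for marker, th in self.foci_thresholds.items():
            _finite(th, "foci_thresholds")
            _require(5.0 <= th <= 8.0, "foci_thresholds",
                     f"threshold {th} for marker {marker!r} outside [5, 8]")
        d_free, d_arrested = self.ld_diffusion
        _finite(d_free, "ld_diffusion")
        _finite(d_arrested, "ld_diffusion")
        _require(d_free >= 0 and d_arrested >= 0, "ld_diffusion",
                 "diffusion coefficients must be non-negative")
        _require(d_arrested <= d_free, "ld_diffusion",
                 "D_arrested must not exceed D_free")
        mean, sd = self.sp_drop_time_distribution
        _finite(mean, "sp_drop_time_distribution")
        _finite(sd, "sp_drop_time_distribution")
        _require(sd >= 0, "sp_drop_time_distribution", "sd must be >= 0")
        _require(self.image_height >= 16 and self.image_width >= 16,
                 "image", "image must be at least 16x16 px")
        _require(self.render_marker in self.foci_thresholds, "render_marker",
                 f"{self.render_marker!r} has no entry in foci_thresholds")

    # ------------------------------------------------------------------
    @property
    def frame_times(self) -> "np.ndarray":  # noqa: F821
        import numpy as np

        dt = self.frame_interval / 60.0
        n = int(math.floor(self.t_end / dt)) + 1
        return np.arange(n) * dt

    @property
    def ph_init(self) -> float:
        return self.ph_params[0]

    @property
    def ph_plateau(self) -> float:
        return self.ph_params[1]

    @property
    def ph_peak_r(self) -> float:
        return self.ph_params[2]

    @property
    def ph_terminal(self) -> float:
        return self.ph_params[3]

    @property
    def ph_gel(self) -> float:
        return self.ph_params[4]

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["phase_times"] = list(self.phase_times)
        d["ph_params"] = list(self.ph_params)
        d["ld_diffusion"] = list(self.ld_diffusion)
        d["sp_drop_time_distribution"] = list(self.sp_drop_time_distribution)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown field")
        kwargs = dict(d)
        for name in ("phase_times", "ph_params", "ld_diffusion",
                     "sp_drop_time_distribution"):
            if name in kwargs and kwargs[name] is not None:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters wrapping the per-stage defaults."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # segmentation / tracking
    min_area: int = 20
    smoothing_sigma: float = 1.0
    lambda_area: float = 5.0
    gate: float | None = None          # px; None -> 0.5 * typical diameter
    # pH quantification
    calibration_noise: float = 0.01    # relative sd of synthetic buffer ratios
    smooth_window: int = 3
    drop_min_amplitude: float = 0.3    # pH units
    drop_alpha: float = 0.01           # F-test level vs flat fit
    # foci
    foci_k: float = 4.0
    mobility_gate_hours: float = 2.0   # ignore displacement before DS+gate
    # fate calls
    ds_margin: float = 2.0             # h of grace after DS end for R- calls
    growth_fold_threshold: float = 1.5
    # phases
    n_breakpoints: int = 3
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        _require(self.min_area >= 1, "min_area", "must be >= 1")
        _require(self.foci_k > 0, "foci_k", "must be positive")
        _require(self.n_breakpoints >= 0, "n_breakpoints", "must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        kwargs = dict(d)
        sim = kwargs.pop("simulation", None)
        cfg = cls(**kwargs) if kwargs else cls()
        if sim is not None:
            cfg.simulation = SimulationConfig.from_dict(sim)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
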