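"""Per-cell state trajectories: cytosolic pH, foci, mitochondria, mobility.

The pH program is piecewise linear per fate. Respiration-competent (R+)
cells decline from the initial pH to a plateau at the diauxic-shift onset,
rebound to a peak while respiring, relax, and finally crash to the terminal
pH at a per-cell stochastic time in stationary phase. Respiration-deficient
(R-) cells crash to the terminal pH during the diauxic shift itself.

Foci form per marker when pH first crosses the marker's threshold downward
and dissolve only if pH rises a hysteresis margin above it. Cytoplasmic
mobility (tracked via a lipid-droplet random walk) is lost the first time
pH reaches the gel point and never recovers.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .lineage import R_MINUS, R_PLUS

__all__ = [
    "ph_template",
    "simulate_ph_trajectories",
    "simulate_marker_states",
    "simulate_random_walk",
    "place_cells",
    "FieldOfViewOverflow",
]


class FieldOfViewOverflow(RuntimeError):
    """Cells no longer fit in the image; use a larger field or fewer founders."""


# ---------------------------------------------------------------------------
# pH program
# ---------------------------------------------------------------------------

def _template_knots(fate: str, config: SimulationConfig,
                    sp_drop_time: float) -> tuple[np.ndarray, np.ndarray]:
    t_ds_start, t_ds_end, t_sp_start = config.phase_times
    ph_init, ph_plateau, ph_peak, ph_terminal, _ = config.ph_params
    if fate == R_MINUS:
        t_done = t_ds_start + config.ds_drop_completion * (t_ds_end - t_ds_start)
        tt = [0.0, t_ds_start, t_done, config.t_end + 1.0]
        ph = [ph_init, ph_plateau, ph_terminal, ph_terminal]
    else:
        t_peak = t_ds_end + 0.4 * (t_sp_start - t_ds_end)
        ph_pre_drop = 0.5 * (ph_plateau + ph_peak) - 0.05
        drop_start = max(float(sp_drop_time), t_sp_start)
        drop_end = drop_start + config.sp_drop_duration
        tt = [0.0, t_ds_start, t_ds_end, t_peak,
              t_sp_start, drop_start, drop_end,
              max(config.t_end, drop_end) + 1.0]
        ph = [ph_init, ph_plateau, ph_plateau, ph_peak,
              ph_pre_drop, ph_pre_drop, ph_terminal, ph_terminal]
    return np.asarray(tt), np.asarray(ph)


def ph_template(times, fate: str, config: SimulationConfig,
                sp_drop_time: float = math.nan) -> np.ndarray:
    """Noise-free pH trajectory for one fate evaluated at ``times`` (hours)."""
    if fate not in (R_PLUS, R_MINUS):
        raise ValueError(f"unknown fate label {fate!r}")
    tt, ph = _template_knots(fate, config, sp_drop_time)
    return np.interp(np.asarray(times, dtype=float), tt, ph)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _area_series(times: np.ndarray, fate: str, config: SimulationConfig) -> np.ndarray:
    """Cell area (px^2) over time: R+ cells double their area during the
    respiration phase; everything else is flat (divisions carry fermentative
    growth)."""
    t_ds_start, t_ds_end, t_sp_start = config.phase_times
    a0 = math.pi * config.cell_radius_px ** 2
    if fate == R_PLUS:
        frac = np.clip((times - t_ds_end) / (t_sp_start - t_ds_end), 0.0, 1.0)
        return a0 * (1.0 + frac)
    return np.full_like(times, a0, dtype=float)


def place_cells(lineage: pd.DataFrame, config: SimulationConfig,
                rng: np.random.Generator) -> pd.DataFrame:
    """Assign a static (x, y) centroid to every cell.

    Founders sit on a regular grid; daughters are placed next to their
    mother at the first non-overlapping position found on rings of
    increasing radius. Raises :class:`FieldOfViewOverflow` when no free
    position remains inside the image. Coordinates are 0-based
    (x = column, y = row).
    """
    r_max = config.cell_radius_px * math.sqrt(2.0)  # after R-phase growth
    pitch = 2.0 * r_max + 4.0
    h, w = config.image_height, config.image_width
    margin = r_max + 2.0
    nx = max(int((w - 2 * margin) // pitch) + 1, 1)
    ny = max(int((h - 2 * margin) // pitch) + 1, 1)

    n_founders = int((lineage["parent_id"].isna()).sum())
    if n_founders > nx * ny:
        raise FieldOfViewOverflow(
            f"{n_founders} founders need more than the {nx * ny} grid positions "
            f"available in a {h}x{w} image; increase the image size or reduce "
            "the number of founders")

    placed: dict[int, tuple[float, float]] = {}
    order = lineage.sort_values("birth_time", kind="stable")

    def overlaps(x: float, y: float) -> bool:
        for (px, py) in placed.values():
            if (px - x) ** 2 + (py - y) ** 2 < (2.0 * r_max + 1.0) ** 2:
                return True
        return False

    founder_i = 0
    for row in order.itertuples(index=False):
        if pd.isna(row.parent_id):
            gx = founder_i % nx
            gy = founder_i // nx
            founder_i += 1
            placed[row.cell_id] = (margin + gx * pitch, margin + gy * pitch)
            continue
        mx, my = placed[int(row.parent_id)]
        pos = None
        for ring in range(1, 40):
            radius = ring * (2.0 * r_max + 1.5)
            n_angles = max(8, 4 * ring)
            start = rng.random() * 2.0 * math.pi
            for k in range(n_angles):
                ang = start + 2.0 * math.pi * k / n_angles
                x = mx + radius * math.cos(ang)
                y = my + radius * math.sin(ang)
                if not (margin <= x <= w - margin and margin <= y <= h - margin):
                    continue
                if not overlaps(x, y):
                    pos = (x, y)
                    break
            if pos is not None:
                break
        if pos is None:
            raise FieldOfViewOverflow(
                "no free position left for a daughter cell; increase the image "
                "size or reduce the number of founders")
        placed[row.cell_id] = pos

    out = lineage[["cell_id"]].copy()
    out["x"] = [placed[c][0] for c in out["cell_id"]]
    out["y"] = [placed[c][1] for c in out["cell_id"]]
    return out


# ---------------------------------------------------------------------------
# state assembly
# ---------------------------------------------------------------------------

def simulate_ph_trajectories(lineage: pd.DataFrame, config: SimulationConfig,
                             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-cell, per-frame ground-truth state (pH, geometry, mobility).

    Returns one row per (cell, frame) for frames at or after the cell's
    birth: ``cell_id, frame, time, x, y, area, ph_true, mobile``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 10)
    if not set(lineage["fate"]).issubset({R_PLUS, R_MINUS}):
        bad = sorted(set(lineage["fate"]) - {R_PLUS, R_MINUS})
        raise ValueError(f"unknown fate label(s) in lineage: {bad}")

    times = config.frame_times
    positions = place_cells(lineage, config, rng)
    pos = dict(zip(positions["cell_id"], zip(positions["x"], positions["y"])))

    chunks = []
    for row in lineage.itertuples(index=False):
        alive = times >= row.birth_time - 1e-9
        t = times[alive]
        if t.size == 0:
            continue
        offset = float(rng.normal(0.0, config.ph_jitter_sd))
        ph = ph_template(t, row.fate, config, row.sp_drop_time) + offset
        gel = ph <= config.ph_gel
        mobile = ~(np.cumsum(gel) > 0)  # false from the first gel frame onward
        x, y = pos[row.cell_id]
        chunks.append(pd.DataFrame({
            "cell_id": row.cell_id,
            "frame": np.nonzero(alive)[0],
            "time": t,
            "x": x,
            "y": y,
            "area": _area_series(t, row.fate, config),
            "ph_true": ph,
            "mobile": mobile,
        }))
    series = pd.concat(chunks, ignore_index=True)
    return series


def _foci_states(ph: np.ndarray, threshold: float, hysteresis: float) -> np.ndarray:
    """Hysteretic foci presence: on when pH <= threshold, off only when pH
    rises above threshold + hysteresis."""
    state = False
    out = np.empty(ph.shape, dtype=bool)
    for i, v in enumerate(ph):
        if not state and v <= threshold:
            state = True
        elif state and v > threshold + hysteresis:
            state = False
        out[i] = state
    return out


def simulate_random_walk(n_steps: int, d: float, rng: np.random.Generator,
                         start: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Unconfined 2-D Brownian walk with per-axis step variance 2*D per frame.

    Returns an ``(n_steps + 1, 2)`` array of positions including the start.
    """
    steps = rng.normal(0.0, math.sqrt(2.0 * d), size=(n_steps, 2))
    out = np.empty((n_steps + 1, 2))
    out[0] = start
    out[1:] = np.asarray(start) + np.cumsum(steps, axis=0)
    return out


def _confined_walk(n: int, d: np.ndarray, radius: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Random walk confined to a disk of ``radius`` by reflection; ``d`` may
    vary per step (mobility arrest). Positions are offsets from the cell
    centre."""
    out = np.empty((n, 2))
    p = rng.uniform(-radius / 2, radius / 2, size=2)
    out[0] = p
    for i in range(1, n):
        sd = math.sqrt(2.0 * d[i - 1])
        p = p + rng.normal(0.0, sd, size=2)
        r = math.hypot(*p)
        if r > radius:
            p = p * ((2 * radius - r) / r if r < 2 * radius else radius / r)
        out[i] = p
    return out


def simulate_marker_states(series: pd.DataFrame, config: SimulationConfig,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Add marker foci, mitochondrial morphology and lipid-droplet positions.

    New columns: ``foci_<marker>`` per configured threshold, ``mito_state``
    (tubular / fragmented / globular), and ``ld_x, ld_y`` — the absolute
    position of the lipid droplet, a confined random walk whose diffusion
    coefficient switches from D_free to D_arrested at the gel event.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 20)
    if not config.foci_thresholds:
        raise ValueError("no foci thresholds configured")
    d_free, d_arrested = config.ld_diffusion
    t_ds_start, t_ds_end, _ = config.phase_times

    out = series.sort_values(["cell_id", "frame"], kind="stable").reset_index(drop=True)
    marker_cols = {m: np.empty(len(out), dtype=bool) for m in config.foci_thresholds}
    mito = np.empty(len(out), dtype=object)
    ld = np.empty((len(out), 2))

    # fates come through pH dynamics; recover them from mobility/pH is not
    # needed — the caller passes the lineage-ordered series, so infer fate
    # from whether the cell went immobile before respiration onset
    for _, idx in out.groupby("cell_id", sort=False).indices.items():
        ph = out["ph_true"].to_numpy()[idx]
        t = out["time"].to_numpy()[idx]
        mobile = out["mobile"].to_numpy()[idx]
        for marker, th in config.foci_thresholds.items():
            marker_cols[marker][idx] = _foci_states(ph, th, config.foci_hysteresis)
        arrested_in_ds = (~mobile & (t < t_ds_end)).any()
        m = np.where(t < t_ds_start, "tubular",
                     "globular" if arrested_in_ds else
                     np.where(t < t_ds_end, "tubular", "fragmented"))
        mito[idx] = m
        radius = np.sqrt(out["area"].to_numpy()[idx] / math.pi)
        d = np.where(mobile, d_free, d_arrested)
        conf_r = max(float(np.min(radius)) - 2.0, 1.0)
        walk = _confined_walk(len(idx), d, conf_r, rng)
        cx = out["x"].to_numpy()[idx]
        cy = out["y"].to_numpy()[idx]
        ld[idx, 0] = cx + walk[:, 0]
        ld[idx, 1] = cy + walk[:, 1]

    for marker, col in marker_cols.items():
        out[f"foci_{marker}"] = col
    out["mito_state"] = mito
    out["ld_x"] = ld[:, 0]
    out["ld_y"] = ld[:, 1]
    return out
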