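"""Ground-truth lineage generation for the synthetic life cycle.

Divisions are event-driven: every cell carries a next-division timer drawn
from the doubling time of the current metabolic phase (fermentation or
respiration). No divisions occur during the diauxic-shift arrest or in
stationary phase, and respiration-deficient (R-) cells never divide again
after the diauxic shift starts. Each founder seeds its own microcolony;
daughters inherit the mother's fate with a configurable probability and
otherwise resample from the population fraction.
"""

from __future__ import annotations

import heapq
import itertools
import math

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "simulate_lineage",
    "simulate_counts",
    "counts_from_lineage",
    "simulate_refeed",
]

R_PLUS = "R_plus"
R_MINUS = "R_minus"

LINEAGE_COLUMNS = [
    "cell_id", "parent_id", "birth_time", "microcolony_id",
    "fate", "rho_status", "sp_drop_time",
]


def _division_interval(config: SimulationConfig, t: float, rng) -> float | None:
    """Hours until the next division for a cell whose timer starts at t."""
    t_ds_start, t_ds_end, t_sp_start = config.phase_times
    if t < t_ds_start:
        base = config.doubling_time_f / 60.0
    elif t_ds_end <= t < t_sp_start:
        base = config.doubling_time_r / 60.0
    else:
        return None
    jitter = config.division_jitter
    if jitter > 0:
        base *= float(rng.lognormal(mean=0.0, sigma=jitter))
    return base


def _sp_drop_time(config: SimulationConfig, rng) -> float:
    """Stationary-phase pH-drop onset (hours, absolute), truncated >= SP start."""
    t_sp = config.phase_times[2]
    mean, sd = config.sp_drop_time_distribution
    if sd == 0:
        return t_sp + max(mean, 0.0)
    while True:
        delay = float(rng.normal(mean, sd))
        if delay >= 0:
            return t_sp + delay


def simulate_lineage(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a population lineage over the full life cycle.

    Returns a table with one row per cell: ``cell_id`` (1-based),
    ``parent_id`` (NA for founders), ``birth_time`` (h), ``microcolony_id``,
    ``fate`` (R_plus / R_minus), ``rho_status`` (rho_plus / rho_minus) and
    ``sp_drop_time`` (h, NA for R- cells). Deterministic given
    ``config.seed`` when ``rng`` is not supplied.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    t_ds_start, t_ds_end, t_sp_start = config.phase_times
    rows: list[dict] = []
    counter = itertools.count()
    events: list[tuple[float, int, int]] = []  # (division time, tiebreak, cell idx)

    def add_cell(parent_idx: int | None, birth: float, colony: int) -> int:
        idx = len(rows)
        if parent_idx is None:
            fate = R_MINUS if rng.random() < config.fraction_r_minus else R_PLUS
        elif birth >= t_ds_start:
            # the respiratory test happens at the DS: buds born after it
            # share their mother's already-revealed competence
            fate = rows[parent_idx]["fate"]
        elif rng.random() < config.inheritance_strength:
            fate = rows[parent_idx]["fate"]
        else:
            fate = R_MINUS if rng.random() < config.fraction_r_minus else R_PLUS
        if fate == R_MINUS:
            rho = ("rho_minus" if rng.random() < config.rho_minus_given_r_minus
                   else "rho_plus")
            sp_drop = math.nan
        else:
            rho = "rho_plus"
            sp_drop = _sp_drop_time(config, rng)
        rows.append({
            "cell_id": idx + 1,
            "parent_id": rows[parent_idx]["cell_id"] if parent_idx is not None else pd.NA,
            "birth_time": birth,
            "microcolony_id": colony,
            "fate": fate,
            "rho_status": rho,
            "sp_drop_time": sp_drop,
        })
        return idx

    def schedule(idx: int, t_from: float) -> None:
        if not config.divisions_enabled:
            return
        # R- cells arrest for good at the diauxic shift
        if rows[idx]["fate"] == R_MINUS and t_from >= t_ds_start:
            return
        interval = _division_interval(config, t_from, rng)
        if interval is None:
            # timer starting inside DS restarts at respiration onset (R+ only)
            if t_from < t_ds_end and rows[idx]["fate"] == R_PLUS:
                interval2 = _division_interval(config, t_ds_end, rng)
                if interval2 is not None:
                    heapq.heappush(events, (t_ds_end + interval2, next(counter), idx))
            return
        heapq.heappush(events, (t_from + interval, next(counter), idx))

    for colony in range(config.n_founders):
        idx = add_cell(None, 0.0, colony)
        schedule(idx, 0.0)

    while events:
        t, _, idx = heapq.heappop(events)
        if t >= config.t_end:
            continue
        t_ds_start_, t_ds_end_, t_sp_start_ = config.phase_times
        in_growth = (t < t_ds_start_) or (t_ds_end_ <= t < t_sp_start_)
        if not in_growth:
            # division fell in an arrest window: defer to respiration onset
            schedule(idx, max(t, t_ds_end_) if t < t_sp_start_ else t)
            continue
        if t >= t_ds_end_ and rows[idx]["fate"] == R_MINUS:
            continue
        child = add_cell(idx, t, rows[idx]["microcolony_id"])
        schedule(idx, t)
        schedule(child, t)

    table = pd.DataFrame(rows, columns=LINEAGE_COLUMNS)
    table["parent_id"] = table["parent_id"].astype("Int64")
    return table


def counts_from_lineage(lineage: pd.DataFrame, times) -> np.ndarray:
    """Number of cells alive (born on or before t) at each time point."""
    births = np.sort(np.asarray(lineage["birth_time"], dtype=float))
    times = np.asarray(times, dtype=float)
    return np.searchsorted(births, times, side="right").astype(float)


def simulate_counts(config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    noise: float = 0.05,
                    n0: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Idealised four-phase colony counts with multiplicative noise.

    Piecewise-exponential expectation: fermentation doublings until the DS
    starts, arrest through the DS, respiration doublings until stationary
    phase, then arrest. Noise is lognormal with the given relative sigma.
    Returns ``(times_h, counts)``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = config.frame_times
    t_ds_start, t_ds_end, t_sp_start = config.phase_times
    slope_f = math.log(2.0) / (config.doubling_time_f / 60.0)
    slope_r = math.log(2.0) / (config.doubling_time_r / 60.0)
    log_n = (math.log(n0 if n0 is not None else config.n_founders)
             + slope_f * np.minimum(t, t_ds_start)
             + slope_r * np.clip(t - t_ds_end, 0.0, t_sp_start - t_ds_end))
    counts = np.exp(log_n)
    if noise > 0:
        counts = counts * rng.lognormal(mean=0.0, sigma=noise, size=t.shape)
    return t, counts


def simulate_refeed(lineage: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    window_hours: float = 6.0) -> pd.DataFrame:
    """Post-refeed regrowth ground truth.

    Each cell regrows with the fate-dependent probability in
    ``config.survival_p``; survivors resume fermentative doublings for
    ``window_hours`` while non-survivors keep a flat area. Returns a table
    with the per-cell area fold change over the window and the survival draw.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    fates = lineage["fate"].to_numpy()
    p = np.array([config.survival_p[f] for f in fates], dtype=float)
    survives = rng.random(len(p)) < p
    growth = 2.0 ** (window_hours * 60.0 / config.doubling_time_f)
    fold = np.where(survives,
                    growth * rng.lognormal(0.0, 0.05, len(p)),
                    rng.lognormal(0.0, 0.03, len(p)))
    return pd.DataFrame({
        "cell_id": lineage["cell_id"],
        "fate": fates,
        "survives": survives,
        "area_fold": fold,
    })
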