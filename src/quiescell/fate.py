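"""Cell-fate classification and lineage statistics.

Respiration-deficient (R-) cells reveal themselves by a cytosolic pH crash
during the diauxic shift and by failing to grow during respiration;
respiration-competent (R+) cells keep a high pH until a stochastic drop in
stationary phase and roughly double their area while respiring. The
inheritance index quantifies how strongly the binary fate clusters within
microcolonies: mean within-colony variance of the 0/1 fate over the pooled
variance — 0 when every colony is internally homogeneous (full
inheritance), 1 in expectation when fates are assigned at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .ph import PhDropFit
from .phases import PhaseSegmentation

__all__ = ["FateCall", "FateClassifier", "classify_fate",
           "inheritance_index", "survival_fraction", "couple_ph_mobility"]

R_PLUS = "R_plus"
R_MINUS = "R_minus"
UNCLASSIFIED = "unclassified"


@dataclass
class FateCall:
    """Fate assignment for one track with the evidence used."""

    track_id: int | None
    fate: str
    t_half: float | None
    ds_window: tuple[float, float]
    r_phase_fold: float | None


class FateClassifier(BaseEstimator):
    """Rule-based R+/R- fate calls from pH-drop timing and growth.

    A drop whose half-time falls at or before the end of the diauxic shift
    (plus a short grace margin) marks an R- cell — the fitted decline of an
    early-crashing cell merges with the fermentation-phase pH decline, so
    no lower bound is imposed; a later half-time marks an R+ cell.
    Without a detected drop the respiration-phase area fold decides:
    growth means R+, a flat area over a trajectory that covers the
    respiration phase means R-, anything shorter stays unclassified.
    """

    def __init__(self, ds_margin: float = 2.0, growth_fold_threshold: float = 1.5,
                 crash_ph: float = 6.3):
        self.ds_margin = ds_margin
        self.growth_fold_threshold = growth_fold_threshold
        self.crash_ph = crash_ph

    def classify(self, drop: PhDropFit | None,
                 segmentation: PhaseSegmentation,
                 r_phase_fold: float | None = None,
                 track_end_time: float | None = None,
                 track_id: int | None = None) -> FateCall:
        if segmentation is None:
            raise ValueError("a phase segmentation is required for fate calls")
        if segmentation.n_segments < 3:
            raise ValueError("segmentation must include a respiration phase")
        _, t_ds_end = segmentation.segment_bounds(1)
        window = (segmentation.t_range[0], t_ds_end + self.ds_margin)
        _, t_r_end = segmentation.segment_bounds(2)

        # only a genuine crash to low pH is fate-defining: the universal
        # fermentation-phase decline to the ~6.9 plateau is also a fitted
        # "drop" but ends high and says nothing about respiration competence
        t_half = (drop.t_half
                  if (drop is not None and drop.drop_detected
                      and drop.ph_after <= self.crash_ph)
                  else None)
        if t_half is not None:
            fate = R_MINUS if t_half <= window[1] else R_PLUS
        elif r_phase_fold is not None and np.isfinite(r_phase_fold):
            covers_r = track_end_time is None or track_end_time >= t_r_end - 1e-9
            if r_phase_fold >= self.growth_fold_threshold:
                fate = R_PLUS
            elif covers_r:
                fate = R_MINUS
            else:
                fate = UNCLASSIFIED
        else:
            fate = UNCLASSIFIED
        return FateCall(track_id=track_id, fate=fate, t_half=t_half,
                        ds_window=window, r_phase_fold=r_phase_fold)


def classify_fate(drop: PhDropFit | None, segmentation: PhaseSegmentation,
                  r_phase_fold: float | None = None,
                  track_end_time: float | None = None,
                  track_id: int | None = None,
                  ds_margin: float = 2.0,
                  growth_fold_threshold: float = 1.5) -> FateCall:
    """Classify one cell; see :class:`FateClassifier`."""
    clf = FateClassifier(ds_margin=ds_margin,
                         growth_fold_threshold=growth_fold_threshold)
    return clf.classify(drop, segmentation, r_phase_fold=r_phase_fold,
                        track_end_time=track_end_time, track_id=track_id)


def inheritance_index(fates, microcolony_ids) -> float:
    """Within-microcolony over pooled variance of a binary phenotype.

    ``fates`` are 0/1 (or boolean) per cell; colonies with fewer than two
    cells are skipped. The index is the mean over microcolonies of the
    unbiased within-colony variance divided by the pooled unbiased
    variance: exactly 0 when every colony is internally homogeneous, and 1
    in expectation — at any colony size — when the phenotype is assigned
    independently at random. (A ratio of standard deviations would be
    biased well below 1 for random assignment in colonies of 10-20 cells.)
    """
    f = np.asarray(fates, dtype=float)
    colonies = np.asarray(microcolony_ids)
    if f.size != colonies.size:
        raise ValueError("fates and microcolony_ids must align")
    if not np.isin(f, (0.0, 1.0)).all():
        raise ValueError("fates must be binary 0/1")
    if np.unique(colonies).size < 2:
        raise ValueError("need at least two microcolonies")
    pooled_var = float(np.var(f, ddof=1))
    if pooled_var == 0:
        raise ValueError("all fates identical; the inheritance index is "
                         "undefined (zero pooled variance)")
    within = [float(np.var(f[colonies == c], ddof=1))
              for c in np.unique(colonies)
              if np.sum(colonies == c) >= 2]
    if not within:
        raise ValueError("no microcolony has two or more cells")
    return float(np.mean(within) / pooled_var)


def survival_fraction(regrowth_flags, stratum_labels=None,
                      conf_level: float = 0.95) -> pd.DataFrame:
    """Fraction of cells that resumed growth after refeeding, per stratum.

    Returns one row per stratum with the fraction and its Wilson score
    interval. Empty strata produce no row.
    """
    from statsmodels.stats.proportion import proportion_confint

    flags = np.asarray(regrowth_flags, dtype=bool)
    strata = (np.asarray(stratum_labels) if stratum_labels is not None
              else np.full(flags.shape, "all"))
    rows = []
    for s in np.unique(strata):
        sel = flags[strata == s]
        n = sel.size
        if n == 0:
            continue
        k = int(sel.sum())
        lo, hi = proportion_confint(k, n, alpha=1 - conf_level, method="wilson")
        rows.append({"stratum": s, "n": n, "fraction": k / n,
                     "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows, columns=["stratum", "n", "fraction",
                                       "ci_low", "ci_high"])


def couple_ph_mobility(drops: dict, events: dict, trajectories: pd.DataFrame,
                       fates: dict | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """Couple each cell's pH drop with its mobility-loss time.

    ``drops`` maps track_id -> :class:`~quiescell.ph.PhDropFit`, ``events``
    maps track_id -> :class:`~quiescell.foci.MobilityLossEvent`;
    ``trajectories`` is the long-format pH table. For every track with a
    detected mobility loss inside its trajectory span, the pH at the loss
    time is linearly interpolated. Returns the per-cell records and a
    summary: median and IQR of pH-at-loss per fate and pooled, plus the
    Pearson and Spearman correlation between the drop half-time and the
    loss time.
    """
    rows = []
    for tid, event in events.items():
        if event is None or event.t_loss is None:
            continue
        sub = trajectories[trajectories["track_id"] == tid].dropna(subset=["ph"])
        if not len(sub):
            continue
        t = sub["time"].to_numpy()
        if not (t.min() - 1e-9 <= event.t_loss <= t.max() + 1e-9):
            continue  # loss time outside the measured span: excluded
        ph_at_loss = float(np.interp(event.t_loss, t, sub["ph"].to_numpy()))
        drop = drops.get(tid)
        t_half = drop.t_half if (drop is not None and drop.drop_detected) else np.nan
        rows.append({"track_id": tid, "t_half": t_half,
                     "t_loss": float(event.t_loss), "ph_at_loss": ph_at_loss,
                     "fate": (fates or {}).get(tid, "all")})
    records = pd.DataFrame(rows, columns=["track_id", "t_half", "t_loss",
                                          "ph_at_loss", "fate"])

    summary: dict = {"by_fate": {}, "pooled": {}}
    if len(records):
        for fate, grp in records.groupby("fate"):
            q1, q2, q3 = np.percentile(grp["ph_at_loss"], [25, 50, 75])
            summary["by_fate"][fate] = {"median_ph_at_loss": float(q2),
                                        "iqr": [float(q1), float(q3)],
                                        "n": int(len(grp))}
        q1, q2, q3 = np.percentile(records["ph_at_loss"], [25, 50, 75])
        summary["pooled"] = {"median_ph_at_loss": float(q2),
                             "iqr": [float(q1), float(q3)],
                             "n": int(len(records))}
        paired = records.dropna(subset=["t_half"])
        if len(paired) >= 3 and paired["t_half"].nunique() > 1 \
                and paired["t_loss"].nunique() > 1:
            summary["pearson_r"] = float(
                stats.pearsonr(paired["t_half"], paired["t_loss"]).statistic)
            summary["spearman_r"] = float(
                stats.spearmanr(paired["t_half"], paired["t_loss"]).statistic)
    return records, summary
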