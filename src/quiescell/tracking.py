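"""Frame-to-frame cell tracking by assignment-cost minimisation.

Regions in consecutive frames are linked by solving a gated optimal
bipartite assignment: the cost of pairing two regions is their centroid
distance plus a weighted relative area change, leaving a region unmatched
costs the gate. Unmatched new regions either start as buds of an adjacent
existing track (until they reach half the mother's area) or as fresh
tracks; unmatched old tracks terminate.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

__all__ = ["CostLinker", "track_cells", "extract_track_features",
           "solve_gated_assignment"]

_BIG = 1e9


def solve_gated_assignment(cost: np.ndarray, gate: float
                           ) -> tuple[list[tuple[int, int]], float]:
    """Minimum-cost matching where any row/column may stay unmatched at a
    price of ``gate`` each.

    Returns the matched (row, col) pairs and the total objective
    (sum of matched costs + gate per unmatched row or column). Solved
    exactly via the standard augmented square assignment problem.
    """
    cost = np.asarray(cost, dtype=float)
    n, m = cost.shape
    size = n + m
    aug = np.full((size, size), 0.0)
    aug[:n, :m] = np.where(cost <= gate, cost, _BIG)
    aug[:n, m:] = _BIG
    aug[n:, :m] = _BIG
    np.fill_diagonal(aug[:n, m:], gate)
    np.fill_diagonal(aug[n:, :m], gate)
    rows, cols = linear_sum_assignment(aug)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols)
             if r < n and c < m and cost[r, c] <= gate]
    matched_cost = sum(cost[r, c] for r, c in pairs)
    total = matched_cost + gate * (n - len(pairs)) + gate * (m - len(pairs))
    return pairs, float(total)


def _regions(mask: np.ndarray) -> pd.DataFrame:
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return pd.DataFrame(columns=["label", "y", "x", "area"])
    centroids = ndi.center_of_mass(np.ones_like(mask), labels=mask, index=labels)
    areas = ndi.sum_labels(np.ones_like(mask), labels=mask, index=labels)
    cy = [c[0] for c in centroids]
    cx = [c[1] for c in centroids]
    return pd.DataFrame({"label": labels, "y": cy, "x": cx,
                         "area": areas.astype(float)})


class CostLinker(BaseEstimator):
    """Gated assignment-cost tracker.

    cost(i, j) = ||centroid_i - centroid_j|| + lambda_area * |dA| / A_i.
    ``gate`` defaults to half the typical cell diameter estimated from the
    median region area of the first non-empty frame.
    """

    def __init__(self, lambda_area: float = 5.0, gate: float | None = None,
                 bud_adjacency_px: float = 4.0, bud_area_fraction: float = 0.5):
        self.lambda_area = lambda_area
        self.gate = gate
        self.bud_adjacency_px = bud_adjacency_px
        self.bud_area_fraction = bud_area_fraction

    # ------------------------------------------------------------------
    def link(self, masks, times=None) -> pd.DataFrame:
        """Link a list of label images into tracks.

        Returns a table with one row per (track, frame):
        ``track_id, frame, time, label, x, y, area, parent_track_id, bud_of``.
        """
        n_frames = len(masks)
        if times is None:
            times = np.arange(n_frames, dtype=float)
        times = np.asarray(times, dtype=float)
        if times.size != n_frames:
            raise ValueError("times and masks must have equal length")
        if n_frames > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame timestamps must be strictly increasing "
                             "and frames consecutive")

        gate = self.gate
        rows: list[dict] = []
        next_id = 1
        # active track state: id -> dict(x, y, area, bud_of, parent)
        active: dict[int, dict] = {}

        for f in range(n_frames):
            regs = _regions(np.asarray(masks[f]))
            if gate is None and len(regs):
                gate = 0.5 * 2.0 * math.sqrt(float(regs["area"].median()) / math.pi)
            if gate is None:
                continue

            prev_ids = list(active.keys())
            matched_new: dict[int, int] = {}  # region idx -> track id
            if prev_ids and len(regs):
                pc = np.array([[active[t]["x"], active[t]["y"]] for t in prev_ids])
                pa = np.array([active[t]["area"] for t in prev_ids])
                nc = regs[["x", "y"]].to_numpy()
                na = regs["area"].to_numpy()
                dist = np.linalg.norm(pc[:, None, :] - nc[None, :, :], axis=2)
                darea = np.abs(na[None, :] - pa[:, None]) / pa[:, None]
                cost = dist + self.lambda_area * darea
                pairs, _ = solve_gated_assignment(cost, gate)
                for r, c in pairs:
                    matched_new[c] = prev_ids[r]

            new_active: dict[int, dict] = {}
            for ridx, reg in enumerate(regs.itertuples(index=False)):
                if ridx in matched_new:
                    tid = matched_new[ridx]
                    state = active[tid]
                    bud_of = state["bud_of"]
                    if bud_of is not None:
                        mother = active.get(bud_of) or new_active.get(bud_of)
                        if (mother is None
                                or reg.area >= self.bud_area_fraction * mother["area"]):
                            bud_of = None  # promoted to an independent daughter
                    parent = state["parent"]
                else:
                    # new region: bud of an adjacent track, or a fresh track
                    tid = next_id
                    next_id += 1
                    bud_of = None
                    parent = None
                    best = None
                    for pid in prev_ids:
                        st = active[pid]
                        d = math.hypot(st["x"] - reg.x, st["y"] - reg.y)
                        touch = (math.sqrt(st["area"] / math.pi)
                                 + math.sqrt(reg.area / math.pi)
                                 + self.bud_adjacency_px)
                        if d <= touch and (best is None or d < best[0]):
                            best = (d, pid)
                    if best is not None:
                        parent = best[1]
                        if reg.area < self.bud_area_fraction * active[parent]["area"]:
                            bud_of = parent
                new_active[tid] = {"x": reg.x, "y": reg.y, "area": reg.area,
                                   "bud_of": bud_of, "parent": parent}
                rows.append({"track_id": tid, "frame": f, "time": times[f],
                             "label": int(reg.label), "x": float(reg.x),
                             "y": float(reg.y), "area": float(reg.area),
                             "parent_track_id": parent, "bud_of": bud_of})
            active = new_active  # unmatched old tracks terminate

        out = pd.DataFrame(rows, columns=["track_id", "frame", "time", "label",
                                          "x", "y", "area", "parent_track_id",
                                          "bud_of"])
        out["parent_track_id"] = out["parent_track_id"].astype("Int64")
        out["bud_of"] = out["bud_of"].astype("Int64")
        return out


def track_cells(masks, times=None, lambda_area: float = 5.0,
                gate: float | None = None) -> pd.DataFrame:
    """Track label images into cell tracks; see :class:`CostLinker`."""
    return CostLinker(lambda_area=lambda_area, gate=gate).link(masks, times)


def extract_track_features(tracks: pd.DataFrame, stack, masks) -> pd.DataFrame:
    """Per-(track, frame) geometry and background-subtracted intensities.

    ``area_total`` adds the areas of buds currently assigned to the track
    (mother + bud, as used for single-cell growth curves). Mean in-mask
    intensity is computed per channel after subtracting the per-frame median
    intensity outside all masks.
    """
    n_frames = stack.n_frames
    if len(masks) != n_frames:
        raise ValueError("number of masks does not match the stack")
    for f in range(n_frames):
        if np.asarray(masks[f]).shape != stack.data.shape[2:]:
            raise ValueError("mask shape does not match the stack frames")

    feats = tracks.copy()
    for ch in stack.channel_names:
        feats[f"mean_{ch}"] = np.nan

    for f, sub in tracks.groupby("frame", sort=True):
        mask = np.asarray(masks[f])
        bg_mask = mask == 0
        labels = sub["label"].to_numpy()
        for ch in stack.channel_names:
            img = stack.channel(ch)[f].astype(float)
            bg = float(np.median(img[bg_mask])) if bg_mask.any() else 0.0
            means = ndi.mean(img, labels=mask, index=labels)
            feats.loc[sub.index, f"mean_{ch}"] = np.asarray(means) - bg

    # fold bud areas into the mother's total area
    feats["area_total"] = feats["area"]
    buds = feats[feats["bud_of"].notna()]
    if len(buds):
        add = buds.groupby(["bud_of", "frame"])["area"].sum()
        for (mother, f), extra in add.items():
            sel = (feats["track_id"] == mother) & (feats["frame"] == f)
            feats.loc[sel, "area_total"] += extra
    return feats
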