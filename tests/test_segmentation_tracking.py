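import itertools

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from quiescell.segmentation import WatershedSegmenter, segment_frame
from quiescell.tracking import (CostLinker, extract_track_features,
                                solve_gated_assignment, track_cells)


def _disk_image(centres, radius=6, shape=(96, 96), level=800.0, bg=200.0):
    img = np.full(shape, bg)
    for (y, x) in centres:
        rr, cc = draw_disk((y, x), radius, shape=shape)
        img[rr, cc] = level
    return img


def test_blank_image_yields_no_regions():
    assert segment_frame(np.zeros((64, 64))).max() == 0
    assert segment_frame(np.full((64, 64), 7.0)).max() == 0


def test_two_disjoint_disks_yield_two_regions():
    img = _disk_image([(30, 30), (70, 64)])
    lab = segment_frame(img)
    assert lab.max() == 2
    # every labelled pixel belongs to exactly one region by construction;
    # sizes match the drawn disks
    sizes = np.bincount(lab.ravel())[1:]
    assert np.all(np.abs(sizes - np.pi * 36) < 30)


def test_touching_disks_split_by_watershed():
    img = _disk_image([(48, 40), (48, 53)])
    lab = segment_frame(img, min_distance=5)
    assert lab.max() == 2


def test_segmentation_invariant_to_affine_rescaling():
    img = _disk_image([(30, 30), (70, 64), (48, 80)])
    a = segment_frame(img)
    b = segment_frame(3.5 * img + 123.0)
    assert np.array_equal(a, b)


def test_segmentation_iou_against_ground_truth(population_run):
    stack = population_run["stack"]
    masks = population_run["masks"]
    f = 10
    truth = stack.labels[f]
    found = masks[f]
    ious = []
    for cid in np.unique(truth)[1:]:
        tsel = truth == cid
        labels, counts = np.unique(found[tsel], return_counts=True)
        best = labels[np.argmax(counts)]
        if best == 0:
            ious.append(0.0)
            continue
        fsel = found == best
        ious.append((tsel & fsel).sum() / (tsel | fsel).sum())
    assert np.mean(ious) >= 0.7


def test_gated_assignment_matches_exhaustive_enumeration():
    rng = np.random.default_rng(0)
    for n, m in [(3, 3), (4, 3), (2, 5), (6, 6)]:
        cost = rng.uniform(0, 10, (n, m))
        gate = 4.0
        pairs, total = solve_gated_assignment(cost, gate)

        best = np.inf
        for k in range(min(n, m) + 1):
            for rows in itertools.combinations(range(n), k):
                for cols in itertools.permutations(range(m), k):
                    if any(cost[r, c] > gate for r, c in zip(rows, cols)):
                        continue
                    tot = (sum(cost[r, c] for r, c in zip(rows, cols))
                           + gate * (n - k) + gate * (m - k))
                    best = min(best, tot)
        assert total == pytest.approx(best, abs=1e-9)


def test_single_translating_cell_tracked_as_one_track():
    masks = []
    for f in range(10):
        img = np.zeros((64, 64), dtype=int)
        rr, cc = draw_disk((30, 12 + 2 * f), 5, shape=(64, 64))
        img[rr, cc] = 1
        masks.append(img)
    tracks = track_cells(masks)
    assert tracks["track_id"].nunique() == 1
    assert len(tracks) == 10


def test_far_jumps_terminate_tracks_instead_of_swapping():
    # both cells jump >> gate: refusing the assignment is cheaper than
    # swapping identities
    m0 = np.zeros((96, 96), dtype=int)
    m1 = np.zeros((96, 96), dtype=int)
    for lab, (y, x) in ((1, (20, 20)), (2, (76, 76))):
        rr, cc = draw_disk((y, x), 5, shape=(96, 96))
        m0[rr, cc] = lab
    for lab, (y, x) in ((1, (20, 60)), (2, (76, 30))):
        rr, cc = draw_disk((y, x), 5, shape=(96, 96))
        m1[rr, cc] = lab
    tracks = track_cells([m0, m1], gate=8.0)
    first = set(tracks[tracks["frame"] == 0]["track_id"])
    second = set(tracks[tracks["frame"] == 1]["track_id"])
    assert first.isdisjoint(second)


def test_nonmonotone_timestamps_rejected():
    masks = [np.zeros((16, 16), dtype=int)] * 3
    with pytest.raises(ValueError, match="increasing"):
        track_cells(masks, times=[0.0, 2.0, 1.0])


def test_new_adjacent_region_recorded_as_bud_then_promoted():
    shape = (72, 72)
    masks = []
    for f in range(6):
        img = np.zeros(shape, dtype=int)
        rr, cc = draw_disk((36, 30), 8, shape=shape)
        img[rr, cc] = 1
        if f >= 1:
            bud_r = 3 + f  # grows past half the mother radius
            rr, cc = draw_disk((36, 44), bud_r, shape=shape)
            img[rr, cc] = 2
        masks.append(img)
    tracks = track_cells(masks, gate=10.0)
    bud = tracks[tracks["track_id"] == 2]
    assert (bud["parent_track_id"] == 1).all()
    assert bud["bud_of"].iloc[0] == 1          # starts as the mother's bud
    assert bud["bud_of"].iloc[-1:].isna().all()  # promoted to a daughter


def test_track_identity_agreement_with_ground_truth(population_run):
    stack = population_run["stack"]
    masks = population_run["masks"]
    tracks = population_run["tracks"]
    # identity agreement: each track must map to a single ground-truth cell
    mapping = {}
    consistent = 0
    total = 0
    for row in tracks.itertuples(index=False):
        sel = masks[row.frame] == row.label
        overlap = stack.labels[row.frame][sel]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            continue
        gt = int(np.bincount(overlap).argmax())
        total += 1
        if row.track_id not in mapping:
            mapping[row.track_id] = gt
        consistent += mapping[row.track_id] == gt
    assert total > 0
    assert consistent / total >= 0.9


def test_feature_extraction_background_subtraction(population_run):
    from quiescell.render import ImageStack

    # uniform synthetic channel: value v inside cells, b outside
    mask = np.zeros((48, 48), dtype=int)
    rr, cc = draw_disk((24, 24), 6, shape=(48, 48))
    mask[rr, cc] = 1
    img = np.where(mask > 0, 700, 150).astype(np.uint16)
    stack = ImageStack(data=np.stack([img[None]] * 4),
                       times=np.array([0.0]),
                       labels=mask[None].astype(np.uint16))
    tracks = track_cells([mask], times=[0.0])
    feats = extract_track_features(tracks, stack, [mask])
    for ch in stack.channel_names:
        assert feats[f"mean_{ch}"].iloc[0] == pytest.approx(700 - 150)


def test_mother_bud_area_total_sums_both_regions():
    from quiescell.render import ImageStack

    shape = (72, 72)
    masks = []
    for f in range(2):
        img = np.zeros(shape, dtype=int)
        rr, cc = draw_disk((36, 30), 8, shape=shape)
        img[rr, cc] = 1
        if f == 1:
            rr, cc = draw_disk((36, 43), 3, shape=shape)
            img[rr, cc] = 2
        masks.append(img)
    data = np.stack([np.stack([np.full(shape, 100, dtype=np.uint16)] * 2)] * 4)
    stack = ImageStack(data=data, times=np.array([0.0, 1.0]),
                       labels=np.zeros((2, *shape), dtype=np.uint16))
    tracks = track_cells(masks, times=[0.0, 1.0], gate=10.0)
    feats = extract_track_features(tracks, stack, masks)
    mother_area = feats[(feats["track_id"] == 1) & (feats["frame"] == 1)]
    own = float(mother_area["area"].iloc[0])
    bud = float(feats[(feats["track_id"] == 2) & (feats["frame"] == 1)]["area"].iloc[0])
    assert float(mother_area["area_total"].iloc[0]) == pytest.approx(own + bud)
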