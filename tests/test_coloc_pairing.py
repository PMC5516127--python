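"""Overlap classification, pooled percentages and greedy pair matching."""

import dataclasses
import math

import numpy as np
import pytest

from synaptomo import coloc_pairing, puncta3d, registration, segmentation
from synaptomo.coloc_pairing import (
    ColocalizationRecord,
    SynapticPair,
    classify_overlap,
    find_pairs,
    percent_pairs_tau,
    percent_positive,
)
from synaptomo.puncta3d import Punctum, PunctaCollection
from synaptomo.segmentation import mask_from_array
from synaptomo.stack_io import ROLE_GFP, ROLE_POSTSYNAPSE, ROLE_PRESYNAPSE, ROLE_TAU
from synaptomo.synthetic_data import SceneConfig, generate_scene


def _punctum(pid, voxels, channel="postsynapse"):
    voxels = np.array(voxels, dtype=np.intp)
    return Punctum(
        id=pid, channel=channel, voxels=voxels,
        centroid_um=tuple((voxels.mean(axis=0)[::-1] + 0.5) * 0.1),
        volume_um3=len(voxels) * 0.1 * 0.1 * 0.07,
        section_span=len(np.unique(voxels[:, 0])),
    )


def _collection(puncta, channel="postsynapse"):
    return PunctaCollection(
        puncta=puncta, channel=channel, pixel_size_um=0.1,
        section_thickness_um=0.07, origin_um=(0.0, 0.0), volume_um3=1.0,
    )


def _point_punctum(pid, x, y, z, channel):
    return Punctum(
        id=pid, channel=channel, voxels=np.array([[0, 0, 0]], dtype=np.intp),
        centroid_um=(x, y, z), volume_um3=0.0007, section_span=1,
    )


def test_overlap_boundary_inclusive():
    voxels = [(0, 0, i) for i in range(10)]
    pc = _collection([_punctum(1, voxels)])
    ref = np.zeros((1, 1, 10), dtype=bool)
    ref[0, 0, :5] = True  # 5 of 10 voxels -> exactly 0.5 -> positive
    recs = classify_overlap(pc, mask_from_array(ref))
    assert recs[0].overlap_fraction == pytest.approx(0.5)
    assert recs[0].positive
    ref[0, 0, 4] = False  # 4 of 10 -> 0.4 -> negative
    recs = classify_overlap(pc, mask_from_array(ref))
    assert recs[0].overlap_fraction == pytest.approx(0.4)
    assert not recs[0].positive


def test_empty_reference_gives_zero_fractions():
    pc = _collection([_punctum(1, [(0, 0, 0), (0, 0, 1)])])
    recs = classify_overlap(pc, mask_from_array(np.zeros((1, 1, 4), dtype=bool)))
    assert recs[0].overlap_fraction == 0.0 and not recs[0].positive


def test_percent_pooling_by_sums():
    # crops with (2 of 20) and (8 of 80) positive -> pooled 10%
    records = [ColocalizationRecord(i, 1.0, i < 2) for i in range(20)]
    records += [ColocalizationRecord(100 + i, 1.0, i < 8) for i in range(80)]
    assert percent_positive(records) == pytest.approx(10.0)
    assert percent_positive([ColocalizationRecord(0, 1.0, True)]) == 100.0
    assert percent_positive([]) is None


def test_pair_distance_boundary():
    pre = _collection([_point_punctum(0, 0.0, 0.0, 0.0, ROLE_PRESYNAPSE)],
                      ROLE_PRESYNAPSE)
    # 3-4-5 triangle scaled: distance exactly 0.5 -> paired (inclusive)
    post = _collection([_point_punctum(0, 0.3, 0.4, 0.0, ROLE_POSTSYNAPSE)],
                       ROLE_POSTSYNAPSE)
    assert len(find_pairs(pre, post)) == 1
    # distance ~0.5099 -> not paired
    post2 = _collection([_point_punctum(0, 0.3, 0.4, 0.1, ROLE_POSTSYNAPSE)],
                        ROLE_POSTSYNAPSE)
    assert find_pairs(pre, post2) == []


def brute_force_pairs(pre, post, max_dist=0.5):
    """Oracle: explicit candidate list + sequential greedy matching."""
    cands = []
    for p in pre:
        for q in post:
            d = math.dist(p.centroid_um, q.centroid_um)
            if d <= max_dist * (1 + 1e-9) + 1e-12:
                cands.append((d, p.id, q.id))
    cands.sort()
    taken_p, taken_q, out = set(), set(), []
    for d, pid, qid in cands:
        if pid not in taken_p and qid not in taken_q:
            taken_p.add(pid)
            taken_q.add(qid)
            out.append((pid, qid))
    return out


@pytest.mark.parametrize("seed", range(5))
def test_greedy_matching_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    pre = _collection(
        [_point_punctum(i, *rng.uniform(0, (10, 10, 2.1)), ROLE_PRESYNAPSE)
         for i in range(200)], ROLE_PRESYNAPSE)
    post = _collection(
        [_point_punctum(i, *rng.uniform(0, (10, 10, 2.1)), ROLE_POSTSYNAPSE)
         for i in range(200)], ROLE_POSTSYNAPSE)
    ours = [(p.pre_id, p.post_id) for p in find_pairs(pre, post)]
    assert ours == brute_force_pairs(pre.puncta, post.puncta)


def test_pair_count_bounds_and_monotonicity():
    rng = np.random.default_rng(11)
    pre = _collection(
        [_point_punctum(i, *rng.uniform(0, (5, 5, 1.0)), ROLE_PRESYNAPSE)
         for i in range(40)], ROLE_PRESYNAPSE)
    post = _collection(
        [_point_punctum(i, *rng.uniform(0, (5, 5, 1.0)), ROLE_POSTSYNAPSE)
         for i in range(30)], ROLE_POSTSYNAPSE)
    pairs = find_pairs(pre, post)
    assert len(pairs) <= min(len(pre), len(post))
    # each punctum at most once
    assert len({p.pre_id for p in pairs}) == len(pairs)
    assert len({p.post_id for p in pairs}) == len(pairs)
    # removing a presynapse never increases the pair count
    smaller = dataclasses.replace(pre, puncta=pre.puncta[1:])
    assert len(find_pairs(smaller, post)) <= len(pairs)
    # raising min distance never decreases, lowering never increases
    assert len(find_pairs(pre, post, 0.3)) <= len(pairs) <= len(find_pairs(pre, post, 0.8))


def test_min_overlap_monotonicity():
    rng = np.random.default_rng(5)
    data = rng.random((4, 20, 20)) < 0.1
    pc = puncta3d.label_components(mask_from_array(data))
    ref = mask_from_array(rng.random((4, 20, 20)) < 0.4)
    counts = []
    for thr in (0.2, 0.4, 0.6, 0.8):
        recs = classify_overlap(pc, ref, min_overlap=thr)
        counts.append(sum(r.positive for r in recs))
    assert counts == sorted(counts, reverse=True)


def test_overlap_invariant_under_whole_volume_translation():
    rng = np.random.default_rng(9)
    data = rng.random((4, 20, 20)) < 0.08
    ref = rng.random((4, 20, 20)) < 0.3
    # clear a border band so np.roll acts as a pure translation
    for arr in (data, ref):
        arr[:, :4, :] = arr[:, -4:, :] = False
        arr[:, :, :4] = arr[:, :, -4:] = False
    f0 = [r.overlap_fraction
          for r in classify_overlap(puncta3d.label_components(mask_from_array(data)),
                                    mask_from_array(ref))]
    shifted_data = np.roll(data, (2, 3), axis=(1, 2))
    shifted_ref = np.roll(ref, (2, 3), axis=(1, 2))
    f1 = [r.overlap_fraction
          for r in classify_overlap(
              puncta3d.label_components(mask_from_array(shifted_data)),
              mask_from_array(shifted_ref))]
    assert sorted(f0) == pytest.approx(sorted(f1))


def test_percent_pairs_tau_and_semantics():
    pairs = [SynapticPair(i, i, 0.1) for i in range(4)]
    pre = [ColocalizationRecord(0, 1, True), ColocalizationRecord(1, 1, True),
           ColocalizationRecord(2, 0, False), ColocalizationRecord(3, 0, False)]
    post = [ColocalizationRecord(0, 1, True), ColocalizationRecord(1, 0, False),
            ColocalizationRecord(2, 1, True), ColocalizationRecord(3, 0, False)]
    # statuses (T,T),(T,F),(F,T),(F,F) -> 25%
    assert percent_pairs_tau(pairs, pre, post) == pytest.approx(25.0)
    none_tau = [ColocalizationRecord(i, 0, False) for i in range(4)]
    assert percent_pairs_tau(pairs, none_tau, none_tau) == 0.0
    assert percent_pairs_tau([], pre, post) is None


def test_planted_pair_tau_fraction_recovered():
    """Tau planted in both members of ~20% of pairs (all presynaptic partners
    tau-positive, postsynaptic flags at 0.2): the pipeline estimate falls
    within the 95% binomial CI of the planted fraction."""
    both, total, planted_both, planted_total = 0, 0, 0, 0
    for seed in range(3):
        cfg = SceneConfig(seed=seed, frac_pre_tau_positive=1.0,
                          frac_post_tau_positive=0.2)
        gt, series = generate_scene(cfg)
        stacks, _ = registration.align_series(series)
        masks = {r: segmentation.binarize_stack(s) for r, s in stacks.items()}
        pre = puncta3d.filter_single_section(
            puncta3d.label_components(masks[ROLE_PRESYNAPSE]))
        post = puncta3d.filter_single_section(
            puncta3d.label_components(masks[ROLE_POSTSYNAPSE]))
        gfp_ids = {r.punctum_id
                   for r in classify_overlap(pre, masks[ROLE_GFP]) if r.positive}
        gfp_pre = dataclasses.replace(
            pre, puncta=[p for p in pre if p.id in gfp_ids])
        pairs = find_pairs(gfp_pre, post)
        pre_recs = classify_overlap(gfp_pre, masks[ROLE_TAU])
        post_recs = classify_overlap(post, masks[ROLE_TAU])
        pct = percent_pairs_tau(pairs, pre_recs, post_recs)
        both += round(pct * len(pairs) / 100)
        total += len(pairs)
        for a, b in gt.pairs():
            planted_total += 1
            planted_both += a.tau_positive and b.tau_positive
    planted_frac = planted_both / planted_total
    half = 1.96 * math.sqrt(planted_frac * (1 - planted_frac) / total)
    assert abs(both / total - planted_frac) <= half + 0.02
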