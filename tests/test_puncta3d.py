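"""3D component formation, the single-section filter, densities, GFP calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synaptomo import puncta3d, registration, segmentation
from synaptomo.errors import ConfigError
from synaptomo.segmentation import mask_from_array
from synaptomo.stack_io import ROLE_GFP, ROLE_PRESYNAPSE
from synaptomo.synthetic_data import SceneConfig, generate_scene


def flood_fill_components(data):
    """Oracle: explicit stack-based 26-connected flood fill."""
    visited = np.zeros_like(data, dtype=bool)
    comps = []
    nz, ny, nx = data.shape
    for z0, y0, x0 in zip(*np.nonzero(data)):
        if visited[z0, y0, x0]:
            continue
        stack, comp = [(z0, y0, x0)], []
        visited[z0, y0, x0] = True
        while stack:
            z, y, x = stack.pop()
            comp.append((z, y, x))
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if dz == dy == dx == 0:
                            continue
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if (
                            0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                            and data[zz, yy, xx] and not visited[zz, yy, xx]
                        ):
                            visited[zz, yy, xx] = True
                            stack.append((zz, yy, xx))
        comps.append(frozenset(comp))
    return set(comps)


def test_in_plane_diagonal_voxels_are_one_component():
    data = np.zeros((1, 4, 4), dtype=bool)
    data[0, 1, 1] = data[0, 2, 2] = True
    pc = puncta3d.label_components(mask_from_array(data))
    assert len(pc) == 1


def test_repeated_disc_spans_three_sections():
    data = np.zeros((8, 10, 10), dtype=bool)
    for k in (4, 5, 6):
        data[k, 3:6, 3:6] = True
    pc = puncta3d.label_components(mask_from_array(data))
    assert len(pc) == 1
    assert pc.puncta[0].section_span == 3


@pytest.mark.parametrize("seed", range(5))
def test_labeling_matches_flood_fill_oracle(seed):
    rng = np.random.default_rng(seed)
    data = rng.random((8, 25, 25)) < 0.04
    pc = puncta3d.label_components(mask_from_array(data))
    ours = {frozenset(map(tuple, p.voxels)) for p in pc}
    assert ours == flood_fill_components(data)


def test_filter_rule_boundary_and_idempotence():
    data = np.zeros((5, 10, 10), dtype=bool)
    data[1, 1, 1] = True                     # span 1: removed
    data[2:4, 5, 5] = True                   # span 2: kept
    pc = puncta3d.label_components(mask_from_array(data))
    kept = puncta3d.filter_single_section(pc)
    assert len(pc) == 2 and len(kept) == 1
    assert kept.puncta[0].section_span == 2
    again = puncta3d.filter_single_section(kept)
    assert [p.id for p in again] == [p.id for p in kept]


def test_filter_removes_exactly_the_planted_speckles():
    """200 disjoint true puncta (span ≥ 2) plus 300 disjoint single-section
    speckles in a perfect mask: the filter removes exactly the 300 speckles."""
    rng = np.random.default_rng(0)
    nz, ny, nx = 8, 72, 72
    data = np.zeros((nz, ny, nx), dtype=bool)
    # 3-px cell grid keeps every object 26-disconnected from its neighbours
    cells = [(3 * r + 1, 3 * c + 1) for r in range(ny // 3) for c in range(nx // 3)]
    rng.shuffle(cells)
    for y, x in cells[:200]:  # true puncta: 2–3 consecutive sections
        span = int(rng.integers(2, 4))
        z0 = int(rng.integers(0, nz - span + 1))
        data[z0 : z0 + span, y, x] = True
    for y, x in cells[200:500]:  # speckles: exactly one section
        data[int(rng.integers(0, nz)), y, x] = True
    pc = puncta3d.label_components(mask_from_array(data))
    kept = puncta3d.filter_single_section(pc)
    removed = [p for p in pc if p.id not in {q.id for q in kept}]
    assert len(pc) == 500
    assert len(kept) == 200
    assert len(removed) == 300
    assert all(p.section_span == 1 for p in removed)
    assert all(p.section_span >= 2 for p in kept)


def test_filter_removes_generator_speckles_end_to_end():
    """On a noise-free, jitter-free generator scene the surviving object
    count equals the planted punctum count to within the merge slack, and
    every surviving object spans at least two sections."""
    cfg = SceneConfig(seed=33, background_noise_sd=0.0, jitter_px=0,
                      speckle_count=2)
    gt, series = generate_scene(cfg)
    data = np.stack(series.channels[ROLE_PRESYNAPSE]) > 0
    pc = puncta3d.label_components(mask_from_array(data, role=ROLE_PRESYNAPSE))
    kept = puncta3d.filter_single_section(pc)
    n_true = len(gt.by_channel(ROLE_PRESYNAPSE))
    assert all(p.section_span >= 2 for p in kept)
    assert abs(len(kept) - n_true) / n_true <= 0.05


def test_density_arithmetic_and_conservation():
    data = np.zeros((30, 100, 100), dtype=bool)
    rng = np.random.default_rng(3)
    # 47 disjoint 2-section bars
    placed = 0
    while placed < 47:
        z = rng.integers(0, 28)
        y, x = rng.integers(0, 96, size=2)
        if data[max(z-1,0):z+3, max(y-2,0):y+4, max(x-2,0):x+4].any():
            continue
        data[z:z+2, y, x] = True
        placed += 1
    pc = puncta3d.label_components(mask_from_array(data))
    assert len(pc) == 47
    d = puncta3d.density(pc)
    assert d == pytest.approx(47 / 210.0)
    assert d * pc.volume_um3 == pytest.approx(len(pc))


def test_empty_collection_density_zero():
    pc = puncta3d.label_components(mask_from_array(np.zeros((2, 4, 4), dtype=bool)))
    assert puncta3d.density(pc) == 0.0


def test_percent_gfp_positive_examples():
    data = np.zeros((4, 40, 40), dtype=bool)
    for i in range(12):
        y = 3 * i + 1
        data[1:3, y, 2:4] = True
    pc = puncta3d.label_components(mask_from_array(data, role=ROLE_PRESYNAPSE))
    assert len(pc) == 12
    # GFP covers 3 of 12 objects fully -> 25%
    gfp = np.zeros_like(data)
    for i in range(3):
        y = 3 * i + 1
        gfp[:, y, :] = True
    pct = puncta3d.percent_gfp_positive(pc, mask_from_array(gfp, role=ROLE_GFP))
    assert pct == pytest.approx(25.0)
    # saturation: all-true reference -> 100%
    all_true = mask_from_array(np.ones_like(data), role=ROLE_GFP)
    assert puncta3d.percent_gfp_positive(pc, all_true) == pytest.approx(100.0)
    # empty collection -> missing, not zero
    empty = puncta3d.label_components(
        mask_from_array(np.zeros_like(data), role=ROLE_PRESYNAPSE)
    )
    assert puncta3d.percent_gfp_positive(empty, all_true) is None


def test_planted_gfp_fraction_recovered():
    """frac_pre_gfp_positive=0.3 over pooled seeds: the classifier estimate
    falls within the 95% binomial CI of 30%."""
    positives, total = 0, 0
    for seed in range(3):
        cfg = SceneConfig(seed=seed, frac_pre_gfp_positive=0.3)
        gt, series = generate_scene(cfg)
        stacks, _ = registration.align_series(series)
        pre_mask = segmentation.binarize_stack(stacks[ROLE_PRESYNAPSE])
        gfp_mask = segmentation.binarize_stack(stacks[ROLE_GFP])
        pc = puncta3d.filter_single_section(puncta3d.label_components(pre_mask))
        pct = puncta3d.percent_gfp_positive(pc, gfp_mask)
        positives += round(pct * len(pc) / 100)
        total += len(pc)
    half = 1.96 * math.sqrt(0.3 * 0.7 / total)
    assert abs(positives / total - 0.3) <= half


def test_clean_scene_count_within_five_percent(clean_scene):
    gt, series = clean_scene
    data = np.stack(series.channels[ROLE_PRESYNAPSE]) > 0
    pc = puncta3d.filter_single_section(
        puncta3d.label_components(mask_from_array(data, role=ROLE_PRESYNAPSE))
    )
    planted = len(gt.by_channel(ROLE_PRESYNAPSE))
    assert abs(len(pc) - planted) / planted <= 0.05


def test_end_to_end_detection_f1_gate(default_scene, aligned_default, masks_default):
    """On the default scene (jitter, noise, speckles) the full chain —
    registration, combined thresholding, labelling, single-section filter —
    detects puncta with object-level F1 ≥ 0.95 against the planted truth."""
    from synaptomo.synthetic_data import detection_f1
    from synaptomo.stack_io import ROLE_POSTSYNAPSE

    gt, _ = default_scene
    for role in (ROLE_PRESYNAPSE, ROLE_POSTSYNAPSE):
        pc = puncta3d.filter_single_section(
            puncta3d.label_components(masks_default[role])
        )
        f1 = detection_f1([p.centroid_um for p in pc], gt.by_channel(role))
        assert f1 >= 0.95, f"{role}: F1 {f1:.3f}"


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=10, deadline=None, derandomize=True)
def test_filter_exactness_property(seed):
    """Removed set is exactly the span-1 objects, by independent recount."""
    rng = np.random.default_rng(seed)
    data = rng.random((6, 20, 20)) < 0.05
    pc = puncta3d.label_components(mask_from_array(data))
    kept = puncta3d.filter_single_section(pc)
    kept_ids = {p.id for p in kept}
    for p in pc:
        span = len(np.unique(p.voxels[:, 0]))  # independent recomputation
        assert (p.id in kept_ids) == (span >= 2)
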