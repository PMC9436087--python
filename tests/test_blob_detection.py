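import math

import numpy as np
import pytest

from sxtinstance import SemanticMask, Tomogram
from sxtinstance.blob_detection import (
    Blob,
    DetectionParams,
    ScaleBank,
    build_scale_bank,
    detect_blobs,
    discrete_sphere_volume,
    estimate_radius,
    find_local_maxima,
    label_connected_clusters,
    overlap_ratio,
    rank_and_select_blobs,
    screen_by_mask,
)
from conftest import make_sphere_volume

PARAMS = DetectionParams()


# ---------------------------------------------------------------- clustering

def flood_fill_components(mask):
    """Brute-force 26-connected component labelling by BFS."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for o in offsets:
                w = tuple(v[i] + o[i] for i in range(3))
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps


def test_two_disconnected_pieces_give_two_clusters():
    mask = np.zeros((10, 10, 10), dtype=np.uint8)
    mask[1, 1, 1:4] = 1
    mask[7, 7, 5:8] = 1
    clusters = label_connected_clusters(SemanticMask(mask), Tomogram(np.zeros((10, 10, 10))))
    assert len(clusters) == 2
    assert clusters[0].offset < clusters[1].offset


def test_empty_mask_gives_no_clusters():
    clusters = label_connected_clusters(
        SemanticMask(np.zeros((5, 5, 5), dtype=np.uint8)), Tomogram(np.zeros((5, 5, 5))))
    assert clusters == []


def test_cluster_count_matches_flood_fill_oracle(rng):
    mask = (rng.random((20, 20, 20)) < 0.08).astype(np.uint8)
    clusters = label_connected_clusters(SemanticMask(mask), Tomogram(np.zeros((20, 20, 20))))
    oracle = flood_fill_components(mask)
    assert len(clusters) == len(oracle)
    # every cluster's support equals one oracle component (in the parent frame)
    oracle_sets = {frozenset(c) for c in oracle}
    for cl in clusters:
        support = frozenset(
            tuple(int(v + o) for v, o in zip(vox, cl.offset))
            for vox in np.argwhere(cl.mask_crop)
        )
        assert support in oracle_sets


def test_bounding_box_pads_two_voxels_and_clips():
    mask = np.zeros((9, 9, 9), dtype=np.uint8)
    mask[0:2, 4, 4] = 1  # touches the z border
    (cl,) = label_connected_clusters(SemanticMask(mask), Tomogram(np.zeros((9, 9, 9))))
    assert cl.bbox == ((0, 3), (2, 6), (2, 6))


# ---------------------------------------------------------------- scale bank

def eq1_truncated_kernel(sigma):
    """Direct evaluation of the Gaussian on the 27 kernel offsets, renormalized."""
    vals = np.empty((3, 3, 3))
    for i, z in enumerate((-1, 0, 1)):
        for j, y in enumerate((-1, 0, 1)):
            for k, x in enumerate((-1, 0, 1)):
                vals[i, j, k] = math.exp(-(x * x + y * y + z * z) / (2 * sigma ** 2))
    return vals / vals.sum()


def _cluster_from(tomo, mask):
    (cl,) = label_connected_clusters(SemanticMask(mask), Tomogram(tomo))
    return cl


def test_scale_bank_preserves_constant_fields():
    mask = np.ones((7, 7, 7), dtype=np.uint8)
    cl = _cluster_from(np.full((7, 7, 7), 0.4, dtype=np.float32), mask)
    bank = build_scale_bank(cl)
    assert len(bank.volumes) == 10
    for vol in bank.volumes:
        np.testing.assert_allclose(vol, 0.4, rtol=1e-6)


def test_impulse_response_equals_renormalized_gaussian():
    tomo = np.zeros((5, 5, 5), dtype=np.float32)
    tomo[2, 2, 2] = 1.0
    mask = np.ones((5, 5, 5), dtype=np.uint8)
    cl = _cluster_from(tomo, mask)
    bank = build_scale_bank(cl)
    np.testing.assert_allclose(
        bank.volumes[0][1:4, 1:4, 1:4], eq1_truncated_kernel(1.0), rtol=1e-6)


def test_impulse_peak_decreases_with_sigma():
    tomo = np.zeros((5, 5, 5), dtype=np.float32)
    tomo[2, 2, 2] = 1.0
    cl = _cluster_from(tomo, np.ones((5, 5, 5), dtype=np.uint8))
    peaks = [vol[2, 2, 2] for vol in build_scale_bank(cl).volumes]
    assert all(a > b for a, b in zip(peaks, peaks[1:]))


# ---------------------------------------------------------------- local maxima

def exhaustive_maxima(volume):
    """All voxels >= every in-grid 26-neighbour and > at least one."""
    out = []
    s = volume.shape
    for z in range(s[0]):
        for y in range(s[1]):
            for x in range(s[2]):
                v = volume[z, y, x]
                ge_all, gt_one = True, False
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if (dz, dy, dx) == (0, 0, 0):
                                continue
                            w = (z + dz, y + dy, x + dx)
                            if not all(0 <= w[i] < s[i] for i in range(3)):
                                continue
                            if volume[w] > v:
                                ge_all = False
                            if volume[w] < v:
                                gt_one = True
                if ge_all and gt_one:
                    out.append((z, y, x))
    return sorted(out)


def test_single_bump_yields_one_candidate():
    tomo, mask = make_sphere_volume([(10, 10, 10)], [5], [0.45], shape=(21, 21, 21))
    cl = _cluster_from(tomo.data, mask.data.astype(np.uint8))
    candidates = find_local_maxima(build_scale_bank(cl))
    assert len(candidates) == 1
    center, sigma = candidates[0]
    assert tuple(center) == tuple(10 - o for o in cl.offset) or sigma >= 1


def test_constant_volume_has_no_strict_maxima():
    cl = _cluster_from(np.full((6, 6, 6), 0.2, dtype=np.float32),
                       np.ones((6, 6, 6), dtype=np.uint8))
    assert find_local_maxima(build_scale_bank(cl)) == []


def test_two_bumps_yield_two_candidates():
    tomo, mask = make_sphere_volume([(8, 8, 8), (8, 8, 16)], [4, 4], [0.45, 0.45],
                                    shape=(17, 17, 25))
    cl = _cluster_from(tomo.data, mask.data.astype(np.uint8))
    candidates = find_local_maxima(build_scale_bank(cl))
    centers = {c for c, _ in candidates}
    apexes = {(8 - cl.offset[0], 8 - cl.offset[1], 8 - cl.offset[2]),
              (8 - cl.offset[0], 8 - cl.offset[1], 16 - cl.offset[2])}
    assert apexes <= centers


def test_maxima_match_exhaustive_oracle_per_scale(rng):
    volume = rng.random((7, 7, 7)).astype(np.float32)
    bank = ScaleBank(sigmas=(1,), volumes=[volume])
    found = [c for c, _ in find_local_maxima(bank)]
    assert found == exhaustive_maxima(volume)


def test_screen_by_mask_is_set_intersection(rng):
    mask = rng.random((6, 6, 6)) < 0.5
    cands = [(tuple(int(v) for v in rng.integers(0, 6, 3)), 1) for _ in range(40)]
    survivors = screen_by_mask(cands, mask)
    assert all(mask[c[0]] for c in survivors)
    assert {c[0] for c in cands if mask[c[0]]} == {c[0] for c in survivors}


# ---------------------------------------------------------------- overlap ratio

def brute_overlap_ratio(center, r, mask):
    vm = vs = 0
    reach = int(math.ceil(r)) + 1
    for dz in range(-reach, reach + 1):
        for dy in range(-reach, reach + 1):
            for dx in range(-reach, reach + 1):
                if dz * dz + dy * dy + dx * dx < r * r:
                    vs += 1
                    w = (center[0] + dz, center[1] + dy, center[2] + dx)
                    if all(0 <= w[i] < mask.shape[i] for i in range(3)) and mask[w]:
                        vm += 1
    return vm / vs


def test_overlap_ratio_inside_filled_mask_is_one():
    mask = np.ones((21, 21, 21), dtype=bool)
    assert overlap_ratio((10, 10, 10), 2.0, mask) == 1.0


def test_overlap_ratio_half_space_matches_brute_force():
    mask = np.zeros((21, 21, 21), dtype=bool)
    mask[:, :, :11] = True  # half space through the centre (x <= 10)
    got = overlap_ratio((10, 10, 10), 5.0, mask)
    expected = brute_overlap_ratio((10, 10, 10), 5.0, mask)
    assert got == pytest.approx(expected)
    assert 0.45 < got < 0.65


def test_overlap_ratio_single_voxel_mask():
    mask = np.zeros((11, 11, 11), dtype=bool)
    mask[5, 5, 5] = True
    assert overlap_ratio((5, 5, 5), 3.0, mask) == pytest.approx(1 / discrete_sphere_volume(3.0))


def test_discrete_ball_at_r_min_has_19_voxels():
    assert discrete_sphere_volume(1.5) == 19


def test_overlap_ratio_at_r_min_is_one_inside_mask():
    mask = np.ones((9, 9, 9), dtype=bool)
    assert overlap_ratio((4, 4, 4), 1.5, mask) == 1.0


# ---------------------------------------------------------------- radius

def test_radius_recovered_for_solid_sphere():
    tomo, mask = make_sphere_volume([(12, 12, 12)], [6], [0.45], shape=(25, 25, 25))
    cl = _cluster_from(tomo.data, mask.data.astype(np.uint8))
    center = tuple(12 - o for o in cl.offset)
    radius, profile = estimate_radius(center, cl)
    assert abs(radius - 6.0) <= 1.0
    for r, a in profile:
        assert a == pytest.approx(brute_overlap_ratio(center, r, cl.mask_crop))


def test_single_voxel_mask_returns_r_min():
    mask = np.zeros((9, 9, 9), dtype=np.uint8)
    mask[4, 4, 4] = 1
    cl = _cluster_from(np.zeros((9, 9, 9), dtype=np.float32), mask)
    center = tuple(4 - o for o in cl.offset)
    radius, _ = estimate_radius(center, cl)
    assert radius == PARAMS.r_min


def test_radius_stopping_rule():
    tomo, mask = make_sphere_volume([(12, 12, 12)], [6], [0.45], shape=(25, 25, 25))
    cl = _cluster_from(tomo.data, mask.data.astype(np.uint8))
    radius, profile = estimate_radius(tuple(12 - o for o in cl.offset), cl)
    ratios = dict(profile)
    assert ratios[radius] >= PARAMS.overlap_threshold
    next_r = radius + PARAMS.r_step
    if next_r in ratios:
        assert ratios[next_r] < PARAMS.overlap_threshold


# ---------------------------------------------------------------- greedy selection

def greedy_oracle(candidates, tomo):
    """Literal re-execution of the ranking + distance rule."""
    ranked = sorted(candidates, key=lambda c: (-tomo[c[0]], c[0]))
    chosen = []
    for center, radius, *_ in ranked:
        if all(math.dist(center, c2) > r2 for c2, r2, *_ in chosen):
            chosen.append((center, radius))
    return [c for c, _ in chosen]


def test_separated_candidates_are_both_selected(rng):
    tomo = rng.random((20, 20, 20)).astype(np.float32)
    cands = [((5, 5, 5), 3.0, 1, ()), ((5, 5, 15), 3.0, 1, ())]
    blobs = rank_and_select_blobs(cands, tomo)
    assert len(blobs) == 2


def test_near_candidate_is_rejected():
    tomo = np.zeros((10, 10, 10), dtype=np.float32)
    tomo[5, 5, 5] = 1.0
    tomo[5, 5, 7] = 0.5
    cands = [((5, 5, 5), 3.0, 1, ()), ((5, 5, 7), 2.0, 1, ())]
    blobs = rank_and_select_blobs(cands, tomo)
    assert [b.center for b in blobs] == [(5, 5, 5)]  # distance 2 <= radius 3


def test_greedy_matches_independent_oracle(rng):
    tomo = rng.random((20, 20, 20)).astype(np.float32)
    cands = []
    for _ in range(50):
        center = tuple(int(v) for v in rng.integers(0, 20, 3))
        cands.append((center, float(rng.uniform(1.5, 5)), 1, ()))
    blobs = rank_and_select_blobs(cands, tomo)
    assert [b.center for b in blobs] == greedy_oracle(cands, tomo)


# ---------------------------------------------------------------- recovery property

@pytest.mark.parametrize("k", [1, 3, 6])
def test_well_separated_spheres_recover_count_and_radii(k):
    radius = 4.0
    centers = [(10, 10, 10 + int(i * 5 * radius)) for i in range(k)]
    shape = (21, 21, 20 + int(k * 5 * radius))
    tomo, mask = make_sphere_volume(centers, [radius] * k, [0.45] * k, shape=shape)
    clusters = label_connected_clusters(mask, tomo)
    assert len(clusters) == k
    blobs = [b for cl in clusters for b in detect_blobs(cl)]
    assert len(blobs) == k
    for b in blobs:
        assert abs(b.radius - radius) <= 1.0
        assert mask.data[b.center]
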