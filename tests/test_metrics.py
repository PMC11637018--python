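"""Overlap/surface metrics vs brute-force oracles, plus the change report."""

import numpy as np
import pytest

from uamt3d.errors import EmptyMaskError
from uamt3d.seg_metrics import (CaseMetrics, MetricReport, asd, dsc, hd95,
                                jaccard, relative_change, surface_voxels)


# -- brute-force oracles -----------------------------------------------------

def surface_bf(mask):
    """Surface = mask voxel with a 6-neighbour background voxel (outside the
    array counts as background)."""
    mask = np.asarray(mask).astype(bool)
    out = []
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for idx in np.argwhere(mask):
        for d in offsets:
            n = idx + d
            if (n < 0).any() or (n >= mask.shape).any() or not mask[tuple(n)]:
                out.append(idx)
                break
    return np.array(out).reshape(-1, 3)


def pooled_bf(a, b, spacing):
    sa = surface_bf(a) * np.asarray(spacing)
    sb = surface_bf(b) * np.asarray(spacing)
    d_ab = [min(np.linalg.norm(p - q) for q in sb) for p in sa]
    d_ba = [min(np.linalg.norm(q - p) for p in sa) for q in sb]
    return np.array(d_ab + d_ba)


def random_nonempty_pair(rng, max_side=8):
    shape = tuple(rng.integers(3, max_side + 1, size=3))
    while True:
        a = rng.random(shape) < rng.uniform(0.1, 0.5)
        b = rng.random(shape) < rng.uniform(0.1, 0.5)
        if a.any() and b.any():
            return a, b


# -- overlap -----------------------------------------------------------------

def cube(shape=(12, 12, 12), lo=1, hi=11, shift=0):
    m = np.zeros(shape, dtype=bool)
    m[lo + shift:hi + shift, lo:hi, lo:hi] = True
    return m


def test_dsc_identity_disjoint_and_shifted_cube():
    a = cube()
    assert dsc(a, a) == 1.0
    b = np.zeros_like(a)
    b[0, 0, 0] = True
    assert dsc(a, b) == 0.0
    shifted = cube(shift=1)
    inter = int((a & shifted).sum())
    assert dsc(a, shifted) == pytest.approx(2 * inter / (a.sum() + shifted.sum()))
    assert dsc(a, shifted) == pytest.approx(0.9)


def test_jaccard_identity_disjoint_and_shifted_cube():
    a = cube()
    shifted = cube(shift=1)
    assert jaccard(a, a) == 1.0
    assert jaccard(a, ~a) == 0.0
    assert jaccard(a, shifted) == pytest.approx(900 / 1100)


def test_dsc_jaccard_algebraic_identity(rng):
    for _ in range(50):
        a, b = random_nonempty_pair(rng)
        j = jaccard(a, b)
        assert dsc(a, b) == pytest.approx(2 * j / (1 + j), abs=1e-9)


def test_both_empty_conventions():
    z = np.zeros((3, 3, 3), dtype=bool)
    assert dsc(z, z) == 1.0 and jaccard(z, z) == 1.0
    assert hd95(z, z) == 0.0 and asd(z, z) == 0.0


def test_empty_single_mask_raises():
    z = np.zeros((3, 3, 3), dtype=bool)
    m = z.copy()
    m[1, 1, 1] = True
    with pytest.raises(EmptyMaskError):
        hd95(m, z)
    with pytest.raises(EmptyMaskError):
        asd(z, m)


# -- surface distances -------------------------------------------------------

def test_two_point_masks_three_voxels_apart():
    a = np.zeros((8, 8, 8), dtype=bool)
    b = np.zeros_like(a)
    a[2, 2, 2] = True
    b[5, 2, 2] = True
    assert hd95(a, b) == pytest.approx(3.0)
    assert asd(a, b) == pytest.approx(3.0)


def test_identity_masks_have_zero_distance():
    a = cube()
    assert hd95(a, a) == 0.0 and asd(a, a) == 0.0


def test_spacing_scales_distances():
    a = np.zeros((8, 8, 8), dtype=bool)
    b = np.zeros_like(a)
    a[2, 2, 2] = True
    b[2, 2, 4] = True
    assert asd(a, b, spacing=(1, 1, 2.5)) == pytest.approx(5.0)


def test_surface_definition_matches_erosion_and_neighbour_oracle(rng):
    for _ in range(30):
        shape = tuple(rng.integers(3, 8, size=3))
        m = rng.random(shape) < 0.4
        ours = {tuple(r) for r in surface_voxels(m)}
        brute = {tuple(r) for r in surface_bf(m)}
        assert ours == brute


def test_distance_metrics_match_exhaustive_oracle(rng):
    for _ in range(60):
        a, b = random_nonempty_pair(rng)
        spacing = rng.uniform(0.5, 3.0, size=3)
        pooled = pooled_bf(a, b, spacing)
        assert hd95(a, b, spacing) == pytest.approx(
            np.percentile(pooled, 95), abs=1e-9)
        assert asd(a, b, spacing) == pytest.approx(pooled.mean(), abs=1e-9)


def test_hd95_bounded_by_full_hausdorff(rng):
    for _ in range(20):
        a, b = random_nonempty_pair(rng)
        pooled = pooled_bf(a, b, (1, 1, 1))
        assert hd95(a, b) <= pooled.max() + 1e-12


def test_metrics_symmetric_and_translation_invariant(rng):
    for _ in range(50):
        a, b = random_nonempty_pair(rng, max_side=6)
        assert dsc(a, b) == dsc(b, a)
        assert jaccard(a, b) == jaccard(b, a)
        assert hd95(a, b) == pytest.approx(hd95(b, a), abs=1e-12)
        assert asd(a, b) == pytest.approx(asd(b, a), abs=1e-12)
    a, b = random_nonempty_pair(rng, max_side=5)
    pad = ((2, 3), (1, 4), (3, 2))
    ap, bp = np.pad(a, pad), np.pad(b, pad)
    assert dsc(a, b) == dsc(ap, bp)
    assert hd95(a, b) == pytest.approx(hd95(ap, bp), abs=1e-12)
    assert asd(a, b) == pytest.approx(asd(ap, bp), abs=1e-12)


# -- relative change and reporting -------------------------------------------

def test_relative_change_examples():
    assert relative_change(0.75, 0.82) == pytest.approx(9.33, abs=5e-3)
    assert relative_change(27.74, 8.93) == pytest.approx(-67.81, abs=5e-3)
    assert relative_change(3.3, 3.3) == 0.0
    with pytest.raises(ValueError):
        relative_change(0.0, 1.0)


def test_report_aggregates_equal_hand_average():
    report = MetricReport(per_case=[
        CaseMetrics("a", 0.9, 0.8, 2.0, 1.0),
        CaseMetrics("b", 0.8, 0.7, 4.0, 2.0),
        CaseMetrics("c", 0.7, 0.6, None, None),  # missing distances skipped
    ])
    agg = report.aggregate()
    assert agg["dsc"]["mean"] == pytest.approx((0.9 + 0.8 + 0.7) / 3)
    assert agg["hd95"]["mean"] == pytest.approx(3.0)
    assert agg["hd95"]["n"] == 2
    assert agg["asd"]["sd"] == pytest.approx(0.5)
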