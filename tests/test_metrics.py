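"""Evaluation metrics against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cavityseg import (
    BinaryMask,
    MetricsResult,
    detection_outcome,
    dsc,
    hd95,
    mask_volume_ml,
    pvd,
    stratify_by_size,
    summarize_cohort,
)
from cavityseg.errors import ConsistencyError

AFF = np.eye(4)


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.asarray(data, np.uint8), np.diag(list(spacing) + [1.0]))


def _random_mask(rng, shape, p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)


# ---------------------------------------------------------------- oracles --

def dsc_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Set-arithmetic Dice on voxel coordinate sets."""
    sa = {tuple(idx) for idx in np.argwhere(a)}
    sb = {tuple(idx) for idx in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def _boundary_oracle(m: np.ndarray) -> list[tuple[int, int, int]]:
    """Foreground voxels with >=1 background 6-neighbor (edges = background)."""
    out = []
    for i, j, k in np.argwhere(m):
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            inside = 0 <= ni < m.shape[0] and 0 <= nj < m.shape[1] and 0 <= nk < m.shape[2]
            if not inside or not m[ni, nj, nk]:
                out.append((i, j, k))
                break
    return out


def hd95_oracle(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """All-pairs boundary-distance 95th percentiles, symmetric max."""
    pa = np.array(_boundary_oracle(a), float) * np.asarray(spacing)
    pb = np.array(_boundary_oracle(b), float) * np.asarray(spacing)
    dmat = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return float(max(
        np.percentile(dmat.min(axis=1), 95), np.percentile(dmat.min(axis=0), 95)
    ))


# ------------------------------------------------------------------- DSC --

class TestDSC:
    def test_identical_masks(self):
        rng = np.random.default_rng(0)
        m = _random_mask(rng, (6, 6, 6))
        m[0, 0, 0] = 1
        assert dsc(_mask(m), _mask(m)) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4)); a[0, 0, 0] = 1
        b = np.zeros((4, 4, 4)); b[3, 3, 3] = 1
        assert dsc(_mask(a), _mask(b)) == 0.0

    def test_shifted_cube_half_overlap(self):
        a = np.zeros((20, 20, 20)); a[0:10, 0:10, 0:10] = 1
        b = np.zeros((20, 20, 20)); b[5:15, 0:10, 0:10] = 1
        assert dsc(_mask(a), _mask(b)) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3))
        assert dsc(_mask(z), _mask(z)) == 1.0
        one = z.copy(); one[1, 1, 1] = 1
        assert dsc(_mask(z), _mask(one)) == 0.0

    def test_matches_set_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = _random_mask(rng, (4, 4, 4), p=rng.random())
            b = _random_mask(rng, (4, 4, 4), p=rng.random())
            assert dsc(_mask(a), _mask(b)) == pytest.approx(
                dsc_oracle(a, b), rel=1e-9, abs=1e-12
            )

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            dsc(_mask(np.zeros((3, 3, 3))), _mask(np.zeros((4, 4, 4))))

    @given(st.integers(0, 2**27 - 1))
    def test_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _random_mask(rng, (5, 5, 5)), _random_mask(rng, (5, 5, 5))
        assert dsc(_mask(a), _mask(b)) == dsc(_mask(b), _mask(a))


# ------------------------------------------------------------------ HD95 --

class TestHD95:
    def test_equal_masks_zero(self):
        rng = np.random.default_rng(1)
        m = _random_mask(rng, (8, 8, 8)); m[4, 4, 4] = 1
        assert hd95(_mask(m), _mask(m)) == 0.0

    def test_single_voxels_three_apart(self):
        a = np.zeros((10, 10, 10)); a[2, 2, 2] = 1
        b = np.zeros((10, 10, 10)); b[2, 5, 2] = 1
        assert hd95(_mask(a), _mask(b)) == pytest.approx(3.0)

    def test_anisotropic_spacing(self):
        a = np.zeros((6, 6, 6)); a[2, 2, 2] = 1
        b = np.zeros((6, 6, 6)); b[2, 2, 3] = 1
        sp = (1.0, 1.0, 3.0)
        assert hd95(_mask(a, sp), _mask(b, sp)) == pytest.approx(3.0)

    def test_empty_mask_gives_nan_with_warning(self):
        z = np.zeros((4, 4, 4))
        m = z.copy(); m[1, 1, 1] = 1
        with pytest.warns(UserWarning, match="empty"):
            assert np.isnan(hd95(_mask(z), _mask(m)))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            shape = tuple(rng.integers(4, 13, size=3))
            spacing = rng.choice([1.0, 1.0, 2.0, 0.5], size=3)
            a = _random_mask(rng, shape, p=0.2)
            b = _random_mask(rng, shape, p=0.2)
            if not a.any() or not b.any():
                continue
            got = hd95(_mask(a, spacing), _mask(b, spacing))
            want = hd95_oracle(a, b, spacing)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_monotone_under_increasing_shift(self):
        base = np.zeros((30, 10, 10)); base[4:8, 4:8, 4:8] = 1
        prev = -1.0
        for shift in range(0, 5):
            shifted = np.roll(base, shift, axis=0)
            d = hd95(_mask(base), _mask(shifted))
            assert d >= prev
            prev = d

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        a = np.zeros((12, 12, 12)); a[3:6, 3:6, 3:6] = _random_mask(rng, (3, 3, 3), 0.6)
        b = np.zeros((12, 12, 12)); b[4:7, 3:6, 3:6] = _random_mask(rng, (3, 3, 3), 0.6)
        if not a.any() or not b.any():
            pytest.skip("degenerate draw")
        d0 = hd95(_mask(a), _mask(b))
        ta, tb = np.roll(a, 3, axis=2), np.roll(b, 3, axis=2)
        assert hd95(_mask(ta), _mask(tb)) == pytest.approx(d0)

    @given(st.integers(0, 2**27 - 1))
    def test_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _random_mask(rng, (6, 6, 6)), _random_mask(rng, (6, 6, 6))
        if not a.any() or not b.any():
            return
        assert hd95(_mask(a), _mask(b)) == pytest.approx(hd95(_mask(b), _mask(a)))


# --------------------------------------------------- volumes / PVD / det --

class TestVolumesAndPVD:
    @pytest.mark.parametrize(
        "n_vox,spacing,expected",
        [(1000, (1, 1, 1), 1.0), (500, (1, 1, 1), 0.5), (100, (2, 2, 2), 0.8)],
    )
    def test_mask_volume(self, n_vox, spacing, expected):
        data = np.zeros((20, 20, 20), np.uint8)
        data.ravel()[:n_vox] = 1
        assert mask_volume_ml(_mask(data, spacing)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "pred,true,expected", [(100.0, 100.0, 0.0), (75.0, 100.0, 25.0), (0.0, 10.0, 100.0)]
    )
    def test_pvd(self, pred, true, expected):
        assert pvd(pred, true) == pytest.approx(expected)

    def test_pvd_zero_truth_is_nan(self):
        assert np.isnan(pvd(1.0, 0.0))


class TestDetectionOutcome:
    def test_one_voxel_overlap_is_true_positive(self):
        t = np.zeros((6, 6, 6)); t[1:4, 1:4, 1:4] = 1
        p = np.zeros((6, 6, 6)); p[3, 3, 3] = 1
        assert detection_outcome(_mask(p), _mask(t)) == "true_positive"

    def test_no_overlap_is_false_negative(self):
        t = np.zeros((6, 6, 6)); t[0, 0, 0] = 1
        p = np.zeros((6, 6, 6)); p[5, 5, 5] = 1
        assert detection_outcome(_mask(p), _mask(t)) == "false_negative"

    def test_control_outcomes(self):
        empty = _mask(np.zeros((4, 4, 4)))
        assert detection_outcome(empty, None) == "true_negative"
        nonempty = np.zeros((4, 4, 4)); nonempty[0, 0, 0] = 1
        assert detection_outcome(_mask(nonempty), None) == "false_positive"


# ------------------------------------------------------ cohort summaries --

def _res(sid, d, h, vt, vp, outcome="true_positive"):
    return MetricsResult(sid, d, h, vt, vp, pvd(vp, vt), outcome)


class TestSummaries:
    def test_perfect_volumes_give_r1_mae0(self):
        results = [_res(f"s{i}", 0.9, 1.0, v, v) for i, v in enumerate((5.0, 10.0, 20.0))]
        s = summarize_cohort(results)
        assert s.volume_pearson_r == pytest.approx(1.0)
        assert s.volume_mae_ml == 0.0

    def test_median_and_iqr(self):
        results = [_res("a", 0.8, 2.0, 5, 5), _res("b", 0.9, 4.0, 9, 10)]
        s = summarize_cohort(results)
        assert s.dsc_median == pytest.approx(0.85)
        assert s.n == 2

    def test_nan_hd95_excluded_and_counted(self):
        results = [_res("a", 0.8, np.nan, 5, 5), _res("b", 0.9, 4.0, 9, 10)]
        s = summarize_cohort(results)
        assert s.hd95_n_excluded == 1
        assert s.hd95_median == pytest.approx(4.0)

    def test_fn_fp_counts(self):
        results = [
            _res("a", 0.0, np.nan, 5, 1, "false_negative"),
            _res("b", 1.0, 0.0, 0, 1, "false_positive"),
        ]
        s = summarize_cohort(results)
        assert (s.fn_count, s.fp_count) == (1, 1)


class TestStratify:
    def test_threshold_partition(self):
        results = [_res("small", 0.8, 2.0, 4.19, 4.0), _res("large", 0.9, 2.0, 33.5, 33.0)]
        table, _ = stratify_by_size(results)
        assert table.loc["small", "n"] == 1
        assert table.loc["large", "n"] == 1

    def test_empty_group_gives_nan_comparisons(self):
        results = [_res(f"s{i}", 0.8, 2.0, 5.0 + i, 5.0) for i in range(4)]
        table, comp = stratify_by_size(results)
        assert table.loc["large", "n"] == 0
        assert np.isnan(comp["dsc"][0])

    def test_identical_groups_show_no_difference(self):
        results = [
            _res(f"a{i}", 0.8, 2.0, 10.0 + 0.1 * i, 9.0) for i in range(5)
        ] + [
            _res(f"b{i}", 0.8, 2.0, 30.0 + 0.1 * i, 29.0) for i in range(5)
        ]
        _, comp = stratify_by_size(results)
        t, p = comp["dsc"]
        assert abs(t) < 1e-9 or np.isnan(t)
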