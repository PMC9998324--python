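"""Agreement metrics and statistics against independent oracles."""

import numpy as np
import pytest

from cinetfc.agreement import (bland_altman, cohens_kappa, dice3d,
                               hausdorff3d, mcnemar, pearson,
                               phase_difference, sens_spec)


# ----------------------------------------------------------------------- dice
class TestDice:
    def test_closed_form_examples(self):
        a = np.zeros((2, 4, 4), dtype=int)
        b = np.zeros((2, 4, 4), dtype=int)
        assert dice3d(a, b) == 1.0  # both empty: agreement on absence
        a[0, 0, 0] = 1
        assert dice3d(a, b, 1) == 0.0
        a[0, 0, 1] = 1
        b[0, 0, 1] = b[0, 0, 2] = 1
        assert dice3d(a, b, 1) == pytest.approx(0.5)  # |A|=|B|=2, overlap 1

    def test_symmetry(self, rng):
        a = rng.integers(0, 3, size=(3, 8, 8))
        b = rng.integers(0, 3, size=(3, 8, 8))
        for s in (1, 2):
            assert dice3d(a, b, s) == dice3d(b, a, s)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice3d(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


# ------------------------------------------------------------------ hausdorff
def _brute_hausdorff(ma, mb, spacing):
    """All-pairs distance oracle over boundary voxels."""
    from scipy import ndimage

    def boundary_pts(m):
        er = ndimage.binary_erosion(m, ndimage.generate_binary_structure(3, 1))
        return np.argwhere(m & ~er) * np.asarray(spacing)

    pa, pb = boundary_pts(ma), boundary_pts(mb)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        m = rng.random((3, 6, 6)) > 0.6
        m[0, 0, 0] = True
        assert hausdorff3d(m.astype(int), m.astype(int)) == 0.0

    def test_single_voxel_slice_distance(self):
        a = np.zeros((6, 5, 5), dtype=int)
        b = np.zeros((6, 5, 5), dtype=int)
        a[1, 2, 2] = 1
        b[4, 2, 2] = 1
        assert hausdorff3d(a, b, 1, spacing=(8.0, 1.0, 1.0)) == pytest.approx(24.0)

    def test_empty_mask_raises(self):
        a = np.zeros((2, 2, 2), dtype=int)
        b = a.copy()
        b[0, 0, 0] = 1
        with pytest.raises(ValueError):
            hausdorff3d(a, b)

    def test_matches_brute_force_oracle(self, rng):
        spacing = (8.0, 1.5, 1.5)
        for _ in range(10):
            a = rng.random((4, 10, 10)) > 0.8
            b = rng.random((4, 10, 10)) > 0.8
            if not (a.any() and b.any()):
                continue
            got = hausdorff3d(a.astype(int), b.astype(int), 1, spacing)
            assert got == pytest.approx(_brute_hausdorff(a, b, spacing))

    def test_symmetric_in_arguments(self, rng):
        a = rng.random((3, 8, 8)) > 0.7
        b = rng.random((3, 8, 8)) > 0.7
        a[0, 0, 0] = b[0, 0, 0] = True
        sp = (8.0, 1.0, 1.0)
        assert hausdorff3d(a.astype(int), b.astype(int), 1, sp) == \
            hausdorff3d(b.astype(int), a.astype(int), 1, sp)


# ----------------------------------------------------------- phase difference
class TestPhaseDifference:
    @pytest.mark.parametrize("auto,manual,n,expected", [
        (12, 10, 25, 8.0),
        (24, 0, 25, -4.0),   # wraps across the cycle boundary
        (0, 24, 25, 4.0),
        (7, 7, 30, 0.0),
    ])
    def test_signed_circular_difference(self, auto, manual, n, expected):
        assert phase_difference(auto, manual, n) == pytest.approx(expected)

    def test_zero_for_equal_phases(self):
        for n in (2, 13, 40):
            for k in range(n):
                assert phase_difference(k, k, n) == 0.0

    def test_short_cycle_rejected(self):
        with pytest.raises(ValueError):
            phase_difference(0, 0, 1)


# --------------------------------------------------------------- Bland–Altman
class TestBlandAltman:
    def test_identical_series(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.bias == 0 and ba.loa_low == 0 and ba.loa_high == 0

    def test_closed_form_two_points(self):
        ba = bland_altman([1.0, -1.0], [0.0, 0.0])
        assert ba.bias == 0
        assert ba.sd_diff == pytest.approx(np.sqrt(2))
        assert ba.loa_high == pytest.approx(1.96 * np.sqrt(2))

    def test_matches_textbook_formula(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        ba = bland_altman(x, y)
        d = x - y
        assert ba.bias == pytest.approx(d.mean())
        assert ba.sd_diff == pytest.approx(d.std(ddof=1))
        assert ba.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


# -------------------------------------------------------------------- Pearson
class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_closed_form_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # manual product-moment computation
        r_manual = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        r, (lo, hi) = pearson(x, y)
        assert r == pytest.approx(r_manual)
        assert lo < r < hi

    def test_fisher_ci_narrows_with_n(self, rng):
        x = rng.normal(size=200)
        y = x + rng.normal(size=200)
        _, (lo_l, hi_l) = pearson(x, y)
        _, (lo_s, hi_s) = pearson(x[:20], y[:20])
        assert (hi_l - lo_l) < (hi_s - lo_s)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------- kappa
class TestKappa:
    def test_perfect_agreement(self):
        k, se = cohens_kappa(["none", "minor", "major"] * 5,
                             ["none", "minor", "major"] * 5)
        assert k == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        a = ["x"] * 45 + ["y"] * 5 + ["x"] * 5 + ["y"] * 45
        b = ["x"] * 45 + ["x"] * 5 + ["y"] * 5 + ["y"] * 45
        k, se = cohens_kappa(a, b)
        assert k == pytest.approx(0.8)  # p_o=0.9, p_e=0.5
        assert se == pytest.approx(np.sqrt(0.9 * 0.1 / (100 * 0.25)))

    def test_independent_labels_near_zero(self, rng):
        a = rng.integers(0, 3, size=4000)
        b = rng.integers(0, 3, size=4000)
        k, _ = cohens_kappa(a, b)
        assert abs(k) < 0.05

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 3, size=100)
        b = (a + (rng.random(100) < 0.3) * rng.integers(1, 3, size=100)) % 3
        k, _ = cohens_kappa(a, b)
        assert k == pytest.approx(cohen_kappa_score(a, b))

    def test_invariant_under_relabeling(self, rng):
        a = rng.integers(0, 3, size=60)
        b = rng.integers(0, 3, size=60)
        relabel = np.array([2, 0, 1])
        assert cohens_kappa(a, b)[0] == pytest.approx(
            cohens_kappa(relabel[a], relabel[b])[0])

    def test_single_category_warns(self):
        with pytest.warns(UserWarning, match="single category"):
            k, se = cohens_kappa(["none"] * 10, ["none"] * 10)
        assert k == 1.0


# ------------------------------------------------------ diagnostic performance
class TestSensSpec:
    def test_perfect_and_inverted(self):
        cond = np.array([True] * 5 + [False] * 5)
        assert sens_spec(cond, cond) == (1.0, 1.0)
        assert sens_spec(~cond, cond) == (0.0, 0.0)

    def test_matches_contingency_oracle(self, rng):
        test = rng.random(200) < 0.4
        cond = rng.random(200) < 0.3
        sens, spec = sens_spec(test, cond)
        tp = np.sum(test & cond); fn = np.sum(~test & cond)
        tn = np.sum(~test & ~cond); fp = np.sum(test & ~cond)
        assert sens == pytest.approx(tp / (tp + fn))
        assert spec == pytest.approx(tn / (tn + fp))

    def test_undefined_metric_is_nan(self):
        sens, spec = sens_spec([True, False], [False, False])
        assert np.isnan(sens) and spec == 0.5


class TestMcNemar:
    def test_identical_series(self):
        a = [True, False, True, False]
        assert mcnemar(a, a) == 1.0

    def test_symmetric_discordance_near_one(self):
        a = [True] * 10 + [False] * 10 + [True] * 30
        b = [False] * 10 + [True] * 10 + [True] * 30
        assert mcnemar(a, b) == pytest.approx(1.0, abs=0.05)

    def test_exact_binomial_oracle(self):
        """Discordant pairs (2, 8): p = 2·P(X ≤ 2 | Bin(10, ½))."""
        from scipy import stats

        a = [True] * 2 + [False] * 8 + [True] * 15
        b = [False] * 2 + [True] * 8 + [True] * 15
        assert mcnemar(a, b) == pytest.approx(stats.binomtest(2, 10, 0.5).pvalue)
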