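import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromapop.luminance import (
    auc_permutation_test,
    circular_align,
    compare_population_correlations,
    peak_correlation_bootstrap,
    peak_shift_bin_test,
    roc_auc,
)


class TestRocAuc:
    def test_identical_multisets_give_chance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert roc_auc(x, x) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3], [4, 5, 6]) == pytest.approx(1.0)

    def test_worked_pair_counting_example(self):
        assert roc_auc([1.0, 2.0], [1.5, 3.0]) == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            wins = sum((bj > ai) + 0.5 * (bj == ai) for ai in a for bj in b)
            assert roc_auc(a, b) == pytest.approx(wins / 100.0)

    def test_reversal_identity_without_ties(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=8), rng.normal(size=9)
        assert roc_auc(a, b) + roc_auc(b, a) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30)
    @given(shift=st.floats(-3, 3), scale=st.floats(0.1, 5))
    def test_monotone_transform_invariance(self, shift, scale):
        rng = np.random.default_rng(14)
        a, b = rng.normal(size=12), rng.normal(size=12)
        f = lambda x: np.exp(scale * x) + shift  # noqa: E731
        assert roc_auc(f(a), f(b)) == pytest.approx(roc_auc(a, b))

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])


class TestAucPermutation:
    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 45)
        b = rng.normal(5, 1, 45)
        auc, p, (lo, hi) = auc_permutation_test(a, b, n_perm=500, seed=3)
        assert auc > hi and p < 0.05

    def test_fixed_seed_reproducible_band(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=45), rng.normal(size=45)
        r1 = auc_permutation_test(a, b, n_perm=300, seed=9)
        r2 = auc_permutation_test(a, b, n_perm=300, seed=9)
        assert r1 == r2


class TestCircularAlign:
    @pytest.mark.parametrize("ref, other, expected", [
        (10.0, 355.0, -5.0),   # worked example: plotted at (10, -5)
        (10.0, 10.0, 10.0),
        (350.0, 5.0, 365.0),
    ])
    def test_examples(self, ref, other, expected):
        assert circular_align(ref, other) == pytest.approx(expected)

    @settings(deadline=None, max_examples=100)
    @given(ref=st.floats(0, 359.999), other=st.floats(0, 359.999))
    def test_result_within_half_turn_of_reference(self, ref, other):
        aligned = circular_align(ref, other)
        assert abs(aligned - ref) <= 180.0
        assert (aligned - other) % 360.0 == pytest.approx(0.0, abs=1e-6) or \
            (other - aligned) % 360.0 == pytest.approx(0.0, abs=1e-6)


class TestPeakCorrelationBootstrap:
    def test_identical_peaks_give_unit_correlation(self):
        rng = np.random.default_rng(5)
        peaks = rng.uniform(0, 360, 60)
        with pytest.warns(UserWarning):
            r, z = peak_correlation_bootstrap(peaks, peaks, n_boot=20, seed=1)
        assert np.allclose(r, 1.0)
        assert np.all(np.isfinite(z))

    def test_independent_peaks_match_alignment_null(self):
        # Aligning each peak to within a half turn of its reference
        # induces a baseline correlation even for independent peaks:
        # cov(a, a+u) = var(a) with u ~ U(-180, 180], so r -> 1/sqrt(2).
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 360, 400)
        b = rng.uniform(0, 360, 400)
        r, _ = peak_correlation_bootstrap(a, b, n_boot=100, seed=2)
        assert np.mean(r) == pytest.approx(1 / np.sqrt(2), abs=0.1)

    def test_smaller_jitter_gives_larger_correlation(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 360, 200)
        r10, _ = peak_correlation_bootstrap(
            base, (base + rng.normal(0, 10, 200)) % 360, n_boot=50, seed=3)
        r40, _ = peak_correlation_bootstrap(
            base, (base + rng.normal(0, 40, 200)) % 360, n_boot=50, seed=3)
        assert np.mean(r10) > np.mean(r40)


class TestComparePopulationCorrelations:
    def test_identical_populations_not_significant(self):
        # the bootstrap-then-t procedure is null-calibrated only when the
        # two populations are the same data (bootstrap draws then share
        # one underlying distribution)
        rng = np.random.default_rng(8)
        base = rng.uniform(0, 360, 100)
        jit = (base + rng.normal(0, 15, 100)) % 360
        p, _ = compare_population_correlations(base, jit, base, jit,
                                               reps=31, n_boot=60, seed=4)
        assert p > 0.05

    def test_planted_jitter_difference_detected(self):
        rng = np.random.default_rng(9)
        base1 = rng.uniform(0, 360, 100)
        base2 = rng.uniform(0, 360, 100)
        tight = (base1 + rng.normal(0, 5, 100)) % 360
        loose = (base2 + rng.normal(0, 35, 100)) % 360
        p, ci = compare_population_correlations(base1, tight, base2, loose,
                                                reps=30, n_boot=60, seed=5)
        assert p < 0.01
        assert ci[0] <= p <= ci[1]

    def test_single_rep_deterministic(self):
        rng = np.random.default_rng(10)
        a, b = rng.uniform(0, 360, 50), rng.uniform(0, 360, 50)
        r1 = compare_population_correlations(a, b, a, b, reps=1, n_boot=30,
                                             seed=6)
        r2 = compare_population_correlations(a, b, a, b, reps=1, n_boot=30,
                                             seed=6)
        assert r1 == r2


class TestPeakShiftBins:
    def test_no_shift_no_significant_bins(self):
        rng = np.random.default_rng(11)
        peaks = rng.uniform(0, 360, 160)
        res = peak_shift_bin_test(peaks, peaks.copy(), n_boot=100, seed=1)
        assert res and all(v[0] > 0.05 for v in res.values())

    def test_shift_planted_in_single_bin_detected(self):
        rng = np.random.default_rng(12)
        # 40 cells per bin, jitter SD 5, +20 degrees planted in bin [45, 90)
        bright = np.concatenate([
            rng.uniform(lo, lo + 45, 40) for lo in range(0, 360, 45)
        ])
        dark = (bright + rng.normal(0, 5, bright.size)) % 360
        in_bin = (bright >= 45) & (bright < 90)
        dark[in_bin] = (dark[in_bin] + 20.0) % 360
        res = peak_shift_bin_test(bright, dark, n_boot=200, seed=2)
        assert res[1][0] < 0.05
        for b, v in res.items():
            if b != 1:
                assert v[0] > 0.05

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(13)
        bright = rng.uniform(0, 360, 80)
        dark = (bright + rng.normal(0, 10, 80)) % 360
        r1 = peak_shift_bin_test(bright, dark, n_boot=50, seed=3)
        r2 = peak_shift_bin_test(bright, dark, n_boot=50, seed=3)
        assert r1 == r2

    def test_sparse_bin_skipped_with_warning(self):
        bright = np.array([10.0, 12.0, 100.0, 110.0, 120.0, 130.0])
        dark = bright.copy()
        with pytest.warns(UserWarning, match="skipped"):
            res = peak_shift_bin_test(bright, dark, n_boot=20, seed=4)
        assert 0 not in res
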