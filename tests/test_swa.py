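"""Per-wavelength t-tests, binarization, matrix assembly, persistence, plots."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from conftest import make_group
from ftirswa import (
    SWAParams,
    Spectrum,
    binarize_pvalues,
    persistent_significant,
    render_swa_plot,
    run_swa,
    smooth_moving_average,
    ttest_per_wavelength,
)
from ftirswa.errors import ConfigError, GridMismatchError, ReplicateCountError


def pooled_t_pvalue_oracle(a, b):
    """Closed-form pooled two-sample t p-value via the incomplete beta."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return special.betainc(df / 2.0, 0.5, df / (df + t * t))


GRID3 = np.array([600.0, 602.0, 604.0])


class TestTTest:
    def test_self_comparison_gives_p_one_everywhere(self, rng, small_grid):
        rows = rng.standard_normal((3, small_grid.size))
        a = make_group("a", rows, small_grid)
        b = make_group("b", rows.copy(), small_grid)
        assert np.allclose(ttest_per_wavelength(a, b), 1.0)

    def test_textbook_example_123_vs_456(self):
        # pooled t = -3.674, df = 4, two-sided p = 0.021312 (incomplete beta)
        a = make_group("a", np.array([[1.0], [2.0], [3.0]]).repeat(2, 1), GRID3[:2])
        b = make_group("b", np.array([[4.0], [5.0], [6.0]]).repeat(2, 1), GRID3[:2])
        p = ttest_per_wavelength(a, b)
        assert p == pytest.approx(0.021311641128756713, abs=1e-12)

    def test_zero_variance_equal_means_gives_p_one(self, small_grid):
        rows = np.full((3, small_grid.size), 5.0)
        a = make_group("a", rows, small_grid)
        b = make_group("b", rows.copy(), small_grid)
        assert np.all(ttest_per_wavelength(a, b) == 1.0)

    def test_zero_variance_unequal_means_gives_p_zero(self, small_grid):
        a = make_group("a", np.full((3, small_grid.size), 5.0), small_grid)
        b = make_group("b", np.full((3, small_grid.size), 6.0), small_grid)
        assert np.all(ttest_per_wavelength(a, b) == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_closed_form_oracle_on_random_3v3(self, seed, small_grid):
        r = np.random.default_rng(seed)
        A = r.standard_normal((3, small_grid.size))
        B = r.standard_normal((3, small_grid.size)) + 0.5
        p = ttest_per_wavelength(make_group("a", A, small_grid), make_group("b", B, small_grid))
        expected = [pooled_t_pvalue_oracle(A[:, j], B[:, j]) for j in range(small_grid.size)]
        assert np.allclose(p, expected, atol=1e-10)

    def test_symmetric_in_group_order(self, rng, small_grid):
        A = rng.standard_normal((3, small_grid.size))
        B = rng.standard_normal((4, small_grid.size))
        ga, gb = make_group("a", A, small_grid), make_group("b", B, small_grid)
        assert np.allclose(ttest_per_wavelength(ga, gb), ttest_per_wavelength(gb, ga))

    def test_replicate_minimum_enforced(self, rng, small_grid):
        a = make_group("a", rng.standard_normal((2, small_grid.size)), small_grid)
        b = make_group("b", rng.standard_normal((3, small_grid.size)), small_grid)
        with pytest.raises(ReplicateCountError):
            ttest_per_wavelength(a, b)

    def test_grid_mismatch_rejected(self, rng):
        a = make_group("a", rng.standard_normal((3, 5)), np.arange(600.0, 610, 2))
        b = make_group("b", rng.standard_normal((3, 5)), np.arange(700.0, 710, 2))
        with pytest.raises(GridMismatchError):
            ttest_per_wavelength(a, b)

    def test_welch_agrees_with_pooled_at_equal_n_equal_variance_scale(self, rng, small_grid):
        A = rng.standard_normal((3, small_grid.size))
        B = rng.standard_normal((3, small_grid.size))
        ga, gb = make_group("a", A, small_grid), make_group("b", B, small_grid)
        p_pooled = ttest_per_wavelength(ga, gb)
        p_welch = ttest_per_wavelength(ga, gb, welch=True)
        # same t statistic at equal n; Welch df <= pooled df, so p_welch >= p_pooled
        assert np.all(p_welch >= p_pooled - 1e-12)


class TestSmoothing:
    def test_window_one_is_identity(self, rng, small_grid):
        s = Spectrum(small_grid, rng.standard_normal(small_grid.size))
        assert smooth_moving_average(s, 1) is s

    def test_constant_spectrum_unchanged(self, small_grid):
        s = Spectrum(small_grid, np.full(small_grid.size, 3.5))
        for w in (2, 5, 10):
            assert np.allclose(smooth_moving_average(s, w).absorbance, 3.5)

    def test_window_larger_than_spectrum_truncates_per_point(self):
        s = Spectrum(np.arange(600.0, 610.0, 2.0), [0.0, 0.0, 10.0, 0.0, 0.0])
        out = smooth_moving_average(s, 10)
        assert np.allclose(out.absorbance, 2.0)  # every window sees all 5 points

    @pytest.mark.parametrize("window", [2, 3, 4, 7, 10])
    def test_matches_brute_force_windowed_mean(self, rng, small_grid, window):
        y = rng.standard_normal(small_grid.size)
        out = smooth_moving_average(Spectrum(small_grid, y), window).absorbance
        half_lo, half_hi = (window - 1) // 2, window // 2
        expected = [
            y[max(0, i - half_lo): i + half_hi + 1].mean() for i in range(y.size)
        ]
        assert np.allclose(out, expected, atol=1e-12)

    def test_grid_unchanged(self, rng, small_grid):
        s = Spectrum(small_grid, rng.standard_normal(small_grid.size))
        assert np.array_equal(smooth_moving_average(s, 10).wavenumbers, small_grid)


class TestBinarize:
    def test_threshold_arithmetic(self):
        assert binarize_pvalues([0.005, 0.05, 0.5], 0.01).tolist() == [1, 0, 0]

    def test_all_ones_give_all_zeros(self):
        assert binarize_pvalues(np.ones(7), 0.01).sum() == 0

    def test_p_exactly_alpha_maps_to_zero(self):
        assert binarize_pvalues([0.01], 0.01).tolist() == [0]

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            binarize_pvalues([0.5, 1.2], 0.01)


class TestRunSwa:
    @staticmethod
    def _groups(n_conditions, rng, grid, shift=0.0):
        return [
            make_group(f"c{i}", rng.standard_normal((3, grid.size)) + i * shift, grid)
            for i in range(n_conditions)
        ]

    @pytest.mark.parametrize("n", range(2, 11))
    def test_comparison_count_laws(self, n, rng, small_grid):
        groups = self._groups(n, rng, small_grid)
        all_pairs = run_swa(groups, SWAParams(mode="all_pairs", smoothing_window=1))
        assert len(all_pairs.comparisons) == (n * n - n) // 2
        vs = run_swa(
            groups,
            SWAParams(mode="vs_control", control_condition="c0", smoothing_window=1),
        )
        assert len(vs.comparisons) == n - 1

    def test_comparisons_ordered_lexicographically(self, rng, small_grid):
        groups = self._groups(3, rng, small_grid)[::-1]  # shuffle input order
        res = run_swa(groups, SWAParams(smoothing_window=1))
        assert res.comparisons == [("c0", "c1"), ("c0", "c2"), ("c1", "c2")]

    def test_percent_matrix_symmetric_zero_diagonal_bounded(self, rng, small_grid):
        groups = self._groups(4, rng, small_grid, shift=1.0)
        res = run_swa(groups, SWAParams(smoothing_window=1))
        m = res.percent_matrix.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)
        assert np.all((m >= 0) & (m <= 100))

    def test_percent_matrix_entry_is_count_over_total(self, rng, small_grid):
        groups = self._groups(2, rng, small_grid, shift=3.0)
        res = run_swa(groups, SWAParams(smoothing_window=1))
        expected = 100.0 * res.significant[0].sum() / small_grid.size
        assert res.percent_matrix.loc["c0", "c1"] == pytest.approx(expected)

    def test_vs_control_fills_only_control_row_and_column(self, rng, small_grid):
        groups = self._groups(4, rng, small_grid)
        res = run_swa(
            groups, SWAParams(mode="vs_control", control_condition="c0", smoothing_window=1)
        )
        m = res.percent_matrix
        assert m.loc["c1", "c2"] != m.loc["c1", "c2"]  # NaN: untested pair
        assert np.isfinite(m.loc["c0"]).all() and np.isfinite(m["c0"]).all()

    def test_missing_control_rejected(self, rng, small_grid):
        groups = self._groups(3, rng, small_grid)
        with pytest.raises(ConfigError):
            run_swa(groups, SWAParams(mode="vs_control", control_condition="nope"))

    def test_fewer_than_two_groups_rejected(self, rng, small_grid):
        with pytest.raises(ConfigError):
            run_swa(self._groups(1, rng, small_grid))

    def test_significant_iff_p_below_alpha(self, rng, small_grid):
        groups = self._groups(3, rng, small_grid, shift=0.8)
        res = run_swa(groups, SWAParams(smoothing_window=1))
        assert np.array_equal(res.significant, (res.pvalues < res.alpha).astype(int))

    def test_smoothing_is_applied_to_absorbance_before_testing(self, rng, small_grid):
        groups = self._groups(2, rng, small_grid, shift=1.0)
        raw = run_swa(groups, SWAParams(smoothing_window=1))
        smoothed = run_swa(groups, SWAParams(smoothing_window=10))
        expected = [
            make_group(g.condition, np.vstack([
                smooth_moving_average(s, 10).absorbance for s in g.spectra
            ]), small_grid)
            for g in groups
        ]
        direct = ttest_per_wavelength(expected[0], expected[1])
        assert np.allclose(smoothed.pvalues[0], direct, atol=1e-12)
        assert not np.allclose(smoothed.pvalues, raw.pvalues)

    def test_bh_correction_never_adds_significance(self, rng, small_grid):
        groups = self._groups(2, rng, small_grid, shift=0.7)
        plain = run_swa(groups, SWAParams(smoothing_window=1))
        bh = run_swa(groups, SWAParams(smoothing_window=1, correction="bh"))
        assert np.all(bh.significant <= plain.significant)


class TestPersistence:
    def test_single_vector_is_identity(self):
        v = np.array([1, 0, 1, 1])
        mask, count = persistent_significant([v])
        assert np.array_equal(mask, v) and count == 3

    def test_elementwise_and(self):
        mask, count = persistent_significant(
            [np.array([1, 1, 0]), np.array([1, 0, 0])]
        )
        assert mask.tolist() == [1, 0, 0] and count == 1

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6))
    def test_matches_set_intersection_oracle(self, seed, k):
        r = np.random.default_rng(seed)
        vectors = [r.integers(0, 2, 40) for _ in range(k)]
        mask, count = persistent_significant(vectors)
        expected = set(np.flatnonzero(vectors[0]))
        for v in vectors[1:]:
            expected &= set(np.flatnonzero(v))
        assert set(np.flatnonzero(mask)) == expected
        assert count == len(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            persistent_significant([np.zeros(3, int), np.zeros(4, int)])


class TestPlot:
    @staticmethod
    def _dot_count(fig):
        return sum(
            len(coll.get_offsets()) for ax in fig.axes for coll in ax.collections
        )

    def test_all_zero_matrix_plots_zero_dots(self, rng, small_grid):
        groups = TestRunSwa._groups(2, rng, small_grid)
        res = run_swa(groups, SWAParams(smoothing_window=1))
        res.significant[:] = 0
        fig = render_swa_plot(res)
        assert self._dot_count(fig) == 0

    def test_fully_significant_comparison_plots_grid_length_dots(self, rng, small_grid):
        groups = TestRunSwa._groups(2, rng, small_grid, shift=100.0)
        res = run_swa(groups, SWAParams(smoothing_window=1))
        res.significant[:] = 1
        fig = render_swa_plot(res)
        assert self._dot_count(fig) == small_grid.size

    def test_dot_count_equals_binary_matrix_sum_and_file_written(
        self, rng, small_grid, tmp_path
    ):
        groups = TestRunSwa._groups(3, rng, small_grid, shift=1.2)
        res = run_swa(groups, SWAParams(smoothing_window=1))
        out = tmp_path / "dots.png"
        fig = render_swa_plot(res, out)
        assert self._dot_count(fig) == int(res.significant.sum())
        assert out.exists() and out.stat().st_size > 0
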