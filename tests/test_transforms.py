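"""Size factors, shifted-log/acosh transformations and post-processing."""

import math

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from countform import (
    CountMatrix,
    SizeFactors,
    TransformSpec,
    TransformedMatrix,
    acosh_transform,
    apply_transform,
    compute_size_factors,
    drop_zero_cells,
    overdispersion_from_pseudo_count,
    pseudo_count_from_overdispersion,
    rescale_cell_sum,
    select_hvg,
    shifted_log,
    simulate_homogeneous,
    z_score,
)
from countform.embed import mean_variance_profile


def counts_from(arr) -> CountMatrix:
    return CountMatrix(sp.csc_matrix(np.asarray(arr)))


class TestSizeFactors:
    def test_mean_depth_mode(self):
        m = counts_from([[10, 20, 30]])
        s = compute_size_factors(m)
        assert np.allclose(s.s, [0.5, 1.0, 1.5])
        assert s.L == 20
        assert np.isclose(s.s.mean(), 1.0)

    def test_identical_totals_give_unit_factors(self):
        m = counts_from([[5, 5], [2, 2]])
        s = compute_size_factors(m)
        assert np.allclose(s.s, 1.0)

    def test_cpm_pseudocount_identity(self):
        # a 5,000-count cell at L = 10^6 has s = 0.005
        m = counts_from([[5000, 5000]])
        s = compute_size_factors(m, mode="fixed_L", L_fixed=1e6)
        assert np.allclose(s.s, 0.005)

    def test_s_times_L_recovers_totals(self, toy_counts):
        for mode, L in [("mean_depth", None), ("fixed_L", 1e4)]:
            s = compute_size_factors(toy_counts, mode=mode, L_fixed=L)
            assert np.allclose(s.s * s.L, toy_counts.cell_totals())

    def test_zero_cell_reported_and_dropped(self):
        m = counts_from([[1, 0], [2, 0]])
        s = compute_size_factors(m)
        assert s.s[1] == 0
        with pytest.warns(UserWarning, match="zero total"):
            m2, s2 = drop_zero_cells(m, s)
        assert m2.n_cells == 1
        assert (s2.s > 0).all()


class TestPseudoCountCalculus:
    @pytest.mark.parametrize(
        "y0,alpha", [(0.005, 50.0), (0.5, 0.5), (1.0, 0.25)]
    )
    def test_reference_pairs(self, y0, alpha):
        assert overdispersion_from_pseudo_count(y0) == pytest.approx(alpha)
        assert pseudo_count_from_overdispersion(alpha) == pytest.approx(y0)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inverse_pair(self, alpha):
        y0 = pseudo_count_from_overdispersion(alpha)
        assert overdispersion_from_pseudo_count(y0) == pytest.approx(alpha)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            pseudo_count_from_overdispersion(bad)
        with pytest.raises(ValueError):
            overdispersion_from_pseudo_count(bad)


class TestShiftedLog:
    def test_zero_maps_to_zero(self, unit_size_factors):
        m = counts_from([[0, 1], [0, 0]])
        t = shifted_log(m, unit_size_factors(2), y0=0.37)
        assert t.toarray()[0, 0] == 0
        assert t.toarray()[1, 1] == 0
        assert sp.issparse(t.values)

    def test_unit_case(self, unit_size_factors):
        m = counts_from([[1]])
        t = shifted_log(m, unit_size_factors(1), y0=1.0)
        assert t.toarray()[0, 0] == pytest.approx(math.log(2))

    def test_two_forms_agree(self):
        # log(y/(y0 s) + 1) vs log(y/s + y0) - log(y0), y=7, s=2, y0=0.5
        m = counts_from([[7]])
        s = SizeFactors(np.array([2.0]), L=1.0, mode="fixed_L")
        t = shifted_log(m, s, y0=0.5)
        direct = math.log(7 / 2 + 0.5) - math.log(0.5)
        assert t.toarray()[0, 0] == pytest.approx(math.log(8), abs=1e-12)
        assert t.toarray()[0, 0] == pytest.approx(direct, abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_sparsity_form_identity_on_random_fixtures(self, seed):
        """log(y/(y0·s)+1) == log(y/s+y0) − log(y0) to 1e−10 elementwise."""
        rng = np.random.default_rng(seed)
        arr = rng.poisson(1.0, size=(20, 10))
        m = counts_from(arr)
        s_vals = np.exp(rng.uniform(-1, 1, size=10))
        s = SizeFactors(s_vals, L=1.0, mode="fixed_L")
        y0 = float(np.exp(rng.uniform(np.log(0.005), np.log(5))))
        t = shifted_log(m, s, y0=y0).toarray()
        direct = np.log(arr / s_vals[None, :] + y0) - np.log(y0)
        assert np.allclose(t, direct, atol=1e-10, rtol=0)

    def test_rejects_nonpositive_y0(self, toy_counts, unit_size_factors):
        with pytest.raises(ValueError):
            shifted_log(toy_counts, unit_size_factors(4), y0=0.0)


class TestAcosh:
    def test_zero_maps_to_zero(self, unit_size_factors):
        m = counts_from([[0, 3]])
        t = acosh_transform(m, unit_size_factors(2), alpha=0.1)
        assert t.toarray()[0, 0] == 0

    def test_small_alpha_limit_is_two_sqrt(self, unit_size_factors):
        m = counts_from([[100]])
        t = acosh_transform(m, unit_size_factors(1), alpha=1e-8)
        assert t.toarray()[0, 0] == pytest.approx(20.0, abs=1e-4)

    def test_alpha_zero_is_exact_limit(self, unit_size_factors):
        m = counts_from([[100, 9]])
        t = acosh_transform(m, unit_size_factors(2), alpha=0.0)
        assert np.allclose(t.toarray(), [[20.0, 6.0]])

    def test_against_log_form_evaluator(self, unit_size_factors):
        # acosh(x) = log(x + sqrt(x^2 - 1)) as an independent evaluator
        m = counts_from([[2]])
        t = acosh_transform(m, unit_size_factors(1), alpha=0.25)
        x = 2 * 0.25 * 2 + 1
        expected = math.log(x + math.sqrt(x * x - 1)) / math.sqrt(0.25)
        assert t.toarray()[0, 0] == pytest.approx(expected, abs=1e-12)
        assert t.toarray()[0, 0] == pytest.approx(2 * math.acosh(2), abs=1e-12)

    def test_rejects_negative_alpha(self, toy_counts, unit_size_factors):
        with pytest.raises(ValueError):
            acosh_transform(toy_counts, unit_size_factors(4), alpha=-0.1)


class TestPostProcessing:
    def test_rescale_columns(self):
        t = TransformedMatrix(np.array([[1.0], [1.0], [2.0]]))
        out = rescale_cell_sum(t)
        assert np.allclose(out.toarray().ravel(), [0.25, 0.25, 0.5])

    def test_rescale_column_sums_one_and_idempotent(self):
        rng = np.random.default_rng(0)
        t = TransformedMatrix(rng.uniform(0.1, 1, size=(6, 4)))
        once = rescale_cell_sum(t)
        assert np.allclose(once.toarray().sum(axis=0), 1.0)
        twice = rescale_cell_sum(once)
        assert np.allclose(once.toarray(), twice.toarray())

    def test_rescale_zero_column_errors(self):
        t = TransformedMatrix(np.array([[0.0, 1.0], [0.0, 1.0]]))
        with pytest.raises(ValueError, match="zero"):
            rescale_cell_sum(t)

    def test_hvg_picks_top_variance(self):
        vals = np.array(
            [
                [1.0, 1.0, 1.0],  # var 0
                [0.0, 3.0, 6.0],  # var 9
                [0.0, 1.0, 2.0],  # var 1
            ]
        )
        out = select_hvg(TransformedMatrix(vals), n=2)
        assert out.genes_kept.tolist() == [1, 2]

    def test_hvg_n_too_large_keeps_all(self):
        out = select_hvg(TransformedMatrix(np.eye(3)), n=10)
        assert out.n_genes == 3

    def test_hvg_tie_break_by_index(self):
        vals = np.array([[0.0, 2.0], [0.0, 2.0], [0.0, 2.0]])
        out = select_hvg(TransformedMatrix(vals), n=2)
        assert out.genes_kept.tolist() == [0, 1]

    def test_zscore_row(self):
        out = z_score(TransformedMatrix(np.array([[1.0, 2.0, 3.0]])))
        assert np.allclose(out.toarray().ravel(), [-1.0, 0.0, 1.0])

    def test_zscore_moments_and_idempotence(self):
        rng = np.random.default_rng(1)
        t = TransformedMatrix(rng.normal(5, 2, size=(10, 30)))
        z1 = z_score(t)
        assert np.allclose(z1.toarray().mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z1.toarray().var(axis=1, ddof=1), 1.0)
        z2 = z_score(z1)
        assert np.allclose(z1.toarray(), z2.toarray(), atol=1e-10)

    def test_zscore_drops_constant_gene(self):
        t = TransformedMatrix(np.array([[1.0, 1.0], [0.0, 2.0]]))
        with pytest.warns(UserWarning, match="constant"):
            out = z_score(t)
        assert out.n_genes == 1

    def test_zscore_all_constant_errors(self):
        with pytest.raises(ValueError):
            z_score(TransformedMatrix(np.ones((2, 3))))


class TestApplyTransform:
    def test_raw_is_identity(self, toy_counts):
        t = apply_transform(toy_counts, TransformSpec(family="raw"))
        assert np.array_equal(t.toarray(), toy_counts.toarray())

    def test_derived_pseudocount(self):
        spec = TransformSpec(family="shifted_log", y0="derived", alpha=0.05)
        y0, _ = spec.resolve_y0_alpha()
        assert y0 == pytest.approx(5.0)

    def test_composition_matches_manual(self, random_sparse_counts):
        m = random_sparse_counts
        spec = TransformSpec(
            family="shifted_log", post=("hvg", "zscore"), hvg_n=10
        )
        combined = apply_transform(m, spec)
        s = compute_size_factors(m)
        m2, s2 = m, s
        if (s.s == 0).any():
            with pytest.warns(UserWarning):
                m2, s2 = drop_zero_cells(m, s)
        manual = z_score(select_hvg(shifted_log(m2, s2, 1.0), 10))
        assert np.allclose(combined.toarray(), manual.toarray())

    def test_cpm_uses_fixed_million(self):
        m = counts_from([[5000], [0]])
        t = apply_transform(m, TransformSpec(family="shifted_log_cpm"))
        # s = 5000/1e6 = 0.005 → log1p(5000/0.005)
        assert t.toarray()[0, 0] == pytest.approx(np.log1p(5000 / 0.005))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            TransformSpec(family="nope")


class TestVarianceStabilization:
    """Gene-level variance profiles on a homogeneous gamma-Poisson simulation."""

    @pytest.fixture()
    def homogeneous(self):
        return simulate_homogeneous(
            n_genes=1000,
            n_cells=800,
            mean_profile=(1.0, 1000.0),
            alpha=0.05,
            size_factor_spread=1.0,
            seed=9,
        )

    @staticmethod
    def _binned_variance_ratio(means, variances, n_bins=5):
        mask = means >= 10
        bins = np.quantile(np.log(means[mask]), np.linspace(0, 1, n_bins + 1))
        idx = np.clip(
            np.digitize(np.log(means[mask]), bins[1:-1]), 0, n_bins - 1
        )
        binned = np.array(
            [variances[mask][idx == b].mean() for b in range(n_bins)]
        )
        return binned.max() / binned.min()

    def test_acosh_flattens_variance_raw_does_not(self, homogeneous):
        m = homogeneous.counts
        s = compute_size_factors(m)
        raw_prof = mean_variance_profile(
            apply_transform(m, TransformSpec(family="raw"))
        )
        t = acosh_transform(m, s, alpha=0.05)
        vst_prof = mean_variance_profile(t)
        raw_means = raw_prof[:, 0]
        assert (
            self._binned_variance_ratio(raw_means, raw_prof[:, 1]) > 100
        )
        # bin by raw expression level; variance after the matched-alpha VST is flat
        assert (
            self._binned_variance_ratio(raw_means, vst_prof[:, 1]) < 2
        )

    def test_low_expression_variance_collapses_after_shifted_log(self):
        m = simulate_homogeneous(
            n_genes=1000,
            n_cells=800,
            mean_profile=(0.01, 1000.0),
            alpha=0.05,
            size_factor_spread=1.0,
            seed=9,
        ).counts
        s = compute_size_factors(m)
        t = shifted_log(m, s, y0=1.0)
        prof = mean_variance_profile(t)
        raw_means = np.asarray(m.values.mean(axis=1)).ravel()
        low = raw_means < 0.1
        assert low.sum() > 20
        assert (prof[low, 1] < 0.05).all()
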