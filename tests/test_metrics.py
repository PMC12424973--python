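"""Circuit diagnostics: sparsity, specialists, dynamic range, scores, nulls."""

import numpy as np
import pytest

from olfec.encoding import make_canonical_expression
from olfec.metrics import (activity_histogram_entropy, canonical_score,
                           count_specialists, default_zero_threshold,
                           effective_rank, fit_lognormal_nonzero,
                           glomerular_purity, make_null_sensing,
                           odorant_dynamic_range, pc_variance_spectrum,
                           robust_coexpression_stats, sparsity_fraction)


class TestSparsity:
    def test_all_above_and_below(self):
        assert sparsity_fraction(np.ones((3, 3)), 0.5) == 0.0
        assert sparsity_fraction(np.full((3, 3), 0.1), 0.5) == 1.0

    def test_half_and_half(self):
        w = np.array([[1.0, 1.0], [1e-9, 1e-9]])
        assert sparsity_fraction(w, 1e-3) == 0.5


class TestLognormalFit:
    def test_recovers_log_sd(self):
        rng = np.random.default_rng(0)
        w = np.exp(-2 + 1.5 * rng.standard_normal((100, 1000)))
        mu, sd, ks = fit_lognormal_nonzero(w, zero_threshold=1e-300)
        assert sd == pytest.approx(1.5, rel=0.02)
        assert mu == pytest.approx(-2.0, abs=0.05)

    def test_constant_entries_zero_sd(self):
        mu, sd, ks = fit_lognormal_nonzero(np.full((4, 5), 2.0), 1e-6)
        assert sd == 0.0 and mu == pytest.approx(np.log(2.0))

    def test_mixture_fits_worse_than_pure(self):
        rng = np.random.default_rng(1)
        pure = np.exp(rng.standard_normal(20_000)).reshape(100, 200)
        mixed = pure.copy().ravel()
        mixed[:10_000] *= np.e**6   # second mode six log-units away
        mixed = mixed.reshape(100, 200)
        ks_pure = fit_lognormal_nonzero(pure, 1e-300)[2]
        ks_mixed = fit_lognormal_nonzero(mixed, 1e-300)[2]
        assert ks_mixed > ks_pure


class TestSpecialists:
    def test_exact_hundredfold_counts(self):
        rng = np.random.default_rng(2)
        w = np.ones((1, 200))
        w[0, 0] = 100.0 * np.percentile(np.ones(200), 99)
        n, pairs = count_specialists(w)
        assert n == 1 and pairs == [(0, 0)]

    def test_constant_row_not_specialist(self):
        assert count_specialists(np.ones((3, 200)))[0] == 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        w = np.exp(rng.standard_normal((20, 300)))
        w[3, 7] = w[3].max() * 1e4
        base = count_specialists(w)
        scaled = count_specialists(w * 123.4)
        assert base[0] == scaled[0] and base[1] == scaled[1]

    def test_lognormal_resample_has_no_specialists(self):
        # i.i.d. log-normal lacks the extreme outliers the criterion needs
        rng = np.random.default_rng(4)
        w = np.exp(1.5 * rng.standard_normal((60, 1000)))
        null = make_null_sensing(w, "lognormalFit", seed=5,
                                 zero_threshold=1e-300)
        assert count_specialists(null)[0] == 0

    def test_short_row_warns(self):
        with pytest.warns(UserWarning):
            count_specialists(np.ones((2, 50)))


class TestDynamicRange:
    def test_single_receptor_closed_form(self):
        w = np.array([[2.0]])
        width = odorant_dynamic_range(w, n=1.0, lo_resp=0.1, hi_resp=0.9,
                                      zero_threshold=1e-300)
        assert width[0] == pytest.approx(2 * np.log10(9.0), abs=1e-6)

    def test_identical_receptors_do_not_widen(self):
        w = np.array([[3.0], [3.0]])
        w1 = odorant_dynamic_range(w[:1], 1.0, zero_threshold=1e-300)
        w2 = odorant_dynamic_range(w, 1.0, zero_threshold=1e-300)
        assert w2[0] == pytest.approx(w1[0])

    def test_disjoint_windows_add(self):
        w = np.array([[1.0], [1e6]])
        width = odorant_dynamic_range(w, 1.0, zero_threshold=1e-300)
        assert width[0] == pytest.approx(2 * 2 * np.log10(9.0), abs=1e-6)

    def test_agrees_with_grid_oracle(self):
        """Union length matches brute-force log-concentration gridding."""
        rng = np.random.default_rng(5)
        n_hill = 1.46
        w = np.exp(2 * rng.standard_normal((4, 3)))
        widths = odorant_dynamic_range(w, n_hill, zero_threshold=1e-300)
        grid = np.arange(-9.0, 9.0, 1e-3)
        conc = 10.0**grid
        for j in range(3):
            resp = (w[:, j:j + 1] * conc)**n_hill
            resp = resp / (1 + resp)
            covered = np.any((resp >= 0.1) & (resp <= 0.9), axis=0)
            assert widths[j] == pytest.approx(covered.sum() * 1e-3, abs=1e-2)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            odorant_dynamic_range(np.ones((2, 2)), 1.0, lo_resp=0.9,
                                  hi_resp=0.1)


class TestCanonicalScore:
    def test_one_hot_scores_one(self):
        for m, l in [(3, 3), (5, 17), (21, 21)]:
            assert canonical_score(make_canonical_expression(m, l)) == 1.0

    def test_uniform_scores_zero(self):
        assert canonical_score(np.full((10, 8), 1 / 8)) == pytest.approx(0.0)

    @pytest.mark.parametrize("kappa, m", [(2, 8), (3, 60), (7, 60)])
    def test_kappa_uniform_closed_form(self, kappa, m):
        e = np.zeros((5, m))
        e[:, :kappa] = 1.0 / kappa
        assert canonical_score(e) == pytest.approx(1 - np.log(kappa) / np.log(m))

    def test_row_sum_violation_rejected(self):
        with pytest.raises(ValueError):
            canonical_score(np.full((2, 4), 0.3))


class TestPCSpectrum:
    def test_isotropic_is_flat(self):
        rng = np.random.default_rng(6)
        spec = pc_variance_spectrum(rng.standard_normal((20_000, 8)))
        assert np.all(np.abs(spec - 1 / 8) < 0.02)

    def test_rank_one_concentrates(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((500, 1))
        spec = pc_variance_spectrum(base @ np.ones((1, 6)))
        assert spec[0] == pytest.approx(1.0)

    def test_sums_to_one_descending(self):
        rng = np.random.default_rng(8)
        spec = pc_variance_spectrum(rng.standard_normal((300, 5)) * [1, 2, 3, 4, 5])
        assert spec.sum() == pytest.approx(1.0)
        assert np.all(np.diff(spec) <= 1e-12)


class TestCoexpression:
    def test_canonical_has_no_robust_pairs(self):
        e = make_canonical_expression(6, 18)
        w = np.exp(np.random.default_rng(9).standard_normal((6, 120)))
        out = robust_coexpression_stats(e, w)
        assert out["robust_pairs"] == [] and out["p_value"] is None

    def test_three_neuron_pair_is_robust(self):
        e = make_canonical_expression(6, 18).copy()
        e[:3] = 0.0
        e[:3, 0] = 0.5
        e[:3, 1] = 0.5
        w = np.exp(np.random.default_rng(10).standard_normal((6, 120)))
        out = robust_coexpression_stats(e, w)
        assert out["robust_pairs"] == [(0, 1)]

    def test_identical_rows_covariance_equals_variance(self):
        e = np.zeros((3, 4))
        e[:, 0] = 0.5
        e[:, 1] = 0.5
        w = np.exp(np.random.default_rng(11).standard_normal((4, 200)))
        w[1] = w[0]
        out = robust_coexpression_stats(e, w)
        assert out["robust_cov"][0] == pytest.approx(np.log(w[0]).var(ddof=1))


class TestNullSensing:
    def test_global_shuffle_preserves_multiset(self):
        rng = np.random.default_rng(12)
        w = rng.random((5, 7))
        null = make_null_sensing(w, "shuffleGlobal", seed=13)
        assert np.array_equal(np.sort(null.ravel()), np.sort(w.ravel()))
        assert not np.array_equal(null, w)

    def test_row_shuffle_preserves_rows(self):
        rng = np.random.default_rng(14)
        w = rng.random((5, 40))
        null = make_null_sensing(w, "shuffleRows", seed=15)
        for a, b in zip(w, null):
            assert np.array_equal(np.sort(a), np.sort(b))

    def test_block_null_correlation_structure(self):
        rng = np.random.default_rng(16)
        w = np.exp(rng.standard_normal((8, 1000)))
        null = make_null_sensing(w, "lognormalBlock", seed=17, n_families=2,
                                 family_corr=0.8, zero_threshold=1e-300)
        corr = np.corrcoef(np.log(null))
        within = [corr[i, j] for i in range(4) for j in range(4) if i < j]
        across = [corr[i, j] for i in range(4) for j in range(4, 8)]
        assert np.mean(within) == pytest.approx(0.8, abs=0.05)
        assert abs(np.mean(across)) < 0.05

    def test_toeplitz_null_decays_with_distance(self):
        rng = np.random.default_rng(18)
        w = np.exp(rng.standard_normal((10, 2000)))
        null = make_null_sensing(w, "lognormalToeplitz", seed=19,
                                 toeplitz_decay=0.6, zero_threshold=1e-300)
        corr = np.corrcoef(np.log(null))
        near = np.mean([corr[i, i + 1] for i in range(9)])
        far = np.mean([corr[i, i + 5] for i in range(5)])
        assert near == pytest.approx(0.6, abs=0.07)
        assert far == pytest.approx(0.6**5, abs=0.1)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            make_null_sensing(np.ones((2, 20)), "bogus")


class TestPurity:
    def test_perfect_convergence_scores_one(self):
        e = make_canonical_expression(4, 12)
        g = np.zeros((4, 12))
        types = np.argmax(e, axis=1)
        for m in range(4):
            g[m, types == m] = 1 / 3
        assert glomerular_purity(g, e) == 1.0

    def test_uniform_pooling_scores_one_over_m(self):
        m, l = 21, 63
        e = make_canonical_expression(m, l)
        g = np.full((m, l), 1 / l)
        assert glomerular_purity(g, e) == pytest.approx(1 / m)


class TestHistogramEntropy:
    def test_uniform_reaches_log_bins(self):
        vals = np.repeat(np.linspace(0, 1, 20), 50) + 1e-9
        h = activity_histogram_entropy(vals, n_bins=20)
        assert h == pytest.approx(np.log(20), abs=0.05)

    def test_degenerate_support_zero(self):
        assert activity_histogram_entropy(np.full(500, 0.3), 10) == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            activity_histogram_entropy(np.ones(50), 10)


class TestEffectiveRank:
    def test_rank_one_is_one(self):
        w = np.outer(np.arange(1, 5), np.arange(1, 11))
        assert effective_rank(w) == pytest.approx(1.0)

    def test_identity_is_m(self):
        assert effective_rank(np.eye(17)) == pytest.approx(17.0)

    def test_iid_lognormal_near_full_rank(self):
        rng = np.random.default_rng(20)
        w = np.exp(rng.standard_normal((60, 1000)))
        assert effective_rank(w) > 40.0

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            effective_rank(np.zeros((3, 3)))
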