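"""MAP fitting, Laplace evidence, and the hierarchical comparison calculus."""

import numpy as np
import pytest
from scipy.stats import beta as beta_dist

from distractor_learn import (GroupSpec, exceedance_probabilities,
                              fit_hierarchical, fit_subject_map, hbi_ttest,
                              protected_exceedance, responsibilities,
                              simulate_group, simulate_rts)
from distractor_learn.design import ExperimentDesign
from distractor_learn.models import ParameterVector, build_design_matrix
from distractor_learn.reference import exp1_categorical_group_spec


@pytest.fixture(scope="module")
def model3_subject(exp1_sequence):
    raw = exp1_categorical_group_spec().group_mean
    return raw, simulate_rts(3, raw, exp1_sequence, noise_sd_ms=10.0, seed=42)


class TestSubjectMAP:
    def test_degenerate_prior_returns_prior_mean(self, model3_subject):
        raw, data = model3_subject
        prior_mean = np.array([-4.0, 0.8, 0.1, -0.03, 0.0])
        fit = fit_subject_map(3, data, prior_mean, np.full(5, 1e-12),
                              n_restarts=0)
        np.testing.assert_allclose(fit.raw, prior_mean, atol=1e-4)

    def test_wide_prior_betas_match_ols(self, model3_subject):
        """With a nearly flat prior the MAP betas equal the ordinary
        least-squares solution on the design matrix at the fitted decay."""
        raw, data = model3_subject
        fit = fit_subject_map(3, data, np.zeros(5), np.full(5, 1e6),
                              n_restarts=2, rng=np.random.default_rng(0))
        pv = ParameterVector(3, fit.raw)
        dm = build_design_matrix(pv, data.sequence, data.rt_ms, data.accuracy)
        y = data.rt_ms[dm.included] / 1000.0
        ols = np.linalg.lstsq(dm.X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.raw[1:], ols, atol=1e-5)

    def test_low_noise_recovery_within_two_posterior_sds(self,
                                                         model3_subject):
        raw, data = model3_subject
        fit = fit_subject_map(3, data, n_restarts=4,
                              rng=np.random.default_rng(1))
        assert np.all(np.abs(fit.raw - raw) <= 2.0 * fit.posterior_sd
                      + 1e-3)

    def test_reproducible_under_fixed_seed(self, model3_subject):
        _, data = model3_subject
        a = fit_subject_map(3, data, n_restarts=2,
                            rng=np.random.default_rng(9))
        b = fit_subject_map(3, data, n_restarts=2,
                            rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a.raw, b.raw)
        assert a.log_evidence == b.log_evidence


class TestComparisonCalculus:
    def test_responsibility_softmax_of_evidence_gap(self):
        # log-evidence gap of ln 3 at equal frequencies -> 0.75 / 0.25
        L = np.array([[np.log(3.0), 0.0]])
        r = responsibilities(L, np.ones(2))
        np.testing.assert_allclose(r, [[0.75, 0.25]], atol=1e-12)
        assert r.sum() == pytest.approx(1.0)

    def test_exceedance_matches_beta_tail(self):
        """K = 2: the Dirichlet exceedance is a Beta tail probability."""
        counts = np.array([9.0, 1.0])
        draws = 10 ** 5
        xp = exceedance_probabilities(counts, draws,
                                      np.random.default_rng(3))
        exact = 1.0 - beta_dist.cdf(0.5, counts[0], counts[1])
        se = np.sqrt(exact * (1 - exact) / draws)
        assert abs(xp[0] - exact) <= 3.0 * se
        assert xp.sum() == pytest.approx(1.0)

    def test_protected_exceedance_identity_and_limits(self):
        counts = np.array([9.0, 1.0])
        rng_draws = dict(n_draws=10 ** 4)
        xp = exceedance_probabilities(counts,
                                      rng=np.random.default_rng(5),
                                      **rng_draws)
        for bor in (0.0, 0.1, 1.0):
            pxp = protected_exceedance(counts, bor,
                                       rng=np.random.default_rng(5),
                                       **rng_draws)
            np.testing.assert_allclose(pxp, xp * (1 - bor) + bor / 2,
                                       atol=1e-12)
        np.testing.assert_allclose(
            protected_exceedance(counts, 1.0, rng=np.random.default_rng(5),
                                 **rng_draws), [0.5, 0.5], atol=1e-12)

    def test_bor_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            protected_exceedance([1.0, 1.0], 1.5)

    @pytest.mark.parametrize("mean,err,dof,expected_t", [
        (0.0, 0.01, 16, 0.0),
        (0.092, 0.0123, 18, 7.4797),
    ])
    def test_hbi_ttest_values(self, mean, err, dof, expected_t):
        t, p = hbi_ttest(mean, err, dof)
        assert t == pytest.approx(expected_t, abs=1e-3)
        if mean == 0:
            assert p == pytest.approx(1.0)
        else:
            assert p < 0.001

    def test_hbi_ttest_error_scaling(self):
        t1, _ = hbi_ttest(0.05, 0.01, 20)
        t2, _ = hbi_ttest(0.05, 0.02, 20)
        assert t1 == pytest.approx(2.0 * t2)


@pytest.fixture(scope="module")
def small_group():
    spec = GroupSpec(3, exp1_categorical_group_spec().group_mean,
                     exp1_categorical_group_spec().group_sd, n_subjects=5)
    design = ExperimentDesign(n_blocks=2, trials_per_block=60, seed=31)
    return simulate_group(spec, design, noise=50.0,
                          rng=np.random.default_rng(8))


class TestHierarchicalFit:
    def test_single_model_pxp_is_one(self, small_group):
        fit = fit_hierarchical([3], small_group.subjects, max_iterations=6,
                               n_restarts=1, exceedance_draws=10 ** 4,
                               rng=np.random.default_rng(0))
        np.testing.assert_allclose(fit.comparison.pxp, [1.0], atol=1e-12)
        np.testing.assert_allclose(fit.comparison.responsibilities, 1.0)

    def test_duplicate_models_split_evenly(self, small_group):
        """Two copies of the same model: equal evidences by symmetry, so
        responsibilities are 1/2, pxp is uniform, and the omnibus risk says
        the frequencies are indistinguishable."""
        fit = fit_hierarchical([7, 7], small_group.subjects,
                               max_iterations=4, n_restarts=0,
                               exceedance_draws=10 ** 4,
                               rng=np.random.default_rng(0))
        np.testing.assert_allclose(fit.comparison.responsibilities, 0.5,
                                   atol=1e-9)
        np.testing.assert_allclose(fit.comparison.pxp, [0.5, 0.5], atol=0.02)
        assert fit.comparison.bor > 0.5

    def test_probability_identities(self, small_group):
        fit = fit_hierarchical([3, 7], small_group.subjects,
                               max_iterations=6, n_restarts=1,
                               exceedance_draws=10 ** 4,
                               rng=np.random.default_rng(2))
        c = fit.comparison
        np.testing.assert_allclose(c.responsibilities.sum(axis=1), 1.0,
                                   atol=1e-12)
        assert c.exceedance.sum() == pytest.approx(1.0, abs=1e-12)
        assert c.pxp.sum() == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= c.bor <= 1.0
        np.testing.assert_allclose(
            c.pxp, c.exceedance * (1 - c.bor) + c.bor / 2, atol=1e-12)
        assert c.model_frequency.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(c.dirichlet_counts >= 1.0)

    def test_single_model_shrinks_subjects_toward_group(self):
        """Empirical-Bayes behavior: when trial noise is large relative to
        the true between-subject spread, the hierarchical per-subject
        estimates are far less dispersed than individual wide-prior fits."""
        mean = np.array([np.log(0.015), 0.895, 0.092, -0.040, -0.006])
        spec = GroupSpec(3, mean, np.array([0.05, 0.01, 0.01, 0.01, 0.01]),
                         n_subjects=6)
        sg = simulate_group(
            spec, ExperimentDesign(n_blocks=1, trials_per_block=60, seed=77),
            noise=150.0, rng=np.random.default_rng(21))
        fit = fit_hierarchical([3], sg.subjects, max_iterations=10,
                               n_restarts=1, exceedance_draws=10 ** 3,
                               rng=np.random.default_rng(0))
        g = fit.groups[3]
        solo = np.array([
            fit_subject_map(3, s, np.zeros(5), np.full(5, 1e6),
                            n_restarts=1, rng=np.random.default_rng(n)).raw
            for n, s in enumerate(sg.subjects)])
        assert np.all(g.subject_map.std(axis=0) < 0.5 * solo.std(axis=0))

    def test_too_few_subjects_rejected(self, small_group):
        with pytest.raises(ValueError, match="2 subjects"):
            fit_hierarchical([3], small_group.subjects[:1])
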