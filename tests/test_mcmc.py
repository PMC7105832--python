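"""Sampler tests: enumeration oracles, prior recovery, constraints, diagnostics.

The exact-oracle tests hold the structural parameters fixed at their
generating values so the chain's only unknowns are the latent classes;
the MCMC class posterior must then match the closed-form enumeration
posterior, which is computed here independently (per-observation loops
over the 2^K classes via the scalar probability functions).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ratercdm as rc
from ratercdm import mcmc

SHORT = mcmc.ChainSchedule(n_chains=2, n_iterations=900, burn_in=300, thin=3)


def enumeration_posterior(table, qmatrix, item_params, eta=None, weights=None):
    """Brute-force class posterior per ratee: loop over classes and observations."""
    K = qmatrix.n_attributes
    profiles = rc.enumerate_profiles(K)
    C = profiles.shape[0]
    weights = np.full(C, 1.0 / C) if weights is None else np.asarray(weights)
    post = np.zeros((table.n_ratees, C))
    rec = table.records
    for c in range(C):
        alpha = profiles[c]
        logp = np.log(weights[c])
        per_obs = []
        for _, row in rec.iterrows():
            e = 0.0 if eta is None else eta[row["rater"]]
            p1 = rc.facets_success_prob(item_params[row["item"]], e, alpha,
                                        qmatrix.row(row["item"]))
            per_obs.append((row["ratee"], np.log(p1 if row["score"] else 1 - p1)))
        for i, lp in per_obs:
            post[i, c] += lp
        post[:, c] += logp
    post -= post.max(axis=1, keepdims=True)
    post = np.exp(post)
    return post / post.sum(axis=1, keepdims=True)


@pytest.fixture(scope="module")
def tiny_table(tiny_qmatrix, tiny_items):
    raters = [rc.RaterParams(severity_eta=0.0), rc.RaterParams(severity_eta=0.0)]
    config = rc.SimulationConfig(tiny_qmatrix, tiny_items, raters, "facets",
                                 design="complete", n_ratees=40, rho=0.3, seed=8)
    return rc.simulate_facets(config)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_class_posterior_matches_enumeration(self, tiny_table, tiny_qmatrix,
                                                 tiny_items, seed):
        """Standard CDM, parameters clamped at truth: MCMC class probabilities
        agree with the exact four-class posterior within Monte-Carlo error."""
        uniform = np.full(4, 0.25)
        summary = mcmc.fit(mcmc.ModelSpec("standard"), tiny_table, tiny_qmatrix,
                           schedule=SHORT, seed=seed,
                           fix_item_params=tiny_items, fix_class_weights=uniform)
        exact = enumeration_posterior(tiny_table, tiny_qmatrix, tiny_items)
        assert np.abs(summary.class_probs - exact).max() < 0.03

    def test_conjugate_single_item_bayes_rule(self):
        """One item, one attribute, known parameters: the class conditional is a
        two-term Bayes computation done by hand."""
        qmatrix = rc.QMatrix(np.array([[1]]))
        params = [rc.ItemParams(-1.0, {0: 2.0})]
        rec = pd.DataFrame({"ratee": [0, 1], "item": [0, 0], "rater": [0, 0],
                            "score": [1, 0]})
        table = rc.RatingsTable(rec, 2, 1, 1)
        summary = mcmc.fit(mcmc.ModelSpec("standard"), table, qmatrix,
                           schedule=mcmc.ChainSchedule(2, 3000, 500, 5), seed=4,
                           fix_item_params=params,
                           fix_class_weights=np.array([0.5, 0.5]))
        p0 = rc.lcdm_success_prob(params[0], [0], [1])  # 0.2689
        p1 = rc.lcdm_success_prob(params[0], [1], [1])  # 0.7311
        want_score1 = p1 / (p0 + p1)
        want_score0 = (1 - p1) / ((1 - p0) + (1 - p1))
        assert summary.class_probs[0, 1] == pytest.approx(want_score1, abs=0.02)
        assert summary.class_probs[1, 1] == pytest.approx(want_score0, abs=0.02)

    def test_collapsed_xi_matches_augmented_chain(self):
        """The analytically collapsed HRM conditional and the explicit
        ξ-augmented chain target the same class posterior."""
        qmatrix = rc.QMatrix(np.array([[1], [1]]))
        items = [rc.ItemParams(-1.0, {0: 2.2}), rc.ItemParams(-0.5, {0: 1.8})]
        raters = [rc.RaterParams(severity_phi=0.0, variability_psi=0.6)] * 2
        config = rc.SimulationConfig(qmatrix, items, raters, "hrm",
                                     design="complete", n_ratees=30, rho=0.0,
                                     seed=12)
        table = rc.simulate_hrm(config)
        kwargs = dict(schedule=mcmc.ChainSchedule(2, 2400, 400, 4),
                      fix_item_params=items, fix_rater_params=raters,
                      fix_class_weights=np.array([0.5, 0.5]))
        collapsed = mcmc.fit(mcmc.ModelSpec("hrm"), table, qmatrix, seed=5, **kwargs)
        augmented = mcmc.fit(mcmc.ModelSpec("hrm"), table, qmatrix, seed=6,
                             augmented=True, **kwargs)
        assert np.abs(collapsed.class_probs - augmented.class_probs).max() < 0.03


@pytest.fixture(scope="module")
def prior_fit():
    """Likelihood disabled: the chain must reproduce the prior."""
    qmatrix = rc.QMatrix(np.array([[1]]))
    rec = pd.DataFrame({"ratee": np.arange(10), "item": 0, "rater": 0,
                        "score": np.tile([0, 1], 5)})
    table = rc.RatingsTable(rec, 10, 1, 1)
    return mcmc.fit(mcmc.ModelSpec("standard"), table, qmatrix,
                    schedule=mcmc.ChainSchedule(2, 26_000, 1_000, 10),
                    seed=9, likelihood_scale=0.0)


@pytest.fixture(scope="module")
def facets_fit(small_facets_table, study_qmatrix):
    return mcmc.fit(mcmc.ModelSpec("facets"), small_facets_table, study_qmatrix,
                    schedule=SHORT, seed=11)


class TestPriorRecovery:
    def test_intercept_draws_reproduce_normal_prior(self, prior_fit):
        idx = prior_fit.param_names.index("lambda[1,0]")
        draws = prior_fit.flat_draws[:, idx]
        ks = stats.kstest(draws, "norm", args=(0.0, 4.0))
        assert ks.pvalue > 0.01

    def test_main_effect_draws_respect_truncation(self, prior_fit):
        idx = prior_fit.param_names.index("lambda[1,1,A1]")
        assert (prior_fit.flat_draws[:, idx] > 0).all()

    def test_flat_likelihood_classes_uniform(self, tiny_qmatrix, tiny_items,
                                             tiny_table):
        summary = mcmc.fit(mcmc.ModelSpec("standard"), tiny_table, tiny_qmatrix,
                           schedule=mcmc.ChainSchedule(2, 1500, 500, 1), seed=10,
                           fix_item_params=tiny_items,
                           fix_class_weights=np.full(4, 0.25),
                           likelihood_scale=0.0)
        counts = np.bincount(summary.class_assignment_draws.ravel(), minlength=4)
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.001


class TestConstraintsAndReproducibility:
    def test_eta_zero_mean_at_every_retained_draw(self, facets_fit):
        eta_cols = [i for i, n in enumerate(facets_fit.param_names)
                    if n.startswith("eta[")]
        sums = facets_fit.flat_draws[:, eta_cols].sum(axis=1)
        assert np.abs(sums).max() < 1e-9

    def test_item_acceptance_in_tuning_band(self, facets_fit):
        assert 0.1 < facets_fit.acceptance["items"] < 0.6
        assert 0.1 < facets_fit.acceptance["raters"] < 0.6

    def test_main_effect_draws_positive(self, facets_fit):
        main_cols = [i for i, n in enumerate(facets_fit.param_names) if ",1,A" in n]
        assert (facets_fit.flat_draws[:, main_cols] > 0).all()

    def test_same_seed_identical_retained_draws(self, tiny_table, tiny_qmatrix):
        a = mcmc.fit(mcmc.ModelSpec("facets"), tiny_table, tiny_qmatrix,
                     schedule=SHORT, seed=21)
        b = mcmc.fit(mcmc.ModelSpec("facets"), tiny_table, tiny_qmatrix,
                     schedule=SHORT, seed=21)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.class_assignment_draws, b.class_assignment_draws)

    def test_facets_with_zero_fixed_severity_equals_standard(self, tiny_table,
                                                             tiny_qmatrix):
        """Clamping every η at zero makes the facets model the standard LCDM:
        the two chains are draw-for-draw identical."""
        fixed = [rc.RaterParams(severity_eta=0.0)] * 2
        fac = mcmc.fit(mcmc.ModelSpec("facets"), tiny_table, tiny_qmatrix,
                       schedule=SHORT, seed=13, fix_rater_params=fixed)
        std = mcmc.fit(mcmc.ModelSpec("standard"), tiny_table, tiny_qmatrix,
                       schedule=SHORT, seed=13)
        n_item = len(std.param_names)
        assert np.array_equal(fac.draws[:, :, :n_item], std.draws)

    def test_psi_draws_positive(self, tiny_qmatrix, tiny_items):
        raters = [rc.RaterParams(severity_phi=0.2, variability_psi=0.7)] * 3
        config = rc.SimulationConfig(tiny_qmatrix, tiny_items, raters, "hrm",
                                     design="complete", n_ratees=60, seed=14)
        table = rc.simulate_hrm(config)
        summary = mcmc.fit(mcmc.ModelSpec("hrm"), table, tiny_qmatrix,
                           schedule=SHORT, seed=15)
        psi_cols = [i for i, n in enumerate(summary.param_names)
                    if n.startswith("psi[")]
        assert (summary.flat_draws[:, psi_cols] > 0).all()

    def test_rater_without_data_rejected(self, tiny_qmatrix, tiny_items):
        rec = pd.DataFrame({"ratee": [0, 1], "item": [0, 1], "rater": [0, 0],
                            "score": [1, 0]})
        table = rc.RatingsTable(rec, 2, 3, 3)
        with pytest.raises(ValueError, match=r"rater\(s\) \[2, 3\]"):
            mcmc.fit(mcmc.ModelSpec("facets"), table, tiny_qmatrix,
                     schedule=SHORT, seed=0)


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        chain = np.random.default_rng(0).normal(size=(1, 200, 3))
        rhat = rc.gelman_rubin(np.repeat(chain, 2, axis=0))
        assert rhat == pytest.approx(np.ones(3), abs=0.01)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, size=(1000, 1)),
                           rng.normal(5, 1, size=(1000, 1))])
        assert rc.gelman_rubin(chains)[0] > 2.0

    def test_iid_chains_converged(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 2000, 4))
        assert (rc.gelman_rubin(chains) < 1.05).all()

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            rc.gelman_rubin(np.zeros((1, 100, 2)))

    def test_constant_parameter_reported_as_converged(self):
        chains = np.ones((2, 50, 1))
        assert rc.gelman_rubin(chains)[0] == 1.0


class TestClassification:
    def test_threshold_at_half(self):
        probs = np.array([[0.9, 0.2], [0.4, 0.6]])
        assert rc.classify_profiles(probs).tolist() == [[1, 0], [0, 1]]

    def test_exact_tie_resolves_to_mastery(self):
        assert rc.classify_profiles(np.full((2, 3), 0.5)).tolist() == \
            [[1, 1, 1], [1, 1, 1]]
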