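"""Synthetic-data tests: profile generation, rating designs, score simulation."""

import numpy as np
import pandas as pd
import pytest

import ratercdm as rc
from ratercdm import constants


class TestGenerateProfiles:
    def test_threshold_values_for_five_attributes(self):
        expected = [-0.9674, -0.4307, 0.0, 0.4307, 0.9674]
        assert rc.mastery_thresholds(5) == pytest.approx(expected, abs=5e-5)

    def test_marginal_mastery_rates(self):
        profiles, _ = rc.generate_profiles(100_000, 5, 0.5, seed=0)
        expected = 1 - np.arange(1, 6) / 6.0
        assert profiles.mean(axis=0) == pytest.approx(expected, abs=0.01)
        assert profiles.mean(axis=0)[2] == pytest.approx(0.5, abs=0.01)

    def test_independent_attributes_when_rho_zero(self):
        profiles, _ = rc.generate_profiles(100_000, 2, 0.0, seed=1)
        corr = np.corrcoef(profiles[:, 0], profiles[:, 1])[0, 1]
        assert abs(corr) < 0.02

    def test_positive_rho_induces_positive_profile_correlation(self):
        profiles, _ = rc.generate_profiles(50_000, 2, 0.7, seed=2)
        assert np.corrcoef(profiles[:, 0], profiles[:, 1])[0, 1] > 0.3

    def test_seed_determinism(self):
        a, theta_a = rc.generate_profiles(500, 5, 0.5, seed=7)
        b, theta_b = rc.generate_profiles(500, 5, 0.5, seed=7)
        assert np.array_equal(a, b) and np.array_equal(theta_a, theta_b)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            rc.generate_profiles(10, 2, 1.0, seed=0)


class TestBuildDesign:
    def test_complete_scores_per_rater(self):
        design = rc.build_design("complete", 500, 10)
        assert design.n_pairs == 5_000
        # 10 items × 500 ratees = 5,000 scores per rater
        assert design.assignment.sum(axis=0).tolist() == [500] * 10

    def test_balanced_column_totals(self):
        design = rc.build_design("balanced", 500, 10)
        assert design.assignment.sum(axis=0).tolist() == [150] * 10
        assert (design.assignment.sum(axis=1) == 3).all()

    def test_unbalanced_column_totals(self):
        design = rc.build_design("unbalanced", 500, 10)
        assert design.assignment.sum(axis=0).tolist() == \
            constants.UNBALANCED_COLUMN_TOTALS
        assert (design.assignment.sum(axis=1) == 3).all()

    def test_random_pair_count(self):
        design = rc.build_design("random", 500, 10, seed=3)
        assert design.n_pairs == 20 * 10 + 480 * 3
        counts = design.assignment.sum(axis=1)
        assert (counts[:20] == 10).all() and (counts[20:] == 3).all()

    @pytest.mark.parametrize("kind", ["complete", "balanced", "unbalanced", "random"])
    def test_connectivity(self, kind):
        design = rc.build_design(kind, 500, 10, seed=4)
        assert design.is_connected()

    def test_generalized_incomplete_sizes(self):
        design = rc.build_design("balanced", 120, 6, seed=0)
        assert (design.assignment.sum(axis=1) == 3).all()
        assert design.is_connected()

    def test_too_few_raters_rejected(self):
        with pytest.raises(ValueError, match="raters"):
            rc.build_design("balanced", 100, 2)

    def test_orphan_ratee_rejected(self):
        with pytest.raises(ValueError, match="no rater"):
            rc.RatingDesign(np.array([[1, 0], [0, 0]], dtype=bool), "complete")


class TestSimulateFacets:
    def test_generating_severities_sum_to_zero(self):
        assert constants.STUDY_RATER_SEVERITIES.sum() == pytest.approx(0.0, abs=1e-12)

    def test_zero_severity_single_rater_matches_lcdm_expectations(
            self, study_qmatrix, study_items):
        config = rc.SimulationConfig(study_qmatrix, study_items,
                                     [rc.RaterParams()], "facets",
                                     design="complete", n_ratees=20_000, seed=11)
        table = rc.simulate_facets(config)
        probs = rc.success_prob_table(study_items, study_qmatrix)
        weights = 2 ** np.arange(4, -1, -1)
        classes = table.true_profiles @ weights
        expected = probs[:, classes].mean(axis=1)
        observed = table.records.groupby("item")["score"].mean().to_numpy()
        assert observed == pytest.approx(expected, abs=0.01)

    def test_rater_mean_ordering_reverses_severity(self, study_qmatrix, study_items,
                                                   study_raters):
        config = rc.SimulationConfig(study_qmatrix, study_items, study_raters,
                                     "facets", design="complete", seed=5)
        table = rc.simulate_facets(config)
        means = table.rater_means().to_numpy()
        eta = constants.STUDY_RATER_SEVERITIES
        # most lenient rater (η=−2.03) scores highest, most severe (η=1.83) lowest
        assert means[np.argmin(eta)] == means.max()
        assert means[np.argmax(eta)] == means.min()
        # ordering holds for every clearly separated severity pair (near-ties
        # like η=0.55 vs 0.57 are within one-dataset sampling noise)
        for a in range(10):
            for b in range(10):
                if eta[a] - eta[b] > 0.05:
                    assert means[a] < means[b]

    def test_seed_determinism_byte_identical(self, study_qmatrix, study_items,
                                             study_raters):
        config = rc.SimulationConfig(study_qmatrix, study_items, study_raters,
                                     "facets", design="random", seed=9)
        a = rc.simulate_facets(config)
        b = rc.simulate_facets(config)
        assert a.records.equals(b.records)
        assert np.array_equal(a.true_profiles, b.true_profiles)


@pytest.fixture(scope="module")
def hrm_raters():
    return [rc.RaterParams(severity_phi=0.0, variability_psi=0.5) for _ in range(4)]


@pytest.fixture(scope="module")
def checklist():
    return rc.generate_checklist_fixture(seed=3)


class TestSimulateHRM:
    def test_tiny_variability_scores_follow_xi(self, study_qmatrix, study_items):
        raters = [rc.RaterParams(severity_phi=0.0, variability_psi=0.01)
                  for _ in range(3)]
        config = rc.SimulationConfig(study_qmatrix, study_items, raters, "hrm",
                                     design="complete", n_ratees=300, seed=13)
        table = rc.simulate_hrm(config)
        rec = table.records
        xi = table.true_xi[rec["ratee"], rec["item"]]
        assert (rec["score"].to_numpy() == xi).mean() > 0.99

    def test_agreement_rate_matches_rating_stage(self, study_qmatrix, study_items,
                                                 hrm_raters):
        config = rc.SimulationConfig(study_qmatrix, study_items, hrm_raters, "hrm",
                                     design="complete", n_ratees=1_000, seed=14)
        table = rc.simulate_hrm(config)
        rec = table.records
        xi = table.true_xi[rec["ratee"], rec["item"]]
        agree = (rec["score"].to_numpy() == xi).mean()
        assert agree == pytest.approx(0.8808, abs=0.01)

    def test_shared_xi_raises_inter_rater_agreement_over_facets(
            self, study_qmatrix, study_items):
        """Shared ideal categories correlate raters; independent facets draws
        (matched on marginal item means) do not."""
        hrm_raters = [rc.RaterParams(severity_phi=0.0, variability_psi=0.5)
                      for _ in range(2)]
        config = rc.SimulationConfig(study_qmatrix, study_items, hrm_raters, "hrm",
                                     design="complete", n_ratees=2_000, seed=15)
        hrm = rc.simulate_hrm(config)
        facets_raters = [rc.RaterParams(severity_eta=0.0) for _ in range(2)]
        config_f = rc.SimulationConfig(study_qmatrix, study_items, facets_raters,
                                       "facets", design="complete",
                                       n_ratees=2_000, seed=15)
        fac = rc.simulate_facets(config_f)

        def agreement(table):
            wide = table.records.pivot_table(index=["ratee", "item"],
                                             columns="rater", values="score")
            return (wide[0] == wide[1]).mean()

        assert agreement(hrm) > agreement(fac)

    def test_independent_xi_mode_breaks_rater_correlation(
            self, study_qmatrix, study_items, hrm_raters):
        config = rc.SimulationConfig(study_qmatrix, study_items, hrm_raters, "hrm",
                                     design="complete", n_ratees=1_500, seed=16,
                                     shared_xi=False)
        table = rc.simulate_hrm(config)
        assert table.true_xi.shape == (1_500, 10, 4)
        # conditional on the profile class, raters are now independent: the
        # within-(ratee,item) score correlation should be near the
        # between-class component only, i.e. lower than under shared xi
        shared = rc.simulate_hrm(rc.SimulationConfig(
            study_qmatrix, study_items, hrm_raters, "hrm", design="complete",
            n_ratees=1_500, seed=16, shared_xi=True))

        def pair_agreement(table):
            wide = table.records.pivot_table(index=["ratee", "item"],
                                             columns="rater", values="score")
            return (wide[0] == wide[1]).mean()

        assert pair_agreement(shared) > pair_agreement(table)


class TestChecklistFixture:
    def test_dimensions(self, checklist):
        table = checklist.ratings
        assert (table.n_ratees, table.n_items, table.n_raters) == (287, 52, 9)
        readers = table.records.groupby("ratee")["rater"].nunique()
        assert readers.isin([1, 2]).all()

    def test_qmatrix_column_sums(self, checklist):
        assert checklist.qmatrix.entries.sum(axis=0).tolist() == [11, 20, 28, 23, 5, 7]

    def test_severe_rater_scores_lower_than_lenient(self, checklist):
        means = checklist.ratings.rater_means()
        # rater 1 (φ=0.40) is the most severe; rater 8 (ψ=1.28) is noisy-lenient
        assert means[0] < means[7]
        assert means[0] == checklist.ratings.rater_means().min()

    def test_truth_retained_and_dina_items(self, checklist):
        assert checklist.ratings.true_profiles.shape == (287, 6)
        assert all(p.constraint_tag == "DINA" for p in checklist.item_params)


class TestRatingsTableValidation:
    def test_duplicate_triples_rejected(self):
        rec = pd.DataFrame({"ratee": [0, 0], "item": [1, 1], "rater": [2, 2],
                            "score": [1, 0]})
        with pytest.raises(ValueError, match="duplicate"):
            rc.RatingsTable(rec, 1, 2, 3)

    def test_non_binary_scores_rejected(self):
        rec = pd.DataFrame({"ratee": [0], "item": [0], "rater": [0], "score": [2]})
        with pytest.raises(ValueError, match="binary"):
            rc.RatingsTable(rec, 1, 1, 1)
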