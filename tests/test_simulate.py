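import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icamp.concordance import concordance_summary, label_gene
from icamp.simulate import (
    SurvivalTruth,
    generate_direction_evidence,
    generate_multistudy,
    generate_survival_cohort,
)
from icamp.survival import logrank_test


class TestMultistudy:
    def test_same_seed_reproduces_everything(self):
        a_studies, a_truth = generate_multistudy(
            n_genes=100, n_consistent_up=10, n_consistent_down=10,
            n_sporadic=10, n_per_class=3, seed=7)
        b_studies, b_truth = generate_multistudy(
            n_genes=100, n_consistent_up=10, n_consistent_down=10,
            n_sporadic=10, n_per_class=3, seed=7)
        assert a_truth == b_truth
        for sa, sb in zip(a_studies, b_studies):
            pd.testing.assert_frame_equal(sa.values, sb.values)

    def test_distinct_seeds_differ(self):
        a, _ = generate_multistudy(n_genes=100, n_consistent_up=10,
                                   n_consistent_down=10, n_sporadic=10,
                                   n_per_class=3, seed=1)
        b, _ = generate_multistudy(n_genes=100, n_consistent_up=10,
                                   n_consistent_down=10, n_sporadic=10,
                                   n_per_class=3, seed=2)
        assert not a[0].values.equals(b[0].values)

    def test_truth_bookkeeping_matches_request(self):
        _, truth = generate_multistudy(
            n_genes=500, n_consistent_up=50, n_consistent_down=30,
            n_sporadic=20, n_per_class=3, seed=0)
        assert len(truth.genes_in("consistent_up")) == 50
        assert len(truth.genes_in("consistent_down")) == 30
        assert len(truth.genes_in("sporadic")) == 20
        assert len(truth.genes_in("null")) == 400

    def test_consistent_effects_share_sign_in_every_study(self):
        _, truth = generate_multistudy(n_genes=200, n_consistent_up=20,
                                       n_consistent_down=20, n_sporadic=10,
                                       n_per_class=3, seed=3)
        for g in truth.genes_in("consistent_up"):
            assert all(truth.effects[s][g] > 0 for s in truth.effects)
        for g in truth.genes_in("consistent_down"):
            assert all(truth.effects[s][g] < 0 for s in truth.effects)

    def test_sporadic_gene_dysregulated_in_exactly_one_study(self):
        _, truth = generate_multistudy(n_genes=200, n_consistent_up=20,
                                       n_consistent_down=20, n_sporadic=30,
                                       n_per_class=3, seed=4)
        for g in truth.genes_in("sporadic"):
            hits = [s for s in truth.effects if g in truth.effects[s]]
            assert len(hits) == 1

    def test_planted_effect_three_is_detectable_by_t_test(self):
        # power oracle: the generator's planted shift must be recoverable
        rejections = 0
        for seed in range(100):
            studies, truth = generate_multistudy(
                n_studies=1, n_genes=20, n_consistent_up=1,
                n_consistent_down=0, n_sporadic=0,
                effect_log2_range=(3.0, 3.0), n_per_class=20, seed=seed)
            g = truth.genes_in("consistent_up")[0]
            row = studies[0].values.loc[g]
            t = stats.ttest_ind(row[studies[0].sample_ids("cancer")],
                                row[studies[0].sample_ids("normal")])
            rejections += t.pvalue < 1e-6
        assert rejections >= 95

    def test_missing_fraction_drops_genes(self):
        studies, _ = generate_multistudy(n_genes=400, n_consistent_up=20,
                                         n_consistent_down=20, n_sporadic=20,
                                         n_per_class=3,
                                         missing_fraction=0.2, seed=5)
        sizes = [len(s.genes) for s in studies]
        assert all(250 < n < 370 for n in sizes)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            generate_multistudy(n_genes=10, n_consistent_up=20, seed=0)


class TestSurvivalCohortGenerator:
    def test_same_seed_reproduces_cohort(self):
        truth = SurvivalTruth({"A": 0.5}, n_null_genes=2)
        a = generate_survival_cohort(truth, 50, seed=1)
        b = generate_survival_cohort(truth, 50, seed=1)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_censoring_rate_achieved_within_tolerance(self):
        truth = SurvivalTruth({"A": 0.3}, n_null_genes=3, censoring_rate=0.3)
        cohort = generate_survival_cohort(truth, 2000, seed=2)
        assert 1 - cohort.events.mean() == pytest.approx(0.30, abs=0.05)

    def test_single_gene_hazard_ratio_recovered(self):
        truth = SurvivalTruth({"A": float(np.log(2.0))})
        cohort = generate_survival_cohort(truth, 1000, seed=3)
        from icamp.survival import _cox_hr

        hr, _ = _cox_hr(cohort.times, cohort.events, cohort.expression("A"))
        assert 1.8 <= hr <= 2.2

    def test_null_genes_show_no_survival_separation(self):
        # expression-split log-rank stays non-significant in >= 90% of seeds
        nonsig = 0
        for seed in range(100):
            truth = SurvivalTruth({}, n_null_genes=1, censoring_rate=0.2)
            cohort = generate_survival_cohort(truth, 80, seed=seed)
            x = cohort.expression("NULL000")
            hi = x > np.median(x)
            _, p = logrank_test(cohort.times[hi], cohort.events[hi],
                                cohort.times[~hi], cohort.events[~hi])
            nonsig += (not np.isfinite(p)) or p > 0.05
        assert nonsig >= 90

    def test_invalid_censoring_rejected(self):
        with pytest.raises(ValueError, match="censoring"):
            SurvivalTruth({"A": 0.1}, censoring_rate=1.0)


def expected_concordance(sensitivity, fcr, n_datasets=6):
    """Enumeration oracle: P(label matches direction) for a true 'up' gene.

    Sums multinomial probabilities of every (n_up, n_down) outcome and
    applies the labeling rule to each.
    """
    p_up = sensitivity
    p_down = (1 - sensitivity) * fcr
    p_none = 1 - p_up - p_down
    total = 0.0
    for n_up in range(n_datasets + 1):
        for n_down in range(n_datasets - n_up + 1):
            n_rest = n_datasets - n_up - n_down
            prob = (
                math.factorial(n_datasets)
                / (math.factorial(n_up) * math.factorial(n_down)
                   * math.factorial(n_rest))
                * p_up**n_up * p_down**n_down * p_none**n_rest
            )
            from icamp.concordance import DirectionEvidence

            if label_gene(DirectionEvidence("G", n_up, n_down,
                                            n_datasets)) == "elevated":
                total += prob
    return total


class TestDirectionEvidenceGenerator:
    def test_perfect_sensitivity_no_false_calls(self):
        evs = generate_direction_evidence({"A": "up", "B": "down"},
                                          sensitivity=1.0,
                                          false_call_rate=0.0, seed=0)
        by_gene = {e.gene: e for e in evs}
        assert by_gene["A"].n_up == by_gene["A"].n_tested
        assert by_gene["A"].n_down == 0
        assert by_gene["B"].n_down == by_gene["B"].n_tested

    def test_zero_sensitivity_yields_unchanged_labels(self):
        evs = generate_direction_evidence({f"G{i}": "up" for i in range(20)},
                                          sensitivity=0.0,
                                          false_call_rate=0.0, seed=1)
        assert all(label_gene(e) == "unchanged" for e in evs)

    def test_concordance_matches_enumeration_oracle(self):
        truth = {f"G{i:03d}": "up" for i in range(500)}
        evs = generate_direction_evidence(truth, sensitivity=0.8,
                                          false_call_rate=0.05, seed=2)
        labels = {e.gene: label_gene(e) for e in evs}
        summary = concordance_summary(labels, [(g, "up") for g in truth])
        observed = summary.n_concordant / 500
        assert observed == pytest.approx(
            expected_concordance(0.8, 0.05), abs=0.1)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="sensitivity"):
            generate_direction_evidence({"A": "up"}, sensitivity=1.5)
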