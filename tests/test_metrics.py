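"""Expected error counts, precision/recall, twin predictions, consensus."""

import math

import numpy as np
import pytest

from pederr.metrics import (
    NO_CONSENSUS,
    consensus_genotypes,
    expected_error_counts,
    metrics_from_confusion,
    observed_twin_mismatches,
    precision_recall,
    predict_twin_mismatches,
)
from pederr.model import ErrorParamKey, ErrorRateTable, param_keys


def _rate_table(structure, overrides=None, default=0.0, parents_na=True):
    rates = {}
    for k in param_keys(structure):
        if parents_na and k.member_index < 2 and (k.true_gt, k.observed) in {(0, 1), (2, 1)}:
            rates[k] = None
        else:
            rates[k] = default
    if overrides:
        for (i, g, c), v in overrides.items():
            rates[ErrorParamKey(i, g, c)] = v
    return ErrorRateTable(structure, rates)


class TestExpectedErrorCounts:
    def test_direct_product(self, quad_structure):
        rates = _rate_table(quad_structure, {(2, 1, 0): 0.001})
        observed = np.zeros((4, 3))
        observed[2, 1] = 10_000
        est = expected_error_counts(rates, observed)
        assert est.member(2)[1, 0] == pytest.approx(10.0)

    def test_error_free_limit(self, quad_structure):
        rates = _rate_table(quad_structure)
        observed = np.array([[5.0, 3.0, 2.0]] * 4)
        est = expected_error_counts(rates, observed)
        W = est.member(2)
        assert np.allclose(np.diag(W[:, :3]), [5, 3, 2])
        off = W.copy()
        off[[0, 1, 2], [0, 1, 2]] = 0
        assert np.allclose(off, 0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_row_sums_conserve_observed_counts(self, quad_structure, seed):
        """sum_c E[W_{g->c}] = x_hat_g whenever the row's rates are complete."""
        rng = np.random.default_rng(seed)
        overrides = {
            (i, g, c): rng.uniform(0, 0.01)
            for i in range(4)
            for g in (0, 1, 2)
            for c in (0, 1, 2, 3)
            if c != g and not (i < 2 and (g, c) in {(0, 1), (2, 1)})
        }
        rates = _rate_table(quad_structure, overrides)
        observed = rng.integers(100, 10_000, size=(4, 3)).astype(float)
        est = expected_error_counts(rates, observed)
        for i in (2, 3):  # children: all nine rates present
            assert np.allclose(est.member(i).sum(axis=1), observed[i])

    def test_pathological_fit_rejected(self, quad_structure):
        rates = _rate_table(quad_structure, {(2, 1, 0): 0.7, (2, 1, 2): 0.4})
        with pytest.raises(ValueError, match="sum above 1"):
            expected_error_counts(rates, np.ones((4, 3)))


class TestPrecisionRecall:
    def test_het_precision_ratio(self):
        W = np.zeros((3, 4))
        W[1, 1] = 990
        W[0, 1] = 5
        W[2, 1] = 5
        W[1, :] = [0, 990, 0, 0]
        m = metrics_from_confusion(W)
        assert m.precision_het == pytest.approx(0.99)
        assert m.recall_het == pytest.approx(1.0)

    def test_perfect_calls(self, quad_structure):
        rates = _rate_table(quad_structure)
        observed = np.array([[100.0, 50.0, 25.0]] * 4)
        mets = precision_recall(expected_error_counts(rates, observed))
        for i in (2, 3):
            for v in mets[i].as_dict().values():
                assert v == pytest.approx(1.0)

    def test_parent_het_precision_is_na(self, quad_structure):
        rates = _rate_table(quad_structure)
        observed = np.array([[100.0, 50.0, 25.0]] * 4)
        mets = precision_recall(expected_error_counts(rates, observed))
        assert math.isnan(mets[0].precision_het)
        assert math.isnan(mets[1].precision_homalt)

    def test_false_positive_rate_lowers_het_precision(self, quad_structure):
        observed = np.array([[10_000.0, 1000.0, 200.0]] * 4)
        prev = 1.1
        for fp in (0.0001, 0.001, 0.01):
            rates = _rate_table(quad_structure, {(2, 0, 1): fp})
            m = precision_recall(expected_error_counts(rates, observed))[2]
            assert m.precision_het < prev
            prev = m.precision_het

    def test_metrics_bounded(self, small_dataset):
        from pederr.model import build_design, fit_error_rates

        mask = small_dataset.informative_mask()
        for fam in small_dataset.families:
            counts = small_dataset.counts_for(fam, mask)
            rates = fit_error_rates(build_design(counts))
            est = expected_error_counts(rates, counts.observed_genotype_counts())
            for m in precision_recall(est).values():
                for v in m.as_dict().values():
                    assert math.isnan(v) or 0.0 <= v <= 1.0

    def test_f1_zero_when_nothing_recovered(self):
        W = np.zeros((3, 4))
        W[1, 0] = 10  # every true het called hom-ref
        W[0, 1] = 4  # and some spurious hets
        m = metrics_from_confusion(W)
        assert m.precision_het == 0 and m.recall_het == 0 and m.f1_het == 0


class TestTwinMismatches:
    def test_error_free_twins_expect_no_mismatches(self, quad_structure):
        rates = _rate_table(quad_structure, parents_na=False)
        observed = np.array([[100.0, 50.0, 25.0]] * 4)
        est = expected_error_counts(rates, observed)
        pred = predict_twin_mismatches(est, 2, est, 3)
        assert pred.total == 0.0

    def test_sum_of_both_directions(self, quad_structure):
        # twin A: 0/1 -> 0/0 errors; twin B: 0/0 -> 0/1 errors
        rates_a = _rate_table(quad_structure, {(2, 1, 0): 3e-4}, parents_na=False)
        rates_b = _rate_table(quad_structure, {(3, 0, 1): 2e-4}, parents_na=False)
        observed = np.zeros((4, 3))
        observed[2, 1] = 10_000  # A called het at 10k sites
        observed[3, 0] = 10_000  # B called hom-ref at 10k sites
        est_a = expected_error_counts(rates_a, observed)
        est_b = expected_error_counts(rates_b, observed)
        pred = predict_twin_mismatches(est_a, 2, est_b, 3)
        # category (A=0/0, B=0/1): A's 0/1->0/0 plus B's 0/0->0/1
        assert pred.ordered[(0, 1)] == pytest.approx(3 + 2)
        assert pred.unordered[(0, 1)] == pytest.approx(5)
        assert pred.total == pytest.approx(5)
        assert pred.total_genotype_only == pytest.approx(5)

    def test_observed_mismatch_tally(self):
        a = np.array([0, 0, 1, 2, 3, 1], dtype=np.int8)
        b = np.array([0, 1, 1, 0, 3, 3], dtype=np.int8)
        obs = observed_twin_mismatches(a, b)
        assert obs[(0, 1)] == 1 and obs[(2, 0)] == 1 and obs[(1, 3)] == 1
        assert sum(obs.values()) == 3

    def test_mismatched_site_sets_rejected(self):
        with pytest.raises(ValueError, match="same site set"):
            observed_twin_mismatches(np.zeros(5, dtype=np.int8), np.zeros(6, dtype=np.int8))


class TestConsensus:
    def test_unanimous_site(self):
        calls = np.array([[1, 1, 1, 1]], dtype=np.int8)
        truth, mets, conf = consensus_genotypes(calls)
        assert truth[0] == 1
        for m in mets:
            assert m.precision_het == 1.0 and m.recall_het == 1.0

    def test_three_of_four_majority_charges_dissenter(self):
        calls = np.array([[1, 1, 1, 0]], dtype=np.int8)
        truth, mets, conf = consensus_genotypes(calls, min_agree=3)
        assert truth[0] == 1
        assert conf[3][1, 0] == 1  # dissenter: true het called hom-ref
        assert mets[3].recall_het == 0.0

    def test_two_two_split_excluded(self):
        calls = np.array([[1, 1, 0, 0], [2, 2, 2, 2]], dtype=np.int8)
        truth, _, conf = consensus_genotypes(calls, min_agree=3)
        assert truth[0] == NO_CONSENSUS
        assert truth[1] == 2
        assert conf[0].sum() == 1  # only the consensus site is scored

    def test_missing_calls_do_not_vote(self):
        calls = np.array([[1, 1, 1, 3]], dtype=np.int8)
        truth, mets, conf = consensus_genotypes(calls, min_agree=3)
        assert truth[0] == 1
        assert conf[3][1, 3] == 1  # missing at a consensus het site: a miss

    def test_majority_threshold_enforced(self):
        calls = np.zeros((3, 4), dtype=np.int8)
        with pytest.raises(ValueError, match="strict majority"):
            consensus_genotypes(calls, min_agree=2)
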