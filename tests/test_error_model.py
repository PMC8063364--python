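"""The Poisson design, constrained MLE, identifiability, and Le Cam bound."""

import numpy as np
import pytest
import scipy.sparse

from pederr.genotypes import FamilyGenotypeCounts
from pederr.model import (
    DesignSystem,
    ErrorParamKey,
    ErrorRateTable,
    build_design,
    fit_error_rates,
    identifiability_report,
    lecam_bound,
    param_keys,
)


def _quad_counts(quad_structure, extra=None):
    counts = {
        (0, 1, 1, 0): 5000,
        (0, 0, 0, 0): 80_000,
        (1, 0, 1, 0): 4000,
        (0, 0, 1, 0): 7,  # Mendelian error: het child of hom-ref parents
    }
    if extra:
        counts.update(extra)
    return FamilyGenotypeCounts(quad_structure, counts, sum(counts.values()))


def test_nine_parameters_per_member(quad_structure):
    keys = param_keys(quad_structure)
    assert len(keys) == 9 * quad_structure.size
    for i in range(quad_structure.size):
        mine = [k for k in keys if k.member_index == i]
        assert len(mine) == 9
        assert {(k.true_gt, k.observed) for k in mine} == {
            (g, c) for g in (0, 1, 2) for c in (0, 1, 2, 3) if c != g
        }


class TestBuildDesign:
    def test_worked_example_row(self, quad_structure):
        design = build_design(_quad_counts(quad_structure))
        r = design.row_tuples.index((0, 0, 1, 0))
        row = design.matrix[r].toarray().ravel()
        nz = {design.columns[j]: row[j] for j in np.nonzero(row)[0]}
        assert nz == {
            ErrorParamKey(1, 1, 0): 5000.0,  # father het read as hom-ref
            ErrorParamKey(2, 0, 1): 80_000.0,  # child het where none existed
            ErrorParamKey(0, 1, 0): 4000.0,  # mother het read as hom-ref
        }
        assert design.y[r] == 7

    def test_all_valid_counts_give_zero_y(self, quad_structure):
        design = build_design(
            FamilyGenotypeCounts(
                quad_structure, {(0, 0, 0, 0): 100, (0, 1, 1, 0): 10}, 110
            )
        )
        assert np.all(design.y == 0)

    def test_unattributable_tuple_dropped(self, quad_structure):
        design = build_design(_quad_counts(quad_structure, {(3, 3, 0, 0): 4}))
        assert ((3, 3, 0, 0), 4) in design.dropped_rows
        assert (3, 3, 0, 0) not in design.row_tuples

    def test_empty_counts_rejected(self, quad_structure):
        with pytest.raises(ValueError):
            build_design(FamilyGenotypeCounts(quad_structure, {}, 0))


class TestFit:
    def test_single_rate_closed_form(self, quad_structure):
        """One row, one active column: the MLE is events/exposure."""
        design = build_design(_quad_counts(quad_structure))
        # zero out everything except the single (0,0,1,0) row to isolate
        keep = design.row_tuples.index((0, 0, 1, 0))
        sub = DesignSystem(
            design.structure,
            [design.row_tuples[keep]],
            np.array([5.0]),
            scipy.sparse.csr_matrix(
                ([1000.0], ([0], [design.column_index[ErrorParamKey(2, 0, 1)]])),
                shape=(1, len(design.columns)),
            ),
            design.columns,
        )
        rates = fit_error_rates(sub)
        assert rates.rate(2, 0, 1) == pytest.approx(0.005, rel=1e-6)

    def test_zero_events_give_zero_rate(self, quad_structure):
        counts = FamilyGenotypeCounts(
            quad_structure, {(0, 0, 0, 0): 50_000, (0, 1, 1, 0): 5000}, 55_000
        )
        rates = fit_error_rates(build_design(counts))
        assert rates.rate(2, 0, 1) == pytest.approx(0.0, abs=1e-9)

    def test_doubling_counts_leaves_rates_invariant(self, quad_structure):
        counts = _quad_counts(quad_structure)
        r1 = fit_error_rates(build_design(counts), tol=1e-12)
        r2 = fit_error_rates(build_design(counts.scaled(2)), tol=1e-12)
        for k, v in r1.rates.items():
            if v is None:
                assert r2.rates[k] is None
            elif v > 1e-8:
                assert r2.rates[k] == pytest.approx(v, rel=1e-3)

    def test_no_rate_is_negative(self, small_dataset):
        mask = small_dataset.informative_mask()
        for fam in small_dataset.families:
            rates = fit_error_rates(build_design(small_dataset.counts_for(fam, mask)))
            assert all(v >= 0 for v in rates.rates.values() if v is not None)

    def test_all_zero_design_rejected(self, quad_structure):
        design = build_design(
            FamilyGenotypeCounts(quad_structure, {(3, 3, 3, 3): 5}, 5)
        )
        with pytest.raises(ValueError):
            fit_error_rates(design)


class TestIdentifiability:
    def test_parental_het_gain_columns_structurally_zero(self, quad_structure):
        report = set(identifiability_report(build_design(_quad_counts(quad_structure))))
        for parent in (0, 1):
            assert ErrorParamKey(parent, 0, 1) in report  # 0/0 -> 0/1
            assert ErrorParamKey(parent, 2, 1) in report  # 1/1 -> 0/1

    def test_child_het_gain_columns_identifiable(self, quad_structure):
        report = set(identifiability_report(build_design(_quad_counts(quad_structure))))
        assert ErrorParamKey(2, 0, 1) not in report
        assert ErrorParamKey(3, 0, 1) not in report

    def test_empty_system_identifies_nothing(self, quad_structure):
        design = build_design(
            FamilyGenotypeCounts(quad_structure, {(3, 3, 3, 3): 5}, 5)
        )
        assert set(identifiability_report(design)) == set(design.columns)

    def test_unidentifiable_reported_as_marker_not_zero(self, small_dataset):
        mask = small_dataset.informative_mask()
        fam = small_dataset.families[0]
        rates = fit_error_rates(build_design(small_dataset.counts_for(fam, mask)))
        assert rates.rate(0, 0, 1) is None
        assert rates.rate(1, 2, 1) is None


class TestLeCamBound:
    def _table(self, structure, rate):
        rates = {k: 0.0 for k in param_keys(structure)}
        rates[ErrorParamKey(0, 0, 1)] = rate
        return ErrorRateTable(structure, rates)

    def test_zero_rates_zero_bound(self, trio_structure):
        counts = FamilyGenotypeCounts(trio_structure, {(0, 0, 0): 100}, 100)
        assert lecam_bound(counts, self._table(trio_structure, 0.0)) == 0.0

    def test_direct_formula(self, trio_structure):
        # delta_v = 0.01 via a single 1% miscall rate on the mother at 0/0
        counts = FamilyGenotypeCounts(trio_structure, {(0, 0, 0): 100}, 100)
        bound = lecam_bound(counts, self._table(trio_structure, 0.01))
        assert bound == pytest.approx(2 * 100 * 0.01**2)

    def test_monotone_in_rates(self, trio_structure):
        counts = FamilyGenotypeCounts(
            trio_structure, {(0, 0, 0): 500, (1, 1, 1): 200}, 700
        )
        bounds = [
            lecam_bound(counts, self._table(trio_structure, r))
            for r in (0.001, 0.005, 0.02)
        ]
        assert bounds == sorted(bounds)
        assert all(b >= 0 for b in bounds)


class TestOracleEquivalence:
    """Small systems solved by an independent refining grid search."""

    @staticmethod
    def _grid_search(A, y, ub, rounds=14, points=21):
        """Brute-force maximizer of the Poisson log-likelihood over a box,
        by iterative grid refinement; no derivative information used."""
        lo = np.zeros(A.shape[1])
        hi = np.full(A.shape[1], ub)
        best = None
        for _ in range(rounds):
            axes = [np.linspace(lo[j], hi[j], points) for j in range(A.shape[1])]
            mesh = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], 1)
            mu = mesh @ A.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = (y * np.log(np.maximum(mu, 1e-300))).sum(1) - mu.sum(1)
            best = mesh[np.argmax(ll)]
            step = (hi - lo) / (points - 1)
            lo = np.maximum(best - 2 * step, 0.0)
            hi = best + 2 * step
        return best

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fit_matches_grid_search(self, seed, quad_structure):
        rng = np.random.default_rng(seed)
        p_true = rng.uniform(1e-4, 5e-3, 3)
        A = rng.integers(5_000, 80_000, size=(5, 3)).astype(float)
        A[rng.random((5, 3)) < 0.3] = 0.0
        A[0, :] = [30_000, 0, 0]  # anchor each parameter in some row
        A[1, :] = [0, 30_000, 0]
        A[2, :] = [0, 0, 30_000]
        y = rng.poisson(A @ p_true).astype(float)
        cols = param_keys(quad_structure)[:3]
        design = DesignSystem(
            quad_structure,
            [(0, 0, 1, 0)] * 5,
            y,
            scipy.sparse.csr_matrix(A),
            cols,
        )
        fitted = np.array(
            [fit_error_rates(design, tol=1e-15).rates[c] for c in cols]
        )
        oracle = self._grid_search(A, y, ub=10 * p_true.max())
        assert np.all(np.abs(fitted - oracle) <= 1e-6)
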