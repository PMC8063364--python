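"""Simulation-study drivers: recovery, twin and consensus experiments.

Each experiment simulates a cohort under the model's assumed generative
process, runs the estimation pipeline on the observed calls only, and scores
the estimates against the simulator's exact ground truth.  They are used by
the test suite and by ``scripts/acceptance.py``; all randomness derives from
the single seed argument.
"""

from __future__ import annotations

import math
from typing import Dict, List

import numpy as np

from .genotypes import FamilyStructure
from .metrics import (
    consensus_genotypes,
    expected_error_counts,
    observed_twin_mismatches,
    precision_recall,
    predict_twin_mismatches,
)
from .model import build_design, fit_error_rates, identifiability_report
from .simulate import SimulatedDataset, SimulationSpec, simulate_dataset, true_metrics

__all__ = [
    "rate_recovery_experiment",
    "twin_band_experiment",
    "consensus_experiment",
]

_METRIC_NAMES = ("precision_het", "recall_het", "precision_homalt", "recall_homalt")


def rate_recovery_experiment(
    seed: int,
    n_families: int = 50,
    children_per_family: int = 2,
    n_sites: int = 1_000_000,
) -> Dict[str, object]:
    """Fit every simulated family and score child rate and metric recovery.

    Returns per-child relative errors of the identifiable error-rate
    estimates, absolute errors of estimated vs true precision/recall, and
    the identifiability audit (are the parental 0/0→0/1 and 1/1→0/1 columns
    structurally zero in every family?).
    """
    spec = SimulationSpec(
        n_families=n_families,
        children_per_family=children_per_family,
        n_sites=n_sites,
        seed=seed,
    )
    ds = simulate_dataset(spec)
    mask = ds.informative_mask()

    rel_errors: List[float] = []
    metric_abs_err: Dict[str, List[float]] = {m: [] for m in _METRIC_NAMES}
    parental_unidentifiable_ok = True
    parental_keys_expected = {(0, 1), (2, 1)}  # (true g, observed c): 0/0->0/1, 1/1->0/1
    for fam in ds.families:
        counts = ds.counts_for(fam, mask)
        design = build_design(counts)
        zero_cols = set(identifiability_report(design))
        for parent in (0, 1):
            for g, c in parental_keys_expected:
                if (parent, g, c) not in {tuple(k) for k in zero_cols}:
                    parental_unidentifiable_ok = False
        rates = fit_error_rates(design)
        est = expected_error_counts(rates, counts.observed_genotype_counts())
        mets = precision_recall(est)
        for ci in range(2, fam.size):
            sid = fam.member_ids[ci]
            P_true = ds.true_rates[sid]
            for g in (0, 1, 2):
                for c in (0, 1, 2, 3):
                    if c == g:
                        continue
                    p_hat = rates.rate(ci, g, c)
                    if p_hat is None:
                        continue
                    rel_errors.append(abs(p_hat - P_true[g, c]) / P_true[g, c])
            truth = true_metrics(ds.true_confusion(sid, mask)).as_dict()
            est_m = mets[ci].as_dict()
            for m in _METRIC_NAMES:
                metric_abs_err[m].append(abs(est_m[m] - truth[m]))

    return {
        "median_rate_relative_error": float(np.median(rel_errors)),
        "n_child_rates": len(rel_errors),
        "metric_median_abs_error": {
            m: float(np.median(v)) for m, v in metric_abs_err.items()
        },
        "metric_abs_errors": metric_abs_err,
        "n_children": n_families * children_per_family,
        "parental_het_columns_all_unidentifiable": parental_unidentifiable_ok,
        "dataset": ds,
    }


def _fit_member_expected_counts(
    ds: SimulatedDataset,
    structure: FamilyStructure,
    member_id: str,
    mask: np.ndarray,
):
    """Fit the given (possibly reduced) family structure and return the
    expected error counts plus the member's index within it."""
    counts = ds.counts_for(structure, mask)
    rates = fit_error_rates(build_design(counts))
    est = expected_error_counts(rates, counts.observed_genotype_counts())
    return est, structure.member_ids.index(member_id)


def twin_band_experiment(
    seed: int, n_pairs: int = 30, n_sites: int = 500_000
) -> Dict[str, object]:
    """Predicted vs observed mismatch totals for monozygotic twin pairs.

    Each simulated family carries an MZ copy of its first child; each twin's
    rates come from a fit on the non-twin family members (parents + twin +
    ordinary sibling, the co-twin excluded).  A pair is 'covered' when the
    observed total mismatch count falls within three Poisson standard
    deviations (3*sqrt(expected)) of the prediction.
    """
    spec = SimulationSpec(
        n_families=n_pairs,
        children_per_family=2,
        n_sites=n_sites,
        duplicate_first_child=True,
        seed=seed,
    )
    ds = simulate_dataset(spec)
    mask = ds.informative_mask()
    covered = 0
    rows = []
    for fam, (a, b) in zip(ds.families, ds.twin_pairs()):
        est_a, ia = _fit_member_expected_counts(
            ds, fam.drop_children([c for c in fam.child_ids if c != b]), a, mask
        )
        est_b, ib = _fit_member_expected_counts(
            ds, fam.drop_children([c for c in fam.child_ids if c != a]), b, mask
        )
        pred = predict_twin_mismatches(est_a, ia, est_b, ib)
        obs = observed_twin_mismatches(
            ds.observed_calls(a)[mask], ds.observed_calls(b)[mask]
        )
        obs_total = sum(obs.values())
        band = 3.0 * math.sqrt(pred.total)
        inside = abs(obs_total - pred.total) <= band
        covered += inside
        rows.append(
            {
                "pair": f"{a}|{b}",
                "expected": pred.total,
                "observed": obs_total,
                "within_3sigma": bool(inside),
            }
        )
    return {
        "fraction_within_3sigma": covered / n_pairs,
        "n_pairs": n_pairs,
        "pairs": rows,
    }


def consensus_experiment(
    seed: int, n_families: int = 4, n_sites: int = 1_000_000, min_agree: int = 3
) -> Dict[str, object]:
    """Family-based vs replicate-consensus precision/recall on simulated
    monozygotic quadruplets.

    Family-based metrics for each replicate come from the fit of the
    quadruplet family as constituted (parents + all four replicates);
    consensus metrics use the >=3-of-4 agreement call as ground truth.
    Reports absolute differences between the two routes.
    """
    spec = SimulationSpec(
        n_families=n_families,
        children_per_family=4,
        n_sites=n_sites,
        monozygotic=True,
        seed=seed,
    )
    ds = simulate_dataset(spec)
    mask = ds.informative_mask()
    diffs: List[float] = []
    per_metric: Dict[str, List[float]] = {m: [] for m in _METRIC_NAMES}
    for fam in ds.families:
        calls = np.stack([ds.observed_calls(c)[mask] for c in fam.child_ids], axis=1)
        _, consensus_mets, _ = consensus_genotypes(calls, min_agree=min_agree)
        counts = ds.counts_for(fam, mask)
        rates = fit_error_rates(build_design(counts))
        est = expected_error_counts(rates, counts.observed_genotype_counts())
        fam_mets = precision_recall(est)
        for child_id, cons in zip(fam.child_ids, consensus_mets):
            ci = fam.member_ids.index(child_id)
            fam_m = fam_mets[ci].as_dict()
            cons_m = cons.as_dict()
            for m in _METRIC_NAMES:
                d = abs(fam_m[m] - cons_m[m])
                per_metric[m].append(d)
                diffs.append(d)
    return {
        "max_abs_difference": float(np.max(diffs)),
        "median_abs_difference": float(np.median(diffs)),
        "per_metric_max": {m: float(np.max(v)) for m, v in per_metric.items()},
        "n_replicates": n_families * 4,
    }
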