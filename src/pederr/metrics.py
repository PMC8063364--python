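"""Precision/recall and validation metrics derived from fitted error rates.

The bridge from rates to metrics is the expected-error-count matrix: with
``x_g`` the number of sites at which an individual truly has genotype ``g``
(estimated by the number of sites at which the individual was *called* ``g``,
errors being rare), the expected number of g→c events is

    E[W_{g→c}] = x_g * P(C_g = c)

Precision and recall at het and hom-alt sites are then ratios of these
expected counts, e.g. precision_het = E[W_{0/1→0/1}] / sum_g E[W_{g→0/1}].
The same ratio formulas applied to *exact* confusion counts (from a
simulator's truth log, or from replicate-consensus calls) give the reference
values the model estimates are validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .genotypes import GT_LABELS, FamilyStructure
from .model import ErrorRateTable

__all__ = [
    "SampleMetrics",
    "ErrorCountEstimates",
    "expected_error_counts",
    "precision_recall",
    "metrics_from_confusion",
    "predict_twin_mismatches",
    "observed_twin_mismatches",
    "TwinMismatchPrediction",
    "consensus_genotypes",
    "NO_CONSENSUS",
]

#: Sentinel used in consensus truth vectors at sites with no majority call.
NO_CONSENSUS = -1


@dataclass(frozen=True)
class SampleMetrics:
    """Per-individual precision/recall/F1 at het and hom-alt sites.

    NaN marks values that cannot be computed (unidentifiable inputs or an
    empty denominator); F1 is the harmonic mean, defined as 0 when
    precision + recall = 0.
    """

    precision_het: float
    recall_het: float
    f1_het: float
    precision_homalt: float
    recall_homalt: float
    f1_homalt: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "precision_het": self.precision_het,
            "recall_het": self.recall_het,
            "f1_het": self.f1_het,
            "precision_homalt": self.precision_homalt,
            "recall_homalt": self.recall_homalt,
            "f1_homalt": self.f1_homalt,
        }


@dataclass
class ErrorCountEstimates:
    """Per-member 3x4 matrices W[g, c] of expected call counts.

    Row ``g`` sums to the member's observed genotype count x_hat_g when all
    rates for ``g`` are identifiable; NaN cells propagate unidentifiability.
    """

    structure: FamilyStructure
    W: Dict[int, np.ndarray]  # member_index -> 3x4

    def member(self, member_index: int) -> np.ndarray:
        return self.W[member_index]


def expected_error_counts(
    rates: ErrorRateTable, observed_counts: np.ndarray
) -> ErrorCountEstimates:
    """E[W_{g→c}] = x_hat_g * P(C_g = c) for every member.

    ``observed_counts`` is the (size x 3) matrix of observed genotype counts
    from the same site set as the fit.  Raises if any member's fitted error
    rates for a genotype sum above 1 (a pathological fit that would imply a
    negative correct-call count).
    """
    structure = rates.structure
    observed_counts = np.asarray(observed_counts, dtype=float)
    if observed_counts.shape != (structure.size, 3):
        raise ValueError("observed_counts must be (family size x 3)")
    W: Dict[int, np.ndarray] = {}
    for i in range(structure.size):
        P = rates.member_matrix(i)
        diag = P[[0, 1, 2], [0, 1, 2]]
        if np.any(diag < 0.0):
            bad = [GT_LABELS[g] for g in range(3) if diag[g] < 0]
            raise ValueError(
                f"pathological fit for {structure.member_ids[i]}: error rates at "
                f"{bad} sum above 1"
            )
        W[i] = observed_counts[i][:, None] * P
    return ErrorCountEstimates(structure, W)


def _ratio(num: float, den: float) -> float:
    if math.isnan(num) or math.isnan(den) or den == 0:
        return float("nan")
    return num / den


def _f1(p: float, r: float) -> float:
    if math.isnan(p) or math.isnan(r):
        return float("nan")
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def metrics_from_confusion(W: np.ndarray) -> SampleMetrics:
    """Precision/recall/F1 ratios from a 3x4 count matrix W[g, c] (expected
    or exact).  NaN cells in a needed sum propagate to NaN."""
    W = np.asarray(W, dtype=float)
    p_het = _ratio(W[1, 1], W[:, 1].sum())
    r_het = _ratio(W[1, 1], W[1, :].sum())
    p_hom = _ratio(W[2, 2], W[:, 2].sum())
    r_hom = _ratio(W[2, 2], W[2, :].sum())
    return SampleMetrics(p_het, r_het, _f1(p_het, r_het), p_hom, r_hom, _f1(p_hom, r_hom))


def precision_recall(est: ErrorCountEstimates) -> Dict[int, SampleMetrics]:
    """Per-member metrics from expected error counts.  For parents the
    het-precision denominator involves the unidentifiable 0/0→0/1 and
    1/1→0/1 rates and therefore comes out NaN; children get full metrics."""
    return {i: metrics_from_confusion(W) for i, W in est.W.items()}


@dataclass
class TwinMismatchPrediction:
    """Expected genotype-call mismatches between monozygotic twins.

    ``ordered[(a, b)]`` is E[#sites where twin A shows call a and twin B
    shows call b], a != b; ``unordered`` sums both directions.  The total is
    reported both over all categories and restricted to genotype-genotype
    mismatches (no ``./.``), since a missing call is a miss rather than a
    discordant genotype.
    """

    ordered: Dict[Tuple[int, int], float]

    @property
    def unordered(self) -> Dict[Tuple[int, int], float]:
        out: Dict[Tuple[int, int], float] = {}
        for (a, b), v in self.ordered.items():
            key = (min(a, b), max(a, b))
            out[key] = out.get(key, 0.0) + v
        return out

    @property
    def total(self) -> float:
        return float(sum(self.ordered.values()))

    @property
    def total_genotype_only(self) -> float:
        return float(sum(v for (a, b), v in self.ordered.items() if a != 3 and b != 3))


def predict_twin_mismatches(
    est_A: ErrorCountEstimates,
    member_A: int,
    est_B: ErrorCountEstimates,
    member_B: int,
) -> TwinMismatchPrediction:
    """E[M_{a,b}] = E[W_{b→a}^(A)] + E[W_{a→b}^(B)] per ordered call pair.

    A term whose "true" genotype index is ``./.`` does not exist (a true
    genotype is never missing) and contributes 0.  Each twin's expected
    counts must come from a fit that excluded the co-twin, so prediction and
    observation are as independent as family data allows.
    """
    WA = est_A.member(member_A)
    WB = est_B.member(member_B)
    ordered: Dict[Tuple[int, int], float] = {}
    for a in (0, 1, 2, 3):
        for b in (0, 1, 2, 3):
            if a == b:
                continue
            term_a = WA[b, a] if b < 3 else 0.0  # twin A truly b, called a
            term_b = WB[a, b] if a < 3 else 0.0  # twin B truly a, called b
            ordered[(a, b)] = float(term_a + term_b)
    return TwinMismatchPrediction(ordered)


def observed_twin_mismatches(
    calls_A: np.ndarray, calls_B: np.ndarray
) -> Dict[Tuple[int, int], int]:
    """Observed mismatch counts between two aligned call vectors, keyed by
    ordered (call_A, call_B) with call_A != call_B."""
    calls_A = np.asarray(calls_A)
    calls_B = np.asarray(calls_B)
    if calls_A.shape != calls_B.shape:
        raise ValueError("twin call vectors must come from the same site set")
    out: Dict[Tuple[int, int], int] = {}
    joint = np.bincount(calls_A.astype(np.int64) * 4 + calls_B, minlength=16)
    for a in (0, 1, 2, 3):
        for b in (0, 1, 2, 3):
            if a != b:
                out[(a, b)] = int(joint[a * 4 + b])
    return out


def consensus_genotypes(
    replicate_calls: np.ndarray, min_agree: int = 3
) -> Tuple[np.ndarray, List[SampleMetrics], List[np.ndarray]]:
    """Replicate-agreement ground truth and per-replicate metrics.

    ``replicate_calls`` is (n_sites, k) over k replicate samples of the same
    individual (e.g. monozygotic quadruplets, k=4).  A site's truth is the
    genotype shared by at least ``min_agree`` replicates (missing calls never
    vote); sites with no such strict-majority call get ``NO_CONSENSUS`` and
    are excluded.  Returns (truth vector, per-replicate metrics, per-replicate
    3x4 confusion counts truth x call).
    """
    calls = np.asarray(replicate_calls)
    if calls.ndim != 2:
        raise ValueError("replicate_calls must be 2-D (sites x replicates)")
    k = calls.shape[1]
    if not (k >= min_agree and min_agree > k / 2):
        raise ValueError(f"min_agree={min_agree} must be a strict majority of k={k}")
    votes = np.stack([(calls == g).sum(axis=1) for g in (0, 1, 2)], axis=1)
    best = votes.argmax(axis=1)
    truth = np.where(votes.max(axis=1) >= min_agree, best, NO_CONSENSUS).astype(np.int8)
    kept = truth != NO_CONSENSUS
    confusions: List[np.ndarray] = []
    metrics: List[SampleMetrics] = []
    t = truth[kept].astype(np.int64)
    for r in range(k):
        c = calls[kept, r].astype(np.int64)
        conf = np.bincount(t * 4 + c, minlength=12)[:12].reshape(3, 4).astype(float)
        confusions.append(conf)
        metrics.append(metrics_from_confusion(conf))
    return truth, metrics, confusions
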