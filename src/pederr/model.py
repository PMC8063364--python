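"""Identity-link Poisson model of Mendelian-error counts.

Each invalid family genotype ``w`` is observed ``Y_w`` times; under rare,
independent genotyping errors the ``Y_w`` are approximately independent
Poissons whose rates are *linear* in the per-individual error probabilities:

    Y_w ~ Pois( sum_v  x_v * P(C_g^(i) = c) )

where the sum runs over the valid neighbors ``v`` of ``w`` (valid tuples one
single-member change away), ``i`` is the changed member, ``g`` its true
genotype in ``v`` and ``c`` its observed call in ``w``.  The unknown true
count ``x_v`` of each valid tuple is replaced by its observed count ``y_v``
(errors being rare, almost all observations of a valid tuple are correct).
The per-individual parameters P(C_g = c), nine per member (3 true genotypes
x 3 wrong observations including ``./.``), are fitted by maximizing the
Poisson log-likelihood subject to nonnegativity.

Certain parental errors never create an invalid tuple — a parent miscalled
0/0→0/1 or 1/1→0/1 still has a genotype compatible with any child it could
truly have had — so those two parameters per parent are structurally
unidentifiable and reported as such (``None``), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse

from .genotypes import (
    ENUMERATION_CAP,
    GT_LABELS,
    FamilyGenotypeCounts,
    FamilyStructure,
    is_mendelian_consistent,
    valid_neighbors,
    valid_set,
)

__all__ = [
    "ErrorParamKey",
    "DesignSystem",
    "ErrorRateTable",
    "param_keys",
    "build_design",
    "fit_error_rates",
    "identifiability_report",
    "lecam_bound",
]

#: Lower bound used for initialization and for guarding log(0); estimates at
#: or below this floor are indistinguishable from zero.
RATE_FLOOR = 1e-12


class ErrorParamKey(NamedTuple):
    """One per-individual error probability P(C_g^(i) = c), c != g."""

    member_index: int
    true_gt: int  # g in {0/0, 0/1, 1/1}
    observed: int  # c in {0/0, 0/1, 1/1, ./.}, c != g

    def label(self, structure: Optional[FamilyStructure] = None) -> str:
        who = (
            structure.member_ids[self.member_index]
            if structure is not None
            else f"member{self.member_index}"
        )
        return f"{who}:{GT_LABELS[self.true_gt]}->{GT_LABELS[self.observed]}"


def param_keys(structure: FamilyStructure) -> List[ErrorParamKey]:
    """The 9 error-rate parameters per member, in member-major order."""
    return [
        ErrorParamKey(i, g, c)
        for i in range(structure.size)
        for g in (0, 1, 2)
        for c in (0, 1, 2, 3)
        if c != g
    ]


@dataclass
class DesignSystem:
    """The linear system behind the Poisson regression.

    Rows are invalid family genotypes with at least one valid neighbor;
    ``matrix[r, k]`` holds the observed count ``y_v`` of the valid neighbor
    of row ``r``'s tuple that realizes parameter ``columns[k]`` (0 if none).
    Invalid tuples observed with positive count but possessing no valid
    neighbor (e.g. two or more missing calls) cannot be attributed to a
    single error and are parked in ``dropped_rows``.
    """

    structure: FamilyStructure
    row_tuples: List[Tuple[int, ...]]
    y: np.ndarray  # observed counts y_w per row
    matrix: scipy.sparse.csr_matrix  # rows x columns neighbor counts
    columns: List[ErrorParamKey]
    dropped_rows: List[Tuple[Tuple[int, ...], int]] = field(default_factory=list)

    @property
    def column_index(self) -> Dict[ErrorParamKey, int]:
        return {k: j for j, k in enumerate(self.columns)}

    def structural_zero_columns(self) -> List[ErrorParamKey]:
        nnz = np.asarray((self.matrix != 0).sum(axis=0)).ravel()
        return [k for k, n in zip(self.columns, nnz) if n == 0]

    def scaled(self, factor: float) -> "DesignSystem":
        return DesignSystem(
            self.structure,
            self.row_tuples,
            self.y * factor,
            self.matrix * factor,
            self.columns,
            [(t, y * factor) for t, y in self.dropped_rows],
        )


def build_design(counts: FamilyGenotypeCounts) -> DesignSystem:
    """Assemble the Poisson system from one family's tuple counts.

    For families within the enumeration cap every invalid tuple of the full
    4**m space forms a row, including tuples observed zero times (their
    ``-mu_w`` likelihood term sharpens the fit); above the cap only observed
    invalid tuples are used.
    """
    if not counts.counts:
        raise ValueError("empty counts: nothing to build a design from")
    structure = counts.family
    m = structure.size
    columns = param_keys(structure)
    col_index = {k: j for j, k in enumerate(columns)}

    if m <= ENUMERATION_CAP:
        from itertools import product

        candidates = (t for t in product((0, 1, 2, 3), repeat=m))
        vs = valid_set(m)
        invalid = [t for t in candidates if t not in vs]
    else:
        invalid = sorted(
            t for t in counts.counts if not is_mendelian_consistent(t)
        )

    row_tuples: List[Tuple[int, ...]] = []
    dropped: List[Tuple[Tuple[int, ...], int]] = []
    data: List[float] = []
    rows: List[int] = []
    cols: List[int] = []
    y: List[float] = []
    for w in invalid:
        nbrs = valid_neighbors(w, structure)
        y_w = counts.counts.get(w, 0)
        if not nbrs:
            if y_w > 0:
                dropped.append((w, y_w))
            continue
        r = len(row_tuples)
        row_tuples.append(w)
        y.append(float(y_w))
        for v, i, g, c in nbrs:
            y_v = counts.counts.get(v, 0)
            if y_v:
                rows.append(r)
                cols.append(col_index[ErrorParamKey(i, g, c)])
                data.append(float(y_v))
    matrix = scipy.sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(row_tuples), len(columns))
    )
    return DesignSystem(structure, row_tuples, np.asarray(y), matrix, columns, dropped)


@dataclass
class ErrorRateTable:
    """Fitted per-individual error probabilities plus fit diagnostics.

    ``rates[key]`` is the MLE of P(C_g^(i) = c) in [0, 1], or ``None`` when
    the parameter is unidentifiable (its design column is identically zero).
    """

    structure: FamilyStructure
    rates: Dict[ErrorParamKey, Optional[float]]
    log_likelihood: float = float("nan")
    n_iter: int = 0
    converged: bool = True

    def rate(self, member_index: int, g: int, c: int) -> Optional[float]:
        return self.rates[ErrorParamKey(member_index, g, c)]

    def member_matrix(self, member_index: int) -> np.ndarray:
        """3x4 matrix P[g, c]; diagonal holds the correct-call probability
        1 - sum of that row's error rates; unidentifiable cells are NaN."""
        P = np.zeros((3, 4))
        for g in (0, 1, 2):
            err = 0.0
            for c in (0, 1, 2, 3):
                if c == g:
                    continue
                p = self.rates[ErrorParamKey(member_index, g, c)]
                P[g, c] = np.nan if p is None else p
                err += 0.0 if p is None else p
            row = P[g, [c for c in (0, 1, 2, 3) if c != g]]
            P[g, g] = np.nan if np.isnan(row).any() else 1.0 - err
        return P

    def unidentifiable(self) -> List[ErrorParamKey]:
        return [k for k, v in self.rates.items() if v is None]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for k in sorted(self.rates):
            v = self.rates[k]
            recs.append(
                {
                    "sample_id": self.structure.member_ids[k.member_index],
                    "role": self.structure.role(k.member_index),
                    "true_genotype": GT_LABELS[k.true_gt],
                    "observed_call": GT_LABELS[k.observed],
                    "rate": "NA" if v is None else f"{v:.10g}",
                }
            )
        return pd.DataFrame.from_records(recs)


def _negloglik_and_grad(p, A, y):
    mu = A @ p
    mu_safe = np.maximum(mu, 1e-300)
    f = -(y @ np.log(mu_safe) - mu.sum())
    grad = -(A.T @ (y / mu_safe - 1.0))
    return f, grad


def fit_error_rates(
    design: DesignSystem, tol: float = 1e-10, max_iter: int = 10_000
) -> ErrorRateTable:
    """Constrained maximum likelihood for the per-individual error rates.

    Maximizes sum_w [ y_w log mu_w - mu_w ] with mu_w linear in the rates
    (identity link) subject to 0 <= p <= 1, via box-constrained L-BFGS-B with
    analytic gradient.  The objective is concave, so the local optimum found
    is global.  Columns that are identically zero are unidentifiable and come
    back as ``None``.
    """
    if design.matrix.shape[0] == 0:
        raise ValueError("design has no rows; cannot fit")
    col_sums = np.asarray(design.matrix.sum(axis=0)).ravel()
    ident = np.nonzero(col_sums > 0)[0]
    if ident.size == 0:
        raise ValueError("all design columns are zero; nothing identifiable")
    A = scipy.sparse.csr_matrix(design.matrix[:, ident])
    y = design.y
    exposure = col_sums[ident]
    # Optimize in column-scaled coordinates q = p * exposure (the expected
    # number of events each parameter accounts for).  Raw rates span many
    # orders of magnitude against exposures of ~n_sites, which conditions the
    # problem badly; in event units all coordinates live on the same scale.
    A_scaled = A @ scipy.sparse.diags(1.0 / exposure)
    # moment-style start: events observed in the column's rows
    q0 = np.maximum(np.asarray((A > 0).astype(float).T @ y).ravel(), RATE_FLOOR)
    res = scipy.optimize.minimize(
        _negloglik_and_grad,
        np.minimum(q0, exposure),
        args=(A_scaled, y),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, e) for e in exposure],  # p in [0, 1]
        options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": tol, "gtol": 1e-12},
    )
    converged = bool(res.success) or res.status == 0
    if not converged:
        import warnings

        warnings.warn(
            f"error-rate fit for family {design.structure.family_id} did not "
            f"converge in {max_iter} iterations: {res.message}",
            RuntimeWarning,
            stacklevel=2,
        )
    rates: Dict[ErrorParamKey, Optional[float]] = {k: None for k in design.columns}
    for j, qj, e in zip(ident, res.x, exposure):
        rates[design.columns[j]] = float(max(qj, 0.0) / e)
    return ErrorRateTable(
        design.structure,
        rates,
        log_likelihood=float(-res.fun),
        n_iter=int(res.nit),
        converged=converged,
    )


def identifiability_report(design: DesignSystem) -> List[ErrorParamKey]:
    """Columns of the design that are identically zero: the parameters this
    family's data can never inform.  Always contains the parental 0/0→0/1 and
    1/1→0/1 keys."""
    return design.structural_zero_columns()


def lecam_bound(counts: FamilyGenotypeCounts, rates: ErrorRateTable) -> float:
    """Le Cam bound 2 * sum_v y_v * delta_v**2 on the total-variation error
    of the independent-Poisson approximation.

    delta_v is the probability that at least one member of valid tuple v is
    miscalled, computed from the fitted rates (unidentifiable rates enter as
    0, making the bound conservative from below in those cells).
    """
    m = counts.family.size
    # per member: probability of miscall given each true genotype
    err = np.zeros((m, 3))
    for k, p in rates.rates.items():
        if p is not None:
            err[k.member_index, k.true_gt] += p
    total = 0.0
    for v, y_v in counts.counts.items():
        if not is_mendelian_consistent(v):
            continue
        ok = 1.0
        for i, g in enumerate(v):
            ok *= 1.0 - err[i, g]
        delta = 1.0 - ok
        total += y_v * delta * delta
    return 2.0 * total
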