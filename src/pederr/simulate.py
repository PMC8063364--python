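"""Synthetic family-sequencing datasets with known error ground truth.

The generator realizes exactly the generative process the error model
assumes: nuclear families of two parents and k children; parental genotypes
drawn under Hardy–Weinberg equilibrium at per-site allele frequencies; each
child receiving one uniformly random allele from each parent (monozygotic
children share one transmission draw); and each member's observed call drawn
independently from a per-individual confusion distribution over
{0/0, 0/1, 1/1, ./.} with small error rates.  Every injected error is
recoverable from the stored true/observed matrices, so exact per-member
confusion counts — and hence exact precision/recall — are available as the
recovery target for the estimation pipeline.

Randomness is organized as a seeded stream hierarchy (allele frequencies /
true rates / one stream per family) so any family can be regenerated
independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .genotypes import FamilyStructure, FamilyGenotypeCounts, count_from_matrix
from .metrics import SampleMetrics, metrics_from_confusion

__all__ = ["SimulationSpec", "SimulatedDataset", "simulate_dataset", "true_metrics"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one simulated dataset.

    Defaults mirror a desk-scale family cohort: 50 quad families (2 parents
    + 2 children) over 1e6 biallelic sites, per-site allele frequencies
    uniform on [0.01, 0.5], and each of the nine per-member error rates drawn
    log-uniformly from [1e-4, 1e-2] — the magnitude range of real short-read
    genotyping error.  ``monozygotic=True`` makes all children of each family
    identical twins (k=2) or quadruplets (k=4) with independent errors;
    ``duplicate_first_child=True`` instead adds one extra child per family
    that is a monozygotic copy of the first child (with independent errors),
    leaving the other children ordinary siblings — the twin-validation
    design, where each twin's rates can be fitted from the non-twin family
    members alone.
    """

    n_families: int = 50
    children_per_family: int = 2
    n_sites: int = 1_000_000
    af_range: Tuple[float, float] = (0.01, 0.5)
    rate_range: Tuple[float, float] = (1e-4, 1e-2)
    monozygotic: bool = False
    duplicate_first_child: bool = False
    seed: int = 0
    explicit_rates: Optional[Dict[str, np.ndarray]] = None  # sample_id -> 3x4

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.children_per_family < 1 or self.n_sites < 1:
            raise ValueError("n_families, children_per_family, n_sites must be >= 1")
        lo, hi = self.af_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("allele-frequency range must satisfy 0 < lo <= hi <= 1")
        rlo, rhi = self.rate_range
        if not (0 <= rlo <= rhi) or 3 * rhi >= 1:
            raise ValueError("error-rate range invalid (per-row error mass must stay < 1)")


def _confusion_matrix_from_rates(rates_3x3: np.ndarray) -> np.ndarray:
    """3x4 row-stochastic confusion matrix from the 9 off-diagonal rates
    (rows g, columns c; rates given as rows of the 3 wrong calls in call
    order, diagonal filled with the remaining mass)."""
    P = np.asarray(rates_3x3, dtype=float)
    if P.shape != (3, 4):
        raise ValueError("expected a 3x4 matrix with arbitrary diagonal")
    P = P.copy()
    for g in range(3):
        off = sum(P[g, c] for c in range(4) if c != g)
        if off >= 1 or np.any(P[g] < 0):
            raise ValueError("error rates per true genotype must be nonnegative and sum < 1")
        P[g, g] = 1.0 - off
    return P


def _draw_member_rates(rng: np.random.Generator, rate_range: Tuple[float, float]) -> np.ndarray:
    lo, hi = rate_range
    out = np.zeros((3, 4))
    for g in range(3):
        for c in range(4):
            if c != g:
                out[g, c] = lo * (hi / lo) ** rng.random() if lo > 0 else hi * rng.random()
    return out


def _transmit(parent_g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Alt-allele transmitted by each parent genotype (vectorized)."""
    t = (parent_g == 2).astype(np.int8)
    het = parent_g == 1
    t[het] = rng.integers(0, 2, int(het.sum()), dtype=np.int8)
    return t


def _apply_confusion(true_g: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    obs = np.empty_like(true_g)
    u = rng.random(true_g.shape[0])
    for g in range(3):
        mask = true_g == g
        cum = np.cumsum(P[g])
        cum[-1] = 1.0
        obs[mask] = np.searchsorted(cum, u[mask], side="right").astype(np.int8)
    return obs


@dataclass
class SimulatedDataset:
    """In-memory simulated cohort plus its complete ground truth."""

    spec: SimulationSpec
    allele_freqs: np.ndarray  # (n_sites,)
    refs: np.ndarray  # (n_sites,) reference bases
    alts: np.ndarray
    families: List[FamilyStructure]
    true_genotypes: Dict[str, np.ndarray]  # family_id -> (n_sites, m) int8
    observed: Dict[str, np.ndarray]  # family_id -> (n_sites, m) int8
    true_rates: Dict[str, np.ndarray]  # sample_id -> 3x4 row-stochastic
    chrom: str = "1"

    def family(self, family_id: str) -> FamilyStructure:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(family_id)

    def twin_pairs(self) -> List[Tuple[str, str]]:
        """(child, its monozygotic copy) per family, for datasets simulated
        with ``duplicate_first_child``."""
        if not self.spec.duplicate_first_child:
            return []
        return [
            (f"{f.family_id}_C1", f"{f.family_id}_C1B") for f in self.families
        ]

    def informative_mask(self) -> np.ndarray:
        """Sites where at least one sample in the dataset shows a
        non-reference genotype (0/1 or 1/1) — the 'informative site' filter."""
        mask = np.zeros(self.spec.n_sites, dtype=bool)
        for obs in self.observed.values():
            mask |= ((obs == 1) | (obs == 2)).any(axis=1)
        return mask

    def counts_for(
        self, family: FamilyStructure, site_mask: Optional[np.ndarray] = None
    ) -> FamilyGenotypeCounts:
        obs = self.observed[family.family_id]
        full = self.family(family.family_id)
        cols = [full.member_ids.index(s) for s in family.member_ids]
        return count_from_matrix(obs[:, cols], family, site_mask)

    def member_column(self, sample_id: str) -> Tuple[str, int]:
        for f in self.families:
            if sample_id in f.member_ids:
                return f.family_id, f.member_ids.index(sample_id)
        raise KeyError(sample_id)

    def observed_calls(self, sample_id: str) -> np.ndarray:
        fid, col = self.member_column(sample_id)
        return self.observed[fid][:, col]

    def true_confusion(
        self, sample_id: str, site_mask: Optional[np.ndarray] = None
    ) -> np.ndarray:
        """Exact 3x4 confusion counts (true genotype x observed call) for one
        sample over the selected sites — the simulator's aggregated truth log."""
        fid, col = self.member_column(sample_id)
        t = self.true_genotypes[fid][:, col].astype(np.int64)
        o = self.observed[fid][:, col].astype(np.int64)
        if site_mask is not None:
            t, o = t[site_mask], o[site_mask]
        return np.bincount(t * 4 + o, minlength=12)[:12].reshape(3, 4).astype(float)

    def iter_truth_log(self):
        """Yield (site_index, sample_id, true_genotype, observed_call) for
        every injected error, in deterministic order."""
        for f in self.families:
            t = self.true_genotypes[f.family_id]
            o = self.observed[f.family_id]
            for col, sid in enumerate(f.member_ids):
                idx = np.nonzero(t[:, col] != o[:, col])[0]
                for i in idx:
                    yield int(i), sid, int(t[i, col]), int(o[i, col])

    # ---- file emission (plain-text VCF/PED/TSV) -------------------------

    def write_ped(self, path) -> None:
        with open(path, "w") as fh:
            for f in self.families:
                fh.write(f"{f.family_id}\t{f.mother_id}\t0\t0\t2\t0\n")
                fh.write(f"{f.family_id}\t{f.father_id}\t0\t0\t1\t0\n")
                for c in f.child_ids:
                    fh.write(f"{f.family_id}\t{c}\t{f.father_id}\t{f.mother_id}\t0\t0\n")

    def write_vcf(self, path) -> None:
        samples: List[str] = []
        cols: List[Tuple[str, int]] = []
        for f in self.families:
            for j, s in enumerate(f.member_ids):
                samples.append(s)
                cols.append((f.family_id, j))
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", 3: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={self.chrom},length={self.spec.n_sites + 1}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##source=pederr-simulate\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(samples)
                + "\n"
            )
            obs_cols = [self.observed[fid][:, j] for fid, j in cols]
            for i in range(self.spec.n_sites):
                calls = "\t".join(gt_str[int(c[i])] for c in obs_cols)
                fh.write(
                    f"{self.chrom}\t{i + 1}\t.\t{self.refs[i]}\t{self.alts[i]}\t.\tPASS\t.\tGT\t{calls}\n"
                )

    def write_truth_log(self, path) -> None:
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", 3: "./."}
        with open(path, "w") as fh:
            fh.write("site_index\tpos\tsample_id\ttrue_genotype\tobserved_call\n")
            for i, sid, g, c in self.iter_truth_log():
                fh.write(f"{i}\t{i + 1}\t{sid}\t{gt_str[g]}\t{gt_str[c]}\n")

    def write_true_rates(self, path) -> None:
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", 3: "./."}
        with open(path, "w") as fh:
            fh.write("sample_id\ttrue_genotype\tobserved_call\trate\n")
            for sid in sorted(self.true_rates):
                P = self.true_rates[sid]
                for g in range(3):
                    for c in range(4):
                        if c != g:
                            fh.write(f"{sid}\t{gt_str[g]}\t{gt_str[c]}\t{P[g, c]:.10g}\n")


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Draw a complete cohort under the model's assumed generative process.

    Fully reproducible from ``spec.seed``: the seed is split into independent
    streams for site properties, true rates, and each family's genotypes and
    errors.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_sites, ss_rates, ss_fams = root.spawn(3)
    rng_sites = np.random.default_rng(ss_sites)
    rng_rates = np.random.default_rng(ss_rates)
    fam_seeds = ss_fams.spawn(spec.n_families)

    lo, hi = spec.af_range
    afs = rng_sites.uniform(lo, hi, spec.n_sites)
    ref_idx = rng_sites.integers(0, 4, spec.n_sites)
    alt_idx = (ref_idx + rng_sites.integers(1, 4, spec.n_sites)) % 4
    refs = _BASES[ref_idx]
    alts = _BASES[alt_idx]

    families: List[FamilyStructure] = []
    true_genotypes: Dict[str, np.ndarray] = {}
    observed: Dict[str, np.ndarray] = {}
    true_rates: Dict[str, np.ndarray] = {}

    k = spec.children_per_family
    for fi in range(spec.n_families):
        fid = f"F{fi:03d}"
        children = [f"{fid}_C{j + 1}" for j in range(k)]
        if spec.duplicate_first_child:
            children.append(f"{fid}_C1B")  # MZ copy of C1; sorts right after it
        fam = FamilyStructure(fid, f"{fid}_M", f"{fid}_F", tuple(children))
        families.append(fam)
        rng = np.random.default_rng(fam_seeds[fi])

        mother = rng.binomial(2, afs).astype(np.int8)
        father = rng.binomial(2, afs).astype(np.int8)
        true = np.empty((spec.n_sites, fam.size), dtype=np.int8)
        true[:, 0], true[:, 1] = mother, father
        if spec.monozygotic:
            child = _transmit(mother, rng) + _transmit(father, rng)
            for j in range(k):
                true[:, 2 + j] = child
        else:
            for j in range(k):
                true[:, 2 + j] = _transmit(mother, rng) + _transmit(father, rng)
        if spec.duplicate_first_child:
            # columns follow sorted child ids: C1, C1B, C2, ... — regenerate
            # the layout so C1B's truth copies C1's
            order = fam.member_ids
            src = {f"{fid}_C{j + 1}": 2 + j for j in range(k)}
            laid = np.empty_like(true)
            laid[:, 0], laid[:, 1] = mother, father
            for col, sid in enumerate(order[2:], start=2):
                key = f"{fid}_C1" if sid == f"{fid}_C1B" else sid
                laid[:, col] = true[:, src[key]]
            true = laid

        obs = np.empty_like(true)
        for col, sid in enumerate(fam.member_ids):
            if spec.explicit_rates is not None and sid in spec.explicit_rates:
                P = _confusion_matrix_from_rates(np.asarray(spec.explicit_rates[sid]))
            else:
                P = _confusion_matrix_from_rates(_draw_member_rates(rng_rates, spec.rate_range))
            true_rates[sid] = P
            obs[:, col] = _apply_confusion(true[:, col], P, rng)
        true_genotypes[fid] = true
        observed[fid] = obs

    return SimulatedDataset(
        spec, afs, refs, alts, families, true_genotypes, observed, true_rates
    )


def true_metrics(confusion: np.ndarray) -> SampleMetrics:
    """Exact precision/recall/F1 from a simulator confusion matrix — the
    oracle target that estimated metrics are compared against."""
    return metrics_from_confusion(confusion)
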