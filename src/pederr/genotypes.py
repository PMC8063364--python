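"""Family-genotype combinatorics.

A *family genotype* is an ordered tuple of genotype calls — mother, father,
then children — at one biallelic site.  A tuple is *valid* when it contains
no missing call and every child's genotype can be produced by drawing one
allele from each parent; every other tuple (including any tuple containing a
missing call) is *invalid*.  Invalid tuples are the observable footprint of
genotyping error in pedigree data, and their counts are the raw input to the
Poisson error model in :mod:`pederr.model`.

Genotype calls are encoded as small integers so tuples double as array
indices: 0 = ``0/0`` (hom-ref), 1 = ``0/1`` (het), 2 = ``1/1`` (hom-alt),
3 = ``./.`` (missing).  For non-missing calls the code equals the number of
alternate alleles carried, which is what makes the Mendelian check a one-line
sum over transmitted alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from functools import lru_cache
from itertools import product
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "GenotypeCall",
    "GT_LABELS",
    "FamilyStructure",
    "FamilyGenotypeCounts",
    "ENUMERATION_CAP",
    "EnumerationTooLargeError",
    "is_mendelian_consistent",
    "enumerate_valid",
    "valid_set",
    "valid_neighbors",
    "count_family_genotypes",
    "count_from_matrix",
    "encode_tuple",
    "decode_code",
]


class GenotypeCall(IntEnum):
    """The four-state call space: three genotypes plus missing (``./.``)."""

    HOMREF = 0
    HET = 1
    HOMALT = 2
    MISSING = 3


GT_LABELS: Dict[int, str] = {0: "0/0", 1: "0/1", 2: "1/1", 3: "./."}

#: Full enumeration of the 4**m tuple space is only attempted for families
#: of at most this many members; larger families are handled lazily from
#: observed tuples (see :func:`pederr.model.build_design`).
ENUMERATION_CAP = 8

# Alternate-allele values a parent with each genotype can transmit.
_TRANSMISSIBLE: Dict[int, Tuple[int, ...]] = {0: (0,), 1: (0, 1), 2: (1,)}


class EnumerationTooLargeError(ValueError):
    """Family too large for exhaustive tuple enumeration; use lazy mode."""


@dataclass(frozen=True)
class FamilyStructure:
    """A nuclear family: one mother, one father, k >= 1 children.

    Member order is fixed as (mother, father, child_1, ..., child_k) and is
    the tuple/column order used everywhere downstream.  Children are stored
    sorted by sample id for determinism; Mendelian validity is invariant
    under child permutation so this is safe.
    """

    family_id: str
    mother_id: str
    father_id: str
    child_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.child_ids:
            raise ValueError(f"family {self.family_id} has no children")
        object.__setattr__(self, "child_ids", tuple(sorted(self.child_ids)))

    @property
    def member_ids(self) -> Tuple[str, ...]:
        return (self.mother_id, self.father_id) + self.child_ids

    @property
    def size(self) -> int:
        return 2 + len(self.child_ids)

    def role(self, member_index: int) -> str:
        if member_index == 0:
            return "mother"
        if member_index == 1:
            return "father"
        return f"child_{member_index - 1}"

    def drop_children(self, keep: Sequence[str]) -> "FamilyStructure":
        """Reduced family keeping only the named children (e.g. for twin
        fits that must exclude the co-twin)."""
        missing = set(keep) - set(self.child_ids)
        if missing:
            raise KeyError(f"not children of {self.family_id}: {sorted(missing)}")
        return FamilyStructure(self.family_id, self.mother_id, self.father_id, tuple(keep))


def _child_compatible(child: int, mother: int, father: int) -> bool:
    for am in _TRANSMISSIBLE[mother]:
        for af in _TRANSMISSIBLE[father]:
            if am + af == child:
                return True
    return False


def is_mendelian_consistent(fg: Sequence[int]) -> bool:
    """True iff ``fg`` has no missing call and every child's genotype can be
    assembled from one allele of each parent.

    ``fg`` is ordered (mother, father, children...) and must have length >= 3.
    """
    if len(fg) < 3:
        raise ValueError("family genotype needs two parents and at least one child")
    if any(c == GenotypeCall.MISSING for c in fg):
        return False
    mother, father = fg[0], fg[1]
    return all(_child_compatible(c, mother, father) for c in fg[2:])


@lru_cache(maxsize=None)
def valid_set(m: int) -> frozenset:
    """All valid family genotypes for a family of ``m`` members."""
    if m > ENUMERATION_CAP:
        raise EnumerationTooLargeError(
            f"family of {m} members exceeds enumeration cap {ENUMERATION_CAP}; "
            "operate lazily from observed tuples instead"
        )
    return frozenset(
        fg for fg in product((0, 1, 2), repeat=m) if is_mendelian_consistent(fg)
    )


def enumerate_valid(structure: FamilyStructure) -> List[Tuple[int, ...]]:
    """The valid family genotypes for ``structure``, in sorted (deterministic)
    order."""
    return sorted(valid_set(structure.size))


def valid_neighbors(
    w: Sequence[int], structure: Optional[FamilyStructure] = None
) -> List[Tuple[Tuple[int, ...], int, int, int]]:
    """Valid tuples differing from the invalid tuple ``w`` at exactly one
    member.

    Each neighbor encodes a single-error explanation of ``w``: the family
    truly had valid genotype ``v`` and member ``i`` was miscalled from its
    true genotype ``g`` (= ``v[i]``) to the observed call ``c`` (= ``w[i]``).
    Returns ``[(v, i, g, c), ...]``, exhaustive and duplicate-free.
    """
    w = tuple(int(c) for c in w)
    if structure is not None and len(w) != structure.size:
        raise ValueError(
            f"tuple of length {len(w)} does not match family size {structure.size}"
        )
    if is_mendelian_consistent(w):
        raise ValueError(f"{w} is valid; neighbors are defined for invalid tuples")
    vs = valid_set(len(w))
    out: List[Tuple[Tuple[int, ...], int, int, int]] = []
    for i, c in enumerate(w):
        for g in (0, 1, 2):
            if g == c:
                continue
            v = w[:i] + (g,) + w[i + 1 :]
            if v in vs:
                out.append((v, i, g, c))
    return out


@dataclass
class FamilyGenotypeCounts:
    """Observed occurrence counts of each family genotype for one family.

    ``counts[t]`` is the number of counted sites at which the family was
    observed with genotype tuple ``t``; ``n_sites`` is the total number of
    counted sites, so ``sum(counts.values()) == n_sites``.
    """

    family: FamilyStructure
    counts: Dict[Tuple[int, ...], int] = field(default_factory=dict)
    n_sites: int = 0

    def __post_init__(self) -> None:
        for t, y in self.counts.items():
            if len(t) != self.family.size:
                raise ValueError(f"tuple {t} does not match family size {self.family.size}")
            if y < 0:
                raise ValueError("counts must be nonnegative")

    def scaled(self, factor: int) -> "FamilyGenotypeCounts":
        return FamilyGenotypeCounts(
            self.family,
            {t: y * factor for t, y in self.counts.items()},
            self.n_sites * factor,
        )

    def observed_genotype_counts(self) -> "np.ndarray":
        """Per-member observed genotype counts x-hat (size x 3): the number
        of counted sites at which each member was called 0/0, 0/1, 1/1."""
        import numpy as np

        x = np.zeros((self.family.size, 3), dtype=float)
        for t, y in self.counts.items():
            for i, c in enumerate(t):
                if c < 3:
                    x[i, c] += y
        return x


def encode_tuple(t: Sequence[int]) -> int:
    """Base-4 encoding of a genotype tuple (member 0 least significant)."""
    code = 0
    for i, c in enumerate(t):
        code += int(c) << (2 * i)
    return code


def decode_code(code: int, m: int) -> Tuple[int, ...]:
    return tuple((code >> (2 * i)) & 3 for i in range(m))


def count_family_genotypes(
    records: Iterable,
    structure: FamilyStructure,
    sample_to_col: Mapping[str, int],
    site_filter=None,
) -> FamilyGenotypeCounts:
    """Tally family genotype tuples over per-site call records.

    ``records`` yields objects with a ``calls`` integer array indexed by the
    columns in ``sample_to_col``; ``site_filter(record)``, when given, selects
    the sites to count.  Raises ``KeyError`` naming any family member absent
    from ``sample_to_col``.
    """
    try:
        cols = [sample_to_col[s] for s in structure.member_ids]
    except KeyError as e:
        raise KeyError(f"sample {e.args[0]!r} not present in call data") from e
    counts: Dict[Tuple[int, ...], int] = {}
    n = 0
    for rec in records:
        if site_filter is not None and not site_filter(rec):
            continue
        t = tuple(int(rec.calls[c]) for c in cols)
        counts[t] = counts.get(t, 0) + 1
        n += 1
    return FamilyGenotypeCounts(structure, counts, n)


def count_from_matrix(
    calls, structure: FamilyStructure, site_mask=None
) -> FamilyGenotypeCounts:
    """Vectorized tally from an (n_sites, m) int call matrix whose columns
    follow the structure's member order."""
    import numpy as np

    calls = np.asarray(calls)
    if calls.ndim != 2 or calls.shape[1] != structure.size:
        raise ValueError("call matrix shape does not match family size")
    if site_mask is not None:
        calls = calls[np.asarray(site_mask, dtype=bool)]
    m = structure.size
    codes = np.zeros(calls.shape[0], dtype=np.int64)
    for i in range(m):
        codes += calls[:, i].astype(np.int64) << (2 * i)
    tallies = np.bincount(codes, minlength=4**m if m <= ENUMERATION_CAP else 0)
    counts = {
        decode_code(int(code), m): int(c)
        for code, c in zip(np.nonzero(tallies)[0], tallies[np.nonzero(tallies)[0]])
    }
    return FamilyGenotypeCounts(structure, counts, int(calls.shape[0]))
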