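"""Pedigree and VCF input: PED/FAM parsing and filtered site streaming.

The PED reader extracts nuclear families (one mother, one father, their
children) from PLINK-style pedigree files; everything past the first four
columns is ignored.  The VCF reader (pysam-backed, transparently bgzipped)
yields one integer call per sample per biallelic SNV, mapping half calls
(``0/.``) to missing and treating phased and unphased genotypes identically.
Site filters — FILTER=PASS only, informative-only (at least one non-reference
genotype in the dataset), autosomes-only, interval membership — are applied
during streaming, with per-reason skip tallies.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterator, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pysam

from .genotypes import FamilyStructure
from .regions import IntervalSet

__all__ = ["SiteRecord", "read_pedigree", "VcfSource", "stream_sites"]

logger = logging.getLogger(__name__)

_AUTOSOMES = {str(i) for i in range(1, 23)}
_SNV_BASES = {"A", "C", "G", "T"}


class SiteRecord(NamedTuple):
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    calls: np.ndarray  # int8 per sample, indexed by sample_to_col


def read_pedigree(path) -> List[FamilyStructure]:
    """Nuclear families from a PED/FAM file.

    Children are grouped by (family id, mother id, father id); individuals
    with either parent recorded as ``0`` are founders.  Groups lacking a
    mother, a father, or any child are skipped with a logged warning.
    """
    groups: Dict[Tuple[str, str, str], List[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: line {ln}: expected >=4 PED columns")
            fam, iid, father, mother = parts[0], parts[1], parts[2], parts[3]
            if father != "0" and mother != "0":
                groups.setdefault((fam, mother, father), []).append(iid)
            elif father != "0" or mother != "0":
                logger.warning(
                    "%s: %s has only one recorded parent; skipped (nuclear "
                    "families need both)",
                    fam,
                    iid,
                )
    families = []
    for (fam, mother, father), children in sorted(groups.items()):
        families.append(FamilyStructure(fam, mother, father, tuple(children)))
    if not families:
        logger.warning("%s: no complete nuclear families found", path)
    return families


def _call_code(gt: Optional[Tuple[Optional[int], ...]]) -> int:
    # half calls and non-diploid records count as missing; phase is ignored
    if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
        return 3
    return int(gt[0]) + int(gt[1])


@dataclass
class VcfSource:
    """A VCF plus the sample->column mapping its records use."""

    path: str
    samples: List[str]

    @property
    def sample_to_col(self) -> Dict[str, int]:
        return {s: i for i, s in enumerate(self.samples)}


def stream_sites(
    vcf_path,
    required_samples: Optional[Sequence[str]] = None,
    pass_only: bool = True,
    informative_only: bool = True,
    autosomes_only: bool = True,
    regions: Optional[IntervalSet] = None,
    skip_counter: Optional[Counter] = None,
) -> Tuple[VcfSource, Iterator[SiteRecord]]:
    """Open a VCF and return (source, record iterator) over filtered sites.

    Only biallelic SNVs are yielded; every rejected record increments a
    reason in ``skip_counter`` (non_biallelic / indel / non_pass /
    non_autosome / uninformative / off_region).  Raises if any required
    sample is absent or if records on a chromosome are not
    position-sorted.
    """
    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)
    if required_samples:
        missing = [s for s in required_samples if s not in samples]
        if missing:
            raise ValueError(f"samples missing from VCF {vcf_path}: {missing}")
    source = VcfSource(str(vcf_path), samples)
    counter = skip_counter if skip_counter is not None else Counter()

    def _norm(chrom: str) -> str:
        return chrom[3:] if chrom.lower().startswith("chr") else chrom

    def gen() -> Iterator[SiteRecord]:
        last: Dict[str, int] = {}
        for rec in vf:
            chrom = _norm(rec.chrom)
            if last.get(chrom, 0) > rec.pos:
                raise ValueError(
                    f"{vcf_path}: unsorted VCF at {rec.chrom}:{rec.pos}"
                )
            last[chrom] = rec.pos
            if autosomes_only and chrom not in _AUTOSOMES:
                counter["non_autosome"] += 1
                continue
            if rec.alts is None or len(rec.alts) != 1:
                counter["non_biallelic"] += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _SNV_BASES or alt not in _SNV_BASES:
                counter["indel"] += 1
                continue
            if pass_only and "PASS" not in rec.filter and len(rec.filter) > 0:
                counter["non_pass"] += 1
                continue
            if regions is not None and not regions.contains(chrom, rec.pos - 1):
                counter["off_region"] += 1
                continue
            calls = np.fromiter(
                (_call_code(rec.samples[s].get("GT")) for s in samples),
                dtype=np.int8,
                count=len(samples),
            )
            if informative_only and not np.any((calls == 1) | (calls == 2)):
                counter["uninformative"] += 1
                continue
            counter["used"] += 1
            yield SiteRecord(chrom, rec.pos, ref, alt, calls)

    return source, gen()
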