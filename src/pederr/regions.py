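"""Genomic-interval restriction and distance-to-target binning.

Interval sets are kept per chromosome as sorted, merged numpy arrays of
half-open [start, end) pairs (BED convention, 0-based).  VCF positions are
1-based; the conversion happens exactly once, at the membership/distance
boundary.  Chromosome names are matched with any ``chr`` prefix stripped.

Besides membership (LCR/HCR restriction, microarray or GWAS site lists) the
module bins off-target WES sites by distance to the nearest capture-target
edge into (0,25], (25,50], (50,75] and (75, inf) bp, the strata in which
off-target call quality is assessed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np

__all__ = [
    "IntervalSet",
    "load_intervals",
    "classify_site",
    "complement_regions",
    "DISTANCE_BINS",
]

DISTANCE_BINS = ("in_target", "0-25", "25-50", "50-75", ">75")


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class IntervalSet:
    """Per-chromosome sorted, merged half-open intervals."""

    intervals: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, triples: Iterable[Tuple[str, int, int]]) -> "IntervalSet":
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in triples:
            if end < start:
                raise ValueError(f"interval end < start: {chrom}:{start}-{end}")
            if end == start:
                continue
            by_chrom.setdefault(_norm_chrom(chrom), []).append((int(start), int(end)))
        out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts: List[int] = []
            ends: List[int] = []
            for s, e in ivs:
                # merge overlapping and adjacent intervals
                if starts and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            out[chrom] = (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
        return cls(out)

    def to_triples(self) -> List[Tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.intervals):
            starts, ends = self.intervals[chrom]
            out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.to_triples() == other.to_triples()

    def is_empty(self) -> bool:
        return not self.intervals

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        pair = self.intervals.get(_norm_chrom(chrom))
        if pair is None:
            return False
        starts, ends = pair
        idx = int(np.searchsorted(starts, pos0, side="right")) - 1
        return idx >= 0 and pos0 < ends[idx]

    def contains_vec(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        pos0 = np.asarray(pos0, dtype=np.int64)
        pair = self.intervals.get(_norm_chrom(chrom))
        if pair is None:
            return np.zeros(pos0.shape, dtype=bool)
        starts, ends = pair
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        res = np.zeros(pos0.shape, dtype=bool)
        res[ok] = pos0[ok] < ends[idx[ok]]
        return res

    def distance(self, chrom: str, pos0: int) -> float:
        """bp from a 0-based position to the nearest interval base; 0 inside,
        inf on a chromosome with no intervals."""
        pair = self.intervals.get(_norm_chrom(chrom))
        if pair is None:
            return float("inf")
        starts, ends = pair
        idx = int(np.searchsorted(starts, pos0, side="right")) - 1
        if idx >= 0 and pos0 < ends[idx]:
            return 0.0
        d_left = pos0 - (ends[idx] - 1) if idx >= 0 else float("inf")
        d_right = starts[idx + 1] - pos0 if idx + 1 < len(starts) else float("inf")
        return float(min(d_left, d_right))


def load_intervals(path) -> IntervalSet:
    """Read a BED file (3+ columns, 0-based half-open; plain or gzipped)
    into a normalized IntervalSet, merging overlaps and adjacencies."""
    opener = gzip.open if str(path).endswith(".gz") else open
    triples: List[Tuple[str, int, int]] = []
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}: line {ln}: non-integer coordinates") from e
            if start < 0 or end < start:
                raise ValueError(f"{path}: line {ln}: bad interval [{start}, {end})")
            triples.append((parts[0], start, end))
    return IntervalSet.from_intervals(triples)


def classify_site(chrom: str, pos_1based: int, targets: IntervalSet) -> str:
    """Distance bin of a 1-based site relative to capture targets.

    Sites inside a target are ``in_target``; otherwise the distance d (bp to
    the nearest target edge) is binned half-open: (0,25] → "0-25",
    (25,50] → "25-50", (50,75] → "50-75", d > 75 (including chromosomes with
    no targets) → ">75".
    """
    d = targets.distance(chrom, pos_1based - 1)
    if d == 0:
        return "in_target"
    if d <= 25:
        return "0-25"
    if d <= 50:
        return "25-50"
    if d <= 75:
        return "50-75"
    return ">75"


def complement_regions(regions: IntervalSet, chrom_sizes: Mapping[str, int]) -> IntervalSet:
    """Exact per-chromosome complement (e.g. HCR = complement of LCR).

    Chromosomes in ``chrom_sizes`` but absent from ``regions`` come back
    whole; a region interval exceeding its chromosome size is an error.
    """
    triples: List[Tuple[str, int, int]] = []
    sizes = {_norm_chrom(c): s for c, s in chrom_sizes.items()}
    for chrom, size in sizes.items():
        pair = regions.intervals.get(chrom)
        if pair is None:
            triples.append((chrom, 0, size))
            continue
        starts, ends = pair
        if ends[-1] > size:
            raise ValueError(
                f"interval [{starts[-1]}, {ends[-1]}) exceeds size {size} of chromosome {chrom}"
            )
        prev = 0
        for s, e in zip(starts, ends):
            if s > prev:
                triples.append((chrom, prev, int(s)))
            prev = int(e)
        if prev < size:
            triples.append((chrom, prev, size))
    return IntervalSet.from_intervals(triples)
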