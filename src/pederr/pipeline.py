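"""End-to-end orchestration: VCF + PED in, rate/metric tables out.

Stages: stream filtered sites → tally family genotype tuples (optionally per
region stratum) → build the Poisson design per family → fit error rates →
derive expected error counts and precision/recall → write TSV tables with a
provenance header.  Twin and replicate-consensus validation runs reuse the
same streaming pass.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import FamilyGenotypeCounts, FamilyStructure, GT_LABELS
from .metrics import (
    SampleMetrics,
    consensus_genotypes,
    expected_error_counts,
    precision_recall,
    predict_twin_mismatches,
)
from .model import ErrorRateTable, build_design, fit_error_rates, lecam_bound
from .regions import IntervalSet, classify_site, load_intervals
from .vcfio import read_pedigree, stream_sites

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "fit_family", "twin_report", "consensus_report"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; mirrored by the CLI flags."""

    vcf_path: str
    ped_path: str
    output_dir: str
    region_beds: Dict[str, str] = field(default_factory=dict)  # label -> BED path
    target_bed: Optional[str] = None  # exome capture targets for distance bins
    filter_pass_only: bool = True
    informative_only: bool = True
    autosomes_only: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        # hash only fields that affect the analysis, not where results land
        skip = {"output_dir", "log_level"}
        blob = json.dumps(
            {k: v for k, v in sorted(self.__dict__.items()) if k not in skip},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return (
        f"# pederr {__version__} config={config.config_hash()} seed={config.seed}\n"
    )


def fit_family(
    counts: FamilyGenotypeCounts,
) -> Tuple[ErrorRateTable, Dict[int, SampleMetrics], float, int]:
    """Fit one family's rates and derive per-member metrics, the Le Cam
    approximation bound, and the number of dropped (unattributable) rows."""
    design = build_design(counts)
    rates = fit_error_rates(design)
    est = expected_error_counts(rates, counts.observed_genotype_counts())
    return rates, precision_recall(est), lecam_bound(counts, rates), len(design.dropped_rows)


def _site_labels(config: RunConfig) -> Tuple[Dict[str, IntervalSet], Optional[IntervalSet]]:
    region_sets = {label: load_intervals(path) for label, path in config.region_beds.items()}
    targets = load_intervals(config.target_bed) if config.target_bed else None
    return region_sets, targets


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Run count → fit → metrics for every family and write the outputs.

    Outputs (all under ``config.output_dir``): ``rates.tsv`` (one row per
    sample per error parameter per region label), ``metrics.tsv`` (one row
    per sample per label), ``diagnostics.json`` (fit diagnostics, Le Cam
    bounds, skip tallies).  Deterministic: rerunning with the same inputs
    produces byte-identical tables.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    families = read_pedigree(config.ped_path)
    if not families:
        raise ValueError(f"no usable nuclear families in {config.ped_path}")
    needed = [s for f in families for s in f.member_ids]
    region_sets, targets = _site_labels(config)

    skip = Counter()
    source, records = stream_sites(
        config.vcf_path,
        required_samples=needed,
        pass_only=config.filter_pass_only,
        informative_only=config.informative_only,
        autosomes_only=config.autosomes_only,
        skip_counter=skip,
    )
    col = source.sample_to_col
    fam_cols = {f.family_id: [col[s] for s in f.member_ids] for f in families}

    # label -> family_id -> {tuple: count}; labels assigned per site
    labels: List[str] = (
        list(region_sets) if region_sets else (["all"] if targets is None else [])
    )
    if targets is not None:
        from .regions import DISTANCE_BINS

        labels = labels + list(DISTANCE_BINS)
    tallies: Dict[str, Dict[str, Dict[tuple, int]]] = {
        lab: {f.family_id: {} for f in families} for lab in labels
    }
    n_sites = Counter()
    for rec in records:
        site_labels = []
        if region_sets:
            site_labels.extend(
                lab for lab, iset in region_sets.items() if iset.contains(rec.chrom, rec.pos - 1)
            )
        elif targets is None:
            site_labels.append("all")
        if targets is not None:
            site_labels.append(classify_site(rec.chrom, rec.pos, targets))
        if not site_labels:
            skip["off_region"] += 1
            continue
        for lab in site_labels:
            n_sites[lab] += 1
            t_lab = tallies[lab]
            for f in families:
                t = tuple(int(rec.calls[c]) for c in fam_cols[f.family_id])
                d = t_lab[f.family_id]
                d[t] = d.get(t, 0) + 1

    rate_rows: List[pd.DataFrame] = []
    metric_rows: List[dict] = []
    diagnostics: Dict[str, dict] = {}
    for lab in labels:
        for f in families:
            counts = FamilyGenotypeCounts(f, tallies[lab][f.family_id], n_sites[lab])
            if not counts.counts:
                logger.warning("family %s has no sites in stratum %s", f.family_id, lab)
                continue
            try:
                rates, mets, bound, n_dropped = fit_family(counts)
            except ValueError as e:
                logger.warning("family %s (%s) excluded: %s", f.family_id, lab, e)
                diagnostics[f"{f.family_id}/{lab}"] = {"error": str(e)}
                continue
            df = rates.to_frame()
            df.insert(1, "family_id", f.family_id)
            df.insert(2, "region_label", lab)
            rate_rows.append(df)
            x = counts.observed_genotype_counts()
            for i, m in mets.items():
                metric_rows.append(
                    {
                        "sample_id": f.member_ids[i],
                        "family_id": f.family_id,
                        "region_label": lab,
                        **{
                            k: ("NA" if np.isnan(v) else f"{v:.8f}")
                            for k, v in m.as_dict().items()
                        },
                        "n_het_calls": int(x[i, 1]),
                        "n_homalt_calls": int(x[i, 2]),
                    }
                )
            diagnostics[f"{f.family_id}/{lab}"] = {
                "log_likelihood": rates.log_likelihood,
                "iterations": rates.n_iter,
                "converged": rates.converged,
                "lecam_bound": bound,
                "n_sites": counts.n_sites,
                "n_dropped_rows": n_dropped,
            }

    paths = {
        "rates": out / "rates.tsv",
        "metrics": out / "metrics.tsv",
        "diagnostics": out / "diagnostics.json",
    }
    header = _provenance(config)
    with open(paths["rates"], "w") as fh:
        fh.write(header)
        pd.concat(rate_rows, ignore_index=True).to_csv(fh, sep="\t", index=False)
    with open(paths["metrics"], "w") as fh:
        fh.write(header)
        pd.DataFrame.from_records(metric_rows).to_csv(fh, sep="\t", index=False)
    with open(paths["diagnostics"], "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "skip_tallies": dict(skip),
                "fits": diagnostics,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    logger.info("skip tallies: %s", dict(skip))
    return paths


def _find_family_of_twins(
    families: Sequence[FamilyStructure], a: str, b: str
) -> FamilyStructure:
    for f in families:
        if a in f.child_ids and b in f.child_ids:
            return f
    raise ValueError(f"twin pair ({a}, {b}) not found as children of one family")


def twin_report(
    config: RunConfig, twin_pairs: Sequence[Tuple[str, str]]
) -> pd.DataFrame:
    """Predicted vs observed genotype mismatches for monozygotic twin pairs.

    Each twin's error rates are fitted on the family with the co-twin
    removed, then expected mismatch counts E[M_{a,b}] are compared with the
    observed counts from the same site set.
    """
    families = read_pedigree(config.ped_path)
    needed = sorted({s for f in families for s in f.member_ids})
    skip = Counter()
    source, records = stream_sites(
        config.vcf_path,
        required_samples=needed,
        pass_only=config.filter_pass_only,
        informative_only=config.informative_only,
        autosomes_only=config.autosomes_only,
        skip_counter=skip,
    )
    col = source.sample_to_col

    structures: Dict[str, FamilyStructure] = {}
    for a, b in twin_pairs:
        fam = _find_family_of_twins(families, a, b)
        others = [c for c in fam.child_ids if c != b]
        structures[a] = fam.drop_children(others)
        structures[b] = fam.drop_children([c for c in fam.child_ids if c != a])

    tallies: Dict[str, Dict[tuple, int]] = {s: {} for s in structures}
    pair_joint: Dict[Tuple[str, str], np.ndarray] = {
        (a, b): np.zeros(16, dtype=np.int64) for a, b in twin_pairs
    }
    n = 0
    cols = {s: [col[m] for m in st.member_ids] for s, st in structures.items()}
    for rec in records:
        n += 1
        for s, cc in cols.items():
            t = tuple(int(rec.calls[c]) for c in cc)
            d = tallies[s]
            d[t] = d.get(t, 0) + 1
        for (a, b), joint in pair_joint.items():
            joint[int(rec.calls[col[a]]) * 4 + int(rec.calls[col[b]])] += 1

    rows = []
    for a, b in twin_pairs:
        est = {}
        for twin in (a, b):
            st = structures[twin]
            counts = FamilyGenotypeCounts(st, tallies[twin], n)
            rates = fit_error_rates(build_design(counts))
            est[twin] = expected_error_counts(rates, counts.observed_genotype_counts())
        ia = structures[a].member_ids.index(a)
        ib = structures[b].member_ids.index(b)
        pred = predict_twin_mismatches(est[a], ia, est[b], ib)
        joint = pair_joint[(a, b)]
        for (x, y), e in sorted(pred.unordered.items()):
            obs = int(joint[x * 4 + y] + joint[y * 4 + x])
            rows.append(
                {
                    "pair_id": f"{a}|{b}",
                    "category": f"{GT_LABELS[x]}/{GT_LABELS[y]}",
                    "expected": e,
                    "observed": obs,
                }
            )
        obs_total = int(sum(joint[x * 4 + y] for x in range(4) for y in range(4) if x != y))
        obs_gt = int(sum(joint[x * 4 + y] for x in range(3) for y in range(3) if x != y))
        rows.append(
            {"pair_id": f"{a}|{b}", "category": "total", "expected": pred.total, "observed": obs_total}
        )
        rows.append(
            {
                "pair_id": f"{a}|{b}",
                "category": "total_genotype_only",
                "expected": pred.total_genotype_only,
                "observed": obs_gt,
            }
        )
    return pd.DataFrame.from_records(rows)


def consensus_report(
    config: RunConfig,
    replicate_groups: Mapping[str, Sequence[str]],
    min_agree: int = 3,
) -> pd.DataFrame:
    """Replicate-agreement precision/recall for groups of samples that are
    sequencing replicates of the same individual (e.g. MZ quadruplets)."""
    needed = sorted({s for ss in replicate_groups.values() for s in ss})
    skip = Counter()
    source, records = stream_sites(
        config.vcf_path,
        required_samples=needed,
        pass_only=config.filter_pass_only,
        informative_only=config.informative_only,
        autosomes_only=config.autosomes_only,
        skip_counter=skip,
    )
    col = source.sample_to_col
    per_group_calls: Dict[str, List[np.ndarray]] = {g: [] for g in replicate_groups}
    for rec in records:
        for g, ss in replicate_groups.items():
            per_group_calls[g].append(rec.calls[[col[s] for s in ss]])
    rows = []
    for g, ss in replicate_groups.items():
        calls = np.asarray(per_group_calls[g])
        truth, mets, _ = consensus_genotypes(calls, min_agree=min_agree)
        n_consensus = int((truth != -1).sum())
        for s, m in zip(ss, mets):
            rows.append(
                {
                    "group_id": g,
                    "sample_id": s,
                    "n_consensus_sites": n_consensus,
                    **{k: ("NA" if np.isnan(v) else round(v, 8)) for k, v in m.as_dict().items()},
                }
            )
    return pd.DataFrame.from_records(rows)
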