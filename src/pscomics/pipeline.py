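"""End-to-end cohort analysis.

Chains the pipeline stages over a cohort directory (as written by
:func:`pscomics.synthetic.simulate_cohort`, or assembled from real call
sets in the same layout): per-tumor consensus filtering and TMB, driver
curation and gene-level tests, clonal-tree reconstruction, immune
subtyping on the count matrix, and subtype-survival association.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import clonal, drivers, subtyping, survival, vcfio
from .config import CALLER_NAMES
from .consensus import CategorySummary, run_consensus

log = logging.getLogger(__name__)


@dataclass
class TumorResult:
    tumor_id: str
    summary: CategorySummary
    tmb: float
    evolution: Optional[clonal.TumorEvolution] = None


@dataclass
class PipelineResult:
    tumors: Dict[str, TumorResult]
    driver_calls: List[drivers.DriverCall]
    mutation_mat: pd.DataFrame
    prevalence: pd.Series
    trunk_map: Dict = field(default_factory=dict)
    convergent: List = field(default_factory=list)
    subtyping: Optional[subtyping.SubtypingResult] = None
    survival_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def mean_tmb(self) -> float:
        return float(np.mean([t.tmb for t in self.tumors.values()]))

    @property
    def branched_fraction(self) -> float:
        calls = [t.evolution.branching for t in self.tumors.values()
                 if t.evolution is not None]
        if not calls:
            return float("nan")
        return sum(c == "branched" for c in calls) / len(calls)


def discover_cohort(cohort_dir, callers=CALLER_NAMES) -> Dict[str, Dict[str, Path]]:
    """Locate per-tumor caller VCFs named ``<tumor>.<caller>.vcf``."""
    cohort_dir = Path(cohort_dir)
    out: Dict[str, Dict[str, Path]] = {}
    for p in sorted(cohort_dir.glob("*.vcf")):
        parts = p.stem.rsplit(".", 1)
        if len(parts) == 2 and parts[1] in callers:
            out.setdefault(parts[0], {})[parts[1]] = p
    return out


def run_pipeline(cohort_dir, *, target_mb: float = 50.0,
                 vaf_threshold: float = 0.05, max_k: int = 5,
                 min_mutations_for_tree: int = 5,
                 nmf_restarts: int = 30, n_top_genes: int = 1500,
                 sam_permutations: int = 500, seed: int = 0
                 ) -> PipelineResult:
    """Run every stage over one cohort directory."""
    cohort_dir = Path(cohort_dir)
    pooled = vcfio.read_pooled_normal(cohort_dir / "pooled_normal.vcf")
    annotations = vcfio.read_annotations(cohort_dir / "annotations.tsv")
    gene_roles = drivers.read_gene_roles(cohort_dir / "gene_roles.tsv")
    vcfs = discover_cohort(cohort_dir)

    tumors: Dict[str, TumorResult] = {}
    all_f2 = []
    for tumor_id, caller_paths in vcfs.items():
        obs = {c: vcfio.read_caller_vcf(p, tumor_id, c)
               for c, p in caller_paths.items()}
        summary, tmb = run_consensus(obs, pooled, annotations,
                                     vaf_threshold=vaf_threshold,
                                     target_mb=target_mb)
        tumors[tumor_id] = TumorResult(tumor_id, summary, tmb)
        all_f2.extend(v for v in summary.f1f2_variants if v.f2)

    driver_calls = drivers.curate_drivers(all_f2, gene_roles)
    mat, prevalence = drivers.mutation_matrix(driver_calls, sorted(tumors))
    convergent = clonal.detect_convergent(driver_calls)

    trunk_map: Dict = {}
    for tumor_id, tres in tumors.items():
        f1f2 = tres.summary.f1f2_variants
        if len(f1f2) < min_mutations_for_tree:
            log.info("%s: %d mutations < %d; clonal analysis skipped",
                     tumor_id, len(f1f2), min_mutations_for_tree)
            continue
        vafs = [(cv.locus, (cv.fwd_vaf + cv.rev_vaf) / 2.0) for cv in f1f2]
        evo = clonal.analyze_tumor(tumor_id, vafs, max_k=max_k, seed=seed)
        tres.evolution = evo
        assignments = {m.locus: m.cluster_id for m in evo.mutations}
        calls_here = [c for c in driver_calls if c.tumor_id == tumor_id]
        trunk_map[tumor_id] = clonal.map_to_trunk(calls_here, evo.tree,
                                                  assignments)

    result = PipelineResult(tumors=tumors, driver_calls=driver_calls,
                            mutation_mat=mat, prevalence=prevalence,
                            trunk_map=trunk_map, convergent=convergent)

    counts_path = cohort_dir / "counts.tsv"
    gmt_path = cohort_dir / "genesets.gmt"
    if counts_path.exists() and gmt_path.exists():
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
        gene_sets = vcfio.read_gmt(gmt_path)
        immune = gene_sets.get("IMMUNE_SIGNATURE", [])
        stromal = gene_sets.get("STROMAL_SIGNATURE", [])
        markers = {k: v for k, v in gene_sets.items()
                   if k not in ("IMMUNE_SIGNATURE", "STROMAL_SIGNATURE")}
        if counts.shape[1] >= 4 and immune:
            result.subtyping = subtyping.subtype_cohort(
                counts, immune, stromal, marker_sets=markers,
                n_restarts=nmf_restarts, n_top_genes=n_top_genes,
                n_perm=sam_permutations, seed=seed)

    clinical_path = cohort_dir / "clinical.tsv"
    if clinical_path.exists() and result.subtyping is not None:
        clinical = pd.read_csv(clinical_path, sep="\t")
        labels = result.subtyping.samples["label"]
        clin = clinical[clinical["sample_id"].isin(labels.index)].copy()
        clin["group"] = labels.loc[clin["sample_id"]].to_numpy()
        adjust = [c for c in ("smoking_ever", "stage_code", "gender_male")
                  if c in clin.columns]
        for endpoint in ("rfs", "os"):
            df = clin.rename(columns={f"{endpoint}_time": "time",
                                      f"{endpoint}_event": "event"})
            try:
                result.survival_tables[endpoint] = survival.survival_summary(
                    df, group_col="group", adjust_for=adjust)
            except ValueError as exc:
                log.warning("%s survival analysis skipped: %s", endpoint, exc)
    return result


def write_pipeline_outputs(result: PipelineResult, outdir) -> None:
    """Tidy per-stage outputs: consensus TSVs, driver matrix, tree JSON,
    subtype TSV, survival TSVs and a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tumor_id, tres in result.tumors.items():
        vcfio.write_consensus_tsv(outdir / f"{tumor_id}.consensus.tsv",
                                  tres.summary.f1f2_variants
                                  + tres.summary.rejected)
    drivers.write_driver_tsv(outdir / "drivers.tsv", result.driver_calls)
    result.mutation_mat.to_csv(outdir / "mutation_matrix.tsv", sep="\t",
                               index_label="gene")
    trees = {tid: t.evolution.to_dict() for tid, t in result.tumors.items()
             if t.evolution is not None}
    with open(outdir / "trees.json", "w") as fh:
        json.dump(trees, fh, indent=1, sort_keys=True)
    if result.subtyping is not None:
        result.subtyping.samples.to_csv(outdir / "subtypes.tsv", sep="\t",
                                        index_label="sample_id")
        result.subtyping.gene_ranking.to_csv(outdir / "gene_ranking.tsv",
                                             sep="\t", index_label="gene")
        result.subtyping.centroids.to_csv(outdir / "centroids.tsv", sep="\t",
                                          index_label="gene")
        diag = {str(k): {"cophenetic": d.cophenetic,
                         "mean_silhouette": d.mean_silhouette}
                for k, d in result.subtyping.rank_diagnostics.items()}
        diag["selected_rank"] = result.subtyping.selected_rank
        with open(outdir / "rank_diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=1, sort_keys=True)
    for endpoint, table in result.survival_tables.items():
        table.to_csv(outdir / f"survival_{endpoint}.tsv", sep="\t",
                     index=False)
    summary = {
        "n_tumors": len(result.tumors),
        "mean_tmb_per_mb": round(result.mean_tmb, 4),
        "f1f2_total": sum(t.summary.counts["f1f2_total"]
                          for t in result.tumors.values()),
        "category_counts": {
            cat: sum(t.summary.counts[cat] for t in result.tumors.values())
            for cat in ("both", "hotspot_rescue", "other_somatic", "rejected")},
        "n_driver_calls": len(result.driver_calls),
        "prevalence": {g: round(float(p), 4)
                       for g, p in result.prevalence.items()},
        "branched_fraction": (None if np.isnan(result.branched_fraction)
                              else round(result.branched_fraction, 4)),
        "n_convergent_events": len(result.convergent),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
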