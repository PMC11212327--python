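"""Synthetic multiomics cohort generator.

Emulates the statistical structure of a 21-tumor PSC study so every
downstream stage — consensus filtering, driver curation, clonal-tree
reconstruction, immune subtyping and survival association — can be run
and validated without any external data:

* planted somatic variants organised into a clonal tree (trunk plus
  0-3 subclonal branches) with cancer cell fractions (CCF);
* three callers observing those variants with caller-specific
  sensitivity, false-positive rate and strand-bias probability, at
  binomial depths around a configurable mean (default 225x), with
  VAF = CCF x purity / 2 under the diploid-heterozygous model;
* a pooled-normal call set carrying germline loci and recurrent
  platform artifacts shared across tumors;
* negative-binomial RNA-seq counts with a planted immune-signature
  effect separating two latent subtypes, and >= 2-fold library-size
  variation;
* exponential recurrence-free / overall survival times with a
  subtype-dependent hazard and uniform administrative censoring.

All randomness flows through a single seed; identical config + seed
gives byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import (CALLER_NAMES, CallerProfile, CohortConfig,
                     DRIVER_GENE_ROLES, ExpressionSpec, SurvivalSpec)
from .consensus import Locus, VariantAnnotation, VariantObservation
from . import vcfio

_CHROMS = [f"chr{i}" for i in range(1, 23)]
_BASES = "ACGT"

# Stage distribution of the cohort (ordinal code 1..7 = IA..IV).
_STAGE_CODES = {"IA": 1, "IB": 2, "IIA": 3, "IIB": 4, "IIIA": 5, "IIIB": 6, "IV": 7}
_STAGE_PROBS = {"IA": 0.143, "IB": 0.333, "IIA": 0.048, "IIB": 0.286,
                "IIIA": 0.095, "IIIB": 0.048, "IV": 0.048}


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class TrueVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    subclone_id: int
    ccf: float
    driver: bool

    @property
    def locus(self) -> Locus:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TumorTruth:
    tumor_id: str
    purity: float
    # tree nodes: {"id": int, "parent": int|None, "ccf": float}; id 0 is the trunk
    tree_nodes: List[dict]
    branched: bool
    variants: List[TrueVariant]

    def node_ccf(self, node_id: int) -> float:
        return next(n["ccf"] for n in self.tree_nodes if n["id"] == node_id)


@dataclass
class GroundTruth:
    """Everything the simulator planted, for recovery checks."""

    tumors: List[TumorTruth]
    subtype_labels: Dict[str, str]          # sample -> IM-H / IM-L (all tumors)
    expression_samples: List[str]           # subset with RNA-seq
    immune_genes: List[str]
    stromal_genes: List[str]
    marker_genes: Dict[str, List[str]]

    def to_json(self, path) -> None:
        d = {
            "tumors": [
                {"tumor_id": t.tumor_id, "purity": t.purity,
                 "tree_nodes": t.tree_nodes, "branched": t.branched,
                 "variants": [asdict(v) for v in t.variants]}
                for t in self.tumors
            ],
            "subtype_labels": self.subtype_labels,
            "expression_samples": self.expression_samples,
            "immune_genes": self.immune_genes,
            "stromal_genes": self.stromal_genes,
            "marker_genes": self.marker_genes,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        tumors = [TumorTruth(
            tumor_id=t["tumor_id"], purity=t["purity"],
            tree_nodes=t["tree_nodes"], branched=t["branched"],
            variants=[TrueVariant(**v) for v in t["variants"]])
            for t in d["tumors"]]
        return cls(tumors=tumors, subtype_labels=d["subtype_labels"],
                   expression_samples=d["expression_samples"],
                   immune_genes=d["immune_genes"],
                   stromal_genes=d["stromal_genes"],
                   marker_genes=d["marker_genes"])


# ---------------------------------------------------------------------------
# clonal architecture and variants
# ---------------------------------------------------------------------------

def _branch_ccfs(rng: np.random.Generator, n_children: int, min_sep: float
                 ) -> Optional[List[float]]:
    """Sibling branch CCFs: sum <= 0.92 (clear of the trunk's
    capacity), each >= 0.12, pairwise separation >= min_sep and the
    largest >= min_sep below the trunk.  None when infeasible."""
    for _ in range(200):
        raw = np.sort(rng.dirichlet(np.ones(n_children))
                      * rng.uniform(0.5, 0.92))[::-1]
        if raw.min() < 0.12 or raw.max() > 1.0 - min_sep:
            continue
        if n_children > 1 and np.min(-np.diff(raw)) < min_sep:
            continue
        return [float(c) for c in raw]
    return None


def _simulate_tree(rng: np.random.Generator, spec) -> Tuple[List[dict], bool]:
    """Trunk (CCF 1 in cancer-cell space) plus 0-3 sibling branches.

    Single-sample CCFs cannot tell a nested chain from siblings, so the
    planted architectures follow the same pigeonhole convention the
    tree builder resolves to: subclones are siblings of the trunk, and
    a tumor is branched when it carries >= 2 of them.
    """
    nodes = [{"id": 0, "parent": None, "ccf": 1.0}]
    branched = bool(rng.random() < spec.p_branched) and spec.max_branches >= 2
    if branched:
        n_children = int(rng.integers(2, spec.max_branches + 1))
        ccfs = None
        while ccfs is None and n_children >= 2:
            ccfs = _branch_ccfs(rng, n_children, spec.min_ccf_sep)
            if ccfs is None:
                n_children -= 1
        if ccfs is None:  # separation infeasible even for 2 branches
            branched = False
            ccfs = _branch_ccfs(rng, 1, spec.min_ccf_sep) or []
    else:
        n_children = int(rng.integers(0, 2))
        ccfs = _branch_ccfs(rng, 1, spec.min_ccf_sep) if n_children else []
        ccfs = ccfs or []
    for i, c in enumerate(ccfs, start=1):
        nodes.append({"id": i, "parent": 0, "ccf": round(c, 4)})
    return nodes, branched


def _random_locus(rng: np.random.Generator, used: set) -> Tuple[str, int, str, str]:
    while True:
        chrom = _CHROMS[int(rng.integers(len(_CHROMS)))]
        pos = int(rng.integers(1, 120_000_000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = _BASES[int(rng.integers(4))]
        alt = rng.choice([b for b in _BASES if b != ref])
        return chrom, pos, ref, str(alt)


_PASSENGER_CONSEQUENCES = np.array(
    ["missense", "synonymous", "other", "stop_gain", "splice", "frameshift",
     "inframe"])
_PASSENGER_CONSEQ_P = np.array([0.45, 0.25, 0.15, 0.05, 0.04, 0.03, 0.03])


def _driver_variant(rng, gene: str, used: set) -> Tuple[TrueVariant, VariantAnnotation]:
    chrom, pos, ref, alt = _random_locus(rng, used)
    if gene == "TP53":
        consequence = str(rng.choice(["stop_gain", "missense", "splice"],
                                     p=[0.4, 0.5, 0.1]))
    elif gene == "KRAS":
        consequence = "missense"
    else:  # MET exon-14 skipping: represented as a splice-consequence variant
        consequence = "splice"
    ann = VariantAnnotation(
        gene=gene, consequence=consequence,
        pan_cancer_count=int(rng.integers(10, 200)), in_clinvar=True,
        acmg_tier=1, gene_role=DRIVER_GENE_ROLES[gene],
        # the MET exon-14 skipping event is a curated pathogenic
        # protein-altering variant despite its splice consequence
        pathogenic_aa_change=(consequence == "missense" or gene == "MET"))
    var = TrueVariant(chrom, pos, ref, alt, gene, consequence,
                      subclone_id=0, ccf=1.0, driver=True)
    return var, ann


def simulate_tumor_truth(tumor_id: str, config: CohortConfig,
                         rng: np.random.Generator,
                         annotations: Dict[Locus, VariantAnnotation]
                         ) -> TumorTruth:
    """Plant one tumor: purity, clonal tree, passenger and driver
    variants with per-variant CCFs (cluster CCF plus Gaussian noise)."""
    spec = config.subclone_spec
    purity = float(rng.uniform(*spec.purity_range))
    nodes, branched = _simulate_tree(rng, spec)
    used: set = set()

    # driver genes present in this tumor; MET exon-14 is mutually
    # exclusive with TP53/KRAS
    present = [g for g, p in config.driver_prevalence.items()
               if rng.random() < p]
    if "MET" in present:
        present = [g for g in present if g not in ("TP53", "KRAS")]

    variants: List[TrueVariant] = []
    node_ids = [n["id"] for n in nodes]
    node_ccfs = {n["id"]: n["ccf"] for n in nodes}

    for gene in present:
        var, ann = _driver_variant(rng, gene, used)
        if len(nodes) > 1 and rng.random() >= config.trunk_driver_rate:
            var.subclone_id = int(rng.choice(node_ids[1:]))
        cluster_ccf = node_ccfs[var.subclone_id]
        var.ccf = float(np.clip(rng.normal(cluster_ccf, spec.ccf_sd), 0.02, 1.2))
        variants.append(var)
        annotations[var.locus] = ann
        # occasional second, distinct TP53 hit: convergent evolution
        if gene == "TP53" and rng.random() < 0.05:
            var2, ann2 = _driver_variant(rng, gene, used)
            var2.subclone_id = int(rng.choice(node_ids))
            var2.ccf = float(np.clip(
                rng.normal(node_ccfs[var2.subclone_id], spec.ccf_sd), 0.02, 1.2))
            variants.append(var2)
            annotations[var2.locus] = ann2

    n_passengers = int(rng.poisson(config.n_true_variants_mean))
    if n_passengers > 0:
        # trunk carries half the mutations; the rest split across subclones
        weights = np.array([0.5 if nid == 0 else 0.5 / max(len(node_ids) - 1, 1)
                            for nid in node_ids])
        weights /= weights.sum()
        counts = rng.multinomial(n_passengers, weights)
        for nid, n_in_cluster in zip(node_ids, counts):
            for _ in range(n_in_cluster):
                chrom, pos, ref, alt = _random_locus(rng, used)
                gene = f"GENE{int(rng.integers(1, 5001)):05d}"
                consequence = str(rng.choice(_PASSENGER_CONSEQUENCES,
                                             p=_PASSENGER_CONSEQ_P))
                ccf = float(np.clip(rng.normal(node_ccfs[nid], spec.ccf_sd),
                                    0.02, 1.2))
                var = TrueVariant(chrom, pos, ref, alt, gene, consequence,
                                  subclone_id=int(nid), ccf=ccf, driver=False)
                variants.append(var)
                # ~3% of passengers carry hotspot-like external evidence
                hotspot = rng.random() < 0.03
                annotations[var.locus] = VariantAnnotation(
                    gene=gene, consequence=consequence,
                    pan_cancer_count=int(rng.integers(4, 40)) if hotspot
                    else int(rng.integers(0, 4)),
                    in_clinvar=bool(hotspot and rng.random() < 0.5),
                    acmg_tier=None, gene_role="none",
                    pathogenic_aa_change=bool(
                        consequence == "missense" and rng.random() < 0.3))
    return TumorTruth(tumor_id=tumor_id, purity=purity, tree_nodes=nodes,
                      branched=branched, variants=variants)


# ---------------------------------------------------------------------------
# caller observations
# ---------------------------------------------------------------------------

def _observe(rng: np.random.Generator, tumor_id: str, caller: str,
             chrom: str, pos: int, ref: str, alt: str, vaf: float,
             mean_depth: int, strand_biased: bool, passed: bool
             ) -> VariantObservation:
    fwd_depth = int(rng.binomial(mean_depth, 0.5))
    rev_depth = int(rng.binomial(mean_depth, 0.5))
    fwd_alt = int(rng.binomial(fwd_depth, vaf))
    rev_alt = int(rng.binomial(rev_depth, vaf))
    if strand_biased:
        # collapse all alternate reads onto one strand
        total = fwd_alt + rev_alt
        if rng.random() < 0.5:
            fwd_alt, rev_alt = min(total, fwd_depth), 0
        else:
            fwd_alt, rev_alt = 0, min(total, rev_depth)
    return VariantObservation(tumor_id, caller, chrom, pos, ref, alt, passed,
                              fwd_alt, rev_alt, fwd_depth, rev_depth)


def simulate_caller_observations(
        true_variants: Sequence[TrueVariant],
        caller_profiles: Sequence[CallerProfile],
        seed, *,
        purity: float = 0.7,
        mean_depth: int = 225,
        target_mb: float = 50.0,
        tumor_id: str = "T") -> Dict[str, List[VariantObservation]]:
    """Observe planted variants through three imperfect callers.

    Each caller reports a true variant with its sensitivity, adds
    Poisson false positives at ``fp_rate_per_mb x target_mb``, and with
    ``strand_bias_prob`` collapses a reported variant's alternate reads
    onto a single strand.  ``seed`` may be an int or a Generator.
    """
    if len(caller_profiles) != 3:
        raise ValueError(
            f"exactly 3 caller profiles required, got {len(caller_profiles)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: Dict[str, List[VariantObservation]] = {}
    fp_used: set = {(v.chrom, v.pos) for v in true_variants}
    for prof in caller_profiles:
        obs: List[VariantObservation] = []
        for v in true_variants:
            if rng.random() >= prof.sensitivity:
                continue
            vaf = v.ccf * purity / 2.0  # diploid heterozygous site
            biased = rng.random() < prof.strand_bias_prob
            obs.append(_observe(rng, tumor_id, prof.name, v.chrom, v.pos,
                                v.ref, v.alt, vaf, mean_depth, biased, True))
        n_fp = int(rng.poisson(prof.fp_rate_per_mb * target_mb))
        for _ in range(n_fp):
            chrom, pos, ref, alt = _random_locus(rng, fp_used)
            vaf = float(rng.uniform(0.02, 0.15))
            obs.append(_observe(rng, tumor_id, prof.name, chrom, pos, ref,
                                alt, vaf, mean_depth, rng.random() < 0.3, True))
        out[prof.name] = obs
    return out


def _simulate_shared_loci(rng: np.random.Generator, n_artifacts: int
                          ) -> Tuple[List[Tuple], List[Tuple]]:
    """Recurrent artifact loci (seen in every tumor and in the pooled
    normal) and germline-only loci (pooled normal only)."""
    used: set = set()
    artifacts = [_random_locus(rng, used) for _ in range(n_artifacts)]
    germline = [_random_locus(rng, used) for _ in range(2 * n_artifacts)]
    return artifacts, germline


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def make_gene_names(spec: ExpressionSpec) -> Tuple[List[str], List[str],
                                                   List[str], List[str]]:
    immune = [f"IMM{i:04d}" for i in range(spec.n_immune_genes)]
    stromal = [f"STR{i:04d}" for i in range(spec.n_stromal_genes)]
    markers = [f"NEUT{i:03d}" for i in range(spec.n_marker_genes)]
    n_rest = spec.n_genes - len(immune) - len(stromal) - len(markers)
    rest = [f"G{i:05d}" for i in range(n_rest)]
    return immune, stromal, markers, rest


def simulate_expression(expr_spec: ExpressionSpec,
                        subtype_labels: Mapping[str, str],
                        immune_geneset: Sequence[str],
                        seed, *,
                        gene_names: Optional[Sequence[str]] = None,
                        stromal_geneset: Sequence[str] = (),
                        marker_geneset: Sequence[str] = (),
                        gene_factor: Optional[np.ndarray] = None,
                        ) -> pd.DataFrame:
    """Negative-binomial gene x sample count matrix.

    Genes in ``immune_geneset`` (and ``marker_geneset``) have their mean
    multiplied by ``2**immune_effect_log2fc`` in IM-H samples; stromal
    genes get half the effect on the log2 scale.  Library-size factors
    span exactly ``libsize_spread``-fold across samples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = list(subtype_labels)
    if gene_names is None:
        imm, stro, mark, rest = make_gene_names(expr_spec)
        gene_names = imm + stro + mark + rest
    genes = list(gene_names)
    n_g, n_s = len(genes), len(samples)

    # gene-intrinsic abundance; pass the same vector to a second call to
    # emulate an external cohort sharing the genes' baseline biology
    if gene_factor is None:
        gene_factor = rng.lognormal(mean=0.0, sigma=0.6, size=n_g)
    else:
        gene_factor = np.asarray(gene_factor, dtype=float)
        if gene_factor.shape != (n_g,):
            raise ValueError("gene_factor length must match gene_names")
    u = rng.uniform(0.0, 1.0, size=n_s)
    if n_s >= 2:
        u[0], u[1] = 0.0, 1.0  # pin the extremes: spread is exact
    lib_factor = expr_spec.libsize_spread ** u

    imm_set = set(immune_geneset) | set(marker_geneset)
    stro_set = set(stromal_geneset)
    log2fc = np.zeros(n_g)
    for i, g in enumerate(genes):
        if g in imm_set:
            log2fc[i] = expr_spec.immune_effect_log2fc
        elif g in stro_set:
            log2fc[i] = expr_spec.immune_effect_log2fc / 2.0

    is_high = np.array([subtype_labels[s] == "IM-H" for s in samples])
    base = expr_spec.baseline_mean * gene_factor  # (n_g,)
    mu = base[:, None] * lib_factor[None, :]
    mu = mu * np.power(2.0, log2fc[:, None] * is_high[None, :])

    size = 1.0 / expr_spec.dispersion  # NB shape parameter
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)
    return pd.DataFrame(counts, index=genes, columns=samples)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _censor_horizon(hazard: float, censor_rate: float) -> float:
    """Upper bound of the uniform censoring window achieving
    approximately ``censor_rate`` for an exponential(hazard) time."""
    if censor_rate <= 0:
        return math.inf

    def p_censor(c):
        return (1.0 - math.exp(-hazard * c)) / (hazard * c) - censor_rate

    # p_censor(c)+rate decreases from 1 (c->0) to 0 (c->inf)
    lo, hi = 1e-9, 1.0
    while p_censor(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            return hi
    return brentq(p_censor, lo, hi)


def simulate_survival(subtype_labels: Mapping[str, str],
                      surv_spec: SurvivalSpec, seed) -> pd.DataFrame:
    """Exponential event times with hazard ``baseline x
    exp(log_hr x 1[IM-L])`` and independent uniform censoring.

    Returns columns sample_id, time (months), event, group.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for sample, label in subtype_labels.items():
        hazard = surv_spec.baseline_hazard * math.exp(
            surv_spec.log_hr_subtype if label == "IM-L" else 0.0)
        t_event = rng.exponential(1.0 / hazard)
        horizon = _censor_horizon(hazard, surv_spec.censor_rate)
        t_censor = rng.uniform(0.0, horizon) if math.isfinite(horizon) else math.inf
        time = max(min(t_event, t_censor), 1e-6)
        event = int(t_event <= t_censor)
        rows.append({"sample_id": sample, "time": time, "event": event,
                     "group": label})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortPaths:
    """File layout written by :func:`simulate_cohort`."""

    outdir: Path
    caller_vcfs: Dict[str, Dict[str, Path]] = field(default_factory=dict)
    pooled_normal: Optional[Path] = None
    annotations: Optional[Path] = None
    gene_roles: Optional[Path] = None
    counts: Optional[Path] = None
    genesets: Optional[Path] = None
    clinical: Optional[Path] = None
    ground_truth: Optional[Path] = None
    config: Optional[Path] = None


def simulate_cohort(config: CohortConfig, outdir) -> Tuple[GroundTruth, CohortPaths]:
    """Generate a complete synthetic cohort and write every file the
    pipeline consumes.

    Deterministic for a fixed config (incl. seed): writes per-tumor
    VCFs for the three callers, a pooled-normal VCF, annotation and
    gene-role TSVs, a gene x sample count matrix, gene sets (GMT), a
    clinical table, the ground truth JSON, and the config YAML.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)
    # independent streams per concern so adding tumors never perturbs
    # expression or survival draws
    rng_truth, rng_callers, rng_shared, rng_expr, rng_surv, rng_clin = (
        np.random.default_rng(s) for s in root.integers(0, 2**31 - 1, size=6))

    tumor_ids = [f"PSC{i + 1:03d}" for i in range(config.n_tumors)]
    annotations: Dict[Locus, VariantAnnotation] = {}
    tumors = [simulate_tumor_truth(tid, config, rng_truth, annotations)
              for tid in tumor_ids]

    artifacts, germline = _simulate_shared_loci(rng_shared, config.n_artifact_loci)

    paths = CohortPaths(outdir=outdir)
    caller_names = [p.name for p in config.caller_profiles]
    for tumor in tumors:
        obs = simulate_caller_observations(
            tumor.variants, config.caller_profiles, rng_callers,
            purity=tumor.purity, mean_depth=config.mean_depth,
            target_mb=config.target_mb, tumor_id=tumor.tumor_id)
        # recurrent artifacts: every caller sees them at germline-like VAF
        for chrom, pos, ref, alt in artifacts:
            for caller in caller_names:
                obs[caller].append(_observe(
                    rng_callers, tumor.tumor_id, caller, chrom, pos, ref, alt,
                    vaf=float(rng_callers.uniform(0.35, 0.65)),
                    mean_depth=config.mean_depth, strand_biased=False,
                    passed=True))
        paths.caller_vcfs[tumor.tumor_id] = {}
        for caller in caller_names:
            p = outdir / f"{tumor.tumor_id}.{caller}.vcf"
            vcfio.write_caller_vcf(p, obs[caller], source=f"synthetic-{caller}")
            paths.caller_vcfs[tumor.tumor_id][caller] = p

    pooled_obs = [
        VariantObservation("pooled_normal", "pooled", chrom, pos, ref, alt,
                           True, 10, 10, 20, 20)
        for chrom, pos, ref, alt in artifacts + germline]
    paths.pooled_normal = outdir / "pooled_normal.vcf"
    vcfio.write_caller_vcf(paths.pooled_normal, pooled_obs,
                           source="synthetic-pooled-normal")

    paths.annotations = outdir / "annotations.tsv"
    vcfio.write_annotations(paths.annotations, annotations)

    paths.gene_roles = outdir / "gene_roles.tsv"
    with open(paths.gene_roles, "w") as fh:
        fh.write("gene\trole\n")
        for gene, role in sorted(DRIVER_GENE_ROLES.items()):
            fh.write(f"{gene}\t{role}\n")

    # latent subtype for every tumor; expression for the first
    # n_expression_samples of them
    subtype_labels = {
        tid: ("IM-H" if rng_expr.random() < config.p_immune_high else "IM-L")
        for tid in tumor_ids}
    expr_samples = tumor_ids[:min(config.n_expression_samples, len(tumor_ids))]
    imm, stro, mark, rest = make_gene_names(config.expr_spec)
    counts = simulate_expression(
        config.expr_spec, {s: subtype_labels[s] for s in expr_samples},
        immune_geneset=imm, seed=rng_expr,
        gene_names=imm + stro + mark + rest,
        stromal_geneset=stro, marker_geneset=mark)
    paths.counts = outdir / "counts.tsv"
    counts.to_csv(paths.counts, sep="\t", index_label="gene")

    paths.genesets = outdir / "genesets.gmt"
    with open(paths.genesets, "w") as fh:
        fh.write("IMMUNE_SIGNATURE\tsynthetic\t" + "\t".join(imm) + "\n")
        fh.write("STROMAL_SIGNATURE\tsynthetic\t" + "\t".join(stro) + "\n")
        fh.write("Neutrophils\tsynthetic\t" + "\t".join(mark) + "\n")

    rfs = simulate_survival(subtype_labels, config.surv_spec, rng_surv)
    os_spec = SurvivalSpec(
        baseline_hazard=config.surv_spec.baseline_hazard * 0.5,
        log_hr_subtype=config.surv_spec.log_hr_subtype,
        censor_rate=config.surv_spec.censor_rate)
    osurv = simulate_survival(subtype_labels, os_spec, rng_surv)

    stages = list(_STAGE_PROBS)
    probs = np.array([_STAGE_PROBS[s] for s in stages])
    probs = probs / probs.sum()
    clin_rows = []
    for i, tid in enumerate(tumor_ids):
        stage = stages[int(rng_clin.choice(len(stages), p=probs))]
        clin_rows.append({
            "sample_id": tid,
            "subtype_truth": subtype_labels[tid],
            "has_expression": int(tid in expr_samples),
            "rfs_time": round(float(rfs.loc[i, "time"]), 4),
            "rfs_event": int(rfs.loc[i, "event"]),
            "recurrence": int(rfs.loc[i, "event"]),
            "os_time": round(float(osurv.loc[i, "time"]), 4),
            "os_event": int(osurv.loc[i, "event"]),
            "stage": stage,
            "stage_code": _STAGE_CODES[stage],
            "gender_male": int(rng_clin.random() < 2.0 / 3.0),
            "smoking_ever": int(rng_clin.random() < 0.952),
        })
    clinical = pd.DataFrame(clin_rows)
    paths.clinical = outdir / "clinical.tsv"
    clinical.to_csv(paths.clinical, sep="\t", index=False)

    truth = GroundTruth(tumors=tumors, subtype_labels=subtype_labels,
                        expression_samples=expr_samples, immune_genes=imm,
                        stromal_genes=stro, marker_genes={"Neutrophils": mark})
    paths.ground_truth = outdir / "ground_truth.json"
    truth.to_json(paths.ground_truth)

    paths.config = outdir / "config.yaml"
    config.to_yaml(paths.config)
    return truth, paths
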