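"""Driver curation and gene-level association tests.

Distills canonical cancer-gene mutations from the F2-rescued variant
set: pathogenic amino-acid changes in oncogenes, or truncating
mutations (stop-gain / splice / frameshift) in tumor suppressor genes.
Gene-level relationships are tested with Fisher's exact test (mutual
exclusivity) and the Pearson chi-squared test (outcome association).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import (ConsensusVariant, Locus, TRUNCATING_CONSEQUENCES)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DriverCall:
    tumor_id: str
    gene: str
    consequence: str
    rationale: str  # oncogene_pathogenic | tsg_truncating
    locus: Locus


def curate_drivers(f2_variants: Sequence[ConsensusVariant],
                   gene_roles: Mapping[str, str]) -> List[DriverCall]:
    """Select canonical cancer-gene mutations from F2-qualified variants.

    A variant qualifies as ``oncogene_pathogenic`` when its gene's role
    is oncogene (or both) and the annotation marks a pathogenic
    amino-acid change in a nonsynonymous consequence; as
    ``tsg_truncating`` when the role is tumor suppressor (or both) and
    the consequence is truncating.  Genes absent from the role table
    count as role "none" and are excluded.
    """
    calls: List[DriverCall] = []
    unknown_genes: Set[str] = set()
    for cv in f2_variants:
        ann = cv.annotation
        if ann is None or not ann.gene:
            continue
        role = gene_roles.get(ann.gene)
        if role is None:
            unknown_genes.add(ann.gene)
            role = "none"
        if ann.consequence == "synonymous":
            continue
        if role in ("tsg", "both") and ann.consequence in TRUNCATING_CONSEQUENCES:
            calls.append(DriverCall(cv.tumor_id, ann.gene, ann.consequence,
                                    "tsg_truncating", cv.locus))
        elif role in ("oncogene", "both") and ann.pathogenic_aa_change:
            calls.append(DriverCall(cv.tumor_id, ann.gene, ann.consequence,
                                    "oncogene_pathogenic", cv.locus))
    if unknown_genes:
        log.info("genes without role annotation treated as 'none': %s",
                 sorted(unknown_genes)[:10])
    return calls


def mutation_matrix(driver_calls: Iterable[DriverCall],
                    tumor_ids: Sequence[str]
                    ) -> Tuple[pd.DataFrame, pd.Series]:
    """Gene x tumor binary mutation matrix plus per-gene prevalence,
    rows sorted by descending prevalence (ties alphabetical)."""
    tumor_ids = list(tumor_ids)
    genes = sorted({c.gene for c in driver_calls})
    mat = pd.DataFrame(0, index=genes, columns=tumor_ids, dtype=int)
    for c in driver_calls:
        if c.tumor_id in mat.columns:
            mat.loc[c.gene, c.tumor_id] = 1
    prevalence = (mat.sum(axis=1) / len(tumor_ids)) if tumor_ids else \
        pd.Series(0.0, index=genes)
    order = prevalence.sort_values(ascending=False, kind="stable")
    order = order.loc[sorted(order.index)].sort_values(
        ascending=False, kind="stable").index
    return mat.loc[order], prevalence.loc[order]


def mutual_exclusivity_test(gene_a_tumors: Set[str], gene_b_tumors: Set[str],
                            n_tumors: int) -> Tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 co-occurrence table.

    Returns (odds_ratio, p).  Complete co-occurrence yields
    ``math.inf`` by the conditional odds-ratio convention; an empty
    gene set gives p = 1.
    """
    union = gene_a_tumors | gene_b_tumors
    if n_tumors < len(union):
        raise ValueError(
            f"n_tumors={n_tumors} smaller than the union of mutated tumors "
            f"({len(union)})")
    both = len(gene_a_tumors & gene_b_tumors)
    a_only = len(gene_a_tumors) - both
    b_only = len(gene_b_tumors) - both
    neither = n_tumors - both - a_only - b_only
    table = [[both, a_only], [b_only, neither]]
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds_ratio), float(p)


def mutation_outcome_association(mutation_status: Sequence[int],
                                 outcome_labels: Sequence[int],
                                 yates: bool = False
                                 ) -> Tuple[float, float, np.ndarray]:
    """Pearson chi-squared test of a binary mutation against a binary
    outcome (no continuity correction by default).

    Returns (chi2, p, expected_counts).  A zero margin is degenerate
    and rejected.
    """
    mutation_status = np.asarray(mutation_status, dtype=int)
    outcome_labels = np.asarray(outcome_labels, dtype=int)
    if mutation_status.shape != outcome_labels.shape:
        raise ValueError("mutation_status and outcome_labels differ in length")
    table = np.zeros((2, 2), dtype=int)
    for m, o in zip(mutation_status, outcome_labels):
        table[m, o] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(
            f"degenerate 2x2 table with a zero margin: {table.tolist()}")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p), expected


def write_driver_tsv(path, driver_calls: Sequence[DriverCall]) -> None:
    rows = [{"tumor_id": c.tumor_id, "gene": c.gene,
             "consequence": c.consequence, "rationale": c.rationale,
             "chrom": c.locus[0], "pos": c.locus[1], "ref": c.locus[2],
             "alt": c.locus[3]}
            for c in sorted(driver_calls,
                            key=lambda c: (c.tumor_id, c.gene, c.locus))]
    pd.DataFrame(rows, columns=["tumor_id", "gene", "consequence",
                                "rationale", "chrom", "pos", "ref", "alt"]
                 ).to_csv(path, sep="\t", index=False)


def read_gene_roles(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene"], df["role"]))
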