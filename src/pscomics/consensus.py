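"""Multi-caller somatic consensus filtering.

Merges the per-tumor output of three somatic variant callers, subtracts
pooled-normal loci (germline variants and platform artifacts), applies
the two retention filters, and computes tumor mutational burden (TMB).

Filter F1 keeps confident somatic calls in any gene: PASS by at least
two of the three callers, with forward and reverse variant allele
frequencies (VAF) each above 5% to remove strand-biased artifacts.
Filter F2 rescues plausible variants in known cancer genes: both strand
VAFs above 5% plus external evidence (pan-cancer recurrence count > 3,
a ClinVar entry, or an ACMG/ICMG tier 1-2 classification).  The union
of the two filters — the F1/F2 list — is the denominator-ready mutation
set used for TMB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

log = logging.getLogger(__name__)

#: Normalized variant identity: (chrom, 1-based pos, ref, alt).
Locus = Tuple[str, int, str, str]

VALID_CONSEQUENCES = frozenset(
    {"missense", "stop_gain", "splice", "synonymous", "frameshift",
     "inframe", "other"})

TRUNCATING_CONSEQUENCES = frozenset({"stop_gain", "splice", "frameshift"})

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantObservation:
    """One caller's record of one candidate somatic variant.

    Read counts are strand-split: ``fwd_alt``/``rev_alt`` alternate-
    allele observations against ``fwd_depth``/``rev_depth`` total
    strand depths.  ``passed`` reflects the caller's FILTER column
    (PASS or not); an observed-but-filtered record still counts as
    observed downstream.
    """

    tumor_id: str
    caller_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    passed: bool
    fwd_alt: int
    rev_alt: int
    fwd_depth: int
    rev_depth: int

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if not (_BASES.issuperset(self.ref) and _BASES.issuperset(self.alt)):
            raise ValueError(
                f"ref/alt must be uppercase ACGT strings, got {self.ref}>{self.alt}")
        if not (0 <= self.fwd_alt <= self.fwd_depth):
            raise ValueError(
                f"fwd_alt={self.fwd_alt} outside [0, fwd_depth={self.fwd_depth}]")
        if not (0 <= self.rev_alt <= self.rev_depth):
            raise ValueError(
                f"rev_alt={self.rev_alt} outside [0, rev_depth={self.rev_depth}]")


@dataclass(frozen=True)
class VariantAnnotation:
    """External evidence attached to a variant for the F2 filter and
    driver curation."""

    gene: str = ""
    consequence: str = "other"
    pan_cancer_count: int = 0
    in_clinvar: bool = False
    acmg_tier: Optional[int] = None  # 1, 2 or None
    gene_role: str = "none"  # oncogene | tsg | both | none
    pathogenic_aa_change: bool = False

    def __post_init__(self):
        if self.consequence not in VALID_CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.acmg_tier not in (1, 2, None):
            raise ValueError(f"acmg_tier must be 1, 2 or None, got {self.acmg_tier!r}")
        if self.gene_role not in ("oncogene", "tsg", "both", "none"):
            raise ValueError(f"unknown gene_role {self.gene_role!r}")
        if self.pan_cancer_count < 0:
            raise ValueError("pan_cancer_count must be >= 0")


#: Annotation used when a variant has no entry in the annotation table:
#: no external evidence, so it can never satisfy the F2 evidence leg.
MISSING_ANNOTATION = VariantAnnotation()


@dataclass(frozen=True)
class CallerVerdict:
    observed: bool
    passed: bool


@dataclass
class ConsensusVariant:
    """Caller-merged record of one normalized variant locus."""

    tumor_id: str
    locus: Locus
    verdicts: Dict[str, CallerVerdict] = field(default_factory=dict)
    fwd_vaf: float = 0.0
    rev_vaf: float = 0.0
    vaf_source: str = ""  # caller whose depths supplied the strand VAFs
    annotation: Optional[VariantAnnotation] = None
    f1: bool = False
    f2: bool = False
    category: str = "rejected"  # both | hotspot_rescue | other_somatic | rejected

    @property
    def n_pass(self) -> int:
        return sum(v.passed for v in self.verdicts.values())


# ---------------------------------------------------------------------------
# variant normalization
# ---------------------------------------------------------------------------

def normalize_variant(chrom: str, pos: int, ref: str, alt: str,
                      reference: Optional[Mapping[str, str]] = None) -> Locus:
    """Normalize a VCF-style variant to a canonical locus key.

    Shared suffix bases are trimmed first, then shared prefix bases
    (advancing ``pos``), always leaving at least one base on each
    allele.  When ``reference`` (a chrom -> sequence mapping, 0-based
    within each sequence) is supplied, indels are additionally
    left-aligned by extending with the preceding reference base while
    the alleles share their last base.  Idempotent by construction.
    """
    ref = ref.upper()
    alt = alt.upper()
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref}) at {chrom}:{pos} is not a variant")

    if reference is not None and chrom in reference and len(ref) != len(alt):
        seq = reference[chrom]
        # left-align: drop shared trailing base, re-extending on the left
        # from the reference when an allele would become empty
        while True:
            if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
                ref, alt = ref[:-1], alt[:-1]
            elif ref[-1] == alt[-1] and pos > 1:
                base = seq[pos - 2].upper()
                ref, alt = base + ref[:-1], base + alt[:-1]
                pos -= 1
            else:
                break
    else:
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]

    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    if ref == alt:
        raise ValueError(f"ref == alt after trimming at {chrom}:{pos}")
    return (chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# merging and strand VAFs
# ---------------------------------------------------------------------------

def strand_vafs(obs: VariantObservation) -> Tuple[float, float]:
    """Forward and reverse VAF of one observation.

    A strand with zero depth has VAF 0 by convention, which fails the
    >5% strand test — the conservative reading for strand-bias removal.
    """
    fwd = obs.fwd_alt / obs.fwd_depth if obs.fwd_depth > 0 else 0.0
    rev = obs.rev_alt / obs.rev_depth if obs.rev_depth > 0 else 0.0
    return fwd, rev


def merge_callers(obs_by_caller: Mapping[str, Sequence[VariantObservation]],
                  primary_caller: str = "ionreporter",
                  reference: Optional[Mapping[str, str]] = None,
                  ) -> List[ConsensusVariant]:
    """Merge per-caller observations of one tumor into consensus records.

    One :class:`ConsensusVariant` per distinct normalized locus; strand
    VAFs come from ``primary_caller``'s record when it observed the
    variant, else from the first caller (in input order) that did.
    Duplicate (caller, locus) pairs are an input error.
    """
    if len(obs_by_caller) > 3:
        raise ValueError(f"at most 3 callers supported, got {len(obs_by_caller)}")
    tumor_ids = {o.tumor_id for obs in obs_by_caller.values() for o in obs}
    if len(tumor_ids) > 1:
        raise ValueError(f"observations span multiple tumors: {sorted(tumor_ids)}")
    tumor_id = tumor_ids.pop() if tumor_ids else ""

    caller_order = list(obs_by_caller)
    merged: Dict[Locus, ConsensusVariant] = {}
    obs_at: Dict[Tuple[str, Locus], VariantObservation] = {}
    for caller in caller_order:
        for obs in obs_by_caller[caller]:
            locus = normalize_variant(obs.chrom, obs.pos, obs.ref, obs.alt,
                                      reference=reference)
            if (caller, locus) in obs_at:
                raise ValueError(
                    f"duplicate record from caller {caller} at locus "
                    f"{locus[0]}:{locus[1]} {locus[2]}>{locus[3]}")
            obs_at[(caller, locus)] = obs
            cv = merged.setdefault(locus, ConsensusVariant(tumor_id, locus))
            cv.verdicts[caller] = CallerVerdict(observed=True, passed=obs.passed)

    for cv in merged.values():
        for caller in caller_order:
            cv.verdicts.setdefault(caller, CallerVerdict(False, False))
        if (primary_caller, cv.locus) in obs_at:
            source = primary_caller
        else:
            source = next(c for c in caller_order if (c, cv.locus) in obs_at)
        cv.fwd_vaf, cv.rev_vaf = strand_vafs(obs_at[(source, cv.locus)])
        cv.vaf_source = source

    return [merged[k] for k in sorted(merged)]


def attach_annotations(variants: Iterable[ConsensusVariant],
                       annotations: Mapping[Locus, VariantAnnotation]
                       ) -> None:
    """Attach annotation records in place; absent loci keep ``None``
    (treated as no external evidence by F2)."""
    missing = 0
    for cv in variants:
        ann = annotations.get(cv.locus)
        if ann is None:
            missing += 1
        cv.annotation = ann
    if missing:
        log.info("annotation missing for %d loci; treated as no evidence", missing)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def apply_filter1(cv: ConsensusVariant, vaf_threshold: float = 0.05) -> bool:
    """F1: PASS by >= 2 of 3 callers and both strand VAFs strictly above
    the threshold."""
    return (cv.n_pass >= 2
            and cv.fwd_vaf > vaf_threshold
            and cv.rev_vaf > vaf_threshold)


def apply_filter2(cv: ConsensusVariant, vaf_threshold: float = 0.05) -> bool:
    """F2: both strand VAFs strictly above the threshold, plus external
    evidence: pan-cancer count > 3 (strict), a ClinVar entry, or ACMG
    tier 1/2."""
    ann = cv.annotation if cv.annotation is not None else MISSING_ANNOTATION
    evidence = (ann.pan_cancer_count > 3 or ann.in_clinvar
                or ann.acmg_tier in (1, 2))
    return cv.fwd_vaf > vaf_threshold and cv.rev_vaf > vaf_threshold and evidence


def pooled_normal_filter(variants: Sequence[ConsensusVariant],
                         pooled_loci: Set[Locus]) -> List[ConsensusVariant]:
    """Remove variants whose normalized locus appears in the pooled
    normal (germline variants and recurrent platform artifacts)."""
    kept = [cv for cv in variants if cv.locus not in pooled_loci]
    removed = len(variants) - len(kept)
    if removed:
        log.info("pooled-normal filter removed %d of %d loci", removed, len(variants))
    return kept


@dataclass
class CategorySummary:
    both: List[ConsensusVariant]
    hotspot_rescue: List[ConsensusVariant]
    other_somatic: List[ConsensusVariant]
    rejected: List[ConsensusVariant]

    @property
    def f1f2_variants(self) -> List[ConsensusVariant]:
        """The retained F1/F2 mutation list (everything not rejected)."""
        return self.both + self.hotspot_rescue + self.other_somatic

    @property
    def counts(self) -> Dict[str, int]:
        c = {"both": len(self.both), "hotspot_rescue": len(self.hotspot_rescue),
             "other_somatic": len(self.other_somatic)}
        c["f1f2_total"] = sum(c.values())
        c["rejected"] = len(self.rejected)
        return c


def categorize(variants: Sequence[ConsensusVariant],
               vaf_threshold: float = 0.05) -> CategorySummary:
    """Evaluate F1/F2 on each variant and partition into categories.

    both = F1 and F2; hotspot_rescue = F2 only (known oncogenic variant
    failing the strict consensus criterion); other_somatic = F1 only;
    rejected = neither.
    """
    summary = CategorySummary([], [], [], [])
    for cv in variants:
        cv.f1 = apply_filter1(cv, vaf_threshold)
        cv.f2 = apply_filter2(cv, vaf_threshold)
        if cv.f1 and cv.f2:
            cv.category = "both"
            summary.both.append(cv)
        elif cv.f2:
            cv.category = "hotspot_rescue"
            summary.hotspot_rescue.append(cv)
        elif cv.f1:
            cv.category = "other_somatic"
            summary.other_somatic.append(cv)
        else:
            cv.category = "rejected"
            summary.rejected.append(cv)
    return summary


def compute_tmb(f1f2_variants, target_size_mb: float) -> float:
    """Tumor mutational burden: retained mutations per megabase of
    sequenced target."""
    if target_size_mb <= 0:
        raise ValueError(f"target_size_mb must be > 0, got {target_size_mb}")
    n = f1f2_variants if isinstance(f1f2_variants, int) else len(f1f2_variants)
    return n / target_size_mb


# ---------------------------------------------------------------------------
# per-tumor pipeline
# ---------------------------------------------------------------------------

def run_consensus(obs_by_caller: Mapping[str, Sequence[VariantObservation]],
                  pooled_loci: Set[Locus],
                  annotations: Mapping[Locus, VariantAnnotation],
                  primary_caller: str = "ionreporter",
                  vaf_threshold: float = 0.05,
                  target_mb: float = 50.0):
    """Merge, pooled-normal filter, annotate, categorize and compute TMB
    for one tumor.  Returns (CategorySummary, tmb)."""
    merged = merge_callers(obs_by_caller, primary_caller=primary_caller)
    somatic = pooled_normal_filter(merged, pooled_loci)
    attach_annotations(somatic, annotations)
    summary = categorize(somatic, vaf_threshold)
    tmb = compute_tmb(summary.f1f2_variants, target_mb)
    return summary, tmb
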