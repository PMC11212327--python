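"""Variant normalization, caller merging, the F1/F2 filters and TMB."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pscomics.consensus import (CallerVerdict, ConsensusVariant,
                                VariantAnnotation, VariantObservation,
                                apply_filter1, apply_filter2, categorize,
                                compute_tmb, merge_callers, normalize_variant,
                                pooled_normal_filter, strand_vafs)


def obs(caller="ionreporter", chrom="chr1", pos=100, ref="A", alt="T",
        passed=True, fa=30, ra=30, fd=100, rd=100, tumor="T1"):
    return VariantObservation(tumor, caller, chrom, pos, ref, alt, passed,
                              fa, ra, fd, rd)


def cv(n_pass=3, fwd=0.2, rev=0.2, ann=None):
    verdicts = {c: CallerVerdict(True, i < n_pass)
                for i, c in enumerate(("mutect", "mutect2", "ionreporter"))}
    return ConsensusVariant("T1", ("chr1", 1, "A", "T"), verdicts,
                            fwd, rev, "ionreporter", ann)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("raw,expected", [
    (("chr1", 100, "AT", "AC"), ("chr1", 101, "T", "C")),   # prefix trim
    (("chr1", 100, "TA", "CA"), ("chr1", 100, "T", "C")),   # suffix trim
    (("chr1", 100, "GATC", "GTTC"), ("chr1", 101, "A", "T")),
    (("chr1", 100, "A", "T"), ("chr1", 100, "A", "T")),     # already minimal
    (("chr1", 100, "ATG", "A"), ("chr1", 100, "ATG", "A")),  # deletion kept
])
def test_normalize_trims_shared_context(raw, expected):
    assert normalize_variant(*raw) == expected


@pytest.mark.parametrize("raw", [
    ("chr1", 100, "A", "A"),     # not a variant
    ("chr1", 100, "", "T"),
    ("chr1", 100, "A", ""),
    ("chr1", 100, "ATT", "ATT"),
])
def test_normalize_rejects_degenerate_alleles(raw):
    with pytest.raises(ValueError):
        normalize_variant(*raw)


def test_normalize_left_aligns_indels_with_reference():
    # CGTTTTA: a T deleted from the run, reported right-shifted at pos 5
    ref_seq = {"chr1": "CGTTTTA"}
    assert normalize_variant("chr1", 5, "TT", "T", reference=ref_seq) == \
        ("chr1", 2, "GT", "G")
    # insertion into the same run
    assert normalize_variant("chr1", 5, "T", "TT", reference=ref_seq) == \
        ("chr1", 2, "G", "GT")


@given(pos=st.integers(1, 10**6),
       core=st.tuples(st.sampled_from("ACGT"), st.sampled_from("ACGT")),
       pad_left=st.text(alphabet="ACGT", max_size=4),
       pad_right=st.text(alphabet="ACGT", max_size=4))
@settings(max_examples=200, deadline=None)
def test_normalize_recovers_unpadded_snv(pos, core, pad_left, pad_right):
    """Padding an SNV with shared context never changes its key, and
    normalization is idempotent."""
    ref, alt = core
    if ref == alt:
        ref, alt = "A", "C"
    raw = ("chr2", pos, pad_left + ref + pad_right, pad_left + alt + pad_right)
    key = normalize_variant(*raw)
    assert key == ("chr2", pos + len(pad_left), ref, alt)
    assert normalize_variant(*key) == key


# ---------------------------------------------------------------------------
# strand VAFs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fa,ra,fd,rd,expected", [
    (6, 3, 100, 80, (0.06, 0.0375)),
    (0, 10, 0, 50, (0.0, 0.2)),      # zero-depth strand reads as VAF 0
    (50, 50, 100, 100, (0.5, 0.5)),
])
def test_strand_vafs(fa, ra, fd, rd, expected):
    got = strand_vafs(obs(fa=fa, ra=ra, fd=fd, rd=rd))
    assert got == pytest.approx(expected)


@given(fd=st.integers(0, 500), rd=st.integers(0, 500), data=st.data())
@settings(max_examples=100, deadline=None)
def test_strand_vafs_bounded(fd, rd, data):
    fa = data.draw(st.integers(0, fd))
    ra = data.draw(st.integers(0, rd))
    fwd, rev = strand_vafs(obs(fa=fa, ra=ra, fd=fd, rd=rd))
    assert 0.0 <= fwd <= 1.0 and 0.0 <= rev <= 1.0


def test_observation_validates_counts():
    with pytest.raises(ValueError):
        obs(fa=101, fd=100)
    with pytest.raises(ValueError):
        obs(ref="N")


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def test_merge_records_verdicts_per_caller():
    merged = merge_callers({
        "mutect": [obs(caller="mutect")],
        "mutect2": [obs(caller="mutect2")],
        "ionreporter": [],
    })
    assert len(merged) == 1
    v = merged[0].verdicts
    assert v["mutect"] == CallerVerdict(True, True)
    assert v["mutect2"] == CallerVerdict(True, True)
    assert v["ionreporter"] == CallerVerdict(False, False)


def test_merge_empty_input():
    assert merge_callers({"mutect": [], "mutect2": [], "ionreporter": []}) == []


def test_merge_rejects_duplicate_caller_locus():
    with pytest.raises(ValueError, match="chr1:100"):
        merge_callers({"mutect": [obs(caller="mutect"), obs(caller="mutect")]})


def test_merge_primary_caller_supplies_vafs():
    merged = merge_callers({
        "mutect": [obs(caller="mutect", fa=10, ra=10)],
        "ionreporter": [obs(fa=40, ra=40)],
    })
    assert merged[0].vaf_source == "ionreporter"
    assert merged[0].fwd_vaf == pytest.approx(0.4)
    # without the primary caller, the first reporting caller is used
    merged = merge_callers({"mutect": [obs(caller="mutect", fa=10, ra=10)],
                            "mutect2": []})
    assert merged[0].vaf_source == "mutect"


def test_merge_matches_set_union_oracle(rng):
    """500 random loci observed by random caller subsets: the merged
    verdict matrix equals a direct per-caller set union."""
    callers = ("mutect", "mutect2", "ionreporter")
    loci = [("chr%d" % rng.integers(1, 23), int(rng.integers(1, 10**7)),
             "A", "T") for _ in range(500)]
    loci = list(dict.fromkeys(loci))
    truth = {}  # locus -> set of (caller, passed)
    per_caller = {c: [] for c in callers}
    for locus in loci:
        for c in callers:
            if rng.random() < 0.5:
                passed = bool(rng.random() < 0.7)
                truth.setdefault(locus, set()).add((c, passed))
                per_caller[c].append(obs(caller=c, chrom=locus[0],
                                         pos=locus[1], passed=passed))
    merged = merge_callers(per_caller)
    assert {m.locus for m in merged} == set(truth)
    for m in merged:
        expected = truth[m.locus]
        for c in callers:
            rec = next(((cc, p) for cc, p in expected if cc == c), None)
            assert m.verdicts[c].observed == (rec is not None)
            assert m.verdicts[c].passed == (rec[1] if rec else False)


def test_merge_order_independence(rng):
    per_caller = {c: [obs(caller=c, pos=int(p), passed=bool(rng.random() < .5))
                      for p in rng.choice(1000, size=50, replace=False)]
                  for c in ("mutect", "mutect2", "ionreporter")}
    a = merge_callers(per_caller)
    shuffled = {c: list(rng.permutation(v)) for c, v in per_caller.items()}
    b = merge_callers(shuffled)
    assert [(m.locus, m.verdicts, m.fwd_vaf, m.rev_vaf) for m in a] == \
           [(m.locus, m.verdicts, m.fwd_vaf, m.rev_vaf) for m in b]


def test_merge_rejects_mixed_tumors():
    with pytest.raises(ValueError, match="multiple tumors"):
        merge_callers({"mutect": [obs(caller="mutect", tumor="T1"),
                                  obs(caller="mutect", pos=5, tumor="T2")]})


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_pass,fwd,rev,expected", [
    (2, 0.06, 0.0375, False),   # strand leg fails
    (3, 0.20, 0.18, True),
    (1, 0.30, 0.30, False),     # consensus leg fails
    (2, 0.051, 0.051, True),
    (2, 0.05, 0.20, False),     # threshold is strict
])
def test_filter1(n_pass, fwd, rev, expected):
    assert apply_filter1(cv(n_pass=n_pass, fwd=fwd, rev=rev)) is expected


@pytest.mark.parametrize("fwd,rev,ann,expected", [
    (0.2, 0.2, VariantAnnotation(pan_cancer_count=4), True),
    (0.2, 0.2, VariantAnnotation(pan_cancer_count=3), False),  # strict > 3
    (0.04, 0.2, VariantAnnotation(in_clinvar=True), False),
    (0.2, 0.2, VariantAnnotation(acmg_tier=2), True),
    (0.2, 0.2, VariantAnnotation(), False),
    (0.2, 0.2, None, False),    # missing annotation = no evidence
])
def test_filter2(fwd, rev, ann, expected):
    assert apply_filter2(cv(fwd=fwd, rev=rev, ann=ann)) is expected


def test_pooled_normal_filter_examples():
    variants = [cv() for _ in range(3)]
    assert pooled_normal_filter(variants, set()) == variants
    assert pooled_normal_filter(variants, {variants[0].locus}) == []


def test_pooled_normal_filter_matches_set_difference(rng):
    variants = []
    for i in range(200):
        v = cv()
        v.locus = ("chr1", int(i) + 1, "A", "T")
        variants.append(v)
    pooled = {v.locus for v in variants if rng.random() < 0.3}
    survivors = pooled_normal_filter(variants, pooled)
    assert {v.locus for v in survivors} == \
        {v.locus for v in variants} - pooled


def test_categorize_partition_and_counts(rng):
    """Random variants: the retained categories are disjoint and their
    union is exactly {v : f1 or f2}; labels obey the flag algebra."""
    variants = []
    for i in range(300):
        ann = VariantAnnotation(pan_cancer_count=int(rng.integers(0, 6)),
                                in_clinvar=bool(rng.random() < 0.2))
        v = cv(n_pass=int(rng.integers(0, 4)),
               fwd=float(rng.uniform(0, 0.3)), rev=float(rng.uniform(0, 0.3)),
               ann=ann)
        v.locus = ("chr1", i + 1, "A", "T")
        variants.append(v)
    summary = categorize(variants)
    retained = {v.locus for v in summary.f1f2_variants}
    expected = {v.locus for v in variants
                if apply_filter1(v) or apply_filter2(v)}
    assert retained == expected
    groups = [summary.both, summary.hotspot_rescue, summary.other_somatic]
    assert sum(len(g) for g in groups) == len(retained)
    for v in summary.both:
        assert v.f1 and v.f2 and v.category == "both"
    for v in summary.hotspot_rescue:
        assert v.f2 and not v.f1
    for v in summary.other_somatic:
        assert v.f1 and not v.f2
    for v in summary.rejected:
        assert not v.f1 and not v.f2


def test_categorize_all_rejected():
    variants = [cv(n_pass=0, fwd=0.01, rev=0.01) for _ in range(5)]
    summary = categorize(variants)
    assert summary.f1f2_variants == [] and len(summary.rejected) == 5


# ---------------------------------------------------------------------------
# TMB
# ---------------------------------------------------------------------------

def test_tmb_worked_value():
    assert compute_tmb(285, 50.0) == pytest.approx(5.7)


def test_tmb_zero_and_linearity():
    assert compute_tmb(0, 50.0) == 0.0
    assert compute_tmb(200, 50.0) == pytest.approx(2 * compute_tmb(100, 50.0))


@pytest.mark.parametrize("bad", [0.0, -1.0])
def test_tmb_rejects_nonpositive_target(bad):
    with pytest.raises(ValueError):
        compute_tmb(10, bad)
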