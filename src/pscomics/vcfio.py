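"""Reading and writing the pipeline's file formats.

Caller output is VCF 4.2 with Ion Torrent-style strand-split counts in
INFO (FSAF/FSAR = forward/reverse alternate observations, FSRF/FSRR =
forward/reverse reference observations).  The key mapping is
configurable for call sets that use different tags.  Annotations, gene
roles and clinical data travel as TSV.
"""

from __future__ import annotations

import csv
from typing import Dict, List, Mapping, Sequence, Set

from cyvcf2 import VCF

from .consensus import (ConsensusVariant, Locus, VariantAnnotation,
                        VariantObservation, normalize_variant)

#: Default INFO-key mapping for strand-split read counts.
DEFAULT_STRAND_KEYS = {
    "fwd_alt": "FSAF", "rev_alt": "FSAR",
    "fwd_ref": "FSRF", "rev_ref": "FSRR",
}

_VCF_HEADER = """##fileformat=VCFv4.2
##source={source}
##INFO=<ID=FSAF,Number=1,Type=Integer,Description="Forward-strand alternate observation count">
##INFO=<ID=FSAR,Number=1,Type=Integer,Description="Reverse-strand alternate observation count">
##INFO=<ID=FSRF,Number=1,Type=Integer,Description="Forward-strand reference observation count">
##INFO=<ID=FSRR,Number=1,Type=Integer,Description="Reverse-strand reference observation count">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FILTER=<ID=caller_fail,Description="Rejected by the caller's internal model">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""

_CONTIGS = [f"chr{i}" for i in range(1, 23)] + ["chrX"]


def write_caller_vcf(path, observations: Sequence[VariantObservation],
                     source: str = "pscomics-synthetic") -> None:
    """Write one caller's observations as a VCF 4.2 file, sorted by
    locus for byte-stable output."""
    contigs = "".join(f"##contig=<ID={c}>\n" for c in _CONTIGS)
    rows = sorted(observations,
                  key=lambda o: (_CONTIGS.index(o.chrom) if o.chrom in _CONTIGS
                                 else len(_CONTIGS), o.chrom, o.pos, o.ref, o.alt))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(source=source, contigs=contigs))
        for o in rows:
            filt = "PASS" if o.passed else "caller_fail"
            dp = o.fwd_depth + o.rev_depth
            info = (f"FSAF={o.fwd_alt};FSAR={o.rev_alt};"
                    f"FSRF={o.fwd_depth - o.fwd_alt};"
                    f"FSRR={o.rev_depth - o.rev_alt};DP={dp}")
            fh.write(f"{o.chrom}\t{o.pos}\t.\t{o.ref}\t{o.alt}\t100\t{filt}\t{info}\n")


def read_caller_vcf(path, tumor_id: str, caller_id: str,
                    strand_keys: Mapping[str, str] = DEFAULT_STRAND_KEYS,
                    ) -> List[VariantObservation]:
    """Read one caller's VCF into observation records.

    Multi-allelic records are split; the FILTER column maps to
    ``passed`` (cyvcf2 reports PASS as ``None``).
    """
    out: List[VariantObservation] = []
    for rec in VCF(str(path)):
        passed = rec.FILTER is None
        fwd_alt = int(rec.INFO.get(strand_keys["fwd_alt"], 0))
        rev_alt = int(rec.INFO.get(strand_keys["rev_alt"], 0))
        fwd_ref = int(rec.INFO.get(strand_keys["fwd_ref"], 0))
        rev_ref = int(rec.INFO.get(strand_keys["rev_ref"], 0))
        for alt in rec.ALT:
            out.append(VariantObservation(
                tumor_id=tumor_id, caller_id=caller_id,
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                passed=passed,
                fwd_alt=fwd_alt, rev_alt=rev_alt,
                fwd_depth=fwd_alt + fwd_ref, rev_depth=rev_alt + rev_ref))
    return out


def read_pooled_normal(path) -> Set[Locus]:
    """Normalized loci present in the pooled-normal call set."""
    loci: Set[Locus] = set()
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            loci.add(normalize_variant(rec.CHROM, rec.POS, rec.REF, alt))
    return loci


def read_gmt(path) -> Dict[str, List[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# annotation / role tables
# ---------------------------------------------------------------------------

_ANN_FIELDS = ["chrom", "pos", "ref", "alt", "gene", "consequence",
               "pan_cancer_count", "in_clinvar", "acmg_tier", "gene_role",
               "pathogenic_aa_change"]


def write_annotations(path, annotations: Mapping[Locus, VariantAnnotation]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ANN_FIELDS)
        for locus in sorted(annotations):
            a = annotations[locus]
            w.writerow([locus[0], locus[1], locus[2], locus[3], a.gene,
                        a.consequence, a.pan_cancer_count,
                        int(a.in_clinvar),
                        a.acmg_tier if a.acmg_tier is not None else "none",
                        a.gene_role, int(a.pathogenic_aa_change)])


def read_annotations(path) -> Dict[Locus, VariantAnnotation]:
    out: Dict[Locus, VariantAnnotation] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            locus = normalize_variant(row["chrom"], int(row["pos"]),
                                      row["ref"], row["alt"])
            tier = None if row["acmg_tier"] in ("none", "") else int(row["acmg_tier"])
            out[locus] = VariantAnnotation(
                gene=row["gene"], consequence=row["consequence"],
                pan_cancer_count=int(row["pan_cancer_count"]),
                in_clinvar=bool(int(row["in_clinvar"])),
                acmg_tier=tier, gene_role=row["gene_role"],
                pathogenic_aa_change=bool(int(row["pathogenic_aa_change"])))
    return out


def write_consensus_tsv(path, variants: Sequence[ConsensusVariant]) -> None:
    """One row per merged variant: verdicts, strand VAFs, filter flags
    and category."""
    callers = sorted({c for v in variants for c in v.verdicts})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["tumor_id", "chrom", "pos", "ref", "alt"]
        for c in callers:
            header += [f"{c}_observed", f"{c}_passed"]
        header += ["fwd_vaf", "rev_vaf", "vaf_source", "gene", "consequence",
                   "f1", "f2", "category"]
        w.writerow(header)
        for v in sorted(variants, key=lambda v: (v.tumor_id, v.locus)):
            ann = v.annotation
            row = [v.tumor_id, *v.locus]
            for c in callers:
                verd = v.verdicts.get(c)
                row += [int(verd.observed if verd else 0),
                        int(verd.passed if verd else 0)]
            row += [f"{v.fwd_vaf:.6g}", f"{v.rev_vaf:.6g}", v.vaf_source,
                    ann.gene if ann else "", ann.consequence if ann else "",
                    int(v.f1), int(v.f2), v.category]
            w.writerow(row)
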