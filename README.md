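# pscomics

A tested, reusable implementation of a multiomics tumor-profiling
pipeline for pulmonary sarcomatoid carcinoma (PSC) — a rare non-small
cell lung cancer with mixed epithelial and sarcoma-like components.
The pipeline takes the outputs of three somatic variant callers, an
RNA-seq count matrix and a clinical table, and produces the analyses a
small surgical cohort study needs: a consensus-filtered somatic
mutation list and tumor mutational burden (TMB), curated cancer-gene
drivers, clonal-evolution trees with branched/linear classification,
transcriptomic immune subtypes (Immune-High vs Immune-Low), and the
association of those subtypes with recurrence-free and overall
survival.

Because cohorts like this are rarely deposited publicly, the package
ships a first-class synthetic-data module that generates complete
cohorts with known ground truth — planted variants, clonal trees,
subtype structure and survival hazards — so every stage is testable
end to end, and statistical properties (recovery rates, test
calibration) are verified against the planted truth.

## The methods

**Consensus somatic filtering.** Per tumor, records from three callers
are merged on normalized variant keys and loci present in a pooled
normal (21 adjacent normal tissues' variants and recurrent platform
artifacts) are removed. Two filters are applied, with strand-split
variant allele frequencies VAF_fwd = alt_fwd/depth_fwd and
VAF_rev = alt_rev/depth_rev:

- **F1** (confident somatic call): PASS by ≥ 2 of 3 callers, and
  VAF_fwd > 5% and VAF_rev > 5% (removes strand-biased artifacts);
- **F2** (known cancer variant rescue): both strand VAFs > 5% and
  external evidence — pan-cancer recurrence count > 3, a ClinVar
  entry, or an ACMG/ICMG tier 1–2 classification.

The union (the F1/F2 list) partitions into *both* / *hotspot rescue*
(F2 only) / *other somatic* (F1 only), and TMB = |F1/F2 list| /
target size in Mb (default 50 Mb).

**Driver curation.** From F2-qualified variants: pathogenic amino-acid
changes in oncogenes, or truncating mutations (stop-gain, splice,
frameshift) in tumor suppressors. Gene-level relationships use
Fisher's exact test (mutual exclusivity, e.g. MET exon-14 skipping vs
TP53/KRAS) and the Pearson chi-squared test (mutation vs recurrence).

**Clonal evolution.** Under a diploid-heterozygous model the cancer
cell fraction of a mutation is CCF = 2·VAF/purity (capped at 1.2).
CCFs are clustered with a 1-D Gaussian mixture (EM, BIC model
selection); clusters form a rooted tree whose trunk is the
highest-CCF cluster, with placement following the pigeonhole sum rule
(clusters sit as siblings as high as sibling CCF sums allow, nesting
only when forced). A tumor is *branched* when ≥ 2 populated sibling
subclones exist; drivers map to trunk or branch; purity is estimated
as 2 × the trunk cluster's mean VAF.

**Immune subtyping.** Counts are TMM-normalized (trimmed mean of
M-values; log2 CPM), restricted to the 1,500 most variable genes, and
clustered by consensus non-negative matrix factorization over random
restarts; the rank is chosen by cophenetic stability of the consensus
matrix (silhouette widths reported). Subtype-discriminating genes are
ranked by a SAM-style moderated d-statistic with permutation p-values;
per-sample immune and stromal infiltration is scored by a
single-sample rank running-sum statistic (ssGSEA-style, weight
rank^0.25); the cluster with the higher immune score is Immune-High
(IM-H). Subtypes project onto external cohorts by nearest-centroid
rank correlation over the SAM gene panel with an assignment margin, so
out-of-distribution samples stay unassigned.

**Survival.** Kaplan–Meier curves, the two-group log-rank test, and
Cox proportional-hazards models (Efron ties; 95% Wald intervals),
univariate and adjusted for smoking, stage (ordinal IA=1 … IV=7) and
gender. Near-separation fits — expected at n = 17 with strong effects
— are flagged by diagnostics rather than reported as point estimates.

## Worked example

```python
import tempfile
from pscomics.config import CohortConfig
from pscomics.synthetic import simulate_cohort
from pscomics import pipeline

cfg = CohortConfig(seed=0)  # 21 tumors, 3 callers, 17 RNA-seq samples
with tempfile.TemporaryDirectory() as td:
    truth, paths = simulate_cohort(cfg, td)
    res = pipeline.run_pipeline(td, seed=0)

print(f"retained somatic mutations (F1/F2): "
      f"{sum(t.summary.counts['f1f2_total'] for t in res.tumors.values())}")
print(f"mean TMB: {res.mean_tmb:.2f} mutations/Mb")
print("driver prevalence:",
      {g: f"{p:.0%}" for g, p in res.prevalence.items()})
print(f"branched evolution: {res.branched_fraction:.0%} of tumors")
print(f"NMF rank selected: {res.subtyping.selected_rank}")
print("subtype sizes:",
      res.subtyping.samples['label'].value_counts().to_dict())
lr = res.survival_tables['rfs']
print(f"RFS log-rank p = {lr[lr.model=='logrank'].iloc[0]['p']:.4f}")
```

prints

```
retained somatic mutations (F1/F2): 5276
mean TMB: 5.02 mutations/Mb
driver prevalence: {'TP53': '43%', 'KRAS': '24%', 'MET': '14%'}
branched evolution: 52% of tumors
NMF rank selected: 2
subtype sizes: {'IM-H': 10, 'IM-L': 7}
RFS log-rank p = 0.0065
```

Reading the output: across the 21 simulated tumors, ~5,300 somatic
mutations survive the consensus filters (≈ 5 mutations/Mb over a 50 Mb
exome target). TP53 is the most prevalent driver, followed by KRAS,
with MET exon-14 skipping mutually exclusive with both. About half
the tumors show branched clonal evolution. The expression matrix
splits cleanly into two stable NMF clusters (10 Immune-High, 7
Immune-Low), and the Immune-Low group relapses significantly earlier
(log-rank p < 0.01) — the planted subtype-dependent hazard recovered
from the simulated clinical table.

The same stages are exposed on the command line:

```sh
pscomics simulate --out cohort/ --seed 1
pscomics run --cohort cohort/ --out results/
pscomics consensus --vcf-a T1.mutect.vcf --vcf-b T1.mutect2.vcf \
    --vcf-c T1.ionreporter.vcf --pooled-normal pooled_normal.vcf \
    --annotations annotations.tsv --out T1.consensus.tsv
pscomics subtype --counts counts.tsv --genesets genesets.gmt --out subtypes/
pscomics project --counts external_counts.tsv --centroids subtypes/centroids.tsv \
    --out projected.tsv
```

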