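"""Cohort simulation configuration.

The defaults describe a 21-tumor pulmonary sarcomatoid carcinoma (PSC)
cohort: deep targeted/exome DNA sequencing analysed by three somatic
callers, RNA-seq on 17 of the tumors, and recurrence-free / overall
survival follow-up.  Every probability, rate and effect size that the
downstream pipeline stages assume is parameterized here so the whole
pipeline can be exercised on synthetic data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence, Tuple

import yaml

#: The three somatic caller slots.  ``ionreporter`` is the designated
#: primary caller whose strand-split depths feed the VAF filters.
CALLER_NAMES = ("mutect", "mutect2", "ionreporter")

#: Canonical cancer genes planted by the simulator with their roles.
#: TP53 carries "both": its hotspot missense mutations act through
#: dominant-negative / gain-of-function mechanisms, so pathogenic
#: amino-acid changes qualify alongside truncating events.
DRIVER_GENE_ROLES = {"TP53": "both", "KRAS": "oncogene", "MET": "oncogene"}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class CallerProfile:
    """Sensitivity / noise profile of one somatic variant caller.

    fp_rate is expressed per megabase of sequenced target;
    strand_bias_prob is the chance a reported true variant has its
    alternate reads collapsed onto a single strand.
    """

    name: str
    sensitivity: float = 0.95
    fp_rate_per_mb: float = 0.5
    strand_bias_prob: float = 0.02

    def validate(self) -> None:
        _require(0.0 <= self.sensitivity <= 1.0,
                 f"caller_profiles[{self.name}].sensitivity must be in [0,1]")
        _require(self.fp_rate_per_mb >= 0.0,
                 f"caller_profiles[{self.name}].fp_rate_per_mb must be >= 0")
        _require(0.0 <= self.strand_bias_prob <= 1.0,
                 f"caller_profiles[{self.name}].strand_bias_prob must be in [0,1]")


@dataclass(frozen=True)
class SubcloneSpec:
    """Planted clonal architecture: a trunk plus 0-3 subclonal branches."""

    p_branched: float = 0.5
    max_branches: int = 3
    purity_range: Tuple[float, float] = (0.4, 0.9)
    ccf_sd: float = 0.05
    min_ccf_sep: float = 0.25

    def validate(self) -> None:
        _require(0.0 <= self.p_branched <= 1.0,
                 "subclone_spec.p_branched must be in [0,1]")
        _require(self.max_branches >= 1,
                 "subclone_spec.max_branches must be a positive count")
        lo, hi = self.purity_range
        _require(0.0 < lo <= hi <= 1.0,
                 "subclone_spec.purity_range must lie within (0,1]")
        _require(self.ccf_sd >= 0.0, "subclone_spec.ccf_sd must be >= 0")
        _require(0.0 <= self.min_ccf_sep < 1.0,
                 "subclone_spec.min_ccf_sep must be in [0,1)")


@dataclass(frozen=True)
class ExpressionSpec:
    """Negative-binomial RNA-seq count model with a planted immune effect.

    Genes in the immune signature have their mean multiplied by
    ``2**immune_effect_log2fc`` in immune-high samples; library sizes
    vary ``libsize_spread``-fold across samples so between-sample
    normalization is non-trivial.
    """

    n_genes: int = 5000
    immune_effect_log2fc: float = 2.0
    dispersion: float = 0.3
    baseline_mean: float = 100.0
    n_immune_genes: int = 100
    n_stromal_genes: int = 50
    n_marker_genes: int = 10
    libsize_spread: float = 3.0

    def validate(self) -> None:
        _require(self.n_genes > 0, "expr_spec.n_genes must be a positive count")
        _require(self.immune_effect_log2fc >= 0.0,
                 "expr_spec.immune_effect_log2fc must be >= 0")
        _require(self.dispersion > 0.0, "expr_spec.dispersion must be > 0")
        _require(self.baseline_mean > 0.0, "expr_spec.baseline_mean must be > 0")
        _require(self.libsize_spread >= 2.0,
                 "expr_spec.libsize_spread must be >= 2 so normalization is exercised")
        needed = self.n_immune_genes + self.n_stromal_genes + self.n_marker_genes
        _require(self.n_genes >= needed,
                 "expr_spec.n_genes must accommodate the signature genes")


@dataclass(frozen=True)
class SurvivalSpec:
    """Exponential event times with a subtype-dependent hazard.

    The hazard of an immune-low sample is ``baseline_hazard *
    exp(log_hr_subtype)``; censoring is independent uniform
    (administrative) and tuned to hit ``censor_rate`` approximately.
    Time units are months.
    """

    baseline_hazard: float = 0.01
    log_hr_subtype: float = math.log(10.0)
    censor_rate: float = 0.35

    def validate(self) -> None:
        _require(self.baseline_hazard > 0.0,
                 "surv_spec.baseline_hazard must be > 0")
        _require(0.0 <= self.censor_rate < 1.0,
                 "surv_spec.censor_rate must be in [0,1)")


def default_caller_profiles() -> Tuple[CallerProfile, ...]:
    return (
        CallerProfile("mutect", sensitivity=0.93, fp_rate_per_mb=0.6, strand_bias_prob=0.02),
        CallerProfile("mutect2", sensitivity=0.95, fp_rate_per_mb=0.4, strand_bias_prob=0.02),
        CallerProfile("ionreporter", sensitivity=0.97, fp_rate_per_mb=0.8, strand_bias_prob=0.03),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Complete parameterization of one synthetic PSC cohort.

    Default prevalences reflect the study cohort: TP53 in ~57% of
    tumors, KRAS in ~28%, MET exon-14 skipping in ~14% and mutually
    exclusive with TP53/KRAS.  Sequencing depth defaults to 225x and
    the target size to 50 Mb (exome scale).
    """

    n_tumors: int = 21
    n_true_variants_mean: int = 285
    driver_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"TP53": 0.57, "KRAS": 0.28, "MET": 0.14})
    caller_profiles: Sequence[CallerProfile] = field(
        default_factory=default_caller_profiles)
    subclone_spec: SubcloneSpec = field(default_factory=SubcloneSpec)
    expr_spec: ExpressionSpec = field(default_factory=ExpressionSpec)
    surv_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    n_expression_samples: int = 17
    mean_depth: int = 225
    target_mb: float = 50.0
    n_artifact_loci: int = 25
    trunk_driver_rate: float = 0.8
    p_immune_high: float = 10.0 / 17.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_tumors >= 0, "n_tumors must be a non-negative count")
        _require(self.n_true_variants_mean >= 0,
                 "n_true_variants_mean must be a non-negative count")
        for gene, p in self.driver_prevalence.items():
            _require(0.0 <= p <= 1.0,
                     f"driver_prevalence[{gene}] must be in [0,1]")
        _require(len(self.caller_profiles) == 3,
                 "caller_profiles must describe exactly 3 callers")
        for prof in self.caller_profiles:
            prof.validate()
        self.subclone_spec.validate()
        self.expr_spec.validate()
        self.surv_spec.validate()
        _require(self.n_expression_samples >= 0,
                 "n_expression_samples must be a non-negative count")
        _require(self.mean_depth > 0, "mean_depth must be a positive count")
        _require(self.target_mb > 0, "target_mb must be > 0")
        _require(self.n_artifact_loci >= 0, "n_artifact_loci must be >= 0")
        _require(0.0 <= self.trunk_driver_rate <= 1.0,
                 "trunk_driver_rate must be in [0,1]")
        _require(0.0 <= self.p_immune_high <= 1.0,
                 "p_immune_high must be in [0,1]")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["driver_prevalence"] = dict(self.driver_prevalence)
        d["caller_profiles"] = [asdict(p) for p in self.caller_profiles]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "caller_profiles" in d:
            d["caller_profiles"] = tuple(
                CallerProfile(**p) for p in d["caller_profiles"])
        for key, sub in (("subclone_spec", SubcloneSpec),
                         ("expr_spec", ExpressionSpec),
                         ("surv_spec", SurvivalSpec)):
            if key in d and isinstance(d[key], Mapping):
                sub_d = dict(d[key])
                if key == "subclone_spec" and "purity_range" in sub_d:
                    sub_d["purity_range"] = tuple(sub_d["purity_range"])
                d[key] = sub(**sub_d)
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
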