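import hashlib
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from pscomics.config import (CallerProfile, CohortConfig, ExpressionSpec,
                             SubcloneSpec, SurvivalSpec)
from pscomics.synthetic import simulate_cohort

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")


def noiseless_profiles():
    """Caller profiles with perfect sensitivity and no noise."""
    return tuple(
        CallerProfile(name, sensitivity=1.0, fp_rate_per_mb=0.0,
                      strand_bias_prob=0.0)
        for name in ("mutect", "mutect2", "ionreporter"))


def small_config(**overrides) -> CohortConfig:
    """A fast cohort: few tumors, small expression matrix."""
    base = dict(
        n_tumors=4, n_true_variants_mean=60, n_expression_samples=4,
        expr_spec=ExpressionSpec(n_genes=400, n_immune_genes=40,
                                 n_stromal_genes=20, n_marker_genes=5),
        n_artifact_loci=10, seed=123,
    )
    base.update(overrides)
    return CohortConfig(**base)


def dir_digest(path) -> str:
    """SHA-256 over file names and contents of a directory tree."""
    h = hashlib.sha256()
    for p in sorted(Path(path).rglob("*")):
        if p.is_file():
            h.update(p.relative_to(path).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """One simulated small cohort shared across read-only tests."""
    outdir = tmp_path_factory.mktemp("cohort")
    truth, paths = simulate_cohort(small_config(), outdir)
    return truth, paths


@pytest.fixture
def rng():
    return np.random.default_rng(20240415)
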