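"""TMM normalization, consensus NMF, SAM ranking, gene-set scoring,
subtype labelling and projection."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, mannwhitneyu

from pscomics.config import ExpressionSpec
from pscomics.subtyping import (fisher_deg, label_subtypes, marker_score,
                                nmf_consensus, nonneg_shift, project_subtypes,
                                sam_rank, select_rank, ssgsea_score,
                                tmm_normalize, top_variable_genes)
from pscomics.synthetic import make_gene_names, simulate_expression


def _matrix(rows, samples=None):
    samples = samples or [f"s{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame(rows, index=samples).T


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def test_tmm_identical_columns_unit_factors(rng):
    col = rng.poisson(50, size=500)
    counts = pd.DataFrame({"a": col, "b": col, "c": col})
    factors, norm = tmm_normalize(counts)
    assert np.allclose(factors, 1.0)
    assert np.allclose(norm["a"], norm["b"])


def test_tmm_absorbs_pure_depth_difference(rng):
    col = rng.poisson(100, size=800) + 1
    counts = pd.DataFrame({"a": col, "b": 2 * col})
    factors, norm = tmm_normalize(counts)
    assert factors["a"] == pytest.approx(factors["b"], rel=1e-6)
    assert np.allclose(norm["a"], norm["b"], atol=1e-6)


def test_tmm_rejects_all_zero_sample():
    counts = pd.DataFrame({"a": [1, 2, 3], "b": [0, 0, 0]})
    with pytest.raises(ValueError, match="b"):
        tmm_normalize(counts)


def test_tmm_matches_edger_reference(rng, tmp_path):
    """Planted-DE fixture with a 3-fold library spread: factors agree
    with edgeR's calcNormFactors."""
    n_g = 1500
    base = rng.lognormal(3, 1, n_g)
    lib = np.array([1.0, 3.0, 1.5, 2.2, 0.8])
    mu = base[:, None] * lib[None, :]
    de = rng.choice(n_g, 75, replace=False)
    mu[de, :2] *= 4  # 5% planted DE genes
    counts = pd.DataFrame(rng.poisson(mu),
                          index=[f"g{i}" for i in range(n_g)],
                          columns=[f"s{i}" for i in range(5)])
    factors, _ = tmm_normalize(counts)
    counts.to_csv(tmp_path / "counts.tsv", sep="\t")
    script = textwrap.dedent("""
        suppressMessages(library(edgeR))
        x <- read.delim("counts.tsv", row.names=1)
        cat(paste(calcNormFactors(as.matrix(x), method="TMM"), collapse=" "))
    """)
    (tmp_path / "oracle.R").write_text(script)
    out = subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path,
                         capture_output=True, text=True, check=True)
    expected = np.array([float(v) for v in out.stdout.split()])
    assert np.allclose(factors.to_numpy(), expected, rtol=0.01)


# ---------------------------------------------------------------------------
# consensus NMF + rank selection
# ---------------------------------------------------------------------------

def _blocked_matrix(rng, n_genes=120, block=10):
    """Two planted sample blocks with disjoint active gene modules."""
    x = rng.uniform(0, 0.5, size=(n_genes, 2 * block))
    x[:40, :block] += 4.0
    x[40:80, block:] += 4.0
    return pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{i}" for i in range(2 * block)])


def test_two_block_structure_selects_rank_two(rng):
    mat = _blocked_matrix(rng)
    diags = nmf_consensus(mat, ranks=range(2, 7), n_restarts=10, seed=0)
    assert diags[2].cophenetic >= 0.99
    assert select_rank(diags) == 2
    labels = diags[2].labels
    assert labels.iloc[:10].nunique() == 1 and labels.iloc[10:].nunique() == 1
    assert labels.iloc[0] != labels.iloc[-1]


def test_noise_matrix_is_unstable_somewhere(rng):
    """Structureless i.i.d. noise: consensus cannot be near-perfect at
    every rank for every seed."""
    flags = []
    for seed in range(3):
        mat = pd.DataFrame(rng.uniform(0.0, 1.0, size=(100, 14)))
        mat.columns = [f"s{i}" for i in range(14)]
        diags = nmf_consensus(mat, ranks=range(2, 7), n_restarts=8, seed=seed)
        flags.append(all(d.cophenetic > 0.98 for d in diags.values()))
    assert not all(flags)


def test_sample_duplication_keeps_co_membership(rng):
    mat = _blocked_matrix(rng)
    dup = pd.concat([mat, mat.add_suffix("_dup", axis=1)], axis=1)
    diags = nmf_consensus(dup, ranks=[2], n_restarts=10, seed=0)
    labels = diags[2].labels
    for s in mat.columns:
        assert labels[s] == labels[s + "_dup"]


def test_nmf_rejects_negative_input():
    mat = pd.DataFrame({"a": [1.0, -0.1], "b": [0.5, 0.2]})
    with pytest.raises(ValueError, match="non-negative"):
        nmf_consensus(mat, ranks=[2], n_restarts=2, seed=0)


def test_ranks_at_or_above_sample_count_skipped(rng):
    mat = _blocked_matrix(rng, block=2)  # 4 samples
    diags = nmf_consensus(mat, ranks=range(2, 7), n_restarts=4, seed=0)
    assert set(diags) == {2, 3}


@pytest.mark.parametrize("coph,expected", [
    ({2: 0.99, 3: 0.90, 6: 0.99}, 2),   # smallest near-max
    ({2: 0.95, 3: 0.90, 4: 0.85}, 2),   # monotone decreasing
    ({2: 0.9, 3: 0.9, 4: 0.9}, 2),      # all equal -> smallest
    ({2: 0.90, 3: 0.99, 4: 0.95}, 3),
])
def test_select_rank(coph, expected):
    assert select_rank(coph) == expected


def test_nonneg_shift_removes_per_gene_baseline():
    mat = pd.DataFrame({"a": [5.0, 1.0], "b": [7.0, 3.0]})
    shifted = nonneg_shift(mat)
    assert (shifted.min(axis=1) == 0).all()
    assert shifted.loc[0, "b"] == 2.0


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _labelled_matrix(rng, n_genes=300, n1=8, n2=9, planted=None, log2fc=2.0):
    x = rng.normal(6.0, 1.0, size=(n_genes, n1 + n2))
    labels = ["A"] * n1 + ["B"] * n2
    if planted:
        x[:planted, n1:] += log2fc
    idx = [f"g{i}" for i in range(n_genes)]
    return pd.DataFrame(x, index=idx,
                        columns=[f"s{i}" for i in range(n1 + n2)]), labels


def test_sam_flat_gene_has_zero_d(rng):
    mat, labels = _labelled_matrix(rng, n_genes=50)
    mat.iloc[0] = 5.0  # identical across samples
    res = sam_rank(mat, labels, n_perm=50, seed=0)
    assert res.loc["g0", "d"] == pytest.approx(0.0)
    assert res.loc["g0", "p"] > 0.9


def test_sam_recovers_planted_genes(rng):
    mat, labels = _labelled_matrix(rng, planted=30, log2fc=2.0)
    res = sam_rank(mat, labels, n_perm=200, seed=0)
    sensitivity = res.iloc[:30]["significant"].mean()
    assert sensitivity >= 0.9
    assert (res.iloc[:30]["direction"] == "up_in_B").all()


def test_sam_requires_two_per_class(rng):
    mat, _ = _labelled_matrix(rng, n1=1, n2=16)
    with pytest.raises(ValueError):
        sam_rank(mat, ["A"] + ["B"] * 16, n_perm=10, seed=0)


# ---------------------------------------------------------------------------
# Fisher DEG
# ---------------------------------------------------------------------------

def test_fisher_deg_equal_proportions_p_one():
    counts = pd.DataFrame({"a1": [100, 900], "a2": [100, 900],
                           "b1": [100, 900], "b2": [100, 900]},
                          index=["g0", "g1"])
    res = fisher_deg(counts, ["A", "A", "B", "B"])
    assert res["p"].min() > 0.99


def test_fisher_deg_matches_enumeration_oracle():
    """The per-gene table [[100,10],[1000,1000]] against the
    hypergeometric enumeration oracle."""
    counts = pd.DataFrame({"a": [100, 1000], "b": [10, 1000]},
                          index=["g0", "rest"])
    res = fisher_deg(counts, ["A", "B"])
    a, b, c, d = 100, 10, 1000, 1000
    n, row1, col1 = a + b + c + d, a + b, a + c
    p_obs = hypergeom.pmf(a, n, col1, row1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    expected = sum(hypergeom.pmf(x, n, col1, row1)
                   for x in range(lo, hi + 1)
                   if hypergeom.pmf(x, n, col1, row1) <= p_obs * (1 + 1e-9))
    assert res.loc["g0", "p"] == pytest.approx(expected, abs=1e-10)
    assert res.loc["g0", "direction"] == "up_in_A"


def test_fisher_deg_excludes_all_zero_genes():
    counts = pd.DataFrame({"a": [0, 5], "b": [0, 7]}, index=["dead", "ok"])
    res = fisher_deg(counts, ["A", "B"])
    assert "dead" not in res.index and "ok" in res.index


# ---------------------------------------------------------------------------
# gene-set / marker scoring
# ---------------------------------------------------------------------------

def test_ssgsea_degenerate_set_scores_zero(rng):
    mat = pd.DataFrame(rng.normal(5, 1, size=(30, 4)),
                       index=[f"g{i}" for i in range(30)],
                       columns=list("abcd"))
    assert (ssgsea_score(mat, list(mat.index)) == 0).all()
    assert (ssgsea_score(mat, ["absent"]) == 0).all()


def test_ssgsea_enriched_sample_scores_higher(rng):
    genes = [f"g{i}" for i in range(100)]
    geneset = genes[:10]
    base = rng.normal(5, 1, size=(100, 2))
    mat = pd.DataFrame(base, index=genes, columns=["plain", "enriched"])
    mat.loc[geneset, "enriched"] += 10  # set genes to the top ranks
    scores = ssgsea_score(mat, geneset)
    assert scores["enriched"] > scores["plain"]


def test_ssgsea_invariant_to_monotone_transform(rng):
    genes = [f"g{i}" for i in range(60)]
    mat = pd.DataFrame(rng.normal(5, 2, size=(60, 5)), index=genes,
                       columns=list("abcde"))
    s1 = ssgsea_score(mat, genes[:15])
    s2 = ssgsea_score(np.exp(mat / 3.0), genes[:15])
    assert np.allclose(s1, s2)


def test_ssgsea_null_sets_center_near_zero(rng):
    genes = [f"g{i}" for i in range(400)]
    mat = pd.DataFrame(rng.normal(0, 1, size=(400, 6)), index=genes)
    mat.columns = list("abcdef")
    scores = [ssgsea_score(mat, list(rng.choice(genes, 50, replace=False)))
              for _ in range(20)]
    assert abs(np.mean([s.mean() for s in scores])) < 0.02


def test_marker_score_behavior(rng):
    genes = [f"m{i}" for i in range(5)] + [f"g{i}" for i in range(20)]
    mat = pd.DataFrame(np.full((25, 3), 2.0), index=genes,
                       columns=list("abc"))
    scores = marker_score(mat, {"cell": genes[:5]})
    assert np.allclose(scores.loc["cell"], 2.0)
    mat2 = mat.copy()
    mat2.loc[genes[:5], "b"] += 1.0  # doubling on the linear scale
    scores2 = marker_score(mat2, {"cell": genes[:5]})
    assert scores2.loc["cell", "b"] > scores2.loc["cell", "a"]
    assert scores2.loc["cell", "a"] == scores.loc["cell", "a"]


def test_marker_effect_detected_across_replicates():
    """Planted neutrophil-marker effect separates the groups by
    rank-sum test in >= 90% of simulations."""
    spec = ExpressionSpec(n_genes=500, n_immune_genes=40, n_stromal_genes=0,
                          n_marker_genes=10, immune_effect_log2fc=2.0)
    imm, stro, mark, rest = make_gene_names(spec)
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        labels = {f"S{i}": ("IM-H" if i < 8 else "IM-L") for i in range(17)}
        counts = simulate_expression(spec, labels, imm, 3000 + rep,
                                     gene_names=imm + mark + rest,
                                     marker_geneset=mark)
        _, norm = tmm_normalize(counts)
        scores = marker_score(norm, {"Neutrophils": mark}).loc["Neutrophils"]
        high = scores[[s for s, l in labels.items() if l == "IM-H"]]
        low = scores[[s for s, l in labels.items() if l == "IM-L"]]
        hits += mannwhitneyu(high, low, alternative="greater").pvalue < 0.05
    assert hits >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# labelling and projection
# ---------------------------------------------------------------------------

def test_label_subtypes_by_immune_score():
    clusters = {"s1": 1, "s2": 1, "s3": 2, "s4": 2}
    names = label_subtypes(clusters, {"s1": 10, "s2": 10, "s3": 2, "s4": 2})
    assert names == {1: "IM-H", 2: "IM-L"}
    # relabelling cluster ids leaves IM-H membership unchanged
    swapped = {s: (2 if c == 1 else 1) for s, c in clusters.items()}
    names2 = label_subtypes(swapped, {"s1": 10, "s2": 10, "s3": 2, "s4": 2})
    assert names2 == {2: "IM-H", 1: "IM-L"}


def test_label_subtypes_equal_means_demands_override():
    with pytest.raises(ValueError, match="override"):
        label_subtypes({"s1": 1, "s2": 2}, {"s1": 5.0, "s2": 5.0})


def test_projection_of_exact_centroid(rng):
    genes = [f"g{i}" for i in range(50)]
    cen = pd.DataFrame({"IM-L": rng.normal(5, 1, 50),
                        "IM-H": rng.normal(5, 1, 50)}, index=genes)
    ext = pd.DataFrame({"x": cen["IM-H"], "y": cen["IM-L"],
                        "mid": cen.mean(axis=1)}, index=genes)
    res = project_subtypes(ext, cen)
    assert res.loc["x", "label"] == "IM-H"
    assert res.loc["y", "label"] == "IM-L"
    assert res.loc["mid", "label"] == "unassigned"  # equidistant


def test_projection_requires_shared_panel(rng):
    cen = pd.DataFrame({"IM-L": [1.0] * 10, "IM-H": [2.0] * 10},
                       index=[f"g{i}" for i in range(10)])
    ext = pd.DataFrame({"x": [1.0] * 10}, index=[f"h{i}" for i in range(10)])
    with pytest.raises(ValueError, match="20"):
        project_subtypes(ext, cen)
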