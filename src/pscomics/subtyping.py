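"""Transcriptomic immune subtyping.

From a raw gene x sample count matrix: TMM between-sample
normalization, consensus non-negative matrix factorization (NMF)
clustering with cophenetic rank selection, SAM-style moderated gene
ranking with permutation significance, Fisher-exact differential
expression on pooled counts, single-sample gene-set (ssGSEA-style)
immune/stromal scoring, marker-mean cell-type scoring, Immune-High /
Immune-Low labelling, and nearest-centroid projection of the subtypes
onto external cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score

log = logging.getLogger(__name__)

IM_HIGH = "IM-H"
IM_LOW = "IM-L"
UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     n_obs: float, n_ref: float,
                     trim_m: float, trim_a: float) -> float:
    """Weighted trimmed mean of M-values of one sample against the
    reference; returns the log2 scaling factor."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok].astype(float), ref[ok].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M; weights are its inverse
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & \
           (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or not np.isfinite(w[keep]).all():
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_normalize(counts: pd.DataFrame, trim_m: float = 0.30,
                  trim_a: float = 0.05) -> Tuple[pd.Series, pd.DataFrame]:
    """Trimmed-mean-of-M-values normalization factors plus the
    log2-CPM matrix computed with effective library sizes.

    The reference sample is the column whose 75th-percentile
    library-size-scaled count is closest to the mean across samples.
    M-values are trimmed 30% from each tail and A-values 5% from each
    tail before the precision-weighted mean; factors are rescaled to
    geometric mean 1.  Normalized value =
    ``log2(count / (libsize x factor) x 1e6 + 1)``.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    libsize = counts.sum(axis=0).astype(float)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")

    q75 = counts.quantile(0.75, axis=0).astype(float) / libsize
    ref_sample = (q75 - q75.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy()
    n_ref = float(libsize[ref_sample])

    log_factors = pd.Series(
        {s: _tmm_pair_factor(counts[s].to_numpy(), ref, float(libsize[s]),
                             n_ref, trim_m, trim_a)
         for s in counts.columns})
    factors = np.power(2.0, log_factors)
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1

    eff_lib = libsize * factors
    norm = np.log2(counts.div(eff_lib, axis=1) * 1e6 + 1.0)
    return factors, norm


# ---------------------------------------------------------------------------
# consensus NMF
# ---------------------------------------------------------------------------

@dataclass
class RankDiagnostics:
    rank: int
    consensus: pd.DataFrame          # sample x sample co-clustering frequency
    cophenetic: float
    mean_silhouette: float
    labels: pd.Series                # consensus (hierarchical) clustering
    best_W: Optional[np.ndarray] = None
    best_H: Optional[np.ndarray] = None


def nmf_consensus(matrix: pd.DataFrame, ranks: Sequence[int] = range(2, 7),
                  n_restarts: int = 30, seed: int = 0
                  ) -> Dict[int, RankDiagnostics]:
    """Consensus NMF over random restarts for each candidate rank.

    ``matrix`` is non-negative genes x samples.  Each restart runs
    multiplicative-update NMF (Frobenius objective, 200 iterations or
    relative tolerance 1e-6) from a random start; the per-run hard
    clustering is the argmax of each sample's coefficient column.  The
    consensus matrix holds co-clustering frequencies; its dissimilarity
    feeds average-linkage hierarchical clustering for the cophenetic
    coefficient, the consensus labels, and silhouette widths.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("NMF input must be non-negative")
    samples = list(matrix.columns)
    n_s = len(samples)
    x = matrix.to_numpy()
    rng = np.random.default_rng(seed)

    out: Dict[int, RankDiagnostics] = {}
    for rank in ranks:
        if rank >= n_s:
            log.warning("rank %d >= %d samples; skipped", rank, n_s)
            continue
        co = np.zeros((n_s, n_s))
        best = None
        for _ in range(n_restarts):
            rs = int(rng.integers(0, 2**31 - 1))
            model = NMF(n_components=rank, init="random", solver="mu",
                        beta_loss="frobenius", max_iter=200, tol=1e-6,
                        random_state=rs)
            with warnings.catch_warnings():
                # the 200-iteration cap is the intended stopping rule
                warnings.simplefilter("ignore")
                w = model.fit_transform(x)
            h = model.components_
            # resolve the W/H scale ambiguity before the argmax:
            # normalize W columns to unit norm, pushing scale into H
            norms = np.linalg.norm(w, axis=0)
            norms[norms == 0] = 1.0
            labels = (h * norms[:, None]).argmax(axis=0)
            co += labels[:, None] == labels[None, :]
            if best is None or model.reconstruction_err_ < best[0]:
                best = (model.reconstruction_err_, w, h)
        consensus = co / n_restarts
        dissim = 1.0 - consensus
        np.fill_diagonal(dissim, 0.0)
        condensed = squareform(dissim, checks=False)
        link = average(condensed)
        if condensed.std() == 0:
            coph = 1.0  # perfectly stable consensus
        else:
            coph = float(cophenet(link, condensed)[0])
            if not np.isfinite(coph):
                coph = 1.0
        labels = pd.Series(fcluster(link, rank, criterion="maxclust"),
                           index=samples)
        if labels.nunique() > 1:
            sil = float(silhouette_score(dissim, labels.to_numpy(),
                                         metric="precomputed"))
        else:
            sil = 0.0
        out[rank] = RankDiagnostics(
            rank=rank, consensus=pd.DataFrame(consensus, index=samples,
                                              columns=samples),
            cophenetic=coph, mean_silhouette=sil, labels=labels,
            best_W=best[1], best_H=best[2])
    if not out:
        raise ValueError("no candidate rank below the sample count")
    return out


def select_rank(diagnostics: Mapping[int, "RankDiagnostics | float"],
                tol: float = 0.02) -> int:
    """Smallest rank whose cophenetic coefficient is within ``tol`` of
    the maximum (ties toward smaller k)."""
    coph = {k: (d.cophenetic if isinstance(d, RankDiagnostics) else float(d))
            for k, d in diagnostics.items()}
    best = max(coph.values())
    return min(k for k, c in sorted(coph.items()) if c >= best - tol)


def top_variable_genes(norm: pd.DataFrame, n_genes: int = 1500) -> pd.DataFrame:
    """Restrict to the most-variable genes (by variance of the
    normalized values); the NMF feature-selection step."""
    variances = norm.var(axis=1)
    keep = variances.sort_values(ascending=False, kind="stable").index[:n_genes]
    return norm.loc[keep.sort_values()]


def nonneg_shift(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene baseline removal for NMF input: subtract each gene's
    minimum across samples.  Keeps the matrix non-negative while
    stripping the constant abundance offset that would otherwise
    dominate the first factor."""
    return matrix.sub(matrix.min(axis=1), axis=0)


# ---------------------------------------------------------------------------
# SAM-style gene ranking
# ---------------------------------------------------------------------------

def sam_rank(matrix: pd.DataFrame, labels: Sequence, n_perm: int = 500,
             seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Moderated difference-of-means ranking with permutation p-values.

    d = (mean2 - mean1) / (s + s0) with pooled standard error s and
    exchangeability constant s0 = median of s over genes.  The null
    distribution pools |d*| across genes over ``n_perm`` label
    permutations; p-values use add-one smoothing.  Classes are the two
    sorted unique labels; direction reports which class a positive d
    favours.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    g1 = labels == classes[0]
    g2 = labels == classes[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each class needs at least 2 samples")

    x = matrix.to_numpy(dtype=float)
    n1, n2 = int(g1.sum()), int(g2.sum())

    def d_stat(x1, x2):
        m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
        v1 = x1.var(axis=1, ddof=1)
        v2 = x2.var(axis=1, ddof=1)
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        s = np.sqrt((1.0 / n1 + 1.0 / n2) * pooled)
        s0 = np.median(s)
        return (m2 - m1) / (s + s0), s

    d, s = d_stat(x[:, g1], x[:, g2])

    rng = np.random.default_rng(seed)
    null: List[np.ndarray] = []
    idx = np.arange(x.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        p1, p2 = perm[:n1], perm[n1:]
        d_star, _ = d_stat(x[:, p1], x[:, p2])
        null.append(np.abs(d_star))
    null_sorted = np.sort(np.concatenate(null))
    n_null = null_sorted.size
    exceed = n_null - np.searchsorted(null_sorted, np.abs(d), side="left")
    p = (1.0 + exceed) / (1.0 + n_null)

    return pd.DataFrame({
        "d": d, "s": s, "p": p,
        "direction": np.where(d > 0, f"up_in_{classes[1]}",
                              f"up_in_{classes[0]}"),
        "significant": p < alpha,
    }, index=matrix.index)


# ---------------------------------------------------------------------------
# Fisher-exact differential expression on pooled counts
# ---------------------------------------------------------------------------

def fisher_deg(raw_counts: pd.DataFrame, labels: Sequence) -> pd.DataFrame:
    """Per-gene two-sided Fisher exact test on pooled group counts.

    For each gene the 2x2 table opposes the gene's summed counts per
    group to the remaining library counts per group.  Genes with zero
    counts in both groups are excluded (logged).  Direction compares
    library-size-corrected group proportions.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    g1 = raw_counts.loc[:, labels == classes[0]].sum(axis=1).astype(int)
    g2 = raw_counts.loc[:, labels == classes[1]].sum(axis=1).astype(int)
    lib1, lib2 = int(g1.sum()), int(g2.sum())

    zero = (g1 == 0) & (g2 == 0)
    if zero.any():
        log.info("fisher_deg: %d all-zero genes excluded", int(zero.sum()))

    rows = {}
    for gene in raw_counts.index[~zero]:
        a, b = int(g1[gene]), int(g2[gene])
        table = [[a, b], [lib1 - a, lib2 - b]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        prop1 = a / lib1 if lib1 else 0.0
        prop2 = b / lib2 if lib2 else 0.0
        direction = (f"up_in_{classes[1]}" if prop2 > prop1
                     else f"up_in_{classes[0]}" if prop1 > prop2 else "none")
        rows[gene] = (p, direction)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["p", "direction"])
    df["significant"] = df["p"] < 0.05
    return df


# ---------------------------------------------------------------------------
# gene-set and marker scoring
# ---------------------------------------------------------------------------

def ssgsea_score(norm: pd.DataFrame, geneset: Sequence[str],
                 alpha: float = 0.25) -> pd.Series:
    """Single-sample gene-set enrichment score per sample.

    Genes are ranked by expression within each sample; the score is the
    sum of the running difference between the in-set and out-set
    cumulative distributions, both weighted by rank^alpha and
    normalized by the number of genes (so random sets score near 0).
    Rank-based, hence invariant to monotone transforms of a sample's
    expression.
    """
    present = [g for g in geneset if g in norm.index]
    n_genes = norm.shape[0]
    in_set = norm.index.isin(present)
    if in_set.all() or not in_set.any():
        log.warning("degenerate gene set (%d of %d genes in set); score 0",
                    int(in_set.sum()), n_genes)
        return pd.Series(0.0, index=norm.columns)

    scores = {}
    for sample in norm.columns:
        expr = norm[sample].to_numpy()
        order = np.argsort(-expr, kind="stable")  # descending expression
        ranks = np.arange(n_genes, 0, -1, dtype=float)  # N..1 down the list
        mask = in_set[order]
        w = np.power(ranks, alpha)
        w_in = w * mask
        w_out = w * ~mask
        p_in = np.cumsum(w_in) / w_in.sum()
        p_out = np.cumsum(w_out) / w_out.sum()
        scores[sample] = float(np.sum(p_in - p_out) / n_genes)
    return pd.Series(scores)


def marker_score(norm: pd.DataFrame,
                 marker_sets: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Cell-type abundance proxy: mean normalized log2 expression over
    each cell type's marker genes (MCPcounter-style)."""
    rows = {}
    for cell_type, markers in marker_sets.items():
        present = [g for g in markers if g in norm.index]
        missing = len(markers) - len(present)
        if missing:
            log.info("%s: %d marker genes missing from matrix",
                     cell_type, missing)
        if not present:
            rows[cell_type] = pd.Series(np.nan, index=norm.columns)
        else:
            rows[cell_type] = norm.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# subtype labelling and projection
# ---------------------------------------------------------------------------

def label_subtypes(clusters: Mapping[str, int],
                   immune_scores: Mapping[str, float]) -> Dict[int, str]:
    """Map cluster ids to IM-H / IM-L: the cluster with the higher mean
    immune score is Immune-High.  Exactly equal means are ambiguous and
    demand a manual override."""
    ids = sorted(set(clusters.values()))
    if len(ids) != 2:
        raise ValueError(f"expected 2 clusters, got {ids}")
    means = {cid: float(np.mean([immune_scores[s] for s, c in clusters.items()
                                 if c == cid]))
             for cid in ids}
    if means[ids[0]] == means[ids[1]]:
        raise ValueError(
            "cluster immune-score means are exactly equal; supply a manual "
            "IM-H/IM-L override")
    high = max(ids, key=lambda c: means[c])
    return {cid: (IM_HIGH if cid == high else IM_LOW) for cid in ids}


def compute_centroids(norm: pd.DataFrame, sample_labels: Mapping[str, str],
                      panel_genes: Sequence[str]) -> pd.DataFrame:
    """Per-gene mean normalized expression of each subtype over the
    discriminating gene panel (for projection reuse)."""
    panel = [g for g in panel_genes if g in norm.index]
    cols = {}
    for label in (IM_LOW, IM_HIGH):
        samples = [s for s, l in sample_labels.items() if l == label]
        if not samples:
            raise ValueError(f"no samples labelled {label}")
        cols[label] = norm.loc[panel, samples].mean(axis=1)
    return pd.DataFrame(cols)


def project_subtypes(external_norm: pd.DataFrame, centroids: pd.DataFrame,
                     margin_threshold: float = 0.1,
                     min_similarity: float = 0.2) -> pd.DataFrame:
    """Nearest-centroid subtype projection with an assignment margin.

    Each external sample is rank-correlated (Spearman) to both subtype
    centroids over the shared panel genes.  The decision correlation is
    computed after subtracting the per-gene centroid mean (a
    training-anchored centering, so the two centroids become
    contrasting profiles), while an uncentered correlation to the
    nearer centroid serves as an absolute-similarity gate against
    out-of-distribution samples.  A sample takes the nearer label when
    the centered-correlation gap is at least ``margin_threshold``, the
    best centered correlation is positive, and the uncentered
    similarity reaches ``min_similarity``; otherwise it stays
    unassigned.
    """
    shared = [g for g in centroids.index if g in external_norm.index]
    if len(shared) < 20:
        raise ValueError(
            f"only {len(shared)} panel genes shared with the external "
            "matrix; >= 20 required")
    cen = centroids.loc[shared]
    center = cen.mean(axis=1)
    cen_c = cen.sub(center, axis=0)
    rows = []
    for sample in external_norm.columns:
        expr = external_norm.loc[shared, sample]
        expr_c = expr - center
        corr = {lab: float(stats.spearmanr(expr_c, cen_c[lab]).statistic)
                for lab in cen.columns}
        best = max(corr, key=corr.get)
        margin = abs(corr[IM_HIGH] - corr[IM_LOW])
        similarity = float(stats.spearmanr(expr, cen[best]).statistic)
        label = best if (margin >= margin_threshold and corr[best] > 0
                         and similarity >= min_similarity) else UNASSIGNED
        rows.append({"sample_id": sample, "corr_im_l": corr[IM_LOW],
                     "corr_im_h": corr[IM_HIGH], "margin": margin,
                     "similarity": similarity, "label": label})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# cohort-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class SubtypingResult:
    """Discovery-cohort subtyping output."""

    samples: pd.DataFrame          # cluster, scores, label, silhouette
    factors: pd.Series             # TMM factors
    norm: pd.DataFrame             # log2 CPM
    rank_diagnostics: Dict[int, RankDiagnostics]
    selected_rank: int
    gene_ranking: pd.DataFrame     # SAM output
    centroids: pd.DataFrame
    cluster_labels: Dict[int, str] = field(default_factory=dict)


def subtype_cohort(counts: pd.DataFrame,
                   immune_geneset: Sequence[str],
                   stromal_geneset: Sequence[str] = (),
                   marker_sets: Optional[Mapping[str, Sequence[str]]] = None,
                   ranks: Sequence[int] = range(2, 7),
                   n_restarts: int = 30,
                   n_top_genes: int = 1500,
                   n_perm: int = 500,
                   seed: int = 0) -> SubtypingResult:
    """Full discovery-cohort subtyping.

    TMM-normalize, cluster by consensus NMF on the top-variable genes,
    pick the rank by cophenetic stability, split samples at the
    consensus clustering of the selected rank, score immune/stromal
    infiltration per sample, name the clusters IM-H / IM-L by immune
    score, and rank subtype-discriminating genes by SAM for the
    projection panel.
    """
    factors, norm = tmm_normalize(counts)
    features = nonneg_shift(top_variable_genes(norm, n_top_genes))
    diags = nmf_consensus(features, ranks=ranks, n_restarts=n_restarts,
                          seed=seed)
    k = select_rank(diags)
    # the subtype split itself is always the two-cluster consensus
    two = diags.get(2, diags[min(diags)])
    clusters = {s: int(c) for s, c in two.labels.items()}

    immune = ssgsea_score(norm, immune_geneset)
    stromal = ssgsea_score(norm, stromal_geneset) if len(stromal_geneset) \
        else pd.Series(0.0, index=norm.columns)
    combined = immune + stromal
    rng_span = combined.max() - combined.min()
    purity_proxy = (combined.max() - combined) / rng_span if rng_span > 0 \
        else pd.Series(0.5, index=combined.index)

    cluster_names = label_subtypes(clusters, immune.to_dict())
    labels = {s: cluster_names[c] for s, c in clusters.items()}

    label_list = [labels[s] for s in norm.columns]
    if min(label_list.count(IM_HIGH), label_list.count(IM_LOW)) >= 2:
        ranking = sam_rank(norm, label_list, n_perm=n_perm, seed=seed)
        panel = list(ranking.index[ranking["significant"]])
        if len(panel) < 20:
            # fall back to the strongest |d| genes so projection stays usable
            panel = list(ranking["d"].abs()
                         .sort_values(ascending=False, kind="stable").index[:50])
    else:
        log.warning("a subtype has < 2 samples; SAM skipped, projection "
                    "panel falls back to top-variable genes")
        ranking = pd.DataFrame(columns=["d", "s", "p", "direction",
                                        "significant"])
        panel = list(top_variable_genes(norm, 50).index)
    centroids = compute_centroids(norm, labels, panel)

    sil = _sample_silhouettes(two)
    samples = pd.DataFrame({
        "cluster": pd.Series(clusters),
        "immune_score": immune,
        "stromal_score": stromal,
        "purity_proxy": purity_proxy,
        "label": pd.Series(labels),
        "silhouette": sil,
    })
    if marker_sets:
        cell_scores = marker_score(norm, marker_sets)
        for cell_type in cell_scores.index:
            samples[f"score_{cell_type}"] = cell_scores.loc[cell_type]
    return SubtypingResult(samples=samples, factors=factors, norm=norm,
                           rank_diagnostics=diags, selected_rank=k,
                           gene_ranking=ranking, centroids=centroids,
                           cluster_labels=cluster_names)


def _sample_silhouettes(diag: RankDiagnostics) -> pd.Series:
    from sklearn.metrics import silhouette_samples
    dissim = 1.0 - diag.consensus.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    labels = diag.labels.to_numpy()
    if len(np.unique(labels)) < 2:
        return pd.Series(0.0, index=diag.labels.index)
    return pd.Series(silhouette_samples(dissim, labels, metric="precomputed"),
                     index=diag.labels.index)
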