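"""Clonal-evolution reconstruction from cancer cell fractions.

A desk-scale subclone analysis: mutation CCFs are estimated from VAFs
under a diploid-heterozygous model (CCF = 2 x VAF / purity), clustered
with a 1-D Gaussian mixture (EM, k selected by BIC), and arranged into
a rooted clonal tree by a deterministic constraint-based builder that
honours the pigeonhole sum rule (sibling CCFs cannot exceed their
parent's).  The tree yields the branched-vs-linear call, trunk/branch
placement of driver mutations, a purity estimate from the trunk
cluster, and convergent-evolution flags.  This rule-based builder is a
deliberate, declared substitute for full MCMC subclonal-phylogeny
samplers; it recovers the quantities the downstream analysis consumes
(cluster count, branching class, trunk membership) when subclones are
reasonably separated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.mixture import GaussianMixture

from .consensus import Locus
from .drivers import DriverCall

log = logging.getLogger(__name__)

CCF_CAP = 1.2      # absorbs sampling noise above 1 under the diploid model
SUM_RULE_TOL = 0.05


@dataclass
class MutationCCF:
    locus: Locus
    vaf: float
    ccf: float
    cluster_id: Optional[int] = None


@dataclass
class TreeNode:
    cluster_id: int
    mean_ccf: float
    n_mutations: int
    parent: Optional[int] = None
    children: List[int] = field(default_factory=list)


@dataclass
class SubcloneTree:
    """Rooted tree of mutation clusters; the root is the trunk."""

    nodes: Dict[int, TreeNode]
    trunk_id: int

    def validate(self, tol: float = SUM_RULE_TOL) -> None:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise AssertionError(f"tree must have one root, found {len(roots)}")
        for node in self.nodes.values():
            if node.parent is not None:
                parent = self.nodes[node.parent]
                if node.mean_ccf > parent.mean_ccf + tol:
                    raise AssertionError(
                        f"child cluster {node.cluster_id} CCF {node.mean_ccf:.3f} "
                        f"exceeds parent {parent.mean_ccf:.3f} + {tol}")
            child_sum = sum(self.nodes[c].mean_ccf for c in node.children)
            if child_sum > node.mean_ccf + tol and node.cluster_id != self.trunk_id:
                raise AssertionError(
                    f"sum rule violated at cluster {node.cluster_id}: "
                    f"children sum {child_sum:.3f} > {node.mean_ccf:.3f} + {tol}")


def estimate_ccfs(vafs: Sequence[Tuple[Locus, float]], purity: float
                  ) -> List[MutationCCF]:
    """CCF = 2 x VAF / purity, clamped to [0, 1.2], for heterozygous
    diploid sites."""
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0,1], got {purity}")
    return [MutationCCF(locus=locus, vaf=vaf,
                        ccf=float(np.clip(2.0 * vaf / purity, 0.0, CCF_CAP)))
            for locus, vaf in vafs]


def cluster_ccf(ccfs: Sequence[MutationCCF], max_k: int = 5, seed: int = 0
                ) -> Tuple[List[MutationCCF], List[float]]:
    """1-D Gaussian-mixture clustering over CCF with BIC model selection.

    EM with k-means++-style initialization and 10 restarts per k;
    clusters are relabelled by descending mean CCF (cluster 0 has the
    highest mean).  Mutations are sorted internally before fitting, so
    input order never affects the fit.  Returns the mutations with
    ``cluster_id`` assigned plus the per-cluster mean CCFs.
    """
    if len(ccfs) == 0:
        raise ValueError("at least one mutation is required")
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    if max_k > len(ccfs):
        log.info("max_k truncated from %d to %d (number of mutations)",
                 max_k, len(ccfs))
        max_k = len(ccfs)
    if len(ccfs) == 1:
        ccfs[0].cluster_id = 0
        return list(ccfs), [ccfs[0].ccf]

    # canonical order: input permutation cannot influence EM init
    order = sorted(range(len(ccfs)), key=lambda i: (ccfs[i].ccf, ccfs[i].locus))
    x = np.array([ccfs[i].ccf for i in order])[:, None]

    best = None
    for k in range(1, max_k + 1):
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             n_init=10, init_params="k-means++",
                             random_state=seed, reg_covar=1e-6)
        gm.fit(x)
        bic = gm.bic(x)
        if best is None or bic < best[0]:
            best = (bic, gm)
    gm = best[1]
    raw_labels = gm.predict(x)
    means = gm.means_.ravel()
    # relabel by descending mean CCF
    rank = {old: new for new, old in
            enumerate(np.argsort(-means, kind="stable"))}
    for idx, raw in zip(order, raw_labels):
        ccfs[idx].cluster_id = rank[raw]
    cluster_means = [float(means[old]) for old in np.argsort(-means, kind="stable")]
    return list(ccfs), cluster_means


def build_tree(cluster_means: Sequence[float],
               cluster_sizes: Optional[Sequence[int]] = None,
               tol: float = SUM_RULE_TOL) -> SubcloneTree:
    """Deterministic constraint-based clonal tree construction.

    The highest-CCF cluster is the trunk.  Each remaining cluster, in
    descending CCF order, attaches to the *largest-CCF* node that
    satisfies both child <= parent and the sum rule (existing children
    + candidate <= parent, within ``tol``); ties break toward the
    lowest cluster index.  Single-sample CCFs cannot distinguish a
    sibling from a nested subclone, so placement follows the pigeonhole
    principle: clusters are siblings as high in the tree as the sum
    rule allows and descend into a subclone only when forced (e.g.
    clusters {1.0, 0.6, 0.5}: 0.6 + 0.5 exceeds the trunk's capacity,
    so 0.5 nests under 0.6 and the tumor reads linear).  A cluster no
    node can host falls back to the trunk as a new branch.
    """
    if len(cluster_means) == 0:
        raise ValueError("no clusters to build a tree from")
    sizes = list(cluster_sizes) if cluster_sizes is not None \
        else [1] * len(cluster_means)
    order = sorted(range(len(cluster_means)),
                   key=lambda i: (-cluster_means[i], i))
    trunk = order[0]
    nodes = {trunk: TreeNode(trunk, float(cluster_means[trunk]), sizes[trunk])}
    for cid in order[1:]:
        ccf = float(cluster_means[cid])
        hosts = []
        for nid, node in nodes.items():
            child_sum = sum(nodes[c].mean_ccf for c in node.children)
            if ccf <= node.mean_ccf + tol and child_sum + ccf <= node.mean_ccf + tol:
                hosts.append(nid)
        if hosts:
            host = max(hosts, key=lambda nid: (nodes[nid].mean_ccf, -nid))
        else:
            host = trunk
        nodes[cid] = TreeNode(cid, ccf, sizes[cid], parent=host)
        nodes[host].children.append(cid)
    tree = SubcloneTree(nodes=nodes, trunk_id=trunk)
    return tree


def classify_branching(tree: SubcloneTree) -> str:
    """branched iff some node has >= 2 children that each contain at
    least one mutation; otherwise linear."""
    for node in tree.nodes.values():
        populated = [c for c in node.children if tree.nodes[c].n_mutations >= 1]
        if len(populated) >= 2:
            return "branched"
    return "linear"


def map_to_trunk(driver_calls: Sequence[DriverCall], tree: SubcloneTree,
                 assignments: Dict[Locus, int]) -> Dict[Locus, str]:
    """Per-driver trunk/branch placement: trunk iff the driver's CCF
    cluster is the tree root."""
    out = {}
    for call in driver_calls:
        cluster = assignments.get(call.locus)
        if cluster is None:
            log.info("driver %s at %s not in CCF assignments; skipped",
                     call.gene, call.locus)
            continue
        out[call.locus] = "trunk" if cluster == tree.trunk_id else "branch"
    return out


def detect_convergent(driver_calls: Iterable[DriverCall]
                      ) -> List[Tuple[str, str, List[Locus]]]:
    """(tumor, gene, loci) triples where >= 2 distinct loci hit the
    same gene in one tumor — the convergent-evolution signature."""
    by_gene: Dict[Tuple[str, str], set] = {}
    for call in driver_calls:
        by_gene.setdefault((call.tumor_id, call.gene), set()).add(call.locus)
    return [(tumor, gene, sorted(loci))
            for (tumor, gene), loci in sorted(by_gene.items())
            if len(loci) >= 2]


def estimate_purity(mutations: Sequence[MutationCCF], tree: SubcloneTree
                    ) -> float:
    """Purity from the trunk cluster: mean trunk VAF x 2 under the
    diploid-heterozygous inversion, clamped to (0, 1]."""
    trunk_vafs = [m.vaf for m in mutations if m.cluster_id == tree.trunk_id]
    if not trunk_vafs:
        raise ValueError("no mutations assigned to the trunk cluster")
    return float(np.clip(2.0 * np.mean(trunk_vafs), 1e-6, 1.0))


@dataclass
class TumorEvolution:
    tumor_id: str
    mutations: List[MutationCCF]
    cluster_means: List[float]
    tree: SubcloneTree
    branching: str
    purity: float

    def to_dict(self) -> dict:
        return {
            "tumor_id": self.tumor_id,
            "cluster_means": [round(c, 6) for c in self.cluster_means],
            "branching": self.branching,
            "purity": round(self.purity, 6),
            "method": "substitute-method call (GMM + constraint tree)",
            "nodes": [{"cluster_id": n.cluster_id,
                       "mean_ccf": round(n.mean_ccf, 6),
                       "n_mutations": n.n_mutations,
                       "parent": n.parent}
                      for n in sorted(self.tree.nodes.values(),
                                      key=lambda n: n.cluster_id)],
            "assignments": {
                f"{m.locus[0]}:{m.locus[1]}:{m.locus[2]}:{m.locus[3]}":
                    m.cluster_id for m in self.mutations},
        }


def analyze_tumor(tumor_id: str, vafs: Sequence[Tuple[Locus, float]],
                  purity: Optional[float] = None, max_k: int = 5,
                  seed: int = 0) -> TumorEvolution:
    """Full per-tumor clonal reconstruction.

    When ``purity`` is not supplied, a provisional estimate (twice the
    mean of the upper VAF quartile, clamped) seeds the CCF transform
    and is then refined from the trunk cluster.
    """
    if purity is None:
        v = np.sort([vaf for _, vaf in vafs])
        top = v[int(0.75 * len(v)):] if len(v) >= 4 else v
        purity = float(np.clip(2.0 * top.mean(), 0.05, 1.0))
    mutations = estimate_ccfs(vafs, purity)
    mutations, means = cluster_ccf(mutations, max_k=max_k, seed=seed)
    sizes = [sum(m.cluster_id == k for m in mutations)
             for k in range(len(means))]
    tree = build_tree(means, sizes)
    tree.validate()
    refined = estimate_purity(mutations, tree)
    return TumorEvolution(tumor_id=tumor_id, mutations=mutations,
                          cluster_means=means, tree=tree,
                          branching=classify_branching(tree),
                          purity=refined)
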