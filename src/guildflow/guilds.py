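"""Co-abundance guild (CAG) inference.

Features that rise and fall together across samples are grouped into
guilds: the repeated-measures correlation matrix is turned into a distance
(``1 - r``), clustered with Ward's minimum-variance linkage, and the
dendrogram is cut from the top by sequential PERMANOVA — a split is kept
only when the two child clades differ significantly (default 9,999
permutations, p < 0.001) in the feature-space distance matrix.  Clades that
fail the test, and children too small to test, become guilds.  Guild
abundances are the per-sample sums of their member features, and guilds are
numbered CAG1, CAG2, ... by descending overall abundance.

A companion co-abundance network keeps the significant strong correlations
(|r| > 0.5, p < 0.05 by default) as signed edges for export to standard
graph formats.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .ordination import _perm_f_batch, _pseudo_f, _ss_decomposition
from .rmcorr import RmCorrMatrix

__all__ = [
    "GuildAssignment",
    "build_network",
    "correlation_distance",
    "ward_tree",
    "cut_tree_permanova",
    "aggregate_guilds",
    "tree_to_newick",
]

DEFAULT_R_THRESHOLD = 0.5
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_TREECUT_PERMUTATIONS = 9_999
DEFAULT_TREECUT_ALPHA = 0.001


@dataclass(frozen=True)
class GuildAssignment:
    """Partition of features into guilds plus the tree that produced it."""

    feature_guild: pd.Series  # feature id -> guild id
    guild_ids: list[str]  # ordered (by descending abundance when known)
    linkage: np.ndarray  # scipy linkage matrix over ``leaf_order``
    leaf_order: list[str]  # feature ids in linkage leaf order
    node_pvalues: dict[int, float]  # internal node id -> PERMANOVA p of its split

    def to_frame(self) -> pd.DataFrame:
        return self.feature_guild.rename("guild").rename_axis("feature_id").reset_index()


def build_network(
    rm: RmCorrMatrix,
    abund: pd.DataFrame,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> nx.Graph:
    """Co-abundance network of significant strong correlations.

    Edges are exactly the non-degenerate pairs with ``|r| > r_threshold``
    (strict) and ``p < p_threshold``; each carries ``r``, ``p`` and a
    ``sign`` attribute.  Node weight = mean relative abundance.
    """
    g = nx.Graph()
    mean_abund = abund.mean(axis=0)
    for fid in rm.feature_ids:
        g.add_node(fid, mean_abundance=float(mean_abund.get(fid, 0.0)))
    n = len(rm.feature_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if rm.degenerate[i, j]:
                continue
            r, p = rm.r[i, j], rm.p[i, j]
            if abs(r) > r_threshold and p < p_threshold:
                g.add_edge(
                    rm.feature_ids[i],
                    rm.feature_ids[j],
                    r=float(r),
                    p=float(p),
                    sign="positive" if r > 0 else "negative",
                )
    return g


def network_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [(a, b, d["r"], d["p"], d["sign"]) for a, b, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p", "sign"])


def correlation_distance(rm: RmCorrMatrix) -> pd.DataFrame:
    """Distance matrix ``d = 1 - r`` (degenerate pairs -> 1, diagonal 0)."""
    d = 1.0 - rm.r
    d[rm.degenerate] = 1.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=rm.feature_ids, columns=rm.feature_ids)


def ward_tree(d: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Ward linkage over a precomputed feature distance matrix.

    Features are sorted lexicographically first so the merge order (and any
    tie-breaking inside the linkage) is deterministic for a given id set.
    Returns the scipy linkage matrix and the leaf order it indexes.
    """
    if d.shape[0] < 2:
        raise ValueError("need at least 2 features to cluster")
    order = sorted(str(c) for c in d.columns)
    mat = d.loc[order, order].to_numpy(dtype=float)
    condensed = squareform(mat, checks=False)
    z = hierarchy.linkage(condensed, method="ward")
    return z, order


def _leaves_per_node(z: np.ndarray, n_leaves: int) -> dict[int, list[int]]:
    """Leaf index list for every node id (leaves 0..n-1, internal n..2n-2)."""
    members: dict[int, list[int]] = {i: [i] for i in range(n_leaves)}
    for k, (a, b, _, _) in enumerate(z):
        members[n_leaves + k] = members[int(a)] + members[int(b)]
    return members


def cut_tree_permanova(
    linkage: np.ndarray,
    d: pd.DataFrame,
    leaf_order: list[str] | None = None,
    n_perm: int = DEFAULT_TREECUT_PERMUTATIONS,
    alpha: float = DEFAULT_TREECUT_ALPHA,
    min_clade: int = 2,
    seed: int | None = None,
    abund: pd.DataFrame | None = None,
) -> GuildAssignment:
    """Cut a dendrogram into guilds by sequential top-down PERMANOVA.

    Starting from the root, each internal node whose two children both have
    at least ``min_clade`` leaves is tested: observations are the node's
    features, the distance matrix is ``d`` restricted to them, and the
    grouping is child membership.  If the permutation p-value (estimated as
    ``(1 + #{F >= F_obs}) / (1 + n_perm)``) is below ``alpha`` the split is
    accepted and both children are visited; otherwise the node's leaf set
    becomes one guild.  A child smaller than ``min_clade`` terminates as its
    own guild without testing.

    When ``abund`` (samples x features) is given, guilds are labelled
    ``CAG1..CAGn`` by descending total abundance; otherwise ``G1..Gn`` in
    leaf order.
    """
    if leaf_order is None:
        leaf_order = [str(c) for c in d.columns]
    if set(leaf_order) != set(map(str, d.columns)):
        raise ValueError("leaf_order and distance matrix cover different features")
    mat = d.loc[leaf_order, leaf_order].to_numpy(dtype=float)
    n = len(leaf_order)
    members = _leaves_per_node(linkage, n)
    rng = np.random.default_rng(seed)

    d2 = mat**2
    node_p: dict[int, float] = {}
    clusters: list[list[int]] = []

    def visit(node: int) -> None:
        if node < n:  # leaf
            clusters.append([node])
            return
        row = linkage[node - n]
        left, right = int(row[0]), int(row[1])
        leaves_l, leaves_r = members[left], members[right]
        if min(len(leaves_l), len(leaves_r)) < min_clade:
            clusters.append(members[node])
            return
        idx = np.array(leaves_l + leaves_r)
        labels = np.array([0] * len(leaves_l) + [1] * len(leaves_r))
        sub = d2[np.ix_(idx, idx)]
        ss_total, ss_within, a = _ss_decomposition(sub, labels)
        f_obs = _pseudo_f(ss_total, ss_within, a, len(idx))
        perms = np.array([labels[rng.permutation(len(labels))] for _ in range(n_perm)])
        f_perm = _perm_f_batch(sub, perms, ss_total)
        p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + n_perm)
        node_p[node] = float(p)
        if p < alpha:
            visit(left)
            visit(right)
        else:
            clusters.append(members[node])

    visit(2 * n - 2)

    # order clusters: by descending total abundance when available
    if abund is not None:
        totals = abund.sum(axis=0)
        weight = [sum(totals.get(leaf_order[i], 0.0) for i in cl) for cl in clusters]
        order = np.argsort(weight)[::-1]
        prefix = "CAG"
    else:
        order = np.argsort([min(cl) for cl in clusters])
        prefix = "G"
    mapping = {}
    guild_ids = []
    for rank, ci in enumerate(order, start=1):
        gid = f"{prefix}{rank}"
        guild_ids.append(gid)
        for i in clusters[ci]:
            mapping[leaf_order[i]] = gid
    feature_guild = pd.Series(mapping, name="guild").loc[leaf_order]
    return GuildAssignment(
        feature_guild=feature_guild,
        guild_ids=guild_ids,
        linkage=linkage,
        leaf_order=list(leaf_order),
        node_pvalues=node_p,
    )


def aggregate_guilds(abund: pd.DataFrame, ga: GuildAssignment) -> pd.DataFrame:
    """Samples x guilds table: per-sample sum of member-feature abundances.

    Columns are ordered by descending overall abundance.  A guild member
    missing from the abundance table is a hard error.
    """
    missing = [f for f in ga.feature_guild.index if f not in abund.columns]
    if missing:
        raise ValueError(f"guild member feature(s) missing from abundance table: {missing}")
    out = pd.DataFrame(index=abund.index)
    for gid in ga.guild_ids:
        members = ga.feature_guild.index[ga.feature_guild == gid]
        out[gid] = abund[members].sum(axis=1)
    order = out.sum(axis=0).sort_values(ascending=False).index
    return out[order]


def tree_to_newick(linkage: np.ndarray, leaf_order: list[str]) -> str:
    """Serialise a scipy linkage tree to Newick with height-based branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def recurse(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_order[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"
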