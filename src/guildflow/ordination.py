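"""Bray-Curtis ordination and permutation statistics.

Implements the community-level statistics of the pipeline: Bray-Curtis
dissimilarity, principal coordinates analysis (PCoA), covariate-adjusted
PCoA (aPCoA, projecting a nuisance factor such as donor out of the
Gower-centered matrix before eigendecomposition), PERMANOVA with optional
restricted (stratified) permutations, pairwise PERMANOVA with
Benjamini-Hochberg correction, and Procrustes superimposition with the
PROTEST permutation test.

PERMANOVA uses the standard pseudo-F built from squared distances::

    SS_total = sum_{i<j} d_ij^2 / N
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    F = (SS_between / (a - 1)) / (SS_within / (N - a))

with p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).  When strata are given,
labels are permuted only within blocks, the standard reading of
"subject-stratified" tests that preserves donor margins.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, spatial

from .association import bh_qvalues  # noqa: E402  (small, dependency-free helper)

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "ProcrustesResult",
    "bray_curtis",
    "pcoa",
    "apcoa",
    "permanova",
    "pairwise_permanova",
    "procrustes_protest",
]


@dataclass(frozen=True)
class OrdinationResult:
    """Sample coordinates on principal axes, ordered by eigenvalue."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_perm: int
    strata: str | None = None


@dataclass(frozen=True)
class ProcrustesResult:
    m2: float
    correlation: float
    p: float
    n_perm: int


def bray_curtis(abund: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (rows).

    ``d(i, j) = sum|x_i - x_j| / sum(x_i + x_j)``, in [0, 1].  A pair of
    all-zero samples gets distance 0 by convention.
    """
    values = abund.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    d = spatial.distance.squareform(spatial.distance.pdist(values, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # 0/0 pairs (both samples empty)
    return pd.DataFrame(d, index=abund.index, columns=abund.index)


def _as_square(d) -> tuple[np.ndarray, list[str]]:
    if isinstance(d, pd.DataFrame):
        mat = d.to_numpy(dtype=float)
        ids = [str(i) for i in d.index]
    else:
        mat = np.asarray(d, dtype=float)
        ids = [str(i) for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return mat, ids


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _eig_ordination(g: np.ndarray, ids: list[str]) -> OrdinationResult:
    eigvals, eigvecs = linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos_sum = eigvals[eigvals > 0].sum()
    keep = eigvals > 1e-8 * max(eigvals.max(), 0.0)
    eigvals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(eigvals)
    prop = eigvals / pos_sum if pos_sum > 0 else np.zeros_like(eigvals)
    return OrdinationResult(
        sample_ids=ids,
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def pcoa(d) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Gower double-centering of ``-d^2/2`` followed by eigendecomposition;
    axes with eigenvalue below ``1e-8 * max`` (including all negative axes
    of non-Euclidean inputs) are dropped, and proportion explained is taken
    over the positive-eigenvalue sum.
    """
    mat, ids = _as_square(d)
    if mat.shape[0] < 3:
        raise ValueError("PCoA requires at least 3 samples")
    return _eig_ordination(_gower_center(mat), ids)


def apcoa(d, metadata: pd.DataFrame, covariate: str = "donor") -> OrdinationResult:
    """Covariate-adjusted PCoA: project the covariate out, then ordinate.

    The Gower-centered matrix ``G`` is pre- and post-multiplied by the
    residual-maker ``H = I - X (X'X)^- X'`` of the covariate's
    indicator design (with intercept), then eigendecomposed as in
    :func:`pcoa`.  With a single-level covariate ``H`` reduces to the
    centering matrix and the result equals plain PCoA.
    """
    mat, ids = _as_square(d)
    if mat.shape[0] < 3:
        raise ValueError("aPCoA requires at least 3 samples")
    levels = metadata.loc[ids, covariate]
    n = len(ids)
    dummies = pd.get_dummies(levels, drop_first=False).to_numpy(dtype=float)
    if dummies.shape[1] >= n:
        raise ValueError(f"covariate {covariate!r} has one sample per level; nothing remains")
    x = np.column_stack([np.ones(n), dummies])
    h = np.eye(n) - x @ np.linalg.pinv(x.T @ x) @ x.T
    g = _gower_center(mat)
    return _eig_ordination(h @ g @ h, ids)


# ---------------------------------------------------------------------------
# PERMANOVA


def _ss_decomposition(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float, int]:
    """(SS_total, SS_within, number of groups) from squared distances."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    levels = np.unique(groups)
    for lev in levels:
        mask = groups == lev
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    return ss_total, ss_within, len(levels)


def _pseudo_f(ss_total: float, ss_within: float, a: int, n: int) -> float:
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _perm_f_batch(d2: np.ndarray, perm_labels: np.ndarray, ss_total: float) -> np.ndarray:
    """Pseudo-F for a batch of label vectors (rows of perm_labels)."""
    n = d2.shape[0]
    levels = np.unique(perm_labels)
    a = len(levels)
    ss_within = np.zeros(perm_labels.shape[0])
    for lev in levels:
        u = (perm_labels == lev).astype(float).T  # n x P
        ng = u.sum(axis=0)
        quad = np.einsum("ip,ip->p", d2 @ u, u)
        ss_within += quad / (2.0 * ng)
    return (ss_total - ss_within) / (a - 1) / (ss_within / (n - a))


def _stratified_permutations(
    groups: np.ndarray, strata: np.ndarray | None, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """n_perm x n label matrix; labels shuffled within strata blocks."""
    n = len(groups)
    out = np.empty((n_perm, n), dtype=groups.dtype)
    if strata is None:
        for i in range(n_perm):
            out[i] = groups[rng.permutation(n)]
        return out
    blocks = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    for i in range(n_perm):
        perm = np.arange(n)
        for idx in blocks:
            perm[idx] = idx[rng.permutation(len(idx))]
        out[i] = groups[perm]
    return out


def _exact_permutations(groups: np.ndarray, strata: np.ndarray | None) -> np.ndarray:
    """Enumerate all distinct label assignments (small designs only)."""
    n = len(groups)
    if strata is not None:
        blocks = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    else:
        blocks = [np.arange(n)]
    total = math.prod(math.factorial(len(b)) for b in blocks)
    if total > 500_000:
        raise ValueError(f"exact enumeration infeasible: {total} arrangements")
    per_block = [list(itertools.permutations(range(len(b)))) for b in blocks]
    rows = []
    for combo in itertools.product(*per_block):
        lab = np.array(groups)
        for idx, perm in zip(blocks, combo):
            lab[idx] = groups[idx[list(perm)]]
        rows.append(lab)
    return np.array(rows)


def permanova(
    d,
    groups,
    n_perm: int | str = 999,
    strata=None,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Parameters
    ----------
    d
        Square symmetric distance matrix (DataFrame or array).
    groups
        Group label per sample (aligned with ``d``; a Series is matched by
        index when ``d`` is a DataFrame).
    n_perm
        Number of random permutations, or ``"exact"`` to enumerate every
        distinct label arrangement (small designs).
    strata
        Optional blocking factor; permutations never move a sample across
        blocks ("subject-stratified" tests).
    seed
        Seed for the permutation stream.
    """
    mat, ids = _as_square(d)
    n = mat.shape[0]
    groups = _align_labels(groups, ids, n, "groups")
    strata_arr = _align_labels(strata, ids, n, "strata") if strata is not None else None

    counts = pd.Series(groups).value_counts()
    if len(counts) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        raise ValueError(f"every group needs >= 2 samples; got {counts.to_dict()}")
    if strata_arr is not None:
        for s in np.unique(strata_arr):
            if len(np.unique(groups[strata_arr == s])) < 2:
                import warnings

                warnings.warn(
                    f"stratum {s!r} contains a single group and contributes no "
                    "permutation freedom",
                    stacklevel=2,
                )

    d2 = mat**2
    ss_total, ss_within, a = _ss_decomposition(d2, groups)
    f_obs = _pseudo_f(ss_total, ss_within, a, n)
    r2 = (ss_total - ss_within) / ss_total if ss_total > 0 else 0.0

    if n_perm == "exact":
        perms = _exact_permutations(groups, strata_arr)
        f_perm = _perm_f_batch(d2, perms, ss_total)
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        n_used = perms.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perms = _stratified_permutations(groups, strata_arr, int(n_perm), rng)
        f_perm = _perm_f_batch(d2, perms, ss_total)
        p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + int(n_perm))
        n_used = int(n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r2=float(r2),
        p=float(p),
        n_perm=n_used,
        strata=None if strata is None else "given",
    )


def _align_labels(labels, ids: list[str], n: int, what: str) -> np.ndarray:
    if isinstance(labels, pd.Series):
        try:
            return labels.loc[ids].to_numpy()
        except KeyError:
            pass  # fall through to positional
    arr = np.asarray(labels)
    if len(arr) != n:
        raise ValueError(f"{what} must align with the distance matrix ({n} samples)")
    return arr


def pairwise_permanova(
    d,
    groups,
    n_perm: int = 999,
    strata=None,
    seed: int | None = None,
    method: str = "BH",
) -> pd.DataFrame:
    """PERMANOVA for every pair of group levels, BH-corrected.

    Returns a DataFrame with one row per unordered pair: group_a, group_b,
    pseudo_f, r2, p and q (Benjamini-Hochberg across all pairs).
    """
    if method != "BH":
        raise ValueError("only Benjamini-Hochberg ('BH') correction is supported")
    mat, ids = _as_square(d)
    groups_arr = _align_labels(groups, ids, mat.shape[0], "groups")
    strata_arr = (
        _align_labels(strata, ids, mat.shape[0], "strata") if strata is not None else None
    )
    levels = sorted(pd.unique(groups_arr))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(levels) * (len(levels) - 1) // 2)
    rows = []
    for k, (ga, gb) in enumerate(itertools.combinations(levels, 2)):
        mask = (groups_arr == ga) | (groups_arr == gb)
        sub = mat[np.ix_(mask, mask)]
        res = permanova(
            sub,
            groups_arr[mask],
            n_perm=n_perm,
            strata=None if strata_arr is None else strata_arr[mask],
            seed=int(child_seeds[k]),
        )
        rows.append((ga, gb, res.pseudo_f, res.r2, res.p))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "pseudo_f", "r2", "p"])
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Procrustes / PROTEST


def _configuration(ord_or_array, n_axes: int | None) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(ord_or_array, OrdinationResult):
        coords, ids = ord_or_array.coordinates, list(ord_or_array.sample_ids)
    elif isinstance(ord_or_array, pd.DataFrame):
        coords, ids = ord_or_array.to_numpy(dtype=float), [str(i) for i in ord_or_array.index]
    else:
        coords, ids = np.asarray(ord_or_array, dtype=float), None
    if n_axes is not None:
        coords = coords[:, :n_axes]
    return coords, ids


def _standardize(conf: np.ndarray) -> np.ndarray:
    c = conf - conf.mean(axis=0)
    norm = np.sqrt((c**2).sum())
    if norm < 1e-300:
        raise ValueError("rank-0 configuration: all points coincide")
    return c / norm


def _m2(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes residual after optimal rotation/scaling."""
    s = linalg.svdvals(x.T @ y).sum()
    return float(max(1.0 - s**2, 0.0))


def procrustes_protest(
    x,
    y,
    n_perm: int = 999,
    seed: int | None = None,
    n_axes: int | None = 2,
) -> ProcrustesResult:
    """Procrustes superimposition of two ordinations with a PROTEST test.

    Both configurations are centred and scaled to unit sum of squares; the
    optimal rotation minimises ``m^2 = 1 - (sum of singular values)^2``.
    ``correlation = sqrt(1 - m^2)`` is the Procrustes correlation.  PROTEST
    permutes the sample rows of ``y``: p = (1 + #{m2_perm <= m2_obs}) /
    (1 + n_perm).  By default the first two axes are compared (the plotted
    ordination); pass ``n_axes=None`` for full rank.
    """
    cx, ids_x = _configuration(x, n_axes)
    cy, ids_y = _configuration(y, n_axes)
    if ids_x is not None and ids_y is not None:
        if set(ids_x) != set(ids_y):
            raise ValueError("ordinations cover different samples")
        order = [ids_y.index(i) for i in ids_x]
        cy = cy[order]
    if cx.shape[0] != cy.shape[0]:
        raise ValueError("configurations must have the same number of samples")
    k = min(cx.shape[1], cy.shape[1])
    cx, cy = _standardize(cx[:, :k]), _standardize(cy[:, :k])
    m2_obs = _m2(cx, cy)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(cy.shape[0])
        if _m2(cx, _standardize(cy[perm])) <= m2_obs + 1e-12:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return ProcrustesResult(
        m2=m2_obs, correlation=float(np.sqrt(max(1.0 - m2_obs, 0.0))), p=float(p), n_perm=n_perm
    )
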