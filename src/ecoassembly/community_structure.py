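"""Pairwise dissimilarities, ordination, and group-level statistics.

Distances are Bray-Curtis (on counts) and unweighted UniFrac (presence/
absence on a rooted phylogeny).  Ordination is PCoA (classical scaling)
and non-metric MDS minimizing Kruskal stress-1 with pool-adjacent-violators
monotone regression.  Group statistics are ANOSIM, SIMPER, and the Mantel
test; both permutation tests switch to complete enumeration when the number
of distinct relabellings does not exceed the requested permutation count,
so small problems get exact p-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .tables_io import ValidationError, ZotuTable, align_table_tree


def _as_labels(groups, ids) -> np.ndarray:
    """Normalize a grouping (mapping/Series/sequence) to an array over ids."""
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    if isinstance(groups, dict):
        missing = [s for s in ids if s not in groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        return np.asarray([groups[s] for s in ids])
    labels = np.asarray(list(groups))
    if len(labels) != len(ids):
        raise ValidationError("group labels do not match number of samples")
    return labels


def bray_curtis(table: ZotuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    d(x, y) = sum_i |x_i - y_i| / sum_i (x_i + y_i)
    """
    totals = table.sample_totals
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValidationError(f"sample {bad!r} has zero total count")
    X = table.matrix.T.astype(float)
    return DistanceMatrix(squareform(pdist(X, metric="braycurtis")),
                          ids=table.sample_ids)


def unweighted_unifrac(table: ZotuTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: fraction of branch length unique to one of the
    two communities, on presence/absence."""
    tips = {t.name for t in tree.tips()}
    missing = set(table.taxon_ids) - tips
    if missing:
        raise ValidationError(
            f"table taxa missing from tree: {sorted(missing)[:10]}"
        )
    if len(tips) > len(table.taxon_ids):
        _, tree = align_table_tree(table, tree)
    return beta_diversity(
        "unweighted_unifrac",
        table.matrix.T,
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree,
    )


@dataclass
class OrdinationResult:
    method: str
    coordinates: pd.DataFrame
    stress: float | None = None
    eigenvalues: np.ndarray | None = None
    negative_eigenvalues: np.ndarray | None = None
    proportion_explained: np.ndarray | None = None
    converged: bool = True
    stress_history: list = field(default_factory=list)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis (classical metric scaling).

    Gower double-centering of -0.5 D^2 followed by eigendecomposition;
    coordinates are eigenvectors scaled by the square root of their
    eigenvalue.  Negative eigenvalues (non-Euclidean input) are dropped
    from the coordinates and reported separately.
    """
    D = np.asarray(dm.data, dtype=float)
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValidationError("distance matrix is not symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        method="pcoa",
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=eigvals[pos],
        negative_eigenvalues=np.abs(eigvals[eigvals < -tol]),
        proportion_explained=eigvals[pos] / eigvals[pos].sum(),
    )


def _nmds_single(D_cond: np.ndarray, X: np.ndarray, max_iter: int,
                 tol: float, tie_order: np.ndarray):
    """SMACOF with monotone regression from one starting configuration.

    Returns (X, stress1, history) where history tracks the normalized
    majorization objective (monotone non-increasing)."""
    n = X.shape[0]
    history = []
    prev = np.inf
    for _ in range(max_iter):
        d = pdist(X)
        # monotone (primary tie treatment: ties pre-sorted by current d)
        dhat = np.empty_like(d)
        dhat[tie_order] = isotonic_regression(d[tie_order]).x
        denom = (dhat ** 2).sum()
        if denom == 0:
            break
        obj = math.sqrt(((d - dhat) ** 2).sum() / denom)
        history.append(obj)
        if prev - obj < tol:
            break
        prev = obj
        # rescale disparities to fixed norm, then Guttman transform
        dhat = dhat * math.sqrt(len(dhat) / denom)
        d_safe = np.where(d > 1e-12, d, 1e-12)
        ratio = squareform(dhat / d_safe)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = (B @ X) / n
    d = pdist(X)
    dhat = np.empty_like(d)
    dhat[tie_order] = isotonic_regression(d[tie_order]).x
    stress1 = math.sqrt(((d - dhat) ** 2).sum() / (d ** 2).sum())
    return X, stress1, history


def nmds(dm: DistanceMatrix, k: int = 2, seed: int = 0, n_starts: int = 4,
         max_iter: int = 300, tol: float = 1e-9) -> OrdinationResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Runs SMACOF with pool-adjacent-violators monotone regression from a
    PCoA configuration plus ``n_starts`` random configurations and keeps
    the solution with the lowest stress-1.  Ties in the input
    dissimilarities get Kruskal's primary treatment (no order constraint
    within a tie block).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = np.asarray(dm.data, dtype=float)
    D_cond = squareform(D, checks=False)
    n = D.shape[0]
    rng = np.random.default_rng(seed)

    starts = []
    pc = pcoa(dm).coordinates.to_numpy()
    if pc.shape[1] >= k:
        starts.append(pc[:, :k].copy())
    else:
        pad = np.zeros((n, k))
        pad[:, : pc.shape[1]] = pc
        starts.append(pad)
    for _ in range(n_starts):
        starts.append(rng.normal(size=(n, k)))

    best = None
    for X0 in starts:
        # primary tie treatment: sort by dissimilarity, ties by the start's
        # configuration distances so tied pairs carry no mutual constraint
        d0 = pdist(X0)
        tie_order = np.lexsort((d0, D_cond))
        X, stress1, hist = _nmds_single(D_cond, X0, max_iter, tol, tie_order)
        if best is None or stress1 < best[1]:
            best = (X, stress1, hist)
    X, stress1, hist = best
    converged = len(hist) < max_iter
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        method="nmds",
        coordinates=pd.DataFrame(X, index=list(dm.ids), columns=cols),
        stress=stress1,
        converged=converged,
        stress_history=hist,
    )


@dataclass
class GroupTestResult:
    method: str
    statistic: float
    p_value: float
    n_permutations: int
    exact: bool = False
    r_squared: float | None = None


def _distinct_label_permutations(labels: np.ndarray):
    """All distinct arrangements of a label multiset."""
    return sorted(set(itertools.permutations(labels)))


def _n_distinct_arrangements(labels: np.ndarray) -> int:
    n = len(labels)
    total = math.factorial(n)
    for _, c in zip(*np.unique(labels, return_counts=True)):
        total //= math.factorial(int(c))
    return total


def _anosim_r(rank_cond: np.ndarray, labels: np.ndarray, iu) -> float:
    within = labels[iu[0]] == labels[iu[1]]
    r_w = rank_cond[within].mean()
    r_b = rank_cond[~within].mean()
    m = len(rank_cond)
    return (r_b - r_w) / (m / 2.0)


def anosim(dm: DistanceMatrix, groups, n_permutations: int = 9999,
           seed: int = 0, exact: bool | None = None) -> GroupTestResult:
    """ANOSIM: rank-based test of between- vs within-group dissimilarity.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2.  The p-value is the +1-corrected fraction of label
    permutations with R at least as large as observed; when the number of
    distinct relabellings is <= ``n_permutations`` (or ``exact=True``)
    every distinct arrangement is enumerated and the p-value is exact.
    """
    ids = list(dm.ids)
    labels = _as_labels(groups, ids)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValidationError(f"group {small!r} has fewer than 2 samples")
    cond = squareform(np.asarray(dm.data), checks=False)
    iu = np.triu_indices(len(ids), k=1)
    rank_cond = rankdata(cond)  # condensed order matches triu order
    r_obs = _anosim_r(rank_cond, labels, iu)

    n_distinct = _n_distinct_arrangements(labels)
    use_exact = exact or (exact is None and n_distinct <= n_permutations)
    if use_exact:
        stats = np.array([
            _anosim_r(rank_cond, np.asarray(perm), iu)
            for perm in _distinct_label_permutations(labels)
        ])
        p = float((stats >= r_obs - 1e-12).mean())
        return GroupTestResult("anosim", float(r_obs), p, len(stats), exact=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(rank_cond, perm, iu) >= r_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return GroupTestResult("anosim", float(r_obs), float(p), n_permutations)


def mantel(dm1: DistanceMatrix, dm2: DistanceMatrix,
           n_permutations: int = 9999, seed: int = 0,
           method: str = "pearson",
           exact: bool | None = None) -> GroupTestResult:
    """Mantel test of correlation between two distance matrices.

    Correlates the off-diagonal entries (Pearson by default, Spearman
    optionally) and assesses significance by jointly permuting rows and
    columns of the second matrix; one-sided (greater).  Reports r and r^2.
    Complete enumeration of the n! permutations is used when feasible.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    ids = list(dm1.ids)
    if set(ids) != set(dm2.ids):
        raise ValidationError("distance matrices have different sample sets")
    D1 = np.asarray(dm1.data)
    D2 = np.asarray(dm2.filter(ids).data)
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    x = D1[iu]

    def corr(vec_y):
        if method == "spearman":
            a, b = rankdata(x), rankdata(vec_y)
        else:
            a, b = x, vec_y
        a = a - a.mean()
        b = b - b.mean()
        denom = math.sqrt((a @ a) * (b @ b))
        if denom == 0:
            raise ValidationError("zero variance in distances; r undefined")
        return float((a @ b) / denom)

    r_obs = corr(D2[iu])
    n_total = math.factorial(n)
    use_exact = exact or (exact is None and n_total <= n_permutations)
    if use_exact:
        stats = np.array([
            corr(D2[np.ix_(p, p)][iu])
            for p in itertools.permutations(range(n))
        ])
        p_val = float((stats >= r_obs - 1e-12).mean())
        return GroupTestResult("mantel", r_obs, p_val, n_total, exact=True,
                               r_squared=r_obs ** 2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        if corr(D2[np.ix_(p, p)][iu]) >= r_obs - 1e-12:
            hits += 1
    p_val = (hits + 1) / (n_permutations + 1)
    return GroupTestResult("mantel", r_obs, float(p_val), n_permutations,
                           r_squared=r_obs ** 2)


def covariate_distance(values: pd.Series, ids=None) -> DistanceMatrix:
    """Euclidean distance matrix of a single numeric covariate."""
    if ids is not None:
        values = values.loc[list(ids)]
    v = values.to_numpy(dtype=float)[:, None]
    return DistanceMatrix(squareform(pdist(v)), ids=list(values.index))


def simper(table: ZotuTable, groups, group_a: str | None = None,
           group_b: str | None = None) -> tuple[pd.DataFrame, float]:
    """SIMPER: per-taxon contributions to between-group Bray-Curtis.

    For each between-group sample pair (j, k), taxon i contributes
    |x_ij - x_ik| / sum_s (x_sj + x_sk); contributions are averaged over
    all between-group pairs.  The per-taxon averages sum exactly to the
    average between-group Bray-Curtis dissimilarity.

    Returns (records, overall) where records is a DataFrame sorted by
    decreasing contribution with percent and cumulative percent columns.
    """
    labels = _as_labels(groups, table.sample_ids)
    uniq = np.unique(labels)
    if group_a is None and group_b is None:
        if len(uniq) != 2:
            raise ValidationError(
                "simper compares exactly two groups; specify group_a/group_b"
            )
        group_a, group_b = uniq
    for g in (group_a, group_b):
        if (labels == g).sum() == 0:
            raise ValidationError(f"group {g!r} has no samples")
    X = table.matrix.astype(float)
    A = X[:, labels == group_a]
    B = X[:, labels == group_b]
    contrib = np.zeros(table.n_taxa)
    n_pairs = 0
    for j in range(A.shape[1]):
        for k in range(B.shape[1]):
            denom = (A[:, j] + B[:, k]).sum()
            contrib += np.abs(A[:, j] - B[:, k]) / denom
            n_pairs += 1
    contrib /= n_pairs
    overall = float(contrib.sum())
    pct = 100.0 * contrib / overall if overall > 0 else np.zeros_like(contrib)
    df = pd.DataFrame(
        {
            "average_contribution": contrib,
            "percent_contribution": pct,
            f"mean_abundance_{group_a}": A.mean(axis=1),
            f"mean_abundance_{group_b}": B.mean(axis=1),
        },
        index=pd.Index(table.taxon_ids, name="taxon_id"),
    ).sort_values("average_contribution", ascending=False, kind="stable")
    df["cumulative_percent"] = df["percent_contribution"].cumsum()
    return df, overall


def shared_taxa(table: ZotuTable, groups) -> dict:
    """Venn-style counts of taxa exclusive to and shared between groups.

    A taxon belongs to a group if it has count > 0 in at least one of the
    group's samples.  Returns a dict mapping each non-empty combination of
    group labels (a sorted tuple) to the number of taxa found in exactly
    those groups; values sum to the number of observed taxa.
    """
    labels = _as_labels(groups, table.sample_ids)
    uniq = list(np.unique(labels))
    presence = {}
    mat = table.matrix > 0
    for g in uniq:
        presence[g] = mat[:, labels == g].any(axis=1)
    regions: dict[tuple, int] = {}
    observed = mat.any(axis=1)
    membership = np.stack([presence[g] for g in uniq])  # groups x taxa
    for idx in np.nonzero(observed)[0]:
        region = tuple(g for gi, g in enumerate(uniq) if membership[gi, idx])
        regions[region] = regions.get(region, 0) + 1
    return regions
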