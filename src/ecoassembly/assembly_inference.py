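"""Null-model partitioning of community assembly processes.

The two-step framework quantifies the processes structuring pairwise
community turnover:

1. Phylogenetic turnover.  For each sample pair the abundance-weighted
   beta mean-nearest-taxon distance (betaMNTD) is compared with a null
   distribution obtained by shuffling taxon identities across the tips of
   the metacommunity phylogeny.  The standardized deviate is the beta
   nearest taxon index (betaNTI).  |betaNTI| above a threshold (default 2)
   signals deterministic selection: positive = heterogeneous selection
   (divergent environments), negative = homogeneous selection.

2. Taxonomic turnover.  For pairs without a selection signal, observed
   Bray-Curtis dissimilarity is compared with dissimilarities of null
   community pairs assembled probabilistically from the metacommunity
   (membership drawn by occurrence frequency conditioned on observed
   richness, reads distributed by metacommunity relative abundance).  The
   Raup-Crick deviate RC_bray in [-1, 1] classifies the residual pairs:
   RC above +0.95 = dispersal limitation, below -0.95 = homogenizing
   dispersal, otherwise ecological drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .tables_io import ValidationError, ZotuTable

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distance matrix."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError("tree has branches without lengths")
    return tree.tip_tip_distances()


def beta_mntd(rel_abund_a, rel_abund_b, patristic: np.ndarray) -> float:
    """Abundance-weighted beta mean nearest taxon distance for one pair.

    betaMNTD = 0.5 * [ sum_i f_iA * min_{j in B} d(i,j)
                     + sum_j f_jB * min_{i in A} d(i,j) ]

    Taxa present in both communities have nearest-taxon distance 0, so
    identical communities score 0.  Relative abundance vectors are indexed
    like the rows/columns of ``patristic``.
    """
    fa = np.asarray(rel_abund_a, dtype=float)
    fb = np.asarray(rel_abund_b, dtype=float)
    D = np.asarray(patristic, dtype=float)
    pa, pb = fa > 0, fb > 0
    if not pa.any() or not pb.any():
        raise ValidationError("betaMNTD undefined for an empty community")
    min_a_to_b = D[np.ix_(pa, pb)].min(axis=1)
    min_b_to_a = D[np.ix_(pa, pb)].min(axis=0)
    return float(0.5 * (fa[pa] @ min_a_to_b + fb[pb] @ min_b_to_a))


def _pairwise_beta_mntd(F: np.ndarray, presence: np.ndarray,
                        D: np.ndarray) -> np.ndarray:
    """All-pairs weighted betaMNTD.

    F : (samples x taxa) relative abundances (rows sum to 1)
    presence : boolean (samples x taxa)
    D : (taxa x taxa) patristic distances

    For each sample s, M[s, i] = min_{j present in s} D[i, j]; the directed
    mean A->B is then F[A] . M[B], and betaMNTD the symmetrized average.
    """
    n_samples, n_taxa = F.shape
    M = np.empty((n_samples, n_taxa))
    for s in range(n_samples):
        M[s] = D[:, presence[s]].min(axis=1)
    G = F @ M.T  # G[a, b] = directed mean a -> b
    return 0.5 * (G + G.T)


def beta_nti(table: ZotuTable, tree: TreeNode, n_null: int = 999,
             seed: int = 0) -> pd.DataFrame:
    """betaMNTD, its taxon-shuffling null distribution, and betaNTI.

    The null shuffles taxon identities across the tips of the phylogeny:
    each randomization applies one joint permutation to the rows/columns of
    the patristic matrix, shared by every sample pair in that
    randomization.  Pairs whose null distribution has zero standard
    deviation get betaNTI = NaN with a warning.

    Returns one row per unordered sample pair with columns sample_a,
    sample_b, beta_mntd_obs, null_mean, null_sd, beta_nti, n_null.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    dm = patristic_distances(tree)
    order = [t for t in table.taxon_ids]
    missing = set(order) - set(dm.ids)
    if missing:
        raise ValidationError(
            f"table taxa missing from tree: {sorted(missing)[:10]}"
        )
    D = np.asarray(dm.filter(order).data)
    F = table.relative_abundance().to_numpy().T  # samples x taxa
    presence = F > 0
    n_samples, n_taxa = F.shape

    obs = _pairwise_beta_mntd(F, presence, D)
    rng = np.random.default_rng(seed)
    nulls = np.empty((n_null, n_samples, n_samples))
    for r in range(n_null):
        # shuffled taxon identities: community i sits on tip perm[i]
        perm = rng.permutation(n_taxa)
        Fp = np.zeros_like(F)
        Fp[:, perm] = F
        nulls[r] = _pairwise_beta_mntd(Fp, Fp > 0, D)

    iu = np.triu_indices(n_samples, k=1)
    null_mean = nulls.mean(axis=0)[iu]
    null_sd = nulls.std(axis=0, ddof=1)[iu] if n_null > 1 else np.zeros(len(iu[0]))
    obs_v = obs[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(null_sd > 1e-12, (obs_v - null_mean) / null_sd, np.nan)
    n_undef = int(np.isnan(bnti).sum())
    if n_undef:
        warnings.warn(
            f"betaNTI undefined (null sd = 0) for {n_undef} pair(s)",
            stacklevel=2,
        )
    ids = table.sample_ids
    return pd.DataFrame(
        {
            "sample_a": [ids[i] for i in iu[0]],
            "sample_b": [ids[j] for j in iu[1]],
            "beta_mntd_obs": obs_v,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "beta_nti": bnti,
            "n_null": n_null,
        }
    )


def _gumbel_topk(weights: np.ndarray, k: int, n_draws: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Boolean (n_draws x n) masks of k distinct items drawn without
    replacement with probability proportional to ``weights`` (Gumbel
    top-k, equivalent to successive weighted draws)."""
    n = len(weights)
    logw = np.full(n, -np.inf)
    ok = weights > 0
    logw[ok] = np.log(weights[ok])
    keys = logw[None, :] + rng.gumbel(size=(n_draws, n))
    idx = np.argpartition(-keys, k - 1, axis=1)[:, :k]
    masks = np.zeros((n_draws, n), dtype=bool)
    np.put_along_axis(masks, idx, True, axis=1)
    return masks


def raup_crick_bray(table: ZotuTable, n_null: int = 999,
                    seed: int = 0) -> pd.DataFrame:
    """Bray-Curtis based Raup-Crick deviate per sample pair.

    For each pair (A, B) the observed Bray-Curtis dissimilarity on counts
    is compared against ``n_null`` null pairs.  Each null community keeps
    the observed richness and read total: membership is drawn without
    replacement with probability proportional to occurrence frequency
    (number of samples containing the taxon), then reads are distributed
    multinomially with probability proportional to metacommunity relative
    abundance restricted to the drawn taxa.

    RC_bray = 2 * [ (#(null < obs) + 0.5 #(null = obs)) / n_null ] - 1,
    with an absolute tie tolerance of 1e-12, so RC_bray lies in [-1, 1].
    Randomness is drawn from an independent stream per sample pair derived
    from the master seed, making results independent of pair order.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    X = table.matrix.T.astype(np.int64)  # samples x taxa
    n_samples, n_taxa = X.shape
    occurrence = (X > 0).sum(axis=0).astype(float)
    meta_p = X.sum(axis=0).astype(float)
    meta_p /= meta_p.sum()
    pool = int((occurrence > 0).sum())
    richness = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)
    if (richness > pool).any():
        raise ValidationError("sample richness exceeds metacommunity pool size")
    if (richness == 0).any():
        raise ValidationError("raup_crick_bray requires non-empty samples")

    def null_counts(k, total, rng):
        masks = _gumbel_topk(occurrence, int(k), n_null, rng)
        probs = meta_p * masks
        probs /= probs.sum(axis=1, keepdims=True)
        return rng.multinomial(int(total), probs)

    rows = []
    ids = table.sample_ids
    for a in range(n_samples):
        for b in range(a + 1, n_samples):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(a, b))
            )
            xa, xb = X[a].astype(float), X[b].astype(float)
            obs = np.abs(xa - xb).sum() / (xa + xb).sum()
            na = null_counts(richness[a], totals[a], rng).astype(float)
            nb = null_counts(richness[b], totals[b], rng).astype(float)
            null_bc = np.abs(na - nb).sum(axis=1) / (na + nb).sum(axis=1)
            below = (null_bc < obs - 1e-12).sum()
            ties = (np.abs(null_bc - obs) <= 1e-12).sum()
            rc = 2.0 * ((below + 0.5 * ties) / n_null) - 1.0
            rows.append((ids[a], ids[b], obs, float(rc)))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b",
                                       "bray_curtis_obs", "rc_bray"])


def assembly_pair_stats(table: ZotuTable, tree: TreeNode,
                        n_null_bnti: int = 999, n_null_rc: int = 999,
                        seed: int = 0) -> pd.DataFrame:
    """betaNTI and RC_bray for every sample pair, merged into one table."""
    bnti = beta_nti(table, tree, n_null=n_null_bnti, seed=seed)
    rc = raup_crick_bray(table, n_null=n_null_rc, seed=seed + 1)
    return bnti.merge(rc, on=["sample_a", "sample_b"], validate="1:1")


def classify_pair(beta_nti_value: float, rc_value: float,
                  bnti_threshold: float = 2.0,
                  rc_threshold: float = 0.95) -> str:
    """Assign one sample pair to an assembly process.

    betaNTI > +t -> heterogeneous selection; betaNTI < -t -> homogeneous
    selection; otherwise RC > +r -> dispersal limitation, RC < -r ->
    homogenizing dispersal, |RC| <= r -> drift.
    """
    if np.isnan(beta_nti_value):
        raise ValueError("cannot classify a pair with undefined betaNTI")
    if beta_nti_value > bnti_threshold:
        return "heterogeneous_selection"
    if beta_nti_value < -bnti_threshold:
        return "homogeneous_selection"
    if rc_value > rc_threshold:
        return "dispersal_limitation"
    if rc_value < -rc_threshold:
        return "homogenizing_dispersal"
    return "drift"


@dataclass
class AssemblyPartition:
    group: str
    fractions: dict
    n_pairs: int
    n_excluded: int
    bnti_threshold: float
    rc_threshold: float


def partition_processes(pair_stats: pd.DataFrame, groups,
                        bnti_threshold: float = 2.0,
                        rc_threshold: float = 0.95,
                        include_between: bool = False) -> pd.DataFrame:
    """Five-way partition of assembly processes per sample group.

    ``groups`` maps sample id -> group label.  For each group, every pair
    with both samples in the group is classified and the class fractions
    (summing to 1) are reported.  With ``include_between=True`` the pairs
    spanning two different groups are partitioned as well, under the label
    ``"A|B"``.  Pairs with undefined betaNTI are excluded and counted in
    ``n_excluded``.
    """
    if bnti_threshold <= 0 or rc_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    df = pair_stats.copy()
    missing = set(df["sample_a"]) | set(df["sample_b"])
    missing -= set(groups)
    if missing:
        raise ValidationError(f"samples without group label: {sorted(missing)[:10]}")
    ga = df["sample_a"].map(groups)
    gb = df["sample_b"].map(groups)
    df["_pair_group"] = np.where(ga == gb, ga,
                                 ["|".join(sorted(p)) for p in zip(ga, gb)])
    if not include_between:
        df = df[ga.to_numpy() == gb.to_numpy()]
    rows = []
    for label, sub in df.groupby("_pair_group", sort=True):
        defined = sub[~sub["beta_nti"].isna()]
        n_excluded = len(sub) - len(defined)
        n_pairs = len(defined)
        counts = dict.fromkeys(PROCESSES, 0)
        for b, r in zip(defined["beta_nti"], defined["rc_bray"]):
            counts[classify_pair(b, r, bnti_threshold, rc_threshold)] += 1
        row = {"group": label, "n_pairs": n_pairs, "n_excluded": n_excluded,
               "bnti_threshold": bnti_threshold, "rc_threshold": rc_threshold}
        for proc in PROCESSES:
            row[proc] = counts[proc] / n_pairs if n_pairs else np.nan
        rows.append(row)
    columns = ["group", "n_pairs", "n_excluded", "bnti_threshold",
               "rc_threshold", *PROCESSES]
    return pd.DataFrame(rows, columns=columns).set_index("group")
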