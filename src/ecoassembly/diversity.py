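"""Per-sample alpha diversity: richness, Shannon, Chao1, Faith's PD.

Shannon entropy defaults to natural log (nats); ``base=2`` gives bits.
Chao1 uses the bias-corrected form, which stays defined when there are no
doubletons.  Faith's phylogenetic diversity defaults to the root-inclusive
convention (branches connecting the observed tips all the way to the root
are counted); ``include_root=False`` sums only branches within the subtree
spanned by the observed tips.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables_io import ZotuTable


def richness(counts) -> int:
    """Number of taxa observed (count > 0)."""
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    return int((c > 0).sum())


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum(p_i log p_i); natural log by default."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    c = np.asarray(counts)
    s_obs = richness(c)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def faith_pd(counts, taxon_ids, tree: TreeNode, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of one sample.

    Sum of branch lengths of the minimal subtree connecting the observed
    taxa (and, by default, the root).
    """
    c = np.asarray(counts)
    present = {t for t, x in zip(taxon_ids, c) if x > 0}
    if not present:
        return 0.0
    tip_index = {t.name: t for t in tree.tips()}
    missing = present - tip_index.keys()
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)[:10]}")
    # union of edges from each observed tip up to the root
    edges = set()
    for name in present:
        node = tip_index[name]
        while node.parent is not None:
            if id(node) in edges:
                break
            edges.add(id(node))
            node = node.parent
    by_id = {id(n): n for n in tree.traverse(include_self=False)}
    nodes = [by_id[e] for e in edges]
    if not include_root:
        # drop the shared path between the observed tips' MRCA and the root
        mrca = tree.lowest_common_ancestor(list(present)) if len(present) > 1 else tip_index[next(iter(present))]
        node = mrca
        shared = set()
        while node.parent is not None:
            shared.add(id(node))
            node = node.parent
        nodes = [n for n in nodes if id(n) not in shared]
    return float(sum(n.length for n in nodes))


def alpha_table(table: ZotuTable, tree: TreeNode | None = None,
                shannon_base: float | None = None,
                include_root: bool = True) -> pd.DataFrame:
    """Alpha-diversity indices for every sample of a table.

    Returns a DataFrame indexed by sample id with columns ``richness``,
    ``shannon``, ``chao1`` and, when a tree is given, ``faith_pd``.
    """
    rows = {}
    taxa = table.taxon_ids
    for s in table.sample_ids:
        c = table.counts[s].to_numpy()
        rec = {
            "richness": richness(c),
            "shannon": shannon(c, base=shannon_base),
            "chao1": chao1(c),
        }
        if tree is not None:
            rec["faith_pd"] = faith_pd(c, taxa, tree, include_root=include_root)
        rows[s] = rec
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def rarefaction_curve(table: ZotuTable, depths, reps: int = 10,
                      seed: int = 0) -> pd.DataFrame:
    """Mean rarefied richness per sample over a grid of depths.

    Long-format output (sample_id, depth, mean_richness) averaged over
    ``reps`` independent subsamples; depths above a sample's total are
    omitted for that sample.
    """
    depths = list(depths)
    if any(d <= 0 for d in depths):
        raise ValueError("depths must be positive")
    if sorted(depths) != depths:
        raise ValueError("depths must be increasing")
    rng = np.random.default_rng(seed)
    records = []
    mat = table.matrix
    totals = mat.sum(axis=0)
    for j, s in enumerate(table.sample_ids):
        col = mat[:, j]
        for d in depths:
            if d > totals[j]:
                continue
            vals = [
                int((rng.multivariate_hypergeometric(col, d) > 0).sum())
                for _ in range(reps)
            ]
            records.append((s, d, float(np.mean(vals))))
    return pd.DataFrame(records, columns=["sample_id", "depth", "mean_richness"])


def group_letters(values: pd.Series, groups: pd.Series, alpha: float = 0.05) -> dict:
    """Compact letter display for group comparisons of an alpha index.

    Pairwise two-sided Mann-Whitney U tests at level ``alpha``; groups that
    share a letter are not significantly different.
    """
    from itertools import combinations
    from scipy.stats import mannwhitneyu

    labels = sorted(groups.unique())
    differ = {g: set() for g in labels}
    for a, b in combinations(labels, 2):
        xa = values[groups == a]
        xb = values[groups == b]
        p = mannwhitneyu(xa, xb, alternative="two-sided").pvalue
        if p < alpha:
            differ[a].add(b)
            differ[b].add(a)
    # greedy letter assignment
    letters = {g: "" for g in labels}
    current = "a"
    for g in labels:
        if letters[g]:
            continue
        members = [g] + [h for h in labels if h not in differ[g] and h != g
                         and all(m not in differ[h] for m in [g])]
        block = [g]
        for h in members[1:]:
            if all(h not in differ[m] for m in block):
                block.append(h)
        for m in block:
            letters[m] += current
        current = chr(ord(current) + 1)
    for g in labels:
        if not letters[g]:
            letters[g] = current
            current = chr(ord(current) + 1)
    return letters
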