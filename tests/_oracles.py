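"""Independent brute-force reference implementations used only by tests.

Everything here is written as directly as possible from the defining
formulas (explicit loops, ancestor walks, exhaustive enumeration) so that
it shares no code path with the package implementations it checks.
"""

import itertools
import math

import numpy as np
from scipy.stats import rankdata


def bray_curtis_pair(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def ancestors_of(tip):
    node = tip
    out = []
    while node.parent is not None:
        out.append(node)
        node = node.parent
    return out


def patristic_pair(tree, name_a, name_b):
    """Path length between two tips via explicit ancestor-walk to the LCA."""
    tips = {t.name: t for t in tree.tips()}
    a_path = ancestors_of(tips[name_a])
    b_path = ancestors_of(tips[name_b])
    b_ids = {id(n): i for i, n in enumerate(b_path)}
    total_a = 0.0
    for n in a_path:
        if id(n) in b_ids:
            lca_idx = b_ids[id(n)]
            return total_a + sum(m.length for m in b_path[:lca_idx])
        total_a += n.length
    return total_a + sum(m.length for m in b_path)


def faith_pd_bruteforce(present, tree, include_root=True):
    """Sum branch lengths whose subtree contains an observed tip."""
    present = set(present)
    total = 0.0
    for node in tree.traverse(include_self=False):
        below = {t.name for t in node.tips(include_self=True)}
        if below & present:
            total += node.length
    if not include_root and present:
        # remove the branches shared by every observed tip (MRCA-to-root)
        for node in tree.traverse(include_self=False):
            below = {t.name for t in node.tips(include_self=True)}
            if present <= below:
                total -= node.length
    return total


def unweighted_unifrac_pair(present_a, present_b, tree):
    present_a, present_b = set(present_a), set(present_b)
    unique = 0.0
    total = 0.0
    for node in tree.traverse(include_self=False):
        below = {t.name for t in node.tips(include_self=True)}
        in_a = bool(below & present_a)
        in_b = bool(below & present_b)
        if in_a or in_b:
            total += node.length
            if in_a != in_b:
                unique += node.length
    return unique / total


def beta_mntd_bruteforce(fa, fb, taxa, dist_lookup):
    """Double-loop weighted mean nearest-taxon distance.

    dist_lookup(t1, t2) returns the patristic distance between two taxa.
    """
    present_a = [t for t, f in zip(taxa, fa) if f > 0]
    present_b = [t for t, f in zip(taxa, fb) if f > 0]
    fa_map = dict(zip(taxa, fa))
    fb_map = dict(zip(taxa, fb))
    mean_ab = sum(
        fa_map[ta] * min(dist_lookup(ta, tb) for tb in present_b)
        for ta in present_a
    )
    mean_ba = sum(
        fb_map[tb] * min(dist_lookup(ta, tb) for ta in present_a)
        for tb in present_b
    )
    return 0.5 * (mean_ab + mean_ba)


def anosim_r_bruteforce(dist_square, labels):
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = rankdata([dist_square[i][j] for i, j in pairs])
    within = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    m = len(pairs)
    return (np.mean(between) - np.mean(within)) / (m / 2.0)


def anosim_exhaustive_p(dist_square, labels):
    """Exact p over all distinct arrangements of the label multiset."""
    r_obs = anosim_r_bruteforce(dist_square, labels)
    perms = sorted(set(itertools.permutations(labels)))
    stats = [anosim_r_bruteforce(dist_square, list(p)) for p in perms]
    return sum(s >= r_obs - 1e-12 for s in stats) / len(stats), len(stats)


def mantel_r_bruteforce(d1, d2):
    n = d1.shape[0]
    x = [d1[i][j] for i in range(n) for j in range(i + 1, n)]
    y = [d2[i][j] for i in range(n) for j in range(i + 1, n)]
    return float(np.corrcoef(x, y)[0, 1])


def mantel_exhaustive_p(d1, d2):
    n = d1.shape[0]
    r_obs = mantel_r_bruteforce(d1, d2)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        d2p = d2[np.ix_(perm, perm)]
        if mantel_r_bruteforce(d1, d2p) >= r_obs - 1e-12:
            count += 1
        total += 1
    return count / total, total


def simper_contributions_bruteforce(counts, taxa, labels, group_a, group_b):
    """Average per-taxon contribution over between-group pairs, as a dict."""
    cols_a = [k for k, g in enumerate(labels) if g == group_a]
    cols_b = [k for k, g in enumerate(labels) if g == group_b]
    contrib = {t: 0.0 for t in taxa}
    n_pairs = 0
    for j in cols_a:
        for k in cols_b:
            denom = sum(counts[i][j] + counts[i][k] for i in range(len(taxa)))
            for i, t in enumerate(taxa):
                contrib[t] += abs(counts[i][j] - counts[i][k]) / denom
            n_pairs += 1
    return {t: v / n_pairs for t, v in contrib.items()}


def beta_mntd_null_tip_shuffle(F, tree, taxa, n_null, seed):
    """Null betaMNTD distribution by permuting tip labels on the tree object.

    Independent route to the package's patristic-row/column permutation:
    relabels the tree's tips, rebuilds the tip-tip distances, and evaluates
    betaMNTD with explicit loops.  Must consume the same RNG stream
    contract: one permutation of taxon indices per randomization.
    """
    rng = np.random.default_rng(seed)
    n_samples = F.shape[0]
    results = np.empty((n_null, n_samples, n_samples))
    for r in range(n_null):
        perm = rng.permutation(len(taxa))
        # community occupying taxon i moves onto tip perm[i]: rename tip
        # taxa[perm[i]] back to taxa[i] on a copy and walk that tree
        relabeled = tree.copy()
        new_name = {taxa[int(perm[i])]: taxa[i] for i in range(len(taxa))}
        for tip in relabeled.tips():
            tip.name = new_name[tip.name]

        def d_shuffled(t1, t2, _tree=relabeled):
            return 0.0 if t1 == t2 else patristic_pair(_tree, t1, t2)

        for a in range(n_samples):
            for b in range(n_samples):
                results[r, a, b] = beta_mntd_bruteforce(
                    F[a], F[b], taxa, d_shuffled
                )
    return results
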