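"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (explicit rank counting,
exhaustive enumeration, explicit covariance-matrix GLS) and deliberately
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def ranks_by_counting(values):
    """Midranks computed by pairwise comparison counting (no sorting library)."""
    values = list(values)
    out = []
    for xi in values:
        less = sum(1 for xj in values if xj < xi)
        equal = sum(1 for xj in values if xj == xi)
        out.append(less + (equal + 1) / 2.0)
    return out


def kruskal_h_oracle(groups):
    """Tie-corrected Kruskal-Wallis H from the explicit rank formula."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    r = ranks_by_counting(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rg = r[start:start + len(g)]
        start += len(g)
        rbar = sum(rg) / len(rg)
        h += len(g) * (rbar - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    # tie correction
    ties = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        ties += t ** 3 - t
    denom = 1.0 - ties / (n ** 3 - n)
    return h / denom


def mannwhitney_exact_p_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free data).

    Enumerates every assignment of the pooled values into a group of size
    len(x); the p-value sums both tails of the exact U distribution at the
    observed statistic.
    """
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n, m = len(x), len(y)

    def u_of(subset):
        rest = [v for v in pooled if v not in subset]
        return sum(1 for a in subset for b in rest if a > b)

    u_obs = u_of(x)
    lo, hi = min(u_obs, n * m - u_obs), max(u_obs, n * m - u_obs)
    count = total = 0
    for combo in itertools.combinations(pooled, n):
        u = u_of(list(combo))
        total += 1
        if u <= lo or u >= hi:
            count += 1
    return count / total


def pearson_permutation_p_oracle(x, y, n_perm=20000, seed=0):
    """Two-sided permutation p for the Pearson correlation."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    r_obs = abs(corr(x, y))
    hits = 0
    for _ in range(n_perm):
        hits += abs(corr(x, rng.permutation(y))) >= r_obs - 1e-12
    return hits / n_perm


def gls_asr_oracle(model):
    """Per-node ancestral estimates by explicit re-rooted matrix GLS.

    For every internal node, builds the tip covariance of the tree re-rooted
    at that node (entry i,j = path length from the node to the point where
    the paths to tips i and j diverge) and evaluates
    (1' C^-1 1)^-1 1' C^-1 x directly.  No message passing, no shortcuts.
    """
    tree = model.phylogeny.tree
    leaves = list(tree.leaf_node_iter())
    blen = model._blen

    adj = {}
    for nd in tree.preorder_node_iter():
        adj.setdefault(nd, [])
        if nd.parent_node is not None:
            length = blen[nd]
            adj[nd].append((nd.parent_node, length))
            adj.setdefault(nd.parent_node, []).append((nd, length))

    out = {}
    for root in tree.preorder_internal_node_iter():
        dist = {root: 0.0}
        prev = {root: None}
        stack = [root]
        while stack:
            u = stack.pop()
            for v, length in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + length
                    prev[v] = u
                    stack.append(v)

        def path_to(a):
            nodes = []
            while a is not None:
                nodes.append(a)
                a = prev[a]
            return nodes

        n = len(leaves)
        C = np.zeros((n, n))
        paths = [path_to(lf) for lf in leaves]
        for i in range(n):
            C[i, i] = dist[leaves[i]]
            si = set(paths[i])
            for j in range(i + 1, n):
                meet = next(u for u in paths[j] if u in si)
                C[i, j] = C[j, i] = dist[meet]
        x = np.array([model.tip_values[lf.taxon.label] for lf in leaves])
        one = np.ones(n)
        Ci = np.linalg.inv(C)
        out[model._internal_ids[root]] = float(one @ Ci @ x / (one @ Ci @ one))
    return out
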