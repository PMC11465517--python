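"""Independent oracles used by the test-suite and acceptance checks.

These deliberately avoid the package's pruning/DP code paths: likelihoods by
exhaustive summation over internal-node states, parsimony costs by exhaustive
enumeration of ancestral assignments, and statistics from first-principles
formulas.
"""

import itertools

import numpy as np
from scipy.linalg import expm

from mitorates.alignment import GAP_CODE
from mitorates.likelihood import discretize_gamma


def enumeration_loglik(tree, msa, model):
    """Log-likelihood by brute-force summation over all internal states.

    Uses scipy's expm for the transition matrices (independent of the
    model's eigendecomposition path) and sums over every assignment of the
    20 states to every internal node.  Exponential cost: <= 4 tips only.
    """
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    tips = tree.tip_ids
    rates = discretize_gamma(model.alpha, model.n_categories)
    sub = msa.subset([tree.labels[t] for t in tips])
    codes = sub.data  # (n_tips, n_sites)
    n_sites = codes.shape[1]
    pi = model.frequencies
    site_L = np.zeros(n_sites)
    for r in rates:
        P = {
            v: expm(model.Q * (tree.lengths[v] * r))
            for v in range(tree.n_nodes)
            if tree.parent[v] >= 0
        }
        total = np.zeros(n_sites)
        for combo in itertools.product(range(20), repeat=len(internals)):
            st = dict(zip(internals, combo))
            w = pi[st[tree.root]] * np.ones(n_sites)
            for v in internals:
                p = tree.parent[v]
                if p >= 0:
                    w *= P[v][st[p], st[v]]
            for ti, v in enumerate(tips):
                obs = codes[ti]
                pv = P[v][st[tree.parent[v]]]
                contrib = np.where(obs >= GAP_CODE, 1.0, pv[np.minimum(obs, 19)])
                w = w * contrib
            total += w
        site_L += total / len(rates)
    return float(np.log(site_L).sum())


def exhaustive_sankoff_cost(tip_counts, tree, max_count):
    """Minimum linear-cost ancestral assignment by full enumeration."""
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    tips = tree.tip_ids
    best = np.inf
    for combo in itertools.product(range(max_count + 1), repeat=len(internals)):
        st = dict(zip(internals, combo))
        for t in tips:
            st[t] = tip_counts[tree.labels[t]]
        cost = sum(
            abs(st[v] - st[int(tree.parent[v])])
            for v in range(tree.n_nodes)
            if tree.parent[v] >= 0
        )
        best = min(best, cost)
    return int(best)


def kruskal_H_by_hand(groups):
    """Tie-corrected Kruskal-Wallis H from the rank-sum definition."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty_like(pooled)
    sorted_vals = pooled[order]
    i = 0
    r = np.arange(1, pooled.size + 1, dtype=float)
    while i < pooled.size:
        j = i
        while j < pooled.size and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = r[i:j].mean()
        i = j
    N = pooled.size
    H = 0.0
    start = 0
    for g in groups:
        n = len(g)
        R = ranks[start : start + n].sum()
        H += R * R / n
        start += n
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
    return H / tie


def spearman_d2(x, y):
    """Spearman rho via the classic 1 - 6*sum(d^2)/(n(n^2-1)) (no ties)."""
    x = np.asarray(x)
    y = np.asarray(y)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = ((rx - ry) ** 2).sum()
    n = x.size
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def gamma_category_means_quadrature(alpha, k):
    """Discrete-gamma category rates by numerical integration."""
    from scipy.integrate import quad
    from scipy.stats import gamma as gd

    qs = gd.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    qs[0], qs[-1] = 0.0, np.inf
    out = []
    for a, b in zip(qs[:-1], qs[1:]):
        ub = b if np.isfinite(b) else gd.ppf(1 - 1e-14, a=alpha, scale=1 / alpha)
        val, _ = quad(
            lambda x: x * gd.pdf(x, a=alpha, scale=1.0 / alpha), a, ub,
            limit=200,
        )
        out.append(val * k)
    return np.asarray(out)
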