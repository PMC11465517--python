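"""Gene-family copy-number evolution on the time tree.

Two analyses operate on an orthogroup-by-species copy-number matrix:

* **Ancestral reconstruction** — Sankoff dynamic programming assigns integer
  copy numbers to internal nodes minimising the total linear cost
  ``sum |child - parent|``; per-branch deltas are then classed as
  expansions / contractions.
* **Discriminative family selection** — a shadow-feature (Boruta-style)
  random-forest procedure finds families whose copy numbers separate two
  labelled species groups: each iteration appends a permuted copy of every
  family, fits an ensemble of trees, and counts which real families beat the
  best shadow importance; families are then confirmed/rejected by a
  Bonferroni-corrected two-sided binomial test on the hit counts, and the
  remaining tentative families are resolved by a rough fix comparing their
  median importance with the median shadow maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

from .trees import TimeTree

__all__ = [
    "AncestralReconstruction",
    "FeatureDecision",
    "reconstruct_ancestral_counts",
    "branch_change_summary",
    "select_discriminative_families",
    "run_group_contrasts",
]


@dataclass
class AncestralReconstruction:
    family: str
    node_counts: np.ndarray       # copy number per node id
    deltas: np.ndarray            # child - parent per node (0 at root)
    cost: int

    def branch_class(self, v: int) -> str:
        d = self.deltas[v]
        return "expansion" if d > 0 else "contraction" if d < 0 else "stable"


def reconstruct_ancestral_counts(
    counts: Mapping[str, int],
    tree: TimeTree,
    max_count: int | None = None,
    family: str = "",
) -> AncestralReconstruction:
    """Minimum-cost ancestral copy numbers under linear cost |child - parent|.

    Sankoff dynamic programming over states 0..max_count (default: max tip
    count + 2, allowing modest overshoot at ancestors).  Ties are broken by
    the smallest count, at the root and at every traceback step, so the
    reconstruction is unique and invariant to tip ordering.
    """
    tip_max = max(counts[tree.labels[t]] for t in tree.tip_ids)
    if max_count is None:
        max_count = tip_max + 2
    if max_count < tip_max:
        raise ValueError(
            f"max_count={max_count} below the largest tip count {tip_max}"
        )
    S = max_count + 1
    states = np.arange(S)
    diff = np.abs(states[:, None] - states[None, :])  # cost parent s -> child c
    INF = np.inf
    cost = np.full((tree.n_nodes, S), 0.0)
    for v in tree.postorder():
        if not tree.children[v]:
            sp = tree.labels[v]
            c = counts[sp]
            if c < 0:
                raise ValueError(f"negative count for {sp}")
            cost[v] = INF
            cost[v, c] = 0.0
        else:
            total = np.zeros(S)
            for u in tree.children[v]:
                total += (diff + cost[u][None, :]).min(axis=1)
            cost[v] = total
    node_counts = np.zeros(tree.n_nodes, dtype=int)
    root_costs = cost[tree.root]
    best = float(root_costs.min())
    node_counts[tree.root] = int(np.flatnonzero(root_costs == best)[0])
    for v in tree.preorder():
        for u in tree.children[v]:
            s = node_counts[v]
            through = np.abs(s - states) + cost[u]
            node_counts[u] = int(np.flatnonzero(through == through.min())[0])
    deltas = np.zeros(tree.n_nodes, dtype=int)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0:
            deltas[v] = node_counts[v] - node_counts[p]
    assert int(np.abs(deltas).sum()) == int(best)
    return AncestralReconstruction(family, node_counts, deltas, int(best))


def branch_change_summary(
    reconstructions: Mapping[str, AncestralReconstruction],
    tree: TimeTree,
    meta=None,
) -> pd.DataFrame:
    """Per-branch tallies of expansions and contractions across families.

    Each branch is identified by its child node id (and tip label when
    terminal).  When metadata is given, each branch is also labelled with the
    species group of the tips below it ('mixed' when they disagree), so
    group-level aggregation is a groupby away.
    """
    exp = np.zeros(tree.n_nodes, dtype=int)
    con = np.zeros(tree.n_nodes, dtype=int)
    for rec in reconstructions.values():
        exp += rec.deltas > 0
        con += rec.deltas < 0
    rows = []
    for v in range(tree.n_nodes):
        if tree.parent[v] < 0:
            continue
        tips = [tree.labels[t] for t in tree.clade_tips(v)]
        grp = "none"
        if meta is not None:
            gs = {meta.group.get(t, "diploid") for t in tips}
            grp = gs.pop() if len(gs) == 1 else "mixed"
        rows.append(
            {
                "node": v,
                "label": tree.labels[v] if not tree.children[v] else "",
                "n_tips": len(tips),
                "group": grp,
                "expansions": int(exp[v]),
                "contractions": int(con[v]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FeatureDecision:
    """Outcome of shadow-feature selection for every family."""

    status: pd.Series                 # family -> confirmed/tentative/rejected
    hits: pd.Series                   # times family beat the best shadow
    n_iterations: int
    importance_history: pd.DataFrame  # iterations x families
    shadow_max_history: np.ndarray

    @property
    def confirmed(self) -> list[str]:
        return list(self.status.index[self.status == "confirmed"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": self.status.index,
                "status": self.status.values,
                "hits": self.hits.values,
                "n_iterations": self.n_iterations,
                "median_importance": self.importance_history.median(axis=0).values,
            }
        )


def select_discriminative_families(
    matrix: pd.DataFrame,
    labels: Mapping[str, int] | pd.Series,
    n_iterations: int = 30,
    fwer: float = 0.01,
    seed: int = 0,
    n_trees: int = 500,
) -> FeatureDecision:
    """Shadow-feature selection of families separating two species classes.

    ``matrix`` is families x species; ``labels`` maps species to 0/1.  Per
    iteration every family column is permuted into a shadow feature, a
    random forest (``n_trees`` trees, mean-decrease-in-impurity importance)
    is fitted on real+shadow features, and a family scores a hit when its
    importance exceeds the iteration's maximum shadow importance.  After
    ``n_iterations`` a family is confirmed (rejected) when its two-sided
    binomial test of hits against 0.5 is significant at ``fwer`` with a
    Bonferroni correction over families and the hit rate is above (below)
    half; remaining tentative families are confirmed by the rough fix iff
    their median importance exceeds the median of the per-iteration shadow
    maxima.
    """
    labels = pd.Series(labels)
    species = [sp for sp in matrix.columns if sp in labels.index]
    y = labels[species].to_numpy()
    if len(np.unique(y)) != 2 or min(np.bincount(y)) < 2:
        raise ValueError("labels must define two classes with >= 2 species each")
    if n_iterations < 20:
        raise ValueError("n_iterations must be >= 20 for a meaningful test")
    X = matrix[species].to_numpy(dtype=float).T  # species x families
    n_fam = X.shape[1]
    fams = list(matrix.index)
    rng = np.random.default_rng(seed)
    hits = np.zeros(n_fam, dtype=int)
    imp_hist = np.empty((n_iterations, n_fam))
    shadow_max = np.empty(n_iterations)
    for it in range(n_iterations):
        shadows = np.empty_like(X)
        for j in range(n_fam):
            shadows[:, j] = X[rng.permutation(X.shape[0]), j]
        Xfull = np.hstack([X, shadows])
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(Xfull, y)
        imp = rf.feature_importances_
        real, shad = imp[:n_fam], imp[n_fam:]
        smax = shad.max() if shad.size else 0.0
        shadow_max[it] = smax
        hits += real > smax
        imp_hist[it] = real
    status = np.full(n_fam, "tentative", dtype=object)
    alpha = fwer / max(n_fam, 1)  # Bonferroni over families
    for j in range(n_fam):
        p = binomtest(int(hits[j]), n_iterations, 0.5).pvalue
        if p < alpha:
            status[j] = "confirmed" if hits[j] > n_iterations / 2 else "rejected"
    med_shadow = float(np.median(shadow_max))
    med_imp = np.median(imp_hist, axis=0)
    for j in range(n_fam):
        if status[j] == "tentative":
            status[j] = "confirmed" if med_imp[j] > med_shadow else "rejected"
    return FeatureDecision(
        pd.Series(status, index=fams, name="status"),
        pd.Series(hits, index=fams, name="hits"),
        n_iterations,
        pd.DataFrame(imp_hist, columns=fams),
        shadow_max,
    )


CONTRASTS = {
    "haplodiploid_vs_diploid": ("haplodiploid", "diploid"),
    "hymenoptera_vs_diploid": ("hymenoptera", "diploid"),
    "other_haplodiploid_vs_diploid": ("other_haplodiploid", "diploid"),
    "bees_ants_vs_sawflies_wasps": ("bees_ants", "sawflies_wasps"),
}


def run_group_contrasts(
    matrix: pd.DataFrame,
    meta,
    n_iterations: int = 30,
    fwer: float = 0.01,
    seed: int = 0,
    n_trees: int = 500,
) -> dict[str, FeatureDecision]:
    """The study's species-group contrasts, with shared settings.

    (a) all haplodiploids vs diploids, (b) hymenopterans vs diploids,
    (c) non-hymenopteran haplodiploids vs diploids, plus the within-order
    bees/ants vs sawflies/wasps contrast.  Contrasts with a class of fewer
    than 2 species are skipped with a warning.
    """
    out: dict[str, FeatureDecision] = {}
    ss = np.random.SeedSequence(seed).spawn(len(CONTRASTS))
    for (name, (pos, neg)), sub_seed in zip(CONTRASTS.items(), ss):
        pos_sp = [s for s in meta.members(pos) if s in matrix.columns]
        neg_sp = [s for s in meta.members(neg) if s in matrix.columns]
        if len(pos_sp) < 2 or len(neg_sp) < 2:
            warnings.warn(
                f"contrast {name}: class sizes {len(pos_sp)}/{len(neg_sp)} "
                "too small, skipped"
            )
            continue
        labels = pd.Series(
            {**{s: 1 for s in pos_sp}, **{s: 0 for s in neg_sp}}
        )
        out[name] = select_discriminative_families(
            matrix[pos_sp + neg_sp], labels, n_iterations=n_iterations,
            fwer=fwer, seed=int(sub_seed.generate_state(1)[0] % (2**31 - 1)),
            n_trees=n_trees,
        )
    return out
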