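"""Evolutionary rates: branch lengths over the chronogram.

The rate unit throughout is amino-acid substitutions per site per million
years (AA/site/MY).  Two per-species summaries are produced:

* *terminal rate* — the terminal branch length (substitutions/site) divided
  by the terminal branch duration (MY, i.e. the parent-node age on the
  ultrametric chronogram), so numerator and denominator cover the same tree
  segment;
* *root-to-tip rate* — the sum of branch lengths on the root-to-tip path
  divided by the root age.  Root-to-tip rates of different species share
  internal branches and are therefore not statistically independent; treat
  group comparisons of them as descriptive.
"""

from __future__ import annotations

import pandas as pd

from .trees import PhyloTree, TimeTree, TopologyMismatchError

__all__ = [
    "terminal_rate",
    "root_to_tip_rate",
    "build_rate_table",
    "age_rate_correlation",
]

RATE_COLUMNS = [
    "species",
    "category",
    "terminal_rate",
    "root_to_tip_rate",
    "terminal_duration",
    "root_age",
    "group",
    "subgroup",
]


def _check_match(phylo: PhyloTree, chrono: TimeTree) -> None:
    tips = set(phylo.tip_labels)
    if not tips <= set(chrono.tip_labels):
        raise TopologyMismatchError(
            "tree tips are not a subset of the chronogram's tips"
        )
    sub = chrono if tips == set(chrono.tip_labels) else chrono.prune_to(tips)
    if not phylo.same_topology(sub):
        raise TopologyMismatchError(
            "estimated tree and chronogram topologies differ"
        )


def terminal_rate(phylo: PhyloTree, chrono: TimeTree, species: str) -> float:
    """Terminal branch length / terminal branch duration (AA/site/MY)."""
    dur = chrono.terminal_duration(species)
    if dur <= 0:
        raise ValueError(
            f"degenerate chronogram: terminal branch of {species!r} has zero "
            "duration"
        )
    length = phylo.lengths[phylo.tip_index()[species]]
    return float(length / dur)


def root_to_tip_rate(phylo: PhyloTree, chrono: TimeTree, species: str) -> float:
    """Sum of root-to-tip branch lengths / root age (AA/site/MY)."""
    age = chrono.root_age
    if age <= 0:
        raise ValueError("degenerate chronogram: zero root age")
    tip = phylo.tip_index()[species]
    total = float(sum(phylo.lengths[v] for v in phylo.path_to_root(tip)))
    return total / age


def build_rate_table(
    category_trees: dict[str, PhyloTree],
    chrono: TimeTree,
    meta,
    check_topology: bool = True,
) -> pd.DataFrame:
    """Long-format rate table: one row per species x category.

    Species missing from a category's tree simply have no row (they are not
    zero-filled).  Group and subgroup labels are joined from the metadata.
    """
    rows = []
    root_age = chrono.root_age
    for cat, phylo in category_trees.items():
        if check_topology:
            _check_match(phylo, chrono)
        sub = (
            chrono
            if set(phylo.tip_labels) == set(chrono.tip_labels)
            else chrono.prune_to(set(phylo.tip_labels))
        )
        for sp in phylo.tip_labels:
            rows.append(
                {
                    "species": sp,
                    "category": cat,
                    "terminal_rate": terminal_rate(phylo, sub, sp),
                    "root_to_tip_rate": root_to_tip_rate(phylo, sub, sp),
                    "terminal_duration": sub.terminal_duration(sp),
                    "root_age": root_age,
                    "group": meta.group.get(sp, "diploid"),
                    "subgroup": meta.subgroup.get(sp, "none"),
                }
            )
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


def age_rate_correlation(table: pd.DataFrame, category: str):
    """Spearman correlation of terminal branch duration vs terminal rate.

    Computed overall and within each species group; returns a tidy frame
    with one row per stratum.  Rates estimated on short recent branches tend
    to exceed those on old saturated branches, which shows up here as a
    negative correlation.
    """
    from .stats import spearman

    sub = table[table["category"] == category]
    if len(sub) < 3:
        raise ValueError(
            f"need >= 3 rows for category {category!r}, found {len(sub)}"
        )
    rows = []
    strata = [("all", sub)] + [
        (g, sub[sub["group"] == g]) for g in sub["group"].unique()
    ]
    for name, part in strata:
        if len(part) < 3:
            rows.append({"stratum": name, "rho": float("nan"),
                         "p_value": float("nan"), "n": len(part)})
            continue
        res = spearman(
            part["terminal_duration"].to_numpy(),
            part["terminal_rate"].to_numpy(),
        )
        rows.append(
            {"stratum": name, "rho": res.rho, "p_value": res.p_value,
             "n": res.n}
        )
    return pd.DataFrame(rows, columns=["stratum", "rho", "p_value", "n"])
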