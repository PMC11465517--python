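"""Nonparametric group comparisons, rate correlations and subsampling designs.

* Kruskal-Wallis omnibus test (tie-corrected H, chi-square p) with the
  Siegel-Castellan multiple-comparison procedure on mean ranks as the
  post hoc step — the procedure behind the classic `kruskalmc` function.
* Spearman rank correlation with the t-approximation p value.
* Correlations of per-species evolutionary rates between a reference gene
  category (typically mtOXPHOS) and other categories, overall and within
  species strata, including derived complex-2 splits of nucOXPHOS.
* Two subsampling designs: the one-hymenopteran-at-a-time terminal-rate
  subsample (keeps divergence times comparable across subsamples) and
  matched control subsampling by gene count and family-size profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTestResult",
    "CorrelationResult",
    "kruskal_wallis",
    "kruskal_posthoc",
    "spearman",
    "category_correlations",
    "hymenopteran_subsample",
    "matched_control_subsample",
]


@dataclass
class GroupTestResult:
    H: float
    df: int
    p_value: float
    mean_ranks: dict[str, float]
    posthoc: pd.DataFrame | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        items = {str(k): np.asarray(v, float) for k, v in groups.items()}
    else:
        items = {f"group{i + 1}": np.asarray(v, float)
                 for i, v in enumerate(groups)}
    for name, x in items.items():
        if x.size == 0:
            raise ValueError(f"group {name!r} is empty")
    return items


def kruskal_wallis(groups) -> GroupTestResult:
    """Kruskal-Wallis rank test over >= 2 samples.

    Average ranks for ties, tie-corrected H, p from the chi-square
    approximation with k-1 degrees of freedom.  If every pooled value is
    identical the test is defined as H=0, p=1.
    """
    items = _as_groups(groups)
    if len(items) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    pooled = np.concatenate(list(items.values()))
    if pooled.size < 3:
        raise ValueError("kruskal_wallis needs a total of >= 3 observations")
    ranks = sps.rankdata(pooled)
    mean_ranks, i = {}, 0
    for name, x in items.items():
        mean_ranks[name] = float(ranks[i : i + x.size].mean())
        i += x.size
    if np.all(pooled == pooled[0]):
        return GroupTestResult(0.0, len(items) - 1, 1.0, mean_ranks)
    H, p = sps.kruskal(*items.values())
    return GroupTestResult(float(H), len(items) - 1, float(p), mean_ranks)


def kruskal_posthoc(groups, alpha: float = 0.05) -> pd.DataFrame:
    """Siegel-Castellan all-pairs comparison after Kruskal-Wallis.

    Pair (i, j) is significant iff
    ``|R_i - R_j| >= z_{1 - alpha/(k(k-1))} * sqrt(N(N+1)/12 * (1/n_i + 1/n_j))``
    where R are mean ranks of the pooled data.  Returns one row per pair with
    the observed and critical differences and the decision.
    """
    items = _as_groups(groups)
    k = len(items)
    if k < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(list(items.values()))
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, i = {}, {}, 0
    for name, x in items.items():
        mean_ranks[name] = float(ranks[i : i + x.size].mean())
        sizes[name] = x.size
        i += x.size
    z = sps.norm.ppf(1.0 - alpha / (k * (k - 1)))
    names = list(items)
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            ga, gb = names[a], names[b]
            obs = abs(mean_ranks[ga] - mean_ranks[gb])
            crit = z * np.sqrt(
                N * (N + 1) / 12.0 * (1.0 / sizes[ga] + 1.0 / sizes[gb])
            )
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "observed_diff": obs,
                    "critical_diff": float(crit),
                    "significant": bool(obs >= crit),
                }
            )
    return pd.DataFrame(rows)


def kruskal_wallis_with_posthoc(groups, alpha: float = 0.05) -> GroupTestResult:
    res = kruskal_wallis(groups)
    res.posthoc = kruskal_posthoc(groups, alpha=alpha)
    return res


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation; p value from the t approximation (n-2 df).

    Ties get average ranks in both vectors.  Zero rank variance (a constant
    vector) is an error rather than a silent NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("spearman needs n >= 3")
    for name, v in (("x", x), ("y", y)):
        if np.all(v == v[0]):
            raise ValueError(
                f"zero variance in the ranks of {name}: correlation undefined"
            )
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), int(x.size))


_DEFAULT_STRATA = ("all", "diploid", "bees_ants", "sawflies_wasps",
                   "other_haplodiploid")


def _stratum_mask(table: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=table.index)
    if stratum in ("bees_ants", "sawflies_wasps"):
        return table["subgroup"] == stratum
    return table["group"] == stratum


def category_correlations(
    table: pd.DataFrame,
    reference: str = "mtOXPHOS",
    others: Sequence[str] | None = None,
    strata: Sequence[str] = _DEFAULT_STRATA,
    rate_type: str = "root_to_tip_rate",
) -> pd.DataFrame:
    """Spearman correlation of per-species rates: reference vs each category.

    Computed over the species present in both categories, overall and within
    each stratum.  Cells with fewer than 3 shared species get NaN with a note
    instead of failing.  Derived categories such as a complex-2-only or
    complex-2-excluded nucOXPHOS set participate like any other category as
    long as the rate table contains rows for them.
    """
    if others is None:
        others = [c for c in table["category"].unique() if c != reference]
    ref = table[table["category"] == reference]
    rows = []
    for other in others:
        oth = table[table["category"] == other]
        merged = ref.merge(
            oth[["species", rate_type]], on="species", suffixes=("", "_other")
        )
        for stratum in strata:
            part = merged[_stratum_mask(merged, stratum)]
            row = {"reference": reference, "category": other,
                   "stratum": stratum, "n": len(part)}
            if len(part) < 3:
                row.update(rho=np.nan, p_value=np.nan,
                           note="insufficient overlap")
            else:
                try:
                    res = spearman(
                        part[rate_type].to_numpy(),
                        part[f"{rate_type}_other"].to_numpy(),
                    )
                    row.update(rho=res.rho, p_value=res.p_value, note="")
                except ValueError as exc:
                    row.update(rho=np.nan, p_value=np.nan, note=str(exc))
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["reference", "category", "stratum", "n", "rho", "p_value",
                 "note"],
    )


def hymenopteran_subsample(
    meta,
    estimator: Callable[[list[str]], Mapping[str, float]],
    group: str = "hymenoptera",
) -> pd.DataFrame:
    """One-at-a-time subsampled terminal rates for a densely sampled group.

    For each member h of ``group`` the estimator is called on
    ``{h} + all species outside the group`` (so every subsample shares the
    same divergence-time structure) and h's terminal rate is recorded; each
    member is used exactly once.  Estimation failures are recorded as NaN
    with a warning and the run continues.
    """
    focal = meta.members(group)
    if not focal:
        raise ValueError(f"no species in group {group!r}")
    others = [sp for sp in meta.species if sp not in set(focal)]
    rows = []
    for h in focal:
        try:
            rates = estimator([h] + others)
            rate = float(rates[h])
        except Exception as exc:  # noqa: BLE001 - keep going per design
            warnings.warn(f"subsample for {h} failed: {exc}")
            rate = float("nan")
        rows.append({"species": h, "terminal_rate": rate,
                     "subgroup": meta.subgroup.get(h, "none")})
    return pd.DataFrame(rows, columns=["species", "terminal_rate", "subgroup"])


def matched_control_subsample(
    pool_presence: Mapping[str, int],
    target_presence: Iterable[int],
    estimator: Callable[[list[str]], Mapping[str, float]],
    n_reps: int = 1000,
    seed: int = 0,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Control-gene subsampling matched on gene count and family size.

    ``pool_presence`` maps each control group id to its species-presence
    count (the family-size proxy); ``target_presence`` is the same profile
    for the target category.  Each replicate draws, without replacement, a
    control subset whose size and per-decile presence profile match the
    target; the estimator maps a list of group ids to per-species rates.
    When a bin cannot supply enough groups the deficit is drawn from the
    nearest bins with a warning.  Returns a long table (replicate, species,
    rate) plus, per replicate, the Spearman correlation of its rates with
    the full-pool rates in ``df.attrs['full_pool_correlations']``.
    """
    pool_ids = list(pool_presence)
    target = np.asarray(list(target_presence))
    if len(pool_ids) < target.size:
        raise ValueError("control pool smaller than the target gene count")
    pool_counts = np.asarray([pool_presence[g] for g in pool_ids])
    edges = np.quantile(pool_counts, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    def _bin(x):
        return np.clip(np.searchsorted(edges, x, side="right") - 1, 0,
                       len(edges) - 2)
    pool_bins = _bin(pool_counts)
    target_bins, target_need = np.unique(_bin(target), return_counts=True)
    by_bin = {bi: np.flatnonzero(pool_bins == bi) for bi in range(len(edges) - 1)}
    rng = np.random.default_rng(seed)
    full_rates = dict(estimator(pool_ids))
    species = sorted(full_rates)
    full_vec = np.array([full_rates[s] for s in species])
    rows, corrs = [], []
    for rep in range(n_reps):
        chosen: list[int] = []
        taken = set()
        for bi, need in zip(target_bins, target_need):
            cands = [i for i in by_bin.get(int(bi), []) if i not in taken]
            if len(cands) < need:
                warnings.warn(
                    f"bin {bi}: only {len(cands)} of {need} control groups; "
                    "relaxing to nearest bins"
                )
                extra = [
                    i
                    for bj in sorted(by_bin, key=lambda b: abs(b - bi))
                    for i in by_bin[bj]
                    if i not in taken and i not in cands
                ]
                cands = cands + extra[: need - len(cands)]
            pick = rng.choice(len(cands), size=int(need), replace=False)
            sel = [cands[int(j)] for j in pick]
            chosen.extend(sel)
            taken.update(sel)
        rates = dict(estimator([pool_ids[i] for i in chosen]))
        rep_vec = np.array([rates.get(s, np.nan) for s in species])
        ok = ~np.isnan(rep_vec)
        corr = (
            spearman(rep_vec[ok], full_vec[ok]).rho if ok.sum() >= 3 else np.nan
        )
        corrs.append(corr)
        for s in species:
            if s in rates:
                rows.append({"replicate": rep, "species": s,
                             "rate": float(rates[s])})
    df = pd.DataFrame(rows, columns=["replicate", "species", "rate"])
    df.attrs["full_pool_correlations"] = corrs
    return df
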