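"""Ecogenomic trait comparisons from functional annotation counts.

Covers the cellulolytic designation (presence of endoglucanase-containing
CAZy families), size-normalized trait abundances (rcpm), trait tables,
Bray-Curtis dissimilarity between units, and nonparametric group tests
(rank-sum / Kruskal-Wallis).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, mannwhitneyu, rankdata

# Endoglucanase-containing glycosyl hydrolase and lytic polysaccharide
# monooxygenase families conferring cellulolytic ability.  GH5 counts only
# via its listed subfamilies; GH61 is canonicalized to its AA9 alias.
_GH5_SUBFAMILIES = (
    1, 2, 4, 5, 7, 8, 9, 11, 12, 13, 15, 16, 18, 19, 22, 23, 24, 25, 26, 27,
    28, 29, 30, 31, 36, 37, 38, 39, 40, 41, 43, 44, 45, 46, 47, 48, 49, 50, 51, 53,
)
ENDOGLUCANASE_FAMILIES: frozenset[str] = frozenset(
    {f"GH5_{i}" for i in _GH5_SUBFAMILIES}
    | {"GH6", "GH7", "GH8", "GH9", "GH12", "GH44", "GH45", "GH48", "GH51",
       "AA9", "GH74", "GH124", "GH131", "AA10"}
)

CHITINASE_FAMILIES: frozenset[str] = frozenset({"GH18", "GH19"})


def canonical_family(family: str) -> str:
    """Canonical family label: trimmed, GH5(4)→GH5_4, GH61→AA9."""
    fam = family.strip().replace("(", "_").rstrip(")").replace(")", "")
    if fam == "GH61":
        return "AA9"
    return fam


def is_cellulolytic(records: pd.DataFrame | dict) -> bool:
    """True iff any annotated family with count > 0 is an endoglucanase family.

    Accepts a long-format records frame (family, count columns) or a
    plain family→count mapping.  Monotone: adding annotations never
    flips True to False.
    """
    if isinstance(records, dict):
        items = records.items()
    else:
        items = zip(records["family"], records["count"])
    return any(
        count > 0 and canonical_family(str(fam)) in ENDOGLUCANASE_FAMILIES
        for fam, count in items
    )


def rcpm(count: float, unit_size: float) -> float:
    """Size-normalized abundance: count × 10⁶ / unit size.

    The default denominator is the unit's size in bases (counts per
    megabase); pass the unit's total mapped reads instead for a
    per-million-mapped-reads normalization.
    """
    if unit_size <= 0:
        raise ValueError(f"unit size must be > 0, got {unit_size}")
    return count * 1e6 / unit_size


@dataclass
class TraitTable:
    """Units × features matrix of rcpm-normalized abundances."""

    values: pd.DataFrame  # units x features, rcpm
    sizes: pd.Series  # bp per unit
    groups: pd.Series | None = None  # group label per unit


def build_trait_table(
    annotations: pd.DataFrame,
    sizes: pd.Series | dict,
    groups: pd.Series | dict | None = None,
    level: str = "family",
) -> TraitTable:
    """Aggregate annotation counts per unit and rcpm-normalize.

    ``level`` selects the feature granularity: "family" or "class"
    (class-level cells are the sums of their family-level cells).
    """
    sizes = pd.Series(sizes, dtype=float)
    key = "family" if level == "family" else "feature_class"
    missing = set(annotations["unit_id"]) - set(sizes.index)
    if missing:
        raise ValueError(f"unit missing size: '{sorted(missing)[0]}'")
    counts = (
        annotations.groupby(["unit_id", key])["count"].sum().unstack(fill_value=0.0)
    )
    counts = counts.reindex(sizes.index, fill_value=0.0)
    values = counts.div(sizes, axis=0) * 1e6
    grp = pd.Series(groups) if groups is not None else None
    return TraitTable(values=values, sizes=sizes, groups=grp)


def bray_curtis(table: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix between unit rows.

    d(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), in [0, 1] for non-negative data.
    """
    if isinstance(table, TraitTable):
        table = table.values
    df = pd.DataFrame(table)
    if len(df) < 2:
        raise ValueError("need at least 2 units")
    x = df.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires non-negative entries")
    d = squareform(pdist(x, metric="braycurtis"))
    if np.any(~np.isfinite(d)):
        raise ValueError("a pair of units has all-zero combined rows")
    return pd.DataFrame(d, index=df.index, columns=df.index)


def _kruskal_h(values: np.ndarray, labels: np.ndarray) -> float:
    n = len(values)
    _, counts = np.unique(values, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n) if n > 1 else 1.0
    if tie == 0:  # all values identical: no rank information, H = 0
        return 0.0
    ranks = rankdata(values)
    h = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return h / tie


def _label_arrangements(labels: np.ndarray):
    """Yield every distinct assignment of the label multiset to positions."""
    uniq, counts = np.unique(labels, return_counts=True)
    n = len(labels)

    def rec(positions: tuple[int, ...], k: int, acc: dict):
        if k == len(uniq) - 1:
            out = dict(acc)
            for p in positions:
                out[p] = uniq[k]
            arr = np.empty(n, dtype=labels.dtype)
            for p, lab in out.items():
                arr[p] = lab
            yield arr
            return
        for chosen in combinations(positions, int(counts[k])):
            acc2 = dict(acc)
            for p in chosen:
                acc2[p] = uniq[k]
            rest = tuple(p for p in positions if p not in chosen)
            yield from rec(rest, k + 1, acc2)

    yield from rec(tuple(range(n)), 0, {})


def _kruskal_exact_p(values: np.ndarray, labels: np.ndarray) -> float:
    """Exact permutation p for the Kruskal-Wallis H statistic (small n)."""
    h_obs = _kruskal_h(values, labels)
    n_ge = 0
    n_tot = 0
    for arr in _label_arrangements(labels):
        n_tot += 1
        if _kruskal_h(values, arr) >= h_obs - 1e-12:
            n_ge += 1
    return n_ge / n_tot


def compare_groups(
    values, group_labels, method: str = "wilcoxon", exact_n: int = 10
) -> tuple[float, float]:
    """Rank-based comparison of ≥2 groups; returns (statistic, p-value).

    ``wilcoxon`` is the two-group rank-sum test (statistic W = sum of the
    first group's ranks); ``kruskal`` the Kruskal-Wallis H test.  When
    the total sample size is ≤ ``exact_n`` the p-value is computed by
    exact permutation enumeration, otherwise by the usual large-sample
    approximation.  Two-sided throughout.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    n = len(values)
    if method == "wilcoxon":
        if len(groups) != 2:
            raise ValueError("wilcoxon requires exactly 2 groups")
        ranks = rankdata(values)
        w = float(ranks[labels == pd.unique(labels)[0]].sum())
        res = mannwhitneyu(
            groups[0], groups[1], alternative="two-sided",
            method="exact" if n <= exact_n else "asymptotic",
        )
        return w, float(res.pvalue)
    if method == "kruskal":
        h = _kruskal_h(values, labels)
        if n <= exact_n:
            return h, _kruskal_exact_p(values, labels)
        return h, float(chi2.sf(h, df=len(groups) - 1))
    raise ValueError(f"unknown method {method!r}")
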