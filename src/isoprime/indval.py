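"""Indicator-value (IndVal) analysis with a permutation null.

For phylotype i and group g, specificity A is the group-equalized mean
abundance share, fidelity B the within-group occurrence frequency, and
IndVal their product:

    A_ig = mean_g(x_i) / sum_h mean_h(x_i)
    B_ig = (# group-g libraries with x_i > 0) / n_g
    IndVal_ig = A_ig * B_ig

The observed statistic for inference is the IndVal of the best group.
Because the best group is selected from the data, the default permutation
null recomputes the *maximum* IndVal across groups for every permuted
labeling ("max" statistic), which keeps the type-I error of the emitted
p-values at the nominal level.  The alternative "best" mode recomputes
IndVal for the observed best group only; it reaches the minimum attainable
p of 1/(N+1) on exhaustive designs but is anti-conservative for
data-selected groups.  Monte-Carlo p-values use the (1 + count) / (N + 1)
correction so p is never zero; on tiny designs where the number of
distinct label assignments does not exceed the requested permutation
count, the null is enumerated exhaustively instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .table import FeatureTable


class IndValError(ValueError):
    pass


@dataclass
class IndValResult:
    phylotype: str
    best_group: str
    specificity_a: float
    fidelity_b: float
    indval: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None


def _as_matrix(table) -> tuple[np.ndarray, list[str], list]:
    if isinstance(table, FeatureTable):
        df = table.counts
    else:
        df = pd.DataFrame(table)
    return df.to_numpy(dtype=float), list(df.columns), list(df.index)


def _group_stats(x: np.ndarray, group_idx: np.ndarray, n_groups: int,
                 group_sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-(phylotype, group) A and B matrices for abundance matrix x."""
    n_taxa = x.shape[0]
    means = np.zeros((n_taxa, n_groups))
    pres = np.zeros((n_taxa, n_groups))
    for g in range(n_groups):
        cols = group_idx == g
        means[:, g] = x[:, cols].mean(axis=1)
        pres[:, g] = (x[:, cols] > 0).sum(axis=1) / group_sizes[g]
    tot = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(tot > 0, means / np.where(tot == 0, 1.0, tot), 0.0)
    return a, pres


def indval_statistic(table, groups) -> pd.DataFrame:
    """A, B and IndVal for every phylotype x group, plus the best group.

    ``groups`` maps library id -> group label (mapping or Series).  A
    phylotype absent everywhere gets IndVal 0 in all groups.  Ties for the
    best group break by group label order (recorded as-is).
    """
    x, libs, taxa = _as_matrix(table)
    groups = pd.Series(groups)
    missing = [l for l in libs if l not in groups.index]
    if missing:
        raise IndValError(f"libraries without group label: {missing}")
    labels = groups.loc[libs]
    group_names = list(pd.unique(labels))
    if len(group_names) < 2:
        raise IndValError("need at least two groups")
    name_to_idx = {g: i for i, g in enumerate(group_names)}
    gidx = labels.map(name_to_idx).to_numpy()
    sizes = np.bincount(gidx, minlength=len(group_names))

    a, b = _group_stats(x, gidx, len(group_names), sizes)
    iv = a * b
    best = iv.argmax(axis=1)  # argmax takes the first (label-order) on ties
    rows = []
    for i, taxon in enumerate(taxa):
        for g, gname in enumerate(group_names):
            rows.append({
                "phylotype": taxon, "group": gname,
                "A": a[i, g], "B": b[i, g], "indval": iv[i, g],
                "best": g == best[i],
            })
    return pd.DataFrame(rows)


def _distinct_assignment_count(sizes: np.ndarray) -> int:
    n = int(sizes.sum())
    total = factorial(n)
    for s in sizes:
        total //= factorial(int(s))
    return total


def _distinct_assignments(gidx: np.ndarray):
    """All distinct arrangements of the group-label multiset (lexicographic)."""
    from sympy.utilities.iterables import multiset_permutations

    yield from (np.array(p) for p in multiset_permutations(sorted(gidx)))


def indval_permutation_test(table, groups, n_permutations: int = 999,
                            seed: int | None = None,
                            statistic: str = "max") -> pd.DataFrame:
    """IndVal with permutation p-values and BH-adjusted q-values.

    ``statistic`` selects the permuted test statistic: ``"max"`` (default)
    compares the observed best-group IndVal against the permutation
    distribution of the across-group maximum, which accounts for best-group
    selection; ``"best"`` recomputes IndVal for the observed best group
    only.
    """
    if n_permutations < 99:
        raise IndValError("need at least 99 permutations")
    if statistic not in ("max", "best"):
        raise IndValError(f"unknown statistic mode: {statistic}")
    x, libs, taxa = _as_matrix(table)
    groups = pd.Series(groups)
    labels = groups.loc[libs]
    group_names = list(pd.unique(labels))
    if len(group_names) < 2:
        raise IndValError("need at least two groups")
    name_to_idx = {g: i for i, g in enumerate(group_names)}
    gidx = labels.map(name_to_idx).to_numpy()
    sizes = np.bincount(gidx, minlength=len(group_names))
    n_groups = len(group_names)

    a, b = _group_stats(x, gidx, n_groups, sizes)
    iv = a * b
    best = iv.argmax(axis=1)
    obs = iv[np.arange(len(taxa)), best]

    def _perm_stat(perm):
        pa, pb = _group_stats(x, perm, n_groups, sizes)
        piv = pa * pb
        if statistic == "max":
            return piv.max(axis=1)
        return piv[np.arange(len(taxa)), best]

    n_distinct = _distinct_assignment_count(sizes)
    exhaustive = n_distinct <= n_permutations
    count_ge = np.zeros(len(taxa))
    if exhaustive:
        n_used = 0
        for perm in _distinct_assignments(gidx):
            count_ge += _perm_stat(perm) >= obs - 1e-12
            n_used += 1
        p = count_ge / n_used
    else:
        rng = np.random.default_rng(seed)
        n_used = n_permutations
        for _ in range(n_permutations):
            count_ge += _perm_stat(rng.permutation(gidx)) >= obs - 1e-12
        p = (1.0 + count_ge) / (n_used + 1.0)
    # constant (permutation-invariant) phylotypes get p = 1 by construction
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    return pd.DataFrame({
        "phylotype": taxa,
        "best_group": [group_names[g] for g in best],
        "A": a[np.arange(len(taxa)), best],
        "B": b[np.arange(len(taxa)), best],
        "indval": obs,
        "p_value": p,
        "q_value": q,
        "n_permutations": n_used,
        "exhaustive": exhaustive,
        "statistic": statistic,
        "seed": seed if not exhaustive else None,
    }).set_index("phylotype")
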