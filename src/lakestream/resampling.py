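"""Permutation-test engine with the study's bespoke test statistics.

All inference rests on label permutation: the response is re-shuffled
uniformly over the predictor B times and the p-value uses the add-one
convention p = (n_extreme + 1) / (B + 1), so the attainable floor is
exactly 1/(B+1) — 0.0001 at B=9999 (phenotype tests) and 0.001 at B=999
(F_ST tests). Difference statistics are compared two-sided via |T|;
chi-square and ANOVA-F, being non-negative, are one-sided.

Statistics
----------
``mean_diff``            lake-stream difference in group means (ages,
                         centroid sizes, fecundity, egg size).
``var_of_group_means``   difference in the variance of population mean
                         sizes between habitats (the permutation unit is
                         the population, not the individual).
``chi_square``           Pearson chi-square on a habitat x plate-morph
                         contingency table built from categorical
                         responses.
``anova_F``              one-way ANOVA F ratio (plate morph vs size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from lakestream.errors import InsufficientDataError


@dataclass
class PermutationResult:
    statistic_name: str
    observed: float
    n_perm: int
    n_extreme: int
    p_value: float
    seed: int
    sidedness: str  # "two_sided_abs" | "one_sided_ge"


@dataclass
class ContingencyTable:
    """Row x column category counts (e.g. habitat x plate morph)."""

    rows: list[str]
    cols: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.rows), len(self.cols)):
            raise ValueError("counts shape does not match row/col labels")
        if (self.counts < 0).any() or not np.issubdtype(
            self.counts.dtype, np.integer
        ):
            raise ValueError("counts must be non-negative integers")
        if self.counts.sum() == 0:
            raise ValueError("grand total must be > 0")


# ---------------------------------------------------------------------------
# statistics (public, directly computable forms)
# ---------------------------------------------------------------------------


def _clean_two_groups(
    values: Sequence[float], groups: Sequence[object], group_order
) -> tuple[np.ndarray, np.ndarray, list]:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = ~np.isnan(v)
    v, g = v[keep], g[keep]
    if group_order is None:
        order = list(dict.fromkeys(g.tolist()))
    else:
        order = list(group_order)
    if len(order) != 2:
        raise InsufficientDataError(
            f"mean_diff requires exactly 2 group levels, got {order}"
        )
    return v, g, order


def stat_mean_diff(
    values: Sequence[float],
    groups: Sequence[object],
    group_order: Sequence[object] | None = None,
) -> float:
    """mean(group A) - mean(group B); by convention A=lake, B=stream.

    Group order defaults to first appearance in ``groups``; pass
    ``group_order=("lake", "stream")`` to fix the sign convention.
    """
    v, g, order = _clean_two_groups(values, groups, group_order)
    a, b = v[g == order[0]], v[g == order[1]]
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError(
            f"empty group after missing-value removal ({order})"
        )
    return float(a.mean() - b.mean())


def stat_var_of_group_means(
    pop_means: Sequence[float],
    habitat_of_pop: Sequence[object],
    group_order: Sequence[object] | None = None,
) -> float:
    """var(habitat-A population means) - var(habitat-B means), n-1 denominator."""
    v, g, order = _clean_two_groups(pop_means, habitat_of_pop, group_order)
    a, b = v[g == order[0]], v[g == order[1]]
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            "variance of population means needs >= 2 populations per habitat"
        )
    return float(a.var(ddof=1) - b.var(ddof=1))


def stat_chi_square(t: ContingencyTable) -> float:
    """Pearson chi-square over cells with positive expectation.

    A degenerate table (a single non-empty row or column) gives 0 with a
    warning rather than an error: under permutation such tables can arise
    and carry no evidence of association.
    """
    counts = t.counts[t.counts.sum(axis=1) > 0][:, t.counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        warnings.warn("degenerate contingency table; chi-square set to 0")
        return 0.0
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = (counts - expected) ** 2 / expected
    return float(cells[expected > 0].sum())


def stat_anova_F(values: Sequence[float], groups: Sequence[object]) -> float:
    """One-way ANOVA F = MS_between / MS_within over k group levels."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = ~np.isnan(v)
    v, g = v[keep], g[keep]
    levels = list(dict.fromkeys(g.tolist()))
    k, n = len(levels), v.size
    if k < 2 or n - k < 1:
        raise InsufficientDataError("ANOVA needs >= 2 groups and residual df")
    grand = v.mean()
    ss_between = ss_within = 0.0
    for lev in levels:
        x = v[g == lev]
        ss_between += x.size * (x.mean() - grand) ** 2
        ss_within += ((x - x.mean()) ** 2).sum()
    if ss_within == 0.0:
        if ss_between == 0.0:
            warnings.warn("zero variance within and between groups; F set to 0")
            return 0.0
        return float("inf")
    return float((ss_between / (k - 1)) / (ss_within / (n - k)))


def contingency_from_labels(
    responses: Sequence[object], groups: Sequence[object]
) -> ContingencyTable:
    """Cross-tabulate categorical responses (e.g. plate morph) by group."""
    resp = np.asarray(responses, dtype=object)
    grp = np.asarray(groups, dtype=object)
    keep = np.array([r is not None for r in resp])
    resp, grp = resp[keep], grp[keep]
    rows = list(dict.fromkeys(grp.tolist()))
    cols = list(dict.fromkeys(resp.tolist()))
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: j for j, c in enumerate(cols)}
    for r, c in zip(grp, resp):
        counts[ri[r], ci[c]] += 1
    return ContingencyTable(rows, cols, counts)


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

# Each factory closes over the (fixed) responses and returns a fast function
# of the permuted labels only; the label vector is what gets shuffled.


def _factory_mean_diff(values, group_order):
    v = np.asarray(values, dtype=float)

    def stat(labels: np.ndarray) -> float:
        return stat_mean_diff(v, labels, group_order)

    return stat


def _factory_var_means(values, group_order):
    v = np.asarray(values, dtype=float)

    def stat(labels: np.ndarray) -> float:
        return stat_var_of_group_means(v, labels, group_order)

    return stat


def _factory_chi_square(values, group_order):
    resp = np.asarray(values, dtype=object)
    keep = np.array([r is not None for r in resp])
    cols = list(dict.fromkeys(resp[keep].tolist()))
    codes = np.array([cols.index(r) if r is not None else -1 for r in resp])

    def stat(labels: np.ndarray) -> float:
        grp = np.asarray(labels, dtype=object)[keep]
        c = codes[keep]
        rows = list(dict.fromkeys(grp.tolist()))
        counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
        for i, r in enumerate(rows):
            counts[i] = np.bincount(c[grp == r], minlength=len(cols))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return stat_chi_square(ContingencyTable(rows, cols, counts))

    return stat


def _factory_anova_F(values, group_order):
    v = np.asarray(values, dtype=float)

    def stat(labels: np.ndarray) -> float:
        return stat_anova_F(v, labels)

    return stat


STATISTICS: dict[str, tuple[Callable, str]] = {
    "mean_diff": (_factory_mean_diff, "two_sided_abs"),
    "var_of_group_means": (_factory_var_means, "two_sided_abs"),
    "chi_square": (_factory_chi_square, "one_sided_ge"),
    "anova_F": (_factory_anova_F, "one_sided_ge"),
}


def perm_test(
    values: Sequence,
    labels: Sequence[object],
    statistic: str = "mean_diff",
    B: int = 9999,
    seed: int = 0,
    group_order: Sequence[object] | None = None,
) -> PermutationResult:
    """Permutation test: shuffle ``labels`` B times, count extreme replicates.

    Ties (|T*| == |T_obs|, or T* == T_obs one-sided) count as extreme,
    and the observed arrangement enters via the add-one convention, so
    the test is exact-conservative: p = (n_extreme + 1)/(B + 1).

    For individual-level tests ``values`` are per-individual responses;
    for the population-level size-variance test pass the population mean
    sizes with one habitat label per population.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if statistic not in STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; options: {sorted(STATISTICS)}"
        )
    if len(values) != len(labels):
        raise ValueError("values and labels must have equal length")
    factory, sidedness = STATISTICS[statistic]
    stat = factory(values, group_order)
    label_arr = np.asarray(labels, dtype=object)
    observed = stat(label_arr)

    numeric = statistic in ("mean_diff", "var_of_group_means", "anova_F")
    if numeric:
        v = np.asarray(values, dtype=float)
        if np.nanstd(v) == 0.0:
            warnings.warn("constant response vector; p-value is 1")
            return PermutationResult(
                statistic, observed, B, B, 1.0, seed, sidedness
            )

    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(B):
        t = stat(label_arr[rng.permutation(label_arr.size)])
        if sidedness == "two_sided_abs":
            if abs(t) >= abs(observed):
                n_extreme += 1
        else:
            if t >= observed:
                n_extreme += 1
    p = (n_extreme + 1) / (B + 1)
    return PermutationResult(statistic, observed, B, n_extreme, p, seed, sidedness)
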