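"""Permutational ANOVA, pairwise permutation tests and pooled chi-square.

The one-way permutational ANOVA computes a pseudo-F from the partition of a
Euclidean distance matrix (the distance-based formulation generalises to
multivariate responses; on univariate data it reduces exactly to the
classical one-way ANOVA F). The null distribution comes from unrestricted
permutation of the raw observations across groups, with the p-value
convention p = (b + 1) / (m + 1), where b counts permuted statistics at
least as extreme as the observed one — this avoids reporting an exact zero
from a sampled null. An exhaustive mode enumerates every distinct group
assignment when that is feasible, in which case the p-value is exact and
seed-independent.

The chi-square contingency test on years-returned counts pools the two
highest return-year categories before testing so that the expected-count
assumption (more than 80% of cells above five) has a chance to hold on
sparse tables; the Pearson statistic is used without continuity correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 999
#: largest number of distinct assignments we are willing to enumerate
EXHAUSTIVE_LIMIT = 200_000


@dataclass
class PermAnovaResult:
    pseudo_F: float
    df_between: int
    df_within: int
    p_perm: float
    n_perm: int
    seed: int | None
    exhaustive: bool = False


@dataclass
class ChiSqResult:
    chi2: float
    df: int
    p: float
    pooled: bool
    expected_table: np.ndarray
    assumption_ok: bool


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, group_ids: np.ndarray) -> float:
    """Pseudo-F from the Euclidean distance partition.

    ``d2`` is the matrix of squared pairwise distances. SS_total =
    sum_{i<j} d_ij^2 / N and SS_within = sum over groups of the analogous
    within-group term; F = (SS_between/df_b) / (SS_within/df_w). For a
    univariate response this equals the classical ANOVA F, and permuting the
    group labels on a fixed distance matrix is the same operation as
    unrestricted permutation of the raw observations.
    """
    n = len(labels)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in group_ids:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    a = len(group_ids)
    df_b, df_w = a - 1, n - a
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        return math.inf if ss_total > ss_within else math.nan
    return ((ss_total - ss_within) / df_b) / ms_within


def _distinct_assignments(labels: np.ndarray):
    """Yield every distinct multiset permutation of the label vector."""
    seen_total = math.factorial(len(labels))
    _, counts = np.unique(labels, return_counts=True)
    for c in counts:
        seen_total //= math.factorial(int(c))
    if seen_total > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"{seen_total} distinct assignments exceed exhaustive limit {EXHAUSTIVE_LIMIT}")
    yield from _multiset_perms(sorted(labels.tolist()))


def _multiset_perms(pool: list):
    if not pool:
        yield ()
        return
    prev = object()
    for i, v in enumerate(pool):
        if v == prev:
            continue
        prev = v
        for rest in _multiset_perms(pool[:i] + pool[i + 1:]):
            yield (v, *rest)


def perm_anova_oneway(groups: dict[str, np.ndarray] | list[np.ndarray],
                      n_perm: int = DEFAULT_N_PERM,
                      seed: int | None = None,
                      exhaustive: bool = False) -> PermAnovaResult:
    """One-way permutational ANOVA on univariate observations.

    Parameters
    ----------
    groups:
        Mapping (or list) of per-group observation arrays; at least two
        groups with at least two observations each.
    n_perm:
        Number of random label permutations (ignored in exhaustive mode).
    seed:
        RNG seed for the sampled null.
    exhaustive:
        Enumerate all distinct group assignments; the p-value is then exact
        and the seed irrelevant.
    """
    arrays = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(a, dtype=float).ravel() for a in arrays]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    x = np.concatenate(arrays)
    labels = np.concatenate([np.full(len(a), i) for i, a in enumerate(arrays)])
    group_ids = np.arange(len(arrays))
    a, n = len(arrays), len(x)

    if np.ptp(x) == 0.0:
        log.warning("zero total variance: pseudo-F undefined, p set to 1")
        return PermAnovaResult(math.nan, a - 1, n - a, 1.0, 0, seed, exhaustive)

    d2 = (x[:, None] - x[None, :]) ** 2
    f_obs = _pseudo_f(d2, labels, group_ids)

    if exhaustive:
        count = total = 0
        for assign in _distinct_assignments(labels):
            total += 1
            if _pseudo_f(d2, np.asarray(assign), group_ids) >= f_obs - 1e-12:
                count += 1
        return PermAnovaResult(f_obs, a - 1, n - a, count / total, total, seed, True)

    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(labels), group_ids) >= f_obs - 1e-12:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return PermAnovaResult(f_obs, a - 1, n - a, p, n_perm, seed, False)


def pairwise_perm_tests(groups: dict[str, np.ndarray],
                        pairs: list[tuple[str, str]] | None = None,
                        n_perm: int = DEFAULT_N_PERM,
                        seed: int | None = None,
                        exhaustive: bool = False,
                        holm: bool = False) -> dict[tuple[str, str], float]:
    """Two-group permutation tests for each requested pair of groups.

    Each pair is tested with the same distance-based pseudo-F (equivalent to
    the squared pseudo-t on two groups). No multiplicity correction is
    applied by default, matching the convention of reporting raw pairwise
    p-values after a significant omnibus test; ``holm`` applies a Holm
    step-down adjustment across the requested pairs.
    """
    if pairs is None:
        pairs = list(itertools.combinations(sorted(groups), 2))
    pvals = {}
    for i, (g1, g2) in enumerate(pairs):
        sub_seed = None if seed is None else seed + i
        res = perm_anova_oneway({g1: groups[g1], g2: groups[g2]},
                                n_perm=n_perm, seed=sub_seed, exhaustive=exhaustive)
        pvals[(g1, g2)] = res.p_perm
    if holm:
        items = sorted(pvals.items(), key=lambda kv: kv[1])
        m = len(items)
        running = 0.0
        for rank, (pair, p) in enumerate(items):
            running = max(running, min(1.0, (m - rank) * p))
            pvals[pair] = running
    return pvals


def chisq_return_years(table, pool_rule: bool = True) -> ChiSqResult:
    """Pearson chi-square test on a sites x years-returned count table.

    ``table`` is a 2-D array or DataFrame of nonnegative integer counts with
    return-year categories as columns in increasing order. With
    ``pool_rule`` the two highest categories are merged before testing. The
    expected-count assumption is recorded as satisfied when more than 80% of
    cells have expected counts above five.
    """
    arr = np.asarray(pd.DataFrame(table).to_numpy(), dtype=float)
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("table must hold nonnegative integer counts")
    pooled = False
    if pool_rule and arr.shape[1] >= 3:
        arr = np.column_stack([arr[:, :-2], arr[:, -2] + arr[:, -1]])
        pooled = True
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after pooling")
    if np.any(arr.sum(axis=1) == 0) or np.any(arr.sum(axis=0) == 0):
        raise ValueError("empty row or column in contingency table")
    if np.allclose(arr, 0):
        raise ValueError("table is all zeros")
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=False)
    assumption_ok = bool((expected > 5).mean() > 0.8)
    if not assumption_ok:
        log.warning("chi-square expected-count assumption violated: only "
                    "%.0f%% of cells have expected counts > 5",
                    100 * (expected > 5).mean())
    return ChiSqResult(float(chi2), int(df), float(p), pooled, expected, assumption_ok)


def chi2_critical(df: int, alpha: float) -> float:
    """Upper-tail critical value of the chi-square distribution."""
    if df < 1 or int(df) != df:
        raise ValueError("df must be a positive integer")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    return float(stats.chi2.isf(alpha, df))


@dataclass
class SideSelection:
    """Outcome of the LB/RB reporting rule."""

    chosen: object | None
    discordant: bool
    lb: object
    rb: object
    note: str


def report_side_selection(result_lb, result_rb, alpha: float = 0.05,
                          p_attr: str = "p_perm") -> SideSelection:
    """Apply the left-flank reporting convention to a pair of test results.

    When the LB and RB results fall in the same significance category at
    ``alpha``, the LB result is reported (the left-based catalogue is
    conventionally the larger sample). Discordant results are returned
    together and flagged for manual review.
    """
    p_lb = getattr(result_lb, p_attr)
    p_rb = getattr(result_rb, p_attr)
    sig_lb, sig_rb = p_lb <= alpha, p_rb <= alpha
    if sig_lb == sig_rb:
        return SideSelection(result_lb, False, result_lb, result_rb,
                             "LB reported (significance categories agree)")
    return SideSelection(None, True, result_lb, result_rb,
                         "LB/RB significance categories disagree; review both")
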