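"""Nonparametric machinery for the trait contrasts.

Kruskal–Wallis tests (chi-square approximation or exhaustive permutation
for small samples), Dunn-type pairwise rank comparisons with Bonferroni
correction and a compact-letter display, experiment-wise relative ranks
on [0, 1], and the cluster-contrast table (per trait and context:
accession-level and cluster-level tests plus the blue-red difference or
blue/red ratio of means).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------

def _kw_statistic(values: np.ndarray, group_sizes: list[int]) -> float:
    """Tie-corrected H for values laid out group by group."""
    n = len(values)
    ranks = stats.rankdata(values)
    h = 0.0
    start = 0
    for size in group_sizes:
        h += ranks[start:start + size].sum() ** 2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0.0:
        return 0.0
    return h / tie


def kruskal_wallis(
    values, groups, method: str = "asymptotic"
) -> tuple[float, int, float]:
    """Kruskal–Wallis H-test of equal locations across groups.

    Returns (H, df, p). ``method="asymptotic"`` uses the chi-square
    approximation with k-1 df; ``method="exact"`` enumerates every
    assignment of the observed values to groups of the observed sizes
    (feasible for small n) and returns P(H >= H_obs).
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must align")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    sizes = [len(s) for s in samples]
    pooled = np.concatenate(samples)

    if np.ptp(pooled) == 0.0:
        return 0.0, len(labels) - 1, 1.0

    h_obs = _kw_statistic(pooled, sizes)
    df = len(labels) - 1
    if method == "asymptotic":
        p = float(stats.chi2.sf(h_obs, df))
        return h_obs, df, p
    if method == "exact":
        n = len(pooled)
        n_assign = 1
        rem = n
        for size in sizes:
            n_assign *= comb(rem, size)
            rem -= size
        if n_assign > 200_000:
            raise ValueError("exact enumeration infeasible for this sample size")
        count = 0
        for assignment in _group_assignments(n, sizes):
            h = _kw_statistic(pooled[assignment], sizes)
            if h >= h_obs - 1e-12:
                count += 1
        return h_obs, df, count / n_assign
    raise ValueError(f"unknown method {method!r}")


def _group_assignments(n: int, sizes: list[int]):
    """Yield index arrays enumerating all splits of range(n) into ordered
    groups of the given sizes."""
    def rec(remaining: tuple[int, ...], sizes_left: list[int]):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for chosen in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in chosen)
            for tail in rec(rest, sizes_left[1:]):
                yield chosen + tail
    for assignment in rec(tuple(range(n)), sizes):
        yield np.asarray(assignment)


# ---------------------------------------------------------------------------
# Dunn pairwise comparisons + compact letter display
# ---------------------------------------------------------------------------

def dunn_pairwise(values, groups, p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn-type z-tests on mean ranks for every group pair.

    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12 (N - 1)). The Bonferroni family is all
    pairwise comparisons of one trait/context.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    n = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    n_pairs = comb(len(labels), 2)
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * n_pairs) if p_adjust == "bonferroni" else p
        rows.append({"group1": g1, "group2": g2, "z": z, "p": p, "p_adj": p_adj})
    return pd.DataFrame(rows)


def pairwise_letters(values, groups, alpha: float = 0.05) -> dict:
    """Compact-letter display from Bonferroni-corrected Dunn comparisons.

    Groups sharing a letter do not differ significantly at ``alpha``.
    Letters are assigned by the insert-and-absorb algorithm with groups
    ordered by mean rank, so the display is deterministic and invariant
    to input order.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) == 1:
        return {labels[0]: "a"}
    pw = dunn_pairwise(values, groups)
    differ = {
        frozenset((r.group1, r.group2)) for r in pw.itertuples() if r.p_adj < alpha
    }
    ranks = stats.rankdata(values)
    order = sorted(labels, key=lambda g: (ranks[groups == g].mean(), str(g)))
    # insert-and-absorb: start with one letter holding every group; each
    # significant pair splits any letter containing both; subset letters
    # are absorbed.
    letter_sets: list[frozenset] = [frozenset(order)]
    for pair in sorted(differ, key=lambda fs: sorted(map(str, fs))):
        g1, g2 = sorted(pair, key=str)
        nxt: list[frozenset] = []
        for s in letter_sets:
            if g1 in s and g2 in s:
                nxt.extend((s - {g1}, s - {g2}))
            else:
                nxt.append(s)
        # absorb: drop any letter contained in another
        letter_sets = [s for s in nxt
                       if not any(s < t for t in nxt) and s]
        letter_sets = list(dict.fromkeys(letter_sets))
    # order letters by the best (lowest) mean rank among their members
    rank_of = {g: ranks[groups == g].mean() for g in order}
    letter_sets.sort(key=lambda s: (min(rank_of[g] for g in s),
                                    sorted(str(g) for g in s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict = {g: "" for g in order}
    for i, s in enumerate(letter_sets):
        for g in order:
            if g in s:
                out[g] += alphabet[i % len(alphabet)]
    return out


# ---------------------------------------------------------------------------
# experiment-wise relative ranks
# ---------------------------------------------------------------------------

def relative_ranks(values) -> np.ndarray:
    """Fractional ranks rescaled to [0, 1] within one experiment.

    Mean ranks for ties, then (r - 1)/(n - 1), so the minimum scores 0 and
    the maximum 1.
    """
    values = np.asarray(values, float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two values per experiment")
    return (stats.rankdata(values) - 1.0) / (n - 1.0)


def combine_across_experiments(scores: pd.DataFrame) -> pd.Series:
    """Mean relative-rank score per accession over the experiments in
    which it appears.

    ``scores`` has columns accession, experiment, score (one row per
    accession x experiment where measured).
    """
    required = {"accession", "experiment", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores needs columns {sorted(required)}")
    if scores["score"].isna().all():
        raise ValueError("no scores to combine")
    dropped = scores.groupby("accession")["score"].apply(lambda s: s.isna().all())
    if dropped.any():
        warnings.warn(
            f"accessions absent from all experiments excluded: "
            f"{sorted(dropped[dropped].index)}", stacklevel=2,
        )
    return scores.dropna(subset=["score"]).groupby("accession")["score"].mean()


def experiment_relative_ranks(
    data: pd.DataFrame, value_col: str,
    accession_col: str = "accession", experiment_col: str = "experiment",
) -> pd.DataFrame:
    """Relative ranks computed experiment-wise on a long table."""
    out = data[[accession_col, experiment_col, value_col]].copy()
    out["score"] = (
        out.groupby(experiment_col)[value_col].transform(lambda v: relative_ranks(v))
    )
    return out.rename(columns={accession_col: "accession", experiment_col: "experiment"})


# ---------------------------------------------------------------------------
# cluster-contrast table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastRow:
    trait: str
    context: str
    p_accessions: float
    p_cluster: float
    difference_blue_minus_red: float | None
    ratio_blue_over_red: float | None


def cluster_contrast_table(
    traits: pd.DataFrame,
    trait_cols: list[str],
    cluster_col: str = "cluster",
    accession_col: str = "accession",
    context_col: str | None = None,
    difference_traits: tuple[str, ...] = ("heading_days",),
) -> pd.DataFrame:
    """Per trait (x context): accession- and cluster-level Kruskal–Wallis
    p-values and the blue-red contrast of means.

    Traits listed in ``difference_traits`` report the blue - red mean
    difference (dates subtract, they do not divide); all others report
    the blue/red mean ratio.
    """
    if cluster_col not in traits.columns:
        raise ValueError(f"missing cluster column {cluster_col!r}")
    if context_col is not None and context_col not in traits.columns:
        raise ValueError(f"missing context column {context_col!r}")
    contexts = (
        [(c, traits[traits[context_col] == c]) for c in pd.unique(traits[context_col])]
        if context_col else [("", traits)]
    )
    rows = []
    for context, sub in contexts:
        for trait in trait_cols:
            d = sub.dropna(subset=[trait])
            _, _, p_acc = kruskal_wallis(d[trait], d[accession_col]) \
                if d[accession_col].nunique() > 1 else (np.nan, 0, np.nan)
            _, _, p_clu = kruskal_wallis(d[trait], d[cluster_col])
            means = d.groupby(cluster_col)[trait].mean()
            blue, red = means.get("blue", np.nan), means.get("red", np.nan)
            diff = blue - red if trait in difference_traits else None
            ratio = blue / red if trait not in difference_traits else None
            rows.append(ContrastRow(trait, context, p_acc, p_clu, diff, ratio))
    return pd.DataFrame([r.__dict__ for r in rows])
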