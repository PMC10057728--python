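"""Kruskal-Wallis, Dunn letters, relative ranks and contrast tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from solina.stats_nonparam import (
    cluster_contrast_table, combine_across_experiments, dunn_pairwise,
    experiment_relative_ranks, kruskal_wallis, pairwise_letters,
    relative_ranks,
)


# -- Kruskal-Wallis ---------------------------------------------------------

def test_identical_observations_give_h_zero_p_one():
    h, df, p = kruskal_wallis([5, 5, 5, 5, 5, 5], ["a", "a", "b", "b", "c", "c"])
    assert h == 0.0 and p == 1.0 and df == 2


def test_h_matches_scipy_reference():
    rng = np.random.default_rng(0)
    for _ in range(20):
        vals = rng.normal(size=15)
        groups = rng.choice(["a", "b", "c"], 15)
        if len(set(groups)) < 3 or min((groups == g).sum() for g in "abc") == 0:
            continue
        h, _, p = kruskal_wallis(vals, groups)
        ref_h, ref_p = sps.kruskal(*(vals[groups == g] for g in "abc"))
        assert h == pytest.approx(ref_h, abs=1e-10)
        assert p == pytest.approx(ref_p, abs=1e-10)


def test_exact_p_matches_independent_enumeration():
    """The exact permutation p equals a from-scratch enumeration that uses
    scipy's H statistic (independent of the implementation under test)."""
    vals = np.array([1.2, 3.4, 2.2, 5.1, 4.4, 0.7, 6.0])
    groups = np.array(["a", "a", "a", "b", "b", "b", "b"])
    h_obs, _, p_exact = kruskal_wallis(vals, groups, method="exact")
    count = total = 0
    for idx_a in itertools.combinations(range(7), 3):
        ga = vals[list(idx_a)]
        gb = vals[[i for i in range(7) if i not in idx_a]]
        h, _ = sps.kruskal(ga, gb)
        total += 1
        count += h >= h_obs - 1e-12
    assert p_exact == pytest.approx(count / total)


def test_p_monotone_in_location_shift():
    """Mean p over replicate draws decreases along an increasing
    location-shift grid (three groups of five)."""
    rng = np.random.default_rng(1)
    groups = np.repeat(["a", "b", "c"], 5)
    mean_ps = []
    for shift in (0.0, 1.0, 2.0, 4.0):
        ps = []
        for _ in range(40):
            base = rng.normal(0, 1, 15)
            vals = base + np.repeat([0.0, shift / 2, shift], 5)
            ps.append(kruskal_wallis(vals, groups)[2])
        mean_ps.append(np.mean(ps))
    assert mean_ps == sorted(mean_ps, reverse=True)


def test_h_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    vals = rng.uniform(1, 10, 12)
    groups = np.repeat(["a", "b", "c"], 4)
    h1, _, _ = kruskal_wallis(vals, groups)
    h2, _, _ = kruskal_wallis(np.exp(vals), groups)
    assert h1 == pytest.approx(h2, abs=1e-10)


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        kruskal_wallis([1, 2], ["a", "a"])


# -- Dunn + letters ---------------------------------------------------------

def test_bonferroni_never_below_raw_p():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=20)
    groups = rng.choice(["a", "b", "c", "d"], 20)
    pw = dunn_pairwise(vals, groups)
    assert (pw["p_adj"] >= pw["p"] - 1e-15).all()
    assert (pw["p_adj"] <= 1.0).all()


def test_single_group_gets_letter_a():
    assert pairwise_letters([1.0, 2.0, 3.0], ["g", "g", "g"]) == {"g": "a"}


def test_separated_groups_get_distinct_letters():
    vals = list(np.r_[np.zeros(8), np.ones(8) * 100])
    groups = ["lo"] * 8 + ["hi"] * 8
    letters = pairwise_letters(vals, groups, alpha=0.05)
    assert letters["lo"] != letters["hi"]
    assert letters["lo"] == "a"


def test_indistinguishable_groups_share_a_letter():
    rng = np.random.default_rng(4)
    vals = rng.normal(0, 1, 18)
    groups = np.repeat(["a", "b", "c"], 6)
    letters = pairwise_letters(vals, groups)
    assert len(set(letters.values())) == 1


def test_letters_invariant_to_input_order():
    rng = np.random.default_rng(5)
    vals = np.r_[rng.normal(0, 1, 8), rng.normal(5, 1, 8), rng.normal(10, 1, 8)]
    groups = np.repeat(["x", "y", "z"], 8)
    base = pairwise_letters(vals, groups)
    order = rng.permutation(24)
    assert pairwise_letters(vals[order], groups[order]) == base


# -- relative ranks ---------------------------------------------------------

def test_relative_rank_examples():
    assert relative_ranks([10, 20, 30]).tolist() == [0.0, 0.5, 1.0]
    assert relative_ranks([5, 5, 9]).tolist() == [0.25, 0.25, 1.0]


def test_relative_rank_bounds_and_order_invariance():
    rng = np.random.default_rng(6)
    vals = rng.uniform(size=30)
    scores = relative_ranks(vals)
    assert scores.min() == 0.0 and scores.max() == 1.0
    order = rng.permutation(30)
    assert np.allclose(relative_ranks(vals[order]), scores[order])


def test_combination_reproduces_per_experiment_mean_ordering():
    rng = np.random.default_rng(7)
    rows = []
    true_quality = {f"acc{i}": i for i in range(6)}
    for exp in range(3):
        vals = {a: q + rng.normal(0, 0.1) for a, q in true_quality.items()}
        scores = relative_ranks(list(vals.values()))
        for (a, _), s in zip(vals.items(), scores):
            rows.append({"accession": a, "experiment": exp, "score": s})
    combined = combine_across_experiments(pd.DataFrame(rows))
    assert list(combined.sort_values().index) == [f"acc{i}" for i in range(6)]


def test_experiment_wise_ranks_long_table():
    df = pd.DataFrame({
        "accession": ["a", "b", "c", "a", "b", "c"],
        "experiment": [1, 1, 1, 2, 2, 2],
        "fvfm": [0.70, 0.75, 0.80, 0.81, 0.72, 0.66],
    })
    out = experiment_relative_ranks(df, "fvfm")
    assert out.loc[out["experiment"] == 1, "score"].tolist() == [0.0, 0.5, 1.0]
    assert out.loc[out["experiment"] == 2, "score"].tolist() == [1.0, 0.5, 0.0]


def test_accession_absent_everywhere_warns():
    df = pd.DataFrame({"accession": ["a", "b"], "experiment": [1, 1],
                       "score": [0.5, np.nan]})
    with pytest.warns(UserWarning, match="excluded"):
        combined = combine_across_experiments(df)
    assert list(combined.index) == ["a"]


# -- contrast table ---------------------------------------------------------

def _trait_frame(blue_vals, red_vals, trait="TKW"):
    rows = []
    for i, v in enumerate(blue_vals):
        rows.append({"accession": f"b{i % 3}", "cluster": "blue", trait: v})
    for i, v in enumerate(red_vals):
        rows.append({"accession": f"r{i % 3}", "cluster": "red", trait: v})
    return pd.DataFrame(rows)


def test_identical_distributions_give_unit_ratio():
    rng = np.random.default_rng(8)
    vals = rng.normal(40, 1, 12)
    df = _trait_frame(vals, vals)
    out = cluster_contrast_table(df, ["TKW"])
    assert out.loc[0, "ratio_blue_over_red"] == pytest.approx(1.0)
    assert out.loc[0, "p_cluster"] > 0.5


def test_heading_date_uses_difference_of_means():
    """Blue heading at 103 d vs red at 124.06 d reports the -21.06 d
    difference (dates subtract rather than divide)."""
    df = _trait_frame([103.0] * 6, [124.06] * 6, trait="heading_days")
    out = cluster_contrast_table(df, ["heading_days"])
    assert out.loc[0, "difference_blue_minus_red"] == pytest.approx(-21.06)
    assert pd.isna(out.loc[0, "ratio_blue_over_red"]) or \
        out.loc[0, "ratio_blue_over_red"] is None


def test_ratio_equals_recomputed_mean_quotient():
    rng = np.random.default_rng(9)
    df = _trait_frame(rng.normal(44, 2, 9), rng.normal(37, 2, 9))
    out = cluster_contrast_table(df, ["TKW"])
    blue = df[df["cluster"] == "blue"]["TKW"].mean()
    red = df[df["cluster"] == "red"]["TKW"].mean()
    assert out.loc[0, "ratio_blue_over_red"] == pytest.approx(blue / red, abs=1e-12)


def test_missing_context_column_rejected():
    df = _trait_frame([1, 2, 3], [4, 5, 6])
    with pytest.raises(ValueError, match="context"):
        cluster_contrast_table(df, ["TKW"], context_col="sowing")
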