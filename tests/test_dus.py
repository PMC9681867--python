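"""One-way ANOVA, Duncan's multiple range test (vs published-table oracle
and the t-test equivalence) and trait-explanation verdicts."""

import numpy as np
import pytest
from scipy import stats

from coresnp import (
    anova_by_cluster,
    correlate_traits,
    duncan_critical_range,
    duncan_mrt,
    explain_trait,
    explain_traits,
)
from coresnp.dus import _q_upper


def _groups(mean_by_label, n=6, seed=0):
    """Exact-mean, unit-within-variance samples per labelled group."""
    rng = np.random.default_rng(seed)
    vals, labs = [], []
    for lab, mu in mean_by_label.items():
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std(ddof=1)
        vals.extend(mu + x)
        labs.extend([lab] * n)
    return np.array(vals), np.array(labs)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_anova_hand_sums_of_squares():
    """{1,2,3} vs {7,8,9}: SSB = 54, SSW = 4, F = 54, df = (1, 4)."""
    res = anova_by_cluster([1, 2, 3, 7, 8, 9], [1, 1, 1, 2, 2, 2])
    assert res.f_statistic == pytest.approx(54.0)
    assert (res.df_between, res.df_error) == (1, 4)
    assert res.p_value == pytest.approx(stats.f.sf(54, 1, 4))
    assert res.p_value == pytest.approx(0.0018, abs=2e-4)


def test_anova_identical_values_p_one():
    res = anova_by_cluster([5, 5, 5, 5], [1, 1, 2, 2])
    assert res.f_statistic == 0.0
    assert res.p_value == 1.0


def test_anova_matches_scipy_unbalanced():
    rng = np.random.default_rng(8)
    y = rng.normal(size=20)
    labels = np.array([1] * 4 + [2] * 7 + [3] * 9)
    res = anova_by_cluster(y, labels)
    f, p = stats.f_oneway(y[labels == 1], y[labels == 2], y[labels == 3])
    assert res.f_statistic == pytest.approx(f, abs=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)


def test_anova_requires_two_clusters():
    with pytest.raises(ValueError):
        anova_by_cluster([1, 2, 3], [1, 1, 1])


def test_anova_missing_phenotypes_dropped():
    res = anova_by_cluster([1, 2, np.nan, 7, 8, np.nan], [1, 1, 1, 2, 2, 2])
    assert res.group_stats["n"].tolist() == [2, 2]


# ---------------------------------------------------------------------------
# studentized range + DMRT
# ---------------------------------------------------------------------------

def test_studentized_range_quantiles_match_printed_tables():
    """q_0.05(p, df) spot values from published studentized-range tables."""
    printed = {
        (2, 20): 2.950, (3, 20): 3.578, (4, 20): 3.958,
        (2, 10): 3.151, (5, 30): 4.102,
    }
    for (span, df), expect in printed.items():
        assert _q_upper(0.05, span, df) == pytest.approx(expect, abs=2e-3)


def test_duncan_multipliers_match_duncan_tables_df20():
    """Duncan least-significant-range multipliers at df=20 (2.95, 3.10,
    3.19 for spans 2..4) from the published Duncan tables."""
    for span, expect in ((2, 2.95), (3, 3.10), (4, 3.19)):
        mult = duncan_critical_range(span, 20, 1.0, 6.0) / np.sqrt(1.0 / 6.0)
        assert mult == pytest.approx(expect, abs=6e-3)


def test_dmrt_equal_means_all_share_letter():
    vals, labs = _groups({1: 0.0, 2: 0.0, 3: 0.0}, seed=1)
    res = duncan_mrt(vals, labs)
    assert set(res.letters.values()) == {"a"}


def test_dmrt_forced_separation_two_letters():
    vals, labs = _groups({1: 0.0, 2: 100.0}, seed=2)
    res = duncan_mrt(vals, labs)
    assert sorted(res.letters.values()) == ["a", "b"]


def test_dmrt_letter_pattern_matches_table_oracle():
    """Means 10, 9.8, 5, 1 with n=6 each and MSE 1 (df=20): gaps compared
    with Duncan ranges R_2=1.20, R_3=1.27, R_4=1.30 from printed tables
    give the pattern a, a, b, c."""
    vals, labs = _groups({1: 10.0, 2: 9.8, 3: 5.0, 4: 1.0}, n=6, seed=3)
    res = duncan_mrt(vals, labs)
    assert res.anova.mse == pytest.approx(1.0)
    assert res.anova.df_error == 20
    assert res.letters == {1: "a", 2: "a", 3: "b", 4: "c"}


def test_dmrt_span2_coincides_with_t_test():
    """For two groups Duncan's span-2 criterion reduces to the two-sample
    t-test at alpha: q(alpha; 2, df) = t(alpha/2, df) * sqrt(2)."""
    for df in (4, 10, 25, 60):
        q = _q_upper(0.05, 2, df)
        t = stats.t.isf(0.025, df)
        assert q == pytest.approx(t * np.sqrt(2), rel=1e-6)
    # and the decisions agree on data near the boundary
    rng = np.random.default_rng(4)
    for trial in range(20):
        y = rng.normal(size=16)
        labs = np.array([1] * 8 + [2] * 8)
        y[labs == 2] += rng.uniform(0, 1.5)
        res = duncan_mrt(y, labs, alpha=0.05)
        separated = res.letters[1] != res.letters[2]
        _, p_t = stats.ttest_ind(y[labs == 1], y[labs == 2])
        assert separated == (p_t < 0.05)


def test_dmrt_separation_monotone_in_gap():
    """Increasing a mean gap never merges letters."""
    vals, labs = _groups({1: 0.0, 2: 1.0, 3: 2.0}, n=8, seed=5)
    n_letters_prev = 0
    for shift in (0.0, 2.0, 6.0, 20.0):
        v = vals.copy()
        v[labs == 3] += shift
        res = duncan_mrt(v, labs)
        n_letters = len(set("".join(res.letters.values())))
        assert n_letters >= n_letters_prev
        n_letters_prev = n_letters


def test_dmrt_letters_stable_under_relabeling():
    vals, labs = _groups({1: 0.0, 2: 5.0, 3: 10.0}, seed=6)
    res1 = duncan_mrt(vals, labs)
    swap = {1: 30, 2: 10, 3: 20}
    res2 = duncan_mrt(vals, np.array([swap[l] for l in labs]))
    assert {swap[c]: l for c, l in res1.letters.items()} == res2.letters


# ---------------------------------------------------------------------------
# explanations
# ---------------------------------------------------------------------------

def _fake_dmrt(letters, p, trait="QN01", alpha=0.05):
    from coresnp.dus import AnovaResult, DmrtResult
    import pandas as pd

    stats_df = pd.DataFrame(
        {"cluster": list(letters), "n": 5, "mean": range(len(letters), 0, -1)}
    )
    return DmrtResult(
        trait_id=trait, alpha=alpha,
        anova=AnovaResult(1.0, p, 1.0, len(letters) - 1, 10, stats_df),
        letters=letters,
    )


def test_explain_two_clean_groups():
    e = explain_trait(_fake_dmrt({1: "a", 2: "a", 3: "b", 4: "b"}, 1e-5))
    assert e.explained and e.n_groups == 2 and not e.overlap
    assert e.grouping == "1,2 / 3,4"


def test_explain_all_same_letter_unexplained():
    e = explain_trait(_fake_dmrt({1: "a", 2: "a", 3: "a"}, 1e-5))
    assert not e.explained and e.n_groups is None


def test_explain_nonsignificant_unexplained():
    e = explain_trait(_fake_dmrt({1: "a", 2: "b"}, 0.2))
    assert not e.explained


def test_explain_overlap_flagged_unclear():
    e = explain_trait(_fake_dmrt({1: "a", 2: "ab", 3: "b"}, 1e-4))
    assert e.explained and e.n_groups == 2
    assert e.overlap and e.unclear_clusters == [2]


def test_explain_traits_picks_smallest_p_marker_set():
    by_set = {
        "F87": {"QN01": _fake_dmrt({1: "a", 2: "b"}, 1e-3)},
        "F24": {"QN01": _fake_dmrt({1: "a", 2: "b"}, 1e-6)},
    }
    out = explain_traits(by_set)
    assert out[0].marker_set == "F24"


def test_explain_invariant_to_cluster_relabeling():
    e1 = explain_trait(_fake_dmrt({1: "a", 2: "a", 3: "b"}, 1e-4))
    e2 = explain_trait(_fake_dmrt({7: "a", 5: "a", 9: "b"}, 1e-4))
    assert (e1.explained, e1.n_groups, e1.overlap) == (
        e2.explained, e2.n_groups, e2.overlap
    )


# ---------------------------------------------------------------------------
# trait correlation
# ---------------------------------------------------------------------------

def test_correlation_self_and_negation():
    import pandas as pd
    from coresnp import TraitTable

    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    tt = TraitTable(
        values=pd.DataFrame({"QN01": x, "QN02": -x},
                            index=[f"v{i}" for i in range(20)]),
        types={"QN01": "QN", "QN02": "QN"},
    )
    corr = correlate_traits(tt)
    assert corr.loc["QN01", "QN01"] == pytest.approx(1.0)
    assert corr.loc["QN01", "QN02"] == pytest.approx(-1.0)


def test_codriven_traits_strongly_correlated():
    """Two traits driven by the same causal marker correlate near 1."""
    from coresnp import PanelSpec, simulate_panel
    import pandas as pd
    from coresnp import TraitTable

    spec = PanelSpec(n_varieties=60, n_markers=100, causal_per_trait=1,
                     effect_size=100.0, noise_sd=0.1, missing_rate=0.0,
                     trait_types=("QN",), seed=2)
    panel, traits, truth = simulate_panel(spec)
    causal = truth.causal_markers["QN01"][0]
    dose = panel.dosage()[:, panel.marker_index(causal)]
    tt = TraitTable(
        values=pd.DataFrame(
            {"QN01": traits.values["QN01"], "QN02": 2.0 * np.nan_to_num(dose) + 1.0},
            index=panel.variety_ids,
        ),
        types={"QN01": "QN", "QN02": "QN"},
    )
    corr = correlate_traits(tt)
    assert corr.loc["QN01", "QN02"] > 0.99
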