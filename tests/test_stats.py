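import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import spectpa as sp
from spectpa import ContingencyTable2x2 as Table
from spectpa.patterns import PatternLabel


# ---------------------------------------------------------------------------
# response labels


@pytest.mark.parametrize(
    "base,follow,expected",
    [(28.66, 48.91, True), (30.0, 34.9, False), (30.0, 35.0, True)],
)
def test_response_label_boundaries(base, follow, expected):
    assert sp.label_response(base, follow) is expected


@pytest.mark.parametrize(
    "base,follow,expected",
    [
        (35.0, 50.0, True),    # reaches 50% -> super
        (30.0, 45.0, False),   # delta exactly 15, below 50 -> not super
        (28.0, 44.0, True),    # delta 16 -> super
    ],
)
def test_super_response_label_boundaries(base, follow, expected):
    assert sp.label_super_response(base, follow) is expected


# ---------------------------------------------------------------------------
# odds ratios and Woolf CI


def test_or_unity_for_balanced_table():
    assert sp.odds_ratio_ci(Table(1, 1, 1, 1)).odds_ratio == pytest.approx(1.0)


def test_or_published_mild_vs_heterogeneous():
    r = sp.odds_ratio_ci(Table(21, 11, 3, 16))
    assert round(r.odds_ratio, 3) == 10.182
    assert round(r.ci_low, 2) == 2.43
    assert round(r.ci_high, 3) == 42.663


def test_or_published_u_vs_homogeneous():
    assert sp.odds_ratio_ci(Table(12, 5, 2, 4)).odds_ratio == pytest.approx(4.8)


def test_or_zero_cell_flagged_not_patched():
    r = sp.odds_ratio_ci(Table(5, 0, 3, 4))  # b = 0 -> OR undefined
    assert not r.or_defined and np.isnan(r.odds_ratio)
    r2 = sp.odds_ratio_ci(Table(0, 5, 3, 4))  # a = 0 -> OR fine, CI undefined
    assert r2.or_defined and r2.odds_ratio == 0.0 and not r2.ci_defined


@settings(derandomize=True, max_examples=50)
@given(st.tuples(*[st.integers(1, 40)] * 4))
def test_or_antisymmetry(cells):
    a, b, c, d = cells
    fwd = sp.odds_ratio_ci(Table(a, b, c, d)).odds_ratio
    rev = sp.odds_ratio_ci(Table(c, d, a, b)).odds_ratio
    assert fwd == pytest.approx(1.0 / rev)


# ---------------------------------------------------------------------------
# chi-square / Fisher


def test_chi2_published_convention():
    stat, p = sp.pearson_chi2(Table(21, 11, 12, 5))
    assert stat == pytest.approx(0.124, abs=5e-4)
    assert p == pytest.approx(0.72, abs=5e-3)


def test_chi2_zero_for_proportional_table():
    stat, p = sp.pearson_chi2(Table(10, 20, 5, 10))
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi2_matches_closed_form_on_random_tables(rng):
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(1, 50, 4))
        stat, _ = sp.pearson_chi2(Table(a, b, c, d))
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(closed, rel=1e-9)


def test_fisher_exact_hypergeometric_enumeration():
    # margins 5/5 and 5/5: observed table prob = 1/C(10,5) = 1/252,
    # two-sided doubles the single extreme table
    assert sp.fisher_exact(Table(5, 0, 0, 5)) == pytest.approx(2 / 252)


def test_expected_cell_rule_selects_fisher():
    test, _ = sp.compare_proportions(Table(2, 4, 3, 16))  # small expected cells
    assert test == "fisher"
    test, _ = sp.compare_proportions(Table(21, 11, 12, 5))
    assert test == "chi2"


def test_bonferroni_capping():
    assert sp.bonferroni([0.01], 6)[0] == pytest.approx(0.06)
    assert sp.bonferroni([0.5], 3)[0] == 1.0
    ps = np.array([0.001, 0.02, 0.4])
    assert np.allclose(sp.bonferroni(ps, 6), [min(1, 6 * p) for p in ps])


# ---------------------------------------------------------------------------
# logistic regression


def test_univariate_logistic_equals_cross_product_or():
    y = np.r_[np.ones(21), np.zeros(11), np.ones(3), np.zeros(16)]
    x = pd.DataFrame({"g": np.r_[np.ones(32), np.zeros(19)]})
    res = sp.logistic_fit(x, y)
    assert res.odds_ratios["g"] == pytest.approx(10.182, abs=1e-3)


def test_logistic_or_identity_random_tables(rng):
    for _ in range(30):
        a, b, c, d = (int(x) for x in rng.integers(2, 30, 4))
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = pd.DataFrame({"g": np.r_[np.ones(a + b), np.zeros(c + d)]})
        assert sp.logistic_fit(x, y).odds_ratios["g"] == pytest.approx(
            (a * d) / (b * c), rel=1e-6
        )


def test_constant_outcome_raises_separation():
    x = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
    with pytest.raises(sp.SeparationError):
        sp.logistic_fit(x, [1, 1, 1, 1])


def test_perfect_separation_raises():
    x = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)]})
    with pytest.raises(sp.SeparationError):
        sp.logistic_fit(x, np.r_[np.zeros(10), np.ones(10)])


def test_per_sd_scaling_changes_or_consistently(rng):
    x = pd.DataFrame({"x": rng.normal(0, 3.0, 500)})
    y = (rng.random(500) < 1 / (1 + np.exp(-0.4 * x["x"]))).astype(float)
    raw = sp.logistic_fit(x, y)
    scaled = sp.logistic_fit(x, y, per_sd=["x"])
    sd = x["x"].std(ddof=1)
    assert scaled.params["x"] == pytest.approx(raw.params["x"] * sd, rel=1e-6)


def test_stepwise_selects_signal_and_drops_noise(rng):
    n = 1500
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    noise = rng.normal(size=n)
    lin = -0.3 + 1.0 * x1 - 0.8 * x2
    y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
    df = pd.DataFrame({"x1": x1, "x2": x2, "noise": noise, "y": y})
    selected, final, uni = sp.stepwise_logistic(df, ["x1", "x2", "noise"], "y")
    assert set(selected) == {"x1", "x2"}
    assert final.params["x1"] == pytest.approx(1.0, abs=2.5 * final.bse["x1"])
    assert len(uni) == 3


# ---------------------------------------------------------------------------
# survival


def test_km_no_events_flat_at_one():
    curve = sp.km_estimator([5.0, 10.0, 20.0], [0, 0, 0])
    assert curve.event_times.size == 0
    assert curve.survival_at(15.0) == 1.0


def test_km_hand_product_limit():
    curve = sp.km_estimator([1.0, 2.0, 3.0], [1, 1, 1])
    assert np.allclose(curve.event_times, [1, 2, 3])
    assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])


def test_km_no_censoring_equals_empirical_survival(rng):
    times = rng.exponential(10.0, 60)
    curve = sp.km_estimator(times, np.ones(60))
    for t in (1.0, 5.0, 12.0):
        assert curve.survival_at(t) == pytest.approx((times > t).mean())


def test_log_rank_identical_groups_zero():
    times = [1, 2, 3, 4, 1, 2, 3, 4]
    events = [1, 1, 0, 1, 1, 1, 0, 1]
    groups = [0, 0, 0, 0, 1, 1, 1, 1]
    stat, p = sp.log_rank(times, events, groups)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# full published-count table


def test_build_table2_reproduces_all_published_ors(printed_cohort):
    out = sp.build_table2(printed_cohort)
    got = dict(zip(out["pairwise"]["contrast"], out["pairwise"]["odds_ratio"]))
    assert round(got["MILD vs U_SHAPED"], 3) == 0.795
    assert round(got["MILD vs HETEROGENEOUS"], 3) == 10.182
    assert round(got["MILD vs HOMOGENEOUS"], 3) == 3.818
    assert round(got["U_SHAPED vs HETEROGENEOUS"], 1) == 12.8
    assert round(got["U_SHAPED vs HOMOGENEOUS"], 1) == 4.8
    assert round(got["HOMOGENEOUS vs HETEROGENEOUS"], 3) == 2.667


def test_build_table2_flags_undefined_contrast(printed_cohort):
    df = printed_cohort.copy()
    # remove every heterogeneous super-responder -> zero cell
    df.loc[(df["pattern"] == "HETEROGENEOUS"), "super_response"] = 0
    out = sp.build_table2(df)
    row = out["pairwise"].set_index("contrast").loc["MILD vs HETEROGENEOUS"]
    assert not row["or_defined"] or not row["ci_defined"]


def test_pattern_table_counts(printed_cohort):
    t = sp.stats.pattern_table(printed_cohort, PatternLabel.MILD,
                               PatternLabel.HETEROGENEOUS)
    assert (t.a, t.b, t.c, t.d) == (21, 11, 3, 16)
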