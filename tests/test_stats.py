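"""Statistical battery: Welch t, variance F, Lilliefors, BH, percentiles,
extreme-stability and T1/T2 classifications, summaries and pooled means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mirstab.errors import ValidationError
from mirstab.stats import (
    bh_adjust,
    classify_extreme_stability,
    group_summary,
    lilliefors_statistic,
    lilliefors_test,
    mean_difference,
    partition_by_thresholds,
    percentile,
    pooled_weighted_mean,
    sd_ratio,
    summarize_and_compare,
    variance_f_test,
    welch_t_test,
)


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

def test_welch_identical_samples():
    t, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (t, p) == (0.0, 1.0)


def test_welch_hand_example():
    t, p = welch_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
    assert t == pytest.approx(-1.0)
    assert p == pytest.approx(0.3466, abs=1e-3)


def test_welch_separated_samples_tiny_p(rng):
    x = rng.normal(0, 1, 200)
    y = rng.normal(5, 1, 200)
    _, p = welch_t_test(x, y)
    assert p < 1e-6


def test_welch_against_scipy_oracle(rng):
    for _ in range(25):
        x = rng.normal(0, 1, int(rng.integers(5, 40)))
        y = rng.normal(0.3, 2, int(rng.integers(5, 40)))
        t, p = welch_t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


def test_welch_rejects_tiny_samples():
    with pytest.raises(ValidationError):
        welch_t_test([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# Variance F
# ---------------------------------------------------------------------------

def test_f_test_equal_variances():
    f, p = variance_f_test([1, 2, 3, 4], [5, 6, 7, 8])
    assert f == pytest.approx(1.0)
    assert p == pytest.approx(1.0)


def test_f_test_ratio_four_matches_f_distribution(rng):
    x = rng.normal(0, 1, 10)
    x = (x - x.mean()) / x.std(ddof=1) * 2.0  # var exactly 4
    y = rng.normal(0, 1, 10)
    y = (y - y.mean()) / y.std(ddof=1)        # var exactly 1
    f, p = variance_f_test(x, y)
    assert f == pytest.approx(4.0)
    dist = sps.f(9, 9)
    assert p == pytest.approx(2 * min(dist.cdf(4.0), dist.sf(4.0)), abs=1e-6)


def test_f_test_two_sided_symmetry(rng):
    x = rng.normal(0, 3, 15)
    y = rng.normal(0, 1, 12)
    f_xy, p_xy = variance_f_test(x, y)
    f_yx, p_yx = variance_f_test(y, x)
    assert f_xy == pytest.approx(1 / f_yx)
    assert p_xy == pytest.approx(p_yx, rel=1e-9)


def test_f_test_zero_denominator_variance():
    with pytest.raises(ValidationError):
        variance_f_test([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


# ---------------------------------------------------------------------------
# Lilliefors
# ---------------------------------------------------------------------------

def test_lilliefors_deterministic_given_seed(rng):
    x = rng.normal(0, 1, 50)
    assert lilliefors_test(x, mc_reps=2000, seed=7) == lilliefors_test(
        x, mc_reps=2000, seed=7
    )


def test_lilliefors_rejects_exponential(rng):
    x = rng.exponential(1.0, 200)
    _, p = lilliefors_test(x, mc_reps=2000, seed=3)
    assert p < 0.01


def test_lilliefors_statistic_matches_statsmodels(rng):
    sm_lf = pytest.importorskip("statsmodels.stats.diagnostic")
    for n in (20, 57, 150):
        x = rng.normal(0, 2, n)
        d, _ = sm_lf.lilliefors(x, dist="norm", pvalmethod="table")
        assert lilliefors_statistic(x) == pytest.approx(d, abs=1e-10)


def test_lilliefors_needs_enough_data():
    with pytest.raises(ValidationError):
        lilliefors_test([1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pvals, expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.05], [0.05]),
        ([0.01, 1.0], [0.02, 1.0]),
    ],
)
def test_bh_hand_computed(pvals, expected):
    assert bh_adjust(pvals) == pytest.approx(expected)


def test_bh_matches_statsmodels(rng):
    mt = pytest.importorskip("statsmodels.stats.multitest")
    p = rng.uniform(0, 1, 40)
    ref = mt.multipletests(p, method="fdr_bh")[1]
    assert bh_adjust(p) == pytest.approx(list(ref), rel=1e-12)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.randoms())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_bh_permutation_equivariance(pvals, pyrandom):
    perm = list(range(len(pvals)))
    pyrandom.shuffle(perm)
    q = bh_adjust(pvals)
    q_perm = bh_adjust([pvals[i] for i in perm])
    assert q_perm == pytest.approx([q[i] for i in perm])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# Percentiles and classifications
# ---------------------------------------------------------------------------

def test_percentile_linear_hand_values():
    vals = [30, 35, 40, 45, 50, 55, 60, 65, 70, 75]
    assert percentile(vals, 10) == pytest.approx(34.5)
    assert percentile(vals, 90) == pytest.approx(70.5)


def test_percentile_nearest_rank():
    vals = [10, 20, 30, 40, 50]
    assert percentile(vals, 10, mode="nearest") == 10
    assert percentile(vals, 50, mode="nearest") == 30
    assert percentile(vals, 90, mode="nearest") == 50


def test_extreme_stability_examples():
    ten = {f"r{i}": float(i) for i in range(1, 11)}
    lab = classify_extreme_stability(ten)
    assert lab.ultra == {"r10"} and lab.unstable == {"r1"}

    twenty = {f"r{i}": float(i) for i in range(1, 21)}
    lab = classify_extreme_stability(twenty)
    assert lab.ultra == {"r19", "r20"} and lab.unstable == {"r1", "r2"}


def test_extreme_stability_degenerate_ties():
    lab = classify_extreme_stability({f"r{i}": 5.0 for i in range(12)})
    assert lab.ultra == set() and lab.unstable == set()


def test_extreme_stability_tail_sizes(rng):
    """On continuous data each tail holds floor(n/10)..ceil(n/10) records."""
    for n in (37, 80, 133):
        vals = {f"r{i}": float(v) for i, v in enumerate(rng.normal(0, 1, n))}
        lab = classify_extreme_stability(vals)
        for tail in (lab.ultra, lab.unstable):
            assert n // 10 <= len(tail) <= -(-n // 10)


def test_partition_thresholds_and_bands():
    sc3 = [30, 35, 40, 45, 50, 55, 60, 65, 70, 75]
    records = {
        "low": ("S_n", 34.0),
        "at_t1": ("S_n", 34.5),     # boundary is inclusive into the middle band
        "mid": ("S_n", 50.0),
        "at_t2": ("S_n", 70.5),
        "high": ("S_n", 71.0),
        "cons_mid": ("S_c2", 40.0),
        "cons_out": ("S_c3", 80.0),
        "ignored": ("excluded", 50.0),
    }
    part = partition_by_thresholds(sc3, records)
    assert (part.t1, part.t2) == (pytest.approx(34.5), pytest.approx(70.5))
    assert part.subgroup["low"] == "S_n_u"
    assert part.subgroup["at_t1"] == "S_n_m"
    assert part.subgroup["mid"] == "S_n_m"
    assert part.subgroup["at_t2"] == "S_n_m"
    assert part.subgroup["high"] == "S_n_s"
    assert part.subgroup["cons_mid"] == "S_c_m"
    assert part.subgroup["cons_out"] is None
    assert "ignored" not in part.subgroup


def test_partition_empty_sc3_is_error():
    with pytest.raises(ValidationError):
        partition_by_thresholds([], {})


# ---------------------------------------------------------------------------
# Summaries, comparisons, pooled means
# ---------------------------------------------------------------------------

def test_group_summary_hand_example():
    assert group_summary([1, 2, 3]) == (3, pytest.approx(2.0), pytest.approx(1.0))


def _toy_dataset(rng):
    rows = []
    specs = {
        ("human", "S_n"): (40, 44.0, 12.0),
        ("human", "S_c1"): (20, 45.0, 8.0),
        ("human", "S_c3"): (15, 44.0, 6.0),
        ("mouse", "S_n"): (30, 41.0, 10.0),
        ("mouse", "S_c3"): (18, 44.0, 6.0),
    }
    k = 0
    for (species, group), (n, mu, sd) in specs.items():
        for _ in range(n):
            rows.append(
                {"id": f"r{k}", "species": species, "group": group,
                 "amfe": rng.normal(mu, sd), "bp_pct": rng.normal(70, 5)}
            )
            k += 1
    return pd.DataFrame(rows)


def test_summarize_and_compare_structure(rng):
    report = summarize_and_compare(_toy_dataset(rng), metrics=("amfe", "bp_pct"))
    # summaries: 5 cells x 2 metrics
    assert len(report.summaries) == 10
    # comparisons: 3 conserved-vs-S_n pairs x 2 metrics
    assert len(report.comparisons) == 6
    assert set(report.comparisons.columns) >= {
        "t_stat", "p_mean", "f_stat", "p_var", "q_mean", "q_var"
    }
    # BH was applied within each metric across its comparisons
    for metric, sub in report.comparisons.groupby("metric"):
        assert sub["q_mean"].tolist() == pytest.approx(
            bh_adjust(sub["p_mean"].tolist())
        )
    assert set(report.pooled["metric"]) == {"amfe", "bp_pct"}


def test_summaries_match_direct_computation(rng):
    data = _toy_dataset(rng)
    report = summarize_and_compare(data, metrics=("amfe",))
    cell = report.summaries[
        (report.summaries.species == "human") & (report.summaries.group == "S_n")
    ].iloc[0]
    raw = data[(data.species == "human") & (data.group == "S_n")]["amfe"]
    assert cell["n"] == len(raw)
    assert cell["mean"] == pytest.approx(raw.mean())
    assert cell["sd"] == pytest.approx(raw.std(ddof=1))


def test_undersized_group_skipped_in_comparisons(rng):
    data = _toy_dataset(rng)
    extra = pd.DataFrame(
        [{"id": f"x{i}", "species": "human", "group": "S_c2",
          "amfe": 44.0 + i, "bp_pct": 70.0} for i in range(4)]
    )
    report = summarize_and_compare(
        pd.concat([data, extra], ignore_index=True), metrics=("amfe",)
    )
    assert not (
        (report.comparisons.species == "human") & (report.comparisons.group == "S_c2")
    ).any()


def test_pooled_weighted_mean_hand_check():
    summaries = pd.DataFrame(
        [
            {"species": "a", "group": "S_n", "metric": "m", "n": 10, "mean": 60.0, "sd": 1},
            {"species": "b", "group": "S_n", "metric": "m", "n": 30, "mean": 68.0, "sd": 1},
            {"species": "a", "group": "S_c3", "metric": "m", "n": 20, "mean": 72.0, "sd": 1},
        ]
    )
    assert pooled_weighted_mean(summaries, "m", ("S_n",)) == pytest.approx(66.0)
    assert pooled_weighted_mean(summaries, "m", ("S_c1", "S_c2", "S_c3")) == 72.0


def test_sd_ratio_and_mean_difference_helpers():
    summaries = pd.DataFrame(
        [
            {"species": "a", "group": "S_n", "metric": "amfe", "n": 10, "mean": 41.0, "sd": 9.0},
            {"species": "a", "group": "S_c3", "metric": "amfe", "n": 20, "mean": 43.8, "sd": 4.5},
        ]
    )
    assert sd_ratio(summaries, "a", "amfe", "S_n", "S_c3") == pytest.approx(2.0)
    assert mean_difference(summaries, "a", "amfe", "S_c3", "S_n") == pytest.approx(2.8)


def test_welch_power_on_planted_amfe_difference(rng):
    """A 4 kcal/mol group-mean AMFE gap (sd 6, n = 60/group), the contrast
    the table1-like generator plants for mouse S_c1 vs S_n, is detected
    with power > 0.8."""
    hits = 0
    for _ in range(500):
        x = rng.normal(45.0, 6.0, 60)
        y = rng.normal(41.0, 6.0, 60)
        _, p = welch_t_test(x, y)
        hits += p < 0.05
    assert hits / 500 > 0.8
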