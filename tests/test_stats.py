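import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from petimm import Cohort, CohortSpec, generate_cohort
from petimm.stats import (
    cox_fit,
    dunn_posthoc,
    km_logrank,
    kruskal_wallis_by_grade,
    mann_whitney,
    recurrence_strat_table,
    roc_cutoff,
    univariate_screen,
)
from oracles import (
    brute_force_dunn_z,
    brute_force_kruskal_h,
    brute_force_youden,
    cox_partial_loglik,
)


def _cohort_from_groups(groups, feature="f"):
    rows = []
    for grade, values in enumerate(groups):
        for v in values:
            rows.append({"id": f"g{grade}_{v}_{len(rows)}", "cd4_grade": grade, feature: v})
    return Cohort(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def test_kruskal_wallis_fully_separated_groups():
    groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
    res = kruskal_wallis_by_grade(_cohort_from_groups(groups), "f", "cd4")
    assert res.h_statistic == pytest.approx(7.2, rel=1e-12)
    assert res.h_statistic == pytest.approx(brute_force_kruskal_h(groups), rel=1e-12)
    assert res.df == 2


def test_kruskal_wallis_identical_groups_gives_zero_h():
    groups = [[1, 2, 3], [1, 2, 3], [1, 2, 3]]
    res = kruskal_wallis_by_grade(_cohort_from_groups(groups), "f", "cd4")
    assert res.h_statistic == pytest.approx(0.0, abs=1e-12)
    res_tied = kruskal_wallis_by_grade(_cohort_from_groups([[5, 5], [5, 5], [5]]), "f", "cd4")
    assert (res_tied.h_statistic, res_tied.p_value) == (0.0, 1.0)


def test_kruskal_wallis_invariant_under_monotone_transform():
    groups = [[1, 5, 2], [9, 3, 4], [8, 7, 12]]
    res1 = kruskal_wallis_by_grade(_cohort_from_groups(groups), "f", "cd4")
    res2 = kruskal_wallis_by_grade(
        _cohort_from_groups([[math.exp(v) for v in g] for g in groups]), "f", "cd4"
    )
    assert res1.h_statistic == pytest.approx(res2.h_statistic, rel=1e-12)


def test_kruskal_wallis_single_group_raises():
    with pytest.raises(ValueError, match="two non-empty"):
        kruskal_wallis_by_grade(_cohort_from_groups([[1, 2, 3]]), "f", "cd4")


def test_dunn_identical_groups_and_antisymmetry():
    groups = [[1, 2, 3], [1, 2, 3], [7, 8, 9]]
    res = dunn_posthoc(_cohort_from_groups(groups), "f", "cd4")
    i01 = res.pairs.index((0, 1))
    assert res.z_values[i01] == pytest.approx(0.0, abs=1e-12)
    assert res.p_values[i01] == pytest.approx(1.0, abs=1e-12)
    i02, i12 = res.pairs.index((0, 2)), res.pairs.index((1, 2))
    assert res.z_values[i02] == pytest.approx(res.z_values[i12], rel=1e-9)


def test_dunn_matches_brute_force_formula():
    rng = np.random.default_rng(0)
    groups = [list(rng.integers(0, 20, 5)) for _ in range(3)]
    groups[2] = [g + 30 for g in groups[2]]  # fully separated third group
    res = dunn_posthoc(_cohort_from_groups(groups), "f", "cd4")
    for (i, j), z in zip(res.pairs, res.z_values):
        assert z == pytest.approx(brute_force_dunn_z(groups, i, j), rel=1e-9)


def test_dunn_adjustments_are_monotone():
    groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
    raw = dunn_posthoc(_cohort_from_groups(groups), "f", "cd4", adjustment="none")
    bonf = dunn_posthoc(_cohort_from_groups(groups), "f", "cd4", adjustment="bonferroni")
    holm = dunn_posthoc(_cohort_from_groups(groups), "f", "cd4", adjustment="holm")
    for p_raw, p_b, p_h in zip(raw.p_values, bonf.p_values, holm.p_values):
        assert p_raw <= p_h <= p_b + 1e-15


def test_mann_whitney_enumeration_and_symmetry():
    df = pd.DataFrame(
        {
            "id": range(6),
            "f": [1, 2, 3, 4, 5, 6],
            "grp": ["a", "a", "a", "b", "b", "b"],
        }
    )
    u, p = mann_whitney(Cohort(df), "f", "grp")
    assert u in (0.0, 9.0)  # U of the first group under either convention
    # exact two-sided p for complete separation with n1=n2=3: 2 * 1/C(6,3)
    assert p == pytest.approx(2 / 20, rel=1e-9)
    df2 = df.assign(grp=df["grp"].map({"a": "b", "b": "a"}))
    u2, p2 = mann_whitney(Cohort(df2), "f", "grp")
    assert u2 == 9.0 - u
    assert p2 == pytest.approx(p, rel=1e-12)


def test_mann_whitney_identical_groups():
    df = pd.DataFrame({"id": range(6), "f": [1, 2, 3, 1, 2, 3], "grp": list("aaabbb")})
    _, p = mann_whitney(Cohort(df), "f", "grp")
    assert p == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


def _tiny_survival_df():
    # six patients, untied event times, one binary covariate
    return pd.DataFrame(
        {
            "id": range(6),
            "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
            "rfs_months": [2.0, 5.0, 11.0, 3.0, 7.0, 13.0],
            "event": [1, 1, 0, 1, 0, 1],
        }
    )


def test_cox_tiny_dataset_matches_hand_partial_likelihood():
    df = _tiny_survival_df()
    res = cox_fit(Cohort(df), ["x"], scalings={"x": 1.0})
    times = df["rfs_months"].tolist()
    events = df["event"].tolist()
    x = df["x"].tolist()
    opt = minimize_scalar(
        lambda b: -cox_partial_loglik(b, times, events, x),
        bounds=(-5, 5),
        method="bounded",
        options={"xatol": 1e-10},
    )
    assert res.coefficients["x"] == pytest.approx(opt.x, abs=1e-5)
    assert res.log_likelihood == pytest.approx(
        cox_partial_loglik(res.coefficients["x"], times, events, x), rel=1e-9
    )


def test_cox_symmetric_groups_give_null_coefficient():
    df = pd.DataFrame(
        {
            "id": range(8),
            "x": [0, 0, 0, 0, 1, 1, 1, 1],
            "rfs_months": [1.0, 4.0, 6.0, 9.0] * 2,
            "event": [1, 0, 1, 0] * 2,
        }
    )
    res = cox_fit(Cohort(df), ["x"], scalings={"x": 1.0})
    assert res.coefficients["x"] == pytest.approx(0.0, abs=1e-8)
    assert res.hazard_ratios["x"] == pytest.approx(1.0, abs=1e-8)


def test_cox_without_events_raises():
    df = _tiny_survival_df().assign(event=0)
    with pytest.raises(ValueError, match="no events"):
        cox_fit(Cohort(df), ["x"])


def test_cox_scaling_changes_coefficient_not_fit():
    cohort = generate_cohort(CohortSpec(n_patients=400, seed=3))
    res_unit = cox_fit(cohort, ["cov_suv"], scalings={"cov_suv": 1.0})
    res_tenth = cox_fit(cohort, ["cov_suv"], scalings={"cov_suv": 0.1})
    assert res_tenth.coefficients["cov_suv"] == pytest.approx(
        0.1 * res_unit.coefficients["cov_suv"], rel=1e-6
    )
    assert res_tenth.p_values["cov_suv"] == pytest.approx(res_unit.p_values["cov_suv"], rel=1e-6)


def test_univariate_screen_selects_strong_rejects_null():
    correct = 0
    reps = 30
    for s in range(reps):
        cohort = generate_cohort(
            CohortSpec(
                n_patients=1000,
                log_hazard_coefs={"slr": math.log(24.901)},
                seed=1000 + s,
            )
        )
        df = cohort.records.copy()
        rng = np.random.default_rng(s)
        df["null_cov"] = rng.normal(size=len(df))
        selected, _ = univariate_screen(Cohort(df), ["slr", "null_cov"], alpha=0.05)
        if "slr" in selected and "null_cov" not in selected:
            correct += 1
    assert correct / reps >= 0.9


def test_univariate_screen_alpha_one_selects_all():
    cohort = generate_cohort(CohortSpec(n_patients=200, seed=5))
    selected, _ = univariate_screen(cohort, ["cov_suv", "slr", "mtv_cm3"], alpha=1.0)
    assert selected == ["cov_suv", "slr", "mtv_cm3"]


def test_univariate_screen_empty_candidates_raise():
    cohort = generate_cohort(CohortSpec(n_patients=50, seed=5))
    with pytest.raises(ValueError, match="empty"):
        univariate_screen(cohort, [])


# ---------------------------------------------------------------------------
# ROC cutoff
# ---------------------------------------------------------------------------


def test_roc_cutoff_perfect_separation_returns_lowest_midpoint():
    df = pd.DataFrame(
        {"id": range(8), "f": [1, 2, 3, 4, 10, 11, 12, 13], "event": [0, 0, 0, 0, 1, 1, 1, 1]}
    )
    res = roc_cutoff(Cohort(df), "f")
    assert res.youden_j == pytest.approx(1.0)
    assert res.cutoff == pytest.approx((4 + 10) / 2.0)
    assert res.direction == "high_positive"


@pytest.mark.parametrize("seed", range(20))
def test_roc_cutoff_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = 60
    x = np.round(rng.normal(size=n), 2)
    y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    df = pd.DataFrame({"id": range(n), "f": x, "event": y})
    res = roc_cutoff(Cohort(df), "f")
    cut, j = brute_force_youden(x, y)
    assert res.youden_j == pytest.approx(j, abs=1e-12)
    assert res.cutoff == pytest.approx(cut, abs=1e-12)


def test_roc_cutoff_near_zero_j_for_independent_feature():
    rng = np.random.default_rng(123)
    ok = 0
    reps = 40
    for _ in range(reps):
        n = 500
        df = pd.DataFrame(
            {
                "id": range(n),
                "f": rng.normal(size=n),
                "event": rng.permutation([1] * 125 + [0] * 375),
            }
        )
        if roc_cutoff(Cohort(df), "f").youden_j <= 0.2:
            ok += 1
    assert ok / reps >= 0.95


def test_roc_cutoff_single_class_raises():
    df = pd.DataFrame({"id": range(4), "f": [1, 2, 3, 4], "event": [1, 1, 1, 1]})
    with pytest.raises(ValueError, match="both outcome classes"):
        roc_cutoff(Cohort(df), "f")


# ---------------------------------------------------------------------------
# Kaplan-Meier and the stratified recurrence table
# ---------------------------------------------------------------------------


def test_km_hand_computed_product_limit():
    # times 5+ 10 15+ 20 (+ censored): S(10) = 2/3, S(20) = 0
    df = pd.DataFrame(
        {
            "id": range(8),
            "rfs_months": [5.0, 10.0, 15.0, 20.0] * 2,
            "event": [0, 1, 0, 1] * 2,
            "grp": ["a"] * 4 + ["b"] * 4,
        }
    )
    curves, chi2, p = km_logrank(Cohort(df), "grp")
    for c in curves.values():
        assert c.survival_at(10.0) == pytest.approx(2 / 3, rel=1e-12)
        assert c.survival_at(20.0) == pytest.approx(0.0, abs=1e-12)
        assert c.survival_at(1.0) == 1.0
    # identical duplicated groups: log-rank cannot distinguish them
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=1e-9)


def test_km_no_events_survival_stays_one():
    df = pd.DataFrame(
        {
            "id": range(6),
            "rfs_months": [3.0, 6.0, 9.0] * 2,
            "event": [0] * 6,
            "grp": list("aaabbb"),
        }
    )
    curves, _, _ = km_logrank(Cohort(df), "grp")
    for c in curves.values():
        assert np.all(c.survival == 1.0)


def test_km_zero_censoring_equals_empirical_survival():
    rng = np.random.default_rng(7)
    times = rng.exponential(10.0, 40).round(3)
    df = pd.DataFrame(
        {
            "id": range(80),
            "rfs_months": np.concatenate([times, times]),
            "event": 1,
            "grp": ["a"] * 40 + ["b"] * 40,
        }
    )
    curves, _, _ = km_logrank(Cohort(df), "grp")
    c = curves["a"]
    for t in (1.0, 5.0, 15.0):
        assert c.survival_at(t) == pytest.approx((times > t).mean(), rel=1e-12)


def _strat_cohort(cells):
    """cells: {(stage_group, imaging_group): (events, total)} -> Cohort."""
    rows = []
    cov_slr = {
        "both_favorable": (0.30, 0.70),
        "mixed": (0.30, 0.90),
        "both_unfavorable": (0.20, 0.90),
    }
    for (sg, ig), (events, total) in cells.items():
        stage = "II" if sg == "I-II" else "III"
        cov, slr = cov_slr[ig]
        for i in range(total):
            rows.append(
                {
                    "id": f"{sg}_{ig}_{i}",
                    "tnm_stage": stage,
                    "cov_suv": cov,
                    "slr": slr,
                    "event": 1 if i < events else 0,
                }
            )
    return Cohort(pd.DataFrame(rows))


def test_strat_table_reproduces_printed_rates():
    cells = {
        ("I-II", "both_favorable"): (1, 19),
        ("I-II", "mixed"): (5, 32),
        ("I-II", "both_unfavorable"): (4, 12),
        ("III-IV", "both_favorable"): (1, 15),
        ("III-IV", "mixed"): (6, 21),
        ("III-IV", "both_unfavorable"): (13, 20),
    }
    table = recurrence_strat_table(_strat_cohort(cells))
    assert round(table.rate("I-II", "both_favorable"), 1) == 5.3
    assert round(table.rate("III-IV", "both_favorable"), 1) == 6.7
    assert round(table.rate("I-II", "both_unfavorable"), 1) == 33.3
    assert round(table.rate("III-IV", "both_unfavorable"), 1) == 65.0
    assert round(table.rate("I-II", "mixed"), 1) == 15.6
    assert round(table.rate("III-IV", "mixed"), 1) == 28.6
    totals = sum(c["total"] for c in table.cells.values())
    assert totals == 119 and table.excluded == 0


def test_strat_table_empty_cell_and_exclusions():
    cells = {("I-II", "both_favorable"): (1, 5), ("III-IV", "mixed"): (2, 4)}
    cohort = _strat_cohort(cells)
    df = cohort.records.copy()
    df.loc[df.index[-1], "cov_suv"] = np.nan
    table = recurrence_strat_table(Cohort(df))
    assert table.rate("I-II", "both_unfavorable") is None
    assert table.excluded == 1
    frame = table.to_frame()
    assert frame["total"].sum() == len(df) - 1
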