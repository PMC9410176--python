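"""Statistical layer: summaries, exact tests vs oracles, OLS calibration."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repolab import (build_summary_table, fisher_exact, fit_linear_model,
                     flag_abnormal, kruskal_wallis, summarize)
from repolab.cohort_stats import format_percent, render_p
from repolab.errors import (CollinearCovariatesError, EmptyGroupError,
                            InvalidReferenceError)


def fisher_oracle(table) -> Fraction:
    """Exact probability-mass enumeration with rational arithmetic."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), 1)
             for k in range(lo, hi + 1)]
    total = sum(probs)
    obs = probs[a - lo]
    return sum(p for p in probs if p <= obs) / total


def test_summarize_hand_case():
    mean, sem, n = summarize([1.0, 2.0, 3.0])
    assert mean == pytest.approx(2.0)
    assert sem == pytest.approx(1.0 / math.sqrt(3.0))  # sd = 1 with n-1
    assert n == 3


def test_summarize_degenerate_cases():
    with pytest.warns(UserWarning, match="single observation"):
        mean, sem, n = summarize([4.2])
    assert (mean, sem, n) == (4.2, 0.0, 1)
    _, sem, _ = summarize([7.0, 7.0, 7.0])
    assert sem == 0.0
    with pytest.raises(EmptyGroupError, match="empty group"):
        summarize([])


def test_flag_abnormal_strict_two_sd_rule():
    assert not flag_abnormal(5.0, 5.0, 1.0)
    assert flag_abnormal(5.0 + 2.0001, 5.0, 1.0)
    assert not flag_abnormal(5.0 - 2.0, 5.0, 1.0)  # "more than" is strict
    with pytest.raises(InvalidReferenceError, match="invalid reference"):
        flag_abnormal(1.0, 0.0, 0.0)


def test_kruskal_wallis_identical_groups():
    h, p = kruskal_wallis([3.0, 3.0], [3.0, 3.0])
    assert (h, p) == (0.0, 1.0)


def test_kruskal_wallis_matches_explicit_rank_arithmetic():
    # ranks 1..6; H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7 = 27/7
    h, p = kruskal_wallis([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert h == pytest.approx(27.0 / 7.0, abs=1e-12)
    assert p == pytest.approx(stats.chi2.sf(27.0 / 7.0, df=1), abs=1e-12)


def test_kruskal_wallis_tie_correction():
    x, y = [1.0, 2.0, 2.0, 4.0], [2.0, 5.0, 6.0, 7.0]
    h, _ = kruskal_wallis(x, y)
    # independent computation: rank formula with tie correction factor
    pooled = np.array(x + y)
    r = stats.rankdata(pooled)
    n = len(pooled)
    h_raw = 12 / (n * (n + 1)) * (r[:4].sum() ** 2 / 4
                                  + r[4:].sum() ** 2 / 4) - 3 * (n + 1)
    ties = np.unique(pooled, return_counts=True)[1]
    h_ref = h_raw / (1 - (ties ** 3 - ties).sum() / (n ** 3 - n))
    assert h == pytest.approx(h_ref, abs=1e-12)


def test_fisher_unit_probability_table():
    # both tables with these margins are equally probable: p = 1
    assert fisher_exact([[1, 0], [0, 1]]) == pytest.approx(1.0)


def test_fisher_statin_style_table_matches_enumeration():
    table = [[30, 20], [27, 47]]  # 60% of 50 vs 36.5% of 74
    p = fisher_exact(table)
    assert p == pytest.approx(float(fisher_oracle(table)), abs=1e-12)
    assert p < 0.05


def test_fisher_zero_margin_warns():
    with pytest.warns(UserWarning, match="zero margin"):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0


def test_fisher_random_tables_match_oracle_and_bounds():
    rng = np.random.default_rng(17)
    for _ in range(200):
        t = rng.integers(0, 13, size=(2, 2))
        if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
            continue
        p = fisher_exact(t)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(float(fisher_oracle(t.tolist())), abs=1e-12)


def test_fisher_doubling_rule():
    table = [[12, 3], [4, 11]]
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), 1)
             for k in range(lo, hi + 1)]
    total = sum(probs)
    lower = sum(probs[:a - lo + 1]) / total
    upper = sum(probs[a - lo:]) / total
    expected = min(1, 2 * min(lower, upper))
    assert fisher_exact(table, method="doubling") == pytest.approx(
        float(expected), abs=1e-12)


def _null_cohort(n=124, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "group": ["control"] * 74 + ["DM/IFG"] * 50,
        "age": rng.normal(57, 10, n),
        "sex": rng.choice(["M", "F"], n),
        "height": rng.normal(1.70, 0.09, n),
        "weight": rng.normal(80, 12, n),
        "dyslipidemia": rng.integers(0, 2, n),
        "hypertension": rng.integers(0, 2, n),
        "fhx_ihd": rng.integers(0, 2, n),
        "aspirin": rng.integers(0, 2, n),
        "acei_arb": rng.integers(0, 2, n),
        "ccb": rng.integers(0, 2, n),
        "beta_blocker": rng.integers(0, 2, n),
        "statin": rng.integers(0, 2, n),
        "thiazide": rng.integers(0, 2, n),
    })
    return df


def test_linear_model_exact_recovery_without_noise():
    df = _null_cohort(seed=1)
    group = (df["group"] != "control").astype(float)
    df["tcrt_averaged"] = 0.44 - 0.36 * group
    res = fit_linear_model(df, outcome="tcrt_averaged")
    coef = res.coefficients["coef"]
    assert coef["group"] == pytest.approx(-0.36, abs=1e-10)
    others = coef.drop("group")
    assert np.all(np.abs(others) < 1e-10)


def test_linear_model_duplicated_covariate_collinear():
    df = _null_cohort(seed=2)
    df["age2"] = df["age"]
    df["tcrt_averaged"] = 0.1
    with pytest.raises(CollinearCovariatesError, match="collinear covariates"):
        fit_linear_model(df, outcome="tcrt_averaged",
                         covariates=["group", "age", "age2"])


def test_linear_model_type_i_error_controlled():
    # pure-noise outcome: coefficient t-statistics should essentially never
    # cross the 0.999 two-sided threshold
    rng = np.random.default_rng(3)
    df = _null_cohort(seed=3)
    crossings = 0
    total = 0
    for _ in range(200):
        df["tcrt_averaged"] = rng.normal(0, 1, len(df))
        res = fit_linear_model(df, outcome="tcrt_averaged")
        t_crit = stats.t.ppf(1 - 0.001 / 2, df=res.n - len(res.coefficients) - 1)
        tstat = np.abs(res.coefficients["coef"] / res.coefficients["se"])
        crossings += int((tstat > t_crit).sum())
        total += len(tstat)
    assert crossings / total < 0.01


def test_linear_model_bias_and_coverage():
    rng = np.random.default_rng(4)
    df = _null_cohort(seed=4)
    group = (df["group"] != "control").astype(float).to_numpy()
    beta = -0.36
    hits = 0
    estimates = []
    n_rep = 400
    for _ in range(n_rep):
        df["tcrt_averaged"] = 0.44 + beta * group + rng.normal(0, 0.3, len(df))
        res = fit_linear_model(df, outcome="tcrt_averaged")
        est = res.coefficients.loc["group", "coef"]
        se = res.coefficients.loc["group", "se"]
        t_crit = stats.t.ppf(0.975, df=res.n - len(res.coefficients) - 1)
        hits += abs(est - beta) <= t_crit * se
        estimates.append(est)
    assert abs(np.mean(estimates) - beta) < 0.01
    assert 0.92 <= hits / n_rep <= 0.98


def test_summary_table_null_cohort_mostly_ns():
    df = _null_cohort(seed=5)
    rng = np.random.default_rng(5)
    df["tcrt_averaged"] = rng.normal(0.4, 0.3, len(df))
    df["tmd_averaged"] = rng.normal(20, 8, len(df))
    table = build_summary_table(df)
    assert len(table) >= 15
    # at alpha = 0.05 on a null cohort, false flags should be rare
    assert table["significant"].sum() <= 2
    assert set(table.loc[~table["significant"], "p_rendered"]) == {"NS"}


def test_summary_table_formatting_rules():
    assert format_percent(27, 74) == "36.5"
    assert render_p(0.6) == "NS"
    assert render_p(0.004) == "<0.01"
    assert render_p(0.03) == "0.03"


def test_summary_table_binary_vs_continuous_routing():
    df = _null_cohort(seed=6)
    table = build_summary_table(df).set_index("variable")
    assert table.loc["statin", "test"] == "fisher_exact"
    assert table.loc["age", "test"] == "kruskal_wallis"
    assert "±" in table.loc["age", "control"]
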