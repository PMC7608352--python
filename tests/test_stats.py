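"""2x2 association statistics, preprocessing rules and the regression battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from cnvpheno.stats import (
    FECUNDITY_CAPS,
    OUTCOME_SPECS,
    AssociationResult,
    ContingencyTable,
    FitFailure,
    OutcomeSpec,
    attainment_proportions,
    fecundity_analysis,
    fit_adjusted_model,
    or_ci_chi2,
    preprocess_outcome,
)


class TestOrCiChi2:
    def test_cvm_table(self):
        """Carrier-by-CVM counts from a ~475k cohort: OR 1.73 [1.08, 2.75]."""
        r = or_ci_chi2(ContingencyTable(18, 2774, 1769, 470611))
        assert round(r.odds_ratio, 2) == 1.73
        assert round(r.ci_low, 2) == 1.08
        assert round(r.ci_high, 2) == 2.75
        assert round(r.p, 2) == 0.03
        assert round(r.prevalence_cases, 2) == 0.64

    def test_neuropsych_table(self):
        r = or_ci_chi2(ContingencyTable(24, 3480, 1808, 481522))
        assert round(r.odds_ratio, 2) == 1.84
        assert round(r.ci_low, 2) == 1.23
        assert round(r.ci_high, 2) == 2.75
        assert round(r.p, 3) == 0.004

    def test_yates_statistic_matches_reference_implementation(self):
        """Cross-check the hand-rolled corrected chi-squared against scipy."""
        for cells in [(18, 2774, 1769, 470611), (7, 13, 29, 111), (5, 5, 5, 5)]:
            a, b, c, d = cells
            r = or_ci_chi2(ContingencyTable(a, b, c, d))
            chi2_ref, p_ref = chi2_contingency(
                [[a, b], [c, d]], correction=True
            )[:2]
            assert r.chi2 == pytest.approx(chi2_ref)
            assert r.p == pytest.approx(p_ref)

    def test_identical_rows_null(self):
        r = or_ci_chi2(ContingencyTable(10, 90, 10, 90))
        assert r.odds_ratio == 1.0
        assert r.p == 1.0  # Yates correction floors the statistic at 0

    def test_single_zero_cell_haldane(self):
        r = or_ci_chi2(ContingencyTable(0, 10, 5, 85))
        assert r.haldane_corrected
        assert r.odds_ratio == pytest.approx((0.5 * 85.5) / (10.5 * 5.5))
        assert r.prevalence_cases == 0.0

    def test_exact_ci_method(self):
        """The conditional-exact interval agrees with scipy's reference and
        is wider than Woolf on a sparse table."""
        from scipy.stats.contingency import odds_ratio as scipy_or

        woolf = or_ci_chi2(ContingencyTable(7, 13, 29, 111))
        exact = or_ci_chi2(ContingencyTable(7, 13, 29, 111), ci_method="exact")
        ref = scipy_or([[7, 13], [29, 111]], kind="conditional")
        assert exact.odds_ratio == pytest.approx(ref.statistic)
        ci = ref.confidence_interval(0.95)
        assert (exact.ci_low, exact.ci_high) == pytest.approx((ci.low, ci.high))
        assert exact.ci_high - exact.ci_low > woolf.ci_high - woolf.ci_low
        assert exact.chi2 == woolf.chi2  # test statistic unchanged

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="zero margin"):
            or_ci_chi2(ContingencyTable(0, 0, 5, 95))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


@settings(derandomize=True, max_examples=200)
@given(st.tuples(*[st.integers(1, 500)] * 4))
def test_or_reciprocity_under_row_swap(cells):
    """Swapping case and control rows inverts the OR, fixes chi2 and p."""
    a, b, c, d = cells
    r1 = or_ci_chi2(ContingencyTable(a, b, c, d))
    r2 = or_ci_chi2(ContingencyTable(c, d, a, b))
    assert r2.odds_ratio == pytest.approx(1 / r1.odds_ratio)
    assert r2.ci_low == pytest.approx(1 / r1.ci_high)
    assert r2.chi2 == pytest.approx(r1.chi2)
    assert r2.p == pytest.approx(r1.p)


def test_woolf_ci_coverage_under_true_or():
    """Simulated 2x2 tables: the 95% CI covers the true OR ~95% of the time."""
    rng = np.random.default_rng(42)
    true_or = 2.0
    p0 = 0.10
    p1 = (true_or * p0 / (1 - p0)) / (1 + true_or * p0 / (1 - p0))
    n_case, n_ctrl = 500, 2000
    hits = 0
    reps = 2000
    for _ in range(reps):
        a = rng.binomial(n_case, p1)
        c = rng.binomial(n_ctrl, p0)
        r = or_ci_chi2(ContingencyTable(a, n_case - a, c, n_ctrl - c))
        hits += r.ci_low <= true_or <= r.ci_high
    assert abs(hits / reps - 0.95) < 0.02


class TestPreprocessing:
    @pytest.mark.parametrize("raw, binary", [(7, 1), (6, 0), (3, 0), (12, 1)])
    def test_numeric_memory_binarization(self, raw, binary):
        kept, _ = preprocess_outcome(
            OUTCOME_SPECS["numeric_memory"], pd.Series([raw])
        )
        assert kept.iloc[0] == binary

    @pytest.mark.parametrize("raw, binary", [(0, 0), (3, 1), (1, 1)])
    def test_pairs_matching_binarization(self, raw, binary):
        kept, _ = preprocess_outcome(
            OUTCOME_SPECS["pairs_matching"], pd.Series([raw])
        )
        assert kept.iloc[0] == binary

    def test_five_sd_rule_single_pass(self):
        rng = np.random.default_rng(0)
        values = pd.Series(np.r_[rng.normal(500, 100, 999), 1e6])
        kept, log = preprocess_outcome(OUTCOME_SPECS["reaction_time"], values)
        assert log["n_removed"] == 1
        assert kept.isna().iloc[-1]
        # mean/SD computed on the pre-removal sample, applied once
        assert log["mean"] == pytest.approx(values.mean())

    def test_fecundity_sex_caps(self):
        values = pd.Series([9, 8, 8, 7, 2])
        sex = pd.Series(["male", "male", "female", "female", "male"])
        kept, log = preprocess_outcome(
            OUTCOME_SPECS["fecundity"], values, sex=sex
        )
        # male 9 (>8) and female 8 (>7) removed; male 8 and female 7 kept
        assert list(kept.isna()) == [True, False, True, False, False]
        assert log["n_removed"] == 2

    def test_non_numeric_reports_row(self):
        with pytest.raises(ValueError, match="row 1"):
            preprocess_outcome(
                OUTCOME_SPECS["reaction_time"], pd.Series([500.0, "fast", 510.0])
            )


def _synthetic_rows(rng, n, effect, family, carrier_rate=0.05):
    carrier = rng.random(n) < carrier_rate
    age = rng.integers(40, 70, n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    lin = 0.01 * (age - 55) + 0.1 * (sex == "male") + effect * carrier
    if family == "linear":
        y = 500 + 100 * lin + rng.normal(0, 50, n)
    elif family == "poisson":
        y = rng.poisson(np.exp(np.log(2.0) + lin))
    else:  # logistic
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
    return pd.DataFrame(
        {"y": y, "carrier": carrier, "age": age, "sex": sex}
    )


class TestAdjustedModels:
    def test_poisson_intercept_closed_form(self):
        """With constant outcome k and no covariate signal, intercept = log k."""
        rows = pd.DataFrame(
            {
                "y": [3.0] * 40,
                "carrier": [False] * 20 + [True] * 20,
                "age": [50] * 40,
                "sex": ["male"] * 40,
            }
        )
        spec = OutcomeSpec("y", "poisson", "none")
        res = fit_adjusted_model(spec, rows, adjust=False)
        assert res.terms["const"].coef == pytest.approx(np.log(3.0), abs=1e-6)
        assert res.terms["deletion"].coef == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize(
        "family, effect",
        [("linear", 25.0), ("poisson", -0.15), ("logistic", 0.6)],
    )
    def test_parameter_recovery_within_3_se(self, family, effect):
        rng = np.random.default_rng(7)
        rows = _synthetic_rows(rng, 60_000, effect if family != "linear" else 0.25,
                               family)
        true = effect if family != "linear" else 25.0
        spec = OutcomeSpec("y", family, "none")
        res = fit_adjusted_model(spec, rows.rename(columns={"y": "y"}), adjust=True)
        t = res.terms["deletion"]
        assert abs(t.coef - true) < 3 * t.se

    def test_single_group_rejected(self):
        rows = pd.DataFrame(
            {"y": [1.0, 2.0], "carrier": [False, False], "age": [50, 60],
             "sex": ["male", "female"]}
        )
        with pytest.raises(FitFailure, match="carrier"):
            fit_adjusted_model(OutcomeSpec("y", "linear", "none"), rows)

    def test_null_coverage(self):
        """Null deletion effect: the 95% Wald CI covers 0 at ~nominal rate."""
        rng = np.random.default_rng(123)
        covered = 0
        reps = 100
        for _ in range(reps):
            rows = _synthetic_rows(rng, 2_000, 0.0, "linear", carrier_rate=0.1)
            res = fit_adjusted_model(OutcomeSpec("y", "linear", "none"), rows)
            lo, hi = res.terms["deletion"].ci
            covered += lo <= 0 <= hi
        assert covered >= 93


class TestMultinomial:
    def test_qualifications_effect_recovery(self):
        rng = np.random.default_rng(5)
        n = 40_000
        carrier = rng.random(n) < 0.05
        # carrier log-odds of degree vs other: -0.5; a_levels vs other: -0.2
        probs_nc = np.array([0.56, 0.33, 0.11])
        odds_c = probs_nc * np.array([1.0, np.exp(-0.5), np.exp(-0.2)])
        probs_c = odds_c / odds_c.sum()
        cats = np.array(["other", "degree", "a_levels"], dtype=object)
        y = np.empty(n, dtype=object)
        y[~carrier] = rng.choice(cats, size=(~carrier).sum(), p=probs_nc)
        y[carrier] = rng.choice(cats, size=carrier.sum(), p=probs_c)
        rows = pd.DataFrame(
            {
                "qualifications": y,
                "carrier": carrier,
                "age": rng.integers(40, 70, n),
                "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            }
        )
        res = fit_adjusted_model(OUTCOME_SPECS["qualifications"], rows)
        deg = res.category_odds["degree"]
        alev = res.category_odds["a_levels"]
        assert abs(deg.coef - (-0.5)) < 3 * deg.se
        assert abs(alev.coef - (-0.2)) < 3 * alev.se


class TestFecundity:
    def test_sex_specific_deficit_detected(self):
        rng = np.random.default_rng(9)
        n = 100_000
        carrier = rng.random(n) < 0.02
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        rate = np.where(
            sex == "male", np.where(carrier, 1.66, 1.80), np.where(carrier, 1.82, 1.82)
        )
        rows = pd.DataFrame(
            {
                "fecundity": rng.poisson(rate),
                "carrier": carrier,
                "age": rng.integers(40, 70, n),
                "sex": sex,
            }
        )
        male, female, inter_p = fecundity_analysis(rows)
        assert male.terms["deletion"].coef < 0
        assert abs(male.terms["deletion"].coef - np.log(1.66 / 1.80)) < (
            3 * male.terms["deletion"].se
        )
        assert abs(female.terms["deletion"].coef) < 3 * female.terms["deletion"].se

    def test_single_sex_input(self):
        rng = np.random.default_rng(2)
        rows = pd.DataFrame(
            {
                "fecundity": rng.poisson(1.8, 500),
                "carrier": rng.random(500) < 0.2,
                "age": rng.integers(40, 70, 500),
                "sex": ["male"] * 500,
            }
        )
        male, female, inter_p = fecundity_analysis(rows)
        assert male is not None and female is None and inter_p is None

    def test_degenerate_all_zero_counts_in_a_group(self):
        rows = pd.DataFrame(
            {
                "fecundity": [0, 0, 0, 0, 2, 1, 2, 3],
                "carrier": [True] * 4 + [False] * 4,
                "age": [50] * 8,
                "sex": ["male"] * 8,
            }
        )
        with pytest.raises(FitFailure):
            fecundity_analysis(rows)


class TestAttainment:
    def test_degree_shares(self):
        freq = pd.DataFrame(
            {
                "non_carrier": [157_988, 54_077, 268_962],
                "carrier": [414, 185, 1_209],
            },
            index=["degree", "a_levels", "other"],
        )
        pct = attainment_proportions(freq)
        assert pct.loc["degree", "non_carrier"] == 32.8
        assert pct.loc["degree", "carrier"] == 22.9  # 414/1808
        assert pct["carrier"].sum() == pytest.approx(100.0, abs=0.2)

    def test_degenerate_single_category(self):
        freq = pd.DataFrame({"g": [0, 0, 10]}, index=["a", "b", "c"])
        pct = attainment_proportions(freq)
        assert list(pct["g"]) == [0.0, 0.0, 100.0]

    def test_zero_total_raises(self):
        freq = pd.DataFrame({"g": [0, 0, 0]}, index=["a", "b", "c"])
        with pytest.raises(ValueError, match="zero group total"):
            attainment_proportions(freq)

    def test_raw_table_odds_within_adjusted_cis(self):
        """Unadjusted odds from the attainment table lie inside the printed
        adjusted 95% CIs (sanity link between the 2x2 and multinomial views)."""
        # degree vs other, a_levels vs other; carriers vs non-carriers
        deg = (414 / 1209) / (157_988 / 268_962)
        alev = (185 / 1209) / (54_077 / 268_962)
        assert 0.51 <= deg <= 0.64
        assert 0.65 <= alev <= 0.88
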