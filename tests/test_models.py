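"""Odds-ratio machinery, regression fits and the descriptive table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from rarestay import models
from rarestay.models import (
    EffectEstimate,
    ModelSpec,
    SeparationError,
    TwoByTwoTable,
    baseline_table,
    fit_log_linear,
    fit_logistic,
    or_from_table,
    run_sensitivity,
)


class TestOrFromTable:
    def test_symmetric_table_is_null(self):
        est = or_from_table(TwoByTwoTable(1, 1, 1, 1))
        assert est.point == 1.0

    def test_zero_cell_raises_named_error(self):
        with pytest.raises(ZeroDivisionError, match="cell b"):
            or_from_table(TwoByTwoTable(3, 0, 2, 5))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(-1, 2, 3, 4)

    def test_exhaustive_small_tables_match_odds_quotient(self):
        """On every table with cells 1..12, the cross-product OR equals the
        quotient of the two groups' event odds."""
        r = np.arange(1, 13)
        a, b, c, d = np.meshgrid(r, r, r, r, indexing="ij")
        cross = (a * d) / (b * c)
        odds_quotient = (a / b) / (c / d)
        assert np.allclose(cross, odds_quotient, rtol=1e-12)

    def test_agrees_with_scipy_sample_odds_ratio(self, rng):
        for _ in range(50):
            cells = rng.integers(1, 40, size=4)
            ours = or_from_table(TwoByTwoTable(*cells)).point
            ref = scipy_odds_ratio(
                [[cells[0], cells[1]], [cells[2], cells[3]]], kind="sample"
            )
            assert ours == pytest.approx(ref.statistic, rel=1e-12)
            lo, hi = ref.confidence_interval(0.95)
            # scipy uses the same log-normal approximation; z differs in the
            # 3rd decimal (1.959964 vs 1.96)
            est = or_from_table(TwoByTwoTable(*cells))
            assert est.ci_low == pytest.approx(lo, rel=5e-4)
            assert est.ci_high == pytest.approx(hi, rel=5e-4)


def logistic_frame(rng, n=4000, beta=0.6):
    """Single binary exposure data with known log-odds effect."""
    x = rng.random(n) < 0.4
    p = 1 / (1 + np.exp(-(-2.0 + beta * x)))
    y = rng.random(n) < p
    return pd.DataFrame(
        {
            "died_in_hospital": y.astype(int),
            "rare_group": np.where(x, "1", "0"),
            "age_group": "18-34",
            "sex": "F",
            "discharge_year": 2012,
            "nonrare_dx_count": 0,
        }
    )


class TestFitLogistic:
    def test_single_binary_covariate_equals_2x2_or(self, rng):
        """With one binary predictor the MLE is the closed-form cross-product
        odds ratio; agreement to 6 significant digits."""
        df = logistic_frame(rng)
        y = df["died_in_hospital"].astype(bool)
        x = df["rare_group"] == "1"
        table = TwoByTwoTable(
            int((y & x).sum()), int((~y & x).sum()),
            int((y & ~x).sum()), int((~y & ~x).sum()),
        )
        closed = or_from_table(table)
        fit = fit_logistic(df, ModelSpec(outcome="mortality"))
        est = fit.estimate("rare_group[1]")
        assert est.point == pytest.approx(closed.point, rel=1e-6)
        assert est.ci_low == pytest.approx(closed.ci_low, rel=1e-6)
        assert est.ci_high == pytest.approx(closed.ci_high, rel=1e-6)

    def test_null_covariate_centres_on_one(self, rng):
        df = logistic_frame(rng, n=20000, beta=0.0)
        est = fit_logistic(df, ModelSpec(outcome="mortality")).estimate("rare_group[1]")
        assert est.ci_low < 1.0 < est.ci_high

    def test_separation_detected(self):
        df = pd.DataFrame(
            {
                "died_in_hospital": [1, 1, 1, 0, 0, 0],
                "rare_group": ["1", "1", "1", "0", "0", "0"],
                "age_group": "18-34",
                "sex": "F",
                "discharge_year": 2012,
                "nonrare_dx_count": 0,
            }
        )
        with pytest.raises(SeparationError):
            fit_logistic(df, ModelSpec(outcome="mortality"))

    def test_collinear_design_rejected(self, rng):
        df = cohort_frame(rng, n=500)
        df["shadow"] = df["nonrare_dx_count"] * 2.0  # linearly dependent column
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(
                df, ModelSpec(outcome="mortality", extra_covariates=("shadow",))
            )


def duration_frame(rng, n=4000, factor=1.0):
    x = rng.random(n) < 0.3
    los = np.exp(np.log(5.0) + np.log(factor) * x + 0.5 * rng.standard_normal(n))
    return pd.DataFrame(
        {
            "los_days": los,
            "rare_group": np.where(x, "1", "0"),
            "age_group": "18-34",
            "sex": "F",
            "discharge_year": 2012,
            "nonrare_dx_count": 0,
        }
    )


class TestFitLogLinear:
    def test_null_effect_recovers_factor_one(self, rng):
        fit = fit_log_linear(duration_frame(rng, n=20000), ModelSpec(outcome="los"))
        est = fit.estimate("rare_group[1]")
        assert est.ci_low < 1.0 < est.ci_high
        assert est.point == pytest.approx(1.0, abs=0.03)

    def test_scale_equivariance(self, rng):
        """Multiplying every duration by a constant leaves all factors alone."""
        df = duration_frame(rng, factor=1.3)
        fit1 = fit_log_linear(df, ModelSpec(outcome="los"))
        df2 = df.assign(los_days=df["los_days"] * 7.0)
        fit2 = fit_log_linear(df2, ModelSpec(outcome="los"))
        for e1, e2 in zip(fit1.estimates, fit2.estimates):
            assert e1.point == pytest.approx(e2.point, rel=1e-10)
            assert e1.ci_low == pytest.approx(e2.ci_low, rel=1e-10)

    def test_known_factor_recovered(self, rng):
        fit = fit_log_linear(
            duration_frame(rng, n=30000, factor=1.28), ModelSpec(outcome="los")
        )
        est = fit.estimate("rare_group[1]")
        assert est.ci_low < 1.28 < est.ci_high

    def test_ci_symmetric_on_log_scale(self, rng):
        """Back-transform consistency: the reported multiplicative CI is the
        exponential of a symmetric log-scale CI."""
        fit = fit_log_linear(duration_frame(rng, factor=1.3), ModelSpec(outcome="los"))
        for est in fit.estimates:
            assert np.log(est.ci_high / est.point) == pytest.approx(
                np.log(est.point / est.ci_low), rel=1e-9
            )

    def test_nonpositive_outcome_rejected(self, rng):
        df = duration_frame(rng, n=50)
        df.loc[0, "los_days"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            fit_log_linear(df, ModelSpec(outcome="los"))


def cohort_frame(rng, n=3000):
    g = rng.choice(["0", "1", ">1"], size=n, p=[0.88, 0.10, 0.02])
    return pd.DataFrame(
        {
            "rare_group": g,
            "age_group": rng.choice(["18-34", "35-49", "50-64", "65-79", "80+"], n),
            "sex": rng.choice(["F", "M"], n),
            "discharge_year": rng.integers(2009, 2018, n),
            "nonrare_dx_count": rng.integers(1, 12, n),
            "died_in_hospital": (rng.random(n) < 0.05).astype(int),
            "icu_admitted": (rng.random(n) < 0.1).astype(int),
            "icu_days": 0.0,
            "los_days": np.exp(rng.standard_normal(n) * 0.5 + 1.6),
            "readmission_info_complete": (rng.random(n) > 0.01).astype(int),
            "readmitted_30d": (rng.random(n) < 0.05).astype(int),
            "unit_group": rng.choice(
                ["internal-medicine-and-related", "surgical", "other"], n
            ),
            "total_stays": rng.integers(1, 5, n),
            "chapters": "",
        }
    )


class TestBaselineTable:
    def test_percentages_and_medians(self, rng):
        df = cohort_frame(rng)
        df.loc[df["died_in_hospital"] == 1, "readmitted_30d"] = 0
        table = baseline_table(df).set_index("row")
        deaths = table.loc["Number of patients who died in hospital"]
        g0 = df[df["rare_group"] == "0"]
        assert deaths["count_0"] == g0["died_in_hospital"].sum()
        assert deaths["pct_0"] == pytest.approx(100 * g0["died_in_hospital"].mean())
        los = table.loc["Length of stay in days"]
        assert los["median_0"] == pytest.approx(g0["los_days"].median())
        icu = table.loc["Total time spent in ICUs in days"]
        assert icu["mean_0"] == pytest.approx(g0["icu_days"].mean())
        assert 0 <= deaths["p_value"] <= 1

    def test_empty_group_percentages_undefined(self, rng):
        df = cohort_frame(rng, n=300)
        df["rare_group"] = "0"  # no exposed patients at all
        table = baseline_table(df).set_index("row")
        assert pd.isna(table.loc["Sex = M", "pct_1"])
        assert table.loc["Sex = M", "count_1"] == 0


class TestSensitivity:
    def test_unknown_analysis_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown sensitivity"):
            run_sensitivity("bootstrap", cohort_frame(rng), ModelSpec(outcome="mortality"))

    def test_degenerate_unit_factor_rejected(self, rng):
        df = cohort_frame(rng)
        df["unit_group"] = "surgical"
        with pytest.raises(ValueError, match="two clinical unit groups"):
            run_sensitivity(
                "rare-by-unit-interaction", df, ModelSpec(outcome="mortality")
            )

    def test_stay_count_and_interaction_terms_present(self, rng):
        df = cohort_frame(rng, n=8000)
        fit = run_sensitivity("stay-count-adjusted", df, ModelSpec(outcome="mortality"))
        assert any(e.term == "total_stays" for e in fit.estimates)
        fit = run_sensitivity(
            "rare-by-nonrare-interaction", df, ModelSpec(outcome="mortality")
        )
        terms = {e.term for e in fit.estimates}
        assert "rare_group[1]:nonrare_dx_count" in terms
        assert "rare_group[>1]:nonrare_dx_count" in terms

    def test_null_interaction_cis_cover_one(self, rng):
        """Data generated without any interaction: interaction CIs cover 1."""
        covered = []
        for seed in range(8):
            df = cohort_frame(np.random.default_rng(seed), n=12000)
            fit = run_sensitivity(
                "rare-by-nonrare-interaction", df, ModelSpec(outcome="mortality")
            )
            for term in ("rare_group[1]:nonrare_dx_count", "rare_group[>1]:nonrare_dx_count"):
                e = fit.estimate(term)
                covered.append(e.ci_low <= 1.0 <= e.ci_high)
        assert np.mean(covered) >= 0.8


class TestEffectEstimate:
    def test_inconsistent_ci_rejected(self):
        with pytest.raises(ValueError):
            EffectEstimate("x", 2.0, 2.5, 3.0, "odds-ratio")

    def test_subgroup_drops_sex_term(self, rng):
        df = cohort_frame(rng, n=6000)
        fit = fit_logistic(df, ModelSpec(outcome="mortality", subgroup_sex="F"))
        assert not any(e.term.startswith("sex") for e in fit.estimates)
        assert fit.n == (df["sex"] == "F").sum()
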