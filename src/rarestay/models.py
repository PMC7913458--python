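"""Descriptive tables and regression models for inpatient outcomes.

Binary outcomes (in-hospital mortality, ICU admission, 30-day readmission)
are modelled by multivariable logistic regression; the skewed durations
(length of stay, ICU length of stay) by ordinary least squares on the
natural-log scale, with coefficients back-transformed by exponentiation so
an Exp(B) of 1.28 reads as a 28% increase.  Every model adjusts for age
group, sex, discharge year and the count of non-rare diagnoses; the
readmission model additionally for the previous-stay category and length of
stay.  Confidence intervals are Wald-type with z = 1.96 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "Z_95",
    "TwoByTwoTable",
    "EffectEstimate",
    "ModelSpec",
    "FitResult",
    "or_from_table",
    "fit_logistic",
    "fit_log_linear",
    "fit_outcome_model",
    "baseline_table",
    "run_sensitivity",
    "SENSITIVITY_ANALYSES",
    "results_to_frame",
]

Z_95 = 1.96

AGE_REF = "18-34"
AGE_LEVELS = ("18-34", "35-49", "50-64", "65-79", "80+")
PREV_LEVELS = ("0", "1", "2", "3+")
UNIT_LEVELS = ("internal-medicine-and-related", "surgical", "other")

OUTCOME_COLUMNS = {
    "mortality": "died_in_hospital",
    "icu_admission": "icu_admitted",
    "readmission_30d": "readmitted_30d",
    "los": "los_days",
    "icu_los": "icu_days",
}
BINARY_OUTCOMES = ("mortality", "icu_admission", "readmission_30d")
DURATION_OUTCOMES = ("los", "icu_los")

SENSITIVITY_ANALYSES = (
    "stay-count-adjusted",
    "rare-by-nonrare-interaction",
    "rare-by-unit-interaction",
)


class SeparationError(RuntimeError):
    """Perfect separation or non-convergence in a logistic fit."""


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure × event contingency table.

    ``a``/``b`` are events/non-events among the exposed, ``c``/``d`` among
    the unexposed.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")


@dataclass(frozen=True)
class EffectEstimate:
    """One covariate's effect: odds ratio or multiplicative duration factor."""

    term: str
    point: float
    ci_low: float
    ci_high: float
    scale: str  # "odds-ratio" | "multiplicative"
    level: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(f"inconsistent CI for {self.term}")
        if min(self.point, self.ci_low, self.ci_high) <= 0:
            raise ValueError(f"non-positive effect bound for {self.term}")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, adjustment set and optional modifications."""

    outcome: str
    include_sex: bool = True
    subgroup_sex: str | None = None  # fit within one sex, dropping the sex term
    extra_covariates: tuple[str, ...] = ()
    interaction: str | None = None  # None | "rare_by_nonrare" | "rare_by_unit"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.subgroup_sex is not None and self.subgroup_sex not in ("F", "M"):
            raise ValueError("subgroup_sex must be 'F' or 'M'")


@dataclass
class FitResult:
    model: str
    estimates: list[EffectEstimate]
    n: int
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def estimate(self, term: str) -> EffectEstimate:
        for est in self.estimates:
            if est.term == term:
                return est
        raise KeyError(term)


def or_from_table(t: TwoByTwoTable) -> EffectEstimate:
    """Cross-product odds ratio with a Wald 95% CI.

    Identical to the coefficient of an unadjusted logistic regression with a
    single binary exposure.  Zero cells raise — no continuity correction is
    applied silently.
    """
    for name in "abcd":
        if getattr(t, name) == 0:
            raise ZeroDivisionError(
                f"cell {name} of the 2x2 table is zero; odds ratio/CI undefined"
            )
    point = (t.a * t.d) / (t.b * t.c)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    log_or = np.log(point)
    return EffectEstimate(
        term="exposure",
        point=float(point),
        ci_low=float(np.exp(log_or - Z_95 * se)),
        ci_high=float(np.exp(log_or + Z_95 * se)),
        scale="odds-ratio",
    )


def _dummies(values: pd.Series, levels: tuple[str, ...], prefix: str) -> pd.DataFrame:
    """Treatment-coded indicators with the first level as reference.

    Levels absent from the data are skipped (their indicator would be a zero
    column and make the design singular).
    """
    values = values.astype(str)
    present = set(values.unique())
    unknown = present - set(levels)
    if unknown:
        raise ValueError(f"{prefix}: unexpected levels {sorted(unknown)}")
    return pd.DataFrame(
        {
            f"{prefix}[{lvl}]": (values == lvl).astype(float)
            for lvl in levels[1:]
            if lvl in present
        },
        index=values.index,
    )


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame]:
    """Response vector and design matrix (with intercept) for a model spec."""
    df = data
    if spec.subgroup_sex is not None:
        df = df.loc[df["sex"].astype(str) == spec.subgroup_sex]
    if len(df) == 0:
        raise ValueError("empty cohort for model fit")

    cols: list[pd.DataFrame | pd.Series] = []
    rare = _dummies(df["rare_group"], ("0", "1", ">1"), "rare_group")
    cols.append(rare)
    cols.append(_dummies(df["age_group"], AGE_LEVELS, "age_group"))
    if spec.include_sex and spec.subgroup_sex is None:
        cols.append(_dummies(df["sex"], ("F", "M"), "sex"))
    year = df["discharge_year"].astype(float)
    cols.append((year - year.min()).rename("discharge_year"))
    cols.append(df["nonrare_dx_count"].astype(float).rename("nonrare_dx_count"))

    if spec.outcome == "readmission_30d":
        cols.append(_dummies(df["previous_stay_category"], PREV_LEVELS, "previous_stays"))
        cols.append(df["los_days"].astype(float).rename("los_days"))

    for extra in spec.extra_covariates:
        cols.append(df[extra].astype(float).rename(extra))

    if spec.interaction == "rare_by_nonrare":
        burden = df["nonrare_dx_count"].astype(float)
        for col in rare.columns:
            cols.append((rare[col] * burden).rename(f"{col}:nonrare_dx_count"))
    elif spec.interaction == "rare_by_unit":
        if df["unit_group"].astype(str).nunique() < 2:
            raise ValueError(
                "unit-group interaction requires at least two clinical unit groups"
            )
        unit = _dummies(df["unit_group"], UNIT_LEVELS, "unit_group")
        cols.append(unit)
        for rcol in rare.columns:
            for ucol in unit.columns:
                cols.append((rare[rcol] * unit[ucol]).rename(f"{rcol}:{ucol}"))
    elif spec.interaction is not None:
        raise ValueError(f"unknown interaction {spec.interaction!r}")

    X = pd.concat(cols, axis=1)
    # constant columns carry no information and break the ML fit
    keep = [c for c in X.columns if X[c].nunique() > 1]
    X = X[keep]
    X.insert(0, "Intercept", 1.0)
    outcome_col = OUTCOME_COLUMNS[spec.outcome]
    y = df[outcome_col]
    return y, X


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]} columns); "
            "check for collinear covariates"
        )


def _term_level(name: str) -> tuple[str, str]:
    if "[" in name and name.endswith("]") and ":" not in name:
        base, level = name[:-1].split("[", 1)
        return base, level
    return name, ""


def fit_logistic(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Maximum-likelihood logistic regression; per-term ORs with Wald 95% CIs."""
    if spec.outcome not in BINARY_OUTCOMES:
        raise ValueError(f"{spec.outcome} is not a binary outcome")
    y, X = build_design(data, spec)
    y = y.astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("logistic outcome must be 0/1")
    _check_rank(X)
    model = sm.Logit(y.to_numpy(), X.to_numpy())
    try:
        fit = model.fit(method="newton", maxiter=100, tol=1e-8, disp=False)
        if not fit.mle_retvals.get("converged", False):
            # Newton can oscillate near-flat likelihoods; retry with a
            # line-search optimizer before declaring separation.
            fit = model.fit(method="lbfgs", maxiter=500, disp=False)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge (possible separation)")
    estimates = []
    for i, name in enumerate(X.columns):
        if name == "Intercept":
            continue
        coef, se = fit.params[i], fit.bse[i]
        if not np.isfinite(se) or se > 1e3:
            raise SeparationError(f"unstable standard error for term {name}")
        term, level = _term_level(name)
        estimates.append(
            EffectEstimate(
                term=name,
                level=level,
                point=float(np.exp(coef)),
                ci_low=float(np.exp(coef - Z_95 * se)),
                ci_high=float(np.exp(coef + Z_95 * se)),
                scale="odds-ratio",
            )
        )
    return FitResult(
        model=spec.outcome,
        estimates=estimates,
        n=len(y),
        converged=True,
        diagnostics={"loglik": float(fit.llf), "iterations": fit.mle_retvals.get("iterations")},
    )


def fit_log_linear(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """OLS on the natural log of a duration outcome; effects are Exp(B).

    Rows with non-positive outcome values must be excluded upstream (the
    ICU-stay cohort already restricts to ICU admissions); any that reach the
    fit raise.
    """
    if spec.outcome not in DURATION_OUTCOMES:
        raise ValueError(f"{spec.outcome} is not a duration outcome")
    y, X = build_design(data, spec)
    y = y.astype(float)
    if (y <= 0).any():
        raise ValueError(
            f"{int((y <= 0).sum())} non-positive {spec.outcome} values reached the "
            "log-linear fit; exclude them upstream"
        )
    _check_rank(X)
    fit = sm.OLS(np.log(y.to_numpy()), X.to_numpy()).fit()
    estimates = []
    for i, name in enumerate(X.columns):
        if name == "Intercept":
            continue
        coef, se = fit.params[i], fit.bse[i]
        term, level = _term_level(name)
        estimates.append(
            EffectEstimate(
                term=name,
                level=level,
                point=float(np.exp(coef)),
                ci_low=float(np.exp(coef - Z_95 * se)),
                ci_high=float(np.exp(coef + Z_95 * se)),
                scale="multiplicative",
            )
        )
    return FitResult(
        model=spec.outcome,
        estimates=estimates,
        n=len(y),
        diagnostics={"sigma": float(np.sqrt(fit.scale)), "r2": float(fit.rsquared)},
    )


def fit_outcome_model(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    if spec.outcome in BINARY_OUTCOMES:
        return fit_logistic(data, spec)
    return fit_log_linear(data, spec)


def run_sensitivity(analysis: str, data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Refit the mortality model with one named modification.

    ``stay-count-adjusted`` adds the patient's total stay count over the
    study period; the interaction analyses add rare-group × non-rare-burden
    or rare-group × clinical-unit-group terms, whose main-effect ORs are then
    read at the reference level of the interacting variable.
    """
    if analysis not in SENSITIVITY_ANALYSES:
        raise ValueError(
            f"unknown sensitivity analysis {analysis!r}; expected one of {SENSITIVITY_ANALYSES}"
        )
    if analysis == "stay-count-adjusted":
        mod = replace(spec, extra_covariates=spec.extra_covariates + ("total_stays",))
    elif analysis == "rare-by-nonrare-interaction":
        mod = replace(spec, interaction="rare_by_nonrare")
    else:
        mod = replace(spec, interaction="rare_by_unit")
    result = fit_outcome_model(data, mod)
    result.model = f"{spec.outcome}:{analysis}"
    return result


def _percent(count: int, total: int) -> float | None:
    return None if total == 0 else 100.0 * count / total


def _median_iqr(values: pd.Series) -> tuple[float, float, float]:
    q1, med, q3 = values.quantile([0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def baseline_table(data: pd.DataFrame) -> pd.DataFrame:
    """Group-wise descriptive table with between-group tests.

    One column set per rare-disease group (0 / 1 / >1): counts and
    percentages for categorical rows (age groups, sex, rare-disease
    chapters, deaths, readmission status, ICU admission), median [IQR] for
    the counts and durations, plus mean (SD) for ICU days.  Chi-squared
    p-values for categorical rows, Kruskal–Wallis for continuous rows.
    Percentages in empty groups are reported as missing, never as 0.
    """
    groups = ["0", "1", ">1"]
    by_group = {g: data.loc[data["rare_group"].astype(str) == g] for g in groups}
    sizes = {g: len(df) for g, df in by_group.items()}
    rows: list[dict] = []

    def categorical_row(label: str, indicator: pd.Series) -> None:
        counts = {g: int(indicator.loc[df.index].sum()) for g, df in by_group.items()}
        table = np.array(
            [
                [counts[g], sizes[g] - counts[g]]
                for g in groups
                if sizes[g] > 0
            ]
        )
        p = np.nan
        if table.shape[0] >= 2 and (table.sum(axis=0) > 0).all():
            p = float(stats.chi2_contingency(table)[1])
        rows.append(
            {
                "row": label,
                "kind": "categorical",
                **{f"count_{g}": counts[g] for g in groups},
                **{f"pct_{g}": _percent(counts[g], sizes[g]) for g in groups},
                "p_value": p,
            }
        )

    def continuous_row(label: str, column: str, with_mean: bool = False) -> None:
        samples = [by_group[g][column].astype(float) for g in groups if sizes[g] > 0]
        if len(samples) >= 2 and pd.concat(samples).nunique() > 1:
            p = float(stats.kruskal(*samples)[1])
        else:
            p = np.nan
        row: dict = {"row": label, "kind": "continuous", "p_value": p}
        for g in groups:
            if sizes[g] == 0:
                row[f"median_{g}"] = row[f"q1_{g}"] = row[f"q3_{g}"] = None
                continue
            med, q1, q3 = _median_iqr(by_group[g][column].astype(float))
            row[f"median_{g}"], row[f"q1_{g}"], row[f"q3_{g}"] = med, q1, q3
            if with_mean:
                row[f"mean_{g}"] = float(by_group[g][column].mean())
                row[f"sd_{g}"] = float(by_group[g][column].std())
        rows.append(row)

    rows.append(
        {"row": "Number of patients per group", "kind": "size",
         **{f"count_{g}": sizes[g] for g in groups}}
    )
    age = data["age_group"].astype(str)
    for level in AGE_LEVELS:
        categorical_row(f"Age group {level}", age == level)
    categorical_row("Sex = M", data["sex"].astype(str) == "M")
    continuous_row("Diagnosis count, excluding rare diseases", "nonrare_dx_count")
    if "chapters" in data.columns:
        chapter_lists = data["chapters"].fillna("").astype(str).str.split(";")
        all_chapters = sorted(
            {c for lst in chapter_lists for c in lst if c}
        )
        for chapter in all_chapters:
            categorical_row(chapter, chapter_lists.map(lambda lst: chapter in lst))
    categorical_row(
        "Number of patients who died in hospital", data["died_in_hospital"].astype(bool)
    )
    if "readmitted_30d" in data.columns:
        complete = data["readmission_info_complete"].astype(bool)
        readmitted = data["readmitted_30d"].fillna(0).astype(bool)
        categorical_row("30-day readmission: No", complete & ~readmitted)
        categorical_row("30-day readmission: Unknown", ~complete)
        categorical_row("30-day readmission: Yes", complete & readmitted)
    continuous_row("Length of stay in days", "los_days")
    categorical_row("ICU admissions", data["icu_admitted"].astype(bool))
    continuous_row("Total time spent in ICUs in days", "icu_days", with_mean=True)
    return pd.DataFrame(rows)


def results_to_frame(results: list[FitResult]) -> pd.DataFrame:
    """Tidy one-row-per-estimate table across fitted models."""
    records = []
    for res in results:
        for est in res.estimates:
            records.append(
                {
                    "model": res.model,
                    "term": est.term,
                    "level": est.level,
                    "estimate": est.point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "scale": est.scale,
                    "n": res.n,
                }
            )
    return pd.DataFrame(
        records,
        columns=["model", "term", "level", "estimate", "ci_low", "ci_high", "scale", "n"],
    )
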