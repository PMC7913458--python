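"""Parameter-recovery studies: generator → pipeline → estimator round trips.

The adjusted coefficients of the emulated study are not reproducible without
its hospital data, so the evidence that the modelling machinery is correct
is a simulation property: generate data with known effects, run the entire
pipeline (matching, selection, cohorts, fits) and compare the estimates to
the configured truth across replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cohort, models
from .models import ModelSpec
from .pipeline import analysis_frame
from .simulate import SyntheticConfig, generate_population
import dataclasses

__all__ = ["true_rare_effects", "replicate_estimates", "run_recovery_study"]

_OUTCOME_EFFECT = {
    "mortality": "mortality",
    "icu_admission": "icu",
    "los": "los",
    "icu_los": "icu_los",
    "readmission_30d": "readmission",
}


def true_rare_effects(config: SyntheticConfig) -> pd.DataFrame:
    """Configured true rare-group effects, one row per (outcome, level)."""
    rows = []
    for outcome, attr in _OUTCOME_EFFECT.items():
        eff = getattr(config.effects, attr)
        for level, value in zip(("1", ">1"), eff.rare):
            rows.append({"outcome": outcome, "level": level, "truth": value})
    return pd.DataFrame(rows)


def replicate_estimates(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """One full pipeline run; rare-group estimates for all five outcomes."""
    cfg = dataclasses.replace(config, seed=int(seed) % (2**31))
    dataset = generate_population(cfg)
    frame, _ = analysis_frame(
        dataset.stays, dataset.diagnoses, dataset.catalogue, seed, exposure_details=False
    )
    rows = []
    for outcome in cohort.OUTCOMES:
        sub, _ = cohort.build_outcome_cohort(frame, outcome)
        fit = models.fit_outcome_model(sub, ModelSpec(outcome=outcome))
        for level in ("1", ">1"):
            est = fit.estimate(f"rare_group[{level}]")
            rows.append(
                {
                    "seed": seed,
                    "outcome": outcome,
                    "level": level,
                    "estimate": est.point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)


def run_recovery_study(
    config: SyntheticConfig, n_replicates: int, base_seed: int = 0
) -> pd.DataFrame:
    """Replicate estimates joined with truth and per-row CI coverage."""
    child_seeds = np.random.SeedSequence(base_seed).generate_state(n_replicates)
    parts = [replicate_estimates(config, int(s) % (2**31)) for s in child_seeds]
    out = pd.concat(parts, ignore_index=True)
    out = out.merge(true_rare_effects(config), on=["outcome", "level"], validate="m:1")
    out["covered"] = (out["ci_low"] <= out["truth"]) & (out["truth"] <= out["ci_high"])
    return out


def summarize_recovery(study: pd.DataFrame) -> pd.DataFrame:
    """Per-effect median estimate, median/truth ratio and CI coverage."""
    def agg(g: pd.DataFrame) -> pd.Series:
        med = float(np.exp(np.median(np.log(g["estimate"]))))
        return pd.Series(
            {
                "truth": g["truth"].iloc[0],
                "median_estimate": med,
                "ratio": med / g["truth"].iloc[0],
                "coverage": float(g["covered"].mean()),
                "n_replicates": len(g),
            }
        )

    return (
        study.groupby(["outcome", "level"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
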