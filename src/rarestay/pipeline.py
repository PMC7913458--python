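"""End-to-end study runs: ingest or simulate, match, cohort, model, report.

A run executes the full analysis sequence — eligibility filtering, random
one-stay-per-patient selection, rare-disease exposure classification, the
per-outcome sub-cohorts, the descriptive baseline table, unadjusted odds
ratios, the five adjusted outcome models, sex-subgroup models and the three
sensitivity analyses — and writes every artifact plus a manifest that
suffices to reproduce it exactly.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, catalogue as catalogue_mod, cohort, exposure, models
from .models import ModelSpec, TwoByTwoTable
from .simulate import SyntheticConfig, SyntheticDataset, generate_population

__all__ = ["RunManifest", "run_study", "load_inputs", "analysis_frame"]


@dataclass
class RunManifest:
    seed: int
    config: dict
    stage_counts: dict[str, int] = field(default_factory=dict)
    stage_seeds: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the top-level one."""
    tag = zlib.crc32(stage.encode()) % (2**31)
    ss = np.random.SeedSequence([seed, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def load_inputs(
    stays_path: str | Path, diagnoses_path: str | Path, catalogue_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame, catalogue_mod.Catalogue]:
    stays = pd.read_csv(stays_path)
    missing = set(cohort.STAY_COLUMNS) - {"previous_stays_2y", "readmitted_30d"} - set(
        stays.columns
    )
    if missing:
        raise ValueError(f"stays table lacks columns {sorted(missing)}")
    diagnoses = pd.read_csv(diagnoses_path)
    if not {"stay_id", "icd10_code"} <= set(diagnoses.columns):
        raise ValueError("diagnoses table needs stay_id and icd10_code columns")
    cat = catalogue_mod.read_catalogue(catalogue_path)
    if {"previous_stays_2y", "readmitted_30d"} - set(stays.columns):
        stays = cohort.annotate_stay_history(stays)
    return stays, diagnoses, cat


def analysis_frame(
    stays: pd.DataFrame,
    diagnoses: pd.DataFrame,
    cat: catalogue_mod.Catalogue,
    seed: int,
    exposure_details: bool = True,
) -> tuple[pd.DataFrame, cohort.FlowReport]:
    """Eligibility → one stay per patient → exposure, merged for modelling."""
    cohort.validate_stays(stays)
    eligible, flow = cohort.filter_eligible(stays, diagnoses)
    selected = cohort.select_one_stay_per_patient(
        eligible, _stage_seed(seed, "select-stay")
    )
    exposures = exposure.summarize_exposures(
        diagnoses.loc[diagnoses["stay_id"].isin(selected["stay_id"])],
        cat,
        details=exposure_details,
    )
    frame = selected.merge(exposures, on="stay_id", how="left", validate="1:1")
    assert frame["rare_count"].notna().all()
    frame["age_group"] = cohort.age_group_series(frame["age_at_admission"])
    frame["previous_stay_category"] = cohort.previous_stay_category_series(
        frame["previous_stays_2y"]
    )
    total = stays.groupby("patient_id").size().rename("total_stays")
    frame = frame.merge(total, left_on="patient_id", right_index=True, how="left")
    return frame, flow


def _unadjusted_ors(frame: pd.DataFrame) -> list[models.FitResult]:
    """Mortality odds ratios for 1 and >1 rare diseases from 2x2 tables."""
    out = []
    died = frame["died_in_hospital"].astype(bool)
    g = frame["rare_group"].astype(str)
    c = int((died & (g == "0")).sum())
    d = int((~died & (g == "0")).sum())
    for label in ("1", ">1"):
        a = int((died & (g == label)).sum())
        b = int((~died & (g == label)).sum())
        try:
            est = models.or_from_table(TwoByTwoTable(a, b, c, d))
        except ZeroDivisionError:
            continue  # degenerate table (e.g. no deaths in a group): no OR row
        est = dataclasses.replace(est, term="rare_group", level=label)
        out.append(
            models.FitResult(
                model=f"mortality:unadjusted[{label}]", estimates=[est], n=a + b + c + d
            )
        )
    return out


def run_study(
    config: SyntheticConfig | None = None,
    *,
    inputs: tuple[str | Path, str | Path, str | Path] | None = None,
    seed: int = 0,
    out_dir: str | Path = "rarestay-run",
) -> RunManifest:
    """Run the whole study and write all artifacts to ``out_dir``.

    Either ``config`` (simulate the inputs) or ``inputs`` (paths to stays,
    diagnoses and catalogue tables) must be given.
    """
    if (config is None) == (inputs is None):
        raise ValueError("provide exactly one of config= or inputs=")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=seed,
        config={},
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )

    if config is not None:
        config = dataclasses.replace(config, seed=_stage_seed(seed, "simulate"))
        manifest.stage_seeds["simulate"] = config.seed
        dataset: SyntheticDataset = generate_population(config)
        stays, diagnoses, cat = dataset.stays, dataset.diagnoses, dataset.catalogue
        manifest.config = {"synthetic": config.to_dict()}
        stays.to_csv(out / "stays.csv", index=False)
        diagnoses.to_csv(out / "diagnoses.csv", index=False)
        catalogue_mod.write_catalogue(cat, out / "catalogue.csv")
        manifest.outputs.update(
            stays=str(out / "stays.csv"),
            diagnoses=str(out / "diagnoses.csv"),
            catalogue=str(out / "catalogue.csv"),
        )
    else:
        stays_path, dx_path, cat_path = inputs
        stays, diagnoses, cat = load_inputs(stays_path, dx_path, cat_path)
        manifest.config = {
            "inputs": {
                "stays": str(stays_path),
                "diagnoses": str(dx_path),
                "catalogue": str(cat_path),
            }
        }

    manifest.stage_counts["input_stays"] = len(stays)
    manifest.stage_counts["input_diagnoses"] = len(diagnoses)
    manifest.stage_seeds["select-stay"] = _stage_seed(seed, "select-stay")

    frame, flow = analysis_frame(stays, diagnoses, cat, seed)
    manifest.stage_counts["eligible_stays"] = flow.n_eligible_stays
    manifest.stage_counts["analyzed_patients"] = len(frame)

    frame.to_csv(out / "analysis_cohort.csv", index=False)
    exposure_cols = [
        "stay_id", "rare_count", "rare_group", "matched_codes",
        "nonrare_dx_count", "chapters",
    ]
    frame[exposure_cols].to_csv(out / "exposure.csv", index=False)

    baseline = models.baseline_table(frame)
    baseline.to_csv(out / "baseline_table.csv", index=False)

    results: list[models.FitResult] = list(_unadjusted_ors(frame))
    cohorts: dict[str, pd.DataFrame] = {}
    for outcome in cohort.OUTCOMES:
        sub, exclusions = cohort.build_outcome_cohort(frame, outcome)
        if outcome == "icu_los" and len(sub) == 0:
            raise ValueError("ICU length-of-stay cohort is empty: no ICU admissions")
        cohorts[outcome] = sub
        flow.outcome_exclusions[outcome] = {**exclusions, "analyzed": len(sub)}
        manifest.stage_counts[f"cohort_{outcome}"] = len(sub)
    for outcome in cohort.OUTCOMES:
        results.append(
            models.fit_outcome_model(cohorts[outcome], ModelSpec(outcome=outcome))
        )

    for sex in ("F", "M"):
        results.append(
            models.fit_outcome_model(
                cohorts["mortality"], ModelSpec(outcome="mortality", subgroup_sex=sex)
            )
        )
        results[-1].model = f"mortality:sex={sex}"

    for analysis in models.SENSITIVITY_ANALYSES:
        results.append(
            models.run_sensitivity(
                analysis, cohorts["mortality"], ModelSpec(outcome="mortality")
            )
        )

    tidy = models.results_to_frame(results)
    tidy.to_csv(out / "results.csv", index=False)
    (out / "results.json").write_text(
        json.dumps(tidy.to_dict(orient="records"), indent=2)
    )
    (out / "flow_report.json").write_text(json.dumps(flow.as_dict(), indent=2))
    manifest.outputs.update(
        analysis_cohort=str(out / "analysis_cohort.csv"),
        exposure=str(out / "exposure.csv"),
        baseline_table=str(out / "baseline_table.csv"),
        results=str(out / "results.csv"),
        results_json=str(out / "results.json"),
        flow_report=str(out / "flow_report.json"),
    )
    manifest.write(out / "manifest.json")
    return manifest


def load_config_file(path: str | Path) -> SyntheticConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SyntheticConfig.from_dict(data)
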