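"""Analysis-population construction from stay and diagnosis tables.

Stays live in a :class:`pandas.DataFrame` with one row per hospital stay
(see :data:`STAY_COLUMNS`); diagnoses in a long table with one row per coded
diagnosis (``stay_id, icd10_code``).  The pipeline is: keep adult stays with
at least one diagnosis, pick one stay per patient uniformly at random, then
carve the per-outcome sub-cohorts (deaths excluded from length-of-stay and
readmission analyses, ICU length-of-stay restricted to ICU stays, and so
on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STAY_COLUMNS",
    "OUTCOMES",
    "FlowReport",
    "filter_eligible",
    "select_one_stay_per_patient",
    "build_outcome_cohort",
    "derive_age_group",
    "derive_previous_stay_category",
    "age_group_series",
    "previous_stay_category_series",
    "annotate_stay_history",
    "validate_stays",
]

#: Expected stay-table columns.  Dates are ISO-8601; booleans are 0/1.
STAY_COLUMNS = [
    "stay_id",
    "patient_id",
    "age_at_admission",
    "sex",
    "admit_date",
    "discharge_date",
    "died_in_hospital",
    "icu_admitted",
    "icu_days",
    "los_days",
    "discharge_year",
    "unit_group",
    "readmission_info_complete",
    "previous_stays_2y",
    "readmitted_30d",
]

OUTCOMES = ("mortality", "icu_admission", "los", "icu_los", "readmission_30d")

AGE_BINS = [18, 35, 50, 65, 80, np.inf]
AGE_LABELS = ["18-34", "35-49", "50-64", "65-79", "80+"]

#: Admissions this many days or fewer after a discharge count as 30-day
#: readmissions (boundary inclusive).
READMISSION_WINDOW_DAYS = 30
#: Look-back window for the previous-stay count, in days.
PREVIOUS_STAY_WINDOW_DAYS = 730


@dataclass
class FlowReport:
    """Row counts at each filtering stage, mirroring a patient-flow diagram."""

    n_input_stays: int = 0
    n_removed_under_18: int = 0
    n_removed_no_diagnosis: int = 0
    n_eligible_stays: int = 0
    n_patients: int = 0
    outcome_exclusions: dict[str, dict[str, int]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input_stays": self.n_input_stays,
            "n_removed_under_18": self.n_removed_under_18,
            "n_removed_no_diagnosis": self.n_removed_no_diagnosis,
            "n_eligible_stays": self.n_eligible_stays,
            "n_patients": self.n_patients,
            "outcome_exclusions": self.outcome_exclusions,
        }


def filter_eligible(
    stays: pd.DataFrame, diagnoses: pd.DataFrame
) -> tuple[pd.DataFrame, FlowReport]:
    """Keep stays of adults (age ≥ 18 at admission) with ≥ 1 coded diagnosis."""
    report = FlowReport(n_input_stays=len(stays))
    adult = stays["age_at_admission"] >= 18
    report.n_removed_under_18 = int((~adult).sum())
    coded = stays["stay_id"].isin(diagnoses["stay_id"].unique())
    report.n_removed_no_diagnosis = int((adult & ~coded).sum())
    kept = stays.loc[adult & coded].copy()
    report.n_eligible_stays = len(kept)
    report.n_patients = kept["patient_id"].nunique()
    return kept, report


def select_one_stay_per_patient(stays: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Pick exactly one stay per patient, uniformly at random.

    Multi-stay patients would otherwise be over-represented, and rare-disease
    patients stay more often, so analyzing all stays would inflate both
    prevalence and outcome associations.  Deterministic for a fixed seed and
    input content: rows are ordered canonically before random keys are drawn.
    """
    rng = np.random.default_rng(seed)
    ordered = stays.sort_values(["patient_id", "stay_id"], kind="mergesort")
    keys = rng.random(len(ordered))
    pick = pd.Series(keys, index=ordered.index).groupby(
        ordered["patient_id"].to_numpy(), sort=True
    ).idxmin()
    return ordered.loc[sorted(pick)].copy()


def build_outcome_cohort(
    selected: pd.DataFrame, outcome: str
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Carve the sub-cohort analyzed for one outcome.

    mortality, icu_admission: every selected stay.
    los, readmission_30d:     in-hospital deaths excluded.
    icu_los:                  deaths excluded and restricted to ICU stays.
    readmission_30d:          additionally requires complete readmission
                              information (previous-stay count and follow-up).
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    cohort = selected
    exclusions: dict[str, int] = {}
    if outcome in ("los", "icu_los", "readmission_30d"):
        died = cohort["died_in_hospital"].astype(bool)
        exclusions["died_in_hospital"] = int(died.sum())
        cohort = cohort.loc[~died]
    if outcome == "icu_los":
        in_icu = cohort["icu_admitted"].astype(bool)
        exclusions["no_icu_admission"] = int((~in_icu).sum())
        cohort = cohort.loc[in_icu]
    if outcome == "readmission_30d":
        complete = cohort["readmission_info_complete"].astype(bool)
        exclusions["readmission_info_incomplete"] = int((~complete).sum())
        cohort = cohort.loc[complete]
    return cohort.copy(), exclusions


def derive_age_group(age: int) -> str:
    """Age band at admission: 18-34, 35-49, 50-64, 65-79 or 80+."""
    if age < 18:
        raise ValueError(f"age {age} below the adult threshold of 18")
    for upper, label in zip(AGE_BINS[1:], AGE_LABELS):
        if age < upper:
            return label
    raise AssertionError("unreachable")


def age_group_series(ages: pd.Series) -> pd.Series:
    if (ages < 18).any():
        bad = ages[ages < 18].iloc[0]
        raise ValueError(f"age {bad} below the adult threshold of 18")
    return pd.cut(ages, bins=AGE_BINS, labels=AGE_LABELS, right=False).astype(str)


def derive_previous_stay_category(n: int) -> str:
    """Previous-stay count category: 0, 1, 2 or 3+."""
    if n < 0:
        raise ValueError("previous-stay count cannot be negative")
    return str(int(n)) if n < 3 else "3+"


def previous_stay_category_series(counts: pd.Series) -> pd.Series:
    if (counts < 0).any():
        raise ValueError("previous-stay count cannot be negative")
    return np.where(counts >= 3, "3+", counts.astype(int).astype(str))


def annotate_stay_history(stays: pd.DataFrame) -> pd.DataFrame:
    """Derive readmission fields from the full, unselected stay history.

    For every stay: ``previous_stays_2y`` counts the patient's admissions in
    the 730 days before this admission, and ``readmitted_30d`` is true when
    any later stay by the same patient starts within 30 days after this
    discharge (boundary inclusive).  Both are computed on *all* stays, before
    any one-per-patient selection: random selection governs which stay is
    analyzed, not which events exist.  In-hospital deaths can never be
    readmitted; a death with a later stay on record is a data error.
    """
    out = stays.copy()
    n = len(out)
    admit_days = (
        pd.to_datetime(out["admit_date"]).to_numpy().astype("datetime64[D]").astype(np.int64)
    )
    disch_days = (
        pd.to_datetime(out["discharge_date"]).to_numpy().astype("datetime64[D]").astype(np.int64)
    )
    order = np.lexsort((admit_days, out["patient_id"].to_numpy()))
    admit_v = admit_days[order]
    disch_v = disch_days[order]
    pid_rank = pd.factorize(out["patient_id"].to_numpy()[order])[0].astype(np.int64)
    died_v = out["died_in_hospital"].to_numpy().astype(bool)[order]

    same_next = np.empty(n, dtype=bool)
    same_next[:-1] = pid_rank[1:] == pid_rank[:-1]
    same_next[-1] = False
    if np.any(died_v & same_next):
        bad = out["patient_id"].to_numpy()[order][died_v & same_next][0]
        raise ValueError(f"patient {bad} has a stay after an in-hospital death")

    # Collapse (patient, day) into one sortable integer key so a single global
    # searchsorted answers per-patient window queries.  Span chosen far beyond
    # any plausible date range in day units.
    span = np.int64(1) << np.int64(40)
    keys = pid_rank * span + admit_v
    lo = np.searchsorted(keys, pid_rank * span + admit_v - PREVIOUS_STAY_WINDOW_DAYS)
    hi = np.searchsorted(keys, pid_rank * span + admit_v)
    prev_sorted = (hi - lo).astype(int)

    # First admission at or after this discharge; within the patient and at
    # most 30 days after discharge ⇒ a 30-day readmission.
    j = np.searchsorted(keys, pid_rank * span + disch_v)
    j_clip = np.minimum(j, n - 1)
    hit = (
        (j < n)
        & (pid_rank[j_clip] == pid_rank)
        & (admit_v[j_clip] <= disch_v + READMISSION_WINDOW_DAYS)
    )
    readmit_sorted = hit & ~died_v

    prev = np.empty(n, dtype=int)
    readmit = np.empty(n, dtype=bool)
    prev[order] = prev_sorted
    readmit[order] = readmit_sorted
    out["previous_stays_2y"] = prev
    out["readmitted_30d"] = readmit.astype(int)
    return out


def validate_stays(stays: pd.DataFrame) -> None:
    """Assert the structural invariants every stay table must satisfy."""
    admit = pd.to_datetime(stays["admit_date"])
    discharge = pd.to_datetime(stays["discharge_date"])
    if (discharge < admit).any():
        raise ValueError("discharge before admission")
    if (stays["los_days"] <= 0).any():
        raise ValueError("non-positive length of stay")
    icu_days = stays["icu_days"].astype(float)
    if (icu_days < 0).any():
        raise ValueError("negative ICU days")
    if ((icu_days > 0) & ~stays["icu_admitted"].astype(bool)).any():
        raise ValueError("ICU days recorded without ICU admission")
    if (icu_days > stays["los_days"].astype(float) + 1e-9).any():
        raise ValueError("ICU days exceed length of stay")
    died = stays["died_in_hospital"].astype(bool)
    readmitted = stays["readmitted_30d"].fillna(0).astype(bool)
    if (died & readmitted).any():
        raise ValueError("an in-hospital death marked as readmitted")
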