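"""Synthetic inpatient populations with known ground-truth effects.

The generator emulates the structure of a large tertiary-care inpatient
cohort: two thirds of patients have a single stay, one third several
(geometric, mean 2.5); 11.5% of patients carry at least one catalogued rare
disease, and roughly one in nine of those carries more than one.  Outcomes
are drawn from the same model families the analysis fits — logistic models
for in-hospital death, ICU admission and 30-day readmission, log-normal
models for length of stay (LOS) and ICU LOS — with configurable true effect
sizes, so estimator recovery of the configured truth is a well-posed check
of the whole pipeline.

Two structural details are generated the hard way on purpose.  First, half
of all rare-disease diagnoses are emitted as longer child codes of their
catalogue entry (extra trailing digit), so the asymmetric truncation
matching is exercised by every dataset, not only by unit tests.  Second,
readmission truth is laid down on the patient timeline: each stay's
readmission event is drawn from the configured logistic model and the gap
to the next admission is sampled consistently (within 30 days of discharge
for events, beyond it otherwise), so the cohort module's date-based flag
derivation reproduces the drawn events exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import cohort as cohort_mod
from .catalogue import Catalogue, CatalogueEntry

__all__ = [
    "BinaryEffects",
    "ReadmissionEffects",
    "DurationEffects",
    "TrueEffects",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_catalogue",
    "generate_population",
]

_STUDY_START = np.datetime64("2009-08-01")
_STUDY_END = np.datetime64("2017-08-31")
_CENTER_YEAR = 2013
_DX_CENTER = 4.0
_LOS_CENTER = 5.0


@dataclass(frozen=True)
class BinaryEffects:
    """True effects of a logistic outcome model, on the odds-ratio scale.

    ``baseline`` is the marginal event rate among patients without rare
    diseases; the intercept is calibrated against it at generation time.
    """

    baseline: float
    rare: tuple[float, float]  # OR for 1 / >1 rare diseases vs 0
    age: tuple[float, float, float, float]  # 35-49, 50-64, 65-79, 80+ vs 18-34
    sex_m: float
    per_dx: float  # per additional non-rare diagnosis
    per_year: float  # per additional discharge year


@dataclass(frozen=True)
class ReadmissionEffects(BinaryEffects):
    previous_stays: tuple[float, float, float] = (1.87, 2.80, 5.86)  # 1, 2, 3+ vs 0
    per_los_day: float = 1.01


@dataclass(frozen=True)
class DurationEffects:
    """True effects of a log-normal duration model (multiplicative scale)."""

    median: float  # reference-group median, days
    sigma: float  # log-scale residual SD
    rare: tuple[float, float]
    age: tuple[float, float, float, float]
    sex_m: float
    per_dx: float
    per_year: float


@dataclass(frozen=True)
class TrueEffects:
    """The full data-generating effect specification, one model per outcome.

    Defaults are the adjusted estimates of the study this generator
    emulates, so default synthetic data carries the reported effect
    structure (mortality ORs 1.80/2.78, ICU 1.64/2.23, LOS factors
    1.28/1.49, ICU-LOS 1.14/1.40, readmission 1.57/1.64).
    """

    mortality: BinaryEffects = BinaryEffects(
        baseline=0.022, rare=(1.80, 2.78), age=(2.05, 3.76, 4.46, 7.88),
        sex_m=1.19, per_dx=1.20, per_year=0.91,
    )
    icu: BinaryEffects = BinaryEffects(
        baseline=0.110, rare=(1.64, 2.23), age=(1.49, 2.18, 2.03, 1.16),
        sex_m=1.71, per_dx=1.20, per_year=0.94,
    )
    readmission: ReadmissionEffects = ReadmissionEffects(
        baseline=0.048, rare=(1.57, 1.64), age=(1.11, 1.33, 1.40, 1.31),
        sex_m=1.26, per_dx=1.02, per_year=0.99,
    )
    los: DurationEffects = DurationEffects(
        median=5.0, sigma=0.70, rare=(1.28, 1.49), age=(1.07, 1.10, 1.04, 0.97),
        sex_m=0.95, per_dx=1.10, per_year=0.99,
    )
    icu_los: DurationEffects = DurationEffects(
        median=1.2, sigma=0.60, rare=(1.14, 1.40), age=(1.03, 0.97, 0.85, 0.71),
        sex_m=0.97, per_dx=1.12, per_year=0.95,
    )

    @classmethod
    def null(cls) -> "TrueEffects":
        """All effects 1.0 (baselines and noise kept): the no-association world."""
        ones4 = (1.0, 1.0, 1.0, 1.0)
        ones2 = (1.0, 1.0)
        return cls(
            mortality=BinaryEffects(0.022, ones2, ones4, 1.0, 1.0, 1.0),
            icu=BinaryEffects(0.110, ones2, ones4, 1.0, 1.0, 1.0),
            readmission=ReadmissionEffects(
                0.048, ones2, ones4, 1.0, 1.0, 1.0,
                previous_stays=(1.0, 1.0, 1.0), per_los_day=1.0,
            ),
            los=DurationEffects(5.0, 0.70, ones2, ones4, 1.0, 1.0, 1.0),
            icu_los=DurationEffects(1.2, 0.60, ones2, ones4, 1.0, 1.0, 1.0),
        )


# Table-style demographic margins by exposure group (0, 1, >1): age-band
# weights and male fraction, matching the study population they emulate.
_AGE_WEIGHTS = (
    (36084, 32924, 31883, 31417, 14496),
    (2280, 2905, 4679, 5160, 2027),
    (291, 382, 593, 615, 172),
)
_MALE_FRACTION = (67557 / 146804, 9437 / 17051, 1179 / 2053)


@dataclass(frozen=True)
class SyntheticConfig:
    """Complete data-generating specification.

    The defaults are the study conditions the generator emulates: 165,908
    analyzed patients of whom one third stayed multiple times, 11.5%
    rare-disease prevalence with 2053/19104 of exposed patients carrying
    more than one rare disease, per-group diagnosis-count medians of about
    4 / 5 / 8, and the effect sizes of :class:`TrueEffects`.
    """

    n_patients: int = 165_908
    multi_stay_fraction: float = 55_028 / 165_908
    stays_per_multi_mean: float = 2.5  # geometric, support >= 2
    max_planned_stays: int = 30
    rare_prevalence: float = 0.115
    p_two_plus_given_rare: float = 2053 / 19104
    rare_extra_mean: float = 0.4  # Poisson extra rare diseases beyond 2 in the >1 group
    catalogue_size: int = 100
    nonrare_pool_size: int = 2000
    child_code_rate: float = 0.5  # rare diagnoses emitted one level deeper
    dx_nb_r: float = 3.0  # negative-binomial shape of the non-rare count
    dx_means: tuple[float, float, float] = (4.65, 5.75, 8.9)  # medians ~ 4 / 5 / 8
    unknown_readmission_rate: float = 0.012
    unit_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)
    age_weights: tuple = _AGE_WEIGHTS
    male_fraction: tuple[float, float, float] = _MALE_FRACTION
    equal_demographics: bool = False  # same age/sex margins in every group
    effects: TrueEffects = field(default_factory=TrueEffects)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.multi_stay_fraction, self.rare_prevalence,
            self.p_two_plus_given_rare, self.child_code_rate,
            self.unknown_readmission_rate, *self.unit_probs, *self.male_fraction,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_patients < 1 or self.catalogue_size < 1:
            raise ValueError("n_patients and catalogue_size must be positive")
        if self.stays_per_multi_mean < 2:
            raise ValueError("multi-stay patients have at least 2 stays")
        for eff in (self.effects.mortality, self.effects.icu, self.effects.readmission):
            values = [*eff.rare, *eff.age, eff.sex_m, eff.per_dx, eff.per_year]
            if isinstance(eff, ReadmissionEffects):
                values += [*eff.previous_stays, eff.per_los_day]
            if any(v <= 0 for v in values):
                raise ValueError("odds ratios must be positive")
            if eff.baseline <= 0 or eff.baseline >= 1:
                if eff.baseline == 0 and any(v != 1.0 for v in values):
                    raise ValueError(
                        "baseline rate 0 contradicts non-unit effect targets"
                    )
                raise ValueError("baseline rates must lie strictly in (0, 1)")
        for eff in (self.effects.los, self.effects.icu_los):
            if min(*eff.rare, *eff.age, eff.sex_m, eff.per_dx, eff.per_year) <= 0:
                raise ValueError("duration factors must be positive")
            if eff.median <= 0 or eff.sigma < 0:
                raise ValueError("duration median must be positive, sigma non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        data = dict(data)
        if "effects" in data and isinstance(data["effects"], dict):
            eff = data["effects"]
            data["effects"] = TrueEffects(
                mortality=BinaryEffects(**_tup(eff["mortality"])),
                icu=BinaryEffects(**_tup(eff["icu"])),
                readmission=ReadmissionEffects(**_tup(eff["readmission"])),
                los=DurationEffects(**_tup(eff["los"])),
                icu_los=DurationEffects(**_tup(eff["icu_los"])),
            )
        for key in ("dx_means", "unit_probs", "male_fraction"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "age_weights" in data:
            data["age_weights"] = tuple(tuple(w) for w in data["age_weights"])
        return cls(**data)


def _tup(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


@dataclass
class SyntheticDataset:
    stays: pd.DataFrame
    diagnoses: pd.DataFrame
    catalogue: Catalogue
    truth: SyntheticConfig


_LETTERS = "ABCDEFGHIJKLMNOPQRSTVZ"  # chapter letters used for synthetic codes


def _all_stems(rng: np.random.Generator) -> np.ndarray:
    stems = np.array(
        [f"{letter}{i:02d}" for letter in _LETTERS for i in range(100)]
    )
    rng.shuffle(stems)
    return stems


def generate_catalogue(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[Catalogue, np.ndarray]:
    """A consolidated toy catalogue plus the disjoint non-rare code pool.

    Catalogue entries are 3- or 4-character codes on distinct 3-character
    stems (hence prefix-free, i.e. already consolidated); the non-rare pool
    uses entirely different stems, so no pool code can ever match the
    catalogue.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    stems = _all_stems(rng)
    need = config.catalogue_size + config.nonrare_pool_size
    if need > len(stems):
        raise ValueError("catalogue_size + nonrare_pool_size exceeds the stem space")
    cat_stems = stems[: config.catalogue_size]
    pool = stems[config.catalogue_size : need]
    extend = rng.random(config.catalogue_size) < 0.3
    digits = rng.integers(0, 10, config.catalogue_size)
    codes = np.where(
        extend, np.char.add(cat_stems.astype(str), digits.astype(str)), cat_stems
    )
    entries = [
        CatalogueEntry(code, f"Synthetic rare disease {code}", "manual")
        for code in sorted(codes)
    ]
    return Catalogue(entries), pool


def _calibrate_intercept(lp: np.ndarray, mask: np.ndarray, target: float) -> float:
    """Intercept making the mean event probability over ``mask`` equal target."""
    sub = lp[mask]
    if len(sub) == 0:
        sub = lp
    return float(
        brentq(lambda c: expit(c + sub).mean() - target, -30.0, 30.0, xtol=1e-10)
    )


def _binary_lp(
    eff: BinaryEffects,
    g1: np.ndarray,
    g2: np.ndarray,
    age_band: np.ndarray,
    male: np.ndarray,
    dx: np.ndarray,
    year: np.ndarray,
) -> np.ndarray:
    age_log = np.concatenate(([0.0], np.log(eff.age)))
    return (
        np.log(eff.rare[0]) * g1
        + np.log(eff.rare[1]) * g2
        + age_log[age_band]
        + np.log(eff.sex_m) * male
        + np.log(eff.per_dx) * (dx - _DX_CENTER)
        + np.log(eff.per_year) * (year - _CENTER_YEAR)
    )


def _duration_lp(
    eff: DurationEffects,
    g1: np.ndarray,
    g2: np.ndarray,
    age_band: np.ndarray,
    male: np.ndarray,
    dx: np.ndarray,
    year: np.ndarray,
) -> np.ndarray:
    age_log = np.concatenate(([0.0], np.log(eff.age)))
    return (
        np.log(eff.rare[0]) * g1
        + np.log(eff.rare[1]) * g2
        + age_log[age_band]
        + np.log(eff.sex_m) * male
        + np.log(eff.per_dx) * (dx - _DX_CENTER)
        + np.log(eff.per_year) * (year - _CENTER_YEAR)
    )


def generate_population(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a complete synthetic dataset: stays, diagnoses and catalogue.

    Bit-exactly reproducible from (config, seed).  Patient timelines are
    built stay by stay: in-hospital death truncates the remaining timeline,
    readmission events pull the next admission inside the 30-day window,
    and a final-stay readmission event appends one extra follow-up stay so
    the event is observable from the dates alone.
    """
    rng = np.random.default_rng(config.seed)
    catalogue, pool = generate_catalogue(config, rng)
    cat_codes = np.array(sorted(catalogue.codes))
    eff = config.effects
    n = config.n_patients

    # --- patient level -------------------------------------------------
    is_multi = rng.random(n) < config.multi_stay_fraction
    planned = np.ones(n, dtype=np.int64)
    extra_mean = config.stays_per_multi_mean - 1.0
    planned[is_multi] = 1 + rng.geometric(1.0 / extra_mean, is_multi.sum())
    planned = np.minimum(planned, config.max_planned_stays)

    is_rare = rng.random(n) < config.rare_prevalence
    two_plus = is_rare & (rng.random(n) < config.p_two_plus_given_rare)
    group = np.zeros(n, dtype=np.int64)
    group[is_rare] = 1
    group[two_plus] = 2

    n_rare = np.zeros(n, dtype=np.int64)
    n_rare[is_rare] = 1
    n_rare[two_plus] = 2 + rng.poisson(config.rare_extra_mean, two_plus.sum())
    n_rare = np.minimum(n_rare, min(6, len(cat_codes)))

    # distinct catalogue entries per rare patient
    entry_offsets = np.zeros(n + 1, dtype=np.int64)
    entry_offsets[1:] = np.cumsum(n_rare)
    entry_flat = np.empty(entry_offsets[-1], dtype=np.int64)
    single = n_rare == 1
    entry_flat[entry_offsets[:-1][single]] = rng.integers(
        len(cat_codes), size=single.sum()
    )
    multi_rare = np.flatnonzero(n_rare >= 2)
    if len(multi_rare):
        keys = rng.random((len(multi_rare), len(cat_codes)))
        ranked = np.argsort(keys, axis=1)
        for row, p in enumerate(multi_rare):
            o = entry_offsets[p]
            entry_flat[o : o + n_rare[p]] = ranked[row, : n_rare[p]]

    age_w = np.array(config.age_weights, dtype=float)
    male_frac = np.array(config.male_fraction, dtype=float)
    if config.equal_demographics:
        age_w = np.tile(age_w[0], (3, 1))
        male_frac = np.full(3, male_frac[0])
    age_probs = age_w / age_w.sum(axis=1, keepdims=True)
    age_cdf = np.cumsum(age_probs, axis=1)
    u = rng.random(n)
    age_band0 = (u[:, None] > age_cdf[group]).sum(axis=1)
    band_lo = np.array([18, 35, 50, 65, 80])
    band_hi = np.array([35, 50, 65, 80, 95])
    age0 = band_lo[age_band0] + rng.integers(
        0, band_hi[age_band0] - band_lo[age_band0]
    )
    male = rng.random(n) < male_frac[group]

    # --- stay level, built position by position ------------------------
    window = int((_STUDY_END - _STUDY_START) / np.timedelta64(1, "D")) - 60
    first_admit = rng.integers(0, window, n)

    k = planned.copy()  # realized stay counts (mutable: deaths truncate,
    # final-stay readmission events extend)
    alive = np.ones(n, dtype=bool)
    admit_hist: list[np.ndarray] = []  # admission day per position (NaN-free, masked)
    records: list[dict[str, np.ndarray]] = []
    hard_cap = config.max_planned_stays + 10
    age_bins = np.array([35, 50, 65, 80], dtype=np.int64)

    next_admit = first_admit.copy()
    intercepts: dict[str, float] = {}  # calibrated once, on the full first-stay set
    # Follow-up stays appended to realize a final-stay readmission event are
    # emitted WITHOUT coded diagnoses: they mark the readmission date for the
    # flag derivation but are removed by the >=1-diagnosis eligibility filter,
    # so realizing an event never changes a patient's selection weights.
    ghost_next = np.zeros(n, dtype=bool)
    position = 0
    while True:
        active = alive & (k > position)
        if not active.any():
            break
        idx = np.flatnonzero(active)
        ghost = ghost_next[idx]
        admit = next_admit[idx]
        age = age0[idx] + ((admit - first_admit[idx]) // 365)
        band = np.searchsorted(age_bins, age, side="right")
        g1 = (group[idx] == 1).astype(float)
        g2 = (group[idx] == 2).astype(float)
        m = male[idx].astype(float)

        mu_extra = np.array(config.dx_means)[group[idx]] - 1.0
        r = config.dx_nb_r
        dx = 1 + rng.negative_binomial(r, r / (r + mu_extra), len(idx))
        dx = np.where(ghost, 0, dx)  # follow-up marker stays carry no codes
        dxf = dx.astype(float)

        year_admit = 2009 + (admit + 212) // 365  # ~calendar year of admission
        lp_los = _duration_lp(eff.los, g1, g2, band, m, dxf, year_admit)
        if "los" not in intercepts:
            base = lp_los[group[idx] == 0] if (group[idx] == 0).any() else lp_los
            intercepts["los"] = float(np.log(eff.los.median) - np.median(base))
        los = np.exp(
            intercepts["los"] + lp_los + eff.los.sigma * rng.standard_normal(len(idx))
        )
        los = np.maximum(los, 0.25)

        disch = admit + np.ceil(los).astype(np.int64)
        year = 2009 + (disch + 212) // 365

        lp_icu = _binary_lp(eff.icu, g1, g2, band, m, dxf, year)
        if "icu" not in intercepts:
            intercepts["icu"] = _calibrate_intercept(
                lp_icu, group[idx] == 0, eff.icu.baseline
            )
        icu_adm = rng.random(len(idx)) < expit(intercepts["icu"] + lp_icu)
        icu_days = np.zeros(len(idx))
        if icu_adm.any():
            lp_id = _duration_lp(eff.icu_los, g1, g2, band, m, dxf, year)
            if "icu_los" not in intercepts:
                base_mask = (group[idx] == 0) & icu_adm
                sub = lp_id[base_mask] if base_mask.any() else lp_id[icu_adm]
                intercepts["icu_los"] = float(
                    np.log(eff.icu_los.median) - np.median(sub)
                )
            draw = np.exp(
                intercepts["icu_los"]
                + lp_id
                + eff.icu_los.sigma * rng.standard_normal(len(idx))
            )
            icu_days[icu_adm] = np.maximum(draw[icu_adm], 0.05)
        # the invariant icu_days <= los is enforced by extending the stay
        clip = icu_days > los
        los = np.where(clip, icu_days + 0.1, los)
        disch = admit + np.ceil(los).astype(np.int64)
        year = 2009 + (disch + 212) // 365

        lp_mort = _binary_lp(eff.mortality, g1, g2, band, m, dxf, year)
        if "mortality" not in intercepts:
            intercepts["mortality"] = _calibrate_intercept(
                lp_mort, group[idx] == 0, eff.mortality.baseline
            )
        died = (rng.random(len(idx)) < expit(intercepts["mortality"] + lp_mort)) & ~ghost

        prev_count = np.zeros(len(idx), dtype=np.int64)
        for past in admit_hist:
            seen = ~np.isnan(past[idx])
            past_admit = past[idx]
            prev_count += (
                seen & (past_admit < admit) & (admit - past_admit <= 730)
            ).astype(np.int64)
        prev_cat = np.minimum(prev_count, 3)

        lp_re = _binary_lp(eff.readmission, g1, g2, band, m, dxf, year)
        prev_log = np.concatenate(([0.0], np.log(eff.readmission.previous_stays)))
        lp_re = (
            lp_re
            + prev_log[prev_cat]
            + np.log(eff.readmission.per_los_day) * (los - _LOS_CENTER)
        )
        if "readmission" not in intercepts:
            intercepts["readmission"] = _calibrate_intercept(
                lp_re, group[idx] == 0, eff.readmission.baseline
            )
        readmit = (
            (rng.random(len(idx)) < expit(intercepts["readmission"] + lp_re))
            & ~died
            & ~ghost
        )

        # deaths truncate the timeline; a final-stay readmission event
        # appends one extra (diagnosis-free) follow-up stay within the cap
        k[idx[died]] = position + 1
        last = k[idx] == position + 1
        extend = readmit & last & (k[idx] < hard_cap)
        readmit = readmit & (~last | extend)
        k[idx[extend]] += 1
        ghost_next[idx] = extend

        has_next = k[idx] > position + 1
        gap = np.where(
            readmit, rng.integers(0, 31, len(idx)), rng.integers(31, 366, len(idx))
        )
        hist = np.full(n, np.nan)
        hist[idx] = admit
        admit_hist.append(hist)
        nxt = np.full(n, -1, dtype=np.int64)
        nxt[idx[has_next]] = (disch + gap)[has_next]
        prev_admit = next_admit
        next_admit = np.where(nxt >= 0, nxt, next_admit)

        records.append(
            {
                "patient": idx,
                "admit": admit,
                "disch": disch,
                "age": age,
                "los": los,
                "icu_adm": icu_adm,
                "icu_days": icu_days,
                "died": died,
                "dx": dx,
                "year": year,
                "readmit_drawn": readmit,
                "prev_drawn": prev_count,
                "ghost": ghost,
            }
        )
        position += 1

    patient = np.concatenate([r["patient"] for r in records])
    order = np.lexsort(
        (np.concatenate([r["admit"] for r in records]), patient)
    )

    def col(name):
        return np.concatenate([r[name] for r in records])[order]

    n_stays = len(patient)
    stays = pd.DataFrame(
        {
            "stay_id": np.arange(n_stays, dtype=np.int64),
            "patient_id": patient[order],
            "age_at_admission": col("age"),
            "sex": np.where(male[patient[order]], "M", "F"),
            "admit_date": (_STUDY_START + col("admit").astype("timedelta64[D]")).astype(
                "datetime64[D]"
            ).astype(str),
            "discharge_date": (
                _STUDY_START + col("disch").astype("timedelta64[D]")
            ).astype("datetime64[D]").astype(str),
            "died_in_hospital": col("died").astype(int),
            "icu_admitted": col("icu_adm").astype(int),
            "icu_days": np.round(col("icu_days"), 3),
            "los_days": np.round(col("los"), 3),
            "discharge_year": col("year"),
            "unit_group": np.array(
                ["internal-medicine-and-related", "surgical", "other"]
            )[
                (
                    rng.random(n_stays)[:, None]
                    > np.cumsum(config.unit_probs)[None, :]
                ).sum(axis=1)
            ],
            "readmission_info_complete": (
                rng.random(n_stays) >= config.unknown_readmission_rate
            ).astype(int),
        }
    )

    # derive the history fields with the cohort module's own rule and check
    # they reproduce the drawn truth
    stays = cohort_mod.annotate_stay_history(stays)
    drawn_readmit = col("readmit_drawn").astype(int)
    drawn_prev = col("prev_drawn")
    if not np.array_equal(stays["readmitted_30d"].to_numpy(), drawn_readmit):
        raise AssertionError("timeline gaps do not reproduce drawn readmission events")
    if not np.array_equal(stays["previous_stays_2y"].to_numpy(), drawn_prev):
        raise AssertionError("previous-stay counts disagree with the drawn timeline")

    diagnoses = _emit_diagnoses(
        config, rng, stays, cat_codes, pool,
        entry_offsets, entry_flat, n_rare, col("dx"), col("ghost"),
    )
    return SyntheticDataset(stays=stays, diagnoses=diagnoses, catalogue=catalogue, truth=config)


def _emit_diagnoses(
    config: SyntheticConfig,
    rng: np.random.Generator,
    stays: pd.DataFrame,
    cat_codes: np.ndarray,
    pool: np.ndarray,
    entry_offsets: np.ndarray,
    entry_flat: np.ndarray,
    n_rare_per_patient: np.ndarray,
    dx_count: np.ndarray,
    ghost: np.ndarray,
) -> pd.DataFrame:
    """Long diagnosis table: every stay re-codes the patient's rare diseases
    (half of them one hierarchy level deeper) plus its non-rare codes.

    Emitted codes are picked from a precomputed vocabulary of display forms
    (plain, child-extended, and dotted variants of the longer codes), so a
    random half of the deeper codes always exercises the dot-stripping
    normalization on ingest.
    """
    stay_ids = stays["stay_id"].to_numpy()
    pids = stays["patient_id"].to_numpy()

    # vocabulary: catalogue codes, their 10 child extensions (plain+dotted),
    # and the non-rare pool
    def dotted(code: str) -> str:
        return code[:3] + "." + code[3:] if len(code) > 3 else code

    n_cat = len(cat_codes)
    cat_plain = cat_codes.astype(str)
    cat_disp = np.array([dotted(c) for c in cat_plain])  # 4-char entries dotted
    child_plain = np.array([c + str(d) for c in cat_plain for d in range(10)])
    child_disp = np.array([dotted(c) for c in child_plain])
    vocab = np.concatenate([cat_plain, cat_disp, child_plain, child_disp, pool])
    CAT, CATD, CHILD, CHILDD, POOL = (
        0, n_cat, 2 * n_cat, 2 * n_cat + 10 * n_cat, 2 * n_cat + 20 * n_cat,
    )

    rare_counts = np.where(ghost, 0, n_rare_per_patient[pids])
    rare_rows = int(rare_counts.sum())
    row_pid = np.repeat(pids, rare_counts)
    pos = np.arange(rare_rows) - np.repeat(
        np.concatenate(([0], np.cumsum(rare_counts)))[:-1], rare_counts
    )
    entry_idx = entry_flat[entry_offsets[row_pid] + pos]
    deepen = rng.random(rare_rows) < config.child_code_rate
    dot = rng.random(rare_rows) < 0.5
    child_digit = rng.integers(0, 10, rare_rows)
    rare_vocab = np.where(
        deepen,
        CHILD + entry_idx * 10 + child_digit + np.where(dot, 10 * n_cat, 0),
        CAT + entry_idx + np.where(dot, n_cat, 0),
    )

    nonrare_rows = int(dx_count.sum())
    nr_vocab = POOL + rng.integers(len(pool), size=nonrare_rows)

    all_stays = np.concatenate([np.repeat(stay_ids, rare_counts), np.repeat(stay_ids, dx_count)])
    codes = vocab[np.concatenate([rare_vocab, nr_vocab])]
    frame = pd.DataFrame({"stay_id": all_stays, "icd10_code": codes})
    frame = frame.sort_values(["stay_id", "icd10_code"], kind="mergesort").reset_index(
        drop=True
    )
    return frame
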