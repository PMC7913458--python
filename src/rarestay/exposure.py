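"""Per-stay rare-disease exposure: count, group (0 / 1 / >1) and burden.

Each stay's coded diagnoses are deduplicated at the normalized-code level
and matched against the catalogue with the asymmetric prefix rule.  Two
patient codes that map to the same catalogue entry (say D57.1 and D57.3
under D57) count as *one* rare disease; distinct unmatched codes form the
non-rare diagnosis count, the disease-burden covariate of the outcome
models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import (
    CODE_PATTERN,
    Catalogue,
    InvalidCodeError,
    chapter_of,
    load_chapter_table,
    match_diagnosis,
    normalize_code,
)

__all__ = ["ExposureSummary", "exposure_group", "summarize_exposure", "summarize_exposures"]

GROUPS = ("0", "1", ">1")


def exposure_group(count: int) -> str:
    """Exposure category from a rare-disease count: "0", "1" or ">1"."""
    if count < 0:
        raise ValueError("rare-disease count cannot be negative")
    if count == 0:
        return "0"
    return "1" if count == 1 else ">1"


@dataclass(frozen=True)
class ExposureSummary:
    """Rare-disease exposure of one stay."""

    stay_id: object
    rare_entries: frozenset[str]
    rare_count: int
    rare_group: str
    chapters: frozenset[str]
    nonrare_dx_count: int

    def __post_init__(self) -> None:
        assert self.rare_count == len(self.rare_entries)
        assert self.rare_group == exposure_group(self.rare_count)


def summarize_exposure(
    stay_id: object,
    codes: list[str],
    catalogue: Catalogue,
    chapter_table: list[tuple[str, str, str]] | None = None,
) -> ExposureSummary:
    """Classify one stay's diagnosis codes.

    Raises :class:`InvalidCodeError` naming the stay when a code cannot be
    normalized.
    """
    if chapter_table is None:
        chapter_table = load_chapter_table()
    normalized = set()
    for raw in codes:
        try:
            normalized.add(normalize_code(raw))
        except InvalidCodeError as exc:
            raise InvalidCodeError(f"stay {stay_id!r}: {exc}") from None
    matched = set()
    nonrare = 0
    for code in normalized:
        entry = match_diagnosis(code, catalogue)
        if entry is None:
            nonrare += 1
        else:
            matched.add(entry.code)
    return ExposureSummary(
        stay_id=stay_id,
        rare_entries=frozenset(matched),
        rare_count=len(matched),
        rare_group=exposure_group(len(matched)),
        chapters=frozenset(chapter_of(c, chapter_table) for c in matched),
        nonrare_dx_count=nonrare,
    )


def summarize_exposures(
    diagnoses: pd.DataFrame, catalogue: Catalogue, details: bool = True
) -> pd.DataFrame:
    """Vectorized exposure summary for a whole diagnosis table.

    Parameters
    ----------
    diagnoses
        Long table with columns ``stay_id`` and ``icd10_code`` (one row per
        coded diagnosis; duplicates allowed, deduplicated here).
    catalogue
        The rare-disease catalogue to match against.
    details
        When false, skip the ``matched_codes`` / ``chapters`` string columns
        (they are reporting conveniences; the counts drive the analysis).

    Returns one row per stay appearing in ``diagnoses``, with columns
    ``stay_id, rare_count, rare_group, matched_codes, nonrare_dx_count,
    chapters`` (code and chapter sets are ``;``-joined sorted strings).

    Normalization, validation and matching run once per *distinct* raw code
    string, so cost scales with the code vocabulary, not the table length.
    """
    raw = diagnoses["icd10_code"].astype(str).to_numpy()
    uniq_raw, inv = np.unique(raw, return_inverse=True)
    norm_u = (
        pd.Series(uniq_raw).str.strip().str.upper().str.replace(".", "", regex=False)
    )
    ok = norm_u.str.match(CODE_PATTERN.pattern).to_numpy()
    if not ok.all():
        bad_u = np.flatnonzero(~ok)[0]
        bad_row = diagnoses.iloc[np.flatnonzero(inv == bad_u)[0]]
        raise InvalidCodeError(
            f"stay {bad_row['stay_id']!r}: malformed ICD-10 code: "
            f"{bad_row['icd10_code']!r}"
        )
    # distinct raw spellings can normalize to the same code
    norm_uniq, norm_of_u = np.unique(norm_u.to_numpy(), return_inverse=True)
    matched_of_norm = np.array(
        [
            (lambda e: e.code if e is not None else "")(match_diagnosis(c, catalogue))
            for c in norm_uniq
        ],
        dtype=object,
    )

    stay_uniq, stay_inv = np.unique(diagnoses["stay_id"].to_numpy(), return_inverse=True)
    n_stays, n_codes = len(stay_uniq), len(norm_uniq)
    code_id = norm_of_u[inv]
    pair = np.unique(stay_inv.astype(np.int64) * n_codes + code_id)
    d_stay = (pair // n_codes).astype(np.int64)
    d_code = (pair % n_codes).astype(np.int64)
    d_matched = matched_of_norm[d_code]
    is_rare = d_matched != ""

    nonrare = np.bincount(d_stay[~is_rare], minlength=n_stays)
    # distinct matched catalogue entries per stay (several patient codes may
    # collapse onto one entry)
    match_uniq, match_id = np.unique(d_matched[is_rare], return_inverse=True)
    rare_pair = np.unique(d_stay[is_rare] * max(len(match_uniq), 1) + match_id)
    rare_count = np.bincount(
        rare_pair // max(len(match_uniq), 1), minlength=n_stays
    )

    out = pd.DataFrame(
        {
            "stay_id": stay_uniq,
            "rare_count": rare_count,
            "nonrare_dx_count": nonrare,
        }
    )
    out["rare_group"] = np.select(
        [out["rare_count"] == 0, out["rare_count"] == 1], ["0", "1"], default=">1"
    )
    if details:
        chapter_table = load_chapter_table()
        chapter_cache = {c: chapter_of(c, chapter_table) for c in match_uniq}
        pairs = pd.DataFrame(
            {
                "stay": rare_pair // max(len(match_uniq), 1),
                "code": match_uniq[rare_pair % max(len(match_uniq), 1)]
                if len(match_uniq)
                else np.array([], dtype=object),
            }
        ).sort_values(["stay", "code"])
        matched_codes = pairs.groupby("stay")["code"].agg(";".join)
        chapters = (
            pairs.assign(chapter=pairs["code"].map(chapter_cache))
            .drop_duplicates(["stay", "chapter"])
            .sort_values(["stay", "chapter"])
            .groupby("stay")["chapter"]
            .agg(";".join)
        )
        out["matched_codes"] = (
            matched_codes.reindex(range(n_stays), fill_value="").to_numpy()
        )
        out["chapters"] = chapters.reindex(range(n_stays), fill_value="").to_numpy()
    else:
        out["matched_codes"] = ""
        out["chapters"] = ""
    return out[
        ["stay_id", "rare_count", "rare_group", "matched_codes", "nonrare_dx_count", "chapters"]
    ]
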