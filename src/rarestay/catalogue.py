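"""Rare-disease catalogue: curation steps and asymmetric ICD-10 prefix matching.

A catalogue is a curated set of ICD-10 codes, each denoting one rare disease.
Catalogue codes act as *wildcards*: a patient's (possibly longer, more
specific) diagnosis code matches a catalogue entry when the catalogue code is
a prefix of the patient code.  The converse never holds — a catalogue code is
never truncated to meet a shorter patient code.  Thus D57.1 (sickle-cell
anaemia without crisis) matches a catalogue entry D57 (sickle-cell
disorders), while a patient coded A92 (other mosquito-borne viral fevers)
does *not* match a catalogue entry A92.4 (Rift Valley fever).

All matching operates on canonical code strings: uppercase, dots and
whitespace removed (``D57.1`` → ``D571``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "CODE_PATTERN",
    "InvalidCodeError",
    "CatalogueEntry",
    "Catalogue",
    "DescriptionLookup",
    "MergeReport",
    "normalize_code",
    "merge_catalogues",
    "consolidate_codes",
    "match_diagnosis",
    "flag_high_prevalence",
    "chapter_of",
    "load_chapter_table",
    "read_catalogue",
    "write_catalogue",
]

#: Canonical ICD-10 code shape: one letter, two digits, up to four further
#: alphanumeric characters (3–7 characters total, no dot).
CODE_PATTERN = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]{0,4}$")

VALID_SOURCES = ("orphadata-confirmed", "walker", "manual")


class InvalidCodeError(ValueError):
    """Raised when a string cannot be normalized into a valid ICD-10 code."""


def normalize_code(raw: str) -> str:
    """Return the canonical form of an ICD-10 code.

    Uppercases, strips whitespace and removes dots, so display forms like
    ``"D57.1"`` or ``"q05"`` become ``"D571"`` / ``"Q05"``.  Raises
    :class:`InvalidCodeError` if the result does not look like an ICD-10
    code (letter + two digits + up to four alphanumerics).
    """
    if raw is None:
        raise InvalidCodeError("code is None")
    code = re.sub(r"[\s.]", "", str(raw)).upper()
    if not code:
        raise InvalidCodeError("empty code after stripping whitespace")
    if not CODE_PATTERN.match(code):
        raise InvalidCodeError(f"malformed ICD-10 code: {raw!r}")
    return code


@dataclass(frozen=True)
class CatalogueEntry:
    """One rare disease: a canonical ICD-10 code plus a human-readable label."""

    code: str
    label: str
    source: str = "manual"

    def __post_init__(self) -> None:
        if not CODE_PATTERN.match(self.code):
            raise InvalidCodeError(
                f"catalogue entry code not canonical: {self.code!r}"
            )
        if not self.label or not str(self.label).strip():
            raise ValueError(f"catalogue entry {self.code} has an empty label")
        if self.source not in VALID_SOURCES:
            raise ValueError(
                f"unknown source {self.source!r}; expected one of {VALID_SOURCES}"
            )


class Catalogue:
    """A set of :class:`CatalogueEntry`, keyed by canonical code.

    Supports the asymmetric prefix ("wildcard") matching used to decide
    whether a patient diagnosis denotes a rare disease; see
    :func:`match_diagnosis`.
    """

    def __init__(self, entries: Iterable[CatalogueEntry] = ()) -> None:
        self._entries: dict[str, CatalogueEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: CatalogueEntry) -> None:
        existing = self._entries.get(entry.code)
        if existing is not None and existing != entry:
            raise ValueError(f"duplicate catalogue code {entry.code}")
        self._entries[entry.code] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[CatalogueEntry]:
        return iter(self._entries.values())

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __getitem__(self, code: str) -> CatalogueEntry:
        return self._entries[code]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Catalogue):
            return NotImplemented
        return self._entries == other._entries

    def get(self, code: str) -> CatalogueEntry | None:
        return self._entries.get(code)

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(self._entries)

    def prefix_violations(self) -> list[tuple[str, str]]:
        """Pairs (shorter, longer) where one entry's code is a strict prefix
        of another's.  Allowed pre-consolidation; empty afterwards."""
        codes = sorted(self._entries)
        out = []
        for i, short in enumerate(codes):
            for longer in codes[i + 1 :]:
                if not longer.startswith(short[0]):
                    break
                if longer != short and longer.startswith(short):
                    out.append((short, longer))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"icd10_code": e.code, "label": e.label, "source": e.source}
                for e in sorted(self, key=lambda e: e.code)
            ],
            columns=["icd10_code", "label", "source"],
        )


class DescriptionLookup:
    """Mapping from canonical ICD-10 code to its official description.

    Stands in for the WHO reference nomenclature used to confirm that a
    candidate (code, description) pair from an external rare-disease mapping
    really denotes the disease the code officially names.
    """

    def __init__(self, mapping: Mapping[str, str]) -> None:
        self._mapping = {normalize_code(k): str(v) for k, v in mapping.items()}

    def get(self, code: str) -> str | None:
        return self._mapping.get(code)

    def __contains__(self, code: str) -> bool:
        return code in self._mapping

    def __len__(self) -> int:
        return len(self._mapping)


@dataclass
class MergeReport:
    """Outcome of a catalogue merge: what was added, rejected, or unresolvable."""

    added: list[str] = field(default_factory=list)
    #: (code, candidate description, official description) for mismatches
    rejected: list[tuple[str, str, str]] = field(default_factory=list)
    #: candidate codes absent from the description lookup
    uncovered: list[str] = field(default_factory=list)
    #: candidate codes already present in the base catalogue
    already_present: list[str] = field(default_factory=list)


def _canonical_description(text: str) -> str:
    return " ".join(str(text).split()).casefold()


def merge_catalogues(
    base: Catalogue,
    candidates: Iterable[tuple[str, str]],
    lookup: DescriptionLookup,
) -> tuple[Catalogue, MergeReport]:
    """Add externally mapped (code, description) candidates to ``base``.

    A candidate is accepted only when its description agrees with the
    official description of that code (case-insensitive, whitespace
    normalized).  This guards against wrong external mappings — e.g. a
    mapping that attaches a rare-diabetes label to E11.9, which officially
    codes common type 2 diabetes, is rejected.  Returns a new catalogue and
    a report listing every rejected or unresolvable candidate.
    """
    merged = Catalogue(base)
    report = MergeReport()
    for raw_code, description in candidates:
        code = normalize_code(raw_code)
        if code in merged:
            report.already_present.append(code)
            continue
        official = lookup.get(code)
        if official is None:
            report.uncovered.append(code)
            continue
        if _canonical_description(description) == _canonical_description(official):
            merged.add(
                CatalogueEntry(code, official, source="orphadata-confirmed")
            )
            report.added.append(code)
        else:
            report.rejected.append((code, str(description), official))
    return merged, report


def consolidate_codes(
    catalogue: Catalogue, children_index: Mapping[str, frozenset[str] | set[str]]
) -> Catalogue:
    """Collapse complete sibling sets onto their parent code.

    ``children_index`` maps a 3- or 4-character parent code to the complete
    set of its valid child codes in the coding system.  Whenever the
    catalogue contains *every* child of a parent, the children are replaced
    by a single parent entry (e.g. Q05.0–Q05.9 → Q05); partial sets are left
    alone.  Applied repeatedly until a fixed point, so a 5-character family
    may collapse through its 4-character parent up to the 3-character one.
    """
    current = {e.code: e for e in catalogue}
    changed = True
    while changed:
        changed = False
        for parent, children in children_index.items():
            parent_code = normalize_code(parent)
            child_codes = {normalize_code(c) for c in children}
            if not child_codes:
                continue
            if child_codes <= current.keys():
                labels = [current[c] for c in sorted(child_codes)]
                for c in child_codes:
                    del current[c]
                if parent_code not in current:
                    current[parent_code] = CatalogueEntry(
                        parent_code, labels[0].label, labels[0].source
                    )
                changed = True
    return Catalogue(current.values())


def match_diagnosis(patient_code: str, catalogue: Catalogue) -> CatalogueEntry | None:
    """Match one patient diagnosis code against the catalogue.

    Returns the entry whose code is the *longest* prefix of ``patient_code``
    (equality counts), or ``None`` when no catalogue code is a prefix.  A
    catalogue code longer than the patient code can never match: patient
    codes may be truncated to meet catalogue codes, catalogue codes are
    never truncated.
    """
    for length in range(len(patient_code), 2, -1):
        entry = catalogue.get(patient_code[:length])
        if entry is not None:
            return entry
    return None


def flag_high_prevalence(
    catalogue: Catalogue,
    matched_counts: Mapping[str, int],
    population_size: int,
    threshold: float = 1.0 / 2000.0,
) -> list[tuple[CatalogueEntry, float]]:
    """Report catalogue entries whose inpatient prevalence reaches ``threshold``.

    Entries matching at least ``threshold`` (default 1/2,000, inclusive) of
    the population are returned sorted by descending prevalence, for manual
    review.  Nothing is removed — a high prevalence is a prompt to
    double-check the entry, not proof it is wrong.
    """
    if population_size <= 0:
        raise ValueError("population_size must be positive")
    flagged = []
    for code, count in matched_counts.items():
        if count < 0:
            raise ValueError(f"negative matched count for {code}")
        entry = catalogue.get(code)
        if entry is None:
            continue
        prevalence = count / population_size
        if prevalence >= threshold:
            flagged.append((entry, prevalence))
    flagged.sort(key=lambda pair: (-pair[1], pair[0].code))
    return flagged


def load_chapter_table() -> list[tuple[str, str, str]]:
    """The packaged ICD-10 chapter ranges as (start, end, label) triples."""
    with resources.files("rarestay.data").joinpath("icd10_chapters.csv").open() as fh:
        frame = pd.read_csv(fh)
    return list(
        frame[["chapter_start", "chapter_end", "label"]].itertuples(index=False, name=None)
    )


def chapter_of(
    code: str, chapter_table: list[tuple[str, str, str]] | None = None
) -> str:
    """ICD-10 chapter label for a canonical code (by its first 3 characters).

    Codes falling outside every range return ``"unclassified"``.
    """
    if chapter_table is None:
        chapter_table = load_chapter_table()
    stem = code[:3]
    for start, end, label in chapter_table:
        if start <= stem <= end:
            return label
    return "unclassified"


def read_catalogue(path: str | Path, sep: str | None = None) -> Catalogue:
    """Read a catalogue from a delimited text file.

    Expects a header with at least ``icd10_code`` and ``label`` columns; a
    third ``source`` column is optional.  Codes are normalized on ingest.
    """
    frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = {"icd10_code", "label"} - set(frame.columns)
    if missing:
        raise ValueError(f"catalogue file {path} lacks columns {sorted(missing)}")
    entries = []
    for row in frame.itertuples(index=False):
        source = getattr(row, "source", "manual")
        if pd.isna(source):
            source = "manual"
        entries.append(
            CatalogueEntry(normalize_code(row.icd10_code), str(row.label), str(source))
        )
    return Catalogue(entries)


def write_catalogue(catalogue: Catalogue, path: str | Path) -> None:
    catalogue.to_frame().to_csv(path, index=False)
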