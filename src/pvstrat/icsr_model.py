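"""Data model and I/O for individual case safety reports (ICSRs).

An ICSR is one spontaneous report of suspected adverse drug reactions for
one patient: a unique case identifier, the patient's sex, one or more
suspect drugs, and one or more reactions coded as MedDRA-style preferred
terms (PTs).  Reactions roll up to System Organ Classes (SOCs) through a
two-level PT -> SOC map; the bundled map is a small mock hierarchy, since
the licensed MedDRA dictionary cannot be redistributed.

Counting downstream is always at the level of the distinct case report, so
this module also owns deduplication: rows or records sharing a case_id are
merged by taking the union of their drug and reaction mentions, and
conflicting sex values collapse to ``unknown``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import EmptyDatasetError, FormatError

logger = logging.getLogger(__name__)

LONG_CSV_COLUMNS = ("case_id", "drug", "reaction_pt", "sex")

UNMAPPED_SOC_CODE = "UNMAPPED"


class Sex(str, Enum):
    """Patient sex as recorded on a report."""

    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


#: Vocabulary accepted in input files (case-insensitive).  Pharmacovigilance
#: exports vary: single letters, full words and ICH numeric codes all occur.
_SEX_ALIASES: dict[str, Sex] = {
    "m": Sex.MALE,
    "male": Sex.MALE,
    "1": Sex.MALE,
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
    "2": Sex.FEMALE,
    "": Sex.UNKNOWN,
    "na": Sex.UNKNOWN,
    "unknown": Sex.UNKNOWN,
}


def parse_sex(value: object) -> Sex:
    """Map a raw sex field to the enum; unrecognised values become unknown."""
    if isinstance(value, Sex):
        return value
    if value is None:
        return Sex.UNKNOWN
    text = str(value).strip().lower()
    try:
        return _SEX_ALIASES[text]
    except KeyError:
        logger.warning("unrecognised sex value %r mapped to unknown", value)
        return Sex.UNKNOWN


@dataclass(frozen=True)
class ReactionTerm:
    """One preferred term with its (single) parent System Organ Class."""

    pt_code: str
    pt_name: str
    soc_code: str
    soc_name: str


def unmapped_term(pt_code: str) -> ReactionTerm:
    """Sentinel term for a PT code that does not resolve in the map."""
    return ReactionTerm(pt_code, pt_code, UNMAPPED_SOC_CODE, "Unmapped")


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated spontaneous report."""

    case_id: str
    sex: Sex
    drugs: frozenset[str]
    reactions: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        object.__setattr__(self, "reactions", frozenset(self.reactions))
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if not self.drugs:
            raise ValueError(f"report {self.case_id!r} has no drugs")
        if not self.reactions:
            raise ValueError(f"report {self.case_id!r} has no reactions")
        if not isinstance(self.sex, Sex):
            object.__setattr__(self, "sex", parse_sex(self.sex))


@dataclass
class Dataset:
    """A collection of case reports plus the PT -> SOC terminology in force."""

    reports: list[CaseReport]
    term_map: dict[str, ReactionTerm]
    _index: object = field(default=None, repr=False, compare=False)

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def map_to_soc(self, pt_code: str) -> ReactionTerm:
        """Resolve a PT code; unknown codes return the UNMAPPED sentinel."""
        return self.term_map.get(pt_code, unmapped_term(pt_code))

    def unmapped_pts(self) -> set[str]:
        """PT codes referenced by reports that do not resolve in term_map."""
        referenced = {pt for r in self.reports for pt in r.reactions}
        return {pt for pt in referenced if pt not in self.term_map}


# ---------------------------------------------------------------------------
# terminology I/O


def load_term_map(path: str | Path) -> dict[str, ReactionTerm]:
    """Read a PT -> SOC map from a CSV with columns pt_code,pt_name,soc_code,soc_name."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ("pt_code", "pt_name", "soc_code", "soc_name")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"term map is missing required column {col!r}")
    terms: dict[str, ReactionTerm] = {}
    for row in df.itertuples(index=False):
        term = ReactionTerm(row.pt_code, row.pt_name, row.soc_code, row.soc_name)
        if term.pt_code in terms and terms[term.pt_code] != term:
            raise FormatError(
                f"PT code {term.pt_code!r} maps to more than one SOC"
            )
        terms[term.pt_code] = term
    return terms


def default_term_map() -> dict[str, ReactionTerm]:
    """The bundled 40-PT mock hierarchy covering common atopic-therapy ADRs."""
    with resources.as_file(
        resources.files("pvstrat.data").joinpath("pt_soc_map.csv")
    ) as path:
        return load_term_map(path)


# ---------------------------------------------------------------------------
# report merging / deduplication


def _merge_records(
    case_id: str,
    sexes: Iterable[Sex],
    drugs: Iterable[str],
    reactions: Iterable[str],
) -> CaseReport:
    observed = {s for s in sexes if s is not Sex.UNKNOWN}
    if len(observed) > 1:
        logger.warning("case %s has conflicting sex values; set to unknown", case_id)
        sex = Sex.UNKNOWN
    elif observed:
        sex = observed.pop()
    else:
        sex = Sex.UNKNOWN
    return CaseReport(case_id, sex, frozenset(drugs), frozenset(reactions))


def deduplicate(reports: Iterable[CaseReport]) -> list[CaseReport]:
    """Collapse reports sharing a case_id into one report per case.

    Drug and reaction mentions are unioned so no mention is lost; conflicting
    non-unknown sexes collapse to unknown.  Output is sorted by case_id, which
    makes the operation deterministic and idempotent.
    """
    groups: dict[str, list[CaseReport]] = {}
    for report in reports:
        groups.setdefault(report.case_id, []).append(report)
    merged = []
    for case_id in sorted(groups):
        group = groups[case_id]
        if len(group) == 1:
            merged.append(group[0])
        else:
            merged.append(
                _merge_records(
                    case_id,
                    (r.sex for r in group),
                    (d for r in group for d in r.drugs),
                    (pt for r in group for pt in r.reactions),
                )
            )
    return merged


# ---------------------------------------------------------------------------
# dataset I/O


def read_icsr(
    path: str | Path,
    format: str = "long_csv",
    term_map: Mapping[str, ReactionTerm] | None = None,
) -> Dataset:
    """Read a dataset from disk.

    ``long_csv`` is one row per case-drug-reaction mention with header
    ``case_id,drug,reaction_pt,sex``; ``json`` is an array of objects with
    the CaseReport fields.  Rows sharing a case_id are merged on read.
    """
    if format == "long_csv":
        reports = _read_long_csv(Path(path))
    elif format == "json":
        reports = _read_json(Path(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    if not reports:
        raise EmptyDatasetError(f"{path} contains no case reports")
    terms = dict(term_map) if term_map is not None else default_term_map()
    dataset = Dataset(reports, terms)
    n_unmapped = len(dataset.unmapped_pts())
    logger.info(
        "read %d case reports from %s (%d unmapped PT codes)",
        dataset.n_reports,
        path,
        n_unmapped,
    )
    return dataset


def _read_long_csv(path: Path) -> list[CaseReport]:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyDatasetError(f"{path} is empty") from None
    for col in LONG_CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path} is missing required column {col!r}")
    if df.empty:
        return []
    rows: dict[str, dict[str, set]] = {}
    for rec in df.itertuples(index=False):
        case_id = str(rec.case_id).strip()
        if not case_id:
            raise FormatError(f"{path} has a row with empty case_id")
        entry = rows.setdefault(
            case_id, {"sexes": set(), "drugs": set(), "reactions": set()}
        )
        entry["sexes"].add(parse_sex(rec.sex))
        if str(rec.drug).strip():
            entry["drugs"].add(str(rec.drug).strip())
        if str(rec.reaction_pt).strip():
            entry["reactions"].add(str(rec.reaction_pt).strip())
    return [
        _merge_records(cid, e["sexes"], e["drugs"], e["reactions"])
        for cid, e in sorted(rows.items())
    ]


def _read_json(path: Path) -> list[CaseReport]:
    text = Path(path).read_text(encoding="utf-8").strip()
    if not text:
        raise EmptyDatasetError(f"{path} is empty")
    records = json.loads(text)
    if not isinstance(records, list):
        raise FormatError(f"{path}: expected a JSON array of case reports")
    reports = []
    for rec in records:
        for key in ("case_id", "drugs", "reactions"):
            if key not in rec:
                raise FormatError(f"{path}: record is missing field {key!r}")
        reports.append(
            CaseReport(
                str(rec["case_id"]),
                parse_sex(rec.get("sex")),
                frozenset(map(str, rec["drugs"])),
                frozenset(map(str, rec["reactions"])),
            )
        )
    return deduplicate(reports)


def write_icsr(dataset: Dataset, path: str | Path, format: str = "long_csv") -> None:
    """Write a dataset; reading the file back reproduces the report multiset."""
    path = Path(path)
    reports = sorted(dataset.reports, key=lambda r: r.case_id)
    if format == "long_csv":
        records = [
            (r.case_id, drug, pt, r.sex.value)
            for r in reports
            for drug in sorted(r.drugs)
            for pt in sorted(r.reactions)
        ]
        pd.DataFrame(records, columns=list(LONG_CSV_COLUMNS)).to_csv(
            path, index=False
        )
    elif format == "json":
        payload = [
            {
                "case_id": r.case_id,
                "sex": r.sex.value,
                "drugs": sorted(r.drugs),
                "reactions": sorted(r.reactions),
            }
            for r in reports
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_term_map(term_map: Mapping[str, ReactionTerm], path: str | Path) -> None:
    rows = [
        (t.pt_code, t.pt_name, t.soc_code, t.soc_name)
        for t in sorted(term_map.values(), key=lambda t: t.pt_code)
    ]
    pd.DataFrame(rows, columns=["pt_code", "pt_name", "soc_code", "soc_name"]).to_csv(
        path, index=False
    )
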