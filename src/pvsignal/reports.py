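"""Report-level data model for spontaneous adverse-event databases.

Spontaneous reporting systems such as JADER (Japan) or FAERS (US) ship as a
small constellation of delimited tables keyed by a case identifier: patient
demographics, drug entries, coded adverse events (MedDRA preferred terms,
PTs), and primary diseases.  This module joins those tables into per-report
records, applies the standard inclusion filters of a case/non-case study
(non-missing sex, a numeric decade age bucket, at least one primary disease),
and classifies each report as a case (any event PT inside a query PT set) or
a non-case.

One report is one counting unit throughout: a report with three matching
drugs and two matching PTs still contributes exactly one case.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Ordered decade age buckets as reported in JADER-style demographics.
DECADE_BUCKETS: tuple[str, ...] = (
    "0-9", "10-19", "20-29", "30-39", "40-49",
    "50-59", "60-69", "70-79", "80-89", "90+",
)

_BUCKET_LOW = {b: 10 * i for i, b in enumerate(DECADE_BUCKETS)}

SEXES = ("male", "female")

_SEX_ALIASES = {
    "male": "male", "m": "male", "man": "male",
    "female": "female", "f": "female", "woman": "female",
}


def bucket_lower_bound(bucket: str) -> int | None:
    """Lower age bound of a decade bucket, or None for qualitative/missing."""
    return _BUCKET_LOW.get(bucket)


def normalize_drug_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    """Lowercase/trim a free-text drug name and apply an optional synonym map.

    Spontaneous-report drug fields are free text (brand names, salts,
    spacing variants); analysis joins on a normalized generic name.
    """
    key = name.strip().lower()
    if synonyms:
        key = synonyms.get(key, key)
    return key


@dataclass(frozen=True)
class DrugEntry:
    """One drug row of a report: name, reporter-assigned role, exposure dates."""

    drug_name: str
    role: str = "suspect"  # "suspect" | "concomitant"
    start_date: datetime.date | None = None
    end_date: datetime.date | None = None

    def __post_init__(self) -> None:
        if self.role not in ("suspect", "concomitant"):
            raise ValueError(f"unknown drug role: {self.role!r}")
        if (
            self.start_date is not None
            and self.end_date is not None
            and self.end_date < self.start_date
        ):
            raise ValueError(
                f"end_date {self.end_date} precedes start_date {self.start_date}"
            )


@dataclass(frozen=True)
class EventEntry:
    """One coded adverse event: MedDRA PT id/name plus onset date if reported."""

    pt_id: str
    pt_name: str = ""
    onset_date: datetime.date | None = None


@dataclass(frozen=True)
class PTSet:
    """A named query set of MedDRA preferred-term identifiers."""

    name: str
    pt_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.pt_ids:
            raise ValueError("PTSet must contain at least one preferred term")
        object.__setattr__(self, "pt_ids", frozenset(str(p) for p in self.pt_ids))

    def __contains__(self, pt_id: str) -> bool:
        return pt_id in self.pt_ids

    def union(self, other: "PTSet", name: str | None = None) -> "PTSet":
        return PTSet(name or f"{self.name}|{other.name}", self.pt_ids | other.pt_ids)

    @classmethod
    def from_yaml(cls, path) -> "PTSet":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(doc["name"], frozenset(str(k) for k in doc["preferred_terms"]))


@dataclass(frozen=True)
class DrugClassDef:
    """A drug class: label plus the set of normalized member generic names."""

    class_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("drug class must have at least one member")
        normalized = [normalize_drug_name(m) for m in self.members]
        if len(set(normalized)) < len(list(self.members)):
            logger.warning(
                "duplicate members collapsed in drug class %s", self.class_name
            )
        object.__setattr__(self, "members", frozenset(normalized))


@dataclass(frozen=True)
class ReportRecord:
    """One spontaneous report: demographics plus its drug and event lists.

    ``age_bucket`` holds either a decade bucket from :data:`DECADE_BUCKETS`,
    a qualitative word (e.g. "elderly") which counts as missing-like for the
    inclusion filters, or None.
    """

    case_id: str
    sex: str | None = None
    age_bucket: str | None = None
    primary_diseases: frozenset[str] = frozenset()
    drugs: tuple[DrugEntry, ...] = ()
    events: tuple[EventEntry, ...] = ()

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"sex must be male/female/None, got {self.sex!r}")
        object.__setattr__(self, "primary_diseases", frozenset(self.primary_diseases))
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "events", tuple(self.events))

    @property
    def has_numeric_age(self) -> bool:
        return self.age_bucket in _BUCKET_LOW

    @property
    def age_lower_bound(self) -> int | None:
        return bucket_lower_bound(self.age_bucket) if self.age_bucket else None


class ReportSet:
    """An ordered collection of reports with unique case ids."""

    def __init__(self, records):
        self.records: list[ReportRecord] = list(records)
        self._by_id = {r.case_id: r for r in self.records}
        if len(self._by_id) != len(self.records):
            raise ValueError("duplicate case_id in ReportSet")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, case_id: str) -> ReportRecord:
        return self._by_id[case_id]

    def __contains__(self, case_id: str) -> bool:
        return case_id in self._by_id

    def __eq__(self, other) -> bool:
        return isinstance(other, ReportSet) and self.records == other.records

    def filter(self, predicate) -> "ReportSet":
        return ReportSet(r for r in self.records if predicate(r))


# ---------------------------------------------------------------------------
# Dialect-driven table IO
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dialect:
    """Column names, delimiter and encoding of the four-table layout.

    Real distributions vary in delimiter and header language, so nothing is
    hardcoded; the default mirrors a JADER-like CSV layout with English
    column names.
    """

    delimiter: str = ","
    encoding: str = "utf-8"
    date_format: str = "%Y-%m-%d"
    demo_cols: dict = field(
        default_factory=lambda: {"case_id": "case_id", "sex": "sex", "age": "age"}
    )
    drug_cols: dict = field(
        default_factory=lambda: {
            "case_id": "case_id", "drug_name": "drug_name", "role": "role",
            "start_date": "start_date", "end_date": "end_date",
        }
    )
    reac_cols: dict = field(
        default_factory=lambda: {
            "case_id": "case_id", "pt_id": "pt_id", "pt_name": "pt_name",
            "onset_date": "onset_date",
        }
    )
    hist_cols: dict = field(
        default_factory=lambda: {"case_id": "case_id", "disease": "disease"}
    )

    @classmethod
    def from_yaml(cls, path) -> "Dialect":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def _read_table(path, dialect: Dialect, required_cols: dict) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep=dialect.delimiter,
            encoding=dialect.encoding,
            dtype=str,
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:  # pandas names the offending line
        raise ValueError(f"malformed row in {path}: {exc}") from exc
    missing = [c for c in required_cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def _parse_date(value: str, dialect: Dialect, path, row: int) -> datetime.date | None:
    if not value:
        return None
    try:
        return datetime.datetime.strptime(value, dialect.date_format).date()
    except ValueError as exc:
        raise ValueError(f"malformed row in {path}, line {row + 2}: {exc}") from exc


def load_report_set(
    demo_path, drug_path, reac_path, hist_path, dialect: Dialect | None = None
) -> ReportSet:
    """Join the four delimited tables into a :class:`ReportSet`.

    Outer-join semantics: the report universe is the union of case ids seen
    in any table; a case present only in the demographics table yields a
    record with empty drug/event lists.  Missing fields stay missing — the
    inclusion filters, not the loader, decide what to drop.  Duplicate
    (case_id, drug, role) rows are collapsed with a warning.
    """
    dialect = dialect or Dialect()
    demo = _read_table(demo_path, dialect, dialect.demo_cols)
    drug = _read_table(drug_path, dialect, dialect.drug_cols)
    reac = _read_table(reac_path, dialect, dialect.reac_cols)
    hist = _read_table(hist_path, dialect, dialect.hist_cols)

    dc, gc, rc, hc = dialect.demo_cols, dialect.drug_cols, dialect.reac_cols, dialect.hist_cols

    before = len(drug)
    drug = drug.drop_duplicates(subset=[gc["case_id"], gc["drug_name"], gc["role"]])
    if len(drug) < before:
        logger.warning(
            "collapsed %d duplicate (case_id, drug, role) rows in %s",
            before - len(drug), drug_path,
        )

    drugs_by_case: dict[str, list[DrugEntry]] = {}
    for i, row in enumerate(drug.itertuples(index=False)):
        row = row._asdict()
        drugs_by_case.setdefault(str(row[gc["case_id"]]), []).append(
            DrugEntry(
                drug_name=normalize_drug_name(row[gc["drug_name"]]),
                role=row[gc["role"]] or "suspect",
                start_date=_parse_date(row[gc["start_date"]], dialect, drug_path, i),
                end_date=_parse_date(row[gc["end_date"]], dialect, drug_path, i),
            )
        )

    events_by_case: dict[str, list[EventEntry]] = {}
    for i, row in enumerate(reac.itertuples(index=False)):
        row = row._asdict()
        events_by_case.setdefault(str(row[rc["case_id"]]), []).append(
            EventEntry(
                pt_id=str(row[rc["pt_id"]]),
                pt_name=row[rc["pt_name"]],
                onset_date=_parse_date(row[rc["onset_date"]], dialect, reac_path, i),
            )
        )

    diseases_by_case: dict[str, set[str]] = {}
    for row in hist.itertuples(index=False):
        row = row._asdict()
        if row[hc["disease"]]:
            diseases_by_case.setdefault(str(row[hc["case_id"]]), set()).add(
                row[hc["disease"]]
            )

    demo_by_case: dict[str, dict] = {}
    for row in demo.itertuples(index=False):
        row = row._asdict()
        demo_by_case[str(row[dc["case_id"]])] = {
            "sex": _SEX_ALIASES.get(row[dc["sex"]].strip().lower()) or None,
            "age": row[dc["age"]].strip() or None,
        }

    all_ids = list(demo_by_case)
    seen = set(all_ids)
    for extra in (drugs_by_case, events_by_case, diseases_by_case):
        for cid in extra:
            if cid not in seen:
                seen.add(cid)
                all_ids.append(cid)

    records = []
    for cid in all_ids:
        d = demo_by_case.get(cid, {"sex": None, "age": None})
        records.append(
            ReportRecord(
                case_id=cid,
                sex=d["sex"],
                age_bucket=d["age"],
                primary_diseases=frozenset(diseases_by_case.get(cid, ())),
                drugs=tuple(drugs_by_case.get(cid, ())),
                events=tuple(events_by_case.get(cid, ())),
            )
        )
    return ReportSet(records)


def write_report_set(reports: ReportSet, outdir, dialect: Dialect | None = None) -> dict:
    """Write a ReportSet back out as the four delimited tables.

    Returns a dict of table name -> written path.  ``load_report_set`` on the
    result reproduces the input (round-trip identity), which is how the
    synthetic generator materializes file-level fixtures.
    """
    from pathlib import Path

    dialect = dialect or Dialect()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = dialect.date_format

    def datestr(d: datetime.date | None) -> str:
        return d.strftime(fmt) if d else ""

    dc, gc, rc, hc = dialect.demo_cols, dialect.drug_cols, dialect.reac_cols, dialect.hist_cols
    demo_rows, drug_rows, reac_rows, hist_rows = [], [], [], []
    for r in reports:
        demo_rows.append(
            {dc["case_id"]: r.case_id, dc["sex"]: r.sex or "", dc["age"]: r.age_bucket or ""}
        )
        for d in r.drugs:
            drug_rows.append({
                gc["case_id"]: r.case_id, gc["drug_name"]: d.drug_name,
                gc["role"]: d.role, gc["start_date"]: datestr(d.start_date),
                gc["end_date"]: datestr(d.end_date),
            })
        for e in r.events:
            reac_rows.append({
                rc["case_id"]: r.case_id, rc["pt_id"]: e.pt_id,
                rc["pt_name"]: e.pt_name, rc["onset_date"]: datestr(e.onset_date),
            })
        for dis in sorted(r.primary_diseases):
            hist_rows.append({hc["case_id"]: r.case_id, hc["disease"]: dis})

    paths = {}
    for name, rows, cols in (
        ("demo", demo_rows, list(dc.values())),
        ("drug", drug_rows, list(gc.values())),
        ("reac", reac_rows, list(rc.values())),
        ("hist", hist_rows, list(hc.values())),
    ):
        path = outdir / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(
            path, sep=dialect.delimiter, index=False, encoding=dialect.encoding
        )
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Inclusion filters and case classification
# ---------------------------------------------------------------------------

def apply_exclusions(
    reports: ReportSet, require_primary_disease_in: set[str] | None = None
) -> ReportSet:
    """Apply the standard case/non-case inclusion filters.

    Retains reports with non-missing sex, a numeric decade age bucket
    (qualitative words like "elderly" count as missing), and at least one
    primary disease.  ``require_primary_disease_in`` optionally restricts to
    reports whose primary diseases intersect a given set — the mechanism used
    to emulate a restriction to, e.g., diabetic patients.  Idempotent.
    """

    def keep(r: ReportRecord) -> bool:
        if r.sex not in SEXES or not r.has_numeric_age or not r.primary_diseases:
            return False
        if require_primary_disease_in is not None:
            return bool(r.primary_diseases & set(require_primary_disease_in))
        return True

    return reports.filter(keep)


def classify_case(report: ReportRecord, pts: PTSet) -> bool:
    """True iff any of the report's event PTs belongs to the query set.

    A report with zero events is invalid input: spontaneous reports exist
    only because an adverse event occurred.
    """
    if not report.events:
        raise ValueError(f"report {report.case_id} has no adverse events")
    return any(e.pt_id in pts.pt_ids for e in report.events)


def is_exposed(
    report: ReportRecord,
    target: DrugClassDef | str,
    include_concomitant: bool = False,
) -> bool:
    """True iff the report carries a target drug in the counted role(s).

    By convention only suspect drugs count; ``include_concomitant`` widens
    the role filter for sensitivity analyses.
    """
    if isinstance(target, DrugClassDef):
        members = target.members
    else:
        members = frozenset({normalize_drug_name(target)})
    roles = ("suspect", "concomitant") if include_concomitant else ("suspect",)
    return any(d.drug_name in members and d.role in roles for d in report.drugs)
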