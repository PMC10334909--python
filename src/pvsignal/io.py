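"""Reading and writing FAERS quarterly-extract ASCII tables.

The FDA Adverse Event Reporting System (FAERS) Quarterly Data Extract
distributes each quarter as a set of dollar-sign-delimited ASCII tables
(DEMO, DRUG, REAC, OUTC, INDI).  The dialect has no quoting and no escape
character, so a field can never legitimately contain the delimiter; real
files nonetheless contain stray bytes and ragged lines.  This module parses
those tables into typed records, writes them back (round-trip identity),
and assembles a date-windowed, multi-quarter dataset.

Parsing policy
--------------
* Columns are located by header name; extra columns are ignored.
* A line with *more* fields than the header has its overflow folded into
  the trailing column (free text in every table we read); a line with
  *fewer* fields is recorded in the rejects report, never silently dropped.
* Undecodable bytes are replaced (FAERS files contain stray non-UTF-8
  bytes).
* Child records (DRUG/REAC/OUTC/INDI) whose ``primaryid`` has no DEMO
  parent cannot form a case and are dropped with a logged count.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

DELIM = "$"

AGE_UNITS = frozenset({"YR", "DEC", "MON", "WK", "DY", "HR"})
SEX_CODES = frozenset({"M", "F", "UNK"})
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: serious outcome codes — any one of these marks the case serious
SERIOUS_OUTCOMES = OUTCOME_CODES


# ---------------------------------------------------------------------------
# records


@dataclass
class DemoRecord:
    """One row of a DEMO table: report-level demographics."""

    primaryid: str
    caseid: str
    caseversion: int = 1
    fda_receipt_date: dt.date | None = None
    event_date: dt.date | None = None
    age_value: float | None = None
    age_unit: str | None = None
    sex: str = "UNK"
    country: str | None = None
    quarter: str | None = None  # provenance, set by the loader; not a file column

    def __post_init__(self) -> None:
        # the two age fields travel together
        if (self.age_value is None) != (self.age_unit is None):
            self.age_value = None
            self.age_unit = None
        if self.sex not in SEX_CODES:
            self.sex = "UNK"


@dataclass
class DrugRecord:
    primaryid: str
    drug_seq: int
    role_code: str
    drugname: str
    indication_pt: str | None = None


@dataclass
class ReactionRecord:
    primaryid: str
    reaction_pt: str


@dataclass
class OutcomeRecord:
    primaryid: str
    outcome_code: str


@dataclass
class IndicationRecord:
    primaryid: str
    indi_drug_seq: int
    indi_pt: str


@dataclass
class Reject:
    """A line that could not be parsed into a record."""

    line_no: int
    reason: str
    raw: str


@dataclass
class ParseResult:
    records: list
    rejects: list[Reject] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class QuarterlyDataset:
    """A (possibly merged) set of FAERS tables sharing one report universe."""

    demo: list[DemoRecord]
    drug: list[DrugRecord]
    reac: list[ReactionRecord]
    outc: list[OutcomeRecord]
    quarter_label: str = ""

    def primaryids(self) -> set[str]:
        return {r.primaryid for r in self.demo}


# ---------------------------------------------------------------------------
# table schemas

#: required columns per table kind; the trailing column absorbs overflow
TABLE_COLUMNS: dict[str, list[str]] = {
    "DEMO": ["primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
             "age", "age_cod", "sex", "reporter_country"],
    "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname"],
    "REAC": ["primaryid", "pt"],
    "OUTC": ["primaryid", "outc_cod"],
    "INDI": ["primaryid", "indi_drug_seq", "indi_pt"],
}


class SchemaError(ValueError):
    """Header is missing a required column."""


def _parse_date(s: str) -> dt.date | None:
    # FAERS dates are YYYYMMDD; partial dates (YYYY, YYYYMM) occur and are
    # treated as unknown rather than guessed.
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None


def _fmt_date(d: dt.date | None) -> str:
    return d.strftime("%Y%m%d") if d is not None else ""


def _fmt_num(x: float | int | None) -> str:
    if x is None:
        return ""
    f = float(x)
    return str(int(f)) if f.is_integer() else repr(f)


def _row_to_demo(get, quarter: str | None) -> DemoRecord:
    ver = get("caseversion")
    age = get("age")
    unit = get("age_cod")
    if unit is not None:
        unit = unit.upper()
        if unit not in AGE_UNITS:
            unit = None
    return DemoRecord(
        primaryid=get("primaryid"),
        caseid=get("caseid"),
        caseversion=int(ver) if ver else 1,
        fda_receipt_date=_parse_date(get("fda_dt") or ""),
        event_date=_parse_date(get("event_dt") or ""),
        age_value=float(age) if age else None,
        age_unit=unit if age else None,
        sex=(get("sex") or "UNK").upper(),
        country=get("reporter_country"),
        quarter=quarter,
    )


def _row_to_drug(get, quarter) -> DrugRecord:
    role = (get("role_cod") or "").upper()
    if role not in ROLE_CODES:
        raise ValueError(f"unknown role code {role!r}")
    name = (get("drugname") or "").strip()
    if not name:
        raise ValueError("empty drugname")
    return DrugRecord(
        primaryid=get("primaryid"),
        drug_seq=int(get("drug_seq")),
        role_code=role,
        drugname=name,
        indication_pt=None,
    )


def _row_to_reac(get, quarter) -> ReactionRecord:
    pt = (get("pt") or "").strip()
    if not pt:
        raise ValueError("empty reaction PT")
    return ReactionRecord(primaryid=get("primaryid"), reaction_pt=pt)


def _row_to_outc(get, quarter) -> OutcomeRecord:
    code = (get("outc_cod") or "").upper()
    if code not in OUTCOME_CODES:
        raise ValueError(f"unknown outcome code {code!r}")
    return OutcomeRecord(primaryid=get("primaryid"), outcome_code=code)


def _row_to_indi(get, quarter) -> IndicationRecord:
    pt = (get("indi_pt") or "").strip()
    if not pt:
        raise ValueError("empty indication PT")
    return IndicationRecord(
        primaryid=get("primaryid"),
        indi_drug_seq=int(get("indi_drug_seq")),
        indi_pt=pt,
    )


_ROW_BUILDERS = {
    "DEMO": _row_to_demo,
    "DRUG": _row_to_drug,
    "REAC": _row_to_reac,
    "OUTC": _row_to_outc,
    "INDI": _row_to_indi,
}


# ---------------------------------------------------------------------------
# parse / write


def parse_table(path: str | Path, kind: str, quarter: str | None = None) -> ParseResult:
    """Parse one FAERS ASCII table into typed records.

    Parameters
    ----------
    path : path to the dollar-delimited file (header line first).
    kind : one of ``DEMO``, ``DRUG``, ``REAC``, ``OUTC``, ``INDI``.
    quarter : optional provenance label stamped onto DEMO records.

    Returns
    -------
    ParseResult with ``.records`` and a ``.rejects`` report of malformed
    lines (wrong field count, invalid codes).  Raises :class:`SchemaError`
    if the header lacks a required column.
    """
    kind = kind.upper()
    required = TABLE_COLUMNS[kind]
    build = _ROW_BUILDERS[kind]

    text = Path(path).read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file, no header")

    header = [h.strip().lower() for h in lines[0].split(DELIM)]
    idx: dict[str, int] = {}
    for col in required:
        if col not in header:
            raise SchemaError(f"{path}: header missing required column {col!r}")
        idx[col] = header.index(col)
    ncol = len(header)
    last_required_is_tail = idx[required[-1]] == ncol - 1

    records: list = []
    rejects: list[Reject] = []
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(DELIM)
        if len(fields) < ncol:
            rejects.append(Reject(line_no, f"{len(fields)} fields, header has {ncol}", line))
            continue
        if len(fields) > ncol:
            if last_required_is_tail:
                # stray delimiter in the trailing free-text column
                fields = fields[: ncol - 1] + [DELIM.join(fields[ncol - 1:])]
            else:
                rejects.append(Reject(line_no, f"{len(fields)} fields, header has {ncol}", line))
                continue

        def get(col: str, _f=fields) -> str | None:
            v = _f[idx[col]].strip()
            return v if v else None

        try:
            records.append(build(get, quarter))
        except (ValueError, TypeError) as exc:
            rejects.append(Reject(line_no, str(exc), line))

    if rejects:
        log.warning("%s: %d malformed line(s) recorded in rejects report", path, len(rejects))
    return ParseResult(records=records, rejects=rejects)


def _record_fields(kind: str, rec) -> list[str]:
    if kind == "DEMO":
        return [
            rec.primaryid, rec.caseid, str(rec.caseversion),
            _fmt_date(rec.fda_receipt_date), _fmt_date(rec.event_date),
            _fmt_num(rec.age_value), rec.age_unit or "",
            rec.sex, rec.country or "",
        ]
    if kind == "DRUG":
        return [rec.primaryid, str(rec.drug_seq), rec.role_code, rec.drugname]
    if kind == "REAC":
        return [rec.primaryid, rec.reaction_pt]
    if kind == "OUTC":
        return [rec.primaryid, rec.outcome_code]
    if kind == "INDI":
        return [rec.primaryid, str(rec.indi_drug_seq), rec.indi_pt]
    raise ValueError(kind)


def write_table(records: Sequence, path: str | Path, kind: str) -> None:
    """Write records as a FAERS-dialect table; ``parse_table`` round-trips it.

    The dialect cannot escape the delimiter, so any ``$`` inside a field is
    replaced by a space (mirroring how real FAERS text is sanitised).
    """
    kind = kind.upper()
    cols = TABLE_COLUMNS[kind]
    out = [DELIM.join(cols)]
    for rec in records:
        fields = [f.replace(DELIM, " ") for f in _record_fields(kind, rec)]
        out.append(DELIM.join(fields))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# multi-quarter loading

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "INDI")


@dataclass
class QuarterFiles:
    """Paths to the five tables of one quarterly extract."""

    label: str
    demo: Path
    drug: Path
    reac: Path
    outc: Path
    indi: Path | None = None

    @classmethod
    def from_dir(cls, directory: str | Path, label: str | None = None) -> "QuarterFiles":
        """Locate DEMO*/DRUG*/... files in a directory by name prefix."""
        directory = Path(directory)

        def find(prefix: str, optional: bool = False) -> Path | None:
            hits = sorted(p for p in directory.iterdir()
                          if p.name.upper().startswith(prefix) and p.is_file())
            if not hits:
                if optional:
                    return None
                raise FileNotFoundError(f"no {prefix}* file in {directory}")
            return hits[0]

        return cls(
            label=label or directory.name,
            demo=find("DEMO"), drug=find("DRUG"), reac=find("REAC"),
            outc=find("OUTC"), indi=find("INDI", optional=True),
        )


def write_dataset(ds: QuarterlyDataset, directory: str | Path) -> QuarterFiles:
    """Write a dataset's four core tables (plus INDI) into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_table(ds.demo, directory / "DEMO.txt", "DEMO")
    write_table(ds.drug, directory / "DRUG.txt", "DRUG")
    write_table(ds.reac, directory / "REAC.txt", "REAC")
    write_table(ds.outc, directory / "OUTC.txt", "OUTC")
    indis = [
        IndicationRecord(d.primaryid, d.drug_seq, d.indication_pt)
        for d in ds.drug if d.indication_pt
    ]
    write_table(indis, directory / "INDI.txt", "INDI")
    return QuarterFiles.from_dir(directory, label=ds.quarter_label or directory.name)


def load_window(
    quarters: Iterable[QuarterFiles],
    window: tuple[dt.date, dt.date],
    date_field: str = "fda_receipt_date",
) -> QuarterlyDataset:
    """Load quarterly extracts and restrict to a closed date window.

    Reports are kept when their windowing date (FDA receipt date by
    default; ``date_field="event_date"`` is the alternative convention)
    falls inside ``[start, end]``, both ends inclusive.  Within one
    quarter a duplicated ``primaryid`` keeps the first occurrence; across
    quarters duplicates are allowed (they are report versions and are
    resolved later by case deduplication).  INDI rows are folded into
    ``DrugRecord.indication_pt`` on (primaryid, drug_seq).
    """
    start, end = window
    if start > end:
        raise ValueError(f"window start {start} after end {end}")
    if date_field not in ("fda_receipt_date", "event_date"):
        raise ValueError(f"unknown date_field {date_field!r}")

    demo_all: list[DemoRecord] = []
    drug_all: list[DrugRecord] = []
    reac_all: list[ReactionRecord] = []
    outc_all: list[OutcomeRecord] = []
    labels: list[str] = []

    for q in quarters:
        labels.append(q.label)
        demo = parse_table(q.demo, "DEMO", quarter=q.label).records
        drug = parse_table(q.drug, "DRUG").records
        reac = parse_table(q.reac, "REAC").records
        outc = parse_table(q.outc, "OUTC").records

        # first-wins within a quarter for duplicated primaryid
        seen: set[str] = set()
        uniq: list[DemoRecord] = []
        dup = 0
        for r in demo:
            if r.primaryid in seen:
                dup += 1
                continue
            seen.add(r.primaryid)
            uniq.append(r)
        if dup:
            log.warning("%s: %d duplicate primaryid row(s) within quarter, kept first", q.label, dup)

        kept = [r for r in uniq if getattr(r, date_field) is not None
                and start <= getattr(r, date_field) <= end]
        kept_ids = {r.primaryid for r in kept}

        if q.indi is not None:
            indi = parse_table(q.indi, "INDI").records
            by_key = {(i.primaryid, i.indi_drug_seq): i.indi_pt for i in indi}
            unjoined = 0
            for d in drug:
                pt = by_key.get((d.primaryid, d.drug_seq))
                if pt is not None:
                    d.indication_pt = pt
            unjoined = len(by_key) - sum(
                1 for d in drug if (d.primaryid, d.drug_seq) in by_key)
            if unjoined > 0:
                log.info("%s: %d INDI row(s) had no matching DRUG row", q.label, unjoined)

        n_orphan = sum(1 for r in drug + reac + outc
                       if r.primaryid not in seen)
        if n_orphan:
            log.warning("%s: dropped %d orphan child record(s) with no DEMO parent",
                        q.label, n_orphan)

        demo_all.extend(kept)
        drug_all.extend(d for d in drug if d.primaryid in kept_ids)
        reac_all.extend(r for r in reac if r.primaryid in kept_ids)
        outc_all.extend(o for o in outc if o.primaryid in kept_ids)

    return QuarterlyDataset(
        demo=demo_all, drug=drug_all, reac=reac_all, outc=outc_all,
        quarter_label="+".join(labels),
    )


def export_csv(records: Sequence, path: str | Path, kind: str) -> None:
    """CSV export of a record list (normalised output convenience)."""
    import pandas as pd

    kind = kind.upper()
    cols = TABLE_COLUMNS[kind]
    rows = [_record_fields(kind, r) for r in records]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
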