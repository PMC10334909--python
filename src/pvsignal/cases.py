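"""Case deduplication and drug/event membership queries.

FAERS is report-oriented: one safety case may appear several times as
successive versions (same ``caseid``, increasing ``caseversion``), and the
same case may recur across quarterly extracts.  Disproportionality counts
must be per *case*, so the pipeline collapses versions to a single
retained report before any counting.

Retention rule: highest ``caseversion``; ties broken by latest FDA receipt
date, then by lexicographically greatest ``primaryid``.  The rule is
deterministic and idempotent.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import (
    DemoRecord,
    DrugRecord,
    OutcomeRecord,
    QuarterlyDataset,
    ReactionRecord,
    ROLE_CODES,
    SERIOUS_OUTCOMES,
)

#: dosage-form / strength tokens stripped from the tail of a drug name
DEFAULT_STOPLIST = frozenset({
    "MG", "MCG", "G", "GM", "ML", "MG/ML", "TABLET", "TABLETS", "TAB",
    "CAPSULE", "CAPSULES", "CAP", "INJECTION", "ORAL", "SOLUTION",
    "SUSPENSION", "CREAM", "HCL", "ER", "XR", "SR",
})

_WS = re.compile(r"\s+")
_NUM = re.compile(r"^\d+(\.\d+)?$")


def normalize_drugname(raw: str, stoplist: frozenset[str] = DEFAULT_STOPLIST) -> str:
    """Normalise a verbatim drug name for matching.

    Uppercase, trim, collapse internal whitespace, then strip trailing
    tokens that are numbers or dosage-form words (``"avapritinib 300 MG"``
    → ``"AVAPRITINIB"``).  Returns ``""`` when nothing survives; callers
    treat that as unmatched.
    """
    tokens = _WS.sub(" ", raw.strip().upper()).split(" ")
    while tokens and (tokens[-1] in stoplist or _NUM.match(tokens[-1])):
        tokens.pop()
    return " ".join(tokens)


@dataclass(frozen=True)
class DrugQuery:
    """Which drug records count as 'the drug' for a 2x2 table.

    ``names`` holds generic and trade synonyms (e.g. AVAPRITINIB and
    AYVAKIT); matching is against the normalised record name, either
    exact or substring.  ``roles`` restricts to FAERS role codes —
    'suspect' means {PS, SS}.
    """

    names: frozenset[str]
    match_mode: str = "exact"  # "exact" | "substring"
    roles: frozenset[str] = frozenset({"PS", "SS"})

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("DrugQuery.names must be nonempty")
        if not self.roles or not self.roles <= ROLE_CODES:
            raise ValueError(f"roles must be a nonempty subset of {sorted(ROLE_CODES)}")
        if self.match_mode not in ("exact", "substring"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        object.__setattr__(self, "names",
                           frozenset(normalize_drugname(n) for n in self.names))

    def matches(self, record: DrugRecord) -> bool:
        if record.role_code not in self.roles:
            return False
        name = normalize_drugname(record.drugname)
        if not name:
            return False
        if self.match_mode == "exact":
            return name in self.names
        return any(q in name for q in self.names)


@dataclass(frozen=True)
class EventQuery:
    """MedDRA preferred terms defining 'the event' (case-insensitive equality)."""

    preferred_terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.preferred_terms:
            raise ValueError("EventQuery.preferred_terms must be nonempty")
        object.__setattr__(self, "preferred_terms",
                           frozenset(t.strip().lower() for t in self.preferred_terms))

    def matches(self, reaction_pt: str) -> bool:
        return reaction_pt.strip().lower() in self.preferred_terms


@dataclass
class CaseReport:
    """One deduplicated safety case: the retained report version."""

    caseid: str
    chosen_primaryid: str
    demographics: DemoRecord
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReactionRecord] = field(default_factory=list)
    outcomes: list[OutcomeRecord] = field(default_factory=list)

    @property
    def serious(self) -> bool:
        """True iff any outcome code marks a serious condition."""
        return any(o.outcome_code in SERIOUS_OUTCOMES for o in self.outcomes)


@dataclass
class DedupResult:
    cases: list[CaseReport]
    n_reports_in: int
    n_discarded: int

    def __iter__(self):
        return iter(self.cases)

    def __len__(self) -> int:
        return len(self.cases)


_EPOCH = dt.date.min


def _retention_key(r: DemoRecord) -> tuple:
    return (r.caseversion, r.fda_receipt_date or _EPOCH, r.primaryid)


def deduplicate(dataset: QuarterlyDataset) -> DedupResult:
    """Collapse report versions into one :class:`CaseReport` per caseid.

    The retained version is the report with the highest caseversion,
    ties broken by latest receipt date, then greatest primaryid.  Child
    records (drugs, reactions, outcomes) are taken from the retained
    report only.
    """
    best: dict[str, DemoRecord] = {}
    for r in dataset.demo:
        cur = best.get(r.caseid)
        if cur is None or _retention_key(r) > _retention_key(cur):
            best[r.caseid] = r

    chosen_ids = {r.primaryid: r.caseid for r in best.values()}
    drugs: dict[str, list[DrugRecord]] = {pid: [] for pid in chosen_ids}
    reacs: dict[str, list[ReactionRecord]] = {pid: [] for pid in chosen_ids}
    outcs: dict[str, list[OutcomeRecord]] = {pid: [] for pid in chosen_ids}
    for d in dataset.drug:
        if d.primaryid in drugs:
            drugs[d.primaryid].append(d)
    for x in dataset.reac:
        if x.primaryid in reacs:
            reacs[x.primaryid].append(x)
    for o in dataset.outc:
        if o.primaryid in outcs:
            outcs[o.primaryid].append(o)

    cases = [
        CaseReport(
            caseid=demo.caseid,
            chosen_primaryid=demo.primaryid,
            demographics=demo,
            drugs=drugs[demo.primaryid],
            reactions=reacs[demo.primaryid],
            outcomes=outcs[demo.primaryid],
        )
        for demo in sorted(best.values(), key=lambda r: r.caseid)
    ]
    n_in = len(dataset.demo)
    return DedupResult(cases=cases, n_reports_in=n_in, n_discarded=n_in - len(cases))


def case_has_drug(case: CaseReport, q: DrugQuery) -> bool:
    """True iff some drug record matches the query's names under its roles."""
    return any(q.matches(d) for d in case.drugs)


def case_has_event(case: CaseReport, q: EventQuery) -> bool:
    """True iff some reaction PT equals (case-insensitively) a query term."""
    return any(q.matches(r.reaction_pt) for r in case.reactions)


def matching_cases(
    cases: Iterable[CaseReport], drug: DrugQuery, event: EventQuery
) -> list[CaseReport]:
    """The case series: cases matching both the drug and the event query."""
    return [c for c in cases if case_has_drug(c, drug) and case_has_event(c, event)]


def cases_to_dataset(cases: Sequence[CaseReport], label: str = "dedup") -> QuarterlyDataset:
    """Repackage deduplicated cases as a dataset (for normalised export)."""
    return QuarterlyDataset(
        demo=[c.demographics for c in cases],
        drug=[d for c in cases for d in c.drugs],
        reac=[r for c in cases for r in c.reactions],
        outc=[o for c in cases for o in c.outcomes],
        quarter_label=label,
    )
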