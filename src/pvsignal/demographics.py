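"""Table-1-style demographic summaries of a drug–event case series.

Counts and integer percentages (round half away from zero, so 84.6 → 85
and 38.46 → 38) for sex, age bins, indication and seriousness, mirroring
the layout of a clinical case-series table.  FAERS ages carry units
(years, decades, months, weeks, days, hours) and are converted to years
before binning; a case with no usable age lands in the Unknown bin so
nothing is silently lost.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from .cases import CaseReport, DrugQuery, EventQuery, matching_cases

log = logging.getLogger(__name__)

#: conversion divisors to years per FAERS age_cod
_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 0.1,          # value in decades → multiply by 10
    "MON": 12.0,
    "WK": 52.1775,
    "DY": 365.25,
    "HR": 8766.0,
}

#: default age bins (closed on both ends, as printed in case-series tables)
DEFAULT_AGE_BINS: tuple[tuple[int, int], ...] = ((31, 50), (51, 60), (61, 70), (71, 80))


def age_to_years(value: float, unit: str) -> float | None:
    """Convert a FAERS age value+unit to years; unknown units → None, logged."""
    if value is None or value < 0:
        return None
    div = _UNIT_TO_YEARS.get(unit)
    if div is None:
        log.warning("unknown age unit %r; treating age as missing", unit)
        return None
    return value / div


def percent(count: int, total: int) -> int:
    """Integer percentage, rounding half away from zero (84.6 → 85, 38.46 → 38)."""
    if total == 0:
        raise ValueError("total must be positive")
    x = 100.0 * count / total
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class DemographicSummary:
    """Binned counts and integer percentages for one case series.

    Percent columns may not sum to 100 because each bin is rounded
    independently.
    """

    n: int
    sex_counts: dict[str, tuple[int, int]]                 # code -> (count, pct)
    age_bins: list[tuple[str, int, int]]                   # (label, count, pct), ordered
    indication_counts: dict[str, tuple[int, int]]          # PT -> (count, pct)
    seriousness: dict[str, tuple[int, int]]                # serious / non-serious
    age_mean_years: float | None
    age_range_years: tuple[float, float] | None
    country_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    coreported_events: list[tuple[str, int]] = field(default_factory=list)

    def format_text(self) -> str:
        lines = [f"Case series (N={self.n}), n (%)", ""]
        lines.append("Sex")
        for code in ("M", "F", "UNK"):
            if code in self.sex_counts:
                c, p = self.sex_counts[code]
                label = {"M": "Male", "F": "Female", "UNK": "Unknown"}[code]
                lines.append(f"  {label:<14s} {c:>4d} ({p})")
        lines.append("Age (years)")
        for label, c, p in self.age_bins:
            lines.append(f"  {label:<14s} {c:>4d} ({p})")
        if self.age_mean_years is not None:
            lo, hi = self.age_range_years
            lines.append(f"  mean {self.age_mean_years:.1f}, range {lo:g} to {hi:g}")
        lines.append("Indication")
        for pt, (c, p) in sorted(self.indication_counts.items(),
                                 key=lambda kv: (-kv[1][0], kv[0])):
            lines.append(f"  {pt:<30s} {c:>4d} ({p})")
        lines.append("Seriousness")
        for key in ("serious", "non-serious"):
            c, p = self.seriousness[key]
            lines.append(f"  {key:<14s} {c:>4d} ({p})")
        return "\n".join(lines)

    def to_frame(self):
        """Long-format DataFrame: breakdown / level / count / percent."""
        import pandas as pd

        rows = []
        for code, (c, p) in self.sex_counts.items():
            rows.append(("sex", code, c, p))
        for label, c, p in self.age_bins:
            rows.append(("age", label, c, p))
        for pt, (c, p) in self.indication_counts.items():
            rows.append(("indication", pt, c, p))
        for key, (c, p) in self.seriousness.items():
            rows.append(("seriousness", key, c, p))
        for country, (c, p) in self.country_counts.items():
            rows.append(("country", country, c, p))
        return pd.DataFrame(rows, columns=["breakdown", "level", "count", "percent"])


def _case_age_years(case: CaseReport) -> float | None:
    demo = case.demographics
    if demo.age_value is None or demo.age_unit is None:
        return None
    return age_to_years(demo.age_value, demo.age_unit)


def summarize(
    cases: Sequence[CaseReport],
    drug: DrugQuery,
    event: EventQuery,
    age_bin_edges: Sequence[tuple[int, int]] = DEFAULT_AGE_BINS,
) -> DemographicSummary:
    """Summarise the cases matching both queries.

    Age bins are closed on both ends as printed (``31-50`` includes 31
    and 50); ages below the first bin fall into an automatically
    prepended ``<lo`` bin, ages above the last into a ``>hi`` bin, and
    missing ages into ``Unknown``.  The indication is read from the drug
    records matching the query (the studied drug's indication), not from
    every drug on the case.  Raises ``ValueError`` when no case matches.
    """
    series = matching_cases(cases, drug, event)
    n = len(series)
    if n == 0:
        raise ValueError("no cases match both the drug and the event query")

    sex_raw = {"M": 0, "F": 0, "UNK": 0}
    for case in series:
        sex_raw[case.demographics.sex] += 1
    sex_counts = {k: (v, percent(v, n)) for k, v in sex_raw.items() if v > 0}

    bins = sorted(age_bin_edges)
    labels = [f"{lo}-{hi}" for lo, hi in bins]
    counts = [0] * len(bins)
    under = over = unknown = 0
    ages: list[float] = []
    for case in series:
        yrs = _case_age_years(case)
        if yrs is None:
            unknown += 1
            continue
        ages.append(yrs)
        placed = False
        for i, (lo, hi) in enumerate(bins):
            if lo <= yrs <= hi:
                counts[i] += 1
                placed = True
                break
        if not placed:
            if yrs < bins[0][0]:
                under += 1
            else:
                over += 1
    age_rows: list[tuple[str, int, int]] = []
    if under:
        age_rows.append((f"<{bins[0][0]}", under, percent(under, n)))
    for label, c in zip(labels, counts):
        age_rows.append((label, c, percent(c, n)))
    if over:
        age_rows.append((f">{bins[-1][1]}", over, percent(over, n)))
    age_rows.append(("Unknown", unknown, percent(unknown, n)))

    indi_raw: dict[str, int] = {}
    for case in series:
        pts = {d.indication_pt for d in case.drugs
               if drug.matches(d) and d.indication_pt}
        if not pts:
            pts = {"Unknown"}
        for pt in pts:
            indi_raw[pt] = indi_raw.get(pt, 0) + 1
    indication_counts = {pt: (c, percent(c, n)) for pt, c in indi_raw.items()}

    n_serious = sum(1 for case in series if case.serious)
    seriousness = {
        "serious": (n_serious, percent(n_serious, n)),
        "non-serious": (n - n_serious, percent(n - n_serious, n)),
    }

    country_raw: dict[str, int] = {}
    for case in series:
        country_raw.setdefault(case.demographics.country or "Unknown", 0)
        country_raw[case.demographics.country or "Unknown"] += 1
    country_counts = {k: (v, percent(v, n)) for k, v in country_raw.items()}

    # plain frequency list of events co-reported with the queried event
    co_raw: dict[str, int] = {}
    for case in series:
        for pt in {r.reaction_pt.strip() for r in case.reactions}:
            if not event.matches(pt):
                co_raw[pt] = co_raw.get(pt, 0) + 1
    coreported = sorted(co_raw.items(), key=lambda kv: (-kv[1], kv[0]))

    return DemographicSummary(
        n=n,
        sex_counts=sex_counts,
        age_bins=age_rows,
        indication_counts=indication_counts,
        seriousness=seriousness,
        age_mean_years=(sum(ages) / len(ages)) if ages else None,
        age_range_years=(min(ages), max(ages)) if ages else None,
        country_counts=country_counts,
        coreported_events=coreported,
    )
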