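"""Disproportionality statistics for drug–event pairs on a 2x2 case table.

Spontaneous-report signal detection asks whether a drug–event pair is
reported more often than independence of drug and event would predict.
All statistics here are functions of the 2x2 table of deduplicated cases

    =============  ==========  =============
    .              event       no event
    =============  ==========  =============
    drug           a           b
    no drug        c           d
    =============  ==========  =============

with n = a+b+c+d.  The module provides

* PRR, the proportional reporting ratio  [a/(a+b)] / [c/(c+d)],
* the one-degree-of-freedom chi-square statistic (Yates-corrected by
  default, uncorrected available),
* ROR, the reporting odds ratio ad/(bc) with Wald 95% CI and a
  Haldane–Anscombe 0.5 correction when a cell is zero,
* the Bayesian information component IC = log2((a+0.5)/(E+0.5)) with
  E = (a+b)(a+c)/n, and its 95% credibility lower bound

      IC025 = IC - 3.3 (a+0.5)^(-1/2) - 2 (a+0.5)^(-3/2),

  the standard closed-form approximation to the 2.5th percentile of the
  shrinkage gamma posterior,

and three signal criteria commonly applied together:

* Evans:  PRR >= 2  and  chi2 >= 4  and  a >= 3   (inclusive bounds),
* ROR rule:  ROR > 1,
* IC rule:  IC025 > 0.

The model/results pair follows the statsmodels convention: build a
:class:`Disproportionality` model from a case list or a table, call
``.fit()``, and read estimates off the returned
:class:`DisproportionalityResults` (or print ``.summary()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cases import CaseReport, DrugQuery, EventQuery, case_has_drug, case_has_event, normalize_drugname

#: 95% two-sided normal multiplier used in the ROR Wald interval
Z95 = 1.96


# ---------------------------------------------------------------------------
# contingency table


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 case counts for one drug–event pair."""

    a: int  # drug and event
    b: int  # drug, no event
    c: int  # event, no drug
    d: int  # neither

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("table total must be at least 1")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count in cell a under independence: (a+b)(a+c)/n."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def swapped(self) -> "ContingencyTable":
        """Rows and columns simultaneously swapped (d,c,b,a)."""
        return ContingencyTable(self.d, self.c, self.b, self.a)


def build_contingency(
    cases: Sequence[CaseReport], drug: DrugQuery, event: EventQuery
) -> ContingencyTable:
    """Count the 2x2 cells over a deduplicated case universe."""
    if not cases:
        raise ValueError("cannot build a contingency table from zero cases")
    a = b = c = d = 0
    for case in cases:
        has_d = case_has_drug(case, drug)
        has_e = case_has_event(case, event)
        if has_d and has_e:
            a += 1
        elif has_d:
            b += 1
        elif has_e:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# statistics


def prr(t: ContingencyTable) -> float:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)].

    Undefined denominators are flagged with non-finite values rather than
    raised, so screening over many pairs continues: ``nan`` when the drug
    margin a+b is zero, ``inf`` when c = 0 with a > 0.
    """
    if t.a + t.b == 0:
        return math.nan
    p1 = t.a / (t.a + t.b)
    if t.c == 0:
        return math.inf if t.a > 0 else math.nan
    p2 = t.c / (t.c + t.d)
    return p1 / p2


def chi_square(t: ContingencyTable, yates: bool = True) -> float:
    """One-df chi-square for the 2x2 table.

    Without Yates: n(ad-bc)^2 / [(a+b)(c+d)(a+c)(b+d)].  With the Yates
    continuity correction the numerator uses (|ad-bc| - n/2)^2, floored at
    zero when |ad-bc| < n/2.  A zero marginal makes the statistic
    undefined (``nan``).
    """
    a, b, c, d, n = t.a, t.b, t.c, t.d, t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    return n * diff * diff / denom


@dataclass(frozen=True)
class RorEstimate:
    ror: float
    ci95: tuple[float, float]
    corrected: bool  # Haldane–Anscombe 0.5 applied to every cell


def ror(t: ContingencyTable) -> RorEstimate:
    """Reporting odds ratio ad/(bc) with Wald 95% CI.

    When any cell is zero the Haldane–Anscombe correction adds 0.5 to
    every cell and the estimate is flagged ``corrected``.
    """
    corrected = 0 in (t.a, t.b, t.c, t.d)
    a, b, c, d = (x + 0.5 for x in (t.a, t.b, t.c, t.d)) if corrected \
        else (float(t.a), float(t.b), float(t.c), float(t.d))
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(est) - Z95 * se)
    hi = math.exp(math.log(est) + Z95 * se)
    return RorEstimate(ror=est, ci95=(lo, hi), corrected=corrected)


def information_component(t: ContingencyTable) -> tuple[float, float]:
    """Shrinkage information component (IC, IC025).

    IC = log2((a+0.5)/(E+0.5)) with E = (a+b)(a+c)/n.  The credibility
    lower bound uses the closed-form approximation
    IC025 = IC - 3.3(a+0.5)^(-1/2) - 2(a+0.5)^(-3/2), which tracks the
    2.5th percentile of the gamma posterior (shape a+0.5, mean
    (a+0.5)E/(E+0.5)) to within a few hundredths.  The 0.5 shrinkage
    makes both quantities defined for every table.
    """
    e = t.expected
    ic = math.log2((t.a + 0.5) / (e + 0.5))
    ic025 = ic - 3.3 * (t.a + 0.5) ** -0.5 - 2.0 * (t.a + 0.5) ** -1.5
    return ic, ic025


def ic025_gamma_quantile(a: int, expected: float, q: float = 0.025) -> float:
    """Gamma-posterior quantile of the information component.

    The exact q-quantile of log2(G/E) with G ~ Gamma(shape a+0.5,
    scale E/(E+0.5)); the closed-form IC025 approximates this at
    q = 0.025.  Exposed so the approximation can be audited.
    """
    from scipy import stats

    g = stats.gamma.ppf(q, a + 0.5, scale=expected / (expected + 0.5))
    return math.log2(g / expected)


# ---------------------------------------------------------------------------
# signal criteria


@dataclass(frozen=True)
class SignalCriteria:
    """Verdicts of the three signal criteria, reported separately and jointly."""

    evans: bool       # PRR >= 2 and chi2 >= 4 and a >= 3
    ror_rule: bool    # ROR > 1
    ic_rule: bool     # IC025 > 0
    notes: tuple[str, ...] = ()

    @property
    def all_three(self) -> bool:
        return self.evans and self.ror_rule and self.ic_rule


def evaluate_signal(
    prr_value: float,
    chi2_value: float,
    n_events: int,
    ror_value: float,
    ic025_value: float,
) -> SignalCriteria:
    """Apply the three signal criteria (Evans thresholds are inclusive).

    A non-finite statistic fails its criterion with an explanatory note
    instead of raising; an infinite PRR (event never reported without the
    drug) still satisfies PRR >= 2.
    """
    notes: list[str] = []

    if math.isnan(prr_value) or math.isnan(chi2_value):
        evans = False
        notes.append("Evans criterion false: PRR or chi-square undefined on this table")
    else:
        evans = prr_value >= 2.0 and chi2_value >= 4.0 and n_events >= 3

    if math.isnan(ror_value):
        ror_rule = False
        notes.append("ROR rule false: ROR undefined on this table")
    else:
        ror_rule = ror_value > 1.0

    if math.isnan(ic025_value):
        ic_rule = False
        notes.append("IC rule false: IC025 undefined on this table")
    else:
        ic_rule = ic025_value > 0.0

    return SignalCriteria(evans=evans, ror_rule=ror_rule, ic_rule=ic_rule,
                          notes=tuple(notes))


# ---------------------------------------------------------------------------
# model / results


class Disproportionality:
    """Disproportionality model for one drug–event pair.

    Parameters
    ----------
    table : ContingencyTable
        2x2 case counts.  Use :meth:`from_cases` to build the table from
        a deduplicated case list and drug/event queries.

    Examples
    --------
    >>> m = Disproportionality(ContingencyTable(13, 187, 146, 24562))
    >>> res = m.fit()
    >>> round(res.prr, 1)
    11.0
    >>> res.criteria.all_three
    True
    """

    def __init__(self, table: ContingencyTable):
        self.table = table

    @classmethod
    def from_cases(
        cls,
        cases: Sequence[CaseReport],
        drug: DrugQuery,
        event: EventQuery,
    ) -> "Disproportionality":
        return cls(build_contingency(cases, drug, event))

    def fit(self, yates: bool = True) -> "DisproportionalityResults":
        t = self.table
        prr_v = prr(t)
        chi2_v = chi_square(t, yates=yates)
        ror_e = ror(t)
        ic_v, ic025_v = information_component(t)
        crit = evaluate_signal(prr_v, chi2_v, t.a, ror_e.ror, ic025_v)
        return DisproportionalityResults(
            table=t, prr=prr_v, chi2=chi2_v, yates=yates,
            ror=ror_e.ror, ror_ci95=ror_e.ci95, ror_corrected=ror_e.corrected,
            expected=t.expected, ic=ic_v, ic025=ic025_v, criteria=crit,
        )


@dataclass(frozen=True)
class DisproportionalityResults:
    """Fitted disproportionality statistics for one drug–event pair."""

    table: ContingencyTable
    prr: float
    chi2: float
    yates: bool
    ror: float
    ror_ci95: tuple[float, float]
    ror_corrected: bool
    expected: float
    ic: float
    ic025: float
    criteria: SignalCriteria

    @property
    def n_events(self) -> int:
        """Observed drug-and-event case count (cell a)."""
        return self.table.a

    def to_dict(self) -> dict:
        t = self.table
        return {
            "a": t.a, "b": t.b, "c": t.c, "d": t.d, "n": t.n,
            "expected": self.expected,
            "prr": self.prr,
            "chi2": self.chi2, "yates": self.yates,
            "ror": self.ror,
            "ror_ci95_lower": self.ror_ci95[0], "ror_ci95_upper": self.ror_ci95[1],
            "ror_corrected": self.ror_corrected,
            "ic": self.ic, "ic025": self.ic025,
            "evans": self.criteria.evans,
            "ror_rule": self.criteria.ror_rule,
            "ic_rule": self.criteria.ic_rule,
            "signal_all_three": self.criteria.all_three,
            "notes": list(self.criteria.notes),
        }

    def summary(self) -> str:
        t = self.table
        chi_label = "chi2 (Yates)" if self.yates else "chi2"
        lines = [
            "Disproportionality analysis (2x2 case counts)",
            "=" * 46,
            f"  a (drug & event)   {t.a:>10d}",
            f"  b (drug only)      {t.b:>10d}",
            f"  c (event only)     {t.c:>10d}",
            f"  d (neither)        {t.d:>10d}",
            f"  n                  {t.n:>10d}",
            f"  expected a         {self.expected:>10.3f}",
            "-" * 46,
            f"  PRR                {self.prr:>10.3f}",
            f"  {chi_label:<18s} {self.chi2:>10.3f}",
            f"  ROR                {self.ror:>10.3f}"
            + ("  (Haldane-Anscombe corrected)" if self.ror_corrected else ""),
            f"  ROR 95% CI         [{self.ror_ci95[0]:.3f}, {self.ror_ci95[1]:.3f}]",
            f"  IC                 {self.ic:>10.3f}",
            f"  IC025              {self.ic025:>10.3f}",
            "-" * 46,
            f"  Evans (PRR>=2, chi2>=4, a>=3)  {self.criteria.evans}",
            f"  ROR > 1                        {self.criteria.ror_rule}",
            f"  IC025 > 0                      {self.criteria.ic_rule}",
            f"  all three criteria             {self.criteria.all_three}",
        ]
        for note in self.criteria.notes:
            lines.append(f"  note: {note}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# screening


def screen_all_pairs(
    cases: Sequence[CaseReport],
    min_a: int = 3,
    yates: bool = True,
    roles: Iterable[str] = ("PS", "SS", "C", "I"),
) -> list[tuple[str, str, DisproportionalityResults]]:
    """Fit every drug–event pair with at least ``min_a`` co-reporting cases.

    Drug names are normalised; membership ignores role by default
    (``roles`` narrows it).  Results are sorted by descending IC025 —
    the most shrinkage-robust ranking for small counts — with a
    deterministic (drug, event) lexicographic tie-break.
    """
    role_set = frozenset(roles)
    n = len(cases)
    if n == 0:
        return []

    drug_cases: dict[str, set[int]] = {}
    event_cases: dict[str, set[int]] = {}
    for i, case in enumerate(cases):
        names = {normalize_drugname(d.drugname) for d in case.drugs
                 if d.role_code in role_set}
        names.discard("")
        for name in names:
            drug_cases.setdefault(name, set()).add(i)
        for pt in {r.reaction_pt.strip().lower() for r in case.reactions}:
            event_cases.setdefault(pt, set()).add(i)

    pt_display = {}
    for case in cases:
        for r in case.reactions:
            pt_display.setdefault(r.reaction_pt.strip().lower(), r.reaction_pt.strip())

    out: list[tuple[str, str, DisproportionalityResults]] = []
    for g, gset in drug_cases.items():
        for e, eset in event_cases.items():
            a = len(gset & eset)
            if a < min_a:
                continue
            b = len(gset) - a
            c = len(eset) - a
            d = n - a - b - c
            res = Disproportionality(ContingencyTable(a, b, c, d)).fit(yates=yates)
            out.append((g, pt_display[e], res))

    out.sort(key=lambda x: (-x[2].ic025, x[0], x[1]))
    return out


def screen_to_frame(hits: list[tuple[str, str, DisproportionalityResults]]):
    """Screening results as a pandas DataFrame (one row per pair)."""
    import pandas as pd

    rows = []
    for g, e, res in hits:
        row = {"drug": g, "event": e}
        row.update(res.to_dict())
        row["notes"] = "; ".join(res.criteria.notes)
        rows.append(row)
    return pd.DataFrame(rows)
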