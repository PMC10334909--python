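"""Synthetic FAERS-format report generator with known ground truth.

Real FAERS extracts are multi-gigabyte external downloads, so every
pipeline stage is exercised against generated quarterly datasets whose
drug–event dependence, duplicate structure and demographics are planted
and recorded.  The association model is a per-pair reporting-rate tilt:
each event's probability for a case is its marginal ``p_e`` multiplied by
``rho[g, e]`` for every generated drug ``g`` present on the case (clipped
at 1, with a warning naming the pair when a requested tilt saturates).
``rho = 1`` everywhere means independence; a planted ``rho`` is what PRR
and ROR estimate.

All randomness flows from a single seeded generator, so a given
configuration is byte-reproducible: identical seed, identical files.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .io import (
    DemoRecord,
    DrugRecord,
    OutcomeRecord,
    QuarterlyDataset,
    ReactionRecord,
    write_dataset,
)

OUTCOME_POOL = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: filler labels for cases where sampling produced no drug / no reaction
#: (every real FAERS report lists at least one of each)
FILLER_DRUG = "UNSPECIFIED MEDICATION"
FILLER_EVENT = "Drug ineffective"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults describe a plausible two-year
    spontaneous-report universe (marginal reporting rates of a few percent,
    a modest duplicate-version rate, mostly-suspect coding).
    """

    n_cases: int = 50_000
    drugs: tuple[tuple[str, float], ...] = (
        ("AVAPRITINIB", 0.02), ("IMATINIB", 0.03), ("OMEPRAZOLE", 0.05),
        ("LISINOPRIL", 0.05), ("METFORMIN", 0.04),
    )
    events: tuple[tuple[str, float], ...] = (
        ("Photosensitivity reaction", 0.005), ("Nausea", 0.05),
        ("Rash", 0.03), ("Fatigue", 0.04), ("Diarrhoea", 0.03),
    )
    #: (drug name, event PT) -> reporting-rate ratio rho (1 = independence)
    associations: Mapping[tuple[str, str], float] = field(default_factory=dict)
    duplicate_version_rate: float = 0.05
    suspect_role_probability: float = 0.9
    sex_probabilities: tuple[tuple[str, float], ...] = (
        ("M", 0.48), ("F", 0.48), ("UNK", 0.04),
    )
    #: mixture over age bins in years; ``None`` bin means age missing
    age_distribution: tuple[tuple[tuple[int, int] | None, float], ...] = (
        ((18, 30), 0.10), ((31, 50), 0.22), ((51, 60), 0.18),
        ((61, 70), 0.25), ((71, 90), 0.17), (None, 0.08),
    )
    serious_probability: float = 0.30
    indication_map: Mapping[str, str] = field(default_factory=dict)
    window: tuple[dt.date, dt.date] = (dt.date(2020, 1, 1), dt.date(2021, 12, 31))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for _, p in list(self.drugs) + list(self.events):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal probability {p} outside [0, 1]")
        for pair, rho in self.associations.items():
            if rho < 0:
                raise ValueError(f"association rho for {pair} must be >= 0")
        for p in (self.duplicate_version_rate, self.suspect_role_probability,
                  self.serious_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually planted, for use as a test oracle."""

    #: (drug, event) -> realized (a, b, c, d) over distinct cases
    pair_counts: dict[tuple[str, str], tuple[int, int, int, int]]
    n_cases: int
    duplicate_primaryids: list[str]
    config: SyntheticConfig


def _quarter_label(d: dt.date) -> str:
    return f"{d.year}Q{(d.month - 1) // 3 + 1}"


def generate(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[QuarterlyDataset, GroundTruth]:
    """Generate one synthetic multi-quarter dataset.

    Returns the in-memory dataset (report versions included, ready for
    deduplication) and the realized :class:`GroundTruth`.  With
    ``out_dir`` the five FAERS-dialect tables are also written there.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drug_names = [name for name, _ in config.drugs]
    drug_p = np.array([p for _, p in config.drugs])
    event_pts = [pt for pt, _ in config.events]
    event_p = np.array([p for _, p in config.events])
    g_idx = {name: i for i, name in enumerate(drug_names)}
    e_idx = {pt: i for i, pt in enumerate(event_pts)}

    presence = rng.random((n, len(drug_names))) < drug_p

    tilt = np.ones((n, len(event_pts)))
    for (gname, ept), rho in sorted(config.associations.items()):
        gi, ei = g_idx[gname], e_idx[ept]
        if event_p[ei] * rho > 1.0:
            warnings.warn(
                f"association ({gname}, {ept}): tilted probability "
                f"{event_p[ei] * rho:.3f} saturates at 1", stacklevel=2)
        tilt[presence[:, gi], ei] *= rho
    p_eff = np.minimum(event_p * tilt, 1.0)
    event_mat = rng.random((n, len(event_pts))) < p_eff

    # realized ground-truth 2x2 counts over distinct cases
    a_mat = presence.T.astype(np.int64) @ event_mat.astype(np.int64)
    drug_margin = presence.sum(axis=0)
    event_margin = event_mat.sum(axis=0)
    pair_counts: dict[tuple[str, str], tuple[int, int, int, int]] = {}
    for gi, gname in enumerate(drug_names):
        for ei, ept in enumerate(event_pts):
            a = int(a_mat[gi, ei])
            b = int(drug_margin[gi]) - a
            c = int(event_margin[ei]) - a
            d = n - a - b - c
            pair_counts[(gname, ept)] = (a, b, c, d)

    # vectorized per-case demographics
    start, end = config.window
    n_days = (end - start).days + 1
    day_offsets = rng.integers(0, n_days, size=n)
    sex_labels = [s for s, _ in config.sex_probabilities]
    sex_w = np.array([w for _, w in config.sex_probabilities], dtype=float)
    sexes = rng.choice(sex_labels, size=n, p=sex_w / sex_w.sum())
    bin_w = np.array([w for _, w in config.age_distribution], dtype=float)
    age_bin_choice = rng.choice(len(config.age_distribution), size=n, p=bin_w / bin_w.sum())
    age_u = rng.random(n)
    serious_mask = rng.random(n) < config.serious_probability
    outcome_choice = rng.integers(0, len(OUTCOME_POOL), size=n)
    suspect_u = rng.random((n, len(drug_names)))
    dup_mask = rng.random(n) < config.duplicate_version_rate
    dup_day_shift = rng.integers(1, 60, size=n)

    demo: list[DemoRecord] = []
    drug: list[DrugRecord] = []
    reac: list[ReactionRecord] = []
    outc: list[OutcomeRecord] = []
    duplicate_primaryids: list[str] = []

    def emit_children(pid: str, i: int) -> None:
        seq = 0
        for gi, gname in enumerate(drug_names):
            if not presence[i, gi]:
                continue
            seq += 1
            role = "PS" if suspect_u[i, gi] < config.suspect_role_probability else "C"
            drug.append(DrugRecord(
                primaryid=pid, drug_seq=seq, role_code=role, drugname=gname,
                indication_pt=config.indication_map.get(gname),
            ))
        if seq == 0:
            drug.append(DrugRecord(pid, 1, "PS", FILLER_DRUG))
        any_event = False
        for ei, ept in enumerate(event_pts):
            if event_mat[i, ei]:
                any_event = True
                reac.append(ReactionRecord(pid, ept))
        if not any_event:
            reac.append(ReactionRecord(pid, FILLER_EVENT))
        if serious_mask[i]:
            outc.append(OutcomeRecord(pid, OUTCOME_POOL[outcome_choice[i]]))

    for i in range(n):
        caseid = str(10_000_001 + i)
        date = start + dt.timedelta(days=int(day_offsets[i]))
        bin_edges = config.age_distribution[age_bin_choice[i]][0]
        if bin_edges is None:
            age_value, age_unit = None, None
        else:
            lo, hi = bin_edges
            age_value = float(lo + int(age_u[i] * (hi - lo + 1)))
            age_unit = "YR"
        pid = caseid + "1"
        demo.append(DemoRecord(
            primaryid=pid, caseid=caseid, caseversion=1,
            fda_receipt_date=date, age_value=age_value, age_unit=age_unit,
            sex=str(sexes[i]), country="US", quarter=_quarter_label(date),
        ))
        emit_children(pid, i)

        if dup_mask[i]:
            # a follow-up version: same case content, mutated mutable fields
            dup_date = min(date + dt.timedelta(days=int(dup_day_shift[i])), end)
            pid2 = caseid + "2"
            demo.append(DemoRecord(
                primaryid=pid2, caseid=caseid, caseversion=2,
                fda_receipt_date=dup_date, age_value=age_value, age_unit=age_unit,
                sex=str(sexes[i]), country="US", quarter=_quarter_label(dup_date),
            ))
            emit_children(pid2, i)
            duplicate_primaryids.append(pid2)

    labels = sorted({r.quarter for r in demo})
    dataset = QuarterlyDataset(
        demo=demo, drug=drug, reac=reac, outc=outc,
        quarter_label="+".join(labels),
    )
    truth = GroundTruth(
        pair_counts=pair_counts, n_cases=n,
        duplicate_primaryids=duplicate_primaryids, config=config,
    )
    if out_dir is not None:
        write_dataset(dataset, out_dir)
    return dataset, truth


# ---------------------------------------------------------------------------
# the published-case-series fixture


#: ages of the 12 index cases with a known age: mean exactly 60 years,
#: range 31–80, binned 3 / 2 / 5 / 2 into 31-50 / 51-60 / 61-70 / 71-80
_INDEX_AGES: tuple[float | None, ...] = (
    31, 43, 50, 55, 60, 62, 64, 66, 68, 70, 71, 80, None,
)
#: 11 male, 2 female
_INDEX_SEX = ("M", "M", "M", "F", "M", "M", "M", "F", "M", "M", "M", "M", "M")
#: 9 gastrointestinal stromal tumour, 4 systemic mastocytosis
_INDEX_INDICATION = tuple(
    ["Gastrointestinal stromal tumour"] * 9 + ["Systemic mastocytosis"] * 4
)
#: 5 of 13 serious
_INDEX_SERIOUS_OUTCOMES = ("HO", "LT", "DE", "DS", "OT", None, None, None,
                           None, None, None, None, None)
_COREPORTED = ("Oedema peripheral", "Lacrimation increased", "Fatigue",
               "Rash", "Abdominal discomfort", "Diarrhoea")
_CONCOMITANTS = ("INSULIN GLARGINE", "INSULIN ASPART", "ONDANSETRON",
                 "DIPHENHYDRAMINE", "LORATADINE", "LOPERAMIDE",
                 "BISACODYL", "TRAMADOL")

_BG_DRUGS = ("IMATINIB", "OMEPRAZOLE", "LISINOPRIL", "METFORMIN",
             "ATORVASTATIN", "AMLODIPINE", "SERTRALINE", "GABAPENTIN")
_BG_EVENTS = ("Nausea", "Headache", "Fatigue", "Rash", "Diarrhoea",
              "Dizziness", "Vomiting", "Pruritus", "Arthralgia", "Insomnia")

STUDY_DRUG = "AVAPRITINIB"
STUDY_EVENT = "Photosensitivity reaction"


def solve_background_cells(
    a: int = 13,
    b: int = 187,
    prr_target: float = 11.0,
    tolerance: float = 0.05,
    n_max: int = 25_000,
) -> tuple[int, int]:
    """Grid-search (c, d) so the fixture's PRR hits ``prr_target``.

    For each candidate c the best integer c+d is ``round(target * c *
    (a+b) / a)``; candidates within ``tolerance`` of the target and with
    total n <= ``n_max`` are kept and the largest such universe is
    returned (a larger background sits closer to the rare-event regime
    of real spontaneous-report data).
    """
    best: tuple[int, int] | None = None
    for c in range(1, n_max):
        cd = round(prr_target * c * (a + b) / a)
        d = cd - c
        if d < 0:
            continue
        n = a + b + c + d
        if n > n_max:
            break
        prr_val = (a / (a + b)) / (c / cd)
        if abs(prr_val - prr_target) <= tolerance:
            best = (c, d)
    if best is None:
        raise ValueError("no background cells satisfy the PRR target")
    return best


def make_paper_like_fixture(
    out_dir: str | Path | None = None,
    seed: int = 0,
    prr_matched: bool = True,
    b_background: int = 187,
    prr_target: float = 11.0,
    n_max: int = 25_000,
) -> tuple[QuarterlyDataset, GroundTruth]:
    """Synthetic report universe built around a 13-case photosensitivity series.

    The 13 index cases (study drug suspect, study event reported) exactly
    reproduce the published case-series marginals: 11 male / 2 female;
    ages binned 3/2/5/2/1-unknown with mean 60 and range 31–80; 9
    gastrointestinal stromal tumour / 4 systemic mastocytosis
    indications; 5 serious; all from the US; one case carrying eight
    concomitant medications, the rest with the study drug alone.  Two
    index cases get a second report version, so deduplication is
    exercised end to end.

    The background cells (b, c, d) are *not* published; they are chosen
    here and recorded in :class:`GroundTruth`.  In the default
    ``prr_matched`` mode c and d are grid-searched so the fixture's PRR
    equals ``prr_target`` to within 0.05; otherwise a small fixed
    background (c=13, d=2187) is used.
    """
    rng = np.random.default_rng(seed)
    a, b = 13, b_background
    if prr_matched:
        c, d = solve_background_cells(a, b, prr_target, n_max=n_max)
    else:
        c, d = 13, 2187

    start, end = dt.date(2020, 1, 1), dt.date(2021, 12, 31)
    demo: list[DemoRecord] = []
    drug: list[DrugRecord] = []
    reac: list[ReactionRecord] = []
    outc: list[OutcomeRecord] = []
    duplicate_primaryids: list[str] = []
    next_id = 20_000_001

    def new_caseid() -> str:
        nonlocal next_id
        cid = str(next_id)
        next_id += 1
        return cid

    def rand_date(lo: dt.date, hi: dt.date) -> dt.date:
        return lo + dt.timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))

    # --- 13 index cases (earliest May 2020, latest November 2021) ---
    index_dates = [rand_date(dt.date(2020, 5, 1), dt.date(2021, 11, 30))
                   for _ in range(13)]
    index_dates[0] = dt.date(2020, 5, 15)
    index_dates[-1] = dt.date(2021, 11, 15)
    for i in range(13):
        cid = new_caseid()
        pid = cid + "1"
        age = _INDEX_AGES[i]
        demo.append(DemoRecord(
            primaryid=pid, caseid=cid, caseversion=1,
            fda_receipt_date=index_dates[i],
            age_value=float(age) if age is not None else None,
            age_unit="YR" if age is not None else None,
            sex=_INDEX_SEX[i], country="US",
            quarter=_quarter_label(index_dates[i]),
        ))
        drug.append(DrugRecord(pid, 1, "PS", STUDY_DRUG,
                               indication_pt=_INDEX_INDICATION[i]))
        if i == 12:
            # the one polypharmacy case: study drug plus 8 concomitants
            for j, name in enumerate(_CONCOMITANTS, start=2):
                drug.append(DrugRecord(pid, j, "C", name))
        reac.append(ReactionRecord(pid, STUDY_EVENT))
        reac.append(ReactionRecord(pid, _COREPORTED[i % len(_COREPORTED)]))
        if _INDEX_SERIOUS_OUTCOMES[i] is not None:
            outc.append(OutcomeRecord(pid, _INDEX_SERIOUS_OUTCOMES[i]))
        if i in (1, 6):
            # inject a superseded earlier version to exercise deduplication
            pid2 = cid + "2"
            later = min(index_dates[i] + dt.timedelta(days=30), end)
            demo.append(DemoRecord(
                primaryid=pid2, caseid=cid, caseversion=2,
                fda_receipt_date=later,
                age_value=float(age) if age is not None else None,
                age_unit="YR" if age is not None else None,
                sex=_INDEX_SEX[i], country="US",
                quarter=_quarter_label(later),
            ))
            drug.append(DrugRecord(pid2, 1, "PS", STUDY_DRUG,
                                   indication_pt=_INDEX_INDICATION[i]))
            reac.append(ReactionRecord(pid2, STUDY_EVENT))
            reac.append(ReactionRecord(pid2, _COREPORTED[i % len(_COREPORTED)]))
            if _INDEX_SERIOUS_OUTCOMES[i] is not None:
                outc.append(OutcomeRecord(pid2, _INDEX_SERIOUS_OUTCOMES[i]))
            duplicate_primaryids.append(pid2)

    def background_case(with_drug: bool, with_event: bool) -> None:
        cid = new_caseid()
        pid = cid + "1"
        date = rand_date(start, end)
        age = float(rng.integers(18, 91)) if rng.random() > 0.1 else None
        demo.append(DemoRecord(
            primaryid=pid, caseid=cid, caseversion=1, fda_receipt_date=date,
            age_value=age, age_unit="YR" if age is not None else None,
            sex="M" if rng.random() < 0.5 else "F", country="US",
            quarter=_quarter_label(date),
        ))
        if with_drug:
            drug.append(DrugRecord(pid, 1, "PS", STUDY_DRUG))
        else:
            drug.append(DrugRecord(pid, 1, "PS",
                                   _BG_DRUGS[int(rng.integers(len(_BG_DRUGS)))]))
        if with_event:
            reac.append(ReactionRecord(pid, STUDY_EVENT))
        else:
            reac.append(ReactionRecord(
                pid, _BG_EVENTS[int(rng.integers(len(_BG_EVENTS)))]))
        if rng.random() < 0.3:
            outc.append(OutcomeRecord(
                pid, OUTCOME_POOL[int(rng.integers(len(OUTCOME_POOL)))]))

    for _ in range(b):
        background_case(with_drug=True, with_event=False)
    for _ in range(c):
        background_case(with_drug=False, with_event=True)
    for _ in range(d):
        background_case(with_drug=False, with_event=False)

    labels = sorted({r.quarter for r in demo})
    dataset = QuarterlyDataset(demo=demo, drug=drug, reac=reac, outc=outc,
                               quarter_label="+".join(labels))
    truth = GroundTruth(
        pair_counts={(STUDY_DRUG, STUDY_EVENT): (a, b, c, d)},
        n_cases=a + b + c + d,
        duplicate_primaryids=duplicate_primaryids,
        config=SyntheticConfig(n_cases=a + b + c + d, seed=seed),
    )
    if out_dir is not None:
        write_dataset(dataset, out_dir)
    return dataset, truth
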