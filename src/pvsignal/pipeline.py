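"""End-to-end run: load → window → deduplicate → 2x2 → statistics → Table 1.

`run_pipeline` is the programmatic entry point behind the command-line
interface.  It writes four artifacts into the output directory:

* ``contingency.csv``   — the 2x2 cell counts,
* ``signal.json``       — all disproportionality statistics, flags and
  criteria verdicts,
* ``table1.csv`` / ``table1.txt`` — the demographic summary,
* ``run_log.txt``       — counts at every filter stage (windowing, dedup,
  rejects), because reproducing the case count N is the fragile step of
  any spontaneous-report analysis.

Every number in the rendered outputs is read off a typed result object;
the renderer recomputes nothing.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cases import DedupResult, DrugQuery, EventQuery, deduplicate, matching_cases
from .demographics import DEFAULT_AGE_BINS, summarize
from .disproportionality import Disproportionality
from .io import QuarterFiles, load_window
from .simulate import make_paper_like_fixture

#: study defaults: the two-year window after the drug's approval, the
#: photosensitivity preferred term, and suspect-role matching
DEFAULT_WINDOW = (dt.date(2020, 1, 1), dt.date(2021, 12, 31))
DEFAULT_DRUG_NAMES = frozenset({"AVAPRITINIB", "AYVAKIT"})
DEFAULT_EVENT_TERMS = frozenset({"Photosensitivity reaction"})


class PipelineError(RuntimeError):
    """Raised when the configured run cannot produce statistics."""


@dataclass
class RunConfig:
    """One pipeline run, as configuration.

    ``input_dirs`` lists quarterly-extract directories; with
    ``use_fixture`` the built-in synthetic case-series universe is
    analysed instead (no external data needed).
    """

    input_dirs: list[Path] = field(default_factory=list)
    use_fixture: bool = False
    window: tuple[dt.date, dt.date] = DEFAULT_WINDOW
    date_field: str = "fda_receipt_date"
    drug_names: frozenset[str] = DEFAULT_DRUG_NAMES
    drug_match_mode: str = "exact"
    drug_roles: frozenset[str] = frozenset({"PS", "SS"})
    event_terms: frozenset[str] = DEFAULT_EVENT_TERMS
    yates: bool = True
    min_a: int = 3
    age_bin_edges: tuple[tuple[int, int], ...] = DEFAULT_AGE_BINS
    out_dir: Path = Path("pvsignal_out")
    seed: int = 0

    @property
    def drug_query(self) -> DrugQuery:
        return DrugQuery(names=frozenset(self.drug_names),
                         match_mode=self.drug_match_mode,
                         roles=frozenset(self.drug_roles))

    @property
    def event_query(self) -> EventQuery:
        return EventQuery(preferred_terms=frozenset(self.event_terms))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat YAML config; keyword arguments override file values."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        kwargs: dict = {}
        if "input_dirs" in raw:
            kwargs["input_dirs"] = [Path(p) for p in raw["input_dirs"]]
        for key in ("use_fixture", "date_field", "drug_match_mode",
                    "yates", "min_a", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "window_start" in raw or "window_end" in raw:
            start = dt.date.fromisoformat(str(raw.get("window_start", DEFAULT_WINDOW[0])))
            end = dt.date.fromisoformat(str(raw.get("window_end", DEFAULT_WINDOW[1])))
            kwargs["window"] = (start, end)
        for key, cast in (("drug_names", frozenset), ("drug_roles", frozenset),
                          ("event_terms", frozenset)):
            if key in raw:
                kwargs[key] = cast(raw[key])
        if "age_bin_edges" in raw:
            kwargs["age_bin_edges"] = tuple(tuple(b) for b in raw["age_bin_edges"])
        if "out_dir" in raw:
            kwargs["out_dir"] = Path(raw["out_dir"])
        return cls(**kwargs)


def _load_cases(cfg: RunConfig, log_lines: list[str]) -> DedupResult:
    if cfg.use_fixture:
        dataset, _ = make_paper_like_fixture(seed=cfg.seed)
        log_lines.append(f"fixture universe: {len(dataset.demo)} report(s)")
    else:
        if not cfg.input_dirs:
            raise PipelineError("no input directories and fixture mode not requested")
        quarters = [QuarterFiles.from_dir(p) for p in cfg.input_dirs]
        dataset = load_window(quarters, cfg.window, date_field=cfg.date_field)
        log_lines.append(
            f"loaded {len(dataset.demo)} report(s) from {len(quarters)} quarter(s) "
            f"within {cfg.window[0]}..{cfg.window[1]} (closed, on {cfg.date_field})")
    dedup = deduplicate(dataset)
    log_lines.append(
        f"deduplication: {dedup.n_reports_in} report(s) -> {len(dedup.cases)} case(s), "
        f"{dedup.n_discarded} superseded version(s) discarded")
    return dedup


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured analysis; returns the result bundle.

    Raises :class:`PipelineError` when zero cases match both queries
    (no statistics are emitted in that situation).
    """
    log_lines: list[str] = [f"run started; seed={cfg.seed}"]
    dedup = _load_cases(cfg, log_lines)
    cases = dedup.cases

    drug_q = cfg.drug_query
    event_q = cfg.event_query
    series = matching_cases(cases, drug_q, event_q)
    log_lines.append(
        f"{len(series)} case(s) match drug {sorted(drug_q.names)} "
        f"(roles {sorted(drug_q.roles)}) and event {sorted(event_q.preferred_terms)}")
    if not series:
        raise PipelineError("zero cases match both the drug and the event query")

    model = Disproportionality.from_cases(cases, drug_q, event_q)
    results = model.fit(yates=cfg.yates)
    table1 = summarize(cases, drug_q, event_q, age_bin_edges=cfg.age_bin_edges)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = results.table
    (out / "contingency.csv").write_text(
        "a,b,c,d,n\n" + f"{t.a},{t.b},{t.c},{t.d},{t.n}\n")
    (out / "signal.json").write_text(json.dumps(results.to_dict(), indent=2) + "\n")
    table1.to_frame().to_csv(out / "table1.csv", index=False)
    (out / "table1.txt").write_text(table1.format_text() + "\n")
    log_lines.append("outputs written: contingency.csv, signal.json, table1.csv, "
                     "table1.txt, run_log.txt")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return {"results": results, "table1": table1, "dedup": dedup,
            "log": log_lines, "out_dir": out}
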