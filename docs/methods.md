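# Methods

## Scope and counting unit

`pvsignal` analyses spontaneous adverse-event reports in the FAERS
Quarterly Data Extract ASCII dialect. The counting unit throughout is the
**deduplicated case**, not the raw report: FAERS distributes successive
versions of the same safety case (same `caseid`, increasing
`caseversion`), and counting versions would inflate every cell of the
2×2 table. The retention rule keeps, per case, the report with the
highest `caseversion`, breaking ties by latest FDA receipt date and then
by lexicographically greatest `primaryid`. The rule is deterministic,
total and idempotent; the discarded-version count is reported because the
resulting case count N is the most fragile quantity when replicating any
published FAERS analysis. Public FAERS offers no authoritative dedup
beyond versioning, so no probabilistic cross-case linkage is attempted.

Windowing uses the FDA receipt date (`fda_dt`) on a closed interval,
the standard convention for defining "reports from period X"; the event
date is a plausible alternative and is exposed as `date_field` on
`load_window`. Reports with an unparseable windowing date are excluded
by the filter rather than guessed.

## Parsing the quarterly dialect

The dialect is dollar-delimited with no quoting or escape mechanism, so
parsing is exact line splitting with per-line accounting: a line with too
few fields goes to a rejects report (never silently dropped), a line with
too many has the overflow folded into the trailing column, which in every
table we read is free text — this tolerates stray delimiters inside
verbatim names. On write, delimiters inside fields are replaced by a
space, mirroring how the distributed files are sanitised; `parse(write(x))
== x` is property-tested. Undecodable bytes are replaced on read. Child
rows with no DEMO parent are dropped with a logged count (they cannot form
a case); INDI rows are joined onto drug records on `(primaryid,
drug_seq)`.

## Drug and event matching

Drug names are normalised (uppercase, whitespace collapse, trailing
numeric/dosage-form tokens stripped against a stop list) and matched
against a query's synonym set (e.g. generic + trade name) either exactly
or by substring. "Suspect drug" means role code PS or SS — FAERS splits
suspects into primary and secondary, and both are suspects. Reaction
matching is exact case-insensitive equality of MedDRA preferred terms;
PT strings are treated as opaque labels (no MedDRA hierarchy or SMQ
expansion). A case is serious iff it carries any of the seven outcome
codes (DE, LT, HO, DS, CA, RI, OT).

## Disproportionality statistics

All statistics are closed-form functions of the 2×2 case counts; the
implementation is authored here and cross-checked in the test suite
against scipy's χ² and statsmodels' odds-ratio interval on shared tables.

* χ² defaults to the Yates-corrected one-df statistic, because the
  classical PRR screening criterion was defined with the corrected
  statistic; the uncorrected variant is a flag away since published
  analyses often do not state which they used. The corrected numerator is
  floored at zero when `|ad−bc| < n/2`.
* Zero-cell policy: PRR and χ² return flagged non-finite values (so a
  screen over thousands of pairs keeps going); ROR applies the
  Haldane–Anscombe +0.5 to every cell and flags the estimate as
  corrected; the IC needs no correction because its +0.5 shrinkage makes
  it defined everywhere.
* The information component follows the shrinkage formulation
  `IC = log2((a+0.5)/(E+0.5))` with the closed-form credibility bound
  `IC025 = IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2)`. The bound is an
  approximation to the 2.5th percentile of the gamma posterior with shape
  `a+0.5` and mean `(a+0.5)·E/(E+0.5)`; `ic025_gamma_quantile` exposes
  the exact quantile, and the suite verifies agreement within 0.05 over
  `a ∈ 1..50` across expected counts from 0.5 to 100 (tolerance asserted:
  0.15), plus a 10⁶-draw Monte-Carlo spot check.
* The three criteria (Evans with inclusive thresholds PRR ≥ 2, χ² ≥ 4,
  a ≥ 3; ROR > 1 strict; IC025 > 0 strict) are reported separately and
  as a conjunction: publications typically claim a signal when each holds
  independently. An undefined statistic fails its criterion with an
  explanatory note rather than raising.
* Pair screening ranks by IC025 descending — the most shrinkage-robust
  key when a is small — with a lexicographic (drug, event) tie-break for
  determinism.

## Synthetic data generator

The generator emulates the five quarterly tables with planted,
recorded structure so that every pipeline claim is checked against ground
truth rather than against the pipeline itself. Cases draw drugs
independently from configured marginals; each event's probability is its
marginal multiplied by the reporting-rate ratio ρ of every present
associated drug, clipped at 1 (a saturating tilt warns naming the pair).
ρ is exactly the quantity PRR and ROR estimate, which gives the
parameter-recovery tests a direct target. Duplicate report versions are
re-emissions with incremented `caseversion` and mutated mutable fields
only (receipt date), so dedup correctness is observable; every case
receives at least one drug and one reaction row (filler labels), as real
reports always have both. All randomness flows from one seeded
`numpy` generator; identical configuration and seed give byte-identical
files.

Default study conditions: 50,000 cases over a two-year window, drug
marginals of 2–5%, event marginals of 0.5–5%, a 5% duplicate-version
rate, 90% suspect-role coding, 30% serious, and an age mixture spanning
Table-1-like bins with 8% missing — values a screener would call typical
for a small-molecule oncology drug in a spontaneous-report database. The
parameter-recovery condition uses drug marginal 0.05 and event marginal
0.01 so the expected co-report count (a ≈ 50–250 across ρ ∈ {2, 5, 10})
puts the ±20% recovery band several standard errors wide; the
false-signal condition uses a 20×20 grid of independent pairs at the same
case count.

What the generator does **not** emulate: misspelled or verbatim free-text
drug names, MedDRA coding noise, reporting-country structure,
time-varying reporting rates, and correlated polypharmacy. Passing tests
therefore demonstrate correctness of the statistics and the plumbing on
clean FAERS-format data, not robustness to real-world name noise — on
real extracts the normalisation stop list and synonym sets do that work
and their coverage is the user's responsibility.

## The case-series fixture

`make_paper_like_fixture` builds a report universe around a 13-case
drug–event series whose demographics reproduce a published
photosensitivity case-series table exactly: 11 male / 2 female; known
ages {31, 43, 50, 55, 60, 62, 64, 66, 68, 70, 71, 80} (mean exactly 60,
range 31–80, binned 3/2/5/2) plus one unknown; indications 9
gastrointestinal stromal tumour / 4 systemic mastocytosis; 5 serious;
all US; one polypharmacy case with eight concomitant medications, the
other twelve with the study drug alone. Two index cases carry a second
report version so deduplication is exercised end to end.

The published analysis does not print its background cells (b, c, d), so
they are chosen and recorded in the fixture's ground truth. With b fixed
at 187 (a 200-report drug margin), c and d are grid-searched so the
fixture PRR equals 11.0 within 0.05; among matching candidates the
largest universe under 25,000 cases is taken (c = 146, d = 24,562),
because a larger background approaches the rare-event regime of a real
report database. Only the case count and PRR are matched by
construction; χ² (≈109 uncorrected, ≈100 Yates), ROR (≈11.7) and IC025
(≈1.99) fall out of that universe unconstrained. They cannot all be
matched simultaneously at desk scale: equality of PRR and ROR to three
digits requires b ≫ a and a universe orders of magnitude larger, so the
fixture is a stand-in for the real extract, not a replica.

A related internal inconsistency in the source table is worth noting for
users comparing against the publication: its text gives one indication
count as 5 while its table prints 4 (31%), and only 9+4 sums to the
series size; the fixture follows the table.

## Numerical and design choices

* Integer percentages round half away from zero (11/13 → 85, 8/13 → 62),
  matching clinical-table convention rather than banker's rounding.
* Age conversion to years: YR×1, DEC×10, MON÷12, WK÷52.1775, DY÷365.25,
  HR÷8766; unknown units become missing with a log line. Age bins are
  closed on both ends as printed; ages outside the configured bins get
  automatically prepended/appended open bins so counts always sum to N.
* The 95% multiplier in the ROR interval is the conventional 1.96 (not
  the fuller-precision normal quantile); the difference is invisible at
  reporting precision and the tests compare against statsmodels at 1e-3.
* `screen_all_pairs` treats any role as exposure by default (a screen is
  exploratory); the single-pair pipeline defaults to suspect-only
  matching, which is the usual confirmatory convention.
* Problem sizes in the test and acceptance runs — the 25k-case fixture,
  50k-case simulations, 20×20 screening grid, exact gamma quantiles plus
  one 10⁶-draw Monte-Carlo check — were chosen so the statistical
  tolerances sit several standard errors wide while a full run stays in
  tens of seconds.

## Known limitations

Spontaneous-report disproportionality measures reporting association,
not incidence or causality; nothing here adjusts for confounding,
stratifies, or models time-to-onset (FAERS lacks onset time). The dedup
rule cannot merge true duplicates filed under different caseids. No
empirical-Bayes (GPS/MGPS) scores are implemented. The XML dialect and
the openFDA JSON API are out of scope; only the quarterly ASCII dialect
is read.
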