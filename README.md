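# pvsignal

Disproportionality signal detection on FAERS-format spontaneous adverse
event reports.

Pharmacovigilance teams screen spontaneous-report databases such as the
FDA Adverse Event Reporting System (FAERS) for drug–event pairs reported
more often than chance would predict. `pvsignal` implements that workflow
end to end for the FAERS Quarterly Data Extract dialect: parsing the
dollar-delimited DEMO/DRUG/REAC/OUTC/INDI tables, windowing by FDA
receipt date, collapsing versioned reports into deduplicated cases,
building drug–event 2×2 case tables, fitting the standard
disproportionality statistics, and summarising the case series
demographics. A synthetic report generator with recorded ground truth
makes every stage testable without downloading FAERS. The worked example
below is a tyrosine-kinase-inhibitor photosensitivity analysis.

## The statistics

For a drug–event pair, over N deduplicated cases:

|          | event | no event |
|----------|-------|----------|
| drug     | a     | b        |
| no drug  | c     | d        |

* **PRR** (proportional reporting ratio) = `[a/(a+b)] / [c/(c+d)]`
* **χ²** — the one-degree-of-freedom statistic
  `n(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)]`, Yates-corrected by default
* **ROR** (reporting odds ratio) = `ad/(bc)`, with Wald 95% CI
  `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` and a Haldane–Anscombe +0.5
  correction when a cell is zero
* **IC** (Bayesian information component) = `log2((a+0.5)/(E+0.5))`,
  `E = (a+b)(a+c)/n`, with the 95% credibility lower bound
  `IC025 = IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2)`

Three signal criteria are evaluated separately and jointly:
Evans (`PRR ≥ 2` ∧ `χ² ≥ 4` ∧ `a ≥ 3`), `ROR > 1`, and `IC025 > 0`.

## Worked example

The built-in fixture is a synthetic 24,908-case report universe whose
13-case drug–event series reproduces a published photosensitivity case
series cell for cell (the background cells are chosen so PRR = 11.0):

```bash
pvsignal signal --fixture --out out/
```

prints

```
Disproportionality analysis (2x2 case counts)
==============================================
  a (drug & event)           13
  b (drug only)             187
  c (event only)            146
  d (neither)             24562
  n                       24908
  expected a              1.277
----------------------------------------------
  PRR                    11.000
  chi2 (Yates)          100.100
  ROR                    11.695
  ROR 95% CI         [6.514, 20.998]
  IC                      2.926
  IC025                   1.987
----------------------------------------------
  Evans (PRR>=2, chi2>=4, a>=3)  True
  ROR > 1                        True
  IC025 > 0                      True
  all three criteria             True
```

Reading it: the pair was reported 13 times where independence predicts
1.28, an eleven-fold disproportion; the χ² and the positive IC025 say the
excess is far outside chance, and all three screening criteria flag a
signal. `pvsignal table1 --fixture` prints the matching case-series
demographics (11 male / 2 female, ages binned 23/15/38/15/8 percent,
indications 69% gastrointestinal stromal tumour / 31% systemic
mastocytosis, 38% serious).

The same analysis runs on real quarterly extracts by passing extract
directories instead of `--fixture`:

```bash
pvsignal signal path/to/2020q1 path/to/2020q2 ... \
    --drug AVAPRITINIB --drug AYVAKIT --event "Photosensitivity reaction" \
    --window-start 2020-01-01 --window-end 2021-12-31
```

Programmatically, the model/results API mirrors statsmodels:

```python
from pvsignal import ContingencyTable, Disproportionality

res = Disproportionality(ContingencyTable(13, 187, 146, 24562)).fit()
res.prr, res.ror_ci95, res.ic025, res.criteria.all_three
print(res.summary())
```

Other subcommands: `parse` (validate one table, report rejected lines),
`dedup` (export deduplicated case tables), `screen` (rank every
drug–event pair by IC025), `fixture` and `simulate` (write synthetic
datasets).

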