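# glycograd

Temporal gradient analysis of blood-glucose responses to **non-standard
physical activity** in free-living type 1 diabetes (T1DM) data.

People with T1DM manage glycaemia with exogenous insulin calibrated to their
*habitual* activity. Activity that exceeds the personal norm — a spontaneous
long walk, unplanned exertion — is not compensated by basal insulin and can
drive blood glucose (BG) down toward hypoglycaemia. `glycograd` implements a
hypothesis-driven pipeline that asks, from wrist actigraphy and continuous
glucose monitoring (CGM) alone, whether such *non-standard* activity is
temporally associated with steeper short-term BG declines. It is aimed at
researchers analysing paired actigraphy + CGM studies and at anyone needing a
tested reference implementation of this class of free-living analysis.

## Method

Two streams enter the pipeline per participant:

* **actigraphy** — activity counts at 15 s epochs, each labelled
  `ACTIVE`, `REST`, `REST-S` (sleep) or `EXCLUDED`;
* **CGM** — glucose in mmol/L at 5 min intervals.

Processing steps:

1. **Clean** epochs: drop labels containing `REST-S` or `EXCLUDED`;
   normalise survivors to `ACTIVE` (label contains "ACTIVE") or `REST`.
2. **Resample** both streams into half-open windows `(start, end]` of width
   *t* ∈ {20, 40, 60} min, summarised by the in-window sample standard
   deviation (a window is `ACTIVE` if any epoch in it is). The last
   in-window CGM reading is kept as the window's glucose level.
3. **Merge** on the window timestamp; windows missing either side are
   excluded.
4. **Gradients** per calendar day within 06:00–23:59:

   grad(x) = (value(x) − value(x − t)) / t

   e.g. glucose falling 7.0 → 6.5 mmol/L across a 20 min window gives
   (6.5 − 7.0)/20 = **−0.025 mmol/L per min**.
5. **Personal baseline**: each participant's mean windowed activity over the
   whole record. A window strictly above the mean is **non-standard PA**;
   at or below it, **standard PA**.
6. **Hypothesis classification** at every instant *x* with a prior gradient
   g_prev (over [x−t, x]) and a post gradient g_post (over [x, x+t]):

   * **H1** (g_prev < 0, BG already falling): does the fall steepen or
     continue under non-standard PA?
   * **H2** (g_prev > 0, BG rising): does non-standard PA slow or reverse
     the rise?

   The trend-directed change d (= g_prev − g_post under H1, g_post − g_prev
   under H2, with an ε = 0.005 mmol/L/min dead zone for "same") maps each
   event to TP/FP/TN/FN:

   | H1              | increase | same | decrease |   | H2              | increase | same | decrease |
   |-----------------|----------|------|----------|---|-----------------|----------|------|----------|
   | non-standard PA | TP       | TP   | FP       |   | non-standard PA | FP       | FP   | TP       |
   | standard PA     | FN       | FN   | TN       |   | standard PA     | TN       | TN   | FN       |

7. **Metrics**: per participant × hypothesis × width — accuracy, precision,
   sensitivity, specificity, F1, and the Matthews correlation coefficient
   MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); cross-participant
   mean/median/mode aggregation; and exact nonparametric consistency tests
   (Wilcoxon signed-rank on correct vs incorrect classifications per
   participant, with rank-biserial effect size, and a Mann–Whitney U
   ignoring pairing). Both tests enumerate their exact null distributions
   in-repo so small-sample results are reproducible bit-for-bit.

A bundled synthetic-data generator produces paired streams with the
structure the analysis assumes — overdispersed baseline counts, scheduled
activity bouts that induce lagged BG declines (activity affects BG ~20 min
after onset), meal/insulin-suspension confounders that blunt declines — plus
ground-truth labels, so the whole pipeline is testable without clinical data.

## Worked example

Run the pipeline on eight synthetic participants at all three widths:

```bash
glyco analyze --out demo --seed 1
```

prints the run manifest summary

```json
{
  "config_hash": "6b3c3536267d17541c97a6837fd37337198d79f6b6b2fbbd23a6c5c92c5fa0d4",
  "seed": 1,
  "n_participants": 8,
  "n_events": 1917
}
```

and writes per-width event tables, per-participant metric tables, an
aggregate report and a consistency report into `demo/`. The 20 min
falling-glucose (H1) table, `demo/metrics_H1_20.csv`:

```
 ID  Accuracy  Precision  Sensitivity  Specificity
P01     85.23      82.86        98.31        58.62
P02     87.64      90.00        94.03        68.18
P03     88.17      87.32        96.88        68.97
P04     92.63      91.55        98.48        79.31
P05     88.89      87.14        98.39        67.86
P06     91.01      90.00        98.44        72.00
P07     90.43      92.96        94.29        79.17
P08     90.00      90.00        96.92        72.00
```

Mean H1 accuracy at 20 min is 89.2% — bout-induced declines are detected
almost perfectly, and the residual specificity loss comes from simulated
carbohydrate/meal confounders, mirroring the behavioural false positives
seen in real free-living data. `demo/consistency_report.json` shows that
correct classifications exceed incorrect ones for every participant:

```
wilcoxon:     W = 0.0, p = 0.0078125, rank-biserial r = 1.0  (exact, n = 8)
mann_whitney: U = 64.0 (maximum possible), p = 0.000155      (exact, n = 16)
```

`glyco report --run-dir demo` renders F1 bar charts per participant × width
and MCC box plots per width from those same CSVs, and
`glyco simulate --out fixtures --seed 1` writes raw CSV fixtures
(actigraphy, CGM, ground-truth sidecar) for one participant.

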