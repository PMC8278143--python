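# cytolapse

Quantitative lifecycle analysis for label-free live-cell imaging experiments
in radiobiology.

In a typical experiment, adherent cells (e.g. CHO-K1) are irradiated and then
imaged by phase-contrast microscopy every 5 minutes for two days. Each frame
is annotated with rectangular bounding boxes, each tagged with one of four
morphology classes: `liv` (attached, "fried-egg" shaped living cell), `round`
(detached, high-edge-contrast mitotic cell), `div` (actively separating cell
pair) and `dead`. From such box streams — produced by a human expert or by an
object detector — this package derives the biological endpoints of the
experiment and the quality scores of the detector, and it ships an
agent-based simulator that generates realistic annotated videos with full
lineage ground truth, so every estimator can be validated against a known
truth.

## What it computes

**Detection scoring** (`cytolapse.detection`). Greedy confidence-ordered
matching of predictions to ground truth at an IoU threshold; per-class
precision, recall and F1 with a 4x4 confusion matrix; average precision (AP)
as the area under the interpolated precision–recall curve; AP̄(class), the
mean AP over IoU thresholds 0.50:0.05:0.95; and

    mAP = mean over classes present of AP̄(class),   reported in percent.

**Growth and survival** (`cytolapse.lifecycle`). Per-class count series
N_c(t), normalised by the initial population and carrying √N Poisson errors;
a weighted fit of the offset-exponential growth model

    n(t) = 1                                  for t ≤ t0
    n(t) = (1 − A) + A · exp((t − t0)/τ)      for t > t0

(t0 = post-handling growth arrest, τ = growth constant, A = amplitude), with
covariance, χ², corrected R² and a 63 % confidence band; the cell-growth
survival fraction CGSF(t) = n_irr(t)/n_sham(t); a division census (maximum
generation depth per founder); and a unique-dead-cell census with
frame-to-frame linking so each dead cell is counted exactly once.

**Conventional assays** (`cytolapse.radiobiology`). Plating efficiency and
survival fraction SF = PE/PE₀ with Gaussian error propagation; the
linear-quadratic dose response SF(D) = exp(−(αD + βD²)) (closed-form
evaluation and exact log-space weighted fit); and Caspase3/7–Sytox gating
(late/early apoptotic, necrotic, vital) with across-sample mean ± SEM.

**Simulation** (`cytolapse.simulate`). An agent-based population following
the lifecycle state machine liv → round → div → two liv daughters, with
uniform 12–16 h cycle times, an initial arrest window, exponential death
hazard (dead is absorbing; dead boxes persist), permanently non-dividing
cells and random-walk motility. A detector emulator adds misses, corner
jitter, class confusion, spurious boxes, confidence scores, NMS and a
100-detection per-frame cap.

Annotation I/O (`cytolapse.annotations`) round-trips VIA-style region JSON,
COCO-style detection JSON and a flat CSV dialect.

## Worked example

Run the full pipeline on a simulated sham/irradiated pair (48 h, 5-min
frames, mild detector noise):

```sh
cytolapse demo --out demo_run --seed 0
```

`demo_run/growth_fits.txt` then contains the two growth fits, e.g.

```
[sham]
offset-exponential growth fit (vital channel, 576 points)
  A   = 1.091 +/- 0.019
  t0  = 5.201 +/- 0.092 h
  tau = 23.12 +/- 0.16 h
  chi2 = 36.45, corrected R^2 = 0.99891
```

i.e. the sham population sat in arrest for ~5.2 h (the configured handling
arrest is 5.7 h) and then grew exponentially, reaching 7.1x its initial size
at 48 h; the irradiated sample grows to only ~4.5x. `demo_run/cgsf.csv`
reports the survival ratio of the two fitted curves and of the raw series,

```
t_h,cgsf_fit,sigma_fit,cgsf_raw,sigma_raw
24.0,0.794...,0.0016...,0.776...,0.108...
48.0,0.600...,0.0017...,0.599...,0.053...
```

so by the growth criterion about 60 % of the irradiated population's
proliferative capacity survives at 48 h. `demo_run/evaluation_*.csv` holds
the per-frame detector scores (per-class AP̄, mAP in percent, class counts);
with the mild noise profile the per-frame mAP stays above 98 % on frames
below the 100-object cap. `death_census_*.csv` gives the unique dead-cell
fractions with their √k/N Poisson errors, and `divisions_*.csv` the
divisions-per-founder histograms.

The individual stages are also available as `cytolapse simulate | perturb |
evaluate | lifecycle | survival | gate | report`, and everything is a plain
library call (`simulate_population`, `map_score`, `fit_growth`, `cgsf`,
`lq_fit`, `gate_fractions`, ...).

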