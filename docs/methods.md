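# Methods

This note records the models, conventions and numerical choices behind
cytolapse, and what the synthetic data can and cannot establish.

## Coordinates and annotation formats

Boxes are 0-based, half-open pixel rectangles `[x_min, x_max) × [y_min,
y_max)`, x right, y down. The VIA dialect's `(x, y, width, height)` rect
shape is converted to corners on read. Class tags are matched
case-insensitively against the alias table {liv, living, live, round, div,
dividing, division, dead}; anything else raises a validation error naming
the tag and frame rather than dropping the object. Ground-truth objects
carry confidence 1.0 so one matching code path serves truth-vs-prediction
and truth-vs-truth comparisons. The VIA reader targets the standard
region-attribute export (regions with `shape_attributes`/
`region_attributes`); frame and video metadata travel in `file_attributes`
and a `_video_meta` block, which VIA itself ignores. Frame timestamps obey
`time_min = frame_index × frame_interval`, so frame 1 at a 5-minute cadence
is timepoint 5 min.

## The population simulator

Each agent follows the state machine liv → round → div → division into two
liv daughters; death can strike from any vital state and is absorbing. The
defaults describe the study conditions the package is aimed at: ~45–56
CHO-K1-like cells in a 1388 × 1040 px field, imaged every 5 min for 48 h,
cycle times uniform on 12–16 h, and an initial arrest of ~5.7–5.8 h during
which no transition of any kind occurs (modelling the phase of constant cell
numbers caused by handling stress). Division is modelled as a dwell in
`round` (default 30 min) followed by `div` (default 15 min) inside the last
portion of the cycle, so the inter-division time equals the drawn cycle
time; dwell times are not quantified in the literature we target and are
plain config values. Founders start desynchronised (uniform age within the
attached part of their cycle). Daughters draw fresh cycle times and
non-dividing flags at birth.

Irradiation has no built-in dose-response law; it is expressed entirely
through configuration. The shipped `irradiated_config()` uses a slightly
longer arrest (5.8 h), slower cycling (13–17.5 h), a 20 % permanently
non-dividing fraction and a death hazard of 0.0025 h⁻¹, against the sham's
5 % and 0.002 h⁻¹. Under these conditions the sham population grows ~7× in
48 h and the irradiated one ~4.5×, i.e. the qualitative contrast of a 4 Gy
proton exposure; the hazard values were chosen once so that a few cells per
hundred die within 24 h, matching the order of magnitude seen in such
experiments.

Box sizes are drawn per class (attached cells large and elongated, round and
dead cells compact), positions take Gaussian random-walk steps of 2 px per
frame, and overlap between agents is allowed — cells crowd; only exactly
coincident placements are rejected. Dead boxes stop moving. Every frame
emission and lineage record derives from one `numpy` generator seeded from
the config, so identical configs give bit-identical videos and lineages.

A config whose arrest exceeds its duration is legal for the simulator alone
(it yields a frozen video, which some tests exploit) but is rejected by the
pipeline before simulation starts, because the downstream growth fit is
meaningless without growth.

## The detector emulator

Per frame: drop each truth object with `miss_prob`; jitter the four corner
coordinates with independent Gaussians (`jitter_sd_px`); re-sample the class
from the row of a 4×4 row-stochastic confusion matrix; draw a confidence
uniformly from the true-positive range; add Poisson-distributed spurious
boxes with confidences from the false-positive range; apply class-agnostic
greedy NMS; keep the `max_detections` highest-confidence boxes (default
100, the practical ceiling of detectors pre-trained with a fixed detection
budget — frames above the cap lose their excess objects, which is exactly
the failure mode the cap models). Object identities are not propagated:
detectors have no notion of identity.

The `mild_noise()` profile (0.25 px jitter, confidence spread, no misses or
spurious boxes, NMS at 0.95 so genuinely overlapping cells are not
suppressed) represents a well-trained detector operating below its capacity
limit; under it, per-frame mAP stays ≥ 90 % on frames under the cap. The
rates are deliberately tunable — real failure statistics below 100 cells are
not published for this class of detector — and the degraded defaults of
`NoiseConfig` (2 % misses, 0.5 px jitter, occasional spurious boxes)
exercise the other failure modes.

## Detection metrics

Matching is greedy over predictions in descending confidence; ties break by
higher IoU, then input order. This is the standard detection-metric
convention and, for small frames, provably coincides with explicit
enumeration (tested against a brute-force oracle). AP uses the all-point
precision-envelope integral by default, consistent with COCO-style
evaluation; the older 11-point average is available behind
`interpolation="11point"`. AP̄ averages AP over IoU ∈ {0.50, 0.55, …, 0.95}.

Classes with zero ground-truth instances in the evaluation scope are
excluded from the mAP mean rather than scored 0 (`absent_class="exclude"`):
most frames contain no dividing cell, and a forced zero would dominate the
per-frame mean unfairly. The alternative policy is one flag away
(`absent_class="zero"`) since published evaluations are not always explicit
about this choice. mAP is reported in percent.

The confusion matrix and P/R/F1 can be computed either from class-agnostic
detection matches (cross-class pairs fill the off-diagonal) or directly from
a classifier's per-object calls; both arrive at `classification_scores`
through the same `MatchResult` structure.

## Growth fit and CGSF

The fit model is piecewise and continuous at t0 (n ≡ 1 for t ≤ t0). The
pre-arrest points are included against the constant branch — they carry
information about t0, which is a genuine free parameter bounded to the data
range. Weights are the inverse squared Poisson errors of the normalised
counts, with a one-count floor so zero counts never produce infinite
weights. The fit is `scipy.optimize.curve_fit` with analytic-free numeric
Jacobians; initial guesses come from the last time the series is ~1 and the
log-slope of the tail. A constant series short-circuits to A = 0 with very
wide t0/τ variances and a `flat` flag.

The confidence band uses linearised propagation of the parameter covariance
(gradient of the model w.r.t. (A, t0, τ), zero below t0) scaled to the
configured two-sided normal level, default 63 % — roughly a one-sigma band.
By default the covariance is the residual-scaled one (`absolute_sigma=False`),
which is robust when the stated Poisson errors are only approximately the
true noise scale.

CGSF(t) = n_irr(t)/n_sham(t) is offered both from the fitted curves (with
the two bands propagated in quadrature, assuming independence — separate
wells) and from the raw normalised series at the nearest frame (with Poisson
propagation), since either reading is defensible for a published time-point
value. Evaluation beyond twice the fitted range warns about extrapolation.

## Censuses

The division census reports, per founder, the maximum generation depth
reached inside the window (depth 4 means at least one fifth-generation
descendant) plus the total number of division events; it walks the lineage
tree and rejects orphan parent references.

The dead-cell census counts every dead cell once: dead boxes are linked
frame-to-frame by object id when present (ids are authoritative; no IoU
fallback) or otherwise by IoU ≥ `link_iou` against the previous analysed
frame's dead boxes, and k is the number of distinct tracks. Because dead
boxes are static, the linking is invariant to frame subsampling that keeps
each track visible at least once. N — the number of distinct cells in the
window — is the count of distinct ids when every object carries one;
without ids it falls back to the initial count plus the positive increments
of the total count (each division adds exactly one cell), an approximation
that over-counts only if detection noise produces spurious count increases.
The reported uncertainty on k/N is √k/N, the Poisson error of a small count
of independent events.

## Clonogenic survival and gating

PE = colonies(≥50 cells)/seeded; the ≥50-cell cut is a data-entry contract.
SF = PE/PE₀ with ΔSF = SF·√((ΔPE/PE)² + (ΔPE₀/PE₀)²). The control
uncertainty is the SEM over ≥2 control wells. For an unreplicated sample the
per-well ΔPE uses the binomial approximation √(PE(1−PE)/seeded); with
replicates, the SEM — sources differ on which is meant by a per-sample PE
error, so the choice is explicit here.

The LQ fit runs on ln SF, which is exactly linear in (α, β); weights
transform as σ_lnSF = σ_SF/SF. Non-negativity is not enforced, so noisy data
can return a slightly negative β; the covariance of the weighted normal
equations is returned and used for linear error propagation in
`lq_evaluate`. Gating fractions are per-sample normalised counts; the SEM
across samples is reported (NaN for a single sample), together with the
derived dead fraction (late apoptotic + necrotic) and the early/late shares
among apoptotic cells.

## Problem sizes and determinism

The test suite and the demo pipeline run complete 48 h videos (576 frames,
up to ~400 objects per frame) in seconds; per-frame detector evaluation in
the pipeline uses a stride (default 12, i.e. one scored frame per hour) to
keep the per-frame mAP table cheap, and the growth-recovery study uses 100
replicate series generated directly from the growth model at 2 %
multiplicative noise. Every stochastic component — simulator, emulator,
synthetic fixtures — is driven by explicit integer seeds, and pipeline
re-runs with the same config and seed produce byte-identical CSV outputs.

## Limitations

The simulator emulates population bookkeeping, not images: no pixel
textures, no segmentation ambiguity, no cell-cell contact artefacts, and
its motility is a diffusion caricature. Passing tests therefore validate
the estimators (counting, matching, fitting, linking) on data whose
generating process is known — they do not certify performance on real
phase-contrast videos, where detector errors are structured (crowding,
focus drift) rather than independent. Vital-cell tracking is deliberately
out of scope; identity linking exists only where the analysis needs it (the
dead-cell census). Senescence, cell-cycle phase structure beyond the four
morphology classes, and any dose–response law inside the simulator are
likewise out of scope.
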