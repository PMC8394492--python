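# Methods

## Model and assumptions

The explainer treats the predictor `b` as an opaque deterministic function
from a batch tensor `X ∈ R^{s×h×n}` to either per-sample output series
(regression, `s×h`) or class scores (classification, `s×c`). Determinism
within a session is part of the contract: a predictor with stochastic
inference (e.g. dropout left on) is out of scope, because every analysis
compares an occluded prediction with an unoccluded reference and attributes
the whole difference to the occlusion. All samples must share `h` and `n`;
ragged sets are not supported, and no preprocessing (resampling, filtering,
beat extraction) is performed.

Occlusion is constant-valued substitution only. Non-constant alternatives
(noise injection, interpolation, signal swapping) probe different questions
and are deliberately excluded.

## Conventions and numerical choices

* Timesteps are 0-based; windows are half-open `[start, end)`. Window `i`
  of duration `d` is `[i·d, min((i+1)·d, h))`, so a signal splits into
  `q = ⌈h/d⌉` windows and the trailing window may be shorter. The trailing
  window is kept as a valid occlusion target; its MAE is computed over the
  full output series, not renormalized by window length.
* The discrepancy is always plain MAE. Per-sample MAEs are averaged per
  sample first and then over samples (rather than pooling all points);
  with equal-length samples the two coincide, but the per-sample vectors
  are retained in every report for inspection.
* The dataset-mean occlusion value is computed **per signal** over all
  samples and timesteps. Physiological channels live on different scales
  (mV vs mmHg), so a global mean would inject an out-of-scale constant into
  most signals. The scalar actually substituted is recorded in each report.
* The default occlusion value is 0.
* Duration counting uses the strict comparison `MAE > T_MAE`, and duration
  in timesteps is `count × d` even when the trailing window is shorter —
  the count is of windows, and reporting multiples of `d` keeps summaries
  comparable across series lengths. `T_MAE` has no default because its
  scale is that of the model's output; `suggest_threshold` derives one as
  a user-chosen quantile (default 0.9) of the per-window MAEs of
  *unoccluded* predictions against ground truth, and the chosen value is
  carried in every result. A zero count means "below tolerance", never
  "no perturbation".
* Ranking tie-breaks are deterministic everywhere: equal window scores
  order by ascending window index, then ascending series index; argmax
  operations (top window, BMU) return the first minimum/maximum in
  row-major order.
* Occlusion experiments are batched: the `q` single-window occlusions of
  one sample are issued to the predictor as one `q`-sample batch plus one
  baseline call, so windowed analysis of one signal costs `q + 1` predicted
  samples per input sample (verifiable in the CLI manifest's call counts).
  This assumes the predictor maps batch elements independently, which holds
  for per-sample sequence models.
* Top-k sub-signal records store the **original** slice values, not the
  occluded ones: downstream morphology clustering is only meaningful on
  real signal shapes. The unoccluded reference prediction is computed once
  per sample rather than once per window — an algebraically identical
  optimization.
* Classification label decisions: argmax over class scores; for a single
  probability column, threshold 0.5. When a probability-output classifier
  provides no loss function, per-sample binary cross-entropy is used.
  Only windows whose occlusion flips the predicted label are candidate
  influential sub-signals, so the candidate list (and the global set) can
  legitimately be empty; that case warns rather than fails.

## SOM and E-matrix

The SOM is an internal implementation of the classic online algorithm:
random uniform weight initialization scaled to the data range, one random
input per step, Euclidean best-matching unit, Gaussian neighbourhood update
with learning rate and width both decaying as `1/(1 + t/(steps/2))`.
Defaults are a 12×17 hexagonal lattice, σ = 2.05, learning rate 0.7 and
1e5 training steps, so the standard configuration is a single constructor
call; tests and the acceptance script use smaller grids and step counts
(hundreds of steps, ≤ 6×8 grids) as their problem sizes. Hexagonal
neighbourhood distances use offset planar coordinates (odd rows shifted by
0.5, row pitch √3/2). Training is exactly reproducible from the config
seed; both initialization and sampling flow from one generator.

Sub-signals shorter than the window duration (trailing windows) are
zero-padded on the right before mapping and stay flagged `truncated`.
E-matrix normalization is global min-max over occupied cells; unoccupied
cells stay 0, and spreads below `1e-12` relative are treated as exact ties
(all occupied cells map to 1.0) so that floating-point accumulation noise
cannot turn a degenerate all-equal map into a spurious contrast. The
unnormalized E-matrix satisfies the conservation identity
`Σ E[u,v]·|S_{u,v}| = Σ_z score(s_z)`, which the tests check directly.

A map trained on one sub-signal set (e.g. from training data) can build an
E-matrix from any other set (e.g. test data): training fits weights only.

## Concordance

External attributions are consumed as provided — raw values are summed per
window by default (an absolute-value option exists but is off), and the
module never computes attributions itself, since that would require model
internals. Agreement is evaluated per (sample, signal) track: the
occlusion-maximal and attribution-maximal window indices are concordant
when they differ by at most the tolerance (default 1 window). Argmax ties
resolve to the lowest index on both sides, keeping the score symmetric.

## Synthetic fixtures: what they do and do not show

The generators produce quasi-periodic morphology — sine mixtures with a
second harmonic, spike trains, an ECG-like train of three Gaussian bumps
per cycle (P/QRS/T), and white noise — with per-signal amplitude, period
and noise controls, all driven by a single seed. Defaults (16 samples ×
250 timesteps × 2 signals, period 50, unit amplitude, noise sd 0.05)
emulate a short two-channel biosignal strip at low sampling rate. The
ECG-like generator is a morphology factory, **not** a physiological
simulator: no RR variability, no pathology classes, no sensor artifacts.

The toy black boxes (constant, echo, linear, window-gated, threshold
classifier) have closed-form occlusion responses, so the pipeline's
rankings and scores can be verified exactly. Passing these checks shows
that the machinery — masking, scoring, ranking, aggregation, clustering,
reporting — is correct and reproducible. It does **not** show that a real
trained network's occlusion scores are faithful explanations of its inner
computation; occlusion measures behavioural sensitivity, and inputs pushed
off the data manifold by constant substitution may elicit responses that no
realistic signal would. That caveat is inherent to the method, not to this
implementation.

## Known limitations

* Stochastic predictors violate the contract (see above).
* Constant-value occlusion can create physiologically impossible inputs;
  the dataset-mean option mitigates but does not remove this.
* Multi-signal *joint window ranking* is not provided: subset occlusion
  exists (any signal subset may be occluded in one window, as in
  both-signals-at-once robustness experiments), but top-k ranking occludes
  one signal at a time.
* Perturbation duration is undefined for classification tasks — the target
  carries no temporal structure.
* The SOM is a visualization aid; no map-quality metrics (quantization
  error curves, U-matrix) are computed beyond the invariants above.
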