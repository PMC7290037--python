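# Methods

This note records the model, the numerical choices, and the limits of the
`nvctf` package in its own words.

## Model

Neurovascular coupling is treated as a linear time-invariant system: a
neuronal activity trace `x(t)` (a relative calcium fluorescence change)
predicts a vascular response `y(t)` (a relative red-blood-cell-velocity or
power-Doppler change) through convolution with an impulse-response kernel,

```
y(t) ≈ k · (x ⊛ TF)(t)
```

where the kernel is a gamma density with a pure time shift and an
amplitude scale:

```
TF(t) = H(t − p3) · p4 · (t − p3)^(p1−1) · p2^p1 · e^(−p2 (t − p3)) / Γ(p1)
```

| parameter | meaning | units | fitting box |
|-----------|--------------------------|-------|------------------------|
| p1 | gamma shape | — | 10⁻³ … 10 (20 for the slow secondary kernel) |
| p2 | gamma rate | 1/s | 10⁻³ … 10 |
| p3 | vascular delay | s | 10⁻³ … 10 (up to 20 for the secondary kernel) |
| p4 | amplitude (kernel integral) | output units · s / input unit | 10⁻³ … 10 |

Because the gamma density integrates to one, the kernel integrates to
`p4`, and its peak sits at the closed-form time `(p1 − 1)/p2 + p3`.
A fitted kernel is **valid** only when it starts at the origin, i.e.
`p1 > 1` (with a 10⁻⁶ numerical margin): for `p1 ≤ 1` the kernel is
maximal or divergent at the shifted origin, which is physiologically
meaningless for a hemodynamic response.

## Signal preparation

- Traces are baseline-corrected as relative changes against the mean of
  the first 5 s before stimulus onset, and optionally median-filtered
  (3-sample window, endpoints untouched).
- Calcium traces are resampled to a uniform 50 ms grid with
  shape-preserving piecewise-cubic (pchip) interpolation; no
  extrapolation beyond the recorded span is permitted.
- Fitting uses the 5–27 s window of a 30 s acquisition (5–59 s for 60 s
  acquisitions), skipping the pre-stimulus segment.

## Prediction and scoring

The discrete prediction is the causal convolution `(x ⊛ TF) · dt`
(left-point Riemann convention) on the calcium grid, linearly interpolated
onto the observation grid. A scalar amplitude `k > 0` is then fitted over
a short window 2–8 s after stimulus onset by a derivative-free simplex
search; this post-hoc rescale cannot change the Pearson coefficient, which
is the headline score throughout. The quadrature error of the left-point
convolution is bounded by `dt/2 · max(TF)`; at dt = 50 ms this stays below
1% of `p4` for kernels in the capillary regime (p1 ≈ 1.3–3.5,
p2 ≈ 0.2–0.6 1/s). Sharper kernels need a finer grid.

## Fitting protocol

Least-squares fitting of the four kernel parameters uses repeated
simulated annealing:

- each run starts from the canonical initial set (6; 1; 0.001; 1) — or the
  incumbent kernel in later iterations — with temperature 100 and
  exponential cooling (factor 0.95 per step, 300 steps by default);
- proposals are temperature-scaled random directions, reflected at the
  box bounds; acceptance follows the Metropolis-style rule
  `1/(1 + exp(ΔSSR/T))`;
- each run ends with a restarted Nelder–Mead polish (up to 5 restarts of
  600 evaluations). The restart matters: the SSR valley is long and flat
  because the four parameters trade off against each other, and a single
  simplex pass stalls far from the minimizer. The identifiable quantity is
  the kernel's peak time rather than any individual parameter.
- A protocol iteration launches 50 such runs (configurable); the best
  valid candidate is kept if it improves the prediction Pearson by more
  than 0.1% relative, and the protocol stops after at most 3 iterations or
  at the first iteration without meaningful improvement. If an iteration
  yields no valid candidate at all, the optimization is repeated with
  fresh runs while iterations remain; if no run in any iteration passes
  the validity screen the fit fails explicitly (`NoValidTFError`) — a
  recording that supports no admissible kernel contributes no kernel.
- All randomness descends from one integer seed through per-run seed
  sequences, so every fit is exactly reproducible.

## Cohort validation and selection

Every subject's kernel predicts every subject's trial, giving a Pearson
cross matrix (diagonal = self prediction). Reported statistics
(`mean_cross`, `cv_cross` = SD/mean) are taken over each row's
off-diagonal entries. **Selection** of the cohort's standard kernel uses
the full row mean, self term included: the standard kernel must perform
well on its own dataset and on the others'. The self term is what
disqualifies a kernel fitted on a corrupted recording — such a kernel can
still predict clean subjects, but it cannot explain its own data. Cells
where a prediction degenerates (identically zero on the rescale window,
or zero-variance inputs) are recorded as NaN and excluded from row
statistics rather than aborting the computation. Ties fall to the lowest
subject index.

## Two-component decomposition

Strong stimulation adds a delayed vascular component. The decomposition
subtracts the amplitude-rescaled standard prediction from the observed
response, fits a second kernel to the residual inside a wider box (shift
up to 20 s), then refits both amplitudes jointly by non-negative least
squares and predicts with the sum of the two components.

## Synthetic generator

The generator exists to exercise the pipeline with known ground truth,
not to model physiology in detail. A boxcar stimulus (default 5 s, onset
10 s) drives a difference-of-exponentials calcium kernel (rise 0.1 s,
decay 1 s, unit peak); the vascular trace is the convolution with a true
kernel (optionally plus a scaled secondary component), with i.i.d.
Gaussian noise expressed as a fraction of the response peak on either
channel. Cohorts share the true kernel up to optional lognormal
inter-subject jitter, redrawn until valid (with a hard failure when
validity is unattainable).

## Problem sizes used in the test suite

Compute-heavy studies run reduced versions of the protocol, each timed
and checked against its target band before being frozen:

- noiseless recovery: full protocol (50 runs × ≤3 iterations), recovers
  the generating kernel to ~10⁻¹¹ s in peak time;
- 10% noise: 4 runs × ≤2 iterations, 20 seeds, median peak-time error
  ≈ 0.13 s (band: ≤ 0.2 s);
- cohort studies: 3–4 runs per subject; clean 6-subject cohort floor
  ≈ 0.99 cross Pearson (band: ≥ 0.95);
- secondary decomposition: 8 runs, recovers a 25 s secondary peak exactly
  on noiseless data.

## Limitations

- Linearity and time invariance are assumed; saturation and
  stimulus-strength-dependent kernels are out of scope (the two-component
  model captures one specific deviation).
- The 50 ms / left-point convolution quadrature is tuned to slow
  hemodynamic kernels; kernels with `max(TF)` ≫ p4/2·(1/dt) would need a
  finer grid.
- The synthetic generator's calcium kinetics and noise model are
  deliberately minimal; it validates the machinery, not the biology.
- The annealing protocol is stochastic: with few runs per iteration the
  validity screen can reject every candidate on noisy data, and fits on
  noise-dominated recordings may legitimately fail.
- Voxel ranking implements the area-under-curve ranking only; statistical
  parametric mapping is out of scope.
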