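# Methods

This note records the models, conventions, parameter defaults and design
choices behind `nmrphaser`, in the spirit of a methods appendix: what the
code computes, what the synthetic data does and does not emulate, and what
a green test establishes.

## 1. Phase model and conventions

A phase state is the pair `(PH0, PH1)` in degrees.  Point `k` (0-based) of
an `N`-point complex spectrum is multiplied by

```
exp(+i * deg2rad(PH0 + PH1 * k/(N-1)))
```

so the left end (index 0, displayed downfield) receives exactly `PH0` and
the right end exactly `PH0 + PH1`; `PH1` is therefore the *total* phase
change across the spectral width, and the endpoint form used by the
score-surface diagnostic is `(left, right) = (PH0, PH0 + PH1)`.  Two
conventions are fixed once and documented rather than inferred:

* **Ramp grid.** The ramp uses `k/(N-1)`, `k = 0..N-1`.  A `k/N` ramp with
  `k = 1..N` differs by exactly one grid step (a `PH1/N` shear plus a
  `PH1/N` offset); at the spectrum sizes involved the difference is far
  below every tolerance in this package, and the `k/(N-1)` form makes the
  endpoint parametrization exact.
* **Sign.** The phase factor is `e^{+i phi}` (`PHASE_SIGN = +1`,
  one constant controls it); *correcting* a known error `phi` means
  applying `-phi`.

FID processing (`process_fid`) is the standard chain: exponential
apodization (default 0.3 Hz), first-point halving (suppresses the constant
baseline offset of the discrete FT), zero-filling to a power of two,
complex FFT with the output ordered left = downfield, and digital-filter
compensation.  The standalone `group_delay_correct` helper applies the
textbook first-order ramp of `-360 * group_delay` degrees; inside
`process_fid` the compensation is instead applied bin-wise in the FFT
domain (`exp(+2 pi i k g / N)` per FFT bin), which is exact for fractional
delays and additionally removes the constant `180 * g` offset that the pure
first-order form leaves for odd delays.

## 2. Synthetic training spectra

The generator produces the world the classifiers are trained for: dense,
biofluid-like 1D proton spectra with controlled phase errors.

**Lineshapes.** Peaks are Voigt profiles synthesized in the *time domain*
— Lorentzian width maps to exponential damping `R = pi * w_L / N` per
sample, Gaussian width to quadratic damping — and Fourier transformed, so
the absorption (real) and dispersion (imaginary) components are mutually
consistent by construction rather than approximated.  `gauss_fraction g`
partitions a requested total FWHH `w` via the inverted Olivero–Longbothum
rule (`w_L = (1-g) w`, `w_G` chosen so the combined Voigt FWHH stays within
a fraction of a percent of `w` for all `g`).  Peak amplitudes are
normalized numerically so the real-part height at resonance equals the
requested height.  For speed, each peak's signal is evaluated only until
its envelope decays below `1e-5` of its initial value; the resulting
truncation ripple is orders of magnitude below the noise floor.

**Fixture peak lists.** The experimental biofluid peak lists behind the
original training material are not publicly deposited, so
`fixture_peaklists` builds synthetic stand-ins with their salient
statistics: >= 100 peaks per list organized in multiplets (splittings 4–14
points), >= 40% of peaks inside a central window spanning 15% of the axis
(the crowded 3–4 ppm region of urine/serum spectra), heights spanning at
least two orders of magnitude.

**Augmentation** (per training list): the axis is split into 8 equal
segments whose contents are shuffled; a uniform `[0, 0.3]` fraction of
peaks is removed; survivors are displaced by up to 2000 points (scaled
proportionally for shorter test axes); widths are resampled uniformly in
`[3, 30]` points and heights log-uniformly over two orders of magnitude;
the axis is mirrored with probability 0.5; each peak spawns a partially
overlapping "shoulder" (offset 0.2–0.8 FWHH, height 20–80% of the parent)
with probability 0.2.  Segment count, removal rate, shoulder statistics
and the inversion probability are package defaults — the upstream design
states the operations but not these rates.

**Background, baseline, noise.** About 30% of samples receive 1–3 broad
background peaks (FWHH 100–500 points) emulating macromolecular baselines;
the published description gives both 500 and 300 points as the cap in
different places, so the default is 500 and configurable.  A smooth
baseline is a shape-preserving piecewise-cubic Hermite (PCHIP) curve
through alternating-sign knots — monotone between knots, hence *exactly*
five interior extrema — rescaled to exactly 0.6% of the tallest peak.
Gaussian noise with per-sample sigma uniform in `[1e-4, 5e-3]` of the
tallest peak (a package default; the upstream description says only that
noise was added) goes independently into both channels.

**Labels.** Each sample is one of three classes per task.  `ph0` task:
`|PH0|` uniform in `[0.5, 5]` degrees (pretraining: `[5, 10]`), sign from
the class, `PH1 = 0`.  `ph1` task: `|PH1|` uniform in `[1, 10]`
(pretraining: `[5, 20]`), sign from the class, plus an accompanying PH0 of
*equal magnitude* and independent random sign — this forces the network to
read the whole spectrum instead of one end.  Baseline and noise are added
before the phase error is injected.  Zero-class samples carry no error.
All randomness flows from one master seed through named substreams, so any
prefix of a dataset is reproducible independent of how much is consumed.

**What the generator does not emulate:** solvent-suppression artifacts,
J-coupling fine structure from an actual spin Hamiltonian, receiver-dead-
time baseline wiggles, ppm calibration, and instrument-specific lineshape
distortions.  A green test on this material therefore establishes that the
method works on dense, noisy, baseline-distorted Voigt spectra — not that
it matches expert phasing on any particular spectrometer output.

## 3. Entropy coarse phasing

The functional used by the original system is not published; this package
uses the standard derivative-entropy objective with a negativity penalty
(ACME-style):

```
H(R) = -sum h_k ln h_k  +  w * sum_{R_k < 0} (R_k / max|R|)^2,
h_k = |dR_k| / sum|dR|
```

with `w = 1000` by default.  `H` is invariant under uniform intensity
rescaling.  The coarse stage evaluates `H` on an exhaustive `(PH0, PH1)`
grid over `[-180, 180]^2` in 10-degree steps (both endpoints included;
ties broken toward the smallest `(|PH0|, |PH1|)`, making the argmin
deterministic).  Spectra longer than 16384 points are evaluated on a
stride-4 copy for speed; correctness tests run undecimated.  On dense
synthetic spectra this stage leaves median residuals of roughly 4–7
degrees per component (the design target is < 10); equivalence with the
original entropy implementation cannot be asserted, only this residual
behavior.

## 4. Tandem classifiers

Architecture (shared trunk for both tasks): a strided 1D CNN front end
(channels 16/32/48/64, kernels 7/5/5/5, strides 4/2/2/2 — an overall
32-points-per-token reduction and a ~119-point receptive field, several
peak widths), layer-normalized tokens into a pre-norm transformer encoder
(4 layers, 4 heads, embed 64, FFN x4, dropout 0.1), pooling over tokens,
and a 3-class head ordered `(negative, zero, positive)`.  About 2.3e5
trainable parameters.  The published model's exact internals (and its
319,347-parameter count) are not public; this configuration is the
package's scaled-down default, and matching the original size is
explicitly not attempted.

The zeroth-order classifier uses plain global average pooling.  The
first-order classifier additionally feeds the *first spatial moment* of
the tokens (a ramp-weighted mean, ramp normalized to [-1, 1] over however
many tokens the input produces) to the head: a first-order phase error is
a linear trend across the spectrum, and a plain token average cancels
exactly the statistic that carries its sign.  In desk-scale pilot runs
this raised ph1 held-out accuracy by about five points; it changes nothing
about the variable-length property.

Position information enters only through a *relative* attention bias:
`bias[h, i, j]` depends on the signed offset `i - j` via `2*32 + 1`
learned scalars per head — half the buckets cover small offsets exactly,
the rest are log-spaced out to the maximum token count (131072 / 32 = 4096
tokens, the maximum field of view).  This makes attention translation
invariant while preserving order and distance, and — together with global
average pooling — lets one set of weights process any length up to 131072
points (inputs are right-padded to a multiple of the token size).

Inputs are two channels, real and imaginary, both divided by `max |real|`
(scale invariance by construction; a real-only ablation is a config
switch).  Whether the original networks see the imaginary channel is
unknown; using it is this package's choice and is part of why the small
error classes are learnable at desk scale.

**Training.** Adam (lr 1e-4, decoupled weight decay 1e-5), batch 4,
categorical cross-entropy, two-stage curriculum: pretraining on the coarse
error ranges, then fine-tuning on the fine ranges ("episodes" are read as
epochs).  Package additions on top of that recipe, chosen to control
overfitting at the scaled-down data size: cosine decay of the learning
rate over each stage, dropout 0.1, a mirror augmentation, and a final
weight choice between the best-validation epoch and the average of the
last third of fine-tuning epochs (whichever validates better).  Training
is fully deterministic for a fixed seed (pure NumPy, no threading
nondeterminism).

The mirror augmentation exploits an exact symmetry: reversing the
frequency axis and conjugating a spectrum yields the mirror-image sample
with phase error `(-PH0 - PH1, PH1)`.  For the ph0 task this is an
in-distribution sample with the outer labels swapped.  For the ph1 task
the mirrored PH0 companion would fall outside the equal-magnitude design,
so the sample is additionally rotated by the known constant phase that
restores a `+-|PH1|` companion with a fresh random sign — keeping the
augmented sample exactly in-distribution with its first-order label
intact.  The same symmetry provides a free two-view test-time ensemble for
the ph0 model (average of the original and label-swapped mirrored
prediction); it is not used at inference for ph1, where the transform is
only valid when the true phase is known.

The scaled-down reference run used throughout the tests: 4096-point
spectra, 600 train / 150 validation samples per task, 15 pretraining + 30
fine-tuning epochs, seed 7.  The pretraining database is 600 samples for
ph0 and 1800 for ph1 (its size is a free parameter of the curriculum; the
harder first-order task benefits measurably from the larger coarse-error
foundation).  The >0.8 held-out accuracy threshold and the 1.5-degree
end-to-end recovery tolerance were recorded against pilot runs at this
seed.

## 5. Iterative correction workflow

`deep_phase` composes three stages; the step policy is this package's
design (the upstream description fixes only the 0.3-degree stop
criterion):

1. **Coarse:** the entropy grid search (can be disabled via
   `PhaserOptions.coarse="none"` when the input is already coarse-phased).
2. **Classifier loop:** query both models; every task whose argmax is not
   "zero" receives a correction of its current step size (initial 2
   degrees) opposing the predicted sign; a task's step halves whenever its
   predicted sign flips, and an oscillation guard forces halving if the
   same (sign pattern, step) state recurs three times.  The loop ends when
   both models answer "zero" or after `max_iterations`.
3. **Refinement:** maximize the sum of the two zero-class probabilities by
   central finite differences (epsilon 0.5 degrees) with step halving on
   non-improvement, stopping when the step drops below 0.3 degrees (with a
   safety cap on iterations).  Accepted steps are monotone in the score by
   construction.

PH0 and PH1 corrections are applied jointly each loop pass (the upstream
ordering is unspecified).  Every applied phase is recorded in the result
trace; the trace composes exactly (associative addition of `PhasePair`s)
to `total_correction`, and `converged` requires both a sub-0.3-degree
final step and "zero" as both models' final answer.  A spectrum with fewer
than ~15 detected peaks (local maxima above 5x a robust MAD noise
estimate) triggers an applicability warning, mirroring the method's stated
domain.

## 6. Numerical choices and edge cases

* Entropy of an all-zero real part is defined as 0 with a warning.
* `grid_search` ties (exact float equality) resolve toward the origin.
* Degenerate all-zero spectra are rejected by the classifier preprocessor.
* Checkpoints (single `.npz` with an embedded JSON manifest) refuse to
  load into a mismatched task or architecture.
* Synthesis accumulates in complex64 (the noise floor is far above
  float32 resolution); analysis-side code is float64.
* JCAMP-DX values are written with 10 significant digits; round-trips are
  good to 1e-6 relative, which bounds the fidelity of file-based
  workflows.

## 7. Known limitations

Only PH0/PH1 are modeled — spectra with quadratic or higher phase errors
will not phase perfectly everywhere.  The classifiers are only valid
inside their training domain (3–30 point linewidths plus broad background,
errors inside the stated ranges, >= ~15 peaks); the entropy stage is the
only guard against grossly out-of-range input.  The desk-scale models are
far smaller and trained on far less data than a production run (18,000
samples x 400 epochs would be the full recipe); accuracy figures from this
repository's tests characterize the scaled-down configuration only.
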