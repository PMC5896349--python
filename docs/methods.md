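# Methods

## Model and pipeline

The pipeline estimates a probesets × arrays matrix of log2 expression
values from probe-level intensities in three stages.

**Background correction.** Observed PM intensity is a convolution
PM = bg + s with bg ~ N(μ, δ²) and s ~ Exp(λ). Conditioning on PM and
completing the square shows s | PM is N(a, b²) truncated to (0, PM),
with a = PM − μ − δ²λ and b = δ; background correction replaces PM by
the mean of that truncated normal,

    E[s | PM] = a + b (φ(a/b) − φ((PM−a)/b)) / (Φ(a/b) + Φ((PM−a)/b) − 1).

The truncation at PM (not only at 0) reflects the view that the
signal cannot exceed the observed intensity; it is what the closed
form above encodes, and the quadrature oracle in the test suite
integrates over exactly (0, PM). Packages that truncate at 0 only
(e.g. limma's `normexp.signal`) give systematically different values
for dim probes; that difference is a modelling choice, not an error.

**Quantile normalization.** Reference = per-rank mean of the sorted
per-array vectors; each array is remapped so its k-th order statistic
becomes reference[k]. Tied values receive the mean of the reference
over the tied rank span, which is deterministic and invariant under
permutation of equal elements.

**Summarization.** Per probeset, log2 intensities follow
Y[j,i] = θ[i] + φ[j] + ε[j,i]. Tukey median polish sweeps row
(probe) medians first, then column (array) medians, folding the
median of the accumulated effects into the overall term each
half-sweep. Expression is overall + array effect.

## Parameter estimation

The convolution model does not come with an estimator. Two are
provided:

* `mle` (default): maximize the convolution log density
  log f(x) = log λ + λ²δ²/2 − λ(x−μ) + log Φ((x−μ−λδ²)/δ)
  over (μ, log δ, log λ) with L-BFGS-B and an analytic gradient
  (inverse Mills ratio computed in log space), started from the mode
  estimator below. At 2×10⁵ probes it recovers all three parameters
  to within ~1–2% relative on simulated data.
* `mode`: the classical ad hoc estimator — kernel-density mode of the
  intensity distribution as μ̂, √2 times the sub-mode spread as δ̂,
  reciprocal mean excess over the mode as λ̂. It is fast but
  structurally biased: the mode of the convolution sits roughly
  μ + δ²λ + 0.95 δ for moderate δλ, so μ̂ overshoots by tens of
  percent. It is kept for comparison and as the MLE starting point,
  not as the default.

Parameters are estimated per array from PM probes only, on the raw
intensity scale, before any log transform. A frozen-parameter mode
(`PipelineConfig.fixed_params`) applies one known parameter set to
every array instead of fitting — useful when the background model is
known exactly (simulation ground truth) or carried over from a
reference batch; it is also what makes the exact no-noise limit of
the pipeline testable, since fitting a background to data that
contains none is ill-posed (any estimator must pin the background to
the left edge of the signal distribution, distorting dim probesets).

## Numerical choices

* Closed form: three evaluation regimes. Bulk (standardized lower
  bound α = −a/b < 4): direct φ/Φ arithmetic. Right tail (α ≥ 4, dim
  probes): scaled complementary error function (`erfcx`) with the
  common exp(−α²/2) factored out, so the ratio never underflows.
  Collapsed interval (PM ≲ 10⁻⁸ δ): the exact limit PM/2. The
  denominator is clamped at 10⁻³⁰⁰. Against direct numerical
  integration the worst relative error over a 216-point grid
  (μ ∈ {0..500}, δ ∈ {10..100}, λ ∈ {10⁻³..10⁻¹}, PM ∈ 1..10⁵) is
  ~2×10⁻¹⁰.
* The quantile reference is accumulated in array index order and
  computed as first + mean(sorted − first); for arrays with identical
  distributions this returns their common sorted vector exactly,
  making re-normalization a floating-point-exact identity.
* Median polish: rows before columns; even-count medians are the mean
  of the central pair; stopping rule is relative change of the total
  absolute residual < tol (default 0.01), at most `max_iter` = 10
  sweeps — the classical defaults. Column residual medians are
  exactly zero at convergence (columns are swept last); row medians
  are only approximately zero under this stopping rule, which is a
  property of the classical algorithm, not a defect. The
  reconstruction identity input = overall + row + column + residual
  holds to floating point regardless of convergence.
* log2 is applied after normalization and before summarization (the
  additive probeset model is only sensible on the log scale); a
  configuration switch can disable it.

## The execution engine

Map stages chunk records (default chunk = ⌈n/workers⌉) onto a joblib
process pool; map output is canonically ordered by (key, input index,
emit index), shuffle sorts groups by key, and every floating-point
reduction order is fixed (the quantile reference accumulates in array
index order). Consequence: output is bit-identical for any worker
count and any chunking, which the tests assert at ≤10⁻¹² and observe
at 0. Cross-array information flows only through the quantile
reference reduce. Worker exceptions surface as `StageError` naming
the offending record or key. This local pool deliberately simulates a
distributed map/reduce deployment; the contract it preserves
(parallel ≡ sequential) is the property such an architecture must
guarantee, while scheduling, block placement and fault tolerance are
out of scope.

## Synthetic data

The generator emulates a two-group expression study on a grid chip:
probesets of 11 PM probes (the convention on the human U133 chip
family), per-probeset baselines θ ~ U(6, 12) log2 units, probe
affinity effects N(0, 0.5²) re-centred to median zero, residual noise
N(0, 0.25²) on the log2 scale, and Gaussian background N(100, 30²)
truncated at zero added on the raw scale. 50 of 500 probesets get a
+2 log2 shift in the second half of 20 arrays. These defaults are the
moderate-noise regime used throughout the tests; intensities and
noise levels are in the range typical of scanned chips.

Two deliberate model inconsistencies: (1) the exponential-signal law
of the background model and the log-normal signal implied by the
additive log2 expression model cannot both hold; the simulator drives
the signal from the expression model because recovering θ is the
scientific target, and the background MLE tolerates the resulting
misspecification (recovery tests that target the background
parameters themselves use `simulate_normexp_sample`, which draws from
the exponential law). (2) The background is truncated at zero since
intensities cannot be negative; at μ/δ ≈ 3.3 the truncated mass is
~0.04% and the estimators absorb it.

What the simulator does not emulate: spatial artifacts, scanner
saturation, batch effects, probe-sequence-dependent affinity,
cross-hybridization. Passing recovery tests therefore demonstrates
correctness of the pipeline's statistics under its own model
assumptions, not robustness to every failure mode of real chips.

Recovered group fold changes are mildly attenuated (≈1.75–1.85
observed for a true 2.0): quantile normalization forces equal
distributions across groups, so a one-sided shift of 10% of probesets
is partly redistributed — a well-known property of global
normalization, visible here because the truth is known.

## Problem sizes and defaults

Default study: 20 arrays × 500 probesets × 11 probes (110 000 PM
probes per array); parameter-recovery checks use 2×10⁵ probes; the
full pipeline on the default study runs in a few seconds per worker
configuration. The benchmark harness defaults to batches of
10–200 files, mirroring a typical throughput experiment; its timings
are reported without assertions because they are hardware-bound.

## Known limitations

* ASCII CEL v3 and the TSV layout dialect only; binary CEL/CDF codecs
  are out of scope.
* MM probes are parsed and can be simulated but never enter the
  pipeline (PM-only correction).
* The background MLE assumes a unimodal intensity distribution with a
  left background bump; arrays violating this (e.g. saturated scans)
  fall back on whatever optimum the likelihood finds.
* Fold-change attenuation by quantile normalization (above) is
  inherent to the method, not corrected for.
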