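# Methods

This note documents the generative model behind the synthetic recordings,
the estimators implemented by the analysis stages, the numerical choices
made where the design was genuinely open, and the known limitations of
both.

## Conventions

Time is stored in seconds at the trace level; kinetic parameters (rise and
decay time constants, latencies, the asynchronous and sucrose-discharge
time constants) are in milliseconds. Current is in pA, charge in pC
(1 pA·s = 1 pC). Raw traces are inward-negative, as in conventional
voltage-clamp EPSC recordings, and carry an explicit polarity flag; all
analysis operates on baseline-subtracted, polarity-rectified magnitude
traces produced by `preprocess`. Sample indexing is 0-based and stimulus
times refer to stimulus onset.

## Generative model

The generator is the minimal quantal-release structure that makes every
analysis stage testable by parameter recovery; it is not a biophysical
simulation of calcium microdomains.

**Quantal waveform.** A single vesicle produces
`k(t) = c·(exp(−t/τ_d) − exp(−t/τ_r))`, with `c` set so the peak equals
the quantal amplitude `q`. Defaults: `q = 20 pA`, `τ_r = 0.5 ms`,
`τ_d = 3 ms`, sampled at 10 kHz and truncated at `8 τ_d` (< 0.04 % of the
charge lost; the 2 % charge-conservation tolerance used in tests reflects
this truncation plus trapezoidal integration). Event amplitudes are
lognormal with mean `q` and coefficient of variation 0.25 — positive by
construction, matching the right-skewed amplitude distributions of real
mEPSCs.

**Spontaneous release** is a homogeneous Poisson process at `mini_rate`
(per cell). The RNG protocol — one Poisson draw for the count, sorted
uniform times, lognormal amplitudes, Gaussian noise last — is part of the
reproducibility contract and is what the RNG-oracle tests replay.

**Evoked release.** An action potential triggers `n_sync` synchronous
vesicles with Gaussian latencies (mean 1 ms, SD 0.2 ms, truncated at 0)
plus `Poisson(async_count_mean)` asynchronous vesicles with
`Exponential(τ_async)` latencies. Defaults place the synchronous peak
~2 ms after the stimulus and the asynchronous tail at `τ_async = 50 ms`
(single EPSCs); neither duration is constrained by published values, so
both are declared defaults rather than inferred quantities.

**Trains.** A readily releasable pool of `pool_size` vesicles starts
full; pulse *k* releases `Binomial(P_k, p)` synchronously, plus
asynchronous events scaled by that pulse's synchronous release (ratio
`async_count_mean / n_sync`), and the pool refills by `ρ·Δt` vesicles per
interval, capped at the resting size. Defaults `pool_size = 500`,
`p = 0.3`, `ρ = 800 s⁻¹` give ~27 % steady-state rundown at 20 Hz —
typical for hippocampal autapses. Stimulus patterns: 20 Hz × 50 pulses
and 40 Hz × 100 pulses (train lengths are declared defaults, chosen long
enough to reach steady-state release for back-extrapolation).

**Sucrose.** Each pooled vesicle fuses with an `Exponential(τ_suc)`
latency from application onset (`τ_suc = 250 ms`); vesicles recruited
during the application release immediately, forming the steady-state
component. The true RRP charge is `pool_size × q × (kernel charge per pA
of peak)`.

**Expected-value mode** propagates means instead of sampling: synchronous
release becomes one aggregate quantum per pulse and asynchronous release
becomes its expected current (an exponential release-rate density
convolved with the unit-charge kernel). This gives exact closed-form
oracles — geometric depletion per pulse, paired-pulse ratio `1 − p`, an
exactly exponential tail — used throughout the tests.

**Recording noise** is additive white Gaussian, default SD 2 pA. The
generator does not emulate line interference, baseline drift, seal
instability, series-resistance filtering or stimulation artifacts, so
passing tests demonstrate estimator correctness under the stated model,
not robustness to every pathology of real recordings. (The preprocessing
stage still blanks a 1 ms post-stimulus window, so artifact-bearing real
data follow the same code path.)

**Genotype presets.** `WT`: `mini_rate = 1.5 Hz`, `n_sync = 150`,
`async_count_mean = 10`, `τ_async = 50 ms`, 100 synapses. `PL`:
`mini_rate = 9 Hz` (6×), `n_sync = 130`, `async_count_mean = 30`,
`τ_async = 80 ms`, 70 synapses (~30 % fewer, so the per-synapse
spontaneous rate is ~8.6× WT). Quantal parameters, synchronous latency,
release probability, pool size and recruitment are identical, so the
presets encode exactly the pattern of a clamping-deficient mutant:
equal total evoked charge (160 quanta in both), equal total RRP, equal
synchronous kinetics and paired-pulse behaviour, with release
redistributed toward spontaneous and asynchronous modes.

## Estimators

**Preprocessing.** Baseline = mean over the 50 ms before the first
stimulus (from the sweep start for stimulus-free recordings); the 1 ms
after each stimulus onset is replaced by linear interpolation; the trace
is rectified positive-up.

**Bi-exponential decay fit.** Nonlinear least squares from the EPSC peak
to the end of the 500 ms fit window, parameterized in `log τ_fast` and
`log(τ_slow − τ_fast)` so the component ordering holds by construction,
with amplitudes bounded at zero. Initialization matters more than the
optimizer here: a small slow component (a few per cent of the charge)
creates a local minimum in which both time constants collapse onto the
fast decay. Two seeds are therefore tried and the better refined fit
kept: (i) exponential peeling — fit the late tail (beyond 5 fast time
constants or below 5 % of the peak) with a mono-exponential, subtract its
extrapolation, fit the early remainder; (ii) a variable-projection grid —
scan `(τ_fast, τ_slow)` pairs on log grids, solving the amplitudes
linearly. Fits whose slow component contributes < 1 % of the fitted
charge, or whose time constants come within 20 % of each other, are
reported as mono-exponential with `A_slow = 0` (so clean purely
synchronous EPSCs still yield a usable fit). Non-convergence is reported
via `converged=False`, never raised.

**Charge decomposition.** `Q_sync = Q_rise + A_f·τ_f` and
`Q_async = A_s·τ_s`, using the analytic integrals of the fitted
exponentials from the peak to infinity — window-independent by design.
The rise integral starts at stimulus onset (consistent with time-to-peak
being measured from stimulus onset). The fraction is NaN when both
charges vanish.

**Paired-pulse ratio.** The second amplitude is measured after
subtracting the extrapolated bi-exponential decay of the first response;
undefined (NaN) when the first response is absent.

**Train division.** The asynchronous envelope interpolates the mean
current over the 2 ms preceding each stimulus (plus one inter-stimulus
interval after the last); its integral over the train window is the
asynchronous charge and the remainder is synchronous. The tail beyond one
inter-stimulus interval after the last stimulus is reported separately
(`tail_tau`, `tail_charge`) and excluded from the train asynchronous
fraction. The envelope method assumes the asynchronous current is
sustained between pulses; for `τ_async` comparable to the
inter-stimulus interval it underestimates the asynchronous charge (by
`1 − (Δ/τ)·e^(−Δ/τ)/(1 − e^(−Δ/τ))` in steady state, ~7 % relative at
`τ_async = 300 ms` and 20 Hz, ~40 % at `τ_async = 50 ms`). The recovery
tests therefore probe the sustained-async regime (`τ_async = 300 ms`),
where the method is accurate to a few per cent; preset-level comparisons
(WT vs PL) are ratio-based and insensitive to this common-mode bias.
Accordingly, the ground-truth asynchronous fraction for trains is defined
over the same analysis window (first stimulus to one interval past the
last).

**Tail fit.** The post-train tail is carried by discrete quanta, so the
current is smoothed with a boxcar of half an inter-stimulus interval
(a boxcar preserves an exponential's time constant exactly) and fitted
with a mono-exponential until it returns to within twice the smoothed
baseline noise SD. With WT-like parameters the tail amplitude (~3 pA) is
close to the noise floor and single-sweep estimates are noisy; this is a
property of the recording conditions, not the fit.

**Back-extrapolation.** Cumulative per-pulse charge vs time of pulse,
ordinary least squares over the final 25 % of pulses; intercept = RRP
charge, slope = recruitment rate, with `r²` as the diagnostic and a flag
for negative slopes (steady state not reached). On the expected-value
depletion model the intercept overestimates the true pool charge by the
factor `(1 + r)·(1 − (P_∞/P_0)(1 − p))` (r = asynchronous/synchronous
ratio), ≈ 1.0 for the default presets — the basis of the 15 % accuracy
check.

**Sucrose estimate.** Steady state = mean over the final 20 % of the
application; RRP charge = integral of (current − steady state) over the
application window, clipped below at zero. The clip is applied to the
integral, not per sample: per-sample clipping rectifies recording and
shot noise around the steady state and inflated the estimate by ~30 % at
realistic noise levels.

**mEPSC detection.** Noise SD via the MAD of the first difference (a
high-pass filter; exact for white Gaussian noise). The trace is smoothed
with a 0.5 ms boxcar, a running median (50 ms blocks, 5-block median)
absorbs drift and sustained summation, and candidates are local maxima
exceeding `k = 4` noise SDs of the smoothed trace in both height and
prominence (prominence rejects noise ripples riding on event decays),
with a 3 ms minimum separation. A candidate must also clear `k` raw-noise
SDs on the unsmoothed trace, which suppresses smoothed noise excursions —
the residual false-event rate is ~0.01 Hz at the default threshold.
Amplitude is the raw maximum within ±0.5 ms of the peak minus the local
baseline (positively biased by roughly one noise SD; negligible at
SNR ≥ 8). Overlapping events merge into single summed events
deliberately, so the amplitude inflation produced by spurious summation
of independent events at high rates is observable rather than corrected
away; at low rates amplitudes reflect the quantal size. Per-synapse rates
are obtained by dividing by an externally supplied synapse count carried
as metadata (synapse counting itself is out of scope).

**Statistics.** Shapiro–Wilk per group at α; if both pass, a two-sided
F-test at the same α selects Student's vs Welch's t; otherwise
Mann–Whitney U (exact when there are no ties and groups are small,
matching exhaustive permutation enumeration; asymptotic with tie
correction otherwise). Constant samples bypass the normality stage to
Mann–Whitney with a warning. Summaries are mean ± SD on the parametric
branches, median ± MAD otherwise; the MAD is unscaled (no 1.4826
factor). No multiple-testing correction is applied; reports state the
number of comparisons. No outlier exclusion is applied at any stage.

**Cohort recovery harness.** `run_recovery` simulates n cells per
genotype (60 s of minis, a single EPSC, a 50 ms paired pulse, 20 Hz and
40 Hz trains, a 2 s sucrose application each), runs every analysis stage
and compares 13 metrics between genotypes. Directional effects
(spontaneous rate, asynchronous fractions) are asserted via significance
plus fold-change thresholds. Metrics expected to be *unchanged* are
asserted with an equivalence-style check — fold change within 15 % of
unity and no strong evidence of difference (p ≥ 0.01) — because a plain
`p ≥ 0.05` criterion falsely rejects a true null for at least one of five
null metrics in roughly a quarter of cohorts, making it unsound as an
assertion of no-effect.

## Problem sizes

Test and acceptance computations use desk-scale problem sizes chosen to
keep statistical error well inside the asserted tolerances: 20 noise
seeds for fit recovery, 8 × 100 s sweeps per rate for detection (with
recovery measured against the generated ground-truth events, isolating
detector bias from Poisson counting noise), 2000 simulations for the
type-I error of the select-then-test procedure, and cohorts of 30 cells
per genotype for the end-to-end comparison.

## Known limitations

* The generator's noise model is white Gaussian; estimator behaviour
  under correlated noise, drift or artifacts is untested.
* The envelope train division is biased low for fast asynchronous decay
  (`τ_async ≲` the inter-stimulus interval); absolute asynchronous
  fractions from 20 Hz presets are underestimates, though between-group
  ratios are preserved.
* Single-sweep tail time constants near the noise floor (WT-like
  parameters) are unreliable; cohort comparisons of `tail_tau` carry wide
  spread.
* No deconvolution-based release-rate estimation, receptor kinetics,
  facilitation or series-resistance correction; vendor acquisition file
  formats are not read (HDF5/CSV only).
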