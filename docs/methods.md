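# Methods

This note documents the models, conventions and numerical choices behind
`cspgram`: what each estimator computes, what the simulator emulates, and
where the design was genuinely open.

## The chi-square periodogram and its variants

Given an evenly sampled series `X_1 … X_N` (sampling interval Δ hours) and a
candidate period of `P` samples, the points are folded row-major into a grid
with `P` columns (point `i` goes to column `i mod P`). With `X̄_h` the mean
of column `h`, `X̄` the mean of the `N_inc` included points, and `K` the
number of rows, the statistic is

    Q_P = K · N_inc · Σ_h (X̄_h − X̄)² / Σ_i (X_i − X̄)²

— the fraction of included variance captured by the column means, scaled to
be approximately χ²(P − 1) under the null of exchangeable noise. Exactly
`E[Q_P] = N_inc (P − 1)/(N_inc − 1) ≈ P − 1` under the null for the
equal-column variants, which the test suite checks by simulation. The mean
and the denominator run over the *included* points only; for the standard
and conservative variants the trailing `D = N − K·P` points are excluded
from every part of the calculation.

Variants:

- **standard** — `K = floor(N/P)`. As `P` grows, `K` drops by one at every
  `P` where `floor(N/P)` changes; the included-point count changes abruptly
  and the periodogram jumps. `find_k_discontinuities` locates these change
  points analytically (the last `P` before the drop); the largest jump sits
  at a test period of which the recording length is a multiple (22.6, 24.0
  and 25.3 h for 68-, 72- and 76-h recordings at 0.1-h sampling). Because
  the statistic falls at the jump, peak periods just above it collapse onto
  the change point — the pinning bias at exactly 24.0 h in 3 × 24-h
  recordings.
- **conservative** — `K = floor(N/P_max)` for every test period, where
  `P_max` is the largest test period scanned. Discontinuity-free, but the
  statistic depends on the scan range, and discarding up to `N − K·P_min`
  points inflates estimation variance.
- **greedy** — columns keep unequal lengths (row-major fill, so exactly the
  first `N mod P` columns hold one extra point), `D = 0`, and `K = N/P`,
  possibly fractional, enters the prefactor as that exact ratio. All data
  are used and the included set never changes, so the periodogram is smooth.

p-values use the upper χ² tail with `df = P − 1`, computed and stored as
`−log10 p` in log space. For statistics so extreme that the library tail
routine underflows, the standard asymptotic continuation of the regularized
upper incomplete gamma, `ln sf ≈ (s−1) ln y − y − ln Γ(s)` with `s = df/2`,
`y = Q_P/2`, keeps the value finite. Period estimates compare test periods
by p-value, not by raw `Q_P`, because `df` varies with `P`.

The test-period grid is one period per integer sample count in
`[ceil(pmin/Δ), floor(pmax/Δ)]` (default 18–30 h); the CSP has no analogue
of oversampling. Hour-to-sample conversions apply a 1e-9 guard before
floor/ceil so that binary rounding of values like 18/0.1 cannot shift the
grid by one sample. A constant series has an undefined variance ratio and is
rejected as an error rather than mapped to 0/0.

## Spectral baselines

- **Lomb-Scargle** — classical phase-offset (τ) form on mean-subtracted
  data, evaluated on the frequency grid `f_j = j/(ofac·T)` (`T` = duration,
  `ofac` = 100 by default, no zero frequency), restricted to periods inside
  the scan window, and normalized by the sample variance so a dominant pure
  tone peaks near `N/2`. Only the peak location feeds period estimation, so
  the normalization convention is cosmetic downstream.
- **FFT** — mean-subtracted, tapered, zero-padded to `pad·N` points
  (`pad` = 100), power `|rfft|²/N`, argmax over in-window bins with no peak
  interpolation. The taper (10% split-cosine at each end, the classical
  periodogram convention; configurable, 0 disables) matters at circadian
  periods in short recordings: with a rectangular window the negative-
  frequency main lobe of a real tone interferes with the positive one and
  shifts the power peak by several padded bins (~0.4 h for a 3-cycle tone),
  an error the taper suppresses to about one padded bin (~0.08 h at 24 h in
  a 72-h recording).

Both spectral grids refine peak *localization* only; spectral resolution is
set by the record length, and a padded/oversampled argmax always stays
within one coarse bin of the unrefined argmax (tested).

## Simulator

`simulate_timecourse` emulates rhythmic recordings as
`A·f(t − φ) + noise` sampled every Δ = 0.1 h by default:

- waveforms `f` map into [−1, 1]: sine; a smooth sawtooth
  `(1/β) Σ_{k=1..100} sin(2πkt/τ)/k²` with β the numerically computed
  maximum of the partial sum (≈1.0149868 for 100 terms, found by a 1e5-point
  grid scan plus bounded refinement to 1e-10 and cached per term count); and
  a smooth square `arctan(sin(2πt/τ)/δ)/arctan(1/δ)` with δ = 0.2.
- noise is either i.i.d. Gaussian (sd 1 by default) added to `A·f`, or
  Poisson counts with mean `A·f + A + 1 ≥ 1`, the count-data analogue in
  which variance tracks the mean.
- the phase φ is drawn uniformly on `[0, τ)` per replicate (or fixed); the
  sign convention (`f(t − φ)`) is arbitrary and irrelevant to estimation.
- replicates split a root `SeedSequence`, so batches are bit-reproducible
  and replicate streams independent.

Defaults (amplitude 2, 0.1-h sampling, Gaussian sd 1, uniform phase) are the
benchmark conditions used throughout the tests and the acceptance script.
The simulator deliberately omits features of real recordings — damping,
period drift, baseline trends, autocorrelated noise, missing samples — so
passing benchmarks demonstrate estimator behavior under stationary
single-period rhythms, not robustness to those complications.

## Benchmark runner

`run_bias_sweep` crosses lengths × true periods × amplitudes × waveforms ×
noise models, simulates `n` replicates per cell (default 100), applies every
requested method to the *same* replicates, and records signed errors
(estimated − true, so underestimation is negative) plus per-cell summaries:
mean, sd (n−1), mean absolute error, median, and 5th/95th percentiles
(linear interpolation). Ties in a periodogram break toward the smallest test
period; a completely flat periodogram returns the smallest test period with
a warning. A method failing on a replicate records a missing value rather
than aborting the sweep.

## Problem sizes and reproducibility

The acceptance script (`scripts/acceptance.py`) uses 100 replicates per
condition — the same replication as the benchmarks it reproduces — and
derives every stream from the single `--seed` argument through a
`SeedSequence` tree. Discontinuity locations are read off the median
periodogram of the 100 replicates as the largest statistic jump between
adjacent test periods (reported as the left member of the pair), and
cross-checked against the analytic `K` change points. The whole run
completes in well under a minute on one CPU; the test suite runs in about a
minute.

## Known limitations

- Evenly sampled input only; the Lomb-Scargle method could in principle
  accept uneven sampling, but the CSP cannot, and the package enforces even
  sampling at read time.
- On strictly noise-free input the chi-square surface saturates near its
  ceiling and the minimum-p rule (whose df varies with the test period)
  drifts a few grid steps for the conservative and greedy variants; with any
  realistic noise the estimators behave as benchmarked. Noise-free series
  are a degenerate input for p-value-based CSP scoring generally.
- The greedy prefactor `K = N/P` slightly overweights the shorter columns,
  so off-peak `Q_P` can marginally exceed `N`; the effect is part of the
  variant's definition and visible only in noise-free edge cases.
- The standard CSP's pinning is reported here as a distributional ceiling:
  at 72 h with true periods just above 24 h, the modal estimate is exactly
  24.0 h and essentially no estimates exceed it, while noise scatters the
  remainder below — so the cell median can sit one grid step under 24.0.
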