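# cspgram

Period estimation for biological rhythms, built around the chi-square
periodogram (CSP) and its failure modes.

The CSP remains one of the most widely used tools for estimating the
free-running period of circadian rhythms from evenly sampled recordings
(wheel-running counts, bioluminescence traces). It is also biased: its grid
layout changes discontinuously across candidate periods, which makes the
periodogram jump at test periods of which the recording length is a
multiple, and makes the method systematically underestimate periods slightly
longer than 24 h — precisely the regime most circadian experiments live in.
`cspgram` implements the standard CSP, two discontinuity-free revisions
(the *conservative* and *greedy* CSPs), Lomb-Scargle and zero-padded-FFT
baselines, a rhythm simulator, and a Monte-Carlo benchmark runner that
quantifies each method's bias and accuracy. It is intended for
chronobiologists analyzing their own recordings and for methodologists
studying period-estimation accuracy.

## The statistic

For a series of `N` points and a candidate period of `P` samples, the points
are folded row-major into a grid with `P` columns, and

```
Q_P = K · N_inc · Σ_h (X̄_h − X̄)² / Σ_i (X_i − X̄)²
```

where `X̄_h` are the column means, `X̄` and the denominator run over the
`N_inc` points included in the grid, and `K` is the number of rows. Under
the no-rhythm null, `Q_P` is approximately χ² with `P − 1` degrees of
freedom; the estimated period is the test period with the smallest p-value.
The three variants differ only in the grid:

| variant      | K               | omitted points D     | discontinuities |
|--------------|-----------------|----------------------|-----------------|
| standard     | `floor(N/P)`    | `N − K·P`            | yes — K drops as P grows |
| conservative | `floor(N/P_max)`| large, K fixed       | none, but data-hungry |
| greedy       | `N/P` (fractional) | 0 (unequal columns) | none |

The Lomb-Scargle periodogram (oversampling factor 100) and a tapered,
zero-padded FFT (padding factor 100) serve as baselines; both estimate the
period as the power argmax over periods 18–30 h.

## Worked example

Simulate a 3-day recording with a 25-h rhythm and estimate its period with
each CSP variant:

```python
import cspgram as cg

spec = cg.SimulationSpec(waveform="sine", period_h=25.0, amplitude=2.0,
                         length_h=72.0, sampling_interval_h=0.1,
                         noise="gaussian", noise_sd=1.0, seed=3)
tc = cg.simulate_timecourse(spec)
for method in ("standard_csp", "conservative_csp", "greedy_csp", "lomb_scargle"):
    res = cg.estimate_from_timecourse(tc, method, true_period_h=25.0)
    print(f"{method:18s} {res.estimated_period_h:6.2f} h  (error {res.error_h:+.2f} h)")
```

```
standard_csp        24.00 h  (error -1.00 h)
conservative_csp    24.80 h  (error -0.20 h)
greedy_csp          24.80 h  (error -0.20 h)
lomb_scargle        24.83 h  (error -0.17 h)
```

The standard CSP lands on exactly 24.0 h — the recording is 3 × 24 h long,
so the number of complete grid rows drops from 3 to 2 just above a 24-h test
period, the statistic jumps down, and the apparent peak locks to 24.0
("pinning"). The revised variants and the Lomb-Scargle baseline get within
0.2 h of the true 25-h period. The same workflow is
available from the shell via `cspgram simulate`, `cspgram estimate` and
`cspgram sweep` (see `cspgram --help`).

The discontinuity itself can be located analytically:

```python
>>> cg.find_k_discontinuities(720, 180, 300)   # 72 h at 0.1-h sampling
[(180, 4, 3), (240, 3, 2)]                     # K drops after 18.0 h and 24.0 h
```

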