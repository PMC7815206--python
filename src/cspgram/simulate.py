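"""Simulator of rhythmic time-courses.

Emulates circadian recordings as a periodic waveform plus noise. Waveforms
map into [-1, 1]:

``sine``
    sin(2*pi*t / tau).
``smooth_sawtooth``
    (1/beta) * sum_{k=1..n} sin(2*pi*k*t/tau) / k^2 with n = 100 and beta
    the maximum of the partial sum over one cycle (~1.01495), so the
    normalized wave peaks at exactly 1. Approximates the gradual-rise /
    sharp-fall shape of many activity rhythms.
``smooth_square``
    arctan(sin(2*pi*t/tau) / delta) / arctan(1/delta) with delta = 0.2, a
    smoothed on/off profile.

Noise models:

``gaussian``
    value = A * f(t - phase) + eps, eps ~ i.i.d. Normal(0, sd^2), sd 1 by
    default.
``poisson``
    integer counts with mean (and variance) x(t) = A * f(t - phase) + A + 1,
    which is >= 1 by construction; a better model for event counts such as
    wheel revolutions.

Defaults (0.1-h sampling, amplitude 2, Gaussian sd 1, phase uniform on
[0, tau)) are the study conditions used throughout the accuracy benchmarks.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .timecourse import TimeCourse

__all__ = [
    "WAVEFORMS",
    "SimulationSpec",
    "waveform_value",
    "sawtooth_norm_beta",
    "simulate_timecourse",
    "simulate_batch",
]

WAVEFORMS = ("sine", "smooth_sawtooth", "smooth_square")
NOISE_MODELS = ("gaussian", "poisson")

SAWTOOTH_TERMS = 100
SQUARE_DELTA = 0.2

_SAMPLE_EPS = 1e-9


def _sawtooth_partial_sum(u: np.ndarray, n_terms: int) -> np.ndarray:
    """sum_{k=1..n} sin(2*pi*k*u) / k^2 for cycle fraction u."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    k = np.arange(1, n_terms + 1)
    return np.sin(2.0 * np.pi * np.outer(u, k)) @ (1.0 / k**2)


@functools.lru_cache(maxsize=None)
def sawtooth_norm_beta(n_terms: int = SAWTOOTH_TERMS) -> float:
    """Peak of |sum_{k=1..n} sin(2*pi*k*u)/k^2| over one cycle.

    Found by a dense grid scan (1e5 points on [0, 1)) followed by bounded
    golden-section refinement; the result normalizes the smooth sawtooth to
    peak at exactly 1. For n = 100 this is ~1.01495.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    grid = np.linspace(0.0, 1.0, 100_000, endpoint=False)
    vals = np.abs(_sawtooth_partial_sum(grid, n_terms))
    i = int(np.argmax(vals))
    step = grid[1] - grid[0]
    res = minimize_scalar(
        lambda u: -np.abs(_sawtooth_partial_sum(u, n_terms))[0],
        bounds=(grid[i] - step, grid[i] + step),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(max(vals[i], -res.fun))


def waveform_value(kind: str, t, period_h: float):
    """Evaluate a unit-amplitude waveform at time ``t`` hours.

    Vectorized over ``t``; returns values in [-1, 1].
    """
    if period_h <= 0:
        raise ValueError("period_h must be positive")
    t = np.asarray(t, dtype=float)
    phase = 2.0 * np.pi * t / period_h
    if kind == "sine":
        return np.sin(phase)
    if kind == "smooth_sawtooth":
        return _sawtooth_partial_sum(t / period_h, SAWTOOTH_TERMS).reshape(t.shape) / sawtooth_norm_beta(
            SAWTOOTH_TERMS
        )
    if kind == "smooth_square":
        return np.arctan(np.sin(phase) / SQUARE_DELTA) / np.arctan(1.0 / SQUARE_DELTA)
    raise ValueError(f"unknown waveform {kind!r}; expected one of {WAVEFORMS}")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulated rhythmic time-course.

    ``phase_h`` is either a fixed shift in hours or ``"random-uniform"`` for
    a phase drawn uniformly on [0, period_h) — the convention used for the
    Monte-Carlo benchmarks, so estimates do not depend on a lucky alignment.
    The waveform enters as ``f(t - phase_h)``.
    """

    waveform: str = "sine"
    period_h: float = 24.0
    amplitude: float = 2.0
    phase_h: float | str = "random-uniform"
    length_h: float = 72.0
    sampling_interval_h: float = 0.1
    noise: str = "gaussian"
    noise_sd: float = 1.0
    seed: int | np.random.SeedSequence = 0

    def __post_init__(self) -> None:
        if self.waveform not in WAVEFORMS:
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.noise not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.period_h <= 0 or self.length_h <= 0 or self.sampling_interval_h <= 0:
            raise ValueError("period_h, length_h and sampling_interval_h must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.noise == "gaussian" and self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if isinstance(self.phase_h, str) and self.phase_h != "random-uniform":
            raise ValueError("phase_h must be a number or 'random-uniform'")


def simulate_timecourse(spec: SimulationSpec) -> TimeCourse:
    """Draw one time-course; bit-identical for identical spec and seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.phase_h == "random-uniform":
        phase = rng.uniform(0.0, spec.period_h)
    else:
        phase = float(spec.phase_h)
    n = int(np.floor(spec.length_h / spec.sampling_interval_h + _SAMPLE_EPS))
    t = np.arange(n) * spec.sampling_interval_h
    f = waveform_value(spec.waveform, t - phase, spec.period_h)
    if spec.noise == "gaussian":
        values = spec.amplitude * f + rng.normal(0.0, spec.noise_sd, n)
    else:
        values = rng.poisson(spec.amplitude * f + spec.amplitude + 1.0).astype(float)
    return TimeCourse(values=values, sampling_interval_h=spec.sampling_interval_h)


def simulate_batch(
    spec: SimulationSpec,
    n_replicates: int,
    base_seed: int | np.random.SeedSequence | None = None,
) -> list[TimeCourse]:
    """Independent replicates via a deterministic stream split of the seed.

    Replicate ``j`` uses the ``j``-th child of ``SeedSequence(base_seed)``,
    so batches are reproducible and each replicate's stream (including its
    random phase) is independent of the others. ``base_seed`` defaults to
    ``spec.seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if base_seed is None:
        base_seed = spec.seed
    ss = (
        base_seed
        if isinstance(base_seed, np.random.SeedSequence)
        else np.random.SeedSequence(base_seed)
    )
    return [simulate_timecourse(replace(spec, seed=child)) for child in ss.spawn(n_replicates)]
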