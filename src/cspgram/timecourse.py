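"""Evenly sampled rhythm time-courses: container, CSV I/O, and truncation.

The :class:`TimeCourse` is the universal input of this package. All public
times and durations are in hours; sample indices never leak through the API.
Even sampling is a hard requirement of the chi-square periodogram, so it is
enforced at read time rather than deferred to the analysis step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeCourse", "read_timecourse_csv", "write_timecourse_csv", "truncate"]

CSV_HEADER = ("time_h", "value")

# Relative tolerance on spacing irregularity accepted at read time.
_SPACING_RTOL = 1e-6

# Absolute guard applied before floor/ceil on hour->sample conversions, so
# that e.g. 69 h / 0.1 h == 690 samples despite binary rounding.
_SAMPLE_EPS = 1e-9


@dataclass(frozen=True)
class TimeCourse:
    """An evenly sampled univariate time-course.

    Parameters
    ----------
    values
        Measurements (arbitrary units, or nonnegative integer counts for
        Poisson-type data). At least two points.
    sampling_interval_h
        Spacing between consecutive points, in hours. Strictly positive.
    start_time_h
        Time of the first point, in hours. Point ``i`` sits at
        ``start_time_h + i * sampling_interval_h``.
    """

    values: np.ndarray
    sampling_interval_h: float
    start_time_h: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("a time-course needs at least 2 points in a 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("time-course values must be finite")
        if not (self.sampling_interval_h > 0):
            raise ValueError("sampling_interval_h must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sampling_interval_h", float(self.sampling_interval_h))
        object.__setattr__(self, "start_time_h", float(self.start_time_h))

    @property
    def n(self) -> int:
        """Number of time-points."""
        return self.values.size

    @property
    def duration_h(self) -> float:
        """Total duration ``n * sampling_interval_h`` in hours."""
        return self.n * self.sampling_interval_h

    @property
    def times_h(self) -> np.ndarray:
        """Sample times in hours."""
        return self.start_time_h + np.arange(self.n) * self.sampling_interval_h


def read_timecourse_csv(path, sampling_interval_h: float | None = None) -> TimeCourse:
    """Read a two-column ``time_h,value`` CSV into a :class:`TimeCourse`.

    Sampling must be even: every spacing is compared against the median
    spacing with relative tolerance 1e-6, and the first offending row is
    named in the error. The sampling interval is inferred from the median
    spacing unless given explicitly.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if tuple(df.columns[:2]) != CSV_HEADER:
        raise ValueError(
            f"expected header {','.join(CSV_HEADER)!r}, got {','.join(map(str, df.columns[:2]))!r}"
        )
    if len(df) < 2:
        raise ValueError("need at least 2 rows")
    times = df["time_h"].to_numpy(dtype=float)
    values = df["value"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
        raise ValueError("non-numeric or non-finite cell in CSV")
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        i = int(np.argmax(diffs <= 0))
        raise ValueError(f"times not strictly increasing at row index {i + 1}")
    med = float(np.median(diffs))
    bad = np.abs(diffs - med) > _SPACING_RTOL * med
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"uneven sampling at row index {i + 1}: spacing {diffs[i]:g} vs median {med:g} "
            "(the chi-square periodogram requires even sampling)"
        )
    interval = med if sampling_interval_h is None else float(sampling_interval_h)
    return TimeCourse(values=values, sampling_interval_h=interval, start_time_h=float(times[0]))


def write_timecourse_csv(tc: TimeCourse, path) -> None:
    """Write a :class:`TimeCourse` with header ``time_h,value``.

    Floats are written with Python's shortest round-tripping repr, so a
    write/read cycle preserves values bit-exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(CSV_HEADER) + "\n")
        for t, v in zip(tc.times_h, tc.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def truncate(tc: TimeCourse, length_h: float) -> TimeCourse:
    """Keep the first ``floor(length_h / sampling_interval_h)`` points.

    Truncation keeps the earliest points; ``start_time_h`` is unchanged.
    Raises if ``length_h`` exceeds the duration or leaves fewer than 2 points.
    """
    if length_h > tc.duration_h + _SAMPLE_EPS:
        raise ValueError(
            f"length_h={length_h} exceeds time-course duration {tc.duration_h:g} h"
        )
    n_keep = int(np.floor(length_h / tc.sampling_interval_h + _SAMPLE_EPS))
    if n_keep < 2:
        raise ValueError(f"length_h={length_h} leaves fewer than 2 points")
    return TimeCourse(
        values=tc.values[:n_keep],
        sampling_interval_h=tc.sampling_interval_h,
        start_time_h=tc.start_time_h,
    )
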