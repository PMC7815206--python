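"""Chi-square periodogram (CSP) variants for circadian period estimation.

For each candidate (test) period of ``P`` samples, the series of ``N`` points
is folded row-major into a grid with ``P`` columns; the ratio of the variance
of the column means to the variance of the included points yields a statistic

    Q_P = K * N_inc * sum_h (Xbar_h - Xbar)^2 / sum_i (X_i - Xbar)^2

that is approximately chi-square distributed with ``P - 1`` degrees of
freedom under the null of no rhythm. The mean ``Xbar`` and the denominator
run over exactly the points included in the grid (``N_inc``).

Three variants differ only in how the grid is laid out:

``standard``
    K = floor(N / P) complete rows; the trailing D = N - K*P points are
    omitted. K drops by one at test periods of which the time-course length
    is a multiple, producing discontinuities in the periodogram and a
    period-dependent underestimation bias.
``conservative``
    K fixed at floor(N / P_max) for every test period, where P_max is the
    largest test period scanned. No discontinuities, but many points are
    discarded and the statistic depends on the scan range.
``greedy``
    Columns may have unequal lengths: every point is used (D = 0) and
    K = N / P, possibly fractional. No discontinuities, no discarded data.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .timecourse import TimeCourse

__all__ = [
    "CSPVariant",
    "GridLayout",
    "Periodogram",
    "make_layout",
    "qp_statistic",
    "qp_pvalue_neglog10",
    "compute_csp",
    "find_k_discontinuities",
    "largest_discontinuity",
    "median_periodogram",
]

_SAMPLE_EPS = 1e-9

_LN10 = np.log(10.0)


class CSPVariant(str, enum.Enum):
    """The three chi-square periodogram grid conventions."""

    STANDARD = "standard"
    CONSERVATIVE = "conservative"
    GREEDY = "greedy"

    @property
    def method_tag(self) -> str:
        return f"{self.value}_csp"


@dataclass(frozen=True)
class GridLayout:
    """Fold of ``N`` points into ``P_samples`` columns for one test period.

    ``K`` is the (possibly fractional, for greedy) number of rows, ``D`` the
    number of trailing points omitted, ``column_counts[h]`` the number of
    entries averaged in column ``h``, and ``included_count`` their sum.
    Points fill the grid row-major: point ``i`` goes to column ``i mod P``.
    """

    P_samples: int
    K: float
    D: int
    column_counts: np.ndarray
    included_count: int
    variant: CSPVariant


def make_layout(
    N: int,
    P: int,
    variant: CSPVariant | str,
    P_max: int | None = None,
) -> GridLayout:
    """Build the variant-specific grid layout for one test period.

    ``P_max`` (largest test period of the scan, in samples) is required for
    the conservative variant and ignored otherwise.
    """
    variant = CSPVariant(variant)
    if not (1 <= P <= N):
        raise ValueError(f"need 1 <= P <= N, got P={P}, N={N}")

    if variant is CSPVariant.STANDARD:
        K = N // P
        included = K * P
        counts = np.full(P, K, dtype=int)
        return GridLayout(P, float(K), N - included, counts, included, variant)

    if variant is CSPVariant.CONSERVATIVE:
        if P_max is None:
            raise ValueError("conservative layout requires P_max")
        if P > P_max:
            raise ValueError(f"P={P} exceeds P_max={P_max}")
        K = N // P_max
        if K < 1:
            raise ValueError("time-course shorter than test period range")
        included = K * P
        counts = np.full(P, K, dtype=int)
        return GridLayout(P, float(K), N - included, counts, included, variant)

    # greedy: row-major fill, so the first N mod P columns get an extra point
    base, extra = divmod(N, P)
    if base < 1 and extra == 0:
        raise ValueError("time-course shorter than test period range")
    counts = np.full(P, base, dtype=int)
    counts[:extra] += 1
    return GridLayout(P, N / P, 0, counts, N, CSPVariant.GREEDY)


def qp_statistic(tc: TimeCourse, layout: GridLayout) -> tuple[float, int]:
    """Evaluate Q_P and its degrees of freedom for one grid layout.

    Returns ``(Qp, df)`` with ``df = P_samples - 1``. Raises on a constant
    (zero-variance) set of included points.
    """
    x = tc.values
    if x.size < layout.included_count:
        raise ValueError("layout was built for a longer time-course")
    P = layout.P_samples
    n_inc = layout.included_count

    if layout.variant is CSPVariant.GREEDY:
        inc = x
        cols = np.arange(inc.size) % P
        col_means = np.bincount(cols, weights=inc, minlength=P) / layout.column_counts
    else:
        inc = x[:n_inc]
        col_means = inc.reshape(-1, P).mean(axis=0)

    grand = inc.mean()
    denom = float(np.sum((inc - grand) ** 2))
    if denom <= 0.0:
        raise ValueError("degenerate time-course: included points have zero variance")
    qp = layout.K * n_inc * float(np.sum((col_means - grand) ** 2)) / denom
    return qp, P - 1


def qp_pvalue_neglog10(Qp: float, df: int) -> float:
    """-log10 of the upper-tail chi-square probability of ``Qp`` at ``df``.

    Computed in log space, so very significant statistics never underflow
    to p = 0.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    ln_sf = stats.chi2.logsf(Qp, df)
    if not np.isfinite(ln_sf):
        # far tail beyond float range: Gamma(s, y)/Gamma(s) ~ y^(s-1) e^-y / Gamma(s)
        s, y = df / 2.0, Qp / 2.0
        ln_sf = (s - 1.0) * np.log(y) - y - special.gammaln(s)
    return float(-ln_sf / _LN10)


@dataclass(frozen=True)
class Periodogram:
    """Per-test-period arrays produced by one period-estimation method.

    ``statistic`` holds Q_P for CSP methods and spectral power for the
    Lomb-Scargle/FFT baselines; ``df``, ``neg_log10_p``, ``K`` and ``D`` are
    empty for the spectral methods.
    """

    method: str
    test_period_h: np.ndarray
    statistic: np.ndarray
    df: np.ndarray
    neg_log10_p: np.ndarray
    K: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.test_period_h, dtype=float)
        if p.size == 0:
            raise ValueError("empty periodogram")
        if np.any(np.diff(p) <= 0):
            raise ValueError("test_period_h must be strictly increasing")
        object.__setattr__(self, "test_period_h", p)
        object.__setattr__(self, "statistic", np.asarray(self.statistic, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the serialization schema (empty columns become NaN)."""
        n = self.test_period_h.size

        def pad(a):
            a = np.asarray(a, dtype=float)
            return a if a.size == n else np.full(n, np.nan)

        return pd.DataFrame(
            {
                "test_period_h": self.test_period_h,
                "statistic": self.statistic,
                "df": pad(self.df),
                "neg_log10_p": pad(self.neg_log10_p),
                "K": pad(self.K),
                "D": pad(self.D),
                "method": self.method,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _period_grid_samples(tc: TimeCourse, pmin_h: float, pmax_h: float) -> np.ndarray:
    """Integer sample counts whose period in hours lies in [pmin_h, pmax_h]."""
    if not (0 < pmin_h < pmax_h):
        raise ValueError("need 0 < pmin_h < pmax_h")
    dt = tc.sampling_interval_h
    p_lo = int(np.ceil(pmin_h / dt - _SAMPLE_EPS))
    p_hi = int(np.floor(pmax_h / dt + _SAMPLE_EPS))
    if p_hi < p_lo:
        raise ValueError("empty test-period grid")
    return np.arange(max(p_lo, 2), p_hi + 1)


def compute_csp(
    tc: TimeCourse,
    variant: CSPVariant | str,
    pmin_h: float = 18.0,
    pmax_h: float = 30.0,
) -> Periodogram:
    """Chi-square periodogram over one test period per integer sample count.

    Test periods are every integer ``P`` in ``[ceil(pmin_h/dt),
    floor(pmax_h/dt)]`` samples; there is no sub-sample interpolation (the
    CSP has no analogue of oversampling or padding).
    """
    variant = CSPVariant(variant)
    grid = _period_grid_samples(tc, pmin_h, pmax_h)
    P_max = int(grid[-1])
    if P_max > tc.n:
        raise ValueError(
            f"pmax_h={pmax_h} needs {P_max} samples but the time-course has {tc.n}"
        )
    qps = np.empty(grid.size)
    dfs = np.empty(grid.size, dtype=int)
    Ks = np.empty(grid.size)
    Ds = np.empty(grid.size, dtype=int)
    for j, P in enumerate(grid):
        layout = make_layout(tc.n, int(P), variant, P_max=P_max)
        qps[j], dfs[j] = qp_statistic(tc, layout)
        Ks[j] = layout.K
        Ds[j] = layout.D
    neglog = np.array([qp_pvalue_neglog10(q, d) for q, d in zip(qps, dfs)])
    return Periodogram(
        method=variant.method_tag,
        test_period_h=grid * tc.sampling_interval_h,
        statistic=qps,
        df=dfs,
        neg_log10_p=neglog,
        K=Ks,
        D=Ds,
    )


def largest_discontinuity(pg: Periodogram) -> tuple[float, float]:
    """Largest jump of the statistic between adjacent test periods.

    Returns ``(test_period_h, jump)`` where ``test_period_h`` is the left
    (smaller) member of the adjacent pair — i.e. the last test period before
    the jump. The jump magnitude is the absolute difference of the
    statistic; the discontinuity of the standard CSP shows up here because K
    drops between the two test periods.
    """
    if pg.statistic.size < 2:
        raise ValueError("need at least two test periods")
    jumps = np.abs(np.diff(pg.statistic))
    i = int(np.argmax(jumps))
    return float(pg.test_period_h[i]), float(jumps[i])


def median_periodogram(pgs: list[Periodogram]) -> Periodogram:
    """Pointwise median of replicate periodograms sharing one period grid."""
    if not pgs:
        raise ValueError("no periodograms given")
    ref = pgs[0]
    for pg in pgs[1:]:
        if pg.method != ref.method or not np.array_equal(pg.test_period_h, ref.test_period_h):
            raise ValueError("periodograms differ in method or test-period grid")
    stat = np.median([pg.statistic for pg in pgs], axis=0)

    def med(attr):
        arrs = [np.asarray(getattr(pg, attr), dtype=float) for pg in pgs]
        return np.median(arrs, axis=0) if arrs[0].size else np.empty(0)

    return Periodogram(
        method=ref.method,
        test_period_h=ref.test_period_h,
        statistic=stat,
        df=med("df"),
        neg_log10_p=med("neg_log10_p"),
        K=med("K"),
        D=med("D"),
    )


def find_k_discontinuities(
    N: int,
    pmin_samples: int,
    pmax_samples: int,
) -> list[tuple[int, int, int]]:
    """Locate every drop of K = floor(N/P) within a test-period scan.

    Returns ``(P_samples, K_before, K_after)`` tuples ordered by P, where
    ``P_samples`` is the last test period before the drop — the position at
    which the standard CSP's periodogram jumps discontinuously.
    """
    if not (0 < pmin_samples < pmax_samples <= N):
        raise ValueError("need 0 < pmin_samples < pmax_samples <= N")
    Ps = np.arange(pmin_samples, pmax_samples + 1)
    Ks = N // Ps
    drops = np.nonzero(np.diff(Ks) < 0)[0]
    return [(int(Ps[i]), int(Ks[i]), int(Ks[i + 1])) for i in drops]
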