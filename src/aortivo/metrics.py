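"""Stiffness summaries and nonparametric statistics.

Effective Young's moduli are the slopes of proportional fits to
stress-stretch curves over stretch in [1.0, 1.3]; the anisotropy index
normalizes their difference.  Cohort comparisons use medians with
interquartile ranges and the exact one-sided Wilcoxon signed-rank test,
whose null distribution is enumerated over all sign assignments of the
ranked absolute differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .constitutive import MaterialParams, stress_stretch_curve

__all__ = [
    "StiffnessSummary",
    "PairedTestResult",
    "effective_young_modulus",
    "anisotropy_index",
    "relative_error",
    "perimeter_change",
    "median_iqr",
    "wilcoxon_exact",
    "effect_size_r",
    "round_half_away",
]


@dataclass(frozen=True)
class StiffnessSummary:
    """Directional stiffness of one subject, with errors relative to a
    reference (typically the ex vivo fit)."""

    YMc: float  # kPa
    YMa: float  # kPa
    AI: float
    RE_YMc: float | None = None  # percent
    RE_YMa: float | None = None  # percent


@dataclass(frozen=True)
class PairedTestResult:
    """Exact one-sided Wilcoxon signed-rank test outcome."""

    W: float
    p: float
    r: float
    n: int
    alternative: str


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero, the convention of the printed tables."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def effective_young_modulus(
    params: MaterialParams,
    direction: str = "c",
    protocol: str = "equibiaxial",
    grid: np.ndarray | None = None,
) -> float:
    """Effective Young's modulus (kPa): the slope E of the proportional fit
    sigma = E * (lambda - 1) to the stress-stretch curve over [1.0, 1.3].

    The fit is anchored through (1, 0) — stress vanishes at unit stretch —
    so the least-squares slope is E = sum(sigma_i * e_i) / sum(e_i^2) with
    e_i = lambda_i - 1.  Default grid: 31 uniform points on [1.0, 1.3].
    """
    curve = stress_stretch_curve(params, direction=direction, protocol=protocol, grid=grid)
    e = curve[:, 0] - 1.0
    denom = float(np.sum(e * e))
    if denom <= 0:
        raise ValueError("degenerate stretch grid: no spread about lambda = 1")
    return float(np.sum(curve[:, 1] * e) / denom)


def anisotropy_index(YMc: float, YMa: float) -> float:
    """Anisotropy index: (YMc - YMa) / ((YMc + YMa)/2), in (-2, 2)."""
    if YMc <= 0 or YMa <= 0:
        raise ValueError("effective moduli must be positive")
    return (YMc - YMa) / (0.5 * (YMc + YMa))


def relative_error(estimate: float, reference: float) -> float:
    """Signed relative error in percent: 100 * (estimate - reference)/reference."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (estimate - reference) / reference


def perimeter_change(min_cm: float, max_cm: float) -> float:
    """Cyclic perimeter change in percent: 100 * (max - min)/min."""
    if min_cm <= 0:
        raise ValueError("minimum perimeter must be positive")
    if max_cm < min_cm:
        raise ValueError("maximum perimeter below minimum")
    return 100.0 * (max_cm - min_cm) / min_cm


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) by linear interpolation between order statistics
    (quantile position 1 + (n-1)*q)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median of an empty sample is undefined")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W+ = sum of positive-signed ranks under
    uniform sign flips.

    Average ranks of tied magnitudes are half-integers; doubling makes every
    rank an integer, so the 2^n enumeration collapses to a polynomial
    convolution over achievable doubled rank sums.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(counts)
        shifted[d:] = counts[: total + 1 - d]
        counts = counts + shifted
    support = np.arange(total + 1) / 2.0
    return support, counts


def wilcoxon_exact(x_paired, y_paired, alternative: str = "less") -> PairedTestResult:
    """Exact one-sided Wilcoxon signed-rank test on paired samples.

    W is the sum of ranks of the positive differences x - y (average ranks
    for tied magnitudes; zero differences dropped with n reduced).  The
    p-value enumerates the full sign-flip null: P(W* <= W) for
    ``alternative='less'`` and P(W* >= W) for ``'greater'``.  The effect
    size r is derived from p via :func:`effect_size_r`.
    """
    if alternative not in ("less", "greater"):
        raise ValueError(f"alternative must be 'less' or 'greater', got {alternative!r}")
    x = np.asarray(x_paired, dtype=float)
    y = np.asarray(y_paired, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; the test is undefined")
    if n > 25:
        raise ValueError(f"exact enumeration supports n <= 25 pairs, got {n}")
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # average rank, 1-based
        i = j + 1
    W = float(np.sum(ranks[d > 0]))
    support, counts = _signed_rank_distribution(ranks)
    total = counts.sum()
    if alternative == "less":
        p = float(counts[support <= W + 1e-9].sum() / total)
    else:
        p = float(counts[support >= W - 1e-9].sum() / total)
    r = effect_size_r(p, n) if 0.0 < p < 1.0 else float("nan")
    return PairedTestResult(W=W, p=p, r=r, n=n, alternative=alternative)


def effect_size_r(p: float, n: int) -> float:
    """Effect size r = Phi^{-1}(1 - p) / sqrt(n): the standard-normal upper
    quantile of the one-sided p-value, normalized by the pair count."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    if n < 1:
        raise ValueError("n must be at least 1")
    return float(norm.isf(p) / math.sqrt(n))
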