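"""Empirical mode decomposition by sifting with cubic-spline envelopes.

A signal x(t) is modelled as a finite sum of intrinsic mode functions (IMFs)
plus a residual trend,

    x(t) = sum_i IMF_i(t) + r(t),

where each IMF is a locally zero-mean oscillation: its extrema and
zero-crossing counts differ by at most one and the mean of its upper and
lower extrema envelopes is approximately zero. Sifting repeatedly subtracts
the envelope mean from the current candidate,

    h_1 = x(t) - m_1,      h_k = h_{k-1} - m_k,

until the Cauchy-style ratio

    SD = sum_t (h_{k-1}(t) - h_k(t))^2 / sum_t h_{k-1}(t)^2

falls below a threshold (default 0.2). The accepted mode is subtracted and
extraction repeats on the remainder until it is monotone-like (fewer than
two maxima or two minima), which becomes the trend. Completeness,
x = sum IMFs + trend, holds exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "EMDConfig",
    "IMFSet",
    "SiftState",
    "find_extrema",
    "mirror_extrema",
    "natural_spline_eval",
    "spline_envelope",
    "mean_envelope",
    "sift_once",
    "sd_criterion",
    "count_zero_crossings",
    "is_imf",
    "emd",
]


@dataclass(frozen=True)
class EMDConfig:
    """Sifting parameters shared by the univariate and multivariate routines.

    sd_threshold
        Stop sifting when the successive-iterate ratio SD drops below this.
        0.2-0.3 is the range recommended in the original HHT literature.
    max_sift_iters
        Hard cap on sifting iterations per mode (guards non-convergence).
        Typical modes converge within ~10 sifts; the high cap only matters
        for rare riding waves that need long sifting to gain their missing
        zero crossings.
    max_imfs
        Hard cap on extracted modes; the remainder becomes the trend.
    boundary_mirror_count
        Number of extrema mirrored about each end before spline fitting,
        to suppress end swings of the natural spline.
    """

    sd_threshold: float = 0.2
    max_sift_iters: int = 200
    max_imfs: int = 12
    boundary_mirror_count: int = 2

    def __post_init__(self):
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if self.max_sift_iters < 1 or self.max_imfs < 1:
            raise ValueError("iteration caps must be >= 1")
        if self.boundary_mirror_count < 1:
            raise ValueError("boundary_mirror_count must be >= 1")


@dataclass
class IMFSet:
    """Ordered IMFs (fastest first) plus the residual trend."""

    imfs: list[np.ndarray]
    trend: np.ndarray
    sample_rate: float

    @property
    def n(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.trend.copy()
        for m in self.imfs:
            out += m
        return out


@dataclass
class SiftState:
    """One sifting iterate: candidate h_k, iteration count, last mean envelope."""

    h: np.ndarray
    k: int = 1
    m: np.ndarray | None = field(default=None)


def find_extrema(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima.

    Flat plateaus contribute the floor of their midpoint index. A series
    with no sign change in its slope returns empty arrays (monotone-like).
    """
    s = np.asarray(s, dtype=float)
    if s.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    d = np.diff(s)
    # zero slopes (plateaus) are skipped; a slope-sign flip across a plateau
    # places the extremum at the floor of the plateau's midpoint
    nz = np.flatnonzero(d)
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    sign = d[nz] > 0
    flip = sign[1:] != sign[:-1]
    idx = (nz[:-1] + 1 + nz[1:]) // 2
    maxima = idx[flip & sign[:-1]]
    minima = idx[flip & ~sign[:-1]]
    return maxima.astype(int), minima.astype(int)


def mirror_extrema(
    idx: np.ndarray, val: np.ndarray, n: int, count: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reflect up to ``count`` extrema about each end of a length-``n`` series.

    ``val`` may be 1-D (one value per extremum) or 2-D ``(K, C)``; rows are
    mirrored together, which is what the multivariate envelope needs.
    """
    idx = np.asarray(idx)
    if idx.size == 0:
        return idx, val
    k = min(count, idx.size)
    left_idx = (2 * 0 - idx[:k])[::-1]  # reflect about sample 0
    right_idx = (2 * (n - 1) - idx[-k:])[::-1]
    left_val = val[:k][::-1]
    right_val = val[-k:][::-1]
    # degenerate reflections (extremum exactly at the end) would duplicate x
    full_idx = np.concatenate([left_idx, idx, right_idx])
    full_val = np.concatenate([left_val, val, right_val])
    keep = np.concatenate([[True], np.diff(full_idx) > 0])
    return full_idx[keep], full_val[keep]


def natural_spline_eval(xk: np.ndarray, yk: np.ndarray, n: int) -> np.ndarray:
    """Natural cubic spline through knots (xk, yk), evaluated at 0..n-1.

    Direct solution of the tridiagonal second-derivative system (equivalent
    to ``CubicSpline(..., bc_type="natural")`` but without per-call
    construction overhead, which dominates sifting cost). ``yk`` may be
    (K,) or (K, C); evaluation broadcasts over trailing axes.
    """
    xk = np.asarray(xk, dtype=float)
    yk = np.asarray(yk, dtype=float)
    k = xk.size
    x = np.arange(n, dtype=float)
    if k == 2:  # degenerates to the chord
        t = (x - xk[0]) / (xk[1] - xk[0])
        return yk[0] + np.multiply.outer(t, yk[1] - yk[0])
    h = np.diff(xk)  # (k-1,)
    slopes = (yk[1:] - yk[:-1]) / (h[:, None] if yk.ndim == 2 else h)
    # tridiagonal system for interior second derivatives, natural ends M=0
    rhs = 6.0 * (slopes[1:] - slopes[:-1])  # (k-2, ...)
    ab = np.zeros((3, k - 2))
    ab[0, 1:] = h[1:-1]
    ab[1] = 2.0 * (h[:-1] + h[1:])
    ab[2, :-1] = h[1:-1]
    m = np.zeros_like(yk)
    m[1:-1] = solve_banded((1, 1), ab, rhs)
    # piecewise evaluation
    i = np.clip(np.searchsorted(xk, x, side="right") - 1, 0, k - 2)
    hi = h[i]
    a = (xk[i + 1] - x) / hi
    b = (x - xk[i]) / hi
    if yk.ndim == 2:
        a, b, hi = a[:, None], b[:, None], hi[:, None]
    return (
        a * yk[i]
        + b * yk[i + 1]
        + ((a**3 - a) * m[i] + (b**3 - b) * m[i + 1]) * hi**2 / 6.0
    )


def spline_envelope(
    s: np.ndarray, extrema: np.ndarray, boundary: int = 2
) -> np.ndarray | None:
    """Natural cubic spline through the (mirrored) extrema of ``s``.

    Returns None when fewer than two extrema are available, which signals
    sifting termination. With exactly two knots the natural spline
    degenerates to the straight line through them.
    """
    s = np.asarray(s, dtype=float)
    extrema = np.asarray(extrema, dtype=int)
    if extrema.size < 2:
        return None
    idx, val = mirror_extrema(extrema, s[extrema], s.size, boundary)
    if idx.size < 2:
        return None
    return natural_spline_eval(idx, val, s.size)


def mean_envelope(s: np.ndarray, boundary: int = 2) -> np.ndarray | None:
    """Half-sum of the upper and lower spline envelopes, or None if undefined."""
    maxima, minima = find_extrema(s)
    upper = spline_envelope(s, maxima, boundary)
    lower = spline_envelope(s, minima, boundary)
    if upper is None or lower is None:
        return None
    return 0.5 * (upper + lower)


def sift_once(state: SiftState, boundary: int = 2) -> SiftState | None:
    """One sifting step: subtract the envelope mean; None when undefined."""
    m = mean_envelope(state.h, boundary)
    if m is None:
        return None
    return SiftState(h=state.h - m, k=state.k + 1, m=m)


def sd_criterion(h_prev: np.ndarray, h_curr: np.ndarray) -> float:
    """Cauchy-style stopping ratio between successive sifting iterates."""
    h_prev = np.asarray(h_prev, dtype=float)
    h_curr = np.asarray(h_curr, dtype=float)
    if h_prev.shape != h_curr.shape:
        raise ValueError("iterates must have equal length")
    denom = float(np.sum(h_prev**2))
    if denom == 0.0:
        raise ZeroDivisionError("SD undefined for a zero-energy iterate")
    return float(np.sum((h_prev - h_curr) ** 2)) / denom


def count_zero_crossings(s: np.ndarray) -> int:
    """Sign changes between consecutive samples; exact zeros count once.

    Zero samples are dropped before counting, so a run of exact zeros
    between opposite signs contributes a single crossing.
    """
    s = np.asarray(s, dtype=float)
    nz = s[s != 0.0]
    if nz.size < 2:
        return 0
    return int(np.sum(np.signbit(nz[:-1]) != np.signbit(nz[1:])))


def is_imf(
    s: np.ndarray, envelope_tol: float = 0.1, boundary: int = 2
) -> tuple[bool, dict]:
    """Check the intrinsic-mode-function definition.

    True iff (a) extrema and zero-crossing counts differ by at most one and
    (b) the RMS of the mean-envelope series is at most ``envelope_tol``
    times the RMS of the signal. The strict zero-mean-envelope condition is
    never met exactly in finite sampling, hence the relative tolerance.
    """
    s = np.asarray(s, dtype=float)
    maxima, minima = find_extrema(s)
    n_ext = maxima.size + minima.size
    n_zc = count_zero_crossings(s)
    rms = float(np.sqrt(np.mean(s**2)))
    m = mean_envelope(s, boundary)
    m_rms = float(np.sqrt(np.mean(m**2))) if m is not None else np.inf
    diag = {
        "n_extrema": n_ext,
        "n_zero_crossings": n_zc,
        "envelope_rms_ratio": (m_rms / rms) if rms > 0 else np.inf,
    }
    ok = (
        abs(n_ext - n_zc) <= 1
        and rms > 0
        and m is not None
        and m_rms <= envelope_tol * rms
    )
    return ok, diag


def _monotone_like(s: np.ndarray) -> bool:
    maxima, minima = find_extrema(s)
    return maxima.size < 2 or minima.size < 2


def emd(
    x: np.ndarray, sample_rate: float = 1.0, config: EMDConfig | None = None
) -> IMFSet:
    """Decompose ``x`` into IMFs plus a trend.

    Deterministic: identical input and config give bit-identical output.
    """
    cfg = config or EMDConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("signal must be 1-D with length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")

    imfs: list[np.ndarray] = []
    residual = x.copy()
    while len(imfs) < cfg.max_imfs and not _monotone_like(residual):
        h = residual.copy()
        for _ in range(cfg.max_sift_iters):
            m = mean_envelope(h, cfg.boundary_mirror_count)
            if m is None:
                break
            h_new = h - m
            energy = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2)) / energy if energy > 0 else 0.0
            h = h_new
            if sd < cfg.sd_threshold and is_imf(h, boundary=cfg.boundary_mirror_count)[0]:
                break
        imfs.append(h)
        residual = residual - h
    return IMFSet(imfs=imfs, trend=residual, sample_rate=sample_rate)
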