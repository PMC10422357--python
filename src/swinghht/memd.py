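"""Multivariate empirical mode decomposition (MEMD).

A C-channel signal (e.g. the three Euler angles of one joint) is decomposed
jointly so that every channel receives the same number of aligned modes: the
local mean is estimated by projecting the signal onto a quasi-uniform set of
direction vectors on the (C-1)-sphere, locating the extrema of each scalar
projection, interpolating the full C-dimensional signal through those
extrema times (upper and lower envelopes per direction, averaged), and
averaging the per-direction envelopes. Sifting then proceeds exactly as in
the univariate case, with the stopping ratio

    SD = sum_{t,c} (h_{k-1} - h_k)^2 / sum_{t,c} h_{k-1}^2

computed over the stacked channels. Direction vectors come from a Hammersley
low-discrepancy point set, so the whole decomposition is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .emd import EMDConfig, find_extrema, mirror_extrema, natural_spline_eval

__all__ = [
    "MEMDConfig",
    "DirectionSet",
    "MultiIMFSet",
    "direction_vectors",
    "multivariate_mean_envelope",
    "memd",
]

_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47)


@dataclass(frozen=True)
class MEMDConfig(EMDConfig):
    """EMD parameters plus the projection-direction count.

    n_directions defaults to max(64, 8*C); 0 selects that rule at call time.
    """

    n_directions: int = 0

    def resolved_directions(self, n_channels: int) -> int:
        if self.n_directions > 0:
            return self.n_directions
        return max(64, 8 * n_channels)


@dataclass(frozen=True)
class DirectionSet:
    """Quasi-uniform unit vectors on the (C-1)-sphere."""

    vectors: np.ndarray  # (D, C), rows unit-norm
    generator: str = "hammersley"

    def __post_init__(self):
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("direction vectors must have unit norm")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


@dataclass
class MultiIMFSet:
    """Aligned modes: ``imfs[i]`` is the (T, C) i-th mode of every channel."""

    imfs: list[np.ndarray]
    trend: np.ndarray  # (T, C)
    sample_rate: float

    @property
    def n(self) -> int:
        return len(self.imfs)

    @property
    def n_channels(self) -> int:
        return self.trend.shape[1]

    def channel(self, c: int):
        """Per-channel view as (list of 1-D imfs, 1-D trend)."""
        return [m[:, c] for m in self.imfs], self.trend[:, c]

    def reconstruct(self) -> np.ndarray:
        out = self.trend.copy()
        for m in self.imfs:
            out += m
        return out


def _van_der_corput(n: int, base: int) -> np.ndarray:
    """First n points of the radical-inverse (van der Corput) sequence."""
    out = np.zeros(n)
    for i in range(n):
        f, denom, k = 0.0, 1.0, i + 1
        while k > 0:
            k, r = divmod(k, base)
            denom *= base
            f += r / denom
        out[i] = f
    return out


def direction_vectors(n_channels: int, n_directions: int) -> DirectionSet:
    """Hammersley point set on the unit (C-1)-sphere.

    C=2 uses evenly spaced angles; C=3 the area-preserving cylindrical map
    of the 2-D Hammersley set (z = 2u - 1, azimuth = 2*pi*v), which keeps
    nearest-neighbour spacing far tighter than generic maps; higher C falls
    back to the inverse-Gaussian-CDF map of the hypercube set. Deterministic
    for fixed (C, D).
    """
    if n_channels < 2:
        raise ValueError("MEMD needs at least 2 channels")
    if n_directions < 2 * n_channels:
        raise ValueError("need at least 2*C directions")
    d = n_directions
    if n_channels == 2:
        ang = 2 * np.pi * (np.arange(d) + 0.5) / d
        vecs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    elif n_channels == 3:
        u = (np.arange(d) + 0.5) / d
        v = _van_der_corput(d, 2)
        z = 2 * u - 1
        rho = np.sqrt(np.clip(1 - z**2, 0.0, 1.0))
        phi = 2 * np.pi * v
        vecs = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    else:
        from scipy.special import ndtri

        cube = np.empty((d, n_channels))
        cube[:, 0] = (np.arange(d) + 0.5) / d
        for c in range(1, n_channels):
            cube[:, c] = _van_der_corput(d, _PRIMES[(c - 1) % len(_PRIMES)])
        gauss = ndtri(np.clip(cube, 1e-12, 1 - 1e-12))
        vecs = gauss / np.linalg.norm(gauss, axis=1, keepdims=True)
    vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    return DirectionSet(vectors=vecs)


def _envelope_through(
    sig: np.ndarray, knots: np.ndarray, boundary: int
) -> np.ndarray | None:
    """Spline of the full (T, C) signal through the given time indices."""
    if knots.size < 2:
        return None
    idx, val = mirror_extrema(knots, sig[knots], sig.shape[0], boundary)
    if idx.size < 2:
        return None
    return natural_spline_eval(idx, val, sig.shape[0])


def multivariate_mean_envelope(
    sig: np.ndarray, dirs: DirectionSet, boundary: int = 2
) -> np.ndarray | None:
    """Local mean of a (T, C) signal, averaged over projection directions.

    Directions whose projection lacks two maxima or two minima are skipped;
    None is returned when every direction is skipped (termination signal).
    """
    proj = sig @ dirs.vectors.T  # (T, D)
    total = np.zeros_like(sig)
    used = 0
    for k in range(dirs.n):
        maxima, minima = find_extrema(proj[:, k])
        if maxima.size < 2 or minima.size < 2:
            continue
        upper = _envelope_through(sig, maxima, boundary)
        lower = _envelope_through(sig, minima, boundary)
        if upper is None or lower is None:
            continue
        total += 0.5 * (upper + lower)
        used += 1
    if used == 0:
        return None
    return total / used


def memd(
    signal: np.ndarray,
    sample_rate: float = 1.0,
    config: MEMDConfig | None = None,
) -> MultiIMFSet:
    """Jointly decompose a (T, C) multichannel signal.

    Every channel receives the same number of modes (the defining MEMD
    property); per-channel completeness holds by construction. Deterministic
    for a fixed config.
    """
    cfg = config or MEMDConfig()
    sig = np.asarray(signal, dtype=float)
    if sig.ndim != 2 or sig.shape[1] < 2:
        raise ValueError("signal must be (T, C) with C >= 2")
    if sig.shape[0] < 8:
        raise ValueError("signal too short to decompose")
    if not np.all(np.isfinite(sig)):
        raise ValueError("signal contains non-finite samples")

    dirs = direction_vectors(sig.shape[1], cfg.resolved_directions(sig.shape[1]))

    imfs: list[np.ndarray] = []
    residual = sig.copy()
    while len(imfs) < cfg.max_imfs:
        m = multivariate_mean_envelope(residual, dirs, cfg.boundary_mirror_count)
        if m is None:
            break  # residual is monotone-like in all directions -> trend
        h = residual.copy()
        for _ in range(cfg.max_sift_iters):
            m = multivariate_mean_envelope(h, dirs, cfg.boundary_mirror_count)
            if m is None:
                break
            h_new = h - m
            energy = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2)) / energy if energy > 0 else 0.0
            h = h_new
            if sd < cfg.sd_threshold:
                break
        imfs.append(h)
        residual = residual - h
    return MultiIMFSet(imfs=imfs, trend=residual, sample_rate=sample_rate)
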