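"""Swing-analysis pipeline: per-joint aggregation, impact synchronization,
ensemble averaging, frequency statistics, and group comparison.

The analysis flow for one trajectory group:

1. decompose each swing's joint (three Euler channels) with MEMD;
2. Hilbert-transform every mode of every channel;
3. collapse the three channels per mode into one joint spectrum:
   amplitude(t) = sqrt(Ax^2 + Ay^2 + Az^2) (Euler axes are orthogonal),
   frequency(t) = mean of the defined channel frequencies;
4. synchronize all swings of the group at the impact frame and trim to the
   smallest common window centered on impact;
5. average frequency and amplitude pointwise across the swings;
6. summarise per-IMF instantaneous frequency as mean, SD and CV = SD/mean.

Comparing a slice group against the straight group reduces to a per-joint
ratio of mean aggregated amplitude in a short pre-impact window; joints
whose ratio exceeds a threshold are flagged as candidate trigger joints
(head-up -> neck, body opening -> lead hip and knee).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .hht import AnalyticMode, HilbertSpectrum, analyze_mode, build_spectrum, default_freq_edges
from .memd import MEMDConfig, MultiIMFSet, memd

__all__ = [
    "JointSpectrum",
    "SwingEnsemble",
    "round_half_up",
    "decompose_joint",
    "aggregate_joint",
    "synchronize",
    "average_ensemble",
    "imf_frequency_stats",
    "build_ensemble",
    "compare_groups",
]

#: default pre-impact window (s) for the excess report
PRE_IMPACT_WINDOW_S = 0.25
#: default amplitude-ratio threshold above which a joint is flagged
EXCESS_RATIO_THRESHOLD = 1.5
#: instantaneous-frequency band (Hz) of actual movement: slice-triggering
#: motions live in the few-to-few-tens-of-Hz modes, while the slowest modes
#: carry posture drift whose leakage would swamp a pre-impact statistic
EXCESS_BAND_HZ = (2.0, 35.0)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.125 -> 0.13), matching printed-table style."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class JointSpectrum:
    """Per-joint, per-mode instantaneous frequency and aggregated amplitude.

    ``frequency[i]`` and ``amplitude[i]`` are the length-T series of mode i
    (fastest first); amplitude is the Euclidean aggregate over the three
    Euler channels (degrees), frequency the across-channel mean (Hz).
    """

    joint: str
    frequency: list[np.ndarray]
    amplitude: list[np.ndarray]
    sample_rate: float
    impact_index: int

    def __post_init__(self):
        if len(self.frequency) != len(self.amplitude):
            raise ValueError("frequency and amplitude must have equal mode counts")
        lengths = {a.size for a in self.frequency} | {a.size for a in self.amplitude}
        if len(lengths) > 1:
            raise ValueError(f"mode series have unequal lengths: {sorted(lengths)}")
        for a in self.amplitude:
            if np.any(a < 0):
                raise ValueError("aggregated amplitude must be non-negative")
        if self.n_modes and not 0 <= self.impact_index < self.n_samples:
            raise ValueError("impact index outside the series")

    @property
    def n_modes(self) -> int:
        return len(self.frequency)

    @property
    def n_samples(self) -> int:
        return self.frequency[0].size if self.frequency else 0

    @property
    def time_axis(self) -> np.ndarray:
        """Seconds, zero at impact."""
        return (np.arange(self.n_samples) - self.impact_index) / self.sample_rate

    def trimmed(self, pre: int, post: int) -> "JointSpectrum":
        lo = self.impact_index - pre
        hi = self.impact_index + post + 1
        if lo < 0 or hi > self.n_samples:
            raise ValueError("window extends beyond the recorded samples")
        return JointSpectrum(
            joint=self.joint,
            frequency=[f[lo:hi].copy() for f in self.frequency],
            amplitude=[a[lo:hi].copy() for a in self.amplitude],
            sample_rate=self.sample_rate,
            impact_index=pre,
        )

    def truncated_modes(self, n: int) -> "JointSpectrum":
        return JointSpectrum(
            joint=self.joint,
            frequency=self.frequency[:n],
            amplitude=self.amplitude[:n],
            sample_rate=self.sample_rate,
            impact_index=self.impact_index,
        )

    def total_amplitude(self) -> np.ndarray:
        """Summed aggregated amplitude over modes, per time sample."""
        return np.sum(self.amplitude, axis=0) if self.n_modes else np.zeros(0)

    def to_spectrum(self, freq_edges: np.ndarray | None = None) -> HilbertSpectrum:
        return build_spectrum(
            list(zip(self.frequency, self.amplitude)),
            time_axis=self.time_axis,
            freq_edges=freq_edges if freq_edges is not None else default_freq_edges(),
            impact_time=0.0,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, imf, frequency_hz, amplitude_deg) table."""
        t = self.time_axis
        rows = []
        for i in range(self.n_modes):
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": t,
                        "imf": i + 1,
                        "frequency_hz": self.frequency[i],
                        "amplitude_deg": self.amplitude[i],
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=["time_s", "imf", "frequency_hz", "amplitude_deg"])
        return pd.concat(rows, ignore_index=True)


def decompose_joint(
    euler: np.ndarray, sample_rate: float, config: MEMDConfig | None = None
) -> MultiIMFSet:
    """MEMD of one joint's (T, 3) Euler-angle series."""
    return memd(euler, sample_rate=sample_rate, config=config)


def aggregate_joint(
    modes: MultiIMFSet,
    joint: str,
    impact_index: int,
) -> JointSpectrum:
    """Collapse aligned per-channel modes into one joint spectrum.

    Per mode: amplitude(t) is the Euclidean norm of the channel amplitudes
    (a channel that is identically zero simply contributes nothing);
    frequency(t) averages the channels whose frequency is defined at t.
    """
    sr = modes.sample_rate
    freqs: list[np.ndarray] = []
    amps: list[np.ndarray] = []
    for m in modes.imfs:
        ana: list[AnalyticMode] = [analyze_mode(m[:, c], sr) for c in range(m.shape[1])]
        amp = np.sqrt(np.sum([a.amplitude**2 for a in ana], axis=0))
        stack = np.vstack([a.frequency for a in ana])
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(stack, axis=0)
        freqs.append(freq)
        amps.append(amp)
    return JointSpectrum(
        joint=joint, frequency=freqs, amplitude=amps, sample_rate=sr, impact_index=impact_index
    )


def synchronize(
    swings: list[dict[str, JointSpectrum]],
) -> tuple[int, int, list[dict[str, JointSpectrum]]]:
    """Align swings at the impact sample and trim to the common window.

    pre  = min over swings of the impact index,
    post = min over swings of (length - 1 - impact index);

    every swing is trimmed to [impact-pre, impact+post], so all trimmed
    swings share length pre+post+1 with the impact at index pre. Returns
    (pre, post, trimmed swings).
    """
    if not swings:
        raise ValueError("need at least one swing")
    pres, posts = [], []
    for sw in swings:
        for js in sw.values():
            if not 0 <= js.impact_index < js.n_samples:
                raise ValueError(f"{js.joint}: impact outside the recorded frames")
            pres.append(js.impact_index)
            posts.append(js.n_samples - 1 - js.impact_index)
    pre, post = min(pres), min(posts)
    trimmed = [{name: js.trimmed(pre, post) for name, js in sw.items()} for sw in swings]
    return pre, post, trimmed


def sync_window(lengths_impacts: list[tuple[int, int]]) -> tuple[int, int, int]:
    """Window arithmetic on bare (length, impact) pairs.

    Returns (pre, post, trimmed_length); the trimming rule applied to a
    capture log without touching the signals themselves.
    """
    if not lengths_impacts:
        raise ValueError("need at least one (length, impact) pair")
    for length, impact in lengths_impacts:
        if not 0 <= impact < length:
            raise ValueError(f"impact {impact} outside [0, {length})")
    pre = min(impact for _, impact in lengths_impacts)
    post = min(length - 1 - impact for length, impact in lengths_impacts)
    return pre, post, pre + post + 1


def average_ensemble(members: list[JointSpectrum]) -> JointSpectrum:
    """Pointwise mean of frequency and amplitude across synchronized members.

    Mode counts are reconciled to the shared minimum (modes are aligned by
    index from the fastest mode down). Frequencies average with NaN-skip;
    a sample is NaN only where every member is undefined.
    """
    if not members:
        raise ValueError("need at least one member")
    lengths = {m.n_samples for m in members}
    impacts = {m.impact_index for m in members}
    if len(lengths) > 1 or len(impacts) > 1:
        raise ValueError("members must be synchronized (equal length and impact index) first")
    n_modes = min(m.n_modes for m in members)
    members = [m.truncated_modes(n_modes) for m in members]
    freq, amp = [], []
    for i in range(n_modes):
        f = np.vstack([m.frequency[i] for m in members])
        a = np.vstack([m.amplitude[i] for m in members])
        with np.errstate(invalid="ignore"):
            freq.append(np.nanmean(f, axis=0))
        amp.append(a.mean(axis=0))
    first = members[0]
    return JointSpectrum(
        joint=first.joint,
        frequency=freq,
        amplitude=amp,
        sample_rate=first.sample_rate,
        impact_index=first.impact_index,
    )


@dataclass
class SwingEnsemble:
    """Impact-synchronized swings of one trajectory class, plus averages.

    ``members[k][joint]`` is swing k's trimmed spectrum; ``averaged[joint]``
    the pointwise ensemble mean; ``imf_stats`` the per-IMF instantaneous-
    frequency summary (mean, SD, CV) pooled over time and members.
    """

    label: str
    members: list[dict[str, JointSpectrum]]
    pre: int
    post: int
    averaged: dict[str, JointSpectrum] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def window_length(self) -> int:
        return self.pre + self.post + 1

    @property
    def joints(self) -> list[str]:
        return list(self.members[0].keys()) if self.members else []


def build_ensemble(label: str, swings: list[dict[str, JointSpectrum]]) -> SwingEnsemble:
    """Synchronize, reconcile mode counts, and average one trajectory group."""
    pre, post, trimmed = synchronize(swings)
    ens = SwingEnsemble(label=label, members=trimmed, pre=pre, post=post)
    for joint in ens.joints:
        ens.averaged[joint] = average_ensemble([sw[joint] for sw in trimmed])
    return ens


def imf_frequency_stats(
    ensemble: SwingEnsemble, joint: str, ddof: int = 1
) -> pd.DataFrame:
    """Per-IMF mean, SD and CV of instantaneous frequency for one joint.

    Statistics pool over time samples and ensemble members (their stated
    purpose is cross-swing variability). CV = SD/mean; rows with zero mean
    report CV as NaN. The ``*_2dp`` columns carry the round-half-up
    2-decimal presentation used in printed tables.
    """
    if ensemble.n_members < 2:
        raise ValueError("need at least two members for an SD")
    n_modes = min(sw[joint].n_modes for sw in ensemble.members)
    rows = []
    for i in range(n_modes):
        pooled = np.concatenate([sw[joint].frequency[i] for sw in ensemble.members])
        pooled = pooled[~np.isnan(pooled)]
        mean = float(pooled.mean())
        sd = float(pooled.std(ddof=ddof))
        cv = sd / mean if mean != 0 else np.nan
        rows.append(
            {
                "imf": i + 1,
                "mean_hz": mean,
                "sd_hz": sd,
                "cv": cv,
                "mean_2dp": round_half_up(mean),
                "sd_2dp": round_half_up(sd),
                "cv_2dp": round_half_up(cv) if np.isfinite(cv) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("imf")


def pre_impact_mean_amplitude(
    js: JointSpectrum,
    window_s: float = PRE_IMPACT_WINDOW_S,
    band_hz: tuple[float, float] = EXCESS_BAND_HZ,
) -> float:
    """Mean movement-band amplitude over [impact - window_s, impact).

    Per time sample, amplitudes of modes whose instantaneous frequency lies
    inside ``band_hz`` are summed; posture-drift modes (below the band) and
    out-of-band artifacts are excluded, then the window is averaged.
    """
    k = int(round(window_s * js.sample_rate))
    lo = max(0, js.impact_index - k)
    if js.impact_index - lo < 1:
        raise ValueError("pre-impact window is empty")
    total = np.zeros(js.impact_index - lo)
    for f, a in zip(js.frequency, js.amplitude):
        f = f[lo : js.impact_index]
        a = a[lo : js.impact_index]
        in_band = (f >= band_hz[0]) & (f <= band_hz[1])
        total += np.where(in_band, a, 0.0)
    return float(total.mean())


def compare_groups(
    baseline: SwingEnsemble,
    candidate: SwingEnsemble,
    window_s: float = PRE_IMPACT_WINDOW_S,
    threshold: float = EXCESS_RATIO_THRESHOLD,
    band_hz: tuple[float, float] = EXCESS_BAND_HZ,
) -> pd.DataFrame:
    """Pre-impact excess report: candidate vs. baseline, per joint.

    For each joint the ratio of mean aggregated amplitude in the pre-impact
    window (candidate/baseline, on the averaged spectra) is computed; joints
    with ratio above ``threshold`` are flagged as candidate trigger joints.
    Descriptive, not inferential: no hypothesis test is attached.

    The two groups are trimmed independently (their windows may differ by a
    few frames); the comparison only requires that both windows cover the
    pre-impact interval, since the ratio is evaluated on [impact - window_s,
    impact) of each group's averaged spectrum.
    """
    if set(baseline.joints) != set(candidate.joints):
        raise ValueError("ensembles must share the same joint set")
    for ens in (baseline, candidate):
        sr = next(iter(ens.averaged.values())).sample_rate
        if ens.pre < int(round(window_s * sr)):
            raise ValueError(
                f"group {ens.label!r}: trimmed window has only {ens.pre} pre-impact "
                f"frames, fewer than the {window_s} s comparison window"
            )
    rows = []
    for joint in baseline.joints:
        a = pre_impact_mean_amplitude(baseline.averaged[joint], window_s, band_hz)
        b = pre_impact_mean_amplitude(candidate.averaged[joint], window_s, band_hz)
        ratio = b / a if a > 0 else np.inf
        rows.append(
            {
                "joint": joint,
                "baseline_amp_deg": a,
                "candidate_amp_deg": b,
                "ratio": ratio,
                "flagged": bool(ratio > threshold),
            }
        )
    return pd.DataFrame(rows).set_index("joint")
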