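"""Model/Results front end for the swing analysis.

``SwingAnalysis`` is constructed from motion clips grouped by trajectory
label (or straight from a BVH directory plus a metadata CSV); ``fit()``
runs decomposition -> Hilbert layer -> aggregation -> synchronization ->
ensemble averaging for every group and returns a ``SwingAnalysisResults``
carrying the ensembles, the per-IMF frequency statistics, diagnostics and a
``summary()`` table. Group comparisons, spectra and plots hang off the
results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pipeline
from .bvh import MotionClip, read_bvh_file, select_joints
from .hht import default_freq_edges
from .memd import MEMDConfig
from .pipeline import (
    EXCESS_RATIO_THRESHOLD,
    PRE_IMPACT_WINDOW_S,
    JointSpectrum,
    SwingEnsemble,
    aggregate_joint,
    build_ensemble,
    decompose_joint,
    imf_frequency_stats,
    round_half_up,
)
from .reference import IMPORTANT_JOINTS

__all__ = ["AnalysisConfig", "SwingAnalysis", "SwingAnalysisResults", "read_metadata"]


@dataclass(frozen=True)
class AnalysisConfig(MEMDConfig):
    """All tunables of the analysis in one place.

    Inherits the sifting/direction parameters; adds the joint-stacking mode
    (``per_joint``: one MEMD call per joint's three Euler channels;
    ``pooled``: all selected joints' channels stacked into one call — the
    sensitivity-analysis variant), the spectrum axis, and the pre-impact
    excess-report window and threshold.
    """

    joint_stacking: str = "per_joint"
    freq_max_hz: float = 40.0
    freq_bin_hz: float = 0.5
    pre_impact_window_s: float = PRE_IMPACT_WINDOW_S
    excess_threshold: float = EXCESS_RATIO_THRESHOLD

    def __post_init__(self):
        super().__post_init__()
        if self.joint_stacking not in ("per_joint", "pooled"):
            raise ValueError("joint_stacking must be 'per_joint' or 'pooled'")
        if self.freq_max_hz <= 0 or self.freq_bin_hz <= 0:
            raise ValueError("frequency axis parameters must be positive")

    def freq_edges(self) -> np.ndarray:
        return default_freq_edges(self.freq_max_hz, self.freq_bin_hz)


def read_metadata(meta_csv) -> pd.DataFrame:
    """Read the swings sidecar (path, impact_frame, label)."""
    meta = pd.read_csv(meta_csv)
    missing = {"path", "impact_frame", "label"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing column(s): {sorted(missing)}")
    return meta


class SwingAnalysis:
    """The swing-comparison model: clips grouped by trajectory label.

    Parameters
    ----------
    clips : list of MotionClip
        Each clip must carry an impact_frame and a label.
    joints : sequence of str, optional
        Joints to analyze; defaults to the head/lead-side set
        (Neck, LeftArm, LeftUpLeg, LeftLeg).
    config : AnalysisConfig, optional
    """

    def __init__(self, clips, joints=None, config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        joints = list(joints) if joints is not None else list(IMPORTANT_JOINTS)
        if not clips:
            raise ValueError("no clips supplied")
        for clip in clips:
            if clip.impact_frame is None:
                raise ValueError("every clip needs an impact_frame annotation")
        self.clips = [select_joints(c, joints) for c in clips]
        self.joints = joints

    @classmethod
    def from_dataset(cls, bvh_dir, meta_csv=None, joints=None, config=None):
        """Build from a directory of BVH files plus a metadata CSV.

        ``meta_csv`` defaults to ``<bvh_dir>/swings.csv``. Paths in the CSV
        resolve relative to the directory.
        """
        bvh_dir = Path(bvh_dir)
        meta = read_metadata(meta_csv if meta_csv is not None else bvh_dir / "swings.csv")
        clips = []
        for rec in meta.itertuples():
            path = bvh_dir / rec.path
            if not path.exists():
                raise FileNotFoundError(f"metadata names a missing file: {path}")
            clips.append(
                read_bvh_file(path, impact_frame=int(rec.impact_frame), label=str(rec.label))
            )
        return cls(clips, joints=joints, config=config)

    # -- fitting ---------------------------------------------------------

    def _joint_spectra(self, clip: MotionClip) -> dict[str, JointSpectrum]:
        cfg = self.config
        if cfg.joint_stacking == "pooled":
            stacked = np.hstack([clip.euler[j] for j in self.joints])
            modes = decompose_joint(stacked, clip.frame_rate, cfg)
            out = {}
            for k, joint in enumerate(self.joints):
                sub = type(modes)(
                    imfs=[m[:, 3 * k : 3 * k + 3] for m in modes.imfs],
                    trend=modes.trend[:, 3 * k : 3 * k + 3],
                    sample_rate=modes.sample_rate,
                )
                out[joint] = aggregate_joint(sub, joint, clip.impact_frame)
            return out
        return {
            joint: aggregate_joint(
                decompose_joint(clip.euler[joint], clip.frame_rate, cfg),
                joint,
                clip.impact_frame,
            )
            for joint in self.joints
        }

    def fit(self) -> "SwingAnalysisResults":
        """Decompose every swing and assemble per-label ensembles."""
        by_label: dict[str, list[dict[str, JointSpectrum]]] = {}
        for clip in self.clips:
            by_label.setdefault(clip.label, []).append(self._joint_spectra(clip))
        ensembles = {
            label: build_ensemble(label, swings) for label, swings in by_label.items()
        }
        return SwingAnalysisResults(model=self, ensembles=ensembles)


@dataclass
class SwingAnalysisResults:
    """Fitted ensembles plus the derived statistics and reports."""

    model: SwingAnalysis
    ensembles: dict[str, SwingEnsemble]
    _stats_cache: dict = field(default_factory=dict, repr=False)

    @property
    def labels(self) -> list[str]:
        return list(self.ensembles)

    @property
    def joints(self) -> list[str]:
        return self.model.joints

    def frequency_stats(self, label: str, joint: str) -> pd.DataFrame:
        """Per-IMF mean/SD/CV of instantaneous frequency (pooled over time
        and swings) for one group and joint."""
        key = (label, joint)
        if key not in self._stats_cache:
            self._stats_cache[key] = imf_frequency_stats(self.ensembles[label], joint)
        return self._stats_cache[key]

    def sync_summary(self) -> pd.DataFrame:
        """Per-group window bookkeeping (members, trimmed length, impact)."""
        rows = []
        for label, ens in self.ensembles.items():
            rows.append(
                {
                    "label": label,
                    "n_swings": ens.n_members,
                    "window_frames": ens.window_length,
                    "impact_index": ens.pre,
                    "window_s": round_half_up(
                        ens.window_length / self._sample_rate(ens), 2
                    ),
                }
            )
        return pd.DataFrame(rows).set_index("label")

    @staticmethod
    def _sample_rate(ens: SwingEnsemble) -> float:
        return next(iter(ens.averaged.values())).sample_rate

    def spectrum(self, label: str, joint: str):
        """Averaged Hilbert spectrum of one group/joint."""
        return self.ensembles[label].averaged[joint].to_spectrum(
            self.model.config.freq_edges()
        )

    def compare(self, baseline: str, candidate: str) -> pd.DataFrame:
        """Pre-impact excess report of ``candidate`` against ``baseline``."""
        cfg = self.model.config
        return pipeline.compare_groups(
            self.ensembles[baseline],
            self.ensembles[candidate],
            window_s=cfg.pre_impact_window_s,
            threshold=cfg.excess_threshold,
        )

    def flagged_joints(self, baseline: str, candidate: str) -> list[str]:
        report = self.compare(baseline, candidate)
        return sorted(report.index[report["flagged"]])

    def summary(self, joint: str | None = None) -> str:
        """Human-readable account of the fit."""
        joint = joint or self.joints[0]
        lines = [
            "Swing HHT analysis",
            "==================",
            f"joints analyzed : {', '.join(self.joints)}",
            f"decomposition   : MEMD, {self.model.config.joint_stacking}, "
            f"SD<{self.model.config.sd_threshold}",
            "",
            "Synchronization",
            self.sync_summary().to_string(),
        ]
        for label in self.labels:
            stats = self.frequency_stats(label, joint)
            lines += [
                "",
                f"Instantaneous frequency by IMF — {joint}, {label} "
                f"(n={self.ensembles[label].n_members} swings)",
                stats[["mean_2dp", "sd_2dp", "cv_2dp"]]
                .rename(columns={"mean_2dp": "mean_hz", "sd_2dp": "sd_hz", "cv_2dp": "cv"})
                .to_string(),
            ]
        return "\n".join(lines)

    # -- plotting --------------------------------------------------------

    def plot_spectrum(self, label: str, joint: str, ax=None):
        """Heat map: time (impact at 0, red marker line) x frequency x amplitude."""
        import matplotlib.pyplot as plt

        spec = self.spectrum(label, joint)
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        t = spec.time_axis
        dt = t[1] - t[0] if t.size > 1 else 1.0
        t_edges = np.concatenate([t - dt / 2, [t[-1] + dt / 2]])
        mesh = ax.pcolormesh(
            t_edges, spec.freq_edges, spec.power.T, shading="flat", cmap="jet"
        )
        ax.axvline(spec.impact_time, color="red", lw=1.5)
        ax.set_xlabel("time from impact [s]")
        ax.set_ylabel("frequency [Hz]")
        ax.set_title(f"{joint} — {label}")
        ax.figure.colorbar(mesh, ax=ax, label="amplitude [deg]")
        return ax
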