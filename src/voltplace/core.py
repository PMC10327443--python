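"""Core containers: fluorescence traces and virtual-track behavior records.

A :class:`Trace` is one cell's fluorescence time series at a fixed sample rate,
tagged with its normalization state.  Fluorescence is recorded in arbitrary
camera units; after bleach correction the record is dimensionless (mean ~1),
and after spike-height normalization subthreshold amplitudes are expressed as
fractions of the cell's median action-potential height.

A :class:`BehaviorTrack` is the time-aligned record of a head-fixed animal
running a unidirectional linear virtual track: position, velocity, trial
index, reward/lick flags and the closed-loop stimulation gate, all sampled on
the same clock as the fluorescence movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Allowed trace normalization states.
NORMALIZATIONS = ("raw", "bleach_corrected", "spike_height")


@dataclass
class Trace:
    data: np.ndarray
    sample_rate: float = 1000.0
    normalization: str = "raw"
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("Trace.data must be one-dimensional")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def __len__(self) -> int:
        return self.data.size

    @property
    def duration_s(self) -> float:
        return self.data.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.size) / self.sample_rate

    def with_data(self, data: np.ndarray, normalization: str | None = None) -> "Trace":
        return replace(
            self,
            data=np.asarray(data, dtype=float),
            normalization=normalization or self.normalization,
        )


@dataclass
class BehaviorTrack:
    """Per-sample behavior record for a unidirectional linear track.

    Within a trial, samples consist of the inter-trial interval (position
    pinned at the track start) followed by a monotone traversal, so position
    is non-decreasing within each trial and ``trial_index`` is non-decreasing
    over the record.
    """

    time: np.ndarray            # s
    position: np.ndarray        # cm, in [0, track_length]
    velocity: np.ndarray        # cm/s
    trial_index: np.ndarray     # int per sample, non-decreasing
    reward_flag: np.ndarray     # bool per sample
    lick_flag: np.ndarray       # bool per sample
    stim_gate: np.ndarray       # bool per sample
    track_length: float = 180.0
    sample_rate: float = 1000.0
    rewarded_trials: np.ndarray = field(default=None)  # bool per trial

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("position", "velocity", "trial_index", "reward_flag", "lick_flag", "stim_gate"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"BehaviorTrack field {name} length mismatch")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_trials(self) -> int:
        return int(self.trial_index.max()) + 1 if len(self.trial_index) else 0

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def trial_mask(self, trials) -> np.ndarray:
        """Boolean sample mask selecting the given trial indices."""
        return np.isin(self.trial_index, np.asarray(list(trials)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "position_cm": self.position,
                "velocity_cms": self.velocity,
                "trial": self.trial_index,
                "reward": self.reward_flag.astype(int),
                "lick": self.lick_flag.astype(int),
                "stim": self.stim_gate.astype(int),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, track_length: float = 180.0) -> "BehaviorTrack":
        t = df["time_s"].to_numpy(float)
        rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1000.0
        return cls(
            time=t,
            position=df["position_cm"].to_numpy(float),
            velocity=df["velocity_cms"].to_numpy(float),
            trial_index=df["trial"].to_numpy(int),
            reward_flag=df["reward"].to_numpy(bool),
            lick_flag=df["lick"].to_numpy(bool),
            stim_gate=df["stim"].to_numpy(bool),
            track_length=track_length,
            sample_rate=float(round(rate)),
        )
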