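"""Core in-memory containers: a multichannel EEG recording and one walking
trial (recording + gait events + clinical metadata).

Conventions
-----------
* Samples are microvolts, shaped ``(n_channels, n_samples)``.
* Times are seconds, 0-based from recording start.
* Gait-relative times are signed seconds with ``walk_start`` at 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import CoverageError, MissingChannelError

#: Channel montage used throughout: six 10-20 scalp sites plus two mastoids.
SCALP_CHANNELS = ("F3", "F4", "Fz", "C3", "C4", "Cz")
MASTOID_CHANNELS = ("M1", "M2")
DEFAULT_CHANNELS = SCALP_CHANNELS + MASTOID_CHANNELS


@dataclass
class EEGRecording:
    """Channels x samples matrix with sampling rate and channel labels."""

    samples: np.ndarray          # (n_channels, n_samples), microvolts
    fs: float                    # Hz
    labels: tuple[str, ...]
    reference: str = "forehead midline"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = tuple(self.labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel by label (a view, not a copy)."""
        try:
            return self.samples[self.labels.index(label)]
        except ValueError:
            raise MissingChannelError(label) from None

    def has_channel(self, label: str) -> bool:
        return label in self.labels

    def copy_with(self, samples: np.ndarray) -> "EEGRecording":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class TrialRecord:
    """One walking trial: recording, gait events and clinical metadata.

    ``walk_start`` / ``walk_end`` are seconds from recording start (first
    step taken / sat back down).  ``dataset_count`` mirrors the cohort
    table: how many EEG measurements exist under this condition.
    """

    recording: EEGRecording
    walk_start: float
    walk_end: float
    patient_id: str = "P0"
    trial_id: str = "T0"
    fog: bool = False
    dataset_count: int = 1
    scores: dict = field(default_factory=dict)   # UPDRS3 / PIGD / BBS / LEDD
    dbs_hz: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.walk_start < self.walk_end <= self.recording.duration + 1e-9:
            raise ValueError(
                "gait events must satisfy 0 <= walk_start < walk_end <= duration"
            )

    def gait_slice(self, t0: float, t1: float) -> np.ndarray:
        """Sample index range for the gait-relative span ``[t0, t1)`` s."""
        fs = self.recording.fs
        i0 = int(round((self.walk_start + t0) * fs))
        i1 = int(round((self.walk_start + t1) * fs))
        if i0 < 0 or i1 > self.recording.n_samples:
            raise CoverageError(
                f"recording covers [{-self.walk_start:.1f}, "
                f"{self.recording.duration - self.walk_start:.1f}] s around gait "
                f"onset; requested [{t0:.1f}, {t1:.1f}] s"
            )
        return np.arange(i0, i1)

    def channel_segment(self, label: str, t0: float, t1: float) -> np.ndarray:
        """One channel restricted to the gait-relative span ``[t0, t1)``."""
        return self.recording.channel(label)[self.gait_slice(t0, t1)]
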