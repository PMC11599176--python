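"""Welch beta-power analysis paralleling the PAC windows.

Each 10-s gait-aligned window is lowpass filtered at 150 Hz (zero-phase),
Welch-estimated (2-s Hann segments, 50% overlap), the power spectrum is
z-scored across the 1-150 Hz support and the z values averaged over
13-30 Hz into a single beta statistic (``beta_z``).  Channels whose
beta_z is an outlier within a window group can be dropped with an
iterative two-sided Smirnov-Grubbs test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import filtfilt, firwin, welch

from .recording import TrialRecord

__all__ = ["PSDResult", "welch_beta", "welch_beta_windows", "grubbs_exclude"]

_SUPPORT = (1.0, 150.0)
_BETA = (13.0, 30.0)


@dataclass
class PSDResult:
    """z-scored Welch spectrum of one window plus its beta-band mean."""

    freqs: np.ndarray
    z_power: np.ndarray
    power: np.ndarray          # raw Welch estimate on the same support
    beta_z: float
    meta: dict = field(default_factory=dict)


def welch_beta(signal: np.ndarray, fs: float, segment_s: float = 2.0,
               lowpass_hz: float = 150.0, meta: dict | None = None) -> PSDResult:
    """Beta power of one window: lowpass, Welch, z-score over 1-150 Hz,
    average 13-30 Hz."""
    x = np.asarray(signal, dtype=float)
    nperseg = int(round(segment_s * fs))
    if x.size < 2 * nperseg:
        raise ValueError(
            f"window ({x.size} samples) must cover at least two Welch "
            f"segments ({2 * nperseg} samples)"
        )
    taps = firwin(int(3.3 * fs / 25.0) | 1, lowpass_hz, fs=fs)
    x = filtfilt(taps, [1.0], x)
    freqs, psd = welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    sel = (freqs >= _SUPPORT[0]) & (freqs <= _SUPPORT[1])
    freqs, psd = freqs[sel], psd[sel]
    z = (psd - psd.mean()) / psd.std()
    beta = (freqs >= _BETA[0]) & (freqs <= _BETA[1])
    return PSDResult(freqs=freqs, z_power=z, power=psd,
                     beta_z=float(z[beta].mean()), meta=meta or {})


def welch_beta_windows(trial: TrialRecord, channel: str,
                       window_starts=(-20.0, -10.0, 0.0, 10.0, 20.0),
                       window_s: float = 10.0) -> list[PSDResult]:
    """beta_z in each fixed gait-aligned window of one channel."""
    out = []
    for t0 in window_starts:
        seg = trial.channel_segment(channel, t0, t0 + window_s)
        out.append(welch_beta(seg, trial.recording.fs,
                              meta={"window_start_s": t0, "channel": channel,
                                    "patient_id": trial.patient_id,
                                    "trial_id": trial.trial_id}))
    return out


def grubbs_exclude(values, alpha: float = 0.05):
    """Iterative two-sided Grubbs outlier partition.

    At each step G = max |x - mean| / sd is compared with the critical
    value G_crit(n, alpha) from the t quantile formula; the most extreme
    value is removed while G exceeds it.  Returns ``(kept_idx,
    excluded_idx, steps)`` where steps lists each step's (G, G_crit).
    A zero-spread sample excludes nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    active = list(range(x.size))
    excluded: list[int] = []
    steps: list[tuple[float, float]] = []
    while len(active) >= 3:
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        k = int(np.argmax(dev))
        G = dev[k] / sd
        n = len(active)
        t_crit = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        G_crit = (n - 1) / np.sqrt(n) * np.sqrt(t_crit**2 / (n - 2 + t_crit**2))
        steps.append((float(G), float(G_crit)))
        if G > G_crit:
            excluded.append(active.pop(k))
        else:
            break
    return active, excluded, steps
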