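"""Readers and writers: EDF recordings, gait-event tables, cohort metadata.

Recordings travel as EDF (16-bit, 1-s data records).  Reading goes through
mne's EDF reader; writing uses a minimal EDF encoder implemented here
(the image standard for this montage; the reader and writer are
independent implementations, which the round-trip tests exploit).

The published trial-condition table is shipped as packaged data
(``data/table2.csv``) so the inclusion bookkeeping is reproducible
without any download.
"""
from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FileFormatError, MissingChannelError
from .recording import EEGRecording, TrialRecord

__all__ = [
    "read_recording", "write_recording",
    "read_events", "write_events",
    "load_cohort", "write_cohort", "load_table2",
]

logger = logging.getLogger(__name__)

_EDF_HEADER_FIXED = 256
_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _num(value: float, width: int = 8) -> bytes:
    for fmt in (f"{value:.{width - 2}g}", f"{value:.3g}", f"{value:.1f}"):
        if len(fmt) <= width:
            return _pad(fmt, width)
    return _pad(fmt[:width], width)


def write_recording(rec: EEGRecording, path) -> Path:
    """Write an EDF file (1-second records, 16-bit samples).

    Non-integer durations are zero-padded to the next whole second.
    Start date/time are fixed so output is byte-for-byte reproducible.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = int(np.ceil(rec.n_samples / fs))
    n_ch = rec.n_channels
    data = np.zeros((n_ch, n_rec * fs))
    data[:, :rec.n_samples] = rec.samples
    pmins, pmaxs, digital = [], [], []
    for x in data:
        lo, hi = float(x.min()), float(x.max())
        if hi - lo < 1e-9:
            hi = lo + 1.0
        pmins.append(lo)
        pmaxs.append(hi)
        gain = (_DIG_MAX - _DIG_MIN) / (hi - lo)
        d = np.round((x - lo) * gain + _DIG_MIN).astype("<i2")
        digital.append(d)
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad(f"Startdate 01-JAN-2020 X X {rec.reference}", 80),
        _pad("01.01.20", 8),
        _pad("00.00.00", 8),
        _pad(str(_EDF_HEADER_FIXED + 256 * n_ch), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_pad(lbl, 16) for lbl in rec.labels),
        b"".join(_pad("AgAgCl electrode", 80) for _ in rec.labels),
        b"".join(_pad("uV", 8) for _ in rec.labels),
        b"".join(_num(v) for v in pmins),
        b"".join(_num(v) for v in pmaxs),
        b"".join(_num(_DIG_MIN) for _ in rec.labels),
        b"".join(_num(_DIG_MAX) for _ in rec.labels),
        b"".join(_pad("", 80) for _ in rec.labels),
        b"".join(_num(fs) for _ in rec.labels),
        b"".join(_pad("", 32) for _ in rec.labels),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            for ch in range(n_ch):
                fh.write(digital[ch][r * fs:(r + 1) * fs].tobytes())
    return path


def read_recording(path) -> EEGRecording:
    """Read an EDF recording into microvolt samples via mne."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FileFormatError(f"could not parse {path} as EDF: {exc}") from exc
    return EEGRecording(
        samples=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        labels=tuple(raw.ch_names),
        reference="as recorded",
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_events(trials, path) -> Path:
    """Tab-separated gait events: trial_id, walk_start_s, walk_end_s."""
    path = Path(path)
    rows = [{"trial_id": t.trial_id, "walk_start_s": t.walk_start,
             "walk_end_s": t.walk_end} for t in trials]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_events(path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    need = {"trial_id", "walk_start_s", "walk_end_s"}
    if not need.issubset(ev.columns):
        raise FileFormatError(f"events table missing columns {need - set(ev.columns)}")
    bad = ev[~(ev["walk_start_s"] < ev["walk_end_s"])]
    if len(bad):
        raise FileFormatError(f"walk_start >= walk_end for trials {list(bad.trial_id)}")
    ev["trial_id"] = ev["trial_id"].astype(str)
    return ev


def write_cohort(table: pd.DataFrame, path) -> Path:
    table.to_csv(Path(path), index=False)
    return Path(path)


_TRUE = {"+", "yes", "true", "1", "y"}
_FALSE = {"-", "−", "no", "false", "0", "n"}


def _to_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise FileFormatError(f"cannot interpret flag value {v!r}")


def load_cohort(metadata_path, events_path=None
                ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Load cohort metadata (and optionally gait events) with typing and
    cross-validation of trial ids.  ``include_flag`` drives every
    downstream stage; included trial / dataset counts are logged."""
    try:
        meta = pd.read_csv(metadata_path)
    except pd.errors.EmptyDataError as exc:
        raise FileFormatError(f"empty metadata file {metadata_path}") from exc
    if meta.empty:
        raise FileFormatError(f"metadata file {metadata_path} has no rows")
    required = {"patient_id", "trial_id", "dataset_count", "PIGD",
                "fog_flag", "include_flag"}
    missing = required - set(meta.columns)
    if missing:
        raise FileFormatError(f"metadata missing columns {sorted(missing)}")
    meta = meta.copy()
    meta["trial_id"] = meta["trial_id"].astype(str)
    meta["patient_id"] = meta["patient_id"].astype(str)
    meta["fog_flag"] = meta["fog_flag"].map(_to_bool)
    meta["include_flag"] = meta["include_flag"].map(_to_bool)
    if (meta["dataset_count"] < 1).any():
        raise FileFormatError("dataset_count must be >= 1")
    events = None
    if events_path is not None:
        events = read_events(events_path)
        unmatched = set(events["trial_id"]) ^ set(meta["trial_id"])
        if unmatched:
            raise FileFormatError(
                f"trial ids do not match between metadata and events: "
                f"{sorted(unmatched)}")
    inc = meta[meta["include_flag"]]
    logger.info("cohort: %d/%d trials included, %d datasets",
                len(inc), len(meta), int(inc["dataset_count"].sum()))
    return meta, events


def load_table2() -> pd.DataFrame:
    """The shipped per-trial condition/status table (11 patients,
    19 trials; the inclusion column reproduces the published
    17-trial / 24-dataset analysis set)."""
    with resources.as_file(resources.files("gaitpac.data") / "table2.csv") as p:
        meta, _ = load_cohort(p)
    return meta


def included_counts(meta: pd.DataFrame) -> dict:
    """Bookkeeping under the inclusion column: trials, EEG datasets and
    channel-datasets (x2 for the C3/C4 pair), plus the FOG split."""
    inc = meta[meta["include_flag"]]
    datasets = int(inc["dataset_count"].sum())
    return {
        "included_trials": int(len(inc)),
        "included_datasets": datasets,
        "included_channel_datasets": 2 * datasets,
        "fog_pos_channel_datasets": 2 * int(inc.loc[inc.fog_flag, "dataset_count"].sum()),
        "fog_neg_channel_datasets": 2 * int(inc.loc[~inc.fog_flag, "dataset_count"].sum()),
    }
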