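"""Data model and disk formats for multichannel surface-EMG recordings.

A recording is a 6-channel matrix of back-muscle sEMG in microvolts. The
fixed protocol channel order is ``[ES-L, LD-L, TR-L, ES-R, LD-R, TR-R]``:
left/right erector spinae, latissimus dorsi and trapezius. On disk a
recording is a CSV (header ``time,<channels...>``, time in seconds) plus a
JSON sidecar carrying the sampling rate and labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Protocol channel order; sensors 1-6 map to these muscles.
DEFAULT_CHANNELS = ("ES-L", "LD-L", "TR-L", "ES-R", "LD-R", "TR-R")

#: Decimal places written to CSV; round-trip error is below 1e-6 uV.
_CSV_DECIMALS = 7


class MovementLabel(str, Enum):
    """The five trunk movements plus rest.

    FSB front side bending, BLS/BRS bend left/right side,
    LT/RT left/right twist.
    """

    FSB = "FSB"
    BLS = "BLS"
    BRS = "BRS"
    LT = "LT"
    RT = "RT"
    REST = "REST"

    @classmethod
    def movement_classes(cls) -> tuple["MovementLabel", ...]:
        """The 5 non-rest classes, in canonical order."""
        return (cls.FSB, cls.BLS, cls.BRS, cls.LT, cls.RT)


class FormatError(ValueError):
    """Malformed recording file (ragged/missing columns, bad header)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a recording invariant."""


@dataclass
class Recording:
    """One multichannel sEMG trial.

    Parameters
    ----------
    signal
        ``(n_channels, n_samples)`` float array, microvolts.
    fs
        Sampling rate in Hz. The acquisition rate is not fixed by the
        protocol; 1000 Hz is the package default for generated data.
    channel_names
        Ordered muscle labels, one per row of ``signal``.
    subject_id, trial_id
        Opaque identifiers.
    movement_label
        One of :class:`MovementLabel`, or ``None`` when unlabeled.
    """

    signal: np.ndarray
    fs: float
    channel_names: Sequence[str] = DEFAULT_CHANNELS
    subject_id: str = ""
    movement_label: Optional[MovementLabel] = None
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError(
                f"signal must be 2-D (channels x samples), got {self.signal.ndim}-D"
            )
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains non-finite samples")
        if isinstance(self.movement_label, str):
            self.movement_label = MovementLabel(self.movement_label)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs

    def with_signal(self, signal: np.ndarray) -> "Recording":
        """Copy of this recording with a replaced signal matrix."""
        return replace(self, signal=np.asarray(signal, dtype=float))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` as CSV + JSON sidecar.

    The CSV has a ``time`` column (seconds) followed by one column per
    channel; values are rounded to 1e-7 uV so the round-trip through
    :func:`read_recording` is lossless to well below 1e-6 uV.
    """
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time": t})
    for name, row in zip(rec.channel_names, rec.signal):
        df[name] = row
    df.to_csv(path, index=False, float_format=f"%.{_CSV_DECIMALS}f")
    meta = {
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "movement_label": rec.movement_label.value if rec.movement_label else None,
        "trial_id": rec.trial_id,
        "channel_names": list(rec.channel_names),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path, meta_path: str | Path | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`.

    The sidecar is authoritative for ``fs``; the CSV time column is only
    checked for consistency (>1% relative mismatch in median spacing is an
    error) and then discarded.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _sidecar_path(path)
    if not meta_path.exists():
        raise FormatError(f"missing metadata sidecar: {meta_path}")
    meta = json.loads(meta_path.read_text())

    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from None
    if "time" not in df.columns:
        raise FormatError(f"{path} lacks a 'time' column")

    channel_names = meta["channel_names"]
    missing = [c for c in channel_names if c not in df.columns]
    if missing:
        raise ValidationError(
            f"sidecar declares channels absent from CSV: {missing}"
        )

    fs = float(meta["fs"])
    t = df["time"].to_numpy()
    if len(t) > 1:
        dt = float(np.median(np.diff(t)))
        if dt <= 0 or abs(dt - 1.0 / fs) > 0.01 / fs:
            raise ValidationError(
                f"time-column spacing {dt:.6g}s inconsistent with sidecar fs={fs}"
            )

    signal = df[channel_names].to_numpy().T
    if not np.all(np.isfinite(signal)):
        raise ValidationError(f"{path} contains non-finite samples")

    label = meta.get("movement_label")
    return Recording(
        signal=signal,
        fs=fs,
        channel_names=channel_names,
        subject_id=meta.get("subject_id", ""),
        movement_label=MovementLabel(label) if label else None,
        trial_id=meta.get("trial_id", ""),
    )
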