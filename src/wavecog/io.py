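"""Epoch and recording I/O: CSV interchange, EDF reading, segmentation.

CSV is the canonical interchange format: one file per epoch (columns are
channels, one row per sample) plus a manifest listing file, label,
sampling rate and length for each epoch.  EDF recordings are supported
read-only through MNE; a minimal EDF writer is provided so round trips
can be exercised without external files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Epoch, EpochSet

__all__ = [
    "EEGRecording",
    "write_epochs",
    "read_epoch_csv_dir",
    "write_edf",
    "read_edf",
    "segment_recording",
]

MANIFEST_NAME = "manifest.csv"


@dataclass
class EEGRecording:
    """A continuous multichannel recording with optional event markers."""

    samples: np.ndarray                  # channels x time
    fs: float
    channel_names: list[str]
    markers: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length must match channel count")
        n = self.samples.shape[1]
        for idx, label in self.markers:
            if not 0 <= idx < n:
                raise ValueError(f"marker {label!r} at {idx} outside record")


def write_epochs(epochs: EpochSet, outdir: str | Path) -> Path:
    """Write one CSV per epoch plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, epoch in enumerate(epochs.epochs):
        fname = f"epoch_{i:05d}.csv"
        pd.DataFrame(epoch.samples.T, columns=epochs.channel_names).to_csv(
            outdir / fname, index=False
        )
        rows.append(
            {
                "epoch_id": i,
                "file": fname,
                "label": epoch.label,
                "fs": epochs.fs,
                "epoch_len": epochs.epoch_len,
            }
        )
    manifest = outdir / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_epoch_csv_dir(
    path: str | Path, manifest: str = MANIFEST_NAME
) -> EpochSet:
    """Read an epoch directory written by :func:`write_epochs`."""
    path = Path(path)
    mpath = path / manifest
    if not mpath.exists():
        raise FileNotFoundError(f"manifest not found: {mpath}")
    mf = pd.read_csv(mpath)
    required = {"epoch_id", "file", "label", "fs", "epoch_len"}
    missing = required - set(mf.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    epochs: list[Epoch] = []
    channel_names: list[str] | None = None
    for row in mf.itertuples(index=False):
        f = path / row.file
        if not f.exists():
            raise FileNotFoundError(f"manifest references missing file: {f}")
        df = pd.read_csv(f)
        if channel_names is None:
            channel_names = list(df.columns)
        elif list(df.columns) != channel_names:
            raise ValueError(f"channel mismatch in {f}")
        if len(df) != int(row.epoch_len):
            raise ValueError(
                f"{f}: expected {int(row.epoch_len)} samples, found {len(df)}"
            )
        epochs.append(
            Epoch(samples=df.to_numpy(dtype=float).T, fs=float(row.fs),
                  label=int(row.label))
        )
    return EpochSet(epochs=epochs, channel_names=channel_names or [])


# ---------------------------------------------------------------------------
# EDF (European Data Format), 16-bit classic variant

_EDF_DIGITAL_MIN, _EDF_DIGITAL_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field too long for EDF header: {text!r}")
    return b.ljust(width)


def write_edf(recording: EEGRecording, path: str | Path) -> Path:
    """Write a classic EDF file, one 1-second data record per second.

    Amplitudes are scaled per channel to the 16-bit digital range; any
    trailing part-second of data is dropped (EDF records are fixed-size).
    Markers are not written (classic EDF has no annotation channel).
    """
    path = Path(path)
    fs = recording.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(fs)  # samples per record per channel
    n_ch = recording.samples.shape[0]
    n_records = recording.samples.shape[1] // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = recording.samples[:, : n_records * spr]
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max <= phys_min
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    scale = (_EDF_DIGITAL_MAX - _EDF_DIGITAL_MIN) / (phys_max - phys_min)
    digital = np.rint(
        (data - phys_min[:, None]) * scale[:, None] + _EDF_DIGITAL_MIN
    ).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("synthetic recording", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    per_field = [
        [_pad(name[:16], 16) for name in recording.channel_names],
        [_pad("EEG", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{v:.8g}"[:8], 8) for v in phys_min],
        [_pad(f"{v:.8g}"[:8], 8) for v in phys_max],
        [_pad(str(_EDF_DIGITAL_MIN), 8)] * n_ch,
        [_pad(str(_EDF_DIGITAL_MAX), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(spr), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in per_field:
            fh.write(b"".join(group))
        for rec in range(n_records):
            chunk = digital[:, rec * spr : (rec + 1) * spr]
            fh.write(chunk.tobytes())  # channel-sequential within a record
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF recording (via MNE); annotations become markers."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as err:
        raise ValueError(f"could not parse EDF file {path}: {err}") from err
    fs = float(raw.info["sfreq"])
    markers = [
        (int(round(onset * fs)), str(desc))
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return EEGRecording(
        samples=raw.get_data(),
        fs=fs,
        channel_names=list(raw.ch_names),
        markers=markers,
    )


def segment_recording(
    rec: EEGRecording,
    start_labels: dict[str, int],
    end_label: str,
    fixed_length: int | None = None,
) -> tuple[EpochSet, int]:
    """Cut marker-delimited segments into a fixed-length EpochSet.

    ``start_labels`` maps start-marker descriptions to class labels; each
    start is paired with the next ``end_label`` marker.  Unpaired starts
    (including a start superseded by another start) are dropped and
    counted, as are segments shorter than the target length.  With
    ``fixed_length=None`` all pairs are cropped to the shortest pair.

    Returns ``(epochs, n_dropped)``.
    """
    events = sorted(rec.markers)
    pairs: list[tuple[int, int, int]] = []  # (start, end, class)
    dropped = 0
    open_start: tuple[int, int] | None = None
    for idx, label in events:
        if label in start_labels:
            if open_start is not None:
                dropped += 1
            open_start = (idx, start_labels[label])
        elif label == end_label:
            if open_start is not None and idx > open_start[0]:
                pairs.append((open_start[0], idx, open_start[1]))
                open_start = None
    if open_start is not None:
        dropped += 1
    if fixed_length is None:
        if not pairs:
            raise ValueError("no valid (start, end) marker pairs found")
        length = min(e - s for s, e, _ in pairs)
    else:
        length = fixed_length
    epochs: list[Epoch] = []
    n = rec.samples.shape[1]
    for s, e, cls in pairs:
        if e - s < length or s + length > n:
            dropped += 1
            continue
        epochs.append(
            Epoch(samples=rec.samples[:, s : s + length], fs=rec.fs, label=cls)
        )
    if not epochs:
        raise ValueError("no valid (start, end) marker pairs found")
    return EpochSet(epochs=epochs, channel_names=list(rec.channel_names)), dropped
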