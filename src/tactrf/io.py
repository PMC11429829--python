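"""Readers and writers: WAV, EDF, TSV, flat binary arrays, run manifests.

Internal pipeline storage is flat binary (``.npy``) arrays with JSON
sidecars — simple and language-portable. WAV goes through
``scipy.io.wavfile``; EDF reading goes through MNE's bundled reader; EDF
writing is a minimal EDF writer (16-bit, one-second records) sufficient for
round-tripping continuous multichannel recordings with their labels and
sampling rate. EDF quantizes to 16 bits over the per-channel physical
range, so round-trip error is bounded by half a quantization step.
"""

from __future__ import annotations

import json
import struct
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .envelope import TactileEnvelope
from .preprocessing import RawEEG


# ---------------------------------------------------------------------------
# WAV

def write_wav(path: str | Path, samples: np.ndarray, fs: float) -> None:
    """Write a float32 WAV file (values are stored verbatim)."""
    wavfile.write(str(path), int(round(fs)), np.asarray(samples, dtype=np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file; returns (samples as float64, fs). Integer PCM is
    rescaled to [-1, 1]."""
    fs, samples = wavfile.read(str(path))
    samples = np.asarray(samples)
    if samples.dtype.kind == "i":
        samples = samples / float(np.iinfo(samples.dtype).max)
    elif samples.dtype.kind == "u":
        info = np.iinfo(samples.dtype)
        samples = (samples.astype(float) - info.max / 2) / (info.max / 2)
    return samples.astype(float), float(fs)


# ---------------------------------------------------------------------------
# EDF

def _edf_field(value: str, width: int) -> bytes:
    encoded = str(value)[:width].encode("ascii")
    return encoded.ljust(width)


def write_edf(path: str | Path, raw: RawEEG, physical_dim: str = "uV") -> None:
    """Write continuous data as a minimal 16-bit EDF file.

    One-second data records; the sampling rate must therefore be a positive
    integer. Data are interpreted in ``physical_dim`` units (default
    microvolts) and quantized to the per-channel min/max range. Event
    markers are not stored (keep them in the run manifest).
    """
    fs = raw.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(fs)
    n_ch = raw.n_channels
    data = raw.data
    n_records = int(np.ceil(data.shape[1] / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, : data.shape[1]] = data

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max <= phys_min
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((padded - phys_min[:, None]) / scale[:, None] + dig_min).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + n_ch)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),
        _edf_field(str(n_ch), 4),
    ])
    sig_headers = b"".join([
        b"".join(_edf_field(label, 16) for label in raw.channel_labels),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(physical_dim, 8) for _ in range(n_ch)),
        b"".join(_edf_field(f"{v:.6g}", 8) for v in phys_min),
        b"".join(_edf_field(f"{v:.6g}", 8) for v in phys_max),
        b"".join(_edf_field(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(_edf_field(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(str(fs), 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_headers)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path: str | Path, physical_dim: str = "uV") -> RawEEG:
    """Read an EDF file into :class:`RawEEG` (values in ``physical_dim``)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units=physical_dim)
    return RawEEG(data=data, fs=float(raw.info["sfreq"]), channel_labels=list(raw.ch_names))


# ---------------------------------------------------------------------------
# flat binary arrays with JSON sidecars

def write_array(path: str | Path, array: np.ndarray, sidecar: dict | None = None) -> None:
    """Save an array as ``.npy`` plus a ``.json`` metadata sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), np.asarray(array))
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=str))


def read_array(path: str | Path) -> tuple[np.ndarray, dict]:
    """Load an array and its sidecar (empty dict if no sidecar exists)."""
    path = Path(path)
    array = np.load(path.with_suffix(".npy"))
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return array, sidecar


def write_envelope(path: str | Path, envelope: TactileEnvelope) -> None:
    write_array(path, envelope.values, dict(
        fs=envelope.fs, condition=envelope.condition,
        trial_index=envelope.trial_index, segment_index=envelope.segment_index,
        all_zero=envelope.all_zero,
    ))


def read_envelope(path: str | Path) -> TactileEnvelope:
    values, meta = read_array(path)
    return TactileEnvelope(
        values=values, fs=float(meta.get("fs", 64.0)),
        condition=meta.get("condition", ""), trial_index=int(meta.get("trial_index", 0)),
        segment_index=int(meta.get("segment_index", 0)),
        all_zero=bool(meta.get("all_zero", False)),
    )


# ---------------------------------------------------------------------------
# TSV and manifests

def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
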