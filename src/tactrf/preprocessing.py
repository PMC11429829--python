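"""EEG preprocessing: filters, resampling, re-referencing, segmentation.

Transforms raw 64-channel recordings into z-scored one-minute segments at
64 Hz aligned to stimulation onset. Two Hann-windowed FIR band-pass presets
are provided: a broad stage (1-40 Hz; high-pass order 500, low-pass order
100, designed at 500 Hz) and a narrow stage matched to the stimulus band
(0.5-6 Hz; orders 2000/200, designed at 250 Hz). Filters are applied
zero-phase by compensating the linear-phase delay of the symmetric FIR, so
TRF latencies are not biased by filtering. Segmentation applies the fixed
89 ms sound-to-marker delay (nearest-sample rounding) before cutting
consecutive one-minute segments, which are then z-scored per channel.

Artifact handling (ICA, bad-channel interpolation) is out of scope; a
``cleaning_hook`` argument on :func:`preprocess` lets callers insert an
external cleaning step between the broad filter stage and re-referencing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable

import numpy as np
from scipy import signal

from .envelope import TARGET_FS

logger = logging.getLogger(__name__)

#: fixed delay between the trial-onset sound and its EEG marker, ms
ONSET_DELAY_MS = 89.0

#: (high-pass Hz, low-pass Hz, high-pass order, low-pass order)
STAGE1_PRESET = dict(low_hz=1.0, high_hz=40.0, low_order=500, high_order=100)
STAGE2_PRESET = dict(low_hz=0.5, high_hz=6.0, low_order=2000, high_order=200)


@dataclass
class RawEEG:
    """Continuous multichannel EEG with event markers.

    ``events`` is a list of (label, sample_index) pairs; indices are
    rescaled by :func:`resample`.
    """

    data: np.ndarray                  # (n_channels, n_samples), volts
    fs: float
    channel_labels: list[str]
    events: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EEGSegment:
    """One-minute, 64 Hz, per-channel z-scored response segment."""

    data: np.ndarray                  # (n_channels, n_samples)
    fs: float = TARGET_FS
    subject: int = 0
    condition: str = ""
    segment_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _fir_zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric (linear-phase) FIR with delay compensation.

    Edges are handled by reflect-padding half the filter length on both
    sides, so output length equals input length.
    """
    half = (taps.size - 1) // 2
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(half, half)], mode="reflect")
    out = signal.fftconvolve(padded, taps[None, :] if data.ndim == 2 else taps, mode="valid")
    return out


def design_fir(order: int, cutoff_hz: float, fs: float, pass_zero: bool) -> np.ndarray:
    """Hann-windowed sinc FIR of the given (even) order."""
    if order % 2:
        raise ValueError(f"filter order must be even, got {order}")
    if cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz at or above Nyquist ({fs / 2} Hz)")
    return signal.firwin(order + 1, cutoff_hz, window="hann", pass_zero=pass_zero, fs=fs)


def filter_stage(
    data: RawEEG,
    low_hz: float,
    high_hz: float,
    low_order: int,
    high_order: int,
) -> RawEEG:
    """Band-pass as a cascade of Hann-window FIR high-pass and low-pass.

    ``low_hz``/``low_order`` specify the high-pass (lower band edge),
    ``high_hz``/``high_order`` the low-pass (upper band edge), matching the
    convention "bandpass filtered from ``low_hz`` to ``high_hz``".
    """
    hp = design_fir(low_order, low_hz, data.fs, pass_zero=False)
    lp = design_fir(high_order, high_hz, data.fs, pass_zero=True)
    out = _fir_zero_phase(data.data, hp)
    out = _fir_zero_phase(out, lp)
    return replace(data, data=out)


def resample(data: RawEEG, target_fs: float) -> RawEEG:
    """Polyphase anti-aliased resampling; event indices are rescaled."""
    if target_fs == data.fs:
        return data
    if target_fs > data.fs:
        raise ValueError(f"target_fs {target_fs} exceeds current fs {data.fs}")
    frac = Fraction(target_fs / data.fs).limit_denominator(10000)
    out = signal.resample_poly(data.data, frac.numerator, frac.denominator, axis=1)
    scale = target_fs / data.fs
    events = [(label, int(round(s * scale))) for label, s in data.events]
    return replace(data, data=out, fs=target_fs, events=events)


def rereference_average(data: RawEEG) -> RawEEG:
    """Re-reference to the average: channel mean at every sample becomes 0."""
    if data.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    return replace(data, data=data.data - data.data.mean(axis=0, keepdims=True))


def align_and_segment(
    data: RawEEG,
    onset_event: str = "stim_onset",
    delay_ms: float = ONSET_DELAY_MS,
    segment_minutes: float = 1.0,
    n_minutes: float | None = None,
    subject: int = 0,
    condition: str = "",
    segment_index_offset: int = 0,
) -> list[EEGSegment]:
    """Cut consecutive fixed-length segments starting at onset + delay.

    The first segment starts at ``onset_sample + round(delay_ms * fs / 1000)``
    (nearest-sample rounding of the 89 ms sound-to-marker delay). Segments
    are contiguous, non-overlapping, and never span beyond the recording;
    ``n_minutes`` caps how much post-onset data is used (default: all).
    """
    onsets = [s for label, s in data.events if label == onset_event]
    if not onsets:
        raise ValueError(
            f"missing onset marker {onset_event!r} "
            f"(subject={subject}, condition={condition!r})"
        )
    start = onsets[0] + int(round(delay_ms * data.fs / 1000.0))
    seg_len = int(round(segment_minutes * 60 * data.fs))
    available = data.n_samples - start
    if n_minutes is not None:
        available = min(available, int(round(n_minutes * 60 * data.fs)))
    n_segments = available // seg_len
    segments = []
    for i in range(n_segments):
        chunk = data.data[:, start + i * seg_len : start + (i + 1) * seg_len]
        segments.append(
            EEGSegment(
                data=chunk.copy(),
                fs=data.fs,
                subject=subject,
                condition=condition,
                segment_index=segment_index_offset + i,
            )
        )
    return segments


def zscore_segment(seg: EEGSegment) -> EEGSegment:
    """z-score each channel: mean 0, SD 1 (population SD). Idempotent."""
    mean = seg.data.mean(axis=1, keepdims=True)
    sd = seg.data.std(axis=1, keepdims=True)
    zero_var = np.flatnonzero(sd[:, 0] == 0)
    if zero_var.size:
        raise ValueError(f"zero-variance channel(s) at index {zero_var.tolist()}")
    return replace(seg, data=(seg.data - mean) / sd)


def preprocess(
    raw: RawEEG,
    onset_event: str = "stim_onset",
    subject: int = 0,
    condition: str = "",
    segment_index_offset: int = 0,
    n_minutes: float | None = None,
    cleaning_hook: Callable[[RawEEG], RawEEG] | None = None,
) -> list[EEGSegment]:
    """Full pipeline: stage-1 filter -> 250 Hz -> (hook) -> average reference
    -> stage-2 filter -> 64 Hz -> align/segment -> z-score."""
    x = filter_stage(raw, **STAGE1_PRESET)
    x = resample(x, 250.0)
    if cleaning_hook is not None:
        x = cleaning_hook(x)
    x = rereference_average(x)
    x = filter_stage(x, **STAGE2_PRESET)
    x = resample(x, TARGET_FS)
    segments = align_and_segment(
        x, onset_event=onset_event, subject=subject, condition=condition,
        segment_index_offset=segment_index_offset, n_minutes=n_minutes,
    )
    return [zscore_segment(s) for s in segments]
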