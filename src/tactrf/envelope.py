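"""Tactile envelope extraction from brush-microphone audio.

The stimulus feature of the encoding model is the low-frequency amplitude
envelope of the sound produced by brush–skin friction. The extraction
pipeline is fixed: absolute value of the analytic (Hilbert) signal, 3rd-order
Butterworth low-pass at 6 Hz, resampling to 64 Hz (the EEG analysis rate),
and division by the maximum value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: analysis sampling rate shared by envelopes and preprocessed EEG, Hz
TARGET_FS = 64.0
#: low-pass cutoff of the envelope, Hz
ENVELOPE_CUTOFF_HZ = 6.0
#: Butterworth order of the envelope low-pass
ENVELOPE_FILTER_ORDER = 3


@dataclass
class AudioTrace:
    """Raw single-channel audio of brush–skin friction.

    Parameters
    ----------
    samples : ndarray
        Pressure-proportional waveform.
    fs : float
        Sampling rate in Hz.
    condition, trial_index : str, int
        Bookkeeping labels carried through the pipeline.
    """

    samples: np.ndarray
    fs: float
    condition: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class TactileEnvelope:
    """Normalized low-frequency stimulus envelope at 64 Hz.

    ``values`` lie in [0, 1] with max exactly 1 after normalization, unless
    the source audio was silent, in which case ``all_zero`` is set and the
    values are identically zero.
    """

    values: np.ndarray
    fs: float = TARGET_FS
    condition: str = ""
    trial_index: int = 0
    segment_index: int = 0
    all_zero: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("envelope must be one-dimensional")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.values.size


def _normalize(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Divide by the maximum; guard the all-zero case with a flag."""
    peak = float(np.max(np.abs(values))) if values.size else 0.0
    if peak == 0.0:
        return values, True
    return values / float(np.max(values)), False


def resample_to(values: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase anti-aliased resampling between arbitrary rational rates.

    Boundaries are line-extrapolated rather than zero-padded: envelopes have
    a nonzero mean, and zero padding would ring (Gibbs) at the edges and
    corrupt the subsequent max-normalization.
    """
    if fs_in == fs_out:
        return np.asarray(values, dtype=float)
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return signal.resample_poly(values, frac.numerator, frac.denominator, padtype="line")


def extract_envelope(
    audio: AudioTrace,
    cutoff_hz: float = ENVELOPE_CUTOFF_HZ,
    order: int = ENVELOPE_FILTER_ORDER,
    target_fs: float = TARGET_FS,
    zero_phase: bool = True,
) -> TactileEnvelope:
    """Extract the normalized tactile envelope from raw audio.

    Pipeline order is fixed: |analytic signal| -> Butterworth low-pass ->
    resample to ``target_fs`` -> divide by the maximum.

    Parameters
    ----------
    audio : AudioTrace
        Input waveform; ``audio.fs`` must exceed ``2 * cutoff_hz``
        comfortably (at least 128 Hz).
    zero_phase : bool
        Apply the Butterworth filter forward-backward (default). A causal
        single-pass alternative is available for comparison; zero-phase
        avoids an envelope lag that would bias TRF latencies.

    Returns
    -------
    TactileEnvelope
        At ``target_fs``, max-normalized. Silent input yields an all-zero
        envelope with ``all_zero=True`` instead of a division by zero.
    """
    if audio.fs <= 128:
        raise ValueError(f"audio fs must exceed 128 Hz, got {audio.fs}")
    warmup = 3 * (order + 1)
    if audio.samples.size <= warmup:
        raise ValueError(f"audio too short for filtering ({audio.samples.size} samples)")

    env = np.abs(signal.hilbert(audio.samples))
    sos = signal.butter(order, cutoff_hz, btype="low", fs=audio.fs, output="sos")
    if zero_phase:
        env = signal.sosfiltfilt(sos, env)
    else:
        env = signal.sosfilt(sos, env)
    env = resample_to(env, audio.fs, target_fs)
    # rectification: filtering/resampling can produce small negative ripple
    env = np.clip(env, 0.0, None)
    values, all_zero = _normalize(env)
    if all_zero:
        logger.warning(
            "all-zero audio for condition=%r trial=%d: envelope flagged",
            audio.condition, audio.trial_index,
        )
    return TactileEnvelope(
        values=values,
        fs=target_fs,
        condition=audio.condition,
        trial_index=audio.trial_index,
        all_zero=all_zero,
    )


def concatenate_and_segment(
    trials: list[TactileEnvelope], segment_minutes: float = 1.0
) -> list[TactileEnvelope]:
    """Concatenate per-trial envelopes and cut into fixed-length segments.

    Three 3-minute trials with 1-minute segments yield nine segments per
    condition. A trailing remainder shorter than one segment is dropped and
    logged.
    """
    if not trials:
        return []
    fs = trials[0].fs
    condition = trials[0].condition
    for t in trials:
        if t.fs != fs:
            raise ValueError(f"mixed sampling rates: {t.fs} vs {fs}")
        if t.condition != condition:
            raise ValueError(f"mixed conditions: {t.condition!r} vs {condition!r}")
    values = np.concatenate([t.values for t in trials])
    seg_len = int(round(segment_minutes * 60 * fs))
    n_segments = values.size // seg_len
    remainder = values.size - n_segments * seg_len
    if remainder:
        logger.info(
            "dropping %.1f s remainder after %d segments (condition=%r)",
            remainder / fs, n_segments, condition,
        )
    return [
        TactileEnvelope(
            values=values[i * seg_len : (i + 1) * seg_len],
            fs=fs,
            condition=condition,
            trial_index=-1,
            segment_index=i,
            all_zero=not np.any(values[i * seg_len : (i + 1) * seg_len]),
        )
        for i in range(n_segments)
    ]


def envelope_power_spectrum(
    envelope: TactileEnvelope, band: tuple[float, float] = (0.5, 8.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Welch-averaged power spectrum of the envelope, restricted to ``band``.

    Returns
    -------
    freqs, power : ndarray
        Frequencies (Hz) within the band and the corresponding power
        spectral density.
    """
    lo, hi = band
    if hi > envelope.fs / 2 or lo < 0:
        raise ValueError(f"band {band} outside (0, Nyquist={envelope.fs / 2}]")
    if lo > 0 and envelope.n_samples < 2 * envelope.fs / lo:
        raise ValueError("envelope too short to resolve the band's lower edge")
    nperseg = min(envelope.n_samples, int(8 * envelope.fs / max(lo, 0.25)))
    freqs, power = signal.welch(envelope.values, fs=envelope.fs, nperseg=nperseg)
    keep = (freqs >= lo) & (freqs <= hi)
    return freqs[keep], power[keep]


def low_frequency_power_fraction(
    envelope: TactileEnvelope, cutoff_hz: float = ENVELOPE_CUTOFF_HZ
) -> float:
    """Fraction of total (DC-excluded) spectral power below ``cutoff_hz``.

    Computed from a plain periodogram of the demeaned envelope. The brush
    strokes are slow, so under default generator settings this exceeds 0.9.
    """
    values = envelope.values - np.mean(envelope.values)
    freqs, power = signal.periodogram(values, fs=envelope.fs)
    total = float(np.sum(power))
    if total == 0.0:
        return 0.0
    return float(np.sum(power[freqs < cutoff_hz]) / total)


def normalize_envelope(envelope: TactileEnvelope) -> TactileEnvelope:
    """Max-normalize an envelope (idempotent; all-zero input is flagged)."""
    values, all_zero = _normalize(envelope.values)
    return replace(envelope, values=values, all_zero=all_zero)
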