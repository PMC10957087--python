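"""Amplitude-envelope extraction, epoching, and segmentation.

The slow (<10 Hz) amplitude envelope of each speech stream is the
stimulus feature for all tracking analyses.  It is computed as the
magnitude of the analytic signal (Hilbert transform), low-pass filtered
at 10 Hz with a zero-phase FIR (the nominal 0 Hz high-pass edge is a
no-op), and resampled to the analysis rate: 128 Hz for TRF estimation,
64 Hz for envelope reconstruction.  Filtering precedes resampling to
avoid aliasing.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .data_model import EPOCH_RATES, EPOCH_SECONDS

#: low-pass edge of the envelope band, Hz
ENVELOPE_LOWPASS_HZ = 10.0


class EpochBoundsError(ValueError):
    """An epoch window extends past the end of the recording."""


def load_wav(path, channel: str | int = "mean") -> tuple[np.ndarray, float]:
    """Read a PCM WAV file as a float mono waveform.

    Parameters
    ----------
    channel
        ``"mean"`` averages stereo channels; an integer selects one.
    """
    rate, audio = wavfile.read(path)
    audio = np.asarray(audio, dtype=float)
    if audio.ndim == 2:
        if channel == "mean":
            audio = audio.mean(axis=1)
        else:
            audio = audio[:, int(channel)]
    return audio, float(rate)


def _lowpass_fir(x: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    """Zero-phase FIR low-pass (Hamming window design).

    Up to half a second of taps, shortened for brief signals so the
    filtfilt edge padding stays valid.
    """
    numtaps = int(min(rate // 2, max(x.size // 4, 3))) | 1
    numtaps = max(numtaps, 11)
    taps = signal.firwin(numtaps, cutoff, fs=rate)
    padlen = min(3 * numtaps, x.size - 1)
    return signal.filtfilt(taps, [1.0], x, padlen=padlen)


def extract_envelope(
    audio: np.ndarray,
    audio_rate: float,
    target_rate: float,
    cutoff: float = ENVELOPE_LOWPASS_HZ,
) -> np.ndarray:
    """Extract the low-pass amplitude envelope of a waveform.

    Returns the magnitude of the analytic signal, low-pass filtered at
    ``cutoff`` Hz (zero-phase) and resampled to ``target_rate``.
    Extraction is amplitude-equivariant: scaling the audio by ``c``
    scales the envelope by ``c``.
    """
    audio = np.asarray(audio, dtype=float)
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio contains non-finite samples")
    if audio_rate <= 2 * cutoff:
        raise ValueError(
            f"audio rate {audio_rate} Hz too low for a {cutoff} Hz envelope"
        )
    if target_rate not in EPOCH_RATES:
        warnings.warn(
            f"target rate {target_rate} Hz is non-standard "
            f"(expected one of {EPOCH_RATES})",
            stacklevel=2,
        )
    env = np.abs(signal.hilbert(audio))
    env = _lowpass_fir(env, audio_rate, cutoff)
    if target_rate != audio_rate:
        env = resample_epoch(env, audio_rate, target_rate)
    return env


def resample_epoch(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Polyphase resampling of an already band-limited epoch (last axis)."""
    if rate_in == rate_out:
        return np.asarray(x, dtype=float)
    g = np.gcd(int(rate_in), int(rate_out))
    return signal.resample_poly(np.asarray(x, dtype=float), int(rate_out) // g,
                                int(rate_in) // g, axis=-1)


def epoch_envelope(
    env: np.ndarray,
    rate: float,
    onsets: np.ndarray,
    duration: float = EPOCH_SECONDS,
) -> list[np.ndarray]:
    """Cut a continuous envelope into fixed-duration line epochs.

    Each epoch has ``round(duration * rate)`` samples.  An onset whose
    window extends past the end of the series raises
    :class:`EpochBoundsError` naming the offending trial.
    """
    env = np.asarray(env, dtype=float)
    n_samples = int(round(duration * rate))
    epochs = []
    for i, onset in enumerate(np.atleast_1d(onsets)):
        start = int(round(onset * rate))
        stop = start + n_samples
        if start < 0 or stop > env.size:
            raise EpochBoundsError(
                f"epoch {i} (onset {onset} s) exceeds the series "
                f"({env.size / rate:.3f} s long)"
            )
        epochs.append(env[start:stop].copy())
    return epochs


def split_segments(values: np.ndarray, n_segments: int = 4) -> list[np.ndarray]:
    """Split a line into ``n_segments`` equal quarters, in temporal order.

    Each segment has ``floor(n / n_segments)`` samples; up to
    ``n_segments - 1`` trailing samples are dropped when the length is
    not divisible (the remainder rule used throughout).
    """
    values = np.asarray(values)
    if values.shape[-1] < 2 * n_segments:
        raise ValueError(
            f"need at least {2 * n_segments} samples to form {n_segments} segments"
        )
    seg_len = values.shape[-1] // n_segments
    return [
        values[..., i * seg_len:(i + 1) * seg_len].copy() for i in range(n_segments)
    ]
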