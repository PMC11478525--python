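"""Audio containers and I/O.

Audio is held as a float64 mono (or stereo) amplitude array in [-1, 1] with
an explicit sample rate.  WAV files are read through :mod:`scipy.io.wavfile`
(PCM 16/24/32-bit and float) and integer formats are rescaled to [-1, 1].
Analysis proceeds at a fixed low rate (8 kHz by default): beat structure
lives far below 4 kHz and the decimation keeps the spectrogram small.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import InvalidInputError

DEFAULT_ANALYSIS_RATE = 8000


@dataclass(frozen=True)
class AudioSignal:
    """A sampled audio waveform.

    Parameters
    ----------
    samples
        Amplitude array, shape ``(n,)`` for mono or ``(n, channels)``.
    sample_rate
        Sampling frequency in Hz, positive.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise InvalidInputError(f"sample_rate must be positive, got {self.sample_rate}")
        if samples.size == 0:
            raise InvalidInputError("empty audio signal")
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("audio contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def is_mono(self) -> bool:
        return self.samples.ndim == 1


def to_mono(audio: AudioSignal) -> AudioSignal:
    """Average channels; a mono signal is returned unchanged."""
    if audio.is_mono:
        return audio
    return AudioSignal(audio.samples.mean(axis=1), audio.sample_rate)


def resample_to_analysis_rate(audio: AudioSignal, target_rate: int = DEFAULT_ANALYSIS_RATE) -> AudioSignal:
    """Convert to mono and resample to ``target_rate``.

    Uses polyphase filtering (:func:`scipy.signal.resample_poly`) with the
    exact rational rate ratio, so duration is preserved to within one
    sample period.  A signal already at the target rate is returned
    unchanged apart from channel averaging.
    """
    if target_rate <= 0:
        raise InvalidInputError(f"target_rate must be positive, got {target_rate}")
    audio = to_mono(audio)
    if audio.sample_rate == target_rate:
        return audio
    ratio = Fraction(int(target_rate), int(audio.sample_rate))
    out = resample_poly(audio.samples, ratio.numerator, ratio.denominator)
    return AudioSignal(out, target_rate)


def load_wav(path: str | Path) -> AudioSignal:
    """Read a WAV file; integer PCM is rescaled to [-1, 1]."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AudioSignal(data, int(rate))


def save_wav(audio: AudioSignal, path: str | Path) -> None:
    """Write 16-bit PCM WAV (clipping to [-1, 1])."""
    clipped = np.clip(audio.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(audio.sample_rate), pcm)
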