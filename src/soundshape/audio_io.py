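"""Audio input/output and waveform conditioning.

All analysis downstream operates on a canonical representation: a mono
float waveform in nominal range [-1, 1] at 44,100 Hz (the rate required for
a filterbank whose top channel sits at 20 kHz). This module reads and writes
RIFF WAV files, mixes multichannel material to mono, resamples, and applies
RMS intensity normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import ArgumentError, AudioFormatError, DegenerateInputError

#: Canonical sampling rate (Hz). The filterbank's 20 kHz top channel needs
#: Nyquist >= 20 kHz; stimuli are synthesized at this rate.
CANONICAL_FS = 44_100

#: Default RMS level applied before acoustic analysis. Balance is a summed
#: energy and therefore gain dependent; fixing intensity upstream makes it
#: comparable across stimuli, mirroring intensity-normalized stimulus sets.
ANALYSIS_RMS = 0.05


@dataclass(frozen=True)
class Waveform:
    """A mono sampled signal.

    Parameters
    ----------
    samples
        Amplitude sequence, dimensionless, nominal range [-1, 1].
    fs
        Sampling rate in Hz, strictly positive.
    label
        Free-text stimulus identifier.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ArgumentError("waveform must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ArgumentError("waveform samples must be finite")
        if not self.fs > 0:
            raise ArgumentError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.fs

    def rms(self) -> float:
        """Root-mean-square amplitude."""
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def scaled(self, gain: float) -> "Waveform":
        """Return a copy scaled by ``gain``."""
        return replace(self, samples=self.samples * gain)


def load_audio(
    path: str | Path,
    target_fs: float | None = CANONICAL_FS,
    label: str | None = None,
) -> Waveform:
    """Read a WAV file as a canonical mono waveform.

    Integer PCM is rescaled to [-1, 1]; multichannel input is mixed to mono
    by channel mean. Unless ``target_fs`` is None, the result is resampled
    to that rate (default: the 44,100 Hz canonical rate).
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except FileNotFoundError:
        raise AudioFormatError(f"audio file not found: {path}") from None
    except Exception as exc:  # wavfile raises bare ValueError on bad RIFF
        raise AudioFormatError(f"cannot read {path} as WAV: {exc}") from exc

    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        # Symmetric scaling by the magnitude of the most negative code.
        scale = float(max(abs(info.min), info.max))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)

    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    elif samples.ndim != 1:
        raise AudioFormatError(f"unsupported channel layout in {path}")

    w = Waveform(samples, float(fs), label=label if label is not None else path.stem)
    if target_fs is not None and fs != target_fs:
        w = resample(w, target_fs)
    return w


def save_audio(w: Waveform, path: str | Path) -> None:
    """Write a waveform as 16-bit PCM WAV."""
    path = Path(path)
    clipped = np.clip(w.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, int(round(w.fs)), pcm)


def resample(w: Waveform, fs_target: float) -> Waveform:
    """Resample to ``fs_target`` Hz, preserving duration within one sample.

    Uses polyphase filtering; for integer rate ratios this is exact in the
    band below the lower Nyquist frequency.
    """
    if not fs_target > 0:
        raise ArgumentError(f"target sampling rate must be positive, got {fs_target}")
    if fs_target == w.fs:
        return w
    # Rational approximation of the rate ratio keeps the polyphase stage exact
    # for the common 22.05k/44.1k/48k conversions.
    from math import gcd

    up = int(round(fs_target))
    down = int(round(w.fs))
    g = gcd(up, down)
    out = resample_poly(w.samples, up // g, down // g)
    return Waveform(out, float(fs_target), label=w.label)


def normalize_rms(w: Waveform, target_rms: float = ANALYSIS_RMS) -> Waveform:
    """Rescale so that the RMS amplitude equals ``target_rms``.

    Idempotent and gain-invariant: any positive rescaling of the input maps
    to the same output.
    """
    if not target_rms > 0:
        raise ArgumentError(f"target RMS must be positive, got {target_rms}")
    current = w.rms()
    if current == 0.0:
        raise DegenerateInputError(
            f"cannot RMS-normalize all-zero waveform {w.label!r}"
        )
    return w.scaled(target_rms / current)
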