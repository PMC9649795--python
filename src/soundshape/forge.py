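"""Synthetic stimulus generation.

Three corpora cover the stimulus classes used in round/spiky judgment
experiments, so the full analysis loop is testable without external audio:

* **Noise bands** — 500 ms bands of white noise through a resonant (formant)
  filter at one of eight center frequencies (300-1200 Hz, bandwidth fc/10),
  amplitude-modulated by a 225-275 ms envelope dip at relative depth
  {0, 0.1, 0.5, 1}; the 8 x 4 factorial gives 32 stimuli.
* **Impact sounds** ("beating") — modal synthesis of struck-membrane sounds
  whose mode frequencies follow a two-term Weyl counting law driven by area
  and perimeter. For equal area, the disk minimizes the perimeter, so round
  drums get lower modes than spiky (large-perimeter) drums: the corpus
  realizes the round-low / spiky-high spectral contrast (round energy mostly
  below 500 Hz, spiky mostly within 500-2000 Hz). 5 round + 5 spiky objects
  x 3 instances = 30 sounds, 200-220 ms.
* **Rolling sounds** — ~200 ms noise carriers with smooth (slow, < 6 dB)
  or sharp (> 8 dB within < 40 ms) amplitude envelopes on wood/plastic
  spectral-tilt presets; 2 shapes x 2 surfaces x 3 instances = 12 originals.
  Their envelopes are extracted and transplanted onto two spectrally shaped
  noise carriers (low-frequency from the smooth-shape mean spectrum,
  high-frequency from the sharp-shape one), adding 24 synthetic stimuli for
  a total of 36.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from . import cochlear
from .audio_io import ANALYSIS_RMS, CANONICAL_FS, Waveform, normalize_rms
from .errors import ArgumentError, DegenerateInputError
from .types import SpectralProfile

__all__ = [
    "NoiseBandSpec",
    "DrumSpec",
    "RollSpec",
    "Envelope",
    "make_noise_band",
    "noise_band_corpus",
    "weyl_modes",
    "synth_impact",
    "beating_corpus",
    "synth_roll",
    "extract_envelope",
    "envelope_db_range",
    "shaped_noise",
    "transplant_envelope",
    "rolling_corpus",
    "scored_noise_corpus",
]

# ---------------------------------------------------------------------------
# noise bands

NOISE_BAND_FCS = (300.0, 500.0, 600.0, 700.0, 800.0, 900.0, 1000.0, 1200.0)
NOISE_BAND_DIPS = (0.0, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class NoiseBandSpec:
    """One amplitude-modulated noise band.

    ``dip_amp`` is the envelope level inside the dip window relative to the
    flanks: 0 is a silent dip, 1 no dip at all. The filter bandwidth is
    always fc/10.
    """

    fc: float
    dip_amp: float
    duration: float = 0.5
    dip_window: tuple[float, float] = (0.225, 0.275)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fc > 0:
            raise ArgumentError(f"center frequency must be positive, got {self.fc}")
        if not 0.0 <= self.dip_amp <= 1.0:
            raise ArgumentError(f"dip amplitude must be in [0, 1], got {self.dip_amp}")
        lo, hi = self.dip_window
        if not (0.0 < lo < hi < self.duration):
            raise ArgumentError(
                f"dip window {self.dip_window} must lie inside (0, {self.duration})"
            )

    @property
    def bandwidth(self) -> float:
        return self.fc / 10.0


def _raised_cosine_ramp(n: int) -> np.ndarray:
    """Half raised-cosine from 0 to 1 over n samples."""
    return 0.5 * (1.0 - np.cos(np.pi * np.arange(n) / max(n, 1)))


def _flat_spectrum_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """White noise with random phase but exactly flat magnitude spectrum.

    The factorial noise-band design manipulates spectral balance through the
    filter center frequency; flat-magnitude excitation makes the realized
    band energy a deterministic function of the filter rather than of the
    noise draw, so the manipulated quantity carries no realization variance.
    """
    spec = np.exp(2j * np.pi * rng.random(n // 2 + 1))
    spec[0] = 1.0
    if n % 2 == 0:
        spec[-1] = np.sign(spec[-1].real) or 1.0
    x = np.fft.irfft(spec, n=n)
    return x / np.sqrt(np.mean(x**2))


def make_noise_band(spec: NoiseBandSpec, fs: float = CANONICAL_FS) -> Waveform:
    """Synthesize one noise-band stimulus.

    White noise is passed through a second-order resonator (-3 dB bandwidth
    fc/10), its intrinsic narrowband amplitude fluctuation is flattened so
    the envelope really is constant outside the dip, and the dip envelope is
    applied. 5 ms raised-cosine onset/offset ramps and 2 ms transitions into
    and out of the dip avoid spectral splatter from hard edges.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * fs))
    noise = _flat_spectrum_noise(rng, n)
    b, a = signal.iirpeak(spec.fc, Q=10.0, fs=fs)
    banded = signal.lfilter(b, a, noise)

    # Narrowband noise fades by several dB on its own; divide out the slow
    # analytic envelope so only the designed dip modulates the stimulus.
    magnitude = np.abs(signal.hilbert(banded))
    lp_b, lp_a = signal.butter(2, 20.0, btype="low", fs=fs)
    slow = signal.filtfilt(lp_b, lp_a, magnitude)
    slow = np.maximum(slow, 0.05 * np.median(slow))
    banded = banded / slow

    env = np.ones(n)
    lo = int(round(spec.dip_window[0] * fs))
    hi = int(round(spec.dip_window[1] * fs))
    ramp = int(round(0.002 * fs))
    env[lo + ramp : hi - ramp] = spec.dip_amp
    down = 1.0 - (1.0 - spec.dip_amp) * _raised_cosine_ramp(ramp)
    env[lo : lo + ramp] = down
    env[hi - ramp : hi] = down[::-1]

    edge = int(round(0.005 * fs))
    env[:edge] *= _raised_cosine_ramp(edge)
    env[n - edge :] *= _raised_cosine_ramp(edge)[::-1]

    label = f"nb_fc{int(spec.fc)}_dip{spec.dip_amp:g}"
    w = Waveform(banded * env, fs, label=label)
    return normalize_rms(w, 0.1)


def noise_band_corpus(
    master_seed: int = 0, fs: float = CANONICAL_FS
) -> tuple[list[Waveform], pd.DataFrame]:
    """Full 8 fc x 4 dip factorial: 32 stimuli plus their design table.

    Each band is realized once per center frequency (one derived seed per
    fc) and its four dip variants share that realization — the dip is an
    envelope manipulation of an existing band, so Continuity is monotone in
    dip depth by construction, not merely in expectation.
    """
    ss = np.random.SeedSequence(master_seed)
    seeds = ss.generate_state(len(NOISE_BAND_FCS)) % (2**31)
    waves: list[Waveform] = []
    rows = []
    for fc, seed in zip(NOISE_BAND_FCS, seeds):
        for dip in NOISE_BAND_DIPS:
            spec = NoiseBandSpec(fc=fc, dip_amp=dip, seed=int(seed))
            w = make_noise_band(spec, fs)
            waves.append(w)
            rows.append(
                {
                    "stimulus": w.label,
                    "fc": fc,
                    "dip_amp": dip,
                    "seed": int(seed),
                }
            )
    return waves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# impact sounds (Weyl/Kac modal synthesis)

#: Perimeter weight amplifying the counting law's perimeter correction so the
#: round/spiky band contrast of the impact corpus is audible at small mode
#: counts; the literal membrane value (1) shifts modes by only a few percent.
PERIMETER_WEIGHT = 8.0

#: Fundamental frequency (Hz) of the unit-area round drum; fixes the wave
#: speed constant of the counting law.
ROUND_DISK_F0 = 220.0


def _default_wave_speed(perimeter_weight: float = PERIMETER_WEIGHT) -> float:
    g = perimeter_weight
    return 2.0 * ROUND_DISK_F0 * np.sqrt(np.pi) / (g + np.sqrt(g * g + 4.0))


@dataclass(frozen=True)
class DrumSpec:
    """A struck membrane: area, perimeter and synthesis parameters."""

    area: float
    perimeter: float
    n_modes: int = 80
    damping: float = 18.0
    duration: float = 0.21
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ArgumentError(f"area must be positive, got {self.area}")
        min_perimeter = 2.0 * np.sqrt(np.pi * self.area)
        if self.perimeter < min_perimeter * (1.0 - 1e-9):
            raise ArgumentError(
                f"perimeter {self.perimeter:.4f} below the isoperimetric minimum "
                f"{min_perimeter:.4f} for area {self.area}"
            )
        if self.n_modes < 1:
            raise ArgumentError("need at least one mode")
        if not self.damping > 0:
            raise ArgumentError("damping must be positive")
        if not 0.200 <= self.duration <= 0.220:
            raise ArgumentError(
                f"impact duration must be within [0.200, 0.220] s, got {self.duration}"
            )

    @classmethod
    def round_drum(cls, area: float, **kwargs) -> "DrumSpec":
        """Minimal-perimeter (disk) drum of the given area."""
        return cls(area=area, perimeter=2.0 * np.sqrt(np.pi * area), **kwargs)

    @classmethod
    def spiky_drum(cls, area: float, perimeter_factor: float = 1.6, **kwargs) -> "DrumSpec":
        """Same-area drum with the disk perimeter inflated by ``perimeter_factor``."""
        return cls(
            area=area,
            perimeter=perimeter_factor * 2.0 * np.sqrt(np.pi * area),
            **kwargs,
        )


def weyl_modes(
    area: float,
    perimeter: float,
    n_modes: int,
    wave_speed: float | None = None,
    perimeter_weight: float = PERIMETER_WEIGHT,
) -> np.ndarray:
    """Mode frequencies from a two-term area/perimeter counting law.

    The cumulative mode count is modeled as N(f) = a f^2 - p f with
    a = pi*area/c^2 and p = perimeter_weight * perimeter / (2 c): the leading
    term grows with area, the negative correction with perimeter. Solving
    N(f_k) = k for k = 1..n gives ascending frequencies; at fixed area a
    larger perimeter raises every mode, and for fixed area the disk (minimal
    perimeter) has the lowest modes.
    """
    spec = DrumSpec(area=area, perimeter=perimeter, n_modes=n_modes)
    c = _default_wave_speed(perimeter_weight) if wave_speed is None else wave_speed
    if not c > 0:
        raise ArgumentError(f"wave speed must be positive, got {c}")
    a = np.pi * spec.area / (c * c)
    p = perimeter_weight * spec.perimeter / (2.0 * c)
    k = np.arange(1, n_modes + 1, dtype=np.float64)
    freqs = (p + np.sqrt(p * p + 4.0 * a * k)) / (2.0 * a)
    if freqs[-1] >= cochlear.DEFAULT_FMAX:
        raise ArgumentError(
            f"top mode {freqs[-1]:.0f} Hz exceeds the analyzable range; "
            "reduce n_modes or increase area"
        )
    return freqs


def synth_impact(spec: DrumSpec, fs: float = CANONICAL_FS) -> Waveform:
    """Render an impact as exponentially damped sinusoids at the Weyl modes.

    Mode amplitudes fall off as 1/k with +-10% seeded jitter and random
    phases; a 4 ms broadband contact click precedes the ring-down. Output is
    RMS-normalized (impact sets were intensity-normalized).
    """
    rng = np.random.default_rng(spec.seed)
    freqs = weyl_modes(spec.area, spec.perimeter, spec.n_modes)
    k = np.arange(1, spec.n_modes + 1, dtype=np.float64)
    amps = k**-1.0 * rng.uniform(0.9, 1.1, size=spec.n_modes)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_modes)

    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    y = np.zeros(n)
    decay = np.exp(-spec.damping * t)
    for a_k, f_k, ph in zip(amps, freqs, phases):
        y += a_k * np.sin(2.0 * np.pi * f_k * t + ph)
    y *= decay

    # Contact transient: a short, quiet broadband click at the onset.
    click_n = int(round(0.004 * fs))
    click = rng.standard_normal(click_n) * _raised_cosine_ramp(click_n)[::-1]
    y[:click_n] += click * (0.05 * np.sqrt(np.mean(y**2)) / max(np.sqrt(np.mean(click**2)), 1e-12))

    edge = int(round(0.002 * fs))
    y[:edge] *= _raised_cosine_ramp(edge)
    tail = int(round(0.005 * fs))
    y[n - tail :] *= _raised_cosine_ramp(tail)[::-1]

    return normalize_rms(Waveform(y, fs, label=f"impact_s{spec.seed}"), 0.1)


#: Areas of the five object pairs; spiky counterparts share the area of their
#: round partner and inflate the disk perimeter by the paired factor.
BEATING_AREAS = (0.25, 0.30, 0.35, 0.40, 0.45)
BEATING_PERIMETER_FACTORS = (1.4, 1.5, 1.6, 1.7, 1.8)
BEATING_INSTANCES = 3


def beating_corpus(
    master_seed: int = 0, fs: float = CANONICAL_FS
) -> tuple[list[Waveform], pd.DataFrame]:
    """30 impact sounds: 5 round and 5 spiky objects, 3 instances each."""
    ss = np.random.SeedSequence(master_seed)
    n_objects = len(BEATING_AREAS)
    seeds = ss.generate_state(2 * n_objects * BEATING_INSTANCES) % (2**31)
    waves: list[Waveform] = []
    rows = []
    k = 0
    for category in ("round", "spiky"):
        for obj in range(n_objects):
            area = BEATING_AREAS[obj]
            for inst in range(BEATING_INSTANCES):
                seed = int(seeds[k])
                rng = np.random.default_rng(seed)
                duration = float(rng.uniform(0.200, 0.220))
                if category == "round":
                    spec = DrumSpec.round_drum(area, duration=duration, seed=seed)
                else:
                    spec = DrumSpec.spiky_drum(
                        area,
                        perimeter_factor=BEATING_PERIMETER_FACTORS[obj],
                        duration=duration,
                        seed=seed,
                    )
                w = synth_impact(spec, fs)
                label = f"beat_{category}{obj + 1}_i{inst + 1}"
                w = Waveform(w.samples, w.fs, label=label)
                waves.append(w)
                rows.append(
                    {
                        "stimulus": label,
                        "category": category,
                        "object": obj + 1,
                        "instance": inst + 1,
                        "area": area,
                        "perimeter": spec.perimeter,
                        "duration": duration,
                        "seed": seed,
                    }
                )
                k += 1
    return waves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rolling sounds, envelopes, shaped noise

#: Envelope extraction parameters: rectification followed by a low-pass at
#: 32 Hz keeps the 40 ms-scale fluctuations that distinguish smooth from
#: sharp trajectories, sampled at a 1 kHz envelope rate.
ENVELOPE_CUTOFF = 32.0
ENVELOPE_RATE = 1000.0


@dataclass(frozen=True)
class Envelope:
    """A nonnegative amplitude envelope sampled at ``rate`` Hz."""

    values: np.ndarray
    rate: float = ENVELOPE_RATE

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size < 1:
            raise ArgumentError("envelope must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ArgumentError("envelope values must be finite and nonnegative")
        if not self.rate > 0:
            raise ArgumentError("envelope rate must be positive")
        object.__setattr__(self, "values", v)

    @property
    def duration(self) -> float:
        return self.values.size / self.rate


@dataclass(frozen=True)
class RollSpec:
    """A rolling-object sound: envelope shape and surface preset."""

    shape: str  # "smooth" | "sharp"
    surface: str = "wood"  # "wood" | "plastic"
    duration: float = 0.200
    seed: int = 0
    n_bursts: int = 4  # sharp only: number of impulsive contact events

    def __post_init__(self) -> None:
        if self.shape not in ("smooth", "sharp"):
            raise ArgumentError(f"shape must be 'smooth' or 'sharp', got {self.shape!r}")
        if self.surface not in ("wood", "plastic"):
            raise ArgumentError(
                f"surface must be 'wood' or 'plastic', got {self.surface!r}"
            )
        if not self.duration > 0.08:
            raise ArgumentError("rolling sound must exceed 80 ms")


def _tilt_filter(x: np.ndarray, fs: float, db_per_octave: float) -> np.ndarray:
    """Apply a constant spectral tilt (dB/octave) in the frequency domain."""
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, d=1.0 / fs)
    ref = 1000.0
    gain = np.ones_like(f)
    pos = f > 0
    gain[pos] = (f[pos] / ref) ** (db_per_octave / (20.0 * np.log10(2.0)))
    return np.fft.irfft(spec * gain, n=x.size)


def synth_roll(spec: RollSpec, fs: float = CANONICAL_FS) -> Waveform:
    """Synthesize one rolling-object sound.

    Smooth rolls: a low-frequency noise band under a slow shallow amplitude
    modulation (global swing < 6 dB, so every > 40 ms window stays < 6 dB).
    Sharp rolls: a high-frequency noise band punctuated by brief contact
    bursts, each raising the envelope by > 8 dB within < 40 ms. Wood vs
    plastic differ only by a fixed +-3 dB/octave spectral tilt.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * fs))
    noise = rng.standard_normal(n)
    if spec.shape == "smooth":
        b, a = signal.butter(4, [100.0, 700.0], btype="bandpass", fs=fs)
    else:
        b, a = signal.butter(4, [900.0, 3000.0], btype="bandpass", fs=fs)
    carrier = signal.lfilter(b, a, noise)
    tilt = 3.0 if spec.surface == "wood" else -3.0
    carrier = _tilt_filter(carrier, fs, tilt if spec.shape == "smooth" else -tilt)

    # Flatten the carrier's intrinsic envelope so the amplitude trajectory
    # is exactly the designed one (the dB constraints are on the envelope).
    magnitude = np.abs(signal.hilbert(carrier))
    lp_b, lp_a = signal.butter(2, 20.0, btype="low", fs=fs)
    slow = signal.filtfilt(lp_b, lp_a, magnitude)
    slow = np.maximum(slow, 0.05 * np.median(slow))
    carrier = carrier / slow

    t = np.arange(n) / fs
    if spec.shape == "smooth":
        # two slow seeded sinusoids, total log-amplitude swing <= +-0.15 nepers
        f1, f2 = rng.uniform(3.0, 5.0), rng.uniform(6.0, 8.0)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        env = np.exp(0.10 * np.sin(2 * np.pi * f1 * t + ph1)
                     + 0.05 * np.sin(2 * np.pi * f2 * t + ph2))
    else:
        env = np.ones(n)
        margin = 0.03
        times = rng.uniform(margin, spec.duration - margin, size=spec.n_bursts)
        sigma = 0.008
        for tc in times:
            env += 4.0 * np.exp(-0.5 * ((t - tc) / sigma) ** 2)

    y = carrier * env
    edge = int(round(0.005 * fs))
    y[:edge] *= _raised_cosine_ramp(edge)
    y[n - edge :] *= _raised_cosine_ramp(edge)[::-1]
    label = f"roll_{spec.shape}_{spec.surface}_s{spec.seed}"
    return normalize_rms(Waveform(y, fs, label=label), 0.1)


def extract_envelope(w: Waveform, cutoff: float = ENVELOPE_CUTOFF,
                     rate: float = ENVELOPE_RATE) -> Envelope:
    """Amplitude envelope: full-wave rectification, low-pass, decimation.

    The zero-phase low-pass (4th-order Butterworth, default 32 Hz) smooths
    carrier fluctuations while preserving modulation at the tens-of-ms scale;
    the result is sampled at the envelope rate (default 1 kHz). The operation
    is linear in input gain.
    """
    rectified = np.abs(w.samples)
    b, a = signal.butter(4, cutoff, btype="low", fs=w.fs)
    smooth = signal.filtfilt(b, a, rectified)
    np.maximum(smooth, 0.0, out=smooth)
    times = np.arange(int(np.floor(w.duration * rate))) / rate
    values = np.interp(times, np.arange(w.samples.size) / w.fs, smooth)
    return Envelope(values=values, rate=rate)


def envelope_db_range(env: Envelope, window: float, edge_trim: float = 0.10) -> float:
    """Largest peak-to-trough dB range within any sliding window.

    Used to verify the smooth/sharp envelope constraints: smooth rolls keep
    every window longer than 40 ms under 6 dB; sharp rolls show at least one
    excursion above 8 dB within less than 40 ms. The first and last
    ``edge_trim`` fraction are excluded so onset/offset ramps do not count
    as excursions.
    """
    v = env.values
    k = int(np.floor(edge_trim * v.size))
    v = v[k : v.size - k] if v.size - 2 * k >= 2 else v
    wlen = max(2, int(round(window * env.rate)))
    if wlen >= v.size:
        wlen = v.size
    floor = max(v.max(), 1e-300) * 1e-6
    v = np.maximum(v, floor)
    windows = np.lib.stride_tricks.sliding_window_view(v, wlen)
    ratios = windows.max(axis=1) / windows.min(axis=1)
    return float(20.0 * np.log10(ratios.max()))


def shaped_noise(
    profile: SpectralProfile,
    duration: float,
    seed: int = 0,
    fs: float = CANONICAL_FS,
    n_iter: int = 4,
) -> Waveform:
    """Stationary noise whose cochleagram mean spectrum matches ``profile``.

    Iterative analysis-resynthesis: starting from white noise, per-channel
    gains sqrt(target/current) are interpolated across frequency and applied
    in the Fourier domain until the long-run mean spectrum matches the
    target (within ~3 dB on channels carrying appreciable energy).
    """
    if profile.center_freqs is None:
        raise ArgumentError("shaped_noise needs a profile with center frequencies")
    target = np.asarray(profile.S, dtype=np.float64)
    if not np.any(target > 0):
        raise DegenerateInputError("all-zero spectral profile")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = rng.standard_normal(n)
    cfs = profile.center_freqs
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    tiny = target[target > 0].min() * 1e-8
    for _ in range(n_iter):
        w = normalize_rms(Waveform(x, fs, label="shaped"), ANALYSIS_RMS)
        current = cochlear.mean_spectrum(
            cochlear.cochleagram(w, n_channels=target.size)
        ).S
        log_gain = 0.5 * (
            np.log(np.maximum(target, tiny)) - np.log(np.maximum(current, tiny))
        )
        interp = np.interp(freqs, cfs, log_gain, left=log_gain[0], right=log_gain[-1])
        x = np.fft.irfft(np.fft.rfft(x) * np.exp(interp), n=n)
    out = normalize_rms(Waveform(x, fs, label="shaped"), 0.1)
    return out


def transplant_envelope(
    env: Envelope,
    carrier: Waveform,
    target_rms: float = 0.1,
    label: str | None = None,
) -> Waveform:
    """Impose an envelope on a carrier: multiply, trim, RMS-normalize.

    The carrier must be at least as long as the envelope; the output has the
    envelope's duration.
    """
    n = int(round(env.duration * carrier.fs))
    if carrier.samples.size < n:
        raise ArgumentError(
            f"carrier ({carrier.duration:.3f} s) shorter than envelope "
            f"({env.duration:.3f} s)"
        )
    times = np.arange(n) / carrier.fs
    env_up = np.interp(times, np.arange(env.values.size) / env.rate, env.values)
    y = carrier.samples[:n] * env_up
    out = Waveform(y, carrier.fs, label=label or f"{carrier.label}_xplant")
    return normalize_rms(out, target_rms)


ROLL_SURFACES = ("wood", "plastic")
ROLL_INSTANCES = 3


def rolling_corpus(
    master_seed: int = 0, fs: float = CANONICAL_FS
) -> tuple[list[Waveform], pd.DataFrame]:
    """36 rolling stimuli: 12 originals plus 24 envelope transplants.

    Originals: smooth/sharp x wood/plastic x 3 instances. Two shaped-noise
    carriers are built from the mean spectra of the smooth (low-frequency,
    LF) and sharp (high-frequency, HF) originals; each of the 12 extracted
    envelopes is transplanted onto both, crossing Acoustic Envelope
    {smooth, sharp} x Spectral Balance {LF, HF} with 6 stimuli per cell.
    """
    ss = np.random.SeedSequence(master_seed)
    seeds = ss.generate_state(2 * len(ROLL_SURFACES) * ROLL_INSTANCES + 2) % (2**31)
    waves: list[Waveform] = []
    rows = []
    k = 0
    for shape in ("smooth", "sharp"):
        for surface in ROLL_SURFACES:
            for inst in range(ROLL_INSTANCES):
                spec = RollSpec(shape=shape, surface=surface, seed=int(seeds[k]))
                w = synth_roll(spec, fs)
                label = f"roll_{shape}_{surface}_i{inst + 1}"
                w = Waveform(w.samples, w.fs, label=label)
                waves.append(w)
                rows.append(
                    {
                        "stimulus": label,
                        "kind": "original",
                        "envelope_shape": shape,
                        "carrier": "original",
                        "surface": surface,
                        "instance": inst + 1,
                        "seed": int(seeds[k]),
                    }
                )
                k += 1

    def _mean_profile(ws: list[Waveform]) -> SpectralProfile:
        mats = [
            cochlear.mean_spectrum(
                cochlear.cochleagram(normalize_rms(w, ANALYSIS_RMS))
            ).S
            for w in ws
        ]
        cfs = cochlear.erb_center_frequencies()
        return SpectralProfile(S=np.mean(mats, axis=0), center_freqs=cfs)

    smooth_profile = _mean_profile(waves[:6])
    sharp_profile = _mean_profile(waves[6:12])
    carriers = {
        "LF": shaped_noise(smooth_profile, duration=0.25, seed=int(seeds[k]), fs=fs),
        "HF": shaped_noise(sharp_profile, duration=0.25, seed=int(seeds[k + 1]), fs=fs),
    }

    originals = list(waves)
    for w, row in zip(originals, rows[:12]):
        env = extract_envelope(w)
        for carrier_name, carrier in carriers.items():
            label = f"xplant_{row['envelope_shape']}_{row['surface']}_i{row['instance']}_{carrier_name}"
            out = transplant_envelope(env, carrier, label=label)
            waves.append(out)
            rows.append(
                {
                    "stimulus": label,
                    "kind": "synthetic",
                    "envelope_shape": row["envelope_shape"],
                    "carrier": carrier_name,
                    "surface": row["surface"],
                    "instance": row["instance"],
                    "seed": row["seed"],
                }
            )
    return waves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic scored experiment for boundary recovery

def scored_noise_corpus(
    n_stimuli: int = 60,
    b_true: int = 25,
    sigma_frac: float = 0.05,
    master_seed: int = 0,
    fc_range: tuple[float, float] = (300.0, 2400.0),
    fs: float = CANONICAL_FS,
) -> tuple[list[Waveform], pd.DataFrame, list]:
    """Noise-band set with scores linear in Balance at a known boundary.

    Center frequencies are log-spaced across ``fc_range`` so spectral energy
    sweeps through the whole boundary-scan region. Noiseless scores map the
    Balance values at ``b_true`` linearly onto [0, 100]; Gaussian noise with
    standard deviation ``sigma_frac`` of that range is added. Returns the
    stimuli, the design/score table, and the per-stimulus index results
    (already computed for the score construction, so recovery studies need
    not re-analyze the audio).
    """
    from . import indices as indices_mod

    ss = np.random.SeedSequence(master_seed)
    seeds = ss.generate_state(n_stimuli + 1) % (2**31)
    fcs = np.geomspace(fc_range[0], fc_range[1], n_stimuli)
    waves = []
    for i, fc in enumerate(fcs):
        spec = NoiseBandSpec(fc=float(fc), dip_amp=1.0, seed=int(seeds[i]))
        w = make_noise_band(spec, fs)
        waves.append(Waveform(w.samples, w.fs, label=f"sweep_{i:03d}"))

    results = indices_mod.analyze_corpus(waves, continuity_eligible=False)
    bal = np.array([r.balance(b_true) for r in results])
    span = bal.max() - bal.min()
    clean = 100.0 * (bal - bal.min()) / span
    rng = np.random.default_rng(int(seeds[-1]))
    scores = clean + rng.normal(0.0, sigma_frac * 100.0, size=n_stimuli)
    table = pd.DataFrame(
        {
            "stimulus": [w.label for w in waves],
            "round_score": scores,
            "scale_min": -100.0,
            "scale_max": 200.0,
            "fc": fcs,
            "balance_true": bal,
        }
    )
    return waves, table, results
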