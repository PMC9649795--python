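"""Shared fixtures: small synthesized corpora, reused across test modules."""

import numpy as np
import pytest

from soundshape import forge, indices
from soundshape.audio_io import Waveform

FS = 44_100


@pytest.fixture(scope="session")
def tone():
    """Factory for pure-tone waveforms."""

    def _tone(freq, duration=0.5, fs=FS, amp=0.1):
        t = np.arange(int(round(duration * fs))) / fs
        return Waveform(amp * np.sin(2 * np.pi * freq * t), fs, label=f"tone{freq}")

    return _tone


@pytest.fixture(scope="session")
def noise_band_set():
    """Noise-band factorial corpus (seed 1) with its index analysis."""
    waves, design = forge.noise_band_corpus(1)
    results = indices.analyze_corpus(waves)
    return waves, design, results


@pytest.fixture(scope="session")
def beating_set():
    """Impact-sound corpus (seed 1) with its index analysis."""
    waves, design = forge.beating_corpus(1)
    results = indices.analyze_corpus(waves, continuity_eligible=False)
    return waves, design, results


@pytest.fixture(scope="session")
def rolling_set():
    """Rolling-sound corpus (seed 1) with its index analysis."""
    waves, design = forge.rolling_corpus(1)
    results = indices.analyze_corpus(waves)
    return waves, design, results
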