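"""Core container types for the time-frequency representation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError


@dataclass(frozen=True)
class Cochleagram:
    """Channels x frames matrix of nonnegative frame energies.

    ``energy[i, t]`` is the mean squared output of gammatone channel ``i``
    (ascending center frequencies) within frame ``t``, on a linear power
    scale.
    """

    energy: np.ndarray
    center_freqs: np.ndarray
    frame_len: float
    frame_hop: float
    fs_origin: float

    def __post_init__(self) -> None:
        energy = np.asarray(self.energy, dtype=np.float64)
        cfs = np.asarray(self.center_freqs, dtype=np.float64)
        if energy.ndim != 2 or energy.shape[1] < 1:
            raise ArgumentError("cochleagram energy must be a 2-D matrix with >= 1 frame")
        if energy.shape[0] != cfs.size:
            raise ArgumentError("channel count mismatch between energy and center_freqs")
        if np.any(energy < 0) or not np.all(np.isfinite(energy)):
            raise ArgumentError("cochleagram energies must be finite and nonnegative")
        if np.any(np.diff(cfs) <= 0):
            raise ArgumentError("center frequencies must be strictly increasing")
        object.__setattr__(self, "energy", energy)
        object.__setattr__(self, "center_freqs", cfs)

    @property
    def n_channels(self) -> int:
        return self.energy.shape[0]

    @property
    def n_frames(self) -> int:
        return self.energy.shape[1]


@dataclass(frozen=True)
class SpectralProfile:
    """Mean spectrum: per-channel energy averaged over frames."""

    S: np.ndarray
    center_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=np.float64)
        if S.ndim != 1 or S.size < 2:
            raise ArgumentError("spectral profile must be a 1-D vector of >= 2 channels")
        if np.any(S < 0) or not np.all(np.isfinite(S)):
            raise ArgumentError("spectral profile values must be finite and nonnegative")
        object.__setattr__(self, "S", S)
        if self.center_freqs is not None:
            cfs = np.asarray(self.center_freqs, dtype=np.float64)
            if cfs.size != S.size:
                raise ArgumentError("center_freqs length must match profile length")
            object.__setattr__(self, "center_freqs", cfs)

    @property
    def n_channels(self) -> int:
        return self.S.size


@dataclass(frozen=True)
class EnergyTrack:
    """Per-frame energy summed across channels."""

    E: np.ndarray
    frame_hop: float = 0.010

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=np.float64)
        if E.ndim != 1 or E.size < 1:
            raise ArgumentError("energy track must be a non-empty 1-D vector")
        if np.any(E < 0) or not np.all(np.isfinite(E)):
            raise ArgumentError("energy track values must be finite and nonnegative")
        object.__setattr__(self, "E", E)

    @property
    def n_frames(self) -> int:
        return self.E.size
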