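"""Shared data containers for scanning-EMG recordings and needle tracks.

A scan consists of stimulus-locked EMG sweeps acquired while a needle
electrode is withdrawn by hand through a motor unit in small steps, together
with the needle-tip and fascial-landmark coordinates labelled on the
concurrent ultrasound image at each position.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScanRecording", "NeedleTrack"]


@dataclass
class ScanRecording:
    """Stimulus-locked EMG sweeps for one scan.

    Parameters
    ----------
    sweeps
        Array of shape ``(n_positions, sweeps_per_position, n_samples)``
        in microvolts. Position index 0 is the deepest (pre-withdrawal)
        needle position.
    sampling_rate_hz
        Acquisition sampling rate in Hz.
    stim_onset_index
        Sample index of stimulus delivery within each sweep; samples before
        it are pre-stimulus baseline.
    """

    sweeps: np.ndarray
    sampling_rate_hz: float
    stim_onset_index: int

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 3:
            raise ValueError(
                "sweeps must be (n_positions, sweeps_per_position, n_samples), "
                f"got shape {self.sweeps.shape}"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not 0 <= self.stim_onset_index < self.sweeps.shape[2]:
            raise ValueError("stim_onset_index outside the sweep")

    @property
    def n_positions(self) -> int:
        return self.sweeps.shape[0]

    @property
    def sweeps_per_position(self) -> int:
        return self.sweeps.shape[1]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[2]

    def time_ms(self) -> np.ndarray:
        """Sweep time axis in ms, 0 at stimulus delivery."""
        idx = np.arange(self.n_samples) - self.stim_onset_index
        return idx * 1000.0 / self.sampling_rate_hz


@dataclass
class NeedleTrack:
    """Needle-tip and landmark image coordinates for each needle position.

    Coordinates are image pixels (x rightward, y increasing with depth),
    as labelled on the ultrasound frame at each position. Exactly three
    fascial-plane landmarks are tracked; their common motion estimates
    probe drift / tissue distortion.
    """

    needle_xy: np.ndarray  # (n_positions, 2)
    landmarks_xy: np.ndarray  # (n_positions, 3, 2)
    pixel_spacing_mm: float = field(default=0.1)

    def __post_init__(self) -> None:
        self.needle_xy = np.asarray(self.needle_xy, dtype=float)
        self.landmarks_xy = np.asarray(self.landmarks_xy, dtype=float)
        if self.needle_xy.ndim != 2 or self.needle_xy.shape[1] != 2:
            raise ValueError("needle_xy must have shape (n_positions, 2)")
        if self.landmarks_xy.shape != (self.needle_xy.shape[0], 3, 2):
            raise ValueError(
                "landmarks_xy must have shape (n_positions, 3, 2) matching "
                f"needle_xy; got {self.landmarks_xy.shape}"
            )
        if np.isnan(self.landmarks_xy).any():
            raise ValueError("missing landmark coordinate (NaN)")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def n_positions(self) -> int:
        return self.needle_xy.shape[0]
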