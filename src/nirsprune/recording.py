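"""Core container for two-wavelength fNIRS intensity recordings.

A recording holds raw light intensities for ``n_channels`` source-detector
pairs at two wavelengths, sampled at a fixed rate, plus the participant
metadata (id, age in months, cohort, task) that the downstream statistical
stage uses as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RawIntensityRecording", "window_bounds"]


@dataclass
class RawIntensityRecording:
    """Raw two-wavelength intensity time series for one participant.

    Parameters
    ----------
    intensity : ndarray, shape (n_channels, 2, n_samples)
        Raw detector intensities; axis 1 indexes the two wavelengths in
        the order given by ``wavelengths``.
    sampling_rate : float
        Sampling frequency in Hz.
    wavelengths : tuple of float
        Source wavelengths in nm, e.g. ``(780.0, 850.0)``.
    participant : dict
        Free-form metadata; recognised keys are ``id``, ``age_months``,
        ``cohort`` and ``task``.
    """

    intensity: np.ndarray
    sampling_rate: float
    wavelengths: tuple[float, float] = (780.0, 850.0)
    participant: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValueError(
                "intensity must have shape (n_channels, 2, n_samples), "
                f"got {self.intensity.shape}"
            )
        if self.intensity.shape[0] == 0:
            raise ValueError("recording must contain at least one channel")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.wavelengths) != 2:
            raise ValueError("exactly two wavelengths are required")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, index: int) -> np.ndarray:
        """Return the (2, n_samples) intensity block for one channel."""
        return self.intensity[index]


def window_bounds(n_samples: int, sampling_rate: float, window_s: float = 3.0) -> list[tuple[int, int]]:
    """Partition ``[0, n_samples)`` into non-overlapping analysis windows.

    Windows are 0-based half-open sample ranges of length
    ``round(window_s * sampling_rate)`` starting at sample 0; a trailing
    partial window is discarded.
    """
    length = int(round(window_s * sampling_rate))
    if length < 2:
        raise ValueError("window must span at least 2 samples")
    n_windows = n_samples // length
    return [(k * length, (k + 1) * length) for k in range(n_windows)]
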