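"""Per-channel motion-artifact detection and clean-window derivation.

Detection follows the Homer-style per-channel amplitude/variance criterion:
the working signal is the optical-density change dOD(t) = -ln(I(t)/mean(I))
per wavelength; a sample is flagged when any ``t_motion``-second window
covering it has a signal range (max - min) exceeding either ``amp_thresh``
or ``stdev_thresh`` times the whole-series standard deviation of the
sample-to-sample differences. Flags are dilated by ``t_mask`` seconds on
each side (truncated at the recording edges, no wraparound), and a flag on
either wavelength flags the channel.

The raw-intensity-to-dOD conversion is isolated in :func:`optical_density`
so the detector's working space can be changed in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .recording import RawIntensityRecording, window_bounds

__all__ = [
    "MotionConfig",
    "MotionMask",
    "optical_density",
    "detect_motion_by_channel",
    "detect_motion",
    "clean_window_indices",
    "percent_motion",
]


@dataclass(frozen=True)
class MotionConfig:
    """Motion-detection parameters (defaults are the established infant values)."""

    t_motion: float = 1.0  # s, sliding detection window
    t_mask: float = 1.0  # s, dilation of each detection
    stdev_thresh: float = 15.0  # multiplier on sd of the sample-to-sample signal
    amp_thresh: float = 0.4  # absolute dOD range threshold

    def __post_init__(self) -> None:
        for name in ("t_motion", "t_mask", "stdev_thresh", "amp_thresh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MotionMask:
    """Per-sample artifact flags for the channels of one recording."""

    flags: np.ndarray  # (n_channels, n_samples) bool
    sampling_rate: float

    def channel_flags(self, channel: int) -> np.ndarray:
        return self.flags[channel]


def optical_density(intensity: np.ndarray) -> np.ndarray:
    """Optical-density change dOD(t) = -ln(I(t) / mean(I)) along the last axis."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        raise ValueError("optical density requires strictly positive intensities")
    mean = intensity.mean(axis=-1, keepdims=True)
    return -np.log(intensity / mean)


def _flag_one_series(dod: np.ndarray, fs: float, config: MotionConfig) -> np.ndarray:
    n = dod.size
    win = int(round(config.t_motion * fs))
    if win < 2:
        raise ValueError("t_motion must span at least 2 samples")
    win = min(win, n)

    diffs = np.diff(dod)
    sd_diff = float(np.std(diffs)) if diffs.size else 0.0
    thresh = min(config.amp_thresh, config.stdev_thresh * sd_diff) if sd_diff > 0 else config.amp_thresh

    # range of each window starting at s: R[s] = max(x[s:s+win]) - min(...)
    sw = np.lib.stride_tricks.sliding_window_view(dod, win)
    rng = sw.max(axis=1) - sw.min(axis=1)
    exceeding = rng > thresh

    flags = np.zeros(n, dtype=bool)
    if exceeding.any():
        # window starting at s covers samples s .. s+win-1
        starts = np.flatnonzero(exceeding)
        for s in starts:
            flags[s : s + win] = True

    if flags.any() and config.t_mask > 0:
        pad = int(round(config.t_mask * fs))
        if pad > 0:
            flags = ndimage.binary_dilation(flags, structure=np.ones(2 * pad + 1, dtype=bool))
    return flags


def detect_motion_by_channel(
    recording: RawIntensityRecording, channel: int, config: MotionConfig = MotionConfig()
) -> np.ndarray:
    """Boolean per-sample artifact flags for one channel (either wavelength flags it)."""
    dod = optical_density(recording.intensity[channel])
    fs = recording.sampling_rate
    return _flag_one_series(dod[0], fs, config) | _flag_one_series(dod[1], fs, config)


def detect_motion(
    recording: RawIntensityRecording,
    config: MotionConfig = MotionConfig(),
    channels: "list[int] | None" = None,
) -> MotionMask:
    """Motion mask over all (or the given) channels of a recording."""
    if channels is None:
        channels = list(range(recording.n_channels))
    flags = np.zeros((recording.n_channels, recording.n_samples), dtype=bool)
    for c in channels:
        flags[c] = detect_motion_by_channel(recording, c, config)
    return MotionMask(flags=flags, sampling_rate=recording.sampling_rate)


def clean_window_indices(
    channel_flags: np.ndarray, bounds: list[tuple[int, int]]
) -> list[int]:
    """Indices of windows containing no flagged sample (half-open ranges)."""
    return [k for k, (a, b) in enumerate(bounds) if not channel_flags[a:b].any()]


def percent_motion(
    mask: MotionMask,
    window_s: float = 3.0,
    channels: "list[int] | None" = None,
) -> float:
    """Percentage of Motion: cross-channel mean % of windows containing motion.

    ``channels`` restricts the mean to the acceptable (non-CSE) channels.
    """
    n_samples = mask.flags.shape[1]
    bounds = window_bounds(n_samples, mask.sampling_rate, window_s)
    if not bounds:
        raise ValueError("recording shorter than one analysis window")
    if channels is None:
        channels = list(range(mask.flags.shape[0]))
    if not channels:
        raise ValueError("no channels to summarise")
    percentages = []
    for c in channels:
        dirty = sum(1 for a, b in bounds if mask.flags[c, a:b].any())
        percentages.append(100.0 * dirty / len(bounds))
    return float(np.mean(percentages))
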