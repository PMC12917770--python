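"""Channel-exclusion procedures: signal-extrema prefilter, CV pruning, SCI/PSP pruning.

Three methods are implemented:

* ``find_cse`` — "channels with signal extrema": channels whose minimum raw
  intensity (over samples and wavelengths) falls below an instrument floor
  (default 3e-4), excluded before any pruning analysis;
* ``prune_cv`` — prune a channel when its two wavelengths' coefficients of
  variation, computed on motion-free data, differ by more than a threshold
  (default 0.2);
* ``prune_qtnirs`` — windowed SCI/PSP assessment: a channel is retained when
  at least ``q_threshold`` of its clean windows pass both the SCI and PSP
  thresholds. ``sci_only_variant`` is the same with the PSP test vacuous.

Channels with no clean (motion-free) windows cannot be certified and are
pruned with their own status code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quality import QTConfig, coefficient_of_variation, evaluate_channel
from .recording import RawIntensityRecording, window_bounds

__all__ = [
    "CVConfig",
    "PruningResult",
    "RETAINED",
    "PRUNED_CV",
    "PRUNED_QT",
    "EXCLUDED_CSE",
    "EXCLUDED_NO_CLEAN_WINDOWS",
    "CSE_MIN_INTENSITY",
    "find_cse",
    "prune_cv",
    "prune_qtnirs",
    "sci_only_variant",
]

RETAINED = "retained"
PRUNED_CV = "pruned_cv"
PRUNED_QT = "pruned_qt"
EXCLUDED_CSE = "excluded_cse"
EXCLUDED_NO_CLEAN_WINDOWS = "excluded_no_clean_windows"

#: Instrument floor on raw intensity below which a channel is unusable.
CSE_MIN_INTENSITY = 3e-4


@dataclass(frozen=True)
class CVConfig:
    """CV-difference pruning parameters.

    The boundary is strict by default (prune only when the wavelength CV
    difference *exceeds* ``diff_threshold``); set ``inclusive`` to prune
    at equality as well.
    """

    diff_threshold: float = 0.2
    inclusive: bool = False

    def __post_init__(self) -> None:
        if self.diff_threshold <= 0:
            raise ValueError("diff_threshold must be positive")


@dataclass
class PruningResult:
    """Per-channel retain/prune status under one method and parameter set."""

    statuses: dict[int, str]
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = {RETAINED, PRUNED_CV, PRUNED_QT, EXCLUDED_CSE, EXCLUDED_NO_CLEAN_WINDOWS}
        bad = set(self.statuses.values()) - allowed
        if bad:
            raise ValueError(f"unknown channel statuses: {bad}")

    @property
    def channels_retained(self) -> int:
        """CR: the number of channels surviving pruning."""
        return sum(1 for s in self.statuses.values() if s == RETAINED)

    @property
    def retained_channels(self) -> list[int]:
        return sorted(c for c, s in self.statuses.items() if s == RETAINED)

    def status(self, channel: int) -> str:
        return self.statuses[channel]


def find_cse(
    recording: RawIntensityRecording, min_intensity: float = CSE_MIN_INTENSITY
) -> set[int]:
    """Channels whose minimum intensity over samples and wavelengths is below the floor."""
    mins = recording.intensity.min(axis=(1, 2))
    return {int(c) for c in np.flatnonzero(mins < min_intensity)}


def _clean_samples(
    recording: RawIntensityRecording,
    channel: int,
    wavelength: int,
    clean: list[int],
    bounds: list[tuple[int, int]],
) -> np.ndarray:
    parts = [recording.intensity[channel, wavelength, a:b] for a, b in (bounds[k] for k in clean)]
    return np.concatenate(parts) if parts else np.empty(0)


def prune_cv(
    recording: RawIntensityRecording,
    clean_windows: dict[int, list[int]],
    config: CVConfig = CVConfig(),
    cse_channels: set[int] | None = None,
    window_s: float = 3.0,
) -> PruningResult:
    """CV-difference pruning on motion-free data.

    Per non-CSE channel, CV is computed for each wavelength on the
    concatenation of that channel's clean windows; the channel is pruned
    when the absolute CV difference exceeds ``config.diff_threshold``.
    """
    cse = cse_channels if cse_channels is not None else find_cse(recording)
    bounds = window_bounds(recording.n_samples, recording.sampling_rate, window_s)
    statuses: dict[int, str] = {}
    for c in range(recording.n_channels):
        if c in cse:
            statuses[c] = EXCLUDED_CSE
            continue
        clean = clean_windows.get(c, [])
        if not clean:
            statuses[c] = EXCLUDED_NO_CLEAN_WINDOWS
            continue
        cvs = [
            coefficient_of_variation(_clean_samples(recording, c, wl, clean, bounds))
            for wl in (0, 1)
        ]
        diff = abs(cvs[0] - cvs[1])
        over = diff >= config.diff_threshold if config.inclusive else diff > config.diff_threshold
        statuses[c] = PRUNED_CV if over else RETAINED
    return PruningResult(
        statuses=statuses,
        method="cv",
        params={"diff_threshold": config.diff_threshold, "inclusive": config.inclusive},
    )


def prune_qtnirs(
    recording: RawIntensityRecording,
    clean_windows: dict[int, list[int]],
    config: QTConfig = QTConfig(),
    cse_channels: set[int] | None = None,
    quality_cache: "dict[int, object] | None" = None,
) -> PruningResult:
    """Windowed SCI/PSP pruning: retain iff good_fraction >= q_threshold.

    ``quality_cache`` maps channel index to a precomputed
    :class:`~nirsprune.quality.ChannelQuality`; supplying it lets a
    threshold sweep reuse the per-window metrics, which do not depend on
    the thresholds.
    """
    cse = cse_channels if cse_channels is not None else find_cse(recording)
    statuses: dict[int, str] = {}
    for c in range(recording.n_channels):
        if c in cse:
            statuses[c] = EXCLUDED_CSE
            continue
        clean = clean_windows.get(c, [])
        if not clean:
            statuses[c] = EXCLUDED_NO_CLEAN_WINDOWS
            continue
        if quality_cache is not None and c in quality_cache:
            quality = quality_cache[c]
        else:
            quality = evaluate_channel(recording, c, config, clean)
            if quality_cache is not None:
                quality_cache[c] = quality
        frac = quality.good_fraction(config.sci_threshold, config.psp_threshold)
        statuses[c] = RETAINED if frac >= config.q_threshold else PRUNED_QT
    return PruningResult(
        statuses=statuses,
        method="qt",
        params={
            "sci_threshold": config.sci_threshold,
            "psp_threshold": config.psp_threshold,
            "q_threshold": config.q_threshold,
        },
    )


def sci_only_variant(
    recording: RawIntensityRecording,
    clean_windows: dict[int, list[int]],
    config: QTConfig = QTConfig(),
    cse_channels: set[int] | None = None,
    quality_cache: "dict[int, object] | None" = None,
) -> PruningResult:
    """SCI-only pruning: the SCI/PSP procedure with ``psp_threshold`` forced to 0."""
    sci_cfg = QTConfig(
        sci_threshold=config.sci_threshold,
        psp_threshold=0.0,
        q_threshold=config.q_threshold,
        window_s=config.window_s,
        cardiac_band=config.cardiac_band,
    )
    result = prune_qtnirs(recording, clean_windows, sci_cfg, cse_channels, quality_cache)
    result.method = "sci"
    return result
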