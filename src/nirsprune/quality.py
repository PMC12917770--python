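"""Scalar signal-quality metrics: CV, SNR, cardiac bandpass, windowed SCI and PSP.

The scalp coupling index (SCI) is the zero-lag correlation of the two
wavelengths' cardiac-band-filtered, normalized window signals: when the
optode is well coupled to the scalp, the cardiac pulse appears coherently
in both wavelengths and SCI approaches 1. The peak spectral power (PSP)
is the peak of the normalized power spectrum of the cross-correlation
sequence of the two window signals: it is high for coherent narrowband
(cardiac-like) content and near zero for incoherent noise.

Conventions pinned by the test suite:

* standard deviations are *population* (ddof=0) throughout;
* windows are 0-based, half-open, non-overlapping from sample 0 with the
  trailing partial window discarded;
* degenerate (zero-variance) windows count as *failing* windows, not as
  missing data — flat-lined data is bad data;
* PSP is a peak *power*: the spectrum is scaled so that a perfectly
  coherent unit-variance sinusoid pair at a DFT bin frequency yields 0.5
  (the power of a unit-amplitude cosine), and the peak search runs over
  the full discrete spectrum of the already-bandpassed signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "QTConfig",
    "ChannelQuality",
    "coefficient_of_variation",
    "snr_db",
    "bandpass_cardiac",
    "normalize_window",
    "sci",
    "psp",
    "evaluate_channel",
]

#: Resting cardiac frequency band for infants, Hz.
INFANT_CARDIAC_BAND = (1.3, 3.2)

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class QTConfig:
    """Windowed SCI/PSP quality-assessment parameters.

    ``q_threshold`` is the minimum fraction of clean windows that must
    pass both the SCI and PSP thresholds for a channel to be retained.
    """

    sci_threshold: float = 0.6
    psp_threshold: float = 0.045
    q_threshold: float = 0.75
    window_s: float = 3.0
    cardiac_band: tuple[float, float] = INFANT_CARDIAC_BAND

    def __post_init__(self) -> None:
        if not 0.0 <= self.sci_threshold <= 1.0:
            raise ValueError("sci_threshold must lie in [0, 1]")
        if self.psp_threshold < 0.0:
            raise ValueError("psp_threshold must be non-negative")
        if not 0.0 <= self.q_threshold <= 1.0:
            raise ValueError("q_threshold must lie in [0, 1]")
        if self.window_s <= 0.0:
            raise ValueError("window_s must be positive")
        lo, hi = self.cardiac_band
        if not 0.0 < lo < hi:
            raise ValueError("cardiac_band must be an increasing positive interval")


@dataclass
class ChannelQuality:
    """Per-window SCI/PSP values for one channel, restricted to clean windows.

    ``sci`` and ``psp`` are aligned with ``window_indices``; degenerate
    windows carry NaN and count as failing in ``good_fraction``.
    """

    window_indices: np.ndarray
    sci: np.ndarray
    psp: np.ndarray
    empty: bool = False
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = ~(np.isfinite(self.sci) & np.isfinite(self.psp))

    @property
    def n_clean_windows(self) -> int:
        return len(self.window_indices)

    def good_fraction(self, sci_threshold: float, psp_threshold: float) -> float:
        """Fraction of clean windows whose SCI and PSP both exceed the thresholds.

        A threshold of exactly 0 disables that test (this is how the
        SCI-only pruning variant is defined); degenerate windows always
        count as failing.
        """
        if self.n_clean_windows == 0:
            raise ValueError("channel has no clean windows")
        with np.errstate(invalid="ignore"):
            good = np.ones(self.n_clean_windows, dtype=bool)
            if sci_threshold > 0:
                good &= self.sci > sci_threshold
            if psp_threshold > 0:
                good &= self.psp > psp_threshold
        good &= ~self.degenerate
        return float(np.count_nonzero(good)) / self.n_clean_windows


def coefficient_of_variation(x: np.ndarray) -> float:
    """CV = sigma / |mu| of an intensity series (population sigma).

    Returns ``inf`` when the mean is zero; scale-invariant under positive
    rescaling of the signal.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("signal is empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    mu = float(np.mean(x))
    sd = float(np.std(x))
    if mu == 0.0:
        return math.inf
    return sd / abs(mu)


def snr_db(x: np.ndarray) -> float:
    """SNR = 20 log10(mu / sigma) in dB, for positive-mean intensity data."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("signal is empty")
    mu = float(np.mean(x))
    if mu <= 0.0:
        raise ValueError("snr_db requires a positive-mean intensity signal")
    sd = float(np.std(x))
    if sd == 0.0:
        return math.inf
    return 20.0 * math.log10(mu / sd)


def bandpass_cardiac(
    x: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = INFANT_CARDIAC_BAND,
) -> np.ndarray:
    """Zero-phase cardiac-band filter (forward-backward 3rd-order Butterworth).

    Passband loss at the band centre is below 1 dB and attenuation one
    octave outside either edge exceeds 20 dB.
    """
    lo, hi = band
    nyq = sampling_rate / 2.0
    if not 0.0 < lo < hi < nyq:
        raise ValueError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    sos = sps.butter(3, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def normalize_window(x: np.ndarray) -> np.ndarray | None:
    """Zero-mean, unit-variance (population) copy; ``None`` if degenerate."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd < _DEGENERATE_TOL:
        return None
    return (x - np.mean(x)) / sd


def sci(x1: np.ndarray, x2: np.ndarray) -> float:
    """Zero-lag cross-correlation of two normalized window signals.

    Equals the Pearson correlation of the underlying window signals;
    symmetric in wavelength order and invariant to positive rescaling.
    """
    x1n = normalize_window(x1)
    x2n = normalize_window(x2)
    if x1n is None or x2n is None:
        raise ValueError("degenerate (zero-variance) window: SCI undefined")
    return float(np.dot(x1n, x2n) / x1n.size)


def _psp_from_normalized(x1n: np.ndarray, x2n: np.ndarray) -> float:
    n = x1n.size
    # biased cross-correlation, lags -(n-1) .. n-1
    rho = np.correlate(x1n, x2n, mode="full") / n
    m = 2 * n - 1
    w = np.hamming(m)
    lags = np.arange(-(n - 1), n)
    tri = 1.0 - np.abs(lags) / n
    # amplitude spectrum scaled so a coherent unit-variance sinusoid pair at a
    # bin frequency has a unit-amplitude cosine cross-correlation; PSP is its
    # peak *power* (A^2 / 2), i.e. 0.5 for perfect coherence.
    ref = float(np.sum(w * tri))
    spectrum = np.abs(np.fft.rfft(w * rho))
    amplitude = 2.0 * spectrum.max() / ref
    return float(amplitude**2 / 2.0)


def psp(x1: np.ndarray, x2: np.ndarray) -> float:
    """Peak power of the normalized cross-correlation spectrum of a window pair.

    The biased cross-correlation sequence of the two normalized signals is
    Hamming-windowed; its discrete amplitude spectrum is scaled so that a
    perfectly coherent unit-variance sinusoid pair has a unit-amplitude
    cosine cross-correlation, and the returned value is the peak power
    A^2/2 of that spectrum — 0.5 for perfect coherence at a bin frequency,
    near 0 for incoherent noise. Invariant to positive rescaling of either
    signal.
    """
    x1n = normalize_window(x1)
    x2n = normalize_window(x2)
    if x1n is None or x2n is None:
        raise ValueError("degenerate (zero-variance) window: PSP undefined")
    return _psp_from_normalized(x1n, x2n)


def evaluate_channel(
    recording,
    channel: int,
    config: QTConfig,
    clean_windows: "list[int] | np.ndarray | None" = None,
) -> ChannelQuality:
    """Windowed SCI/PSP assessment of one channel on its clean windows.

    The channel's two wavelength series are cardiac-bandpass filtered over
    the full recording, partitioned into ``window_s`` windows, and SCI/PSP
    are computed per clean window. ``clean_windows`` is the motion module's
    clean-window index set; ``None`` means all windows are clean.
    """
    from .recording import window_bounds  # local import to avoid cycle at module load

    bounds = window_bounds(recording.n_samples, recording.sampling_rate, config.window_s)
    if clean_windows is None:
        clean = list(range(len(bounds)))
    else:
        clean = sorted(int(k) for k in clean_windows)

    x1 = bandpass_cardiac(recording.intensity[channel, 0], recording.sampling_rate, config.cardiac_band)
    x2 = bandpass_cardiac(recording.intensity[channel, 1], recording.sampling_rate, config.cardiac_band)

    sci_vals = np.full(len(clean), np.nan)
    psp_vals = np.full(len(clean), np.nan)
    for j, k in enumerate(clean):
        a, b = bounds[k]
        w1 = normalize_window(x1[a:b])
        w2 = normalize_window(x2[a:b])
        if w1 is None or w2 is None:
            continue  # degenerate window: stays NaN, counts as failing
        sci_vals[j] = np.dot(w1, w2) / w1.size
        psp_vals[j] = _psp_from_normalized(w1, w2)

    return ChannelQuality(
        window_indices=np.asarray(clean, dtype=int),
        sci=sci_vals,
        psp=psp_vals,
        empty=(len(clean) == 0),
    )
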