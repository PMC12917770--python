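"""Synthetic infant-fNIRS recordings and cohorts with known ground truth.

The generator emulates the statistical structure the pruning analysis
assumes rather than the optics of a real instrument: each channel's
intensity at each wavelength is

    I(t) = baseline * exp(-artifact_dOD(t)) * instability(t) *
           (1 + a(c) * cardiac(t) + response(t) + drift(t) + noise(t))

where ``cardiac`` is a shared pulse waveform (sinusoid plus a small second
harmonic) at a participant-specific heart rate inside the infant band,
``a(c)`` grows linearly with the channel's coupling quality ``c`` in
[0, 1], and the second wavelength receives the mixture
``c * cardiac + (1 - c) * independent`` so that the cross-wavelength
cardiac coherence — and hence SCI/PSP — is controlled by ``c``.  Motion
artifacts (spikes and box-car baseline steps) are injected in
optical-density space; dead channels ("channels with signal extrema") get
a baseline below the instrument floor; designated task-relevant channels
carry a slow evoked hemodynamic response on a block design.

Cohorts draw participant-level coupling and motion parameters with
configurable age/cohort/task/motion effects, recorded in the ground truth
so parameter-recovery tests know what was injected.  Per-participant
random streams are derived deterministically from the master seed and the
participant's cell, so a cohort is reproducible under subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .quality import INFANT_CARDIAC_BAND
from .recording import RawIntensityRecording

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "MotionEvent",
    "CohortDesign",
    "generate_recording",
    "generate_cohort",
    "simulate_analysis_table",
]

AGES_MONTHS = (5, 8, 12, 18, 24)
COHORTS = ("Gambia", "UK")
TASKS = ("HaND", "SNS")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording.

    Defaults mirror the study conditions: 34 channels (17 per hemisphere),
    10 Hz sampling, 780/850 nm, infant cardiac band 1.3-3.2 Hz.
    """

    n_channels: int = 34
    sampling_rate: float = 10.0
    wavelengths: tuple[float, float] = (780.0, 850.0)
    duration: float = 300.0  # s
    cardiac_band: tuple[float, float] = INFANT_CARDIAC_BAND
    #: Beta(a, b) parameters of the per-channel coupling-quality draw.
    coupling_beta: tuple[float, float] = (5.0, 2.0)
    #: Explicit per-channel coupling qualities; overrides ``coupling_beta``.
    coupling_quality: tuple[float, ...] | None = None
    motion_rate: float = 2.0  # expected artifacts per minute
    motion_amplitude_range: tuple[float, float] = (0.3, 1.2)  # dOD units
    cse_probability: float = 0.05
    trc_indices: tuple[int, ...] = (2, 3, 19, 20)
    response_amplitude: float = 0.01  # fraction of baseline
    cardiac_amplitude: float = 0.015  # fraction of baseline at c = 1
    noise_sd: float = 0.004  # white sensor noise, fraction of baseline
    drift_amplitude: float = 0.008  # fraction of baseline, < 0.1 Hz
    #: Low-frequency coupling-instability scale: poorly coupled optodes show
    #: large slow intensity fluctuations that differ between wavelengths
    #: (driving both CV-difference pruning and reduced SNR).
    instability_scale: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        lo, hi = self.cardiac_band
        if not 0 < lo < hi < self.sampling_rate / 2:
            raise ValueError("cardiac_band must lie within (0, Nyquist)")
        if self.coupling_quality is not None:
            if len(self.coupling_quality) != self.n_channels:
                raise ValueError("coupling_quality must list one value per channel")
            if not all(0.0 <= c <= 1.0 for c in self.coupling_quality):
                raise ValueError("coupling qualities must lie in [0, 1]")
        if not 0.0 <= self.cse_probability <= 1.0:
            raise ValueError("cse_probability must lie in [0, 1]")
        if any(i < 0 or i >= self.n_channels for i in self.trc_indices):
            raise ValueError("trc_indices must lie in [0, n_channels)")
        if self.motion_rate < 0:
            raise ValueError("motion_rate must be non-negative")


@dataclass(frozen=True)
class MotionEvent:
    onset: float  # s
    duration: float  # s
    kind: str  # "spike" | "step"
    amplitude: float  # dOD units


@dataclass
class GroundTruth:
    """What the generator actually injected, for testing against."""

    coupling_quality: np.ndarray  # per channel, in [0, 1]
    motion_events: list[MotionEvent]
    cse_channels: set[int]
    cardiac_frequency: float  # Hz
    injected_effects: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortDesign:
    """Factorial design of a synthetic cohort.

    ``effects`` holds the injected fixed effects, all on the logit of the
    participant's mean coupling quality unless noted:

    * ``age_coupling`` — per unit of standardised age;
    * ``cohort_coupling`` — second-listed cohort minus first;
    * ``task_coupling`` — second-listed task minus first;
    * ``motion_coupling`` — per unit of the participant's standardised
      motion rate (negative means motion-prone infants couple worse);
    * ``age_motion`` — effect of standardised age on log motion rate.
    """

    ages: tuple[int, ...] = AGES_MONTHS
    cohorts: tuple[str, ...] = COHORTS
    tasks: tuple[str, ...] = TASKS
    n_participants: int = 3
    effects: dict[str, float] = field(default_factory=dict)
    base_coupling: float = 0.70  # cohort-mean coupling quality under null effects
    coupling_sd: float = 0.6  # participant scatter on the logit scale
    base_motion_rate: float = 2.0  # artifacts per minute
    motion_rate_sd: float = 0.5  # participant scatter on the log scale

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("each design cell needs at least one participant")
        if not (self.ages and self.cohorts and self.tasks):
            raise ValueError("design has an empty factor")
        if not 0 < self.base_coupling < 1:
            raise ValueError("base_coupling must lie in (0, 1)")


def _cardiac_waveform(t: np.ndarray, freq: float, phase: float) -> np.ndarray:
    """Pulse-like waveform: fundamental plus a 20% second harmonic, unit variance."""
    s = np.sin(2 * np.pi * freq * t + phase) + 0.2 * np.sin(4 * np.pi * freq * t + 2 * phase)
    return s / np.sqrt(0.5 + 0.5 * 0.2**2)


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance noise confined to ``band`` (for the uncoupled cardiac stand-in)."""
    from .quality import bandpass_cardiac

    x = bandpass_cardiac(rng.standard_normal(n), fs, band)
    sd = x.std()
    return x / sd if sd > 0 else x


def _lowfreq_noise(rng: np.random.Generator, n: int, fs: float, cutoff: float = 0.5) -> np.ndarray:
    """Unit-variance slow fluctuation (< ``cutoff`` Hz), below the cardiac band."""
    from scipy import signal as sps

    sos = sps.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _coupling_amplitude(c: float) -> float:
    # modulation depth grows linearly with coupling; even poor channels pulse a little
    return 0.2 + 0.8 * c


def _schedule_motion(rng: np.random.Generator, config: SimulationConfig) -> list[MotionEvent]:
    n_events = int(round(config.motion_rate * config.duration / 60.0))
    events = []
    lo, hi = config.motion_amplitude_range
    for _ in range(n_events):
        duration = float(rng.uniform(0.2, 1.0))
        onset = float(rng.uniform(0.0, max(config.duration - duration, 0.0)))
        kind = "spike" if rng.random() < 0.6 else "step"
        amplitude = float(rng.uniform(lo, hi))
        events.append(MotionEvent(onset=onset, duration=duration, kind=kind, amplitude=amplitude))
    return sorted(events, key=lambda e: e.onset)


def _artifact_dod(t: np.ndarray, events: list[MotionEvent]) -> np.ndarray:
    dod = np.zeros_like(t)
    for ev in events:
        if ev.kind == "spike":
            sd = max(ev.duration / 4.0, 1e-3)
            dod += ev.amplitude * np.exp(-0.5 * ((t - (ev.onset + ev.duration / 2)) / sd) ** 2)
        else:  # box-car baseline step
            dod += np.where((t >= ev.onset) & (t < ev.onset + ev.duration), ev.amplitude, 0.0)
    return dod


def _block_response(t: np.ndarray, amplitude: float) -> np.ndarray:
    """Evoked hemodynamic response on a 30-s block design (10 s stimulation)."""
    from scipy.signal import fftconvolve

    if amplitude == 0:
        return np.zeros_like(t)
    dt = t[1] - t[0] if t.size > 1 else 0.1
    boxcar = ((t % 30.0) < 10.0).astype(float)
    # canonical-ish gamma HRF, peak ~5 s
    ht = np.arange(0, 20.0, dt)
    hrf = (ht / 5.0) ** 2 * np.exp(-(ht - 5.0) / 2.0)
    hrf /= hrf.max()
    resp = fftconvolve(boxcar, hrf, mode="full")[: t.size]
    peak = np.abs(resp).max()
    return amplitude * resp / peak if peak > 0 else np.zeros_like(t)


def generate_recording(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[RawIntensityRecording, GroundTruth]:
    """Generate one labelled synthetic recording.

    Returns the recording together with the ground truth (per-channel
    coupling quality, motion schedule, dead channels, cardiac frequency).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.sampling_rate))
    if n < 2:
        raise ValueError("duration too short for the sampling rate")
    t = np.arange(n) / config.sampling_rate

    lo, hi = config.cardiac_band
    margin = 0.15 * (hi - lo)
    cardiac_freq = float(rng.uniform(lo + margin, hi - margin))
    phase = float(rng.uniform(0, 2 * np.pi))
    cardiac = _cardiac_waveform(t, cardiac_freq, phase)

    if config.coupling_quality is not None:
        coupling = np.asarray(config.coupling_quality, dtype=float)
    else:
        a, b = config.coupling_beta
        coupling = rng.beta(a, b, size=config.n_channels)

    cse = {int(c) for c in np.flatnonzero(rng.random(config.n_channels) < config.cse_probability)}
    events = _schedule_motion(rng, config)
    artifact = _artifact_dod(t, events)
    artifact_gain = np.exp(-artifact)

    response = _block_response(t, config.response_amplitude)

    intensity = np.empty((config.n_channels, 2, n))
    for c in range(config.n_channels):
        q = float(coupling[c])
        baseline = 2e-4 if c in cse else float(rng.uniform(0.5, 2.0))
        amp = config.cardiac_amplitude * _coupling_amplitude(q)
        independent = _bandlimited_noise(rng, n, config.sampling_rate, config.cardiac_band)
        cardiac_w2 = q * cardiac + (1.0 - q) * independent
        drift_f = float(rng.uniform(0.02, 0.08))
        drift_ph = float(rng.uniform(0, 2 * np.pi))
        drift = config.drift_amplitude * np.sin(2 * np.pi * drift_f * t + drift_ph)
        resp = response if c in config.trc_indices else 0.0
        for w, cardiac_w in enumerate((cardiac, cardiac_w2)):
            noise = config.noise_sd * rng.standard_normal(n)
            # slow coupling instability, multiplicative (absorption-like) and
            # independent per wavelength; severity grows as coupling degrades
            instab_amp = config.instability_scale * (1.0 - q) ** 2 * rng.uniform(0.3, 1.0)
            instab = np.exp(instab_amp * _lowfreq_noise(rng, n, config.sampling_rate))
            series = (
                baseline * (1.0 + amp * cardiac_w + resp + drift + noise) * instab * artifact_gain
            )
            intensity[c, w] = np.maximum(series, 1e-9)  # detector floor, keeps dOD defined

    recording = RawIntensityRecording(
        intensity=intensity,
        sampling_rate=config.sampling_rate,
        wavelengths=config.wavelengths,
    )
    truth = GroundTruth(
        coupling_quality=coupling,
        motion_events=events,
        cse_channels=cse,
        cardiac_frequency=cardiac_freq,
    )
    return recording, truth


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _participant_seed(master_seed: int, age: int, cohort: str, task: str, index: int) -> np.random.Generator:
    # deterministic per participant and independent of which other cells exist
    ss = np.random.SeedSequence(
        entropy=int(master_seed) & 0x7FFFFFFF,
        spawn_key=(int(age), COHORTS.index(cohort) if cohort in COHORTS else hash(cohort) & 0xFFFF,
                   TASKS.index(task) if task in TASKS else hash(task) & 0xFFFF, int(index)),
    )
    return np.random.default_rng(ss)


def generate_cohort(
    design: CohortDesign, config: SimulationConfig
) -> tuple[list[tuple[RawIntensityRecording, GroundTruth]], pd.DataFrame]:
    """Generate a full factorial cohort plus its participant table.

    Each participant draws a mean coupling quality (logit scale) and a
    motion rate (log scale) carrying the design's injected effects, then a
    recording via :func:`generate_recording` with per-channel couplings
    scattered around the participant mean.
    """
    recordings: list[tuple[RawIntensityRecording, GroundTruth]] = []
    rows = []
    eff = design.effects
    ages = np.asarray(design.ages, dtype=float)
    age_mu, age_sd = ages.mean(), (ages.std() if ages.std() > 0 else 1.0)
    base_logit = float(np.log(design.base_coupling / (1 - design.base_coupling)))

    pid = 0
    for age in design.ages:
        for cohort in design.cohorts:
            for task in design.tasks:
                for k in range(design.n_participants):
                    rng = _participant_seed(config.seed, age, cohort, task, k)
                    age_z = (age - age_mu) / age_sd
                    log_rate = (
                        np.log(max(design.base_motion_rate, 1e-6))
                        + eff.get("age_motion", 0.0) * age_z
                        + design.motion_rate_sd * rng.standard_normal()
                    )
                    motion_rate = float(np.exp(log_rate))
                    rate_z = (np.log(motion_rate) - np.log(design.base_motion_rate)) / max(
                        design.motion_rate_sd, 1e-9
                    )
                    logit = (
                        base_logit
                        + eff.get("age_coupling", 0.0) * age_z
                        + eff.get("cohort_coupling", 0.0) * (design.cohorts.index(cohort))
                        + eff.get("task_coupling", 0.0) * (design.tasks.index(task))
                        + eff.get("motion_coupling", 0.0) * rate_z
                        + design.coupling_sd * rng.standard_normal()
                    )
                    mean_c = float(np.clip(_sigmoid(logit), 0.02, 0.98))
                    kappa = 8.0  # concentration of channel couplings about the participant mean
                    p_config = replace(
                        config,
                        motion_rate=motion_rate,
                        coupling_beta=(kappa * mean_c, kappa * (1 - mean_c)),
                        coupling_quality=None,
                    )
                    rec, truth = generate_recording(p_config, rng=rng)
                    rec.participant.update(
                        {"id": f"P{pid:03d}", "age_months": age, "cohort": cohort, "task": task}
                    )
                    truth.injected_effects = dict(eff)
                    truth.injected_effects.update(
                        {"participant_mean_coupling": mean_c, "participant_motion_rate": motion_rate}
                    )
                    recordings.append((rec, truth))
                    rows.append(
                        {
                            "id": f"P{pid:03d}",
                            "age_months": age,
                            "cohort": cohort,
                            "task": task,
                            "mean_coupling": mean_c,
                            "motion_rate": motion_rate,
                        }
                    )
                    pid += 1
    return recordings, pd.DataFrame(rows)


def simulate_analysis_table(
    betas: dict[str, float],
    n_participants: int = 20,
    sci_values: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
    psp_values: tuple[float, ...] = (0.01, 0.03, 0.05, 0.08, 0.1),
    resid_sd: float = 1.0,
    participant_sd: float = 0.5,
    vc_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw participant-by-threshold analysis rows directly from the linear model.

    This is the row-level generator used to validate the statistical stage:
    the outcome is built from the named fixed effects (``betas`` keyed by
    scaled-variable names ``sci``, ``psp``, ``age``, ``pom``, ``cse``,
    ``task``, ``cohort`` and interactions like ``sci:pom``), a participant
    random intercept, threshold-by-cohort variance components, and Gaussian
    noise — so a fit should recover exactly what was injected.
    """
    rng = np.random.default_rng(seed)
    ages = rng.choice(AGES_MONTHS, size=n_participants)
    cohorts = rng.choice(COHORTS, size=n_participants)
    tasks = rng.choice(TASKS, size=n_participants)
    poms = rng.uniform(0, 60, size=n_participants)
    cses = rng.poisson(1.5, size=n_participants)
    u_id = participant_sd * rng.standard_normal(n_participants)
    u_sci_coh = {
        (s, ch): vc_sd * rng.standard_normal() for s in sci_values for ch in COHORTS
    }
    u_psp_coh = {
        (p, ch): vc_sd * rng.standard_normal() for p in psp_values for ch in COHORTS
    }

    def z(v, vals):
        vals = np.asarray(vals, dtype=float)
        sd = vals.std(ddof=1)
        return (v - vals.mean()) / sd if sd > 0 else 0.0

    rows = []
    for i in range(n_participants):
        for s in sci_values:
            for p in psp_values:
                x = {
                    "sci": z(s, sci_values * n_participants),
                    "psp": z(p, psp_values * n_participants),
                    "age": z(ages[i], ages),
                    "pom": z(poms[i], poms),
                    "cse": z(cses[i], cses),
                    "task": 1.0 if tasks[i] == TASKS[1] else 0.0,
                    "cohort": 1.0 if cohorts[i] == COHORTS[1] else 0.0,
                }
                y = u_id[i] + u_sci_coh[(s, cohorts[i])] + u_psp_coh[(p, cohorts[i])]
                for term, beta in betas.items():
                    parts = term.split(":")
                    val = 1.0
                    for part in parts:
                        val *= x[part]
                    y += beta * val
                y += resid_sd * rng.standard_normal()
                rows.append(
                    {
                        "id": f"P{i:03d}",
                        "age": float(ages[i]),
                        "cohort": cohorts[i],
                        "task": tasks[i],
                        "pom": float(poms[i]),
                        "cse": float(cses[i]),
                        "sci_thr": s,
                        "psp_thr": p,
                        "outcome": float(y),
                    }
                )
    return pd.DataFrame(rows)
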