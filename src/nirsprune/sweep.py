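"""Threshold sweeps, retention-matched comparison against CV pruning, and the
quality/retention trade-off tool.

A sweep evaluates every (sci_threshold, psp_threshold) grid point for every
participant, producing one row per combination with the channels-retained
count (CR) and the mean SNR over retained task-relevant channels (TRC SNR),
plus SCI-only rows (psp_threshold = 0) and one CV-pruning row per
participant. Per-window SCI/PSP values are computed once per channel and
re-thresholded across the grid, so the full sweep costs little more than a
single quality pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .motion import MotionConfig, clean_window_indices, detect_motion, percent_motion
from .pruning import (
    CVConfig,
    EXCLUDED_NO_CLEAN_WINDOWS,
    PRUNED_QT,
    RETAINED,
    PruningResult,
    find_cse,
    prune_cv,
)
from .quality import QTConfig, evaluate_channel, snr_db
from .recording import RawIntensityRecording, window_bounds

__all__ = [
    "SweepGrid",
    "MatchResult",
    "trc_snr",
    "participant_quality",
    "run_sweep",
    "exclusion_rule",
    "match_to_cv",
    "tradeoff_trend",
]


def _default_sci() -> tuple[float, ...]:
    return tuple(np.round(np.arange(1, 19) * 0.05, 10))  # 0.05 .. 0.90


def _default_psp() -> tuple[float, ...]:
    return tuple(np.round(np.arange(1, 21) * 0.005, 10))  # 0.005 .. 0.100


@dataclass(frozen=True)
class SweepGrid:
    """SCI x PSP threshold grids (defaults: 18 x 20 = 360 combinations)."""

    sci_values: tuple[float, ...] = field(default_factory=_default_sci)
    psp_values: tuple[float, ...] = field(default_factory=_default_psp)

    def __post_init__(self) -> None:
        for name, vals, lo, hi in (
            ("sci_values", self.sci_values, 0.0, 1.0),
            ("psp_values", self.psp_values, 0.0, np.inf),
        ):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0 or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be non-empty and strictly increasing")
            if arr[0] <= lo or arr[-1] > hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi}]")

    @property
    def n_points(self) -> int:
        return len(self.sci_values) * len(self.psp_values)


@dataclass
class MatchResult:
    """Retention-matched ranking of grid points against CV pruning."""

    table: pd.DataFrame  # per grid point: d_cr, d_excl, ranks, combined
    selected: tuple[float, float]  # (sci_thr, psp_thr) with minimal combined rank
    cv_mean_cr: float
    cv_n_excluded: int


def trc_snr(
    recording: RawIntensityRecording,
    pruning: PruningResult,
    trc_set: "set[int] | list[int]",
    clean_windows: dict[int, list[int]] | None = None,
    window_s: float = 3.0,
) -> float:
    """Mean SNR (dB) over retained task-relevant channels; NaN if none retained.

    Per channel the SNR is computed on the concatenated clean-window raw
    intensities, averaged over the two wavelengths.
    """
    trc = sorted(set(int(c) for c in trc_set))
    if not trc:
        raise ValueError("trc_set is empty")
    retained = [c for c in trc if pruning.statuses.get(c) == RETAINED]
    if not retained:
        return float("nan")
    bounds = window_bounds(recording.n_samples, recording.sampling_rate, window_s)
    values = []
    for c in retained:
        clean = (
            clean_windows.get(c, []) if clean_windows is not None else list(range(len(bounds)))
        )
        if not clean:
            continue
        keep = np.concatenate([np.arange(*bounds[k]) for k in clean])
        values.append(
            np.mean([snr_db(recording.intensity[c, w, keep]) for w in (0, 1)])
        )
    return float(np.mean(values)) if values else float("nan")


def participant_quality(
    recording: RawIntensityRecording,
    qt_config: QTConfig = QTConfig(),
    motion_config: MotionConfig = MotionConfig(),
):
    """One-pass per-participant preprocessing shared by every grid point.

    Returns ``(cse, clean_windows, quality_cache, pom)``: the CSE channel
    set, per-channel clean-window indices, per-channel
    :class:`~nirsprune.quality.ChannelQuality`, and the percentage of
    motion over acceptable channels.
    """
    cse = find_cse(recording)
    mask = detect_motion(recording, motion_config)
    bounds = window_bounds(recording.n_samples, recording.sampling_rate, qt_config.window_s)
    clean_windows = {
        c: clean_window_indices(mask.flags[c], bounds) for c in range(recording.n_channels)
    }
    acceptable = [c for c in range(recording.n_channels) if c not in cse]
    pom = percent_motion(mask, qt_config.window_s, acceptable) if acceptable else float("nan")
    quality_cache = {
        c: evaluate_channel(recording, c, qt_config, clean_windows[c])
        for c in acceptable
        if clean_windows[c]
    }
    return cse, clean_windows, quality_cache, pom


def _qt_result_from_cache(
    recording, cse, clean_windows, quality_cache, sci_thr, psp_thr, q_threshold, method
) -> PruningResult:
    from .pruning import EXCLUDED_CSE

    statuses = {}
    for c in range(recording.n_channels):
        if c in cse:
            statuses[c] = EXCLUDED_CSE
        elif not clean_windows.get(c):
            statuses[c] = EXCLUDED_NO_CLEAN_WINDOWS
        else:
            frac = quality_cache[c].good_fraction(sci_thr, psp_thr)
            statuses[c] = RETAINED if frac >= q_threshold else PRUNED_QT
    return PruningResult(
        statuses=statuses,
        method=method,
        params={"sci_threshold": sci_thr, "psp_threshold": psp_thr, "q_threshold": q_threshold},
    )


def run_sweep(
    cohort: "list[tuple[RawIntensityRecording, object]] | list[RawIntensityRecording]",
    trc_indices: "set[int] | list[int]",
    grid: SweepGrid = SweepGrid(),
    qt_config: QTConfig = QTConfig(),
    motion_config: MotionConfig = MotionConfig(),
    cv_config: CVConfig = CVConfig(),
    exclusion_fraction: float = 0.60,
) -> pd.DataFrame:
    """Sweep all grid points plus SCI-only and CV pruning over a cohort.

    Returns a long-format table with one row per participant x method x
    parameter combination: ``method`` is ``'qt'`` (full grid), ``'sci'``
    (psp_threshold = 0) or ``'cv'``; columns carry CR, TRC SNR, the
    participant-exclusion flag, PoM and the CSE count.
    """
    rows = []
    for item in cohort:
        recording = item[0] if isinstance(item, tuple) else item
        p = recording.participant
        cse, clean_windows, quality_cache, pom = participant_quality(
            recording, qt_config, motion_config
        )
        acceptable = recording.n_channels - len(cse)
        base = {
            "id": p.get("id", "P000"),
            "age_months": p.get("age_months", np.nan),
            "cohort": p.get("cohort", ""),
            "task": p.get("task", ""),
            "pom": pom,
            "n_cse": len(cse),
            "n_acceptable": acceptable,
        }

        # per-channel SNR on clean-window data does not depend on thresholds
        bounds = window_bounds(recording.n_samples, recording.sampling_rate, qt_config.window_s)
        snr_by_channel = {}
        for c in set(int(i) for i in trc_indices):
            clean = clean_windows.get(c, [])
            if not clean:
                continue
            keep = np.concatenate([np.arange(*bounds[k]) for k in clean])
            snr_by_channel[c] = np.mean(
                [snr_db(recording.intensity[c, w, keep]) for w in (0, 1)]
            )

        def add_row(method, sci_thr, psp_thr, result):
            cr = result.channels_retained
            vals = [
                snr_by_channel[c]
                for c in snr_by_channel
                if result.statuses.get(c) == RETAINED
            ]
            rows.append(
                {
                    **base,
                    "method": method,
                    "sci_thr": sci_thr,
                    "psp_thr": psp_thr,
                    "cr": cr,
                    "trc_snr": float(np.mean(vals)) if vals else np.nan,
                    "excluded": exclusion_rule(cr, acceptable, exclusion_fraction),
                }
            )

        cv_result = prune_cv(recording, clean_windows, cv_config, cse)
        add_row("cv", np.nan, np.nan, cv_result)
        for s in grid.sci_values:
            add_row(
                "sci", s, 0.0,
                _qt_result_from_cache(recording, cse, clean_windows, quality_cache,
                                      s, 0.0, qt_config.q_threshold, "sci"),
            )
            for q in grid.psp_values:
                add_row(
                    "qt", s, q,
                    _qt_result_from_cache(recording, cse, clean_windows, quality_cache,
                                          s, q, qt_config.q_threshold, "qt"),
                )
    return pd.DataFrame(rows)


def exclusion_rule(cr: int, acceptable_channel_count: int, fraction: float = 0.60) -> bool:
    """Participant excluded iff CR < fraction x acceptable (non-CSE) channels."""
    if acceptable_channel_count <= 0:
        return True
    return cr < fraction * acceptable_channel_count


def match_to_cv(sweep_table: pd.DataFrame, method: str = "qt") -> MatchResult:
    """Rank grid points by similarity to CV pruning and select the closest.

    Two ascending rankings — distance in mean CR across participants and
    distance in the number of excluded participants — are combined by rank
    sum (ties averaged within each ranking); the minimal combined rank is
    selected, with ties broken toward lower (sci, psp) thresholds.
    """
    if sweep_table.empty:
        raise ValueError("sweep table is empty")
    cv = sweep_table[sweep_table["method"] == "cv"]
    if cv.empty:
        raise ValueError("sweep table has no CV rows to match against")
    cv_mean_cr = float(cv["cr"].mean())
    cv_excl = int(cv["excluded"].sum())

    sub = sweep_table[sweep_table["method"] == method]
    if sub.empty:
        raise ValueError(f"sweep table has no '{method}' rows")
    grouped = (
        sub.groupby(["sci_thr", "psp_thr"], dropna=False)
        .agg(mean_cr=("cr", "mean"), n_excluded=("excluded", "sum"))
        .reset_index()
    )
    grouped["d_cr"] = (grouped["mean_cr"] - cv_mean_cr).abs()
    grouped["d_excl"] = (grouped["n_excluded"] - cv_excl).abs()
    grouped["rank_cr"] = rankdata(grouped["d_cr"], method="average")
    grouped["rank_excl"] = rankdata(grouped["d_excl"], method="average")
    grouped["combined"] = grouped["rank_cr"] + grouped["rank_excl"]

    best = grouped[grouped["combined"] == grouped["combined"].min()]
    best = best.sort_values(["sci_thr", "psp_thr"], kind="mergesort").iloc[0]
    return MatchResult(
        table=grouped,
        selected=(float(best["sci_thr"]), float(best["psp_thr"])),
        cv_mean_cr=cv_mean_cr,
        cv_n_excluded=cv_excl,
    )


def tradeoff_trend(
    sweep_table: pd.DataFrame, method: str = "qt", n_recommend: int = 1
) -> pd.DataFrame:
    """Quality/retention trade-off: monotone trend of TRC SNR against CR.

    Grid points are reduced to group means (over participants with a
    defined TRC SNR); an isotonic (monotone) trend of mean TRC SNR against
    mean CR is fitted and each grid point's residual computed. Grid points
    with the largest positive residual — quality above trend at comparable
    retention — are recommended; ties prefer higher retention.
    Returns the per-grid-point table sorted so recommended rows come first,
    with a boolean ``recommended`` column.
    """
    from sklearn.isotonic import IsotonicRegression

    sub = sweep_table[(sweep_table["method"] == method) & sweep_table["trc_snr"].notna()]
    grouped = (
        sub.groupby(["sci_thr", "psp_thr"], dropna=False)
        .agg(mean_snr=("trc_snr", "mean"), mean_cr=("cr", "mean"))
        .reset_index()
    )
    if len(grouped) < 3:
        raise ValueError("trade-off trend needs at least 3 grid points with defined TRC SNR")
    iso = IsotonicRegression(increasing="auto", out_of_bounds="clip")
    trend = iso.fit_transform(grouped["mean_cr"], grouped["mean_snr"])
    grouped["trend"] = trend
    grouped["residual"] = grouped["mean_snr"] - grouped["trend"]
    order = grouped.sort_values(
        ["residual", "mean_cr"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
    order["recommended"] = False
    order.loc[: n_recommend - 1, "recommended"] = True
    return order
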