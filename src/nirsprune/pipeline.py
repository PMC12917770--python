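"""End-to-end pipeline driver: simulate/load -> QC -> sweep -> match -> fit -> report.

Every intermediate is persisted as CSV (plus SNIRF for recordings and JSON
for fitted effects) so runs are inspectable and resumable: with
``resume=True`` a stage whose output file already exists is skipped and
its table reloaded, so deleting one intermediate regenerates only the
downstream stages.  A run manifest records the configuration hash, seeds
and per-stage row counts; identical configurations yield byte-identical
CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mlm import bootstrap_fixed_effects, fit_method_model
from .motion import MotionConfig
from .pruning import CVConfig
from .quality import QTConfig
from .simulate import CohortDesign, SimulationConfig, generate_cohort
from .sweep import SweepGrid, match_to_cv, run_sweep, tradeoff_trend

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "summarize", "load_config"]

#: Recommended threshold minima for infant data (quality/retention guidance).
RECOMMENDED_MIN_SCI = 0.6
RECOMMENDED_MIN_PSP = 0.04


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    design: CohortDesign = field(default_factory=CohortDesign)
    motion: MotionConfig = field(default_factory=MotionConfig)
    qt: QTConfig = field(default_factory=QTConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    grid: SweepGrid = field(default_factory=SweepGrid)
    n_boot: int = 200
    stats_seed: int = 0
    bonferroni_m: int = 3
    exclusion_fraction: float = 0.60
    write_snirf: bool = False  # recordings to SNIRF (off by default: bulky)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    stats_seed: int
    started: str
    row_counts: dict = field(default_factory=dict)


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file of nested sections."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, cls in (
        ("simulation", SimulationConfig),
        ("design", CohortDesign),
        ("motion", MotionConfig),
        ("qt", QTConfig),
        ("cv", CVConfig),
        ("grid", SweepGrid),
    ):
        if key in raw:
            section = dict(raw[key])
            for k, v in section.items():
                if isinstance(v, list):
                    section[k] = tuple(v)
            kwargs[key] = cls(**section)
    for key in ("n_boot", "stats_seed", "bonferroni_m", "exclusion_fraction", "write_snirf"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # default float formatting is shortest-round-trip, so reloading an
    # intermediate reproduces the exact doubles (resume stays byte-stable)
    df.to_csv(path, index=False)


def _matched_method_rows(sweep_df: pd.DataFrame) -> pd.DataFrame:
    """One row per participant x method at the retention-matched parameters."""
    qt_match = match_to_cv(sweep_df, "qt")
    sci_match = match_to_cv(sweep_df, "sci")
    cv_rows = sweep_df[sweep_df["method"] == "cv"]
    qt_rows = sweep_df[
        (sweep_df["method"] == "qt")
        & (sweep_df["sci_thr"] == qt_match.selected[0])
        & (sweep_df["psp_thr"] == qt_match.selected[1])
    ]
    sci_rows = sweep_df[
        (sweep_df["method"] == "sci") & (sweep_df["sci_thr"] == sci_match.selected[0])
    ]
    out = pd.concat([cv_rows, sci_rows, qt_rows], ignore_index=True)
    out.attrs["qt_selected"] = qt_match.selected
    out.attrs["sci_selected"] = sci_match.selected
    return out


def run_pipeline(config: PipelineConfig, output_dir, resume: bool = False) -> dict:
    """Run the full analysis and persist every stage under ``output_dir``.

    Returns a bundle dict with the stage tables and fitted results.
    Any stage failure is re-raised annotated with the stage name.
    """
    from . import __version__

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.hash(),
        package_version=__version__,
        seed=config.simulation.seed,
        stats_seed=config.stats_seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    bundle: dict = {"output_dir": str(out)}

    def stage(name, path, fn, reader=pd.read_csv):
        fpath = out / path
        if resume and fpath.exists():
            return reader(fpath)
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return result

    # --- simulate ---------------------------------------------------------
    recordings, participants = generate_cohort(config.design, config.simulation)
    _write_csv(participants, out / "participants.csv")
    manifest.row_counts["participants"] = len(participants)
    bundle["participants"] = participants
    if config.write_snirf:
        from .io_snirf import write_snirf

        snirf_dir = out / "snirf"
        snirf_dir.mkdir(exist_ok=True)
        for rec, _ in recordings:
            write_snirf(rec, snirf_dir / f"{rec.participant['id']}.snirf")

    # --- sweep (CSE, motion, clean windows, quality, pruning, grid) -------
    def do_sweep():
        df = run_sweep(
            recordings,
            trc_indices=config.simulation.trc_indices,
            grid=config.grid,
            qt_config=config.qt,
            motion_config=config.motion,
            cv_config=config.cv,
            exclusion_fraction=config.exclusion_fraction,
        )
        _write_csv(df, out / "sweep.csv")
        return df

    sweep_df = stage("sweep", "sweep.csv", do_sweep)
    manifest.row_counts["sweep"] = len(sweep_df)
    bundle["sweep"] = sweep_df

    # --- retention match --------------------------------------------------
    def do_match():
        rows = _matched_method_rows(sweep_df)
        meta = pd.DataFrame(
            {
                "method": ["qt", "sci"],
                "sci_thr": [rows.attrs["qt_selected"][0], rows.attrs["sci_selected"][0]],
                "psp_thr": [rows.attrs["qt_selected"][1], rows.attrs["sci_selected"][1]],
            }
        )
        _write_csv(rows, out / "matched_rows.csv")
        _write_csv(meta, out / "matched_params.csv")
        return rows

    matched = stage("match", "matched_rows.csv", do_match)
    manifest.row_counts["matched"] = len(matched)
    bundle["matched"] = matched

    # --- method model -----------------------------------------------------
    def do_method_fit():
        fit = fit_method_model(matched, outcome="trc_snr", m=config.bonferroni_m)
        df = pd.DataFrame(
            [
                {
                    "term": e.term,
                    "estimate": e.estimate,
                    "se": e.se,
                    "p_raw": e.p_raw,
                    "p_corrected": e.p_corrected,
                }
                for e in fit.effects
            ]
        )
        _write_csv(df, out / "method_contrasts.csv")
        return df

    contrasts = stage("method_model", "method_contrasts.csv", do_method_fit)
    bundle["method_contrasts"] = contrasts

    # --- full model (bootstrap) ------------------------------------------
    def do_full_fit():
        sub = sweep_df[sweep_df["method"] == "qt"].rename(columns={"age_months": "age",
                                                                   "n_cse": "cse"})
        fit = bootstrap_fixed_effects(
            sub, outcome="trc_snr", n_boot=config.n_boot, seed=config.stats_seed
        )
        df = pd.DataFrame(
            [
                {
                    "term": e.term,
                    "estimate": e.estimate,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "se": e.se,
                    "p": e.p_corrected,
                }
                for e in fit.effects
            ]
        )
        _write_csv(df, out / "full_model_effects.csv")
        return df

    effects = stage("full_model", "full_model_effects.csv", do_full_fit)
    bundle["full_model_effects"] = effects

    # --- trade-off trend --------------------------------------------------
    def do_trend():
        df = tradeoff_trend(sweep_df, "qt")
        _write_csv(df, out / "tradeoff.csv")
        return df

    trend = stage("tradeoff", "tradeoff.csv", do_trend)
    bundle["tradeoff"] = trend

    with open(out / "manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def summarize(output_dir) -> str:
    """Human-readable report over a completed run directory."""
    out = Path(output_dir)
    required = [
        "participants.csv",
        "sweep.csv",
        "matched_rows.csv",
        "matched_params.csv",
        "method_contrasts.csv",
        "full_model_effects.csv",
        "tradeoff.csv",
    ]
    missing = [f for f in required if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run bundle; missing: {', '.join(missing)}")

    sweep = pd.read_csv(out / "sweep.csv")
    matched_params = pd.read_csv(out / "matched_params.csv")
    contrasts = pd.read_csv(out / "method_contrasts.csv")
    effects = pd.read_csv(out / "full_model_effects.csv")
    trend = pd.read_csv(out / "tradeoff.csv")

    lines = ["# nirsprune run summary", ""]
    by_method = (
        sweep.groupby("method")
        .agg(mean_cr=("cr", "mean"), mean_trc_snr=("trc_snr", "mean"),
             n_excluded=("excluded", "sum"))
        .reset_index()
    )
    lines.append("## Retention and quality by method (all grid points pooled)")
    lines.append(by_method.to_string(index=False))
    lines.append("")
    lines.append("## Retention-matched parameters")
    lines.append(matched_params.to_string(index=False))
    lines.append("")
    lines.append("## Method contrasts (TRC SNR, dB; Bonferroni-corrected)")
    lines.append(contrasts.to_string(index=False))
    lines.append("")
    lines.append("## Full-model fixed effects (bootstrap, scaled units)")
    lines.append(effects.to_string(index=False))
    lines.append("")
    rec = trend[trend["recommended"]]
    lines.append("## Trade-off recommendation")
    lines.append(rec.to_string(index=False))
    low = rec[
        (rec["sci_thr"] < RECOMMENDED_MIN_SCI) | (rec["psp_thr"] < RECOMMENDED_MIN_PSP)
    ]
    if not low.empty:
        lines.append(
            f"note: recommended point(s) fall below the suggested infant minima "
            f"(sci >= {RECOMMENDED_MIN_SCI}, psp >= {RECOMMENDED_MIN_PSP}); "
            "treat retention there with caution."
        )
    return "\n".join(lines) + "\n"
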