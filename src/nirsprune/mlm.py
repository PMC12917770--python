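"""Mixed-model comparison of pruning methods with row-resampling bootstrap.

Two models are provided.  The method model,

    outcome ~ pruning method + (1 | participant),

compares TRC SNR between CV, SCI-only and full SCI/PSP pruning at
retention-matched parameters through the three pairwise contrasts, with
Bonferroni correction over the contrasts.  The full model,

    outcome ~ SCI*PSP + Age*SCI + Age*PSP + SCI*PoM + PSP*PoM + Age*PoM
              + Task + Cohort + CSE
              + (1 | participant) + (1 | SCI:Cohort) + (1 | PSP:Cohort),

quantifies how the two thresholds, age and motion prevalence drive signal
quality (TRC SNR) or channel retention (CR).  The threshold-by-cohort
random intercepts are expressed as variance components within the
participant grouping (statsmodels' MixedLM supports only nested variance
components); all numeric variables, outcome included, are scaled and
centred (z-scored with sample sd) before fitting.

Model residuals on real data of this kind are non-normal, so percentile
bootstrap over rows (resampled with replacement, fixed seed) is the
primary inference path; model-based Wald p-values are carried only as
diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScaledVariable",
    "EffectEstimate",
    "FitResult",
    "scale_center",
    "bonferroni",
    "fit_method_model",
    "fit_full_model",
    "bootstrap_fixed_effects",
]

@dataclass
class ScaledVariable:
    """A z-scored variable with its original location and scale."""

    values: np.ndarray
    mean: float
    sd: float
    degenerate: bool = False


@dataclass
class EffectEstimate:
    term: str
    estimate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    se: float = float("nan")
    p_corrected: float = float("nan")
    p_raw: float = float("nan")


@dataclass
class FitResult:
    effects: list[EffectEstimate]
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def effect(self, term: str) -> EffectEstimate:
        for e in self.effects:
            if e.term == term:
                return e
        raise KeyError(term)

    @property
    def terms(self) -> list[str]:
        return [e.term for e in self.effects]


def scale_center(x) -> ScaledVariable:
    """z-score a vector: (x - mean) / sample sd; constant vectors map to zeros."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("scale_center needs at least 2 values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return ScaledVariable(values=np.zeros_like(x), mean=mean, sd=0.0, degenerate=True)
    return ScaledVariable(values=(x - mean) / sd, mean=mean, sd=sd)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, m * p)


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups, vc_formula=None):
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=groups, vc_formula=vc_formula)
        try:
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        except Exception:
            fit = model.fit(reml=True, method="powell", maxiter=500)
    return fit


def fit_method_model(
    rows: pd.DataFrame,
    outcome: str = "trc_snr",
    methods: tuple[str, ...] = ("cv", "sci", "qt"),
    m: int | None = None,
) -> FitResult:
    """Pairwise pruning-method contrasts under a participant random intercept.

    ``rows`` holds one row per participant x method (columns ``id``,
    ``method`` and the outcome).  Each of the three pairwise contrasts is
    estimated by a mixed model on the corresponding two-method subset;
    Wald p-values are Bonferroni-multiplied by the number of contrasts.
    """
    rows = rows.dropna(subset=[outcome])
    if rows["id"].nunique() < 2:
        raise ValueError("method model needs at least 2 participants")
    pairs = [
        (a, b) for i, a in enumerate(methods) for b in methods[i + 1 :]
    ]
    m_eff = m if m is not None else len(pairs)
    effects = []
    converged = True
    for a, b in pairs:
        sub = rows[rows["method"].isin([a, b])].copy()
        if sub.empty or sub["method"].nunique() < 2:
            continue
        sub["method"] = pd.Categorical(sub["method"], categories=[a, b])
        fit = _fit_mixedlm(f"{outcome} ~ C(method)", sub, groups=sub["id"])
        converged &= bool(fit.converged)
        term = f"C(method)[T.{b}]"
        beta = float(fit.params[term])
        p_raw = float(fit.pvalues[term])
        if np.isnan(p_raw):  # zero-variance contrast: exact null
            p_raw = 1.0
        effects.append(
            EffectEstimate(
                term=f"{b} - {a}",
                estimate=beta,
                se=float(fit.bse[term]),
                p_raw=p_raw,
                p_corrected=bonferroni(min(max(p_raw, 0.0), 1.0), m_eff),
            )
        )
    return FitResult(effects=effects, converged=converged, diagnostics={"m": m_eff})


def _prepare_full_model_frame(
    rows: pd.DataFrame, outcome: str, age_categorical: bool
) -> tuple[pd.DataFrame, str]:
    """Scale/centre variables and build the model formula.

    Degenerate variables (constant after scaling, or single-level factors)
    are dropped from the formula together with every term that involves
    them, so designs that lack variation in a covariate — e.g. a cohort
    with no CSE channels anywhere, or a single-task cell — still fit.
    """
    need = {"id", "sci_thr", "psp_thr", "age", "pom", "cse", "task", "cohort", outcome}
    missing = need - set(rows.columns)
    if missing:
        raise ValueError(f"analysis rows are missing columns: {sorted(missing)}")
    d = rows.dropna(subset=[outcome]).copy()
    if len(d) < 10:
        raise ValueError("too few rows to fit the full model")
    out = {
        "id": d["id"].to_numpy(),
        "outcome": scale_center(d[outcome]).values,
        "sci_cohort": (d["sci_thr"].astype(str) + ":" + d["cohort"].astype(str)).to_numpy(),
        "psp_cohort": (d["psp_thr"].astype(str) + ":" + d["cohort"].astype(str)).to_numpy(),
    }
    degenerate: set[str] = set()
    for name, col in (("sci", "sci_thr"), ("psp", "psp_thr"), ("pom", "pom"), ("cse", "cse")):
        sv = scale_center(d[col])
        out[name] = sv.values
        if sv.degenerate:
            degenerate.add(name)
    for name in ("task", "cohort"):
        out[name] = d[name].astype(str).to_numpy()
        if d[name].nunique() < 2:
            degenerate.add(name)
    if age_categorical:
        out["age"] = d["age"].astype(str).to_numpy()
        if d["age"].nunique() < 2:
            degenerate.add("age")
    else:
        sv = scale_center(d["age"])
        out["age"] = sv.values
        if sv.degenerate:
            degenerate.add("age")

    terms = ["sci*psp", "age*sci", "age*psp", "sci*pom", "psp*pom", "age*pom",
             "task", "cohort", "cse"]
    kept = [
        t for t in terms
        if not any(v in degenerate for v in t.split("*"))
    ]
    if not kept:
        raise ValueError("every model term is degenerate; nothing to fit")
    formula = "outcome ~ " + " + ".join(kept)
    return pd.DataFrame(out), formula


def fit_full_model(
    rows: pd.DataFrame,
    outcome: str = "trc_snr",
    age_categorical: bool = False,
    variance_components: bool = True,
) -> FitResult:
    """Fit the full threshold/age/motion fixed-effects model on scaled variables.

    ``rows`` is a long table with columns ``id, sci_thr, psp_thr, age,
    pom, cse, task, cohort`` and the outcome column.  Returns the fixed
    effects with model-based (Wald) diagnostics; use
    :func:`bootstrap_fixed_effects` for the primary intervals.  A
    non-converged fit is returned flagged, not raised.
    """
    d, formula = _prepare_full_model_frame(rows, outcome, age_categorical)
    vc = (
        {"sci_cohort": "0 + C(sci_cohort)", "psp_cohort": "0 + C(psp_cohort)"}
        if variance_components
        else None
    )
    fit = _fit_mixedlm(formula, d, groups=d["id"], vc_formula=vc)
    effects = []
    for term in fit.params.index:
        if term == "Group Var" or term.endswith("Var") or term.endswith("Cov"):
            continue
        effects.append(
            EffectEstimate(
                term=term,
                estimate=float(fit.params[term]),
                se=float(fit.bse[term]),
                p_raw=float(fit.pvalues[term]),
            )
        )
    return FitResult(
        effects=effects,
        converged=bool(fit.converged),
        diagnostics={"loglike": float(fit.llf), "n": int(len(d))},
    )


def bootstrap_fixed_effects(
    rows: pd.DataFrame,
    outcome: str = "trc_snr",
    n_boot: int = 1000,
    seed: int = 0,
    age_categorical: bool = False,
    variance_components: bool = True,
    ci: float = 0.95,
) -> FitResult:
    """Percentile bootstrap of the full model's fixed effects.

    Rows are resampled with replacement ``n_boot`` times (fixed seed); the
    model is refitted on each resample.  The reported estimate is the mean
    of the bootstrap estimates, the CI the 2.5/97.5 percentiles (at the
    default coverage) and the SE the bootstrap standard deviation.  A
    corrected p-value is derived from the fraction of bootstrap estimates
    crossing zero (two-sided, uncorrected family of 1).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    d = rows.dropna(subset=[outcome]).reset_index(drop=True)
    n = len(d)
    estimates: dict[str, list[float]] = {}
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = d.iloc[idx]
        try:
            fit = fit_full_model(sample, outcome, age_categorical, variance_components)
        except (ValueError, KeyError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        for e in fit.effects:
            estimates.setdefault(e.term, []).append(e.estimate)
    if not estimates:
        raise RuntimeError("every bootstrap resample failed to fit")
    alpha = (1.0 - ci) / 2.0
    effects = []
    for term, vals in estimates.items():
        arr = np.asarray(vals)
        p_boot = 2.0 * min(np.mean(arr > 0), np.mean(arr < 0))
        effects.append(
            EffectEstimate(
                term=term,
                estimate=float(arr.mean()),
                ci_low=float(np.percentile(arr, 100 * alpha)),
                ci_high=float(np.percentile(arr, 100 * (1 - alpha))),
                se=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
                p_raw=float(p_boot),
                p_corrected=float(min(1.0, p_boot)),
            )
        )
    return FitResult(
        effects=effects,
        converged=(n_failed < n_boot),
        diagnostics={"n_boot": n_boot, "n_failed": n_failed, "seed": seed},
    )
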