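"""End-to-end analysis: records table -> derived variables -> all mixed
models -> constrained-resampling null test.

The analysis battery mirrors the study design:

====================  =========================================================
analysis              model
====================  =========================================================
lifetime_pups         Poisson GLMM, all breeders: lifetime pups ~ peak effort
                      (linear+quadratic) + peak age (linear+quadratic)
                      + lifespan + primiparity, cohort intercept
lifetime_recruits     the same with a negative-binomial response
peak_year_timing      binomial GLMM on the mast-experienced females' annual
                      records: peak-year status ~ mast flag, female-in-cohort
annual_pups_mast      Poisson GLMM, annual pups ~ mast flag, female-in-cohort
annual_recruits_mast  NB GLMM, annual recruits ~ mast flag, female-in-cohort
mast_peak_fitness     NB GLMM, mast-experienced: lifetime recruits ~ mast-peak
                      flag + lifespan + primiparity, cohort intercept
mast_constraint       binomial GLMM, mast-experienced: mast-peak flag ~ age at
                      mast (linear+quadratic) + pre-peak rate, cohort intercept
post_peak_survival    Gaussian LMM, mast-experienced: post-peak lifespan ~
                      mast peak * peak effort + peak age, cohort intercept
post_peak_repro       Poisson GLMM, same terms, response post-peak pups
====================  =========================================================

Every model is reduced by backward selection (interactions and quadratics
first, threshold p < 0.05); continuous predictors are standardized within
each analysis; primiparity is coded 1 = yearling with delayed as reference
and mast flags 0/1 with non-mast reference. The vertex of the peak-effort
parabola is back-converted to pups with each analysis's own scaling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calendar import MastCalendar
from .glmm import (FitResult, ModelSpec, backward_select, bootstrap_ci,
                   fit_glmm, vertex_in_natural_units)
from .lifehistory import (annual_table, build_analysis_sets,
                          frame_to_histories, read_records_csv,
                          summarize_females)
from .nulltest import NullDistribution, null_slope_distribution

ANALYSES = (
    "lifetime_pups", "lifetime_recruits", "peak_year_timing",
    "annual_pups_mast", "annual_recruits_mast", "mast_peak_fitness",
    "mast_constraint", "post_peak_survival", "post_peak_reproduction",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline options.

    ``subset`` picks the female set for the lifetime models: ``full_set``
    (default), ``multi_year_set`` (single-year breeders excluded) or
    ``never_mast_set``; the mast-conditional analyses always use the
    mast-experienced females compatible with that subset and are skipped
    with a reason when none exist. ``n_boot`` switches the reported CIs
    from Wald to parametric bootstrap (slower).
    """

    seed: int = 0
    alpha: float = 0.05
    subset: str = "full_set"
    run_null_test: bool = True
    n_null_iterations: int = 1000
    n_boot: int = 0              # 0 = Wald CIs only
    backward_selection: bool = True

    def __post_init__(self) -> None:
        if self.subset not in ("full_set", "multi_year_set", "never_mast_set"):
            raise ValueError(f"unknown subset {self.subset!r}")


@dataclass
class AnalysisReport:
    """All fitted models plus derived quantities and provenance."""

    fits: dict[str, FitResult]
    skipped: dict[str, str]
    selection_traces: dict[str, list]
    vertex_pups: float
    vertex_recruits: float
    group_means: dict[str, dict]
    null_test: NullDistribution | None
    n_females: dict[str, int]
    provenance: dict

    def to_dir(self, path) -> None:
        """Serialize: one coefficient CSV per model plus a JSON summary."""
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        for name, fit in self.fits.items():
            fit.summary().to_csv(out / f"model_{name}.csv", index=False)
        summary = {
            "skipped": self.skipped,
            "vertex_pups": self.vertex_pups,
            "vertex_recruits": self.vertex_recruits,
            "group_means": self.group_means,
            "n_females": self.n_females,
            "null_test": self.null_test.summary() if self.null_test else None,
            "variance_components": {
                n: f.variance_components for n, f in self.fits.items()},
            "provenance": self.provenance,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)


def _model_specs() -> dict[str, ModelSpec]:
    lifetime_terms = ("peak_effort", "peak_effort^2", "peak_age", "peak_age^2",
                      "lifespan", "primiparity")
    lifetime_scaled = ("peak_effort", "peak_age", "lifespan")
    post_terms = ("mast_peak", "peak_effort", "mast_peak:peak_effort", "peak_age")
    post_scaled = ("peak_effort", "peak_age")
    return {
        "lifetime_pups": ModelSpec(
            "lifetime_pups", "poisson", lifetime_terms,
            "cohort_intercept", lifetime_scaled),
        "lifetime_recruits": ModelSpec(
            "lifetime_recruits", "negative_binomial", lifetime_terms,
            "cohort_intercept", lifetime_scaled),
        "peak_year_timing": ModelSpec(
            "is_peak_year", "binomial", ("is_mast",),
            "female_in_cohort_intercepts"),
        "annual_pups_mast": ModelSpec(
            "pups", "poisson", ("is_mast",), "female_in_cohort_intercepts"),
        "annual_recruits_mast": ModelSpec(
            "recruits", "negative_binomial", ("is_mast",),
            "female_in_cohort_intercepts"),
        "mast_peak_fitness": ModelSpec(
            "lifetime_recruits", "negative_binomial",
            ("mast_peak", "lifespan", "primiparity"),
            "cohort_intercept", ("lifespan",)),
        "mast_constraint": ModelSpec(
            "mast_peak", "binomial",
            ("age_at_mast", "age_at_mast^2", "pre_peak_rate"),
            "cohort_intercept", ("age_at_mast", "pre_peak_rate")),
        "post_peak_survival": ModelSpec(
            "post_peak_lifespan", "gaussian", post_terms,
            "cohort_intercept", post_scaled),
        "post_peak_reproduction": ModelSpec(
            "post_peak_pups", "poisson", post_terms,
            "cohort_intercept", post_scaled),
    }


def _fit_one(spec: ModelSpec, data: pd.DataFrame, cfg: AnalysisConfig,
             seed_offset: int):
    if cfg.backward_selection:
        final_spec, fit, trace = backward_select(spec, data, alpha=cfg.alpha)
    else:
        final_spec, fit, trace = spec, fit_glmm(spec, data), []
    if cfg.n_boot > 0:
        bootstrap_ci(fit, n_boot=cfg.n_boot,
                     seed=(cfg.seed + seed_offset) % 2**31)
    return fit, trace


def group_descriptives(annual: pd.DataFrame, summaries: pd.DataFrame) -> dict:
    """Raw-data means +/- SD by mast status (annual records) and by
    mast-peak status (per-female summaries). Groups of one report a
    missing SD; recruitment proportions are pooled (total recruits / total
    pups) and given in percent."""

    def stat(x):
        x = np.asarray(x, dtype=float)
        return {
            "n": int(x.size),
            "mean": float(np.mean(x)) if x.size else math_nan,
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else math_nan,
        }

    math_nan = float("nan")
    out: dict[str, dict] = {}
    for flag, label in ((0, "nonmast"), (1, "mast")):
        sub = annual[annual["is_mast"] == flag]
        out[f"annual_pups_{label}"] = stat(sub["pups"])
        out[f"annual_recruits_{label}"] = stat(sub["recruits"])
        tot_pups = float(sub["pups"].sum())
        out[f"recruit_percent_{label}"] = {
            "n": int(len(sub)),
            "mean": 100.0 * float(sub["recruits"].sum()) / tot_pups
            if tot_pups else math_nan,
            "sd": math_nan,
        }
    mast_exp = summaries[summaries["experienced_mast"] & summaries["is_breeder"]]
    for flag, label in ((False, "nonmast_peak"), (True, "mast_peak")):
        sub = mast_exp[mast_exp["mast_peak"] == flag]
        out[f"lifetime_recruits_{label}"] = stat(sub["lifetime_recruits"])
        out[f"prop_recruited_percent_{label}"] = stat(100.0 * sub["prop_recruited"])
        out[f"post_peak_lifespan_{label}"] = stat(sub["post_peak_lifespan"])
    return out


def run_full_analysis(
    records,
    calendar: MastCalendar,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the whole battery on a records table (path or DataFrame).

    Derives the per-female summaries and flagged annual table, fits every
    analysis (with backward selection), computes the quadratic optima of
    peak effort in natural pup units, the raw-data group descriptives, and
    — unless disabled — the constrained-resampling null for the
    peak-effort slope of the selected lifetime-pups model.
    """
    cfg = config or AnalysisConfig()
    if isinstance(records, (str, Path)):
        records = read_records_csv(records)
    histories = frame_to_histories(records)
    summaries = summarize_females(histories, calendar)
    sets = build_analysis_sets(summaries)
    lifetime_data = sets[cfg.subset]
    if len(lifetime_data) == 0:
        raise ValueError(f"analysis subset {cfg.subset!r} is empty after filtering")

    # mast-conditional analyses: mast-experienced females inside the subset
    mast_data = lifetime_data[lifetime_data["experienced_mast"]].reset_index(drop=True)
    mast_ids = set(mast_data["female_id"])
    annual = annual_table(histories, calendar)
    annual_mast = annual[annual["female_id"].isin(mast_ids)].reset_index(drop=True)
    # the constraint/post-peak models need cohort & female id columns only;
    # summaries already carry them

    # int-code flags for design matrices
    for frame in (lifetime_data, mast_data):
        frame["mast_peak"] = frame["mast_peak"].astype(int)

    specs = _model_specs()
    fits: dict[str, FitResult] = {}
    skipped: dict[str, str] = {}
    traces: dict[str, list] = {}
    datasets = {
        "lifetime_pups": lifetime_data,
        "lifetime_recruits": lifetime_data,
        "peak_year_timing": annual_mast,
        "annual_pups_mast": annual_mast,
        "annual_recruits_mast": annual_mast,
        "mast_peak_fitness": mast_data,
        "mast_constraint": mast_data,
        "post_peak_survival": mast_data,
        "post_peak_reproduction": mast_data,
    }
    for off, (name, spec) in enumerate(specs.items()):
        data = datasets[name]
        if len(data) == 0:
            skipped[name] = "empty analysis set"
            continue
        try:
            fits[name], traces[name] = _fit_one(spec, data, cfg, off + 1)
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            skipped[name] = str(exc)

    def vertex(name):
        fit = fits.get(name)
        if fit is None or "peak_effort^2" not in fit.terms:
            return float("nan")
        v = vertex_in_natural_units(fit, "peak_effort")
        return v.natural_vertex if v.has_maximum else float("nan")

    null = None
    if cfg.run_null_test and "lifetime_pups" in fits:
        fit = fits["lifetime_pups"]
        if "peak_effort" in fit.spec.fixed_terms:
            null = null_slope_distribution(
                lifetime_data, fit.spec,
                n_iterations=cfg.n_null_iterations,
                seed=cfg.seed % 2**31, observed_fit=fit)
        else:
            skipped["null_test"] = "peak_effort dropped from lifetime-pups model"

    prov = {
        "input_sha256": hashlib.sha256(
            records.to_csv(index=False).encode()).hexdigest(),
        "seed": cfg.seed, "alpha": cfg.alpha, "subset": cfg.subset,
        "n_boot": cfg.n_boot, "n_null_iterations": cfg.n_null_iterations,
        "backward_selection": cfg.backward_selection,
    }
    return AnalysisReport(
        fits=fits, skipped=skipped, selection_traces=traces,
        vertex_pups=vertex("lifetime_pups"),
        vertex_recruits=vertex("lifetime_recruits"),
        group_means=group_descriptives(annual_mast, summaries)
        if len(annual_mast) else {},
        null_test=null,
        n_females={k: int(v["female_id"].nunique()) for k, v in sets.items()},
        provenance=prov,
    )


def sensitivity_reruns(
    records,
    calendar: MastCalendar,
    config: AnalysisConfig | None = None,
    subset: str = "multi_year_set",
) -> AnalysisReport:
    """Repeat the analysis on a restricted female set (default: excluding
    single-year breeders; ``never_mast_set`` restricts to females that
    never saw a mast, where every mast-conditional model is skipped)."""
    from dataclasses import replace

    cfg = replace(config or AnalysisConfig(), subset=subset)
    return run_full_analysis(records, calendar, cfg)
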