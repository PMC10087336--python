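"""End-to-end orchestration of the four meta-analyses.

Each analysis runs the same pipeline on its own effect subset: normalize
dispersions, compute effect sizes, clean, subset, fit a set of candidate
measurement-error models, rank them by WAIC, summarize the best model,
decompose heterogeneity and run the publication-bias diagnostic. Analyses
with the ``gen`` moderator are run twice — once on the full subset without
``gen`` and once on the reduced subset (effects reporting a generations
count) with it — because not every study reports experiment duration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import data_model, effect_size, meta_model, heterogeneity, diagnostics
from .data_model import AssayRecord, EffectRecord
from .meta_model import McmcSettings, ModelSpec, ModelFitSummary

log = logging.getLogger("tpcmeta")

ANALYSES = ("at_selection", "two_point", "multipoint", "hotter_is_better")

#: random-effect structure per analysis: species and study always; TPC ID
#: added when several assay points share a curve
RANDOM_LEVELS = {
    "at_selection": ("species", "study"),
    "two_point": ("species", "study", "tpc"),
    "multipoint": ("species", "study", "tpc"),
    "hotter_is_better": ("species", "study"),
}

#: candidate fixed-effect sets per analysis (intercept is implicit);
#: 'gen' variants are generated on the fly for the reduced data set
MODEL_SETS: dict[str, dict[str, tuple[str, ...]]] = {
    "at_selection": {"intercept": (), "var": ("var",)},
    "two_point": {"intercept": (), "abs_dt": ("abs_dt",),
                  "abs_dt+var": ("abs_dt", "var")},
    "multipoint": {
        "intercept": (),
        "linear": ("dt",),
        "quadratic": ("dt", "dt2"),
        "cubic": ("dt", "dt2", "dt3"),
        "cubic+var": ("dt", "dt2", "dt3", "var"),
        "cubic+var+sign": ("dt", "dt2", "dt3", "var", "sign"),
    },
    "hotter_is_better": {"intercept": (), "var": ("var",)},
}


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class AnalysisConfig:
    input_path: str | Path
    analysis: str
    outdir: str | Path
    seed: int = 0
    models: tuple[str, ...] | None = None     # names from MODEL_SETS
    mcmc: McmcSettings = McmcSettings()
    outlier_threshold: float = 20.0
    include_gen: bool = True

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ValueError(f"unknown analysis {self.analysis!r}; "
                             f"choose from {ANALYSES}")


@dataclass
class AnalysisReport:
    analysis: str
    ranking: pd.DataFrame
    best: ModelFitSummary
    heterogeneity: heterogeneity.HeterogeneitySummary
    funnel: diagnostics.FunnelReport
    n_effects: int
    n_excluded: int
    ranking_reduced: pd.DataFrame | None = None
    best_reduced: ModelFitSummary | None = None


def prepare_effects(records: Sequence[AssayRecord],
                    outlier_threshold: float = 20.0
                    ) -> tuple[list[EffectRecord], list[data_model.Exclusion]]:
    """Normalize dispersion, compute effect sizes, apply exclusion rules."""
    normalized = [data_model.normalize_dispersion(r) for r in records]
    effects = effect_size.compute_effects(normalized)
    return data_model.apply_exclusions(effects, outlier_threshold)


def _fit_model_set(effects: Sequence[EffectRecord], analysis: str,
                   model_names: Sequence[str], mcmc: McmcSettings,
                   seed: int, with_gen: bool
                   ) -> tuple[pd.DataFrame, ModelFitSummary,
                              meta_model.PosteriorDraws, ModelSpec,
                              meta_model.Design]:
    levels = RANDOM_LEVELS[analysis]
    fits: list[ModelFitSummary] = []
    per_name: dict[str, tuple] = {}
    for k, mname in enumerate(model_names):
        terms = MODEL_SETS[analysis][mname]
        if with_gen:
            terms = terms + ("gen",)
            mname = mname + "+gen"
        spec = ModelSpec(name=mname, fixed_terms=terms,
                         random_levels=levels, mcmc=mcmc)
        design = meta_model.build_design(effects, spec, subset_label=analysis)
        draws = meta_model.fit(design, spec, seed=seed + 1000 * (k + 1))
        summary = meta_model.summarize(draws, design, name=mname)
        if not summary.converged:
            log.warning("model %s: max split-R-hat %.3f > %.2f",
                        mname, summary.max_rhat, meta_model.RHAT_LIMIT)
        fits.append(summary)
        per_name[mname] = (draws, spec, design, summary)
    ranking = meta_model.rank_models(fits)
    best_name = ranking["model"].iloc[0]
    draws, spec, design, best = per_name[best_name]
    return ranking, best, draws, spec, design


def run_analysis(cfg: AnalysisConfig) -> AnalysisReport:
    """Execute one published analysis end to end and write its report bundle."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = data_model.read_assay_table(cfg.input_path)
    effects, excl = prepare_effects(records, cfg.outlier_threshold)
    data_model.write_exclusion_log(excl, outdir / "exclusions.csv")

    if cfg.analysis == "hotter_is_better":
        normalized = [data_model.normalize_dispersion(r) for r in records]
        hib = meta_model.hotter_is_better_effects(normalized)
        subset, _ = data_model.apply_exclusions(hib, cfg.outlier_threshold)
    else:
        subset = data_model.build_subsets(effects)[cfg.analysis]
    if not subset:
        raise PipelineError(f"analysis {cfg.analysis!r}: empty effect subset")
    data_model.write_effect_table(subset, outdir / "effects.csv")

    model_names = list(cfg.models or MODEL_SETS[cfg.analysis])
    ranking, best, draws, spec, design = _fit_model_set(
        subset, cfg.analysis, model_names, cfg.mcmc, cfg.seed,
        with_gen=False)

    # second pass on the reduced data set with the generations moderator
    ranking_red = best_red = None
    reduced = [e for e in subset if e.generations is not None]
    if cfg.include_gen and len(reduced) >= 10 and len(
            {e.generations for e in reduced}) > 1:
        ranking_red, best_red, *_ = _fit_model_set(
            reduced, cfg.analysis, model_names, cfg.mcmc, cfg.seed + 7,
            with_gen=True)

    s2 = heterogeneity.typical_sampling_variance(
        [e.rel_fitness_se for e in subset])
    het = heterogeneity.i2_posterior(draws, s2)
    funnel = diagnostics.bias_test(
        subset, random_levels=RANDOM_LEVELS[cfg.analysis],
        mcmc=cfg.mcmc, seed=cfg.seed + 99)

    _write_report(cfg, outdir, ranking, best, het, funnel, draws, design,
                  spec, ranking_red, best_red)
    return AnalysisReport(
        analysis=cfg.analysis, ranking=ranking, best=best, heterogeneity=het,
        funnel=funnel, n_effects=len(subset), n_excluded=len(excl),
        ranking_reduced=ranking_red, best_reduced=best_red)


def _write_report(cfg, outdir: Path, ranking, best, het, funnel, draws,
                  design, spec, ranking_red, best_red) -> None:
    best.params.to_csv(outdir / "best_model_params.csv", index=False)
    ranking.to_csv(outdir / "model_ranking.csv", index=False)
    het.to_frame().to_csv(outdir / "heterogeneity.csv", index=False)
    funnel.funnel.to_csv(outdir / "funnel.csv", index=False)
    if ranking_red is not None:
        ranking_red.to_csv(outdir / "model_ranking_reduced.csv", index=False)
        best_red.params.to_csv(outdir / "best_model_params_reduced.csv",
                               index=False)
    if any(t in spec.fixed_terms for t in ("dt", "abs_dt")):
        dt = _grid(design)
        for var in ("de_novo", "standing"):
            curve = meta_model.predict_curve(
                draws, design, spec, dt, {"variation_source": var})
            curve.to_csv(outdir / f"prediction_{var}.csv", index=False)
    summary = {
        "analysis": cfg.analysis,
        "seed": cfg.seed,
        "mcmc": dataclasses.asdict(cfg.mcmc),
        "n_effects": int(design.n),
        "best_model": best.name,
        "best_waic": best.waic,
        "max_rhat": best.max_rhat,
        "converged": bool(best.converged),
        "bias_verdict": funnel.verdict,
        "bias_slope_interval": [funnel.slope_lo, funnel.slope_hi],
        "I2_total_mean": het.total.i2_mean,
        "s2_typical": het.s2_typical,
    }
    if best_red is not None:
        summary["best_model_reduced"] = best_red.name
    (outdir / "run_log.json").write_text(json.dumps(summary, indent=2))


def _grid(design: meta_model.Design) -> np.ndarray:
    rng = meta_model._observed_dt(design) or (0.0, 1.0)
    return np.linspace(rng[0], rng[1], 41)
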