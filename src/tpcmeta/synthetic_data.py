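"""Synthetic thermal-selection experiments with the hierarchy the analyses assume.

Two generators live here. :func:`simulate_experiment` emulates an extracted
assay table: species carry baseline thermal performance curves (TPCs),
studies and TPC replicates perturb them, a scenario transforms the derived
(selected) curve relative to its ancestor, and replicate-level measurement
noise produces heteroscedastic means and SEs — the same species > study >
TPC > assay-point structure the meta-analytic models decompose.
:func:`simulate_effects_direct` is the generative twin of the
measurement-error model itself (known truth attached), used for parameter
recovery and model-selection checks.

The TPC functional form is a standard negatively skewed unimodal curve:
Gaussian rise below the thermal optimum, quadratic fall to zero at the
critical maximum. Scenarios mirror the classical hypotheses for TPC
evolution: a pure optimum shift, "Hotter is better" (shift plus height
gain), a generalist-specialist trade-off (wider but lower), "Hotter is
wider" (shift plus widening at preserved height), and a null (no change).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data_model import AssayRecord, EffectRecord

SCENARIOS = ("null", "shift", "hotter_is_better", "generalist_specialist",
             "hotter_is_wider")


@dataclass(frozen=True)
class TPCShape:
    """Unimodal, negatively skewed thermal performance curve.

    ``sigma_rise`` controls the gentle Gaussian rise below ``t_opt``;
    performance falls quadratically between ``t_opt`` and the critical
    limit ``t_max`` and is zero beyond it.
    """
    r_max: float
    t_opt: float
    t_max: float
    sigma_rise: float

    def __post_init__(self) -> None:
        if not self.t_opt < self.t_max:
            raise ValueError("need t_opt < t_max")
        if self.r_max <= 0 or self.sigma_rise <= 0:
            raise ValueError("r_max and sigma_rise must be > 0")


def tpc_value(shape: TPCShape, temp: float | np.ndarray) -> np.ndarray:
    """Evaluate the curve; continuous at the optimum, zero at/beyond t_max."""
    t = np.asarray(temp, float)
    rise = shape.r_max * np.exp(
        -((t - shape.t_opt) / (2.0 * shape.sigma_rise)) ** 2)
    frac = (t - shape.t_opt) / (shape.t_opt - shape.t_max)
    fall = shape.r_max * np.clip(1.0 - frac ** 2, 0.0, None)
    out = np.where(t <= shape.t_opt, rise,
                   np.where(t < shape.t_max, fall, 0.0))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SimScenario:
    """Generative settings for one synthetic meta-analytic data set.

    Defaults describe a moderate experimental-evolution landscape: 8
    species, 2 studies each, 2 TPC measurements per study, five assay
    temperatures bracketing an ancestral optimum of 25 degC, selection 3
    degC above the ancestral regime, 6 replicate assays per mean, and a
    measurement noise of 0.05 on a maximal fitness of about 1.
    """
    scenario: str = "shift"
    n_species: int = 8
    n_studies_per_species: int = 2
    n_tpcs_per_study: int = 2
    assay_temps: tuple[float, ...] = (19.0, 22.0, 25.0, 28.0, 31.0)
    selection_shift: float = 3.0
    height_gain: float = 0.10
    width_change: float = 0.20
    noise_sd: float = 0.05
    replicate_count: int = 6
    reproduction_mode_mix: Mapping[str, float] = field(
        default_factory=lambda: {"discrete": 0.5, "fission": 0.3,
                                 "continuous": 0.2})
    generation_time: float = 2.0
    missing_generations_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if list(self.assay_temps) != sorted(set(self.assay_temps)):
            raise ValueError("assay_temps must be strictly increasing")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.height_gain <= -1 or self.width_change <= -1:
            raise ValueError("fractional changes must be > -1")


def _derived_shape(anc: TPCShape, scn: SimScenario) -> TPCShape:
    s = scn.selection_shift
    if scn.scenario == "null":
        return anc
    if scn.scenario == "shift":
        return replace(anc, t_opt=anc.t_opt + s, t_max=anc.t_max + s)
    if scn.scenario == "hotter_is_better":
        return replace(anc, t_opt=anc.t_opt + s, t_max=anc.t_max + s,
                       r_max=anc.r_max * (1.0 + scn.height_gain))
    if scn.scenario == "generalist_specialist":
        # widen both flanks; height pays for width (area-preserving trade-off)
        w = 1.0 + scn.width_change
        return replace(anc, sigma_rise=anc.sigma_rise * w,
                       t_max=anc.t_opt + (anc.t_max - anc.t_opt) * w,
                       r_max=anc.r_max / w)
    if scn.scenario == "hotter_is_wider":
        w = 1.0 + scn.width_change
        return replace(anc, t_opt=anc.t_opt + s,
                       sigma_rise=anc.sigma_rise * w,
                       t_max=anc.t_max + s + (anc.t_max - anc.t_opt) * (w - 1))
    raise AssertionError(scn.scenario)


def simulate_experiment(scn: SimScenario) -> list[AssayRecord]:
    """Draw a full synthetic assay table, deterministic given ``scn.seed``.

    Species and studies perturb the ancestral curve (optimum, height);
    variation source alternates at the species level (mirroring the
    real-data confound where the moderators Var, Rep and Comp are strongly
    associated with one another); replicate measurements give each mean a
    simulated SE. Fitness means are truncated just above zero so that
    ratio-mode effect sizes stay defined.
    """
    rng = np.random.default_rng(scn.seed)
    modes = list(scn.reproduction_mode_mix)
    mode_p = np.array([scn.reproduction_mode_mix[m] for m in modes], float)
    mode_p = mode_p / mode_p.sum()
    records: list[AssayRecord] = []
    control_temp = float(np.median(scn.assay_temps))
    selection_temp = control_temp + scn.selection_shift
    for isp in range(scn.n_species):
        sp = f"sp{isp:02d}"
        de_novo = isp % 2 == 0
        sp_topt = control_temp + rng.normal(0.0, 1.0)
        sp_logr = rng.normal(0.0, 0.15)
        mode = str(rng.choice(modes, p=mode_p))
        for ist in range(scn.n_studies_per_species):
            st = f"{sp}_study{ist}"
            st_topt = sp_topt + rng.normal(0.0, 0.5)
            st_logr = sp_logr + rng.normal(0.0, 0.10)
            generations = float(np.round(rng.lognormal(
                5.5 if de_novo else 3.5, 0.5)))
            gen_missing = rng.random() < scn.missing_generations_frac
            disp_type = str(rng.choice(["se", "sd", "ci95_halfwidth"],
                                       p=[0.6, 0.3, 0.1]))
            for itpc in range(scn.n_tpcs_per_study):
                tpc = f"{st}_tpc{itpc}"
                anc = TPCShape(
                    r_max=float(np.exp(st_logr + rng.normal(0.0, 0.05))),
                    t_opt=float(st_topt + rng.normal(0.0, 0.3)),
                    t_max=float(st_topt + 8.0 + rng.normal(0.0, 0.3)),
                    sigma_rise=5.0)
                der = _derived_shape(anc, scn)
                for temp in scn.assay_temps:
                    rec = _assay_point(rng, scn, tpc, st, sp, mode, de_novo,
                                       generations if not gen_missing else
                                       None, selection_temp, control_temp,
                                       float(temp), anc, der, disp_type)
                    records.append(rec)
    return records


def _assay_point(rng, scn: SimScenario, tpc: str, study: str, species: str,
                 mode: str, de_novo: bool, generations: float | None,
                 selection_temp: float, control_temp: float, temp: float,
                 anc: TPCShape, der: TPCShape,
                 disp_type: str) -> AssayRecord:
    mu_anc = tpc_value(anc, temp)
    mu_sel = tpc_value(der, temp)
    reps_sel = rng.normal(mu_sel, scn.noise_sd, scn.replicate_count)
    reps_anc = rng.normal(mu_anc, scn.noise_sd, scn.replicate_count)
    n = scn.replicate_count
    floor = 1e-3  # ratio modes need positive means
    f_sel = max(float(reps_sel.mean()), floor)
    f_anc = max(float(reps_anc.mean()), floor)
    sd_sel = float(reps_sel.std(ddof=1))
    sd_anc = float(reps_anc.std(ddof=1))
    if disp_type == "se":
        d_sel, d_anc = sd_sel / math.sqrt(n), sd_anc / math.sqrt(n)
    elif disp_type == "sd":
        d_sel, d_anc = sd_sel, sd_anc
    else:  # ci95_halfwidth of the mean
        d_sel = 1.96 * sd_sel / math.sqrt(n)
        d_anc = 1.96 * sd_anc / math.sqrt(n)
    return AssayRecord(
        study_id=study, species_id=species, tpc_id=tpc,
        reproduction_mode=mode,
        variation_source="de_novo" if de_novo else "standing",
        comparison="ancestor" if de_novo else "control",
        sexual=not de_novo,
        generations=generations,
        generation_time=scn.generation_time if mode == "continuous" else None,
        selection_temp=selection_temp, control_temp=control_temp,
        assay_temp=temp,
        f_sel_mean=f_sel, f_anc_mean=f_anc,
        disp_sel=d_sel, disp_anc=d_anc, disp_type=disp_type,
        n_replicates=n if disp_type == "sd" else None)


def simulate_effects_direct(
        mu: float = 0.18,
        poly_beta: tuple[float, ...] = (),
        sigma_species: float = 0.22,
        sigma_study: float = 0.17,
        sigma_tpc: float = 0.0,
        n_effects: int = 200,
        n_species: int = 10,
        n_studies_per_species: int = 4,
        se_range: tuple[float, float] = (0.02, 0.2),
        dt_range: tuple[float, float] | None = None,
        seed: int = 0) -> tuple[list[EffectRecord], dict]:
    """Draw effects straight from the measurement-error model, truth attached.

    ``poly_beta`` gives coefficients on (dT, dT^2, dT^3, ...) added to the
    grand mean ``mu``; dT is Uniform over ``dt_range`` (all zero when None).
    Effects are spread evenly over species and studies; each effect is its
    own TPC when ``sigma_tpc > 0``. Returns the effects and a truth dict
    with every generative parameter.
    """
    rng = np.random.default_rng(seed)
    n_studies = n_species * n_studies_per_species
    u_sp = rng.normal(0.0, sigma_species, n_species)
    u_st = rng.normal(0.0, sigma_study, n_studies)
    effects: list[EffectRecord] = []
    for i in range(n_effects):
        isp = i % n_species
        ist = i % n_studies
        dt = float(rng.uniform(*dt_range)) if dt_range else 0.0
        mean = mu + sum(b * dt ** (k + 1) for k, b in enumerate(poly_beta))
        theta = mean + u_sp[isp] + u_st[ist]
        if sigma_tpc > 0:
            theta += rng.normal(0.0, sigma_tpc)
        s = float(rng.uniform(*se_range))
        y = float(rng.normal(theta, s))
        effects.append(EffectRecord(
            effect_id=f"e{i:04d}",
            study_id=f"study{ist:03d}",
            species_id=f"sp{isp:02d}",
            tpc_id=f"tpc{i:04d}" if sigma_tpc > 0 else f"tpc{ist:03d}",
            rel_fitness=y, rel_fitness_se=s,
            rel_assay_temp=dt, sign="higher",
            variation_source="de_novo" if isp % 2 == 0 else "standing",
            generations=100.0, n_assay_temps_in_tpc=1, mode_used="discrete"))
    truth = {"mu": mu, "poly_beta": poly_beta,
             "sigma_species": sigma_species, "sigma_study": sigma_study,
             "sigma_tpc": sigma_tpc, "seed": seed}
    return effects, truth
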