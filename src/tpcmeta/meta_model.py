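"""Bayesian multilevel measurement-error meta-analysis.

Model
-----
Each observed relative fitness ``y_i`` is a noisy measurement, with known
sampling SE ``s_i``, of a latent true effect::

    y_i      ~ Normal(theta_i, s_i^2)
    theta_i  = x_i' beta + u_species(i) + u_study(i) + u_tpc(i)
    u_level  ~ Normal(0, sigma_level^2)

so effects are weighted by study precision and heterogeneity is decomposed
across the biological hierarchy (species > study > TPC). There is no
residual level beyond the finest grouping: within-TPC scatter is absorbed by
``sigma_tpc`` (or ``sigma_study`` when the analysis has no TPC level).

Priors are vaguely informative on the effect-size scale: Normal(0, 1) on
the intercept and coefficients of centered predictors, Exponential(1) on
level SDs; both are configurable via :class:`PriorSpec`.

Posterior sampling is by a blocked Gibbs sampler: the coefficient vector and
every random-effect block are conjugate normal updates given the rest, and
each level SD is updated by univariate slice sampling under its Exponential
prior. Convergence is monitored with split-R-hat (arviz) across chains.

Model comparison uses WAIC computed from the pointwise log-likelihood of
``y_i`` conditional on the sampled coefficients and random effects (latent
``theta_i`` integrated analytically, which here reduces the per-point
variance to ``s_i^2``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import arviz as az
from scipy.special import logsumexp

from .data_model import AssayRecord, EffectRecord
from .effect_size import compute_effect

LOG_2PI = math.log(2.0 * math.pi)

#: term vocabulary -> human-readable meaning (single source of truth)
BASE_TERMS = ("var", "gen", "sign", "dt", "dt2", "dt3", "abs_dt", "se")

RHAT_LIMIT = 1.05


class DesignError(ValueError):
    """A model specification cannot be realized on the given effects."""


@dataclass(frozen=True)
class PriorSpec:
    """Prior settings: Normal(0, beta_sd^2) coefficients, Exponential(sd_rate)
    level SDs."""
    beta_sd: float = 1.0
    sd_rate: float = 1.0


@dataclass(frozen=True)
class McmcSettings:
    iterations: int = 30_000
    warmup: int = 1_000
    chains: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be < iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect terms, random-effect levels and sampler settings.

    ``fixed_terms`` draws from: ``var`` (de-novo vs standing genetic
    variation), ``gen`` (number of generations, standardized), ``sign``
    (selection at higher/lower/equal temperature than the control regime),
    ``dt``/``dt2``/``dt3`` (raw powers of relative assay temperature,
    centered at the selection temperature), ``abs_dt`` (absolute relative
    assay temperature, for two-point reaction norms), ``se`` (the sampling
    SE itself, for the Egger-style bias model), plus ``a:b`` products of
    any two of these. The intercept is always present.
    """
    name: str
    fixed_terms: tuple[str, ...] = ()
    random_levels: tuple[str, ...] = ("species", "study")
    priors: PriorSpec = PriorSpec()
    mcmc: McmcSettings = McmcSettings()

    def __post_init__(self) -> None:
        if not self.random_levels:
            raise ValueError("random_levels must be nonempty")
        for t in self.fixed_terms:
            parts = t.split(":")
            if len(parts) > 2 or any(p not in BASE_TERMS for p in parts):
                raise ValueError(f"unknown fixed term {t!r}")
        for lvl in self.random_levels:
            if lvl not in ("species", "study", "tpc"):
                raise ValueError(f"unknown random level {lvl!r}")


@dataclass(frozen=True)
class Design:
    """Numeric design bundle: response, sampling SEs, fixed-effect matrix and
    random-level index maps."""
    y: np.ndarray
    s: np.ndarray
    X: np.ndarray
    colnames: tuple[str, ...]
    level_codes: Mapping[str, np.ndarray]
    level_labels: Mapping[str, tuple[str, ...]]
    centering: Mapping[str, float]
    subset_label: str = ""

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class PosteriorDraws:
    """Post-warmup draws from all chains, concatenated chain-major."""
    beta: np.ndarray                  # (draws, p)
    sigma2: np.ndarray                # (draws, n_levels)
    u: dict[str, np.ndarray]          # level -> (draws, n_groups)
    colnames: tuple[str, ...]
    level_names: tuple[str, ...]
    chains: int
    iterations: int
    warmup: int
    rhat: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    @property
    def converged(self) -> bool:
        r = self.max_rhat
        return bool(np.isfinite(r) and r <= RHAT_LIMIT)

    def sigma2_of(self, level: str) -> np.ndarray:
        return self.sigma2[:, self.level_names.index(level)]


@dataclass(frozen=True)
class ModelFitSummary:
    name: str
    params: pd.DataFrame        # parameter, median, q2.5, q97.5
    waic: float
    lppd: float
    p_waic: float
    waic_se: float
    n_effects: int
    subset_label: str
    max_rhat: float
    converged: bool


# ---------------------------------------------------------------------------
# Design construction


def _term_context(effects: Sequence[EffectRecord],
                  se: np.ndarray | None = None) -> dict[str, np.ndarray]:
    dt = np.array([e.rel_assay_temp for e in effects], float)
    ctx = {
        "dt": dt,
        "var": np.array([1.0 if e.variation_source == "de_novo" else 0.0
                         for e in effects]),
        "sign_higher": np.array([1.0 if e.sign == "higher" else 0.0
                                 for e in effects]),
        "sign_lower": np.array([1.0 if e.sign == "lower" else 0.0
                                for e in effects]),
    }
    gens = [e.generations for e in effects]
    ctx["gen_raw"] = np.array([np.nan if g is None else g for g in gens])
    if se is not None:
        ctx["se_raw"] = se
    return ctx


def _columns_for(term: str, ctx: dict, centering: dict
                 ) -> tuple[list[np.ndarray], list[str]]:
    if term == "var":
        return [ctx["var"]], ["var[de_novo]"]
    if term == "sign":
        return ([ctx["sign_higher"], ctx["sign_lower"]],
                ["sign[higher]", "sign[lower]"])
    if term == "gen":
        g = (ctx["gen_raw"] - centering["gen_mean"]) / centering["gen_sd"]
        return [g], ["gen(std)"]
    if term == "dt":
        return [ctx["dt"]], ["dT"]
    if term == "dt2":
        return [ctx["dt"] ** 2], ["dT^2"]
    if term == "dt3":
        return [ctx["dt"] ** 3], ["dT^3"]
    if term == "abs_dt":
        return [np.abs(ctx["dt"])], ["|dT|"]
    if term == "se":
        return [ctx["se_raw"] - centering["se_mean"]], ["se(centered)"]
    if ":" in term:
        a, b = term.split(":")
        ca, na = _columns_for(a, ctx, centering)
        cb, nb = _columns_for(b, ctx, centering)
        return [ca[0] * cb[0]], [f"{na[0]}:{nb[0]}"]
    raise DesignError(f"unknown term {term!r}")


def build_design(effects: Sequence[EffectRecord], spec: ModelSpec,
                 subset_label: str = "") -> Design:
    """Assemble the numeric design: y, s, indicator-coded moderators, raw
    centered polynomial terms and per-level group indices.

    Requesting the ``gen`` moderator on effects with missing generation
    counts is an error: fit that model on the reduced data set instead
    (every analysis is run twice, with and without ``gen``).
    """
    if not effects:
        raise DesignError("no effects in subset")
    y = np.array([e.rel_fitness for e in effects], float)
    s = np.array([np.nan if e.rel_fitness_se is None else e.rel_fitness_se
                  for e in effects], float)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise DesignError("all effects need a finite positive SE; "
                          "run apply_exclusions first")

    ctx = _term_context(effects, se=s)
    centering: dict[str, float] = {}
    needs_gen = any("gen" in t.split(":") for t in spec.fixed_terms)
    if needs_gen:
        if np.any(np.isnan(ctx["gen_raw"])):
            raise DesignError(
                "moderator 'gen' requested but some effects lack a "
                "generations count; use the reduced data set "
                "(effects with generations reported)")
        centering["gen_mean"] = float(ctx["gen_raw"].mean())
        sd = float(ctx["gen_raw"].std())
        centering["gen_sd"] = sd if sd > 0 else 1.0
    if any("se" in t.split(":") for t in spec.fixed_terms):
        centering["se_mean"] = float(s.mean())

    cols = [np.ones(len(effects))]
    names = ["intercept"]
    for t in spec.fixed_terms:
        cs, ns = _columns_for(t, ctx, centering)
        cols.extend(cs)
        names.extend(ns)
    X = np.column_stack(cols)

    level_fields = {"species": "species_id", "study": "study_id",
                    "tpc": "tpc_id"}
    level_codes: dict[str, np.ndarray] = {}
    level_labels: dict[str, tuple[str, ...]] = {}
    for lvl in spec.random_levels:
        vals = [getattr(e, level_fields[lvl]) for e in effects]
        labels = tuple(sorted(set(vals)))
        idx = {lab: i for i, lab in enumerate(labels)}
        level_codes[lvl] = np.array([idx[v] for v in vals], dtype=np.intp)
        level_labels[lvl] = labels
    return Design(y=y, s=s, X=X, colnames=tuple(names),
                  level_codes=level_codes, level_labels=level_labels,
                  centering=centering, subset_label=subset_label)


# ---------------------------------------------------------------------------
# Gibbs sampler


def _slice_sample_positive(logf: Callable[[float], float], x0: float,
                           rng: np.random.Generator, width: float = 0.5,
                           max_steps: int = 64) -> float:
    """One slice-sampling update for a scalar with support (0, inf)."""
    logy = logf(x0) - rng.exponential()
    left = x0 - rng.uniform(0.0, width)
    right = left + width
    steps = max_steps
    while left > 1e-12 and steps > 0 and logf(left) > logy:
        left -= width
        steps -= 1
    left = max(left, 1e-12)
    steps = max_steps
    while steps > 0 and logf(right) > logy:
        right += width
        steps -= 1
    while True:
        x1 = rng.uniform(left, right)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def fit(design: Design, spec: ModelSpec,
        seed: int | None = None) -> PosteriorDraws:
    """Sample the posterior of the measurement-error mixed model.

    Reproducible given ``seed`` (overrides ``spec.mcmc.seed`` when given).
    Non-convergence (split-R-hat > 1.05 on any coefficient or level SD) is
    recorded in ``PosteriorDraws.rhat``; summaries flag it, sampling never
    fails silently.
    """
    mc = spec.mcmc
    if seed is None:
        seed = mc.seed if mc.seed is not None else 0
    n, p = design.X.shape
    levels = tuple(spec.random_levels)
    n_groups = {lvl: len(design.level_labels[lvl]) for lvl in levels}
    w = 1.0 / design.s ** 2
    X, y = design.X, design.y
    Xw = X * w[:, None]
    prior_prec = np.eye(p) / spec.priors.beta_sd ** 2
    XtWX = X.T @ Xw
    kept = mc.iterations - mc.warmup

    beta_out = np.empty((mc.chains * kept, p))
    sig2_out = np.empty((mc.chains * kept, len(levels)))
    u_out = {lvl: np.empty((mc.chains * kept, n_groups[lvl]))
             for lvl in levels}

    root = np.random.SeedSequence(seed)
    for c, child in enumerate(root.spawn(mc.chains)):
        rng = np.random.default_rng(child)
        # initialize at the (ridge-regularized) WLS solution, jittered per chain
        beta = np.linalg.solve(XtWX + prior_prec, Xw.T @ y)
        beta = beta + 0.05 * rng.standard_normal(p)
        sigma = {lvl: 0.1 * (1.0 + 0.5 * rng.random()) for lvl in levels}
        u = {lvl: np.zeros(n_groups[lvl]) for lvl in levels}
        off = c * kept
        for it in range(mc.iterations):
            u_total = np.zeros(n)
            for lvl in levels:
                u_total += u[lvl][design.level_codes[lvl]]
            # beta | rest  (conjugate normal)
            A = XtWX + prior_prec
            b = Xw.T @ (y - u_total)
            chol = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(chol.T, z)
            fixed = X @ beta
            # u_level | rest  (conjugate normal per group)
            for lvl in levels:
                codes = design.level_codes[lvl]
                others = u_total - u[lvl][codes]
                resid = y - fixed - others
                prec_g = np.bincount(codes, weights=w,
                                     minlength=n_groups[lvl])
                prec_g = prec_g + 1.0 / sigma[lvl] ** 2
                mean_g = np.bincount(codes, weights=w * resid,
                                     minlength=n_groups[lvl]) / prec_g
                u[lvl] = mean_g + rng.standard_normal(
                    n_groups[lvl]) / np.sqrt(prec_g)
                u_total = others + u[lvl][codes]
            # translation move: shift mass between the intercept and each
            # level's effects (u_g -> u_g - delta, b0 -> b0 + delta); the
            # likelihood is invariant, so delta's conditional is Gaussian
            # from the priors alone -- breaks the intercept/level-mean
            # correlation that otherwise stalls mixing
            for lvl in levels:
                m = n_groups[lvl]
                prec_d = m / sigma[lvl] ** 2 + 1.0 / spec.priors.beta_sd ** 2
                mean_d = (u[lvl].sum() / sigma[lvl] ** 2
                          - beta[0] / spec.priors.beta_sd ** 2) / prec_d
                delta = mean_d + rng.standard_normal() / math.sqrt(prec_d)
                u[lvl] = u[lvl] - delta
                beta[0] += delta
            fixed = X @ beta
            u_total = np.zeros(n)
            for lvl in levels:
                u_total += u[lvl][design.level_codes[lvl]]
            # sigma_level | u  (slice sampling, Exponential(rate) prior on SD)
            for lvl in levels:
                ss = float(u[lvl] @ u[lvl])
                m = n_groups[lvl]
                rate = spec.priors.sd_rate

                def logf(sig: float, ss=ss, m=m, rate=rate) -> float:
                    return -m * math.log(sig) - ss / (2.0 * sig * sig) \
                        - rate * sig

                sigma[lvl] = _slice_sample_positive(logf, sigma[lvl], rng)
            if it >= mc.warmup:
                j = off + it - mc.warmup
                beta_out[j] = beta
                for li, lvl in enumerate(levels):
                    sig2_out[j, li] = sigma[lvl] ** 2
                    u_out[lvl][j] = u[lvl]

    draws = PosteriorDraws(
        beta=beta_out, sigma2=sig2_out, u=u_out,
        colnames=design.colnames, level_names=levels,
        chains=mc.chains, iterations=mc.iterations, warmup=mc.warmup)
    draws.rhat = _compute_rhat(draws)
    return draws


def _compute_rhat(draws: PosteriorDraws) -> dict[str, float]:
    kept = draws.iterations - draws.warmup
    out: dict[str, float] = {}

    def rhat_of(x: np.ndarray) -> float:
        arr = x.reshape(draws.chains, kept)
        return float(az.rhat(arr))

    for j, name in enumerate(draws.colnames):
        out[f"beta[{name}]"] = rhat_of(draws.beta[:, j])
    for li, lvl in enumerate(draws.level_names):
        out[f"sigma[{lvl}]"] = rhat_of(np.sqrt(draws.sigma2[:, li]))
    return out


# ---------------------------------------------------------------------------
# WAIC


def pointwise_loglik(draws: PosteriorDraws, design: Design) -> np.ndarray:
    """Pointwise log-likelihood matrix (draws x effects).

    Entry (d, i) is the log normal density of ``y_i`` given draw d, with the
    latent true effect integrated analytically: conditioning on every
    sampled random-effect level present in the design, the predictive
    variance is ``s_i^2`` plus the variance of any level the design does not
    index (marginalized).
    """
    mu = draws.beta @ design.X.T  # (D, n)
    var = np.broadcast_to(design.s ** 2, mu.shape).copy()
    for li, lvl in enumerate(draws.level_names):
        if lvl in design.level_codes:
            mu = mu + draws.u[lvl][:, design.level_codes[lvl]]
        else:
            var = var + draws.sigma2[:, li][:, None]
    ll = -0.5 * (LOG_2PI + np.log(var) + (design.y - mu) ** 2 / var)
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError("non-finite pointwise log-likelihood")
    return ll


def waic(pointwise: np.ndarray) -> dict[str, float]:
    """WAIC on the deviance scale from a (draws x effects) log-likelihood
    matrix; the per-point log predictive density uses log-sum-exp."""
    d = pointwise.shape[0]
    lppd_i = logsumexp(pointwise, axis=0) - math.log(d)
    p_i = pointwise.var(axis=0, ddof=1) if d > 1 else np.zeros(
        pointwise.shape[1])
    elpd_i = lppd_i - p_i
    n = elpd_i.size
    se = float(np.sqrt(n) * np.std(-2.0 * elpd_i, ddof=1)) if n > 1 else 0.0
    return {
        "waic": float(-2.0 * elpd_i.sum()),
        "lppd": float(lppd_i.sum()),
        "p_waic": float(p_i.sum()),
        "se": se,
    }


def summarize(draws: PosteriorDraws, design: Design,
              name: str = "model") -> ModelFitSummary:
    """Posterior medians and 95% compatibility intervals plus WAIC."""
    rows = []
    for j, col in enumerate(draws.colnames):
        q = np.quantile(draws.beta[:, j], [0.5, 0.025, 0.975])
        rows.append((f"beta[{col}]", q[0], q[1], q[2]))
    for li, lvl in enumerate(draws.level_names):
        q = np.quantile(draws.sigma2[:, li], [0.5, 0.025, 0.975])
        rows.append((f"sigma2[{lvl}]", q[0], q[1], q[2]))
    params = pd.DataFrame(rows, columns=["parameter", "median", "q2.5",
                                         "q97.5"])
    w = waic(pointwise_loglik(draws, design))
    return ModelFitSummary(
        name=name, params=params, waic=w["waic"], lppd=w["lppd"],
        p_waic=w["p_waic"], waic_se=w["se"], n_effects=design.n,
        subset_label=design.subset_label, max_rhat=draws.max_rhat,
        converged=draws.converged)


def rank_models(fits: Sequence[ModelFitSummary]) -> pd.DataFrame:
    """Rank fitted models by WAIC (ascending) with Akaike-style weights."""
    if not fits:
        raise ValueError("no fits to rank")
    subsets = {(f.subset_label, f.n_effects) for f in fits}
    if len(subsets) > 1:
        raise ValueError(f"fits span different effect subsets: {subsets}")
    df = pd.DataFrame({
        "model": [f.name for f in fits],
        "waic": [f.waic for f in fits],
        "waic_se": [f.waic_se for f in fits],
        "p_waic": [f.p_waic for f in fits],
        "converged": [f.converged for f in fits],
    }).sort_values("waic", kind="stable").reset_index(drop=True)
    df["delta_waic"] = df["waic"] - df["waic"].iloc[0]
    rel = np.exp(-0.5 * df["delta_waic"].to_numpy())
    df["weight"] = rel / rel.sum()
    return df


# ---------------------------------------------------------------------------
# Prediction


def predict_mu_draws(draws: PosteriorDraws, design: Design, spec: ModelSpec,
                     grid: np.ndarray,
                     moderators: Mapping[str, object] | None = None
                     ) -> np.ndarray:
    """Per-draw population-level mean ``mu`` on a dT grid, shape
    (grid points, draws); random effects at zero."""
    moderators = dict(moderators or {})
    grid = np.asarray(grid, float)
    g = grid.size
    ctx = {
        "dt": grid,
        "var": np.full(g, 1.0 if moderators.get(
            "variation_source", "standing") == "de_novo" else 0.0),
        "sign_higher": np.full(g, 1.0 if moderators.get(
            "sign", "equal") == "higher" else 0.0),
        "sign_lower": np.full(g, 1.0 if moderators.get(
            "sign", "equal") == "lower" else 0.0),
        "gen_raw": np.full(g, float(moderators.get("generations", np.nan))),
        "se_raw": np.full(g, design.centering.get("se_mean", np.nan)),
    }
    cols = [np.ones(g)]
    for t in spec.fixed_terms:
        cs, _ = _columns_for(t, ctx, dict(design.centering))
        cols.extend(cs)
    Xg = np.column_stack(cols)
    if Xg.shape[1] != draws.beta.shape[1]:
        raise DesignError("spec does not match the fitted design")
    return Xg @ draws.beta.T  # (g, D)


def predict_curve(draws: PosteriorDraws, design: Design, spec: ModelSpec,
                  grid: np.ndarray,
                  moderators: Mapping[str, object] | None = None
                  ) -> pd.DataFrame:
    """Population-level prediction of mean relative fitness over a dT grid.

    Random effects are set to zero; the interval is the per-grid-point 95%
    quantile band of the posterior of ``mu``. Moderator settings:
    ``variation_source`` ('de_novo'/'standing'), ``sign``
    ('higher'/'lower'/'equal'), ``generations`` (raw count). Grid points
    outside the fitted dT range are flagged as extrapolation.
    """
    grid = np.asarray(grid, float)
    mu = predict_mu_draws(draws, design, spec, grid, moderators)
    q = np.quantile(mu, [0.5, 0.025, 0.975], axis=1)
    # observed dT range: recover from the design's dT column if present
    dt_obs = _observed_dt(design)
    extrap = (grid < dt_obs[0]) | (grid > dt_obs[1]) if dt_obs else \
        np.zeros(grid.size, bool)
    return pd.DataFrame({
        "dT": grid, "median": q[0], "q2.5": q[1], "q97.5": q[2],
        "extrapolated": extrap,
    })


def _observed_dt(design: Design) -> tuple[float, float] | None:
    for j, name in enumerate(design.colnames):
        if name == "dT":
            col = design.X[:, j]
            return float(col.min()), float(col.max())
        if name == "|dT|":
            col = design.X[:, j]
            return (0.0, float(col.max()))
    return None


# ---------------------------------------------------------------------------
# Hotter is better


def hotter_is_better_effects(records: Sequence[AssayRecord]
                             ) -> list[EffectRecord]:
    """Max-vs-max relative fitness per TPC, for TPCs assayed at more than
    three temperatures.

    For each TPC the maximal fitness of the selected line (over assay
    temperatures) is compared against the maximal fitness of the ancestor/
    control line, using the TPC's reproduction mode; the SE is propagated
    from the dispersions at the two argmax points. Ties in the maximum take
    the lowest temperature. Requires dispersions normalized to SE.
    """
    by_tpc: dict[str, list[AssayRecord]] = {}
    for r in records:
        by_tpc.setdefault(r.tpc_id, []).append(r)
    effects: list[EffectRecord] = []
    for tpc_id in sorted(by_tpc):
        rows = sorted(by_tpc[tpc_id], key=lambda r: r.assay_temp)
        temps = {round(r.assay_temp, 6) for r in rows}
        if len(temps) <= 3:
            continue
        if any(r.disp_type != "se" for r in rows):
            raise ValueError(f"tpc {tpc_id}: dispersion not normalized to SE")
        sel_row = max(rows, key=lambda r: (r.f_sel_mean, -r.assay_temp))
        anc_row = max(rows, key=lambda r: (r.f_anc_mean, -r.assay_temp))
        r0 = rows[0]
        res = compute_effect(sel_row.f_sel_mean, anc_row.f_anc_mean,
                             sel_row.disp_sel, anc_row.disp_anc,
                             r0.reproduction_mode, r0.generation_time)
        effects.append(EffectRecord(
            effect_id=f"{tpc_id}@max",
            study_id=r0.study_id, species_id=r0.species_id, tpc_id=tpc_id,
            rel_fitness=res.rel_fitness, rel_fitness_se=res.rel_fitness_se,
            rel_assay_temp=0.0,
            sign=_sign_of(r0), variation_source=r0.variation_source,
            generations=r0.generations, n_assay_temps_in_tpc=len(temps),
            mode_used=res.mode_used))
    return effects


def _sign_of(r: AssayRecord) -> str:
    from .effect_size import classify_sign
    return classify_sign(r.selection_temp, r.control_temp)
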