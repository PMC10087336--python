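"""Moderator collinearity screening and publication-bias assessment.

Categorical moderators of the meta-analysis (reproduction mode, source of
genetic variation, comparison type) tend to be strongly confounded across
experimental-evolution studies; before any model uses them jointly they are
screened with tetrachoric correlations (binary-binary) and point-biserial
correlations (binary-continuous). Publication bias is assessed with funnel
data (effect vs. SE) and an Egger-style multilevel regression: the main
measurement-error model refitted with the sampling SE as an additional
moderator; a slope interval covering zero indicates no consistent
small-study asymmetry.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.integrate import fixed_quad

from .data_model import EffectRecord
from . import meta_model


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    method: str                      # point_biserial | tetrachoric | pearson
    estimate: float
    boundary: bool = False           # tetrachoric hit +/-1 (zero cell)


@dataclass(frozen=True)
class FunnelReport:
    funnel: pd.DataFrame             # columns: effect, se
    slope_median: float
    slope_lo: float
    slope_hi: float
    verdict: str                     # 'no consistent bias' | 'bias indicated'
    unidentifiable: bool = False

    @property
    def covers_zero(self) -> bool:
        return self.slope_lo <= 0.0 <= self.slope_hi


def point_biserial(binary: Sequence[int], cont: Sequence[float]) -> float:
    """Point-biserial correlation between a 0/1 variable and a continuous one:
    (mean1 - mean0)/sd * sqrt(p(1-p)), population sd."""
    b = np.asarray(binary, int)
    x = np.asarray(cont, float)
    if b.size != x.size:
        raise ValueError("length mismatch")
    if not (np.any(b == 0) and np.any(b == 1)):
        raise ValueError("both groups must be nonempty")
    sd = x.std()  # population sd
    if sd == 0:
        raise ValueError("continuous variable has zero variance")
    p = b.mean()
    r = (x[b == 1].mean() - x[b == 0].mean()) / sd * math.sqrt(p * (1 - p))
    return float(np.clip(r, -1.0, 1.0))


def _phi2(h: float, k: float, rho: float, order: int = 120) -> float:
    """Bivariate standard normal CDF P(X <= h, Y <= k) by numerical
    integration of the conditional-normal form over x in (-inf, h]."""
    if rho >= 1.0:
        return stats.norm.cdf(min(h, k))
    if rho <= -1.0:
        return max(0.0, stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0)
    denom = math.sqrt(1.0 - rho * rho)

    def integrand(x):
        return stats.norm.pdf(x) * stats.norm.cdf((k - rho * x) / denom)

    lo = min(h - 12.0, -12.0)
    val, _ = fixed_quad(integrand, lo, h, n=order)
    return float(np.clip(val, 0.0, 1.0))


def tetrachoric(table: Sequence[Sequence[float]]) -> CorrelationResult:
    """Maximum-likelihood tetrachoric correlation from a 2x2 table.

    Models the two dichotomies as thresholded coordinates of a bivariate
    standard normal; thresholds come from the marginal proportions, and rho
    maximizes the multinomial cell-probability likelihood. A zero cell gives
    the signed boundary value +/-1, flagged, rather than a continuity
    correction.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a nonnegative 2x2 count matrix")
    n = t.sum()
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: correlation undefined")
    if np.any(t == 0):
        # perfect-association limit
        sign = 1.0 if (t[0, 0] + t[1, 1]) >= (t[0, 1] + t[1, 0]) else -1.0
        return CorrelationResult("", "tetrachoric", sign, boundary=True)
    p_x1 = t[1].sum() / n       # P(row variable = 1)
    p_y1 = t[:, 1].sum() / n    # P(col variable = 1)
    h = stats.norm.ppf(1.0 - p_x1)
    k = stats.norm.ppf(1.0 - p_y1)

    def negll(rho: float) -> float:
        # cell order [[00, 01], [10, 11]]
        p00 = _phi2(h, k, rho)
        p01 = (1.0 - p_x1) - p00
        p10 = (1.0 - p_y1) - p00
        p11 = 1.0 - p00 - p01 - p10
        probs = np.array([p00, p01, p10, p11])
        if np.any(probs <= 0):
            return np.inf
        return float(-(t.ravel() * np.log(probs)).sum())

    res = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    return CorrelationResult("", "tetrachoric", float(res.x))


def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[~np.isnan(x)])
    return vals.size <= 2 and np.all(np.isin(vals, (0.0, 1.0)))


@dataclass(frozen=True)
class ModeratorScreen:
    correlations: list[CorrelationResult]
    flagged: list[str]               # "A~B" pairs above threshold
    drop_recommendation: list[str]   # moderators to drop (one kept per cluster)


def screen_moderators(moderators: pd.DataFrame,
                      threshold: float = 0.7) -> ModeratorScreen:
    """Pairwise-correlate moderator columns and flag collinear pairs.

    Binary-binary pairs use the tetrachoric correlation, binary-continuous
    the point-biserial, continuous-continuous Pearson. Within each cluster
    of flagged pairs the first column (in table order) is recommended for
    retention and the rest for dropping.
    """
    cols = list(moderators.columns)
    if len(cols) < 2:
        raise ValueError("need at least two moderators")
    results: list[CorrelationResult] = []
    flagged: list[str] = []
    partner: dict[str, set[str]] = {c: set() for c in cols}
    for a, b in itertools.combinations(cols, 2):
        mask = moderators[a].notna() & moderators[b].notna()
        xa = moderators.loc[mask, a].astype(float).to_numpy()
        xb = moderators.loc[mask, b].astype(float).to_numpy()
        a_bin, b_bin = _is_binary(xa), _is_binary(xb)
        pair = f"{a}~{b}"
        if a_bin and b_bin:
            tab = np.zeros((2, 2))
            for va, vb in zip(xa.astype(int), xb.astype(int)):
                tab[va, vb] += 1
            r = tetrachoric(tab)
            results.append(CorrelationResult(pair, "tetrachoric",
                                             r.estimate, r.boundary))
        elif a_bin or b_bin:
            bin_x, cont_x = (xa, xb) if a_bin else (xb, xa)
            est = point_biserial(bin_x.astype(int), cont_x)
            results.append(CorrelationResult(pair, "point_biserial", est))
        else:
            est = float(np.corrcoef(xa, xb)[0, 1])
            results.append(CorrelationResult(pair, "pearson", est))
        if abs(results[-1].estimate) > threshold:
            flagged.append(pair)
            partner[a].add(b)
            partner[b].add(a)
    # union-find-lite clustering over flagged pairs
    drop: list[str] = []
    seen: set[str] = set()
    for c in cols:
        if c in seen or not partner[c]:
            continue
        cluster = {c}
        stack = [c]
        while stack:
            cur = stack.pop()
            for nxt in partner[cur]:
                if nxt not in cluster:
                    cluster.add(nxt)
                    stack.append(nxt)
        ordered = [x for x in cols if x in cluster]
        drop.extend(ordered[1:])
        seen |= cluster
    return ModeratorScreen(results, flagged, drop)


def correlations_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.pair, r.method, r.estimate, r.boundary) for r in results],
        columns=["pair", "method", "estimate", "boundary"])


def bias_test(effects: Sequence[EffectRecord],
              random_levels: tuple[str, ...] = ("species", "study"),
              mcmc: meta_model.McmcSettings | None = None,
              seed: int | None = None) -> FunnelReport:
    """Egger-style multilevel publication-bias test.

    Refits the measurement-error model with the (centered) sampling SE as a
    fixed moderator on top of the main model's random-effect structure. The
    verdict is 'no consistent bias' when the 95% interval of the SE slope
    covers zero. Degenerate SE spread (all equal) is flagged as
    unidentifiable rather than fitted.
    """
    se = np.array([e.rel_fitness_se for e in effects], float)
    y = np.array([e.rel_fitness for e in effects], float)
    funnel = pd.DataFrame({"effect": y, "se": se})
    if np.ptp(se) < 1e-12:
        return FunnelReport(funnel, math.nan, math.nan, math.nan,
                            "slope unidentifiable: no SE spread",
                            unidentifiable=True)
    mc = mcmc or meta_model.McmcSettings(iterations=4_000, warmup=1_000,
                                         chains=2)
    spec = meta_model.ModelSpec(name="egger", fixed_terms=("se",),
                                random_levels=random_levels, mcmc=mc)
    design = meta_model.build_design(effects, spec, subset_label="bias")
    draws = meta_model.fit(design, spec, seed=seed)
    j = design.colnames.index("se(centered)")
    q = np.quantile(draws.beta[:, j], [0.5, 0.025, 0.975])
    covers = q[1] <= 0.0 <= q[2]
    return FunnelReport(
        funnel, float(q[0]), float(q[1]), float(q[2]),
        "no consistent bias" if covers else "bias indicated")
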