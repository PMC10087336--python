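"""Posterior heterogeneity decomposition: level variances and multilevel I^2.

I^2 is the share of total variance attributable to true-effect heterogeneity
rather than sampling error, computed per random-effect level and in total.
Sampling error enters through a single "typical" within-effect sampling
variance (Higgins-Thompson, the metafor convention)::

    s~^2 = (k - 1) * sum(w_i) / ((sum w_i)^2 - sum(w_i^2)),   w_i = 1/se_i^2

and, per posterior draw,

    I2_level = sigma2_level / (sum_levels sigma2 + s~^2) * 100
    I2_total = sum_levels sigma2 / (sum_levels sigma2 + s~^2) * 100

so level I^2 values add exactly to the total within every draw. Working with
full posteriors of the sigma2 makes means and 95% compatibility intervals of
I^2 immediate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .meta_model import PosteriorDraws


@dataclass(frozen=True)
class LevelHeterogeneity:
    sigma2_median: float
    sigma2_lo: float
    sigma2_hi: float
    i2_mean: float
    i2_median: float
    i2_lo: float
    i2_hi: float


@dataclass(frozen=True)
class HeterogeneitySummary:
    """Per-level and total heterogeneity; the paper's convention is to report
    posterior means for I^2 and medians for effects, so both are carried."""
    levels: Mapping[str, LevelHeterogeneity]
    total: LevelHeterogeneity
    s2_typical: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, lv in list(self.levels.items()) + [("total", self.total)]:
            rows.append((name, lv.sigma2_median, lv.sigma2_lo, lv.sigma2_hi,
                         lv.i2_mean, lv.i2_median, lv.i2_lo, lv.i2_hi))
        return pd.DataFrame(rows, columns=[
            "level", "sigma2_median", "sigma2_lo", "sigma2_hi",
            "I2_mean", "I2_median", "I2_lo", "I2_hi"])


def typical_sampling_variance(se: Sequence[float]) -> float:
    """Higgins-Thompson typical sampling variance from per-effect SEs."""
    se = np.asarray(se, float)
    k = se.size
    if k < 2:
        raise ValueError("need at least two effects")
    if np.any(se <= 0):
        raise ValueError("all SEs must be > 0")
    w = 1.0 / se ** 2
    sw = w.sum()
    return float((k - 1) * sw / (sw ** 2 - (w ** 2).sum()))


def i2_posterior(draws: PosteriorDraws,
                 s2_typical: float) -> HeterogeneitySummary:
    """Per-draw multilevel I^2 and variance summaries over the posterior."""
    if not s2_typical > 0:
        raise ValueError("s2_typical must be > 0")
    sig2 = draws.sigma2  # (D, L)
    total_sig2 = sig2.sum(axis=1)
    denom = total_sig2 + s2_typical
    i2_levels = sig2 / denom[:, None] * 100.0
    i2_total = total_sig2 / denom * 100.0

    def summarize(s2: np.ndarray, i2: np.ndarray) -> LevelHeterogeneity:
        qs2 = np.quantile(s2, [0.5, 0.025, 0.975])
        qi2 = np.quantile(i2, [0.5, 0.025, 0.975])
        return LevelHeterogeneity(
            sigma2_median=float(qs2[0]), sigma2_lo=float(qs2[1]),
            sigma2_hi=float(qs2[2]),
            i2_mean=float(i2.mean()), i2_median=float(qi2[0]),
            i2_lo=float(qi2[1]), i2_hi=float(qi2[2]))

    levels = {lvl: summarize(sig2[:, li], i2_levels[:, li])
              for li, lvl in enumerate(draws.level_names)}
    return HeterogeneitySummary(
        levels=levels, total=summarize(total_sig2, i2_total),
        s2_typical=s2_typical)
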