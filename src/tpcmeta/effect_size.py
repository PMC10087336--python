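"""Relative fitness effect sizes and propagated standard errors.

Relative fitness of a thermally selected line against its ancestor or
control is a selection-coefficient-like quantity whose form depends on the
reproduction system:

* discrete, non-overlapping generations:  ``f_s/f_a - 1``
* continuous growth (rates):              ``(f_s - f_a) * G`` with generation
  time ``G`` putting different time scales on a per-generation scale
* binary fission:                         ``(f_s/f_a - 1) * ln 2``

Standard errors are propagated to first order assuming uncorrelated errors:
the ratio modes use the relative-error quadrature form
``|f_s/f_a| * sqrt((d f_s/f_s)^2 + (d f_a/f_a)^2)`` (times ``ln 2`` for
fission), the continuous mode the exact linear form
``sqrt(d f_s^2 + d f_a^2) * G``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .data_model import AssayRecord, EffectRecord, TEMP_TOL

LN2 = math.log(2.0)


class EffectSizeError(ValueError):
    """Inputs outside the domain of an effect-size formula."""


@dataclass(frozen=True)
class EffectSizeResult:
    rel_fitness: float
    rel_fitness_se: float | None
    mode_used: str


def relfit_discrete(f_sel: float, f_anc: float) -> float:
    """Relative fitness for discrete, non-overlapping generations."""
    _check_ratio_inputs(f_sel, f_anc)
    return f_sel / f_anc - 1.0


def relfit_continuous(f_sel: float, f_anc: float, generation_time: float) -> float:
    """Relative fitness for continuous growers; rates scaled by generation time."""
    if generation_time is None or not generation_time > 0:
        raise EffectSizeError(
            f"generation_time must be > 0, got {generation_time!r}")
    return (f_sel - f_anc) * generation_time


def relfit_fission(f_sel: float, f_anc: float) -> float:
    """Relative fitness for binary fission (discrete form scaled by ln 2)."""
    _check_ratio_inputs(f_sel, f_anc)
    return (f_sel / f_anc - 1.0) * LN2


def _check_ratio_inputs(f_sel: float, f_anc: float) -> None:
    if f_anc == 0:
        raise EffectSizeError("f_anc must be nonzero in ratio modes")
    # Negative fitness correlates (counts, rates of increase, fecundities)
    # make the ratio uninterpretable as a selection coefficient.
    if f_sel < 0 or f_anc < 0:
        raise EffectSizeError("negative fitness mean in a ratio mode")


def propagate_se(f_sel: float, f_anc: float, se_sel: float, se_anc: float,
                 mode: str, generation_time: float | None = None) -> float:
    """First-order propagated SE of relative fitness, uncorrelated errors."""
    if se_sel < 0 or se_anc < 0:
        raise EffectSizeError("standard errors must be >= 0")
    if mode == "continuous":
        if generation_time is None or not generation_time > 0:
            raise EffectSizeError("continuous mode needs generation_time > 0")
        return math.hypot(se_sel, se_anc) * generation_time
    if mode in ("discrete", "fission"):
        if f_sel == 0 or f_anc == 0:
            raise EffectSizeError(
                "relative-error propagation undefined at zero fitness mean")
        base = abs(f_sel / f_anc) * math.hypot(se_sel / f_sel, se_anc / f_anc)
        return base * LN2 if mode == "fission" else base
    raise EffectSizeError(f"unknown mode {mode!r}")


def compute_effect(f_sel: float, f_anc: float, se_sel: float | None,
                   se_anc: float | None, mode: str,
                   generation_time: float | None = None) -> EffectSizeResult:
    """Relative fitness plus propagated SE for one assay; SE stays missing
    when either input dispersion is missing."""
    if mode == "discrete":
        rf = relfit_discrete(f_sel, f_anc)
    elif mode == "continuous":
        rf = relfit_continuous(f_sel, f_anc, generation_time)
    elif mode == "fission":
        rf = relfit_fission(f_sel, f_anc)
    else:
        raise EffectSizeError(f"unknown reproduction mode {mode!r}")
    if se_sel is None or se_anc is None:
        se: float | None = None
    else:
        se = propagate_se(f_sel, f_anc, se_sel, se_anc, mode, generation_time)
    return EffectSizeResult(rf, se, mode)


def classify_sign(selection_temp: float, control_temp: float,
                  temp_tol: float = TEMP_TOL) -> str:
    """Was selection at a higher, lower or equal temperature than the
    ancestral/control regime?"""
    d = selection_temp - control_temp
    if abs(d) <= temp_tol:
        return "equal"
    return "higher" if d > 0 else "lower"


def compute_effects(records: Sequence[AssayRecord]) -> list[EffectRecord]:
    """One :class:`EffectRecord` per assay row, mode dispatched per row.

    Requires dispersions already normalized to standard errors
    (:func:`tpcmeta.data_model.normalize_dispersion`). Errors carry the
    offending row's TPC and assay temperature.
    """
    n_temps: dict[str, int] = {}
    for r in records:
        key = r.tpc_id
        n_temps.setdefault(key, 0)
    temps_by_tpc: dict[str, set] = {}
    for r in records:
        temps_by_tpc.setdefault(r.tpc_id, set()).add(round(r.assay_temp, 6))

    effects: list[EffectRecord] = []
    for i, r in enumerate(records):
        if r.disp_type != "se":
            raise EffectSizeError(
                f"row {i} (tpc {r.tpc_id}): dispersion not normalized to SE")
        try:
            res = compute_effect(r.f_sel_mean, r.f_anc_mean, r.disp_sel,
                                 r.disp_anc, r.reproduction_mode,
                                 r.generation_time)
        except EffectSizeError as exc:
            raise EffectSizeError(
                f"row {i} (tpc {r.tpc_id}, assay {r.assay_temp} degC): {exc}"
            ) from exc
        effects.append(EffectRecord(
            effect_id=f"{r.tpc_id}@{r.assay_temp:g}",
            study_id=r.study_id,
            species_id=r.species_id,
            tpc_id=r.tpc_id,
            rel_fitness=res.rel_fitness,
            rel_fitness_se=res.rel_fitness_se,
            rel_assay_temp=r.assay_temp - r.selection_temp,
            sign=classify_sign(r.selection_temp, r.control_temp),
            variation_source=r.variation_source,
            generations=r.generations,
            n_assay_temps_in_tpc=len(temps_by_tpc[r.tpc_id]),
            mode_used=res.mode_used,
        ))
    return effects
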