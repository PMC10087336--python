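"""Dataset schema and flat-table handling for TPC selection-experiment meta-analysis.

The analysis unit is one fitness assay: a selected (derived) line and its
ancestor/control line measured at one assay temperature, extracted from one
thermal-selection experiment. Rows nest as species > study > TPC > assay
point. This module defines the two record types (:class:`AssayRecord` before
effect-size computation, :class:`EffectRecord` after), reads and writes the
flat CSV schema (``tpcmeta-v1``), converts reported dispersion measures to
standard errors, applies the cleaning rules of the meta-analysis, and splits
the cleaned effects into the four analysis subsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SCHEMA_TAG = "tpcmeta-v1"

#: |assay - selection| below which an assay counts as "at the selection
#: temperature"; digitized temperatures can carry rounding error.
TEMP_TOL = 0.25

REPRODUCTION_MODES = ("discrete", "continuous", "fission")
VARIATION_SOURCES = ("de_novo", "standing")
COMPARISONS = ("ancestor", "control")
DISP_TYPES = ("se", "sd", "ci95_halfwidth")
SIGNS = ("higher", "lower", "equal")

ASSAY_COLUMNS = [
    "study_id", "species_id", "tpc_id",
    "reproduction_mode", "variation_source", "comparison", "sexual",
    "generations", "generation_time",
    "selection_temp", "control_temp", "assay_temp",
    "f_sel_mean", "f_anc_mean",
    "disp_sel", "disp_anc", "disp_type", "n_replicates",
]

EFFECT_COLUMNS = [
    "effect_id", "study_id", "species_id", "tpc_id",
    "rel_fitness", "rel_fitness_se", "rel_assay_temp", "sign",
    "variation_source", "generations", "n_assay_temps_in_tpc", "mode_used",
]


class SchemaError(ValueError):
    """A table or row violates the tpcmeta-v1 schema."""


@dataclass(frozen=True)
class AssayRecord:
    """One extracted fitness measurement pair (selected vs. ancestor/control).

    ``generations`` may be missing (``None``): not every study reports how
    long selection lasted. ``generation_time`` is required for continuous
    growers (rate-based fitness), ``n_replicates`` whenever dispersion is
    reported as a standard deviation.
    """

    study_id: str
    species_id: str
    tpc_id: str
    reproduction_mode: str
    variation_source: str
    comparison: str
    sexual: bool
    generations: float | None
    generation_time: float | None
    selection_temp: float
    control_temp: float
    assay_temp: float
    f_sel_mean: float
    f_anc_mean: float
    disp_sel: float | None
    disp_anc: float | None
    disp_type: str
    n_replicates: int | None

    def __post_init__(self) -> None:
        if self.reproduction_mode not in REPRODUCTION_MODES:
            raise SchemaError(
                f"unknown reproduction_mode {self.reproduction_mode!r}")
        if self.variation_source not in VARIATION_SOURCES:
            raise SchemaError(
                f"unknown variation_source {self.variation_source!r}")
        if self.comparison not in COMPARISONS:
            raise SchemaError(f"unknown comparison {self.comparison!r}")
        if self.disp_type not in DISP_TYPES:
            raise SchemaError(f"unknown disp_type {self.disp_type!r}")
        for name in ("disp_sel", "disp_anc"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise SchemaError(f"{name} must be >= 0, got {v}")
        if self.reproduction_mode == "continuous" and (
                self.generation_time is None or self.generation_time <= 0):
            raise SchemaError(
                "generation_time required (and > 0) for continuous mode")
        if self.disp_type == "sd" and (
                self.n_replicates is None or self.n_replicates < 1):
            raise SchemaError("n_replicates required when disp_type='sd'")
        if self.generations is not None and self.generations < 0:
            raise SchemaError("generations must be nonnegative")


@dataclass(frozen=True)
class EffectRecord:
    """One relative-fitness effect size, the unit of the meta-analysis.

    ``rel_fitness_se`` may be missing (``None``) until :func:`apply_exclusions`
    removes such rows; ``sign`` encodes whether selection happened at a
    higher, lower or equal temperature than the ancestral/control regime.
    """

    effect_id: str
    study_id: str
    species_id: str
    tpc_id: str
    rel_fitness: float
    rel_fitness_se: float | None
    rel_assay_temp: float
    sign: str
    variation_source: str
    generations: float | None
    n_assay_temps_in_tpc: int
    mode_used: str

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise SchemaError(f"unknown sign {self.sign!r}")
        if not math.isfinite(self.rel_fitness):
            raise SchemaError(f"non-finite rel_fitness in {self.effect_id}")


# ---------------------------------------------------------------------------
# CSV I/O


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_int(v) -> int | None:
    f = _opt_float(v)
    return None if f is None else int(f)


def read_assay_table(path: str | Path,
                     dialect: str = SCHEMA_TAG) -> list[AssayRecord]:
    """Read a flat assay CSV into :class:`AssayRecord` rows.

    Missing optional fields (empty cells) become ``None``, never zero.
    Malformed rows raise :class:`SchemaError` naming the offending row.
    """
    if dialect != SCHEMA_TAG:
        raise SchemaError(f"unknown schema dialect {dialect!r}")
    df = pd.read_csv(path, dtype={"study_id": str, "species_id": str,
                                  "tpc_id": str})
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(AssayRecord(
                study_id=str(row["study_id"]),
                species_id=str(row["species_id"]),
                tpc_id=str(row["tpc_id"]),
                reproduction_mode=str(row["reproduction_mode"]),
                variation_source=str(row["variation_source"]),
                comparison=str(row["comparison"]),
                sexual=_parse_bool(row["sexual"]),
                generations=_opt_float(row["generations"]),
                generation_time=_opt_float(row["generation_time"]),
                selection_temp=float(row["selection_temp"]),
                control_temp=float(row["control_temp"]),
                assay_temp=float(row["assay_temp"]),
                f_sel_mean=float(row["f_sel_mean"]),
                f_anc_mean=float(row["f_anc_mean"]),
                disp_sel=_opt_float(row["disp_sel"]),
                disp_anc=_opt_float(row["disp_anc"]),
                disp_type=str(row["disp_type"]),
                n_replicates=_opt_int(row["n_replicates"]),
            ))
        except (SchemaError, ValueError, TypeError) as exc:
            raise SchemaError(f"row {i} (0-based, after header): {exc}") from exc
    return records


def _parse_bool(v) -> bool:
    if isinstance(v, (bool,)):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "1.0", "yes"):
        return True
    if s in ("false", "0", "0.0", "no"):
        return False
    raise ValueError(f"cannot parse boolean from {v!r}")


def write_assay_table(records: Iterable[AssayRecord],
                      path: str | Path) -> None:
    df = pd.DataFrame([asdict(r) for r in records], columns=ASSAY_COLUMNS)
    df.to_csv(path, index=False)


def effects_to_frame(effects: Iterable[EffectRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in effects], columns=EFFECT_COLUMNS)


def write_effect_table(effects: Iterable[EffectRecord],
                       path: str | Path) -> None:
    effects_to_frame(effects).to_csv(path, index=False)


def read_effect_table(path: str | Path) -> list[EffectRecord]:
    df = pd.read_csv(path, dtype={c: str for c in
                                  ("effect_id", "study_id", "species_id",
                                   "tpc_id", "sign", "variation_source",
                                   "mode_used")})
    out = []
    for i, row in df.iterrows():
        try:
            out.append(EffectRecord(
                effect_id=str(row["effect_id"]),
                study_id=str(row["study_id"]),
                species_id=str(row["species_id"]),
                tpc_id=str(row["tpc_id"]),
                rel_fitness=float(row["rel_fitness"]),
                rel_fitness_se=_opt_float(row["rel_fitness_se"]),
                rel_assay_temp=float(row["rel_assay_temp"]),
                sign=str(row["sign"]),
                variation_source=str(row["variation_source"]),
                generations=_opt_float(row["generations"]),
                n_assay_temps_in_tpc=int(row["n_assay_temps_in_tpc"]),
                mode_used=str(row["mode_used"]),
            ))
        except (SchemaError, ValueError, TypeError) as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Dispersion normalization


def normalize_dispersion(record: AssayRecord) -> AssayRecord:
    """Convert reported dispersion to a standard error.

    Standard deviations are divided by sqrt(n_replicates); half-widths of 95%
    confidence intervals by 1.96; standard errors pass through. Idempotent.
    Missing dispersions stay missing.
    """
    if record.disp_type == "se":
        return record
    if record.disp_type == "sd":
        if record.n_replicates is None:
            raise SchemaError(
                f"tpc {record.tpc_id}: sd dispersion without n_replicates")
        k = math.sqrt(record.n_replicates)
    elif record.disp_type == "ci95_halfwidth":
        k = 1.96
    else:  # pragma: no cover - blocked by __post_init__
        raise SchemaError(f"unknown disp_type {record.disp_type!r}")

    def conv(v: float | None) -> float | None:
        return None if v is None else v / k

    return replace(record, disp_sel=conv(record.disp_sel),
                   disp_anc=conv(record.disp_anc), disp_type="se")


# ---------------------------------------------------------------------------
# Cleaning


@dataclass(frozen=True)
class Exclusion:
    effect_id: str
    reason: str


def apply_exclusions(effects: Sequence[EffectRecord],
                     outlier_threshold: float = 20.0,
                     ) -> tuple[list[EffectRecord], list[Exclusion]]:
    """Remove effects the measurement-error model cannot use.

    Drops relative-fitness outliers above ``outlier_threshold``, effects with
    a zero standard error (infinite weight) and effects with no reported
    error at all. Returns the kept effects plus a per-row exclusion log.
    Idempotent on its own output.
    """
    kept: list[EffectRecord] = []
    log: list[Exclusion] = []
    for e in effects:
        if e.rel_fitness > outlier_threshold:
            log.append(Exclusion(e.effect_id,
                                 f"outlier: rel_fitness {e.rel_fitness:g} > "
                                 f"{outlier_threshold:g}"))
        elif e.rel_fitness_se is None or math.isnan(e.rel_fitness_se):
            log.append(Exclusion(e.effect_id, "no error measurement reported"))
        elif e.rel_fitness_se == 0:
            log.append(Exclusion(e.effect_id, "error estimate of zero"))
        else:
            kept.append(e)
    return kept, log


def write_exclusion_log(log: Iterable[Exclusion], path: str | Path) -> None:
    pd.DataFrame([asdict(x) for x in log],
                 columns=["effect_id", "reason"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Analysis subsets


def build_subsets(effects: Sequence[EffectRecord],
                  temp_tol: float = TEMP_TOL) -> dict[str, list[EffectRecord]]:
    """Split cleaned effects into the four analysis subsets.

    ``at_selection``: assay at the selection temperature (|dT| <= temp_tol);
    ``two_point``: effects from TPCs assayed at exactly two temperatures;
    ``multipoint``: TPCs with three or more assay temperatures;
    ``hib_candidates``: TPCs with more than three assay temperatures, the
    pool for the Hotter-is-better maximal-fitness comparison.
    """
    by_tpc: dict[str, list[EffectRecord]] = {}
    for e in effects:
        by_tpc.setdefault(e.tpc_id, []).append(e)

    subsets: dict[str, list[EffectRecord]] = {
        "at_selection": [], "two_point": [], "multipoint": [],
        "hib_candidates": []}
    for e in effects:
        if abs(e.rel_assay_temp) <= temp_tol:
            subsets["at_selection"].append(e)
    for tpc_effects in by_tpc.values():
        n_temps = len({round(e.rel_assay_temp, 6) for e in tpc_effects})
        if n_temps == 2:
            subsets["two_point"].extend(tpc_effects)
        elif n_temps >= 3:
            subsets["multipoint"].extend(tpc_effects)
        if n_temps > 3:
            subsets["hib_candidates"].extend(tpc_effects)
    return subsets
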