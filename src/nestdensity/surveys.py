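"""Survey data model and validated readers/writers.

The raw units of every estimate in this package are a set of line
transects (each with a habitat stratum and a length in km) and the nest
observations recorded along them (perpendicular distance in metres and
an ordinal decay class A–E).  An optional per-transect covariate table
carries the forest-structure and landscape predictors used by the
model-averaging stage.

Files are delimited text with a header row; column order is free and
header matching is case-insensitive.  Distances are metres, transect
lengths kilometres, densities per km²; all unit conversion is internal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

HABITATS = ("logged_forest", "salvage_logged", "oil_palm_remnant")
DECAY_CLASSES = ("A", "B", "C", "D", "E")

#: Minimum nest count per stratum for a reliable detection function.
MIN_NESTS_PER_HABITAT = 60
#: Minimum total transect length (km) per stratum for low-density sites.
MIN_EFFORT_KM = 3.0


class SchemaError(ValueError):
    """A required column is missing or a value is outside its domain."""


class IntegrityError(ValueError):
    """Cross-table referential integrity is violated."""


@dataclass(frozen=True)
class Transect:
    id: str
    habitat: str
    length_km: float

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise SchemaError(
                f"unknown habitat {self.habitat!r} for transect {self.id!r}; "
                f"expected one of {HABITATS}"
            )
        if not self.length_km > 0:
            raise SchemaError(f"transect {self.id!r}: length_km must be > 0")


@dataclass(frozen=True)
class NestObservation:
    transect_id: str
    perp_distance_m: float
    decay_class: str

    def __post_init__(self) -> None:
        if self.perp_distance_m < 0:
            raise IntegrityError(
                f"negative perpendicular distance {self.perp_distance_m} "
                f"on transect {self.transect_id!r}"
            )
        if self.decay_class not in DECAY_CLASSES:
            raise SchemaError(
                f"unknown decay class {self.decay_class!r}; expected A–E"
            )


@dataclass(frozen=True)
class CovariateRecord:
    transect_id: str
    canopy_height_mean_m: float
    canopy_height_sd_m: float
    n_layers: float
    shannon_pai: float
    forest_cover_pct: float
    dist_to_forest_m: float

    def __post_init__(self) -> None:
        if self.canopy_height_sd_m < 0:
            raise SchemaError(f"{self.transect_id!r}: canopy_height_sd_m < 0")
        if self.n_layers < 0 or self.shannon_pai < 0 or self.dist_to_forest_m < 0:
            raise SchemaError(f"{self.transect_id!r}: negative covariate value")
        if not 0 <= self.forest_cover_pct <= 100:
            raise SchemaError(
                f"{self.transect_id!r}: forest_cover_pct outside [0, 100]"
            )


@dataclass
class SurveyDataset:
    """Transects, nest observations and (optionally) covariates.

    Referential integrity is enforced at construction: every observation
    and covariate record must point at a known transect id, and transect
    ids must be unique.
    """

    transects: tuple[Transect, ...]
    observations: tuple[NestObservation, ...] = ()
    covariates: tuple[CovariateRecord, ...] | None = None

    def __post_init__(self) -> None:
        self.transects = tuple(self.transects)
        self.observations = tuple(self.observations)
        if self.covariates is not None:
            self.covariates = tuple(self.covariates)
        ids = [t.id for t in self.transects]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise IntegrityError(f"duplicate transect ids: {sorted(dupes)}")
        known = set(ids)
        orphans = sorted({o.transect_id for o in self.observations} - known)
        if orphans:
            raise IntegrityError(
                f"observations reference unknown transects: {orphans}"
            )
        if self.covariates is not None:
            orphans = sorted({c.transect_id for c in self.covariates} - known)
            if orphans:
                raise IntegrityError(
                    f"covariates reference unknown transects: {orphans}"
                )

    # -- convenience views ------------------------------------------------
    def transects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.id, t.habitat, t.length_km) for t in self.transects],
            columns=["id", "habitat", "length_km"],
        )

    def observations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(o.transect_id, o.perp_distance_m, o.decay_class) for o in self.observations],
            columns=["transect_id", "perp_distance_m", "decay_class"],
        )

    def covariates_frame(self) -> pd.DataFrame | None:
        if self.covariates is None:
            return None
        return pd.DataFrame([vars(c) for c in self.covariates])

    def habitat_of(self, transect_id: str) -> str:
        for t in self.transects:
            if t.id == transect_id:
                return t.habitat
        raise KeyError(transect_id)

    def nest_counts(self, truncation_w_m: float | None = None) -> pd.DataFrame:
        """Per-transect nest counts (optionally within a truncation distance).

        Returns a frame with one row per transect: id, habitat, length_km,
        n_nests.  Transects with no observations get a count of zero.
        """
        counts = {t.id: 0 for t in self.transects}
        for o in self.observations:
            if truncation_w_m is None or o.perp_distance_m < truncation_w_m:
                counts[o.transect_id] += 1
        out = self.transects_frame()
        out["n_nests"] = [counts[i] for i in out["id"]]
        return out


# ---------------------------------------------------------------------------
# Readers


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def read_survey(
    transect_path: str | Path,
    nest_path: str | Path | None = None,
    covariate_path: str | Path | None = None,
) -> SurveyDataset:
    """Read and validate a survey from delimited text files.

    Raises :class:`SchemaError` for missing columns or out-of-domain
    values, :class:`IntegrityError` for orphan transect references.
    """
    tdf = _read_table(transect_path, ["id", "habitat", "length_km"])
    transects = tuple(
        Transect(str(r.id), str(r.habitat), float(r.length_km))
        for r in tdf.itertuples()
    )
    observations: tuple[NestObservation, ...] = ()
    if nest_path is not None:
        ndf = _read_table(nest_path, ["transect_id", "perp_distance_m", "decay_class"])
        observations = tuple(
            NestObservation(str(r.transect_id), float(r.perp_distance_m), str(r.decay_class))
            for r in ndf.itertuples()
        )
    covariates = None
    if covariate_path is not None:
        cols = [
            "transect_id", "canopy_height_mean_m", "canopy_height_sd_m",
            "n_layers", "shannon_pai", "forest_cover_pct", "dist_to_forest_m",
        ]
        cdf = _read_table(covariate_path, cols)
        covariates = tuple(
            CovariateRecord(str(r[0]), *map(float, r[1:]))
            for r in cdf[cols].itertuples(index=False)
        )
    return SurveyDataset(transects, observations, covariates)


# ---------------------------------------------------------------------------
# Validation report


@dataclass
class ValidationReport:
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.warnings


def validate_dataset(dataset: SurveyDataset) -> ValidationReport:
    """Report-only survey design checks; never mutates or rejects data.

    Warns when a habitat stratum falls below the 60-nest minimum commonly
    required for a reliable great-ape detection function, or below 3 km of
    total effort (the minimum for density estimation at low ape density).
    """
    report = ValidationReport()
    counts: dict[str, int] = {h: 0 for h in HABITATS}
    effort: dict[str, float] = {h: 0.0 for h in HABITATS}
    present: set[str] = set()
    for t in dataset.transects:
        effort[t.habitat] += t.length_km
        present.add(t.habitat)
    for o in dataset.observations:
        counts[dataset.habitat_of(o.transect_id)] += 1
    for h in HABITATS:
        if h not in present:
            continue
        if counts[h] < MIN_NESTS_PER_HABITAT:
            report.warnings.append(
                f"{h}: {counts[h]} nest observations, below 60-nest minimum "
                "for reliable detection-function estimation"
            )
        if effort[h] < MIN_EFFORT_KM:
            report.warnings.append(
                f"{h}: {effort[h]:.1f} km total effort, below the 3 km minimum"
            )
    return report


# ---------------------------------------------------------------------------
# Result writing


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    summary: Mapping | None = None,
) -> list[Path]:
    """Write one CSV per named table plus a JSON run summary.

    Re-running with identical inputs produces byte-identical files:
    floats are serialised with `repr` (pandas' default round-trip
    formatting) and the summary JSON is key-sorted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    summary = dict(summary or {})
    summary["tables"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
    }
    spath = out_dir / "run_summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    written.append(spath)
    return written
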