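"""Nest and orang-utan density estimation.

Standing-crop nest counts are converted to ape density in two steps.
Nest density on a transect of length L (km) with effective strip width
w (m) is

    D_nest = N / (L · 2w)            [nests/km², w converted to km]

and ape density is obtained by dividing out the nest multiplier

    D_ape = D_nest / (p · r · t)

where p is the proportion of nest-building individuals, r the nest
production rate (nests/individual/day) and t the mean nest decay time
(days).  The product p·r·t is the expected number of standing nests per
individual at any instant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .surveys import HABITATS, SurveyDataset


@dataclass(frozen=True)
class ParameterSet:
    """The (p, r, t) triple converting nest density to ape density."""

    p: float  # proportion of nest builders, in (0, 1]
    r: float  # nests per individual per day
    t: float  # nest decay time, days

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.r <= 0 or self.t <= 0:
            raise ValueError(f"r and t must be positive, got r={self.r}, t={self.t}")

    @property
    def nests_per_individual(self) -> float:
        return self.p * self.r * self.t


@dataclass(frozen=True)
class DensityEstimate:
    transect_id: str
    habitat: str
    n_nests: int
    length_km: float
    encounter_rate: float  # nests/km
    esw_m: float
    nest_density: float  # nests/km²
    ape_density: float  # ind/km²


def encounter_rate(n_nests: int, length_km: float) -> float:
    """Nests encountered per km of transect walked."""
    if length_km <= 0:
        raise ValueError("length_km must be positive")
    if n_nests < 0:
        raise ValueError("n_nests must be non-negative")
    return n_nests / length_km


def nest_density(n_nests: int, length_km: float, esw_m: float) -> float:
    """Nests per km² from count, effort and effective strip width."""
    if length_km <= 0:
        raise ValueError("length_km must be positive")
    if esw_m <= 0:
        raise ValueError("esw_m must be positive")
    if n_nests < 0:
        raise ValueError("n_nests must be non-negative")
    return n_nests / (length_km * 2.0 * esw_m / 1000.0)


def orangutan_density(nest_density_km2: float, params: ParameterSet) -> float:
    """Ape density (ind/km²) from nest density via the p·r·t multiplier."""
    if nest_density_km2 < 0:
        raise ValueError("nest density must be non-negative")
    return nest_density_km2 / params.nests_per_individual


def estimate_from_counts(
    counts: pd.DataFrame,
    esw_by_habitat: Mapping[str, float],
    params: ParameterSet,
) -> list[DensityEstimate]:
    """Per-transect density estimates from a count table.

    `counts` needs columns id, habitat, length_km, n_nests.  Each
    transect uses its habitat's pooled ESW; all arithmetic is at full
    precision, rounding happens only at report time.
    """
    missing = sorted(set(counts["habitat"]) - set(esw_by_habitat))
    if missing:
        raise KeyError(f"no ESW supplied for habitat(s): {missing}")
    out = []
    for row in counts.itertuples():
        esw = float(esw_by_habitat[row.habitat])
        nd = nest_density(int(row.n_nests), float(row.length_km), esw)
        out.append(
            DensityEstimate(
                transect_id=str(row.id),
                habitat=str(row.habitat),
                n_nests=int(row.n_nests),
                length_km=float(row.length_km),
                encounter_rate=encounter_rate(int(row.n_nests), float(row.length_km)),
                esw_m=esw,
                nest_density=nd,
                ape_density=orangutan_density(nd, params),
            )
        )
    return out


def estimate_all(
    dataset: SurveyDataset,
    esw_by_habitat: Mapping[str, float],
    params: ParameterSet,
    truncation_w_m: float = 40.0,
) -> list[DensityEstimate]:
    """Per-transect estimates from raw observations.

    Counts nests within the truncation distance (the same records the
    detection function was fitted to), then applies
    :func:`estimate_from_counts`.
    """
    counts = dataset.nest_counts(truncation_w_m=truncation_w_m)
    return estimate_from_counts(counts, esw_by_habitat, params)


def estimates_frame(estimates: Iterable[DensityEstimate]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])


LANDSCAPE = "landscape"


def habitat_summary(estimates: Iterable[DensityEstimate]) -> pd.DataFrame:
    """Mean/sd/se/min/max of ape density per habitat plus a landscape row.

    The landscape row is the unweighted mean over all transects (not
    effort-weighted).  Sample sd (n−1); a single-transect habitat gets
    missing sd/se.
    """
    df = estimates_frame(estimates)
    if df.empty:
        raise ValueError("no estimates to summarise")
    rows = []
    groups = [(h, df[df["habitat"] == h]) for h in HABITATS if (df["habitat"] == h).any()]
    groups.append((LANDSCAPE, df))
    for label, g in groups:
        d = g["ape_density"].to_numpy(float)
        n = len(d)
        sd = float(np.std(d, ddof=1)) if n > 1 else math.nan
        rows.append(
            {
                "habitat": label,
                "n_transects": n,
                "mean": float(np.mean(d)),
                "sd": sd,
                "se": sd / math.sqrt(n) if n > 1 else math.nan,
                "min": float(np.min(d)),
                "max": float(np.max(d)),
            }
        )
    return pd.DataFrame(rows)


def report_table(estimates: Iterable[DensityEstimate]) -> pd.DataFrame:
    """Per-transect report rounded to the 1 dp convention of field reports."""
    df = estimates_frame(estimates)
    df["encounter_rate"] = df["encounter_rate"].round(1)
    df["nest_density"] = df["nest_density"].round(1)
    df["ape_density"] = df["ape_density"].round(1)
    return df
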