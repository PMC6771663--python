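"""Parameter sensitivity of the density conversion.

Ape density scales as 1/(p·r·t), and all three conversion parameters
are borrowed from other study sites, so the analysis propagates a
low/medium/high level for each parameter through a full 3×3×3 factorial
grid (27 combinations) of density estimates.  Three "fixed" subsets —
one parameter held at its medium value while the other two vary — show
how much each parameter alone contributes to the spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .density import ParameterSet, orangutan_density


@dataclass(frozen=True)
class ParameterGrid:
    """(low, medium, high) levels for each of p, r, t."""

    p: tuple[float, float, float]
    r: tuple[float, float, float]
    t: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, levels in (("p", self.p), ("r", self.r), ("t", self.t)):
            if not (levels[0] < levels[1] < levels[2]):
                # degenerate all-equal grids are allowed for testing
                if not (levels[0] == levels[1] == levels[2]):
                    raise ValueError(
                        f"{name} levels must satisfy low < medium < high "
                        f"(or all equal), got {levels}"
                    )

    @property
    def medium(self) -> ParameterSet:
        return ParameterSet(self.p[1], self.r[1], self.t[1])


def build_parameter_grid(levels: ParameterGrid) -> list[ParameterSet]:
    """Full factorial over the level triples: 27 parameter sets.

    Deterministic p-major order (p outermost, then r, then t), each
    axis iterated low → medium → high.
    """
    return [
        ParameterSet(p, r, t)
        for p in levels.p
        for r in levels.r
        for t in levels.t
    ]


SUBSET_LABELS = ("t-fixed", "r-fixed", "p-fixed")


def fixed_parameter_subsets(levels: ParameterGrid) -> dict[str, list[ParameterSet]]:
    """The three 9-member subsets with one parameter held at medium.

    "t-fixed" varies p and r with t at medium, and so on; each subset
    contains the all-medium centre combination, and together the three
    subsets cover the 27 − 2³ = 19 combinations having at least one
    parameter at its medium value.
    """
    grid = build_parameter_grid(levels)
    return {
        "t-fixed": [s for s in grid if s.t == levels.t[1]],
        "r-fixed": [s for s in grid if s.r == levels.r[1]],
        "p-fixed": [s for s in grid if s.p == levels.p[1]],
    }


def sensitivity_densities(
    nest_densities: pd.DataFrame,
    parameter_sets: Sequence[ParameterSet],
    label: str = "grid",
) -> pd.DataFrame:
    """Ape density per transect per parameter combination (long format).

    `nest_densities` needs columns transect_id, habitat, nest_density
    (full precision).  Returns columns: subset, p, r, t, transect_id,
    habitat, ape_density.
    """
    rows = []
    for ps in parameter_sets:
        for rec in nest_densities.itertuples():
            rows.append(
                (
                    label, ps.p, ps.r, ps.t,
                    rec.transect_id, rec.habitat,
                    orangutan_density(float(rec.nest_density), ps),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["subset", "p", "r", "t", "transect_id", "habitat", "ape_density"],
    )


def sensitivity_table(
    nest_densities: pd.DataFrame, levels: ParameterGrid
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format densities for the three fixed subsets, plus ranges.

    Ranges are per (subset, habitat) min/max over transect-level
    estimates across the subset's 9 parameter combinations.
    """
    if nest_densities.empty:
        empty = pd.DataFrame(
            columns=["subset", "p", "r", "t", "transect_id", "habitat", "ape_density"]
        )
        return empty, pd.DataFrame(columns=["subset", "habitat", "min", "max"])
    long = pd.concat(
        [
            sensitivity_densities(nest_densities, subset, label)
            for label, subset in fixed_parameter_subsets(levels).items()
        ],
        ignore_index=True,
    )
    ranges = (
        long.groupby(["subset", "habitat"], sort=False)["ape_density"]
        .agg(["min", "max"])
        .reset_index()
    )
    return long, ranges


def sensitivity_histogram(
    long: pd.DataFrame, bin_width: float = 0.25
) -> pd.DataFrame:
    """Binned estimate counts per subset (histogram table, 0.25 ind/km² bins)."""
    if long.empty:
        return pd.DataFrame(columns=["subset", "bin_lower", "bin_upper", "count"])
    top = float(long["ape_density"].max())
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    rows = []
    for label, g in long.groupby("subset", sort=False):
        counts, _ = np.histogram(g["ape_density"], bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append((label, float(lo), float(hi), int(c)))
    return pd.DataFrame(rows, columns=["subset", "bin_lower", "bin_upper", "count"])
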