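"""Habitat-level comparison tests.

Report-only gates around the density pipeline: Shapiro–Wilk normality
and Bartlett variance-homogeneity checks, one-way ANOVA with Tukey HSD
post-hoc contrasts on transect-level values, and a χ² homogeneity test
of the perpendicular-distance distributions across habitats (which
justifies comparing encounter rates between strata).  Every function is
a pure function of its inputs; the pipeline proceeds regardless of the
outcomes, as is conventional for these diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detection import BinnedDistances


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: tuple[int, ...] | int | None
    p_value: float
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _check_groups(groups: Mapping[str, Sequence[float]], min_per_group: int = 2) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for label, values in groups.items():
        if len(values) < min_per_group:
            raise ValueError(
                f"group {label!r} has {len(values)} values; need ≥ {min_per_group}"
            )


def oneway_anova(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Classical one-way ANOVA: F = MS_between / MS_within, df (k−1, n−k)."""
    _check_groups(groups)
    arrays = [np.asarray(v, float) for v in groups.values()]
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    return TestResult("one-way ANOVA", float(f), (k - 1, n - k), float(p),
                      tuple(groups))


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> list[TestResult]:
    """Tukey honest-significant-difference pairwise comparisons."""
    _check_groups(groups)
    labels = list(groups)
    res = stats.tukey_hsd(*[np.asarray(groups[g], float) for g in labels])
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out.append(
                TestResult(
                    "Tukey HSD",
                    float(res.statistic[i, j]),
                    None,
                    float(res.pvalue[i, j]),
                    (labels[i], labels[j]),
                )
            )
    return out


def normality_test(values: Sequence[float]) -> TestResult:
    """Shapiro–Wilk test of normality (requires n ≥ 3)."""
    v = np.asarray(values, float)
    if len(v) < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 values")
    w, p = stats.shapiro(v)
    return TestResult("Shapiro-Wilk", float(w), None, float(p))


def variance_homogeneity_test(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Bartlett's test of equal variances across groups."""
    _check_groups(groups)
    k, p = stats.bartlett(*[np.asarray(v, float) for v in groups.values()])
    return TestResult("Bartlett", float(k), len(groups) - 1, float(p), tuple(groups))


def distance_distribution_homogeneity(
    binned_by_habitat: Mapping[str, BinnedDistances],
) -> TestResult:
    """χ² homogeneity of perpendicular-distance distributions across habitats.

    Builds the habitat × distance-class contingency table (all strata
    must share bin edges), merging distance classes rightward until
    every expected count is ≥ 1; df = (habitats − 1)·(used bins − 1).
    """
    if len(binned_by_habitat) < 2:
        raise ValueError("need binned distances for at least two habitats")
    items = list(binned_by_habitat.items())
    edges0 = items[0][1].bin_edges_m
    for label, b in items[1:]:
        if not np.array_equal(b.bin_edges_m, edges0):
            raise ValueError(f"bin edges for {label!r} differ from the others")
    table = np.vstack([b.counts for _, b in items]).astype(float)

    # merge distance classes (columns) rightward until every expected ≥ 1
    def expected(tab: np.ndarray) -> np.ndarray:
        return np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()

    while table.shape[1] > 1 and np.any(expected(table) < 1.0):
        table = np.hstack([table[:, :-2], table[:, -2:].sum(axis=1, keepdims=True)])
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(
        "chi-square homogeneity", float(chi2), int(df), float(p),
        tuple(label for label, _ in items),
    )


def results_table(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "test": r.name,
                "groups": "|".join(r.groups),
                "statistic": r.statistic,
                "df": str(r.df) if r.df is not None else "",
                "p_value": r.p_value,
            }
            for r in results
        ]
    )
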