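"""Published per-transect survey summary from a Bornean orang-utan study.

A 2017 standing-crop nest survey in Sabah, Malaysian Borneo, covered
three habitat strata: continuous logged forest (Ulu Segama Forest
Reserve and a Virgin Jungle Reserve), remnant forest in a recently
salvage-logged area, and forest remnants within oil palm plantations.
The published summary table lists, for each of 28 analysed transects,
the nest count, transect length, and the habitat-pooled effective strip
width fitted by the original analysts.  Those ESWs (15.5 / 14.3 /
14.7 m) cannot be re-derived here because the raw perpendicular
distances are embargoed; they are treated as inputs.

Per-transect rows are `(site_id, habitat, n_nests, length_km)`.
Transect lengths are printed to 1 dp, so the published encounter-rate
column (computed by the original analysts from unrounded lengths)
occasionally differs from ``n / length`` at the final digit.
"""

from __future__ import annotations

from .density import ParameterSet
from .sensitivity import ParameterGrid
from .surveys import SurveyDataset, Transect

#: (site_id, habitat, n_nests, length_km) for the 28 published transects.
SABAH_TRANSECT_ROWS: tuple[tuple[str, str, int, float], ...] = (
    ("LF1", "logged_forest", 31, 1.8),
    ("LF2", "logged_forest", 23, 2.0),
    ("LF3", "logged_forest", 25, 2.0),
    ("LFR", "logged_forest", 15, 1.0),
    ("LFE1", "logged_forest", 17, 2.0),
    ("LFE2", "logged_forest", 24, 1.5),
    ("LFE3", "logged_forest", 24, 1.2),
    ("LFE4", "logged_forest", 17, 1.0),
    ("LFER", "logged_forest", 25, 1.6),
    ("VJR_R", "logged_forest", 25, 1.6),
    ("VJR_1", "logged_forest", 37, 1.2),
    ("VJR_2", "logged_forest", 10, 1.0),
    ("RR0", "salvage_logged", 30, 1.6),
    ("RR5", "salvage_logged", 26, 1.5),
    ("RR15", "salvage_logged", 28, 1.6),
    ("RR30", "salvage_logged", 29, 1.7),
    ("RR60", "salvage_logged", 11, 1.5),
    ("RR120", "salvage_logged", 21, 1.6),
    ("Block_B", "salvage_logged", 28, 1.9),
    ("Block_C", "salvage_logged", 29, 2.1),
    ("Block_D", "salvage_logged", 24, 2.4),
    ("Block_E", "salvage_logged", 43, 2.3),
    ("OP02", "oil_palm_remnant", 13, 1.6),
    ("OP03", "oil_palm_remnant", 9, 1.3),
    ("OP07", "oil_palm_remnant", 1, 1.8),
    ("OP12", "oil_palm_remnant", 6, 1.8),
    ("OP14", "oil_palm_remnant", 16, 1.8),
    ("OP16", "oil_palm_remnant", 7, 1.8),
)

#: Published per-transect encounter rate (nests/km) and orang-utan density
#: (ind/km²), both printed to 1 dp, keyed by site id.  Kept for comparison
#: only; every estimate in this package is recomputed from counts.
SABAH_PUBLISHED_COLUMNS: dict[str, tuple[float, float]] = {
    "LF1": (17.2, 2.5), "LF2": (11.5, 1.7), "LF3": (12.5, 1.8),
    "LFR": (15.0, 2.2), "LFE1": (8.5, 1.3), "LFE2": (15.7, 2.3),
    "LFE3": (20.0, 2.9), "LFE4": (17.0, 2.5), "LFER": (15.6, 2.3),
    "VJR_R": (15.6, 2.3), "VJR_1": (30.8, 4.5), "VJR_2": (10.0, 1.5),
    "RR0": (19.1, 3.0), "RR5": (17.3, 2.8), "RR15": (17.5, 2.8),
    "RR30": (17.1, 2.7), "RR60": (7.3, 1.2), "RR120": (13.1, 2.1),
    "Block_B": (14.6, 2.3), "Block_C": (13.8, 2.2), "Block_D": (9.5, 1.5),
    "Block_E": (19.1, 3.0),
    "OP02": (8.1, 1.3), "OP03": (7.0, 1.1), "OP07": (0.6, 0.1),
    "OP12": (3.4, 0.5), "OP14": (8.9, 1.4), "OP16": (4.0, 0.6),
}

#: Habitat-pooled effective strip widths (m) fitted by the original analysts.
SABAH_ESW_BY_HABITAT: dict[str, float] = {
    "logged_forest": 15.5,
    "salvage_logged": 14.3,
    "oil_palm_remnant": 14.7,
}

#: Medium (reference) conversion parameters: proportion of nest builders p,
#: nest production rate r (nests/ind/day), nest decay time t (days).
SABAH_PARAMS = ParameterSet(p=0.85, r=1.00, t=259.0)

#: Low/medium/high levels for the parameter sensitivity grid.
SABAH_PARAM_LEVELS = ParameterGrid(
    p=(0.82, 0.85, 0.88),
    r=(0.84, 1.00, 1.16),
    t=(202.0, 259.0, 602.0),
)


def load_sabah_survey() -> SurveyDataset:
    """The published 28-transect survey as a (summary-level) dataset.

    Only per-transect counts are known, not individual perpendicular
    distances, so the dataset carries no observations; pair it with
    :func:`load_sabah_counts` and the published ESWs for estimation.
    """
    return SurveyDataset(
        transects=tuple(
            Transect(sid, habitat, length)
            for sid, habitat, _, length in SABAH_TRANSECT_ROWS
        )
    )


def load_sabah_counts():
    """Per-transect nest counts as a DataFrame (id, habitat, length_km, n_nests)."""
    import pandas as pd

    return pd.DataFrame(
        [(sid, h, length, n) for sid, h, n, length in SABAH_TRANSECT_ROWS],
        columns=["id", "habitat", "length_km", "n_nests"],
    )
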