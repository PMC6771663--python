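import numpy as np
import pandas as pd
import pytest

from nestdensity.datasets import (
    SABAH_ESW_BY_HABITAT,
    SABAH_PARAMS,
    load_sabah_counts,
)
from nestdensity.density import estimate_from_counts
from nestdensity.surveys import NestObservation, SurveyDataset, Transect


@pytest.fixture(scope="session")
def sabah_counts():
    return load_sabah_counts()


@pytest.fixture(scope="session")
def sabah_estimates(sabah_counts):
    return estimate_from_counts(sabah_counts, SABAH_ESW_BY_HABITAT, SABAH_PARAMS)


@pytest.fixture
def tiny_survey_files(tmp_path):
    """3-transect, 5-observation survey written as delimited text."""
    tpath = tmp_path / "transects.csv"
    npath = tmp_path / "nests.csv"
    tpath.write_text(
        "id,habitat,length_km\n"
        "A,logged_forest,1.5\n"
        "B,salvage_logged,2.0\n"
        "C,oil_palm_remnant,0.8\n"
    )
    npath.write_text(
        "transect_id,perp_distance_m,decay_class\n"
        "A,1.2,A\nA,15.0,C\nB,3.4,B\nB,39.9,E\nC,0.0,D\n"
    )
    return tpath, npath


@pytest.fixture
def small_dataset():
    transects = (
        Transect("A", "logged_forest", 1.5),
        Transect("B", "salvage_logged", 2.0),
    )
    observations = (
        NestObservation("A", 1.2, "A"),
        NestObservation("A", 15.0, "C"),
        NestObservation("B", 3.4, "B"),
    )
    return SurveyDataset(transects, observations)


@pytest.fixture(scope="session")
def half_normal_binned():
    """n=1000 distances from a half-normal (σ=12.4) detection process."""
    from nestdensity.detection import bin_distances

    rng = np.random.default_rng(20170401)
    sigma = 12.4
    x = rng.uniform(0, 60, 40000)
    kept = x[rng.uniform(size=len(x)) < np.exp(-(x**2) / (2 * sigma**2))][:1000]
    return bin_distances(kept, 4.0, 40.0), sigma
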