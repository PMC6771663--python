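"""Configuration-driven end-to-end runs.

A :class:`RunConfig` describes one analysis: where the survey comes
from (files, an in-repo count table, or the simulator), the binning and
truncation settings, the conversion-parameter levels, and the screening
thresholds.  :func:`run_pipeline` executes the stages in order —
read/validate (or simulate) → bin → fit/select detection per habitat →
per-transect densities → habitat summaries and comparison tests →
parameter sensitivity → (if covariates exist) model averaging — writes
every table plus a JSON report, and is deterministic for a fixed
(config, seed).

Defaults reproduce the reference field protocol: 4 m distance classes,
40 m truncation, the six-model detection set, (p, r, t) =
(.85, 1.00, 259), collinearity thresholds r = .7 and GVIF = 5.

A "skip-detection" mode accepts externally supplied ESWs per habitat,
because reproducing a published summary table requires the originally
fitted strip widths, not refitted ones.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import comparisons, density, sensitivity
from .averaging import build_predictor_matrix, model_average
from .density import ParameterSet
from .detection import bin_distances, fit_six_models, fits_table, select_best_model
from .sensitivity import ParameterGrid
from .simulate import SimulationConfig, simulate_covariates, simulate_survey
from .surveys import HABITATS, SurveyDataset, read_survey, validate_dataset, write_results

log = logging.getLogger("nestdensity")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    # input: exactly one of (transects_path, counts_path, simulate)
    transects_path: str | None = None
    nests_path: str | None = None
    covariates_path: str | None = None
    counts_path: str | None = None
    simulate: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    bin_width_m: float = 4.0
    truncation_w_m: float = 40.0
    max_adj_terms: int = 3
    params: ParameterSet = field(default_factory=lambda: ParameterSet(0.85, 1.00, 259.0))
    param_levels: ParameterGrid = field(
        default_factory=lambda: ParameterGrid(
            p=(0.82, 0.85, 0.88), r=(0.84, 1.00, 1.16), t=(202.0, 259.0, 602.0)
        )
    )
    esw_by_habitat: dict[str, float] | None = None  # skip-detection mode
    r_threshold: float = 0.7
    gvif_threshold: float = 5.0
    cooks_threshold: float = 1.0
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "params" in raw:
            raw["params"] = ParameterSet(**raw["params"])
        if "param_levels" in raw:
            raw["param_levels"] = ParameterGrid(
                **{k: tuple(v) for k, v in raw["param_levels"].items()}
            )
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            if "param_truth" in sim:
                sim["param_truth"] = ParameterSet(**sim["param_truth"])
            if "transect_plan" in sim:
                sim["transect_plan"] = tuple((h, float(l)) for h, l in sim["transect_plan"])
            raw["simulation"] = SimulationConfig(**sim)
        return cls(**raw)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage label
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write results under ``config.out_dir``.

    Returns the run report (also written as JSON).  Any stage error is
    re-raised as :class:`StageError` naming the stage.
    """
    tables: dict[str, pd.DataFrame] = {}
    report: dict = {"seed": config.seed, "stages": []}

    # --- input -------------------------------------------------------------
    truth = None
    counts = None
    dataset: SurveyDataset | None = None
    if config.simulate:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        dataset, truth = _stage("simulate")(simulate_survey, sim)
        covrecs, cov_truth = _stage("simulate")(simulate_covariates, sim)
        dataset = SurveyDataset(dataset.transects, dataset.observations, covrecs)
        report["true_density"] = truth.true_density
        report["true_esw_m"] = truth.true_esw_m
        log.info("simulated %d transects, %d observations",
                 len(dataset.transects), len(dataset.observations))
    elif config.counts_path is not None:
        counts = _stage("read")(pd.read_csv, config.counts_path)
    elif config.transects_path is not None:
        dataset = _stage("read")(
            read_survey, config.transects_path, config.nests_path, config.covariates_path
        )
    else:
        raise StageError("stage 'read' failed: no input configured")
    report["stages"].append("read")

    # --- validate ----------------------------------------------------------
    if dataset is not None:
        validation = _stage("validate")(validate_dataset, dataset)
        report["validation_warnings"] = validation.warnings
        for wmsg in validation.warnings:
            log.warning("validation: %s", wmsg)
        report["stages"].append("validate")

    # --- detection ---------------------------------------------------------
    esw = dict(config.esw_by_habitat) if config.esw_by_habitat else None
    binned_by_habitat = {}
    if dataset is not None and dataset.observations:
        obs = dataset.observations_frame()
        obs["habitat"] = [dataset.habitat_of(t) for t in obs["transect_id"]]
        for habitat in HABITATS:
            x = obs.loc[obs["habitat"] == habitat, "perp_distance_m"]
            if len(x) == 0:
                continue
            b = bin_distances(x, config.bin_width_m, config.truncation_w_m)
            binned_by_habitat[habitat] = b
            log.info("%s: %d nests binned, %d discarded at %.0f m truncation",
                     habitat, b.total, b.n_discarded, config.truncation_w_m)
    if esw is None:
        if not binned_by_habitat:
            raise StageError(
                "stage 'detection' failed: no observations and no ESWs supplied"
            )
        esw = {}
        all_fits = []
        for habitat, b in binned_by_habitat.items():
            fits = _stage("detection")(fit_six_models, b, config.max_adj_terms)
            best = _stage("detection")(select_best_model, fits)
            esw[habitat] = best.esw_m
            ft = fits_table(fits)
            ft.insert(0, "habitat", habitat)
            all_fits.append(ft)
        tables["detection_models"] = pd.concat(all_fits, ignore_index=True)
        report["stages"].append("detection")
    report["esw_by_habitat"] = esw

    # --- densities ---------------------------------------------------------
    if counts is None:
        counts = dataset.nest_counts(truncation_w_m=config.truncation_w_m)
    estimates = _stage("density")(
        density.estimate_from_counts, counts, esw, config.params
    )
    est_df = density.estimates_frame(estimates)
    tables["density_by_transect"] = density.report_table(estimates)
    summary = _stage("density")(density.habitat_summary, estimates)
    tables["habitat_summary"] = summary.round(2)
    report["habitat_mean_density"] = dict(
        zip(summary["habitat"], summary["mean"].round(4))
    )
    if truth is not None:
        report["truth_vs_estimate"] = {
            h: {"true": truth.true_density[h],
                "estimated": float(summary.loc[summary["habitat"] == h, "mean"].iloc[0])}
            for h in truth.true_density
        }
    report["stages"].append("density")

    # --- comparison tests --------------------------------------------------
    groups = {
        h: est_df.loc[est_df["habitat"] == h, "ape_density"].tolist()
        for h in HABITATS
        if (est_df["habitat"] == h).sum() >= 2
    }
    results = []
    if len(groups) >= 2:
        rate_groups = {
            h: est_df.loc[est_df["habitat"] == h, "encounter_rate"].tolist()
            for h in groups
        }
        results.append(comparisons.normality_test(est_df["ape_density"]))
        results.append(comparisons.variance_homogeneity_test(groups))
        results.append(comparisons.oneway_anova(groups))
        results.extend(comparisons.tukey_hsd(groups))
        results.append(comparisons.oneway_anova(rate_groups))
        if len(binned_by_habitat) >= 2:
            results.append(
                comparisons.distance_distribution_homogeneity(binned_by_habitat)
            )
        tables["comparison_tests"] = comparisons.results_table(results)
        report["stages"].append("compare")

    # --- sensitivity -------------------------------------------------------
    nd = est_df[["transect_id", "habitat", "nest_density"]]
    long, ranges = _stage("sensitivity")(
        sensitivity.sensitivity_table, nd, config.param_levels
    )
    tables["sensitivity_long"] = long
    tables["sensitivity_ranges"] = ranges
    tables["sensitivity_histogram"] = sensitivity.sensitivity_histogram(long)
    report["stages"].append("sensitivity")

    # --- model averaging ---------------------------------------------------
    cov = dataset.covariates_frame() if dataset is not None else None
    if cov is not None:
        response = dict(zip(est_df["transect_id"], est_df["ape_density"]))
        habitat_by_transect = dict(zip(est_df["transect_id"], est_df["habitat"]))
        matrix = build_predictor_matrix(cov, response, habitat_by_transect)
        out = _stage("averaging")(
            model_average, matrix,
            config.r_threshold, config.gvif_threshold, config.cooks_threshold,
        )
        tables["model_selection"] = out["selection"]
        tables["averaged_coefficients"] = out["averaged"]
        tables["cooks_distance"] = out["cooks"]
        report["n_candidate_models"] = len(out["fits"])
        report["excluded_pairs"] = [list(p) for p in out["screen"].excluded_pairs]
        report["stages"].append("averaging")
    else:
        log.info("no covariates: model-averaging stage skipped")
        report["model_averaging"] = "skipped (no covariates)"

    # --- write -------------------------------------------------------------
    written = _stage("write")(write_results, tables, config.out_dir, report)
    report["written"] = [str(p) for p in written]
    return report
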