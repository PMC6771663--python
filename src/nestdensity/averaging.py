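"""Information-theoretic covariate inference for transect-level density.

Transect-level ape density (or nest encounter rate) is regressed on
forest-structure and landscape predictors with ordinary least squares.
Following the standard multimodel protocol: predictors are standardised
to mean 0 and sd 0.5 (binary dummies centred only) so effect sizes are
directly comparable; predictor pairs with |Pearson r| ≥ 0.7 or terms
with generalised VIF ≥ 5 are screened; all subsets of the remaining
terms (the habitat factor entering as a block of dummy contrasts with
logged forest as the reference) are fitted, including the intercept-only
model; models are ranked by small-sample corrected AIC and given Akaike
weights w_m = exp(−Δ_m/2)/Σ exp(−Δ/2); and coefficients are combined by
*full* (zero-substitution) model averaging with unconditional standard
errors, so terms that appear in few good models are shrunk toward zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .surveys import HABITATS

#: Reference habitat absorbed into the intercept.
REFERENCE_HABITAT = HABITATS[0]

NUMERIC_PREDICTORS = (
    "canopy_height_mean_m",
    "canopy_height_sd_m",
    "n_layers",
    "shannon_pai",
    "forest_cover_pct",
    "dist_to_forest_m",
)


@dataclass
class PredictorMatrix:
    """Response vector plus predictor columns and factor-block structure.

    ``predictors`` holds one numeric column per continuous predictor and
    one 0/1 dummy column per non-reference habitat level;
    ``factor_blocks`` maps a term name (e.g. ``habitat``) to its dummy
    columns, which always enter and leave candidate models together.
    """

    response: np.ndarray
    predictors: pd.DataFrame
    factor_blocks: dict[str, list[str]] = field(default_factory=dict)
    standardization: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, float)
        if len(self.response) != len(self.predictors):
            raise ValueError("response and predictor rows differ")
        if self.predictors.isna().any().any() or np.any(np.isnan(self.response)):
            raise ValueError("missing cells are not allowed")

    @property
    def terms(self) -> list[str]:
        dummy_cols = {c for cols in self.factor_blocks.values() for c in cols}
        numeric = [c for c in self.predictors.columns if c not in dummy_cols]
        return numeric + list(self.factor_blocks)

    def columns_for(self, term: str) -> list[str]:
        return self.factor_blocks.get(term, [term])


def build_predictor_matrix(
    covariates: pd.DataFrame,
    response: Mapping[str, float] | pd.Series,
    habitat_by_transect: Mapping[str, str],
) -> PredictorMatrix:
    """Assemble the global design from a covariate table and a response.

    Rows are matched by ``transect_id``; habitat becomes dummy contrasts
    against the reference level (logged forest).
    """
    cov = covariates.set_index("transect_id")
    ids = [i for i in cov.index if i in dict(response)]
    if len(ids) < len(cov):
        raise ValueError("every covariate row needs a response value")
    y = np.array([float(dict(response)[i]) for i in ids])
    pred = cov.loc[ids, list(NUMERIC_PREDICTORS)].astype(float).reset_index(drop=True)
    dummy_cols = []
    for level in HABITATS:
        if level == REFERENCE_HABITAT:
            continue
        col = f"habitat_{level}"
        pred[col] = [1.0 if habitat_by_transect[i] == level else 0.0 for i in ids]
        dummy_cols.append(col)
    return PredictorMatrix(y, pred, {"habitat": dummy_cols})


# ---------------------------------------------------------------------------
# Standardisation


def standardize_predictors(matrix: PredictorMatrix) -> PredictorMatrix:
    """Rescale to mean 0 / sd 0.5 (continuous) or centre only (binary).

    The continuous rule x → (x − mean)/(2·sd) puts coefficients on the
    same footing as a centred binary contrast, making averaged effect
    sizes directly comparable.  Already-standardised input is unchanged
    (idempotent).  Raises for a constant predictor, naming it.
    """
    dummy_cols = {c for cols in matrix.factor_blocks.values() for c in cols}
    out = matrix.predictors.copy()
    record: dict[str, tuple[float, float]] = {}
    for col in out.columns:
        x = out[col].to_numpy(float)
        mean = float(np.mean(x))
        is_binary = len(np.unique(x)) == 2 and set(np.unique(x)) <= {0.0, 1.0}
        if col in dummy_cols or is_binary:
            out[col] = x - mean
            record[col] = (mean, 1.0)
            continue
        sd = float(np.std(x, ddof=1))
        if sd == 0:
            raise ValueError(f"predictor {col!r} is constant and cannot be standardised")
        out[col] = (x - mean) / (2.0 * sd)
        record[col] = (mean, sd)
    return PredictorMatrix(
        matrix.response.copy(), out, dict(matrix.factor_blocks), record
    )


# ---------------------------------------------------------------------------
# Collinearity screening


@dataclass
class CollinearityScreen:
    excluded_pairs: list[tuple[str, str]]
    correlations: pd.DataFrame
    gvif: dict[str, float]
    gvif_flagged: list[str]


def _gvif(matrix: PredictorMatrix) -> dict[str, float]:
    """Generalised VIF per term via the correlation-determinant formulation.

    GVIF_j = det(R_jj)·det(R_(-j)) / det(R) on the correlation matrix of
    the global design (excluding the intercept); for one-column terms
    this reduces to the ordinary VIF.
    """
    X = matrix.predictors.to_numpy(float)
    cols = list(matrix.predictors.columns)
    R = np.corrcoef(X, rowvar=False)
    det_R = np.linalg.det(R)
    out: dict[str, float] = {}
    for term in matrix.terms:
        idx = [cols.index(c) for c in matrix.columns_for(term)]
        other = [i for i in range(len(cols)) if i not in idx]
        det_jj = np.linalg.det(R[np.ix_(idx, idx)])
        det_oo = np.linalg.det(R[np.ix_(other, other)]) if other else 1.0
        # a singular global design (e.g. a duplicated column) gives GVIF = ∞
        out[term] = float(det_jj * det_oo / det_R) if det_R > 1e-300 else math.inf
    return out


def collinearity_screen(
    matrix: PredictorMatrix,
    r_threshold: float = 0.7,
    gvif_threshold: float = 5.0,
) -> CollinearityScreen:
    """Flag predictor pairs with |r| ≥ 0.7 and terms with GVIF ≥ 5.

    Flagged pairs may not co-occur in any candidate model.  The
    threshold is strict: a pair at r = 0.69 is not flagged.
    """
    if len(matrix.terms) < 2:
        raise ValueError("need at least two predictors to screen")
    if len(matrix.predictors) <= len(matrix.predictors.columns):
        import warnings

        warnings.warn(
            "fewer rows than global-model columns: rank-deficient design",
            stacklevel=2,
        )
    cols = list(matrix.predictors.columns)
    col_term = {}
    for term in matrix.terms:
        for c in matrix.columns_for(term):
            col_term[c] = term
    R = pd.DataFrame(
        np.corrcoef(matrix.predictors.to_numpy(float), rowvar=False),
        index=cols, columns=cols,
    )
    pairs: set[tuple[str, str]] = set()
    for a, b in itertools.combinations(cols, 2):
        if col_term[a] == col_term[b]:
            continue
        if abs(R.loc[a, b]) >= r_threshold:
            pairs.add(tuple(sorted((col_term[a], col_term[b]))))
    gvif = _gvif(matrix)
    flagged = [t for t, v in gvif.items() if v >= gvif_threshold]
    return CollinearityScreen(sorted(pairs), R, gvif, flagged)


# ---------------------------------------------------------------------------
# All-subsets enumeration and OLS fits


def enumerate_models(
    terms: Sequence[str],
    exclusions: Iterable[tuple[str, str]] = (),
) -> list[tuple[str, ...]]:
    """All term subsets containing no excluded pair, intercept-only first.

    Deterministic order: subsets are generated by size, then by the
    positions of their terms in ``terms``.
    """
    terms = list(terms)
    excl = {tuple(sorted(p)) for p in exclusions}
    unknown = {t for p in excl for t in p} - set(terms)
    if unknown:
        raise ValueError(f"exclusion pairs reference unknown predictors: {sorted(unknown)}")
    models: list[tuple[str, ...]] = []
    for size in range(len(terms) + 1):
        for combo in itertools.combinations(terms, size):
            if any(tuple(sorted(p)) in excl for p in itertools.combinations(combo, 2)):
                continue
            models.append(combo)
    return models


@dataclass
class ModelFit:
    terms: tuple[str, ...]
    coefficients: dict[str, float]  # column → β (intercept under "intercept")
    std_errors: dict[str, float]
    sigma2_ml: float
    log_likelihood: float
    k: int  # parameter count incl. intercept and residual variance
    aic: float
    aicc: float
    akaike_weight: float = math.nan
    _results: object = field(default=None, repr=False, compare=False)


def fit_linear_model(matrix: PredictorMatrix, terms: Sequence[str]) -> ModelFit:
    """OLS with Gaussian likelihood; AICc = AIC + 2k(k+1)/(n−k−1).

    k counts the intercept, every design column, and the residual
    variance.  Raises for singular designs and for n ≤ k.
    """
    terms = tuple(terms)
    cols = [c for t in terms for c in matrix.columns_for(t)]
    X = sm.add_constant(matrix.predictors[cols], has_constant="add") if cols else pd.DataFrame(
        {"const": np.ones(len(matrix.response))}
    )
    n = len(matrix.response)
    k = X.shape[1] + 1  # + residual variance
    if n <= k:
        raise ValueError(f"n = {n} too small for k = {k} parameters")
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        raise ValueError(f"singular design for terms {terms}")
    res = sm.OLS(matrix.response, X).fit()
    ll = float(res.llf)  # Gaussian log-likelihood at the ML variance
    aic = -2.0 * ll + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    coefs = {("intercept" if c == "const" else c): float(v) for c, v in res.params.items()}
    ses = {("intercept" if c == "const" else c): float(v) for c, v in res.bse.items()}
    return ModelFit(
        terms=terms,
        coefficients=coefs,
        std_errors=ses,
        sigma2_ml=float(res.ssr / n),
        log_likelihood=ll,
        k=k,
        aic=aic,
        aicc=aicc,
        _results=res,
    )


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """w_m = exp(−Δ_m/2) / Σ exp(−Δ/2), Δ relative to the minimum AICc."""
    a = np.asarray(aicc_values, float)
    if len(a) == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def fit_all_models(
    matrix: PredictorMatrix,
    exclusions: Iterable[tuple[str, str]] = (),
) -> list[ModelFit]:
    """Fit every candidate subset and attach Akaike weights."""
    fits = [fit_linear_model(matrix, m) for m in enumerate_models(matrix.terms, exclusions)]
    for f, w in zip(fits, akaike_weights([f.aicc for f in fits])):
        f.akaike_weight = float(w)
    return fits


# ---------------------------------------------------------------------------
# Full model averaging


def average_coefficients(fits: Sequence[ModelFit], matrix: PredictorMatrix) -> pd.DataFrame:
    """Full (zero-substitution) model-averaged coefficients.

    β̄_j = Σ_m w_m·β_{j,m} with β = 0 (variance 0) in models excluding
    term j.  The unconditional standard error uses the Burnham–Anderson
    combination se = Σ_m w_m·sqrt(var_m + (β_{j,m} − β̄_j)²); the 95% CI
    is β̄ ± 1.96·se, and relative importance is the summed weight of
    models containing the term.
    """
    w = np.array([f.akaike_weight for f in fits], float)
    if not math.isclose(w.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("model weights must be normalised")
    all_cols = ["intercept"] + [
        c for t in matrix.terms for c in matrix.columns_for(t)
    ]
    col_term = {"intercept": None}
    for t in matrix.terms:
        for c in matrix.columns_for(t):
            col_term[c] = t
    rows = []
    for col in all_cols:
        betas = np.array([f.coefficients.get(col, 0.0) for f in fits])
        ses = np.array([f.std_errors.get(col, 0.0) for f in fits])
        beta_bar = float(np.sum(w * betas))
        se_uncond = float(np.sum(w * np.sqrt(ses**2 + (betas - beta_bar) ** 2)))
        term = col_term[col]
        importance = float(
            np.sum(w[[term in f.terms for f in fits]])
        ) if term is not None else 1.0
        rows.append(
            {
                "coefficient": col,
                "estimate": beta_bar,
                "se": se_uncond,
                "ci_lower": beta_bar - 1.96 * se_uncond,
                "ci_upper": beta_bar + 1.96 * se_uncond,
                "importance": importance,
            }
        )
    return pd.DataFrame(rows)


def selection_table(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """One row per candidate model, ranked by AICc."""
    df = pd.DataFrame(
        [
            {
                "terms": "+".join(f.terms) if f.terms else "(intercept)",
                "k": f.k,
                "log_likelihood": f.log_likelihood,
                "aicc": f.aicc,
                "akaike_weight": f.akaike_weight,
            }
            for f in fits
        ]
    )
    df = df.sort_values("aicc", kind="stable", ignore_index=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    return df


# ---------------------------------------------------------------------------
# Influence diagnostics


def cooks_distance(fit: ModelFit, threshold: float = 1.0) -> pd.DataFrame:
    """Per-observation Cook's distance for an OLS fit, flagging D > 1."""
    if fit._results is None:
        raise ValueError("fit carries no regression results")
    d = OLSInfluence(fit._results).cooks_distance[0]
    return pd.DataFrame(
        {"row": np.arange(len(d)), "cooks_d": d, "flagged": d > threshold}
    )


def model_average(
    matrix: PredictorMatrix,
    r_threshold: float = 0.7,
    gvif_threshold: float = 5.0,
    cooks_threshold: float = 1.0,
) -> dict:
    """Standardise → screen → all-subsets OLS → AICc weights → full average.

    Returns the screen, the fitted models, the selection table, the
    averaged coefficients, and Cook's distances for the global model.
    When influential rows (D > threshold) exist, averaged coefficients
    are also recomputed without them.
    """
    std = standardize_predictors(matrix)
    screen = collinearity_screen(std, r_threshold, gvif_threshold)
    fits = fit_all_models(std, screen.excluded_pairs)
    averaged = average_coefficients(fits, std)
    global_fit = fit_linear_model(std, std.terms)
    cooks = cooks_distance(global_fit, cooks_threshold)
    result = {
        "screen": screen,
        "fits": fits,
        "selection": selection_table(fits),
        "averaged": averaged,
        "cooks": cooks,
        "averaged_without_influential": None,
    }
    if cooks["flagged"].any():
        keep = ~cooks["flagged"].to_numpy()
        sub = PredictorMatrix(
            std.response[keep],
            std.predictors.loc[keep].reset_index(drop=True),
            dict(std.factor_blocks),
            std.standardization,
        )
        sub_fits = fit_all_models(sub, screen.excluded_pairs)
        result["averaged_without_influential"] = average_coefficients(sub_fits, sub)
    return result
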