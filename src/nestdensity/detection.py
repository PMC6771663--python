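"""Conventional distance sampling on binned perpendicular distances.

Nest distances are aggregated into fixed-width distance classes (4 m by
default, truncated at 40 m) and a detection function g(x) — the
probability of detecting a nest at perpendicular distance x, with
g(0) = 1 — is fitted by maximising the multinomial likelihood with cell
probabilities

    π_i = ∫_{bin i} g(x) dx / ∫_0^w g(x) dx.

The candidate set is the six standard key/series combinations: uniform
key with cosine or simple-polynomial adjustments, half-normal key with
cosine or Hermite-polynomial adjustments, and hazard-rate key with
cosine or simple-polynomial adjustments.  Adjustment terms are added
forward (up to 3), keeping the AIC-best count; the best of the six
models by AIC supplies the effective strip width

    ESW = ∫_0^w ĝ(x) dx.

Keys: uniform g(x)=1; half-normal g(x)=exp(−x²/2σ²); hazard-rate
g(x)=1−exp(−(x/σ)^{−b}).  Adjustment series (argument scaled by the
truncation width w, or by σ for Hermite): cosine term j is cos(jπx/w),
simple-polynomial term j is (x/w)^{2j}, Hermite term j is H_{2j}(x/σ).
Series start at order j=1 for the uniform key and j=2 otherwise, the
conventional choice (a first-order term would be redundant with the
key's own scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.polynomial import hermite as nph
from scipy import integrate, optimize, stats

KEYS = ("uniform", "half_normal", "hazard_rate")
ADJUSTMENTS = ("none", "cosine", "simple_poly", "hermite")

#: The six key/adjustment combinations fitted to each stratum.
SIX_MODELS: tuple[tuple[str, str], ...] = (
    ("uniform", "cosine"),
    ("uniform", "simple_poly"),
    ("half_normal", "cosine"),
    ("half_normal", "hermite"),
    ("hazard_rate", "cosine"),
    ("hazard_rate", "simple_poly"),
)

_N_KEY_PARAMS = {"uniform": 0, "half_normal": 1, "hazard_rate": 2}
#: Increase threshold (on a 200-point grid) above which a fitted g(x) is
#: declared non-monotone and excluded from model selection.
_MONOTONE_TOL = 1e-6


class SelectionError(RuntimeError):
    """No converged, monotone detection fit to select from."""


@dataclass(frozen=True)
class BinnedDistances:
    """Histogram of perpendicular distances on half-open bins [lo, hi)."""

    bin_edges_m: np.ndarray
    counts: np.ndarray
    truncation_w_m: float
    n_discarded: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_m, float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "bin_edges_m", edges)
        object.__setattr__(self, "counts", counts)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if edges[0] != 0 or not math.isclose(edges[-1], self.truncation_w_m):
            raise ValueError("bins must span [0, truncation_w_m]")
        if len(counts) != len(edges) - 1 or np.any(counts < 0):
            raise ValueError("counts must be non-negative, one per bin")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def bin_distances(
    distances_m: Iterable[float],
    bin_width_m: float = 4.0,
    truncation_w_m: float = 40.0,
) -> BinnedDistances:
    """Aggregate distances into half-open classes [lo, hi), truncating at w.

    Distances ≥ w (including exactly w, by the half-open convention) are
    counted in ``n_discarded``; sum(counts) + n_discarded equals the
    input size.
    """
    if bin_width_m <= 0:
        raise ValueError("bin_width_m must be positive")
    if truncation_w_m <= 0:
        raise ValueError("truncation_w_m must be positive")
    x = np.asarray(list(distances_m), float)
    if np.any(x < 0):
        raise ValueError("distances must be non-negative")
    n_bins = int(math.ceil(truncation_w_m / bin_width_m - 1e-12))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width_m, truncation_w_m)
    kept = x[x < truncation_w_m]
    counts = np.histogram(kept, bins=edges)[0] if len(kept) else np.zeros(n_bins, int)
    return BinnedDistances(
        bin_edges_m=edges,
        counts=counts.astype(int),
        truncation_w_m=float(truncation_w_m),
        n_discarded=int(len(x) - len(kept)),
    )


# ---------------------------------------------------------------------------
# Detection function evaluation


def _key_fn(key: str, x: np.ndarray, key_params: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, float)
    if key == "uniform":
        return np.ones_like(x)
    if key == "half_normal":
        (sigma,) = key_params
        if sigma <= 0:
            raise ValueError("half-normal scale σ must be positive")
        return np.exp(-(x**2) / (2 * sigma**2))
    if key == "hazard_rate":
        sigma, b = key_params
        if sigma <= 0 or b <= 0:
            raise ValueError("hazard-rate σ and shape b must be positive")
        with np.errstate(divide="ignore", over="ignore"):
            z = np.where(x > 0, (x / sigma) ** (-b), np.inf)
        return -np.expm1(-z)
    raise ValueError(f"unknown key {key!r}")


def _series_orders(key: str, adjustment: str, n_terms: int) -> list[int]:
    start = 1 if key == "uniform" else 2
    return list(range(start, start + n_terms))


def _adjustment_series(
    key: str,
    adjustment: str,
    order: int,
    x: np.ndarray,
    truncation_w_m: float,
    key_params: Sequence[float],
) -> np.ndarray:
    x = np.asarray(x, float)
    if adjustment == "cosine":
        return np.cos(order * np.pi * x / truncation_w_m)
    if adjustment == "simple_poly":
        return (x / truncation_w_m) ** (2 * order)
    if adjustment == "hermite":
        if key == "uniform":
            raise ValueError("Hermite adjustments require a scaled key (σ)")
        sigma = key_params[0]
        coef = np.zeros(2 * order + 1)
        coef[-1] = 1.0
        return nph.hermval(x / sigma, coef)
    raise ValueError(f"unknown adjustment {adjustment!r}")


def _g_unscaled(
    key: str,
    adjustment: str,
    params: Sequence[float],
    x: np.ndarray,
    truncation_w_m: float,
    n_adj_terms: int,
) -> np.ndarray:
    """key(x)·(1 + Σ a_j·series_j(x)), before rescaling to g(0)=1."""
    nk = _N_KEY_PARAMS[key]
    key_params = list(params[:nk])
    coeffs = list(params[nk:nk + n_adj_terms])
    g = _key_fn(key, x, key_params)
    if coeffs:
        adj = np.ones_like(np.asarray(x, float))
        for a, order in zip(coeffs, _series_orders(key, adjustment, len(coeffs))):
            adj = adj + a * _adjustment_series(
                key, adjustment, order, x, truncation_w_m, key_params
            )
        g = g * adj
    return g


def detection_probability(
    key: str,
    params: Sequence[float],
    x_m: float | np.ndarray,
    truncation_w_m: float,
    adjustment: str = "none",
    n_adj_terms: int = 0,
) -> float | np.ndarray:
    """Detection probability g(x), rescaled so that g(0) = 1.

    ``params`` holds the key parameters (σ, and b for hazard-rate)
    followed by ``n_adj_terms`` adjustment coefficients.  Adjusted
    functions can exceed 1 or dip below 0 away from the origin; the
    monotonicity screen in :func:`fit_detection` guards against using
    such shapes.
    """
    scalar = np.isscalar(x_m)
    x = np.atleast_1d(np.asarray(x_m, float))
    g = _g_unscaled(key, adjustment, params, x, truncation_w_m, n_adj_terms)
    g0 = float(
        _g_unscaled(key, adjustment, params, np.array([0.0]), truncation_w_m, n_adj_terms)[0]
    )
    if g0 <= 0:
        raise ValueError("adjustment coefficients give non-positive g(0)")
    g = g / g0
    return float(g[0]) if scalar else g


# ---------------------------------------------------------------------------
# Likelihood


def _gauss_legendre_nodes(edges: np.ndarray, n_nodes: int = 16):
    """Nodes/weights for fixed-order Gauss–Legendre quadrature per bin."""
    z, wts = np.polynomial.legendre.leggauss(n_nodes)
    lo, hi = edges[:-1, None], edges[1:, None]
    nodes = 0.5 * (hi - lo) * z[None, :] + 0.5 * (hi + lo)
    weights = 0.5 * (hi - lo) * wts[None, :]
    return nodes, weights


def cell_probabilities(
    binned: BinnedDistances,
    key: str,
    adjustment: str,
    params: Sequence[float],
    n_adj_terms: int,
    _quad=None,
) -> np.ndarray:
    """π_i = ∫_{bin i} g / ∫_0^w g.  Returns NaN cells if any integral ≤ 0."""
    nodes, weights = _quad if _quad is not None else _gauss_legendre_nodes(binned.bin_edges_m)
    x = np.concatenate([[0.0], nodes.ravel()])
    g_all = _g_unscaled(key, adjustment, params, x, binned.truncation_w_m, n_adj_terms)
    if g_all[0] <= 0:  # sign-flipped adjustment: g(0) must stay positive
        return np.full(binned.n_bins, np.nan)
    g = g_all[1:].reshape(nodes.shape)
    cell = (weights * g).sum(axis=1)
    total = cell.sum()
    if total <= 0 or np.any(cell <= 0):
        return np.full(binned.n_bins, np.nan)
    return cell / total


def binned_log_likelihood(
    binned: BinnedDistances,
    key: str,
    adjustment: str,
    params: Sequence[float],
    n_adj_terms: int = 0,
    _quad=None,
) -> float:
    """Multinomial log-likelihood Σ n_i log π_i (no multinomial constant)."""
    pi = cell_probabilities(binned, key, adjustment, params, n_adj_terms, _quad)
    n = binned.counts
    if np.any(~np.isfinite(pi)) or np.any(pi[n > 0] <= 0):
        return -np.inf
    occupied = n > 0
    return float(np.sum(n[occupied] * np.log(pi[occupied])))


@dataclass(frozen=True)
class DetectionFit:
    key: str
    adjustment: str
    n_adj_terms: int
    params: np.ndarray
    log_likelihood: float
    n_params: int
    aic: float
    esw_m: float
    truncation_w_m: float
    gof_chi2: float = math.nan
    gof_df: int = 0
    gof_p: float = math.nan
    monotone_ok: bool = True
    converged: bool = True
    at_boundary: bool = False

    def g(self, x_m):
        """Fitted detection probability, g(0) = 1."""
        return detection_probability(
            self.key, self.params, x_m, self.truncation_w_m,
            self.adjustment, self.n_adj_terms,
        )


def effective_strip_width(fit: DetectionFit, truncation_w_m: float | None = None) -> float:
    """ESW = ∫_0^w ĝ(x) dx by adaptive quadrature (relative tol 1e-8)."""
    w = fit.truncation_w_m if truncation_w_m is None else truncation_w_m
    esw, _ = integrate.quad(
        lambda x: float(fit.g(x)), 0.0, w, epsrel=1e-8, limit=200
    )
    return esw


def _monotone_ok(fit_like: Callable[[np.ndarray], np.ndarray], w: float) -> bool:
    grid = np.linspace(0.0, w, 200)
    try:
        g = np.asarray(fit_like(grid), float)
    except ValueError:  # e.g. adjusted shape with non-positive g(0)
        return False
    return bool(np.all(np.diff(g) <= _MONOTONE_TOL)) and bool(np.all(g >= -_MONOTONE_TOL))


# -- optimisation -----------------------------------------------------------

_LOG_SIGMA_SPAN = (math.log(1e-2), math.log(10.0))  # relative to w
_LOG_B_SPAN = (math.log(0.2), math.log(50.0))


def _pack(key: str, params: np.ndarray) -> np.ndarray:
    """Natural → optimiser scale (log for σ and b, raw for coefficients)."""
    nk = _N_KEY_PARAMS[key]
    out = np.array(params, float)
    out[:nk] = np.log(out[:nk])
    return out


def _unpack(key: str, theta: np.ndarray) -> np.ndarray:
    nk = _N_KEY_PARAMS[key]
    out = np.array(theta, float)
    out[:nk] = np.exp(out[:nk])
    return out


def _fit_at_n_terms(
    binned: BinnedDistances,
    key: str,
    adjustment: str,
    n_terms: int,
    starts: Sequence[np.ndarray],
    quad,
) -> tuple[np.ndarray, float, bool, bool]:
    """Maximise the binned likelihood; returns (params, ll, converged, at_boundary)."""
    w = binned.truncation_w_m
    nk = _N_KEY_PARAMS[key]

    def nll(theta: np.ndarray) -> float:
        params = _unpack(key, theta)
        ll = binned_log_likelihood(binned, key, adjustment, params, n_terms, quad)
        return 1e12 if not np.isfinite(ll) else -ll

    bounds: list[tuple[float, float]] = []
    if nk >= 1:
        bounds.append((_LOG_SIGMA_SPAN[0] + math.log(w), _LOG_SIGMA_SPAN[1] + math.log(w)))
    if nk == 2:
        bounds.append(_LOG_B_SPAN)
    bounds.extend([(-5.0, 5.0)] * n_terms)

    best = None
    for x0 in starts:
        if len(bounds) == 0:  # uniform key, no adjustments: nothing to fit
            return np.empty(0), -nll(np.empty(0)), True, False
        res = optimize.minimize(
            nll, _pack(key, x0), method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = _unpack(key, best.x)
    at_boundary = any(
        min(x - lo, hi - x) < 1e-6 for x, (lo, hi) in zip(best.x, bounds[:nk])
    )
    converged = bool(best.success) and best.fun < 1e11
    return params, -best.fun, converged, at_boundary


def _default_starts(key: str, w: float, n_terms: int) -> list[np.ndarray]:
    """Five deterministic multi-starts over a log-spaced σ grid."""
    sigmas = np.geomspace(w / 20.0, w, 5)
    starts = []
    if key == "uniform":
        starts.append(np.zeros(n_terms))
    elif key == "half_normal":
        for s in sigmas:
            starts.append(np.concatenate([[s], np.zeros(n_terms)]))
    else:
        for s in sigmas:
            starts.append(np.concatenate([[s, 2.0], np.zeros(n_terms)]))
    return starts


def fit_detection(
    binned: BinnedDistances,
    key: str,
    adjustment: str = "none",
    max_adj_terms: int = 3,
) -> DetectionFit:
    """Fit one key/series family, forward-selecting adjustment terms by AIC.

    Terms are added one at a time (0..max_adj_terms), each new fit warm-
    started from the previous solution with the new coefficient at zero;
    the AIC-best term count is kept.  A failed optimisation yields a
    flagged (``converged=False``) result rather than an exception.
    """
    if binned.total < 1:
        raise ValueError("need at least one binned observation to fit")
    if key not in KEYS:
        raise ValueError(f"unknown key {key!r}")
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    if adjustment == "hermite" and key == "uniform":
        raise ValueError("Hermite adjustments require a scaled key")
    w = binned.truncation_w_m
    quad = _gauss_legendre_nodes(binned.bin_edges_m)
    max_terms = 0 if adjustment == "none" else max_adj_terms

    best: dict | None = None
    prev_params: np.ndarray | None = None
    for n_terms in range(max_terms + 1):
        if n_terms == 0:
            starts = _default_starts(key, w, 0)
        else:
            starts = [np.concatenate([prev_params, [0.0]])]
        params, ll, converged, at_boundary = _fit_at_n_terms(
            binned, key, adjustment, n_terms, starts, quad
        )
        n_params = _N_KEY_PARAMS[key] + n_terms
        aic = -2.0 * ll + 2.0 * n_params
        prev_params = params
        if converged and (best is None or aic < best["aic"] - 1e-9):
            best = dict(
                params=params, ll=ll, aic=aic, n_terms=n_terms,
                n_params=n_params, at_boundary=at_boundary,
            )
    if best is None:  # no term count converged
        n_params = _N_KEY_PARAMS[key]
        fit = DetectionFit(
            key=key, adjustment=adjustment, n_adj_terms=0,
            params=np.array(prev_params if prev_params is not None else []),
            log_likelihood=-math.inf, n_params=n_params, aic=math.inf,
            esw_m=math.nan, truncation_w_m=w,
            monotone_ok=False, converged=False,
        )
        return fit

    fit = DetectionFit(
        key=key,
        adjustment=adjustment if best["n_terms"] > 0 else adjustment,
        n_adj_terms=best["n_terms"],
        params=best["params"],
        log_likelihood=best["ll"],
        n_params=best["n_params"],
        aic=best["aic"],
        esw_m=math.nan,
        truncation_w_m=w,
        at_boundary=best["at_boundary"],
        converged=True,
    )
    monotone = _monotone_ok(fit.g, w)
    # a scaled key fitted to a single occupied bin has no interior maximum:
    # the likelihood plateaus as σ shrinks, so the scale is not identified
    at_boundary = fit.at_boundary or (
        _N_KEY_PARAMS[key] > 0 and int(np.count_nonzero(binned.counts)) == 1
    )
    esw = effective_strip_width(fit) if monotone else math.nan
    chi2, df, p = gof_chisquare(fit, binned)
    return replace(
        fit, esw_m=esw, monotone_ok=monotone, at_boundary=at_boundary,
        gof_chi2=chi2, gof_df=df, gof_p=p,
    )


def fit_six_models(binned: BinnedDistances, max_adj_terms: int = 3) -> list[DetectionFit]:
    """Fit the standard six key/adjustment combinations."""
    return [fit_detection(binned, k, a, max_adj_terms) for k, a in SIX_MODELS]


def select_best_model(fits: Iterable[DetectionFit]) -> DetectionFit:
    """Minimum-AIC fit among converged, monotone candidates.

    Ties within ΔAIC < 1e-6 go to the fewest parameters, then to the
    fixed key order uniform < half-normal < hazard-rate.
    """
    valid = [f for f in fits if f.converged and f.monotone_ok and np.isfinite(f.aic)]
    if not valid:
        raise SelectionError("no converged, monotone detection fit available")
    key_rank = {k: i for i, k in enumerate(KEYS)}
    best_aic = min(f.aic for f in valid)
    contenders = [f for f in valid if f.aic < best_aic + 1e-6]
    contenders.sort(key=lambda f: (f.n_params, key_rank[f.key]))
    return contenders[0]


def gof_chisquare(fit: DetectionFit, binned: BinnedDistances) -> tuple[float, int, float]:
    """Pearson χ² goodness of fit on the binned data.

    Bins whose expected count falls below 0.5 are merged rightward
    (a trailing small group folds into its neighbour on the left);
    df = used bins − 1 − n_params, floored at 1.
    """
    pi = cell_probabilities(
        binned, fit.key, fit.adjustment, fit.params, fit.n_adj_terms
    )
    expected = pi * binned.total
    observed = binned.counts.astype(float)
    exp_groups: list[float] = []
    obs_groups: list[float] = []
    acc_e = acc_o = 0.0
    for e, o in zip(expected, observed):
        acc_e += e
        acc_o += o
        if acc_e >= 0.5:
            exp_groups.append(acc_e)
            obs_groups.append(acc_o)
            acc_e = acc_o = 0.0
    if acc_e > 0 or acc_o > 0:
        if exp_groups:
            exp_groups[-1] += acc_e
            obs_groups[-1] += acc_o
        else:
            exp_groups.append(acc_e)
            obs_groups.append(acc_o)
    exp_arr = np.array(exp_groups)
    obs_arr = np.array(obs_groups)
    chi2 = float(np.sum((obs_arr - exp_arr) ** 2 / exp_arr))
    df = max(len(exp_arr) - 1 - fit.n_params, 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def fits_table(fits: Iterable[DetectionFit]):
    """Model-comparison table (one row per fitted key/series family)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "key": f.key,
                "adjustment": f.adjustment,
                "n_adj_terms": f.n_adj_terms,
                "n_params": f.n_params,
                "log_likelihood": f.log_likelihood,
                "aic": f.aic,
                "esw_m": f.esw_m,
                "gof_chi2": f.gof_chi2,
                "gof_df": f.gof_df,
                "gof_p": f.gof_p,
                "monotone_ok": f.monotone_ok,
                "converged": f.converged,
                "at_boundary": f.at_boundary,
            }
            for f in fits
        ]
    )
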