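"""Independent brute-force oracles shared across test modules.

These deliberately avoid the package's own code paths: explicit subset
enumeration, raw least squares via numpy, and the textbook AICc /
Akaike-weight / zero-substitution formulas written out directly.
"""

import itertools
import math

import numpy as np
import pandas as pd


def brute_force_average(y, X: pd.DataFrame) -> dict:
    """Full model-averaged (estimate, unconditional se, importance) per column."""
    y = np.asarray(y, float)
    n = len(y)
    cols = list(X.columns)
    models = []
    for size in range(len(cols) + 1):
        models.extend(itertools.combinations(cols, size))
    results = []
    for terms in models:
        D = np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in terms])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta
        s2_ml = resid @ resid / n
        ll = -0.5 * n * (math.log(2 * math.pi * s2_ml) + 1)
        k = D.shape[1] + 1
        aicc = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        cov = s2_ml * n / (n - D.shape[1]) * np.linalg.inv(D.T @ D)
        results.append(
            (
                terms,
                dict(zip(("intercept",) + terms, beta)),
                dict(zip(("intercept",) + terms, np.sqrt(np.diag(cov)))),
                aicc,
            )
        )
    aiccs = np.array([r[3] for r in results])
    w = np.exp(-(aiccs - aiccs.min()) / 2)
    w /= w.sum()
    out = {}
    for col in ["intercept"] + cols:
        betas = np.array([r[1].get(col, 0.0) for r in results])
        ses = np.array([r[2].get(col, 0.0) for r in results])
        bbar = float(np.sum(w * betas))
        se = float(np.sum(w * np.sqrt(ses**2 + (betas - bbar) ** 2)))
        imp = (
            1.0
            if col == "intercept"
            else float(sum(wi for wi, r in zip(w, results) if col in r[1]))
        )
        out[col] = (bbar, se, imp)
    return out


def sample_half_normal_distances(rng, sigma: float, n: int, strip_m: float = 60.0):
    """Detected perpendicular distances under uniform placement + half-normal
    thinning, by rejection; returns exactly n distances."""
    out = []
    while len(out) < n:
        x = rng.uniform(0, strip_m, 4 * n)
        kept = x[rng.uniform(size=len(x)) < np.exp(-(x**2) / (2 * sigma**2))]
        out.extend(kept.tolist())
    return np.array(out[:n])
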