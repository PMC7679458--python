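"""Significance and feature-level inference for the prediction model.

Three procedures:

* **Permutation MSE null** — scores are randomly re-paired with
  participants; the full stratified k-fold fit (folds re-stratified on the
  permuted scores, alpha fixed at alpha*) is re-run per permutation and the
  out-of-fold MSE recorded. The p-value is the proportion of permuted MSEs
  less than or equal to the observed one (optionally with the (c+1)/(P+1)
  correction that avoids p = 0).
* **Bootstrap edge identification** — participants are resampled with
  replacement B times (default 1000); a ridge model at alpha* is fit on
  each full resample; an edge "contributes" when the percentile confidence
  interval of its weight (default 99%) lies entirely above or below zero.
* **Residual specificity** — state scores are regressed on trait scores by
  OLS and the connectivity model is asked to predict the residuals,
  checking that predictive signal is state-specific rather than shared
  with trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .connectome import edge_table
from .errors import InputError
from .prediction import (
    CVConfig,
    ModelResult,
    cv_mse_fixed_alpha,
    fit_predict_cv,
    stratified_folds,
    _fit_fold,
)


@dataclass
class PermutationResult:
    real_mse: float
    permuted_mse: np.ndarray
    p_value: float
    n_permutations: int
    convention: str = "proportion"

    @property
    def permuted_mean(self) -> float:
        return float(np.mean(self.permuted_mse))

    def summary(self) -> dict:
        q = np.percentile(self.permuted_mse, [2.5, 50, 97.5])
        return {
            "real_mse": self.real_mse,
            "permuted_mean_mse": self.permuted_mean,
            "permuted_mse_q025": float(q[0]),
            "permuted_mse_median": float(q[1]),
            "permuted_mse_q975": float(q[2]),
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    alpha_star: float,
    n_permutations: int = 10_000,
    cfg: CVConfig | None = None,
    seed: int = 0,
    real_mse: float | None = None,
    add_one: bool = False,
) -> PermutationResult:
    """Permutation null of the k-fold prediction MSE at fixed alpha*.

    Each permutation re-pairs scores with participants, re-stratifies the
    folds on the permuted scores (stratification is part of the pipeline
    under test) and records the concatenated out-of-fold MSE.
    """
    cfg = cfg or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cfg.validate(n_samples=y.size)
    if n_permutations < 1:
        raise InputError("n_permutations must be >= 1")
    if alpha_star <= 0:
        raise InputError("alpha_star must be > 0")
    if real_mse is None:
        folds = stratified_folds(y, cfg.n_folds, cfg.seed)
        real_mse = cv_mse_fixed_alpha(X, y, folds, alpha_star, cfg.standardize)
    rng = np.random.default_rng(seed)
    perm_mse = np.empty(n_permutations)
    for b in range(n_permutations):
        y_perm = y[rng.permutation(y.size)]
        folds = stratified_folds(
            y_perm, cfg.n_folds, seed=int(rng.integers(0, 2**31 - 1))
        )
        perm_mse[b] = cv_mse_fixed_alpha(X, y_perm, folds, alpha_star, cfg.standardize)
    count = int(np.sum(perm_mse <= real_mse))
    if add_one:
        p = (count + 1) / (n_permutations + 1)
    else:
        p = count / n_permutations
    return PermutationResult(
        real_mse=float(real_mse),
        permuted_mse=perm_mse,
        p_value=float(p),
        n_permutations=n_permutations,
        convention="add_one" if add_one else "proportion",
    )


@dataclass
class BootstrapEdgeTable:
    """Per-edge bootstrap summary; ``table`` rows follow the canonical edge order."""

    table: pd.DataFrame
    n_bootstrap: int
    level: float
    alpha_star: float
    n_redrawn: int = 0

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def _bca_interval(W, full_w, jack_w, level):
    """Bias-corrected and accelerated percentile bounds per column."""
    from scipy.stats import norm

    B = W.shape[0]
    prop = np.clip((W < full_w).mean(axis=0), 1.0 / (B + 1), B / (B + 1.0))
    z0 = norm.ppf(prop)
    jd = jack_w.mean(axis=0) - jack_w
    denom = (jd**2).sum(axis=0) ** 1.5
    accel = np.where(denom > 0, (jd**3).sum(axis=0) / np.where(denom > 0, 6 * denom, 1), 0.0)
    alpha_half = (100.0 - level) / 200.0
    lo_hi = []
    for z_a in (norm.ppf(alpha_half), norm.ppf(1 - alpha_half)):
        adj = norm.cdf(z0 + (z0 + z_a) / (1 - accel * (z0 + z_a)))
        q = np.clip(adj * 100.0, 0.0, 100.0)
        lo_hi.append(
            np.array([np.percentile(W[:, e], q[e]) for e in range(W.shape[1])])
        )
    return lo_hi[0], lo_hi[1]


def bootstrap_edges(
    X: np.ndarray,
    y: np.ndarray,
    alpha_star: float,
    n_channels: int,
    n_bootstrap: int = 1000,
    level: float = 99.0,
    seed: int = 0,
    standardize: bool = False,
    ci_method: str = "percentile",
) -> BootstrapEdgeTable:
    """Bootstrap CIs of every edge weight; CI-excludes-zero rule.

    Each of the B resamples (participants drawn with replacement) gets one
    ridge model at alpha* fit on the full resample. A degenerate resample
    (zero target variance) is redrawn and counted. ``ci_method`` selects
    plain percentile bounds (default) or bias-corrected accelerated (BCa)
    bounds with a jackknife acceleration estimate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_bootstrap < 2:
        raise InputError("n_bootstrap must be >= 2")
    if not 0 < level < 100:
        raise InputError("level must be a percentage in (0, 100)")
    if ci_method not in ("percentile", "bca"):
        raise InputError(f"unknown ci_method {ci_method!r}")
    N = y.size
    rng = np.random.default_rng(seed)
    W = np.empty((n_bootstrap, X.shape[1]))
    n_redrawn = 0
    for b in range(n_bootstrap):
        while True:
            idx = rng.integers(0, N, N)
            if np.std(y[idx]) > 0:
                break
            n_redrawn += 1
        w, _, _ = _fit_fold(X[idx], y[idx], X[:1], alpha_star, standardize)
        W[b] = w
    mean_w = W.mean(axis=0)
    full_w, _, _ = _fit_fold(X, y, X[:1], alpha_star, standardize)
    if ci_method == "bca":
        jack = np.empty((N, X.shape[1]))
        keep = np.ones(N, dtype=bool)
        for i in range(N):
            keep[i] = False
            jack[i], _, _ = _fit_fold(X[keep], y[keep], X[:1], alpha_star, standardize)
            keep[i] = True
        lo, hi = _bca_interval(W, full_w, jack, level)
    else:
        half = (100.0 - level) / 2.0
        lo = np.percentile(W, half, axis=0)
        hi = np.percentile(W, 100.0 - half, axis=0)
    significant = (lo > 0) | (hi < 0)
    tab = edge_table(n_channels)
    tab["weight"] = mean_w
    tab["weight_full_sample"] = full_w
    tab["ci_low"] = lo
    tab["ci_high"] = hi
    tab["significant"] = significant
    tab["sign"] = np.where(mean_w >= 0, "positive", "negative")
    return BootstrapEdgeTable(
        table=tab,
        n_bootstrap=n_bootstrap,
        level=level,
        alpha_star=alpha_star,
        n_redrawn=n_redrawn,
    )


def residual_specificity(
    X: np.ndarray, state: np.ndarray, trait: np.ndarray, cfg: CVConfig | None = None
) -> ModelResult:
    """Predict the residuals of state regressed on trait (OLS with intercept).

    A positive out-of-fold r on the residual target shows the connectivity
    model captures state-specific variance not shared with trait.
    """
    state = np.asarray(state, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if trait.std() == 0:
        raise InputError("trait has zero variance; cannot regress state on trait")
    resid = sm.OLS(state, sm.add_constant(trait)).fit().resid
    if np.std(resid) <= 1e-10 * max(np.std(state), 1e-30):
        raise InputError("state is an exact linear function of trait; residuals degenerate")
    return fit_predict_cv(X, resid, cfg, target="residual")
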