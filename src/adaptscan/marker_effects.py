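"""Ridge-regression BLUP of marker effects for the fitness-proxy trait.

Model: y = 1*mu + X g + e with marker effects g ~ N(0, sigma2_g I) and
residuals e ~ N(0, sigma2_e I); X is the genotype matrix coded {-1, 0, +1}
(0 = heterozygote) with mean-imputed missing values. Variance components are
estimated by REML through a spectral decomposition of the marker
cross-product K = X X' (single random effect, so the restricted likelihood
is a one-dimensional function of lambda = sigma2_e / sigma2_g), after which
the effects are the ridge/BLUP solution at that lambda:

    g = X' (K + lambda I)^-1 (y - 1 mu),   mu = GLS intercept.

This is the standard single-kernel mixed-model solver (exact and
deterministic, O(n^3) in the number of phenotyped plants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exceptions import ConfigurationError, DegenerateFitError


@dataclass
class MarkerEffectModel:
    """Fitted ridge-BLUP model."""

    mu: float
    effects: np.ndarray
    sigma2_g: float
    sigma2_e: float
    lam: float
    marker_ids: np.ndarray
    training_ids: list = field(default_factory=list)

    def predict(self, coded: np.ndarray) -> np.ndarray:
        return self.mu + np.asarray(coded, float) @ self.effects


def prepare_matrix(dosages: np.ndarray, marker_ids=None, max_missing: float = 0.5):
    """Code dosages {0,1,2} as {-1,0,+1}, filter and impute missing markers.

    Markers with a missing fraction strictly greater than ``max_missing`` are
    removed; remaining missing entries are imputed with the marker's mean
    coded value. Returns (coded matrix, retained marker ids, retained mask).
    """
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if marker_ids is None:
        marker_ids = np.arange(m)
    marker_ids = np.asarray(marker_ids)
    coded = dosages - 1.0
    missing_frac = np.isnan(coded).mean(axis=0)
    keep = missing_frac <= max_missing
    if not keep.any():
        raise DegenerateFitError("all markers exceed the missingness threshold")
    coded = coded[:, keep]
    col_mean = np.nanmean(coded, axis=0)
    idx = np.where(np.isnan(coded))
    coded[idx] = col_mean[idx[1]]
    return coded, marker_ids[keep], keep


def train_split(sample_ids, fraction: float = 0.6, rng=None):
    """Uniform random train/holdout split; training size = round(fraction*n)."""
    if not (0 < fraction < 1):
        raise ConfigurationError("fraction must lie in (0,1)")
    ids = list(sample_ids)
    if len(ids) < 5:
        raise ConfigurationError("need at least 5 samples to split")
    rng = rng or np.random.default_rng(0)
    n_train = int(round(fraction * len(ids)))
    perm = rng.permutation(len(ids))
    train = [ids[i] for i in sorted(perm[:n_train])]
    hold = [ids[i] for i in sorted(perm[n_train:])]
    return train, hold


def z_transform(y: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit variance; errors on constant input."""
    y = np.asarray(y, dtype=float)
    sd = y.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateFitError("trait has zero variance")
    return (y - y.mean()) / sd


def ridge_solve(coded: np.ndarray, y: np.ndarray, lam: float):
    """Dual-form ridge solution at fixed lambda: GLS intercept and effects."""
    X = np.asarray(coded, float)
    y = np.asarray(y, float)
    n = len(y)
    K = X @ X.T
    Vinv = np.linalg.inv(K + lam * np.eye(n))
    ones = np.ones(n)
    mu = float(ones @ Vinv @ y) / float(ones @ Vinv @ ones)
    g = X.T @ (Vinv @ (y - mu))
    return mu, g


def _reml_profile(theta: np.ndarray, eta2: np.ndarray):
    """Restricted log-likelihood profile in lambda (up to a constant)."""
    q = len(theta)

    def neg_ll(log_lam):
        lam = np.exp(log_lam)
        d = theta + lam
        return float(np.sum(np.log(d)) + q * np.log(np.sum(eta2 / d)))

    return neg_ll


def fit_ridge_blup(coded: np.ndarray, y: np.ndarray, marker_ids=None,
                   training_ids=None) -> MarkerEffectModel:
    """REML variance components + BLUP marker effects.

    ``y`` must already be Z-transformed by the caller (standardization is an
    explicit, separate step). Eigen-decomposes S (K + I) S with S the
    intercept-projection, profiles the restricted likelihood over lambda on
    the non-null eigenvalues, then solves the dual ridge system.
    """
    X = np.asarray(coded, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < 3:
        raise DegenerateFitError("need at least 3 samples")
    if X.shape[0] != n:
        raise ConfigurationError("genotype matrix and trait length differ")
    if y.std(ddof=1) == 0:
        raise DegenerateFitError("trait has zero variance")
    if marker_ids is None:
        marker_ids = np.arange(X.shape[1])

    K = X @ X.T
    S = np.eye(n) - np.full((n, n), 1.0 / n)
    # offset by +I keeps the decomposition positive; subtracted back below
    vals, vecs = np.linalg.eigh(S @ (K + np.eye(n)) @ S)
    # drop the null direction spanned by the intercept (smallest eigenvalue)
    theta = np.clip(vals[1:] - 1.0, 0.0, None)
    eta = vecs[:, 1:].T @ y
    eta2 = eta**2

    neg_ll = _reml_profile(theta, eta2)
    res = minimize_scalar(neg_ll, bounds=(np.log(1e-8), np.log(1e8)),
                          method="bounded", options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    sigma2_g = float(np.sum(eta2 / (theta + lam)) / len(theta))
    sigma2_e = lam * sigma2_g
    mu, g = ridge_solve(X, y, lam)
    return MarkerEffectModel(
        mu=mu,
        effects=g,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        lam=lam,
        marker_ids=np.asarray(marker_ids),
        training_ids=list(training_ids) if training_ids is not None else [],
    )


def cross_replicate_retain(model_a: MarkerEffectModel,
                           model_b: MarkerEffectModel) -> np.ndarray:
    """Markers with a finite nonzero effect in BOTH replicate models.

    Ridge effects are generically nonzero, so this is a presence criterion:
    it removes markers filtered out (missingness) in either replicate, not
    markers whose effect signs disagree.
    """
    def present(model):
        ok = np.isfinite(model.effects) & (model.effects != 0.0)
        return set(np.asarray(model.marker_ids)[ok].tolist())

    kept = present(model_a) & present(model_b)
    ids_a = [m for m in np.asarray(model_a.marker_ids).tolist() if m in kept]
    return np.asarray(ids_a, dtype=model_a.marker_ids.dtype)


def effects_frame(models: dict) -> pd.DataFrame:
    """Long-format export of per-replicate marker effects.

    ``models`` maps (treatment, replicate) -> MarkerEffectModel.
    """
    rows = []
    for (treatment, replicate), model in models.items():
        rows.append(pd.DataFrame({
            "marker_id": model.marker_ids,
            "treatment": treatment,
            "replicate": replicate,
            "effect": model.effects,
        }))
    return pd.concat(rows, ignore_index=True)
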