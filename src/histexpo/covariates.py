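"""Geographic-covariate pruning and partial-least-squares dimension reduction.

Hundreds of geographic variables (traffic, land use, emissions, elevation,
vegetation) are far too many to enter a kriging mean directly.  They are
first pruned of uninformative columns and then reduced to a small number of
PLS scores: linear combinations chosen to maximize covariance with the
response (site-level long-term mean, and re-used for the trend coefficient).
Two scores are the default throughout the model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["prune_covariates", "PLSScores"]


def prune_covariates(covariates: pd.DataFrame, max_mode_freq: float = 0.85,
                     min_sd: float = 0.0) -> pd.DataFrame:
    """Drop uninformative geographic variables.

    A variable is removed when it has any missing value, when its standard
    deviation is below ``min_sd`` (constants always go), or when its most
    frequent value occurs in more than ``max_mode_freq`` of sites.  Column
    order of the survivors is preserved.
    """
    if covariates.shape[1] == 0:
        raise ValueError("covariate table has no variables")
    n = len(covariates)
    keep = []
    for col in covariates.columns:
        x = covariates[col]
        if x.isna().any():
            continue
        sd = float(x.std(ddof=1)) if n > 1 else 0.0
        if sd < min_sd or sd == 0.0:
            continue
        if x.value_counts().iloc[0] / n > max_mode_freq:
            continue
        keep.append(col)
    if not keep:
        raise ValueError("all covariates were pruned; loosen the thresholds")
    return covariates[keep]


class PLSScores(TransformerMixin, BaseEstimator):
    """Deterministic NIPALS partial least squares producing site scores.

    Variables are standardized (mean 0, sd 1 with ddof=1) and the response is
    centered before extraction.  The first weight vector is proportional to
    the covariance between the standardized variables and the centered
    response; subsequent components are extracted after rank-one deflation of
    X.  Training scores have mutually orthogonal columns.  Signs are fixed so
    that the largest-magnitude entry of each weight vector is positive, making
    fits reproducible across platforms.

    New locations are projected with the rotation ``R = W (P'W)^{-1}``, which
    reproduces the training scores exactly on the training rows.

    Parameters
    ----------
    n_components : int, default 2
        Number of score columns k.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D and aligned with y")
        k = int(self.n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        self.center_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ValueError("constant covariate column; prune before fitting")
        self.scale_ = sd
        self.response_center_ = float(y.mean())
        Xc = (X - self.center_) / self.scale_
        yc = y - self.response_center_

        n, p = Xc.shape
        W = np.zeros((p, k))
        P = np.zeros((p, k))
        T = np.zeros((n, k))
        Xd, yd = Xc.copy(), yc.copy()
        for j in range(k):
            w = Xd.T @ yd
            nw = np.linalg.norm(w)
            if nw < 1e-12 * max(1.0, np.linalg.norm(yd)) or nw == 0.0:
                raise ValueError(f"rank deficiency: no covariance left for component {j + 1}")
            w /= nw
            if w[np.argmax(np.abs(w))] < 0:
                w = -w
            t = Xd @ w
            tt = t @ t
            if tt <= 1e-12:
                raise ValueError(f"rank deficiency: degenerate scores at component {j + 1}")
            p_j = Xd.T @ t / tt
            q_j = yd @ t / tt
            Xd = Xd - np.outer(t, p_j)
            yd = yd - q_j * t
            W[:, j], P[:, j], T[:, j] = w, p_j, t
        self.weights_ = W
        self.loadings_ = P
        self.rotation_ = W @ np.linalg.inv(P.T @ W)
        self.feature_names_in_ = names
        self.scores_ = T
        return self

    def _align(self, X):
        if isinstance(X, pd.DataFrame) and self.feature_names_in_ is not None:
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise KeyError(f"covariates missing fitted variables: {missing}")
            X = X[self.feature_names_in_]
        return np.asarray(X, dtype=float)

    def transform(self, X):
        """Project covariates to the k score columns (name-aligned for DataFrames)."""
        check_is_fitted(self, "weights_")
        X = self._align(X)
        return (X - self.center_) / self.scale_ @ self.rotation_

    def to_dict(self) -> dict:
        check_is_fitted(self, "weights_")
        return {
            "n_components": int(self.n_components),
            "center": self.center_.tolist(),
            "scale": self.scale_.tolist(),
            "weights": self.weights_.tolist(),
            "loadings": self.loadings_.tolist(),
            "response_center": self.response_center_,
            "feature_names": self.feature_names_in_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSScores":
        m = cls(n_components=d["n_components"])
        m.center_ = np.asarray(d["center"], dtype=float)
        m.scale_ = np.asarray(d["scale"], dtype=float)
        m.weights_ = np.asarray(d["weights"], dtype=float)
        m.loadings_ = np.asarray(d["loadings"], dtype=float)
        m.rotation_ = m.weights_ @ np.linalg.inv(m.loadings_.T @ m.weights_)
        m.response_center_ = float(d["response_center"])
        m.feature_names_in_ = d.get("feature_names")
        return m
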