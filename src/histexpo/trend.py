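"""Temporal trend basis: SVD estimation and historical back-extrapolation.

The model assumes a single shared temporal pattern f(t); each site scales it
by a coefficient beta(s).  Over the monitored years (1999-2010) f is the
first singular vector of the site x year matrix of row-centered log annual
averages, restricted to sites with long series and computed with iterative
rank-one imputation of the missing cells.  Before 1999 no dense PM2.5
network exists, so f is extended by one of three strategies:

* ``pm25_extrapolated`` — straight-line extrapolation of the monitored trend;
* ``sulfate_proxy`` — a sulfate-network trend (observed from 1987), affinely
  calibrated to f on the overlap years, with a linear tail before 1987;
* ``visibility_proxy`` — a visual-range trend observed over the whole window,
  affinely calibrated the same way.

All three share the monitored-years trend exactly; they differ only before
the dense network begins.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "TrendBasis",
    "site_year_matrix",
    "estimate_trend_svd",
    "extend_trend_linear",
    "extend_trend_proxy",
]

TREND_SOURCES = ("pm25_extrapolated", "sulfate_proxy", "visibility_proxy")


@dataclasses.dataclass
class TrendBasis:
    """A temporal basis defined at every year of the study window.

    ``f`` is aligned with ``years`` and has no missing entries; over the
    monitored span it equals the primary SVD trend by construction.
    ``calib_intercept``/``calib_slope`` record the affine map applied to a
    proxy trend (0 and 1 for the extrapolation approach).
    """

    years: np.ndarray
    f: np.ndarray
    source: str
    calib_intercept: float = 0.0
    calib_slope: float = 1.0

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.f = np.asarray(self.f, dtype=float)
        if len(self.years) != len(self.f):
            raise ValueError("years and f lengths differ")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("trend basis has non-finite values")

    def value(self, years) -> np.ndarray:
        """f evaluated at the requested years (error outside the range)."""
        years = np.atleast_1d(np.asarray(years, dtype=int))
        idx = np.searchsorted(self.years, years)
        bad = (idx >= len(self.years)) | (self.years[np.clip(idx, 0, len(self.years) - 1)] != years)
        if np.any(bad):
            raise ValueError(f"years outside trend range: {years[bad].tolist()}")
        return self.f[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years, "f": self.f, "source": self.source,
            "calib_intercept": self.calib_intercept, "calib_slope": self.calib_slope,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrendBasis":
        df = df.sort_values("year")
        return cls(years=df["year"].to_numpy(), f=df["f"].to_numpy(),
                   source=str(df["source"].iloc[0]),
                   calib_intercept=float(df["calib_intercept"].iloc[0]),
                   calib_slope=float(df["calib_slope"].iloc[0]))


def site_year_matrix(annual: pd.DataFrame, years: list[int] | None = None,
                     log_scale: bool = True, min_years: int | None = None,
                     scale: str | None = None) -> pd.DataFrame:
    """Pivot QC'd annual records to a site x year matrix (NaN where unobserved).

    Only ``included`` records enter.  Rows with ``min_years`` or fewer
    observed entries are dropped (strictly-greater eligibility: the default
    for the 12 monitored years is > 6).  When ``min_years`` is None, half the
    year span is used.  ``scale`` is "log" (default), "raw", or "inverse"
    (reciprocal, supporting extinction ~ 1 / visual range for visibility
    proxies); the legacy ``log_scale`` flag maps to log/raw.
    """
    if scale is None:
        scale = "log" if log_scale else "raw"
    df = annual.loc[annual.get("included", True).astype(bool)] if "included" in annual else annual
    if years is not None:
        df = df.loc[df["year"].isin(years)]
    mat = df.pivot_table(index="site_id", columns="year", values="value", aggfunc="mean")
    if years is not None:
        mat = mat.reindex(columns=sorted(years))
    if scale in ("log", "inverse"):
        if (mat <= 0).any().any():
            raise ValueError(f"non-positive annual averages cannot use scale={scale!r}")
        mat = np.log(mat) if scale == "log" else 1.0 / mat
    elif scale != "raw":
        raise ValueError("scale must be 'log', 'raw' or 'inverse'")
    if min_years is None:
        min_years = mat.shape[1] // 2
    mat = mat.loc[mat.notna().sum(axis=1) > min_years]
    return mat


def estimate_trend_svd(matrix: pd.DataFrame | np.ndarray, max_iter: int = 200,
                       tol: float = 1e-8, smooth_df: int | None = None) -> np.ndarray:
    """First temporal singular vector of an incomplete site x year matrix.

    Each row (site) is centered on its own observed mean, missing cells are
    filled iteratively by alternating a rank-one SVD reconstruction with
    re-imputation, and the returned vector is the first right singular vector
    scaled by ``s1 / sqrt(n_sites)`` so it carries the amplitude of a typical
    site's temporal swing.  Sign convention: f(first year) >= f(last year),
    matching a pollutant that declines over the window.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two eligible site rows")
    obs = np.isfinite(X)
    if not obs.any(axis=0).all():
        bad = np.where(~obs.any(axis=0))[0]
        raise ValueError(f"years with no observations at columns {bad.tolist()}")
    row_mean = np.nanmean(X, axis=1, keepdims=True)
    Xc = X - row_mean
    filled = np.where(obs, Xc, 0.0)
    prev = filled[~obs]
    converged = max_iter == 0
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        recon = s[0] * np.outer(U[:, 0], Vt[0])
        filled[~obs] = recon[~obs]
        if prev.size == 0 or np.max(np.abs(filled[~obs] - prev)) < tol:
            converged = True
            break
        prev = filled[~obs].copy()
    if not converged:
        warnings.warn("trend SVD imputation did not converge; returning last iterate",
                      RuntimeWarning, stacklevel=2)
    U, s, Vt = np.linalg.svd(filled, full_matrices=False)
    if s[0] <= 1e-12 * max(1.0, np.abs(Xc[obs]).max() if obs.any() else 1.0):
        warnings.warn("no temporal signal after row-centering; returning zero trend",
                      RuntimeWarning, stacklevel=2)
        return np.zeros(X.shape[1])
    f = s[0] / np.sqrt(X.shape[0]) * Vt[0]
    if f[0] < f[-1]:
        f = -f
    if smooth_df is not None:
        # optional smoothing: project onto polynomials with smooth_df terms
        # (annual bases have few points; off by default)
        if not 2 <= smooth_df < len(f):
            raise ValueError("smooth_df must be in [2, n_years)")
        t = np.arange(len(f), dtype=float)
        B = np.vander(t, smooth_df, increasing=True)
        f = B @ np.linalg.lstsq(B, f, rcond=None)[0]
    return f


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coef = np.polyfit(x, y, 1)
    return float(coef[1]), float(coef[0])  # intercept, slope


def extend_trend_linear(fitted_years, fitted_f, target_years) -> TrendBasis:
    """Extend the monitored trend to earlier years by straight-line extrapolation.

    An OLS line of f on calendar year over the monitored span provides the
    pre-period values; the monitored years keep the estimated (not fitted)
    trend.
    """
    fitted_years = np.asarray(fitted_years, dtype=int)
    fitted_f = np.asarray(fitted_f, dtype=float)
    if len(fitted_years) < 3:
        raise ValueError("need at least 3 fitted years for linear extrapolation")
    target_years = np.asarray(sorted(target_years), dtype=int)
    a, b = _ols_line(fitted_years, fitted_f)
    hist = a + b * target_years
    years = np.concatenate([target_years, fitted_years])
    f = np.concatenate([hist, fitted_f])
    order = np.argsort(years)
    return TrendBasis(years=years[order], f=f[order], source="pm25_extrapolated")


def extend_trend_proxy(primary_years, primary_f, proxy_matrix: pd.DataFrame,
                       source: str, proxy_start: int | None = None,
                       target_start: int = 1980, max_iter: int = 200,
                       tol: float = 1e-8) -> TrendBasis:
    """Back-extend the monitored trend using a proxy network's own SVD trend.

    The proxy trend g(t) is estimated from ``proxy_matrix`` (columns are
    years) by the same incomplete-matrix SVD; an OLS calibration of the
    primary f on g over the overlap years yields (a, b); historical years
    covered by the proxy get ``a + b g(t)``; years before the proxy begins
    get a straight-line extrapolation of the calibrated proxy trend; the
    monitored years keep the primary trend.
    """
    primary_years = np.asarray(primary_years, dtype=int)
    primary_f = np.asarray(primary_f, dtype=float)
    proxy_years = np.asarray(sorted(proxy_matrix.columns), dtype=int)
    proxy_matrix = proxy_matrix.reindex(columns=proxy_years)
    overlap = np.intersect1d(primary_years, proxy_years)
    if len(overlap) < 3:
        raise ValueError(f"proxy overlaps primary trend by {len(overlap)} years; need >= 3")
    g = estimate_trend_svd(proxy_matrix, max_iter=max_iter, tol=tol)
    g_at = dict(zip(proxy_years.tolist(), g))
    go = np.array([g_at[y] for y in overlap])
    fo = primary_f[np.searchsorted(primary_years, overlap)]
    if float(np.std(go)) < 1e-12:
        raise ValueError("degenerate proxy trend: no variation over the overlap years")
    a, b = _ols_line(go, fo)
    if abs(b) < 1e-12:
        raise ValueError("degenerate calibration: proxy trend uncorrelated with primary trend")

    start = int(proxy_start) if proxy_start is not None else int(proxy_years.min())
    hist_years = np.arange(target_start, int(primary_years.min()))
    calibrated = {int(y): a + b * g_at[y] for y in proxy_years}
    # line through the full calibrated proxy span, for years before the proxy begins
    la, lb = _ols_line(proxy_years, np.array([calibrated[int(y)] for y in proxy_years]))
    f_hist = np.array([
        calibrated[int(y)] if int(y) in calibrated and int(y) >= start else la + lb * y
        for y in hist_years
    ])
    years = np.concatenate([hist_years, primary_years])
    f = np.concatenate([f_hist, primary_f])
    order = np.argsort(years)
    return TrendBasis(years=years[order], f=f[order], source=source,
                      calib_intercept=a, calib_slope=b)
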