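"""The composite spatio-temporal exposure model.

Log annual-average PM2.5 at site s and year t is decomposed as

    log y(s, t) = mu(s) + beta(s) * f(t) + eps(s, t)

with a spatially varying long-term mean mu(s), a spatially varying
coefficient beta(s) on a single temporal basis f(t), and spatially dependent
but temporally independent residuals eps.  Estimation is staged:

1. per-site OLS of log y on [1, f(t)] at sites with long series gives
   (mu_hat_s, beta_hat_s);
2. two PLS scores are extracted from the geographic covariates against
   mu_hat;
3. mu_hat is modeled by universal kriging on the PLS scores (exponential
   covariance, ML/REML);
4. beta_hat is regressed on the same scores with iid errors (no spatial
   structure — zero range and partial sill — in the primary configuration);
5. residuals at all included site-years feed a pooled exponential covariance
   shared across years (simple kriging at prediction time).

Predictions at a new location/year combine the kriged mean surface, the
regression trend coefficient, f(t), and — for years with monitoring data —
the simple-kriged annual residual; the result is exponentiated back to
ug/m3.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .covariates import PLSScores
from .kriging import CovarianceParams, UniversalKriging, fit_covariance_pooled, simple_krige
from .trend import TrendBasis, site_year_matrix

__all__ = ["site_trend_regression", "SpatioTemporalModel", "save_model", "load_model"]


def site_trend_regression(y: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Per-site OLS of log values on [1, f]: returns (mu_hat, beta_hat)."""
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if len(y) != len(f) or len(y) < 2:
        raise ValueError("need >= 2 aligned observations")
    if float(np.std(f)) < 1e-12:
        raise ValueError("trend basis is constant over the observed years")
    X = np.column_stack([np.ones(len(f)), f])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[0]), float(coef[1])


class SpatioTemporalModel(BaseEstimator):
    """Staged spatio-temporal model for log annual-average PM2.5.

    Parameters
    ----------
    n_pls : int, default 2
        Number of PLS scores used in both the mean and trend-coefficient
        regressions.
    min_trend_years : int, default 6
        Sites need strictly more observed years than this to enter the
        site-level trend regressions.
    method : {"ml", "reml"}, default "ml"
        Likelihood for the mean-field covariance parameters.
    pls_response : {"mean", "trend-coef"}, default "mean"
        With "mean" the two PLS scores fitted against the site-level
        long-term means are re-used in the trend-coefficient regression;
        "trend-coef" fits a separate PLS against the site-level trend
        coefficients for that regression.
    beta_spatial : bool, default False
        Give the trend coefficient an exponential spatial field (sensitivity
        configuration); the primary configuration keeps iid errors only.
    residual_krige : bool, default True
        Interpolate annual residuals at prediction time for years with
        monitoring data (years without data always get zero residual).
    lognormal_correction : bool, default False
        Multiply back-transformed predictions by exp(sigma^2/2) using the
        fitted residual-variance components.
    n_restarts : int, default 3
        Optimizer multistarts for each covariance fit.
    random_state : int, optional
        Seed for optimizer multistarts.
    """

    def __init__(self, n_pls: int = 2, min_trend_years: int = 6, method: str = "ml",
                 pls_response: str = "mean", beta_spatial: bool = False,
                 residual_krige: bool = True, lognormal_correction: bool = False,
                 n_restarts: int = 3, random_state: int | None = None):
        self.n_pls = n_pls
        self.min_trend_years = min_trend_years
        self.method = method
        self.pls_response = pls_response
        self.beta_spatial = beta_spatial
        self.residual_krige = residual_krige
        self.lognormal_correction = lognormal_correction
        self.n_restarts = n_restarts
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, annual: pd.DataFrame, sites: pd.DataFrame, covariates: pd.DataFrame,
            trend: TrendBasis):
        """Fit all stages.

        ``annual`` has QC'd records [site_id, year, value, included];
        ``sites`` has [site_id, lon, lat]; ``covariates`` is indexed by
        site_id with numeric columns; ``trend`` must cover the observed
        years.
        """
        ann = annual.loc[annual["included"].astype(bool),
                         ["site_id", "year", "value"]].copy()
        if (ann["value"] <= 0).any():
            raise ValueError("included annual averages must be positive (log scale)")
        ann = ann.sort_values(["site_id", "year"]).reset_index(drop=True)
        ann["logy"] = np.log(ann["value"].to_numpy(dtype=float))
        ann["f"] = trend.value(ann["year"].to_numpy())

        site_idx = sites.set_index("site_id")
        missing_sites = set(ann["site_id"]) - set(site_idx.index)
        if missing_sites:
            raise KeyError(f"sites table missing {sorted(missing_sites)[:5]} ...")

        # stage 1: site-level trend regressions at long-series sites
        counts = ann.groupby("site_id")["year"].nunique()
        eligible = counts.index[counts > self.min_trend_years]
        if len(eligible) < 10:
            raise ValueError("fewer than 10 sites eligible for trend regression")
        mu_hat, beta_hat = {}, {}
        for sid, sub in ann.loc[ann["site_id"].isin(eligible)].groupby("site_id"):
            mu_hat[sid], beta_hat[sid] = site_trend_regression(sub["logy"].to_numpy(),
                                                               sub["f"].to_numpy())
        eligible = sorted(mu_hat)
        mu_vec = np.array([mu_hat[s] for s in eligible])
        beta_vec = np.array([beta_hat[s] for s in eligible])

        # stage 2: PLS scores against the site-level long-term means
        cov_fit = covariates.loc[eligible]
        self.pls_ = PLSScores(n_components=self.n_pls).fit(cov_fit, mu_vec)
        scores = self.pls_.scores_
        coords = site_idx.loc[eligible, ["lon", "lat"]].to_numpy(dtype=float)

        # stage 3: universal kriging of the long-term mean on the PLS scores
        self.mean_model_ = UniversalKriging(method=self.method, n_restarts=self.n_restarts,
                                            random_state=self.random_state)
        self.mean_model_.fit(np.column_stack([coords, scores]), mu_vec)

        # stage 4: trend-coefficient regression (iid errors in the primary config)
        self.pls_beta_ = None
        scores_b = scores
        if self.pls_response == "trend-coef":
            self.pls_beta_ = PLSScores(n_components=self.n_pls).fit(cov_fit, beta_vec)
            scores_b = self.pls_beta_.scores_
        elif self.pls_response != "mean":
            raise ValueError("pls_response must be 'mean' or 'trend-coef'")
        Xb = np.column_stack([np.ones(len(scores_b)), scores_b])
        gamma, *_ = np.linalg.lstsq(Xb, beta_vec, rcond=None)
        resid_b = beta_vec - Xb @ gamma
        dof = max(len(beta_vec) - Xb.shape[1], 1)
        var_b = float(resid_b @ resid_b) / dof
        self.gamma_ = gamma
        self.gamma_se_ = np.sqrt(np.diag(np.linalg.inv(Xb.T @ Xb)) * var_b)
        self.beta_variance_ = var_b
        # per-site OLS weights on the trend basis, kept for the correlated-error
        # standard errors computed after the residual covariance is fitted:
        # beta_hat_s = sum_t w_s(t) y_st with w = (f - fbar_s) / S_ff(s)
        all_years = sorted(ann["year"].unique())
        W_rows = []
        for sid in eligible:
            sub = ann.loc[ann["site_id"] == sid]
            w_row = np.zeros(len(all_years))
            fc = sub["f"].to_numpy() - sub["f"].mean()
            w_row[np.searchsorted(all_years, sub["year"].to_numpy())] = fc / (fc @ fc)
            W_rows.append(w_row)
        W = np.asarray(W_rows)
        self.beta_field_ = None
        if self.beta_spatial:
            bk = UniversalKriging(method=self.method, n_restarts=self.n_restarts,
                                  random_state=self.random_state)
            bk.fit(np.column_stack([coords, scores_b]), beta_vec)
            self.beta_field_ = bk

        # stage 5: residuals at ALL included site-years (kriged mu/beta where
        # the site was ineligible for its own trend regression)
        all_sites = sorted(ann["site_id"].unique())
        extra = [s for s in all_sites if s not in mu_hat]
        mu_all = dict(zip(eligible, mu_vec))
        beta_all = dict(zip(eligible, beta_vec))
        if extra:
            locs = site_idx.loc[extra, ["lon", "lat"]].to_numpy(dtype=float)
            sc = self.pls_.transform(covariates.loc[extra])
            mu_x = self.mean_model_.predict(np.column_stack([locs, sc]))
            beta_x = self._beta_at(locs, covariates.loc[extra])
            mu_all.update(zip(extra, mu_x))
            beta_all.update(zip(extra, beta_x))
        ann["resid"] = (ann["logy"].to_numpy()
                        - ann["site_id"].map(mu_all).to_numpy(dtype=float)
                        - ann["site_id"].map(beta_all).to_numpy(dtype=float) * ann["f"].to_numpy())

        groups, self.residuals_by_year_ = [], {}
        for year, sub in ann.groupby("year"):
            c = site_idx.loc[sub["site_id"], ["lon", "lat"]].to_numpy(dtype=float)
            r = sub["resid"].to_numpy(dtype=float)
            if len(sub) >= 10:
                groups.append((c, r))
            self.residuals_by_year_[int(year)] = (c, r)
        if len(groups) < 2:
            raise ValueError("need >= 2 years with >= 10 sites for the residual model")
        self.residual_cov_, self.residual_loglik_, self.residual_converged_ = \
            fit_covariance_pooled(groups, n_restarts=self.n_restarts,
                                  random_state=self.random_state)

        # correlated-error standard errors for gamma: beta_hat errors inherit
        # the residual field's spatial covariance through the per-site OLS
        # weights, Cov(bh_s, bh_s') = C(d_ss') * sum_t w_s(t) w_s'(t), plus the
        # structural iid variation of the coefficient field itself
        from .kriging import exponential_covariance, pairwise_distances_km
        Dm = pairwise_distances_km(coords)
        Vcorr = exponential_covariance(Dm, self.residual_cov_) * (W @ W.T)
        v_struct = max(var_b - float(np.mean(np.diag(Vcorr))), 0.0)
        V = Vcorr + v_struct * np.eye(len(coords))
        XtXi = np.linalg.inv(Xb.T @ Xb)
        gamma_cov = XtXi @ (Xb.T @ V @ Xb) @ XtXi
        self.gamma_se_ = np.sqrt(np.diag(gamma_cov))

        self.trend_ = trend
        self.site_table_ = pd.DataFrame({
            "site_id": all_sites,
            "lon": site_idx.loc[all_sites, "lon"].to_numpy(dtype=float),
            "lat": site_idx.loc[all_sites, "lat"].to_numpy(dtype=float),
            "mu_hat": [mu_all[s] for s in all_sites],
            "beta_hat": [beta_all[s] for s in all_sites],
            "trend_eligible": [s in set(eligible) for s in all_sites],
        })
        self.fit_years_ = sorted(ann["year"].unique().tolist())
        self.fit_meta_ = {
            "n_sites": len(all_sites), "n_eligible": len(eligible),
            "n_obs": len(ann),
            "mean_loglik": self.mean_model_.loglik_,
            "mean_converged": self.mean_model_.converged_,
            "residual_loglik": self.residual_loglik_,
            "residual_converged": self.residual_converged_,
            "random_state": self.random_state,
        }
        return self

    def _beta_at(self, coords: np.ndarray, cov_rows) -> np.ndarray:
        pls = self.pls_beta_ if self.pls_beta_ is not None else self.pls_
        scores = pls.transform(cov_rows)
        if self.beta_field_ is not None:
            return self.beta_field_.predict(np.column_stack([coords, scores]))
        return np.column_stack([np.ones(len(scores)), scores]) @ self.gamma_

    # -------------------------------------------------------------- predict
    def predict(self, locations: pd.DataFrame, covariates: pd.DataFrame,
                years, return_components: bool = False) -> pd.DataFrame:
        """Predict annual averages (ug/m3) at new locations and years.

        ``locations`` has [location_id, lon, lat]; ``covariates`` is indexed
        by location_id.  Years must lie within the trend range.  Output
        columns: location_id, year, pred_ugm3, pred_log, resid_component.
        """
        check_is_fitted(self, "mean_model_")
        years = [int(y) for y in np.atleast_1d(years)]
        f_years = self.trend_.value(years)
        loc_ids = locations["location_id" if "location_id" in locations else "site_id"].tolist()
        coords = locations[["lon", "lat"]].to_numpy(dtype=float)
        scores = self.pls_.transform(covariates.loc[loc_ids])
        mu = self.mean_model_.predict(np.column_stack([coords, scores]))
        beta = self._beta_at(coords, covariates.loc[loc_ids])

        frames = []
        for year, ft in zip(years, f_years):
            eps = np.zeros(len(loc_ids))
            if self.residual_krige and year in self.residuals_by_year_:
                c, r = self.residuals_by_year_[year]
                eps = simple_krige(self.residual_cov_, c, r, coords)
            pred_log = mu + beta * ft + eps
            pred = np.exp(pred_log)
            if self.lognormal_correction:
                pred = pred * np.exp(0.5 * self.residual_cov_.sill())
            frames.append(pd.DataFrame({
                "location_id": loc_ids, "year": year, "pred_ugm3": pred,
                "pred_log": pred_log, "resid_component": eps,
                "mu": mu, "beta": beta, "f": ft,
            }))
        out = pd.concat(frames, ignore_index=True)
        if not return_components:
            out = out[["location_id", "year", "pred_ugm3", "pred_log", "resid_component"]]
        return out

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        check_is_fitted(self, "mean_model_")
        mm = self.mean_model_
        return {
            "format_version": 1,
            "params": self.get_params(),
            "pls": self.pls_.to_dict(),
            "pls_beta": None if self.pls_beta_ is None else self.pls_beta_.to_dict(),
            "trend": {
                "years": self.trend_.years.tolist(), "f": self.trend_.f.tolist(),
                "source": self.trend_.source,
                "calib_intercept": self.trend_.calib_intercept,
                "calib_slope": self.trend_.calib_slope,
            },
            "mean_model": {
                "alpha": mm.alpha_.tolist(), "alpha_se": mm.alpha_se_.tolist(),
                "covariance": mm.covariance_.to_dict(), "loglik": mm.loglik_,
                "converged": mm.converged_,
                "coords": mm._coords.tolist(), "design": mm._design.tolist(),
                "y": mm._y.tolist(),
            },
            "trend_model": {
                "gamma": self.gamma_.tolist(), "gamma_se": self.gamma_se_.tolist(),
                "variance": self.beta_variance_,
            },
            "residual_model": {
                "covariance": self.residual_cov_.to_dict(),
                "by_year": {str(y): {"coords": c.tolist(), "resid": r.tolist()}
                            for y, (c, r) in self.residuals_by_year_.items()},
            },
            "site_table": self.site_table_.to_dict(orient="list"),
            "fit_years": self.fit_years_,
            "fit_meta": self.fit_meta_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpatioTemporalModel":
        m = cls(**d["params"])
        m.pls_ = PLSScores.from_dict(d["pls"])
        m.pls_beta_ = (PLSScores.from_dict(d["pls_beta"])
                       if d.get("pls_beta") else None)
        t = d["trend"]
        m.trend_ = TrendBasis(years=np.asarray(t["years"]), f=np.asarray(t["f"]),
                              source=t["source"], calib_intercept=t["calib_intercept"],
                              calib_slope=t["calib_slope"])
        mmid = d["mean_model"]
        mm = UniversalKriging(optimize=False, **mmid["covariance"])
        mm.fit(np.column_stack([np.asarray(mmid["coords"]),
                                np.asarray(mmid["design"])[:, 1:]]),
               np.asarray(mmid["y"]))
        mm.loglik_ = mmid["loglik"]
        mm.converged_ = mmid["converged"]
        m.mean_model_ = mm
        m.gamma_ = np.asarray(d["trend_model"]["gamma"], dtype=float)
        m.gamma_se_ = np.asarray(d["trend_model"]["gamma_se"], dtype=float)
        m.beta_variance_ = float(d["trend_model"]["variance"])
        m.beta_field_ = None
        m.residual_cov_ = CovarianceParams.from_dict(d["residual_model"]["covariance"])
        m.residuals_by_year_ = {
            int(y): (np.asarray(v["coords"], dtype=float), np.asarray(v["resid"], dtype=float))
            for y, v in d["residual_model"]["by_year"].items()}
        m.site_table_ = pd.DataFrame(d["site_table"])
        m.fit_years_ = d["fit_years"]
        m.fit_meta_ = d["fit_meta"]
        return m


def save_model(model: SpatioTemporalModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path) -> SpatioTemporalModel:
    with open(path) as fh:
        return SpatioTemporalModel.from_dict(json.load(fh))


def annual_matrix_for_trend(annual: pd.DataFrame, years, min_years: int = 6) -> pd.DataFrame:
    """Convenience: the log site x year matrix feeding trend estimation."""
    return site_year_matrix(annual, years=list(years), log_scale=True, min_years=min_years)
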