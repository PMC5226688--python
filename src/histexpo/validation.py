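"""Model evaluation: cross-validation, MSE-based R2, and stratified tables.

All statistics are computed on the concentration (ug/m3) scale.  The
headline statistic is the MSE-based R2,

    R2 = 1 - MSE / Var(observations),

which scores predictions against the identity line and so, unlike a squared
correlation, penalizes bias and attenuation.  It can be negative; reports
clamp at 0.00 but the raw value is preserved for analysis.  Cross-validation
folds hold out whole sites (all their years), so held-out predictions are
spatially out-of-sample.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .model import SpatioTemporalModel

__all__ = [
    "mse_r2", "rmse", "calibration_line", "format_r2", "make_folds",
    "CVResult", "cross_validate", "external_validate", "trend_spread",
]


def mse_r2(observed, predicted) -> float:
    """1 - MSE / population variance of the observations (may be negative)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be aligned with length >= 2")
    var = float(np.mean((obs - obs.mean()) ** 2))
    if var == 0.0:
        raise ValueError("observations have zero variance; R2 undefined")
    return 1.0 - float(np.mean((obs - pred) ** 2)) / var


def rmse(observed, predicted) -> float:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 1:
        raise ValueError("observed and predicted must be aligned and non-empty")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def calibration_line(observed, predicted) -> tuple[float, float]:
    """OLS of predictions on observations: returns (intercept, slope).

    Slopes below 1 flag attenuated (over-smoothed) predictions.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 3:
        raise ValueError("need >= 3 pairs for a calibration line")
    if float(np.std(obs)) < 1e-12:
        raise ValueError("constant observations; calibration line undefined")
    slope, intercept = np.polyfit(obs, pred, 1)
    return float(intercept), float(slope)


def format_r2(r2: float) -> str:
    """Report formatter: negative R2 prints as 0.00."""
    return f"{max(r2, 0.0):.2f}"


def make_folds(site_ids, k: int = 5, seed: int | None = None,
               regions: dict | None = None) -> dict:
    """Assign each site (all its years) to one of k folds.

    Balanced (sizes differ by at most 1, per region when ``regions`` maps
    site_id -> region) and deterministic given the seed.
    """
    site_ids = list(site_ids)
    if k < 2 or k > len(site_ids):
        raise ValueError("need 2 <= k <= number of sites")
    rng = np.random.default_rng(seed)
    assignment = {}
    if regions:
        strata = {}
        for s in site_ids:
            strata.setdefault(regions.get(s), []).append(s)
        groups = [sorted(v) for _, v in sorted(strata.items(), key=lambda kv: str(kv[0]))]
    else:
        groups = [sorted(site_ids)]
    for group in groups:
        order = rng.permutation(len(group))
        for i, j in enumerate(order):
            assignment[group[j]] = i % k
    return assignment


def _stats(obs, pred) -> dict:
    out = {"n_obs": int(len(obs)), "rmse": rmse(obs, pred)}
    try:
        out["r2"] = mse_r2(obs, pred)
    except ValueError:
        out["r2"] = float("nan")
    try:
        out["intercept"], out["slope"] = calibration_line(obs, pred)
    except ValueError:
        out["intercept"] = out["slope"] = float("nan")
    return out


@dataclasses.dataclass
class CVResult:
    """Held-out prediction table plus the stratified statistic suite."""

    table: pd.DataFrame
    overall: dict
    by_year: pd.DataFrame
    by_region: pd.DataFrame
    temporal_site_median: dict

    def summary_text(self) -> str:
        lines = ["stratum            n_sites  n_obs    R2     RMSE"]

        def row(name, nsites, st):
            return (f"{name:<18} {nsites:>7} {st['n_obs']:>6}  "
                    f"{format_r2(st['r2']):>5}  {st['rmse']:>6.2f}")

        lines.append(row("All", self.table["site_id"].nunique(), self.overall))
        for _, r in self.by_year.iterrows():
            lines.append(row(str(int(r["year"])), int(r["n_sites"]), r))
        for _, r in self.by_region.iterrows():
            lines.append(row(str(r["region"]), int(r["n_sites"]), r))
        return "\n".join(lines)


def summarize_table(table: pd.DataFrame, min_site_years: int = 6) -> CVResult:
    """Compute the full stratified statistic suite from a prediction table.

    ``table`` columns: site_id, year, region, observed, predicted.
    """
    obs = table["observed"].to_numpy(dtype=float)
    pred = table["predicted"].to_numpy(dtype=float)
    overall = _stats(obs, pred)
    by_year = []
    for year, sub in table.groupby("year"):
        st = _stats(sub["observed"].to_numpy(), sub["predicted"].to_numpy())
        st.update(year=int(year), n_sites=sub["site_id"].nunique())
        by_year.append(st)
    by_region = []
    if "region" in table.columns and table["region"].notna().any():
        for region, sub in table.groupby("region"):
            st = _stats(sub["observed"].to_numpy(), sub["predicted"].to_numpy())
            st.update(region=region, n_sites=sub["site_id"].nunique())
            by_region.append(st)
    site_r2, site_rmse = [], []
    for _, sub in table.groupby("site_id"):
        if sub["year"].nunique() > min_site_years:
            o = sub["observed"].to_numpy()
            p = sub["predicted"].to_numpy()
            if len(o) >= 2 and np.std(o) > 0:
                site_r2.append(mse_r2(o, p))
                site_rmse.append(rmse(o, p))
    temporal = {
        "n_sites": len(site_r2),
        "r2_median": float(np.median(site_r2)) if site_r2 else float("nan"),
        "rmse_median": float(np.median(site_rmse)) if site_rmse else float("nan"),
    }
    return CVResult(table=table,
                    overall=overall,
                    by_year=pd.DataFrame(by_year),
                    by_region=pd.DataFrame(by_region) if by_region else pd.DataFrame(),
                    temporal_site_median=temporal)


def cross_validate(annual: pd.DataFrame, sites: pd.DataFrame, covariates: pd.DataFrame,
                   trend, k: int = 5, seed: int | None = None,
                   stratify_by_region: bool = False,
                   model_params: dict | None = None) -> CVResult:
    """k-fold site-based cross-validation of the full pipeline.

    For each fold the complete model (PLS, mean field, trend coefficient,
    residual covariance) is refitted on the remaining folds and the held-out
    site-years are predicted; residual kriging sees only training residuals.
    The shared trend basis is treated as fixed.
    """
    ann = annual.loc[annual["included"].astype(bool)]
    cv_sites = sorted(ann["site_id"].unique())
    region_map = None
    if stratify_by_region and "region" in sites.columns:
        region_map = dict(zip(sites["site_id"], sites["region"]))
    folds = make_folds(cv_sites, k=k, seed=seed, regions=region_map)

    rows = []
    for fold in range(k):
        held = {s for s, f in folds.items() if f == fold}
        train_ann = ann.loc[~ann["site_id"].isin(held)]
        test_ann = ann.loc[ann["site_id"].isin(held)]
        if train_ann.empty or test_ann.empty:
            raise RuntimeError(f"fold {fold} has an empty train or test split")
        model = SpatioTemporalModel(**(model_params or {}))
        try:
            model.fit(train_ann, sites, covariates, trend)
        except Exception as exc:  # noqa: BLE001 - stage context for the caller
            raise RuntimeError(f"fold {fold} failed to fit: {exc}") from exc
        locs = sites.loc[sites["site_id"].isin(held), ["site_id", "lon", "lat"]]
        preds = model.predict(locs, covariates, sorted(test_ann["year"].unique()))
        merged = test_ann.merge(preds, left_on=["site_id", "year"],
                                right_on=["location_id", "year"], how="left")
        sub = pd.DataFrame({
            "site_id": merged["site_id"], "year": merged["year"],
            "observed": merged["value"], "predicted": merged["pred_ugm3"],
            "fold": fold,
        })
        rows.append(sub)
    table = pd.concat(rows, ignore_index=True)
    if "region" in sites.columns:
        table = table.merge(sites[["site_id", "region"]], on="site_id", how="left")
    else:
        table["region"] = pd.NA
    return summarize_table(table)


def external_validate(model: SpatioTemporalModel, external_annual: pd.DataFrame,
                      external_sites: pd.DataFrame,
                      external_covariates: pd.DataFrame) -> CVResult:
    """Out-of-sample validation of a fitted model against an external network.

    No refitting: the fitted model predicts every included external
    site-year and the same statistic suite is computed.
    """
    ann = external_annual.loc[external_annual["included"].astype(bool)]
    locs = external_sites.loc[external_sites["site_id"].isin(ann["site_id"].unique()),
                              ["site_id", "lon", "lat"]]
    missing = set(ann["site_id"]) - set(locs["site_id"])
    if missing:
        raise KeyError(f"external sites table missing {sorted(missing)[:5]}")
    preds = model.predict(locs, external_covariates, sorted(ann["year"].unique()))
    merged = ann.merge(preds, left_on=["site_id", "year"],
                       right_on=["location_id", "year"], how="left")
    table = pd.DataFrame({
        "site_id": merged["site_id"], "year": merged["year"],
        "observed": merged["value"], "predicted": merged["pred_ugm3"],
    })
    if "region" in external_sites.columns:
        table = table.merge(external_sites[["site_id", "region"]], on="site_id", how="left")
    else:
        table["region"] = pd.NA
    return summarize_table(table)


def trend_spread(predictions_by_approach: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-site-year max minus min prediction across trend approaches.

    Input tables need columns [site_id (or location_id), year, predicted or
    pred_ugm3]; all approaches must cover the same site-years.  Output has
    per-row spreads; aggregate per-year medians with
    ``out.groupby("year")["spread"].median()``.
    """
    if len(predictions_by_approach) < 2:
        raise ValueError("need >= 2 approaches to compute a spread")
    frames = []
    for name, df in predictions_by_approach.items():
        df = df.rename(columns={"location_id": "site_id", "pred_ugm3": "predicted"})
        frames.append(df.set_index(["site_id", "year"])["predicted"].rename(name))
    wide = pd.concat(frames, axis=1)
    if wide.isna().any().any():
        raise ValueError("approaches are not aligned on the same site-years")
    out = wide.max(axis=1) - wide.min(axis=1)
    return out.rename("spread").reset_index()
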