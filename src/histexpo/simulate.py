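"""Synthetic monitoring worlds with the statistical structure the model assumes.

No real monitoring data ships with the package, so every stage is exercised
on generated worlds that emulate the study design: a dense "primary" PM2.5
network observed only in the final 12 years of a 31-year window, a sparse
historical validation network observed in the 1990s, and two proxy networks
(a sulfate-like series from 1987 and a visibility-like series over the whole
window) whose temporal patterns are affine in the true trend.

Truth is retained (mu* and beta* fields, f*, covariance parameters) so
recovery tests can compare estimates against it.  Generation is fully
deterministic: each random component draws from its own stream spawned from
the world seed, so regenerating with the same seed is bit-identical and
scaling a noise parameter rescales exactly the same draws (paired
noise-inflation experiments).
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np
import pandas as pd

from .kriging import CovarianceParams, pairwise_distances_km

__all__ = ["WorldConfig", "SyntheticWorld", "generate_world", "degrade", "world_a",
           "WORLD_A_SEED"]

WORLD_A_SEED = 20160624

# longitude thresholds for the three-region split used throughout
REGION_THRESHOLDS = [(-95.0, "East"), (-115.0, "MountainWest"), (-180.0, "WestCoast")]


@dataclasses.dataclass
class WorldConfig:
    """Generator settings; the defaults are the canonical study conditions."""

    years: tuple[int, int] = (1980, 2010)
    primary_years: tuple[int, int] = (1999, 2010)
    validation_years: tuple[int, int] = (1990, 1998)
    sulfate_years: tuple[int, int] = (1987, 2010)
    visibility_years: tuple[int, int] = (1980, 2010)
    n_primary: int = 400
    n_validation: int = 70
    n_sulfate: int = 100
    n_visibility: int = 150
    # bounding box of the continental-US study domain (lon, lat degrees)
    lon_range: tuple[float, float] = (-124.0, -68.0)
    lat_range: tuple[float, float] = (26.0, 48.0)
    # fraction of sites placed as close satellites of earlier sites, emulating
    # urban multi-monitor clustering (also what identifies the nugget)
    cluster_fraction: float = 0.3
    cluster_scale_km: float = 15.0
    # geographic covariates: p noisy linear views of 2 latent spatial factors
    n_covariates: int = 50
    covariate_noise_sd: float = 0.5
    latent_range_km: float = 800.0
    # long-term mean field mu*(s) = a0 + a1 L1 + a2 L2 + GP
    mean_intercept: float = 2.4
    mean_latent_coefs: tuple[float, float] = (0.45, -0.30)
    mean_cov: CovarianceParams = dataclasses.field(
        default_factory=lambda: CovarianceParams(200.0, 0.04, 0.02))
    # trend coefficient field beta*(s) = g0 + g1 L1 + g2 L2 + iid
    beta_intercept: float = 1.0
    beta_latent_coefs: tuple[float, float] = (0.20, -0.10)
    beta_noise_sd: float = 0.10
    # spatio-temporal residuals: one exponential GP per year plus nugget
    residual_cov: CovarianceParams = dataclasses.field(
        default_factory=lambda: CovarianceParams(300.0, 0.006, 0.002))
    # true trend f*: piecewise linear, steeper decline before 2000
    trend_shape: str = "piecewise"  # or "linear"
    trend_knots: tuple = ((1980, 0.90), (2000, 0.15), (2010, -0.15))
    trend_linear: tuple = ((1980, 0.60), (2010, -0.30))
    # proxies: log proxy = site_effect + loading * f*(t) + noise
    sulfate_loading: float = 1.3
    sulfate_site_mean: float = 1.1
    sulfate_site_sd: float = 0.30
    visibility_loading: float = -0.8  # visual range improves as PM2.5 falls
    visibility_site_mean: float = 2.5
    visibility_site_sd: float = 0.15
    proxy_noise_sd: float = 0.05
    # observation-noise multiplier (scales residual GP, nugget and proxy noise)
    noise_factor: float = 1.0
    # optional daily disaggregation of the primary network (QC testing)
    make_daily: bool = False
    daily_sd: float = 2.0


@dataclasses.dataclass
class SyntheticWorld:
    config: WorldConfig
    seed: int
    sites: pd.DataFrame                    # site_id, lon, lat, region, network
    covariates: pd.DataFrame               # indexed by site_id (primary+validation)
    annual: dict[str, pd.DataFrame]        # per network, QC schema
    truth: dict
    daily: pd.DataFrame | None = None
    degradations: list = dataclasses.field(default_factory=list)

    def network_sites(self, network: str) -> pd.DataFrame:
        return self.sites.loc[self.sites["network"] == network].reset_index(drop=True)


def _f_star(cfg: WorldConfig) -> pd.Series:
    years = np.arange(cfg.years[0], cfg.years[1] + 1)
    if cfg.trend_shape == "linear":
        (y0, f0), (y1, f1) = cfg.trend_linear
        f = f0 + (f1 - f0) * (years - y0) / (y1 - y0)
    elif cfg.trend_shape == "piecewise":
        ky = np.array([k[0] for k in cfg.trend_knots], dtype=float)
        kf = np.array([k[1] for k in cfg.trend_knots], dtype=float)
        f = np.interp(years, ky, kf)
    else:
        raise ValueError(f"unknown trend_shape {cfg.trend_shape!r}")
    return pd.Series(f, index=years, name="f_star")


def _gp_draw(coords: np.ndarray, range_km: float, variance: float,
             rng: np.random.Generator, jitter: float = 1e-8) -> np.ndarray:
    if variance <= 0:
        return np.zeros(len(coords))
    D = pairwise_distances_km(coords)
    cov = variance * np.exp(-D / range_km)
    cov[np.diag_indices(len(coords))] += jitter
    L = np.linalg.cholesky(cov)
    return L @ rng.standard_normal(len(coords))


def _region_of(lon: float) -> str:
    for min_lon, name in REGION_THRESHOLDS:
        if lon >= min_lon:
            return name
    return REGION_THRESHOLDS[-1][1]


def generate_world(config: WorldConfig | dict | None = None, seed: int = WORLD_A_SEED) -> SyntheticWorld:
    """Generate a deterministic synthetic monitoring world."""
    if config is None:
        cfg = WorldConfig()
    elif isinstance(config, dict):
        known = {f.name for f in dataclasses.fields(WorldConfig)}
        bad = sorted(set(config) - known)
        if bad:
            raise ValueError(f"unknown world-config keys: {bad}")
        kwargs = dict(config)
        for key in ("mean_cov", "residual_cov"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = CovarianceParams.from_dict(kwargs[key])
        cfg = WorldConfig(**kwargs)
    else:
        cfg = config
    _validate_config(cfg)

    streams = np.random.SeedSequence(seed).spawn(10)
    (rng_coords, rng_latent, rng_cov, rng_mu, rng_beta,
     rng_resid, rng_sulf, rng_vis, rng_daily, _spare) = (np.random.default_rng(s) for s in streams)

    def draw_sites(n, network, prefix):
        lon = rng_coords.uniform(*cfg.lon_range, n)
        lat = rng_coords.uniform(*cfg.lat_range, n)
        n_cluster = int(round(cfg.cluster_fraction * n))
        if n_cluster > 0 and n > n_cluster:
            parents = rng_coords.integers(0, n - n_cluster, size=n_cluster)
            # satellite sites jittered around a parent (degrees ~ km / 111)
            scale_deg = cfg.cluster_scale_km / 111.0
            lon[n - n_cluster:] = np.clip(
                lon[parents] + scale_deg * rng_coords.standard_normal(n_cluster), *cfg.lon_range)
            lat[n - n_cluster:] = np.clip(
                lat[parents] + scale_deg * rng_coords.standard_normal(n_cluster), *cfg.lat_range)
        return pd.DataFrame({
            "site_id": [f"{prefix}{i:04d}" for i in range(n)],
            "lon": lon, "lat": lat,
            "region": [_region_of(x) for x in lon],
            "network": network,
        })

    primary = draw_sites(cfg.n_primary, "primary", "P")
    validation = draw_sites(cfg.n_validation, "validation", "V")
    sulfate = draw_sites(cfg.n_sulfate, "sulfate", "S")
    visibility = draw_sites(cfg.n_visibility, "visibility", "W")
    sites = pd.concat([primary, validation, sulfate, visibility], ignore_index=True)

    # latent spatial factors and derived fields over the PM2.5 site set
    pm_sites = pd.concat([primary, validation], ignore_index=True)
    coords = pm_sites[["lon", "lat"]].to_numpy(dtype=float)
    L1 = _gp_draw(coords, cfg.latent_range_km, 1.0, rng_latent)
    L2 = _gp_draw(coords, cfg.latent_range_km, 1.0, rng_latent)

    loadings = rng_cov.standard_normal((2, cfg.n_covariates))
    noise = rng_cov.standard_normal((len(pm_sites), cfg.n_covariates)) * cfg.covariate_noise_sd
    Xcov = np.outer(L1, loadings[0]) + np.outer(L2, loadings[1]) + noise
    covariates = pd.DataFrame(Xcov, index=pm_sites["site_id"],
                              columns=[f"geo{j:03d}" for j in range(cfg.n_covariates)])

    mu_gp = _gp_draw(coords, cfg.mean_cov.range_km, cfg.mean_cov.partial_sill, rng_mu)
    mu_nug = np.sqrt(cfg.mean_cov.nugget) * rng_mu.standard_normal(len(pm_sites))
    mu_star = (cfg.mean_intercept + cfg.mean_latent_coefs[0] * L1
               + cfg.mean_latent_coefs[1] * L2 + mu_gp + mu_nug)
    beta_star = (cfg.beta_intercept + cfg.beta_latent_coefs[0] * L1
                 + cfg.beta_latent_coefs[1] * L2
                 + cfg.beta_noise_sd * rng_beta.standard_normal(len(pm_sites)))

    f_star = _f_star(cfg)
    nf = cfg.noise_factor
    obs_years = range(min(cfg.validation_years[0], cfg.primary_years[0]),
                      max(cfg.validation_years[1], cfg.primary_years[1]) + 1)
    resid = {}
    for year in obs_years:
        gp = _gp_draw(coords, cfg.residual_cov.range_km, cfg.residual_cov.partial_sill, rng_resid)
        nug = np.sqrt(cfg.residual_cov.nugget) * rng_resid.standard_normal(len(pm_sites))
        resid[year] = nf * (gp + nug)

    pm_pos = {s: i for i, s in enumerate(pm_sites["site_id"])}

    def annual_table(block: pd.DataFrame, year_lo: int, year_hi: int) -> pd.DataFrame:
        rows = []
        for sid in block["site_id"]:
            i = pm_pos[sid]
            for year in range(year_lo, year_hi + 1):
                logy = mu_star[i] + beta_star[i] * f_star.loc[year] + resid[year][i]
                rows.append((sid, year, float(np.exp(logy))))
        df = pd.DataFrame(rows, columns=["site_id", "year", "value"])
        df["n_valid"] = pd.NA
        df["n_scheduled"] = pd.NA
        df["max_gap_days"] = pd.NA
        df["included"] = True
        return df

    annual = {
        "primary": annual_table(primary, *cfg.primary_years),
        "validation": annual_table(validation, *cfg.validation_years),
    }

    def proxy_table(block, years, loading, site_mean, site_sd, rng):
        a = site_mean + site_sd * rng.standard_normal(len(block))
        rows = []
        for i, sid in enumerate(block["site_id"]):
            for year in range(years[0], years[1] + 1):
                logv = a[i] + loading * f_star.loc[year] \
                    + nf * cfg.proxy_noise_sd * rng.standard_normal()
                rows.append((sid, year, float(np.exp(logv))))
        df = pd.DataFrame(rows, columns=["site_id", "year", "value"])
        df["n_valid"] = pd.NA
        df["n_scheduled"] = pd.NA
        df["max_gap_days"] = pd.NA
        df["included"] = True
        return df

    annual["sulfate"] = proxy_table(sulfate, cfg.sulfate_years, cfg.sulfate_loading,
                                    cfg.sulfate_site_mean, cfg.sulfate_site_sd, rng_sulf)
    annual["visibility"] = proxy_table(visibility, cfg.visibility_years, cfg.visibility_loading,
                                       cfg.visibility_site_mean, cfg.visibility_site_sd, rng_vis)

    daily = None
    if cfg.make_daily:
        daily = _daily_from_annual(annual["primary"], cfg.daily_sd, rng_daily)

    truth = {
        "mu_star": pd.Series(mu_star, index=pm_sites["site_id"]),
        "beta_star": pd.Series(beta_star, index=pm_sites["site_id"]),
        "f_star": f_star,
        "latents": pd.DataFrame({"L1": L1, "L2": L2}, index=pm_sites["site_id"]),
        "mean_cov": cfg.mean_cov,
        "residual_cov": CovarianceParams(cfg.residual_cov.range_km,
                                         cfg.residual_cov.partial_sill * nf ** 2,
                                         cfg.residual_cov.nugget * nf ** 2),
        "mean_intercept": cfg.mean_intercept,
        "beta_intercept": cfg.beta_intercept,
    }
    return SyntheticWorld(config=cfg, seed=seed, sites=sites, covariates=covariates,
                          annual=annual, truth=truth, daily=daily)


def _validate_config(cfg: WorldConfig) -> None:
    bad = []
    for name in ("n_primary", "n_validation", "n_sulfate", "n_visibility", "n_covariates"):
        if getattr(cfg, name) < 1:
            bad.append(name)
    for name in ("covariate_noise_sd", "beta_noise_sd", "proxy_noise_sd", "noise_factor", "daily_sd"):
        if getattr(cfg, name) < 0:
            bad.append(name)
    if cfg.years[0] >= cfg.years[1]:
        bad.append("years")
    if bad:
        raise ValueError(f"invalid world config values for: {bad}")


def _daily_from_annual(annual: pd.DataFrame, daily_sd: float,
                       rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for _, r in annual.iterrows():
        dates = pd.date_range(f"{int(r['year'])}-01-01", f"{int(r['year'])}-12-31", freq="D")
        vals = np.clip(r["value"] + daily_sd * rng.standard_normal(len(dates)), 0.01, None)
        rows.append(pd.DataFrame({"site_id": r["site_id"], "date": dates, "value": vals}))
    return pd.concat(rows, ignore_index=True)


def degrade(world: SyntheticWorld, operation: str, params: dict | None = None,
            seed: int | None = None) -> SyntheticWorld:
    """Return a degraded copy of a world (truth fields unchanged).

    Operations: ``drop-sites`` {network, n}, ``drop-years`` {network, years},
    ``add-gap`` {site_id, year, start_doy, length}, ``inflate-noise``
    {factor} (observation noise sds scaled by 1 + factor; factor 0 is the
    identity), ``protocol-noise`` {network, log_sd} (multiplicative lognormal
    measurement error on one network's annual values, emulating a sampler
    with an inconsistent protocol).
    """
    params = dict(params or {})
    if operation == "inflate-noise":
        factor = float(params.get("factor", 0.0))
        cfg = copy.deepcopy(world.config)
        cfg.noise_factor = world.config.noise_factor * (1.0 + factor)
        new = generate_world(cfg, seed=world.seed)
        new.degradations = world.degradations + [{"operation": operation, "params": params}]
        return new

    new = copy.deepcopy(world)
    new.degradations = world.degradations + [{"operation": operation, "params": params}]
    if operation == "drop-sites":
        network = params["network"]
        n_keep = int(params["n"])
        block = new.network_sites(network)
        if n_keep < 1 or n_keep >= len(block):
            raise ValueError("drop-sites needs 1 <= n < current network size")
        rng = np.random.default_rng(seed)
        keep = set(rng.choice(block["site_id"].to_numpy(), size=n_keep, replace=False))
        drop = set(block["site_id"]) - keep
        new.sites = new.sites.loc[~new.sites["site_id"].isin(drop)].reset_index(drop=True)
        new.annual[network] = new.annual[network].loc[
            ~new.annual[network]["site_id"].isin(drop)].reset_index(drop=True)
        new.covariates = new.covariates.loc[~new.covariates.index.isin(drop)]
    elif operation == "drop-years":
        network = params["network"]
        years = set(int(y) for y in params["years"])
        tab = new.annual[network]
        tab = tab.loc[~tab["year"].isin(years)].reset_index(drop=True)
        if tab.empty:
            raise ValueError("drop-years would remove all data for the network")
        new.annual[network] = tab
    elif operation == "protocol-noise":
        network = params["network"]
        # default matches the error magnitude of a 1980s non-reference sampler
        # (reported RMSE/mean ratios near 0.3 for such networks)
        log_sd = float(params.get("log_sd", 0.25))
        rng = np.random.default_rng(seed)
        tab = new.annual[network].copy()
        tab["value"] = tab["value"].to_numpy() * np.exp(log_sd * rng.standard_normal(len(tab)))
        new.annual[network] = tab
    elif operation == "add-gap":
        if new.daily is None:
            raise ValueError("add-gap requires a world generated with make_daily=True")
        sid, year = params["site_id"], int(params["year"])
        start_doy = int(params.get("start_doy", 100))
        length = int(params["length"])
        d = pd.to_datetime(new.daily["date"])
        doy = d.dt.dayofyear
        mask = ((new.daily["site_id"] == sid) & (d.dt.year == year)
                & (doy >= start_doy) & (doy < start_doy + length))
        if not mask.any():
            raise ValueError("add-gap matched no daily records")
        new.daily = new.daily.loc[~mask].reset_index(drop=True)
    else:
        raise ValueError(f"unknown degrade operation {operation!r}")
    if all(tab.empty for tab in new.annual.values()):
        raise ValueError("degradation removed all data")
    return new


def world_a(noise_factor: float = 1.0, make_daily: bool = False) -> SyntheticWorld:
    """The canonical test world ("world-A", seed 20160624)."""
    cfg = WorldConfig(noise_factor=noise_factor, make_daily=make_daily)
    return generate_world(cfg, seed=WORLD_A_SEED)
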