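import numpy as np
import pytest

import histexpo as hx


def make_trend(world, approach="pm25"):
    """Estimate the trend basis from a world's networks, one of the three ways."""
    y0, y1 = world.config.primary_years
    years = list(range(y0, y1 + 1))
    mat = hx.site_year_matrix(world.annual["primary"], years=years, min_years=6)
    f = hx.estimate_trend_svd(mat)
    t0 = world.config.years[0]
    if approach == "pm25":
        return hx.extend_trend_linear(years, f, range(t0, y0))
    network = "sulfate" if approach == "sulfate" else "visibility"
    span = world.config.sulfate_years if approach == "sulfate" else world.config.visibility_years
    pyears = list(range(span[0], span[1] + 1))
    pmat = hx.site_year_matrix(world.annual[network], years=pyears,
                               min_years=len(pyears) // 2)
    return hx.extend_trend_proxy(years, f, pmat, source=f"{approach}_proxy",
                                 proxy_start=span[0], target_start=t0)


TINY = dict(n_primary=60, n_validation=24, n_sulfate=25, n_visibility=30,
            n_covariates=12)


@pytest.fixture(scope="session")
def tiny_world():
    """A small world for fast unit tests (same structure as world-A)."""
    return hx.generate_world(dict(TINY), seed=7)


@pytest.fixture(scope="session")
def tiny_trend(tiny_world):
    return make_trend(tiny_world, "pm25")


@pytest.fixture(scope="session")
def tiny_model(tiny_world, tiny_trend):
    return hx.SpatioTemporalModel(random_state=0, n_restarts=2).fit(
        tiny_world.annual["primary"], tiny_world.sites, tiny_world.covariates, tiny_trend)


@pytest.fixture(scope="session")
def world_a():
    """The canonical 400-site fixture world."""
    return hx.world_a()


@pytest.fixture(scope="session")
def world_a_trend(world_a):
    return make_trend(world_a, "pm25")


@pytest.fixture(scope="session")
def world_a_model(world_a, world_a_trend):
    return hx.SpatioTemporalModel(random_state=1).fit(
        world_a.annual["primary"], world_a.sites, world_a.covariates, world_a_trend)


def exact_model_world(n_sites=40, seed=3, beta_linear=True, noise=0.0):
    """Data generated exactly from the model equation with controllable noise.

    mu and beta are exact linear functions of two covariates (so the PLS
    scores span them), and observations are mu + beta * f with optional iid
    noise; used for noiseless self-consistency and interpolation checks.
    """
    rng = np.random.default_rng(seed)
    import pandas as pd
    lon = rng.uniform(-120, -70, n_sites)
    lat = rng.uniform(27, 47, n_sites)
    sites = pd.DataFrame({"site_id": [f"X{i:03d}" for i in range(n_sites)],
                          "lon": lon, "lat": lat, "region": "East"})
    cov = pd.DataFrame({"c1": rng.standard_normal(n_sites),
                        "c2": rng.standard_normal(n_sites)},
                       index=sites["site_id"])
    years = np.arange(1999, 2011)
    f = 0.2 - 0.03 * (years - 1999)
    f = f - f.mean()
    mu = 2.5 + 0.4 * cov["c1"].to_numpy() - 0.2 * cov["c2"].to_numpy()
    if beta_linear:
        beta = 1.0 + 0.15 * cov["c1"].to_numpy() + 0.05 * cov["c2"].to_numpy()
    else:
        beta = 1.0 + 0.1 * rng.standard_normal(n_sites)
    rows = []
    for i, sid in enumerate(sites["site_id"]):
        for year, ft in zip(years, f):
            logy = mu[i] + beta[i] * ft + noise * rng.standard_normal()
            rows.append((sid, int(year), float(np.exp(logy))))
    annual = pd.DataFrame(rows, columns=["site_id", "year", "value"])
    annual["included"] = True
    trend = hx.TrendBasis(years=years, f=f, source="pm25_extrapolated")
    return sites, cov, annual, trend, mu, beta
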