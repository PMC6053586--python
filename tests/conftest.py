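"""Shared fixtures: simulated terrain, tracks, and model-recovery datasets.

The heavier end-to-end objects (multi-bird simulated tracking days, the
two-region prediction landscape, the n=20,000 parameter-recovery table)
are session-scoped so the full suite builds each of them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from soarscape import behavior_classifier as bc
from soarscape import soaring_glm as sg
from soarscape import soaring_prediction as sp
from soarscape import synthetic_data as sd
from soarscape import track_features as tf
from soarscape.geo import local_to_lonlat

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Model-averaged coefficient magnitudes used as simulation truth for
#: parameter-recovery checks (thermal / orographic soaring responses).
THERMAL_COEFS = {
    "intercept": -0.591,
    "elevation": 4.82e-4,
    "elevation2": -6.15e-7,
    "slope": -0.035,
    "slope2": 5.69e-4,
    "wind_speed": -0.091,
    "v": -0.001,
    "hs": 4.19e-3,
    "temperature": 1.72e-4,
}
OROGRAPHIC_COEFS = {
    "intercept": -1.29,
    "elevation": -9.70e-4,
    "elevation2": 4.70e-7,
    "slope": 0.034,
    "slope2": -1.06e-4,
    "wind_speed": 0.047,
    "v": 3.26e-4,
    "hs": -2.28e-5,
    "temperature": -2.29e-3,
}


def make_covariate_table(n: int, seed: int) -> pd.DataFrame:
    """Covariates on realistic scales (m, deg, m/s, hill-shade units, C)."""
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame(
        {
            "elevation": rng.uniform(0, 2000, n),
            "slope": rng.uniform(0, 45, n),
            "wind_speed": rng.gamma(2.0, 2.0, n),
            "v": rng.uniform(0, 180, n),
            "hs": rng.uniform(0, 255, n),
            "temperature": rng.uniform(5, 35, n),
        }
    )
    return sg.add_quadratic_terms(cov)


@pytest.fixture(scope="session")
def ridge_dem():
    return sd.simulate_dem(3, (200, 200), 30.0, {"kind": "ridges"})


@pytest.fixture(scope="session")
def sim_bundle(ridge_dem):
    """Three birds, default regime parameters, features on kept segments."""
    tracks = []
    for i, bird in enumerate(["b1", "b2", "b3"]):
        sched = [
            ("perched", 300.0),
            ("thermal_soaring", 240.0),
            ("gliding", 240.0),
            ("orographic_soaring", 240.0),
        ] * 4
        cfg = sd.SimulationConfig(
            seed=10 + i,
            regime_schedule=sched,
            start_x=2500 + 300 * i,
            start_y=1200 + 200 * i,
            bird_id=bird,
            start_time=pd.Timestamp(f"2012-06-0{i + 1} 09:10:00"),
        )
        tracks.append(sd.simulate_track(cfg, ridge_dem))
    fixes = tf.prepare_fixes(pd.concat(tracks, ignore_index=True))
    fixes = tf.filter_fixes_for_analysis(fixes)
    segments = tf.segment_track(fixes)
    kept, removal_log = tf.flag_data_poor_segments(segments, fixes)
    features = tf.extract_features(kept, fixes)
    return {
        "dem": ridge_dem,
        "fixes": fixes,
        "segments": segments,
        "kept": kept,
        "removal_log": removal_log,
        "features": features,
    }


@pytest.fixture(scope="session")
def trained_forest(sim_bundle):
    feat = sim_bundle["features"].dropna(subset=tf.FEATURE_COLUMNS)
    model, report = bc.train(feat, seed=1)
    return {"model": model, "report": report, "features": feat}


@pytest.fixture(scope="session")
def recovery_data():
    """n=20,000 covariates + responses simulated at printed-magnitude coefficients."""
    cov = make_covariate_table(20_000, seed=7)
    y_thermal = sd.simulate_glm_response(3, cov, THERMAL_COEFS)
    y_oro = sd.simulate_glm_response(4, cov, OROGRAPHIC_COEFS)
    return {"cov": cov, "thermal": y_thermal, "orographic": y_oro}


@pytest.fixture(scope="session")
def averaged_models(recovery_data):
    cov = recovery_data["cov"]
    mt = sg.model_average(
        sg.all_subsets_aic(recovery_data["thermal"], cov), response="thermal_soaring"
    )
    mo = sg.model_average(
        sg.all_subsets_aic(recovery_data["orographic"], cov),
        response="orographic_soaring",
    )
    return {"thermal": mt, "orographic": mo}


def nests_for(dem, region: str, n: int = 3, seed: int = 0, clearance: float = 3200.0):
    rng = np.random.default_rng(seed)
    xs = rng.uniform(clearance, dem.ncols * dem.cell_size - clearance, n)
    ys = rng.uniform(clearance, dem.nrows * dem.cell_size - clearance, n)
    lon, lat = local_to_lonlat(xs, ys, dem.ref_lon, dem.ref_lat)
    return pd.DataFrame(
        {
            "nest_id": [f"{region}{i}" for i in range(n)],
            "region": region,
            "lon": lon,
            "lat": lat,
        }
    )


@pytest.fixture(scope="session")
def two_region_summaries(averaged_models):
    """Monthly summaries over a flat and a rugged synthetic landscape.

    Three 3-km territories per region, 100 weather scenarios per month
    sampled from two-year hourly series (windier over the rugged region).
    """
    dem_flat = sd.simulate_dem(
        11, (300, 300), 30.0, {"kind": "ridges", "ridge_height": 60, "n_ridges": 1, "base": 120}
    )
    dem_rugged = sd.simulate_dem(
        12, (300, 300), 30.0, {"kind": "ridges", "ridge_height": 600, "n_ridges": 3, "base": 400}
    )
    wx_flat = sd.simulate_weather(
        21, "2012-01-01", "2014-01-01", sd.WeatherParams(station="flat")
    )
    wx_rugged = sd.simulate_weather(
        22, "2012-01-01", "2014-01-01", sd.WeatherParams(station="rugged", wind_mean=5.0)
    )
    scen_flat = sp.sample_scenarios(wx_flat, 100, seed=5, region="flat")
    scen_rugged = sp.sample_scenarios(wx_rugged, 100, seed=6, region="rugged")
    terr_flat = sp.build_territories(nests_for(dem_flat, "flat", seed=0), dem_flat)
    terr_rugged = sp.build_territories(nests_for(dem_rugged, "rugged", seed=1), dem_rugged)
    mt, mo = averaged_models["thermal"], averaged_models["orographic"]
    summary = pd.concat(
        [
            sp.monthly_summary_table(mt, mo, terr_flat, scen_flat),
            sp.monthly_summary_table(mt, mo, terr_rugged, scen_rugged),
        ],
        ignore_index=True,
    )
    return summary
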