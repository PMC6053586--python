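"""Monthly soaring-probability prediction over circular nest territories.

A territory is the set of DEM cells whose centers lie within a 3-km
buffer of a known nest site.  For each calendar month, weather scenarios
(hourly records between 07:00 and 19:00 local, pooled across years) are
sampled at random; for each scenario the averaged thermal and orographic
models are inverse-logit-evaluated in every territory cell, using the
cell's elevation/slope, hill shade at the scenario's own timestamp, and
the angle of incidence between cell aspect and the scenario's wind
direction.  Cell probabilities are averaged over the territory and then
over the month's scenarios; the thermal and orographic means are summed
into a total soaring potential in [0, 2].  Regions are compared month by
month with Welch's two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from soarscape.geo import lonlat_to_local
from soarscape.raster import Dem
from soarscape.soaring_glm import AveragedModel
from soarscape.terrain_covariates import (
    TerrainGrid,
    angle_of_incidence,
    hill_shade,
    slope_aspect,
    solar_position,
)

#: Local (SAST) hour range of usable weather scenarios, inclusive.
SCENARIO_HOURS = (7, 19)


@dataclass
class Territory:
    """Circular nest buffer with its member DEM cells and static terrain."""

    nest_id: str
    region: str
    lon: float
    lat: float
    radius_m: float
    rows: np.ndarray  # member cell rows (row 0 = north)
    cols: np.ndarray
    elevation: np.ndarray = field(repr=False, default=None)
    slope: np.ndarray = field(repr=False, default=None)
    aspect: np.ndarray = field(repr=False, default=None)

    @property
    def n_cells(self) -> int:
        return len(self.rows)

    @property
    def flat_fraction(self) -> float:
        return float(np.mean(np.isnan(self.aspect)))


def build_territories(
    nests: pd.DataFrame,
    dem: Dem,
    radius_m: float = 3000.0,
    terrain: TerrainGrid | None = None,
    exclude_mask: np.ndarray | None = None,
) -> list[Territory]:
    """Territories for a nest table (``nest_id, region, lon, lat``).

    Cell membership is center-within-radius.  ``exclude_mask`` (same
    shape as the DEM, True = excluded, e.g. sea) removes cells.  Nests
    outside the DEM extent raise an error listing their ids.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    terrain = terrain or slope_aspect(dem)
    nx, ny = lonlat_to_local(
        nests["lon"].to_numpy(), nests["lat"].to_numpy(), dem.ref_lon, dem.ref_lat
    )
    inside = dem.contains(nx, ny)
    if not np.all(inside):
        bad = nests.loc[~inside, "nest_id"].tolist()
        raise ValueError(f"nests outside DEM extent: {bad}")

    xc = dem.x_centers()
    yc = dem.y_centers()
    xx, yy = np.meshgrid(xc, yc)
    territories = []
    for i, rec in nests.reset_index(drop=True).iterrows():
        d2 = (xx - nx[i]) ** 2 + (yy - ny[i]) ** 2
        member = d2 <= radius_m**2
        # the nest's own cell always belongs, however small the buffer
        r0, c0 = dem.cell_index(nx[i], ny[i])
        member[r0, c0] = True
        if exclude_mask is not None:
            member &= ~exclude_mask
        rows, cols = np.nonzero(member)
        territories.append(
            Territory(
                nest_id=str(rec["nest_id"]),
                region=str(rec["region"]),
                lon=float(rec["lon"]),
                lat=float(rec["lat"]),
                radius_m=radius_m,
                rows=rows,
                cols=cols,
                elevation=dem.z[rows, cols],
                slope=terrain.slope_deg[rows, cols],
                aspect=terrain.aspect_deg[rows, cols],
            )
        )
    return territories


def sample_scenarios(
    weather: pd.DataFrame,
    n_per_month: int = 100,
    hours: tuple[int, int] = SCENARIO_HOURS,
    seed: int | None = None,
    region: str = "",
) -> pd.DataFrame:
    """Draw ``n_per_month`` weather scenarios per calendar month.

    Records are pooled across years ("irrespective of year"), restricted
    to local (UTC+2) hours within ``hours`` inclusive, and sampled
    uniformly without replacement; a month with too few valid records is
    sampled with replacement (with a warning).  Rows with missing values
    are excluded first.
    """
    rng = np.random.default_rng(seed)
    wx = weather.copy()
    wx["timestamp"] = pd.to_datetime(wx["timestamp"])
    wx = wx.dropna(subset=["temp_c", "wind_speed_ms", "wind_dir_deg"])
    local = wx["timestamp"] + pd.Timedelta(hours=2)
    wx["local_hour"] = local.dt.hour
    wx["month"] = local.dt.month
    wx = wx.loc[(wx["local_hour"] >= hours[0]) & (wx["local_hour"] <= hours[1])]

    out = []
    for month in range(1, 13):
        pool = wx.loc[wx["month"] == month]
        if len(pool) == 0:
            raise ValueError(f"no valid weather records for month {month}")
        replace = len(pool) < n_per_month
        if replace:
            warnings.warn(
                f"month {month}: only {len(pool)} records, sampling with replacement",
                RuntimeWarning,
            )
        take = rng.choice(len(pool), size=n_per_month, replace=replace)
        sampled = pool.iloc[take].copy()
        sampled["scenario"] = np.arange(n_per_month)
        out.append(sampled)
    result = pd.concat(out, ignore_index=True)
    result["region"] = region
    return result


@dataclass
class PredictionSurface:
    """Per-cell soaring probability for one territory, behavior, scenario."""

    nest_id: str
    region: str
    behavior: str
    month: int
    scenario: int
    probs: np.ndarray

    @property
    def mean_prob(self) -> float:
        return float(np.mean(self.probs))


def _scenario_covariates(
    territory: Territory, scenario: pd.Series
) -> pd.DataFrame:
    """Per-cell model covariates for one weather scenario.

    Hill shade uses the scenario record's own timestamp with solar
    position evaluated at the nest (cells span ~3 km; the solar geometry
    difference across a territory is negligible).  Flat cells take the
    territory-mean angle of incidence of that scenario (90 if the whole
    territory is flat), so the linear predictor stays computable without
    inventing windward structure on plains.
    """
    az, zen = solar_position([scenario["timestamp"]], territory.lon, territory.lat)
    hs = hill_shade(zen[0], territory.slope, az[0], territory.aspect)
    v = angle_of_incidence(territory.aspect, scenario["wind_dir_deg"])
    if np.isnan(v).any():
        fill = float(np.nanmean(v)) if not np.isnan(v).all() else 90.0
        v = np.where(np.isnan(v), fill, v)
    n = territory.n_cells
    return pd.DataFrame(
        {
            "elevation": territory.elevation,
            "elevation2": territory.elevation**2,
            "slope": territory.slope,
            "slope2": territory.slope**2,
            "wind_speed": np.full(n, float(scenario["wind_speed_ms"])),
            "v": v,
            "hs": hs,
            "temperature": np.full(n, float(scenario["temp_c"])),
        }
    )


def predict_surface(
    model: AveragedModel,
    territory: Territory,
    scenario: pd.Series,
    behavior: str = "",
) -> PredictionSurface:
    """Inverse-logit probability of one soaring mode in every territory cell."""
    cov = _scenario_covariates(territory, scenario)
    missing = [t for t in model.terms if t not in cov.columns]
    if missing:
        raise ValueError(f"model terms not computable for cells: {missing}")
    probs = model.predict(cov)
    return PredictionSurface(
        nest_id=territory.nest_id,
        region=territory.region,
        behavior=behavior or model.response,
        month=int(scenario["month"]),
        scenario=int(scenario.get("scenario", 0)),
        probs=probs,
    )


def summarize_monthly(surfaces: list[PredictionSurface]) -> pd.DataFrame:
    """Territory x month summary: mean thermal, mean orographic, total.

    Probabilities are averaged over cells and then over the month's
    scenarios (the order is immaterial for means, and the result is
    invariant to scenario order).  ``total`` is the sum of the two
    behavior means, in [0, 2].
    """
    rows = [
        (s.nest_id, s.region, s.behavior, s.month, s.mean_prob) for s in surfaces
    ]
    df = pd.DataFrame(rows, columns=["nest_id", "region", "behavior", "month", "p"])
    wide = (
        df.groupby(["nest_id", "region", "month", "behavior"])["p"]
        .mean()
        .unstack("behavior")
        .reset_index()
    )
    wide = wide.rename(
        columns={"thermal_soaring": "thermal_mean", "orographic_soaring": "orographic_mean"}
    )
    for col in ("thermal_mean", "orographic_mean"):
        if col not in wide.columns:
            wide[col] = np.nan
    wide["total"] = wide["thermal_mean"] + wide["orographic_mean"]
    return wide.sort_values(["region", "nest_id", "month"]).reset_index(drop=True)


def monthly_summary_table(
    thermal_model: AveragedModel,
    orographic_model: AveragedModel,
    territories: list[Territory],
    scenarios: pd.DataFrame,
) -> pd.DataFrame:
    """Memory-light driver: per-scenario surfaces reduced on the fly."""
    rows = []
    for terr in territories:
        for _, scen in scenarios.iterrows():
            for behavior, model in (
                ("thermal_soaring", thermal_model),
                ("orographic_soaring", orographic_model),
            ):
                s = predict_surface(model, terr, scen, behavior)
                rows.append((terr.nest_id, terr.region, behavior, s.month, s.mean_prob))
    df = pd.DataFrame(rows, columns=["nest_id", "region", "behavior", "month", "p"])
    wide = (
        df.groupby(["nest_id", "region", "month", "behavior"])["p"]
        .mean()
        .unstack("behavior")
        .reset_index()
        .rename(
            columns={
                "thermal_soaring": "thermal_mean",
                "orographic_soaring": "orographic_mean",
            }
        )
    )
    wide["total"] = wide["thermal_mean"] + wide["orographic_mean"]
    return wide.sort_values(["region", "nest_id", "month"]).reset_index(drop=True)


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's two-sample t statistic, Welch-Satterthwaite df, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def compare_regions(
    summaries: pd.DataFrame,
    region_a: str,
    region_b: str,
    columns: tuple[str, ...] = ("thermal_mean", "orographic_mean", "total"),
) -> pd.DataFrame:
    """Monthly Welch tests between two regions' territory summaries."""
    rows = []
    for month in sorted(summaries["month"].unique()):
        sub = summaries.loc[summaries["month"] == month]
        a = sub.loc[sub["region"] == region_a]
        b = sub.loc[sub["region"] == region_b]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >= 2 territories per region in month {month}")
        for col in columns:
            t, df, p = welch_test(a[col].to_numpy(), b[col].to_numpy())
            rows.append((month, col, t, df, p))
    return pd.DataFrame(rows, columns=["month", "measure", "t", "df", "p"])
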