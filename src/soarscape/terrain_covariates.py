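"""Topographic and meteorological covariates for soaring models.

From a DEM this module derives slope and aspect (Horn 8-neighbor
stencil), and combines them with solar geometry and hourly weather into
the two interaction covariates the soaring models use:

- hill shade ``hs = max(0, 255 (cos z cos theta + sin z sin theta
  cos(alpha - beta)))`` with solar zenith ``z``, azimuth ``alpha``,
  terrain slope ``theta`` and aspect ``beta`` — an illumination index in
  [0, 255] proxying the sun exposure that drives thermal uplift;
- the angle of incidence ``v`` in [0, 180] between the direction a slope
  faces and the direction the wind comes from — 180 means wind directly
  hitting the slope (maximal orographic uplift potential), 90 wind
  parallel to the slope, 0 wind from directly behind it.

Aspect uses the direction the slope faces (downhill direction, degrees
clockwise from north); wind direction uses the meteorological "from"
convention.  Solar position follows NOAA solar-calculator geometry,
accurate to a fraction of a degree over 1950-2050.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from soarscape.raster import Dem


@dataclass
class TerrainGrid:
    """Slope/aspect rasters derived from a DEM (same shape, row 0 = north)."""

    slope_deg: np.ndarray
    aspect_deg: np.ndarray
    flat: np.ndarray  # True where the gradient vanishes (aspect undefined)
    border: np.ndarray  # True on edge cells (one-sided stencil support)


def slope_aspect(dem: Dem) -> TerrainGrid:
    """Horn finite-difference slope and facing-direction aspect.

    Slope is ``atan(|grad h|)`` in degrees; aspect is the compass
    direction of the downslope (facing) direction, 0 = north, clockwise.
    Edge cells are computed on a replicated border and flagged.
    """
    z = np.pad(dem.z, 1, mode="edge")
    c = dem.cell_size
    # 8-neighbor views (row 0 = north): N up, S down, E right, W left
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * c)
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * c)
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    flat = grad < 1e-9
    aspect[flat] = np.nan
    border = np.zeros(dem.shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    return TerrainGrid(slope_deg=slope, aspect_deg=aspect, flat=flat, border=border)


# ------------------------------------------------------------------- solar


def solar_position(timestamps_utc, lon, lat) -> tuple[np.ndarray, np.ndarray]:
    """Solar azimuth and zenith (degrees) at UTC instants.

    NOAA solar-calculator geometry: fractional-year Fourier series for the
    equation of time and solar declination, then the hour angle at the
    site longitude.  Azimuth is degrees clockwise from north; zenith above
    90 means the sun is below the horizon.
    """
    times = pd.DatetimeIndex(pd.to_datetime(timestamps_utc))
    doy = times.dayofyear.to_numpy(dtype=float)
    hour = (
        times.hour.to_numpy() + times.minute.to_numpy() / 60.0 + times.second.to_numpy() / 3600.0
    )
    gamma = 2.0 * np.pi / 365.0 * (doy - 1.0 + (hour - 12.0) / 24.0)

    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )

    lon = np.asarray(lon, dtype=float)
    lat_r = np.radians(np.asarray(lat, dtype=float))
    tst = hour * 60.0 + eqtime + 4.0 * lon  # true solar time, minutes (UTC frame)
    ha = np.radians(tst / 4.0 - 180.0)

    cos_zen = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    zenith = np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    east = -np.sin(ha) * np.cos(decl)
    north = np.cos(lat_r) * np.sin(decl) - np.sin(lat_r) * np.cos(decl) * np.cos(ha)
    azimuth = np.degrees(np.arctan2(east, north)) % 360.0
    return azimuth, zenith


# -------------------------------------------------- interaction covariates


def hill_shade(zenith_deg, slope_deg, azimuth_deg, aspect_deg):
    """Illumination index ``255 (cos z cos theta + sin z sin theta
    cos(alpha - beta))``, floored at 0.

    Angles enter in degrees and are converted to radians internally.  A
    flat cell (aspect undefined) contributes only through ``cos theta``
    since ``sin theta = 0`` kills the aspect term; NaN aspect is treated
    as 0 there.
    """
    z = np.radians(np.asarray(zenith_deg, dtype=float))
    th = np.radians(np.asarray(slope_deg, dtype=float))
    al = np.radians(np.asarray(azimuth_deg, dtype=float))
    be = np.asarray(aspect_deg, dtype=float)
    be = np.radians(np.where(np.isnan(be), 0.0, be))
    hs = 255.0 * (np.cos(z) * np.cos(th) + np.sin(z) * np.sin(th) * np.cos(al - be))
    return np.maximum(hs, 0.0)


def angle_of_incidence(aspect_deg, wind_from_deg):
    """Angle of incidence ``v`` in [0, 180] between slope facing and wind.

    ``v = 180 - angular separation(aspect, wind-from)``: 180 when the wind
    blows straight onto the slope face, 0 when it comes from directly
    behind.  Symmetric in its arguments; NaN aspect (flat cell) yields NaN.
    """
    a = np.asarray(aspect_deg, dtype=float) % 360.0
    w = np.asarray(wind_from_deg, dtype=float) % 360.0
    d = np.abs(a - w)
    d = np.minimum(d, 360.0 - d)
    return 180.0 - d


# -------------------------------------------------------------- annotation


def annotate_fixes(
    fixes: pd.DataFrame,
    dem: Dem,
    weather: pd.DataFrame,
    terrain: TerrainGrid | None = None,
    station_map: dict[str, str] | None = None,
    max_gap_min: float = 30.0,
) -> pd.DataFrame:
    """Attach terrain and weather covariates to flying fixes.

    Each fix is joined to the nearest-in-time hourly weather record of its
    station (gaps beyond ``max_gap_min`` flag the row ``weather_missing``
    and such rows are excluded from modeling); terrain values come from
    the DEM cell containing the fix; hill shade is evaluated at the fix's
    own timestamp and location; ``v`` combines the cell aspect with the
    record's wind direction (NaN over flat cells).
    """
    df = fixes.copy().reset_index(drop=True)
    terrain = terrain or slope_aspect(dem)

    if "x" not in df.columns:
        from soarscape.geo import lonlat_to_local

        df["x"], df["y"] = lonlat_to_local(
            df["lon"].to_numpy(), df["lat"].to_numpy(), dem.ref_lon, dem.ref_lat
        )
    rows, cols = dem.cell_index(df["x"].to_numpy(), df["y"].to_numpy())
    df["elevation"] = dem.z[rows, cols]
    df["slope"] = terrain.slope_deg[rows, cols]
    df["aspect"] = terrain.aspect_deg[rows, cols]

    # nearest-hour weather join per station
    wx = weather.copy()
    wx["timestamp"] = pd.to_datetime(wx["timestamp"])
    if station_map is None:
        stations = wx["station"].unique()
        if len(stations) != 1:
            raise ValueError("station_map required with multiple stations")
        station_of = pd.Series(stations[0], index=df.index)
    else:
        station_of = df["bird_id"].map(station_map)
        if station_of.isna().any():
            missing = sorted(df.loc[station_of.isna(), "bird_id"].unique())
            raise ValueError(f"no station mapped for birds: {missing}")

    ts = pd.to_datetime(df["timestamp_utc"])
    temp = np.full(len(df), np.nan)
    wind_speed = np.full(len(df), np.nan)
    wind_dir = np.full(len(df), np.nan)
    gap_ok = np.zeros(len(df), dtype=bool)
    for station, wgrp in wx.groupby("station"):
        sel = np.flatnonzero((station_of == station).to_numpy())
        if not len(sel):
            continue
        wgrp = wgrp.sort_values("timestamp")
        wt = wgrp["timestamp"].astype("int64").to_numpy() / 1e9
        ft = ts.iloc[sel].astype("int64").to_numpy() / 1e9
        pos = np.searchsorted(wt, ft)
        pos = np.clip(pos, 1, len(wt) - 1)
        left, right = pos - 1, pos
        nearest = np.where(np.abs(ft - wt[left]) <= np.abs(wt[right] - ft), left, right)
        gap = np.abs(ft - wt[nearest])
        ok = gap <= max_gap_min * 60.0
        temp[sel] = wgrp["temp_c"].to_numpy()[nearest]
        wind_speed[sel] = wgrp["wind_speed_ms"].to_numpy()[nearest]
        wind_dir[sel] = wgrp["wind_dir_deg"].to_numpy()[nearest]
        gap_ok[sel] = ok
    df["temperature"] = temp
    df["wind_speed"] = wind_speed
    df["wind_dir_deg"] = wind_dir
    df["weather_missing"] = ~gap_ok

    az, zen = solar_position(ts, df["lon"].to_numpy(), df["lat"].to_numpy())
    df["hs"] = hill_shade(zen, df["slope"], az, df["aspect"])
    df["v"] = angle_of_incidence(df["aspect"], df["wind_dir_deg"])
    df.attrs["n_weather_missing"] = int(df["weather_missing"].sum())
    return df
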