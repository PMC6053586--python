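"""Synthetic tracking data, terrain, and weather for soaring-flight analysis.

Real high-resolution raptor tracking data are access-controlled, so every
downstream stage of this package is exercised against simulated stand-ins:
3-s-interval 3D GPS trajectories alternating between four flight regimes
(perched, gliding, orographic soaring, thermal soaring), digital elevation
models with flats and ridges, and seasonal hourly weather series.  The
regime kinematics encode the behavioral signatures the classifier must
recover: thermalling is spiral flight with steady altitude gain and little
horizontal displacement, orographic soaring is straight terrain-following
flight without altitude loss, gliding is straight descending flight, and
perching is pure GPS noise around a fixed ground position.

All simulator defaults are stand-ins chosen to sit inside realistic raptor
flight envelopes while remaining separable in feature space; they are not
estimates from any real bird.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from soarscape.geo import local_to_lonlat
from soarscape.raster import Dem

#: The four behavioral categories, in the fixed tie-break order used
#: throughout the package (argmax ties resolve to the earlier label).
BEHAVIORS = ("perched", "gliding", "orographic_soaring", "thermal_soaring")

TRACK_COLUMNS = [
    "bird_id",
    "timestamp_utc",
    "lon",
    "lat",
    "alt_asl_m",
    "alt_agl_m",
    "true_label",
]


@dataclass
class SimulationConfig:
    """Parameters of one simulated flight bout.

    The regime schedule is an ordered list of ``(behavior, duration_s)``
    pairs executed back to back at ``fix_interval`` sampling.  Defaults:
    thermal climb 1.5 m/s on a 25-m-radius circle completed every 20 s;
    glide sink 1.0 m/s at 15 m/s ground speed; orographic soaring at
    10 m/s holding 50 m above ground; perched speed zero.  GPS noise is
    isotropic Gaussian per axis, applied after the kinematics.
    """

    seed: int = 0
    fix_interval: float = 3.0
    regime_schedule: list[tuple[str, float]] = field(
        default_factory=lambda: [
            ("perched", 300.0),
            ("thermal_soaring", 240.0),
            ("gliding", 240.0),
            ("orographic_soaring", 240.0),
        ]
    )
    thermal_climb_rate: float = 1.5
    thermal_circle_period: float = 20.0
    thermal_circle_radius: float = 25.0
    thermal_drift_speed: float = 0.0
    glide_sink_rate: float = 1.0
    orographic_ground_clearance: float = 50.0
    horizontal_speed_by_behavior: dict[str, float] = field(
        default_factory=lambda: {
            "perched": 0.0,
            "gliding": 15.0,
            "orographic_soaring": 10.0,
        }
    )
    gps_noise_sd: float = 1.5
    start_x: float = 1500.0
    start_y: float = 1500.0
    start_alt_asl: float | None = None
    start_heading: float = 90.0
    start_time: pd.Timestamp = field(
        default_factory=lambda: pd.Timestamp("2012-06-01 09:00:00")
    )
    bird_id: str = "bird01"

    def __post_init__(self) -> None:
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be positive")
        for name in (
            "thermal_climb_rate",
            "thermal_circle_period",
            "thermal_circle_radius",
            "thermal_drift_speed",
            "glide_sink_rate",
            "orographic_ground_clearance",
            "gps_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for label, duration in self.regime_schedule:
            if label not in BEHAVIORS:
                raise ValueError(f"unknown behavior label {label!r}")
            if duration <= 0:
                raise ValueError("regime durations must be positive")


# ---------------------------------------------------------------------- DEM


def simulate_dem(
    seed: int,
    shape: tuple[int, int] = (100, 100),
    cell_size: float = 30.0,
    ridge_spec: dict | None = None,
    ref_lon: float = 18.5,
    ref_lat: float = -32.1,
) -> Dem:
    """Generate a deterministic synthetic elevation grid.

    ``ridge_spec`` selects the landscape family:

    - ``{"kind": "flat", "elevation": h}`` — constant surface.
    - ``{"kind": "plane", "dz_dx": gx, "dz_dy": gy, "base": h}`` — inclined
      plane with the given west-east / south-north gradients (m per m).
    - ``{"kind": "ridges", ...}`` — north-south Gaussian ridges over a base
      plain with smooth low-amplitude roughness; the western quarter of the
      grid is kept flat (slope < 2 deg) while ridge flanks exceed 20 deg.
    """
    nrows, ncols = shape
    if nrows <= 0 or ncols <= 0:
        raise ValueError("DEM dimensions must be positive")
    if nrows < 8 or ncols < 8:
        raise ValueError("DEM must be at least 8x8")
    spec = dict(ridge_spec or {"kind": "ridges"})
    kind = spec.pop("kind", "ridges")

    # cell-center coordinates; row 0 = north
    x = (np.arange(ncols) + 0.5) * cell_size
    y_top = nrows * cell_size
    y = y_top - (np.arange(nrows) + 0.5) * cell_size
    xx, yy = np.meshgrid(x, y)

    if kind == "flat":
        z = np.full(shape, float(spec.get("elevation", 300.0)))
    elif kind == "plane":
        base = float(spec.get("base", 300.0))
        z = base + spec.get("dz_dx", 0.0) * xx + spec.get("dz_dy", 0.0) * yy
    elif kind == "ridges":
        rng = np.random.default_rng(seed)
        base = float(spec.get("base", 250.0))
        height = float(spec.get("ridge_height", 450.0))
        sigma = float(spec.get("ridge_width", 180.0))
        n_ridges = int(spec.get("n_ridges", 2))
        rough_sd = float(spec.get("roughness_sd", 2.0))
        z = np.full(shape, base)
        # ridges confined to the eastern 3/4 so the west stays a plain
        lo = 0.35 * ncols * cell_size
        hi = 0.9 * ncols * cell_size
        centers = rng.uniform(lo, hi, size=n_ridges)
        for cx in centers:
            z += height * np.exp(-((xx - cx) ** 2) / (2.0 * sigma**2))
        rough = rng.normal(0.0, 1.0, size=shape)
        rough = gaussian_filter(rough, sigma=3.0, mode="nearest")
        taper = np.clip((xx / (ncols * cell_size) - 0.15) / 0.15, 0.0, 1.0)
        z += rough_sd * rough * taper
    else:
        raise ValueError(f"unknown DEM kind {kind!r}")

    return Dem(z=z, cell_size=cell_size, ref_lon=ref_lon, ref_lat=ref_lat)


# ------------------------------------------------------------------ weather


@dataclass
class WeatherParams:
    """Seasonal/diurnal structure of the synthetic hourly weather series.

    Temperature is a sinusoidal seasonal cycle (southern-hemisphere phase:
    warmest in mid-January) plus a diurnal cycle peaking at 14:00 local
    (UTC+2) plus Gaussian noise.  Wind speed is Gamma-distributed; wind
    direction is von Mises around a prevailing direction.
    """

    mean_temp: float = 18.0
    seasonal_amp: float = 6.0
    diurnal_amp: float = 5.0
    temp_noise_sd: float = 1.5
    wind_mean: float = 4.0
    wind_shape: float = 2.0
    prevailing_dir: float = 180.0
    dir_concentration: float = 1.5
    station: str = "synthetic"


def simulate_weather(
    seed: int,
    start: str | pd.Timestamp,
    end: str | pd.Timestamp,
    params: WeatherParams | None = None,
) -> pd.DataFrame:
    """Hourly weather records on ``[start, end)`` (UTC timestamps).

    Returns a DataFrame with columns ``timestamp, temp_c, wind_speed_ms,
    wind_dir_deg, station``.
    """
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if end <= start:
        raise ValueError("end must be after start")
    params = params or WeatherParams()
    rng = np.random.default_rng(seed)

    times = pd.date_range(start, end, freq="h", inclusive="left")
    doy = times.dayofyear.to_numpy(dtype=float)
    local_hour = ((times.hour + 2) % 24).to_numpy(dtype=float)  # SAST = UTC+2

    seasonal = params.seasonal_amp * np.cos(2 * np.pi * (doy - 15.0) / 365.25)
    diurnal = params.diurnal_amp * np.cos(2 * np.pi * (local_hour - 14.0) / 24.0)
    temp = (
        params.mean_temp
        + seasonal
        + diurnal
        + rng.normal(0.0, params.temp_noise_sd, size=len(times))
    )
    if params.wind_mean > 0:
        wind = rng.gamma(
            params.wind_shape, params.wind_mean / params.wind_shape, size=len(times)
        )
    else:
        wind = np.zeros(len(times))
    if params.dir_concentration > 0:
        direction = np.degrees(
            rng.vonmises(
                np.radians(params.prevailing_dir - 180.0),
                params.dir_concentration,
                size=len(times),
            )
        ) + 180.0
    else:
        direction = rng.uniform(0.0, 360.0, size=len(times))
    direction = direction % 360.0

    return pd.DataFrame(
        {
            "timestamp": times,
            "temp_c": temp,
            "wind_speed_ms": wind,
            "wind_dir_deg": direction,
            "station": params.station,
        }
    )


# -------------------------------------------------------------------- track


def simulate_track(
    config: SimulationConfig, dem: Dem
) -> pd.DataFrame:
    """Simulate one bird's fix sequence over ``dem`` under ``config``.

    Kinematics run in the DEM's local meter frame and are converted to
    lon/lat only at export.  Altitude above ground is altitude above sea
    level minus the bilinear DEM elevation at the (noisy) fix, so the
    AGL/ASL/terrain identity holds exactly at zero noise.

    Returns a DataFrame with :data:`TRACK_COLUMNS` (one row per fix, at
    ``fix_interval`` spacing) plus local ``x``/``y`` meter columns.
    """
    if not config.regime_schedule:
        raise ValueError("regime_schedule must be non-empty")
    rng = np.random.default_rng(config.seed)
    dt = config.fix_interval

    x, y = float(config.start_x), float(config.start_y)
    if not dem.contains(x, y):
        raise ValueError("start position outside DEM extent")
    ground0 = float(dem.sample_bilinear(x, y))
    alt = ground0 if config.start_alt_asl is None else float(config.start_alt_asl)
    heading = math.radians(config.start_heading)

    xs: list[float] = []
    ys: list[float] = []
    alts: list[float] = []
    labels: list[str] = []

    width = dem.ncols * dem.cell_size
    height = dem.nrows * dem.cell_size
    margin = 0.08 * min(width, height)

    def _aim_interior() -> float:
        """Heading toward a random point in the central half of the DEM."""
        tx = dem.xll + width * rng.uniform(0.3, 0.7)
        ty = dem.yll + height * rng.uniform(0.3, 0.7)
        return math.atan2(tx - x, ty - y)

    fix_index = 0
    for label, duration in config.regime_schedule:
        n_steps = int(round(duration / dt))
        if label in ("gliding", "orographic_soaring"):
            heading = _aim_interior()
        if label == "perched":
            alt = float(dem.sample_bilinear(x, y))
        elif label == "thermal_soaring":
            # place the circle so the current position lies on it with the
            # current heading tangent to it (turning left)
            phase = heading - math.pi / 2.0
            cx = x - config.thermal_circle_radius * math.cos(phase + math.pi)
            cy = y - config.thermal_circle_radius * math.sin(phase + math.pi)
            drift_dir = rng.uniform(0.0, 2 * math.pi)
        for _ in range(n_steps):
            if label == "perched":
                pass  # stationary; exported noise supplies all displacement
            elif label == "thermal_soaring":
                phase += 2 * math.pi * dt / config.thermal_circle_period
                cx += config.thermal_drift_speed * dt * math.cos(drift_dir)
                cy += config.thermal_drift_speed * dt * math.sin(drift_dir)
                new_x = cx + config.thermal_circle_radius * math.cos(phase + math.pi)
                new_y = cy + config.thermal_circle_radius * math.sin(phase + math.pi)
                heading = math.atan2(new_x - x, new_y - y)
                x, y = new_x, new_y
                alt += config.thermal_climb_rate * dt
            elif label in ("gliding", "orographic_soaring"):
                default = 15.0 if label == "gliding" else 10.0
                speed = config.horizontal_speed_by_behavior.get(label, default)
                near_edge = (
                    x < dem.xll + margin
                    or x > dem.xll + width - margin
                    or y < dem.yll + margin
                    or y > dem.yll + height - margin
                )
                if near_edge:
                    heading = _aim_interior()
                elif label == "gliding":
                    # a gliding bird loses altitude; if the descent would
                    # meet rising ground, steer toward the lowest terrain
                    # ahead (valley following) instead of climbing the slope
                    ahead_x = x + 150.0 * math.sin(heading)
                    ahead_y = y + 150.0 * math.cos(heading)
                    if dem.contains(ahead_x, ahead_y) and (
                        alt - config.glide_sink_rate * dt
                        < float(dem.sample_bilinear(ahead_x, ahead_y)) + 15.0
                    ):
                        options = heading + np.linspace(0.0, 2 * math.pi, 16, endpoint=False)
                        ox = x + 150.0 * np.sin(options)
                        oy = y + 150.0 * np.cos(options)
                        ok = dem.contains(ox, oy)
                        ground_ahead = np.where(
                            ok, dem.sample_bilinear(ox, oy), np.inf
                        )
                        heading = float(options[int(np.argmin(ground_ahead))])
                x += speed * dt * math.sin(heading)
                y += speed * dt * math.cos(heading)
                if label == "gliding":
                    alt -= config.glide_sink_rate * dt
                else:
                    if not dem.contains(x, y):
                        raise ValueError(
                            f"track left DEM extent at fix index {fix_index}"
                        )
                    alt = float(dem.sample_bilinear(x, y)) + (
                        config.orographic_ground_clearance
                    )
            if not dem.contains(x, y):
                raise ValueError(f"track left DEM extent at fix index {fix_index}")
            # keep flying fixes above ground even while gliding
            if label == "gliding":
                ground = float(dem.sample_bilinear(x, y))
                alt = max(alt, ground + 5.0)
            xs.append(x)
            ys.append(y)
            alts.append(alt)
            labels.append(label)
            fix_index += 1

    n = len(xs)
    noise = rng.normal(0.0, config.gps_noise_sd, size=(n, 3))
    if config.gps_noise_sd == 0:
        noise = np.zeros((n, 3))
    px = np.asarray(xs) + noise[:, 0]
    py = np.asarray(ys) + noise[:, 1]
    palt = np.asarray(alts) + noise[:, 2]
    agl = palt - dem.sample_bilinear(px, py)
    lon, lat = local_to_lonlat(px, py, dem.ref_lon, dem.ref_lat)
    times = config.start_time + pd.to_timedelta((np.arange(n) + 1) * dt, unit="s")

    return pd.DataFrame(
        {
            "bird_id": config.bird_id,
            "timestamp_utc": times,
            "lon": lon,
            "lat": lat,
            "alt_asl_m": palt,
            "alt_agl_m": agl,
            "true_label": labels,
            "x": px,
            "y": py,
        }
    )


def simulate_glm_response(
    seed: int, covariate_table: pd.DataFrame, coefficients: dict[str, float]
) -> np.ndarray:
    """Bernoulli outcomes from a logistic model over ``covariate_table``.

    ``coefficients`` maps term names to values and must contain
    ``"intercept"``; every other key must be a column of the table.
    """
    if "intercept" not in coefficients:
        raise ValueError("coefficients must include 'intercept'")
    missing = [
        name
        for name in coefficients
        if name != "intercept" and name not in covariate_table.columns
    ]
    if missing:
        raise ValueError(f"coefficient names missing from covariates: {missing}")
    eta = np.full(len(covariate_table), float(coefficients["intercept"]))
    for name, coef in coefficients.items():
        if name == "intercept":
            continue
        eta += coef * covariate_table[name].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    return (rng.random(len(covariate_table)) < expit(eta)).astype(int)


# ------------------------------------------------------------------- export


def export_track_csv(track: pd.DataFrame, path) -> None:
    """Write a track table in the delimited interchange layout."""
    track.loc[:, TRACK_COLUMNS].to_csv(path, index=False)


def export_weather_csv(weather: pd.DataFrame, path) -> None:
    weather.to_csv(path, index=False)
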