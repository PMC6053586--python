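"""Windowed movement features for flight-behavior classification.

Each GPS fix is characterized by the 90-s track segment around it (all
fixes of the same bird within +/-45 s) and six features computed on that
segment:

a. mean three-dimensional instantaneous speed (m/s);
b. rate of change of altitude above sea level (OLS slope vs time, m/s);
c. rate of change of altitude above ground level (OLS slope vs time, m/s);
d. R^2 of altitude-ASL vs time;
e. R^2 of altitude-AGL vs altitude-ASL;
f. dominant frequency of the periodogram of the heading series (cycles/s).

Thermalling produces steady ASL gain (b > 0), tight ASL/AGL coupling
(e near 1) and a strong periodic heading signature (high f); orographic
soaring is straight flight holding altitude above ground; gliding is
straight descending flight; perching is near-zero speed.

Data-quality rules: fixes are kept only at sampling intervals <= 6 s and
(optionally) within the 11:00-15:00 SAST midday window; segments with
fewer than five fixes or without any 3-s-interval fix are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from soarscape.geo import bearing_deg, lonlat_to_local

#: SAST is a fixed UTC+2 offset (South Africa observes no DST).
SAST_UTC_OFFSET_H = 2

FEATURE_COLUMNS = [
    "a_speed",
    "b_rate_asl",
    "c_rate_agl",
    "d_r2_asl_time",
    "e_r2_agl_asl",
    "f_domfreq",
]


@dataclass
class TrackSegment:
    """All fixes of one bird within +/- ``half_window_s`` of a focal fix.

    ``start``/``stop`` index the bird's time-sorted fix array; ``focal`` is
    the absolute index of the focal fix in the prepared fix table.
    """

    bird_id: str
    focal: int
    start: int
    stop: int

    @property
    def n_fixes(self) -> int:
        return self.stop - self.start


# ------------------------------------------------------------- preparation


def prepare_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """Sort fixes, attach local meter coordinates and sampling intervals.

    The sampling interval of a fix is the gap to its predecessor within
    the same bird; the first fix of a bird takes the following gap so it
    is not spuriously dropped by the interval filter.
    """
    df = fixes.copy()
    df["timestamp_utc"] = pd.to_datetime(df["timestamp_utc"])
    df = df.sort_values(["bird_id", "timestamp_utc"], kind="mergesort")
    df = df.reset_index(drop=True)
    if "x" not in df.columns or "y" not in df.columns:
        ref_lon = float(df["lon"].mean())
        ref_lat = float(df["lat"].mean())
        x, y = lonlat_to_local(df["lon"].to_numpy(), df["lat"].to_numpy(), ref_lon, ref_lat)
        df["x"] = x
        df["y"] = y
    t = df["timestamp_utc"].astype("int64").to_numpy() / 1e9
    interval = np.empty(len(df))
    for _, idx in df.groupby("bird_id", sort=False).indices.items():
        ts = t[idx]
        if len(ts) == 1:
            interval[idx] = np.nan
            continue
        gaps = np.diff(ts)
        interval[idx[1:]] = gaps
        interval[idx[0]] = gaps[0]
    df["interval_s"] = interval
    df["t_s"] = t
    return df


def filter_fixes_for_analysis(
    fixes: pd.DataFrame,
    max_interval_s: float = 6.0,
    time_window: tuple[int, int] | None = (11, 15),
) -> pd.DataFrame:
    """Keep fixes sampled at <= ``max_interval_s`` inside the midday window.

    The local-time filter is half-open ``[start, end)`` in SAST (UTC+2);
    pass ``time_window=None`` to disable it.
    """
    df = fixes if "interval_s" in fixes.columns else prepare_fixes(fixes)
    keep = df["interval_s"].to_numpy() <= max_interval_s
    if time_window is not None:
        local = df["timestamp_utc"] + pd.Timedelta(hours=SAST_UTC_OFFSET_H)
        hour = local.dt.hour + local.dt.minute / 60.0 + local.dt.second / 3600.0
        keep &= (hour >= time_window[0]) & (hour < time_window[1])
    return df.loc[keep].reset_index(drop=True)


# ------------------------------------------------------------ segmentation


def segment_track(fixes: pd.DataFrame, half_window_s: float = 45.0) -> list[TrackSegment]:
    """One segment per fix: all same-bird fixes in the closed window
    ``[t - half_window_s, t + half_window_s]``."""
    df = fixes if "t_s" in fixes.columns else prepare_fixes(fixes)
    segments: list[TrackSegment] = []
    for bird, idx in df.groupby("bird_id", sort=False).indices.items():
        ts = df["t_s"].to_numpy()[idx]
        base = idx[0]
        lo = np.searchsorted(ts, ts - half_window_s, side="left")
        hi = np.searchsorted(ts, ts + half_window_s, side="right")
        for k in range(len(ts)):
            segments.append(
                TrackSegment(bird_id=bird, focal=base + k, start=base + lo[k], stop=base + hi[k])
            )
    return segments


def flag_data_poor_segments(
    segments: list[TrackSegment], fixes: pd.DataFrame
) -> tuple[list[TrackSegment], pd.DataFrame]:
    """Drop segments with < 5 fixes or with no fix sampled at 3 s.

    A fix counts as 3-s data when its sampling interval rounds to 3 s.
    Returns the kept segments and a removal log with one reason per
    removed segment (``few_locations`` takes precedence).
    """
    interval = fixes["interval_s"].to_numpy()
    kept: list[TrackSegment] = []
    log_rows = []
    for seg in segments:
        if seg.n_fixes < 5:
            log_rows.append((seg.focal, "few_locations"))
            continue
        member_iv = interval[seg.start : seg.stop]
        if not np.any(np.abs(member_iv - 3.0) <= 0.5):
            log_rows.append((seg.focal, "no_3s_data"))
            continue
        kept.append(seg)
    log = pd.DataFrame(log_rows, columns=["focal", "reason"])
    return kept, log


# ----------------------------------------------------------------- features


def _ols_slope_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Simple-regression slope and R^2 via centered normal equations.

    A zero-variance response yields slope 0 and R^2 defined as 0 (the
    0/0 case), so perched segments remain representable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x - x.mean()
    ym = y - y.mean()
    sxx = float(xm @ xm)
    syy = float(ym @ ym)
    sxy = float(xm @ ym)
    if sxx <= 0.0:
        return 0.0, 0.0
    if syy <= 0.0:
        return 0.0, 0.0
    slope = sxy / sxx
    r2 = (sxy * sxy) / (sxx * syy)
    return slope, min(r2, 1.0)


def mean_speed_3d(seg: TrackSegment, fixes: pd.DataFrame) -> float:
    """Mean over consecutive-fix 3D speeds ||d(x, y, alt_asl)|| / dt."""
    sl = slice(seg.start, seg.stop)
    if seg.n_fixes < 2:
        return np.nan
    x = fixes["x"].to_numpy()[sl]
    y = fixes["y"].to_numpy()[sl]
    z = fixes["alt_asl_m"].to_numpy()[sl]
    t = fixes["t_s"].to_numpy()[sl]
    dt = np.diff(t)
    d = np.sqrt(np.diff(x) ** 2 + np.diff(y) ** 2 + np.diff(z) ** 2)
    return float(np.mean(d / dt))


def altitude_regressions(
    seg: TrackSegment, fixes: pd.DataFrame
) -> tuple[float, float, float, float]:
    """(b, c, d, e): ASL and AGL trend slopes plus the two R^2 values.

    b and d come from the regression of altitude ASL on time; e from the
    regression of altitude AGL on altitude ASL.  c is reported in m/s as
    the slope of altitude AGL on time (the AGL-on-ASL slope itself is
    dimensionless and enters only through e).
    """
    sl = slice(seg.start, seg.stop)
    t = fixes["t_s"].to_numpy()[sl]
    asl = fixes["alt_asl_m"].to_numpy()[sl]
    agl = fixes["alt_agl_m"].to_numpy()[sl]
    b, d = _ols_slope_r2(t, asl)
    c, _ = _ols_slope_r2(t, agl)
    _, e = _ols_slope_r2(asl, agl)
    return b, c, d, e


def heading_series(seg: TrackSegment, fixes: pd.DataFrame) -> np.ndarray:
    """Compass bearings (degrees) of consecutive-fix displacements."""
    sl = slice(seg.start, seg.stop)
    x = fixes["x"].to_numpy()[sl]
    y = fixes["y"].to_numpy()[sl]
    return bearing_deg(np.diff(x), np.diff(y))


def dominant_frequency(
    headings: np.ndarray, sample_interval_s: float, unwrap: bool = False
) -> float:
    """Frequency (cycles/s) of maximal periodogram density of a heading series.

    The series is linearly detrended (not unwrapped by default: the
    360-degree wrap of circling flight produces a sawtooth whose period
    is itself the circling period, a strong and useful signature).  A
    constant series returns 0.  Requires >= 8 headings.
    """
    h = np.asarray(headings, dtype=float)
    if len(h) < 8:
        return np.nan
    if unwrap:
        h = np.degrees(np.unwrap(np.radians(h)))
    freqs, power = signal.periodogram(
        h, fs=1.0 / sample_interval_s, window="boxcar", detrend="linear"
    )
    freqs, power = freqs[1:], power[1:]  # drop the zero-frequency bin
    if not len(power) or np.max(power) < 1e-12:
        return 0.0
    return float(freqs[np.argmax(power)])


def _modal_interval(seg: TrackSegment, fixes: pd.DataFrame) -> float:
    iv = fixes["interval_s"].to_numpy()[seg.start : seg.stop]
    vals, counts = np.unique(np.round(iv).astype(int), return_counts=True)
    return float(vals[np.argmax(counts)])


def extract_features(
    segments: list[TrackSegment],
    fixes: pd.DataFrame,
    unwrap_headings: bool = False,
) -> pd.DataFrame:
    """Feature table keyed by focal fix (one row per segment).

    Rows where any feature is undefined (too few fixes or headings) carry
    NaN in that feature and ``missing_any=True``.  Extraction is pure:
    the same fixes always yield the identical table.
    """
    rows = []
    for seg in segments:
        a = mean_speed_3d(seg, fixes)
        b, c, d, e = altitude_regressions(seg, fixes)
        f = dominant_frequency(
            heading_series(seg, fixes), _modal_interval(seg, fixes), unwrap=unwrap_headings
        )
        rows.append((seg.focal, a, b, c, d, e, f))
    feat = pd.DataFrame(rows, columns=["focal"] + FEATURE_COLUMNS)
    meta_cols = ["bird_id", "timestamp_utc", "lon", "lat"]
    if "true_label" in fixes.columns:
        meta_cols.append("true_label")
    meta = fixes.loc[feat["focal"].to_numpy(), meta_cols].reset_index(drop=True)
    out = pd.concat([meta, feat.drop(columns=["focal"])], axis=1)
    out["missing_any"] = out[FEATURE_COLUMNS].isna().any(axis=1)
    return out
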