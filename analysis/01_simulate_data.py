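"""Simulate the study inputs: terrain, weather, nests, and eagle tracks.

Real high-resolution eagle tracking and station weather are
access-controlled, so the whole analysis runs on synthetic stand-ins
with the same structure: two contrasting 9 x 9 km landscapes (a flat
plain and a rugged ridge landscape), two years of hourly weather per
region, nest sites for three territories per region, and nine bird-days
of 3-s GPS fixes (three birds, three days each) cycling through the four
flight regimes over the rugged terrain.

Writes delimited text and ESRI ASCII rasters under results/data/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from soarscape import synthetic_data as sd
from soarscape.geo import local_to_lonlat

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    dem_flat = sd.simulate_dem(
        seed + 10, (300, 300), 30.0,
        {"kind": "ridges", "ridge_height": 60, "n_ridges": 1, "base": 120},
    )
    dem_rugged = sd.simulate_dem(
        seed + 11, (300, 300), 30.0,
        {"kind": "ridges", "ridge_height": 600, "n_ridges": 3, "base": 400},
    )
    dem_flat.write_ascii(OUT / "dem_flat.asc")
    dem_rugged.write_ascii(OUT / "dem_rugged.asc")

    for name, wseed, params in (
        ("flat", seed + 20, sd.WeatherParams(station="flat")),
        ("rugged", seed + 21, sd.WeatherParams(station="rugged", wind_mean=5.0)),
    ):
        wx = sd.simulate_weather(wseed, "2012-01-01", "2014-01-01", params)
        sd.export_weather_csv(wx, OUT / f"weather_{name}.csv")
        print(f"weather_{name}: {len(wx)} hourly records")

    # three nests per region, placed with full 3-km buffers inside each DEM
    import numpy as np

    nest_rows = []
    for region, dem, nseed in (("flat", dem_flat, seed + 30), ("rugged", dem_rugged, seed + 31)):
        rng = np.random.default_rng(nseed)
        for i in range(3):
            x = rng.uniform(3200, dem.ncols * 30 - 3200)
            y = rng.uniform(3200, dem.nrows * 30 - 3200)
            lon, lat = local_to_lonlat(x, y, dem.ref_lon, dem.ref_lat)
            nest_rows.append((f"{region}{i}", region, float(lon), float(lat)))
    nests = pd.DataFrame(nest_rows, columns=["nest_id", "region", "lon", "lat"])
    nests.to_csv(OUT / "nests.csv", index=False)

    # nine bird-days over the rugged landscape, 11:10-12:18 SAST each day
    tracks = []
    day_cycle = [
        ("perched", 300.0),
        ("thermal_soaring", 240.0),
        ("gliding", 240.0),
        ("orographic_soaring", 240.0),
    ] * 4
    for b, bird in enumerate(["eagle01", "eagle02", "eagle03"]):
        for d in range(3):
            cfg = sd.SimulationConfig(
                seed=seed + 100 * b + d,
                regime_schedule=day_cycle,
                start_x=2500.0 + 400 * b,
                start_y=1200.0 + 300 * d,
                bird_id=bird,
                start_time=pd.Timestamp(f"2012-06-{10 * d + 1:02d} 09:10:00"),
            )
            tracks.append(sd.simulate_track(cfg, dem_rugged))
    track = pd.concat(tracks, ignore_index=True)
    sd.export_track_csv(track, OUT / "tracks.csv")
    print(f"tracks: {len(track)} fixes, {track['bird_id'].nunique()} birds, "
          f"{track['timestamp_utc'].dt.date.nunique()} days")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    main(parser.parse_args().seed)
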