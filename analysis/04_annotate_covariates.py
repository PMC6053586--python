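"""Attach terrain and weather covariates to the classified flying fixes.

Each flying fix gets its DEM cell's elevation, slope, and aspect, the
nearest-in-time hourly weather record (30-min tolerance), hill shade at
the fix's own timestamp, and the angle of incidence between cell aspect
and wind direction.

Reads results/labeled_flying.csv, results/data/dem_rugged.asc and
results/data/weather_rugged.csv; writes results/covariates.csv.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from soarscape import terrain_covariates as tc
from soarscape.raster import Dem

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    flying = pd.read_csv(ROOT / "labeled_flying.csv", parse_dates=["timestamp_utc"])
    dem = Dem.read_ascii(ROOT / "data" / "dem_rugged.asc")
    weather = pd.read_csv(ROOT / "data" / "weather_rugged.csv", parse_dates=["timestamp"])

    annotated = tc.annotate_fixes(flying, dem, weather)
    annotated.to_csv(ROOT / "covariates.csv", index=False)
    print(f"annotated {len(annotated)} flying fixes "
          f"({annotated.attrs['n_weather_missing']} without usable weather)")
    print(annotated[["elevation", "slope", "hs", "v", "wind_speed", "temperature"]]
          .describe().loc[["mean", "std", "min", "max"]].round(2))


if __name__ == "__main__":
    main()
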