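"""Predict monthly soaring probability over territories in both regions.

Builds 3-km circular territories around the six nests, samples 100
weather scenarios per month per region from the two-year hourly series,
evaluates the averaged thermal and orographic models in every territory
cell under every scenario, and summarizes cell-then-scenario means per
territory and month.  Regions are compared with monthly Welch t-tests,
and the monthly curves are plotted.

Reads the outputs of 01 and 05; writes results/monthly_summary.csv,
results/welch_tests.csv and results/fig_monthly_soaring.png.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from soarscape import soaring_prediction as sp
from soarscape.raster import Dem
from soarscape.soaring_glm import AveragedModel

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    thermal = AveragedModel.from_json((ROOT / "model_thermal.json").read_text())
    oro = AveragedModel.from_json((ROOT / "model_orographic.json").read_text())
    nests = pd.read_csv(ROOT / "data" / "nests.csv")

    summaries = []
    for i, region in enumerate(("flat", "rugged")):
        dem = Dem.read_ascii(ROOT / "data" / f"dem_{region}.asc")
        weather = pd.read_csv(
            ROOT / "data" / f"weather_{region}.csv", parse_dates=["timestamp"]
        )
        scenarios = sp.sample_scenarios(weather, 100, seed=seed + i, region=region)
        territories = sp.build_territories(
            nests.loc[nests["region"] == region], dem, radius_m=3000.0
        )
        print(f"{region}: {len(territories)} territories of "
              f"~{territories[0].n_cells} cells, {len(scenarios)} scenarios")
        summaries.append(sp.monthly_summary_table(thermal, oro, territories, scenarios))
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(ROOT / "monthly_summary.csv", index=False)

    welch = sp.compare_regions(summary, "flat", "rugged")
    welch.to_csv(ROOT / "welch_tests.csv", index=False)

    piv = summary.groupby(["region", "month"])[
        ["thermal_mean", "orographic_mean", "total"]
    ].mean()
    print("\nregion-mean monthly soaring probability:")
    print(piv.round(3))
    n_sig = int((welch.loc[welch["measure"] == "thermal_mean", "p"] < 0.05).sum())
    print(f"\nthermal difference flat vs rugged significant in {n_sig}/12 months "
          f"(Welch p < 0.05)")

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), sharex=True)
    for ax, col, title in zip(
        axes,
        ["thermal_mean", "orographic_mean", "total"],
        ["Thermal soaring", "Orographic soaring", "Combined total"],
    ):
        for region, color in (("flat", "tab:blue"), ("rugged", "tab:green")):
            sub = summary[summary["region"] == region]
            mean = sub.groupby("month")[col].mean()
            spread = sub.groupby("month")[col].std()
            ax.errorbar(mean.index, mean, yerr=spread, label=region, color=color,
                        capsize=2, marker="o", ms=3)
        ax.set_title(title)
        ax.set_xlabel("month")
    axes[0].set_ylabel("predicted probability")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(ROOT / "fig_monthly_soaring.png", dpi=120)
    print(f"figure written to {ROOT / 'fig_monthly_soaring.png'}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    main(parser.parse_args().seed)
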