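"""Fit beta-sigmoid growth curves on thermal time and derive shoot phenotypes.

Converts each plant's height series from calendar days to growing degree
days, fits the four-parameter beta-sigmoid, and derives the time of
maximal shoot growth, the maximal growth rate and the end of growth (in
days after sowing), comparing against the generator's ground truth.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from fieldomics import growth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--trial", type=Path, default=Path("results/simulated_trial"))
    ap.add_argument("--out", type=Path, default=Path("results/growth"))
    args = ap.parse_args()

    series = pd.read_csv(args.trial / "growth_series.csv")
    temp = pd.read_csv(args.trial / "temperature.csv")
    temps = growth.TemperatureSeries(
        days=temp["day"].to_numpy(int), temps=temp["temp_c"].to_numpy(float)
    )
    truth = json.loads((args.trial / "truth.json").read_text())["growth_params"]
    sowing = int(temps.days[0])

    rows = []
    for plant, sub in series.groupby("plant_id"):
        ages = growth.gdd_transform(sub["day"].to_numpy(), temps)
        fit = growth.fit_growth_curve(ages, sub["height_cm"].to_numpy())
        row = {"plant_id": plant, "converged": fit.converged, "rss": fit.rss,
               "h0": fit.h0, "hmax": fit.hmax, "tm_gdd": fit.tm, "te_gdd": fit.te}
        if fit.converged:
            try:
                summary = growth.growth_summary(fit, temps, sowing)
                row.update(max_rate_cm_per_gdd=summary.max_rate,
                           tm_das=summary.tm_das, te_das=summary.te_das)
            except ValueError:
                row["converged"] = False
        rows.append(row)
    table = pd.DataFrame(rows).set_index("plant_id")

    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "growth_parameters.csv")

    fitted = table[table["converged"]]
    tm_err = [
        abs(fitted.loc[p, "tm_gdd"] - truth[p]["tm"]) / truth[p]["tm"]
        for p in fitted.index
    ]
    print(f"fitted {len(fitted)}/{len(table)} plants")
    print(f"median tm: {fitted['tm_gdd'].median():.0f} GDD "
          f"({fitted['tm_das'].median():.0f} DAS); "
          f"median te: {fitted['te_gdd'].median():.0f} GDD")
    print(f"median max growth rate: {fitted['max_rate_cm_per_gdd'].median():.3f} cm/GDD")
    print(f"median relative tm error vs truth: {np.median(tm_err)*100:.1f}%")


if __name__ == "__main__":
    main()
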