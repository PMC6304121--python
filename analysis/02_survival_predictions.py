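"""How long can nodule-acquired PHB sustain a resting cell in the soil?

Fits the annual soil-temperature sinusoid to monthly means, sums the daily
PHB budget for the 20-month inter-crop gap under deep dormancy, and builds
days-supported curves across the five metabolic states for a grid of PHB
endowments. Writes results/survival_curves.csv and
results/survival_summary.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rhizophb.survival_model import (
    STATE_ORDER,
    TemperatureModel,
    days_supported,
    fit_temperature_model,
    phb_biomass_fraction,
    phb_required,
    soil_temperature,
    survival_curve,
)

OUT = Path(__file__).resolve().parents[1] / "results"
START_DAY = 258  # 15 September: starvation begins at soya-bean harvest
TWENTY_MONTHS = 608  # round(20 * 365 / 12)


def main() -> None:
    OUT.mkdir(exist_ok=True)

    # monthly means consistent with southern-Minnesota soil at 20 cm depth
    truth = TemperatureModel(t_max=25.0, t_min=-3.0, delta=121.0)
    months = [
        (m, float(soil_temperature((m - 0.5) * 365 / 12, truth)))
        for m in range(1, 13)
    ]
    fit = fit_temperature_model(months)
    model = fit.model
    print(
        f"temperature fit: Tmax {model.t_max:.1f} C, Tmin {model.t_min:.1f} C, "
        f"midpoint day {model.delta:.0f}"
    )

    budget = phb_required(TWENTY_MONTHS, START_DAY, "dormancy", temp_model=model)
    print(
        f"dormancy budget for {TWENTY_MONTHS} d from day {START_DAY}: "
        f"{budget:.2e} pg PHB"
    )
    print(
        "a cell holding 2 pg PHB is "
        f"{phb_biomass_fraction(2.0):.0%} storage polymer by mass"
    )

    grid = np.round(np.logspace(np.log10(0.001), np.log10(3.0), 25), 6)
    curves = survival_curve(grid, START_DAY, STATE_ORDER, temp_model=model,
                            max_days=200_000)
    rows = [
        {"state": c.state, "phb_pg": p, "days_supported": d, "censored": cen}
        for c in curves
        for p, d, cen in zip(c.phb_pg, c.days, c.censored)
    ]
    pd.DataFrame(rows).to_csv(OUT / "survival_curves.csv", index=False)

    key_points = {}
    for phb, label in ((0.042, "low-PHB strain geometric mean"),
                       (1.0, "high-PHB strain geometric mean")):
        per_state = {
            s: days_supported(phb, START_DAY, s, temp_model=model,
                              max_days=200_000).days
            for s in ("full_somatic_maintenance", "dormancy")
        }
        key_points[label] = {"phb_pg": phb, **per_state}
        print(
            f"{label} ({phb} pg): full somatic maintenance "
            f"{per_state['full_somatic_maintenance']} d, dormancy "
            f">= {per_state['dormancy']} d"
        )

    summary = {
        "temperature_model": {"t_max": model.t_max, "t_min": model.t_min,
                              "delta": model.delta},
        "dormancy_budget_608d_pg": budget,
        "phb_2pg_biomass_fraction": phb_biomass_fraction(2.0),
        "key_points": key_points,
    }
    (OUT / "survival_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {OUT / 'survival_curves.csv'} and survival_summary.json")


if __name__ == "__main__":
    main()
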