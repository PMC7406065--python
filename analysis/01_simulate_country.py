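"""Generate the desk-scale synthetic country and its household survey.

Writes the bulky tables (villages, covariates, census, survey) under
scratch/run/ and a compact summary of the simulated population under
results/01_country_summary.json.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from popdensity import io as pio
from popdensity import synthetic as syn
from popdensity.config import desk_design, desk_scenario

SEED = 1
OUT = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    scenario = desk_scenario(seed=SEED)
    design = desk_design(seed=SEED + 1)
    frame = syn.generate_admin_frame(scenario)
    covars = syn.generate_covariates(frame, scenario)
    census = syn.generate_census(frame, covars, scenario)
    sample = syn.draw_survey(frame, covars, census, design, scenario)

    scenario.to_yaml(OUT / "scenario.yaml")
    design.to_yaml(OUT / "design.yaml")
    pio.write_csv("villages", frame, OUT / "villages.csv")
    pio.write_csv("covariates", covars, OUT / "covariates.csv")
    pio.write_csv("census", census, OUT / "census.csv")
    pio.write_csv("survey_households", sample.households, OUT / "survey.csv")
    pio.write_csv("survey_psus", sample.psus, OUT / "survey_psus.csv")

    d = census["density"]
    summary = {
        "n_villages": int(len(frame)),
        "n_subdistricts": int(frame["sub_district_id"].nunique()),
        "n_districts": int(frame["district_id"].nunique()),
        "urban_fraction": float((frame["sector"] == "urban").mean()),
        "mean_area_km2": float(frame["area_km2"].mean()),
        "density_mean": float(d.mean()),
        "density_sd": float(d.std()),
        "density_min": float(d.min()),
        "density_max": float(d.max()),
        "n_villages_surveyed": int(sample.psus["village_id"].nunique()),
        "n_households_surveyed": int(len(sample.households)),
    }
    with open(RESULTS / "01_country_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    print("Simulated country written to", OUT)
    print(
        f"density mean {summary['density_mean']:.0f} /km^2, "
        f"sd {summary['density_sd']:.0f} (right-skewed, sd > mean), "
        f"{summary['urban_fraction']:.1%} urban villages"
    )
    print(
        f"survey: {summary['n_villages_surveyed']} villages, "
        f"{summary['n_households_surveyed']} households"
    )


if __name__ == "__main__":
    main()
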