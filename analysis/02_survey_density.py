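"""Estimate village density from the survey and check census concordance.

Reads the tables written by 01_simulate_country.py, computes the
survey-based village densities (single-PSU villages only), and reports the
correlation with the census realization -- the diagnostic that justifies
using survey densities as the model's response variable.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from popdensity import io as pio
from popdensity.survey_density import estimate_village_density, survey_census_concordance
from popdensity.synthetic import SurveySample

RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main() -> None:
    frame = pio.read_csv("villages", RUN / "villages.csv")
    census = pio.read_csv("census", RUN / "census.csv")
    sample = SurveySample(
        households=pio.read_csv("survey_households", RUN / "survey.csv"),
        psus=pio.read_csv("survey_psus", RUN / "survey_psus.csv"),
    )

    est = estimate_village_density(sample, frame)
    pio.write_csv("hies_density", est, RUN / "hies_density.csv")
    corr = survey_census_concordance(est, census)

    inc = est.loc[est["included"], "hies_density"]
    summary = {
        "n_sampled_villages": int(len(est)),
        "n_included_single_psu": int(est["included"].sum()),
        "excluded_multi_psu_fraction": float(1.0 - est["included"].mean()),
        "survey_density_mean": float(inc.mean()),
        "survey_density_sd": float(inc.std()),
        "survey_census_correlation": float(corr),
    }
    with open(RESULTS / "02_survey_density.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    print(
        f"{summary['n_included_single_psu']} single-PSU villages kept "
        f"({summary['excluded_multi_psu_fraction']:.1%} excluded as multi-PSU)"
    )
    print(f"survey-census density correlation: {corr:.3f}")


if __name__ == "__main__":
    main()
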