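"""Schema-validated CSV I/O for the pipeline's tabular artifacts.

Every table the pipeline writes or reads passes through these helpers so a
renamed or missing column fails loudly at the boundary instead of
propagating NaNs.
"""

from __future__ import annotations

import pandas as pd

from .design import SchemaError

SCHEMAS: dict[str, list[str]] = {
    "villages": ["village_id", "district_id", "sub_district_id", "sector", "area_km2", "log_area"],
    "covariates": ["village_id"],          # plus free-form covariate columns
    "census": ["village_id", "population", "density"],
    "survey_households": ["household_id", "village_id", "psu_id", "household_size", "design_weight"],
    "survey_psus": [
        "psu_id",
        "village_id",
        "psu_census_population",
        "psu_census_share",
        "psu_stage_prob",
        "village_prob",
    ],
    "hies_density": ["village_id", "hies_density", "n_psus_sampled", "included"],
    "predictions": ["village_id", "density_pred"],
}


def validate(table: str, df: pd.DataFrame) -> pd.DataFrame:
    required = SCHEMAS.get(table)
    if required is None:
        raise SchemaError(f"unknown table kind {table!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} missing columns {missing}")
    return df


def write_csv(table: str, df: pd.DataFrame, path) -> None:
    validate(table, df).to_csv(path, index=False)


def read_csv(table: str, path) -> pd.DataFrame:
    return validate(table, pd.read_csv(path))
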