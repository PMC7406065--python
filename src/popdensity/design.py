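"""Design matrix for the density model.

Columns split into a penalized block X (geo-spatial covariates) and a
forced block Z that every model keeps: the urban indicator, log village
area, and district fixed effects in reference-category coding (the
lexicographically first district is dropped).  The intercept is handled by
the solvers and is never a column here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """Raised when required columns are missing or malformed."""


@dataclass
class DesignMatrix:
    data: np.ndarray                      # n x p, float
    columns: list[str]
    penalized: np.ndarray                 # bool mask over columns
    village_ids: np.ndarray
    sub_district_ids: np.ndarray
    reference_district: str | None = None

    def __post_init__(self) -> None:
        if self.data.shape[1] != len(self.columns):
            raise SchemaError("column count mismatch")
        self.penalized = np.asarray(self.penalized, dtype=bool)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def penalized_columns(self) -> list[str]:
        return [c for c, p in zip(self.columns, self.penalized) if p]

    @property
    def forced_columns(self) -> list[str]:
        return [c for c, p in zip(self.columns, self.penalized) if not p]

    def col(self, name: str) -> np.ndarray:
        return self.data[:, self.columns.index(name)]

    def take_rows(self, idx: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(
            data=self.data[idx],
            columns=list(self.columns),
            penalized=self.penalized.copy(),
            village_ids=self.village_ids[idx],
            sub_district_ids=self.sub_district_ids[idx],
            reference_district=self.reference_district,
        )

    def take_columns(self, names: list[str]) -> "DesignMatrix":
        idx = [self.columns.index(c) for c in names]
        return DesignMatrix(
            data=self.data[:, idx],
            columns=list(names),
            penalized=self.penalized[idx],
            village_ids=self.village_ids,
            sub_district_ids=self.sub_district_ids,
            reference_district=self.reference_district,
        )


def build_design_matrix(
    frame: pd.DataFrame,
    covars: pd.DataFrame,
    covariate_names: list[str] | None = None,
    village_ids: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble X (penalized covariates) and Z (forced controls) per village.

    ``covariate_names`` selects and orders the penalized block (default:
    every non-id column of ``covars``).  ``village_ids`` restricts and
    orders rows.  District dummies are built from the *full* frame's
    district set so train/predict matrices share columns.
    """
    merged = frame.merge(covars, on="village_id", validate="one_to_one")
    if village_ids is not None:
        merged = merged.set_index("village_id").loc[np.asarray(village_ids)].reset_index()
    if covariate_names is None:
        covariate_names = [c for c in covars.columns if c != "village_id"]
    missing = [c for c in covariate_names if c not in merged.columns]
    if missing:
        raise SchemaError(f"covariates missing from table: {missing}")

    districts = sorted(frame["district_id"].unique())
    reference = districts[0]
    blocks: list[np.ndarray] = []
    names: list[str] = []
    pen: list[bool] = []
    for c in covariate_names:
        blocks.append(merged[c].to_numpy(dtype=float))
        names.append(c)
        pen.append(True)
    blocks.append((merged["sector"].to_numpy() == "urban").astype(float))
    names.append("urban")
    pen.append(False)
    blocks.append(merged["log_area"].to_numpy(dtype=float))
    names.append("log_area")
    pen.append(False)
    for d in districts[1:]:
        blocks.append((merged["district_id"].to_numpy() == d).astype(float))
        names.append(f"district[{d}]")
        pen.append(False)

    data = np.column_stack(blocks)
    return DesignMatrix(
        data=data,
        columns=names,
        penalized=np.array(pen),
        village_ids=merged["village_id"].to_numpy(),
        sub_district_ids=merged["sub_district_id"].to_numpy(),
        reference_district=reference,
    )
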