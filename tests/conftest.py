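"""Shared fixtures: one desk-scale synthetic country per test session."""

import numpy as np
import pytest

from popdensity import synthetic as syn
from popdensity.config import desk_design, desk_scenario
from popdensity.design import DesignMatrix


@pytest.fixture(scope="session")
def desk_country():
    """Frame, covariates and census for the default desk scenario."""
    cfg = desk_scenario(seed=42)
    frame = syn.generate_admin_frame(cfg)
    covars = syn.generate_covariates(frame, cfg)
    census = syn.generate_census(frame, covars, cfg)
    return cfg, frame, covars, census


@pytest.fixture(scope="session")
def desk_survey(desk_country):
    cfg, frame, covars, census = desk_country
    design = desk_design(seed=7)
    sample = syn.draw_survey(frame, covars, census, design, cfg)
    return design, sample


def random_design_matrix(
    rng: np.random.Generator, n: int, p_pen: int, p_forced: int = 2
) -> DesignMatrix:
    """Small unstructured design matrix for solver-level tests."""
    data = rng.normal(size=(n, p_pen + p_forced))
    cols = [f"x{j}" for j in range(p_pen)] + [f"z{j}" for j in range(p_forced)]
    return DesignMatrix(
        data=data,
        columns=cols,
        penalized=np.array([True] * p_pen + [False] * p_forced),
        village_ids=np.array([f"V{i}" for i in range(n)]),
        sub_district_ids=np.array([f"S{i % 5}" for i in range(n)]),
    )
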