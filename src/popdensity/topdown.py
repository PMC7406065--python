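"""Top-down redistribution baselines and the census-staleness experiment.

Top-down products distribute a parent unit's census population to its
villages either by area (equal density everywhere in the parent, the
areal-weighting rule) or proportionally to an ancillary covariate such as
built-up area (dasymetric mapping).  Both conserve the parent total
exactly.  The staleness experiment quantifies the failure mode these
products share: anchored to an old census, they cannot track migration,
whereas the bottom-up model is re-calibrated by a fresh survey.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RNG_SURVEY, ScenarioConfig, SurveyDesign
from .design import SchemaError, build_design_matrix
from .evaluation import AccuracyReport, accuracy_report
from .model import (GridSpec, _drop_degenerate_columns, compute_weights,
                    fit_density_model, predict_density)
from . import synthetic as syn
from .survey_density import estimate_village_density

logger = logging.getLogger(__name__)


def _redistribute(
    parents: pd.DataFrame,
    children: pd.DataFrame,
    value_col: str,
) -> pd.DataFrame:
    for col in ("parent_id", "population"):
        if col not in parents.columns:
            raise SchemaError(f"parents table lacks column {col!r}")
    for col in ("village_id", "parent_id", "area_km2", value_col):
        if col not in children.columns:
            raise SchemaError(f"children table lacks column {col!r}")
    orphan = set(children["parent_id"]) - set(parents["parent_id"])
    if orphan:
        raise SchemaError(f"children reference unknown parents: {sorted(orphan)[:5]}")
    out = children.merge(parents[["parent_id", "population"]], on="parent_id")
    totals = out.groupby("parent_id")[value_col].transform("sum")
    if (totals <= 0).any():
        bad = out.loc[totals <= 0, "parent_id"].unique()
        raise ValueError(f"nonpositive redistribution total in parents: {bad[:5]}")
    out["count"] = out["population"] * out[value_col] / totals
    out["density"] = out["count"] / out["area_km2"]
    return out[["village_id", "parent_id", "count", "density"]]


def redistribute_areal(parents: pd.DataFrame, children: pd.DataFrame) -> pd.DataFrame:
    """Equal-weighting redistribution: counts proportional to village area.

    Density is constant within each parent (parent population over summed
    area); counts sum exactly to the parent total.
    """
    if (children["area_km2"] <= 0).any():
        raise ValueError("village areas must be positive")
    return _redistribute(parents, children, "area_km2")


def redistribute_covariate(
    parents: pd.DataFrame, children: pd.DataFrame, covariate: str
) -> pd.DataFrame:
    """Dasymetric redistribution: counts proportional to a covariate.

    Parents whose children all have a zero covariate fall back to areal
    weighting with a warning.
    """
    if covariate not in children.columns:
        raise SchemaError(f"children table lacks covariate {covariate!r}")
    vals = children[covariate]
    if (vals < 0).any():
        raise ValueError(f"covariate {covariate!r} must be nonnegative")
    totals = children.groupby("parent_id")[covariate].transform("sum")
    degenerate = totals == 0
    if degenerate.any():
        bad = children.loc[degenerate, "parent_id"].unique()
        logger.warning(
            "all-zero covariate %r in parents %s; falling back to areal weighting",
            covariate,
            list(bad[:5]),
        )
        work = children.copy()
        work.loc[degenerate, covariate] = work.loc[degenerate, "area_km2"]
        return _redistribute(parents, work, covariate)
    return _redistribute(parents, children, covariate)


# ---------------------------------------------------------------------------
# Staleness experiment
# ---------------------------------------------------------------------------

@dataclass
class StalenessResult:
    bottom_up: AccuracyReport          # bottom-up model vs t1 census
    topdown_t0: AccuracyReport         # covariate top-down anchored at t0 census
    topdown_t1: AccuracyReport         # same product anchored at t1 (no staleness)
    realized_migration: float          # fraction of t1 population shifted vs t0 shares
    village_ids: np.ndarray            # evaluation set (shared by all arms)


def evolve_census(
    frame: pd.DataFrame,
    census_t0: pd.DataFrame,
    config: ScenarioConfig,
    migration_concentration: float = 2.0,
    local_concentration: float = 25.0,
    growth: float = 1.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Second-period census: hierarchical Dirichlet re-weighting of
    sub-district population shares.

    Migration is modelled as regional shocks plus local churn: district
    shares are re-drawn from a Dirichlet with concentration
    ``migration_concentration * D`` (smaller = more cross-district
    migration), and within each district the sub-district shares from a
    Dirichlet with concentration ``local_concentration * S_d``.  Village
    populations are rescaled proportionally within their sub-district and
    re-rounded; a national ``growth`` factor applies on top.  Returns the
    t1 census and the realized migration fraction (half the L1 distance
    between the t0 and t1 sub-district share vectors; ~0.25 at the
    defaults).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
    df = census_t0.merge(
        frame[["village_id", "district_id", "sub_district_id", "area_km2"]],
        on="village_id",
    )
    sub_pop = df.groupby(["district_id", "sub_district_id"])["population"].sum()
    shares = sub_pop / sub_pop.sum()

    dist_shares = shares.groupby("district_id").sum()
    D = len(dist_shares)
    alpha_d = np.clip(migration_concentration * D * dist_shares.to_numpy(), 0.5, None)
    new_dist = pd.Series(rng.dirichlet(alpha_d), index=dist_shares.index)

    new_shares = shares.copy()
    for d, within in shares.groupby("district_id"):
        rel = (within / within.sum()).to_numpy()
        alpha_s = np.clip(local_concentration * len(rel) * rel, 1e-3, None)
        new_rel = rng.dirichlet(alpha_s) if len(rel) > 1 else np.ones(1)
        new_shares.loc[within.index] = new_dist[d] * new_rel

    realized = 0.5 * float(np.abs(new_shares.to_numpy() - shares.to_numpy()).sum())
    factor = pd.Series(
        growth * new_shares.to_numpy() / shares.to_numpy(),
        index=shares.index.get_level_values("sub_district_id"),
    )
    scale = factor.reindex(df["sub_district_id"]).to_numpy()
    new_pop = np.rint(df["population"].to_numpy() * scale).astype(np.int64)
    out = pd.DataFrame(
        {
            "village_id": df["village_id"],
            "population": new_pop,
            "density": new_pop / df["area_km2"].to_numpy(),
        }
    )
    return out, realized


def staleness_experiment(
    config: ScenarioConfig,
    design: SurveyDesign,
    covariate: str = "builtup",
    migration_concentration: float = 2.0,
    local_concentration: float = 25.0,
    growth: float = 1.05,
    seed: int = 0,
    grid_spec: GridSpec | None = None,
) -> StalenessResult:
    """Bottom-up (t1 survey) vs t0-anchored top-down, both judged by t1 census.

    One frame and covariate table; census at t0, an evolved census at t1, a
    survey drawn at t1.  The top-down arm redistributes *t0* sub-district
    totals by the covariate (what an aging gridded product does); the
    bottom-up arm fits the density model to the t1 survey and predicts all
    non-surveyed villages.  Reports are paired on the identical village set
    (non-surveyed villages with positive t1 population).
    """
    if grid_spec is None:
        grid_spec = GridSpec(n_lambda=30, lambda_min_ratio=1e-3)
    frame = syn.generate_admin_frame(config)
    covars = syn.generate_covariates(frame, config)
    census_t0 = syn.generate_census(frame, covars, config)
    census_t1, realized = evolve_census(
        frame, census_t0, config, migration_concentration, local_concentration,
        growth, seed=seed,
    )

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(RNG_SURVEY,)))
    sample = syn.draw_survey(frame, covars, census_t1, design, config, rng=rng)
    est = estimate_village_density(sample, frame)
    train = est.loc[est["included"]]

    dm_train = _drop_degenerate_columns(
        build_design_matrix(frame, covars, village_ids=train["village_id"].to_numpy())
    )
    pops = census_t1.set_index("village_id")["population"]
    wv = compute_weights(pops.reindex(train["village_id"]), "inverse_pop")
    model, _ = fit_density_model(
        dm_train,
        train["hies_density"].to_numpy(),
        wv.w,
        grid_spec=grid_spec,
        seed=seed,
        scheme="inverse_pop",
    )

    surveyed = set(sample.sampled_villages)
    eval_frame = frame.loc[~frame["village_id"].isin(surveyed)]
    truth = census_t1.set_index("village_id").loc[eval_frame["village_id"]]
    keep = truth["population"].to_numpy() > 0
    eval_ids = eval_frame["village_id"].to_numpy()[keep]
    truth_d = truth["density"].to_numpy()[keep]

    dm_eval = build_design_matrix(frame, covars, village_ids=eval_ids)
    pred_bu = predict_density(model, dm_eval)

    children = frame.merge(covars[["village_id", covariate]], on="village_id")
    children = children.rename(columns={"sub_district_id": "parent_id"})

    def _td(census: pd.DataFrame) -> np.ndarray:
        parents = (
            census.merge(frame[["village_id", "sub_district_id"]], on="village_id")
            .groupby("sub_district_id")["population"]
            .sum()
            .rename_axis("parent_id")
            .reset_index()
        )
        td = redistribute_covariate(parents, children, covariate)
        return td.set_index("village_id")["density"].reindex(eval_ids).to_numpy()

    return StalenessResult(
        bottom_up=accuracy_report(truth_d, pred_bu, scale="density"),
        topdown_t0=accuracy_report(truth_d, _td(census_t0), scale="density"),
        topdown_t1=accuracy_report(truth_d, _td(census_t1), scale="density"),
        realized_migration=realized,
        village_ids=eval_ids,
    )
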