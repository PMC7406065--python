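"""End-to-end orchestration: simulate -> survey -> fit -> predict -> evaluate.

``run_experiment`` executes the whole bottom-up pipeline on one synthetic
country and returns (optionally writes) every artifact: the survey-derived
density table, fitted models under both weight schemes, out-of-sample
accuracy on the non-surveyed villages for densities and counts, the
survey-census concordance diagnostic, and the direct-vs-model CV
comparison.  ``subsample_training`` refits on random training subsets to
probe sensitivity to training-sample size.

A master seed spawns per-stage child seeds deterministically (scenario,
survey, folds), so a manifest plus config reproduces every output bit for
bit on one platform.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from . import synthetic as syn
from .config import RNG_SURVEY, ScenarioConfig, SurveyDesign
from .design import build_design_matrix
from .evaluation import (
    AccuracyReport,
    CVReport,
    accuracy_report,
    density_to_count,
    direct_cv,
    model_cv,
)
from .model import (
    GridSpec,
    _drop_degenerate_columns,
    compute_weights,
    fit_density_model,
    fit_selection_probit,
    predict_density,
)
from .survey_density import estimate_village_density, survey_census_concordance


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunResult:
    manifest: dict
    frame: pd.DataFrame
    covariates: pd.DataFrame
    census: pd.DataFrame
    survey_density: pd.DataFrame
    concordance: float
    models: dict                         # scheme -> FittedDensityModel
    predictions: pd.DataFrame            # non-surveyed villages, per scheme
    reports: dict                        # (scheme, scale) -> AccuracyReport
    cv_direct: CVReport
    cv_model: CVReport
    in_sample_r2: dict = field(default_factory=dict)


def _spawn_seed(master: int, k: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(k,)).generate_state(1)[0] % (2**31))


def run_experiment(
    scenario: ScenarioConfig,
    design: SurveyDesign,
    grid_spec: GridSpec | None = None,
    k_folds: int = 5,
    master_seed: int | None = None,
    out_dir: str | Path | None = None,
    schemes: tuple[str, ...] = ("inverse_pop", "balance_corrected"),
) -> RunResult:
    """Run the full bottom-up pipeline on one synthetic country.

    Evaluation is restricted to non-surveyed villages with positive census
    population, mirroring the out-of-sample design of the study.
    """
    if grid_spec is None:
        grid_spec = GridSpec(n_lambda=50, lambda_min_ratio=1e-4)
    if master_seed is not None:
        scenario = ScenarioConfig.from_dict(
            {**scenario.to_dict(), "seed": _spawn_seed(master_seed, 0)}
        )
        design = SurveyDesign.from_dict(
            {**design.to_dict(), "seed": _spawn_seed(master_seed, 1)}
        )
    fold_seed = _spawn_seed(design.seed, 2)

    cfg_digest = hashlib.sha256(
        json.dumps({"scenario": scenario.to_dict(), "design": design.to_dict()},
                   sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest: dict = {
        "config_hash": cfg_digest,
        "seeds": {
            "scenario": scenario.seed,
            "survey": design.seed,
            "folds": fold_seed,
        },
        "stages": {},
        "outputs": {},
    }

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    raise StageError(name, manifest, exc) from exc

        return _Timer()

    with stage("simulate"):
        frame = syn.generate_admin_frame(scenario)
        covars = syn.generate_covariates(frame, scenario)
        census = syn.generate_census(frame, covars, scenario)

    with stage("survey"):
        sample = syn.draw_survey(frame, covars, census, design, scenario)
        est = estimate_village_density(sample, frame)
        concordance = survey_census_concordance(est, census)

    train = est.loc[est["included"]]
    train_ids = train["village_id"].to_numpy()
    y_train = train["hies_density"].to_numpy()
    pops = census.set_index("village_id")["population"]

    with stage("fit"):
        dm_train = _drop_degenerate_columns(
            build_design_matrix(frame, covars, village_ids=train_ids)
        )
        models: dict = {}
        in_sample_r2: dict = {}
        for scheme in schemes:
            if scheme == "balance_corrected":
                base = models.get("inverse_pop")
                selected = (
                    base.selected
                    if base is not None
                    else models[next(iter(models))].selected
                    if models
                    else None
                )
                if not selected:
                    # selection on the forced geo controls when LASSO keeps nothing
                    sel_tab = frame.set_index("village_id")[["log_area"]]
                else:
                    sel_tab = covars.set_index("village_id")[selected]
                in_survey = sel_tab.index.isin(train_ids)
                selection = fit_selection_probit(sel_tab, in_survey)
                wv = compute_weights(
                    pops.reindex(train_ids), scheme, selection=selection
                )
            else:
                wv = compute_weights(pops.reindex(train_ids), scheme)
            model, cv = fit_density_model(
                dm_train, y_train, wv.w, grid_spec=grid_spec, k=k_folds,
                seed=fold_seed, scheme=scheme,
            )
            models[scheme] = model
            fitted = predict_density(model, dm_train)
            r = np.corrcoef(y_train, fitted)[0, 1]
            in_sample_r2[scheme] = float(r * r)

    with stage("predict"):
        surveyed = set(sample.sampled_villages)
        mask = ~frame["village_id"].isin(surveyed)
        eval_ids = frame.loc[mask, "village_id"].to_numpy()
        truth = census.set_index("village_id").reindex(eval_ids)
        pos = truth["population"].to_numpy() > 0
        eval_ids = eval_ids[pos]
        dm_eval = build_design_matrix(frame, covars, village_ids=eval_ids)
        predictions = pd.DataFrame({"village_id": eval_ids})
        for scheme, model in models.items():
            predictions[f"density_pred_{scheme}"] = predict_density(model, dm_eval)

    with stage("evaluate"):
        truth = census.set_index("village_id").reindex(eval_ids)
        reports: dict = {}
        for scheme in models:
            dpred = predictions[f"density_pred_{scheme}"].to_numpy()
            reports[(scheme, "density")] = accuracy_report(
                truth["density"].to_numpy(), dpred, scale="density"
            )
            cpred = density_to_count(dpred, frame, village_ids=eval_ids)
            reports[(scheme, "count")] = accuracy_report(
                truth["population"].to_numpy(), cpred, scale="count"
            )

    with stage("cv_comparison"):
        vweights = (
            sample.psus.drop_duplicates("village_id")
            .set_index("village_id")["village_prob"]
            .rdiv(1.0)
        )
        cv_direct = direct_cv(est, frame, vweights)
        dm_all = build_design_matrix(frame, covars)
        ref_scheme = schemes[0]
        cv_model = model_cv(models[ref_scheme], dm_all)

    result = RunResult(
        manifest=manifest,
        frame=frame,
        covariates=covars,
        census=census,
        survey_density=est,
        concordance=concordance,
        models=models,
        predictions=predictions,
        reports=reports,
        cv_direct=cv_direct,
        cv_model=cv_model,
        in_sample_r2=in_sample_r2,
    )
    if out_dir is not None:
        _write_outputs(result, sample, Path(out_dir))
    return result


def _write_outputs(result: RunResult, sample: syn.SurveySample, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pio.write_csv("villages", result.frame, out / "villages.csv")
    pio.write_csv("covariates", result.covariates, out / "covariates.csv")
    pio.write_csv("census", result.census, out / "census.csv")
    pio.write_csv("survey_households", sample.households, out / "survey.csv")
    pio.write_csv("survey_psus", sample.psus, out / "survey_psus.csv")
    pio.write_csv("hies_density", result.survey_density, out / "hies_density.csv")
    result.predictions.to_csv(out / "predictions.csv", index=False)
    for scheme, model in result.models.items():
        model.to_json(out / f"model_{scheme}.json")
    report_payload = {
        f"{scheme}:{scale}": rep.to_dict()
        for (scheme, scale), rep in result.reports.items()
    }
    report_payload["concordance"] = result.concordance
    report_payload["in_sample_r2"] = result.in_sample_r2
    report_payload["mean_direct_cv"] = result.cv_direct.mean_cv
    report_payload["mean_model_cv"] = result.cv_model.mean_cv
    with open(out / "reports.json", "w") as fh:
        json.dump(report_payload, fh, indent=2)
    result.manifest["outputs"] = {
        p.name: str(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)


def subsample_training(
    scenario: ScenarioConfig,
    design: SurveyDesign,
    fractions: tuple[float, ...] = (1.0, 0.5, 0.25),
    grid_spec: GridSpec | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> dict[float, AccuracyReport]:
    """Training-size robustness: refit on random training subsets.

    The evaluation set (non-surveyed villages) is fixed; at each fraction a
    seeded random subset of the training villages refits the full two-step
    model.  Returns the density-scale accuracy per fraction.
    """
    if grid_spec is None:
        grid_spec = GridSpec(n_lambda=40, lambda_min_ratio=1e-4)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    frame = syn.generate_admin_frame(scenario)
    covars = syn.generate_covariates(frame, scenario)
    census = syn.generate_census(frame, covars, scenario)
    sample = syn.draw_survey(frame, covars, census, design, scenario)
    est = estimate_village_density(sample, frame)
    train = est.loc[est["included"]]
    train_ids = train["village_id"].to_numpy()
    y_all = train.set_index("village_id")["hies_density"]
    pops = census.set_index("village_id")["population"]

    surveyed = set(sample.sampled_villages)
    eval_ids = frame.loc[~frame["village_id"].isin(surveyed), "village_id"].to_numpy()
    truth = census.set_index("village_id").reindex(eval_ids)
    pos = truth["population"].to_numpy() > 0
    eval_ids = eval_ids[pos]
    truth_d = truth["density"].to_numpy()[pos]
    dm_eval = build_design_matrix(frame, covars, village_ids=eval_ids)

    rng = np.random.default_rng(seed)
    out: dict[float, AccuracyReport] = {}
    for frac in fractions:
        if frac == 1.0:
            ids = train_ids
        else:
            n_keep = int(np.floor(frac * len(train_ids)))
            if n_keep < 2 * k_folds:
                raise ValueError(f"fraction {frac} leaves too few rows for {k_folds}-fold CV")
            ids = rng.choice(train_ids, size=n_keep, replace=False)
        dm_tr = _drop_degenerate_columns(build_design_matrix(frame, covars, village_ids=ids))
        wv = compute_weights(pops.reindex(ids), "inverse_pop")
        model, _ = fit_density_model(
            dm_tr, y_all.reindex(ids).to_numpy(), wv.w,
            grid_spec=grid_spec, k=k_folds, seed=seed, scheme="inverse_pop",
        )
        pred = predict_density(model, dm_eval)
        out[frac] = accuracy_report(truth_d, pred, scale="density")
    return out
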