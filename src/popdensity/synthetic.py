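"""Synthetic country generator: admin frame, covariates, census, survey.

Emulates the data a bottom-up density study consumes -- a village frame
nested in sub-districts and districts, Gaussian-copula geo-spatial
covariates with mixed bounded/skewed marginals, a census realized from a
log-linear density model, and a two-stage stratified household survey with
exact inverse-probability design weights -- so the downstream estimation
pipeline can be exercised and validated without any external data.

RNG discipline: every stochastic stage consumes its own substream spawned
deterministically from ``ScenarioConfig.seed`` (see the RNG_* keys in
:mod:`popdensity.config`), so identical configs reproduce identical tables
at full precision.  The survey stage uses ``SurveyDesign.seed`` so repeated
survey replicates can be drawn on one fixed country.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .config import (
    RNG_ADMIN,
    RNG_CENSUS,
    RNG_COVARIATES,
    RNG_DISTRICT_EFFECTS,
    ConfigurationError,
    ScenarioConfig,
    SurveyDesign,
)

logger = logging.getLogger(__name__)

SECTOR_URBAN = "urban"
SECTOR_RURAL = "rural_estate"

LINPRED_LIMIT = 30.0


class DesignError(ValueError):
    """Raised when a survey design is infeasible for the given frame."""


# ---------------------------------------------------------------------------
# Admin frame
# ---------------------------------------------------------------------------

def _partition_counts(total: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly split `total` units into `n_groups` nonempty groups."""
    if total < n_groups:
        raise ConfigurationError(f"cannot split {total} units into {n_groups} nonempty groups")
    extra = total - n_groups
    if extra == 0:
        return np.ones(n_groups, dtype=int)
    shares = rng.dirichlet(np.full(n_groups, 2.0))
    alloc = rng.multinomial(extra, shares)
    return alloc + 1


def generate_admin_frame(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the village frame: ids, hierarchy, sector, area.

    Returns a DataFrame with columns ``village_id, district_id,
    sub_district_id, sector, area_km2, log_area``; every district contains
    at least one sub-district and every sub-district at least one village.
    """
    rng = config.rng(RNG_ADMIN)
    D, S, V = config.n_districts, config.n_subdistricts, config.n_villages

    sub_per_district = _partition_counts(S, D, rng)
    district_of_sub = np.repeat(np.arange(D), sub_per_district)
    vil_per_sub = _partition_counts(V, S, rng)
    sub_of_village = np.repeat(np.arange(S), vil_per_sub)

    district_ids = np.array([f"D{d + 1:03d}" for d in range(D)])
    sub_ids = np.array([f"S{s + 1:04d}" for s in range(S)])
    village_ids = np.array([f"V{v + 1:06d}" for v in range(V)])

    sector = np.where(
        rng.random(V) < config.urban_fraction, SECTOR_URBAN, SECTOR_RURAL
    )
    log_area = rng.normal(config.area_log_mean, config.area_log_sd, size=V)
    area = np.exp(log_area)

    return pd.DataFrame(
        {
            "village_id": village_ids,
            "district_id": district_ids[district_of_sub[sub_of_village]],
            "sub_district_id": sub_ids[sub_of_village],
            "sector": sector,
            "area_km2": area,
            "log_area": np.log(area),
        }
    )


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def _marginal_transform(z: np.ndarray, family: str, mu: float, sigma: float) -> np.ndarray:
    x = mu + sigma * z
    if family == "lognormal":
        return np.exp(x)
    if family == "logitnormal":
        return 100.0 * expit(x)
    if family == "normal":
        return x
    raise ConfigurationError(f"unknown covariate family {family!r}")


def generate_covariates(frame: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Draw one row of geo-spatial covariates per village.

    Latent normals follow the configured Gaussian copula; each column is
    then pushed through its marginal family.  Bounded (logit-normal)
    columns stay inside [0, 100] by construction.
    """
    if not config.covariates:
        raise ConfigurationError("covariate_spec is empty")
    rng = config.rng(RNG_COVARIATES)
    n = len(frame)
    p = len(config.covariates)
    z = rng.standard_normal((n, p))
    if config.correlation is not None:
        corr = np.asarray(config.correlation, dtype=float)
        evals, evecs = np.linalg.eigh(corr)
        if evals.min() < -1e-10:
            raise ConfigurationError("correlation matrix is not positive semi-definite")
        root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
        z = z @ root.T
    out = {"village_id": frame["village_id"].to_numpy()}
    for j, spec in enumerate(config.covariates):
        out[spec.name] = _marginal_transform(z[:, j], spec.family, spec.mu, spec.sigma)
    return pd.DataFrame(out)


def copula_spearman(pearson_latent: float) -> float:
    """Spearman correlation implied by a Gaussian copula with latent Pearson r."""
    return 6.0 / np.pi * np.arcsin(pearson_latent / 2.0)


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

def district_effects(config: ScenarioConfig, district_ids: np.ndarray) -> pd.Series:
    """Ground-truth district effects (mean-zero normal draws, fixed by seed)."""
    ids = np.asarray(sorted(set(district_ids)))
    if config.district_effect_sd == 0:
        vals = np.zeros(len(ids))
    else:
        rng = config.rng(RNG_DISTRICT_EFFECTS)
        vals = rng.normal(0.0, config.district_effect_sd, size=len(ids))
        vals -= vals.mean()
    return pd.Series(vals, index=ids, name="district_effect")


def expected_density(
    frame: pd.DataFrame, covars: pd.DataFrame, config: ScenarioConfig
) -> np.ndarray:
    """mu_v = exp(alpha + beta.X_v + gamma.Z_v), the generating mean density."""
    merged = frame.merge(covars, on="village_id", validate="one_to_one")
    eta = np.full(len(merged), config.true_alpha, dtype=float)
    for name, coef in config.true_beta.items():
        eta += coef * merged[name].to_numpy()
    gamma = config.true_gamma
    if "urban" in gamma:
        eta += gamma["urban"] * (merged["sector"].to_numpy() == SECTOR_URBAN)
    if "log_area" in gamma:
        eta += gamma["log_area"] * merged["log_area"].to_numpy()
    eff = district_effects(config, frame["district_id"].to_numpy())
    eta += eff.reindex(merged["district_id"]).to_numpy()
    bad = np.abs(eta) > LINPRED_LIMIT
    if bad.any():
        vid = merged.loc[bad, "village_id"].iloc[0]
        raise FloatingPointError(
            f"linear predictor out of range (|eta| > {LINPRED_LIMIT}) "
            f"first at village {vid}"
        )
    return np.exp(eta)


def generate_census(
    frame: pd.DataFrame, covars: pd.DataFrame, config: ScenarioConfig
) -> pd.DataFrame:
    """Realize village census populations from the log-linear density model.

    Expected counts are mu_v * area_v; noise is Poisson, negative binomial
    with dispersion theta (variance m + m^2/theta), or none (deterministic
    rounding).  ``density`` is exactly population / area.
    """
    mu = expected_density(frame, covars, config)
    area = frame["area_km2"].to_numpy()
    mean_count = mu * area
    if config.noise == "none":
        pop = np.rint(mean_count).astype(np.int64)
    elif config.noise == "poisson":
        rng = config.rng(RNG_CENSUS)
        pop = rng.poisson(mean_count).astype(np.int64)
    else:  # negbin: gamma-Poisson mixture
        rng = config.rng(RNG_CENSUS)
        theta = float(config.negbin_theta)
        lam = rng.gamma(theta, mean_count / theta)
        pop = rng.poisson(lam).astype(np.int64)
    return pd.DataFrame(
        {
            "village_id": frame["village_id"].to_numpy(),
            "population": pop,
            "density": pop / area,
        }
    )


# ---------------------------------------------------------------------------
# Survey
# ---------------------------------------------------------------------------

@dataclass
class SurveySample:
    """A drawn household survey.

    ``households``: household_id, village_id, psu_id, household_size,
    design_weight (1 / overall inclusion probability).
    ``psus``: psu_id, village_id, psu_census_population, psu_census_share,
    psu_stage_prob (pi_village * pi_psu), village_prob (pi_village).
    """

    households: pd.DataFrame
    psus: pd.DataFrame

    @property
    def sampled_villages(self) -> np.ndarray:
        return self.psus["village_id"].unique()


def village_inclusion_probs(
    frame: pd.DataFrame,
    covars: pd.DataFrame,
    census: pd.DataFrame,
    design: SurveyDesign,
) -> pd.DataFrame:
    """First-stage village inclusion probabilities per the design.

    Villages with zero census population are out of frame (no households to
    list).  With no tilt, probabilities are n_h/N_h within each stratum
    (district x sector); with a tilt, probabilities are proportional to
    Phi(sum_c tilt_c * standardized covariate c), rescaled within stratum to
    preserve the expected sample size.
    Returns frame-indexed DataFrame with columns pi (0 for out-of-frame) and
    stratum.
    """
    df = frame.merge(census[["village_id", "population"]], on="village_id")
    df = df.merge(covars, on="village_id")
    df["stratum"] = df["district_id"] + ":" + df["sector"]
    eligible = df["population"].to_numpy() > 0

    if design.selection_tilt:
        idx = np.zeros(len(df))
        for name, coef in design.selection_tilt.items():
            x = df[name].to_numpy(dtype=float)
            sd = x.std()
            idx += coef * (x - x.mean()) / (sd if sd > 0 else 1.0)
        base = stats.norm.cdf(idx)
    else:
        base = np.ones(len(df))

    pi = np.zeros(len(df))
    for _, grp in df.groupby("stratum"):
        mask = np.zeros(len(df), dtype=bool)
        mask[grp.index] = True
        mask &= eligible
        n_elig = int(mask.sum())
        if n_elig == 0:
            # a stratum whose villages are all unpopulated contributes no sample
            logger.warning(
                "stratum %r has no populated villages; skipping",
                grp["stratum"].iloc[0],
            )
            continue
        if design.stratum_sample_sizes is not None:
            n_take = design.stratum_sample_sizes.get(grp["stratum"].iloc[0], 0)
        else:
            n_take = max(1, int(round(design.village_sampling_fraction * n_elig)))
        if n_take > n_elig:
            raise DesignError(
                f"stratum {grp['stratum'].iloc[0]!r}: requested {n_take} of {n_elig} villages"
            )
        b = base[mask]
        p = n_take * b / b.sum()
        # iterate the cap: clipped mass is redistributed proportionally
        for _ in range(50):
            over = p > 1.0
            if not over.any():
                break
            p = np.clip(p, None, 1.0)
            deficit = n_take - p.sum()
            room = p < 1.0
            if deficit <= 1e-12 or not room.any():
                break
            p[room] *= 1.0 + deficit / p[room].sum()
        pi[mask] = np.clip(p, 1e-12, 1.0)
    out = df[["village_id", "stratum", "population"]].copy()
    out["pi"] = pi
    return out


def _partition_households(pop: int, mean_size: float, rng: np.random.Generator) -> np.ndarray:
    """Split a village population into household sizes summing exactly to pop."""
    if pop <= 0:
        return np.zeros(0, dtype=int)
    n_guess = max(8, int(2.5 * pop / mean_size))
    sizes = 1 + rng.poisson(mean_size - 1.0, size=n_guess)
    cum = np.cumsum(sizes)
    while cum[-1] < pop:  # pragma: no cover - n_guess is generous
        extra = 1 + rng.poisson(mean_size - 1.0, size=n_guess)
        sizes = np.concatenate([sizes, extra])
        cum = np.cumsum(sizes)
    k = int(np.searchsorted(cum, pop))
    sizes = sizes[: k + 1].copy()
    sizes[-1] -= cum[k] - pop  # truncate the last household
    if sizes[-1] == 0:
        sizes = sizes[:-1]
    return sizes


def draw_survey(
    frame: pd.DataFrame,
    covars: pd.DataFrame,
    census: pd.DataFrame,
    design: SurveyDesign,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> SurveySample:
    """Draw one two-stage stratified survey replicate.

    Stage 1 (villages): SRS without replacement per stratum, or Poisson
    sampling under a covariate tilt.  Stage 2: census blocks (PSUs) of
    roughly ``households_per_block`` households partition each sampled
    village; ``psus_per_village`` blocks are drawn by SRS, then
    ``households_per_psu`` households by SRS within each block.  Design
    weights are exact inverse inclusion probabilities, so the
    Horvitz-Thompson total sum(weight * household_size) is unbiased for the
    census total.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(0,)))
    probs = village_inclusion_probs(frame, covars, census, design)
    pi = probs["pi"].to_numpy()
    eligible = pi > 0

    take = np.zeros(len(probs), dtype=bool)
    if design.selection_tilt:
        take[eligible] = rng.random(int(eligible.sum())) < pi[eligible]
    else:
        for _, grp in probs[eligible].groupby("stratum"):
            n_take = int(round(grp["pi"].iloc[0] * len(grp)))
            n_take = min(max(n_take, 1), len(grp))
            chosen = rng.choice(grp.index.to_numpy(), size=n_take, replace=False)
            take[chosen] = True
            # pi is exactly n_take/N under SRSWOR
            pi[grp.index] = n_take / len(grp)

    hh_rows: list[tuple] = []
    psu_rows: list[tuple] = []
    mean_size = config.mean_household_size
    for i in np.flatnonzero(take):
        vid = probs["village_id"].iloc[i]
        vpop = int(probs["population"].iloc[i])
        sizes = _partition_households(vpop, mean_size, rng)
        M = len(sizes)
        n_blocks = max(1, int(round(M / design.households_per_block)))
        block_of = np.minimum(
            np.arange(M) * n_blocks // M, n_blocks - 1
        )  # equal contiguous blocks
        n_psu_take = design.psus_per_village
        if design.multi_psu_fraction > 0 and rng.random() < design.multi_psu_fraction:
            n_psu_take += 1
        n_psu_take = min(n_psu_take, n_blocks)
        pi_psu = n_psu_take / n_blocks
        blocks = rng.choice(n_blocks, size=n_psu_take, replace=False)
        for b in blocks:
            members = np.flatnonzero(block_of == b)
            Mb = len(members)
            m = min(design.households_per_psu, Mb)
            pi_hh = m / Mb
            picked = rng.choice(members, size=m, replace=False)
            psu_id = f"{vid}:B{b + 1:03d}"
            block_pop = int(sizes[members].sum())
            psu_rows.append(
                (psu_id, vid, block_pop, block_pop / vpop, pi[i] * pi_psu, pi[i])
            )
            w = 1.0 / (pi[i] * pi_psu * pi_hh)
            for h in picked:
                hh_rows.append((f"{psu_id}:H{h + 1:05d}", vid, psu_id, int(sizes[h]), w))

    households = pd.DataFrame(
        hh_rows,
        columns=["household_id", "village_id", "psu_id", "household_size", "design_weight"],
    )
    psus = pd.DataFrame(
        psu_rows,
        columns=[
            "psu_id",
            "village_id",
            "psu_census_population",
            "psu_census_share",
            "psu_stage_prob",
            "village_prob",
        ],
    )
    return SurveySample(households=households, psus=psus)
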