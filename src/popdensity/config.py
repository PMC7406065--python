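"""Scenario and survey-design configuration.

A :class:`ScenarioConfig` fully determines a synthetic country: the admin
hierarchy (districts > sub-districts > villages), the village-level
geo-spatial covariates (Gaussian-copula dependence, mixed marginals), and
the log-linear ground truth for population density

    E[density_v] = exp(alpha + beta . X_v + gamma . Z_v),

where ``Z_v`` holds the urban indicator, log village area and district
effects.  A :class:`SurveyDesign` determines the two-stage stratified
household survey drawn on top of that country.

Both objects round-trip losslessly through YAML so an analysis run can be
reproduced from its config file alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

VALID_FAMILIES = ("lognormal", "logitnormal", "normal")
VALID_NOISE = ("none", "poisson", "negbin")

# fixed spawn keys for per-stage RNG substreams (documented consumption order)
RNG_ADMIN = 0
RNG_COVARIATES = 1
RNG_DISTRICT_EFFECTS = 2
RNG_CENSUS = 3
RNG_SURVEY = 4


class ConfigurationError(ValueError):
    """Raised when a scenario or design fails validation."""


@dataclass
class CovariateSpec:
    """One geo-spatial covariate: a marginal family plus latent-scale params.

    ``lognormal``    -> exp(mu + sigma*z)            (night lights, slope)
    ``logitnormal``  -> 100 * expit(mu + sigma*z)    (built-up %, tree cover %)
    ``normal``       -> mu + sigma*z
    """

    name: str
    family: str
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.family not in VALID_FAMILIES:
            raise ConfigurationError(
                f"unknown covariate family {self.family!r} for {self.name!r}; "
                f"expected one of {VALID_FAMILIES}"
            )
        if self.sigma < 0:
            raise ConfigurationError(f"sigma < 0 for covariate {self.name!r}")


@dataclass
class ScenarioConfig:
    n_districts: int = 8
    n_subdistricts: int = 50
    n_villages: int = 1000
    urban_fraction: float = 0.092
    # log village area: mean 1.25, sd 0.81 gives mean area ~4.8 km^2
    area_log_mean: float = 1.25
    area_log_sd: float = 0.81
    covariates: list[CovariateSpec] = field(default_factory=list)
    # Gaussian-copula correlation among the latent normals (row-major, or None)
    correlation: list[list[float]] | None = None
    true_alpha: float = 6.0
    true_beta: dict[str, float] = field(default_factory=dict)
    true_gamma: dict[str, float] = field(default_factory=dict)  # urban, log_area
    district_effect_sd: float = 0.0
    noise: str = "poisson"
    negbin_theta: float | None = None
    mean_household_size: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_districts, self.n_subdistricts, self.n_villages)
        if any(int(c) <= 0 for c in counts):
            raise ConfigurationError(f"admin counts must be positive, got {counts}")
        if not (self.n_districts <= self.n_subdistricts <= self.n_villages):
            raise ConfigurationError(
                "need n_districts <= n_subdistricts <= n_villages, got "
                f"{counts}"
            )
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ConfigurationError("urban_fraction must lie in [0, 1]")
        if self.noise not in VALID_NOISE:
            raise ConfigurationError(
                f"unknown noise model {self.noise!r}; expected one of {VALID_NOISE}"
            )
        if self.noise == "negbin":
            if self.negbin_theta is None or self.negbin_theta <= 0:
                raise ConfigurationError("negbin noise requires positive negbin_theta")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate covariate names")
        unknown = set(self.true_beta) - set(names)
        if unknown:
            raise ConfigurationError(f"true_beta keys not in covariate_spec: {sorted(unknown)}")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            p = len(self.covariates)
            if corr.shape != (p, p):
                raise ConfigurationError(
                    f"correlation matrix shape {corr.shape} != ({p}, {p})"
                )
            if not np.allclose(corr, corr.T):
                raise ConfigurationError("correlation matrix not symmetric")
            if not np.allclose(np.diag(corr), 1.0):
                raise ConfigurationError("correlation matrix diagonal must be 1")
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise ConfigurationError("correlation matrix is not positive semi-definite")

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["covariates"] = [CovariateSpec(**c) for c in d.get("covariates", [])]
        d["true_beta"] = dict(d.get("true_beta", {}))
        d["true_gamma"] = dict(d.get("true_gamma", {}))
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- RNG plumbing --------------------------------------------------------
    def rng(self, stage_key: int) -> np.random.Generator:
        """Deterministic per-stage substream derived from the scenario seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage_key,)))


@dataclass
class SurveyDesign:
    """Two-stage stratified household survey (strata = district x sector).

    Stage 1 samples villages within each stratum -- simple random sampling
    without replacement when ``selection_tilt`` is empty, otherwise Poisson
    sampling with probit-tilted inclusion probabilities (so a probit on the
    tilted covariates is the correctly specified selection model).  Stage 2
    samples one census block (PSU) per village and a fixed number of
    households within the block.  Design weights are exact inverse inclusion
    probabilities at every stage.
    """

    village_sampling_fraction: float = 0.12
    stratum_sample_sizes: dict[str, int] | None = None  # overrides fraction
    psus_per_village: int = 1
    households_per_psu: int = 10
    households_per_block: int = 80
    # fraction of sampled villages where one extra PSU is drawn; such
    # villages are excluded downstream, emulating the ~97% single-PSU rate
    multi_psu_fraction: float = 0.03
    selection_tilt: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.village_sampling_fraction <= 1.0:
            raise ConfigurationError("village_sampling_fraction must lie in (0, 1]")
        for name, val in (
            ("psus_per_village", self.psus_per_village),
            ("households_per_psu", self.households_per_psu),
            ("households_per_block", self.households_per_block),
        ):
            if int(val) <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")
        if not 0.0 <= self.multi_psu_fraction < 1.0:
            raise ConfigurationError("multi_psu_fraction must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SurveyDesign":
        d = dict(d)
        d["selection_tilt"] = dict(d.get("selection_tilt", {}))
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SurveyDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _default_covariates() -> list[CovariateSpec]:
    # Marginals sized to the field's typical village-level summaries: skewed
    # night lights near zero, built-up around 10% with long right tail,
    # tree cover near 45%, slope a few degrees.
    return [
        CovariateSpec("nightlights", "lognormal", -0.8, 1.1),
        CovariateSpec("builtup", "logitnormal", -2.6, 1.6),
        CovariateSpec("treecover", "logitnormal", -0.2, 1.2),
        CovariateSpec("slope", "lognormal", 2.0, 0.6),
    ]


def _default_correlation() -> list[list[float]]:
    # nightlights & built-up strongly positive; both negative with tree
    # cover; slope mildly negative with built-up.
    return [
        [1.0, 0.55, -0.35, -0.10],
        [0.55, 1.0, -0.45, -0.20],
        [-0.35, -0.45, 1.0, 0.25],
        [-0.10, -0.20, 0.25, 1.0],
    ]


def desk_scenario(
    seed: int = 0, noise: str = "negbin", negbin_theta: float | None = 8.0
) -> ScenarioConfig:
    """Desk-scale country: 1,000 villages in 50 sub-districts, 8 districts.

    Ground-truth coefficients give a right-skewed national density
    distribution (sd > mean, mean on the order of 10^3 persons/km^2) with
    density increasing in built-up fraction and night lights, decreasing in
    tree cover, slope and log area, and an urban premium.  The default
    negative-binomial dispersion (theta = 8) adds the unobserved village
    heterogeneity real censuses show, putting model accuracy in a realistic
    rather than a near-perfect regime.
    """
    return ScenarioConfig(
        n_districts=8,
        n_subdistricts=50,
        n_villages=1000,
        covariates=_default_covariates(),
        correlation=_default_correlation(),
        true_alpha=7.3,
        true_beta={
            "nightlights": 0.10,
            "builtup": 0.035,
            "treecover": -0.008,
            "slope": -0.03,
        },
        true_gamma={"urban": 0.5, "log_area": -0.55},
        district_effect_sd=0.25,
        noise=noise,
        negbin_theta=negbin_theta if noise == "negbin" else None,
        seed=seed,
    )


def national_scenario(
    seed: int = 0, noise: str = "negbin", negbin_theta: float | None = 8.0
) -> ScenarioConfig:
    """National-scale preset: 13,970 villages, 331 sub-districts, 25 districts."""
    cfg = desk_scenario(seed=seed, noise=noise, negbin_theta=negbin_theta)
    cfg.n_districts = 25
    cfg.n_subdistricts = 331
    cfg.n_villages = 13970
    return cfg


def selection_bias_scenario(
    seed: int = 0,
) -> tuple[ScenarioConfig, SurveyDesign, list[str]]:
    """Study conditions for the selection-correction analysis.

    Survey field work under-samples the densest, most built-up villages
    (inclusion probability declines in built-up fraction -- a probit tilt,
    so the probit selection equation is correctly specified).  An
    unobserved bounded "services" covariate, strongly correlated with
    built-up area, also drives density but is not available to the model,
    so the log-linear fit is misspecified and the covariate distribution of
    the training sample matters.  Returns (scenario, design, candidate
    covariates offered to the model); the hidden covariate is excluded from
    the candidates.
    """
    cfg = ScenarioConfig(
        n_districts=4,
        n_subdistricts=20,
        n_villages=800,
        covariates=[
            CovariateSpec("nightlights", "lognormal", -0.8, 1.1),
            CovariateSpec("builtup", "logitnormal", -2.6, 1.6),
            CovariateSpec("treecover", "logitnormal", -0.2, 1.2),
            CovariateSpec("services", "logitnormal", -1.0, 2.0),
        ],
        correlation=[
            [1.0, 0.55, -0.35, 0.45],
            [0.55, 1.0, -0.45, 0.9],
            [-0.35, -0.45, 1.0, -0.4],
            [0.45, 0.9, -0.4, 1.0],
        ],
        true_alpha=6.2,
        true_beta={
            "nightlights": 0.08,
            "builtup": 0.02,
            "treecover": -0.008,
            "services": 0.015,
        },
        true_gamma={"urban": 0.4, "log_area": -0.55},
        district_effect_sd=0.2,
        noise="poisson",
        seed=seed,
    )
    design = SurveyDesign(
        village_sampling_fraction=0.25,
        selection_tilt={"builtup": -0.8},
        seed=seed,
    )
    candidates = ["nightlights", "builtup", "treecover"]
    return cfg, design, candidates


def desk_design(seed: int = 0, tilt: dict[str, float] | None = None) -> SurveyDesign:
    """Survey design companion to :func:`desk_scenario` (~12% of villages)."""
    return SurveyDesign(
        village_sampling_fraction=0.12,
        psus_per_village=1,
        households_per_psu=10,
        households_per_block=80,
        selection_tilt=dict(tilt or {}),
        seed=seed,
    )
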