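# Methods

This note records the statistical model, the synthetic data-generating
process, the estimation machinery, and the numerical and design choices
behind them. Everything quantitative claimed here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## 1. The estimating model

Village population density $P_v$ (persons/km², continuous) is modelled as

$$\log E[P_v \mid X_v, Z_v] = \alpha + \beta X_v + \gamma Z_v,$$

with $X_v$ the geo-spatial covariate block (penalized during selection)
and $Z_v$ the forced controls: an urban indicator, log village area, and
district fixed effects in reference coding (the lexicographically first
district is the reference — an arbitrary but deterministic choice). The
model is fitted as a **Poisson pseudo-likelihood**: the response is a
continuous density, not a count, so the estimator solves the quasi-Poisson
score equations; no distributional Poisson claim is made. Density is
modelled (rather than counts) because village areas vary over two orders
of magnitude and the count scale would be dominated by area.

With observation weights $w_v$, the selection objective is

$$\min_{\alpha,\tau}\;\; \sum_v u_v\,\big(e^{\eta_v} - P_v\,\eta_v\big)
\;+\; \lambda \sum_{j \in \text{penalized}} |\tau_j|,
\qquad u_v = w_v \Big/ \sum_k w_k,$$

i.e. the weights are normalized to sum to one inside the objective. This
makes the $\tfrac1N$ log-likelihood scaling and the $\lambda$ scale
comparable across weight schemes (uniform, $1/\mathrm{pop}$,
balance-corrected); without a convention the meaning of $\lambda$ would
silently change with the weights.

### Solver

The path is solved by proximal Newton: at each $\lambda$ (100 log-spaced
values from $\lambda_{\max}$ down to $10^{-4}\lambda_{\max}$ by default,
warm-started), an outer IRLS linearization is followed by cyclic
coordinate descent with soft-thresholding on the working least-squares
problem. Penalized columns are standardized to zero weighted mean and
unit weighted variance before thresholding; coefficients are
de-standardized on output. The intercept is profiled out exactly and the
inner sweeps run on the Gram matrix (covariance updates), so a coordinate
update costs O(p). Step-halving guarantees monotone descent of the
penalized objective. $\lambda_{\max}$ is computed from the score of the
forced-only fit, and for $\lambda \ge \lambda_{\max}$ the exact solution
(all penalized coefficients zero, forced-only MLE) is returned without
iteration.

Tolerances: outer IRLS stops at relative objective change $10^{-8}$ *and*
a KKT subgradient violation below $10^{-6}\max(1,\lambda_{\max})$; inner
sweeps stop at maximum coefficient change $10^{-10}$ (at most 1,000
sweeps). On small instances the solver's objective agrees with a generic
bound-constrained optimizer (SLSQP on the positive/negative-part split) to
far better than $10^{-4}$, and KKT conditions hold below $10^{-5}$; both
are re-certified by the test suite on 50 random instances.

$\lambda^\*$ minimizes the mean over five folds of the per-fold
response-scale RMSE between held-out densities and $e^{\hat\eta}$; folds
come from a seeded permutation, and exact ties break toward the larger
(sparser) $\lambda$. Training folds that lose a district drop that dummy
for the fold (logged), treating its out-of-fold effect as the reference
level. The **post-LASSO refit** re-estimates the unpenalized model on the
selected-plus-forced support; an empty selection reduces to the
forced-only model (logged, not an error).

Cluster-robust covariance: sandwich $A^{-1} B A^{-1}$ with scores summed
within sub-districts and a $G/(G-1)$ small-sample factor. This is the
covariance the delta-method CV uses.

### Selection correction

The survey may over- or under-sample villages in ways correlated with the
covariates. A maximum-likelihood probit of survey membership on the
LASSO-selected covariates (fitted on the whole frame) yields
$\hat\pi_v$; the corrected weights are $1/(\mathrm{pop}_v\hat\pi_v)$ with
$\hat\pi_v$ floored at $p_{\text{floor}} = 0.01$ before inversion
(unbounded weights otherwise; the number of floored villages is reported
on the weight vector). Probabilities enter only through the weights.

## 2. Survey-side density estimation

The survey observes households inside sampled census blocks (PSUs). For
each sampled PSU: the PSU population estimate is the within-PSU
Horvitz–Thompson total $\sum_h w_h s_h \times \pi^{\text{stage}}_v$, where
$w_h$ is the household's overall design weight, $s_h$ its size, and
$\pi^{\text{stage}}_v$ the product of the village- and PSU-stage inclusion
probabilities (carried in the PSU metadata). Multiplying by
$\pi^{\text{stage}}_v$ reduces the overall expansion factor to the
within-PSU one — using the overall weight directly would inflate the PSU
estimate by $1/\pi^{\text{stage}}_v$ and, under one-PSU-per-village
designs, make the village estimate scale like population squared. The
village estimate is the PSU estimate divided by the PSU's census share of
village population; density divides by area. Under full enumeration with
unit weights and share 1 this reproduces census density exactly (tested).

Villages with more than one sampled PSU are flagged and excluded, not
imputed. A sampled village with zero enumerated persons is an error, not
a zero density. The concordance diagnostic is the Pearson correlation of
survey vs census density over included villages.

## 3. The synthetic country

The generator emulates the structure such a study consumes:

* **Admin frame.** Defaults: 1,000 villages in 50 sub-districts in 8
  districts ("desk" scale; a "national" preset has 13,970 / 331 / 25).
  Every district keeps ≥1 sub-district and every sub-district ≥1 village
  (Dirichlet-multinomial allocation). Village areas are lognormal with
  log-mean 1.25 and log-sd 0.81 (mean ≈ 4.8 km²); 9.2% of villages are
  urban.
* **Covariates.** A Gaussian copula with configured latent correlation
  feeds mixed marginals: lognormal (night lights, slope), logit-normal
  bounded in [0, 100] (built-up %, tree cover %), or normal. Bounded
  columns cannot leave [0, 100] by construction. The copula's implied
  rank correlation, $(6/\pi)\arcsin(r/2)$, is verified by Monte Carlo.
* **Census.** $\mu_v = \exp(\alpha + \beta X_v + \gamma Z_v)$ with
  mean-zero normal district effects; counts are Poisson, negative binomial
  (gamma–Poisson, variance $m + m^2/\theta$), or deterministic rounding
  when noise is off. A linear predictor beyond $|\eta| > 30$ aborts,
  naming the offending village. The desk default uses $\theta = 8$:
  censuses show far more village-level heterogeneity than a pure Poisson
  count model, and this dispersion puts model accuracy in a realistic
  (rather than near-perfect) regime. Default coefficients produce a
  right-skewed national density distribution with mean ≈ 1,350 /km², sd ≈
  2,900, max ≈ 46,000 — the orders of magnitude a lower-middle-income
  census shows.
* **Survey.** Two-stage stratified (strata = district × sector).
  Stage 1: simple random sampling without replacement within strata
  (proportional allocation at ~12% of villages by default), or — with a
  covariate tilt — Poisson sampling with probabilities proportional to
  $\Phi(\text{tilted covariate index})$, so the probit selection equation
  is correctly specified. Stage 2: the village's census population is
  partitioned into households (sizes $1 + \mathrm{Poisson}(3)$, mean 4,
  truncated to conserve population exactly); contiguous blocks of ~80
  households form PSUs; one PSU per village and 10 households per PSU are
  drawn by SRS. In 3% of sampled villages a second PSU is drawn,
  reproducing the multi-PSU exclusions a real frame produces. All design
  weights are exact inverse inclusion probabilities, making the
  Horvitz–Thompson total unbiased for the census total (verified over 500
  replicates). Strata whose villages are all unpopulated are skipped with
  a warning.
* **Determinism.** Each stage consumes its own substream spawned from the
  scenario seed with a fixed key (admin=0, covariates=1, district
  effects=2, census=3, survey=4); identical configs give bit-identical
  tables. Configs round-trip through YAML.

What the generator does **not** emulate: spatial autocorrelation of
covariates or densities (no geometry exists), measurement error in the
covariates, household non-response, and within-village covariate
heterogeneity. Passing tests therefore certify the estimation machinery
under the model's own assumptions, not the accuracy such a model attains
on real imagery and surveys.

## 4. Evaluation

* R² is reported as the squared Pearson correlation between prediction
  and truth by default; $1 - \mathrm{SSE}/\mathrm{SST}$ is also computed
  and stored. Relative errors are computed over positive-truth villages
  only (the excluded count is recorded); they are identical on the
  density and count scales because counts are densities times area.
* Out-of-sample R² via cross-validation runs the *entire* two-step
  procedure inside each training fold and pools held-out predictions.
* **Direct CV** per sub-district: weighted mean of survey densities with
  the with-replacement approximation
  $\widehat{\mathrm{var}} = \tfrac{n}{n-1}\sum_i \big(w_i (y_i - \bar y_w)
  / \sum_k w_k\big)^2$ — the joint-inclusion (without-replacement) form is
  not used; at the default ~12% sampling fractions the approximation is
  conservative by well under 15% (verified against a 1,000-replicate
  resampling oracle). Sub-districts with one sampled village have no
  variance estimate and are excluded from the summary mean (flagged).
* **Model CV** per sub-district: delta method around the mean of
  predicted densities, $\nabla \bar g^\top V \nabla \bar g$ with $V$ the
  cluster-robust coefficient covariance; for an intercept-only model this
  collapses to $\bar g^2 \mathrm{var}(\hat\alpha)$ exactly (tested).

## 5. Top-down baselines and staleness

Redistribution operates village-within-sub-district (no raster grid —
the evaluation unit is the village, so a grid would add nothing at this
scale): areal weighting (counts proportional to area, density constant
within the parent) or covariate-proportional (dasymetric). Both conserve
parent totals exactly; an all-zero covariate falls back to areal with a
warning.

The staleness experiment draws a second census by re-weighting population
shares hierarchically: district shares from a Dirichlet centred on the
old shares (concentration 2–3 × D; strong regional shocks), sub-district
shares within districts from a much more concentrated Dirichlet (local
churn), plus 5% national growth. Migration is summarized as half the L1
distance between sub-district share vectors (~20–30% at the defaults).
The hierarchical form reflects that migration waves are regionally
driven; it also means a freshly surveyed bottom-up model can absorb the
regional component through its district effects, which is exactly the
mechanism being demonstrated. A bottom-up model fitted to a survey taken
*after* the migration is compared against covariate redistribution
anchored to the *old* census, both scored against the new census on the
identical (non-surveyed) village set.

## 6. The selection-bias study conditions

Demonstrating the balance correction requires selection to matter, which
under a correctly specified model it would not (selection on modelled
covariates is ignorable). The preset scenario therefore includes a
bounded "services" covariate that drives density, is strongly correlated
(latent 0.9) with built-up area, but is *not* offered to the model; the
survey under-samples built-up villages (probit tilt −0.8 — field
operations skipping dense urban blocks). The misspecified fit then
depends on the training covariate distribution, and inverse-probability
reweighting moves it toward the frame-optimal fit: the corrected weights
reduce the absolute bias of the frame-wide mean predicted density in ≥80%
of replicates (tested over 50).

## 7. Problem sizes and runtime

Tests and the acceptance script run at desk scale — 1,000 villages,
~120-village surveys, 25–50 point $\lambda$ grids for replicated
experiments — chosen so the full suite completes in a few minutes while
every statistical property under test (unbiasedness, recovery,
correction, coverage) is already resolvable at that scale. The national
preset (13,970 villages) runs the same pipeline in seconds and is used
only where admin-count fidelity matters.

## 8. Known limitations

* The pseudo-likelihood ignores the survey-estimation error in the
  response; villages estimated from 10 households carry the same weight
  structure as they would with full enumeration.
* The with-replacement variance approximation is mildly conservative at
  larger sampling fractions.
* The probit correction conditions only on LASSO-selected covariates;
  selection on unobservables orthogonal to them is not correctable and is
  not simulated.
* District effects are fixed effects; no shrinkage across districts, so
  districts with few surveyed villages estimate noisily.
* No spatial or temporal correlation; the staleness experiment moves
  population multiplicatively within sub-districts.
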