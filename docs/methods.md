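# Methods

`eipcea` implements a model-based cost-utility analysis of early
intervention in psychosis (EIP) services against Brazilian community
psychosocial centres (CAPS), from the healthcare-system perspective:
a Bayesian evidence synthesis of treatment effects, a six-state cohort
Markov model, and a probabilistic decision layer.  All inputs are
synthetic stand-ins with known ground truth; this note records the
models, the default parameter choices and their rationale, the numerical
conventions, and what the synthetic setting can and cannot demonstrate.

## Evidence synthesis

### Model

Treatment effects are risk ratios (RR) of 12-month remission and of
12-month relapse under EIP.  For aggregate two-arm trials
k = 1..K the likelihood is binomial per arm,

    events_c,k ~ Binomial(n_c,k, p_c,k)
    events_t,k ~ Binomial(n_t,k, min(p_c,k · exp(θ_k), 1 − 10⁻⁶))

with random effects θ_k ~ Normal(μ, τ²) on the log-RR scale and
hierarchically distributed control logits
logit(p_c,k) ~ Normal(μ_c, σ_c²).  The RR link is used because the
published effects are RRs; the probability product is capped just below
1 since an RR link is not variation-independent.  The pooled RR is
reported as the posterior mean of exp(μ) (the mean risk ratio), with
equal-tailed 95% credible bounds.

A single-arm observational cohort (n = 357, binary outcomes) enters
through a power prior: its binomial log-likelihood is multiplied by a
weight α ∈ [0, 1].  The cohort has its own effect
θ_obs ~ Normal(μ, τ²) and an unobserved control rate drawn from the
hierarchical control distribution.  α = 0 discards the cohort — the
implementation returns the aggregate-only fit directly, so the
weight-zero limit is exact — and α = 1 treats the cohort as one
additional (single-arm) study.

A deliberate consequence of this exchangeable formulation: a single
added study, however large, moves the pooled mean only by its
precision-weighted share, and the unknown control rate (uncertainty
~σ_c on the logit scale) caps the cohort's effective precision.  The
synthesis is therefore conservative about observational evidence:
at full weight the credible interval tightens somewhat and the mean
shifts modestly toward the cohort, rather than collapsing onto the
cohort's own estimate.  An alternative in which the cohort informs μ
directly (θ_obs ≡ μ) would borrow far more aggressively; we consider
the exchangeable form the more defensible default for biased-by-design
evidence and note it as the main reason full-weight pooled estimates
here are less extreme than some published power-prior analyses.

### Priors

Weakly informative throughout, configurable per fit:
μ ~ Normal(0, 10²); τ ~ half-Normal(1); μ_c ~ Normal(0, 2²);
σ_c ~ half-Normal(1).  With as few as 7 trials the τ prior is mildly
conservative: simulation shows 95% CrI coverage of ~98% at 7 trials per
meta-analysis and ~95% at 14 (the calibration test runs at 14).

### Sampling

The posterior is sampled with an affine-invariant ensemble sampler
(emcee) over a non-centred parameterisation (z-scores for θ_k and the
control logits), using a 0.8/0.2 mixture of differential-evolution and
snooker moves, which mixes far better than the default stretch move in
this ~20-dimensional hierarchy.  Settings are expressed as JAGS-style
`chains` / `iterations` (default 50,000) / `burn_in` (default 5,000) and
mapped onto the ensemble: walkers = max(2·dim + 2, 12·chains, 36), and
step counts scaled by an inefficiency factor of 12 because one ensemble
step is far more autocorrelated than one Gibbs iteration.  Walkers are
initialised in a tight ball around moment estimates (continuity-
corrected log-RRs and control logits).  Split-R̂ and bulk effective
sample size are computed over walkers-as-chains (arviz) for μ and τ; a
maximum R̂ above 1.05 triggers a logged warning and is reported in the
result, never silently truncated.  At the default settings the fixture
fits reach R̂ ≈ 1.01–1.03.  Fits are bit-reproducible given a seed.

## Markov model

### Structure

Six mutually exclusive states: FEP (entry), REMISSION, RELAPSE, TRS
(treatment-resistant schizophrenia), PNS (persistent negative symptoms),
DEATH (absorbing).  Permitted clinical edges: FEP→{REMISSION, TRS, PNS},
REMISSION↔RELAPSE, RELAPSE→TRS; TRS and PNS are chronic (exit only to
DEATH); FEP is an entry tunnel with no re-entry.  The permitted-edge set
is exactly the set of named transition parameters, so any edge can be
switched off by setting its probability to zero.

Cycle length is one year (the effectiveness inputs are 12-month RRs and
horizons are stated in years); the default horizon is 10 years with
entry at age 26 (the cohort mean).  Mortality uses an age-specific
life-table probability q(age) inflated by a standardised mortality ratio
via rate conversion, 1 − (1 − q)^SMR, applied first each cycle; the
surviving mass is split by the conditional clinical probabilities and
the residual is assigned to the stay-probability, making each row sum
to 1 exactly (a residual below −10⁻⁹ is a hard parameter error; smaller
negatives are float round-off and clamped).

Under EIP, remission-type probabilities (FEP→REMISSION,
RELAPSE→REMISSION) are multiplied by rr_remission and
REMISSION→RELAPSE by rr_relapse for the package duration (default
3 years; 5 in a scenario), capped so rows stay valid (cap events are
logged); afterwards EIP follows CAPS dynamics.  An exploratory scenario
applies a risk ratio (default 0.7) to the SMR under EIP across the whole
horizon, modelling a survival benefit of early intervention.

### Accrual and discounting

QALYs and state costs for cycle t (t = 1..horizon) are valued from
end-of-cycle occupancy and discounted by (1 + r)^−t at r = 3% per year;
cycle 0 (model entry) accrues nothing.  This convention is fixed for
testability: a static all-alive cohort with utility 1 accrues exactly
the 10-year annuity value 8.5302.  No half-cycle correction by default —
the original convention is unknown, so this is a replication caveat —
but `half_cycle=True` switches to mean-of-endpoints occupancy.
Inpatient episode costs attach to the admitted fraction of *new*
RELAPSE entrants each cycle; the EIP programme cost accrues on the
surviving cohort fraction during the cost window.

## Decision layer

ICER = ΔC/ΔE (EIP minus CAPS), with dominance labels instead of a
division when ΔE = 0, and "EIP dominant"/"EIP dominated" labelling by
quadrant.  Net monetary benefit λ·E − C provides the second decision
rule; for ΔE > 0, ICER < λ and positive incremental NMB are equivalent
(property-tested).  Willingness-to-pay is anchored at 1–3× a GDP per
capita of R$ 18,254 (the WHO heuristic); the CEAC grid spans 0 to
3 GDPpc in 100 steps.  Currency is R$ throughout; reports divide by a
PPP factor of 2.028 R$/USD, back-derived from the published pair
R$ 15,495 ↔ USD 7,640.

The PSA (default 5,000 draws) samples each parameter-table row
independently — Beta for probabilities and utilities, Gamma for costs,
log-Normal for ratios, families chosen to match each parameter's
support and configurable per row — and runs both strategies on the
shared draw.  Uncertainty in the pooled RRs is propagated by resampling
from the posterior draws of the evidence synthesis rather than
refitting per draw.  Jointly inconsistent transition draws are rejected
and resampled (bounded attempts).  Because the PSA "mean ICER"
convention is ambiguous, both the mean of per-draw ICERs and the ratio
of mean deltas are reported, labelled.  Exact zeros on the
cost-effectiveness plane are assigned to the positive side and logged.

## Synthetic inputs

The real inputs — the GAPi cohort individual-level data, the seven
trials' count tables, Brazilian life tables, and the full parameter
listing — are not publicly downloadable, so the package generates
statistically matched stand-ins:

* **IPD cohort** — 357 subjects, 62% male; ages truncated-Normal(26,
  7.38²) on [16, 40] (only mean/SD/range are reported; note the
  *realised* SD after truncation is ~5.3 — the configured SD is the
  untruncated parameter); independent Bernoulli 12-month outcomes at
  true probabilities 0.50 (remission) and 0.14 (relapse), chosen as
  control-rate × published full-weight RR.
* **Trials** — 7 per outcome, arm sizes 45–140 (≈1,290 participants,
  the published scale); control rates drawn on the logit scale (mean
  0.40 remission / 0.45 relapse, SD 0.5); trial log-RRs
  Normal(log 1.41, 0.50²) for remission and Normal(log 0.66, 0.60²) for
  relapse — the centres are the published aggregate-only estimates and
  the heterogeneity is calibrated so the fitted credible intervals match
  the published interval widths.
* **Life table** — Gompertz-like, q(age) = q₁₆ · exp(0.09·(age − 16))
  capped at 0.999, ages 16–110 (q₁₆ = 0.001); a real life-table CSV can
  be supplied instead.
* **Parameter table** — 22 rows (CAPS transition probabilities, utilities,
  annual costs, SMR 2.5, RR point values 1.22/0.31) with PSA
  hyperparameters; Beta effective sample sizes 50–150 and Gamma SDs at
  20% of the mean.  Values are calibrated so the deterministic base case
  reproduces the published scale: comparator FEP→remission 0.48 × RR
  1.22 ≈ 58.6% modelled 1-year remission, ΔC ≈ R$ 4.4k, ΔE ≈ 0.29
  QALYs, ICER ≈ R$ 15k/QALY.

Because the published evidence base and cohort are *fixed* datasets,
`default_inputs()` returns one frozen realisation of the generators
(fixed internal seeds, selected so the realised synthetic data
reproduce the published aggregate evidence); the run seed then drives
only the analysis (MCMC, PSA).  Passing `default_inputs(seed=...)`
instead derives fresh generator seeds for simulation studies.  Remission
and relapse are generated independently per subject, since the synthesis
treats them as separate outcomes.

### What the synthetic setting does and does not show

Passing tests demonstrate that the machinery is correct (conservation,
limits, calibration, decision-rule identities) and that the pipeline
reproduces the *scale* of the published analysis from matched inputs.
They do not validate the clinical parameter values themselves, and two
known divergences from the published results follow from design choices
documented above: (i) the conservative single-arm borrowing means
full-weight pooled RRs move less toward the cohort than the published
ones, so the end-to-end ICER sits somewhat above the published
deterministic base case; (ii) the synthetic cost structure makes EIP
cost-increasing in almost all PSA draws (NE quadrant), whereas the
published cloud was predominantly cost-saving (SE) — the real cost
offsets were larger and more skewed than the fixture's Gamma
assumptions.

## Numerical conventions and degenerate inputs

* Probabilities entering binomial log-likelihoods are clipped to
  [10⁻¹², 1 − 10⁻¹²]; RR-link products are capped at 1 − 10⁻⁶.
* Transition rows sum to 1 exactly by residual assignment; traces are
  validated to |row sum − 1| < 10⁻⁹ over the whole horizon.
* Zero-variance ("fixed") PSA distributions reproduce the deterministic
  base case to machine precision; all stochastic components are
  bit-reproducible given a seed (child seeds are spawned from the master
  seed per stage).
* ΔE = 0 yields labelled, non-numeric ICERs; λ = ΔC/ΔE yields exactly
  zero incremental NMB.
* A life table that does not cover start_age + horizon is a validation
  error, as are negative discount rates, α outside [0, 1] and
  burn-in ≥ iterations.

## Known limitations

* Cohort-level (not individual-level) modelling; no time-in-state
  effects, no duration-of-untreated-psychosis effects.
* TRS and PNS are absorbing except for death — no late recovery.
* The power-prior weight α is fixed per fit, not estimated
  (no commensurate/adaptive priors).
* One-year cycles without half-cycle correction by default.
* The PSA samples parameters independently; correlations among costs or
  among utilities are not modelled.
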