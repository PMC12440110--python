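# Methods

This package implements, end to end and on synthetic data with known ground
truth, the computational core of a two-part analysis of reward learning and
mesocorticolimbic network influence in depression: (1) hierarchical Bayesian
Q-learning models of a bi-valent two-armed bandit task, and (2) dependency
network analysis (DEPNA) of an 8-node brain network centered on the ventral
tegmental area (VTA), together with the covariate-adjusted association layer
that connects both to group membership and symptom/hormone measures.

## The bandit task and the Q-learning models

The task presents 90 intermixed trials, 30 each of three types (gain, loss,
neutral), each type with its own fixed stimulus pair and an 80/20
probabilistic contingency. Outcome coding follows the standard
Pessiglione-style convention, configurable in `TaskConfig`: gain trials pay
+1 with probability 0.8 on the better stimulus (0.2 on the worse), loss
trials deliver −1 unless avoided (the better stimulus avoids the loss with
probability 0.8), neutral trials always pay 0. "Correct" means choosing the
better (reward-maximizing / loss-avoiding) stimulus; on loss trials this is
the loss-avoiding arm, which keeps learning curves comparable across
valences.

Agents learn chosen-action values by the delta rule
`Q_t(s,a) = Q_{t−1}(s,a) + α (r_t − Q_{t−1}(s,a))`, with Q initialized at
zero and only the chosen arm updated, and choose via a softmax with inverse
temperature β. Model 1 has a single learning rate α; models 2–3 split it
into `alpha_gain` (gain trials) and `alpha_loss` (loss trials). Neutral
trials are assigned `alpha_gain`, which is inert under default coding (zero
outcomes on zero-initialized values produce zero prediction errors); the
assignment is configurable. Model 3 shares the subject-level likelihood of
model 2 but gives each clinical group its own set of group-level
hyperparameters (location and scale for every parameter).

The compliance filter excludes subjects below 50% correct on gain AND loss
trials (the conjunctive reading of "across both"), or with no responses at
all; a configuration switch selects the disjunctive rule.

An identifiability note that shapes several tests: with zero-initialized
values, loss trials are intrinsically more informative about their learning
rate than gain trials. A sampled loss arm goes negative and immediately
looks worse than the unsampled arm at 0, driving continued arm switching;
a sampled gain arm goes positive and locks choice in early. Learning-rate
recovery is therefore systematically better for `alpha_loss` than
`alpha_gain` at matched populations. The recovery study is designed
accordingly: truths span the supports broadly (probit-scale SD 1.2 around
a location of 0.4 for the learning rates; β log-normal with median 5 and
log-SD 0.7, sharp enough for choices to reveal value dynamics yet spread
enough for β itself to be identified), and the fitted model's hyperprior
scale is set to HalfNormal(1.0) so the population posterior can admit that
spread — a narrower scale prior over-shrinks subject parameters drawn this
widely and visibly under-covers at the support edges. Under truths drawn
narrowly (probit SD ≤ 0.8, the clinical-population regime), pooled
`alpha_gain` recovery correlation drops to ~0.45 regardless of chain
length; this is an information limit of 30 gain trials with early lock-in,
not a sampler artifact, and it is why the clinical group contrast uses the
partially pooled estimates rather than per-subject point estimates alone.

## Hierarchical Bayesian estimation

Subject parameters live on an unconstrained scale: α-type parameters map
through the inverse probit (`α = Φ(z)`), β through `exp`. Each unconstrained
coordinate is partially pooled, `z_i ~ Normal(μ, σ)`, with weakly
informative priors `μ ~ Normal(0, 1)` and `σ ~ HalfNormal(0.5)`; all priors
are exposed on `ModelSpec` so alternative values can be dropped in.

No Hamiltonian Monte Carlo backend is available in this package's
dependency footprint, so the sampler is authored here as a blocked
random-walk Metropolis scheme in the non-centered parameterization
(`z_i = μ + σ e_i`, `e_i ~ N(0,1)`), chosen after the centered variant
showed the classic funnel pathology (group scales sticking near zero with
effective sample sizes in the single digits):

* per-subject joint proposals on `e_i`, vectorized across the cohort, with
  per-subject step sizes adapted during warmup toward 35% acceptance;
* one joint `(μ, log σ)` proposal per group per iteration, which rigidly
  shifts/rescales that group's subject parameters (one cohort likelihood
  evaluation);
* an interweaved centered update (conjugate Gibbs draw for μ, log-scale
  Metropolis for σ, no likelihood cost) at the end of every iteration.
  Alternating centered and non-centered conditionals keeps σ mobile both
  when the subject likelihoods dominate (90 trials is informative) and when
  the prior does;
* hypers are frozen for the first quarter of warmup so subject effects can
  localize before the scale adapts.

Defaults are 4 chains × (1000 warmup + 1000 kept) draws; the simulation
harnesses (model recovery, WAIC replication) use reduced presets
(2 × 300–800) chosen so the full replicate studies complete on one CPU in a
few minutes while R-hat on the hypers stays near 1. Convergence diagnostics
(max R-hat, min ESS via ArviZ, Metropolis acceptance) ship with every fit;
acceptance below 10% raises a warning on the fit object rather than failing
silently. Identical data + config + seed reproduce identical draws.

WAIC is computed per trial (trials are the exchangeable likelihood units):
`lppd = Σ_t log mean_s exp(ll_ts)`, `p_waic = Σ_t var_s(ll_ts)` (sample
variance, ddof 1 — ArviZ uses the population variance, an O(1/draws)
difference the cross-check test accounts for), `waic = −2(lppd − p_waic)`,
with pairwise differences and standard errors from the pointwise
contributions. The posterior predictive check replays each subject's own
schedule under randomly drawn posterior parameters and compares the
cohort-mean trial-position accuracy curve per valence with the pointwise
95% predictive band.

## Dependency network analysis

For each subject's node × time panel: Pearson correlation matrix C; the
first-order partial correlation
`PC(j,k|i) = (C_jk − C_ji C_ki) / √((1−C_ji²)(1−C_ki²))`; the correlation
influence `d(j,k|i) = max(0, atanh C_jk − atanh PC(j,k|i))` (Fisher-z is
applied to both terms before differencing; a flag preserves the raw
difference variant); the average influence
`D(j,i) = (1/(n−1)) Σ_{R∉{i,j}} d(j,R|i)`; and the influencing
(column-sum) / influenced (row-sum) degrees. Numerical conventions:

* Correlations of magnitude 1 — the diagonal, or degenerate off-diagonal
  pairs — are pulled to 0.99 before `atanh` so the transform stays finite;
  the reported correlation diagonal remains exactly 1, and diagonal terms
  never enter the influence sums.
* The degenerate self-partner R = j is excluded from D's average while the
  printed 1/(n−1) normalization is retained (group contrasts are invariant
  to this constant; `normalization="n-2"` switches to the partner count).
* Outlier exclusion for degree analyses removes values more than 3 sample
  SDs from the mean, computed once, non-iteratively.
* Degree and edge analyses are covariate-adjusted OLS regressions; the edge
  family (all ordered hub↔target pairs) carries Benjamini–Hochberg FDR,
  while the single-hub degree analyses are reported uncorrected. Edge
  direction convention: `D[target, hub]` is the edge hub → target.

## The synthetic cohort generator

Each subject's brain panel is an order-1 vector autoregression
`x_t = A x_{t−1} + ε_t`, `ε ~ N(0, noise_sd² I)`, with the planted directed
influence on the hub's outgoing coefficients `A[target, hub]`. Any
coefficient matrix with spectral radius ≥ 1 is rejected. One deliberate
design choice: the hub's self-decay defaults to 0.7 while other nodes use
0.2. With homogeneous small decay, a pure lag-1 drive is almost orthogonal
to the hub's *contemporaneous* series, so a contemporaneous
partial-correlation method cannot attribute the targets' shared variance to
the hub and the influence ranking inverts; a slowly mixing (autocorrelated)
hub keeps its drive in phase with itself, making the planted directionality
recoverable — which is the generator's purpose. At coupling 0.4 and
T = 1000 the hub ranks first in influencing degree in ≳ 98% of subjects.

Group differences enter as an additive coupling delta for MDD-labelled
subjects; covariate associations can be planted as linear coefficients on
the hub coupling per standardized covariate unit. Behavioral truths are
drawn per group from probit-normal (learning rates) and log-normal (β)
population distributions; the defaults (HC `alpha_gain` 0.35 vs MDD 0.20,
shared `alpha_loss` 0.30, β median 3) encode a reward-specific learning
deficit. Covariates (age, sex, medication, a preprocessing covariate,
anhedonia/depression/anxiety scores, hormones) are drawn from plausible
clinical ranges, independent of everything except where an association is
planted; the full ground truth is serialized next to every generated
cohort.

What the generator does *not* emulate: hemodynamic convolution, realistic
fMRI noise spectra (1/f, physiological confounds), motion, scanner drift,
or missingness. Passing tests therefore demonstrate that the analysis code
recovers what it is designed to recover under a known linear-Gaussian
generative process — not that real resting-state data satisfy these
assumptions.

## Statistical layer

Group contrasts and degree/edge analyses use OLS with dummy-coded binary
covariates and listwise deletion; rank-deficient designs fail loudly with
the collinear columns named. Symptom and hormone analyses use partial
Pearson correlations via double residualization (t test on n − 2 − k df),
which reduces exactly to the matrix partial-correlation formula in the
single-covariate case. The independent-samples rank-sum test enumerates all
group assignments exactly (valid under ties, via midranks) when the pooled
sample is ≤ 10 and otherwise uses the tie-corrected normal approximation;
a paired signed-rank variant is exposed separately because group contrasts
in this design are unpaired. The learning-curve model is the linear mixed
model `correct ~ group × trial_type + trial + (1 | subject)` fit on the
binary outcome exactly as specified (a GEE logistic option is provided);
gain is the reference-coded "1" level so a reward-specific deficit loads on
the interaction with a negative sign.

## Pipeline and reproducibility

`mesoinfluence.pipeline.run_pipeline` chains simulate → fit → depna →
associate → report into a run directory with a manifest (config, derived
stage seeds, timings, output hashes). Stage seeds derive from the master
seed through fixed per-stage codes, so enabling/disabling one stage never
perturbs another's random stream. The numbered scripts under `analysis/`
are the narrative interface to the same library calls; all computation
lives in `src/mesoinfluence/` where the tests import it.

## Problem sizes used by the test harnesses

Replicate studies run at deliberately desk-scale sizes chosen as the
smallest that make the targeted property statistically unambiguous: model
comparison at 20 replicate cohorts of 30 subjects; parameter recovery at 20
replicates of 30 subjects × 90 trials with the reduced sampler preset;
hub-recovery at 50 subjects × 1000 timepoints; mixed-model power at 30
replicate cohorts of 70 subjects with a pronounced planted reward-learning
deficit (`alpha_gain` 0.55 vs 0.07, population probit SD 0.15), calibrated
beforehand to ~90% power so the ≥80% acceptance bound has margin.

## Known limitations

* The Metropolis sampler mixes more slowly than gradient-based HMC; hyper
  ESS per 1000 draws is modest, and very small cohorts (< 10 subjects) with
  weak likelihoods may need longer chains than the defaults.
* DEPNA's "influence" is a partial-correlation construct, not causal
  discovery; the generator was designed so that its ground-truth
  directionality is recoverable by this construct, and the limits of that
  equivalence (e.g. homogeneous-decay VARs) are documented above.
* The mixed model treats a binary outcome linearly, exactly as the analysis
  it mirrors; coefficients are interpretable as accuracy differences but
  variance is heteroscedastic by construction.
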