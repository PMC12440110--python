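# mesoinfluence

Reward-learning computational modeling and brain-network influence analysis
for a VTA-centered mesocorticolimbic circuit, on synthetic cohorts with
known ground truth.

Major depressive disorder is associated with blunted learning from reward
and altered dominance of the ventral tegmental area (VTA) over its
mesocorticolimbic targets. Testing analysis code for such studies is hard
because the interesting quantities — learning rates, directed network
influence — are latent. This package pairs every analysis stage with a
generator that plants the ground truth it should recover:

* **Bandit task + Q-learning agents** (`mesoinfluence.bandit`): a 90-trial
  two-armed task (30 gain / 30 loss / 30 neutral trials, 80/20
  contingencies); delta-rule agents
  `Q_t(s,a) = Q_{t-1}(s,a) + α(r_t − Q_{t-1}(s,a))` with softmax choice
  `p(a) ∝ exp(βQ(a))`, single or valence-specific learning rates; RPE
  regressor traces; the <50%-correct compliance filter.
* **Hierarchical Bayesian inference** (`mesoinfluence.inference`):
  non-centered hierarchical models fit by an adaptive blocked
  Metropolis-within-Gibbs sampler (α via inverse probit, β via exp;
  `μ ~ N(0,1)`, `σ ~ HalfNormal(0.5)`), per-trial pointwise
  log-likelihoods, WAIC model comparison with pairwise standard errors,
  posterior predictive checks, and a simulate→fit→compare parameter
  recovery harness.
* **Dependency network analysis** (`mesoinfluence.depna`): per-subject
  correlation-influence matrices `d(j,k|i) = max(0, z(C_jk) − z(PC_jk|i))`,
  average influence `D(j,i)`, influencing/influenced degrees, 3-SD outlier
  exclusion, covariate-adjusted degree regressions and directed hub edge
  graphs with BH-FDR.
* **Association layer** (`mesoinfluence.stats`): Fisher-z seed-to-ROI
  connectivity, adjusted group contrasts and partial correlations over ROI
  families, BH-FDR, exact/approximate rank-sum tests, the learning-curve
  mixed model `correct ~ group × trial_type + trial + (1|subject)`, and
  cross-state Spearman consistency.
* **Synthetic cohorts** (`mesoinfluence.synthetic`): VAR(1) brain panels
  with a planted directed hub, group-level behavioral populations, and a
  clinical covariate table with plantable linear associations; every cohort
  ships with its serialized ground truth.
* **Pipeline** (`mesoinfluence.pipeline`): seed-disciplined orchestration
  of all stages with a replayable manifest.

See `docs/methods.md` for the models, priors, sampler design and numerical
conventions.

## Worked example

```python
import numpy as np
from mesoinfluence import bandit, depna, inference, synthetic

# a cohort with a planted reward-learning deficit and a stronger MDD hub
net = synthetic.NetSimConfig(n_timepoints=300, group_coupling_delta=0.15)
cohort, panel, records, truth = synthetic.simulate_cohort(
    net, bandit.TaskConfig(), synthetic.PopulationSpec(), 30, seed=20260923
)

# fit the two-learning-rate model and compare against the one-rate model
cfg = inference.SamplerConfig(chains=2, warmup=800, draws=800, seed=7)
fits = {
    f"model{m}": inference.fit_hierarchical(inference.ModelSpec(model_id=m), records, cfg)
    for m in (1, 2)
}
print(inference.compute_waic(fits).table.round(1))

# VTA influencing degree per subject
D = depna.dependency_matrix(depna.correlation_matrix(panel.subject(0), list(net.node_names)))
print(np.round(depna.influence_degrees(D).influencing, 3))
```

The same analysis, run by `python analysis/02_fit_models.py` and
`python analysis/03_network_influence.py`, prints (numbers from the actual
run at seed 20260923):

```
WAIC (deviance scale):
          lppd  p_waic    waic
model1 -3018.2    43.0  6122.5
model2 -2993.1    60.2  6106.7
preferred model: model2
PPC: observed accuracy inside 95% band at 98% of positions
rank-sum alpha_gain_hat: HC median 0.282 vs MDD 0.254 (W=1051, p=0.0444)
rank-sum alpha_loss_hat: HC median 0.289 vs MDD 0.315 (W=835, p=0.2369)
mixed model group x trial-type interaction: beta=-0.0449, p=0.1080

VTA influencing degree ~ group (n=60, 0 outlier(s) excluded): beta=0.2754, t=3.46, p=0.0011
VTA influenced degree ~ group (n=60, 0 outlier(s) excluded): beta=0.3406, t=6.33, p=0.0000
```

WAIC correctly prefers the two-learning-rate generative model and the
posterior predictive band covers the observed learning curves. The
recovered reward learning rates separate the groups in the planted
direction (`alpha_gain` lower in MDD, `alpha_loss` and `beta` null, as
planted); at this moderate effect size the trial-level mixed-model
interaction is negative but only trend-level, while the parameter-based
contrast is significant — the model-based analysis is the more sensitive
instrument. The MDD group's stronger planted hub coupling appears as a
higher VTA influencing degree. The numbered scripts under `analysis/` walk
through the full sequence (simulate, fit/compare, network influence,
connectivity associations, parameter recovery) and write their tables and
figures under `results/`.

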