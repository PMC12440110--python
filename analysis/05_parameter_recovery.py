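"""Parameter recovery study for the two-learning-rate model.

Draws 30 agents with widely spread true parameters, simulates their
sessions, refits the hierarchical model, and reports true-vs-estimated
correlations, 95% credible-interval coverage and the cross-parameter
identifiability (correlation of estimation errors). Writes the recovery
table and figure under results/recovery/.
"""

from pathlib import Path

import numpy as np
from scipy.stats import norm

from mesoinfluence import bandit, inference

SEED = 20260923
OUT = Path(__file__).resolve().parent.parent / "results" / "recovery"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    task = bandit.TaskConfig()
    # truths span the supports broadly; the fitted hyperprior scale admits
    # that spread (see docs/methods.md on the recovery-study design)
    truths = [
        bandit.AgentParams(
            model_id=2,
            alpha_gain=float(norm.cdf(rng.normal(norm.ppf(0.4), 1.2))),
            alpha_loss=float(norm.cdf(rng.normal(norm.ppf(0.4), 1.2))),
            beta=float(np.exp(rng.normal(np.log(5.0), 0.7))),
        )
        for _ in range(30)
    ]
    sessions = [bandit.generate_schedule(task, rng) for _ in range(30)]
    report = inference.parameter_recovery(
        inference.ModelSpec(model_id=2, prior_sigma_sd=1.0),
        truths,
        sessions,
        inference.SamplerConfig(chains=2, warmup=800, draws=800, seed=SEED % 2**16),
        seed=SEED % 2**16 + 1,
    )
    report.table.to_csv(OUT / "recovery.csv", index=False)
    report.plot(OUT / "recovery.png")
    for p in ("alpha_gain", "alpha_loss", "beta"):
        print(
            f"{p}: true-estimate r = {report.correlation(p):.3f}, "
            f"95% CI coverage = {100*report.coverage(p):.0f}%"
        )
    print(
        "identifiability: err-corr(alpha_gain, beta) = "
        f"{report.error_correlation('alpha_gain', 'beta'):.3f}"
    )


if __name__ == "__main__":
    main()
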