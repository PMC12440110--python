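"""Fit the Q-learning models to the simulated cohort and compare them.

Reads the behavioral records written by 01_simulate_cohort.py (regenerated
in memory from the same seed for simplicity), fits the one- and
two-learning-rate hierarchical models, ranks them by WAIC, runs the
posterior predictive check, and tests the group difference in recovered
reward learning rates with a rank-sum test. Outputs under results/fits/.
"""

from pathlib import Path

import pandas as pd

from mesoinfluence import bandit, inference, stats, synthetic

SEED = 20260923
OUT = Path(__file__).resolve().parent.parent / "results" / "fits"


def main() -> None:
    net = synthetic.NetSimConfig(n_timepoints=300, group_coupling_delta=0.15)
    task = bandit.TaskConfig()
    pop = synthetic.PopulationSpec()
    cohort, _, records, truth = synthetic.simulate_cohort(net, task, pop, 30, seed=SEED)
    include = bandit.compliance_filter(records)
    kept = [r for r, ok in zip(records, include) if ok]
    groups = cohort.set_index("subject_id").loc[[r.subject_id for r in kept], "group"]

    OUT.mkdir(parents=True, exist_ok=True)
    scfg = inference.SamplerConfig(chains=2, warmup=800, draws=800, seed=SEED % 2**16)
    fits = {}
    for m in (1, 2):
        fits[f"model{m}"] = inference.fit_hierarchical(
            inference.ModelSpec(model_id=m), kept, scfg
        )
    waic = inference.compute_waic(fits)
    waic.table.to_csv(OUT / "waic.csv")
    waic.pairwise.to_csv(OUT / "waic_pairwise.csv", index=False)
    print("WAIC (deviance scale):")
    print(waic.table.round(1))
    print(f"preferred model: {waic.best}")

    best = fits["model2"]
    ppc = inference.posterior_predictive(best, kept, n_rep=200, seed=1)
    ppc.plot(OUT / "ppc.png")
    print(f"PPC: observed accuracy inside 95% band at {100*ppc.coverage():.0f}% of positions")

    est = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in kept],
            "group": groups.to_numpy(),
            "alpha_gain_hat": best.subject_posterior_mean("alpha_gain"),
            "alpha_loss_hat": best.subject_posterior_mean("alpha_loss"),
            "beta_hat": best.subject_posterior_mean("beta"),
        }
    )
    est.to_csv(OUT / "subject_estimates.csv", index=False)
    for p in ("alpha_gain_hat", "alpha_loss_hat", "beta_hat"):
        hc = est.loc[est["group"] == "HC", p]
        mdd = est.loc[est["group"] == "MDD", p]
        w, pv = stats.rank_sum_test(hc, mdd)
        print(f"rank-sum {p}: HC median {hc.median():.3f} vs MDD {mdd.median():.3f} (W={w:.0f}, p={pv:.4f})")

    tt = bandit.records_to_frame(kept).merge(cohort[["subject_id", "group"]], on="subject_id")
    mm = stats.learning_mixed_model(tt)
    mm.to_csv(OUT / "mixed_model.csv")
    row = mm.loc["interaction"]
    print(f"mixed model group x trial-type interaction: beta={row['coef']:.4f}, p={row['p']:.4f}")


if __name__ == "__main__":
    main()
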