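"""Hierarchical Bayesian fitting of the Q-learning models.

Three models of increasing structure are fit to cohorts of bandit sessions:

* model 1 -- one learning rate alpha and one inverse temperature beta per
  subject;
* model 2 -- valence-specific learning rates alpha_gain / alpha_loss plus
  beta;
* model 3 -- like model 2 but with separate group-level hyperparameters for
  each clinical group, so each group gets its own population posterior.

Subject parameters live on an unconstrained scale (z), with alpha = Phi(z)
(inverse probit) and beta = exp(z), and are partially pooled through
group-level Normal(mu, sigma) population distributions with weakly
informative priors mu ~ Normal(0, 1) and sigma ~ HalfNormal(0.5). All priors
are config-exposed.

Sampling uses a blocked random-walk Metropolis scheme in the non-centered
parameterization (z_i = mu + sigma * e_i with e_i ~ Normal(0, 1)), which
removes the funnel between group scales and subject effects at small n:
per-subject joint updates of e_i (vectorized across subjects, proposal
scales adapted during warmup), then a joint (mu, log sigma) update per
group that rigidly shifts/rescales all of that group's subject parameters.
Because 90 trials make the subject likelihoods informative, each iteration
finishes with an interweaved *centered* resampling of the hypers given the
realized subject parameters (conjugate draw for mu, log-scale Metropolis
for sigma, no likelihood cost); alternating the two parameterizations keeps
the group scale mobile whichever regime the posterior is in. Hypers stay
frozen for the first quarter of warmup so the subject effects can find the
data before the scale adapts. Both likelihood-bearing blocks cost one
vectorized cohort evaluation per iteration.
Draws are exposed as plain arrays and as an ArviZ ``InferenceData`` (R-hat,
effective sample size), and the per-trial pointwise log-likelihood needed
for WAIC is stored with every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .bandit import AgentParams, BehavioralRecord, TaskSession, simulate_agent

__all__ = [
    "ModelSpec",
    "SamplerConfig",
    "PosteriorFit",
    "WaicResult",
    "RecoveryReport",
    "PPCResult",
    "log_likelihood",
    "fit_hierarchical",
    "compute_waic",
    "posterior_predictive",
    "parameter_recovery",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which Q-learning model to fit and how its parameters are transformed.

    ``param_names`` are the unconstrained coordinates; learning-rate
    parameters map to [0, 1] through the inverse probit and beta to (0, inf)
    through exp. Model 3 splits every group-level hyperparameter by the
    cohort's clinical group.
    """

    model_id: int = 2
    prior_mu_sd: float = 1.0
    prior_sigma_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValueError(f"model_id must be 1, 2 or 3, got {self.model_id}")

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.model_id == 1:
            return ("alpha", "beta")
        return ("alpha_gain", "alpha_loss", "beta")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def grouped(self) -> bool:
        return self.model_id == 3

    def to_natural(self, z: np.ndarray) -> np.ndarray:
        """Map unconstrained draws (..., P) to natural parameter scale."""
        nat = np.empty_like(z)
        for p, name in enumerate(self.param_names):
            nat[..., p] = np.exp(z[..., p]) if name == "beta" else norm.cdf(z[..., p])
        return nat

    def alpha_index_by_trial_type(self) -> np.ndarray:
        """Param index supplying the learning rate for (gain, loss, neutral)."""
        if self.model_id == 1:
            return np.array([0, 0, 0])
        return np.array([0, 1, 0])  # neutral shares alpha_gain

    def params_from_natural(self, nat_row: np.ndarray) -> AgentParams:
        if self.model_id == 1:
            return AgentParams(model_id=1, alpha=float(nat_row[0]), beta=float(nat_row[1]))
        return AgentParams(
            model_id=self.model_id,
            alpha_gain=float(nat_row[0]),
            alpha_loss=float(nat_row[1]),
            beta=float(nat_row[2]),
        )


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings. The default is 4 chains of 1000 warmup + 1000 kept draws."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    init_step: float = 0.3
    target_accept: float = 0.35
    min_accept_warn: float = 0.10

    @classmethod
    def fast(cls, seed: int = 0) -> "SamplerConfig":
        """Reduced-budget preset for simulation harnesses (2 x 400 + 400)."""
        return cls(chains=2, warmup=400, draws=400, seed=seed)


class _StackedData:
    """Cohort behavioral arrays stacked subject x trial for vectorized replay."""

    def __init__(self, records: list[BehavioralRecord]):
        n_trials = {r.session.n_trials for r in records}
        if len(n_trials) != 1:
            raise ValueError("all records must share one session length")
        self.n_subjects = len(records)
        self.n_trials = n_trials.pop()
        self.n_pairs = records[0].session.n_pairs
        shape = (self.n_subjects, self.n_trials)
        self.choice = np.empty(shape, dtype=np.int64)
        self.outcome = np.empty(shape)
        self.pair = np.empty(shape, dtype=np.int64)
        self.ttype = np.empty(shape, dtype=np.int64)
        self.responded = np.empty(shape, dtype=bool)
        for i, rec in enumerate(records):
            self.choice[i] = np.where(rec.responded, rec.choices, 0)
            self.outcome[i] = np.where(rec.responded, rec.outcomes, 0.0)
            self.pair[i] = rec.session.pair_id
            self.ttype[i] = rec.session.trial_type
            self.responded[i] = rec.responded
        self.subject_ids = [r.subject_id for r in records]


def _replay_loglik(
    spec: ModelSpec, nat: np.ndarray, data: _StackedData, pointwise: bool = False
) -> np.ndarray:
    """Log-likelihood of observed choices under natural params ``nat`` (S, P).

    Returns per-subject totals (S,), or the per-trial matrix (S, T) when
    ``pointwise``. Omitted trials contribute exactly zero.
    """
    S, T = data.choice.shape
    aidx = spec.alpha_index_by_trial_type()
    alpha_by_type = nat[:, aidx]  # (S, 3)
    beta = nat[:, -1]
    q = np.zeros((S, data.n_pairs, 2))
    rows = np.arange(S)
    out = np.zeros((S, T)) if pointwise else np.zeros(S)
    for t in range(T):
        p = data.pair[:, t]
        qp = q[rows, p, :]  # (S, 2)
        zq = beta[:, None] * qp
        zq = zq - zq.max(axis=1, keepdims=True)
        lse = np.log(np.exp(zq).sum(axis=1))
        c = data.choice[:, t]
        resp = data.responded[:, t]
        ll_t = np.where(resp, zq[rows, c] - lse, 0.0)
        if np.any(np.isnan(ll_t)):
            bad = int(np.flatnonzero(np.isnan(ll_t))[0])
            raise FloatingPointError(f"NaN in Q replay at trial {t}, subject {bad}")
        if pointwise:
            out[:, t] = ll_t
        else:
            out += ll_t
        alpha_t = alpha_by_type[rows, data.ttype[:, t]]
        rpe = data.outcome[:, t] - qp[rows, c]
        q[rows, p, c] = qp[rows, c] + np.where(resp, alpha_t * rpe, 0.0)
    return out


def log_likelihood(
    spec: ModelSpec, params: AgentParams, record: BehavioralRecord
) -> np.ndarray:
    """Per-trial log p(choice_t | Q_t, beta) for one subject.

    Q-values are replayed deterministically from the observed
    choice/outcome sequence; no-response trials contribute 0.
    """
    data = _StackedData([record])
    if spec.model_id == 1:
        nat = np.array([[params.alpha, params.beta]])
    else:
        nat = np.array([[params.alpha_gain, params.alpha_loss, params.beta]])
    return _replay_loglik(spec, nat, data, pointwise=True)[0]


@dataclass
class PosteriorFit:
    """MCMC draws plus diagnostics for one hierarchical model fit.

    Array shapes: ``z`` (chains, draws, subjects, params) on the
    unconstrained scale, ``subject_params`` its natural-scale transform,
    ``mu``/``sigma`` (chains, draws, groups, params), ``pointwise_ll``
    (chains, draws, subjects, trials).
    """

    spec: ModelSpec
    param_names: tuple[str, ...]
    group_names: tuple[str, ...]
    subject_ids: list[str]
    z: np.ndarray
    subject_params: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    pointwise_ll: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    warnings_: list = field(default_factory=list)

    @property
    def n_draws_total(self) -> int:
        return self.z.shape[0] * self.z.shape[1]

    def flat_ll(self) -> np.ndarray:
        """Pointwise log-likelihood as (total draws, total trials)."""
        c, d, s, t = self.pointwise_ll.shape
        return self.pointwise_ll.reshape(c * d, s * t)

    def subject_posterior_mean(self, param: str) -> np.ndarray:
        p = self.param_names.index(param)
        return self.subject_params[..., p].mean(axis=(0, 1))

    def subject_ci(self, param: str, prob: float = 0.95) -> np.ndarray:
        p = self.param_names.index(param)
        lo, hi = (1 - prob) / 2, 1 - (1 - prob) / 2
        flat = self.subject_params[..., p].reshape(-1, len(self.subject_ids))
        return np.quantile(flat, [lo, hi], axis=0).T

    def to_inference_data(self):
        import arviz as az

        post = {
            "mu": self.mu,
            "sigma": self.sigma,
            "z": self.z,
            "subject_params": self.subject_params,
        }
        return az.from_dict(
            posterior=post,
            log_likelihood={"choice": self.pointwise_ll},
        )

    def summary(self) -> dict:
        out = dict(self.diagnostics)
        out["param_names"] = list(self.param_names)
        out["group_names"] = list(self.group_names)
        for p, name in enumerate(self.param_names):
            out[f"mu_{name}_mean"] = float(self.mu[..., :, p].mean())
            out[f"sigma_{name}_mean"] = float(self.sigma[..., :, p].mean())
        return out


def fit_hierarchical(
    spec: ModelSpec,
    records: list[BehavioralRecord],
    sampler_cfg: SamplerConfig | None = None,
    groups: list[str] | None = None,
) -> PosteriorFit:
    """Fit one hierarchical Q-learning model to a cohort of sessions.

    ``groups`` (one clinical label per record) is required for model 3 and
    ignored otherwise. Identical data + config + seed reproduce identical
    draws.
    """
    if len(records) < 2:
        raise ValueError("hierarchical fitting needs at least 2 subjects")
    cfg = sampler_cfg or SamplerConfig()
    data = _StackedData(records)
    S, P = data.n_subjects, spec.n_params

    if spec.grouped:
        if groups is None:
            raise ValueError("model 3 requires per-subject group labels")
        group_names = tuple(sorted(set(groups)))
        group_idx = np.array([group_names.index(g) for g in groups])
    else:
        group_names = ("all",)
        group_idx = np.zeros(S, dtype=np.int64)
    G = len(group_names)
    counts = np.bincount(group_idx, minlength=G).astype(float)

    root = np.random.SeedSequence(cfg.seed)
    chain_seeds = root.spawn(cfg.chains)

    z_out = np.empty((cfg.chains, cfg.draws, S, P))
    mu_out = np.empty((cfg.chains, cfg.draws, G, P))
    sigma_out = np.empty((cfg.chains, cfg.draws, G, P))
    accept_frac = np.empty(cfg.chains)

    for ch in range(cfg.chains):
        rng = np.random.default_rng(chain_seeds[ch])
        mu = rng.normal(0.0, 0.1, size=(G, P))
        sigma = np.full((G, P), spec.prior_sigma_sd)
        e = rng.normal(0.0, 0.5, size=(S, P))  # non-centered subject effects
        step = np.full(S, cfg.init_step)
        hyper_step = np.full(G, 0.15)
        z = mu[group_idx] + sigma[group_idx] * e
        cur_ll = _replay_loglik(spec, spec.to_natural(z), data)
        n_acc = 0
        n_tot = 0
        for it in range(cfg.warmup + cfg.draws):
            in_warmup = it < cfg.warmup
            gamma = min(0.25, 2.0 / np.sqrt(it + 2))
            # -- subject block: joint RW on e_i, standard-normal prior
            prop_e = e + step[:, None] * rng.standard_normal((S, P))
            prop_z = mu[group_idx] + sigma[group_idx] * prop_e
            prop_ll = _replay_loglik(spec, spec.to_natural(prop_z), data)
            log_r = (prop_ll - cur_ll) - 0.5 * (prop_e**2 - e**2).sum(axis=1)
            acc = np.log(rng.random(S)) < log_r
            e[acc] = prop_e[acc]
            cur_ll[acc] = prop_ll[acc]
            if in_warmup:
                step *= np.exp(gamma * (acc.astype(float) - cfg.target_accept))
                step = np.clip(step, 1e-3, 5.0)
            else:
                n_acc += int(acc.sum())
                n_tot += S
            if it < cfg.warmup // 4:
                continue  # hypers frozen while subject effects localize
            # -- hyper block: joint (mu, log sigma) RW per group; rigidly
            #    moves the group's subject parameters, one likelihood eval
            prop_mu = mu + hyper_step[:, None] * rng.standard_normal((G, P))
            prop_sigma = sigma * np.exp(hyper_step[:, None] * rng.standard_normal((G, P)))
            prop_z = prop_mu[group_idx] + prop_sigma[group_idx] * e
            prop_ll = _replay_loglik(spec, spec.to_natural(prop_z), data)
            dll = np.zeros(G)
            np.add.at(dll, group_idx, prop_ll - cur_ll)
            # priors: mu ~ N(0, s_mu); sigma ~ half-N(0, s_sig) with log-scale Jacobian
            dprior = (
                -0.5 * (prop_mu**2 - mu**2).sum(axis=1) / spec.prior_mu_sd**2
                - 0.5 * (prop_sigma**2 - sigma**2).sum(axis=1) / spec.prior_sigma_sd**2
                + np.log(prop_sigma / sigma).sum(axis=1)
            )
            acc_h = np.log(rng.random(G)) < dll + dprior
            for g in np.flatnonzero(acc_h):
                mu[g] = prop_mu[g]
                sigma[g] = prop_sigma[g]
                sel = group_idx == g
                cur_ll[sel] = prop_ll[sel]
            if in_warmup:
                hyper_step *= np.exp(gamma * (acc_h.astype(float) - 0.25))
                hyper_step = np.clip(hyper_step, 1e-3, 2.0)
            # -- interweave: centered resampling of hypers given realized z
            #    (z and hence the likelihood are untouched; e is re-derived)
            z = mu[group_idx] + sigma[group_idx] * e
            for g in range(G):
                zg = z[group_idx == g]
                prec = 1.0 / spec.prior_mu_sd**2 + counts[g] / sigma[g] ** 2
                mean = (zg.sum(axis=0) / sigma[g] ** 2) / prec
                mu[g] = mean + rng.standard_normal(P) / np.sqrt(prec)
                dev2 = ((zg - mu[g]) ** 2).sum(axis=0)

                def _lp(s: np.ndarray) -> np.ndarray:
                    # centered conditional of sigma + half-Normal prior + log Jacobian
                    return (
                        -counts[g] * np.log(s)
                        - 0.5 * dev2 / s**2
                        - 0.5 * (s / spec.prior_sigma_sd) ** 2
                        + np.log(s)
                    )

                prop_s = sigma[g] * np.exp(0.3 * rng.standard_normal(P))
                acc_s = np.log(rng.random(P)) < _lp(prop_s) - _lp(sigma[g])
                sigma[g] = np.where(acc_s, prop_s, sigma[g])
            e = (z - mu[group_idx]) / sigma[group_idx]
            if not in_warmup:
                k = it - cfg.warmup
                z_out[ch, k] = mu[group_idx] + sigma[group_idx] * e
                mu_out[ch, k] = mu
                sigma_out[ch, k] = sigma
        accept_frac[ch] = n_acc / max(1, n_tot)

    subject_params = spec.to_natural(z_out)
    # pointwise log-likelihood for every kept draw (thinned only by draws config)
    pw = np.empty((cfg.chains, cfg.draws, S, data.n_trials))
    for ch in range(cfg.chains):
        for k in range(cfg.draws):
            pw[ch, k] = _replay_loglik(spec, subject_params[ch, k], data, pointwise=True)

    fit = PosteriorFit(
        spec=spec,
        param_names=spec.param_names,
        group_names=group_names,
        subject_ids=data.subject_ids,
        z=z_out,
        subject_params=subject_params,
        mu=mu_out,
        sigma=sigma_out,
        pointwise_ll=pw,
        diagnostics={"mean_accept": float(accept_frac.mean())},
    )
    fit.diagnostics.update(_convergence_diagnostics(mu_out, sigma_out))
    if accept_frac.mean() < cfg.min_accept_warn:
        msg = f"low Metropolis acceptance ({accept_frac.mean():.3f}); treat draws with suspicion"
        fit.warnings_.append(msg)
        warnings.warn(msg)
    return fit


def _convergence_diagnostics(mu: np.ndarray, sigma: np.ndarray) -> dict:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior={"mu": mu, "sigma": sigma})
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    return {
        "rhat_max": float(
            max(rhat["mu"].values.max(), rhat["sigma"].values.max())
        ),
        "ess_min": float(min(ess["mu"].values.min(), ess["sigma"].values.min())),
    }


@dataclass
class WaicResult:
    """Widely applicable information criterion on the deviance scale."""

    table: pd.DataFrame  # index: model label; columns lppd, p_waic, waic
    pairwise: pd.DataFrame  # model_a, model_b, d_waic, se

    @property
    def best(self) -> str:
        return str(self.table["waic"].idxmin())


def _waic_components(flat_ll: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(lppd, p_waic, pointwise waic contributions) from (draws, points) ll."""
    m = flat_ll.max(axis=0)
    lppd_i = m + np.log(np.exp(flat_ll - m).mean(axis=0))
    p_i = flat_ll.var(axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_i)
    return float(lppd_i.sum()), float(p_i.sum()), waic_i


def compute_waic(fits: list[PosteriorFit] | dict) -> WaicResult:
    """WAIC per model with pairwise differences and their standard errors.

    lppd = sum_t log mean_draws exp(ll_t); p_waic = sum_t var_draws(ll_t);
    waic = -2 (lppd - p_waic). Pointwise terms are per trial; difference SEs
    follow sqrt(N var(waic_i^A - waic_i^B)).
    """
    if not isinstance(fits, dict):
        fits = {f"model{f.spec.model_id}": f for f in fits}
    lls = {k: f.flat_ll() for k, f in fits.items()}
    n_points = {ll.shape[1] for ll in lls.values()}
    if len(n_points) != 1:
        raise ValueError("fits cover different trial counts; WAIC not comparable")
    rows, pointwise = {}, {}
    for k, ll in lls.items():
        lppd, p_waic, waic_i = _waic_components(ll)
        rows[k] = {"lppd": lppd, "p_waic": p_waic, "waic": -2.0 * (lppd - p_waic)}
        pointwise[k] = waic_i
    table = pd.DataFrame(rows).T
    pairs = []
    keys = list(fits)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = keys[i], keys[j]
            diff = pointwise[a] - pointwise[b]
            pairs.append(
                {
                    "model_a": a,
                    "model_b": b,
                    "d_waic": float(diff.sum()),
                    "se": float(np.sqrt(diff.size * diff.var(ddof=1))),
                }
            )
    return WaicResult(table, pd.DataFrame(pairs))


@dataclass
class PPCResult:
    """Posterior predictive check of trial-wise choice accuracy.

    ``observed[k, j]`` is the cohort mean correct-choice rate on the j-th
    trial of type k; ``band`` holds the pointwise predictive quantiles of the
    replicated curves.
    """

    trial_types: tuple[str, ...]
    observed: np.ndarray  # (types, trials_per_type)
    band: np.ndarray  # (types, trials_per_type, 2) lo/hi
    replicated_mean: np.ndarray

    def coverage(self) -> float:
        inside = (self.observed >= self.band[..., 0]) & (self.observed <= self.band[..., 1])
        return float(inside.mean())

    def plot(self, path=None):
        """Observed accuracy curves over the posterior predictive band."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(self.trial_types), figsize=(9, 3.2), sharey=True)
        x = np.arange(1, self.observed.shape[1] + 1)
        for k, (ax, name) in enumerate(zip(np.atleast_1d(axes), self.trial_types)):
            ax.fill_between(x, self.band[k, :, 0], self.band[k, :, 1], alpha=0.3,
                            label="posterior predictive")
            ax.plot(x, self.replicated_mean[k], "--", lw=1)
            ax.plot(x, self.observed[k], "k.-", lw=1, label="observed")
            ax.set_title(f"{name} trials")
            ax.set_xlabel("trial within type")
        np.atleast_1d(axes)[0].set_ylabel("correct-choice rate")
        np.atleast_1d(axes)[0].legend(frameon=False, fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _accuracy_curve(records: list[BehavioralRecord], n_per_type: int) -> np.ndarray:
    """Mean correct rate by within-type trial position, types x positions."""
    acc = np.zeros((2, n_per_type))
    cnt = np.zeros((2, n_per_type))
    for rec in records:
        for k in (0, 1):  # gain, loss
            idx = np.flatnonzero(rec.session.trial_type == k)
            correct = rec.correct[idx]
            resp = rec.responded[idx]
            acc[k, : idx.size] += np.where(resp, correct, 0)
            cnt[k, : idx.size] += resp
    with np.errstate(invalid="ignore"):
        return acc / cnt


def posterior_predictive(
    fit: PosteriorFit,
    records: list[BehavioralRecord],
    n_rep: int = 200,
    prob: float = 0.95,
    seed: int = 0,
) -> PPCResult:
    """Replicate cohorts from posterior draws and compare accuracy curves.

    For each of ``n_rep`` random posterior draws, every subject replays their
    own schedule with their drawn parameters; the cohort-mean correct-rate
    curve per trial type is summarized into a pointwise predictive band.
    """
    rng = np.random.default_rng(seed)
    n_per_type = int((records[0].session.trial_type == 0).sum())
    observed = _accuracy_curve(records, n_per_type)
    C, D = fit.z.shape[:2]
    draws = rng.integers(0, C * D, size=n_rep)
    curves = np.empty((n_rep, 2, n_per_type))
    for r, d in enumerate(draws):
        ch, k = divmod(int(d), D)
        reps = []
        for s, rec in enumerate(records):
            params = fit.spec.params_from_natural(fit.subject_params[ch, k, s])
            reps.append(simulate_agent(params, rec.session, rng))
        curves[r] = _accuracy_curve(reps, n_per_type)
    lo, hi = (1 - prob) / 2, 1 - (1 - prob) / 2
    band = np.stack(
        [np.quantile(curves, lo, axis=0), np.quantile(curves, hi, axis=0)], axis=-1
    )
    return PPCResult(("gain", "loss"), observed, band, curves.mean(axis=0))


@dataclass
class RecoveryReport:
    """Simulate -> fit -> compare, per parameter."""

    table: pd.DataFrame  # subject rows: param, truth, post_mean, ci_lo, ci_hi, inside

    def coverage(self, param: str | None = None) -> float:
        t = self.table if param is None else self.table[self.table["param"] == param]
        return float(t["inside"].mean())

    def correlation(self, param: str) -> float:
        t = self.table[self.table["param"] == param]
        return float(np.corrcoef(t["truth"], t["post_mean"])[0, 1])

    def error_correlation(self, param_a: str, param_b: str) -> float:
        """Correlation of estimation errors across subjects (identifiability)."""
        ta = self.table[self.table["param"] == param_a].reset_index()
        tb = self.table[self.table["param"] == param_b].reset_index()
        return float(
            np.corrcoef(ta["post_mean"] - ta["truth"], tb["post_mean"] - tb["truth"])[0, 1]
        )

    def plot(self, path=None):
        """True-vs-estimated scatter with credible intervals, one panel per parameter."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        params = list(dict.fromkeys(self.table["param"]))
        fig, axes = plt.subplots(1, len(params), figsize=(3.2 * len(params), 3.2))
        for ax, name in zip(np.atleast_1d(axes), params):
            t = self.table[self.table["param"] == name]
            ax.errorbar(
                t["truth"], t["post_mean"],
                yerr=[t["post_mean"] - t["ci_lo"], t["ci_hi"] - t["post_mean"]],
                fmt="o", ms=3, lw=0.8, alpha=0.7,
            )
            lims = [min(t["truth"].min(), t["post_mean"].min()),
                    max(t["truth"].max(), t["post_mean"].max())]
            ax.plot(lims, lims, "k--", lw=0.8)
            ax.set_title(f"{name} (r={self.correlation(name):.2f})")
            ax.set_xlabel("true")
        np.atleast_1d(axes)[0].set_ylabel("posterior mean")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def parameter_recovery(
    spec: ModelSpec,
    true_params: list[AgentParams],
    sessions: list[TaskSession],
    sampler_cfg: SamplerConfig | None = None,
    seed: int = 0,
    groups: list[str] | None = None,
) -> RecoveryReport:
    """Simulate each true agent through its session, refit, and report recovery."""
    rng = np.random.default_rng(seed)
    records = [
        simulate_agent(p, s, rng, subject_id=f"sub-{i:03d}")
        for i, (p, s) in enumerate(zip(true_params, sessions, strict=True))
    ]
    fit = fit_hierarchical(spec, records, sampler_cfg, groups=groups)
    rows = []
    for p, name in enumerate(spec.param_names):
        truths = np.array([getattr(tp, name) for tp in true_params], dtype=float)
        means = fit.subject_posterior_mean(name)
        ci = fit.subject_ci(name)
        for s in range(len(true_params)):
            rows.append(
                {
                    "subject": s,
                    "param": name,
                    "truth": truths[s],
                    "post_mean": means[s],
                    "ci_lo": ci[s, 0],
                    "ci_hi": ci[s, 1],
                    "inside": bool(ci[s, 0] <= truths[s] <= ci[s, 1]),
                }
            )
    return RecoveryReport(pd.DataFrame(rows))
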