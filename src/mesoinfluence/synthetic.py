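"""Synthetic cohorts with known ground truth.

Every downstream stage of the pipeline -- hierarchical model fitting,
dependency-network influence, covariate-adjusted associations -- is exercised
on cohorts generated here, where the true subject parameters, the true
directed network coupling and every planted covariate association are known
and stored next to the data.

Three generators cooperate:

* an order-1 vector autoregression (VAR(1)) produces each subject's
  node x time panel, with a designated hub node whose outgoing coupling is
  the ground-truth "influence" that the dependency-network analysis should
  recover;
* Q-learning agents with subject-level parameters drawn from group-level
  distributions play the bandit task, giving behavioral records whose true
  learning rates are known;
* a covariate table (demographics, symptom scores, hormones) is drawn with
  optionally planted linear links from covariates to the hub coupling.

Defaults mirror a two-group (HC/MDD) design of about 30 subjects per group
on an 8-node network (VTA hub plus 7 mesocorticolimbic targets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bandit import AgentParams, BehavioralRecord, TaskConfig, generate_schedule, simulate_agent
from scipy.stats import norm

__all__ = [
    "DEFAULT_NODES",
    "NetSimConfig",
    "PopulationSpec",
    "TimeSeriesPanel",
    "GroundTruth",
    "StationarityError",
    "build_var_matrix",
    "spectral_radius",
    "simulate_timeseries_panel",
    "simulate_cohort",
    "write_cohort",
    "read_ground_truth",
]

DEFAULT_NODES = ("VTA", "vmPFC", "dmPFC", "sgACC", "plACC", "NAc", "BLA", "hippocampus")


class StationarityError(ValueError):
    """The VAR coefficient matrix has spectral radius >= 1."""


class ConfigError(ValueError):
    """A population or network configuration is invalid."""


@dataclass(frozen=True)
class NetSimConfig:
    """VAR(1) network simulator settings.

    ``hub_out_coupling`` is the lag-1 weight from the hub onto every target
    (the planted directed influence); ``hub_in_coupling`` the reverse;
    ``group_coupling_delta`` is added to the hub's outgoing weight for
    MDD-labelled subjects. ``self_decay`` sits on the diagonal; the hub gets
    its own, larger ``hub_self_decay``: a slowly mixing hub keeps its lag-1
    drive in phase with its own current value, which is what lets a
    contemporaneous-correlation influence method see the planted
    directionality at all (with homogeneous decay the hub's drive on its
    targets is orthogonal to its own present series and the influence
    ranking inverts).
    """

    n_nodes: int = 8
    node_names: tuple[str, ...] = DEFAULT_NODES
    n_timepoints: int = 300
    hub_index: int = 0
    hub_out_coupling: float = 0.3
    hub_in_coupling: float = 0.0
    self_decay: float = 0.2
    hub_self_decay: float = 0.7
    noise_sd: float = 1.0
    group_coupling_delta: float = 0.0
    burn_in: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ConfigError("n_nodes must be >= 3")
        if len(self.node_names) != self.n_nodes:
            raise ConfigError("node_names length must equal n_nodes")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not (0 <= self.hub_index < self.n_nodes):
            raise ConfigError("hub_index out of range")


@dataclass(frozen=True)
class PopulationSpec:
    """Group-level behavioral parameter distributions, on interpretable scales.

    Learning-rate locations are probabilities in (0, 1); subjects are drawn on
    the probit scale (alpha = Phi(z), z ~ Normal(probit(mean), sd)). beta is
    log-normal with median ``beta_median``.
    """

    alpha_gain_mean: dict = field(default_factory=lambda: {"HC": 0.35, "MDD": 0.20})
    alpha_loss_mean: dict = field(default_factory=lambda: {"HC": 0.30, "MDD": 0.30})
    alpha_sd_probit: float = 0.4
    beta_median: dict = field(default_factory=lambda: {"HC": 3.0, "MDD": 3.0})
    beta_sd_log: float = 0.3
    model_id: int = 2

    def __post_init__(self) -> None:
        for d in (self.alpha_gain_mean, self.alpha_loss_mean):
            for g, v in d.items():
                if not (0.0 < v < 1.0):
                    raise ConfigError(
                        f"learning-rate location for group {g!r} must lie strictly in (0, 1), got {v}"
                    )
        for g, v in self.beta_median.items():
            if v <= 0:
                raise ConfigError(f"beta median for group {g!r} must be > 0, got {v}")


@dataclass
class TimeSeriesPanel:
    """Stack of per-subject node x time matrices."""

    data: np.ndarray  # (n_subjects, n_nodes, n_timepoints)
    node_names: tuple[str, ...]
    subject_ids: list[str]

    def subject(self, i: int) -> np.ndarray:
        return self.data[i]


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst should recover."""

    agent_params: dict  # subject_id -> {"alpha_gain":..., "alpha_loss":..., "beta":...}
    hub_out_coupling: dict  # subject_id -> realized hub outgoing weight
    planted_coupling_coefs: dict  # covariate -> coefficient on hub coupling (per SD)
    population: dict  # the PopulationSpec fields

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def build_var_matrix(cfg: NetSimConfig, hub_out: float | None = None) -> np.ndarray:
    """Assemble the VAR(1) coefficient matrix A (x_t = A x_{t-1} + noise).

    A[j, i] carries the influence of node i at t-1 on node j at t. Raises
    :class:`StationarityError` when the spectral radius reaches 1.
    """
    n, h = cfg.n_nodes, cfg.hub_index
    out = cfg.hub_out_coupling if hub_out is None else hub_out
    A = np.eye(n) * cfg.self_decay
    A[h, h] = cfg.hub_self_decay
    for j in range(n):
        if j == h:
            continue
        A[j, h] = out
        A[h, j] = cfg.hub_in_coupling
    rho = spectral_radius(A)
    if rho >= 1.0:
        raise StationarityError(f"VAR coefficient matrix is non-stationary (spectral radius {rho:.3f})")
    return A


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def _simulate_var(A: np.ndarray, T: int, noise_sd: float, burn_in: int, rng: np.random.Generator) -> np.ndarray:
    n = A.shape[0]
    x = np.zeros(n)
    out = np.empty((n, T))
    eps = rng.normal(0.0, noise_sd, size=(burn_in + T, n))
    for t in range(burn_in + T):
        x = A @ x + eps[t]
        if t >= burn_in:
            out[:, t - burn_in] = x
    return out


def simulate_timeseries_panel(
    cfg: NetSimConfig,
    group_labels: list[str],
    rng: np.random.Generator | None = None,
    hub_out_per_subject: np.ndarray | None = None,
    subject_ids: list[str] | None = None,
) -> TimeSeriesPanel:
    """One VAR(1) panel per subject, deterministic given config + seed.

    MDD-labelled subjects get ``group_coupling_delta`` added to their hub
    outgoing weight; ``hub_out_per_subject`` overrides the weight entirely
    (used when covariate associations are planted on the coupling).
    """
    if len(group_labels) < 1:
        raise ConfigError("need at least one subject")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_subj = len(group_labels)
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(n_subj)]
    data = np.empty((n_subj, cfg.n_nodes, cfg.n_timepoints))
    for i, g in enumerate(group_labels):
        if hub_out_per_subject is not None:
            hub_out = float(hub_out_per_subject[i])
        else:
            hub_out = cfg.hub_out_coupling + (cfg.group_coupling_delta if g == "MDD" else 0.0)
        A = build_var_matrix(cfg, hub_out=hub_out)
        data[i] = _simulate_var(A, cfg.n_timepoints, cfg.noise_sd, cfg.burn_in, rng)
    return TimeSeriesPanel(data, cfg.node_names, subject_ids)


def _draw_agent_params(group: str, pop: PopulationSpec, rng: np.random.Generator) -> AgentParams:
    a_g = float(norm.cdf(rng.normal(norm.ppf(pop.alpha_gain_mean[group]), pop.alpha_sd_probit)))
    a_l = float(norm.cdf(rng.normal(norm.ppf(pop.alpha_loss_mean[group]), pop.alpha_sd_probit)))
    beta = float(np.exp(rng.normal(np.log(pop.beta_median[group]), pop.beta_sd_log)))
    if pop.model_id == 1:
        return AgentParams(model_id=1, alpha=a_g, beta=beta)
    return AgentParams(model_id=pop.model_id, alpha_gain=a_g, alpha_loss=a_l, beta=beta)


def _draw_covariates(groups: list[str], rng: np.random.Generator) -> pd.DataFrame:
    n = len(groups)
    is_mdd = np.array([g == "MDD" for g in groups])
    age = np.clip(rng.normal(35, 12, n), 18, 65).round(1)
    sex = np.where(rng.random(n) < 0.6, "F", "M")
    medicated = is_mdd & (rng.random(n) < 0.5)
    daw = rng.normal(0.0, 1.0, n)
    teps_a = np.where(is_mdd, rng.normal(35, 7, n), rng.normal(45, 6, n)).round(1)
    teps_c = np.where(is_mdd, rng.normal(33, 6, n), rng.normal(40, 5, n)).round(1)
    madrs = np.where(is_mdd, np.clip(rng.normal(28, 7, n), 7, 60), np.clip(rng.normal(2, 2, n), 0, 8)).round(0)
    sticsa = np.clip(np.where(is_mdd, rng.normal(52, 10, n), rng.normal(35, 8, n)), 21, 84).round(0)
    estradiol = np.exp(rng.normal(np.log(50), 0.8, n)).round(1)
    testosterone = np.where(
        sex == "M", np.exp(rng.normal(np.log(450), 0.35, n)), np.exp(rng.normal(np.log(30), 0.4, n))
    ).round(1)
    return pd.DataFrame(
        {
            "group": groups,
            "age": age,
            "sex": sex,
            "medicated": medicated,
            "daw": daw,
            "teps_a": teps_a,
            "teps_c": teps_c,
            "madrs": madrs,
            "sticsa": sticsa,
            "estradiol": estradiol,
            "testosterone": testosterone,
        }
    )


def simulate_cohort(
    cfg_net: NetSimConfig,
    cfg_task: TaskConfig,
    cfg_pop: PopulationSpec,
    n_per_group: dict | int,
    seed: int | None = None,
    planted_coupling: dict | None = None,
) -> tuple[pd.DataFrame, TimeSeriesPanel, list[BehavioralRecord], GroundTruth]:
    """Draw a full two-group cohort: covariates, brain panels and behavior.

    ``n_per_group`` is either one count for both groups or a
    ``{"HC": n, "MDD": m}`` mapping. ``planted_coupling`` maps covariate
    names to linear coefficients on the hub outgoing weight per standardized
    covariate unit (in addition to any ``group_coupling_delta``); every
    planted coefficient is recorded in the returned :class:`GroundTruth`.
    """
    if isinstance(n_per_group, int):
        n_per_group = {"HC": n_per_group, "MDD": n_per_group}
    for g, cnt in n_per_group.items():
        if cnt < 1:
            raise ConfigError(f"n_per_group for {g!r} must be >= 1, got {cnt}")
    rng = np.random.default_rng(seed)
    groups = [g for g in ("HC", "MDD") if g in n_per_group for _ in range(n_per_group[g])]
    n = len(groups)
    subject_ids = [f"sub-{i:03d}" for i in range(n)]

    cohort = _draw_covariates(groups, rng)
    cohort.insert(0, "subject_id", subject_ids)
    if cohort["subject_id"].duplicated().any():
        raise ConfigError("duplicate subject ids")

    planted_coupling = dict(planted_coupling or {})
    hub_out = np.full(
        n,
        cfg_net.hub_out_coupling,
    ) + np.where(np.array(groups) == "MDD", cfg_net.group_coupling_delta, 0.0)
    for cov, coef in planted_coupling.items():
        x = cohort[cov].astype(float).to_numpy()
        hub_out = hub_out + coef * (x - x.mean()) / x.std()
    panel = simulate_timeseries_panel(
        cfg_net, groups, rng, hub_out_per_subject=hub_out, subject_ids=subject_ids
    )

    records: list[BehavioralRecord] = []
    truth_params: dict = {}
    for i, sid in enumerate(subject_ids):
        params = _draw_agent_params(groups[i], cfg_pop, rng)
        session = generate_schedule(cfg_task, rng)
        records.append(simulate_agent(params, session, rng, subject_id=sid))
        truth_params[sid] = {
            "model_id": params.model_id,
            "alpha": params.alpha,
            "alpha_gain": params.alpha_gain,
            "alpha_loss": params.alpha_loss,
            "beta": params.beta,
        }

    truth = GroundTruth(
        agent_params=truth_params,
        hub_out_coupling={sid: float(h) for sid, h in zip(subject_ids, hub_out)},
        planted_coupling_coefs=planted_coupling,
        population=asdict(cfg_pop),
    )
    return cohort, panel, records, truth


def write_cohort(
    out_dir: str | Path,
    cohort: pd.DataFrame,
    panel: TimeSeriesPanel,
    records: list[BehavioralRecord],
    truth: GroundTruth,
) -> Path:
    """Write cohort CSV, per-subject time-series TSVs, the behavioral trial
    CSV and the ground-truth JSON under ``out_dir``."""
    from .bandit import records_to_frame

    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    assert cohort["subject_id"].is_unique, "cohort violates unique-subject invariant"
    assert np.isfinite(cohort.select_dtypes("number").to_numpy()).all(), "non-finite covariate"
    cohort.to_csv(out / "cohort.csv", index=False)
    for i, sid in enumerate(panel.subject_ids):
        df = pd.DataFrame(panel.data[i].T, columns=list(panel.node_names))
        df.to_csv(out / "timeseries" / f"{sid}.tsv", sep="\t", index=False)
    records_to_frame(records).to_csv(out / "behavior.csv", index=False)
    (out / "ground_truth.json").write_text(truth.to_json())
    return out


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
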