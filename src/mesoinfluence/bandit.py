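"""Two-armed probabilistic bandit task and Q-learning agents.

The task interleaves three trial types -- gain, loss and neutral -- each with
its own fixed stimulus pair. One stimulus of each pair is the "good" arm: on
gain trials it pays the gain outcome with probability ``p_good`` (the other
with ``p_bad``); on loss trials it *avoids* the loss outcome with probability
``p_good``. Neutral trials always pay the neutral outcome. Agents learn arm
values by a delta rule,

    Q_t(s, a) = Q_{t-1}(s, a) + alpha * (reward_t - Q_{t-1}(s, a)),

with Q initialized at zero for every stimulus, and choose through a softmax
with inverse temperature beta. The reward prediction error (RPE) is the
bracketed term. Models with valence-specific learning rates apply alpha_gain
on gain trials and alpha_loss on loss trials (neutral trials use alpha_gain,
which is inert under the default zero-valued neutral outcome).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRIAL_TYPES = ("gain", "loss", "neutral")

__all__ = [
    "TRIAL_TYPES",
    "TaskConfig",
    "TaskSession",
    "AgentParams",
    "QTrace",
    "BehavioralRecord",
    "generate_schedule",
    "sample_outcome",
    "choice_prob",
    "q_update",
    "simulate_agent",
    "compute_rpe_trace",
    "compliance_filter",
    "records_to_frame",
]


class ParameterError(ValueError):
    """An agent or task parameter is outside its support."""


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the bandit task.

    Defaults give the canonical 90-trial session: 30 gain, 30 loss and 30
    neutral trials with an 80/20 contingency and +1 / -1 / 0 outcomes.
    """

    n_trials_per_type: int = 30
    p_good: float = 0.8
    p_bad: float = 0.2
    gain_value: float = 1.0
    loss_value: float = -1.0
    neutral_value: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials_per_type < 1:
            raise ParameterError("n_trials_per_type must be >= 1")
        if not (0.0 <= self.p_bad < self.p_good <= 1.0):
            raise ParameterError(
                f"require 0 <= p_bad < p_good <= 1, got p_bad={self.p_bad}, p_good={self.p_good}"
            )

    @property
    def n_trials(self) -> int:
        return 3 * self.n_trials_per_type


@dataclass(frozen=True)
class TaskSession:
    """A realized trial schedule.

    ``trial_type[t]`` in {0: gain, 1: loss, 2: neutral}; ``pair_id`` equals the
    trial-type code (one fixed stimulus pair per type). ``high_arm[p]`` is the
    good arm (0 or 1) of pair ``p``. ``lottery[t, a]`` is the pre-drawn outcome
    the agent receives if it picks arm ``a`` on trial ``t``.
    """

    config: TaskConfig
    trial_type: np.ndarray  # (n_trials,) int codes into TRIAL_TYPES
    pair_id: np.ndarray  # (n_trials,) int
    high_arm: np.ndarray  # (n_pairs,) int
    lottery: np.ndarray  # (n_trials, 2) float

    @property
    def n_trials(self) -> int:
        return int(self.trial_type.size)

    @property
    def n_pairs(self) -> int:
        return int(self.high_arm.size)

    def trial_type_names(self) -> np.ndarray:
        return np.asarray(TRIAL_TYPES, dtype=object)[self.trial_type]


@dataclass(frozen=True)
class AgentParams:
    """Q-learning free parameters.

    model_id 1 uses a single learning rate ``alpha``; models 2 and 3 split it
    into ``alpha_gain`` (gain and neutral trials) and ``alpha_loss`` (loss
    trials). ``beta`` is the softmax inverse temperature.
    """

    model_id: int = 2
    alpha: float | None = None
    alpha_gain: float | None = None
    alpha_loss: float | None = None
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ParameterError(f"model_id must be 1, 2 or 3, got {self.model_id}")
        if self.beta <= 0:
            raise ParameterError(f"beta must be > 0, got {self.beta}")
        if self.model_id == 1:
            if self.alpha is None:
                raise ParameterError("model 1 requires alpha")
            _check_unit(self.alpha, "alpha")
        else:
            if self.alpha_gain is None or self.alpha_loss is None:
                raise ParameterError("models 2-3 require alpha_gain and alpha_loss")
            _check_unit(self.alpha_gain, "alpha_gain")
            _check_unit(self.alpha_loss, "alpha_loss")

    def learning_rates(self) -> np.ndarray:
        """Learning rate per trial-type code (gain, loss, neutral)."""
        if self.model_id == 1:
            return np.array([self.alpha, self.alpha, self.alpha], dtype=float)
        # neutral trials share the gain learning rate; with zero-valued
        # neutral outcomes and zero initialization this choice is inert
        return np.array([self.alpha_gain, self.alpha_loss, self.alpha_gain], dtype=float)


def _check_unit(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1], got {x}")


@dataclass
class QTrace:
    """Per-trial value trace of an agent run or replay.

    ``q_pair[t]`` holds the active pair's two Q-values *before* the trial-t
    update; ``rpe[t] = outcome[t] - q_pair[t, choice[t]]``.
    """

    trial_type: np.ndarray
    pair_id: np.ndarray
    choice: np.ndarray
    outcome: np.ndarray
    q_pair: np.ndarray  # (n_trials, 2)
    rpe: np.ndarray

    @property
    def q_chosen(self) -> np.ndarray:
        return self.q_pair[np.arange(self.choice.size), self.choice]

    def rpe_subset(self, trial_type_code: int) -> np.ndarray:
        return self.rpe[self.trial_type == trial_type_code]


@dataclass
class BehavioralRecord:
    """One subject's observed session: choices, outcomes and the value trace."""

    subject_id: str
    session: TaskSession
    choices: np.ndarray
    outcomes: np.ndarray
    responded: np.ndarray  # bool, False on omitted trials
    trace: QTrace | None = None

    @property
    def correct(self) -> np.ndarray:
        """Chose the high-probability (loss-avoiding) arm; False when omitted."""
        high = self.session.high_arm[self.session.pair_id]
        return (self.choices == high) & self.responded

    def correct_rate(self, trial_type_code: int | None = None) -> float:
        mask = self.responded.copy()
        if trial_type_code is not None:
            mask &= self.session.trial_type == trial_type_code
        if mask.sum() == 0:
            return np.nan
        return float(self.correct[mask].mean())


def generate_schedule(cfg: TaskConfig, rng: np.random.Generator | None = None) -> TaskSession:
    """Build an intermixed schedule with exactly ``n_trials_per_type`` of each type.

    The interleaving permutation, the good-arm assignment of each pair and the
    per-trial outcome lotteries are all drawn from ``rng`` (or from
    ``cfg.seed``), so identical config + seed reproduces the identical session.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trials_per_type
    trial_type = rng.permutation(np.repeat(np.arange(3), n))
    pair_id = trial_type.copy()
    high_arm = rng.integers(0, 2, size=3)
    lottery = np.empty((trial_type.size, 2))
    for arm in (0, 1):
        is_high = high_arm[pair_id] == arm
        lottery[:, arm] = sample_outcome(cfg, trial_type, is_high, rng)
    return TaskSession(cfg, trial_type, pair_id, high_arm, lottery)


def sample_outcome(
    cfg: TaskConfig,
    trial_type: np.ndarray | int,
    is_high_arm: np.ndarray | bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the outcome of choosing one arm.

    Gain trials pay ``gain_value`` with probability ``p_good`` on the good arm
    (``p_bad`` otherwise) and 0 else. Loss trials pay ``loss_value`` unless
    avoided, which the good arm does with probability ``p_good``. Neutral
    trials always pay ``neutral_value``.
    """
    trial_type = np.asarray(trial_type)
    scalar = trial_type.ndim == 0
    trial_type = np.atleast_1d(trial_type)
    is_high = np.broadcast_to(np.atleast_1d(is_high_arm), trial_type.shape)
    p_hit = np.where(is_high, cfg.p_good, cfg.p_bad)  # pay prob (gain) / avoid prob (loss)
    u = rng.random(trial_type.shape)
    out = np.zeros(trial_type.shape)
    gain = trial_type == 0
    loss = trial_type == 1
    neutral = trial_type == 2
    out[gain] = np.where(u[gain] < p_hit[gain], cfg.gain_value, 0.0)
    out[loss] = np.where(u[loss] < p_hit[loss], 0.0, cfg.loss_value)
    out[neutral] = cfg.neutral_value
    return out[0] if scalar else out


def choice_prob(q: np.ndarray, beta: float) -> np.ndarray:
    """Softmax choice probabilities p_a = exp(beta q_a) / sum_b exp(beta q_b).

    Guarded against overflow by subtracting the row max before exponentiation.
    Accepts a length-2 vector or an (..., 2) array.
    """
    if beta <= 0:
        raise ParameterError(f"beta must be > 0, got {beta}")
    q = np.asarray(q, dtype=float)
    z = beta * q
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def q_update(q_prev: float | np.ndarray, alpha: float, reward: float | np.ndarray):
    """Delta-rule value update: q + alpha * (reward - q)."""
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha must lie in [0, 1], got {alpha}")
    return q_prev + alpha * (np.asarray(reward) - q_prev)


def simulate_agent(
    params: AgentParams,
    session: TaskSession,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "sim",
) -> BehavioralRecord:
    """Run one agent through a session.

    On each trial the agent softmax-chooses between the active pair's arms,
    receives that arm's pre-drawn lottery outcome, and updates only the chosen
    arm's Q-value with the trial-type-appropriate learning rate.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    alphas = params.learning_rates()
    n = session.n_trials
    q = np.zeros((session.n_pairs, 2))
    choices = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n)
    q_pair = np.empty((n, 2))
    rpe = np.empty(n)
    for t in range(n):
        p = session.pair_id[t]
        q_pair[t] = q[p]
        pr = choice_prob(q[p], params.beta)
        c = int(rng.random() < pr[1])
        r = session.lottery[t, c]
        choices[t] = c
        outcomes[t] = r
        rpe[t] = r - q[p, c]
        q[p, c] += alphas[session.trial_type[t]] * rpe[t]
    trace = QTrace(session.trial_type.copy(), session.pair_id.copy(), choices, outcomes, q_pair, rpe)
    return BehavioralRecord(
        subject_id, session, choices, outcomes, np.ones(n, dtype=bool), trace
    )


def compute_rpe_trace(
    params: AgentParams,
    choices: np.ndarray,
    outcomes: np.ndarray,
    session: TaskSession,
    responded: np.ndarray | None = None,
) -> QTrace:
    """Deterministically replay the delta rule over observed choices/outcomes.

    Produces the trial-by-trial RPE vector used as a model-based regressor:
    the full-task RPE series, from which gain- and loss-trial subsets can be
    taken via :meth:`QTrace.rpe_subset`. Omitted trials (``responded`` False)
    leave values untouched and get an RPE of NaN.
    """
    choices = np.asarray(choices)
    outcomes = np.asarray(outcomes)
    n = session.n_trials
    if choices.size != n or outcomes.size != n:
        raise ValueError(
            f"choices/outcomes length ({choices.size}/{outcomes.size}) does not match session ({n})"
        )
    if responded is None:
        responded = np.ones(n, dtype=bool)
    alphas = params.learning_rates()
    q = np.zeros((session.n_pairs, 2))
    q_pair = np.empty((n, 2))
    rpe = np.full(n, np.nan)
    for t in range(n):
        p = session.pair_id[t]
        q_pair[t] = q[p]
        if not responded[t]:
            continue
        c = int(choices[t])
        rpe[t] = outcomes[t] - q[p, c]
        q[p, c] += alphas[session.trial_type[t]] * rpe[t]
    return QTrace(
        session.trial_type.copy(), session.pair_id.copy(), choices.copy(),
        outcomes.copy(), q_pair, rpe,
    )


def compliance_filter(
    records: list[BehavioralRecord], threshold: float = 0.5, rule: str = "and"
) -> np.ndarray:
    """Inclusion mask for the behavioral compliance criterion.

    A subject is excluded when their correct-choice rate falls below
    ``threshold`` on gain AND loss trials (``rule='and'``, the default; set
    ``rule='or'`` for the stricter either-type reading), or when they failed
    to make any selection at all.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if rule not in ("and", "or"):
        raise ValueError(f"rule must be 'and' or 'or', got {rule!r}")
    include = np.ones(len(records), dtype=bool)
    for i, rec in enumerate(records):
        if not rec.responded.any():
            include[i] = False
            continue
        low_gain = rec.correct_rate(0) < threshold
        low_loss = rec.correct_rate(1) < threshold
        bad = (low_gain and low_loss) if rule == "and" else (low_gain or low_loss)
        if bad:
            include[i] = False
    return include


def records_to_frame(records: list[BehavioralRecord]) -> pd.DataFrame:
    """Long-format trial table (one row per trial) for the behavioral CSV."""
    frames = []
    for rec in records:
        sess = rec.session
        trace = rec.trace
        if trace is None:
            raise ValueError(f"record {rec.subject_id} has no QTrace; replay it first")
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "trial": np.arange(sess.n_trials),
                    "trial_type": sess.trial_type_names(),
                    "choice": rec.choices,
                    "correct": rec.correct.astype(int),
                    "outcome": rec.outcomes,
                    "q_chosen": trace.q_chosen,
                    "rpe": trace.rpe,
                    "responded": rec.responded.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
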