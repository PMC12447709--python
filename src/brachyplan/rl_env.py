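"""Gym-style planning environment: the agent tunes planning weights, an inner
dwell-time optimization produces the plan, and the reward tracks score change.

State: the flattened metrics vector (scaled by fixed goal-like constants)
concatenated with the 8 planning weights mapped to [0, 1] on a log scale.
Actions: for each of the 8 weights one multiplicative increase and one
decrease (by ``step_factor``), plus a do-nothing action that terminates the
episode — 17 discrete actions in total.  A step that would push a weight
outside its bounds leaves the weights untouched and costs a fixed penalty.
Reward: 100 x the change in the fractional (0-1) plan score, minus any
boundary penalty.  Episodes truncate after ``max_steps`` steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .dvh import METRIC_ORDER, PlanMetrics
from .dwell_opt import (
    DwellSolution,
    OptimizerConfig,
    TPPVector,
    TPP_NAMES,
    optimize_dwell,
)
from .phantom import PatientCase
from .scoring import ScoreConfig, plan_score

N_ACTIONS = 17
NO_OP = N_ACTIONS - 1

#: Per-metric scale dividing each entry of the metrics vector so that a plan
#: sitting exactly at its clinical goals encodes to ~1.0 per entry.
METRIC_SCALES = {
    "d90_hr": 100.0,
    "d50_hr": 150.0,
    "d20_hr": 200.0,
    "v100_hr": 100.0,
    "v150_hr": 50.0,
    "v200_hr": 20.0,
    "d90_ir": 100.0,
    "p_bladder": 100.0,
    "p_rectum": 100.0,
    "p_sigmoid": 100.0,
    "p_small_bowel": 100.0,
    "p_large_bowel": 100.0,
}
_SCALE_VEC = np.array([METRIC_SCALES[m] for m in METRIC_ORDER])


class ActionSpec(NamedTuple):
    index: int
    kind: str  # "increase" | "decrease" | "no_op"
    tpp_index: int | None


def action_table() -> list[ActionSpec]:
    """The 17 discrete actions: (increase, decrease) per weight, then no-op."""
    table = []
    for i, _name in enumerate(TPP_NAMES):
        table.append(ActionSpec(2 * i, "increase", i))
        table.append(ActionSpec(2 * i + 1, "decrease", i))
    table.append(ActionSpec(NO_OP, "no_op", None))
    return table


def encode_observation(metrics: PlanMetrics, tpp: TPPVector) -> np.ndarray:
    """Flatten (metrics, weights) into the fixed-length state vector."""
    m = metrics.as_vector() / _SCALE_VEC
    w = (np.log(tpp.weights) - np.log(tpp.lo)) / (np.log(tpp.hi) - np.log(tpp.lo))
    obs = np.concatenate([m, w])
    if not np.all(np.isfinite(obs)):
        raise ValueError("non-finite entry in observation")
    return obs


@dataclass
class StepRecord:
    action: int
    reward: float
    score: float
    tpp: np.ndarray


@dataclass
class EpisodeRecord:
    case_id: str
    steps: list[StepRecord] = field(default_factory=list)
    termination: str | None = None  # "max_steps" | "no_op"
    initial_score: float = 0.0

    @property
    def final_score(self) -> float:
        return self.steps[-1].score if self.steps else self.initial_score


class PlanningEnv:
    """Gymnasium-signature environment over one or more patient cases.

    ``reset`` samples a patient and log-uniform initial weights, runs the
    inner optimization, and returns (observation, info); ``step`` returns
    (observation, reward, terminated, truncated, info).  Scores in ``info``
    are percent; the reward uses the fractional scale internally.
    """

    def __init__(
        self,
        cases: list[PatientCase],
        score_config: ScoreConfig | None = None,
        optimizer_config: OptimizerConfig | None = None,
        max_steps: int = 5,
        boundary_penalty: float = 1.0,
        tpp_lo: float = 0.01,
        tpp_hi: float = 100.0,
        step_factor: float = 1.5,
        seed: int | None = None,
    ):
        if not cases:
            raise ValueError("at least one patient case is required")
        for c in cases:
            if c.dij is None:
                raise ValueError(f"case {c.id!r} has no dose-influence matrices")
        self.cases = list(cases)
        self.score_config = score_config or ScoreConfig()
        self.optimizer_config = optimizer_config or OptimizerConfig()
        self.max_steps = max_steps
        self.boundary_penalty = boundary_penalty
        self.tpp_lo, self.tpp_hi = tpp_lo, tpp_hi
        self.step_factor = step_factor
        self._rng = np.random.default_rng(seed)
        self._table = action_table()
        self.observation_size = len(METRIC_ORDER) + len(TPP_NAMES)
        self.n_actions = N_ACTIONS
        self._case: PatientCase | None = None
        self.record: EpisodeRecord | None = None

    # -- episode mechanics -------------------------------------------------
    def _optimize(self) -> tuple[DwellSolution, float]:
        sol = optimize_dwell(self._case, self._tpp, self.optimizer_config)
        frac = plan_score(sol.final_metrics, self.score_config).R / 100.0
        return sol, frac

    def reset(self, seed: int | None = None):
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        self._case = self.cases[self._rng.integers(len(self.cases))]
        self._tpp = TPPVector.sample(
            self._rng, self.tpp_lo, self.tpp_hi, self.step_factor
        )
        self._solution, self._score = self._optimize()
        self._n_steps = 0
        self._done = False
        self.record = EpisodeRecord(
            case_id=self._case.id, initial_score=self._score * 100.0
        )
        obs = encode_observation(self._solution.final_metrics, self._tpp)
        info = {
            "case_id": self._case.id,
            "score": self._score * 100.0,
            "metrics": self._solution.final_metrics,
            "solution": self._solution,
        }
        return obs, info

    def step(self, action: int):
        if self._case is None or self._done:
            raise RuntimeError("call reset() before step()")
        if not (0 <= int(action) < N_ACTIONS):
            raise ValueError(f"invalid action index {action}")
        spec = self._table[int(action)]
        self._n_steps += 1
        info: dict = {"case_id": self._case.id, "boundary": False}
        terminated = False

        if spec.kind == "no_op":
            reward = 0.0
            terminated = True
        else:
            w = self._tpp.weights[spec.tpp_index]
            new_w = w * self.step_factor if spec.kind == "increase" else w / self.step_factor
            if not (self.tpp_lo <= new_w <= self.tpp_hi):
                # illegal update: weights unchanged, plan unchanged, fixed penalty
                reward = -self.boundary_penalty
                info["boundary"] = True
            else:
                prev = self._score
                self._tpp = self._tpp.replace_weight(spec.tpp_index, new_w)
                self._solution, self._score = self._optimize()
                reward = 100.0 * (self._score - prev)

        truncated = (not terminated) and self._n_steps >= self.max_steps
        self._done = terminated or truncated
        if self._done:
            self.record.termination = "no_op" if terminated else "max_steps"
        self.record.steps.append(
            StepRecord(
                action=int(action),
                reward=reward,
                score=self._score * 100.0,
                tpp=self._tpp.weights.copy(),
            )
        )
        obs = encode_observation(self._solution.final_metrics, self._tpp)
        info.update(
            score=self._score * 100.0,
            metrics=self._solution.final_metrics,
            solution=self._solution,
        )
        return obs, reward, terminated, truncated, info

    # convenience accessors used by evaluation/reporting
    @property
    def current_case(self) -> PatientCase:
        return self._case

    @property
    def current_tpp(self) -> TPPVector:
        return self._tpp

    @property
    def current_solution(self) -> DwellSolution:
        return self._solution
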