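"""Clinically shaped plan scoring: per-metric ramps, OAR sparing bonuses,
and the normalized plan score R in [0, 100].

Each scored metric carries a goal, a tolerance window, a weight and a
direction.  Within the tolerance window the score ramps linearly, so R is
continuous piecewise-linear in every metric — small deviations from goals
produce proportional reward changes, which stabilizes RL training.  OAR
metrics additionally earn a bonus growing linearly with the sparing margin
below the clinical limit.  The total is normalized:

    R = (sum_i S_i + sum_s Bonus_s) / (sum_i w_i + Bonus_max) * 100
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dvh import PlanMetrics
from .phantom import OAR_NAMES


@dataclass(frozen=True)
class MetricGoal:
    goal: float
    tol: float
    weight: float
    direction: str  # "higher" | "lower" | "target"

    def __post_init__(self):
        if self.tol <= 0 or self.weight < 0:
            raise ValueError("tol must be > 0 and weight >= 0")
        if self.direction not in ("higher", "lower", "target"):
            raise ValueError(f"unknown direction {self.direction!r}")


def _default_metrics() -> dict[str, MetricGoal]:
    cfg = {
        "d90_hr": MetricGoal(100.0, 5.0, 2.0, "target"),
        "d90_ir": MetricGoal(100.0, 5.0, 2.0, "target"),
        "v150_hr": MetricGoal(50.0, 10.0, 1.0, "lower"),
        "v200_hr": MetricGoal(20.0, 10.0, 1.0, "lower"),
    }
    for s in OAR_NAMES:
        cfg[f"p_{s}"] = MetricGoal(100.0, 10.0, 1.0, "lower")
    return cfg


@dataclass
class ScoreConfig:
    """Goals, tolerances, weights and OAR bonus coefficients.

    Defaults encode common clinical practice for cervix HDR plans (target
    coverage at prescription +-5%, hot-spot volumes kept moderate, every OAR
    D2cc under its individualized threshold) and are fully configurable.
    """

    metrics: dict[str, MetricGoal] = field(default_factory=_default_metrics)
    bonus: dict[str, float] = field(default_factory=lambda: {s: 0.2 for s in OAR_NAMES})

    @property
    def bonus_max(self) -> float:
        """Sum over OARs of the maximal achievable bonus b * w."""
        total = 0.0
        for s, b in self.bonus.items():
            key = f"p_{s}"
            if key in self.metrics:
                total += b * self.metrics[key].weight
        return total

    @property
    def weight_sum(self) -> float:
        return sum(m.weight for m in self.metrics.values())


@dataclass
class ScoreBreakdown:
    scores: dict[str, float]
    bonuses: dict[str, float]
    R: float  # percent in [0, 100]


def score_metric(v: float, goal: float, tol: float, w: float, direction: str) -> float:
    """Generalized per-metric score: full weight at goal, linear ramp in the window."""
    if direction == "higher":
        if v >= goal:
            return w
        if v >= goal - tol:
            return w * (v - (goal - tol)) / tol
        return 0.0
    if direction == "lower":
        if v <= goal:
            return w
        if v <= goal + tol:
            return w * ((goal + tol) - v) / tol
        return 0.0
    if direction == "target":
        dev = abs(v - goal)
        return w * (1.0 - dev / tol) if dev <= tol else 0.0
    raise ValueError(f"unknown direction {direction!r}")


def oar_bonus(v: float, goal: float, w: float, b: float) -> float:
    """Sparing bonus, linear in the margin below the limit, capped at b*w."""
    if v < 0:
        raise ValueError("p_s must be nonnegative")
    return min(b * w, b * w * max(0.0, (goal - v) / goal))


def plan_score(metrics: PlanMetrics, cfg: ScoreConfig | None = None) -> ScoreBreakdown:
    """Normalized plan score R (percent) with per-metric breakdown."""
    cfg = cfg or ScoreConfig()
    denom = cfg.weight_sum + cfg.bonus_max
    if denom <= 0:
        raise ValueError("score normalization denominator is zero")

    scores = {}
    for name, g in cfg.metrics.items():
        scores[name] = score_metric(metrics.value(name), g.goal, g.tol, g.weight, g.direction)

    bonuses = {}
    for s, b in cfg.bonus.items():
        key = f"p_{s}"
        if key in cfg.metrics:
            g = cfg.metrics[key]
            bonuses[s] = oar_bonus(metrics.p[s], g.goal, g.weight, b)

    R = (sum(scores.values()) + sum(bonuses.values())) / denom * 100.0
    return ScoreBreakdown(scores=scores, bonuses=bonuses, R=R)
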