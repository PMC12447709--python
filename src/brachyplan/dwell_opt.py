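"""Log-domain Adam optimization of dwell times under the composite clinical loss.

The loss combines intermediate-risk coverage, high-risk hot-spot control,
OAR sparing and hard constraint penalties:

    L_CTVIR    = w_IR * (D90_IR - 100)^2
    L_hotspots = w_D50 * (D50_HR / 150)^2 + w_D20 * (D20_HR / 200)^2
    L_OAR      = sum_s w_s * (p_s / 100)^2
    Penalty    = 100 * |D90_HR - 100| + sum_s 10 * w_s * max(p_s - 100, 0)
    L          = L_CTVIR + L_hotspots + L_OAR + Penalty

with every D-metric in percent of its prescription and p_s the OAR D2cc in
percent of its threshold.  Dwell times are parameterized as d = exp(u) so
positivity is structural, and u is updated with Adam.  Gradients flow
through the order-statistic DVH metrics via the single voxel that realizes
each statistic (a subgradient of the piecewise-linear sort-based metric);
the |.| kink uses sign(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dvh import (
    PlanMetrics,
    compute_plan_metrics,
    d2cc_index,
    dose_quantile_index,
)
from .phantom import CTV_HR, CTV_IR, OAR_NAMES, PatientCase

#: Fixed ordering of the 8 treatment planning parameters.
TPP_NAMES = ("ir", "d50", "d20") + OAR_NAMES


@dataclass
class TPPVector:
    """The 8 tunable planning weights with shared bounds and action step.

    Order: w_IR, w_D50, w_D20, then one weight per OAR
    (bladder, rectum, sigmoid, small bowel, large bowel).
    """

    weights: np.ndarray = field(default_factory=lambda: np.ones(len(TPP_NAMES)))
    lo: float = 0.01
    hi: float = 100.0
    step_factor: float = 1.5

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(TPP_NAMES),):
            raise ValueError(f"expected {len(TPP_NAMES)} weights")
        if not (0 < self.lo <= self.hi):
            raise ValueError("bounds must satisfy 0 < lo <= hi")
        if np.any(self.weights < self.lo) or np.any(self.weights > self.hi):
            raise ValueError("weights outside bounds")

    def __getitem__(self, name: str) -> float:
        return float(self.weights[TPP_NAMES.index(name)])

    def replace_weight(self, index: int, value: float) -> "TPPVector":
        w = self.weights.copy()
        w[index] = value
        return TPPVector(w, self.lo, self.hi, self.step_factor)

    @classmethod
    def sample(cls, rng: np.random.Generator, lo: float = 0.01, hi: float = 100.0,
               step_factor: float = 1.5) -> "TPPVector":
        """Log-uniform draw within bounds (natural measure for multiplicative steps)."""
        w = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(TPP_NAMES)))
        return cls(w, lo, hi, step_factor)


@dataclass
class OptimizerConfig:
    learning_rate: float = 0.01
    max_iterations: int = 5000
    patience: int = 500
    min_improvement: float = 0.1
    hotspot_form: str = "ratio"  # "ratio": (D50/150)^2; "deviation": ((D50-150)/150)^2
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.patience < 1 or self.min_improvement < 0:
            raise ValueError("patience >= 1 and min_improvement >= 0 required")
        if self.hotspot_form not in ("ratio", "deviation"):
            raise ValueError(f"unknown hotspot_form {self.hotspot_form!r}")


@dataclass
class LossBreakdown:
    total: float
    ctv_ir: float
    hotspots: float
    oar: float
    penalty: float


@dataclass
class DwellSolution:
    d_star: np.ndarray
    loss_trace: np.ndarray
    final_metrics: PlanMetrics
    converged: bool
    breakdown: LossBreakdown


def planning_loss(
    metrics: PlanMetrics, tpp: TPPVector, hotspot_form: str = "ratio"
) -> LossBreakdown:
    """Composite clinical loss and its four components for given metrics."""
    w_ir, w_d50, w_d20 = (tpp[n] for n in ("ir", "d50", "d20"))
    l_ir = w_ir * (metrics.d90_ir - 100.0) ** 2
    if hotspot_form == "ratio":
        l_hot = w_d50 * (metrics.d50_hr / 150.0) ** 2 + w_d20 * (metrics.d20_hr / 200.0) ** 2
    else:
        l_hot = (
            w_d50 * ((metrics.d50_hr - 150.0) / 150.0) ** 2
            + w_d20 * ((metrics.d20_hr - 200.0) / 200.0) ** 2
        )
    l_oar = sum(tpp[s] * (metrics.p[s] / 100.0) ** 2 for s in OAR_NAMES)
    penalty = 100.0 * abs(metrics.d90_hr - 100.0) + sum(
        10.0 * tpp[s] * max(metrics.p[s] - 100.0, 0.0) for s in OAR_NAMES
    )
    total = l_ir + l_hot + l_oar + penalty
    return LossBreakdown(total=total, ctv_ir=l_ir, hotspots=l_hot, oar=l_oar, penalty=penalty)


def _initial_dwell(case: PatientCase) -> np.ndarray:
    """Uniform dwell times scaled so the mean CTV_HR dose equals rx_HR."""
    row_sum = case.dij.matrices[CTV_HR].sum(axis=1)
    mean_unit_dose = float(row_sum.mean())
    if mean_unit_dose <= 0:
        raise RuntimeError("CTV_HR receives zero dose from unit dwell times")
    t0 = case.prescriptions.rx_hr / mean_unit_dose
    return np.full(case.dij.n_dwells, t0)


def optimize_dwell(
    case: PatientCase,
    tpp: TPPVector,
    cfg: OptimizerConfig | None = None,
    d0: np.ndarray | None = None,
) -> DwellSolution:
    """Minimize the composite loss over dwell times in the log domain.

    Runs Adam on u = log(d), with early stopping once no improvement larger
    than ``min_improvement`` is seen for ``patience`` iterations.  The best
    iterate is tracked and returned, so the final loss never exceeds the
    initial one.  Fully deterministic for fixed inputs.
    """
    cfg = cfg or OptimizerConfig()
    if case.dij is None:
        raise ValueError("case has no dose-influence matrices; run tg43 first")
    mats = case.dij.matrices
    rx_hr = case.prescriptions.rx_hr
    rx_ir = case.prescriptions.rx_ir
    thr = case.prescriptions.oar_thresholds
    vv = case.dij.voxel_volume

    d = _initial_dwell(case) if d0 is None else np.asarray(d0, dtype=float).copy()
    if np.any(d <= 0):
        raise ValueError("initial dwell times must be strictly positive")
    u = np.log(d)
    m = np.zeros_like(u)
    v = np.zeros_like(u)

    best_loss = np.inf
    best_d = d.copy()
    wait = 0
    converged = False
    trace = []

    w_ir, w_d50, w_d20 = (tpp[n] for n in ("ir", "d50", "d20"))

    for it in range(1, cfg.max_iterations + 1):
        d = np.exp(u)
        dose_hr = mats[CTV_HR] @ d
        dose_ir = mats[CTV_IR] @ d

        i90_hr = dose_quantile_index(dose_hr, 90)
        i50_hr = dose_quantile_index(dose_hr, 50)
        i20_hr = dose_quantile_index(dose_hr, 20)
        i90_ir = dose_quantile_index(dose_ir, 90)
        d90_hr = 100.0 * dose_hr[i90_hr] / rx_hr
        d50_hr = 100.0 * dose_hr[i50_hr] / rx_hr
        d20_hr = 100.0 * dose_hr[i20_hr] / rx_hr
        d90_ir = 100.0 * dose_ir[i90_ir] / rx_ir

        loss = w_ir * (d90_ir - 100.0) ** 2
        if cfg.hotspot_form == "ratio":
            loss += w_d50 * (d50_hr / 150.0) ** 2 + w_d20 * (d20_hr / 200.0) ** 2
            g50 = 2.0 * w_d50 * d50_hr / 150.0**2
            g20 = 2.0 * w_d20 * d20_hr / 200.0**2
        else:
            loss += (
                w_d50 * ((d50_hr - 150.0) / 150.0) ** 2
                + w_d20 * ((d20_hr - 200.0) / 200.0) ** 2
            )
            g50 = 2.0 * w_d50 * (d50_hr - 150.0) / 150.0**2
            g20 = 2.0 * w_d20 * (d20_hr - 200.0) / 200.0**2
        loss += 100.0 * abs(d90_hr - 100.0)

        # gradient w.r.t. dwell times, accumulated metric by metric
        g_d = (2.0 * w_ir * (d90_ir - 100.0)) * (100.0 / rx_ir) * mats[CTV_IR][i90_ir]
        g_d = g_d + (g50 * (100.0 / rx_hr)) * mats[CTV_HR][i50_hr]
        g_d += (g20 * (100.0 / rx_hr)) * mats[CTV_HR][i20_hr]
        g_d += (100.0 * np.sign(d90_hr - 100.0)) * (100.0 / rx_hr) * mats[CTV_HR][i90_hr]

        for s in OAR_NAMES:
            dose_s = mats[s] @ d
            idx = d2cc_index(dose_s, vv)
            p_s = 100.0 * dose_s[idx] / thr[s]
            w_s = tpp[s]
            loss += w_s * (p_s / 100.0) ** 2
            coeff = 2.0 * w_s * p_s / 100.0**2
            if p_s > 100.0:
                loss += 10.0 * w_s * (p_s - 100.0)
                coeff += 10.0 * w_s
            g_d += (coeff * (100.0 / thr[s])) * mats[s][idx]

        if it == 1 and not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss {loss!r} at initialization (d0 mean {d.mean():.3g} s)"
            )
        trace.append(loss)

        if loss < best_loss:
            if best_loss - loss > cfg.min_improvement:
                wait = 0
            else:
                wait += 1
            best_loss = loss
            best_d = d.copy()
        else:
            wait += 1
        if wait >= cfg.patience:
            converged = True
            break

        g_u = g_d * d  # chain rule through d = exp(u)
        m = cfg.beta1 * m + (1 - cfg.beta1) * g_u
        v = cfg.beta2 * v + (1 - cfg.beta2) * g_u**2
        m_hat = m / (1 - cfg.beta1**it)
        v_hat = v / (1 - cfg.beta2**it)
        u -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.eps)

    final_metrics = compute_plan_metrics(case, best_d)
    breakdown = planning_loss(final_metrics, tpp, cfg.hotspot_form)
    return DwellSolution(
        d_star=best_d,
        loss_trace=np.asarray(trace),
        final_metrics=final_metrics,
        converged=converged,
        breakdown=breakdown,
    )


def normalize_to_prescription(d: np.ndarray, case: PatientCase) -> np.ndarray:
    """Rescale dwell times so D90 of the high-risk CTV is exactly 100%.

    Every dose metric is linear in the global dwell scale, so all D-metrics
    and p_s values scale by the same factor.  Reporting convention only; the
    optimization loop never applies it.
    """
    metrics = compute_plan_metrics(case, d)
    if metrics.d90_hr <= 0:
        raise ValueError("cannot normalize: CTV_HR D90 is zero")
    return np.asarray(d, dtype=float) * (100.0 / metrics.d90_hr)
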