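"""DVH metrics: D90/D50/D20, Vx, D2cc and the per-plan clinical metric set.

Dose-volume quantiles use an order-statistic convention without
interpolation: Dx is the k-th smallest dose with k = ceil((1 - x/100) * N),
so exactly one voxel carries the value (and, downstream, the gradient).
D2cc is the n-th highest dose with n = round(2000 mm^3 / voxel_volume),
minimum 1; structures smaller than 2 cc fall back to their minimum dose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phantom import CTV_HR, CTV_IR, OAR_NAMES, PatientCase

logger = logging.getLogger(__name__)

#: Fixed ordering of the flat metrics vector (all values in percent).
METRIC_ORDER = (
    "d90_hr",
    "d50_hr",
    "d20_hr",
    "v100_hr",
    "v150_hr",
    "v200_hr",
    "d90_ir",
    "p_bladder",
    "p_rectum",
    "p_sigmoid",
    "p_small_bowel",
    "p_large_bowel",
)


def dose_from_dwell(dij_structure: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Voxel doses in Gy for one structure: matrix-vector product Dij @ d."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or dij_structure.shape[1] != len(d):
        raise ValueError(
            f"dwell vector length {len(d)} does not match {dij_structure.shape[1]} dwell positions"
        )
    if np.any(d < 0):
        raise ValueError("dwell times must be nonnegative")
    return dij_structure @ d


def _dx_index(n: int, x: float) -> int:
    """0-based index into the sorted (ascending) dose vector for Dx."""
    if not (0 < x <= 100):
        raise ValueError("x must be in (0, 100]")
    k = int(np.ceil((1.0 - x / 100.0) * n))
    return int(np.clip(k, 1, n)) - 1


def dose_quantile(dose: np.ndarray, x: float) -> float:
    """Dx: minimum dose received by the hottest x% of the volume (Gy)."""
    dose = np.asarray(dose, dtype=float)
    if dose.size == 0:
        raise ValueError("empty dose vector")
    k = _dx_index(dose.size, x)
    return float(np.partition(dose, k)[k])


def dose_quantile_index(dose: np.ndarray, x: float) -> int:
    """Index of the voxel that realizes Dx (the subgradient carrier)."""
    dose = np.asarray(dose, dtype=float)
    if dose.size == 0:
        raise ValueError("empty dose vector")
    k = _dx_index(dose.size, x)
    return int(np.argpartition(dose, k)[k])


def volume_fraction(dose: np.ndarray, level: float) -> float:
    """Vx: percent of voxels receiving at least ``level`` Gy."""
    dose = np.asarray(dose, dtype=float)
    if dose.size == 0:
        raise ValueError("empty dose vector")
    return 100.0 * float(np.count_nonzero(dose >= level)) / dose.size


def _d2cc_rank(n_voxels: int, voxel_volume: float) -> int:
    if voxel_volume <= 0:
        raise ValueError("voxel volume must be positive")
    return max(1, int(round(2000.0 / voxel_volume)))


def d2cc(dose: np.ndarray, voxel_volume: float) -> float:
    """Minimum dose to the hottest 2 cm^3 (Gy)."""
    dose = np.asarray(dose, dtype=float)
    if dose.size == 0:
        raise ValueError("empty dose vector")
    n = _d2cc_rank(dose.size, voxel_volume)
    if n >= dose.size:
        logger.warning(
            "structure volume %.1f mm^3 < 2 cc; D2cc falls back to the minimum dose",
            dose.size * voxel_volume,
        )
        return float(dose.min())
    return float(np.partition(dose, dose.size - n)[dose.size - n])


def d2cc_index(dose: np.ndarray, voxel_volume: float) -> int:
    """Index of the voxel that realizes D2cc."""
    dose = np.asarray(dose, dtype=float)
    n = _d2cc_rank(dose.size, voxel_volume)
    if n >= dose.size:
        return int(np.argmin(dose))
    k = dose.size - n
    return int(np.argpartition(dose, k)[k])


@dataclass
class PlanMetrics:
    """Clinical plan metrics, target values in percent of prescription.

    ``d2cc_gy`` holds per-OAR D2cc in Gy/fraction; ``p`` the same values as a
    percent of the patient-specific threshold (p_s = 100 * D2cc / threshold).
    """

    d90_hr: float
    d50_hr: float
    d20_hr: float
    v100_hr: float
    v150_hr: float
    v200_hr: float
    d90_ir: float
    d2cc_gy: dict[str, float]
    p: dict[str, float]

    def as_vector(self) -> np.ndarray:
        """Flat metrics vector in the fixed :data:`METRIC_ORDER` ordering."""
        vals = [getattr(self, name) for name in METRIC_ORDER[:7]]
        vals += [self.p[name.removeprefix("p_")] for name in METRIC_ORDER[7:]]
        return np.asarray(vals, dtype=float)

    def value(self, name: str) -> float:
        if name.startswith("p_"):
            return self.p[name.removeprefix("p_")]
        return getattr(self, name)


def compute_plan_metrics(case: PatientCase, d: np.ndarray) -> PlanMetrics:
    """All clinical metrics for dwell-time vector ``d`` (seconds)."""
    if case.dij is None:
        raise ValueError("case has no dose-influence matrices; run tg43 first")
    mats = case.dij.matrices
    for name in (CTV_HR, CTV_IR) + OAR_NAMES:
        if name not in mats:
            raise ValueError(f"missing dose-influence matrix for structure {name!r}")

    rx_hr = case.prescriptions.rx_hr
    rx_ir = case.prescriptions.rx_ir
    dose_hr = dose_from_dwell(mats[CTV_HR], d)
    dose_ir = dose_from_dwell(mats[CTV_IR], d)

    d2 = {}
    p = {}
    for name in OAR_NAMES:
        val = d2cc(dose_from_dwell(mats[name], d), case.dij.voxel_volume)
        d2[name] = val
        p[name] = 100.0 * val / case.prescriptions.oar_thresholds[name]

    return PlanMetrics(
        d90_hr=100.0 * dose_quantile(dose_hr, 90) / rx_hr,
        d50_hr=100.0 * dose_quantile(dose_hr, 50) / rx_hr,
        d20_hr=100.0 * dose_quantile(dose_hr, 20) / rx_hr,
        v100_hr=volume_fraction(dose_hr, rx_hr),
        v150_hr=volume_fraction(dose_hr, 1.5 * rx_hr),
        v200_hr=volume_fraction(dose_hr, 2.0 * rx_hr),
        d90_ir=100.0 * dose_quantile(dose_ir, 90) / rx_ir,
        d2cc_gy=d2,
        p=p,
    )
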