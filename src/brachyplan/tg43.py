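"""TG-43 dose engine: dose-influence matrices from dwell positions to voxels.

Implements the AAPM TG-43 dose-rate equation

    D(r, theta) = Sk * Lambda * G(r, theta)/G(r0, theta0) * g(r) * F

with a point-source mode (1-D anisotropy phi_an(r), the default) and a
line-source geometry factor for the 2-D mode.  The default source is an
Ir-192 HDR stepping source with radial-dose and anisotropy tables following
the published mHDR-v2 consensus data (Daskalov et al., Med. Phys. 25 (1998)
2200; AAPM TG-43U1), coarsened to the radii this planner evaluates.

Dij entries are stored in Gy per second of dwell at the nominal air-kerma
strength, so ``dose_Gy = Dij @ dwell_seconds``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .phantom import PatientCase, STRUCTURE_NAMES

logger = logging.getLogger(__name__)

R0_MM = 10.0
THETA0_DEG = 90.0

# Ir-192 HDR (mHDR-v2) consensus radial dose function g(r), r in mm.
_IR192_G_R_MM = np.array(
    [1.0, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0]
)
_IR192_G = np.array(
    [0.990, 0.994, 0.998, 0.999, 1.000, 1.001, 1.001, 0.998, 0.992, 0.983, 0.970, 0.934, 0.886]
)

# 1-D anisotropy function phi_an(r), r in mm.
_IR192_PHI_R_MM = np.array([2.5, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0])
_IR192_PHI = np.array([0.973, 0.970, 0.967, 0.964, 0.962, 0.960, 0.958, 0.957, 0.955, 0.953])

#: 10 Ci of Ir-192 in air-kerma strength units U (1 U = 1 uGy m^2 / h).
DEFAULT_SK_U = 40_800.0
#: Dose-rate constant for the mHDR-v2 source, cGy / (h * U).
DEFAULT_LAMBDA = 1.109


@dataclass
class SourceModel:
    """HDR source description and TG-43 lookup tables.

    ``g_table`` / ``aniso_table`` are ``(r_mm, value)`` pairs; ``None`` means
    the corresponding factor is identically 1 (useful for unit checks and
    idealized phantoms).  ``mode`` selects the geometry factor: ``"point"``
    uses inverse square with 1-D anisotropy, ``"line"`` the line-source
    geometry factor with active length ``L``.
    """

    Lambda: float = DEFAULT_LAMBDA
    Sk: float = DEFAULT_SK_U
    L: float = 3.5
    mode: str = "point"
    g_table: tuple[np.ndarray, np.ndarray] | None = None
    aniso_table: tuple[np.ndarray, np.ndarray] | None = None
    r0: float = R0_MM
    theta0: float = THETA0_DEG

    def __post_init__(self):
        if self.Lambda <= 0 or self.Sk <= 0:
            raise ValueError("Lambda and Sk must be positive")
        if self.mode not in ("point", "line"):
            raise ValueError(f"unknown source mode {self.mode!r}")
        if self.g_table is not None:
            r, g = self.g_table
            if not np.isclose(np.interp(self.r0, r, g), 1.0, atol=5e-3):
                raise ValueError("radial dose function must satisfy g(r0) ~= 1")

    @classmethod
    def ir192_hdr(cls, Sk: float = DEFAULT_SK_U, mode: str = "point") -> "SourceModel":
        """Ir-192 HDR source with embedded consensus tables."""
        return cls(
            Lambda=DEFAULT_LAMBDA,
            Sk=Sk,
            mode=mode,
            g_table=(_IR192_G_R_MM.copy(), _IR192_G.copy()),
            aniso_table=(_IR192_PHI_R_MM.copy(), _IR192_PHI.copy()),
        )

    # -- table lookups -----------------------------------------------------
    def g(self, r_mm) -> np.ndarray:
        """Radial dose function, log-linear interpolation, clamped at edges."""
        r_mm = np.asarray(r_mm, dtype=float)
        if self.g_table is None:
            return np.ones_like(r_mm)
        rt, gt = self.g_table
        if np.any(r_mm < rt[0]) or np.any(r_mm > rt[-1]):
            logger.debug("g(r) evaluated outside table support; clamping at edges")
        return np.exp(np.interp(r_mm, rt, np.log(gt)))

    def phi_an(self, r_mm) -> np.ndarray:
        r_mm = np.asarray(r_mm, dtype=float)
        if self.aniso_table is None:
            return np.ones_like(r_mm)
        rt, pt = self.aniso_table
        return np.interp(r_mm, rt, pt)


def geometry_factor(r_mm, theta_deg=90.0, L_mm: float = 0.0) -> np.ndarray:
    """Normalized TG-43 geometry factor G(r, theta) / G(r0, theta0).

    ``L_mm == 0`` selects the point-source form (r0/r)^2; otherwise the
    standard line-source form beta / (L r sin(theta)) is used, with the
    on-axis limit 1/(r^2 - L^2/4).
    """
    r = np.asarray(r_mm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("geometry factor undefined at r <= 0")
    if L_mm == 0.0:
        return (R0_MM / r) ** 2

    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    r, theta = np.broadcast_arrays(r, theta)

    def _G(r, theta):
        half = L_mm / 2.0
        sin_t = np.sin(theta)
        cos_t = np.cos(theta)
        on_axis = np.abs(sin_t) < 1e-6
        sin_safe = np.where(on_axis, 1.0, sin_t)
        # angles subtended by the source ends at the calculation point
        beta = np.arctan2(r * cos_t + half, r * sin_safe) - np.arctan2(
            r * cos_t - half, r * sin_safe
        )
        G = np.abs(beta) / (L_mm * r * np.abs(sin_safe))
        G_axis = 1.0 / np.maximum(r**2 - half**2, 1e-12)
        return np.where(on_axis, G_axis, G)

    G0 = _G(np.asarray(R0_MM), np.deg2rad(np.asarray(THETA0_DEG)))
    return _G(r, theta) / G0


def dose_rate_point(source: SourceModel, r_mm, theta_deg=90.0) -> np.ndarray:
    """TG-43 dose rate in cGy/h at polar coordinates (r, theta) from one dwell."""
    r = np.asarray(r_mm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("dose rate undefined at r <= 0")
    L = source.L if source.mode == "line" else 0.0
    G = geometry_factor(r, theta_deg, L_mm=L)
    return source.Sk * source.Lambda * G * source.g(r) * source.phi_an(r)


@dataclass
class DoseInfluenceSet:
    """Per-structure dose-influence matrices (Gy/s), rows = retained voxels."""

    matrices: dict[str, np.ndarray]
    voxel_volume: float
    n_dwells: int
    source: SourceModel = field(repr=False, default=None)

    def __post_init__(self):
        for name, m in self.matrices.items():
            if m.shape[1] != self.n_dwells:
                raise ValueError(f"matrix for {name!r} has wrong dwell count")
            if not np.all(np.isfinite(m)) or np.any(m < 0):
                raise ValueError(f"matrix for {name!r} has invalid entries")


CGY_H_TO_GY_S = 1.0 / 100.0 / 3600.0


def build_dose_influence(
    case: PatientCase, source: SourceModel | None = None
) -> DoseInfluenceSet:
    """Compute the Dij matrices for every structure of a case.

    Each entry (i, j) is the dose rate in Gy per second delivered to voxel i
    by a unit dwell at position j.  Applicator-adjacent voxels are assumed to
    have been excluded already (the phantom generator does this), so all
    source-voxel distances are strictly positive.
    """
    source = source or SourceModel.ir192_hdr()
    dwell = case.channels.all_dwell_positions
    dirs = case.channels.all_dwell_directions
    matrices: dict[str, np.ndarray] = {}
    for name in STRUCTURE_NAMES:
        s = case.structures.get(name)
        if s is None or s.n_voxels == 0:
            raise ValueError(f"structure {name!r} has no retained voxels")
        diff = s.coords[:, None, :] - dwell[None, :, :]  # (N, M, 3)
        r = np.linalg.norm(diff, axis=2)
        if np.any(r <= 0):
            raise ValueError(f"structure {name!r} contains a voxel at a dwell position")
        if source.mode == "line":
            cos_t = np.einsum("nmj,mj->nm", diff, dirs) / r
            theta = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
        else:
            theta = 90.0
        matrices[name] = dose_rate_point(source, r, theta) * CGY_H_TO_GY_S
    dij = DoseInfluenceSet(
        matrices=matrices,
        voxel_volume=case.grid.voxel_volume,
        n_dwells=len(dwell),
        source=source,
    )
    case.dij = dij
    return dij
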