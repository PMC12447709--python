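"""Synthetic patient phantoms for HDR brachytherapy planning.

A phantom emulates the geometry a cervix brachytherapy planner works with:
an intrauterine tandem plus interstitial needles, a high-risk CTV ellipsoid
centred on the tandem tip, an intermediate-risk CTV obtained by margin
expansion, and the five organs at risk (bladder, rectum, sigmoid, small
bowel, large bowel) at anatomically plausible offsets.  Prescriptions and
per-OAR D2cc thresholds are sampled within published clinical ranges.

All quantities are in physical millimetres, voxel-centre convention, axes
fixed as (x right, y anterior, z superior).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

CTV_HR = "ctv_hr"
CTV_IR = "ctv_ir"
OAR_NAMES = ("bladder", "rectum", "sigmoid", "small_bowel", "large_bowel")
STRUCTURE_NAMES = (CTV_HR, CTV_IR) + OAR_NAMES

#: Clinical sampling ranges, Gy per fraction (prescriptions over 5 fractions).
RX_HR_RANGE = (3.23, 6.20)
RX_IR_RANGE = (2.13, 4.99)
OAR_THRESHOLD_RANGES = {
    "bladder": (4.74, 5.50),
    "rectum": (2.82, 4.34),
    "sigmoid": (1.79, 4.34),
    "small_bowel": (1.83, 3.61),
    "large_bowel": (2.48, 4.08),
}


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid: spacing and dims per axis, origin = centre of voxel (0,0,0)."""

    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    dims: tuple[int, int, int] = (80, 80, 80)
    origin: tuple[float, float, float] | None = None

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on all axes")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1 on all axes")
        if self.origin is None:
            # centre the grid on the world origin
            orig = tuple(-(d - 1) / 2.0 * s for d, s in zip(self.dims, self.spacing))
            object.__setattr__(self, "origin", orig)

    @property
    def voxel_volume(self) -> float:
        """mm^3 per voxel."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def meshgrid(self):
        return np.meshgrid(*(self.axis_coords(i) for i in range(3)), indexing="ij")

    def coords_of(self, mask: np.ndarray) -> np.ndarray:
        """Physical mm coordinates (N, 3) of the centres of True voxels."""
        idx = np.argwhere(mask)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin) - np.asarray(self.spacing) / 2.0
        hi = lo + np.asarray(self.spacing) * np.asarray(self.dims)
        return lo, hi


@dataclass
class Structure:
    """A named anatomical structure: binary mask plus occupied voxel-centre coords."""

    name: str
    mask: np.ndarray
    coords: np.ndarray

    @classmethod
    def from_mask(cls, name: str, mask: np.ndarray, grid: VoxelGrid) -> "Structure":
        return cls(name=name, mask=mask.astype(bool), coords=grid.coords_of(mask))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Channel:
    """One applicator channel: control points, interpolated centerline, dwell positions.

    ``directions`` holds the unit tangent of the centerline at each dwell
    position (used by the line-source dose mode).
    """

    control_points: np.ndarray
    centerline: np.ndarray
    dwell_positions: np.ndarray
    directions: np.ndarray
    radius: float = 1.0


@dataclass
class ChannelSet:
    channels: list[Channel] = field(default_factory=list)
    dwell_spacing: float = 5.0

    @property
    def all_dwell_positions(self) -> np.ndarray:
        return np.vstack([c.dwell_positions for c in self.channels])

    @property
    def all_dwell_directions(self) -> np.ndarray:
        return np.vstack([c.directions for c in self.channels])

    @property
    def n_dwells(self) -> int:
        return sum(len(c.dwell_positions) for c in self.channels)


@dataclass
class PrescriptionSet:
    """Per-fraction prescription doses and per-OAR D2cc thresholds (Gy/fx)."""

    rx_hr: float
    rx_ir: float
    oar_thresholds: dict[str, float]
    n_fractions: int = 5

    def __post_init__(self):
        if not (self.rx_hr > self.rx_ir > 0):
            raise ValueError("prescriptions must satisfy rx_hr > rx_ir > 0")
        if any(t <= 0 for t in self.oar_thresholds.values()):
            raise ValueError("all OAR thresholds must be positive")


@dataclass
class PatientCase:
    """Everything the planner needs for one anatomy.

    ``dij`` is filled by :func:`brachyplan.tg43.build_dose_influence`.
    """

    id: str
    grid: VoxelGrid
    structures: dict[str, Structure]
    channels: ChannelSet
    prescriptions: PrescriptionSet
    dij: "object | None" = None  # tg43.DoseInfluenceSet once built


@dataclass(frozen=True)
class GeometryParams:
    """Sampling ranges (mm) for the phantom geometry. Defaults are clinic-scale."""

    hr_semi_axes_xy: tuple[float, float] = (12.0, 18.0)
    hr_semi_axis_z: tuple[float, float] = (15.0, 22.0)
    ir_margin: tuple[float, float] = (4.0, 7.0)
    n_needles: tuple[int, int] = (2, 4)
    needle_offset: tuple[float, float] = (6.0, 12.0)
    bladder_radius: tuple[float, float] = (13.0, 17.0)
    rectum_radius: tuple[float, float] = (7.0, 10.0)
    sigmoid_radius: tuple[float, float] = (6.0, 9.0)
    bowel_radius: tuple[float, float] = (10.0, 14.0)
    oar_gap: tuple[float, float] = (3.0, 6.0)
    dwell_spacing: float = 5.0
    channel_radius: float = 1.0
    exclusion_radius: float = 2.0

    def scaled(self, factor: float) -> "GeometryParams":
        """Uniformly shrink/grow every length range (desk-scale problem sizes)."""

        def s(rng):
            return (rng[0] * factor, rng[1] * factor)

        return replace(
            self,
            hr_semi_axes_xy=s(self.hr_semi_axes_xy),
            hr_semi_axis_z=s(self.hr_semi_axis_z),
            ir_margin=s(self.ir_margin),
            needle_offset=s(self.needle_offset),
            bladder_radius=s(self.bladder_radius),
            rectum_radius=s(self.rectum_radius),
            sigmoid_radius=s(self.sigmoid_radius),
            bowel_radius=s(self.bowel_radius),
        )


# ---------------------------------------------------------------------------
# channel construction


def build_channels(
    control_point_sets: list[np.ndarray],
    dwell_spacing: float = 5.0,
    radius: float = 1.0,
    centerline_step: float = 1.0,
) -> ChannelSet:
    """Interpolate smooth centerlines through control points and place dwells.

    Each channel needs >= 2 control points; the centerline is a natural cubic
    spline through them, reparameterized by arc length, and dwell positions
    are dropped every ``dwell_spacing`` mm along the arc (both ends included
    when the length divides evenly).
    """
    channels = []
    for cps in control_point_sets:
        cps = np.asarray(cps, dtype=float)
        if cps.ndim != 2 or cps.shape[1] != 3 or len(cps) < 2:
            raise ValueError("each channel needs >= 2 control points of shape (k, 3)")
        seg = np.linalg.norm(np.diff(cps, axis=0), axis=1)
        if np.any(seg < 1e-9):
            raise ValueError("duplicate consecutive control points")
        # chord-length parameterization
        t = np.concatenate([[0.0], np.cumsum(seg)])
        if len(cps) == 2:
            spline = None
        else:
            spline = CubicSpline(t, cps, axis=0, bc_type="natural")

        def _eval(tt):
            if spline is None:
                w = (tt / t[-1])[:, None]
                return (1 - w) * cps[0] + w * cps[1]
            return spline(tt)

        # dense sampling -> arc length table
        tt = np.linspace(0.0, t[-1], max(200, int(t[-1] * 20)))
        dense = _eval(tt)
        ds = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(ds)])
        total = arc[-1]

        def _at_arc(s):
            return _eval(np.interp(s, arc, tt))

        # centerline polyline at ~centerline_step mm resolution
        s_line = np.linspace(0.0, total, max(2, int(np.ceil(total / centerline_step)) + 1))
        centerline = _at_arc(s_line)

        n_dwell = int(np.floor(total / dwell_spacing + 1e-9)) + 1
        s_dwell = np.arange(n_dwell) * dwell_spacing
        dwell = _at_arc(s_dwell)
        # unit tangents via small central differences in arc length
        eps = 0.5
        fwd = _at_arc(np.minimum(s_dwell + eps, total))
        bwd = _at_arc(np.maximum(s_dwell - eps, 0.0))
        tang = fwd - bwd
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)

        channels.append(
            Channel(
                control_points=cps,
                centerline=centerline,
                dwell_positions=dwell,
                directions=tang,
                radius=radius,
            )
        )
    return ChannelSet(channels=channels, dwell_spacing=dwell_spacing)


def min_channel_distance(coords: np.ndarray, channels: ChannelSet) -> np.ndarray:
    """Minimum distance (mm) from each coord to any channel centerline polyline."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    best = np.full(len(coords), np.inf)
    for ch in channels.channels:
        a = ch.centerline[:-1]
        b = ch.centerline[1:]
        ab = b - a  # (S, 3)
        ab2 = np.einsum("ij,ij->i", ab, ab)
        # (N, S, 3) broadcasting in chunks to bound memory
        chunk = max(1, int(2_000_000 / max(len(a), 1)))
        for lo in range(0, len(coords), chunk):
            p = coords[lo : lo + chunk]
            ap = p[:, None, :] - a[None, :, :]
            tproj = np.einsum("nsj,sj->ns", ap, ab) / np.maximum(ab2, 1e-30)
            tproj = np.clip(tproj, 0.0, 1.0)
            closest = a[None, :, :] + tproj[..., None] * ab[None, :, :]
            d = np.linalg.norm(p[:, None, :] - closest, axis=2).min(axis=1)
            best[lo : lo + chunk] = np.minimum(best[lo : lo + chunk], d)
    return best


def exclude_applicator_voxels(
    coords: np.ndarray, channels: ChannelSet, radius: float
) -> np.ndarray:
    """Drop coords within ``radius`` mm of any channel centerline.

    Voxels inside or hugging the applicator are invalid dose evaluation
    points (they sit in hardware, not tissue).
    """
    for ch in channels.channels:
        if radius < ch.radius:
            raise ValueError("exclusion radius must be >= channel radius")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    keep = min_channel_distance(coords, channels) > radius
    retained = coords[keep]
    if len(retained) == 0:
        logger.warning("applicator exclusion removed every coordinate")
    return retained


# ---------------------------------------------------------------------------
# phantom assembly


def _ellipsoid_mask(grid: VoxelGrid, center, semi_axes) -> np.ndarray:
    X, Y, Z = grid.meshgrid()
    cx, cy, cz = center
    a, b, c = semi_axes
    return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0


def _capsule_mask(grid: VoxelGrid, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` of segment p0-p1 (a tubular organ section)."""
    X, Y, Z = grid.meshgrid()
    p = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    t = np.clip((p - p0) @ d / (d @ d), 0.0, 1.0)
    dist = np.linalg.norm(p - (p0 + t[:, None] * d), axis=1)
    return (dist <= radius).reshape(grid.dims)


def _sphere_mask(grid: VoxelGrid, center, radius) -> np.ndarray:
    return _ellipsoid_mask(grid, center, (radius, radius, radius))


def generate_case(
    seed: int,
    grid: VoxelGrid | None = None,
    params: GeometryParams | None = None,
    case_id: str | None = None,
) -> PatientCase:
    """Generate one reproducible synthetic patient case.

    Deterministic for a given ``(seed, grid, params)``.  The high-risk CTV is
    an ellipsoid centred on the tandem tip, the intermediate-risk CTV its
    margin expansion (strict containment by construction), OARs are placed at
    fixed anatomical offsets and made disjoint from the high-risk CTV, and
    applicator-adjacent voxels are excluded from every structure mask.
    """
    grid = grid or VoxelGrid()
    params = params or GeometryParams()
    rng = np.random.default_rng(seed)

    u = rng.uniform
    a = u(*params.hr_semi_axes_xy)
    b = u(*params.hr_semi_axes_xy)
    c = u(*params.hr_semi_axis_z)
    margin = u(*params.ir_margin)

    lo_box, hi_box = grid.bounding_box
    half_extent = float(min(np.abs(lo_box).min(), np.abs(hi_box).min()))
    r_bladder = u(*params.bladder_radius)
    gap = u(*params.oar_gap)
    # feasibility: CTV_IR plus the anterior bladder must fit inside the grid
    needed = max(c + margin, b + margin + 2 * gap + 2 * r_bladder)
    if needed >= half_extent:
        raise ValueError(
            f"infeasible geometry: structures extend {needed:.1f} mm from centre "
            f"but the grid half-extent is only {half_extent:.1f} mm"
        )

    # ---- applicator: curved tandem through the CTV + straight needles
    tip = np.array([0.0, 0.0, 0.0])  # CTV_HR centre == tandem tip
    curve = u(2.0, 5.0)
    tandem_cp = np.array(
        [
            [0.0, -curve, -3.0 * c - 20.0],
            [0.0, -curve / 2, -1.5 * c],
            [0.0, 0.0, tip[2]],
        ]
    )
    cp_sets = [tandem_cp]
    n_needles = int(rng.integers(params.n_needles[0], params.n_needles[1] + 1))
    for _ in range(n_needles):
        r_off = u(*params.needle_offset)
        theta = u(0.0, 2 * np.pi)
        x0, y0 = r_off * np.cos(theta), r_off * np.sin(theta)
        cp_sets.append(
            np.array([[x0, y0, -2.0 * c - 15.0], [x0, y0, 0.6 * c]])
        )
    channels = build_channels(
        cp_sets, dwell_spacing=params.dwell_spacing, radius=params.channel_radius
    )

    # ---- structures
    hr = _ellipsoid_mask(grid, tip, (a, b, c))
    ir = _ellipsoid_mask(grid, tip, (a + margin, b + margin, c + margin))

    y_bladder = b + gap + r_bladder
    masks = {
        CTV_HR: hr,
        CTV_IR: ir,
        "bladder": _sphere_mask(grid, (0.0, y_bladder, u(5.0, 15.0)), r_bladder),
        "rectum": _capsule_mask(
            grid,
            (0.0, -(b + gap + u(*params.rectum_radius)), -2.0 * c - 10.0),
            (0.0, -(b + gap + u(*params.rectum_radius)), c),
            u(*params.rectum_radius),
        ),
        "sigmoid": _capsule_mask(
            grid,
            (0.0, -(b + gap), c + u(3.0, 8.0)),
            (u(-10, 10), -(b + gap) - 10.0, c + 25.0),
            u(*params.sigmoid_radius),
        ),
        "small_bowel": _sphere_mask(
            grid,
            (u(10, 20), u(0, 12), c + margin + gap + u(*params.bowel_radius)),
            u(*params.bowel_radius),
        ),
        "large_bowel": _capsule_mask(
            grid,
            (-0.6 * half_extent, u(-5, 8), c + margin + gap + 12.0),
            (0.6 * half_extent, u(-5, 8), c + margin + gap + 12.0),
            u(*params.bowel_radius) * 0.7,
        ),
    }
    for name in OAR_NAMES:  # OARs never overlap the high-risk CTV
        masks[name] &= ~hr

    # applicator exclusion applied to the masks themselves so coords == mask
    structures: dict[str, Structure] = {}
    for name in STRUCTURE_NAMES:
        mask = masks[name]
        coords = grid.coords_of(mask)
        if len(coords):
            keep = min_channel_distance(coords, channels) > params.exclusion_radius
            if not np.all(keep):
                idx = np.argwhere(mask)[~keep]
                mask = mask.copy()
                mask[tuple(idx.T)] = False
                coords = coords[keep]
        if len(coords) == 0:
            raise ValueError(f"infeasible geometry: structure '{name}' is empty")
        structures[name] = Structure(name=name, mask=mask, coords=coords)

    if structures[CTV_IR].n_voxels <= structures[CTV_HR].n_voxels:
        raise ValueError("infeasible geometry: CTV_IR does not strictly contain CTV_HR")

    rx_hr = u(*RX_HR_RANGE)
    rx_ir = u(RX_IR_RANGE[0], min(RX_IR_RANGE[1], 0.95 * rx_hr))
    thresholds = {name: u(*OAR_THRESHOLD_RANGES[name]) for name in OAR_NAMES}
    prescriptions = PrescriptionSet(rx_hr=rx_hr, rx_ir=rx_ir, oar_thresholds=thresholds)

    return PatientCase(
        id=case_id or f"phantom-{seed:04d}",
        grid=grid,
        structures=structures,
        channels=channels,
        prescriptions=prescriptions,
    )
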