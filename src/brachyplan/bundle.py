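"""Plan-bundle persistence: one .npz container with a versioned JSON manifest.

The bundle stores the grid, structure masks, channel control points, dwell
parameters, prescriptions, optionally the Dij matrices, and optionally a
dwell solution.  Channels and voxel coordinates are rebuilt deterministically
on load from the control points and masks, so the round trip is
bit-identical on every stored array.  A compatibility writer for
MATLAB-style .mat Dij files is provided with a documented schema.
"""

from __future__ import annotations

import json

import numpy as np
import scipy.io

from .dwell_opt import DwellSolution
from .phantom import (
    STRUCTURE_NAMES,
    ChannelSet,
    PatientCase,
    PrescriptionSet,
    Structure,
    VoxelGrid,
    build_channels,
)
from .tg43 import DoseInfluenceSet, SourceModel

BUNDLE_VERSION = "1.0"


def save_bundle(
    path: str,
    case: PatientCase,
    solution: DwellSolution | None = None,
    include_dij: bool = True,
) -> None:
    """Write a case (and optionally its plan) to a versioned .npz bundle."""
    manifest = {
        "format_version": BUNDLE_VERSION,
        "case_id": case.id,
        "units": {"length": "mm", "dose": "Gy", "dwell_time": "s", "dij": "Gy/s"},
        "conventions": {
            "axes": "x right, y anterior, z superior",
            "voxel": "centre",
            "structures": list(STRUCTURE_NAMES),
        },
        "n_channels": len(case.channels.channels),
        "dij_included": bool(include_dij and case.dij is not None),
        "solution_included": solution is not None,
    }
    arrays: dict[str, np.ndarray] = {
        "grid_spacing": np.asarray(case.grid.spacing, float),
        "grid_dims": np.asarray(case.grid.dims, np.int64),
        "grid_origin": np.asarray(case.grid.origin, float),
        "rx": np.asarray([case.prescriptions.rx_hr, case.prescriptions.rx_ir], float),
        "n_fractions": np.asarray(case.prescriptions.n_fractions),
        "oar_threshold_values": np.asarray(
            [case.prescriptions.oar_thresholds[s] for s in STRUCTURE_NAMES[2:]], float
        ),
    }
    for name in STRUCTURE_NAMES:
        arrays[f"mask_{name}"] = case.structures[name].mask
    for i, ch in enumerate(case.channels.channels):
        arrays[f"channel{i}_control_points"] = ch.control_points
        arrays[f"channel{i}_radius"] = np.asarray(ch.radius)
    arrays["dwell_spacing"] = np.asarray(case.channels.dwell_spacing)

    if manifest["dij_included"]:
        for name in STRUCTURE_NAMES:
            arrays[f"dij_{name}"] = case.dij.matrices[name]
        arrays["dij_voxel_volume"] = np.asarray(case.dij.voxel_volume)
    if solution is not None:
        arrays["solution_d_star"] = solution.d_star
        arrays["solution_loss_trace"] = solution.loss_trace

    arrays["manifest_json"] = np.asarray(json.dumps(manifest))
    np.savez(path, **arrays)


def load_bundle(path: str, source: SourceModel | None = None):
    """Load a bundle; returns ``(case, d_star_or_None, manifest)``.

    Refuses bundles whose manifest version does not match.  If the Dij
    matrices were omitted on write, ``manifest['dij_included']`` is False and
    the caller can rebuild them with :func:`brachyplan.tg43.build_dose_influence`.
    """
    with np.load(path, allow_pickle=False) as z:
        if "manifest_json" not in z:
            raise ValueError("bundle missing field 'manifest_json'")
        manifest = json.loads(str(z["manifest_json"]))
        version = manifest.get("format_version")
        if version != BUNDLE_VERSION:
            raise ValueError(
                f"unsupported bundle format_version {version!r}; expected {BUNDLE_VERSION!r}"
            )
        grid = VoxelGrid(
            spacing=tuple(z["grid_spacing"]),
            dims=tuple(int(d) for d in z["grid_dims"]),
            origin=tuple(z["grid_origin"]),
        )
        structures = {}
        for name in STRUCTURE_NAMES:
            key = f"mask_{name}"
            if key not in z:
                raise ValueError(f"bundle missing field {key!r}")
            structures[name] = Structure.from_mask(name, z[key], grid)
        cps = [
            z[f"channel{i}_control_points"] for i in range(manifest["n_channels"])
        ]
        radius = float(z["channel0_radius"])
        channels: ChannelSet = build_channels(
            cps, dwell_spacing=float(z["dwell_spacing"]), radius=radius
        )
        rx = z["rx"]
        prescriptions = PrescriptionSet(
            rx_hr=float(rx[0]),
            rx_ir=float(rx[1]),
            oar_thresholds=dict(
                zip(STRUCTURE_NAMES[2:], z["oar_threshold_values"].tolist())
            ),
            n_fractions=int(z["n_fractions"]),
        )
        case = PatientCase(
            id=manifest["case_id"],
            grid=grid,
            structures=structures,
            channels=channels,
            prescriptions=prescriptions,
        )
        if manifest["dij_included"]:
            case.dij = DoseInfluenceSet(
                matrices={n: z[f"dij_{n}"] for n in STRUCTURE_NAMES},
                voxel_volume=float(z["dij_voxel_volume"]),
                n_dwells=channels.n_dwells,
                source=source,
            )
        d_star = z["solution_d_star"] if manifest["solution_included"] else None
    return case, d_star, manifest


def save_dij_mat(path: str, case: PatientCase) -> None:
    """Write the Dij matrices as a MATLAB .mat file.

    Schema: one variable ``dij_<structure>`` per structure (rows voxels,
    columns dwell positions, Gy/s), plus ``voxel_volume_mm3`` and ``case_id``.
    """
    if case.dij is None:
        raise ValueError("case has no dose-influence matrices")
    data = {f"dij_{name}": case.dij.matrices[name] for name in STRUCTURE_NAMES}
    data["voxel_volume_mm3"] = case.dij.voxel_volume
    data["case_id"] = case.id
    scipy.io.savemat(path, data)
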