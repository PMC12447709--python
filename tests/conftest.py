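import numpy as np
import pytest

from brachyplan.dwell_opt import OptimizerConfig
from brachyplan.phantom import (
    CTV_HR,
    CTV_IR,
    OAR_NAMES,
    ChannelSet,
    GeometryParams,
    PatientCase,
    PrescriptionSet,
    Structure,
    VoxelGrid,
    build_channels,
    generate_case,
)
from brachyplan.tg43 import DoseInfluenceSet, SourceModel, build_dose_influence

#: Desk-scale problem size used throughout the suite: 2.5 mm voxels on a
#: 64^3 grid with the phantom geometry shrunk to 75% of clinic scale.
DESK_GRID = VoxelGrid(spacing=(2.5, 2.5, 2.5), dims=(64, 64, 64))
DESK_PARAMS = GeometryParams().scaled(0.75)
DESK_OPT = OptimizerConfig(max_iterations=800, patience=150)


def make_case(seed: int) -> PatientCase:
    case = generate_case(seed, grid=DESK_GRID, params=DESK_PARAMS)
    build_dose_influence(case, SourceModel.ir192_hdr())
    return case


@pytest.fixture(scope="session")
def small_case() -> PatientCase:
    return make_case(10)


@pytest.fixture(scope="session")
def cases3() -> list[PatientCase]:
    return [make_case(s) for s in (10, 11, 12)]


def make_toy_case(
    g: float = 0.02,
    rx_hr: float = 5.0,
    rx_ir: float = 3.0,
    hr_matrix: np.ndarray | None = None,
    ir_matrix: np.ndarray | None = None,
    oar_matrices: dict | None = None,
    voxel_volume: float = 8.0,
) -> PatientCase:
    """Minimal hand-built case: matrices injected directly, no phantom geometry.

    Defaults: one CTV_HR voxel fed by one dwell with influence ``g`` Gy/s,
    a CTV_IR voxel scaled so both targets hit 100% at the same dwell time,
    and zero-dose OARs.
    """
    hr = np.atleast_2d(hr_matrix if hr_matrix is not None else [[g]]).astype(float)
    ir = np.atleast_2d(
        ir_matrix if ir_matrix is not None else hr * (rx_ir / rx_hr)
    ).astype(float)
    n_dwells = hr.shape[1]
    mats = {CTV_HR: hr, CTV_IR: ir}
    for name in OAR_NAMES:
        default = np.zeros((1, n_dwells))
        mats[name] = np.atleast_2d((oar_matrices or {}).get(name, default)).astype(float)

    channels = build_channels(
        [np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 5.0 * (n_dwells - 1) + 1e-6]])]
        if n_dwells > 1
        else [np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])],
        dwell_spacing=5.0,
    )
    structures = {
        name: Structure(name=name, mask=np.ones(m.shape[0], bool), coords=np.zeros((m.shape[0], 3)))
        for name, m in mats.items()
    }
    case = PatientCase(
        id="toy",
        grid=VoxelGrid(dims=(2, 2, 2)),
        structures=structures,
        channels=channels,
        prescriptions=PrescriptionSet(
            rx_hr=rx_hr,
            rx_ir=rx_ir,
            oar_thresholds={s: 4.0 for s in OAR_NAMES},
        ),
    )
    case.dij = DoseInfluenceSet(
        matrices=mats, voxel_volume=voxel_volume, n_dwells=n_dwells
    )
    return case
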