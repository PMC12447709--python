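import numpy as np
import pytest

from brachyplan.phantom import (
    CTV_HR,
    CTV_IR,
    OAR_NAMES,
    RX_HR_RANGE,
    RX_IR_RANGE,
    OAR_THRESHOLD_RANGES,
    GeometryParams,
    VoxelGrid,
    build_channels,
    exclude_applicator_voxels,
    generate_case,
    min_channel_distance,
)

SMALL_GRID = VoxelGrid(spacing=(2.5, 2.5, 2.5), dims=(56, 56, 56))
SMALL_PARAMS = GeometryParams().scaled(0.7)


def test_generate_case_is_deterministic():
    a = generate_case(5, grid=SMALL_GRID, params=SMALL_PARAMS)
    b = generate_case(5, grid=SMALL_GRID, params=SMALL_PARAMS)
    for name in a.structures:
        assert np.array_equal(a.structures[name].mask, b.structures[name].mask)
    assert np.array_equal(
        a.channels.all_dwell_positions, b.channels.all_dwell_positions
    )
    assert a.prescriptions == b.prescriptions


def test_target_containment_and_oar_disjointness():
    case = generate_case(1, grid=SMALL_GRID, params=SMALL_PARAMS)
    hr = case.structures[CTV_HR]
    ir = case.structures[CTV_IR]
    assert hr.n_voxels > 0
    assert ir.n_voxels > hr.n_voxels
    assert np.all(ir.mask[hr.mask])  # strict containment
    for name in OAR_NAMES:
        assert not np.any(case.structures[name].mask & hr.mask)
    assert len(case.channels.channels) >= 2
    assert case.channels.n_dwells >= 10


def test_sampled_prescriptions_stay_inside_clinical_ranges():
    """100 seeds: prescriptions and thresholds fall in the published ranges."""
    for seed in range(100):
        case = generate_case(seed, grid=SMALL_GRID, params=SMALL_PARAMS)
        rx = case.prescriptions
        assert RX_HR_RANGE[0] <= rx.rx_hr <= RX_HR_RANGE[1]
        assert RX_IR_RANGE[0] <= rx.rx_ir <= RX_IR_RANGE[1]
        assert rx.rx_hr > rx.rx_ir
        for name, (lo, hi) in OAR_THRESHOLD_RANGES.items():
            assert lo <= rx.oar_thresholds[name] <= hi


def test_infeasible_geometry_raises():
    tiny = VoxelGrid(spacing=(2.0, 2.0, 2.0), dims=(10, 10, 10))
    with pytest.raises(ValueError, match="infeasible"):
        generate_case(0, grid=tiny)


def test_structure_coords_match_masks():
    case = generate_case(2, grid=SMALL_GRID, params=SMALL_PARAMS)
    lo, hi = case.grid.bounding_box
    for s in case.structures.values():
        assert len(s.coords) == s.mask.sum()
        assert np.all(s.coords >= lo) and np.all(s.coords <= hi)


# ---------------------------------------------------------------------------
# channels


def test_straight_channel_dwell_count():
    cs = build_channels([np.array([[0, 0, 0], [0, 0, 50.0]])], dwell_spacing=5.0)
    assert len(cs.channels[0].dwell_positions) == 11
    d = cs.channels[0].dwell_positions
    assert np.allclose(np.linalg.norm(np.diff(d, axis=0), axis=1), 5.0, atol=1e-6)


def test_arc_channel_interpolation_accuracy():
    """Centerline through circle-arc control points stays within 0.5 mm of the arc."""
    R = 40.0
    ang = np.linspace(0, np.pi / 2, 6)
    cps = np.stack([R * np.cos(ang), R * np.sin(ang), np.zeros_like(ang)], axis=1)
    cs = build_channels([cps], dwell_spacing=5.0)
    dev = np.abs(np.linalg.norm(cs.channels[0].centerline[:, :2], axis=1) - R)
    assert dev.max() < 0.5


def test_channel_input_validation():
    with pytest.raises(ValueError):
        build_channels([np.array([[0.0, 0.0, 0.0]])])
    with pytest.raises(ValueError, match="duplicate"):
        build_channels([np.array([[0, 0, 0], [0, 0, 0], [0, 0, 10.0]])])


# ---------------------------------------------------------------------------
# applicator exclusion


def _brute_min_distance(coords, channels):
    out = np.full(len(coords), np.inf)
    for ch in channels.channels:
        for a, b in zip(ch.centerline[:-1], ch.centerline[1:]):
            ab = b - a
            t = np.clip((coords - a) @ ab / (ab @ ab), 0, 1)
            d = np.linalg.norm(coords - (a + t[:, None] * ab), axis=1)
            out = np.minimum(out, d)
    return out


def test_exclusion_matches_bruteforce_point_to_segment():
    rng = np.random.default_rng(42)
    cs = build_channels(
        [
            np.array([[0, 0, -30], [2, 1, 0], [0, 3, 30.0]]),
            np.array([[10, 0, -30], [10, 0, 30.0]]),
        ]
    )
    coords = rng.uniform(-40, 40, size=(1000, 3))
    retained = exclude_applicator_voxels(coords, cs, radius=5.0)
    expected = coords[_brute_min_distance(coords, cs) > 5.0]
    assert np.array_equal(retained, expected)


def test_exclusion_trivial_cases():
    cs = build_channels([np.array([[0, 0, 0], [0, 0, 20.0]])])
    far = np.array([[30.0, 30.0, 10.0]])
    assert len(exclude_applicator_voxels(far, cs, radius=2.0)) == 1
    on_line = np.array([[0.0, 0.0, 10.0]])
    assert len(exclude_applicator_voxels(on_line, cs, radius=2.0)) == 0


def test_exclusion_monotone_in_radius():
    rng = np.random.default_rng(0)
    cs = build_channels([np.array([[0, 0, -20], [0, 0, 20.0]])])
    coords = rng.uniform(-15, 15, size=(500, 3))
    d = min_channel_distance(coords, cs)
    small = {tuple(c) for c in coords[d > 2.0]}
    large = {tuple(c) for c in coords[d > 6.0]}
    assert large <= small


def test_exclusion_radius_below_channel_radius_rejected():
    cs = build_channels([np.array([[0, 0, 0], [0, 0, 20.0]])], radius=1.5)
    with pytest.raises(ValueError):
        exclude_applicator_voxels(np.zeros((1, 3)), cs, radius=1.0)
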