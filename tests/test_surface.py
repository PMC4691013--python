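import numpy as np
import pytest

from tomoaccess import (SegmentationMask, accessible_area_curve, biomass_stats,
                        build_contour_tree, compute_acrt, compute_aedt,
                        compute_edt, extract_surface,
                        sample_surface_accessibility, select_seed, tag_tree)
from tomoaccess.phantoms import make_dumbbell, make_rough_wall


def full_chain(mask, strategy, faces=None):
    edt = compute_edt(mask)
    tree = build_contour_tree(edt)
    tagged = tag_tree(tree, select_seed(mask, strategy, faces))
    return compute_acrt(compute_aedt(edt, tagged))


def test_ball_mesh_area_close_to_analytic(ball_mask):
    mesh = extract_surface(ball_mask)
    analytic = 4 * np.pi * 20.0 ** 2
    assert abs(mesh.total_area() - analytic) / analytic < 0.05
    assert (mesh.vertices.min() >= 0) and (mesh.vertices.max() <= 45)


def test_triangle_areas_agree_with_trimesh(ball_mask):
    """Independent mesh-area computation cross-checks ours."""
    import trimesh

    mesh = extract_surface(ball_mask)
    tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    assert mesh.total_area() == pytest.approx(tm.area, rel=1e-9)


def test_box_mesh_area_close_to_analytic():
    labels = np.zeros((26, 26, 26), np.int8)
    labels[3:23, 3:23, 3:23] = 1
    mesh = extract_surface(SegmentationMask(labels, 1.0))
    analytic = 6 * 20.0 ** 2
    assert abs(mesh.total_area() - analytic) / analytic < 0.05


def test_single_voxel_gives_small_closed_mesh():
    labels = np.zeros((5, 5, 5), np.int8)
    labels[2, 2, 2] = 1
    mesh = extract_surface(SegmentationMask(labels, 1.0))
    assert mesh.total_area() > 0
    assert mesh.triangles.max() < len(mesh.vertices)
    # closed surface: every edge shared by exactly two triangles
    edges = np.sort(mesh.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    assert (counts == 2).all()


def test_single_phase_masks_rejected():
    with pytest.raises(ValueError):
        extract_surface(SegmentationMask(np.ones((4, 4, 4), np.int8), 1.0))
    with pytest.raises(ValueError):
        extract_surface(SegmentationMask(np.zeros((4, 4, 4), np.int8), 1.0))


def test_epsilon_monotonicity():
    mask, _ = make_rough_wall((16, 32, 32), 1.0, amplitude=4.0, rng_seed=2)
    acrt = full_chain(mask, "lumen")
    mesh = extract_surface(mask)
    v1 = sample_surface_accessibility(mesh, acrt, epsilon=1.1)
    v2 = sample_surface_accessibility(mesh, acrt, epsilon=2.5)
    assert (v2 >= v1 - 1e-12).all()
    with pytest.raises(ValueError, match="positive"):
        sample_surface_accessibility(mesh, acrt, epsilon=0.0)


def test_sealed_cavity_walls_read_zero():
    """Lumen-seeded accessibility is exactly 0 on a sealed cavity's wall."""
    mask, truth = make_dumbbell((48, 40, 48), 1.0, R1=10, R2=6, a=0,
                                open_side="left", lumen=True)
    acrt = full_chain(mask, "lumen")
    mesh = extract_surface(mask)
    vv = sample_surface_accessibility(mesh, acrt)      # default 1.1 voxels
    c2 = np.asarray(truth["center2_voxel"], dtype=float)
    sealed = np.linalg.norm(mesh.vertices - c2, axis=1) < truth["R2_nm"] + 1.0
    assert sealed.any()
    assert (vv[sealed] == 0.0).all()


def test_curve_endpoints_and_monotonicity():
    mask, _ = make_rough_wall((16, 32, 32), 1.0, amplitude=4.0, rng_seed=2)
    acrt = full_chain(mask, "lumen")
    mesh = extract_surface(mask)
    vv = sample_surface_accessibility(mesh, acrt)
    curve = accessible_area_curve(mesh, vv, mask=mask)
    assert curve.area[0] == pytest.approx(mesh.total_area())
    assert curve.frac_total_area[0] == pytest.approx(1.0)
    assert (np.diff(curve.area) <= 1e-9).all()
    big = accessible_area_curve(mesh, vv, radii=[vv.max() + 1.0], mask=mask)
    assert big.area[0] == 0.0
    with pytest.raises(ValueError, match="empty"):
        accessible_area_curve(mesh, vv, radii=[])


def test_dumbbell_curve_drop_matches_analytic():
    """Crossing the bottleneck radius removes the far cavity and channel."""
    mask, truth = make_dumbbell((64, 40, 64), 1.0, R1=10, R2=6, a=3,
                                open_side="left", lumen=True)
    acrt = full_chain(mask, "lumen")
    mesh = extract_surface(mask)
    vv = sample_surface_accessibility(mesh, acrt)
    a, R1, R2 = (truth["bottleneck_nm"], truth["R1_nm"], truth["R2_nm"])
    curve = accessible_area_curve(mesh, vv, radii=[a - 0.5, a + 0.5], mask=mask)
    drop = curve.area[0] - curve.area[1]
    L = (truth["center2_voxel"][2] - truth["center1_voxel"][2]) \
        - np.sqrt(R1 ** 2 - a ** 2) - np.sqrt(R2 ** 2 - a ** 2)
    predicted = 4 * np.pi * R2 ** 2 \
        - 2 * np.pi * R2 * (R2 - np.sqrt(R2 ** 2 - a ** 2)) \
        + 2 * np.pi * a * L
    assert drop == pytest.approx(predicted, rel=0.10)


def test_mean_rule_no_smaller_than_all_rule():
    mask, _ = make_rough_wall((16, 32, 32), 1.0, amplitude=4.0, rng_seed=2)
    acrt = full_chain(mask, "lumen")
    mesh = extract_surface(mask)
    vv = sample_surface_accessibility(mesh, acrt)
    radii = np.linspace(0, vv.max(), 10)
    strict = accessible_area_curve(mesh, vv, radii=radii, rule="all")
    mean = accessible_area_curve(mesh, vv, radii=radii, rule="mean")
    assert (mean.area >= strict.area - 1e-9).all()


def test_biomass_stats_cube_volume_exact():
    labels = np.zeros((14, 14, 14), np.int8)
    labels[2:12, 2:12, 2:12] = 1
    mask = SegmentationMask(labels, 2.0)
    stats = biomass_stats(mask, extract_surface(mask))
    assert stats["biomass_volume_um3"] * 1e9 == pytest.approx(8000.0)


def test_ball_area_to_volume_ratio(ball_mask):
    stats = biomass_stats(ball_mask, extract_surface(ball_mask))
    ratio_nm = stats["area_per_volume_per_um"] / 1e3   # 1/um -> 1/nm
    assert ratio_nm == pytest.approx(3.0 / 20.0, rel=0.10)


def test_rough_wall_ratio_exceeds_flat():
    flat, _ = make_rough_wall((16, 48, 48), 1.0, amplitude=0.0, rng_seed=0)
    rough, _ = make_rough_wall((16, 48, 48), 1.0, amplitude=6.0,
                               wavelength=20.0, rng_seed=0)
    s_flat = biomass_stats(flat, extract_surface(flat))
    s_rough = biomass_stats(rough, extract_surface(rough))
    assert s_rough["area_per_volume_per_um"] > s_flat["area_per_volume_per_um"]


def test_large_probe_crossover_rough_vs_flat():
    """Big probes touch a corrugated wall only at ridges."""
    frac = {}
    for name, amp in (("flat", 0.0), ("rough", 6.0)):
        mask, _ = make_rough_wall((16, 48, 48), 1.0, amplitude=amp,
                                  wavelength=20.0, rng_seed=0)
        acrt = full_chain(mask, "lumen")
        mesh = extract_surface(mask)
        vv = sample_surface_accessibility(mesh, acrt)
        curve = accessible_area_curve(mesh, vv, radii=[1.0, 12.0], mask=mask)
        frac[name] = curve.frac_total_area
    assert frac["rough"][1] < frac["flat"][1]
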