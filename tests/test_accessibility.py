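import numpy as np
import pytest

from tomoaccess import (aedt_threshold_sweep_oracle, aedt_widest_path_oracle,
                        build_contour_tree, compute_acrt, compute_aedt,
                        compute_edt, select_seed, sphere_max_paint, tag_tree)
from tomoaccess.phantoms import (make_delaminated_slab, make_dumbbell,
                                 make_random_blobs, make_rough_wall)
from tomoaccess.volume_io import LUMEN, SegmentationMask


def tree_aedt(mask, strategy, faces=None, connectivity=6):
    edt = compute_edt(mask)
    tree = build_contour_tree(edt, connectivity=connectivity)
    seed = select_seed(mask, strategy, faces)
    return edt, seed, compute_aedt(edt, tag_tree(tree, seed))


# ---------------------------------------------------------------- seeds

def test_lumen_seed_takes_exactly_lumen_voxels():
    labels = np.zeros((6, 6, 6), np.int8)
    labels[0] = 1
    labels[3, :, :3] = LUMEN           # a lumen sliver
    mask = SegmentationMask(labels, 1.0)
    seed = select_seed(mask, "lumen")
    assert len(seed.voxels) == int(mask.lumen.sum())


def test_lumen_seed_without_labels_fails(blob_mask):
    labels = blob_mask.labels.copy()
    labels[labels == LUMEN] = 0
    with pytest.raises(ValueError, match="lumen"):
        select_seed(SegmentationMask(labels, 1.0), "lumen")


def test_boundary_default_faces_pick_thinnest_axis():
    labels = np.zeros((8, 16, 16), np.int8)
    labels[4] = 1
    seed = select_seed(SegmentationMask(labels, 1.0), "boundary")
    assert seed.faces == ("z-", "z+")
    assert set(np.unique(seed.voxels[:, 0])) == {0, 7}

    labels = np.zeros((16, 16, 8), np.int8)
    labels[:, :, 4] = 1
    seed = select_seed(SegmentationMask(labels, 1.0), "boundary")
    assert seed.faces == ("x-", "x+")


def test_all_biomass_face_gives_empty_seed_error():
    labels = np.zeros((6, 8, 8), np.int8)
    labels[0] = 1                       # z- face fully biomass
    with pytest.raises(ValueError, match="empty seed"):
        select_seed(SegmentationMask(labels, 1.0), "boundary", faces=("z-",))


# ---------------------------------------------------------------- tagging

def test_strategy_none_reproduces_plain_transforms(blob_mask):
    edt, _, aedt = tree_aedt(blob_mask, "none")
    assert np.array_equal(aedt.values, edt.values)
    assert np.array_equal(compute_acrt(aedt).values,
                          sphere_max_paint(edt).values)


def test_convex_void_fully_seeded_gives_edt():
    """Seed covering the open region: no bottleneck governs anywhere."""
    mask, _ = make_rough_wall((16, 32, 32), 1.0, amplitude=0.0, rng_seed=0)
    edt, _, aedt = tree_aedt(mask, "lumen")
    assert np.array_equal(aedt.values, edt.values)


def test_dumbbell_bottleneck_limits_far_cavity():
    mask, truth = make_dumbbell((64, 40, 64), 1.0, R1=10, R2=6, a=3,
                                open_side="left")
    edt, _, aedt = tree_aedt(mask, "boundary", faces=("x-",))
    a = truth["bottleneck_nm"]
    c2 = truth["center2_voxel"]
    assert abs(aedt.values[c2] - a) <= 1.0
    # near the right cavity wall the EDT itself is the binding constraint
    wall = (edt.values > 0) & (edt.values < a - 1.0)
    z, y, x = np.indices(mask.shape)
    right = x > (truth["center1_voxel"][2] + truth["center2_voxel"][2]) // 2
    sel = wall & right
    assert sel.any()
    assert np.array_equal(aedt.values[sel], edt.values[sel])


def test_sealed_cavity_is_inaccessible():
    mask, truth = make_dumbbell((48, 40, 48), 1.0, R1=10, R2=6, a=0,
                                open_side="left")
    _, _, aedt = tree_aedt(mask, "boundary", faces=("x-",))
    c2 = truth["center2_voxel"]
    assert aedt.values[c2] == 0.0


def test_acrt_labels_entire_cavity_with_bottleneck():
    mask, truth = make_dumbbell((64, 40, 64), 1.0, R1=10, R2=6, a=3,
                                open_side="left")
    edt, _, aedt = tree_aedt(mask, "boundary", faces=("x-",))
    acrt = compute_acrt(aedt)
    a, c2, R2 = truth["bottleneck_nm"], truth["center2_voxel"], truth["R2_nm"]
    z, y, x = np.indices(mask.shape, dtype=float)
    cavity = ((z - c2[0]) ** 2 + (y - c2[1]) ** 2 + (x - c2[2]) ** 2
              <= (R2 - 1.0) ** 2) & mask.void
    assert np.all(np.abs(acrt.values[cavity] - a) <= 1.0)


def test_aedt_below_edt_and_acrt_below_crt(blob_mask):
    edt = compute_edt(blob_mask)
    crt = sphere_max_paint(edt)
    for strategy in ("lumen", "boundary"):
        _, _, aedt = tree_aedt(blob_mask, strategy)
        assert (aedt.values <= edt.values + 1e-12).all()
        assert (compute_acrt(aedt).values <= crt.values + 1e-12).all()


def test_seed_monotonicity(blob_mask):
    """A larger seed never reduces accessibility."""
    _, _, one_face = tree_aedt(blob_mask, "boundary", faces=("z-",))
    _, _, two_faces = tree_aedt(blob_mask, "boundary", faces=("z-", "z+"))
    assert (one_face.values <= two_faces.values + 1e-12).all()


def test_strategy_ordering_on_delaminated_slab():
    mask, _ = make_delaminated_slab((24, 48, 24), 1.0, n_gaps=2,
                                    gap_half_widths=[2.0])
    edt = compute_edt(mask)
    tree = build_contour_tree(edt)
    acrt = {}
    for strategy in ("lumen", "boundary", "none"):
        seed = select_seed(mask, strategy)
        acrt[strategy] = compute_acrt(compute_aedt(edt, tag_tree(tree, seed)))
    assert (acrt["lumen"].values <= acrt["boundary"].values + 1e-12).all()
    assert (acrt["boundary"].values <= acrt["none"].values + 1e-12).all()


def test_neck_governs_lumen_access_to_gap():
    mask, truth = make_delaminated_slab((24, 48, 24), 1.0, n_gaps=1,
                                        gap_half_widths=[3.0],
                                        connect_to_lumen=True,
                                        neck_radius=1.5)
    edt, _, aedt = tree_aedt(mask, "lumen")
    acrt = compute_acrt(aedt)
    gap = (edt.values > 2.0) & ~mask.lumen & mask.void
    assert gap.any()
    neck = truth["neck_radius_nm"]
    assert np.all(np.abs(acrt.values[gap] - neck) <= 1.0)


# ---------------------------------------------------------------- oracles

@pytest.mark.parametrize("connectivity", [6, 26])
@pytest.mark.parametrize("strategy", ["lumen", "boundary", "none"])
def test_tree_aedt_equals_widest_path_oracle(strategy, connectivity):
    mask, _ = make_random_blobs((16, 16, 16), 1.0, rng_seed=4, lumen_depth=3)
    edt, seed, aedt = tree_aedt(mask, strategy, connectivity=connectivity)
    oracle = aedt_widest_path_oracle(edt, seed, connectivity)
    assert np.array_equal(aedt.values, oracle.values)


def test_oracles_cross_check():
    mask, _ = make_random_blobs((16, 16, 16), 1.0, rng_seed=9, lumen_depth=3)
    edt = compute_edt(mask)
    for strategy in ("lumen", "boundary"):
        seed = select_seed(mask, strategy)
        wp = aedt_widest_path_oracle(edt, seed, 6)
        sweep = aedt_threshold_sweep_oracle(edt, seed, 6)
        assert np.array_equal(wp.values, sweep.values)
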