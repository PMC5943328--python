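"""Trabecular morphometry: porosity, thickness, separation, SAD, SMI."""

import numpy as np
import pytest

import tpms_scaffold as ts
from tpms_scaffold.volumes import BinaryVolume, Domain, VoxelVolume


@pytest.fixture(scope="module")
def dom64():
    return Domain.cube(1.0, 64)


# ---------------------------------------------------------------------------
# segmentation + porosity
# ---------------------------------------------------------------------------

def test_segment_two_valued_volume():
    vals = np.zeros((8, 8, 8))
    vals[:4] = 100.0
    gray = VoxelVolume(vals, (0.1, 0.1, 0.1))
    mask = ts.segment(gray, 50.0)
    np.testing.assert_array_equal(mask.mask, vals == 100.0)


def test_segment_below_min_warns_all_solid():
    gray = VoxelVolume(np.full((4, 4, 4), 7.0), (1, 1, 1))
    with pytest.warns(UserWarning, match="degenerate"):
        mask = ts.segment(gray, -1.0)
    assert ts.porosity(mask) == 0.0


def test_segment_largest_component_filter():
    vals = np.zeros((10, 10, 10))
    vals[:5] = 100.0       # large slab
    vals[8, 8, 8] = 100.0  # isolated speck
    gray = VoxelVolume(vals, (1, 1, 1))
    kept = ts.segment(gray, 50.0, largest_component=True)
    assert kept.mask.sum() == 500


def test_segment_recovers_noisy_phantom_fraction(dom64):
    slab, _ = ts.make_slab(0.4, dom64)
    gray = ts.render_grayscale(
        slab, 200, 50, blur_sigma_voxels=1.0, noise_sigma=7.5, seed=11
    )
    seg = ts.segment(gray, 125.0)
    assert seg.solid_fraction == pytest.approx(slab.solid_fraction, abs=0.02)


def test_porosity_extremes_and_half_slab(dom64):
    all_pore = BinaryVolume(np.zeros((4, 4, 4), bool), (1, 1, 1))
    assert ts.porosity(all_pore) == 1.0
    half, _ = ts.make_slab(0.5, dom64)
    assert ts.porosity(half) == pytest.approx(0.5, abs=1 / 64)


def test_gyroid_porosity_is_half(dom64):
    gyro, truth = ts.make_gyroid_block(dom64)
    assert ts.porosity(gyro) == pytest.approx(0.5, abs=0.01)
    assert truth["porosity"] == 0.5


# ---------------------------------------------------------------------------
# local thickness (TT / TS)
# ---------------------------------------------------------------------------

def test_slab_thickness_within_one_voxel(dom64):
    slab, _ = ts.make_slab(0.2, dom64)
    _, tt, sd = ts.local_thickness(slab, "solid")
    assert tt == pytest.approx(0.2, abs=1 / 64)
    assert sd == pytest.approx(0.0, abs=1e-9)


def test_cylinder_thickness_is_diameter(dom64):
    cyl, _ = ts.make_cylinder(0.1, dom64)
    _, tt, _ = ts.local_thickness(cyl, "solid")
    # voxelized rod: largest inscribed sphere diameter = 2R up to ~1.5 voxels
    assert tt == pytest.approx(0.2, abs=1.5 / 64)


def test_slab_array_thickness_and_separation(dom64):
    arr, truth = ts.make_slab_array(0.2, 0.3, dom64)
    _, tt, _ = ts.local_thickness(arr, "solid")
    _, tsep, _ = ts.local_thickness(arr, "pore")
    assert tt == pytest.approx(truth["tt"], abs=1 / 64)
    assert tsep == pytest.approx(truth["ts"], abs=1 / 64)


def test_complement_duality(dom64):
    arr, _ = ts.make_slab_array(0.2, 0.3, dom64)
    _, ts_pore, _ = ts.local_thickness(arr, "pore")
    _, tt_inv, _ = ts.local_thickness(arr.invert(), "solid")
    assert ts_pore == pytest.approx(tt_inv, rel=1e-12)


def test_thickness_scales_with_spacing(dom64):
    slab, _ = ts.make_slab(0.2, dom64)
    scaled = BinaryVolume(
        slab.mask, tuple(3.0 * s for s in slab.spacing), slab.origin
    )
    _, tt1, _ = ts.local_thickness(slab, "solid")
    _, tt3, _ = ts.local_thickness(scaled, "solid")
    assert tt3 == pytest.approx(3.0 * tt1, rel=1e-9)


def test_thickness_requires_isotropic_and_nonempty():
    aniso = BinaryVolume(np.ones((4, 4, 4), bool), (1, 1, 2))
    with pytest.raises(ValueError, match="isotropic"):
        ts.local_thickness(aniso, "solid")
    empty = BinaryVolume(np.zeros((4, 4, 4), bool), (1, 1, 1))
    with pytest.raises(ValueError, match="empty"):
        ts.local_thickness(empty, "solid")


# ---------------------------------------------------------------------------
# surface area density
# ---------------------------------------------------------------------------

def test_slab_sad_counts_only_free_faces(dom64):
    slab, truth = ts.make_slab(0.2, dom64)
    sad_bv, sad_tv = ts.surface_area_density(slab)
    # two free faces, cut faces excluded: S = 2A, BV = t*A -> 2/t
    assert sad_bv == pytest.approx(truth["sad"], rel=0.05)
    # exact identity: S/TV = (S/BV) * solid fraction
    assert sad_tv == pytest.approx(sad_bv * slab.solid_fraction, rel=1e-9)


def test_sphere_sad_is_three_over_radius(dom64):
    sph, truth = ts.make_sphere(0.3, dom64)
    sad_bv, _ = ts.surface_area_density(sph)
    assert sad_bv == pytest.approx(truth["sad"], rel=0.03)


def test_sad_scales_inversely_with_size(dom64):
    sph, _ = ts.make_sphere(0.3, dom64)
    scaled = BinaryVolume(sph.mask, tuple(2.0 * s for s in sph.spacing))
    sad1, _ = ts.surface_area_density(sph)
    sad2, _ = ts.surface_area_density(scaled)
    assert sad2 == pytest.approx(sad1 / 2.0, rel=1e-9)


def test_sad_requires_solid():
    empty = BinaryVolume(np.zeros((8, 8, 8), bool), (1, 1, 1))
    with pytest.raises(ValueError):
        ts.surface_area_density(empty)


# ---------------------------------------------------------------------------
# SMI
# ---------------------------------------------------------------------------

def test_smi_plate_rod_sphere_limits():
    dom = Domain.cube(1.0, 96)
    slab, _ = ts.make_slab(0.2, dom)
    cyl, _ = ts.make_cylinder(0.1, dom)
    sph, _ = ts.make_sphere(0.3, dom)
    assert ts.smi(slab) == pytest.approx(0.0, abs=0.15)
    assert ts.smi(cyl) == pytest.approx(3.0, abs=0.15)
    assert ts.smi(sph) == pytest.approx(4.0, abs=0.15)


def test_smi_scale_invariant(dom64):
    sph, _ = ts.make_sphere(0.3, dom64)
    scaled = BinaryVolume(sph.mask, tuple(5.0 * s for s in sph.spacing))
    assert ts.smi(scaled) == pytest.approx(ts.smi(sph), abs=1e-9)


def test_smi_degenerate_masks_rejected():
    full = BinaryVolume(np.ones((8, 8, 8), bool), (1, 1, 1))
    with pytest.raises(ValueError):
        ts.smi(full)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def test_report_contract_and_io(tmp_path, dom64):
    gyro, _ = ts.make_gyroid_block(dom64)
    rep = ts.analyze(gyro)
    assert rep.porosity + rep.solid_fraction == pytest.approx(1.0)
    assert rep.tt_mean > 0 and rep.ts_mean > 0 and rep.sad > 0
    assert np.isfinite(rep.smi)
    rep.to_json(str(tmp_path / "r.json"))
    rep.to_csv(str(tmp_path / "r.csv"))
    import json

    loaded = json.loads((tmp_path / "r.json").read_text())
    assert loaded["porosity"] == pytest.approx(rep.porosity)
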