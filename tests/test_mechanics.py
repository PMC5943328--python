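"""Material law and voxel finite-element homogenization."""

import numpy as np
import pytest

import tpms_scaffold as ts
from tpms_scaffold.mechanics import (
    LoadCase,
    MaterialField,
    apply_floor,
    density_from_gray,
    homogenize,
    modulus_from_density,
    von_mises,
)
from tpms_scaffold.volumes import VoxelVolume


# ---------------------------------------------------------------------------
# gray -> density -> modulus
# ---------------------------------------------------------------------------

def test_density_affine_map_through_calibration_points():
    gray = VoxelVolume(
        np.array([[[0.0, 127.5, 255.0, 200.0]]]), (1, 1, 1)
    )
    rho = density_from_gray(gray, ((0.0, 0.0), (255.0, 2.0)))
    np.testing.assert_allclose(
        rho.values[0, 0], [0.0, 1.0, 2.0, 200 / 255 * 2], rtol=1e-12
    )


def test_density_negative_extrapolation_clamped():
    gray = VoxelVolume(np.array([[[-50.0]]]), (1, 1, 1))
    with pytest.warns(UserWarning, match="clamped"):
        rho = density_from_gray(gray, ((0.0, 0.0), (255.0, 2.0)))
    assert rho.values[0, 0, 0] == 0.0


def test_identical_calibration_grays_rejected():
    gray = VoxelVolume(np.zeros((2, 2, 2)), (1, 1, 1))
    with pytest.raises(ValueError):
        density_from_gray(gray, ((10.0, 0.0), (10.0, 1.0)))


def test_modulus_power_law_values():
    assert modulus_from_density(1.0) == pytest.approx(6850.0, abs=0.0)
    # independent oracle: log-space evaluation of the high branch
    oracle = np.exp(np.log(4239.0) + 2.39 * np.log(2.0))
    assert modulus_from_density(2.0) == pytest.approx(oracle, rel=1e-12)
    assert modulus_from_density(0.0) == 0.0


def test_modulus_branch_point_uses_low_branch():
    assert modulus_from_density(1.68) == pytest.approx(
        6850.0 * 1.68**1.49, rel=1e-12
    )
    # the printed law is discontinuous there: the high branch would differ
    assert modulus_from_density(1.68) != pytest.approx(
        4239.0 * 1.68**2.39, rel=1e-4
    )


def test_negative_density_rejected():
    with pytest.raises(ValueError):
        modulus_from_density(-0.1)


@pytest.mark.parametrize(
    "e_in, e_out", [(4.9, 0.01), (5.0, 0.01), (6.0, 6.0), (0.0, 0.01)]
)
def test_floor_rule_boundary_inclusive(e_in, e_out):
    assert apply_floor(e_in) == e_out


def test_floor_rule_conserves_counts():
    rng = np.random.default_rng(3)
    e = rng.uniform(0.0, 50.0, (16, 16, 16))
    floored = apply_floor(e)
    assert (floored == 0.01).sum() == (e <= 5.0).sum()
    np.testing.assert_array_equal(floored[e > 5.0], e[e > 5.0])


# ---------------------------------------------------------------------------
# von Mises closed forms
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "stress, expected",
    [
        ([7, 7, 7, 0, 0, 0], 0.0),          # hydrostatic
        ([10, 0, 0, 0, 0, 0], 10.0),        # uniaxial
        ([0, 0, 0, 2, 0, 0], 2 * np.sqrt(3)),  # pure shear
    ],
)
def test_von_mises_closed_forms(stress, expected):
    assert von_mises(stress) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# homogenization
# ---------------------------------------------------------------------------

def _uniform(n, e0, nu, h=0.1):
    return MaterialField(
        np.ones((n, n, n)), np.full((n, n, n), e0), (h, h, h), nu=nu
    )


def test_uniform_block_identity_at_zero_poisson():
    mat = _uniform(16, 123.0, 0.0)
    res = homogenize(mat, LoadCase(direction=0, strain=0.01))
    assert res.e_app == pytest.approx(123.0, rel=1e-3)
    assert res.mean_von_mises == pytest.approx(1.23, rel=1e-3)


def test_series_laminate_harmonic_mean():
    n = 16
    e = np.full((n, n, n), 100.0)
    e[n // 2:] = 300.0
    mat = MaterialField(np.ones((n, n, n)), e, (0.1,) * 3, nu=0.0)
    res = homogenize(mat, LoadCase(direction=0, strain=0.01))
    assert res.e_app == pytest.approx(150.0, rel=0.01)


def test_linearity_in_modulus():
    # all voxels above the floor so doubling leaves the structural mask alone
    rng = np.random.default_rng(7)
    e = rng.uniform(10.0, 200.0, (8, 8, 8))
    m1 = MaterialField(np.ones((8, 8, 8)), e, (0.1,) * 3, nu=0.3)
    m2 = MaterialField(np.ones((8, 8, 8)), 2 * e, (0.1,) * 3, nu=0.3)
    r1 = homogenize(m1, LoadCase(0), tol=1e-10)
    r2 = homogenize(m2, LoadCase(0), tol=1e-10)
    assert r2.e_app == pytest.approx(2 * r1.e_app, rel=1e-4)
    assert r2.mean_von_mises == pytest.approx(2 * r1.mean_von_mises, rel=1e-4)


def test_removing_material_never_stiffens():
    spec = ts.preset("G", cell_size=1.0)
    dom = ts.Domain.cube(1.0, 12)
    vals = ts.sample_grid(spec, dom).values
    e_apps = []
    for level in (0.6, 0.2, -0.2):  # nested solids, shrinking
        mask = vals <= level
        e = np.where(mask, 1000.0, 0.01)
        mat = MaterialField(mask.astype(float), e, tuple(dom.spacing), nu=0.3)
        e_apps.append(homogenize(mat, LoadCase(0)).e_app)
    assert e_apps[0] >= e_apps[1] >= e_apps[2]


def test_cubic_symmetry_direction_independence():
    spec = ts.preset("P", cell_size=1.0).with_level(0.4)
    dom = ts.Domain.cube(1.0, 12)
    mask = ts.sample_grid(spec, dom).values <= 0.4
    e = np.where(mask, 5000.0, 0.01)
    mat = MaterialField(mask.astype(float), e, tuple(dom.spacing), nu=0.3)
    e_apps = [
        homogenize(mat, LoadCase(direction=d), tol=1e-9).e_app for d in range(3)
    ]
    assert max(e_apps) == pytest.approx(min(e_apps), rel=1e-3)


def test_von_mises_uniform_state_matches_strain():
    mat = _uniform(8, 200.0, 0.0)
    res = homogenize(mat, LoadCase(direction=2, strain=0.01), keep_von_mises=True)
    assert res.von_mises.shape == (8, 8, 8)
    np.testing.assert_allclose(res.von_mises, 2.0, rtol=1e-6)


def test_clamped_loaded_face_stiffer_than_free():
    mat = _uniform(12, 100.0, 0.45)
    free = homogenize(mat, LoadCase(direction=0))
    clamped = homogenize(mat, LoadCase(direction=0, clamp_loaded=True))
    assert clamped.e_app > free.e_app


def test_invalid_load_and_material_rejected():
    with pytest.raises(ValueError):
        LoadCase(direction=3)
    with pytest.raises(ValueError):
        LoadCase(strain=0.5)
    with pytest.raises(ValueError, match="floor"):
        MaterialField(np.ones((4, 4, 4)), np.zeros((4, 4, 4)), (1, 1, 1))
    aniso = MaterialField(
        np.ones((4, 4, 4)), np.ones((4, 4, 4)), (1, 1, 2)
    )
    with pytest.raises(ValueError, match="isotropic"):
        homogenize(aniso, LoadCase(0))
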