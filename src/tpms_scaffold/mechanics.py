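"""Image-based material mapping and voxel finite-element homogenization.

Material model
--------------
Micro-CT gray values map linearly to apparent density (two-point
calibration); density maps to elastic modulus through the trabecular-bone
power law

    E = 6850 * rho^1.49 MPa   for rho <= 1.68 g/cm^3
    E = 4239 * rho^2.39 MPa   for rho >  1.68 g/cm^3,

after which every voxel at or below 5 MPa is floored to 0.01 MPa — a
near-air stiffness that keeps the global stiffness matrix positive
definite while contributing negligible load path.  Poisson's ratio is a
single shared value, 0.3 by default.

Homogenization
--------------
The volume is meshed one trilinear hexahedral element per voxel.  For a
loading direction d the face at min-d is fully clamped; the face at max-d
receives a uniform compressive normal displacement of ``strain * span``
(tangentially free by default, clamped with ``clamp_loaded=True``); the
lateral faces are traction-free.  The linear system is solved matrix-free
with Jacobi-preconditioned conjugate gradients.  The apparent modulus is
(reaction force / apparent cross-section area) / strain, and the von Mises
stress is evaluated from the element-centroid stress tensor and averaged
over structural voxels (those above the 0.01 MPa floor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .volumes import VoxelVolume

__all__ = [
    "MaterialField",
    "LoadCase",
    "HomogenizationResult",
    "density_from_gray",
    "modulus_from_density",
    "apply_floor",
    "material_from_density",
    "material_from_gray",
    "homogenize",
    "von_mises",
    "MODULUS_FLOOR_MPA",
    "MODULUS_FLOOR_THRESHOLD_MPA",
    "DENSITY_BRANCH_POINT",
]

MODULUS_FLOOR_MPA = 0.01
MODULUS_FLOOR_THRESHOLD_MPA = 5.0
DENSITY_BRANCH_POINT = 1.68  # g/cm^3


# ---------------------------------------------------------------------------
# material mapping
# ---------------------------------------------------------------------------

def density_from_gray(
    gray: VoxelVolume,
    calibration: tuple[tuple[float, float], tuple[float, float]],
) -> VoxelVolume:
    """Affine gray -> density (g/cm^3) through two (gray, density) points.

    Negative extrapolations are clamped to zero with a warning.
    """
    (g1, d1), (g2, d2) = calibration
    if g1 == g2:
        raise ValueError("calibration gray values must differ")
    slope = (d2 - d1) / (g2 - g1)
    rho = d1 + slope * (gray.values - g1)
    if np.any(rho < 0):
        warnings.warn("negative densities clamped to 0", stacklevel=2)
        rho = np.clip(rho, 0.0, None)
    return VoxelVolume(rho, gray.spacing, gray.origin)


def modulus_from_density(rho):
    """Piecewise power law E(rho) in MPa; the branch point uses the low branch.

    Note the two branches do not meet at rho = 1.68 (about 14.8 vs 14.7 GPa)
    — the law is applied exactly as calibrated, discontinuity included.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("density must be non-negative")
    out = np.where(
        rho <= DENSITY_BRANCH_POINT,
        6850.0 * rho**1.49,
        4239.0 * rho**2.39,
    )
    return out if out.ndim else float(out)


def apply_floor(modulus):
    """Set every voxel with E <= 5 MPa to exactly 0.01 MPa (near-air)."""
    e = np.asarray(modulus, dtype=float)
    out = np.where(e <= MODULUS_FLOOR_THRESHOLD_MPA, MODULUS_FLOOR_MPA, e)
    return out if out.ndim else float(out)


@dataclass
class MaterialField:
    """Per-voxel density and (floored) modulus with a shared Poisson ratio."""

    density: np.ndarray   # g/cm^3
    modulus: np.ndarray   # MPa, floor already applied
    spacing: tuple[float, float, float]  # mm
    nu: float = 0.3

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, float)
        self.modulus = np.asarray(self.modulus, float)
        if self.density.shape != self.modulus.shape or self.density.ndim != 3:
            raise ValueError("density and modulus must be matching 3D arrays")
        if np.any(self.modulus <= 0):
            raise ValueError("modulus must be positive everywhere (apply the floor)")
        if not (0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape

    @property
    def structural_mask(self) -> np.ndarray:
        """Voxels above the near-air floor — the load-bearing phase."""
        return self.modulus > MODULUS_FLOOR_MPA


def material_from_density(
    density: np.ndarray, spacing, nu: float = 0.3
) -> MaterialField:
    """Density volume -> material field via the power law + floor rule."""
    e = apply_floor(modulus_from_density(density))
    return MaterialField(np.asarray(density, float), e, tuple(spacing), nu)


def material_from_gray(
    gray: VoxelVolume,
    calibration: tuple[tuple[float, float], tuple[float, float]],
    nu: float = 0.3,
) -> MaterialField:
    rho = density_from_gray(gray, calibration)
    return material_from_density(rho.values, gray.spacing, nu)


@dataclass(frozen=True)
class LoadCase:
    """Uniaxial compression along one axis at a prescribed strain."""

    direction: int = 0            # 0, 1 or 2 (paper's directions 1, 2, 3)
    strain: float = 0.01          # compressive, dimensionless
    clamp_loaded: bool = False    # also fix tangential dofs on the loaded face

    def __post_init__(self) -> None:
        if self.direction not in (0, 1, 2):
            raise ValueError("direction must be 0, 1 or 2")
        if not (0.0 < self.strain < 0.1):
            raise ValueError("strain must lie in (0, 0.1)")


@dataclass
class HomogenizationResult:
    direction: int
    e_app: float            # apparent modulus, MPa
    mean_von_mises: float   # over structural voxels, MPa
    reaction_force: float   # N
    strain: float
    iterations: int
    residual: float
    von_mises: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# trilinear hexahedral element
# ---------------------------------------------------------------------------

# local node order = binary (dx, dy, dz) offsets
_LOCAL_NODES = np.array(
    [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
     (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)],
    dtype=int,
)


def _elastic_matrix(nu: float) -> np.ndarray:
    """6x6 isotropic stiffness for E = 1, engineering shear strains."""
    lam = nu / ((1 + nu) * (1 - 2 * nu))
    mu = 1.0 / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = lam + 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def _shape_gradients(xi: np.ndarray, h: float) -> np.ndarray:
    """(8, 3) physical shape-function gradients at local point xi in [-1,1]^3."""
    signs = 2 * _LOCAL_NODES - 1  # (8,3) of +-1
    grads = np.empty((8, 3))
    for a in range(8):
        s = signs[a]
        for i in range(3):
            g = s[i] / 8.0
            for j in range(3):
                if j != i:
                    g *= 1 + s[j] * xi[j]
            grads[a, i] = g * (2.0 / h)  # d(xi)/dx = 2/h
    return grads


def _b_matrix(xi: np.ndarray, h: float) -> np.ndarray:
    """(6, 24) strain-displacement matrix at a local point."""
    dN = _shape_gradients(xi, h)
    B = np.zeros((6, 24))
    for a in range(8):
        c = 3 * a
        B[0, c + 0] = dN[a, 0]
        B[1, c + 1] = dN[a, 1]
        B[2, c + 2] = dN[a, 2]
        B[3, c + 0] = dN[a, 1]; B[3, c + 1] = dN[a, 0]
        B[4, c + 1] = dN[a, 2]; B[4, c + 2] = dN[a, 1]
        B[5, c + 0] = dN[a, 2]; B[5, c + 2] = dN[a, 0]
    return B


def hex_stiffness(nu: float, h: float) -> np.ndarray:
    """(24, 24) element stiffness for a cube of edge h and unit modulus."""
    C = _elastic_matrix(nu)
    g = 1.0 / np.sqrt(3.0)
    detJ = (h / 2.0) ** 3
    KE = np.zeros((24, 24))
    for sx in (-g, g):
        for sy in (-g, g):
            for sz in (-g, g):
                B = _b_matrix(np.array([sx, sy, sz]), h)
                KE += B.T @ C @ B * detJ
    return KE


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _element_dofs(shape: tuple[int, int, int]) -> np.ndarray:
    """(n_elem, 24) global dof indices, x-major node numbering."""
    nx, ny, nz = shape
    nyn, nzn = ny + 1, nz + 1
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    base = (ii * nyn + jj) * nzn + kk  # node (i, j, k)
    nodes = np.empty((nx * ny * nz, 8), dtype=np.int64)
    for a, (dx, dy, dz) in enumerate(_LOCAL_NODES):
        nodes[:, a] = (((ii + dx) * nyn + (jj + dy)) * nzn + (kk + dz)).ravel()
    dofs = (3 * nodes[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    return dofs


def homogenize(
    material: MaterialField,
    load: LoadCase,
    tol: float = 1e-8,
    maxiter: int | None = None,
    keep_von_mises: bool = False,
) -> HomogenizationResult:
    """Apparent modulus and von Mises summary for one loading direction."""
    shape = material.shape
    if any(n < 2 for n in shape):
        raise ValueError("need at least 2 voxels per axis")
    if not np.allclose(material.spacing, material.spacing[0], rtol=1e-9):
        raise ValueError("homogenization requires isotropic voxels")
    h = material.spacing[0]
    nu = material.nu
    d = load.direction

    KE = hex_stiffness(nu, h)
    edof = _element_dofs(shape)
    Ee = material.modulus.ravel()
    n_nodes = (shape[0] + 1) * (shape[1] + 1) * (shape[2] + 1)
    ndof = 3 * n_nodes

    # node index grids for BC selection
    gx, gy, gz = np.meshgrid(
        np.arange(shape[0] + 1), np.arange(shape[1] + 1), np.arange(shape[2] + 1),
        indexing="ij",
    )
    node_idx_d = (gx, gy, gz)[d].ravel()
    fixed_nodes = node_idx_d == 0
    loaded_nodes = node_idx_d == shape[d]

    span = shape[d] * h
    u_load = -load.strain * span  # compression toward the fixed face

    prescribed = np.zeros(ndof, dtype=bool)
    u = np.zeros(ndof)
    for comp in range(3):
        dof_ids = 3 * np.flatnonzero(fixed_nodes) + comp
        prescribed[dof_ids] = True  # u = 0
    comp_ids = 3 * np.flatnonzero(loaded_nodes) + d
    prescribed[comp_ids] = True
    u[comp_ids] = u_load
    if load.clamp_loaded:
        for comp in range(3):
            if comp != d:
                ids = 3 * np.flatnonzero(loaded_nodes) + comp
                prescribed[ids] = True  # tangential u = 0
    free = ~prescribed
    n_free = int(free.sum())

    flat = edof.ravel()

    def K_mul(vec_full: np.ndarray) -> np.ndarray:
        ue = vec_full[edof]
        fe = (ue @ KE) * Ee[:, None]
        return np.bincount(flat, weights=fe.ravel(), minlength=ndof)

    # Jacobi preconditioner from the assembled diagonal
    diagKE = np.diag(KE)
    diag = np.bincount(
        flat, weights=(Ee[:, None] * diagKE[None, :]).ravel(), minlength=ndof
    )
    inv_diag_free = 1.0 / diag[free]

    rhs = -K_mul(u)[free]

    it_count = 0

    def matvec(vf: np.ndarray) -> np.ndarray:
        full = np.zeros(ndof)
        full[free] = vf
        return K_mul(full)[free]

    def cb(_):
        nonlocal it_count
        it_count += 1

    A = LinearOperator((n_free, n_free), matvec=matvec)
    M = LinearOperator((n_free, n_free), matvec=lambda v: inv_diag_free * v)
    if maxiter is None:
        maxiter = int(100 * 20 * round(np.prod(shape) ** (1 / 3)))
    uf, info = cg(A, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M, callback=cb)
    if info > 0:
        res = np.linalg.norm(matvec(uf) - rhs) / max(np.linalg.norm(rhs), 1e-300)
        raise RuntimeError(
            f"CG did not converge in {maxiter} iterations "
            f"(relative residual {res:.3e})"
        )
    u[free] = uf
    residual = float(
        np.linalg.norm(matvec(uf) - rhs) / max(np.linalg.norm(rhs), 1e-300)
    )

    # reaction on the loaded face (normal component)
    f_int = K_mul(u)
    reaction = float(f_int[comp_ids].sum())
    lateral = [ax for ax in range(3) if ax != d]
    area = (shape[lateral[0]] * h) * (shape[lateral[1]] * h)  # mm^2, apparent
    force = abs(reaction)  # N (MPa * mm^2)
    e_app = (force / area) / load.strain

    vm = von_mises_from_solution(u, edof, Ee, nu, h, shape)
    struct = material.structural_mask.ravel()
    mean_vm = float(vm.ravel()[struct].mean()) if struct.any() else 0.0

    return HomogenizationResult(
        direction=d,
        e_app=e_app,
        mean_von_mises=mean_vm,
        reaction_force=force,
        strain=load.strain,
        iterations=it_count,
        residual=residual,
        von_mises=vm if keep_von_mises else None,
    )


def von_mises_from_solution(u, edof, Ee, nu, h, shape) -> np.ndarray:
    """Per-element von Mises stress from the centroid stress tensor (MPa)."""
    Bc = _b_matrix(np.zeros(3), h)
    C = _elastic_matrix(nu)
    strain = u[edof] @ Bc.T            # (n_elem, 6)
    stress = (strain @ C.T) * Ee[:, None]
    return von_mises(stress).reshape(shape)


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises scalar from Voigt stress [sxx, syy, szz, sxy, syz, szx]."""
    s = np.asarray(stress, float)
    sxx, syy, szz = s[..., 0], s[..., 1], s[..., 2]
    sxy, syz, szx = s[..., 3], s[..., 4], s[..., 5]
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )
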