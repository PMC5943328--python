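"""Analytic test geometries and synthetic micro-CT-like volumes.

Every phantom is voxelized by center-inclusion (a voxel is solid iff its
center lies inside the analytic shape), so the returned ground-truth
record is exact at any resolution; imaging realism (blur, noise) is layered
on separately by :func:`render_grayscale`.  These volumes stand in for
micro-CT scans when exercising the morphometry, mechanics and tuning
modules end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .blending import TransitionSpec, default_steepness, multi_blend
from .fields import ImplicitField, preset, sample_grid
from .volumes import BinaryVolume, Domain, VoxelVolume

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_slab",
    "make_slab_array",
    "make_cylinder",
    "make_sphere",
    "make_gyroid_block",
    "render_grayscale",
    "make_gradient_demo",
]

PHANTOM_KINDS = (
    "slab", "slab_array", "cylinder", "sphere", "gyroid_block", "gradient_demo"
)


@dataclass(frozen=True)
class PhantomSpec:
    kind: str
    domain: Domain
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(
                f"unknown phantom kind {self.kind!r}; valid: {PHANTOM_KINDS}"
            )


def make_phantom(spec: PhantomSpec) -> tuple[BinaryVolume, dict]:
    """Dispatch to the kind-specific generator; returns (volume, truth)."""
    fns = {
        "slab": make_slab,
        "slab_array": make_slab_array,
        "cylinder": make_cylinder,
        "sphere": make_sphere,
        "gyroid_block": make_gyroid_block,
    }
    if spec.kind == "gradient_demo":
        raise ValueError("use make_gradient_demo for the gradient demo artifact")
    return fns[spec.kind](domain=spec.domain, **spec.params)


def _coords(domain: Domain):
    ax, ay, az = domain.axes()
    return ax[:, None, None], ay[None, :, None], az[None, None, :]


def _box_extent(domain: Domain) -> np.ndarray:
    return np.asarray(domain.upper, float) - np.asarray(domain.lower, float)


def make_slab(thickness: float, domain: Domain, axis: int = 2) -> tuple[BinaryVolume, dict]:
    """A plate spanning the box, centered along ``axis``.  Ideal SMI 0."""
    ext = _box_extent(domain)
    if not (0 < thickness < ext[axis]):
        raise ValueError("slab thickness must fit inside the domain")
    center = 0.5 * (domain.lower[axis] + domain.upper[axis])
    c = _coords(domain)[axis]
    mask = np.abs(c - center) <= thickness / 2.0
    mask = np.broadcast_to(mask, domain.resolution).copy()
    vol = BinaryVolume(mask, tuple(domain.spacing), tuple(domain.origin))
    truth = {
        "porosity": 1.0 - thickness / ext[axis],
        "tt": thickness,
        "sad": 2.0 / thickness,
        "smi": 0.0,
    }
    return vol, truth


def make_slab_array(
    thickness: float, gap: float, domain: Domain, axis: int = 2
) -> tuple[BinaryVolume, dict]:
    """Periodic parallel plates (thickness t, gap g) along ``axis``.

    Ideal TT = t and TS = g; porosity = g/(t+g) when the box holds an
    integer number of periods.
    """
    if thickness <= 0 or gap <= 0:
        raise ValueError("thickness and gap must be positive")
    period = thickness + gap
    c = _coords(domain)[axis] - domain.lower[axis]
    phase = np.mod(c + thickness / 2.0, period)
    mask = phase <= thickness
    mask = np.broadcast_to(mask, domain.resolution).copy()
    vol = BinaryVolume(mask, tuple(domain.spacing), tuple(domain.origin))
    truth = {
        "porosity": gap / period,
        "tt": thickness,
        "ts": gap,
        "smi": 0.0,
    }
    return vol, truth


def make_cylinder(
    radius: float, domain: Domain, axis: int = 2
) -> tuple[BinaryVolume, dict]:
    """A rod spanning the box along ``axis``, centered.  Ideal SMI 3."""
    ext = _box_extent(domain)
    lateral = [i for i in range(3) if i != axis]
    if not all(2 * radius < ext[i] for i in lateral):
        raise ValueError("cylinder must fit inside the domain cross-section")
    cs = _coords(domain)
    centers = [0.5 * (domain.lower[i] + domain.upper[i]) for i in range(3)]
    r2 = sum((cs[i] - centers[i]) ** 2 for i in lateral)
    mask = np.broadcast_to(r2 <= radius**2, domain.resolution).copy()
    vol = BinaryVolume(mask, tuple(domain.spacing), tuple(domain.origin))
    area = ext[lateral[0]] * ext[lateral[1]]
    truth = {
        "porosity": 1.0 - np.pi * radius**2 / area,
        "tt": 2.0 * radius,
        "sad": 2.0 / radius,
        "smi": 3.0,
    }
    return vol, truth


def make_sphere(radius: float, domain: Domain) -> tuple[BinaryVolume, dict]:
    """A fully interior ball, centered.  Ideal SAD 3/R, SMI 4."""
    ext = _box_extent(domain)
    if not np.all(2 * radius < ext):
        raise ValueError("sphere must fit strictly inside the domain")
    cs = _coords(domain)
    centers = [0.5 * (domain.lower[i] + domain.upper[i]) for i in range(3)]
    r2 = sum((cs[i] - centers[i]) ** 2 for i in range(3))
    mask = r2 <= radius**2
    vol = BinaryVolume(mask, tuple(domain.spacing), tuple(domain.origin))
    truth = {
        "porosity": 1.0 - (4.0 / 3.0) * np.pi * radius**3 / np.prod(ext),
        "tt": 2.0 * radius,
        "sad": 3.0 / radius,
        "smi": 4.0,
    }
    return vol, truth


def make_gyroid_block(
    domain: Domain, level: float = 0.0, cell_size: float | None = None
) -> tuple[BinaryVolume, dict]:
    """Voxelized gyroid (G preset); at level 0 the two labyrinths are equal."""
    if cell_size is None:
        cell_size = float(_box_extent(domain)[0])
    g = preset("G", cell_size=cell_size).with_level(level)
    vol = sample_grid(g, domain).binarize(level)
    truth = {"porosity": 0.5 if level == 0.0 else None}
    return vol, truth


def render_grayscale(
    bin_vol: BinaryVolume,
    foreground: float = 200.0,
    background: float = 50.0,
    blur_sigma_voxels: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> VoxelVolume:
    """Synthetic CT-like rendering: gray assignment + blur + Gaussian noise.

    Deterministic for a fixed seed.  With zero blur and noise the mask is
    exactly recoverable by thresholding at the gray midpoint.
    """
    if blur_sigma_voxels < 0 or noise_sigma < 0:
        raise ValueError("blur and noise sigmas must be non-negative")
    gray = np.where(bin_vol.mask, float(foreground), float(background))
    if blur_sigma_voxels > 0:
        gray = ndimage.gaussian_filter(gray, blur_sigma_voxels)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        gray = gray + rng.normal(0.0, noise_sigma, gray.shape)
    return VoxelVolume(gray, bin_vol.spacing, bin_vol.origin)


def make_gradient_demo(
    resolution: int = 64,
    cell_size: float = 4.0,
    n_cells: int = 3,
    outer: str = "TGab",
    inner: str = "TGc",
    k: float | None = None,
    transition: str = "plane",
) -> dict:
    """End-to-end graded scaffold: outer unit | inner unit | outer unit.

    Stacks ``n_cells`` unit cells along x and fuses the inner unit into the
    middle third through two plane transitions (or a single spherical
    transition with ``transition='sphere'``).  Returns the composite field,
    the sampled volume, the binary solid and a watertight mesh, ready for
    morphometry or STL export.
    """
    from .meshing import cap_boundary

    if k is None:
        k = default_steepness(cell_size)
    length = n_cells * cell_size
    domain = Domain(
        (0.0, 0.0, 0.0), (length, cell_size, cell_size),
        (n_cells * resolution, resolution, resolution),
    )
    f_outer = preset(outer, cell_size=cell_size)
    f_inner = preset(inner, cell_size=cell_size)
    if transition == "plane":
        # a fused unit is active where its G < 0, so G = x0 - x switches to
        # the new unit for x > x0: inner past length/3, outer again past 2/3
        t1 = TransitionSpec.plane((-1.0, 0.0, 0.0), -length / 3.0, k)
        t2 = TransitionSpec.plane((-1.0, 0.0, 0.0), -2.0 * length / 3.0, k)
        composite = multi_blend([(f_outer, None), (f_inner, t1), (f_outer, t2)])
    elif transition == "sphere":
        center = (length / 2.0, cell_size / 2.0, cell_size / 2.0)
        t1 = TransitionSpec.sphere(center, cell_size / 2.0, k)
        composite = multi_blend([(f_outer, None), (f_inner, t1)])
    else:
        raise ValueError("transition must be 'plane' or 'sphere'")
    volume = sample_grid(composite, domain)
    solid = volume.binarize(composite.level)
    mesh = cap_boundary(volume, composite.level)
    return {
        "field": composite,
        "domain": domain,
        "volume": volume,
        "solid": solid,
        "mesh": mesh,
    }
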