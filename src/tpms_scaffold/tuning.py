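"""Calibrate TPMS structural parameters against porosity or stiffness targets.

The level constant (or an amplitude scale on the oscillatory terms) is the
free parameter; both porosity and apparent modulus respond monotonically to
it over sensible brackets, so plain bisection is used — each modulus
evaluation runs a full voxel FE solve, which is noise-free but expensive
and discretization-stepped, conditions under which bracketing beats
gradient methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fields import FieldSpec, sample_grid
from .mechanics import (
    LoadCase,
    MaterialField,
    apply_floor,
    homogenize,
    modulus_from_density,
)
from .volumes import Domain

__all__ = [
    "TuningResult",
    "fit_level_to_porosity",
    "fit_to_modulus",
    "scaffold_material",
]


@dataclass
class TuningResult:
    parameter: str
    value: float
    achieved: float
    target: float
    iterations: int
    history: list[tuple[float, float]] = field(default_factory=list, repr=False)


def fit_level_to_porosity(
    spec: FieldSpec,
    target: float,
    domain: Domain,
    bounds: tuple[float, float] | None = None,
    tolerance: float = 0.005,
    max_iter: int = 100,
) -> TuningResult:
    """Bisect the level constant until voxel porosity matches ``target``.

    Porosity = fraction of voxels with phi > level is non-increasing in the
    level, so any bracket whose endpoint porosities straddle the target
    converges.  Default bounds span the sampled field range.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target porosity must lie in (0, 1)")
    values = sample_grid(spec, domain).values

    def porosity_at(level: float) -> float:
        return float((values > level).mean())

    if bounds is None:
        bounds = (float(values.min()) - 1e-9, float(values.max()) + 1e-9)
    lo, hi = sorted(bounds)
    p_lo, p_hi = porosity_at(lo), porosity_at(hi)
    # porosity decreases with level: p(lo) >= p(hi)
    if not (p_hi - tolerance <= target <= p_lo + tolerance):
        raise ValueError(
            f"target porosity {target} not bracketed by bounds "
            f"({lo}: {p_lo:.3f}, {hi}: {p_hi:.3f}); widen the bounds"
        )
    history = []
    level, achieved = lo, p_lo
    for it in range(1, max_iter + 1):
        level = 0.5 * (lo + hi)
        achieved = porosity_at(level)
        history.append((level, achieved))
        if abs(achieved - target) <= tolerance:
            break
        if achieved > target:  # too porous -> raise level (more solid)
            lo = level
        else:
            hi = level
    return TuningResult("level", level, achieved, target, len(history), history)


def scaffold_material(
    spec: FieldSpec,
    domain: Domain,
    solid_density: float = 1.0,
    nu: float = 0.3,
) -> MaterialField:
    """Binarize a field and map solid voxels to bone-law modulus.

    Solid voxels get the modulus of ``solid_density`` (g/cm^3) through the
    density power law; pore voxels fall to the 0.01 MPa near-air floor.
    """
    mask = sample_grid(spec, domain).values <= spec.level
    rho = np.where(mask, solid_density, 0.0)
    e = apply_floor(modulus_from_density(rho))
    return MaterialField(rho, e, tuple(domain.spacing), nu)


def _apply_parameter(spec: FieldSpec, parameter: str, value: float) -> FieldSpec:
    if parameter == "level":
        return spec.with_level(value)
    if parameter == "amplitude_scale":
        return spec.scale_amplitudes(value)
    raise ValueError("free parameter must be 'level' or 'amplitude_scale'")


def fit_to_modulus(
    spec: FieldSpec,
    target: float,
    direction: int = 0,
    parameter: str = "level",
    bounds: tuple[float, float] = (-1.0, 1.0),
    tolerance: float = 0.02,
    resolution: int = 32,
    verify_resolution: int | None = None,
    solid_density: float = 1.0,
    nu: float = 0.3,
    strain: float = 0.01,
    max_iter: int = 60,
    grid_points: int = 9,
) -> TuningResult:
    """Drive the homogenized apparent modulus to ``target`` (relative tol).

    Searches by bisection at ``resolution``^3 over one unit cell; if the
    bracket endpoints do not straddle the target, a coarse grid scan looks
    for a straddling sub-interval first (with a warning).  An optional
    final evaluation at ``verify_resolution`` reports the achieved modulus
    on a finer grid.
    """
    if target <= 0:
        raise ValueError("target modulus must be positive")
    load = LoadCase(direction=direction, strain=strain)

    def e_app_at(value: float, res: int) -> float:
        s = _apply_parameter(spec, parameter, value)
        domain = Domain.cube(s.cell_size, res)
        mat = scaffold_material(s, domain, solid_density, nu)
        return homogenize(mat, load).e_app

    history: list[tuple[float, float]] = []

    def f(value: float) -> float:
        e = e_app_at(value, resolution)
        history.append((value, e))
        return e - target

    lo, hi = sorted(bounds)
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0 or f_hi == 0:
        value = lo if f_lo == 0 else hi
    elif f_lo * f_hi > 0:
        warnings.warn(
            "bracket endpoints do not straddle the target modulus; "
            "falling back to a grid scan",
            stacklevel=2,
        )
        grid = np.linspace(lo, hi, grid_points)
        fg = [f(v) for v in grid[1:-1]]
        fg = [f_lo] + fg + [f_hi]
        sign_change = [
            i for i in range(len(grid) - 1) if fg[i] * fg[i + 1] <= 0
        ]
        if not sign_change:
            raise ValueError(
                "no sign change found in the search interval; the target "
                "modulus is unreachable with these bounds"
            )
        i = sign_change[0]
        lo, hi, f_lo, f_hi = grid[i], grid[i + 1], fg[i], fg[i + 1]
        value = 0.5 * (lo + hi)
    else:
        value = 0.5 * (lo + hi)

    achieved = None
    for _ in range(max_iter):
        value = 0.5 * (lo + hi)
        fv = f(value)
        achieved = fv + target
        if abs(fv) <= tolerance * target:
            break
        if (fv < 0) == (f_lo < 0):
            lo, f_lo = value, fv
        else:
            hi, f_hi = value, fv
    if achieved is None:  # pragma: no cover - max_iter >= 1 always evaluates
        achieved = e_app_at(value, resolution)
    if verify_resolution is not None and verify_resolution != resolution:
        achieved = e_app_at(value, verify_resolution)
        history.append((value, achieved))
    return TuningResult(parameter, value, achieved, target, len(history), history)
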