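"""Nodal (trigonometric) TPMS implicit fields.

A triply periodic minimal surface is approximated here by its nodal form: a
short sum of products of sines and cosines,

    phi(r) = sum_k A_k * f_x(2*pi*n_x*x/L + p_x) * f_y(...) * f_z(...),

where each factor f is ``sin``, ``cos`` or the constant 1, n are integer
frequency multipliers and L is the physical unit-cell edge (``cell_size``,
mm).  The scaffold surface is the level set {phi = level} and the solid
phase is {phi <= level}: raising the level adds material for the P-like
presets.  Presets cover the classic P, D and G (gyroid) cells plus the two
tubular-gyroid bone units TGab and TGc, which add second-harmonic
cosine-product terms and a negative constant offset to the gyroid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .volumes import Domain, VoxelVolume

__all__ = [
    "AxisFactor",
    "TrigTerm",
    "FieldSpec",
    "ImplicitField",
    "eval_field",
    "preset",
    "PRESET_NAMES",
    "sample_grid",
    "solid_fraction",
    "field_to_dict",
    "field_from_dict",
    "save_field",
    "load_field",
    "MAX_SAMPLE_VOXELS",
]

#: Guard against runaway grid allocations in sample_grid (overridable per call).
MAX_SAMPLE_VOXELS = 2**27  # 512^3

_FACTORS = ("sin", "cos", "unity")


@dataclass(frozen=True)
class AxisFactor:
    """One axis factor of a trigonometric product term."""

    fn: str = "unity"  # 'sin' | 'cos' | 'unity'
    freq: int = 1      # integer frequency multiplier (cycles per cell)
    phase: float = 0.0  # radians

    def __post_init__(self) -> None:
        if self.fn not in _FACTORS:
            raise ValueError(f"unknown factor {self.fn!r}; use one of {_FACTORS}")
        if self.fn != "unity" and (int(self.freq) != self.freq or self.freq < 0):
            raise ValueError("frequency multiplier must be a non-negative integer")

    def __call__(self, angle: np.ndarray) -> np.ndarray:
        if self.fn == "unity":
            return np.ones_like(angle)
        f = np.sin if self.fn == "sin" else np.cos
        return f(self.freq * angle + self.phase)


@dataclass(frozen=True)
class TrigTerm:
    """amplitude * f_x(X) * f_y(Y) * f_z(Z); all-unity factors give a constant."""

    amplitude: float
    factors: tuple[AxisFactor, AxisFactor, AxisFactor]

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if len(self.factors) != 3:
            raise ValueError("a term needs exactly three axis factors")

    @property
    def is_constant(self) -> bool:
        return all(f.fn == "unity" for f in self.factors)


class ImplicitField:
    """Minimal interface for anything sample-able as a scalar field.

    Subclasses implement ``__call__(points) -> values`` on (..., 3) mm
    coordinates and expose ``level`` (the iso-value of the surface) and a
    representative ``cell_size`` used for default transition steepness.
    """

    level: float = 0.0
    cell_size: float = 1.0

    def __call__(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class FieldSpec(ImplicitField):
    """A nodal TPMS field: trigonometric terms + iso-level + physical cell size."""

    terms: tuple[TrigTerm, ...]
    level: float = 0.0
    cell_size: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.terms = tuple(self.terms)
        if not self.terms:
            raise ValueError("a FieldSpec needs at least one term")
        if not (np.isfinite(self.cell_size) and self.cell_size > 0):
            raise ValueError("cell_size must be a positive length in mm")
        if not np.isfinite(self.level):
            raise ValueError("level must be finite")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return eval_field(self, points)

    def with_level(self, level: float) -> "FieldSpec":
        return FieldSpec(self.terms, level, self.cell_size, self.name)

    def scale_amplitudes(self, factor: float) -> "FieldSpec":
        """Scale the non-constant term amplitudes.

        The constant terms are left untouched: scaling *every* amplitude
        would leave the {phi <= level} solid unchanged whenever level folds
        into a constant term, so only the oscillatory part is a useful free
        parameter.
        """
        new = tuple(
            t if t.is_constant else TrigTerm(t.amplitude * factor, t.factors)
            for t in self.terms
        )
        return FieldSpec(new, self.level, self.cell_size, self.name)

    @property
    def constant_part(self) -> float:
        """Sum of pure-constant term amplitudes (e.g. -4 for TGab, -12 for TGc)."""
        return float(sum(t.amplitude for t in self.terms if t.is_constant))


def eval_field(spec: FieldSpec, points: np.ndarray) -> np.ndarray:
    """Evaluate the trigonometric sum at physical points (mm).

    Coordinates are mapped to angles as ``2*pi * point / cell_size`` so one
    period spans exactly one cell edge on every axis; the level constant is
    *not* subtracted — the surface is the set {value = level}.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[-1] != 3:
        raise ValueError("points must have shape (..., 3)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    ang = (2.0 * np.pi / spec.cell_size) * pts
    out = np.zeros(pts.shape[:-1])
    for term in spec.terms:
        prod = np.full(pts.shape[:-1], term.amplitude)
        for axis, fac in enumerate(term.factors):
            if fac.fn != "unity":
                prod = prod * fac(ang[..., axis])
        out += prod
    return out


def _t(amplitude, fx=None, fy=None, fz=None):
    def mk(f):
        if f is None:
            return AxisFactor("unity")
        fn, freq = f
        return AxisFactor(fn, freq)

    return TrigTerm(amplitude, (mk(fx), mk(fy), mk(fz)))


def _preset_P() -> tuple[TrigTerm, ...]:
    # cos X + cos Y + cos Z
    return (
        _t(1.0, ("cos", 1), None, None),
        _t(1.0, None, ("cos", 1), None),
        _t(1.0, None, None, ("cos", 1)),
    )


def _preset_D() -> tuple[TrigTerm, ...]:
    # cos X cos Y cos Z - sin X sin Y sin Z
    return (
        _t(1.0, ("cos", 1), ("cos", 1), ("cos", 1)),
        _t(-1.0, ("sin", 1), ("sin", 1), ("sin", 1)),
    )


def _preset_G() -> tuple[TrigTerm, ...]:
    # sin X cos Y + sin Z cos X + sin Y cos Z
    return (
        _t(1.0, ("sin", 1), ("cos", 1), None),
        _t(1.0, ("cos", 1), None, ("sin", 1)),
        _t(1.0, None, ("sin", 1), ("cos", 1)),
    )


def _tubular_g(a1: float, a2: float, const: float) -> tuple[TrigTerm, ...]:
    # a1*(cos x sin y + cos y sin z + cos z sin x)
    #   - a2*(cos 2x cos 2y + cos 2y cos 2z + cos 2z cos 2x) + const
    return (
        _t(a1, ("cos", 1), ("sin", 1), None),
        _t(a1, None, ("cos", 1), ("sin", 1)),
        _t(a1, ("sin", 1), None, ("cos", 1)),
        _t(-a2, ("cos", 2), ("cos", 2), None),
        _t(-a2, None, ("cos", 2), ("cos", 2)),
        _t(-a2, ("cos", 2), None, ("cos", 2)),
        _t(const),
    )


_PRESETS = {
    "P": _preset_P,
    "D": _preset_D,
    "G": _preset_G,
    # Tubular-G bone units: gyroid-like first harmonic, second-harmonic
    # cosine products, and a constant offset folded into the term sum
    # (surface at level 0).  TGab is the coarse outer unit, TGc the finer
    # inner one.
    "TGab": lambda: _tubular_g(20.0, 0.5, -4.0),
    "TGc": lambda: _tubular_g(10.0, 2.0, -12.0),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, cell_size: float = 1.0) -> FieldSpec:
    """Return a named TPMS unit (P, D, G, TGab, TGc) with the given cell edge."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    return FieldSpec(_PRESETS[name](), level=0.0, cell_size=cell_size, name=name)


def sample_grid(
    spec: ImplicitField,
    domain: Domain,
    max_voxels: int = MAX_SAMPLE_VOXELS,
) -> VoxelVolume:
    """Sample a field at the voxel centers of ``domain``."""
    if domain.n_voxels > max_voxels:
        raise ValueError(
            f"domain has {domain.n_voxels} voxels, exceeding the guard of "
            f"{max_voxels}; raise max_voxels explicitly for very large grids"
        )
    values = spec(domain.grid())
    return VoxelVolume(values, tuple(domain.spacing), tuple(domain.origin))


def solid_fraction(spec: ImplicitField, domain: Domain) -> float:
    """Voxel-count estimate of the solid fraction of {phi <= level}."""
    vol = sample_grid(spec, domain)
    return float((vol.values <= spec.level).mean())


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def field_to_dict(spec: FieldSpec) -> dict:
    return {
        "name": spec.name,
        "cell_size": spec.cell_size,
        "level": spec.level,
        "terms": [
            {
                "amplitude": t.amplitude,
                "factors": [
                    {"fn": f.fn, "freq": f.freq, "phase": f.phase}
                    for f in t.factors
                ],
            }
            for t in spec.terms
        ],
    }


def field_from_dict(d: dict) -> FieldSpec:
    terms = tuple(
        TrigTerm(
            float(t["amplitude"]),
            tuple(
                AxisFactor(
                    f.get("fn", "unity"),
                    int(f.get("freq", 1)),
                    float(f.get("phase", 0.0)),
                )
                for f in t["factors"]
            ),
        )
        for t in d["terms"]
    )
    return FieldSpec(
        terms,
        level=float(d.get("level", 0.0)),
        cell_size=float(d.get("cell_size", 1.0)),
        name=str(d.get("name", "")),
    )


def save_field(spec: FieldSpec, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(field_to_dict(spec), fh, indent=2)


def load_field(path: str) -> FieldSpec:
    with open(path) as fh:
        return field_from_dict(json.load(fh))
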