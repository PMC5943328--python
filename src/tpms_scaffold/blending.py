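"""Sigmoid fusion of TPMS units into functionally graded fields.

Two implicit fields phi_1, phi_2 are merged into a single continuous field

    phi_sf = alpha * phi_1 + (1 - alpha) * phi_2,
    alpha  = 1 / (1 + exp(-k * G)),

where G(x, y, z) = 0 is the transition boundary (a plane, a sphere, or a
general quadric) and k > 0 sets how sharp the transition is.  Far on the
G > 0 side the blend follows phi_1; far on the G < 0 side, phi_2; on the
boundary itself both contribute equally.

The two units may carry different iso-levels, so the blend combines the
*level-shifted* fields (phi_i - level_i); the fused surface is then always
the zero level set of the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .fields import FieldSpec, ImplicitField

__all__ = [
    "TransitionSpec",
    "BlendSpec",
    "BlendField",
    "weight",
    "blend_eval",
    "multi_blend",
    "default_steepness",
    "transition_to_dict",
    "transition_from_dict",
]


def default_steepness(cell_size: float) -> float:
    """k such that the transition band spans roughly one unit cell.

    The logistic weight moves from ~0.1 to ~0.9 over a width of about
    4.4/(k*|grad G|); with a unit-gradient boundary, k = 2*pi/cell_size puts
    that band at ~0.7 cell — the transition completes within one cell.
    """
    return 2.0 * np.pi / cell_size


@dataclass(frozen=True)
class TransitionSpec:
    """A transition boundary {G = 0} plus the sigmoid steepness k.

    kinds:
      - ``plane``:   G = n . r - d          (coefficients: nx, ny, nz, d)
      - ``sphere``:  G = |r - c|^2 - R^2    (coefficients: cx, cy, cz, R)
      - ``quadric``: G = a0 x^2 + a1 y^2 + a2 z^2 + a3 xy + a4 yz + a5 zx
                        + a6 x + a7 y + a8 z + a9
    """

    kind: str
    coefficients: tuple[float, ...]
    k: float

    _N_COEFFS = {"plane": 4, "sphere": 4, "quadric": 10}

    def __post_init__(self) -> None:
        if self.kind not in self._N_COEFFS:
            raise ValueError(
                f"unknown transition kind {self.kind!r}; "
                f"use one of {tuple(self._N_COEFFS)}"
            )
        object.__setattr__(
            self, "coefficients", tuple(float(c) for c in self.coefficients)
        )
        n = self._N_COEFFS[self.kind]
        if len(self.coefficients) != n:
            raise ValueError(f"{self.kind} transition needs {n} coefficients")
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError("steepness k must be positive")

    @classmethod
    def plane(cls, normal, offset: float, k: float) -> "TransitionSpec":
        n = np.asarray(normal, float)
        return cls("plane", (*n, float(offset)), k)

    @classmethod
    def sphere(cls, center, radius: float, k: float) -> "TransitionSpec":
        c = np.asarray(center, float)
        return cls("sphere", (*c, float(radius)), k)

    def g(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the boundary function G at (..., 3) points."""
        p = np.asarray(points, float)
        c = self.coefficients
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        if self.kind == "plane":
            return c[0] * x + c[1] * y + c[2] * z - c[3]
        if self.kind == "sphere":
            return (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 - c[3] ** 2
        return (
            c[0] * x * x + c[1] * y * y + c[2] * z * z
            + c[3] * x * y + c[4] * y * z + c[5] * z * x
            + c[6] * x + c[7] * y + c[8] * z + c[9]
        )


def weight(g_value, k: float):
    """Logistic weight alpha = 1/(1 + exp(-k*G)); 0.5 on the boundary."""
    if not (np.isfinite(k) and k > 0):
        raise ValueError("steepness k must be positive")
    return expit(k * np.asarray(g_value, float))


@dataclass
class BlendSpec:
    """Two units and the transition fusing them (field_1 active where G > 0)."""

    field_1: ImplicitField
    field_2: ImplicitField
    transition: TransitionSpec


class BlendField(ImplicitField):
    """Callable fused field; its surface is the zero level set."""

    def __init__(self, spec: BlendSpec):
        self.spec = spec
        self.level = 0.0
        # representative period for meshing/steepness defaults
        self.cell_size = min(spec.field_1.cell_size, spec.field_2.cell_size)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return blend_eval(self.spec, points)


def blend_eval(blend: BlendSpec, points: np.ndarray) -> np.ndarray:
    """alpha*(phi_1 - level_1) + (1-alpha)*(phi_2 - level_2) at mm points."""
    s = blend
    alpha = weight(s.transition.g(points), s.transition.k)
    v1 = np.asarray(s.field_1(points), float) - s.field_1.level
    v2 = np.asarray(s.field_2(points), float) - s.field_2.level
    return alpha * v1 + (1.0 - alpha) * v2


def multi_blend(
    units: list[tuple[ImplicitField, TransitionSpec | None]],
) -> ImplicitField:
    """Cascade two-field blends over an ordered unit list.

    The first unit is the base (its transition entry is ignored and may be
    None); each subsequent unit is fused in on the G < 0 side of its own
    transition: result_i = blend(result_{i-1} as field_1, unit_i as field_2).
    Near triple junctions the result is order-dependent — documented, not
    symmetrized.
    """
    if not units:
        raise ValueError("multi_blend needs at least one unit")
    current: ImplicitField = units[0][0]
    for unit_field, transition in units[1:]:
        if transition is None:
            raise ValueError("every unit after the first needs a transition")
        current = BlendField(BlendSpec(current, unit_field, transition))
    return current


def transition_to_dict(t: TransitionSpec) -> dict:
    return {"type": t.kind, "coefficients": list(t.coefficients), "k": t.k}


def transition_from_dict(d: dict) -> TransitionSpec:
    return TransitionSpec(d["type"], tuple(d["coefficients"]), float(d["k"]))
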