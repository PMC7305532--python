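"""Uncorrected mechanical force model: a simply supported beam loaded at the
bracket of the target tooth.

The archwire segment between the two anchorage teeth is modelled as a simply
supported Euler-Bernoulli beam of span ``l``, bending stiffness ``E I_z`` and
a transverse point load ``P`` applied at ``x = a`` (measured from the distal
support).  Small deflections: ``v'' = M(x)/(E I_z)``, ``v(0) = v(l) = 0``.
Imposing a root-ward displacement ``d`` at the load point, the restoring
(orthodontic) force equals the load producing that deflection.

Two force variants are exposed:

``printed``
    ``F = 6 E I_z d / (a (l^2 - a^2 - b^2))`` — the published load-deflection
    relation, used as the calibration baseline.
``rederived``
    ``F = 3 E I_z l d / (a^2 b^2)`` — the load-point stiffness implied by the
    deflection profile itself.  The published relation drops a factor ``b/l``
    between the profile and the force (for a centred load they differ by
    exactly 2), so both are kept and calibrations record which one they used.

Sign convention: ``x`` runs from the distal support (x=0) to the mesial one
(x=l); deflection ``v`` is negative root-ward; forces are reported as
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .archwire import ArchwireSpec, LoopGeometry

__all__ = [
    "VARIANTS",
    "LoadCase",
    "DeflectionProfile",
    "bending_moment",
    "deflection_profile",
    "theoretical_force",
    "load_for_displacement",
]

VARIANTS = ("printed", "rederived")


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")


@dataclass(frozen=True)
class LoadCase:
    """A loaded archwire: spec plus the applied point load ``load`` (N).

    ``displacement`` (m) is the magnitude of the load-point deflection this
    load produces; the orthodontic force is its reaction, equal in magnitude.
    """

    spec: ArchwireSpec
    load: float

    def __post_init__(self) -> None:
        if self.load < 0:
            raise ValueError(f"load must be non-negative, got {self.load}")

    @property
    def displacement(self) -> float:
        """Load-point deflection magnitude |v(a)| = P a^2 b^2 / (3 E I l), m."""
        s = self.spec
        a, b, l = s.offset_distance, s.mesial_distance, s.anchorage_distance
        return self.load * a**2 * b**2 / (3.0 * s.elastic_modulus * s.second_moment * l)


def bending_moment(x: float | np.ndarray, load: float, geometry: LoopGeometry) -> float | np.ndarray:
    """Internal bending moment M(x) (N*m) of the simply supported span.

    M(x) = (P b / l) x on [0, a] and (P b / l) x - P (x - a) on [a, l];
    the two branches agree at x = a and vanish at both supports.
    """
    l = geometry.anchorage_distance
    a = geometry.offset_distance
    b = geometry.mesial_distance
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > l):
        raise ValueError(f"x must lie in [0, {l}], got values outside the span")
    m = load * b / l * x - load * np.maximum(x - a, 0.0)
    return float(m) if m.ndim == 0 else m


@dataclass(frozen=True)
class DeflectionProfile:
    """Deflection and slope of the loaded span on a position grid.

    ``constant_c`` and ``constant_d`` are the integration constants of the
    slope/deflection integrals in the E*I-scaled sense: the boundary and
    continuity conditions give C1 = C2 = -(P b / l)(l^2 - b^2)/6 and
    D1 = D2 = 0 (divide by E I_z for the physical slope).
    """

    case: LoadCase
    positions: np.ndarray
    deflection: np.ndarray
    slope: np.ndarray
    constant_c: float = field(repr=False, default=0.0)
    constant_d: float = field(repr=False, default=0.0)

    def to_csv(self, path: str | Path) -> None:
        """Two-column export (x_mm, v_mm)."""
        arr = np.column_stack([self.positions * 1e3, self.deflection * 1e3])
        np.savetxt(path, arr, delimiter=",", header="x_mm,v_mm", comments="")


def _profile_arrays(case: LoadCase, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = case.spec
    P = case.load
    E, I = s.elastic_modulus, s.second_moment
    l, a, b = s.anchorage_distance, s.offset_distance, s.mesial_distance
    ei = E * I
    c = -(P * b / l) * (l**2 - b**2) / 6.0  # EI-scaled integration constant

    left = x <= a
    v = np.empty_like(x)
    th = np.empty_like(x)
    # 0 <= x <= a
    v[left] = -(P * b * x[left]) / (6.0 * ei * l) * (l**2 - x[left] ** 2 - b**2)
    th[left] = (P * b / l * x[left] ** 2 / 2.0 + c) / ei
    # a <= x <= l
    xr = x[~left]
    v[~left] = -(P * b) / (6.0 * ei * l) * (
        (l / b) * (xr - a) ** 3 + (l**2 - b**2) * xr - xr**3)
    th[~left] = (P * b / l * xr**2 / 2.0 - P * (xr - a) ** 2 / 2.0 + c) / ei
    return v, th


def deflection_profile(case: LoadCase, num: int = 201) -> DeflectionProfile:
    """Closed-form deflection curve of the loaded span.

    v(x) = -(P b x)/(6 E I l) (l^2 - x^2 - b^2)                 on [0, a]
    v(x) = -(P b)/(6 E I l) [ (l/b)(x-a)^3 + (l^2-b^2) x - x^3 ] on [a, l]

    The grid always contains the load point x = a so branch continuity is
    directly observable.
    """
    s = case.spec
    l, a = s.anchorage_distance, s.offset_distance
    x = np.unique(np.concatenate([np.linspace(0.0, l, num), [a]]))
    v, th = _profile_arrays(case, x)
    P, b = case.load, s.mesial_distance
    c = -(P * b / l) * (l**2 - b**2) / 6.0
    return DeflectionProfile(case, x, v, th, constant_c=c, constant_d=0.0)


def theoretical_force(spec: ArchwireSpec, displacement_mm: float, variant: str = "printed") -> float:
    """Orthodontic force (N) for an imposed load-point displacement (mm).

    Linear in displacement, elastic modulus and second moment.  See the module
    docstring for the two variants.
    """
    _check_variant(variant)
    if displacement_mm < 0:
        raise ValueError(f"displacement must be non-negative, got {displacement_mm} mm")
    d = displacement_mm * 1e-3
    E, I = spec.elastic_modulus, spec.second_moment
    l, a, b = spec.anchorage_distance, spec.offset_distance, spec.mesial_distance
    denom = l**2 - a**2 - b**2  # = 2 a b for b = l - a
    if denom <= 0:
        raise ValueError(f"degenerate geometry: l^2 - a^2 - b^2 = {denom} <= 0")
    if variant == "printed":
        return 6.0 * E * I * d / (a * denom)
    return 3.0 * E * I * l * d / (a**2 * b**2)


def load_for_displacement(spec: ArchwireSpec, displacement_mm: float) -> LoadCase:
    """Load case whose load-point deflection magnitude equals the given
    displacement; its load equals ``theoretical_force(..., "rederived")``."""
    P = theoretical_force(spec, displacement_mm, "rederived")
    return LoadCase(spec, P)
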