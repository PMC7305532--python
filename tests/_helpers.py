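"""Shared independent oracles and random-case generators for the tests."""

import numpy as np
from scipy.integrate import cumulative_trapezoid

from orthoforce import (ArchwireSpec, CrossSection, LoopGeometry, Material,
                        bending_moment)


def integrate_deflection(spec: ArchwireSpec, load: float, n: int = 4001):
    """Brute-force beam oracle: double numerical integration of
    v'' = M(x)/(E I_z) with v(0) = v(l) = 0.

    Independent of the closed-form implementation: only the bending-moment
    statics enter.  Returns (x, v).
    """
    l = spec.anchorage_distance
    a = spec.offset_distance
    x = np.unique(np.concatenate([np.linspace(0.0, l, n), [a]]))
    curvature = np.asarray(bending_moment(x, load, spec.geometry)) \
        / (spec.elastic_modulus * spec.second_moment)
    theta = cumulative_trapezoid(curvature, x, initial=0.0)
    v_part = cumulative_trapezoid(theta, x, initial=0.0)
    theta0 = -v_part[-1] / l  # enforce v(l) = 0
    return x, v_part + theta0 * x


def oracle_force(spec: ArchwireSpec, displacement_mm: float, n: int = 4001) -> float:
    """Force required for a load-point displacement, from the integration
    oracle: unit-load deflection at x = a, then linearity."""
    x, v = integrate_deflection(spec, 1.0, n)
    idx = int(np.argmin(np.abs(x - spec.offset_distance)))
    delta_unit = abs(v[idx])
    return displacement_mm * 1e-3 / delta_unit


def random_spec(rng: np.random.Generator) -> ArchwireSpec:
    """A random valid archwire: material, section kind, span and load point."""
    material = Material("random", float(rng.uniform(5e10, 2.5e11)))
    if rng.random() < 0.5:
        section = CrossSection("round", diameter=float(rng.uniform(2e-4, 8e-4)))
    else:
        section = CrossSection("rectangular",
                               height=float(rng.uniform(2e-4, 8e-4)),
                               width=float(rng.uniform(2e-4, 8e-4)))
    l = float(rng.uniform(0.01, 0.04))
    a = float(rng.uniform(0.15, 0.85)) * l
    return ArchwireSpec("RANDOM", material, section, LoopGeometry(l, a))
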