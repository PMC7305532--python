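"""Archwire domain types and the compact archwire naming code.

A second-sequential-loop archwire is described by a nine-character code such
as ``S16162010``:

* one material letter — ``S`` stainless steel, ``A`` Australian wire;
* two dimension pairs in thousandths of an inch describing the cross-section.
  ``1616`` is a 0.016" x 0.016" square wire; a leading ``00`` pair denotes a
  round wire whose diameter is the second pair (``0016`` = 0.016" round).
  For rectangular wires the *first* pair is the dimension lying in the
  deflection (occlusal-gingival) plane, i.e. the one cubed in the second
  moment of area;
* the anchorage distance ``l`` in mm (archwire length between the two
  anchorage teeth), then the offset distance ``a`` in mm (load point to the
  distal anchorage tooth).  The mesial distance is ``b = l - a``.

All stored quantities are SI (m, Pa); user-facing interfaces take mm.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "MIL",
    "Material",
    "CrossSection",
    "LoopGeometry",
    "ArchwireSpec",
    "ParseError",
    "GeometryError",
    "MaterialLookupError",
    "DEFAULT_MATERIALS",
    "EFFECTIVE_MATERIALS",
    "load_material_library",
    "parse_code",
    "render_code",
    "second_moment",
]

#: one thousandth of an inch, in metres
MIL = 2.54e-5

_CODE_RE = re.compile(r"^(?P<material>[A-Z])(?P<dim1>\d{2})(?P<dim2>\d{2})"
                      r"(?P<anchorage>\d{2})(?P<offset>\d{2})$")


class ParseError(ValueError):
    """Malformed archwire code; the message names the offending field."""


class GeometryError(ValueError):
    """Loop geometry violates 0 < a < l."""


class MaterialLookupError(LookupError):
    """Material letter absent from the material library."""


@dataclass(frozen=True)
class Material:
    """Archwire material: elastic modulus ``E`` (Pa) and Poisson ratio.

    The Poisson ratio is carried for completeness; no implemented equation
    consumes it (bending of a slender wire is governed by ``E`` alone).
    """

    name: str
    elastic_modulus: float
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if not self.elastic_modulus > 0:
            raise ValueError(f"elastic modulus must be positive, got {self.elastic_modulus}")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError(f"Poisson ratio must lie in [0, 0.5), got {self.poisson_ratio}")


@dataclass(frozen=True)
class CrossSection:
    """Round or rectangular wire cross-section.

    For rectangular wires ``height`` is the dimension in the deflection
    direction (the one cubed in ``second_moment``) and ``width`` the
    transverse one.  ``diameter`` applies to round wires only.
    """

    kind: str  # "round" | "rectangular"
    diameter: float | None = None
    height: float | None = None
    width: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "round":
            if self.diameter is None or not self.diameter > 0:
                raise ValueError(f"round section needs a positive diameter, got {self.diameter}")
            if self.height is not None or self.width is not None:
                raise ValueError("round section takes no height/width")
        elif self.kind == "rectangular":
            if self.height is None or not self.height > 0:
                raise ValueError(f"rectangular section needs a positive height, got {self.height}")
            if self.width is None or not self.width > 0:
                raise ValueError(f"rectangular section needs a positive width, got {self.width}")
            if self.diameter is not None:
                raise ValueError("rectangular section takes no diameter")
        else:
            raise ValueError(f"unknown section kind {self.kind!r}")

    @property
    def second_moment(self) -> float:
        """Second moment of area I_z about the bending axis, m^4."""
        if self.kind == "round":
            return math.pi * self.diameter**4 / 64.0
        return self.width * self.height**3 / 12.0

    @property
    def area(self) -> float:
        """Cross-sectional area, m^2."""
        if self.kind == "round":
            return math.pi * self.diameter**2 / 4.0
        return self.width * self.height

    @property
    def shape(self) -> str:
        """Shape tag: ``round``, ``square`` or ``rectangular``."""
        if self.kind == "round":
            return "round"
        return "square" if math.isclose(self.height, self.width) else "rectangular"


@dataclass(frozen=True)
class LoopGeometry:
    """Span geometry of the loaded loop: anchorage distance ``l`` and offset
    distance ``a`` from the distal support, both in metres."""

    anchorage_distance: float
    offset_distance: float

    def __post_init__(self) -> None:
        l, a = self.anchorage_distance, self.offset_distance
        if not l > 0:
            raise GeometryError(f"anchorage distance must be positive, got {l}")
        if not 0 < a < l:
            raise GeometryError(
                f"offset distance must satisfy 0 < a < l, got a={a}, l={l}")

    @property
    def mesial_distance(self) -> float:
        """b = l - a, distance from load point to the mesial support (m)."""
        return self.anchorage_distance - self.offset_distance


@dataclass(frozen=True)
class ArchwireSpec:
    """A fully specified archwire: code, material, section and loop geometry."""

    code: str
    material: Material
    section: CrossSection
    geometry: LoopGeometry

    # convenience accessors used throughout the force model
    @property
    def elastic_modulus(self) -> float:
        return self.material.elastic_modulus

    @property
    def second_moment(self) -> float:
        return self.section.second_moment

    @property
    def anchorage_distance(self) -> float:
        return self.geometry.anchorage_distance

    @property
    def offset_distance(self) -> float:
        return self.geometry.offset_distance

    @property
    def mesial_distance(self) -> float:
        return self.geometry.mesial_distance


#: Textbook material library (default): standard orthodontic stainless steel,
#: and Australian wire scaled by the measured stiffness ratio of the two wires.
DEFAULT_MATERIALS: Mapping[str, Material] = {
    "S": Material("stainless steel", 1.79e11),
    "A": Material("Australian", 1.57e11),
}

#: Effective moduli of the reference measurement campaign, identified by
#: matching the refit anchorage-distance correction slope (and the material
#: correction slope) to the published coefficient functions.  Use these when
#: refit coefficients are to be compared against the published ones.
EFFECTIVE_MATERIALS: Mapping[str, Material] = {
    "S": Material("stainless steel (effective)", 7.92e10),
    "A": Material("Australian (effective)", 6.97e10),
}


def load_material_library(path: str | Path | None = None) -> dict[str, Material]:
    """Load a material library from a JSON file.

    The file maps material letters to ``{"name", "E_Pa", "poisson"}``.  With
    ``path=None`` the packaged default (textbook) library is loaded.
    """
    if path is None:
        raw = resources.files("orthoforce.data").joinpath("materials.json").read_text()
    else:
        raw = Path(path).read_text()
    entries = json.loads(raw)
    return {
        letter: Material(spec["name"], float(spec["E_Pa"]), float(spec.get("poisson", 0.3)))
        for letter, spec in entries.items()
    }


def parse_code(
    code: str,
    material_library: Mapping[str, Material] | None = None,
    *,
    substitutions: Mapping[str, str] | None = None,
) -> ArchwireSpec:
    """Parse an archwire naming code into a fully populated :class:`ArchwireSpec`.

    Parameters
    ----------
    code
        Nine-character code, e.g. ``"S16162010"``.
    material_library
        Letter -> :class:`Material` map; defaults to :data:`DEFAULT_MATERIALS`.
    substitutions
        Optional code -> code rewriting applied before parsing.  The returned
        spec keeps the *original* code so measurement columns keyed by it
        still resolve; only material/section/geometry come from the rewrite.
        The canonical use is reading the 0.020"x0.010" offset-comparison wire
        as its 0.016"x0.016" stand-in (``{"S20102007": "S16162007"}``).
    """
    if material_library is None:
        material_library = DEFAULT_MATERIALS
    effective = code
    if substitutions and code in substitutions:
        effective = substitutions[code]
    m = _CODE_RE.match(effective)
    if m is None:
        raise ParseError(
            f"archwire code {effective!r} does not match "
            "M DDDD LL AA (material letter, two 2-digit section dimension "
            "pairs, anchorage mm, offset mm)")
    letter = m["material"]
    if letter not in material_library:
        raise MaterialLookupError(
            f"material letter {letter!r} not in library {sorted(material_library)}")
    d1, d2 = int(m["dim1"]), int(m["dim2"])
    if d1 == 0:
        if d2 == 0:
            raise ParseError(f"code {effective!r}: round wire needs a nonzero diameter pair")
        section = CrossSection("round", diameter=d2 * MIL)
    else:
        if d2 == 0:
            raise ParseError(f"code {effective!r}: second section dimension pair is zero")
        section = CrossSection("rectangular", height=d1 * MIL, width=d2 * MIL)
    l_mm, a_mm = int(m["anchorage"]), int(m["offset"])
    if a_mm >= l_mm:
        raise GeometryError(
            f"code {effective!r}: offset distance {a_mm} mm must be smaller "
            f"than anchorage distance {l_mm} mm")
    geometry = LoopGeometry(l_mm * 1e-3, a_mm * 1e-3)
    return ArchwireSpec(code, material_library[letter], section, geometry)


def render_code(spec: ArchwireSpec) -> str:
    """Inverse of :func:`parse_code` (modulo the material library)."""
    letter = spec.code[0]
    if spec.section.kind == "round":
        dims = f"00{round(spec.section.diameter / MIL):02d}"
    else:
        dims = (f"{round(spec.section.height / MIL):02d}"
                f"{round(spec.section.width / MIL):02d}")
    l_mm = round(spec.geometry.anchorage_distance * 1e3)
    a_mm = round(spec.geometry.offset_distance * 1e3)
    return f"{letter}{dims}{l_mm:02d}{a_mm:02d}"


def second_moment(section: CrossSection) -> float:
    """Second moment of area I_z (m^4): pi d^4/64 for round wires,
    width * height^3 / 12 for rectangular ones (height = deflection-direction
    dimension)."""
    return section.second_moment
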