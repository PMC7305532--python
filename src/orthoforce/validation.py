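"""Corrected force prediction and relative-error validation.

The corrected prediction applies the composed correction factor to the beam
baseline, ``F = K_F * F_theo`` under the multiplicative convention (or
``F_theo / K_F`` under the ``divide`` fidelity switch).  Validation reports
per-point relative errors ``100 |F_pred - F_exp| / F_exp``, per-archwire means
over the displacement grid, and the spread of those means across archwires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import beam
from .archwire import ArchwireSpec, Material, DEFAULT_MATERIALS, parse_code
from .calibration import CorrectionCoefficients, compose_KF
from .dataset import MeasurementTable

__all__ = ["ValidationError", "corrected_force", "relative_error",
           "validate", "ValidationReport"]


class ValidationError(ValueError):
    pass


def corrected_force(spec: ArchwireSpec, displacement_mm: float,
                    coeffs: CorrectionCoefficients) -> float:
    """Corrected orthodontic force prediction (N).

    Uses the baseline variant and correction convention recorded on the
    coefficients; linear in displacement, zero at zero displacement.
    """
    f_theo = beam.theoretical_force(spec, displacement_mm, coeffs.variant)
    kf = compose_KF(spec, coeffs)
    return kf * f_theo if coeffs.convention == "multiply" else f_theo / kf


def relative_error(f_pred: float, f_exp: float) -> float:
    """100 |F_pred - F_exp| / F_exp (%)."""
    if f_exp <= 0:
        raise ValueError(f"experimental force must be positive, got {f_exp}")
    return 100.0 * abs(f_pred - f_exp) / f_exp


@dataclass(frozen=True)
class ValidationReport:
    """Relative errors of corrected predictions against a measurement table.

    ``per_point`` is a displacement x archwire frame of percent errors;
    ``per_archwire`` the mean error of each archwire over its displacements.
    ``min_mean_error``/``max_mean_error`` summarise the per-archwire means
    (the conventional headline range); the per-point extremes are also kept
    since a bare "error range" can refer to either.
    """

    per_point: pd.DataFrame = field(repr=False)
    per_archwire: pd.Series = field(repr=False)
    variant: str
    convention: str
    base_mode: str
    in_sample: bool

    @property
    def min_mean_error(self) -> float:
        return float(self.per_archwire.min())

    @property
    def max_mean_error(self) -> float:
        return float(self.per_archwire.max())

    @property
    def min_point_error(self) -> float:
        return float(self.per_point.min().min())

    @property
    def max_point_error(self) -> float:
        return float(self.per_point.max().max())

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "convention": self.convention,
            "base_mode": self.base_mode,
            "in_sample": self.in_sample,
            "per_archwire_mean_error_pct": {k: float(v) for k, v in
                                            self.per_archwire.items()},
            "mean_error_range_pct": [self.min_mean_error, self.max_mean_error],
            "point_error_range_pct": [self.min_point_error, self.max_point_error],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def per_point_csv(self, path: str | Path) -> None:
        """Per-point percent errors as CSV (displacement rows, code columns)."""
        self.per_point.to_csv(path, float_format="%.4f")

    def __str__(self) -> str:
        lines = [
            "Validation report"
            + ("  [in-sample: validated on the calibration table]" if self.in_sample else ""),
            f"variant={self.variant}  convention={self.convention}  base_mode={self.base_mode}",
            f"{'archwire':<12}{'mean rel. error %':>20}",
        ]
        for code, err in self.per_archwire.items():
            lines.append(f"{code:<12}{err:>20.2f}")
        lines.append(f"{'min/max of means':<12}{self.min_mean_error:>14.2f} /"
                     f" {self.max_mean_error:.2f}")
        return "\n".join(lines)


def validate(
    table: MeasurementTable,
    coeffs: CorrectionCoefficients,
    *,
    material_library: Mapping[str, Material] | None = None,
    substitutions: Mapping[str, str] | None = None,
    variant: str | None = None,
    in_sample: bool = False,
) -> ValidationReport:
    """Validate corrected predictions against a measurement table.

    ``variant``, if given, must equal the coefficients' baseline variant —
    mixing calibration and prediction baselines is refused.  Zero-displacement
    rows (if any) are skipped since the relative error is undefined there.
    """
    if variant is not None and variant != coeffs.variant:
        raise ValidationError(
            f"requested baseline variant {variant!r} but the coefficients were "
            f"calibrated against {coeffs.variant!r}")
    lib = material_library or DEFAULT_MATERIALS
    if not table.codes:
        raise ValidationError("empty measurement table")
    errors: dict[str, dict[float, float]] = {}
    for code in table.codes:
        spec = parse_code(code, lib, substitutions=substitutions)
        col = {}
        for d in table.displacements:
            if d == 0:
                continue
            f_pred = corrected_force(spec, float(d), coeffs)
            col[float(d)] = relative_error(f_pred, table.force(code, float(d)))
        errors[code] = col
    per_point = pd.DataFrame(errors)
    per_point.index.name = "displacement_mm"
    if per_point.empty:
        raise ValidationError("no non-zero displacement rows to validate")
    per_archwire = per_point.mean(axis=0)
    return ValidationReport(per_point, per_archwire, coeffs.variant,
                            coeffs.convention, coeffs.base_mode, in_sample)
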