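"""Measurement tables: CSV I/O, the packaged reference table, replicate math.

A measurement table is a displacement x archwire grid of measured orthodontic
forces: one row per imposed displacement (mm, strictly increasing), one column
per archwire code, cells in newtons.  CSV layout::

    displacement_mm,S16162010,S16162210,...
    0.5,0.32,0.25,...

An optional leading ``replicate`` column stores stacked repeated measurement
runs; :func:`load_table` then averages them and keeps the individual runs on
the returned table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "MeasurementTable",
    "load_table",
    "write_table",
    "builtin_table1",
    "average_replicates",
]


class FormatError(ValueError):
    """Measurement CSV violates the table contract."""


@dataclass(frozen=True)
class MeasurementTable:
    """Displacement x archwire grid of measured forces.

    ``frame`` is indexed by displacement (mm) with archwire codes as columns,
    values in N.  ``replicates`` optionally holds the individual runs the
    frame averages.
    """

    frame: pd.DataFrame
    replicates: tuple[pd.DataFrame, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        if f.empty:
            raise FormatError("measurement table is empty")
        disp = f.index.to_numpy(dtype=float)
        if np.any(np.diff(disp) <= 0):
            raise FormatError("displacements must be strictly increasing")
        if f.isna().any().any():
            bad = [(i, c) for c in f.columns for i in f.index[f[c].isna()]]
            raise FormatError(f"non-numeric or missing force cells at {bad[:5]}")
        if (f.to_numpy() < 0).any():
            raise FormatError("forces must be non-negative")
        if self.replicates is not None:
            for r in self.replicates:
                if list(r.index) != list(f.index) or list(r.columns) != list(f.columns):
                    raise FormatError("replicate grids do not match the averaged table")

    @property
    def displacements(self) -> np.ndarray:
        """Displacement grid in mm."""
        return self.frame.index.to_numpy(dtype=float)

    @property
    def codes(self) -> list[str]:
        return list(self.frame.columns)

    def force(self, code: str, displacement_mm: float) -> float:
        """Measured force (N) for one archwire at one displacement."""
        return float(self.frame.at[displacement_mm, code])

    def to_csv(self, path: str | Path) -> None:
        write_table(self, path)


def _parse_frame(df: pd.DataFrame, where: str) -> pd.DataFrame:
    if "displacement_mm" not in df.columns:
        raise FormatError(f"{where}: missing required 'displacement_mm' header")
    codes = [c for c in df.columns if c not in ("displacement_mm", "replicate")]
    if not codes:
        raise FormatError(f"{where}: no archwire force columns")
    try:
        out = df[["displacement_mm", *codes]].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{where}: non-numeric cell ({exc})") from None
    dup = out["displacement_mm"].duplicated()
    if dup.any():
        raise FormatError(
            f"{where}: duplicated displacement rows at "
            f"{out['displacement_mm'][dup].tolist()}")
    return out.set_index("displacement_mm").sort_index()


def load_table(path: str | Path) -> MeasurementTable:
    """Read a measurement table from CSV.

    A ``replicate`` column, if present, marks stacked repeated runs; they are
    averaged element-wise and retained on ``.replicates``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    if "replicate" in df.columns:
        runs = [_parse_frame(g.drop(columns="replicate"), f"{path} replicate {k}")
                for k, g in df.groupby("replicate", sort=True)]
        return average_replicates([MeasurementTable(r) for r in runs])
    return MeasurementTable(_parse_frame(df, str(path)))


def _format_frame(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.map(lambda v: f"{v:.2f}")
    out.index = [np.format_float_positional(d, trim="0") for d in frame.index]
    out.index.name = frame.index.name
    return out


def write_table(table: MeasurementTable, path: str | Path) -> None:
    """Write a table to CSV (2-decimal forces, as conventionally printed;
    displacements keep their natural decimals).

    If the table carries replicates they are written stacked with a
    ``replicate`` column, so the file round-trips through :func:`load_table`.
    """
    path = Path(path)
    if table.replicates:
        parts = []
        for k, r in enumerate(table.replicates, start=1):
            part = _format_frame(r).reset_index()
            part.insert(0, "replicate", k)
            parts.append(part)
        pd.concat(parts).to_csv(path, index=False)
    else:
        _format_frame(table.frame).reset_index().to_csv(path, index=False)


@lru_cache(maxsize=1)
def _table1_text() -> str:
    return resources.files("orthoforce.data").joinpath("table1.csv").read_text()


def builtin_table1() -> MeasurementTable:
    """The packaged reference measurement table.

    Ten archwire types measured at ten displacements (0.5-5.0 mm, 0.5 mm
    steps); each cell is the mean of three repeated measurement runs of the
    unidirectional orthodontic force in N.  The ten codes form four
    single-parameter comparison groups around the reference wire S16162010:
    anchorage distance (20/22/24/26 mm), offset distance (10/9/8/7 mm),
    cross-section (square/rectangular/round) and material (stainless steel /
    Australian).
    """
    df = pd.read_csv(StringIO(_table1_text()))
    return MeasurementTable(_parse_frame(df, "builtin reference table"))


def average_replicates(tables: list[MeasurementTable]) -> MeasurementTable:
    """Element-wise mean of replicate tables with identical grids."""
    if not tables:
        raise FormatError("no replicate tables given")
    first = tables[0].frame
    for t in tables[1:]:
        if list(t.frame.columns) != list(first.columns) or \
                not np.array_equal(t.frame.index.to_numpy(), first.index.to_numpy()):
            raise FormatError("replicate tables have mismatched displacements or columns")
    mean = sum(t.frame for t in tables) / len(tables)
    return MeasurementTable(mean, replicates=tuple(t.frame for t in tables))
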