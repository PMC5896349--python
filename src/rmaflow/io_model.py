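"""Probe-level data containers and text-format I/O.

Two plain-text dialects are supported:

* **ASCII CEL version 3** — the classic ``[CEL]`` / ``[HEADER]`` /
  ``[INTENSITY]`` sectioned format, one file per array.  Only the fields
  this pipeline consumes are required: ``Cols=`` / ``Rows=`` in the
  header, and ``X Y MEAN STDV NPIXELS`` data lines in the intensity
  section.  The MEAN column is the probe intensity; STDV and NPIXELS
  are parsed but ignored.

* **TSV chip layout** — a replacement for the binary CDF chip
  description.  Line 1 is a preamble ``#layout<TAB>name=...<TAB>
  rows=...<TAB>cols=...``; line 2 is the column header
  ``probeset_id  x  y  is_pm``; every further line places one probe
  cell.  Coordinates are 0-based with ``x`` the column and ``y`` the
  row, matching the CEL [INTENSITY] convention.  Probe order within a
  probeset is the order of appearance in the file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class LayoutError(ValueError):
    """A chip layout violates its structural invariants."""


@dataclass(frozen=True)
class Probe:
    """One probe cell: location on the grid plus probeset membership."""

    probeset_id: str
    x: int  # column, 0-based
    y: int  # row, 0-based
    is_pm: bool


@dataclass
class ChipLayout:
    """Maps grid cells to probesets; the CDF analog.

    Probes are kept in file order; that order defines the stable probe
    rank within each probeset used throughout the pipeline.
    """

    name: str
    n_rows: int
    n_cols: int
    probes: list[Probe]

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise LayoutError("layout dimensions must be positive")
        seen: set[tuple[int, int]] = set()
        pm_count: dict[str, int] = {}
        for p in self.probes:
            if not (0 <= p.x < self.n_cols and 0 <= p.y < self.n_rows):
                raise LayoutError(
                    f"probe at ({p.x},{p.y}) outside {self.n_cols}x{self.n_rows} grid"
                )
            if (p.x, p.y) in seen:
                raise LayoutError(f"duplicate probe position ({p.x},{p.y})")
            seen.add((p.x, p.y))
            pm_count.setdefault(p.probeset_id, 0)
            if p.is_pm:
                pm_count[p.probeset_id] += 1
        for ps, k in pm_count.items():
            if k == 0:
                raise LayoutError(f"probeset {ps!r} has no PM probes")

    @property
    def probeset_ids(self) -> list[str]:
        """Probeset identifiers in order of first appearance."""
        out: list[str] = []
        seen: set[str] = set()
        for p in self.probes:
            if p.probeset_id not in seen:
                seen.add(p.probeset_id)
                out.append(p.probeset_id)
        return out

    def pm_index(self) -> list[tuple[str, int]]:
        """Keys ``(probeset_id, rank)`` for every PM probe, in file order.

        Rank counts PM probes within a probeset starting at 0.  The key
        order is a function of the layout only.
        """
        counters: dict[str, int] = {}
        keys: list[tuple[str, int]] = []
        for p in self.probes:
            if p.is_pm:
                r = counters.get(p.probeset_id, 0)
                counters[p.probeset_id] = r + 1
                keys.append((p.probeset_id, r))
        return keys


@dataclass
class ArrayIntensities:
    """Raw fluorescence intensities for one array, indexed ``[y, x]``."""

    array_id: str
    values: np.ndarray  # shape (n_rows, n_cols)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise FormatError("intensity grid must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise FormatError(f"array {self.array_id!r} has non-finite intensities")
        if np.any(self.values < 0):
            raise FormatError(f"array {self.array_id!r} has negative intensities")


@dataclass
class ArraySet:
    """A batch of same-layout arrays — the AffyBatch analog."""

    layout: ChipLayout
    arrays: list[ArrayIntensities] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [a.array_id for a in self.arrays]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate array_ids in ArraySet")
        shape = (self.layout.n_rows, self.layout.n_cols)
        for a in self.arrays:
            if a.values.shape != shape:
                raise FormatError(
                    f"array {a.array_id!r} shape {a.values.shape} does not match "
                    f"layout {shape}"
                )

    @property
    def array_ids(self) -> list[str]:
        return [a.array_id for a in self.arrays]


@dataclass
class ExpressionMatrix:
    """Summarized log2 expression: probesets x arrays."""

    probeset_ids: list[str]
    array_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probeset_ids), len(self.array_ids)):
            raise FormatError("expression matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression matrix has non-finite values")


# ---------------------------------------------------------------------------
# CEL v3 (ASCII) reading / writing
# ---------------------------------------------------------------------------

def read_cel(path: str | os.PathLike, layout: ChipLayout) -> ArrayIntensities:
    """Parse an ASCII CEL-v3 file into an intensity grid.

    The grid dimensions in the ``[HEADER]`` section must match *layout*.
    The array id is the file basename without its extension.
    """
    sections: dict[str, list[str]] = {}
    current: str | None = None
    with open(path, "r") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            stripped = line.strip()
            if stripped.startswith("[") and stripped.endswith("]"):
                current = stripped[1:-1].upper()
                sections[current] = []
            elif current is not None:
                sections[current].append(line)

    for required in ("CEL", "HEADER", "INTENSITY"):
        if required not in sections:
            raise FormatError(f"{path}: missing [{required}] section")

    header: dict[str, str] = {}
    for line in sections["HEADER"]:
        if "=" in line:
            k, v = line.split("=", 1)
            header[k.strip()] = v.strip()
    try:
        n_cols = int(header["Cols"])
        n_rows = int(header["Rows"])
    except KeyError as exc:
        raise FormatError(f"{path}: [HEADER] missing {exc.args[0]}=") from None
    if (n_rows, n_cols) != (layout.n_rows, layout.n_cols):
        raise FormatError(
            f"{path}: header dims {n_cols}x{n_rows} (Cols x Rows) do not match "
            f"layout {layout.n_cols}x{layout.n_rows}"
        )

    grid = np.full((n_rows, n_cols), np.nan)
    n_seen = 0
    for lineno, line in enumerate(sections["INTENSITY"], start=1):
        s = line.strip()
        if not s or "=" in s:  # NumberCells= / CellHeader= metadata lines
            continue
        parts = s.split()
        if len(parts) < 3:
            raise FormatError(
                f"{path}: [INTENSITY] line {lineno}: expected X Y MEAN ..., got {s!r}"
            )
        try:
            x, y, mean = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError:
            raise FormatError(
                f"{path}: [INTENSITY] line {lineno}: unparseable fields {s!r}"
            ) from None
        if not (0 <= x < n_cols and 0 <= y < n_rows):
            raise FormatError(
                f"{path}: [INTENSITY] line {lineno}: cell ({x},{y}) outside grid"
            )
        if mean < 0:
            raise FormatError(
                f"{path}: [INTENSITY] line {lineno}: negative intensity {mean}"
            )
        grid[y, x] = mean
        n_seen += 1

    if np.any(np.isnan(grid)):
        missing = int(np.isnan(grid).sum())
        raise FormatError(
            f"{path}: [INTENSITY] covers {n_seen} cells; {missing} grid cells missing"
        )

    array_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return ArrayIntensities(array_id=array_id, values=grid)


def write_cel(arr: ArrayIntensities, path: str | os.PathLike) -> None:
    """Write an intensity grid as an ASCII CEL-v3 file.

    STDV and NPIXELS are emitted as constants (0 and 1): nothing
    downstream consumes them.
    """
    n_rows, n_cols = arr.values.shape
    with open(path, "w") as fh:
        fh.write("[CEL]\nVersion=3\n\n")
        fh.write(f"[HEADER]\nCols={n_cols}\nRows={n_rows}\n\n")
        fh.write("[INTENSITY]\n")
        fh.write(f"NumberCells={n_rows * n_cols}\n")
        fh.write("CellHeader=X\tY\tMEAN\tSTDV\tNPIXELS\n")
        for y in range(n_rows):
            for x in range(n_cols):
                fh.write(f"{x}\t{y}\t{arr.values[y, x]:.6f}\t0.0\t1\n")


# ---------------------------------------------------------------------------
# Layout TSV reading / writing
# ---------------------------------------------------------------------------

def read_layout(path: str | os.PathLike) -> ChipLayout:
    """Parse the TSV chip-layout dialect into a :class:`ChipLayout`."""
    with open(path, "r") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("#layout"):
        raise FormatError(f"{path}: first line must be a '#layout' preamble")

    meta: dict[str, str] = {}
    for token in lines[0].split("\t")[1:]:
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k.strip()] = v.strip()
    try:
        name = meta["name"]
        n_rows = int(meta["rows"])
        n_cols = int(meta["cols"])
    except KeyError as exc:
        raise FormatError(f"{path}: preamble missing {exc.args[0]}=") from None

    if len(lines) < 2 or lines[1].split("\t")[:4] != ["probeset_id", "x", "y", "is_pm"]:
        raise FormatError(f"{path}: expected header 'probeset_id\\tx\\ty\\tis_pm'")

    probes: list[Probe] = []
    for lineno, line in enumerate(lines[2:], start=3):
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}: line {lineno}: expected 4 fields")
        try:
            probes.append(
                Probe(
                    probeset_id=parts[0],
                    x=int(parts[1]),
                    y=int(parts[2]),
                    is_pm=bool(int(parts[3])),
                )
            )
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: unparseable fields") from None

    return ChipLayout(name=name, n_rows=n_rows, n_cols=n_cols, probes=probes)


def write_layout(layout: ChipLayout, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"#layout\tname={layout.name}\trows={layout.n_rows}\tcols={layout.n_cols}\n"
        )
        fh.write("probeset_id\tx\ty\tis_pm\n")
        for p in layout.probes:
            fh.write(f"{p.probeset_id}\t{p.x}\t{p.y}\t{int(p.is_pm)}\n")


# ---------------------------------------------------------------------------
# PM extraction and expression output
# ---------------------------------------------------------------------------

@dataclass
class PMMatrix:
    """PM intensities for an ArraySet: one column per array.

    ``keys[k] = (probeset_id, rank)`` labels row *k*; the key order is
    determined by the layout alone.
    """

    keys: list[tuple[str, int]]
    array_ids: list[str]
    values: np.ndarray  # shape (n_pm_probes, n_arrays)


def extract_pm(aset: ArraySet) -> PMMatrix:
    """Pull PM intensities out of the grids, in layout probe order.

    MM probes are excluded (pm-only correction); every array yields a
    vector of identical length.
    """
    keys = aset.layout.pm_index()
    coords = [(p.y, p.x) for p in aset.layout.probes if p.is_pm]
    ys = np.array([c[0] for c in coords], dtype=int)
    xs = np.array([c[1] for c in coords], dtype=int)
    cols = [a.values[ys, xs] for a in aset.arrays]
    values = (
        np.column_stack(cols) if cols else np.empty((len(keys), 0))
    )
    return PMMatrix(keys=keys, array_ids=aset.array_ids, values=values)


def write_expression(em: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write the expression matrix as tab-delimited text.

    First column is the probeset id; remaining columns are the arrays in
    batch order.  Values carry 6 decimal places.
    """
    with open(path, "w") as fh:
        fh.write("probeset_id\t" + "\t".join(em.array_ids) + "\n")
        for i, ps in enumerate(em.probeset_ids):
            row = "\t".join(f"{v:.6f}" for v in em.values[i])
            fh.write(f"{ps}\t{row}\n")


def read_expression(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a matrix written by :func:`write_expression`."""
    with open(path, "r") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "probeset_id":
            raise FormatError(f"{path}: expected 'probeset_id' header column")
        array_ids = header[1:]
        probeset_ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            probeset_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(array_ids)))
    return ExpressionMatrix(probeset_ids=probeset_ids, array_ids=array_ids, values=values)
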