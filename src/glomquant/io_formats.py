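"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* Synapse tables: one record per PSD, as TSV or JSON.  Columns / keys:
  ``psd_id, tbar_id, pre_body, post_body, tbar_x, tbar_y, tbar_z,
  psd_x, psd_y, psd_z`` (+ optional ``confidence``).  PSD-granular records
  make contact expansion a projection: the PSD is the counting unit.
* Cell tables: TSV with header ``body_id, name, class, subtype, soma,
  volume_um3`` (+ optional ``in_matrix``).
* Contact matrices: a dense labelled grid (first row / first column carry
  cell names, as in deposited spreadsheets) or a 3-column edge list
  ``pre, post, count``; CSV or XLSX (first sheet).
* Point clouds: CSV with ``x, y, z`` columns in nm, or ``x_voxel`` etc. for
  8 nm voxel units which are converted on read.

All readers reject malformed input with an error naming the offending line
or cell rather than silently coercing, and none of them sniffs delimiters:
the dialect is always explicit, so reads are deterministic.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    MAJOR_CLASSES,
    SUBTYPE_CLASS,
    CellBody,
    GlomerulusDataset,
    PSD,
    TBar,
)

__all__ = [
    "MatrixTable",
    "read_synapse_table",
    "write_synapse_table",
    "read_cell_table",
    "write_cell_table",
    "read_matrix",
    "write_matrix",
    "read_point_cloud",
    "write_point_cloud",
]

NM_PER_VOXEL = 8.0  # isotropic FIB-SEM voxel pitch

_SYNAPSE_COLUMNS = (
    "psd_id",
    "tbar_id",
    "pre_body",
    "post_body",
    "tbar_x",
    "tbar_y",
    "tbar_z",
    "psd_x",
    "psd_y",
    "psd_z",
)

_CELL_COLUMNS = ("body_id", "name", "class", "subtype", "soma", "volume_um3")


class FormatError(ValueError):
    """Malformed external file."""


@dataclass
class MatrixTable:
    """A labelled contact-count table: rows presynaptic, columns postsynaptic."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def is_square(self) -> bool:
        return self.row_labels == self.col_labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.row_labels, columns=self.col_labels
        )


# ---------------------------------------------------------------------------
# synapse tables


def _parse_synapse_record(rec: dict, where: str) -> tuple[int, tuple, PSD]:
    try:
        psd_id = int(rec["psd_id"])
        tbar_id = int(rec["tbar_id"])
        pre_body = int(rec["pre_body"])
        post_body = int(rec["post_body"])
        tpos = tuple(float(rec[f"tbar_{ax}"]) for ax in "xyz")
        ppos = tuple(float(rec[f"psd_{ax}"]) for ax in "xyz")
    except KeyError as exc:
        raise FormatError(f"{where}: missing field {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{where}: malformed value ({exc})") from exc
    return tbar_id, (tpos, pre_body), PSD(psd_id, tbar_id, post_body, ppos)


def read_synapse_table(path, dialect: str = "tsv") -> tuple[list[TBar], list[PSD]]:
    """Read a PSD-granular synapse table.

    One PSD per row (TSV) or per object (JSON list).  T-bars are deduplicated
    by ``tbar_id``; inconsistent duplicate T-bar descriptions and duplicate
    ``psd_id`` values are rejected.  The result does not depend on row order
    beyond the order of the returned lists.
    """
    path = Path(path)
    if dialect == "tsv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or not set(_SYNAPSE_COLUMNS) <= set(
                reader.fieldnames
            ):
                missing = set(_SYNAPSE_COLUMNS) - set(reader.fieldnames or ())
                raise FormatError(f"{path}: missing columns {sorted(missing)}")
            records = [
                (f"{path}:line {i}", rec)
                for i, rec in enumerate(reader, start=2)
            ]
    elif dialect == "json":
        with path.open(encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise FormatError(f"{path}: expected a JSON list of synapse objects")
        records = [(f"{path}:element {i}", rec) for i, rec in enumerate(data)]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    tbar_info: dict[int, tuple] = {}
    psds: list[PSD] = []
    seen_psd: set[int] = set()
    for where, rec in records:
        tbar_id, info, psd = _parse_synapse_record(rec, where)
        if psd.psd_id in seen_psd:
            raise FormatError(f"{where}: duplicate psd_id {psd.psd_id}")
        seen_psd.add(psd.psd_id)
        if tbar_id in tbar_info:
            if tbar_info[tbar_id] != info:
                raise FormatError(
                    f"{where}: tbar {tbar_id} redefined with different "
                    "position or pre_body"
                )
        else:
            tbar_info[tbar_id] = info
        psds.append(psd)

    tbars = [
        TBar(tbar_id, pos, pre) for tbar_id, (pos, pre) in sorted(tbar_info.items())
    ]
    return tbars, psds


def write_synapse_table(
    tbars: Sequence[TBar], psds: Sequence[PSD], path, dialect: str = "tsv"
) -> None:
    """Write a synapse table (inverse of :func:`read_synapse_table`)."""
    path = Path(path)
    by_id = {t.tbar_id: t for t in tbars}
    rows = []
    for psd in psds:
        tbar = by_id[psd.tbar_id]
        rows.append(
            {
                "psd_id": psd.psd_id,
                "tbar_id": psd.tbar_id,
                "pre_body": tbar.pre_body,
                "post_body": psd.post_body,
                "tbar_x": tbar.position[0],
                "tbar_y": tbar.position[1],
                "tbar_z": tbar.position[2],
                "psd_x": psd.position[0],
                "psd_y": psd.position[1],
                "psd_z": psd.position[2],
            }
        )
    if dialect == "tsv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_SYNAPSE_COLUMNS, delimiter="\t")
            writer.writeheader()
            writer.writerows(rows)
    elif dialect == "json":
        with path.open("w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=None, separators=(",", ":"))
            fh.write("\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# cell tables


def read_cell_table(path) -> list[CellBody]:
    """Read a cell metadata table (TSV) into :class:`CellBody` records.

    Class and subtype strings are validated against the taxonomy; unknown
    values are rejected with the offending line number.
    """
    path = Path(path)
    cells: list[CellBody] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(_CELL_COLUMNS) <= set(
            reader.fieldnames
        ):
            missing = set(_CELL_COLUMNS) - set(reader.fieldnames or ())
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for lineno, rec in enumerate(reader, start=2):
            where = f"{path}:line {lineno}"
            if rec["class"] not in MAJOR_CLASSES:
                raise FormatError(f"{where}: unknown class {rec['class']!r}")
            subtype = rec["subtype"] or "unknown"
            if subtype not in SUBTYPE_CLASS:
                raise FormatError(f"{where}: unknown subtype {subtype!r}")
            try:
                body_id = int(rec["body_id"])
                volume = float(rec["volume_um3"]) if rec["volume_um3"] else 0.0
            except ValueError as exc:
                raise FormatError(f"{where}: malformed value ({exc})") from exc
            in_matrix = rec.get("in_matrix", "1") not in ("0", "false", "False")
            cells.append(
                CellBody(
                    body_id=body_id,
                    name=rec["name"],
                    cell_class=rec["class"],
                    subtype=subtype,
                    soma_location=rec.get("soma", ""),
                    volume_um3=volume,
                    in_matrix=in_matrix,
                )
            )
    return cells


def write_cell_table(cells: Iterable[CellBody], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_CELL_COLUMNS + ("in_matrix",))
        for c in cells:
            writer.writerow(
                [
                    c.body_id,
                    c.name,
                    c.cell_class,
                    c.subtype,
                    c.soma_location,
                    repr(c.volume_um3),
                    int(c.in_matrix),
                ]
            )


# ---------------------------------------------------------------------------
# contact matrices


def _grid_from_rows(rows: list[list], path) -> MatrixTable:
    header = rows[0]
    col_labels = [str(c).strip() for c in header[1:]]
    row_labels: list[str] = []
    counts: list[list[int]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(
                f"{path}:row {i}: ragged row ({len(row)} cells, "
                f"expected {len(header)})"
            )
        label = str(row[0]).strip()
        # deposited spreadsheets may interpose a class/group banner row with
        # no counts; tolerate it by skipping fully blank count rows
        values = row[1:]
        if all(v in (None, "") for v in values) and label:
            continue
        row_labels.append(label)
        parsed: list[int] = []
        for j, v in enumerate(values, start=2):
            if v in (None, ""):
                parsed.append(0)
                continue
            try:
                fv = float(v)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}:row {i}, column {j}: non-numeric cell {v!r}"
                ) from None
            if fv != int(fv):
                raise FormatError(
                    f"{path}:row {i}, column {j}: non-integer count {v!r}"
                )
            parsed.append(int(fv))
        counts.append(parsed)
    return MatrixTable(row_labels, col_labels, np.array(counts, dtype=np.int64))


def _edges_to_table(edges: list[tuple[str, str, int]]) -> MatrixTable:
    labels = sorted({e[0] for e in edges} | {e[1] for e in edges})
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for pre, post, count in edges:
        counts[index[pre], index[post]] += count
    return MatrixTable(labels, list(labels), counts)


def read_matrix(path, format: str = "csv", layout: str = "auto") -> MatrixTable:
    """Read a contact matrix.

    Parameters
    ----------
    format
        ``"csv"`` or ``"xlsx"`` (first sheet only).
    layout
        ``"dense"`` for a labelled grid, ``"edges"`` for a ``pre, post,
        count`` edge list, or ``"auto"`` to decide from the header: a
        3-column file whose header is exactly ``pre, post, count`` is read
        as an edge list, anything else as a dense grid.
    """
    path = Path(path)
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            rows = [row for row in csv.reader(fh)]
    elif format == "xlsx":
        frame = pd.read_excel(path, sheet_name=0, header=None, engine="openpyxl")
        rows = frame.where(frame.notna(), "").values.tolist()
    else:
        raise ValueError(f"unknown format {format!r}")
    if not rows:
        raise FormatError(f"{path}: empty matrix file")

    header = [str(c).strip().lower() for c in rows[0]]
    if layout == "auto":
        layout = "edges" if header == ["pre", "post", "count"] else "dense"
    if layout == "edges":
        if header != ["pre", "post", "count"]:
            raise FormatError(f"{path}: edge list must have header pre,post,count")
        edges = []
        for i, row in enumerate(rows[1:], start=2):
            if len(row) != 3:
                raise FormatError(f"{path}:row {i}: ragged row")
            try:
                count = float(row[2])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}:row {i}, column 3: non-numeric count {row[2]!r}"
                ) from None
            if count != int(count):
                raise FormatError(
                    f"{path}:row {i}, column 3: non-integer count {row[2]!r}"
                )
            edges.append((str(row[0]).strip(), str(row[1]).strip(), int(count)))
        return _edges_to_table(edges)
    if layout == "dense":
        return _grid_from_rows(rows, path)
    raise ValueError(f"unknown layout {layout!r}")


def write_matrix(
    matrix: MatrixTable, path, format: str = "csv", layout: str = "dense"
) -> None:
    """Write a matrix deterministically (bit-stable for fixed input)."""
    path = Path(path)
    if layout == "dense":
        if format == "csv":
            with path.open("w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow([""] + matrix.col_labels)
                for label, row in zip(matrix.row_labels, matrix.counts):
                    writer.writerow([label] + [int(v) for v in row])
        elif format == "xlsx":
            matrix.to_frame().to_excel(path, engine="openpyxl")
        else:
            raise ValueError(f"unknown format {format!r}")
    elif layout == "edges":
        if format != "csv":
            raise ValueError("edge-list layout is CSV only")
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["pre", "post", "count"])
            for i, pre in enumerate(matrix.row_labels):
                for j, post in enumerate(matrix.col_labels):
                    if matrix.counts[i, j]:
                        writer.writerow([pre, post, int(matrix.counts[i, j])])
    else:
        raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# point clouds


def read_point_cloud(path, unit: str | None = None) -> np.ndarray:
    """Read a 3D synapse point cloud CSV into an ``(n, 3)`` nm array.

    Column headers ``x, y, z`` declare nm; ``x_voxel, y_voxel, z_voxel``
    declare 8 nm voxel units, converted on read.  Passing ``unit`` ("nm" or
    "voxel") overrides the header.  Row order is preserved.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if not rows:
        raise FormatError(f"{path}: empty point cloud file")
    header = [c.strip().lower() for c in rows[0]]
    if header[:3] == ["x", "y", "z"]:
        inferred = "nm"
    elif header[:3] == ["x_voxel", "y_voxel", "z_voxel"]:
        inferred = "voxel"
    else:
        raise FormatError(
            f"{path}: header must be x,y,z (nm) or x_voxel,y_voxel,z_voxel"
        )
    unit = unit or inferred
    if unit not in ("nm", "voxel"):
        raise ValueError(f"unknown unit {unit!r}")
    points = np.empty((len(rows) - 1, 3), dtype=float)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) < 3:
            raise FormatError(f"{path}:line {i}: expected 3 coordinates")
        for j in range(3):
            try:
                points[i - 2, j] = float(row[j])
            except ValueError:
                raise FormatError(
                    f"{path}:line {i}: non-numeric coordinate {row[j]!r}"
                ) from None
    if unit == "voxel":
        points *= NM_PER_VOXEL
    return points


def write_point_cloud(points: np.ndarray, path, unit: str = "nm") -> None:
    points = np.asarray(points, dtype=float)
    path = Path(path)
    if unit == "nm":
        header, values = ["x", "y", "z"], points
    elif unit == "voxel":
        header, values = (
            ["x_voxel", "y_voxel", "z_voxel"],
            points / NM_PER_VOXEL,
        )
    else:
        raise ValueError(f"unknown unit {unit!r}")
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in values:
            writer.writerow([repr(float(v)) for v in row])
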