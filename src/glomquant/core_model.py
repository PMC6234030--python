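"""Domain model for glomerulus connectome quantification.

The unit of annotation is the polyadic synapse: one presynaptic T-bar ribbon
(:class:`TBar`) opposed by one or more postsynaptic densities (:class:`PSD`),
each PSD on a different (or occasionally the same) neurite.  Cells are
identified neuron bodies (:class:`CellBody`) carrying a class label from the
antennal-lobe taxonomy: olfactory receptor neurons arriving ipsi- or
contralaterally (ORN_ipsi / ORN_contra), projection neurons (PN), local
interneurons (LN), minor identified cells ("other"), and orphan neurite
fragments that could not be traced to a soma ("orphan").

Every downstream quantity (contact matrices, flows, reciprocity) is a count,
ratio or percentage over these types; there is no continuous model here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import math

__all__ = [
    "MAJOR_CLASSES",
    "SUBTYPE_CLASS",
    "SUBTYPES",
    "CLASS_ORDER",
    "ORPHAN_SENTINEL",
    "CellBody",
    "TBar",
    "PSD",
    "DirectedContact",
    "GlomerulusDataset",
    "validate_dataset",
]

#: Major cell classes recognised by the pipeline.
MAJOR_CLASSES = ("ORN_ipsi", "ORN_contra", "PN", "LN", "other", "orphan")

#: Row/column ordering used for matrix exports: outputs first (PNs), then
#: interneurons, then inputs, then minor cells and orphans.
CLASS_ORDER = ("PN", "LN", "ORN_ipsi", "ORN_contra", "other", "orphan")

#: Controlled subtype vocabulary and the major class each subtype implies.
#: "unknown" is compatible with any class so that non-VA1v datasets load.
SUBTYPE_CLASS = {
    "mPN1": "PN",
    "mPN1_external": "PN",
    "mlPN1": "PN",
    "mlPN2": "PN",
    "mlPN3": "PN",
    "lPN2": "PN",
    "lPN2_comm": "PN",
    "lPN4": "PN",
    "LN1": "LN",
    "LN2L": "LN",
    "LN2V": "LN",
    "LN3": "LN",
    "LN4": "LN",
    "LN6": "LN",
    "LNV": "LN",
    "LN_LV": "LN",
    "LN_comm": "LN",
    "AST3": "other",
    "5HT": "other",
    "unknown": None,
}

SUBTYPES = tuple(SUBTYPE_CLASS)

#: body_id used for contacts whose pre/post neurite could not be resolved to
#: any body in the cell table.  Distinct from identified orphan *bodies*,
#: which appear in the cell table with cell_class == "orphan".
ORPHAN_SENTINEL = -1


@dataclass(frozen=True)
class CellBody:
    """An identified neuron body (or orphan fragment) within the glomerulus.

    Parameters
    ----------
    body_id
        Unique integer identifier within a dataset.
    name
        Text label, e.g. ``"mPN1_a"``.
    cell_class
        One of :data:`MAJOR_CLASSES`.
    subtype
        Entry of the controlled vocabulary :data:`SUBTYPES`; ``"unknown"``
        when no finer identification exists.
    soma_location
        Free-text tag (cortex region or tract of entry).
    volume_um3
        Intraglomerular neurite volume in cubic micrometres; 0 when unknown.
    in_matrix
        Whether the body is eligible for the contact matrix.  Reconstructed
        cells excluded by convention (e.g. the single 5-HT cell) carry False.
    """

    body_id: int
    name: str
    cell_class: str
    subtype: str = "unknown"
    soma_location: str = ""
    volume_um3: float = 0.0
    in_matrix: bool = True


@dataclass(frozen=True)
class TBar:
    """A presynaptic T-bar ribbon: position in nm and the body bearing it."""

    tbar_id: int
    position: tuple[float, float, float]
    pre_body: int


@dataclass(frozen=True)
class PSD:
    """One postsynaptic density opposite a T-bar."""

    psd_id: int
    tbar_id: int
    post_body: int
    position: tuple[float, float, float]


@dataclass(frozen=True)
class DirectedContact:
    """One directed pre -> post pairing contributed by a single PSD."""

    pre_body: int
    post_body: int
    tbar_id: int

    @property
    def is_autapse(self) -> bool:
        return self.pre_body == self.post_body


@dataclass
class GlomerulusDataset:
    """A complete annotated glomerulus: cells, T-bars, PSDs and volume."""

    cells: list[CellBody] = field(default_factory=list)
    tbars: list[TBar] = field(default_factory=list)
    psds: list[PSD] = field(default_factory=list)
    neuropile_volume_um3: float = 1.0

    def cells_by_id(self) -> dict[int, CellBody]:
        return {c.body_id: c for c in self.cells}

    def tbars_by_id(self) -> dict[int, TBar]:
        return {t.tbar_id: t for t in self.tbars}

    def class_of(self, body_id: int) -> str:
        """Major class of a body; the orphan sentinel maps to ``"orphan"``."""
        if body_id == ORPHAN_SENTINEL:
            return "orphan"
        cell = self.cells_by_id().get(body_id)
        return cell.cell_class if cell is not None else "orphan"


def _check_position(name: str, ident: int, pos: Sequence[float], out: list[str]) -> None:
    if len(pos) != 3:
        out.append(f"{name} {ident}: position must have 3 coordinates")
        return
    for coord in pos:
        if not math.isfinite(coord):
            out.append(f"{name} {ident}: non-finite coordinate {coord!r}")
            return
        if coord < 0:
            out.append(f"{name} {ident}: negative coordinate {coord!r}")
            return


def validate_dataset(dataset: GlomerulusDataset) -> list[str]:
    """Check every type invariant; return a list of human-readable violations.

    Violations are reported, never raised, and the dataset is not mutated.
    An empty list means the dataset satisfies all invariants:

    * unique body, T-bar and PSD identifiers;
    * cell classes from the taxonomy, subtypes consistent with their class;
    * non-negative volumes and finite, non-negative positions;
    * every PSD referencing an existing T-bar;
    * every pre/post body reference resolving to a cell or to the orphan
      sentinel;
    * positive neuropile volume.
    """
    violations: list[str] = []

    seen_bodies: set[int] = set()
    for cell in dataset.cells:
        if cell.body_id in seen_bodies:
            violations.append(f"cell {cell.body_id}: duplicate body_id")
        seen_bodies.add(cell.body_id)
        if cell.cell_class not in MAJOR_CLASSES:
            violations.append(
                f"cell {cell.body_id}: unknown cell_class {cell.cell_class!r}"
            )
        implied = SUBTYPE_CLASS.get(cell.subtype, "__missing__")
        if implied == "__missing__":
            violations.append(
                f"cell {cell.body_id}: unknown subtype {cell.subtype!r}"
            )
        elif implied is not None and implied != cell.cell_class:
            violations.append(
                f"cell {cell.body_id}: subtype {cell.subtype!r} implies class "
                f"{implied!r}, not {cell.cell_class!r}"
            )
        if not (cell.volume_um3 >= 0):
            violations.append(
                f"cell {cell.body_id}: negative volume {cell.volume_um3!r}"
            )

    seen_tbars: set[int] = set()
    for tbar in dataset.tbars:
        if tbar.tbar_id in seen_tbars:
            violations.append(f"tbar {tbar.tbar_id}: duplicate tbar_id")
        seen_tbars.add(tbar.tbar_id)
        _check_position("tbar", tbar.tbar_id, tbar.position, violations)
        if tbar.pre_body != ORPHAN_SENTINEL and tbar.pre_body not in seen_bodies:
            violations.append(
                f"tbar {tbar.tbar_id}: pre_body {tbar.pre_body} not in cell table"
            )

    seen_psds: set[int] = set()
    for psd in dataset.psds:
        if psd.psd_id in seen_psds:
            violations.append(f"psd {psd.psd_id}: duplicate psd_id")
        seen_psds.add(psd.psd_id)
        if psd.tbar_id not in seen_tbars:
            violations.append(
                f"psd {psd.psd_id}: references missing tbar {psd.tbar_id}"
            )
        if psd.post_body != ORPHAN_SENTINEL and psd.post_body not in seen_bodies:
            violations.append(
                f"psd {psd.psd_id}: post_body {psd.post_body} not in cell table"
            )
        _check_position("psd", psd.psd_id, psd.position, violations)

    if not (dataset.neuropile_volume_um3 > 0):
        violations.append(
            f"neuropile_volume_um3 must be > 0, got {dataset.neuropile_volume_um3!r}"
        )

    return violations
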