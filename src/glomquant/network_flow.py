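"""Class-level flow aggregation, ratio-based classification and network export.

Flow percentages are shares of the *grand total* of contacts among included
bodies (so the shares of all class pairs sum to 100%), which is how
class-level pathway charts for these volumes are normalized.

The ratio classifier predicts the major class of a cell from its pre:post
contact ratio alone: ORNs are predominantly presynaptic (class ratios near
4-5), LNs balanced (near 1), PNs predominantly postsynaptic (near 0.2-0.4).
The default thresholds 2.5 and 0.6 sit between those clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import CLASS_ORDER, GlomerulusDataset
from .matrix_pipeline import ContactMatrix

__all__ = [
    "ClassificationRules",
    "aggregate_by_class",
    "classify_by_ratio",
    "export_network",
    "class_labels",
]


def class_labels(
    dataset: GlomerulusDataset, bodies: list[int], level: str = "major"
) -> dict[int, str]:
    """Class (or subtype) label per body; the orphan sentinel and bodies
    missing from the cell table are labelled "orphan"."""
    cells = dataset.cells_by_id()
    labels: dict[int, str] = {}
    for b in bodies:
        cell = cells.get(b)
        if cell is None:
            labels[b] = "orphan"
        elif level == "major":
            labels[b] = cell.cell_class
        elif level == "subtype":
            labels[b] = cell.subtype if cell.subtype != "unknown" else cell.cell_class
        else:
            raise ValueError(f"unknown level {level!r}")
    return labels


def aggregate_by_class(
    matrix: ContactMatrix,
    classes: dict[int, str],
    level: str = "major",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate a cell matrix by class label.

    Returns ``(class_matrix, flows)`` where ``class_matrix`` is a square
    DataFrame of summed contacts (rows presynaptic) and ``flows`` a long
    table with one row per ordered class pair carrying ``contacts`` and
    ``percent_of_total`` (share of the grand total, so percentages over all
    class pairs sum to 100).

    Raises if any matrix body lacks a label.
    """
    unlabelled = [b for b in matrix.bodies if b not in classes]
    if unlabelled:
        raise ValueError(f"bodies without class labels: {unlabelled}")

    known_order = {c: i for i, c in enumerate(CLASS_ORDER)}
    labels = sorted(
        {classes[b] for b in matrix.bodies},
        key=lambda c: (known_order.get(c, len(known_order)), c),
    )
    idx = {c: i for i, c in enumerate(labels)}
    agg = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for ii, b_pre in enumerate(matrix.bodies):
        row = matrix.counts[ii]
        i = idx[classes[b_pre]]
        for jj, b_post in enumerate(matrix.bodies):
            if row[jj]:
                agg[i, idx[classes[b_post]]] += row[jj]
    class_matrix = pd.DataFrame(agg, index=labels, columns=labels)

    total = agg.sum()
    rows = []
    for pre in labels:
        for post in labels:
            contacts = int(class_matrix.loc[pre, post])
            rows.append(
                {
                    "pre_class": pre,
                    "post_class": post,
                    "contacts": contacts,
                    "percent_of_total": 100.0 * contacts / total if total else np.nan,
                }
            )
    return class_matrix, pd.DataFrame(rows)


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds on the pre:post ratio separating the major classes.

    ratio >= ``orn_min`` -> ORN; ``pn_max`` < ratio < ``orn_min`` -> LN;
    ratio <= ``pn_max`` -> PN; NaN ratio -> unclassifiable.
    ``boundary_margin`` is the relative distance to a threshold below which
    a prediction is annotated as near-boundary.
    """

    orn_min: float = 2.5
    pn_max: float = 0.6
    boundary_margin: float = 0.2


def classify_by_ratio(
    stats: pd.DataFrame, rules: ClassificationRules | None = None
) -> pd.DataFrame:
    """Predict the major class of every body from its pre:post ratio.

    ``stats`` is the table from
    :func:`glomquant.matrix_pipeline.per_cell_stats` (only the
    ``pre_post_ratio`` column is used).  Returns a DataFrame indexed like
    ``stats`` with columns ``predicted_class`` (ORN / LN / PN /
    unclassifiable) and ``note`` ("near_boundary" when the ratio is within
    ``boundary_margin`` of a threshold, else "").
    """
    rules = rules or ClassificationRules()
    preds, notes = [], []
    for ratio in stats["pre_post_ratio"]:
        if not np.isfinite(ratio):
            preds.append("unclassifiable")
            notes.append("undefined_ratio")
            continue
        if ratio >= rules.orn_min:
            preds.append("ORN")
        elif ratio > rules.pn_max:
            preds.append("LN")
        else:
            preds.append("PN")
        near = any(
            thr * (1 - rules.boundary_margin)
            <= ratio
            <= thr * (1 + rules.boundary_margin)
            for thr in (rules.orn_min, rules.pn_max)
        )
        notes.append("near_boundary" if near else "")
    return pd.DataFrame(
        {"predicted_class": preds, "note": notes}, index=stats.index
    )


def relabel_ln_subtypes(
    matrix: ContactMatrix,
    dataset: GlomerulusDataset,
    min_orn_contacts: int = 1,
) -> dict[int, str]:
    """Split LN bodies into LN2L (contacting ORNs) vs LN1 (not).

    The two major LN groups share soma location and entry tract and are
    distinguished by whether they make or receive at least
    ``min_orn_contacts`` contacts with ORNs.  Returns a body_id -> subtype
    mapping for the LN bodies in the matrix; other bodies are untouched.
    """
    cells = dataset.cells_by_id()
    orn_idx = [
        i
        for i, b in enumerate(matrix.bodies)
        if b in cells and cells[b].cell_class in ("ORN_ipsi", "ORN_contra")
    ]
    out: dict[int, str] = {}
    for i, b in enumerate(matrix.bodies):
        cell = cells.get(b)
        if cell is None or cell.cell_class != "LN":
            continue
        orn_contacts = int(
            matrix.counts[i, orn_idx].sum() + matrix.counts[orn_idx, i].sum()
        )
        out[b] = "LN2L" if orn_contacts >= min_orn_contacts else "LN1"
    return out


def _as_graph(
    matrix: pd.DataFrame | ContactMatrix, node_attrs: dict | None = None
) -> nx.DiGraph:
    frame = matrix.to_frame() if isinstance(matrix, ContactMatrix) else matrix
    graph = nx.DiGraph()
    for node in frame.index:
        attrs = (node_attrs or {}).get(node, {})
        graph.add_node(str(node), **attrs)
    for pre in frame.index:
        for post in frame.columns:
            count = int(frame.loc[pre, post])
            if count:
                graph.add_edge(str(pre), str(post), count=count)
    return graph


def export_network(
    matrix: pd.DataFrame | ContactMatrix,
    path,
    format: str = "graphml",
    node_attrs: dict | None = None,
) -> None:
    """Export a (cell- or class-level) matrix as a directed network file.

    ``format`` is one of ``"graphml"``, ``"dot"`` or ``"edgelist"`` (CSV
    ``pre, post, count``, re-readable by
    :func:`glomquant.io_formats.read_matrix`).  Nodes keep the matrix
    order; edges carry the contact count; self-loops encode recurrent
    (within-class or autaptic) contacts.  ``node_attrs`` maps node label to
    a dict of attributes (e.g. class, cell count).
    """
    path = Path(path)
    graph = _as_graph(matrix, node_attrs)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "dot":
        lines = ["digraph glomerulus {"]
        for node, attrs in graph.nodes(data=True):
            extra = "".join(f' {k}="{v}"' for k, v in sorted(attrs.items()))
            lines.append(f'  "{node}" [{extra.strip()}];' if extra else f'  "{node}";')
        for u, v, attrs in graph.edges(data=True):
            lines.append(f'  "{u}" -> "{v}" [label={attrs["count"]}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "edgelist":
        frame = matrix.to_frame() if isinstance(matrix, ContactMatrix) else matrix
        with path.open("w", newline="", encoding="utf-8") as fh:
            fh.write("pre,post,count\n")
            for pre in frame.index:
                for post in frame.columns:
                    count = int(frame.loc[pre, post])
                    if count:
                        fh.write(f"{pre},{post},{count}\n")
    else:
        raise ValueError(f"unsupported format {format!r}")
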