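"""Headline statistics of a labelled contact matrix.

Computes, from any cell-by-cell contact matrix (e.g. a deposited
connectivity spreadsheet read by :func:`glomquant.io_formats.read_matrix`,
or a matrix built by the pipeline), the selectivity and reciprocity
numbers used to characterize a glomerulus connectome: possible vs
connected ordered pairs, the >= 3 and > 10 strength tails, reciprocal-pair
counts, and — when class labels are available — class-aggregate pre:post
ratios and presynaptic output shares.
"""

from __future__ import annotations

import numpy as np

from .io_formats import MatrixTable
from .matrix_pipeline import ContactMatrix, connectivity_summary
from .reciprocity import pair_table, reciprocity_analysis

__all__ = ["matrix_report"]


def matrix_report(
    table: MatrixTable,
    classes: dict[str, str] | None = None,
    min_each: int = 3,
    band: tuple[float, float] = (0.25, 4.0),
    band_mode: str = "within",
) -> dict:
    """Selectivity and reciprocity summary of a labelled contact matrix.

    ``classes`` optionally maps each row/column label to a major class
    (ORN_ipsi / ORN_contra / PN / LN / other / orphan); class-dependent
    entries are omitted when it is not given.

    Returns a flat dict: ``n_bodies``, ``possible_pairs``,
    ``connected_pairs``, ``pct_connected``, ``pairs_ge3``,
    ``pct_ge3_of_connected``, ``pairs_gt10``, ``n_reciprocal``,
    ``n_strong``, ``pct_reciprocal`` and, with classes,
    ``orn_pre_share_pct``, ``orn_ipsi_pre_post_ratio``,
    ``orn_contra_pre_post_ratio``.
    """
    if not table.is_square:
        raise ValueError("matrix_report requires a square labelled matrix")
    bodies = list(range(len(table.row_labels)))
    matrix = ContactMatrix(bodies, table.counts)
    report = connectivity_summary(matrix)
    _, summary = reciprocity_analysis(
        pair_table(matrix), min_each=min_each, band=band, band_mode=band_mode
    )
    report.update(
        n_pairs_universe=summary.n_universe,
        n_reciprocal=summary.n_reciprocal,
        n_strong=summary.n_strong,
        pct_reciprocal=summary.pct_reciprocal,
    )

    if classes is not None:
        missing = [lab for lab in table.row_labels if lab not in classes]
        if missing:
            raise ValueError(f"labels without class: {missing[:5]}")
        counts = np.asarray(table.counts)
        total = counts.sum()
        label_classes = [classes[lab] for lab in table.row_labels]

        def _ratio(cls_members) -> float:
            idx = [i for i, c in enumerate(label_classes) if c in cls_members]
            pre = counts[idx, :].sum()
            post = counts[:, idx].sum()
            return float(pre / post) if post else float("nan")

        orn = {"ORN_ipsi", "ORN_contra"}
        orn_idx = [i for i, c in enumerate(label_classes) if c in orn]
        report.update(
            orn_pre_share_pct=100.0 * counts[orn_idx, :].sum() / total
            if total
            else float("nan"),
            orn_ipsi_pre_post_ratio=_ratio({"ORN_ipsi"}),
            orn_contra_pre_post_ratio=_ratio({"ORN_contra"}),
            pn_pre_post_ratio=_ratio({"PN"}),
            ln_pre_post_ratio=_ratio({"LN"}),
        )
    return report
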