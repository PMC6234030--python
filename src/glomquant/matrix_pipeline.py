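"""From polyadic synapses to the cell-level contact matrix and statistics.

The counting unit throughout is the *contact*: one PSD yields one directed
pre -> post contact, so a T-bar with k PSDs contributes k contacts (the k
intercepts are coordinately linked but counted separately, matching how
connectivity matrices for these volumes are tabulated).  Autapses (pre ==
post) are retained and land on the matrix diagonal.  T-bars with no PSD are
dropped before any counting.

The inclusion rule for the matrix is a minimum number of contacts per body.
Two readings of "more than 50 contacts" are supported via ``count_mode``:
``"total"`` (pre + post >= min_total, the default) and ``"either"`` (pre >=
min_total or post >= min_total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    CLASS_ORDER,
    DirectedContact,
    GlomerulusDataset,
    ORPHAN_SENTINEL,
)

__all__ = [
    "ContactMatrix",
    "expand_contacts",
    "cell_contact_totals",
    "filter_included_bodies",
    "build_contact_matrix",
    "per_cell_stats",
    "class_stats",
    "strength_distribution",
    "StrengthDistribution",
    "connectivity_summary",
    "synapse_density",
    "active_tbars",
]

logger = logging.getLogger(__name__)


@dataclass
class ContactMatrix:
    """Square contact-count matrix over an ordered list of included bodies."""

    bodies: list[int]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.bodies)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over bodies")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self._index = {b: i for i, b in enumerate(self.bodies)}

    def index(self, body_id: int) -> int:
        return self._index[body_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.bodies, columns=self.bodies)


def active_tbars(dataset: GlomerulusDataset) -> list:
    """T-bars with at least one PSD (bare T-bars are excluded from counting)."""
    with_psd = {p.tbar_id for p in dataset.psds}
    return [t for t in dataset.tbars if t.tbar_id in with_psd]


def expand_contacts(dataset: GlomerulusDataset) -> list[DirectedContact]:
    """Expand polyadic synapses into one directed contact per PSD.

    PSDs whose T-bar or whose own body reference cannot be resolved to the
    cell table are attributed to the orphan sentinel and logged, never
    dropped, so contact counts are conserved.
    """
    bodies = {c.body_id for c in dataset.cells}
    tbar_pre = {t.tbar_id: t.pre_body for t in dataset.tbars}
    contacts: list[DirectedContact] = []
    n_unresolved = 0
    for psd in dataset.psds:
        pre = tbar_pre.get(psd.tbar_id, ORPHAN_SENTINEL)
        if pre != ORPHAN_SENTINEL and pre not in bodies:
            pre = ORPHAN_SENTINEL
            n_unresolved += 1
        post = psd.post_body
        if post != ORPHAN_SENTINEL and post not in bodies:
            post = ORPHAN_SENTINEL
            n_unresolved += 1
        contacts.append(DirectedContact(pre, post, psd.tbar_id))
    if n_unresolved:
        logger.warning(
            "%d contact endpoints could not be resolved to the cell table; "
            "attributed to the orphan sentinel",
            n_unresolved,
        )
    return contacts


def cell_contact_totals(contacts: list[DirectedContact]) -> pd.DataFrame:
    """Per-body presynaptic, postsynaptic and total contact counts.

    Totals conserve: the column sums of ``pre_contacts`` and
    ``post_contacts`` each equal the number of contacts.
    """
    pre: dict[int, int] = {}
    post: dict[int, int] = {}
    for c in contacts:
        pre[c.pre_body] = pre.get(c.pre_body, 0) + 1
        post[c.post_body] = post.get(c.post_body, 0) + 1
    bodies = sorted(set(pre) | set(post))
    frame = pd.DataFrame(
        {
            "pre_contacts": [pre.get(b, 0) for b in bodies],
            "post_contacts": [post.get(b, 0) for b in bodies],
        },
        index=pd.Index(bodies, name="body_id"),
    )
    frame["total"] = frame["pre_contacts"] + frame["post_contacts"]
    return frame


def filter_included_bodies(
    totals: pd.DataFrame, min_total: int = 51, count_mode: str = "total"
) -> list[int]:
    """Bodies meeting the inclusion criterion, sorted by id.

    ``count_mode="total"``: pre + post >= ``min_total`` (the default 51
    implements "more than 50 contacts").  ``count_mode="either"``: at least
    ``min_total`` pre- or postsynaptic contacts.  The orphan sentinel is
    never included (identified orphan bodies, which have their own ids, are).
    """
    if count_mode == "total":
        mask = totals["total"] >= min_total
    elif count_mode == "either":
        mask = (totals["pre_contacts"] >= min_total) | (
            totals["post_contacts"] >= min_total
        )
    else:
        raise ValueError(f"unknown count_mode {count_mode!r}")
    included = [int(b) for b in totals.index[mask] if b != ORPHAN_SENTINEL]
    return sorted(included)


def _class_order_key(dataset: GlomerulusDataset):
    cells = dataset.cells_by_id()
    rank = {cls: i for i, cls in enumerate(CLASS_ORDER)}

    def key(body_id: int):
        cell = cells.get(body_id)
        if cell is None:
            return (rank["orphan"], "", body_id)
        return (rank.get(cell.cell_class, len(rank)), cell.name, body_id)

    return key


def build_contact_matrix(
    contacts: list[DirectedContact],
    included: list[int],
    dataset: GlomerulusDataset | None = None,
    order: str = "class",
) -> ContactMatrix:
    """Count contacts into a square matrix over the included bodies.

    Entry (i, j) is the number of contacts with pre = body i and post =
    body j; the diagonal carries autapses.  Contacts touching an excluded
    body are left out (the conservation identity
    ``counts.sum() + excluded-touching contacts == len(contacts)`` holds).

    ``order="class"`` sorts bodies by class (PN, LN, ORN_ipsi, ORN_contra,
    other, orphan) then name, matching matrix-figure convention; it
    requires ``dataset``.  ``order="id"`` sorts by body id.
    """
    if not included:
        raise ValueError("included body set is empty")
    if order == "class":
        if dataset is None:
            raise ValueError('order="class" requires the dataset for labels')
        bodies = sorted(included, key=_class_order_key(dataset))
    elif order == "id":
        bodies = sorted(included)
    else:
        raise ValueError(f"unknown order {order!r}")
    index = {b: i for i, b in enumerate(bodies)}
    counts = np.zeros((len(bodies), len(bodies)), dtype=np.int64)
    for c in contacts:
        i = index.get(c.pre_body)
        j = index.get(c.post_body)
        if i is not None and j is not None:
            counts[i, j] += 1
    return ContactMatrix(bodies, counts)


def per_cell_stats(
    dataset: GlomerulusDataset, contacts: list[DirectedContact]
) -> pd.DataFrame:
    """Per-cell synaptic statistics table.

    Columns mirror the per-cell tables published with dense reconstructions:
    name, class, subtype, volume, T-bar count (T-bars with >= 1 PSD),
    pre_contacts (PSDs driven by the cell's T-bars), post_contacts (PSDs on
    the cell), psds_per_tbar, pre_post_ratio and tbar_density (T-bars per
    µm³ of intraglomerular volume).  Undefined ratios (zero denominator)
    are NaN, never infinity, so tables serialize cleanly.
    """
    totals = cell_contact_totals(contacts)
    tbar_counts: dict[int, int] = {}
    for t in active_tbars(dataset):
        tbar_counts[t.pre_body] = tbar_counts.get(t.pre_body, 0) + 1

    rows = []
    for cell in dataset.cells:
        b = cell.body_id
        n_tbars = tbar_counts.get(b, 0)
        pre = int(totals["pre_contacts"].get(b, 0))
        post = int(totals["post_contacts"].get(b, 0))
        rows.append(
            {
                "body_id": b,
                "name": cell.name,
                "cell_class": cell.cell_class,
                "subtype": cell.subtype,
                "volume_um3": cell.volume_um3,
                "n_tbars": n_tbars,
                "pre_contacts": pre,
                "post_contacts": post,
                "total_contacts": pre + post,
                "psds_per_tbar": pre / n_tbars if n_tbars else np.nan,
                "pre_post_ratio": pre / post if post else np.nan,
                "tbar_density": n_tbars / cell.volume_um3
                if cell.volume_um3 > 0
                else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("body_id")


def class_stats(stats: pd.DataFrame, by: str = "cell_class") -> pd.DataFrame:
    """Mean ± SD of the per-cell statistics grouped by class or subtype."""
    numeric = [
        "n_tbars",
        "pre_contacts",
        "post_contacts",
        "total_contacts",
        "psds_per_tbar",
        "pre_post_ratio",
        "tbar_density",
    ]
    grouped = stats.groupby(by)[numeric]
    out = grouped.agg(["mean", "std", "count"])
    # aggregate ratio of class totals (robust to per-cell undefined ratios)
    sums = stats.groupby(by)[["pre_contacts", "post_contacts"]].sum()
    out[("aggregate_pre_post_ratio", "")] = (
        sums["pre_contacts"] / sums["post_contacts"].replace(0, np.nan)
    )
    return out


@dataclass
class StrengthDistribution:
    """Histogram of connection strengths over nonzero ordered cell pairs."""

    histogram: pd.Series  # index: strength, value: number of ordered pairs

    @property
    def n_connected(self) -> int:
        return int(self.histogram.sum())

    def tail(self, k: int) -> int:
        """Number of ordered connected pairs with strength >= k."""
        return int(self.histogram[self.histogram.index >= k].sum())

    def tail_fraction(self, k: int) -> float:
        return self.tail(k) / self.n_connected if self.n_connected else np.nan


def strength_distribution(matrix: ContactMatrix) -> StrengthDistribution:
    """Distribution of per-pair contact counts over all nonzero ordered pairs
    (diagonal included: an autapse pairing is a connected pair)."""
    values = matrix.counts[matrix.counts > 0]
    series = pd.Series(values).value_counts().sort_index()
    series.index.name = "strength"
    return StrengthDistribution(series)


def connectivity_summary(matrix: ContactMatrix) -> dict:
    """Selectivity summary of a contact matrix.

    Reports the number of possible ordered pairs (n²), how many are actually
    connected, and the >= 3 and > 10 strength tails used to describe pathway
    strength.
    """
    dist = strength_distribution(matrix)
    n = len(matrix.bodies)
    possible = n * n
    connected = dist.n_connected
    return {
        "n_bodies": n,
        "possible_pairs": possible,
        "connected_pairs": connected,
        "pct_connected": 100.0 * connected / possible if possible else np.nan,
        "pairs_ge3": dist.tail(3),
        "pct_ge3_of_connected": 100.0 * dist.tail_fraction(3),
        "pairs_gt10": dist.tail(11),
        "total_contacts": int(matrix.counts.sum()),
    }


def synapse_density(dataset: GlomerulusDataset) -> float:
    """Synapses (T-bars with >= 1 PSD) per µm³ of neuropile volume."""
    if not (dataset.neuropile_volume_um3 > 0):
        raise ValueError("neuropile volume must be positive")
    return len(active_tbars(dataset)) / dataset.neuropile_volume_um3
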