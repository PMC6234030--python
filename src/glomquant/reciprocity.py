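"""Reciprocal connectivity between cell pairs.

A cell pair {a, b} is *reciprocal* when both directions carry at least
``min_each`` contacts (default 3, the minimum to acknowledge a pathway).
The *direction ratio* of a pair is forward/backward contacts; the *strong
reciprocity* criterion additionally constrains the ratio to a band (default
[0.25, 4]).  Two readings of the band are supported: ``band_mode="within"``
keeps pairs whose ratio lies inside the closed band (neither direction more
than four times the other) and ``band_mode="outside"`` keeps pairs at least
four times stronger in one direction.

The universe against which percentages are quoted is configurable: by
default, all unordered pairs whose *stronger* direction carries at least
``min_each`` contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .matrix_pipeline import ContactMatrix

__all__ = [
    "PairReciprocity",
    "ReciprocitySummary",
    "pair_table",
    "reciprocity_analysis",
    "reciprocity_matrix",
    "class_pair_reciprocity",
]


@dataclass(frozen=True)
class PairReciprocity:
    """Both directions of one unordered cell pair (a < b by id).

    ``ratio`` is forward/backward (a→b over b→a), NaN when backward is 0.
    ``reciprocal`` and ``strong`` are False until set by
    :func:`reciprocity_analysis`.
    """

    body_a: int
    body_b: int
    forward: int
    backward: int
    ratio: float
    reciprocal: bool = False
    strong: bool = False

    @property
    def stronger(self) -> int:
        return max(self.forward, self.backward)

    @property
    def weaker(self) -> int:
        return min(self.forward, self.backward)


@dataclass
class ReciprocitySummary:
    n_universe: int
    n_reciprocal: int
    n_strong: int
    pct_reciprocal: float
    pct_strong: float
    mean_stronger: float
    sd_stronger: float
    mean_weaker: float
    sd_weaker: float
    mean_strength: float
    sd_strength: float


def pair_table(matrix: ContactMatrix) -> list[PairReciprocity]:
    """All unordered pairs with at least one contact in either direction.

    The diagonal (autapses) is excluded; counts are read directly from the
    matrix.  Pairs are ordered by (body_a, body_b) with body_a < body_b.
    """
    order = np.argsort(matrix.bodies)
    pairs: list[PairReciprocity] = []
    counts = matrix.counts
    for ii in range(len(order)):
        for jj in range(ii + 1, len(order)):
            i, j = order[ii], order[jj]
            fwd = int(counts[i, j])
            bwd = int(counts[j, i])
            if fwd + bwd == 0:
                continue
            ratio = fwd / bwd if bwd else np.nan
            pairs.append(
                PairReciprocity(matrix.bodies[i], matrix.bodies[j], fwd, bwd, ratio)
            )
    return pairs


def reciprocity_analysis(
    pairs: list[PairReciprocity],
    min_each: int = 3,
    band: tuple[float, float] = (0.25, 4.0),
    band_mode: str = "within",
    universe: str = "stronger_ge_min",
) -> tuple[list[PairReciprocity], ReciprocitySummary]:
    """Annotate pairs with reciprocity flags and summarize.

    A pair is reciprocal iff min(forward, backward) >= ``min_each``.  A
    reciprocal pair is strong iff its ratio satisfies the band under the
    chosen mode (the closed band is used, so a ratio exactly 4 or 0.25 is
    "within").  Pairs with an undefined ratio are never reciprocal (backward
    = 0 implies weaker = 0 < min_each) and are excluded from ratio means.

    ``universe`` sets the denominator for percentages: ``"stronger_ge_min"``
    (pairs whose stronger direction >= min_each), ``"any_nonzero"`` (all
    input pairs), or ``"sum_ge_min"`` (forward + backward >= min_each).
    """
    lo, hi = band
    if lo > hi:
        raise ValueError(f"invalid band: {lo} > {hi}")
    if band_mode not in ("within", "outside"):
        raise ValueError(f"unknown band_mode {band_mode!r}")

    annotated: list[PairReciprocity] = []
    for p in pairs:
        reciprocal = p.weaker >= min_each
        strong = False
        if reciprocal and np.isfinite(p.ratio):
            inside = lo <= p.ratio <= hi
            strong = inside if band_mode == "within" else not inside
        annotated.append(replace(p, reciprocal=reciprocal, strong=strong))

    if universe == "stronger_ge_min":
        uni = [p for p in annotated if p.stronger >= min_each]
    elif universe == "any_nonzero":
        uni = list(annotated)
    elif universe == "sum_ge_min":
        uni = [p for p in annotated if p.forward + p.backward >= min_each]
    else:
        raise ValueError(f"unknown universe {universe!r}")

    recip = [p for p in annotated if p.reciprocal]
    strong_pairs = [p for p in annotated if p.strong]
    stronger = np.array([p.stronger for p in recip], dtype=float)
    weaker = np.array([p.weaker for p in recip], dtype=float)
    both = np.concatenate([stronger, weaker]) if recip else np.array([])

    def _mean(a):
        return float(a.mean()) if a.size else np.nan

    def _sd(a):
        return float(a.std(ddof=1)) if a.size > 1 else np.nan

    n_uni = len(uni)
    summary = ReciprocitySummary(
        n_universe=n_uni,
        n_reciprocal=len(recip),
        n_strong=len(strong_pairs),
        pct_reciprocal=100.0 * len(recip) / n_uni if n_uni else np.nan,
        pct_strong=100.0 * len(strong_pairs) / n_uni if n_uni else np.nan,
        mean_stronger=_mean(stronger),
        sd_stronger=_sd(stronger),
        mean_weaker=_mean(weaker),
        sd_weaker=_sd(weaker),
        mean_strength=_mean(both),
        sd_strength=_sd(both),
    )
    return annotated, summary


def reciprocity_matrix(
    pairs: list[PairReciprocity], bodies: list[int]
) -> pd.DataFrame:
    """Square ratio matrix over ``bodies`` for export.

    Entry (i, j) = contacts(i→j)/contacts(j→i) for pairs flagged
    reciprocal; values are reflected about the diagonal as inverses (0.25
    one way corresponds to 4 the other).  Non-qualifying entries are NaN.
    """
    frame = pd.DataFrame(np.nan, index=bodies, columns=bodies)
    for p in pairs:
        if not p.reciprocal or p.backward == 0 or p.forward == 0:
            continue
        frame.loc[p.body_a, p.body_b] = p.forward / p.backward
        frame.loc[p.body_b, p.body_a] = p.backward / p.forward
    return frame


def class_pair_reciprocity(
    pairs: list[PairReciprocity],
    classes: dict[int, str],
    min_each: int = 3,
) -> pd.DataFrame:
    """Reciprocity summarized per unordered class pair.

    For each unordered pair of class labels (X, Y) with at least one
    qualifying cell pair (stronger direction >= ``min_each``), reports:

    * ``n_pairs`` — qualifying cell pairs with one member in X, one in Y;
    * ``pct_reciprocal`` — share of those that are reciprocal (both
      directions >= min_each, taken from the pairs' flags);
    * ``dominant_pre`` / ``pct_dominant`` — the class that is presynaptic
      in the majority of reciprocal pairs and its share of them (pairs with
      equal counts in both directions are counted in neither direction);
    * ``mean_ratio`` — mean over reciprocal pairs of the ratio oriented
      dominant-class-pre over the other direction.

    Classes with no qualifying pairs simply do not appear.
    """
    missing = {p.body_a for p in pairs if p.body_a not in classes} | {
        p.body_b for p in pairs if p.body_b not in classes
    }
    if missing:
        raise ValueError(f"bodies without class labels: {sorted(missing)}")

    buckets: dict[tuple[str, str], list[PairReciprocity]] = {}
    for p in pairs:
        if p.stronger < min_each:
            continue
        ca, cb = classes[p.body_a], classes[p.body_b]
        key = tuple(sorted((ca, cb)))
        buckets.setdefault(key, []).append(p)

    rows = []
    for (cx, cy), members in sorted(buckets.items()):
        recip = [p for p in members if p.reciprocal]
        # direction votes: which class is pre in the stronger direction
        votes = {cx: 0, cy: 0}
        ratios: list[float] = []
        for p in recip:
            pre_class = classes[p.body_a] if p.forward > p.backward else (
                classes[p.body_b] if p.backward > p.forward else None
            )
            if pre_class is not None:
                votes[pre_class] += 1
        if recip:
            dominant = max(votes, key=lambda c: (votes[c], c))
            for p in recip:
                a_is_dom = classes[p.body_a] == dominant
                if classes[p.body_a] == classes[p.body_b]:
                    # same-class pair: orient stronger over weaker
                    ratios.append(p.stronger / p.weaker if p.weaker else np.nan)
                elif a_is_dom:
                    ratios.append(p.forward / p.backward if p.backward else np.nan)
                else:
                    ratios.append(p.backward / p.forward if p.forward else np.nan)
            ratios = [r for r in ratios if np.isfinite(r)]
            pct_dom = 100.0 * votes[dominant] / len(recip)
        else:
            dominant, pct_dom = "", np.nan
        rows.append(
            {
                "class_a": cx,
                "class_b": cy,
                "n_pairs": len(members),
                "n_reciprocal": len(recip),
                "pct_reciprocal": 100.0 * len(recip) / len(members),
                "dominant_pre": dominant,
                "pct_dominant": pct_dom,
                "mean_ratio": float(np.mean(ratios)) if ratios else np.nan,
            }
        )
    return pd.DataFrame(rows)
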