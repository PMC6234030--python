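"""Synthetic glomerulus generator with ground truth for every pipeline stage.

The generator emulates the statistical structure of a densely reconstructed
antennal-lobe glomerulus:

* a census of 51 ipsilateral ORNs, 56 contralateral ORNs, 18 PNs and 56 LNs,
  plus a handful of minor identified cells and orphan fragments (192 bodies
  in all at the defaults);
* polyadic synapses with 1-9 PSDs per T-bar and mean 3.4 (a shifted
  truncated-Poisson law whose rate is tuned numerically to the target mean);
* class-dependent contact propensities calibrated so the expected class-flow
  shares match the study percentages (ORN output 59.8% of all contacts,
  split 39.5 / 14.5 / 5.9 to PN / LN / ORN, and so on);
* heavy-tailed per-pair connection strengths, grown by a Pólya-urn
  (preferential-attachment) scheme over partner cells;
* occasional PN autapses, and T-bar positions clustered around glomerulus
  centres so density mapping sees realistic plateaus.

A single seeded NumPy generator drives every draw, in a documented order
(vol* cell T-bar counts, T-bar positions, PSD counts, PSD target classes,
partner assignment, PSD offsets), so the same seed and config give an
identical dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import poisson

from .core_model import CellBody, GlomerulusDataset, PSD, TBar

__all__ = [
    "SpatialConfig",
    "SynthConfig",
    "GroundTruth",
    "psd_rate_for_mean",
    "truncated_psd_mean",
    "generate_glomerulus",
    "generate_point_cloud",
]

UM = 1000.0  # nm per µm

#: Share (%) of all contacts carried by each ordered pair of major classes.
DEFAULT_FLOW_TARGETS: dict[str, dict[str, float]] = {
    "ORN": {"PN": 39.5, "LN": 14.5, "ORN": 5.9},
    "LN": {"PN": 10.4, "ORN": 7.8, "LN": 9.6},
    "PN": {"LN": 6.4, "PN": 4.1, "ORN": 1.8},
}

_LN_SUBTYPES = (
    ["LN1"] * 17 + ["LN2L"] * 24 + ["LN2V"] + ["LN3"] + ["LN4"] + ["LN6"] * 2
    + ["LNV"] * 3 + ["LN_LV"] * 3 + ["LN_comm"] * 4
)
_PN_SUBTYPES = (
    ["mPN1"] * 3 + ["mlPN1"] * 2 + ["mlPN2"] * 3 + ["mlPN3"] * 2
    + ["lPN2"] * 4 + ["lPN2_comm"] + ["lPN4"] * 3
)
_OTHER_SUBTYPES = ["AST3", "5HT", "unknown", "unknown", "unknown"]


@dataclass(frozen=True)
class SpatialConfig:
    """Glomerulus centre layout for T-bar / point-cloud placement."""

    centers_um: tuple[tuple[float, float, float], ...] = ((25.0, 25.0, 25.0),)
    sigma_um: float = 4.5
    n_points: int = 50_000  # desk-scale point-cloud size
    weights: tuple[float, ...] | None = None  # per-centre mixing weights


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition defaults for the synthetic glomerulus.

    ``n_tbars`` is the expected total number of T-bars (minor cells
    included); per-cell counts are negative-binomial with dispersion
    ``nb_dispersion``.  ``flow_targets`` are shares (%) of all contacts per
    ordered major-class pair and drive both the allocation of T-bars to
    presynaptic classes and the per-PSD choice of target class.
    ``tail_alpha`` is the Pólya-urn reinforcement per assigned contact
    (heavier tails for larger values) and ``partner_shape`` the gamma shape
    of the static per-partner attractiveness (smaller = more skewed).
    """

    census: dict[str, int] = field(
        default_factory=lambda: {
            "ORN_ipsi": 51,
            "ORN_contra": 56,
            "PN": 18,
            "LN": 56,
            "other": 5,
            "orphan": 6,
        }
    )
    n_tbars: int = 11_144
    psd_mean: float = 3.4
    psd_max: int = 9
    flow_targets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FLOW_TARGETS.items()}
    )
    ipsi_share: float = 0.70  # ipsilateral share of ORN presynaptic output
    ipsi_post_share: float = 0.75  # ipsilateral share of ORN-targeted contacts
    nb_dispersion: float = 80.0
    minor_tbar_mean: float = 25.0
    minor_redirect_rate: float = 0.0175  # PSDs rewired to minor/orphan bodies
    autapse_rate: float = 0.01  # per-PSD autapse probability for PN T-bars
    tail_alpha: float = 5.0
    tail_alpha_by_pool: dict[str, float] | None = None  # overrides per post pool
    partner_shape: float = 100.0
    neuropile_volume_um3: float = 4858.0
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    seed: int = 0


@dataclass
class GroundTruth:
    """Generator-side truth used to score the pipeline."""

    classes: pd.DataFrame  # body_id, name, true_class, major, subtype
    pair_counts: pd.DataFrame  # pre_body, post_body, count (realized)
    config: SynthConfig


# ---------------------------------------------------------------------------
# PSD-count law


def truncated_psd_mean(rate: float, psd_max: int = 9) -> float:
    """Mean of 1 + X with X ~ Poisson(rate) truncated to 0..psd_max-1."""
    k = np.arange(psd_max)
    pmf = poisson.pmf(k, rate)
    pmf = pmf / pmf.sum()
    return float(1.0 + (k * pmf).sum())


def psd_rate_for_mean(target_mean: float = 3.4, psd_max: int = 9) -> float:
    """Poisson rate whose shifted truncated law has the target mean."""
    if not 1.0 < target_mean < psd_max:
        raise ValueError("target mean must lie strictly between 1 and psd_max")
    return brentq(
        lambda lam: truncated_psd_mean(lam, psd_max) - target_mean, 1e-6, 50.0
    )


def _draw_psd_counts(rng: np.random.Generator, n: int, rate: float, psd_max: int):
    """n draws of 1 + truncated Poisson(rate), vectorized with redraws."""
    out = 1 + rng.poisson(rate, size=n)
    bad = out > psd_max
    while bad.any():
        out[bad] = 1 + rng.poisson(rate, size=int(bad.sum()))
        bad = out > psd_max
    return out


# ---------------------------------------------------------------------------
# glomerulus generation


def _build_cells(config: SynthConfig) -> tuple[list[CellBody], dict[str, list[int]]]:
    cells: list[CellBody] = []
    members: dict[str, list[int]] = {}
    body_id = 100
    for cls in ("ORN_ipsi", "ORN_contra", "PN", "LN", "other", "orphan"):
        n = config.census.get(cls, 0)
        if cls == "LN" and n == len(_LN_SUBTYPES):
            subtypes = _LN_SUBTYPES
        elif cls == "PN" and n == len(_PN_SUBTYPES):
            subtypes = _PN_SUBTYPES
        elif cls == "other" and n == len(_OTHER_SUBTYPES):
            subtypes = _OTHER_SUBTYPES
        else:
            subtypes = ["unknown"] * n
        soma = {
            "ORN_ipsi": "antennal_nerve",
            "ORN_contra": "commissure",
            "PN": "lateral",
            "LN": "dorsolateral",
            "other": "posterior",
            "orphan": "",
        }[cls]
        ids = []
        counters: dict[str, int] = {}
        for sub in subtypes:
            counters[sub] = counters.get(sub, 0) + 1
            stem = sub if sub != "unknown" else cls
            cells.append(
                CellBody(
                    body_id=body_id,
                    name=f"{stem}_{counters[sub]}",
                    cell_class=cls,
                    subtype=sub,
                    soma_location=soma,
                )
            )
            ids.append(body_id)
            body_id += 1
        members[cls] = ids
    return cells, members


def _tbar_means(config: SynthConfig, members: dict[str, list[int]]) -> dict[str, float]:
    """Expected T-bars per cell, per class, from the flow pre-shares."""
    pre_share = {cls: sum(row.values()) for cls, row in config.flow_targets.items()}
    total_share = sum(pre_share.values())
    n_minor = len(members["other"]) + len(members["orphan"])
    main_tbars = config.n_tbars - n_minor * config.minor_tbar_mean
    if main_tbars <= 0:
        raise ValueError("n_tbars too small for the minor-cell allocation")
    means: dict[str, float] = {}
    orn = main_tbars * pre_share["ORN"] / total_share
    if members["ORN_ipsi"]:
        means["ORN_ipsi"] = orn * config.ipsi_share / len(members["ORN_ipsi"])
    if members["ORN_contra"]:
        means["ORN_contra"] = orn * (1 - config.ipsi_share) / len(members["ORN_contra"])
    for cls in ("PN", "LN"):
        if members[cls]:
            means[cls] = (
                main_tbars * pre_share[cls] / total_share / len(members[cls])
            )
    for cls in ("other", "orphan"):
        means[cls] = config.minor_tbar_mean
    return means


def generate_glomerulus(
    config: SynthConfig | None = None,
) -> tuple[GlomerulusDataset, GroundTruth]:
    """Generate a synthetic glomerulus dataset plus ground truth.

    The returned dataset passes :func:`glomquant.core_model.validate_dataset`
    and carries, for the default configuration, roughly the study-scale
    totals: ~11,100 T-bars, ~37,800 PSDs with mean 3.4 per T-bar, 192 bodies
    exceeding 50 contacts, and class-flow shares matching ``flow_targets``.
    """
    config = config or SynthConfig()
    for cls, row in config.flow_targets.items():
        if sum(row.values()) <= 0:
            raise ValueError(f"propensity row {cls!r} is all zero")
    rng = np.random.default_rng(config.seed)

    cells, members = _build_cells(config)
    means = _tbar_means(config, members)
    pool_of = {
        "ORN_ipsi": "ORN",
        "ORN_contra": "ORN",
        "PN": "PN",
        "LN": "LN",
    }
    # post pools: ORN pool mixes ipsi+contra members
    pools = {
        "ORN": members["ORN_ipsi"] + members["ORN_contra"],
        "PN": members["PN"],
        "LN": members["LN"],
    }
    minor_bodies = members["other"] + members["orphan"]

    # overall post-class shares (column sums of the flow matrix), used for
    # PSDs emitted by minor cells
    post_share = {"PN": 0.0, "LN": 0.0, "ORN": 0.0}
    for row in config.flow_targets.values():
        for post, share in row.items():
            post_share[post] += share
    post_classes = ("PN", "LN", "ORN")
    post_probs_minor = np.array([post_share[c] for c in post_classes])
    post_probs_minor = post_probs_minor / post_probs_minor.sum()

    # --- draw 1: per-cell T-bar counts (negative binomial), fixed cell order
    k = config.nb_dispersion
    tbar_counts: dict[int, int] = {}
    for cell in cells:
        mu = means.get(cell.cell_class, 0.0)
        if mu <= 0:
            tbar_counts[cell.body_id] = 0
            continue
        tbar_counts[cell.body_id] = int(
            rng.negative_binomial(k, k / (k + mu))
        )

    # --- draw 2: per-cell intraglomerular volumes from T-bar density
    volumes: dict[int, float] = {}
    for cell in cells:
        density = rng.gamma(9.0, 2.5 / 9.0)  # T-bars per µm³, mean 2.5
        volumes[cell.body_id] = (tbar_counts[cell.body_id] + 1) / density
    cells = [replace(c, volume_um3=round(volumes[c.body_id], 3)) for c in cells]

    # --- draw 3: T-bar positions (Gaussian mixture over glomerulus centres)
    spatial = config.spatial
    if spatial.sigma_um <= 0:
        raise ValueError("sigma_um must be positive")
    centers = np.asarray(spatial.centers_um, dtype=float) * UM
    weights = (
        np.asarray(spatial.weights, dtype=float)
        if spatial.weights is not None
        else np.ones(len(centers))
    )
    weights = weights / weights.sum()

    tbars: list[TBar] = []
    tbar_pre: list[int] = []
    tbar_id = 1
    for cell in cells:
        n = tbar_counts[cell.body_id]
        if n == 0:
            continue
        which = rng.choice(len(centers), size=n, p=weights)
        pos = centers[which] + rng.normal(0.0, spatial.sigma_um * UM, size=(n, 3))
        pos = np.clip(pos, 0.0, None)
        for row in pos:
            tbars.append(TBar(tbar_id, (row[0], row[1], row[2]), cell.body_id))
            tbar_pre.append(cell.body_id)
            tbar_id += 1

    # --- draw 4: PSD counts per T-bar
    rate = psd_rate_for_mean(config.psd_mean, config.psd_max)
    psd_counts = _draw_psd_counts(rng, len(tbars), rate, config.psd_max)

    # --- draws 5-7: per-PSD target class, partner assignment (Pólya urn),
    # and PSD position offsets
    class_of = {c.body_id: c.cell_class for c in cells}
    row_probs: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for pre_pool, row in config.flow_targets.items():
        names = tuple(row)
        probs = np.array([row[n] for n in names], dtype=float)
        row_probs[pre_pool] = (names, np.cumsum(probs / probs.sum()))
    post_cum_minor = np.cumsum(post_probs_minor)

    base_attract = {
        pool: rng.gamma(config.partner_shape, 1.0 / config.partner_shape, len(ids))
        for pool, ids in pools.items()
    }
    # ORN-targeted contacts concentrate on ipsilateral axons: tilt the ORN
    # pool's attractiveness so ipsi members carry ipsi_post_share of them
    n_ipsi, n_contra = len(members["ORN_ipsi"]), len(members["ORN_contra"])
    if n_ipsi and n_contra:
        tilt = np.ones(n_ipsi + n_contra)
        tilt[:n_ipsi] = config.ipsi_post_share / n_ipsi
        tilt[n_ipsi:] = (1.0 - config.ipsi_post_share) / n_contra
        base_attract["ORN"] *= tilt * (n_ipsi + n_contra)
    alpha_by_pool = {pool: config.tail_alpha for pool in pools}
    alpha_by_pool.update(config.tail_alpha_by_pool or {})
    urns: dict[tuple[int, str], np.ndarray] = {}

    psds: list[PSD] = []
    psd_id = 1
    for t_idx, tbar in enumerate(tbars):
        pre_body = tbar.pre_body
        pre_cls = class_of[pre_body]
        pre_pool = pool_of.get(pre_cls)
        n_psd = psd_counts[t_idx]
        tpos = np.array(tbar.position)
        for _ in range(n_psd):
            u = rng.random()
            if u < config.minor_redirect_rate and minor_bodies:
                choices = [b for b in minor_bodies if b != pre_body] or minor_bodies
                post_body = choices[rng.integers(len(choices))]
            elif (
                pre_cls == "PN"
                and rng.random() < config.autapse_rate
            ):
                post_body = pre_body
            else:
                if pre_pool is None:  # minor presynaptic cell
                    post_pool = post_classes[
                        int(np.searchsorted(post_cum_minor, rng.random(), side="right"))
                    ]
                else:
                    names, cum = row_probs[pre_pool]
                    post_pool = names[
                        int(np.searchsorted(cum, rng.random(), side="right"))
                    ]
                key = (pre_body, post_pool)
                urn = urns.get(key)
                if urn is None:
                    urn = base_attract[post_pool].copy()
                    urns[key] = urn
                pool_ids = pools[post_pool]
                cum_urn = np.cumsum(urn)
                j = int(
                    np.searchsorted(cum_urn, rng.random() * cum_urn[-1], side="right")
                )
                # autapses only arise via the explicit autapse channel:
                # reject self-draws when an alternative partner exists
                while pool_ids[j] == pre_body and len(pool_ids) > 1:
                    j = int(
                        np.searchsorted(
                            cum_urn, rng.random() * cum_urn[-1], side="right"
                        )
                    )
                urn[j] += alpha_by_pool[post_pool]
                post_body = pool_ids[j]
            offset = rng.normal(0.0, 150.0, size=3)
            ppos = np.clip(tpos + offset, 0.0, None)
            psds.append(PSD(psd_id, tbar.tbar_id, post_body, tuple(ppos)))
            psd_id += 1

    dataset = GlomerulusDataset(
        cells=cells,
        tbars=tbars,
        psds=psds,
        neuropile_volume_um3=config.neuropile_volume_um3,
    )

    major = {
        "ORN_ipsi": "ORN",
        "ORN_contra": "ORN",
        "PN": "PN",
        "LN": "LN",
        "other": "other",
        "orphan": "orphan",
    }
    classes = pd.DataFrame(
        {
            "body_id": [c.body_id for c in cells],
            "name": [c.name for c in cells],
            "true_class": [c.cell_class for c in cells],
            "major": [major[c.cell_class] for c in cells],
            "subtype": [c.subtype for c in cells],
        }
    ).set_index("body_id")

    pre_of_tbar = {t.tbar_id: t.pre_body for t in tbars}
    pair_counter: dict[tuple[int, int], int] = {}
    for psd in psds:
        key = (pre_of_tbar[psd.tbar_id], psd.post_body)
        pair_counter[key] = pair_counter.get(key, 0) + 1
    pair_counts = pd.DataFrame(
        [
            {"pre_body": a, "post_body": b, "count": n}
            for (a, b), n in sorted(pair_counter.items())
        ]
    )

    return dataset, GroundTruth(classes=classes, pair_counts=pair_counts, config=config)


# ---------------------------------------------------------------------------
# point clouds


def generate_point_cloud(
    config: SynthConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a synapse point cloud from the configured glomerulus mixture.

    Returns ``(positions_nm, true_labels)`` where label k means the point
    was drawn from centre k (0-based), for oracle scoring of segmentation.
    """
    config = config or SynthConfig()
    spatial = config.spatial
    if spatial.sigma_um <= 0:
        raise ValueError("sigma_um must be positive")
    if len(spatial.centers_um) < 1:
        raise ValueError("at least one glomerulus centre is required")
    rng = np.random.default_rng(config.seed)
    centers = np.asarray(spatial.centers_um, dtype=float) * UM
    weights = (
        np.asarray(spatial.weights, dtype=float)
        if spatial.weights is not None
        else np.ones(len(centers))
    )
    weights = weights / weights.sum()
    labels = rng.choice(len(centers), size=spatial.n_points, p=weights)
    points = centers[labels] + rng.normal(
        0.0, spatial.sigma_um * UM, size=(spatial.n_points, 3)
    )
    points = np.clip(points, 0.0, None)
    return points, labels
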