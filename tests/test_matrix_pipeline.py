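import numpy as np
import pandas as pd
import pytest

from glomquant import (
    CellBody,
    ContactMatrix,
    GlomerulusDataset,
    PSD,
    TBar,
    build_contact_matrix,
    cell_contact_totals,
    expand_contacts,
    filter_included_bodies,
    per_cell_stats,
    strength_distribution,
    synapse_density,
    connectivity_summary,
)
from glomquant.core_model import ORPHAN_SENTINEL
from tests.conftest import small_config
from glomquant import generate_glomerulus


def _dataset(cells, tbars, psds, volume=100.0):
    return GlomerulusDataset(cells, tbars, psds, neuropile_volume_um3=volume)


def _cells(*ids):
    return [CellBody(i, f"cell_{i}", "LN") for i in ids]


def test_one_tbar_expands_to_one_contact_per_psd():
    ds = _dataset(
        _cells(1, 2, 3, 4),
        [TBar(10, (0, 0, 0), 1)],
        [PSD(k, 10, post, (0, 0, 0)) for k, post in enumerate([2, 3, 4])],
    )
    contacts = expand_contacts(ds)
    assert [(c.pre_body, c.post_body) for c in contacts] == [(1, 2), (1, 3), (1, 4)]


def test_autapse_contact_flagged_and_retained():
    ds = _dataset(
        _cells(1), [TBar(10, (0, 0, 0), 1)], [PSD(1, 10, 1, (0, 0, 0))]
    )
    (contact,) = expand_contacts(ds)
    assert contact.is_autapse


def test_unresolvable_body_goes_to_orphan_sentinel(caplog):
    ds = _dataset(
        _cells(1), [TBar(10, (0, 0, 0), 1)], [PSD(1, 10, 99, (0, 0, 0))]
    )
    with caplog.at_level("WARNING"):
        (contact,) = expand_contacts(ds)
    assert contact.post_body == ORPHAN_SENTINEL
    assert "orphan" in caplog.text


def test_contact_count_equals_psd_count(small_dataset):
    dataset, _ = small_dataset
    contacts = expand_contacts(dataset)
    assert len(contacts) == len(dataset.psds)


def test_totals_conserve_and_match_brute_force(small_dataset):
    dataset, _ = small_dataset
    contacts = expand_contacts(dataset)
    totals = cell_contact_totals(contacts)
    assert totals["pre_contacts"].sum() == len(contacts)
    assert totals["post_contacts"].sum() == len(contacts)
    # independent tally loop
    pre, post = {}, {}
    for c in contacts:
        pre[c.pre_body] = pre.get(c.pre_body, 0) + 1
        post[c.post_body] = post.get(c.post_body, 0) + 1
    for b in totals.index:
        assert totals.loc[b, "pre_contacts"] == pre.get(b, 0)
        assert totals.loc[b, "post_contacts"] == post.get(b, 0)


def test_inclusion_boundary_at_51_total_contacts():
    totals = pd.DataFrame(
        {"pre_contacts": [30, 30], "post_contacts": [20, 21], "total": [50, 51]},
        index=pd.Index([1, 2], name="body_id"),
    )
    assert filter_included_bodies(totals, min_total=51) == [2]
    # "either" reading: at least 51 pre or 51 post
    totals2 = pd.DataFrame(
        {"pre_contacts": [51, 50], "post_contacts": [0, 50], "total": [51, 100]},
        index=pd.Index([1, 2], name="body_id"),
    )
    assert filter_included_bodies(totals2, 51, count_mode="either") == [1]


def test_filter_agrees_with_brute_force(small_dataset):
    dataset, _ = small_dataset
    totals = cell_contact_totals(expand_contacts(dataset))
    included = filter_included_bodies(totals, min_total=51)
    brute = sorted(
        b
        for b in totals.index
        if b != ORPHAN_SENTINEL
        and totals.loc[b, "pre_contacts"] + totals.loc[b, "post_contacts"] >= 51
    )
    assert included == brute


def test_zero_matrix_when_no_contacts_among_included():
    ds = _dataset(
        _cells(1, 2, 3), [TBar(10, (0, 0, 0), 1)], [PSD(1, 10, 2, (0, 0, 0))]
    )
    contacts = expand_contacts(ds)
    matrix = build_contact_matrix(contacts, [3], ds)
    assert matrix.counts.sum() == 0


def test_contact_conservation_through_matrix(small_dataset):
    dataset, _ = small_dataset
    contacts = expand_contacts(dataset)
    totals = cell_contact_totals(contacts)
    included = set(filter_included_bodies(totals))
    matrix = build_contact_matrix(contacts, sorted(included), dataset)
    touching_excluded = sum(
        1
        for c in contacts
        if c.pre_body not in included or c.post_body not in included
    )
    assert matrix.counts.sum() + touching_excluded == len(dataset.psds)


def test_matrix_diagonal_carries_autapses(small_dataset):
    dataset, _ = small_dataset
    contacts = expand_contacts(dataset)
    included = filter_included_bodies(cell_contact_totals(contacts))
    matrix = build_contact_matrix(contacts, included, dataset)
    autapses = {}
    for c in contacts:
        if c.is_autapse and c.pre_body in set(included):
            autapses[c.pre_body] = autapses.get(c.pre_body, 0) + 1
    for b, n in autapses.items():
        assert matrix.counts[matrix.index(b), matrix.index(b)] == n


def test_permuting_synapse_order_leaves_outputs_unchanged(small_dataset):
    dataset, _ = small_dataset
    rng = np.random.default_rng(0)
    shuffled = GlomerulusDataset(
        cells=list(dataset.cells),
        tbars=[dataset.tbars[i] for i in rng.permutation(len(dataset.tbars))],
        psds=[dataset.psds[i] for i in rng.permutation(len(dataset.psds))],
        neuropile_volume_um3=dataset.neuropile_volume_um3,
    )
    for ds in (dataset, shuffled):
        contacts = expand_contacts(ds)
        included = filter_included_bodies(cell_contact_totals(contacts))
        matrix = build_contact_matrix(contacts, included, ds)
        stats = per_cell_stats(ds, contacts)
        if ds is dataset:
            ref_matrix, ref_stats, ref_bodies = matrix.counts, stats, matrix.bodies
    assert matrix.bodies == ref_bodies
    assert (matrix.counts == ref_matrix).all()
    pd.testing.assert_frame_equal(stats, ref_stats)


def test_per_cell_stats_worked_example():
    # 10 T-bars with 3 PSDs each onto cell 2; 5 PSDs back onto cell 1
    cells = _cells(1, 2)
    tbars = [TBar(i, (0, 0, 0), 1) for i in range(10)]
    tbars.append(TBar(99, (0, 0, 0), 2))
    psds = [
        PSD(100 + 3 * i + j, i, 2, (0, 0, 0)) for i in range(10) for j in range(3)
    ]
    psds += [PSD(900 + k, 99, 1, (0, 0, 0)) for k in range(5)]
    ds = _dataset(cells, tbars, psds)
    stats = per_cell_stats(ds, expand_contacts(ds))
    assert stats.loc[1, "psds_per_tbar"] == 3.0
    assert stats.loc[1, "pre_post_ratio"] == 6.0


def test_undefined_ratios_are_nan_not_inf():
    ds = _dataset(
        _cells(1, 2), [TBar(10, (0, 0, 0), 1)], [PSD(1, 10, 2, (0, 0, 0))]
    )
    stats = per_cell_stats(ds, expand_contacts(ds))
    assert np.isnan(stats.loc[1, "pre_post_ratio"])  # cell 1 has no post
    assert np.isnan(stats.loc[2, "psds_per_tbar"])  # cell 2 has no T-bars
    assert np.isfinite(stats["pre_contacts"]).all()


def test_strength_distribution_matches_brute_force():
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = rng.integers(2, 12)
        counts = rng.integers(0, 8, size=(n, n))
        matrix = ContactMatrix(list(range(n)), counts)
        dist = strength_distribution(matrix)
        brute = {}
        for i in range(n):
            for j in range(n):
                if counts[i, j] > 0:
                    brute[counts[i, j]] = brute.get(counts[i, j], 0) + 1
        assert dict(dist.histogram) == brute
        for k in (1, 3, 11):
            assert dist.tail(k) == sum(v for s, v in brute.items() if s >= k)


def test_all_unit_strengths_have_empty_tail():
    matrix = ContactMatrix([1, 2], np.array([[0, 1], [1, 0]]))
    assert strength_distribution(matrix).tail(3) == 0


def test_synapse_density_from_printed_totals():
    cells = [CellBody(1, "a", "LN")]
    tbars = [TBar(i, (0, 0, 0), 1) for i in range(11_144)]
    psds = [PSD(i, i, 1, (0, 0, 0)) for i in range(11_144)]
    ds = GlomerulusDataset(cells, tbars, psds, neuropile_volume_um3=4858.0)
    assert round(synapse_density(ds), 2) == 2.29


def test_density_edge_cases():
    ds = GlomerulusDataset(_cellless := [], [], [], neuropile_volume_um3=10.0)
    assert synapse_density(ds) == 0.0
    ds_half = GlomerulusDataset([], [], [], neuropile_volume_um3=5.0)
    assert synapse_density(ds_half) == 0.0
    with pytest.raises(ValueError):
        synapse_density(GlomerulusDataset([], [], [], neuropile_volume_um3=0.0))


def test_density_scales_inversely_with_volume(small_dataset):
    dataset, _ = small_dataset
    halved = GlomerulusDataset(
        dataset.cells,
        dataset.tbars,
        dataset.psds,
        neuropile_volume_um3=dataset.neuropile_volume_um3 / 2,
    )
    assert synapse_density(halved) == pytest.approx(2 * synapse_density(dataset))


def test_bare_tbars_dropped_before_counting():
    ds = _dataset(
        _cells(1, 2),
        [TBar(10, (0, 0, 0), 1), TBar(11, (0, 0, 0), 1)],  # 11 has no PSD
        [PSD(1, 10, 2, (0, 0, 0))],
        volume=1.0,
    )
    assert synapse_density(ds) == 1.0
    stats = per_cell_stats(ds, expand_contacts(ds))
    assert stats.loc[1, "n_tbars"] == 1


def test_possible_pairs_in_summary():
    matrix = ContactMatrix(list(range(5)), np.zeros((5, 5), dtype=int))
    assert connectivity_summary(matrix)["possible_pairs"] == 25
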