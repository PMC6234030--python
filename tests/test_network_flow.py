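import numpy as np
import pandas as pd
import pytest

from glomquant import (
    ClassificationRules,
    ContactMatrix,
    aggregate_by_class,
    class_labels,
    classify_by_ratio,
    export_network,
    read_matrix,
    relabel_ln_subtypes,
)
from glomquant.matrix_pipeline import (
    build_contact_matrix,
    cell_contact_totals,
    expand_contacts,
    filter_included_bodies,
)


def _matrix(counts, bodies=None):
    counts = np.asarray(counts)
    return ContactMatrix(bodies or list(range(len(counts))), counts)


def test_single_class_matrix_is_one_flow_at_100_percent():
    m = _matrix([[0, 3], [2, 0]])
    classes = {0: "LN", 1: "LN"}
    class_matrix, flows = aggregate_by_class(m, classes)
    assert class_matrix.loc["LN", "LN"] == 5
    assert flows.percent_of_total.sum() == pytest.approx(100.0)


def test_aggregation_matches_brute_force_on_random_matrices():
    rng = np.random.default_rng(9)
    labels = ["PN", "LN", "ORN_ipsi"]
    for _ in range(30):
        n = rng.integers(2, 12)
        counts = rng.integers(0, 9, size=(n, n))
        classes = {i: labels[rng.integers(0, 3)] for i in range(n)}
        m = _matrix(counts)
        class_matrix, flows = aggregate_by_class(m, classes)
        for pre in set(classes.values()):
            for post in set(classes.values()):
                brute = sum(
                    counts[i, j]
                    for i in range(n)
                    for j in range(n)
                    if classes[i] == pre and classes[j] == post
                )
                assert class_matrix.loc[pre, post] == brute
        assert class_matrix.values.sum() == counts.sum()  # Σ-commutation


def test_percentages_invariant_to_uniform_scaling():
    counts = np.array([[0, 4], [2, 6]])
    classes = {0: "PN", 1: "LN"}
    _, flows1 = aggregate_by_class(_matrix(counts), classes)
    _, flows3 = aggregate_by_class(_matrix(counts * 3), classes)
    pd.testing.assert_series_equal(
        flows1.percent_of_total, flows3.percent_of_total
    )


def test_unlabelled_body_raises_listing_ids():
    with pytest.raises(ValueError, match=r"\[1\]"):
        aggregate_by_class(_matrix([[0, 1], [0, 0]]), {0: "PN"})


@pytest.mark.parametrize(
    "ratio, expected",
    [
        (3.9, "ORN"),  # ipsilateral ORN class mean
        (5.3, "ORN"),
        (1.0, "LN"),  # LNs balance pre and post
        (2.5, "ORN"),  # closed boundary
        (0.6, "PN"),
        (0.23, "PN"),
        (float("nan"), "unclassifiable"),
    ],
)
def test_ratio_classifier_rules(ratio, expected):
    stats = pd.DataFrame({"pre_post_ratio": [ratio]}, index=[1])
    assert classify_by_ratio(stats).loc[1, "predicted_class"] == expected


def test_near_boundary_predictions_are_annotated():
    stats = pd.DataFrame({"pre_post_ratio": [2.4, 10.0]}, index=[1, 2])
    out = classify_by_ratio(stats)
    assert out.loc[1, "note"] == "near_boundary"
    assert out.loc[2, "note"] == ""


def test_classifier_deterministic_under_custom_rules():
    stats = pd.DataFrame({"pre_post_ratio": [1.5]}, index=[1])
    strict = ClassificationRules(orn_min=1.2, pn_max=0.3)
    assert classify_by_ratio(stats, strict).loc[1, "predicted_class"] == "ORN"


def test_export_graphml_single_edge(tmp_path):
    import networkx as nx

    m = _matrix([[0, 7], [0, 0]], bodies=[1, 2])
    path = tmp_path / "net.graphml"
    export_network(m, path, format="graphml")
    g = nx.read_graphml(path)
    assert list(g.edges(data="count")) == [("1", "2", 7)]


def test_export_edgelist_round_trip(tmp_path):
    counts = np.array([[1, 5, 0], [0, 0, 2], [3, 0, 0]])
    m = _matrix(counts, bodies=[10, 20, 30])
    path = tmp_path / "net.csv"
    export_network(m, path, format="edgelist")
    back = read_matrix(path)
    idx = {lab: i for i, lab in enumerate(back.row_labels)}
    for i, bi in enumerate([10, 20, 30]):
        for j, bj in enumerate([10, 20, 30]):
            if counts[i, j]:
                assert back.counts[idx[str(bi)], idx[str(bj)]] == counts[i, j]


def test_export_dot_contains_self_loop(tmp_path):
    frame = pd.DataFrame(
        [[4, 2], [1, 3]], index=["PN", "LN"], columns=["PN", "LN"]
    )
    path = tmp_path / "net.dot"
    export_network(frame, path, format="dot")
    text = path.read_text()
    assert '"PN" -> "PN"' in text  # recurrent within-class loop


def test_unsupported_export_format():
    with pytest.raises(ValueError, match="unsupported format"):
        export_network(_matrix([[0]]), "x.bin", format="bin")


def test_study_class_network_has_recurrent_loops(study_dataset, study_contacts):
    dataset, _ = study_dataset
    included = filter_included_bodies(cell_contact_totals(study_contacts))
    matrix = build_contact_matrix(study_contacts, included, dataset)
    labels = class_labels(dataset, matrix.bodies)
    class_matrix, _ = aggregate_by_class(matrix, labels)
    for cls in ("PN", "LN", "ORN_ipsi"):
        assert class_matrix.loc[cls, cls] > 0


def test_ln_relabelling_by_orn_contact():
    from glomquant import CellBody, GlomerulusDataset

    cells = [
        CellBody(1, "LN_a", "LN"),
        CellBody(2, "LN_b", "LN"),
        CellBody(3, "ORN_a", "ORN_ipsi"),
    ]
    ds = GlomerulusDataset(cells=cells)
    counts = np.array([[0, 2, 0], [0, 0, 4], [0, 0, 0]])
    m = _matrix(counts, bodies=[1, 2, 3])
    labels = relabel_ln_subtypes(m, ds)
    assert labels == {1: "LN1", 2: "LN2L"}
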