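import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

import atlasq.annotation as ann
from atlasq import normalize_log1p
from atlasq.exceptions import ParameterError, ValidationError

from conftest import make_dataset


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

TAX = {
    "Epithelial": {
        "markers": ["EPCAM"],
        "children": {
            "Goblet": {"markers": ["MUC2"]},
            "Stem": {"markers": ["OLFM4", "LGR5"]},
        },
    },
    "Mesenchymal": {"markers": ["VIM"], "children": {"Fibroblast": {"markers": ["COL1A1"]}}},
}


def test_taxonomy_from_dict_levels():
    tax = ann.LabelTaxonomy.from_dict(TAX)
    assert tax.labels_at_level(1) == ["Epithelial", "Mesenchymal"]
    assert tax.labels_at_level(2) == ["Fibroblast", "Goblet", "Stem"]
    assert tax.children_of("Epithelial") == ["Goblet", "Stem"]
    assert tax.markers_of("Stem") == ("OLFM4", "LGR5")


def test_taxonomy_empty_markers_rejected():
    with pytest.raises(ValidationError):
        ann.LabelTaxonomy.from_dict({"A": {"markers": []}})


def test_taxonomy_orphan_level2_rejected():
    with pytest.raises(ValidationError):
        ann.LabelTaxonomy(
            {"B": ann.TaxonomyNode("B", 2, "missing", ("g",))}
        )


# ---------------------------------------------------------------------------
# marker AUC / FC
# ---------------------------------------------------------------------------

def test_auc_perfect_separation():
    assert ann.marker_auc([1, 2, 0, 0], [True, True, False, False]) == 1.0


def test_auc_constant_gene():
    assert ann.marker_auc([3, 3, 3, 3], [True, True, False, False]) == 0.5


def test_auc_pair_enumeration_example():
    # in = (1,3), out = (2,4): only the pair (3,2) wins -> 1/4
    assert ann.marker_auc([1, 3, 2, 4], [True, True, False, False]) == 0.25


def test_auc_one_empty_class_errors():
    with pytest.raises(ParameterError):
        ann.marker_auc([1, 2], [True, True])


def brute_force_auc(expr, mask):
    expr = np.asarray(expr, dtype=float)
    wins = ties = 0
    pairs = 0
    for i in np.flatnonzero(mask):
        for j in np.flatnonzero(~np.asarray(mask)):
            pairs += 1
            if expr[i] > expr[j]:
                wins += 1
            elif expr[i] == expr[j]:
                ties += 1
    return (wins + 0.5 * ties) / pairs


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 10_000))
def test_auc_equals_pair_counting_and_scipy(seed):
    r = np.random.default_rng(seed)
    n1, n2 = r.integers(1, 8, size=2)
    expr = r.integers(0, 4, size=n1 + n2).astype(float)  # many ties
    mask = np.zeros(n1 + n2, dtype=bool)
    mask[:n1] = True
    auc = ann.marker_auc(expr, mask)
    assert auc == pytest.approx(brute_force_auc(expr, mask), abs=1e-12)
    u = mannwhitneyu(expr[mask], expr[~mask], alternative="two-sided").statistic
    assert auc == pytest.approx(u / (n1 * n2), abs=1e-12)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_auc_class_swap_and_monotone_invariance(seed):
    r = np.random.default_rng(seed)
    expr = r.normal(size=12)
    mask = np.zeros(12, dtype=bool)
    mask[:5] = True
    auc = ann.marker_auc(expr, mask)
    assert ann.marker_auc(expr, ~mask) == pytest.approx(1 - auc, abs=1e-12)
    assert ann.marker_auc(np.exp(3 * expr) + 2, mask) == pytest.approx(auc, abs=1e-12)


def test_fc_hand_values():
    assert ann.marker_fc([2.0, 2.0, 0.5, 0.5], [True, True, False, False]) == 1.5
    assert ann.marker_fc([1, 2, 1, 2], [True, True, False, False]) == 0.0


def test_fc_equals_two_means(rng):
    expr = rng.normal(size=30)
    mask = rng.random(30) < 0.4
    if not mask.any() or mask.all():
        mask[0] = True
        mask[1] = False
    assert ann.marker_fc(expr, mask) == pytest.approx(
        expr[mask].mean() - expr[~mask].mean(), rel=1e-12
    )


# ---------------------------------------------------------------------------
# graph clustering
# ---------------------------------------------------------------------------

def test_cluster_two_blobs(rng):
    a = rng.normal(0, 1, size=(100, 2))
    b = rng.normal(0, 1, size=(100, 2)) + 20.0  # 10 sigma per axis
    emb = np.vstack([a, b])
    cl = ann.cluster_graph(emb, k=50, resolution=1.0, seed=0)
    assert cl.n_clusters == 2
    # purity 1.0: each blob maps to exactly one cluster
    assert len(set(cl.labels[:100])) == 1
    assert len(set(cl.labels[100:])) == 1
    assert cl.labels[0] != cl.labels[150]


def test_cluster_identical_points():
    emb = np.zeros((20, 3))
    cl = ann.cluster_graph(emb, k=5, resolution=1.0, seed=0)
    assert cl.n_clusters == 1


def test_cluster_deterministic(rng):
    emb = rng.normal(size=(80, 4))
    a = ann.cluster_graph(emb, k=10, resolution=2.0, seed=3)
    b = ann.cluster_graph(emb, k=10, resolution=2.0, seed=3)
    assert np.array_equal(a.labels, b.labels)


def test_cluster_k_too_large(rng):
    with pytest.raises(ParameterError):
        ann.cluster_graph(rng.normal(size=(5, 2)), k=5, resolution=1.0)


# ---------------------------------------------------------------------------
# score_types
# ---------------------------------------------------------------------------

def _two_label_dataset():
    # cluster 0 expresses EPCAM/MUC2, cluster 1 expresses VIM/COL1A1
    genes = ["EPCAM", "MUC2", "OLFM4", "LGR5", "VIM", "COL1A1", "other"]
    up, dn = 50, 1
    rows = []
    for _ in range(30):
        rows.append([up, up, dn, dn, dn, dn, 10])
    for _ in range(30):
        rows.append([dn, dn, dn, dn, up, up, 10])
    ds = normalize_log1p(make_dataset(np.array(rows), gene_ids=genes))
    clusters = ann.ClusterAssignment(
        labels=np.array([0] * 30 + [1] * 30), resolution=1.0
    )
    return ds, clusters


def test_score_types_level1_assignment():
    ds, clusters = _two_label_dataset()
    tax = ann.LabelTaxonomy.from_dict(TAX)
    tbl = ann.score_types(ds, clusters, tax, level=1)
    assert tbl.assigned == {0: "Epithelial", 1: "Mesenchymal"}
    sub = tbl.table.set_index(["cluster", "label"])
    assert sub.loc[(0, "Epithelial"), "auc_max"] == 1.0
    assert sub.loc[(0, "Epithelial"), "score"] == pytest.approx(
        (sub.loc[(0, "Epithelial"), "auc_max"] + sub.loc[(0, "Epithelial"), "fc_max"]) / 2
    )


def test_score_types_hierarchy_consistency():
    ds, clusters = _two_label_dataset()
    tax = ann.LabelTaxonomy.from_dict(TAX)
    table = ann.annotate_hierarchy(ds, clusters, tax, max_level=2)
    for _, row in table.iterrows():
        if row["level2"] is not None:
            assert tax.nodes[row["level2"]].parent == row["level1"]
    assert table.loc[1, "level2"] == "Fibroblast"


def test_score_types_tie_flagged():
    # two labels sharing the identical single marker -> tie, lexicographic
    tax = ann.LabelTaxonomy.from_dict(
        {"B_label": {"markers": ["EPCAM"]}, "A_label": {"markers": ["EPCAM"]}}
    )
    ds, clusters = _two_label_dataset()
    tbl = ann.score_types(ds, clusters, tax, level=1)
    assert tbl.assigned[0] == "A_label"
    assert 0 in tbl.ties


def test_score_types_missing_marker_warns():
    ds, clusters = _two_label_dataset()
    tax = ann.LabelTaxonomy.from_dict(
        {"A": {"markers": ["EPCAM", "NOT_A_GENE"]}, "B": {"markers": ["VIM"]}}
    )
    with pytest.warns(UserWarning, match="NOT_A_GENE"):
        tbl = ann.score_types(ds, clusters, tax, level=1)
    assert tbl.assigned[0] == "A"


def test_score_types_simulated_recovery(sim_reference, sim_model):
    ds, truth = sim_reference
    from atlasq import make_taxonomy

    tax = make_taxonomy(truth)
    clusters = ann.ClusterAssignment(
        labels=pd.Categorical(ds.cell_meta["level2"]).codes, resolution=0
    )
    table = ann.annotate_hierarchy(ds, clusters, tax, max_level=2)
    cats = pd.Categorical(ds.cell_meta["level2"]).categories
    for c, row in table.iterrows():
        assert row["level2"] == cats[c]
        assert tax.nodes[row["level2"]].parent == row["level1"]


# ---------------------------------------------------------------------------
# majority reannotation
# ---------------------------------------------------------------------------

def test_majority_simple():
    cl = ann.ClusterAssignment(labels=np.array([0, 0, 0]), resolution=1)
    assert ann.majority_reannotate(cl, ["A", "A", "B"]) == {0: "A"}


def test_majority_tie_goes_to_globally_abundant():
    # cluster 0 = [A, B]; B is globally more abundant
    cl = ann.ClusterAssignment(labels=np.array([0, 0, 1, 1, 1]), resolution=1)
    out = ann.majority_reannotate(cl, ["A", "B", "B", "B", "A"])
    assert out[0] == "B"


def test_majority_matches_brute_force(rng):
    labels = rng.choice(list("ABCD"), size=200)
    clusters = ann.ClusterAssignment(labels=rng.integers(0, 8, size=200),
                                     resolution=1)
    out = ann.majority_reannotate(clusters, labels)
    glob = pd.Series(labels).value_counts()
    for c in range(clusters.n_clusters):
        sub = pd.Series(labels[clusters.mask(c)]).value_counts()
        best = sub[sub == sub.max()].index
        best = sorted(best, key=lambda l: (-glob[l], l))
        assert out[c] == best[0]


# ---------------------------------------------------------------------------
# refine_markers
# ---------------------------------------------------------------------------

def test_refine_markers_planted_marker_first(rng):
    n = 40
    counts = rng.poisson(5.0, size=(2 * n, 20))
    counts[:n, 0] += 60  # gene g0 only in label A
    ds = normalize_log1p(make_dataset(counts))
    labels = ["A"] * n + ["B"] * n
    markers, _, _ = ann.refine_markers(ds, labels, top_n=3, seed=0)
    assert markers["A"][0] == "g0"


def test_refine_markers_no_subsample_when_large(rng):
    counts = rng.poisson(5.0, size=(30, 10)) + 1
    ds = normalize_log1p(make_dataset(counts))
    labels = ["A"] * 15 + ["B"] * 15
    a, _, _ = ann.refine_markers(ds, labels, subsample=10_000, top_n=2, seed=1)
    b, _, _ = ann.refine_markers(ds, labels, subsample=10_000, top_n=2, seed=2)
    assert a == b  # no randomness when subsample >= n


def test_refine_markers_matches_exhaustive_ranksum(rng):
    counts = rng.poisson(4.0, size=(50, 20)) + 1
    counts[:25, 3] += 15
    counts[25:, 7] += 15
    ds = normalize_log1p(make_dataset(counts))
    labels = ["A"] * 25 + ["B"] * 25
    markers, _, _ = ann.refine_markers(ds, labels, top_n=1, seed=0)
    X = ds.lognorm.toarray()
    for label, mask in [("A", np.arange(50) < 25), ("B", np.arange(50) >= 25)]:
        stats = []
        for j in range(20):
            u = mannwhitneyu(X[mask, j], X[~mask, j],
                             alternative="two-sided", use_continuity=False,
                             method="asymptotic")
            # signed z from U1
            n1, n2 = mask.sum(), (~mask).sum()
            stats.append(u.statistic - n1 * n2 / 2)
        best = int(np.argmax(stats))
        assert markers[label] == [f"g{best}"]


def test_refine_markers_small_label_skipped(rng):
    counts = rng.poisson(4.0, size=(10, 5)) + 1
    ds = normalize_log1p(make_dataset(counts))
    labels = ["A"] * 8 + ["B"] * 2
    with pytest.warns(UserWarning, match="skipped"):
        markers, _, _ = ann.refine_markers(ds, labels, top_n=2)
    assert "B" not in markers


def test_rank_sum_zscores_match_scipy(rng):
    X = rng.poisson(3.0, size=(40, 15)).astype(float)
    mask = np.zeros(40, dtype=bool)
    mask[:17] = True
    z, p = ann.rank_sum_zscores(X, mask)
    for j in range(15):
        res = mannwhitneyu(X[mask, j], X[~mask, j], alternative="two-sided",
                           use_continuity=False, method="asymptotic")
        assert p[j] == pytest.approx(res.pvalue, rel=1e-9)
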