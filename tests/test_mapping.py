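import numpy as np
import pandas as pd
import pytest

import atlasq.mapping as mp
from atlasq import (
    HVGSet,
    fit_reference,
    normalize_log1p,
    select_hvg,
    simulate_query,
    transform_query,
)
from atlasq.exceptions import ConfigurationError, ParameterError, ValidationError

from conftest import make_dataset


# ---------------------------------------------------------------------------
# fit_reference / transform_query
# ---------------------------------------------------------------------------

def test_transform_reference_self_consistency(sim_reference, sim_model):
    ds, _ = sim_reference
    coords = transform_query(sim_model, ds)
    np.testing.assert_allclose(coords, sim_model.ref_coords, atol=1e-8)


def test_fit_reference_rank2_reconstruction(rng):
    # counts lie (in log space) near a rank-2 structure
    base = rng.uniform(1, 3, size=(2, 40))
    weights = rng.dirichlet([1, 1], size=60)
    rate = 200 * (weights @ base)
    counts = rng.poisson(rate * 50)
    ds = normalize_log1p(make_dataset(counts, tissue="t", level1="a", level2="b"))
    hvg = HVGSet(gene_ids=tuple(ds.gene_ids), n=40)
    model = fit_reference(ds, hvg, d=40)
    # variance concentrates in few dimensions: top-5 coords carry >90%
    var = model.ref_coords.var(axis=0)
    assert var[:5].sum() / var.sum() > 0.9


def test_fit_reference_separates_programs(rng):
    counts = rng.poisson(2.0, size=(60, 30))
    counts[:30, :10] += 40
    counts[30:, 10:20] += 40
    ds = normalize_log1p(make_dataset(counts, tissue="t", level1="x", level2="y"))
    model = fit_reference(ds, HVGSet(tuple(ds.gene_ids), n=30), d=5)
    a, b = model.ref_coords[:30], model.ref_coords[30:]
    between = np.linalg.norm(a.mean(0) - b.mean(0))
    within = max(np.linalg.norm(a - a.mean(0), axis=1).mean(),
                 np.linalg.norm(b - b.mean(0), axis=1).mean())
    assert between > within


def test_fit_reference_d_too_large(sim_reference):
    ds, _ = sim_reference
    hvg = select_hvg(ds, n=10)
    with pytest.raises(ParameterError):
        fit_reference(ds, hvg, d=11)


def test_transform_query_gene_permutation(sim_reference, sim_model):
    ds, _ = sim_reference
    sub = ds.subset_cells(np.arange(5))
    perm = np.random.default_rng(0).permutation(sub.n_genes)
    shuffled = sub.subset_genes(sub.gene_ids.to_numpy()[perm])
    np.testing.assert_allclose(
        transform_query(sim_model, sub), transform_query(sim_model, shuffled),
        atol=1e-10,
    )


def test_transform_query_zero_fill_oracle(sim_reference, sim_model):
    ds, _ = sim_reference
    sub = ds.subset_cells(np.arange(8))
    model_genes = list(sim_model.gene_ids)
    dropped = set(model_genes[::10])  # remove 10% of model genes
    keep = [g for g in sub.gene_ids if g not in dropped]
    query = sub.subset_genes(keep)
    with pytest.warns(UserWarning, match="zero-filled"):
        coords = transform_query(sim_model, query)
    # oracle: explicit zero-fill then project
    X = np.zeros((8, len(model_genes)))
    lookup = {g: j for j, g in enumerate(keep)}
    dense = query.lognorm.toarray()
    for j, g in enumerate(model_genes):
        if g in lookup:
            X[:, j] = dense[:, lookup[g]]
    expected = (X - sim_model.center) / sim_model.scale @ sim_model.components.T
    np.testing.assert_allclose(coords, expected, atol=1e-10)


def test_transform_query_insufficient_overlap(sim_reference, sim_model):
    ds, _ = sim_reference
    few = [g for g in ds.gene_ids if g not in set(sim_model.gene_ids)][:5]
    if len(few) < 5:
        few = list(ds.gene_ids[:5])
        query = ds.subset_cells(np.arange(3)).subset_genes(few)
        with pytest.raises(ValidationError):
            transform_query(sim_model, query)


# ---------------------------------------------------------------------------
# knn_search
# ---------------------------------------------------------------------------

def test_knn_query_at_reference_point(rng):
    ref = rng.normal(size=(50, 4))
    res = mp.knn_search(ref, ref[7][None, :], k=1)
    assert res.indices[0, 0] == 7
    assert res.distances[0, 0] == 0.0


def test_knn_matches_brute_force(rng):
    ref = rng.normal(size=(20, 3))
    query = rng.normal(size=(9, 3))
    res = mp.knn_search(ref, query, k=5)
    for i in range(9):
        d = np.linalg.norm(ref - query[i], axis=1)
        order = np.argsort(d, kind="stable")[:5]
        assert list(res.indices[i]) == list(order)
        np.testing.assert_allclose(res.distances[i], d[order], atol=1e-9)
        assert np.all(np.diff(res.distances[i]) >= -1e-12)


def test_knn_duplicate_reference_tie_break():
    ref = np.zeros((6, 2))  # all identical -> ties everywhere
    res = mp.knn_search(ref, np.zeros((1, 2)), k=4)
    assert list(res.indices[0]) == [0, 1, 2, 3]


def test_knn_parameter_errors(rng):
    ref = rng.normal(size=(5, 2))
    with pytest.raises(ParameterError):
        mp.knn_search(ref, ref, k=0)
    with pytest.raises(ParameterError):
        mp.knn_search(ref, ref, k=6)


# ---------------------------------------------------------------------------
# transfer_labels / on_target_fraction
# ---------------------------------------------------------------------------

def _knn(indices, distances=None):
    indices = np.asarray(indices)
    if distances is None:
        distances = np.tile(np.arange(indices.shape[1], dtype=float),
                            (indices.shape[0], 1))
    return mp.KNNResult(indices=indices, distances=np.asarray(distances, float))


def test_transfer_mode_and_confidence():
    labels = pd.Series(["A", "A", "B"])
    out = mp.transfer_labels(_knn([[0, 1, 2]]), labels, k=3)
    assert out.loc[0, "label"] == "A"
    assert out.loc[0, "confidence"] == pytest.approx(2 / 3)


def test_transfer_unanimous_confidence_one():
    labels = pd.Series(["X"] * 5)
    out = mp.transfer_labels(_knn([[0, 1, 2, 3, 4]]), labels, k=5)
    assert out.loc[0, "confidence"] == 1.0


def test_transfer_tie_inverse_distance():
    labels = pd.Series(["A", "B"])
    # neighbor 0 (A) at distance 1, neighbor 1 (B) at distance 3 -> A wins tie
    out = mp.transfer_labels(_knn([[0, 1]], [[1.0, 3.0]]), labels, k=2)
    assert out.loc[0, "label"] == "A"
    # equidistant -> lexicographic
    out = mp.transfer_labels(_knn([[1, 0]], [[2.0, 2.0]]), labels, k=2)
    assert out.loc[0, "label"] == "A"


def test_transfer_matches_brute_force(rng):
    labels = pd.Series(rng.choice(["A", "B", "C"], size=30))
    idx = np.stack([rng.permutation(30)[:7] for _ in range(20)])
    dist = np.sort(rng.random((20, 7)), axis=1)
    out = mp.transfer_labels(_knn(idx, dist), labels, k=7)
    for i in range(20):
        counts = pd.Series(labels.to_numpy()[idx[i]]).value_counts()
        top = counts[counts == counts.max()].index.tolist()
        assert out.loc[i, "label"] in top
        assert out.loc[i, "confidence"] == pytest.approx(counts.max() / 7)


def test_transfer_self_map_confidence(sim_reference, sim_model):
    ds, _ = sim_reference
    nn = mp.knn_search(sim_model, sim_model.ref_coords, k=1)
    out = mp.transfer_labels(nn, sim_model.ref_labels["level2"], k=1)
    assert (out["label"].to_numpy() == ds.cell_meta["level2"].to_numpy()).all()
    assert (out["confidence"] == 1.0).all()


def test_on_target_fraction_basic():
    res = mp.on_target_fraction(["gut", "gut", "gut", "lung"], "gut",
                                confidence=[1, 1, 0.8, 0.6])
    assert res["fraction"] == 0.75
    assert res["mean_confidence_off"] == pytest.approx(0.6)


def test_on_target_all_match_off_confidence_null():
    res = mp.on_target_fraction(["gut", "gut"], "gut", confidence=[1.0, 0.9])
    assert res["fraction"] == 1.0
    assert res["mean_confidence_off"] is None


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def test_layout_requires_fit(sim_model):
    import dataclasses

    bare = dataclasses.replace(sim_model, layout_coords=None, layout_model=None)
    with pytest.raises(ConfigurationError):
        mp.transform_layout(bare, np.zeros((1, sim_model.d)))


def test_layout_barycentric_hand_weights():
    import dataclasses

    ref_coords = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
    layout = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    model = mp.ReferenceModel(
        gene_ids=np.array(["g"], dtype=object),
        center=np.zeros(1), scale=np.ones(1),
        components=np.zeros((2, 1)),
        ref_coords=ref_coords,
        ref_labels=pd.DataFrame(index=["a", "b", "c"]),
        layout_coords=layout,
    )
    # query at (2,0): neighbors 0 and 1 at distance 2 each -> weights .5/.5
    out = mp.transform_layout(model, np.array([[2.0, 0.0]]), k_fallback=2)
    np.testing.assert_allclose(out[0], [5.0, 0.0], atol=1e-12)
    # query at a reference point lands exactly on its layout position
    out = mp.transform_layout(model, np.array([[0.0, 4.0]]), k_fallback=2)
    np.testing.assert_allclose(out[0], [0.0, 10.0], atol=1e-12)


def test_layout_pca2_reference_cell(sim_model):
    mp.fit_layout(sim_model, method="pca2")
    out = mp.transform_layout(sim_model, sim_model.ref_coords[:3])
    np.testing.assert_allclose(out, sim_model.layout_coords[:3], atol=1e-9)
    sim_model.layout_coords = None
    sim_model.layout_model = None


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_model_roundtrip(tmp_path, sim_reference, sim_model):
    ds, _ = sim_reference
    mp.save_model(sim_model, tmp_path / "model")
    back = mp.load_model(tmp_path / "model")
    np.testing.assert_allclose(back.ref_coords, sim_model.ref_coords, atol=1e-9)
    np.testing.assert_allclose(back.components, sim_model.components, atol=1e-12)
    assert list(back.gene_ids) == list(sim_model.gene_ids)
    coords_a = transform_query(sim_model, ds.subset_cells(np.arange(4)))
    coords_b = transform_query(back, ds.subset_cells(np.arange(4)))
    np.testing.assert_allclose(coords_a, coords_b, atol=1e-8)


# ---------------------------------------------------------------------------
# end-to-end invariants
# ---------------------------------------------------------------------------

def test_predicted_tissue_proportions_sum_to_one(small_spec, sim_reference, sim_model):
    _, truth = sim_reference
    q, _ = simulate_query(small_spec, truth, n_cells=200,
                          off_target_fraction=0.2, seed=5)
    coords = transform_query(sim_model, normalize_log1p(q))
    nn = mp.knn_search(sim_model, coords, k=100)
    pred = mp.transfer_labels(nn, sim_model.ref_labels["tissue"], k=100)
    props = pred["label"].value_counts(normalize=True)
    assert props.sum() == pytest.approx(1.0)
    assert ((pred["confidence"] > 0) & (pred["confidence"] <= 1)).all()


def test_layout_umap_transform_reproducible(sim_model):
    pytest.importorskip("umap")
    import dataclasses

    model = dataclasses.replace(sim_model, layout_coords=None, layout_model=None)
    mp.fit_layout(model, method="umap", seed=0, n_neighbors=15)
    assert model.layout_coords.shape == (model.n_ref, 2)
    out1 = mp.transform_layout(model, model.ref_coords[:5])
    out2 = mp.transform_layout(model, model.ref_coords[:5])
    np.testing.assert_allclose(out1, out2, atol=1e-6)
    # a reference cell lands near its own layout position
    d = np.linalg.norm(out1 - model.layout_coords[:5], axis=1)
    spread = np.linalg.norm(
        model.layout_coords - model.layout_coords.mean(0), axis=1).mean()
    assert np.median(d) < spread
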