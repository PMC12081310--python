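"""Reference-model fitting, query projection, kNN label transfer.

The reference model is a deliberately simple, fully deterministic linear
embedding (center/scale over a frozen HVG list, then PCA). Externally
trained embeddings can be substituted by constructing a
:class:`ReferenceModel` directly from coordinate files — everything
downstream only touches ``gene_ids``, the transform, and the stored
reference coordinates/labels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .dataset import ExpressionDataset, HVGSet
from .exceptions import ConfigurationError, ParameterError, ValidationError

DEFAULT_K_LABEL = 100  # neighbors for label/tissue transfer
DEFAULT_K_MATCH = 10   # neighbors for the matched reference profile


@dataclass
class ReferenceModel:
    """Frozen gene space + linear projection + reference coordinates/labels."""

    gene_ids: np.ndarray            # (G,) frozen HVG order
    center: np.ndarray              # (G,)
    scale: np.ndarray               # (G,) never zero
    components: np.ndarray          # (d, G) orthonormal rows
    ref_coords: np.ndarray          # (n_ref, d)
    ref_labels: pd.DataFrame        # index: ref cell id; tissue/level1/2/3 columns
    ref_lognorm: sparse.csr_matrix | None = None  # (n_ref, G), for matched profiles
    layout_coords: np.ndarray | None = None        # (n_ref, 2)
    layout_model: object = field(default=None, repr=False)  # in-memory UMAP, optional

    @property
    def d(self) -> int:
        return self.components.shape[0]

    @property
    def n_ref(self) -> int:
        return self.ref_coords.shape[0]

    # -- transform --------------------------------------------------------
    def transform_matrix(self, X: np.ndarray) -> np.ndarray:
        """Project a dense (cells x G) matrix already aligned to gene_ids."""
        Z = (np.asarray(X, dtype=float) - self.center) / self.scale
        return Z @ self.components.T


def fit_reference(
    ds: ExpressionDataset,
    hvg: HVGSet,
    d: int = 30,
    store_lognorm: bool = True,
) -> ReferenceModel:
    """Fit the linear reference model on the HVG-restricted lognorm layer.

    Genes are centered and scaled (population SD; zero-SD genes get scale 1),
    then projected onto the top ``d`` principal components (deterministic
    full SVD with sign convention: largest-|loading| entry positive).
    """
    lognorm = ds.require_lognorm()
    gene_ids = list(hvg.gene_ids)
    if d > len(gene_ids):
        raise ParameterError(f"d={d} exceeds the {len(gene_ids)} HVGs")
    idx = ds.gene_ids.get_indexer(gene_ids)
    if (idx < 0).any():
        raise ValidationError("HVG set contains genes absent from the dataset")
    X = np.asarray(lognorm[:, idx].todense(), dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - center) / scale
    # deterministic PCA via SVD of the centered/scaled matrix
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    components = vt[:d]
    # fix sign ambiguity: make the largest-magnitude loading positive
    for i in range(components.shape[0]):
        j = int(np.abs(components[i]).argmax())
        if components[i, j] < 0:
            components[i] = -components[i]
    coords = Z @ components.T

    label_cols = [c for c in ("tissue", "level1", "level2", "level3")
                  if c in ds.cell_meta.columns]
    ref_labels = ds.cell_meta[label_cols].copy()
    return ReferenceModel(
        gene_ids=np.asarray(gene_ids, dtype=object),
        center=center,
        scale=scale,
        components=components,
        ref_coords=coords,
        ref_labels=ref_labels,
        ref_lognorm=sparse.csr_matrix(lognorm[:, idx]) if store_lognorm else None,
    )


def transform_query(
    model: ReferenceModel,
    ds: ExpressionDataset,
    max_missing_fraction: float = 0.5,
) -> np.ndarray:
    """Project a normalized query into the reference latent space.

    Query genes are aligned to ``model.gene_ids`` by id; model genes absent
    from the query are zero-filled (count recorded as a warning). More than
    ``max_missing_fraction`` missing genes aborts.
    """
    lognorm = ds.require_lognorm()
    idx = ds.gene_ids.get_indexer(model.gene_ids)
    missing = int((idx < 0).sum())
    if missing > max_missing_fraction * len(model.gene_ids):
        raise ValidationError(
            f"{missing}/{len(model.gene_ids)} model genes missing from query; "
            "insufficient overlap"
        )
    if missing:
        warnings.warn(f"{missing} model genes missing from query; zero-filled",
                      stacklevel=2)
    X = np.zeros((ds.n_cells, len(model.gene_ids)))
    present = idx >= 0
    X[:, present] = np.asarray(lognorm[:, idx[present]].todense(), dtype=float)
    return model.transform_matrix(X)


# ---------------------------------------------------------------------------
# Exact kNN
# ---------------------------------------------------------------------------

@dataclass
class KNNResult:
    indices: np.ndarray    # (n_query, k) reference row indices
    distances: np.ndarray  # (n_query, k) ascending per row

    @property
    def k(self) -> int:
        return self.indices.shape[1]


def knn_search(
    model: ReferenceModel | np.ndarray,
    query_coords: np.ndarray,
    k: int,
    chunk: int = 2048,
) -> KNNResult:
    """Exact Euclidean kNN against the reference coordinates.

    Ties in distance are broken by reference index (stable sort), so results
    are fully deterministic.
    """
    ref = model.ref_coords if isinstance(model, ReferenceModel) else np.asarray(model)
    query = np.atleast_2d(np.asarray(query_coords, dtype=float))
    if k <= 0:
        raise ParameterError("k must be positive")
    if k > ref.shape[0]:
        raise ParameterError(f"k={k} exceeds reference size {ref.shape[0]}")
    ref_sq = (ref**2).sum(axis=1)
    indices = np.empty((query.shape[0], k), dtype=int)
    distances = np.empty((query.shape[0], k))
    for start in range(0, query.shape[0], chunk):
        q = query[start:start + chunk]
        d2 = (q**2).sum(axis=1)[:, None] + ref_sq[None, :] - 2.0 * q @ ref.T
        np.maximum(d2, 0.0, out=d2)
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        rows = np.arange(q.shape[0])[:, None]
        indices[start:start + chunk] = order
        distances[start:start + chunk] = np.sqrt(d2[rows, order])
    return KNNResult(indices=indices, distances=distances)


# ---------------------------------------------------------------------------
# Label transfer
# ---------------------------------------------------------------------------

def transfer_labels(
    neighbors: KNNResult,
    ref_labels: pd.Series | np.ndarray,
    k: int = DEFAULT_K_LABEL,
) -> pd.DataFrame:
    """Modal label among the first ``k`` neighbors, with modal fraction as
    confidence.

    Ties: larger summed inverse distance wins, then lexicographic label
    order.
    """
    labels = np.asarray(pd.Series(ref_labels), dtype=object)
    if pd.isna(labels).any():
        raise ValidationError("reference labels contain missing values")
    if neighbors.k < k:
        raise ParameterError(f"neighbor table has {neighbors.k} < k={k} columns")
    idx = neighbors.indices[:, :k]
    dist = neighbors.distances[:, :k]
    nb_labels = labels[idx]
    out_label = np.empty(idx.shape[0], dtype=object)
    out_conf = np.empty(idx.shape[0])
    inv = 1.0 / np.maximum(dist, 1e-12)
    for i in range(idx.shape[0]):
        uniq, counts = np.unique(nb_labels[i].astype(str), return_counts=True)
        top = counts.max()
        cands = uniq[counts == top]
        if len(cands) > 1:
            weight = {c: inv[i][nb_labels[i].astype(str) == c].sum() for c in cands}
            best = max(weight.values())
            cands = sorted(c for c, w in weight.items() if w == best)
        out_label[i] = cands[0]
        out_conf[i] = top / k
    return pd.DataFrame({"label": out_label, "confidence": out_conf})


def on_target_fraction(
    predicted_tissue: np.ndarray | pd.Series,
    expected_tissue: str,
    confidence: np.ndarray | pd.Series | None = None,
) -> dict:
    """Fraction of cells whose predicted tissue matches ``expected_tissue``.

    Also reports mean prediction confidence within the on- and off-target
    groups (``None`` for an empty group).
    """
    if not expected_tissue:
        raise ParameterError("expected_tissue must be non-empty")
    pred = np.asarray(pd.Series(predicted_tissue), dtype=object)
    flags = pred == expected_tissue
    result = {
        "fraction": float(flags.mean()),
        "on_target": flags,
        "mean_confidence_on": None,
        "mean_confidence_off": None,
    }
    if confidence is not None:
        conf = np.asarray(confidence, dtype=float)
        if flags.any():
            result["mean_confidence_on"] = float(conf[flags].mean())
        if (~flags).any():
            result["mean_confidence_off"] = float(conf[~flags].mean())
    return result


# ---------------------------------------------------------------------------
# 2D layout
# ---------------------------------------------------------------------------

def fit_layout(
    model: ReferenceModel, method: str = "umap", seed: int = 0, **kwargs
) -> ReferenceModel:
    """Fit a 2D layout of the reference coordinates onto the model.

    ``umap`` keeps the fitted UMAP object in memory for out-of-sample
    transform; ``pca2`` just stores the first two latent dimensions. Either
    way ``layout_coords`` is populated, which is all the barycentric
    fallback needs.
    """
    if method == "umap":
        from umap import UMAP

        um = UMAP(n_components=2, random_state=seed, **kwargs)
        model.layout_coords = um.fit_transform(model.ref_coords)
        model.layout_model = um
    elif method == "pca2":
        model.layout_coords = model.ref_coords[:, :2].copy()
        model.layout_model = None
    else:
        raise ParameterError(f"unknown layout method: {method!r}")
    return model


def transform_layout(
    model: ReferenceModel,
    query_coords: np.ndarray,
    k_fallback: int = 2,
) -> np.ndarray:
    """Place query cells in the stored 2D layout.

    Uses the fitted UMAP transform when available; otherwise inverse-distance
    weighted barycentric placement among the ``k_fallback`` nearest reference
    cells (a query coinciding with a reference cell lands exactly on it).
    """
    if model.layout_coords is None:
        raise ConfigurationError("no fitted 2D layout; call fit_layout first")
    query_coords = np.atleast_2d(query_coords)
    if model.layout_model is not None:
        return np.asarray(model.layout_model.transform(query_coords))
    nn = knn_search(model, query_coords, k=k_fallback)
    out = np.empty((query_coords.shape[0], 2))
    for i in range(query_coords.shape[0]):
        d = nn.distances[i]
        if d[0] == 0.0:
            out[i] = model.layout_coords[nn.indices[i, 0]]
            continue
        w = 1.0 / d
        w = w / w.sum()
        out[i] = w @ model.layout_coords[nn.indices[i]]
    return out


# ---------------------------------------------------------------------------
# Serialization (text formats only)
# ---------------------------------------------------------------------------

def save_model(model: ReferenceModel, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"gene_id": model.gene_ids, "center": model.center, "scale": model.scale}
    ).to_csv(path / "genes.tsv", sep="\t", index=False)
    np.savetxt(path / "components.tsv", model.components, delimiter="\t")
    np.savetxt(path / "coords.tsv", model.ref_coords, delimiter="\t")
    model.ref_labels.reset_index().to_csv(path / "labels.tsv", sep="\t", index=False)
    if model.ref_lognorm is not None:
        spio.mmwrite(path / "ref_lognorm.mtx", sparse.coo_matrix(model.ref_lognorm))
    if model.layout_coords is not None:
        np.savetxt(path / "layout.tsv", model.layout_coords, delimiter="\t")
    (path / "meta.json").write_text(json.dumps({"d": model.d, "version": 1}))
    return path


def load_model(path: str | Path) -> ReferenceModel:
    path = Path(path)
    genes = pd.read_csv(path / "genes.tsv", sep="\t")
    components = np.atleast_2d(np.loadtxt(path / "components.tsv", delimiter="\t"))
    coords = np.atleast_2d(np.loadtxt(path / "coords.tsv", delimiter="\t"))
    labels = pd.read_csv(path / "labels.tsv", sep="\t", index_col=0)
    ref_lognorm = None
    if (path / "ref_lognorm.mtx").exists():
        ref_lognorm = sparse.csr_matrix(spio.mmread(path / "ref_lognorm.mtx"))
    layout = None
    if (path / "layout.tsv").exists():
        layout = np.atleast_2d(np.loadtxt(path / "layout.tsv", delimiter="\t"))
    return ReferenceModel(
        gene_ids=genes["gene_id"].to_numpy(dtype=object),
        center=genes["center"].to_numpy(),
        scale=genes["scale"].to_numpy(),
        components=components,
        ref_coords=coords,
        ref_labels=labels,
        ref_lognorm=ref_lognorm,
        layout_coords=layout,
    )
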