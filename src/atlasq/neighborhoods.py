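"""Neighborhood construction and cross-dataset correlation for fidelity
scoring.

Index cells are sampled uniformly, each neighborhood is the index cell plus
its k-1 nearest cells, and a neighborhood's profile is the mean
log-normalized expression of its members over a shared HVG list. Profiles of
two datasets are compared pairwise by Pearson correlation over genes; per
cell type the maximum (or median) similarity summarizes fidelity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import ParameterError, ValidationError
from .mapping import knn_search


@dataclass
class NeighborhoodSet:
    """Sampled index cells, their k-member neighborhoods, mean profiles."""

    index_cells: np.ndarray       # (m,) cell row indices
    membership: np.ndarray        # (m, k) member row indices (index cell first)
    profiles: np.ndarray          # (m, G) mean lognorm over members
    gene_ids: np.ndarray          # (G,) shared HVG order
    annotation: pd.DataFrame | None = None  # per neighborhood: celltype/tissue/sample

    @property
    def n_neighborhoods(self) -> int:
        return self.index_cells.shape[0]

    @property
    def k(self) -> int:
        return self.membership.shape[1]


def build_neighborhoods(
    coords: np.ndarray,
    lognorm,
    gene_ids,
    hvg_shared,
    k: int = 30,
    prop: float = 0.1,
    seed: int = 0,
    cell_annotation: pd.DataFrame | None = None,
) -> NeighborhoodSet:
    """Sample ceil(prop * n) index cells and build k-member neighborhoods.

    Neighborhood annotation (when ``cell_annotation`` is given) is the modal
    value of each column over the members.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not (0 < prop <= 1):
        raise ParameterError("prop must be in (0, 1]")
    if k > n:
        raise ParameterError(f"k={k} exceeds the {n} cells")
    hvg_shared = list(hvg_shared)
    if not hvg_shared:
        raise ParameterError("hvg_shared is empty")
    gene_index = pd.Index(np.asarray(gene_ids, dtype=object))
    cols = gene_index.get_indexer(hvg_shared)
    if (cols < 0).any():
        raise ValidationError("hvg_shared contains genes absent from the dataset")

    rng = np.random.default_rng(seed)
    m = math.ceil(prop * n)
    index_cells = np.sort(rng.choice(n, size=m, replace=False))

    nn = knn_search(coords, coords[index_cells], k=k)
    # make the index cell the first member (it is its own 0-distance neighbor,
    # but duplicate coordinates can reorder ties)
    membership = nn.indices.copy()
    for i, ic in enumerate(index_cells):
        row = membership[i]
        if row[0] != ic:
            pos = np.flatnonzero(row == ic)
            if pos.size:
                row[0], row[pos[0]] = row[pos[0]], row[0]
            else:
                row[-1] = ic
                row[0], row[-1] = row[-1], row[0]

    X = lognorm[:, cols]
    X = np.asarray(X.todense(), dtype=float) if sparse.issparse(X) else np.asarray(X, dtype=float)
    profiles = np.stack([X[membership[i]].mean(axis=0) for i in range(m)])

    annotation = None
    if cell_annotation is not None:
        rows = []
        for i in range(m):
            members = cell_annotation.iloc[membership[i]]
            rows.append({c: members[c].mode().iloc[0] for c in cell_annotation.columns})
        annotation = pd.DataFrame(rows)
    return NeighborhoodSet(
        index_cells=index_cells,
        membership=membership,
        profiles=profiles,
        gene_ids=np.asarray(hvg_shared, dtype=object),
        annotation=annotation,
    )


@dataclass
class SimilarityMatrix:
    """Pairwise Pearson correlations between neighborhood profiles."""

    values: np.ndarray  # (m_A, m_B); NaN where a profile is constant
    annotation_a: pd.DataFrame | None
    annotation_b: pd.DataFrame | None


def cross_correlate(a: NeighborhoodSet, b: NeighborhoodSet) -> SimilarityMatrix:
    """Pearson correlation over genes for every neighborhood pair.

    Constant profiles give undefined correlation, recorded as NaN and
    excluded from all downstream summaries.
    """
    if not np.array_equal(a.gene_ids, b.gene_ids):
        raise ValidationError("neighborhood sets use different gene orders")
    if a.profiles.shape[1] < 3:
        raise ParameterError("need at least 3 shared genes")
    A = a.profiles - a.profiles.mean(axis=1, keepdims=True)
    B = b.profiles - b.profiles.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (A @ B.T) / np.outer(na, nb)
    corr[na == 0, :] = np.nan
    corr[:, nb == 0] = np.nan
    corr = np.clip(corr, -1.0, 1.0, out=corr)
    return SimilarityMatrix(values=corr, annotation_a=a.annotation,
                            annotation_b=b.annotation)


def summarize_similarity(
    s: SimilarityMatrix,
    by: str = "celltype",
    stat: str = "max",
    axis: str = "a",
) -> pd.DataFrame:
    """Per-neighborhood best match on the other axis, aggregated by group.

    ``axis='a'`` summarizes rows (each A-neighborhood's max over B), grouped
    by the ``by`` column of A's annotation; ``stat`` is 'max' or 'median'.
    """
    if stat not in {"max", "median"}:
        raise ParameterError("stat must be 'max' or 'median'")
    if axis == "a":
        vals, ann = s.values, s.annotation_a
    elif axis == "b":
        vals, ann = s.values.T, s.annotation_b
    else:
        raise ParameterError("axis must be 'a' or 'b'")
    if ann is None or by not in ann.columns:
        raise ValidationError(f"annotation column {by!r} missing")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        best = np.nanmax(vals, axis=1)
    rows = []
    for group, idx in ann.groupby(by).groups.items():
        x = best[np.asarray(idx)]
        x = x[~np.isnan(x)]
        if x.size == 0:
            warnings.warn(f"group {group!r} has no valid similarities; skipped",
                          stacklevel=2)
            continue
        agg = float(np.max(x)) if stat == "max" else float(np.median(x))
        rows.append({by: group, "n_neighborhoods": int(len(idx)),
                     "similarity": agg})
    return pd.DataFrame(rows)


def contrast_protocols(
    s_by_protocol: dict[str, np.ndarray],
) -> dict[tuple[str, str], np.ndarray]:
    """Elementwise differences of aligned correlation matrices per protocol
    pair; diff(A, B) = -diff(B, A)."""
    names = sorted(s_by_protocol)
    shapes = {s_by_protocol[n].shape for n in names}
    if len(shapes) > 1:
        raise ValidationError("protocol matrices are not aligned")
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[(a, b)] = s_by_protocol[a] - s_by_protocol[b]
    return out
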