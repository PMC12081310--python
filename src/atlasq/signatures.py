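"""Drug-target signature scoring and cell-type assignment rules.

A signature's raw score per cell is the mean log-normalized expression of
its present genes; scores are then z-scaled per signature across all cells.
A signature is assigned to a cell type when strictly more than half of that
type's cells score above the signature's global median; signatures assigned
to at least two types are multicellular, and cell types are compared by the
cosine similarity of their binary membership vectors over multicellular
signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .dataset import ExpressionDataset
from .exceptions import ParameterError


@dataclass
class SignatureScores:
    raw: pd.DataFrame      # cells x signatures, mean lognorm of present genes
    scaled: pd.DataFrame   # per-signature z-score across cells
    n_genes_used: dict[str, int]
    degenerate: set[str] = field(default_factory=set)  # sd == 0 signatures


def score_signatures(
    ds: ExpressionDataset, signatures: dict[str, list[str]]
) -> SignatureScores:
    """Score every signature in every cell.

    Signatures with no present genes are skipped with a warning. A zero-SD
    signature gets an all-zero scaled column and is flagged degenerate.
    """
    if not signatures:
        raise ParameterError("empty signature collection")
    lognorm = ds.require_lognorm()
    X = np.asarray(lognorm.todense(), dtype=float) if sparse.issparse(lognorm) else np.asarray(lognorm)
    gene_index = {g: i for i, g in enumerate(ds.gene_ids.astype(str))}

    raw_cols, used = {}, {}
    degenerate: set[str] = set()
    for name, genes in signatures.items():
        cols = [gene_index[g] for g in genes if g in gene_index]
        if not cols:
            warnings.warn(f"signature {name!r} has no genes in the dataset; skipped",
                          stacklevel=2)
            continue
        raw_cols[name] = X[:, cols].mean(axis=1)
        used[name] = len(cols)
    if not raw_cols:
        raise ParameterError("no scorable signatures")
    raw = pd.DataFrame(raw_cols, index=ds.cell_ids)
    scaled = raw.copy()
    for name in raw.columns:
        vals = raw[name].to_numpy()
        sd = vals.std()
        if sd == 0 or np.all(vals == vals[0]):  # constant column
            scaled[name] = 0.0
            degenerate.add(name)
        else:
            scaled[name] = (vals - vals.mean()) / sd
    return SignatureScores(raw=raw, scaled=scaled, n_genes_used=used,
                           degenerate=degenerate)


@dataclass
class SignatureAssignment:
    assigned: pd.DataFrame          # cell types x signatures, boolean
    multicellular: pd.Series        # per signature: assigned in >= 2 types
    exceedance: pd.DataFrame        # fraction of type's cells above the median


def assign_to_celltypes(
    scores: SignatureScores | pd.DataFrame,
    cell_type_labels,
    min_cells: int = 5,
    use: str = "scaled",
) -> SignatureAssignment:
    """Assign each signature to the cell types where > 50% of cells exceed
    the signature's global median score (strict inequalities on both sides).

    Cell types with fewer than ``min_cells`` cells are skipped with a
    warning. ``use`` picks the scaled (default) or raw score table when a
    :class:`SignatureScores` is given.
    """
    table = scores if isinstance(scores, pd.DataFrame) else getattr(scores, use)
    labels = pd.Series(np.asarray(cell_type_labels, dtype=object), index=table.index)
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ParameterError("need at least 2 cell types")
    medians = table.median(axis=0)
    above = table.gt(medians, axis=1)

    kept = []
    rows = []
    for t in types:
        mask = (labels == t).to_numpy()
        if mask.sum() < min_cells:
            warnings.warn(f"cell type {t!r} has < {min_cells} cells; skipped",
                          stacklevel=2)
            continue
        kept.append(t)
        rows.append(above[mask].mean(axis=0))
    exceedance = pd.DataFrame(rows, index=kept, columns=table.columns)
    assigned = exceedance > 0.5
    multicellular = assigned.sum(axis=0) >= 2
    return SignatureAssignment(assigned=assigned, multicellular=multicellular,
                               exceedance=exceedance)


def celltype_cosine(assignment: SignatureAssignment) -> pd.DataFrame:
    """Pairwise cosine similarity of cell-type membership vectors over
    multicellular signatures; a zero vector yields NaN against everything."""
    multi = assignment.multicellular[assignment.multicellular].index
    if len(multi) == 0:
        warnings.warn("no multicellular signatures; empty cosine table",
                      stacklevel=2)
        return pd.DataFrame()
    M = assignment.assigned[multi].to_numpy(dtype=float)
    norms = np.linalg.norm(M, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = (M @ M.T) / np.outer(norms, norms)
    cos[norms == 0, :] = np.nan
    cos[:, norms == 0] = np.nan
    return pd.DataFrame(cos, index=assignment.assigned.index,
                        columns=assignment.assigned.index)
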