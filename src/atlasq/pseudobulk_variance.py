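"""Sample-level pseudo-bulk: summed counts, PCA loadings, covariate R^2.

Counts of all cells in a sample are summed per gene and log1p-transformed.
PCA on the top HVGs of the log layer gives sample scores; per principal
component the top/bottom loading genes are reported, and covariate
association is quantified as the R^2 of a one-way linear model (one-hot for
categoricals, raw for numeric covariates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .dataset import ExpressionDataset
from .exceptions import ParameterError, ValidationError


@dataclass
class PseudobulkTable:
    counts: pd.DataFrame      # samples x genes, summed raw counts
    log_layer: pd.DataFrame   # ln(1 + counts)
    covariates: pd.DataFrame  # per-sample metadata + total_counts/total_genes

    @property
    def samples(self) -> pd.Index:
        return self.counts.index


def pseudobulk(ds: ExpressionDataset, sample_key: str = "sample_id") -> PseudobulkTable:
    """Sum counts per sample; log layer = ln(1 + sum).

    Categorical cell metadata that is constant within a sample is carried
    over as a sample covariate; ``total_counts`` and ``total_genes`` are
    always added.
    """
    if sample_key not in ds.cell_meta.columns:
        raise ValidationError(f"cell_meta has no column {sample_key!r}")
    samples = ds.cell_meta[sample_key].astype(str)
    uniq = sorted(samples.unique())
    indicator = sparse.csr_matrix(
        (np.ones(ds.n_cells),
         (pd.Categorical(samples, categories=uniq).codes, np.arange(ds.n_cells))),
        shape=(len(uniq), ds.n_cells),
    )
    sums = np.asarray((indicator @ ds.counts).todense())
    counts = pd.DataFrame(sums, index=pd.Index(uniq, name=sample_key),
                          columns=ds.gene_ids)
    log_layer = np.log1p(counts)

    cov = pd.DataFrame(index=counts.index)
    for col in ds.cell_meta.columns:
        if col == sample_key:
            continue
        per_sample = ds.cell_meta.groupby(samples)[col].agg(
            lambda s: s.iloc[0] if s.nunique(dropna=False) == 1 else np.nan
        )
        if per_sample.notna().all():
            cov[col] = per_sample.reindex(counts.index)
    cov["total_counts"] = counts.sum(axis=1)
    cov["total_genes"] = (counts > 0).sum(axis=1)
    return PseudobulkTable(counts=counts, log_layer=log_layer, covariates=cov)


@dataclass
class PCALoadings:
    scores: pd.DataFrame                  # samples x PCs
    loadings: pd.DataFrame                # genes x PCs
    top_genes: dict[str, list[str]]       # per PC: highest loadings
    bottom_genes: dict[str, list[str]]    # per PC: lowest loadings
    explained_variance_ratio: np.ndarray


def pca_loadings(
    table: PseudobulkTable,
    n_hvg: int = 500,
    n_top: int = 200,
    n_pcs: int = 2,
) -> PCALoadings:
    """PCA of the log layer restricted to the ``n_hvg`` most variable genes.

    Genes are centered, not scaled. For each of the first ``n_pcs``
    components the ``n_top`` highest- and lowest-loading genes are returned.
    """
    if len(table.samples) < 3:
        raise ParameterError("need at least 3 samples")
    log = table.log_layer
    variances = log.var(axis=0, ddof=1)
    if n_hvg > log.shape[1]:
        n_hvg = log.shape[1]
    hvg = variances.sort_values(ascending=False).index[:n_hvg]
    X = log[hvg].to_numpy()
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    n_pcs = min(n_pcs, vt.shape[0])
    comps = vt[:n_pcs]
    for i in range(n_pcs):
        j = int(np.abs(comps[i]).argmax())
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    scores = Xc @ comps.T
    pc_names = [f"PC{i + 1}" for i in range(n_pcs)]
    loadings = pd.DataFrame(comps.T, index=hvg, columns=pc_names)
    top, bottom = {}, {}
    for pc in pc_names:
        order = loadings[pc].sort_values(ascending=False)
        top[pc] = list(order.index[: min(n_top, len(order))])
        bottom[pc] = list(order.index[-min(n_top, len(order)):])
    total_var = (Xc**2).sum()
    evr = (s[:n_pcs] ** 2) / total_var if total_var > 0 else np.zeros(n_pcs)
    return PCALoadings(
        scores=pd.DataFrame(scores, index=table.samples, columns=pc_names),
        loadings=loadings,
        top_genes=top,
        bottom_genes=bottom,
        explained_variance_ratio=evr,
    )


def covariate_variance(
    scores: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """R^2 of each PC explained by each covariate (one-way linear model).

    Categorical covariates are one-hot encoded (equivalently, R^2 of group
    means); numeric covariates use simple linear regression. Constant
    covariates are skipped with a warning.
    """
    rows = []
    for cov_name in covariates.columns:
        cov = covariates[cov_name].reindex(scores.index)
        if cov.nunique(dropna=False) < 2:
            warnings.warn(f"covariate {cov_name!r} is constant; skipped",
                          stacklevel=2)
            continue
        numeric = pd.api.types.is_numeric_dtype(cov)
        for pc in scores.columns:
            y = scores[pc].to_numpy(dtype=float)
            sst = ((y - y.mean()) ** 2).sum()
            if sst == 0:
                r2 = 0.0
            elif numeric:
                x = cov.to_numpy(dtype=float)
                r = np.corrcoef(x, y)[0, 1]
                r2 = 0.0 if np.isnan(r) else float(r**2)
            else:
                fitted = pd.Series(y, index=scores.index).groupby(cov).transform("mean")
                ssr = ((y - fitted.to_numpy()) ** 2).sum()
                r2 = float(1.0 - ssr / sst)
            rows.append(dict(pc=pc, covariate=cov_name, r2=r2))
    return pd.DataFrame(rows)
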