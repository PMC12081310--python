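"""Seeded synthetic data: multi-tissue reference atlases and query datasets
with known ground truth.

The generative model: each cell type carries a program of mean
log-expression (a flat baseline with a planted block of marker genes);
shared cell types appear in several tissues with identical programs plus a
small per-tissue offset; a fetal->adult maturation gradient moves cells
along a fixed gene-axis. Per-cell rates are the program probabilities times
a log-normal library size, and counts are negative binomial (gamma-Poisson)
with a common dispersion. Everything is a pure function of the spec and a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .annotation import LabelTaxonomy, TaxonomyNode
from .dataset import ExpressionDataset
from .exceptions import ParameterError


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic atlas generator."""

    n_tissues: int = 3
    types_per_tissue: int = 4
    n_shared_types: int = 1           # first indices; identical program across tissues
    n_genes: int = 2000
    markers_per_type: int = 40
    marker_log_fold: float = 2.0
    tissue_offset_sd: float = 0.2     # applied to shared-type cells only
    maturation_weight: float = 0.3
    n_maturation_genes: int = 100
    cells_per_type: int = 200
    samples_per_tissue: int = 2
    libsize_log_mean: float = np.log(2000.0)
    libsize_log_sd: float = 0.25
    dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 1 or self.types_per_tissue < 1:
            raise ParameterError("need at least one tissue and one type")
        if self.n_shared_types > self.types_per_tissue:
            raise ParameterError("n_shared_types exceeds types_per_tissue")
        needed = (self.n_shared_types
                  + self.n_tissues * (self.types_per_tissue - self.n_shared_types))
        if needed * self.markers_per_type + self.n_maturation_genes > self.n_genes:
            raise ParameterError("not enough genes for the requested marker blocks")

    def with_seed(self, seed: int) -> "SimSpec":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Everything the simulator knows about the generated cells."""

    cell_meta: pd.DataFrame            # tissue, level1, level2, sample_id,
                                       # maturation, off_target, perturbed
    rate: np.ndarray                   # (n_cells, n_genes) expected counts
    dispersion: float
    type_table: pd.DataFrame           # level2, level1, shared, tissues
    markers: dict[str, list[str]]      # level2 -> marker gene ids
    maturation_axis: np.ndarray        # (n_genes,) gradient direction
    perturbed_genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# internal program construction
# ---------------------------------------------------------------------------

def _gene_ids(n: int) -> np.ndarray:
    return np.array([f"g{i:05d}" for i in range(n)], dtype=object)


def _build_programs(spec: SimSpec, rng: np.random.Generator):
    """Program log-mean per (type, tissue) plus marker bookkeeping."""
    gene_ids = _gene_ids(spec.n_genes)
    shared = [f"shared_t{j}" for j in range(spec.n_shared_types)]
    type_names: list[str] = []
    type_tissues: dict[str, list[str]] = {}
    tissues = [f"tissue{t}" for t in range(spec.n_tissues)]
    for name in shared:
        type_names.append(name)
        type_tissues[name] = list(tissues)
    for t, tissue in enumerate(tissues):
        for j in range(spec.n_shared_types, spec.types_per_tissue):
            name = f"{tissue}_t{j}"
            type_names.append(name)
            type_tissues[name] = [tissue]

    # disjoint marker blocks, then the maturation block
    markers: dict[str, np.ndarray] = {}
    cursor = 0
    for name in type_names:
        markers[name] = np.arange(cursor, cursor + spec.markers_per_type)
        cursor += spec.markers_per_type
    maturation_idx = np.arange(cursor, cursor + spec.n_maturation_genes)

    base = np.zeros(spec.n_genes)
    programs: dict[str, np.ndarray] = {}
    for name in type_names:
        prog = base.copy()
        prog[markers[name]] += spec.marker_log_fold
        programs[name] = prog

    offsets = {
        tissue: rng.normal(0.0, spec.tissue_offset_sd, size=spec.n_genes)
        for tissue in tissues
    }
    axis = np.zeros(spec.n_genes)
    axis[maturation_idx] = rng.normal(0.0, 1.0, size=spec.n_maturation_genes)

    # level 1: split type index space into two classes
    level1_of = {}
    for name in type_names:
        j = int(name.rsplit("t", 1)[1])
        level1_of[name] = "classA" if j < max(spec.types_per_tissue // 2, 1) else "classB"

    type_table = pd.DataFrame(
        {
            "level2": type_names,
            "level1": [level1_of[n] for n in type_names],
            "shared": [n in shared for n in type_names],
            "tissues": [",".join(type_tissues[n]) for n in type_names],
        }
    )
    marker_ids = {n: list(gene_ids[markers[n]]) for n in type_names}
    return gene_ids, tissues, type_names, type_tissues, programs, offsets, axis, \
        level1_of, type_table, marker_ids


def _nb_counts(rng: np.random.Generator, rate: np.ndarray, dispersion: float):
    if dispersion <= 1e-12:
        return rng.poisson(rate)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, rate * dispersion)
    return rng.poisson(lam)


def _cells_to_dataset(
    counts: np.ndarray, cell_meta: pd.DataFrame, gene_ids: np.ndarray
) -> ExpressionDataset:
    gene_meta = pd.DataFrame(
        {"symbol": gene_ids, "biotype": "protein_coding"},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ExpressionDataset(
        counts=sparse.csr_matrix(counts),
        cell_meta=cell_meta,
        gene_meta=gene_meta,
    )


def _generate_cells(
    spec: SimSpec,
    rng: np.random.Generator,
    assignments: list[tuple[str, str]],  # (level2 type, tissue) per cell
    programs: dict[str, np.ndarray],
    offsets: dict[str, np.ndarray],
    axis: np.ndarray,
    shared_names: set[str],
    maturation_base: float = 0.0,
):
    n = len(assignments)
    log_mean = np.empty((n, spec.n_genes))
    maturation = rng.uniform(0.0, 1.0, size=n) + maturation_base
    for i, (tname, tissue) in enumerate(assignments):
        lm = programs[tname].copy()
        if tname in shared_names:
            lm = lm + offsets[tissue]
        lm = lm + spec.maturation_weight * maturation[i] * axis
        log_mean[i] = lm
    p = np.exp(log_mean)
    p /= p.sum(axis=1, keepdims=True)
    libsize = rng.lognormal(spec.libsize_log_mean, spec.libsize_log_sd, size=n)
    rate = p * libsize[:, None]
    counts = _nb_counts(rng, rate, spec.dispersion)
    return counts, rate.astype(np.float32), maturation


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def simulate_reference(spec: SimSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate the multi-tissue reference atlas described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    (gene_ids, tissues, type_names, type_tissues, programs, offsets, axis,
     level1_of, type_table, marker_ids) = _build_programs(spec, rng)
    shared_names = set(type_table.loc[type_table["shared"], "level2"])

    assignments: list[tuple[str, str]] = []
    for tname in type_names:
        for tissue in type_tissues[tname]:
            assignments.extend([(tname, tissue)] * spec.cells_per_type)
    counts, rate, maturation = _generate_cells(
        spec, rng, assignments, programs, offsets, axis, shared_names
    )
    n = len(assignments)
    cell_ids = [f"ref_c{i:06d}" for i in range(n)]
    tissue_col = [a[1] for a in assignments]
    type_col = [a[0] for a in assignments]
    sample_idx = rng.integers(0, spec.samples_per_tissue, size=n)
    cell_meta = pd.DataFrame(
        {
            "sample_id": [f"{t}_s{j}" for t, j in zip(tissue_col, sample_idx)],
            "tissue": tissue_col,
            "stem_cell_source": "unknown",
            "dataset_id": "sim_reference",
            "level1": [level1_of[t] for t in type_col],
            "level2": type_col,
            "maturation": maturation,
            "off_target": False,
            "perturbed": False,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    ds = _cells_to_dataset(counts, cell_meta, gene_ids)
    truth = GroundTruth(
        cell_meta=cell_meta,
        rate=rate,
        dispersion=spec.dispersion,
        type_table=type_table,
        markers=marker_ids,
        maturation_axis=axis,
    )
    return ds, truth


def simulate_query(
    spec: SimSpec,
    ref_truth: GroundTruth,
    target_tissue: str | None = None,
    n_cells: int = 1000,
    off_target_fraction: float = 0.0,
    maturation_shift: float = 0.0,
    seed: int | None = None,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a query dataset drawn from the target tissue's programs with
    a planted fraction of off-target cells from other tissues' unique types.
    """
    if not (0 <= off_target_fraction < 1):
        raise ParameterError("off_target_fraction must be in [0, 1)")
    rng = np.random.default_rng(spec.seed + 7_777 if seed is None else seed)
    # rebuild the deterministic program structure from the spec seed
    prog_rng = np.random.default_rng(spec.seed)
    (gene_ids, tissues, type_names, type_tissues, programs, offsets, axis,
     level1_of, type_table, _) = _build_programs(spec, prog_rng)
    shared_names = set(type_table.loc[type_table["shared"], "level2"])
    if target_tissue is None:
        target_tissue = tissues[0]
    if target_tissue not in tissues:
        raise ParameterError(f"unknown tissue {target_tissue!r}")

    n_off = int(round(off_target_fraction * n_cells))
    n_on = n_cells - n_off
    target_types = [t for t in type_names if target_tissue in type_tissues[t]]
    other_unique = [
        t for t in type_names
        if t not in shared_names and target_tissue not in type_tissues[t]
    ]
    if n_off and not other_unique:
        raise ParameterError("no off-target types available in this spec")

    assignments: list[tuple[str, str]] = []
    off_flags: list[bool] = []
    for t in rng.choice(target_types, size=n_on):
        assignments.append((t, target_tissue))
        off_flags.append(False)
    for t in rng.choice(other_unique, size=n_off) if n_off else []:
        assignments.append((t, type_tissues[t][0]))
        off_flags.append(True)

    counts, rate, maturation = _generate_cells(
        spec, rng, assignments, programs, offsets, axis, shared_names,
        maturation_base=maturation_shift,
    )
    n = len(assignments)
    cell_ids = [f"q_c{i:06d}" for i in range(n)]
    cell_meta = pd.DataFrame(
        {
            "sample_id": "query_s0",
            "tissue": [a[1] for a in assignments],
            "stem_cell_source": "unknown",
            "dataset_id": "sim_query",
            "level1": [level1_of[a[0]] for a in assignments],
            "level2": [a[0] for a in assignments],
            "maturation": maturation,
            "off_target": off_flags,
            "perturbed": False,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    ds = _cells_to_dataset(counts, cell_meta, gene_ids)
    truth = GroundTruth(
        cell_meta=cell_meta,
        rate=rate,
        dispersion=spec.dispersion,
        type_table=ref_truth.type_table,
        markers=ref_truth.markers,
        maturation_axis=axis,
    )
    return ds, truth


def inject_perturbation(
    ds: ExpressionDataset,
    truth: GroundTruth,
    genes: list[str],
    log_fold: float,
    cell_mask: np.ndarray,
    seed: int = 0,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Multiply selected cells' expected counts by exp(log_fold) for the
    selected genes and regenerate those cells' counts.

    With ``log_fold = 0`` the masked cells are redrawn from the unchanged
    model (distributionally identical); non-selected genes keep their
    expectation either way.
    """
    import warnings as _warnings

    cell_mask = np.asarray(cell_mask, dtype=bool)
    gene_idx = ds.gene_ids.get_indexer(genes)
    if (gene_idx < 0).any():
        raise ParameterError("perturbation genes absent from the dataset")
    if not cell_mask.any():
        _warnings.warn("empty cell mask; returning dataset unchanged", stacklevel=2)
        return ds, truth

    rng = np.random.default_rng(seed)
    rate = truth.rate.copy()
    rate[np.ix_(cell_mask, gene_idx)] *= np.exp(log_fold)
    new_counts = ds.counts.toarray()
    new_counts[cell_mask] = _nb_counts(rng, rate[cell_mask].astype(float),
                                       truth.dispersion)
    cell_meta = truth.cell_meta.copy()
    cell_meta.loc[cell_mask, "perturbed"] = True
    out_ds = ExpressionDataset(
        counts=sparse.csr_matrix(new_counts),
        cell_meta=cell_meta,
        gene_meta=ds.gene_meta,
    )
    out_truth = GroundTruth(
        cell_meta=cell_meta,
        rate=rate,
        dispersion=truth.dispersion,
        type_table=truth.type_table,
        markers=truth.markers,
        maturation_axis=truth.maturation_axis,
        perturbed_genes=sorted(set(truth.perturbed_genes) | set(genes)),
    )
    return out_ds, out_truth


def program_gene_pool(
    truth: GroundTruth,
    exclude_tissue: str | None = None,
    n: int | None = None,
) -> list[str]:
    """Planted program (marker) genes, optionally excluding the types of one
    tissue — a natural pool of perturbation targets that load on the
    embedding (disease/cytokine states shift program genes, not flat
    background genes)."""
    pool: list[str] = []
    for _, row in truth.type_table.iterrows():
        if exclude_tissue is not None and exclude_tissue in row["tissues"].split(","):
            continue
        pool.extend(truth.markers[row["level2"]])
    return pool if n is None else pool[:n]


def make_taxonomy(truth: GroundTruth) -> LabelTaxonomy:
    """Two-level taxonomy from the planted programs: level-1 classes get the
    union of their children's markers; level-2 types get their own block."""
    nodes: dict[str, TaxonomyNode] = {}
    for l1, group in truth.type_table.groupby("level1"):
        union: list[str] = []
        for t in group["level2"]:
            union.extend(truth.markers[t])
        nodes[l1] = TaxonomyNode(label=l1, level=1, parent=None,
                                 markers=tuple(union))
        for t in group["level2"]:
            nodes[t] = TaxonomyNode(label=t, level=2, parent=l1,
                                    markers=tuple(truth.markers[t]))
    return LabelTaxonomy(nodes)
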