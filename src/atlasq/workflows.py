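"""End-to-end assessment workflows and their run configuration.

``run_incorporate`` reproduces the standard recipe: normalize the query,
project it into the reference latent space, transfer labels from the 100
nearest reference neighbors, reconstruct the 10-NN matched reference and
its distance, and emit per-sample composition tables. ``run_perturbation_
assessment`` chains that for a control/treated pair and adds paired
differential expression, DEG categorization, optional gene-set enrichment
and a per-cell-type distance comparison.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import de as de_mod
from .dataset import (
    DEFAULT_N_HVG,
    DEFAULT_TARGET_SUM,
    ExpressionDataset,
    normalize_log1p,
    read_dataset,
)
from .assessment import matched_reference
from .exceptions import AtlasqError
from .mapping import (
    DEFAULT_K_LABEL,
    DEFAULT_K_MATCH,
    ReferenceModel,
    knn_search,
    load_model,
    on_target_fraction,
    transfer_labels,
    transform_query,
)

logger = logging.getLogger("atlasq")


@dataclass
class RunConfig:
    """Parameters of an assessment run; serialized next to the outputs."""

    model_dir: str | None = None
    query_path: str | None = None
    out_dir: str = "atlasq_out"
    k_label: int = DEFAULT_K_LABEL
    k_match: int = DEFAULT_K_MATCH
    target_sum: float = DEFAULT_TARGET_SUM
    n_hvg: int = DEFAULT_N_HVG
    alpha: float = 0.05
    seed: int = 0
    expected_tissue: str | None = None
    gmt_path: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_label < 1 or self.k_match < 1:
            raise AtlasqError("all k parameters must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def snapshot(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(self.to_json())


def _stage(name: str):
    """Decorator tagging failures with the pipeline stage that raised."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except AtlasqError as exc:
                raise AtlasqError(f"[stage: {name}] {exc}") from exc

        return inner

    return wrap


@_stage("incorporate")
def run_incorporate(
    config: RunConfig,
    model: ReferenceModel | None = None,
    query: ExpressionDataset | None = None,
    write: bool = True,
) -> dict:
    """Project a query onto the reference and assess it.

    Returns a report dict; when ``write`` is set, emits ``cells.tsv``,
    ``proportions.tsv``, ``report.json`` and a config snapshot under
    ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    if model is None:
        if config.model_dir is None:
            raise AtlasqError("no model given (set model_dir)")
        model = load_model(config.model_dir)
    if query is None:
        if config.query_path is None:
            raise AtlasqError("no query given (set query_path)")
        query = read_dataset(config.query_path)
    if query.lognorm is None:
        query = normalize_log1p(query, target_sum=config.target_sum)
    logger.info("projecting %d query cells onto %d reference cells",
                query.n_cells, model.n_ref)

    coords = transform_query(model, query)
    k_needed = max(config.k_label, config.k_match)
    nn = knn_search(model, coords, k=min(k_needed, model.n_ref))

    cells = pd.DataFrame(index=query.cell_ids)
    for col in model.ref_labels.columns:
        pred = transfer_labels(nn, model.ref_labels[col],
                               k=min(config.k_label, nn.k))
        cells[f"predicted_{col}"] = pred["label"].to_numpy()
        cells[f"confidence_{col}"] = pred["confidence"].to_numpy()
    if model.ref_lognorm is not None:
        match = matched_reference(model, coords, k=min(config.k_match, model.n_ref))
        cells["distance_to_atlas"] = match.distance_to_atlas
    else:
        cells["distance_to_atlas"] = nn.distances[:, : config.k_match].mean(axis=1)

    sample_ids = (query.cell_meta["sample_id"].astype(str)
                  if "sample_id" in query.cell_meta.columns
                  else pd.Series("sample0", index=query.cell_ids))
    label_col = ("predicted_level2" if "predicted_level2" in cells.columns
                 else cells.columns[0])
    proportions = (
        cells.assign(sample_id=sample_ids.to_numpy())
        .groupby("sample_id")[label_col]
        .value_counts(normalize=True)
        .rename("proportion")
        .reset_index()
    )

    report: dict = {
        "n_query_cells": int(query.n_cells),
        "n_reference_cells": int(model.n_ref),
        "k_label": config.k_label,
        "k_match": config.k_match,
        "median_distance_to_atlas": float(np.median(cells["distance_to_atlas"])),
    }
    if config.expected_tissue and "predicted_tissue" in cells.columns:
        ot = on_target_fraction(
            cells["predicted_tissue"], config.expected_tissue,
            confidence=cells["confidence_tissue"],
        )
        report["on_target_fraction"] = ot["fraction"]
        report["mean_confidence_on"] = ot["mean_confidence_on"]
        report["mean_confidence_off"] = ot["mean_confidence_off"]

    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.snapshot(out_dir)
        cells.to_csv(out_dir / "cells.tsv", sep="\t")
        proportions.to_csv(out_dir / "proportions.tsv", sep="\t", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    report["cells"] = cells
    report["proportions"] = proportions
    report["coords"] = coords
    return report


@_stage("perturbation-assessment")
def run_perturbation_assessment(
    config: RunConfig,
    control: ExpressionDataset,
    treated_a: ExpressionDataset,
    treated_b: ExpressionDataset | None = None,
    model: ReferenceModel | None = None,
    gene_sets: dict[str, list[str]] | None = None,
    write: bool = True,
) -> dict:
    """Assess one or two treated samples against the atlas cohort.

    Per condition: incorporate, paired F-test against the matched reference.
    With two treatments the DEGs are categorized into condition-specific /
    shared / atlas-up sets and (optionally) tested for gene-set enrichment.
    A per-cell-type Mann-Whitney compares treated vs control atlas
    distances.
    """
    if model is None:
        if config.model_dir is None:
            raise AtlasqError("no model given (set model_dir)")
        model = load_model(config.model_dir)
    if model.ref_lognorm is None:
        raise AtlasqError("model must store reference lognorm for paired DE")

    out_dir = Path(config.out_dir)
    conditions = {"control": control, "treatment_A": treated_a}
    if treated_b is not None:
        conditions["treatment_B"] = treated_b

    sub = dataclasses.replace(config, expected_tissue=None)
    results: dict[str, dict] = {}
    de_results: dict[str, de_mod.DEResult] = {}
    for name, ds in conditions.items():
        cfg = dataclasses.replace(sub, out_dir=str(out_dir / name))
        rep = run_incorporate(cfg, model=model, query=ds, write=write)
        if ds.lognorm is None:
            ds = normalize_log1p(ds, target_sum=config.target_sum)
        match = matched_reference(model, rep["coords"],
                                  k=min(config.k_match, model.n_ref))
        idx = ds.gene_ids.get_indexer(model.gene_ids)
        X = np.zeros((ds.n_cells, len(model.gene_ids)))
        present = idx >= 0
        X[:, present] = np.asarray(ds.lognorm[:, idx[present]].todense())
        de_results[name] = de_mod.paired_f_test(
            X, match.profiles, gene_ids=model.gene_ids, alpha=config.alpha
        )
        results[name] = rep

    report: dict = {"n_conditions": len(conditions)}
    for name, der in de_results.items():
        report[f"n_deg_{name}"] = int((der.table["p_adj"] < config.alpha).sum())

    if treated_b is not None:
        cats = de_mod.categorize_degs(de_results["treatment_A"],
                                      de_results["treatment_B"],
                                      alpha=config.alpha)
        report["deg_categories"] = {k: sorted(v) for k, v in cats.as_dict().items()}
        if gene_sets is None and config.gmt_path:
            from .io import read_gmt

            gene_sets = read_gmt(config.gmt_path)
        if gene_sets:
            universe = set(map(str, model.gene_ids))
            enrich = {}
            for cat, genes in cats.as_dict().items():
                if genes:
                    enrich[cat] = de_mod.fisher_enrichment(genes, gene_sets, universe)
            report["enrichment"] = enrich

    # distance comparison per predicted cell type, treated vs control
    ctl_cells = results["control"]["cells"]
    dist_rows = []
    for name in conditions:
        if name == "control":
            continue
        trt_cells = results[name]["cells"]
        if "predicted_level2" not in trt_cells.columns:
            continue
        for ct in sorted(set(trt_cells["predicted_level2"])):
            x = trt_cells.loc[trt_cells["predicted_level2"] == ct,
                              "distance_to_atlas"]
            y = ctl_cells.loc[ctl_cells["predicted_level2"] == ct,
                              "distance_to_atlas"]
            if len(x) >= 3 and len(y) >= 3:
                _, p = stats.mannwhitneyu(x, y, alternative="two-sided")
                dist_rows.append(dict(condition=name, cell_type=ct,
                                      median_treated=float(x.median()),
                                      median_control=float(y.median()),
                                      p=float(p)))
    distance_table = pd.DataFrame(dist_rows)

    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.snapshot(out_dir)
        for name, der in de_results.items():
            der.table.to_csv(out_dir / f"de_{name}.tsv", sep="\t", index=False)
        if len(distance_table):
            distance_table.to_csv(out_dir / "distance_by_celltype.tsv",
                                  sep="\t", index=False)
        serializable = {k: v for k, v in report.items() if k != "enrichment"}
        (out_dir / "report.json").write_text(json.dumps(serializable, indent=2))

    report["de"] = de_results
    report["distance_by_celltype"] = distance_table
    report["incorporations"] = results
    return report
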