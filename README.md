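# atlasq

Reference-atlas query assessment for single-cell organoid transcriptomics.

`atlasq` projects new single-cell datasets onto a reference atlas and asks
the questions that matter when judging an organoid protocol, perturbation or
disease model:

- **Where do my cells map?** Linear reference embedding (center/scale + PCA
  over a frozen HVG list), exact kNN search, and 100-NN label/tissue
  transfer with per-cell confidence; on/off-target quantification.
- **How far are they from the atlas?** Each query cell gets a *matched
  reference* — the mean expression of its 10 nearest atlas cells — and a
  distance-to-atlas (mean of those 10 distances). Large distances flag
  states absent from the healthy reference; an ROC over the distance scores
  disease/novel-state detection, and Leiden clustering with an enrichment
  rule calls disease-state clusters.
- **What changed?** A paired F-type test per gene on cell-matched
  differences against the matched reference (msd/variance ratio with an
  exactly calibrated null), Wilcoxon group DE, BH correction, DEG
  categorization across two conditions, and Fisher gene-set enrichment.
- **How faithful is the model?** Milo-style neighborhoods (30-NN around
  sampled index cells) correlated across datasets over shared HVGs;
  max/median per-cell-type similarity summaries and protocol contrasts.
- **What drives sample variance?** Pseudo-bulk per sample, PCA loadings,
  and covariate R² attribution.
- **Which drug-target signatures light up?** Per-cell signature scoring
  (mean lognorm, z-scaled), the >50%-above-median cell-type assignment
  rule, multicellular flags, and cell-type cosine similarity.
- **Hierarchical annotation.** Marker AUC + log-fold-change scoring of
  Leiden clusters against a 3-level label taxonomy, majority-vote
  reannotation, and Wilcoxon marker refinement.

Everything is exercisable offline on the built-in synthetic atlas generator
(`atlasq.simulate`): seeded multi-tissue references with shared cell types,
a maturation gradient, negative-binomial counts, planted off-target
fractions and perturbed gene sets with full ground truth.

## Quick start (CLI)

```bash
# simulate a reference atlas and a query, fit a model, incorporate
atlasq simulate --seed 0 --out ref/
atlasq fit-ref --data ref/ --n-hvg 1000 --dim 20 --out model/
atlasq incorporate --model model/ --query query/ \
    --expected-tissue tissue0 --out run/
atlasq de --model model/ --query query/ --out de.tsv
atlasq fidelity --a organoid/ --b primary/ --stat max --by celltype --out fid.tsv
atlasq pseudobulk --data ref/ --by sample_id --out pb/
atlasq signatures --data ref/ --gmt chembl.gmt --labels level2 --out sig/
```

Subcommands: `ingest, normalize, annotate, fit-ref, map, assess, de,
fidelity, pseudobulk, signatures, simulate, incorporate, perturb-assess`.
All tabular outputs are TSV, matrices are Matrix Market text; every run
writes a `config.json` snapshot for provenance.

Datasets are directories of `matrix.mtx` (cells × genes) + `cells.tsv` +
`genes.tsv`; gene sets are GMT; taxonomies are nested JSON
(`{"Epithelial": {"markers": [...], "children": {...}}}`).

## Python API

```python
import atlasq as aq

spec = aq.SimSpec(seed=0)
ref, truth = aq.simulate_reference(spec)
ref = aq.normalize_log1p(aq.filter_cells_qc(ref, 100, 50))
model = aq.fit_reference(ref, aq.select_hvg(ref, n=1000), d=20)

query, qtruth = aq.simulate_query(spec, truth, off_target_fraction=0.3)
coords = aq.transform_query(model, aq.normalize_log1p(query))
nn = aq.knn_search(model, coords, k=100)
pred = aq.transfer_labels(nn, model.ref_labels["tissue"], k=100)
print(aq.on_target_fraction(pred["label"], "tissue0")["fraction"])  # ~0.70

match = aq.matched_reference(model, coords, k=10)   # paired pseudo-controls
de = aq.paired_f_test(..., match.profiles)          # DE vs the atlas cohort
```

## Tests and acceptance report

```bash
python -m pytest -q                     # full suite incl. tests/test_acceptance.py
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes every acceptance-criterion quantity from
scratch (oracle equivalence, F-statistic identity and calibration, label
transfer and off-target recovery, distance-based detection, annotation
recovery, fidelity self-test, variance attribution, signature rules) on
seeded synthetic fixtures and writes them as JSON. All randomness derives
from `--seed`.
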