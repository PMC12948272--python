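# gpinn

Knowledge-hierarchy-informed sparse neural networks for copy-number-variant
(CNV) case/control cohorts, with degree-normalized layer-wise Shapley
interpretation, calibrated confidence gating, and permutation-based
validation of the top-ranked genes.

## Who this is for

Statistical geneticists and computational biologists who want to prioritize
disease genes from gene-level CNV profiles while keeping the classifier's
reasoning inspectable: every connection in the network corresponds to a gene
→ term or term → term relation in a biological knowledge base (an ontology
branch and a pathway branch), so attributions on internal nodes are read
directly as pathway- and process-level statements.

## The model

- **Input.** Per-sample CNV calls encoded per gene as −1 (deletion),
  +1 (duplication), 0 (unaltered); built from BED-like segment files by any
  ≥ 1 bp overlap with gene models, or supplied as a ready matrix.
- **Gene selection.** A binary tissue filter keeps genes with TPM > 1 in the
  tissue of interest.
- **Architecture.** A diagonal fusion layer combines each gene's deletion and
  duplication channels into one gene node (no cross-gene terms); two branches
  of masked dense layers follow, one compiled from each knowledge hierarchy
  stratified into L1–L5 by distance from the gene layer. Weights are
  multiplied by fixed binary connectivity masks, so only biologically
  supported connections are trainable — sparse by construction, and masked
  weights are *exactly* zero at all times. Each sparse layer carries a scalar
  sigmoid head; the prediction is the mean of all head probabilities.
- **Interpretation.** Each layer is treated as the feature set of its
  downstream sub-network and attributed with Shapley values φᵢ (exact subset
  enumeration for layers of width ≤ 12, antithetic permutation sampling
  above). Attributions are degree-normalized, φᵢᵃᵈʲ = φᵢ/dᵢ, to discount hub
  inflation, and averaged over the cross-validation folds,
  φᵢᶜᵒᵐᵇ = (1/K) Σₖ φᵢᵏ.
- **Uncertainty.** Probabilities are calibrated by isotonic regression fitted
  on the validation fold; confidence = 2·|p − 0.5|; a knee-selected
  confidence threshold (subject to ≥ 70% coverage, composite Youden/coverage
  score as fallback) gates which predictions enter the interpretation stage.
- **Validation.** The top-ranked decile is tested against a reference gene
  list with a Monte-Carlo permutation null (exact hypergeometric as the
  analytic oracle), Z = (X_obs − μ)/σ, p = #(X_rand ≥ X_obs)/N; clinical
  benefit is summarized by diagnostic yield and phenotype specificity.

The network, its training (Adam, per-head binary cross-entropy) and the
Shapley estimators are implemented directly on numpy for exact
reproducibility and layer-level access.

## Worked example

```python
from gpinn import SyntheticSpec, make_hierarchy, make_cohort
from gpinn.pipeline import PipelineConfig, run_pipeline
from gpinn.network import ModelConfig

spec = SyntheticSpec(n_samples=800, n_genes=60,
                     n_terms_per_layer=((12, 6, 3, 2, 1), (10, 5, 2, 1, 1)),
                     n_causal=6, beta=2.5, cnv_rate=0.2, seed=9)
onto, path = make_hierarchy(spec)
matrix, labels, truth = make_cohort(spec, (onto, path))

cfg = PipelineConfig(k_folds=4, seed=9,
                     model=ModelConfig(epochs=400, batch_size=64, seed=9))
result = run_pipeline(matrix, labels, onto, path, config=cfg,
                      reference_set=set(truth["causal_genes"]))

print(result.summary())
print("top genes:", result.ranking.ids)
print("planted causal:", truth["causal_genes"])
print("overlap p-value:", result.permutation.p)
```

prints

```
{'k_folds': 4, 'accuracy_mean': 0.75375, 'f1_mean': 0.7583607992977602,
 'auc_roc_mean': 0.8467260473901099, 'auc_pr_mean': 0.866676926073888,
 'full_accuracy': 0.75875, 'gated_accuracy': 0.7861111111111111,
 'gated_coverage': 0.9, 'n_top_genes': 6}
top genes: ['G12', 'G46', 'G49', 'G53', 'G15', 'G42']
planted causal: ['G12', 'G15', 'G42', 'G46', 'G49', 'G53']
overlap p-value: 0.0
```

Read: 4-fold cross-validated ROC-AUC 0.847 on a cohort where six planted
genes drive case status through a logistic model; the attribution top decile
(6 of 60 genes) recovers exactly the six planted genes; gating to the 90% most
confident predictions raises accuracy from 0.759 to 0.786; and no random gene
set among 1000 permutations matched the observed overlap (report p < 0.001 —
the result object flags when the observed value exceeds every null draw).

The same pipeline is available from the shell:

```bash
gpinn simulate --out ws --seed 9
gpinn build-graph --ws ws
gpinn train --ws ws --folds 5 --seed 9
gpinn gate --ws ws
gpinn validate --top top.txt --reference ref.txt --universe univ.txt --n 1000
```

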