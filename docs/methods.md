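# Methods

## Problem setting

`gpinn` targets gene prioritization from case/control copy-number-variant
(CNV) cohorts. Per-sample CNV segment calls are collapsed to a ternary
sample × gene matrix (−1 deletion, +1 duplication, 0 unaltered), and a
classifier whose connectivity is compiled from biological knowledge
hierarchies is trained to separate cases from controls. Because the network's
wiring mirrors gene-set membership and term–term relations, attributions on
its internal nodes are directly readable as statements about genes, pathways
and ontology terms.

## Hierarchy compilation

Each knowledge branch (an ontology such as GO, a pathway database such as
Reactome) is a DAG with gene leaves and term internal nodes; edges point from
child to parent. Compilation proceeds in three steps:

1. **Stratification.** Each term's layer index is its shortest-path distance
   from the gene layer (minimum over annotated genes' paths), clamped at
   `n_layers` (default 5). The clamp can leave chains of terms in the final
   layer; those chains are collapsed into their nearest retained ancestor, so
   the final layer holds the root-most representatives. Distance-from-genes
   rather than distance-from-root was chosen because gene annotations, not
   root depth, determine how early a term can receive signal; the assignment
   rule is otherwise an open design point.
2. **Re-wiring.** An edge whose endpoints land in non-adjacent layers is
   realized as a chain of identity pass-through units in the intervening
   layers, preserving connectivity while keeping every compiled connection
   between adjacent strata. Edges that point sideways or backwards after
   stratification (possible when a parent is annotated closer to the gene
   layer than its child) are dropped with a warning and counted in the
   stratification summary — they cannot be represented in a feed-forward
   stack without re-orienting information flow.
3. **Masking.** One binary connectivity mask per adjacent layer pair (plus
   gene → L1) is emitted with lexicographic node ordering, so masks, weights
   and attributions are reproducible across runs. Cohort genes absent from a
   branch receive a pass-through chain to the final layer so no input feature
   is silently dropped.

Terms with no annotated gene anywhere below them are retained in the graph
but excluded from the compiled network (they can never carry signal).
GO-style multi-root branches are treated as a single branch; genes annotated
to a term are *not* propagated to ancestors beyond explicit edges — the
layered network itself performs that propagation.

## Network

The two branches share one gene layer. Ternary input is split into per-gene
channels (A = duplication indicator, D = deletion indicator) and fused by a
diagonal layer — each gene node is a linear combination of that gene's
channels only. A binary gene mask (tissue filtration: TPM > 1 in the target
tissue, max over selected tissues, strict inequality) zeroes genes not
expressed in the tissue of interest. Branch layers are dense layers whose
weights are elementwise-multiplied by the fixed connectivity mask in the
forward pass, so masked weights are exactly zero at all times and receive no
gradient. Hidden activations are tanh (bounded, signed, zero-preserving —
appropriate for signed copy-number effects); each sparse layer has a scalar
sigmoid auxiliary head, and the model output is the uniform (configurable)
mean of all head probabilities. The loss is head-weighted binary
cross-entropy; per-head losses are logged so each layer's training progress
is visible. Aggregating all heads both realizes multi-layer output extraction
and short-circuits vanishing gradients through the deeper strata.

The network is implemented directly on numpy (explicit forward/backward and
an Adam optimizer). At the problem sizes this package addresses (hundreds to
thousands of samples, 10²–10⁴ genes) this is fast, exactly reproducible given
a seed, and keeps layer activations and sub-network evaluation — which the
attribution machinery needs — first-class.

Defaults: learning rate 0.001 (Adam), 200 epochs, batch size 200, dropout
0.05 (accepted range 0.05–0.1, warning outside it). The learning rate halves
after a 10-epoch validation-loss plateau with a floor of 1e-5, and the
best-validation-epoch weights are restored after training; the plateau
schedule is a design choice where only "dynamic learning-rate callbacks" was
prescribed.

## Cross-validation

Stratified k-fold (default k = 20 for full studies; the synthetic acceptance
runs use k = 5 to fit a desktop budget). Each fold serves as the test set in
turn; the cyclically next fold is the validation set (used for the LR
schedule, best-epoch restoration, calibration and gate selection), the rest
train. At k = 2 the validation set reuses the training fold. Confusion-matrix
metrics follow the standard identities; a prediction is positive when the
probability strictly exceeds the threshold. ROC-AUC is the rank statistic and
AUC-PR the interpolation-free step summation (scikit-learn implementations).

## Layer-wise Shapley attribution

Each layer's activations are treated as the feature set of the downstream
sub-network; heads not downstream of the layer are held at the explained
sample's actual values. A feature "absent" from a coalition takes its value
from a background set — a class-balanced random subsample of training inputs
fixed per fold by seed (function default 100; the pipeline uses 8 as a
problem-size choice, see below). Layers of width ≤ 12 are solved by exact
subset enumeration of the Shapley formula; wider layers use permutation
sampling with antithetic permutation pairs (a permutation and its reverse),
which makes the estimator exact for main effects and pairwise interactions
and preserves the local-accuracy identity Σφ + E[f(background)] = f(x)
exactly by telescoping.

Per-sample attributions are reduced to the mean absolute value per node over
the explained samples — by default all test samples retained by the
confidence gate, tying interpretation to reliable predictions. Node
attributions are divided by the node's total degree (in + out) in the
knowledge hierarchy, discounting the importance inflation of highly connected
hubs; degree-0 nodes are left un-normalized with a warning, and pass-through
units take their compiled-network degree. Degree-normalized attributions are
averaged arithmetically across folds; a node absent from some folds is
averaged over the folds where present and flagged. Ranking uses the absolute
combined value with lexicographic tie-breaks; the sign is retained in
reports. The Sankey export keeps the top-n nodes per layer, pools the rest
into per-layer residual nodes, and distributes each source's |φ| over its
outgoing edges proportionally to target scores (uniformly when all targets
score zero).

## Calibration and confidence gating

Isotonic regression (monotone least squares, solved by pool-adjacent-
violators via scikit-learn) is fitted on the validation fold and applied to
test probabilities; out-of-range inputs clamp to the fitted range.
Confidence is 2·|p − 0.5|. The classification threshold th* maximizes
accuracy over midpoints of sorted unique probabilities plus {0, 1}, smallest
threshold on ties. The gate threshold is chosen on the validation fold by
scanning candidate confidence cutoffs (0 plus every unique confidence
value): at each, Youden's J = sensitivity + specificity − 1 on the retained
subset and the coverage C are computed; the knee (maximum discrete concavity,
difference-of-differences) of the J-vs-threshold curve among candidates with
C ≥ 0.70 is selected, falling back to the maximizer of the composite
S = w_J·N(J) + w_C·N(C) with min–max normalization over the candidate set and
default w_J = w_C = 0.5. Youden's J is computed on calibrated probabilities.
Gating is strict (confidence > threshold). If no candidate meets the coverage
floor (degenerate calibrated distributions, e.g. label-permuted nulls), the
pipeline disables the gate rather than abstain on everything. All candidates
are recorded for audit.

## Permutation validation and clinical formulas

Overlap of the top-ranked genes with a reference list is tested against N
(default 1000) random same-size gene sets drawn without replacement — by
default from the non-overlapping pool (universe minus the top set), with a
switch for whole-universe sampling; the two nulls differ and the choice is
recorded in the output. p = count(X_random ≥ X_observed)/N with an optional
(count+1)/(N+1) estimator; Z = (X_observed − μ)/σ, reported as null when the
null is degenerate. When no null draw reaches the observed overlap the result
is flagged so it can be reported as p < 1/N. The exact hypergeometric
distribution is the analytic oracle on small universes. The clinical-benefit
formulas are exact arithmetic: D(g) = 1 iff V_path > 0 and E_max ≥ 2,
diagnostic yield = ΣD/N·100%, phenotype specificity = ΣV_ND/ΣV_path·100%.

## Synthetic data

The generator emulates the statistical structure of a real study: two layered
branch DAGs (default term counts 32/16/8/4/1 and 24/12/6/3/1, every gene
annotated in both branches), a ternary cohort where each gene is altered with
probability `cnv_rate` (deletion/duplication split by `dup_fraction`) and
labels follow P(case|x) = σ(base_rate + Σ_causal β·x_g) with signed effects
by default (duplication +β, deletion −β; a magnitude-only switch exists), a
TPM table where tissue-specific genes (including the causal genes, mirroring
disease genes expressed in disease tissue) exceed 1 TPM only in the target
tissue, and an evidence table with a planted flagged fraction. Ground truth
is emitted as sidecar JSON. Defaults: 2000 samples, 200 genes, 10 causal
genes, β = 1.5, CNV rate 0.1.

It does **not** model CNV length or recurrence distributions, linkage,
population structure, measurement noise in expression, or correlated gene
sets; passing tests therefore demonstrate correctness of the machinery and
recoverability of planted signal, not performance on real cohorts.

Under these defaults the label noise is substantial: the Bayes-optimal
ROC-AUC of the generative model (exact enumeration over the causal genes'
alteration counts) is 0.785, so cross-validated AUCs near 0.70–0.73 reflect
the information content of the data rather than an optimization failure, and
the interesting guarantee is the recovery of the planted causal genes in the
attribution top decile.

## Problem sizes and numerical choices

The end-to-end runs use 5 folds, a background of 8 reference samples and 8
antithetic permutations per explained sample for layers wider than 12, and
all gated test samples (optionally capped) as the explained set; these sizes
keep a full run on one CPU core to a couple of minutes while leaving the
estimators' exactness properties (local accuracy, exact enumeration on narrow
layers) intact. Ties everywhere break lexicographically by node id; all
randomness flows from explicit integer seeds; TSV outputs use a fixed float
format so identical configurations reproduce byte-identical files.

## Known limitations

- Backward/lateral hierarchy edges are dropped, not re-oriented; a branch
  where many parents are annotated shallower than their children loses edges.
- The permutation-sampling Shapley estimator is exact only up to pairwise
  interactions; higher-order interaction attributions on wide layers carry
  Monte-Carlo error.
- Isotonic calibration on small validation folds produces coarse step
  functions; confidence candidates are correspondingly coarse.
- Single-machine, CPU-only training; no GPU or distributed support.
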