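"""End-to-end orchestration: compile, cross-validate, calibrate, gate, explain.

Glues the stage modules together the way a full study runs them:

1. build and stratify both knowledge branches, compile connectivity masks
   against the cohort's gene roster;
2. stratified k-fold cross-validation of the masked dual-branch network;
3. per fold, fit isotonic calibration on the validation split, pick the
   accuracy-optimal class threshold and the knee-selected confidence gate on
   the validation split, and apply both to the test split;
4. layer-wise Shapley attribution of the gated test samples against a
   class-balanced training background, degree normalization, fold averaging;
5. ranking of the top gene fraction and permutation overlap testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import explain as ex
from . import hierarchy as hg
from . import uncertainty as unc
from . import validate as val
from .genomics import TernaryMatrix
from .network import ModelConfig
from .synthetic import Branch
from .training import FoldResult, cross_validate, evaluate, summarize

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    k_folds: int = 5
    top_fraction: float = 0.10
    min_coverage: float = 0.70
    w_j: float = 0.5
    w_c: float = 0.5
    # Shapley estimator problem sizes (permutation sampling above exact width)
    shap_n_perm: int = 8
    shap_background_size: int = 8
    shap_exact_max_width: int = 12
    max_explained_per_fold: int | None = None  # None = all gated test samples
    n_permutations: int = 1000
    seed: int = 0
    # ablation switches
    permute_labels: bool = False
    single_branch: str | None = None  # "ontology" or "pathway"


@dataclass
class PipelineResult:
    fold_metrics: pd.DataFrame
    attributions: pd.DataFrame       # per fold/layer/node, phi and phi_adjusted
    combined: pd.DataFrame           # fold-averaged attributions
    ranking: ex.RankedFeatures
    gate_reports: list[unc.GateResult]
    full_accuracy: float
    gated_accuracy: float
    gated_coverage: float
    models: list
    masks_ontology: list
    masks_pathway: list
    rewired_edges: list
    permutation: val.PermutationResult | None = None

    def summary(self) -> dict:
        m = self.fold_metrics
        return {
            "k_folds": len(m),
            "accuracy_mean": float(m["accuracy"].mean()),
            "f1_mean": float(m["f1"].mean()),
            "auc_roc_mean": float(m["auc_roc"].mean()),
            "auc_pr_mean": float(m["auc_pr"].mean()),
            "full_accuracy": self.full_accuracy,
            "gated_accuracy": self.gated_accuracy,
            "gated_coverage": self.gated_coverage,
            "n_top_genes": len(self.ranking.ids),
        }


def compile_masks(
    onto: Branch | hg.HierarchyGraph,
    path: Branch | hg.HierarchyGraph,
    gene_roster: list[str],
    n_layers: int = 5,
):
    """Stratify both branches and build mask stacks sharing one gene ordering."""
    graphs = [b.graph() if isinstance(b, Branch) else b for b in (onto, path)]
    strats = [hg.stratify(g, n_layers=n_layers) for g in graphs]
    stacks = [hg.masks(s, g, gene_roster=gene_roster) for s, g in zip(strats, graphs)]
    # merged degree table: hierarchy degrees plus pass-through units
    degrees: dict[str, int] = {}
    for g in graphs:
        for node, d in hg.degree(g).items():
            degrees[node] = degrees.get(node, 0) + d
    for stack in stacks:
        for node, d in hg.stratified_degree(stack).items():
            degrees.setdefault(node, d)
    edges = []
    for s, stack in zip(strats, stacks):
        seen = set()
        for cm_i, cm in enumerate(stack, start=1):
            for u, v, _one in cm.to_triplets():
                if (u, v, cm_i) not in seen:
                    seen.add((u, v, cm_i))
                    edges.append((u, v, cm_i))
    return stacks[0], stacks[1], degrees, strats, edges


def run_pipeline(
    matrix: TernaryMatrix,
    labels: pd.Series,
    onto: Branch | hg.HierarchyGraph,
    path: Branch | hg.HierarchyGraph,
    gene_mask: dict[str, int] | None = None,
    config: PipelineConfig | None = None,
    reference_set: set[str] | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    genes = list(matrix.gene_ids)
    masks_o, masks_p, degrees, _strats, edges = compile_masks(
        onto, path, genes, n_layers=cfg.model.n_layers
    )
    gm = gene_mask or dict.fromkeys(genes, 1)

    y = labels.loc[matrix.sample_ids].to_numpy(dtype=int)
    if cfg.permute_labels:
        y = np.random.default_rng(cfg.seed + 99).permutation(y)
    x = matrix.values.astype(float)

    model_cfg = cfg.model
    if cfg.single_branch is not None:
        n = model_cfg.n_layers
        w = [1.0 / n if br == cfg.single_branch else 0.0
             for br in ("ontology", "pathway") for _ in range(n)]
        model_cfg = ModelConfig(**{**model_cfg.__dict__, "aux_head_weighting": w})

    results: list[FoldResult] = cross_validate(
        model_cfg, masks_o, masks_p, gm, x, y, k=cfg.k_folds, seed=cfg.seed
    )
    fold_metrics = summarize(results)

    attribution_frames = []
    gate_reports = []
    pooled_true, pooled_pred_full, pooled_pred_gated = [], [], []
    pooled_retained = 0
    pooled_total = 0
    for r in results:
        cal = unc.fit_isotonic(r.y_prob_val, y[r.val_idx])
        p_val = unc.apply_calibration(cal, r.y_prob_val)
        p_test = unc.apply_calibration(cal, r.y_prob_test)
        th_star = unc.optimal_class_threshold(y[r.val_idx], p_val)
        try:
            gate_res = unc.select_confidence_threshold(
                y[r.val_idx], p_val, w_j=cfg.w_j, w_c=cfg.w_c,
                min_coverage=cfg.min_coverage, class_threshold=th_star,
            )
        except ValueError:
            # degenerate confidence distribution (e.g. calibrated probabilities
            # collapsed onto 0.5): keep everything rather than abstain on all
            log.warning("fold %d: no gate meets the coverage floor; gating disabled", r.fold)
            _, cov0 = unc.gate(p_val, 0.0)
            gate_res = unc.GateResult(
                class_threshold=th_star, confidence_threshold=0.0,
                coverage=cov0, youden=float("nan"), composite=float("nan"),
                knee_used=False, w_j=cfg.w_j, w_c=cfg.w_c,
                min_coverage=cfg.min_coverage,
                candidates=pd.DataFrame(
                    columns=["threshold", "coverage", "youden", "n_j", "n_c", "composite"]
                ),
            )
        gate_reports.append(gate_res)
        retained, coverage = unc.gate(p_test, gate_res.confidence_threshold)
        y_test = y[r.test_idx]
        pred = (p_test > th_star).astype(int)
        pooled_true.append(y_test)
        pooled_pred_full.append(pred)
        pooled_pred_gated.append((y_test[retained], pred[retained]))
        pooled_retained += len(retained)
        pooled_total += len(y_test)

        # explain the gated test samples against a balanced training background
        explain_idx = np.asarray(r.test_idx)[retained]
        if explain_idx.size == 0:
            explain_idx = np.asarray(r.test_idx)
        if (cfg.max_explained_per_fold is not None
                and explain_idx.size > cfg.max_explained_per_fold):
            sub = np.random.default_rng(cfg.seed + 7 + r.fold).choice(
                explain_idx.size, size=cfg.max_explained_per_fold, replace=False
            )
            explain_idx = explain_idx[np.sort(sub)]
        background = ex.select_background(
            x[r.train_idx], y[r.train_idx],
            size=cfg.shap_background_size, seed=cfg.seed + 13 + r.fold,
        )
        attr = ex.explain_fold(
            r.model, x[explain_idx], background, fold=r.fold,
            n_perm=cfg.shap_n_perm,
            background_size=cfg.shap_background_size,
            exact_max_width=cfg.shap_exact_max_width,
            seed=cfg.seed + 29 + r.fold,
        )
        attribution_frames.append(attr)
        log.info("fold %d: gate threshold %.3f coverage %.2f, %d explained",
                 r.fold, gate_res.confidence_threshold, coverage, explain_idx.size)

    attributions = pd.concat(attribution_frames, ignore_index=True)
    attributions = ex.degree_normalize(attributions, degrees)
    combined = ex.aggregate_folds(attributions)
    ranking = ex.rank_top_fraction(combined, fraction=cfg.top_fraction, branch="gene")

    y_true = np.concatenate(pooled_true)
    y_full = np.concatenate(pooled_pred_full)
    full_accuracy = float((y_true == y_full).mean())
    gt = np.concatenate([t for t, _ in pooled_pred_gated])
    gp = np.concatenate([p for _, p in pooled_pred_gated])
    gated_accuracy = float((gt == gp).mean()) if gt.size else float("nan")
    gated_coverage = pooled_retained / pooled_total

    permutation = None
    if reference_set is not None:
        permutation = val.permutation_overlap(
            set(ranking.ids), set(reference_set), set(genes),
            n_iter=cfg.n_permutations, seed=cfg.seed + 41,
        )

    return PipelineResult(
        fold_metrics=fold_metrics,
        attributions=attributions,
        combined=combined,
        ranking=ranking,
        gate_reports=gate_reports,
        full_accuracy=full_accuracy,
        gated_accuracy=gated_accuracy,
        gated_coverage=gated_coverage,
        models=[r.model for r in results],
        masks_ontology=masks_o,
        masks_pathway=masks_p,
        rewired_edges=edges,
        permutation=permutation,
    )
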