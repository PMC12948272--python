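"""Self-contained synthetic fixtures for every pipeline stage.

Emulates the statistical structure the pipeline expects from real cohorts:
two knowledge-branch DAGs (an ontology-like and a pathway-like hierarchy), a
ternary CNV cohort whose case/control labels follow a logistic model driven
by a planted set of causal genes, a gene x tissue TPM reference with known
tissue-specific genes, and a clinical-evidence table with planted diagnostic
flags.  Ground truth (causal genes, tissue-specific genes, planted yield) is
emitted as first-class sidecar data so tests never re-derive it.

It does not attempt realistic CNV length/recurrence distributions, linkage
structure or population stratification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genomics import ExpressionReference, TernaryMatrix
from .hierarchy import HierarchyGraph, build_graph


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults define the standard study conditions."""

    n_samples: int = 2000
    n_genes: int = 200
    # per-branch term counts per layer, gene-adjacent first
    n_terms_per_layer: tuple = ((32, 16, 8, 4, 1), (24, 12, 6, 3, 1))
    fanout: float = 1.5            # mean parents per term
    n_causal: int = 10
    beta: float = 1.5              # per-causal-gene log-odds of a non-zero CNV
    base_rate: float = 0.0         # logistic intercept
    cnv_rate: float = 0.1          # per-gene alteration probability
    dup_fraction: float = 0.5
    signed_effects: bool = True    # dup -> +beta, del -> -beta; else |x| effects
    n_tissues: int = 5
    tissue_specific_fraction: float = 0.6
    target_tissue: str = "tissue_0"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_genes:
            raise ValueError("n_causal cannot exceed n_genes")
        for p in (self.cnv_rate, self.dup_fraction, self.tissue_specific_fraction):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class Branch:
    name: str
    gene_sets: dict[str, set[str]]
    relations: set[tuple[str, str]]

    def graph(self) -> HierarchyGraph:
        return build_graph(self.gene_sets, self.relations, branch=self.name)

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for term in sorted(self.gene_sets):
                members = "\t".join(sorted(self.gene_sets[term]))
                fh.write(f"{term}\tsynthetic term\t{members}\n")

    def write_relations(self, path) -> None:
        with open(path, "w") as fh:
            for child, parent in sorted(self.relations):
                fh.write(f"{child}\t{parent}\n")


def gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def make_hierarchy(spec: SyntheticSpec) -> tuple[Branch, Branch]:
    """Two layered DAG branches; acyclic by construction (edges only cross
    adjacent layers toward the root) and every gene annotated to >= 1 term in
    each branch."""
    rng = np.random.default_rng(spec.seed)
    genes = gene_names(spec.n_genes)
    branches = []
    for name, sizes in zip(("ontology", "pathway"), spec.n_terms_per_layer):
        if any(s < 1 for s in sizes):
            raise ValueError("layer sizes must be >= 1")
        prefix = "GO" if name == "ontology" else "RP"
        terms = [
            [f"{prefix}:{l + 1}:{j:03d}" for j in range(s)]
            for l, s in enumerate(sizes)
        ]
        # gene annotations: round-robin guarantees non-empty leaf terms,
        # plus one extra random membership for about half the genes
        gene_sets: dict[str, set[str]] = {t: set() for t in terms[0]}
        for i, g in enumerate(genes):
            gene_sets[terms[0][i % len(terms[0])]].add(g)
        for g in genes:
            if rng.random() < 0.5:
                gene_sets[terms[0][rng.integers(len(terms[0]))]].add(g)
        # term-term relations: every term gets >= 1 parent in the next layer
        relations: set[tuple[str, str]] = set()
        for l in range(len(sizes) - 1):
            children, parents = terms[l], terms[l + 1]
            for i, c in enumerate(children):
                relations.add((c, parents[i % len(parents)]))
                extra = rng.poisson(max(spec.fanout - 1.0, 0.0))
                for _ in range(extra):
                    relations.add((c, parents[rng.integers(len(parents))]))
        branches.append(Branch(name, gene_sets, relations))
    return branches[0], branches[1]


def make_cohort(
    spec: SyntheticSpec,
    hierarchy: tuple[Branch, Branch] | None = None,
) -> tuple[TernaryMatrix, pd.Series, dict]:
    """Ternary CNV cohort with labels ~ Bernoulli(sigmoid(base + sum beta_g x_g)).

    Causal genes are drawn from genes annotated in the hierarchy (all genes,
    when no hierarchy is given).  Returns (matrix, labels, truth) where truth
    records the planted causal genes and their signed effects.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if hierarchy is not None:
        annotated = sorted(
            set().union(*(set().union(*b.gene_sets.values()) for b in hierarchy))
        )
    else:
        annotated = gene_names(spec.n_genes)
    genes = gene_names(spec.n_genes)
    causal = sorted(str(g) for g in rng.choice(annotated, size=spec.n_causal, replace=False))

    altered = rng.random((spec.n_samples, spec.n_genes)) < spec.cnv_rate
    sign = np.where(rng.random((spec.n_samples, spec.n_genes)) < spec.dup_fraction, 1, -1)
    x = np.where(altered, sign, 0).astype(np.int8)

    col = {g: j for j, g in enumerate(genes)}
    causal_cols = [col[g] for g in causal]
    if spec.signed_effects:
        eta = spec.base_rate + spec.beta * x[:, causal_cols].sum(axis=1)
    else:
        eta = spec.base_rate + spec.beta * np.abs(x[:, causal_cols]).sum(axis=1)
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(spec.n_samples) < prob).astype(int)

    width = len(str(spec.n_samples - 1))
    samples = [f"S{i:0{width}d}" for i in range(spec.n_samples)]
    matrix = TernaryMatrix(samples, genes, x)
    labels = pd.Series(y, index=samples, name="label")
    truth = {
        "causal_genes": causal,
        "beta": spec.beta,
        "signed_effects": spec.signed_effects,
        "base_rate": spec.base_rate,
    }
    return matrix, labels, truth


def make_expression(
    spec: SyntheticSpec,
    must_express: list[str] | None = None,
) -> tuple[ExpressionReference, dict]:
    """TPM reference where designated tissue-specific genes exceed 1 TPM in
    the target tissue and stay <= 1 elsewhere.

    ``must_express`` (e.g. the planted causal genes) are forced into the
    tissue-specific set, mirroring disease genes expressed in the disease
    tissue.
    """
    rng = np.random.default_rng(spec.seed + 2)
    genes = gene_names(spec.n_genes)
    tissues = [f"tissue_{t}" for t in range(spec.n_tissues)]
    target = tissues.index(spec.target_tissue)
    n_specific = int(round(spec.tissue_specific_fraction * spec.n_genes))
    specific = set(rng.choice(genes, size=n_specific, replace=False))
    specific |= set(must_express or ())
    tpm = rng.uniform(0.0, 1.0, size=(spec.n_genes, spec.n_tissues))
    for i, g in enumerate(genes):
        if g in specific:
            tpm[i, target] = rng.uniform(2.0, 50.0)
        else:
            tpm[i, target] = rng.uniform(0.0, 1.0)
    expr = ExpressionReference(genes, tissues, tpm)
    return expr, {"tissue_specific_genes": sorted(specific), "target_tissue": spec.target_tissue}


def make_clinical_table(
    ranked_genes: list[str],
    flagged_fraction: float = 0.5,
    nd_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Evidence table with a planted fraction of diagnostically flagged genes.

    Flagged genes get V_path > 0 and E_max >= 2; the rest violate at least one
    condition.  V_ND <= V_path always.  The planted yield is recorded as truth.
    """
    rng = np.random.default_rng(seed)
    n = len(ranked_genes)
    n_flagged = int(round(flagged_fraction * n))
    flags = np.zeros(n, dtype=int)
    flags[rng.choice(n, size=n_flagged, replace=False)] = 1
    rows = []
    for r, (g, d) in enumerate(zip(ranked_genes, flags), start=1):
        if d:
            v_path = int(rng.integers(1, 20))
            e_max = int(rng.integers(2, 5))
        else:
            if rng.random() < 0.5:
                v_path, e_max = 0, int(rng.integers(0, 5))
            else:
                v_path, e_max = int(rng.integers(1, 20)), int(rng.integers(0, 2))
        v_nd = int(rng.binomial(v_path, nd_fraction))
        rows.append((g, r, v_path, e_max, v_nd))
    table = pd.DataFrame(rows, columns=["gene", "rank", "v_path", "e_max", "v_nd"])
    total_path = int(table["v_path"].sum())
    truth = {
        "planted_yield_pct": 100.0 * n_flagged / n,
        "planted_specificity_pct": (
            100.0 * table["v_nd"].sum() / total_path if total_path else None
        ),
    }
    return table, truth


def write_cohort(directory, spec: SyntheticSpec) -> dict:
    """Generate and write every fixture a pipeline run consumes; returns paths."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    onto, path = make_hierarchy(spec)
    matrix, labels, truth = make_cohort(spec, (onto, path))
    expr, expr_truth = make_expression(spec, must_express=truth["causal_genes"])

    onto.write_gmt(d / "ontology.gmt")
    onto.write_relations(d / "ontology_relations.tsv")
    path.write_gmt(d / "pathway.gmt")
    path.write_relations(d / "pathway_relations.tsv")
    matrix.write_tsv(d / "cnv_matrix.tsv")
    labels.to_csv(d / "labels.tsv", sep="\t", header=False)
    expr.write_tsv(d / "expression.tsv")
    truth = {**truth, **expr_truth, "spec": asdict(spec)}
    truth["spec"]["n_terms_per_layer"] = [list(t) for t in spec.n_terms_per_layer]
    with open(d / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return {
        "ontology_gmt": str(d / "ontology.gmt"),
        "ontology_relations": str(d / "ontology_relations.tsv"),
        "pathway_gmt": str(d / "pathway.gmt"),
        "pathway_relations": str(d / "pathway_relations.tsv"),
        "matrix": str(d / "cnv_matrix.tsv"),
        "labels": str(d / "labels.tsv"),
        "expression": str(d / "expression.tsv"),
        "truth": str(d / "truth.json"),
    }
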