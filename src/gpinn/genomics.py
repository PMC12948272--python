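"""CNV encoding, tissue-expression gene selection and class balancing.

Per-sample CNV segment calls are collapsed to a gene-level ternary matrix:
-1 for a deletion hitting the gene, +1 for a duplication, 0 otherwise.
Coordinates are 0-based half-open internally; any overlap of at least 1 bp
counts as a hit.  A gene hit by both a deletion and a duplication in the same
sample is set to 0 with a warning (no direction is fabricated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

SVTYPES = ("del", "dup")


@dataclass(frozen=True)
class CNVSegment:
    sample: str
    chrom: str
    start: int
    end: int
    svtype: str  # "del" or "dup"

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"svtype must be one of {SVTYPES}, got {self.svtype!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")


@dataclass(frozen=True)
class GeneModel:
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")


@dataclass
class TernaryMatrix:
    """Sample x gene matrix with entries in {-1, 0, +1}."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("values shape does not match id lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        bad = np.setdiff1d(np.unique(self.values), [-1, 0, 1])
        if bad.size:
            raise ValueError(f"entries outside {{-1,0,1}}: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TernaryMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=np.int8))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, path) -> "TernaryMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls.from_frame(df)

    def subset_samples(self, sample_ids: list[str]) -> "TernaryMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return TernaryMatrix(list(sample_ids), list(self.gene_ids), self.values[rows])


@dataclass
class ExpressionReference:
    """Gene x tissue TPM table."""

    gene_ids: list[str]
    tissue_ids: list[str]
    tpm: np.ndarray

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        if self.tpm.shape != (len(self.gene_ids), len(self.tissue_ids)):
            raise ValueError("tpm shape does not match id lists")
        if (self.tpm < 0).any():
            raise ValueError("TPM values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tpm, index=self.gene_ids, columns=self.tissue_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionReference":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def read_segments(path, one_based: bool = False) -> list[CNVSegment]:
    """Read a BED-like TSV (sample, chrom, start, end, svtype)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["sample", "chrom", "start", "end", "svtype"],
        dtype={"sample": str, "chrom": str},
        comment="#",
    )
    offset = 1 if one_based else 0
    return [
        CNVSegment(r.sample, r.chrom, int(r.start) - offset, int(r.end), r.svtype)
        for r in df.itertuples()
    ]


def read_gene_models(path) -> list[GeneModel]:
    """Read a gene-model BED (chrom, start, end, gene)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "gene": str}, comment="#",
    )
    return [GeneModel(r.gene, r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


def encode_cnv(
    segments: list[CNVSegment],
    genes: list[GeneModel],
    samples: list[str] | None = None,
    exclude_y: bool = True,
) -> TernaryMatrix:
    """Collapse segment calls to the gene-level ternary matrix.

    Parameters
    ----------
    samples
        Optional roster; samples with no segments appear as all-zero rows only
        when listed here.  Defaults to the samples present in ``segments``.
    exclude_y
        Drop Y-chromosome genes (default on, mirroring cohorts that exclude
        sex-chromosome CNVs).
    """
    if len({g.gene for g in genes}) != len(genes):
        raise ValueError("duplicate gene symbols in gene models")
    if exclude_y:
        genes = [g for g in genes if g.chrom.lstrip("chr") != "Y"]

    trees: dict[str, IntervalTree] = {}
    for g in sorted(genes, key=lambda g: g.gene):
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene)

    gene_ids = sorted(g.gene for g in genes)
    gcol = {g: j for j, g in enumerate(gene_ids)}
    if samples is None:
        sample_ids = sorted({s.sample for s in segments})
    else:
        sample_ids = list(samples)
    srow = {s: i for i, s in enumerate(sample_ids)}

    n, m = len(sample_ids), len(gene_ids)
    hit_del = np.zeros((n, m), dtype=bool)
    hit_dup = np.zeros((n, m), dtype=bool)
    unknown_chroms: set[str] = set()
    for seg in segments:
        if seg.sample not in srow:
            continue
        tree = trees.get(seg.chrom)
        if tree is None:
            unknown_chroms.add(seg.chrom)
            continue
        i = srow[seg.sample]
        target = hit_del if seg.svtype == "del" else hit_dup
        for iv in tree.overlap(seg.start, seg.end):
            target[i, gcol[iv.data]] = True
    if unknown_chroms:
        warnings.warn(
            f"segments on unknown chromosome(s) skipped: {sorted(unknown_chroms)}",
            stacklevel=2,
        )

    values = hit_dup.astype(np.int8) - hit_del.astype(np.int8)
    conflict = hit_del & hit_dup
    if conflict.any():
        values[conflict] = 0
        warnings.warn(
            f"{int(conflict.sum())} sample-gene pair(s) hit by both a deletion "
            "and a duplication set to 0",
            stacklevel=2,
        )
    return TernaryMatrix(sample_ids, gene_ids, values)


# ---------------------------------------------------------------------------
# gene selection and balancing
# ---------------------------------------------------------------------------

def tissue_filter(
    expr: ExpressionReference,
    tissues: set[str],
    threshold: float = 1.0,
) -> dict[str, int]:
    """Binary gene mask: 1 iff max TPM over the selected tissues is > threshold."""
    unknown = sorted(set(tissues) - set(expr.tissue_ids))
    if unknown:
        raise ValueError(f"unknown tissue id(s): {unknown}")
    cols = [expr.tissue_ids.index(t) for t in sorted(tissues)]
    keep = expr.tpm[:, cols].max(axis=1) > threshold
    return {g: int(k) for g, k in zip(expr.gene_ids, keep)}


def apply_gene_mask(matrix: TernaryMatrix, mask: dict[str, int]) -> TernaryMatrix:
    """Drop columns whose mask is 0, preserving the order of survivors."""
    missing = [g for g in matrix.gene_ids if g not in mask]
    if missing:
        raise ValueError(f"mask missing {len(missing)} matrix gene(s), e.g. {missing[:3]}")
    keep = [j for j, g in enumerate(matrix.gene_ids) if mask[g]]
    if not keep:
        raise ValueError("gene mask removes every feature")
    return TernaryMatrix(
        list(matrix.sample_ids),
        [matrix.gene_ids[j] for j in keep],
        matrix.values[:, keep],
    )


def read_labels(path) -> pd.Series:
    """Read a (sample, 0/1) TSV into a Series indexed by sample id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"],
                     dtype={"sample": str}, comment="#")
    s = pd.Series(df["label"].to_numpy(dtype=int), index=df["sample"])
    if not set(np.unique(s.to_numpy())) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return s


def balance_undersample(
    matrix: TernaryMatrix,
    labels: pd.Series,
    seed: int,
) -> tuple[TernaryMatrix, pd.Series]:
    """Uniformly undersample the majority class to the minority-class size.

    Deterministic given ``seed``; the returned samples are in sorted-id order.
    """
    labels = labels.loc[matrix.sample_ids]
    y = labels.to_numpy()
    cases = [s for s, v in zip(matrix.sample_ids, y) if v == 1]
    controls = [s for s, v in zip(matrix.sample_ids, y) if v == 0]
    if not cases or not controls:
        raise ValueError("both classes must be non-empty to balance")
    n = min(len(cases), len(controls))
    rng = np.random.default_rng(seed)
    keep_cases = sorted(rng.choice(sorted(cases), size=n, replace=False)) if len(cases) > n else sorted(cases)
    keep_controls = sorted(rng.choice(sorted(controls), size=n, replace=False)) if len(controls) > n else sorted(controls)
    keep = sorted(keep_cases + keep_controls)
    return matrix.subset_samples(keep), labels.loc[keep]
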