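"""Monte-Carlo permutation overlap testing and clinical-benefit formulas.

The enrichment of a top-ranked gene set against a disease reference list is
judged against a null distribution of overlaps from random gene sets of the
same size.  Sampling defaults to the non-overlapping pool (universe minus the
top set); the conventional whole-universe null is available via a switch.
The exact hypergeometric distribution is the analytic oracle for this test on
small universes.

Clinical benefit of a prioritized gene list is summarized by the diagnostic
flag D(g) = 1 iff the gene carries at least one pathogenic variant with
multi-submitter-or-better evidence (E_max >= 2), the diagnostic yield
(percentage of flagged genes), and the phenotype specificity (percentage of
pathogenic variants that are phenotype-specific).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

EVIDENCE_LEVELS = (0, 1, 2, 3, 4)


@dataclass
class PermutationResult:
    x_observed: int
    null_values: np.ndarray
    mu: float
    sigma: float
    z: float | None
    p: float
    n_iter: int
    seed: int
    pool: str                      # "non_overlapping" or "universe"
    plus_one: bool
    below_resolution: bool         # True when no null draw reached x_observed

    def to_json(self, path) -> None:
        payload = dict(self.__dict__)
        payload["null_values"] = self.null_values.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)


def permutation_overlap(
    top_set: set[str],
    reference_set: set[str],
    universe: set[str],
    n_iter: int = 1000,
    seed: int = 0,
    sample_from_universe: bool = False,
    plus_one: bool = False,
) -> PermutationResult:
    """Empirical overlap test of ``top_set`` against ``reference_set``.

    Null feature sets of size |top_set| are drawn uniformly without
    replacement, by default from the non-overlapping pool (universe minus the
    top set).  ``p = count(X_random >= X_observed) / N``; ``plus_one`` enables
    the (count+1)/(N+1) estimator.  ``Z = (X_observed - mu)/sigma`` is None
    when the null is degenerate (sigma = 0).
    """
    top_set, reference_set, universe = set(top_set), set(reference_set), set(universe)
    if not top_set <= universe:
        raise ValueError("top_set must be a subset of the universe")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ref_in_universe = reference_set & universe
    if not ref_in_universe:
        warnings.warn("reference set does not intersect the universe", stacklevel=2)

    x_observed = len(top_set & reference_set)
    pool = sorted(universe if sample_from_universe else universe - top_set)
    k = len(top_set)
    if len(pool) < k:
        raise ValueError(
            f"sampling pool ({len(pool)}) smaller than top set ({k}); "
            "use sample_from_universe=True"
        )
    ref = np.isin(np.array(pool), sorted(ref_in_universe))
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter, dtype=int)
    for j in range(n_iter):
        draw = rng.choice(len(pool), size=k, replace=False)
        null[j] = int(ref[draw].sum())

    mu = float(null.mean())
    sigma = float(null.std(ddof=0))
    z = (x_observed - mu) / sigma if sigma > 0 else None
    count = int((null >= x_observed).sum())
    p = (count + 1) / (n_iter + 1) if plus_one else count / n_iter
    return PermutationResult(
        x_observed=x_observed, null_values=null, mu=mu, sigma=sigma,
        z=z, p=float(p), n_iter=n_iter, seed=seed,
        pool="universe" if sample_from_universe else "non_overlapping",
        plus_one=plus_one,
        below_resolution=(count == 0),
    )


# ---------------------------------------------------------------------------
# clinical-benefit formulas
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("gene", "rank", "v_path", "e_max", "v_nd")


def check_evidence_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"evidence table missing column(s): {missing}")
    if table.empty:
        raise ValueError("evidence table is empty")
    if (table["v_path"] < 0).any() or (table["v_nd"] < 0).any():
        raise ValueError("variant counts must be non-negative")
    if (table["v_nd"] > table["v_path"]).any():
        raise ValueError("phenotype-specific counts cannot exceed pathogenic counts")
    if not table["e_max"].isin(EVIDENCE_LEVELS).all():
        raise ValueError(f"e_max must be in {EVIDENCE_LEVELS}")
    return table


def read_evidence_table(path) -> pd.DataFrame:
    return check_evidence_table(pd.read_csv(path, sep="\t", dtype={"gene": str}))


def diagnostic_flag(v_path, e_max):
    """D(g) = 1 iff V_path(g) > 0 and E_max(g) >= 2."""
    v_path = np.asarray(v_path)
    e_max = np.asarray(e_max)
    if (v_path < 0).any():
        raise ValueError("pathogenic variant counts must be non-negative")
    return ((v_path > 0) & (e_max >= 2)).astype(int)


def diagnostic_yield(table: pd.DataFrame) -> float:
    """Percentage of prioritized genes with confirmed diagnostic evidence."""
    check_evidence_table(table)
    d = diagnostic_flag(table["v_path"], table["e_max"])
    return float(d.sum() / len(table) * 100.0)


def phenotype_specificity(table: pd.DataFrame) -> float:
    """Percentage of pathogenic variants that are phenotype-specific."""
    check_evidence_table(table)
    total = float(table["v_path"].sum())
    if total == 0:
        raise ValueError("no pathogenic variants in the table")
    return float(table["v_nd"].sum() / total * 100.0)


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
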