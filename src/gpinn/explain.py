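"""Layer-wise Shapley attribution with degree normalization and fold aggregation.

Each network layer is treated as the feature set of its downstream
sub-network: the Shapley value of node i at layer l is its average marginal
contribution to the model output over feature coalitions, where an "absent"
feature takes its value from a reference (background) activation set.  Widths
up to ``exact_max_width`` are solved by exact subset enumeration of the
Shapley formula; wider layers use an antithetic permutation-sampling
estimator, which preserves the local-accuracy identity
``sum_i phi_i + E[f(background)] = f(x)`` exactly.

Node attributions are the mean absolute per-sample value, then divided by the
node's total graph degree (discounting hub inflation) and averaged across
cross-validation folds.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import DualBranchModel

GENE_LAYER = ("gene", 0)


@dataclass
class ShapResult:
    """Per-sample attributions for one layer of one fold."""

    branch: str            # "gene", "ontology" or "pathway"
    layer: int             # 0 = gene layer
    node_ids: list[str]
    phi: np.ndarray        # (n_explained, width)
    base: np.ndarray       # (n_explained,) expected output over background
    fx: np.ndarray         # (n_explained,) actual output
    method: str            # "exact" or "permutation"

    def local_accuracy_gap(self) -> float:
        return float(np.max(np.abs(self.phi.sum(axis=1) + self.base - self.fx)))


def _shapley_weights(d: int) -> np.ndarray:
    """w[s] = s!(d-s-1)!/d! for coalition size s."""
    fact = [math.factorial(i) for i in range(d + 1)]
    return np.array([fact[s] * fact[d - s - 1] / fact[d] for s in range(d)])


def _exact_phi(g, h_x: np.ndarray, h_bg: np.ndarray) -> np.ndarray:
    """Exact Shapley values by subset enumeration (one explained sample)."""
    d = h_x.shape[0]
    n_bg = h_bg.shape[0]
    n_sub = 1 << d
    bits = (np.arange(n_sub)[:, None] >> np.arange(d)[None, :]) & 1  # (2^d, d)
    comp = np.where(bits[:, None, :].astype(bool), h_x[None, None, :], h_bg[None, :, :])
    f = g(comp.reshape(-1, d)).reshape(n_sub, n_bg).mean(axis=1)
    sizes = bits.sum(axis=1)
    w = _shapley_weights(d)
    phi = np.zeros(d)
    for i in range(d):
        without = np.flatnonzero(bits[:, i] == 0)
        phi[i] = np.sum(w[sizes[without]] * (f[without | (1 << i)] - f[without]))
    return phi


def _sampled_phi(g, h_x, h_bg, n_perm: int, rng) -> np.ndarray:
    """Permutation-sampling Shapley values with antithetic permutation pairs."""
    d = h_x.shape[0]
    n_bg = h_bg.shape[0]
    perms = []
    for _ in range(max(1, n_perm // 2)):
        p = rng.permutation(d)
        perms.extend([p, p[::-1]])
    phi = np.zeros(d)
    for p in perms:
        comp = np.repeat(h_bg[:, None, :], d + 1, axis=1)  # (n_bg, d+1, d)
        for j, feat in enumerate(p):
            comp[:, j + 1:, feat] = h_x[feat]
        vals = g(comp.reshape(-1, d)).reshape(n_bg, d + 1)
        marg = (vals[:, 1:] - vals[:, :-1]).mean(axis=0)
        phi[p] += marg
    return phi / len(perms)


def select_background(
    x_train: np.ndarray, y_train: np.ndarray, size: int = 100, seed: int = 0
) -> np.ndarray:
    """Class-balanced random subsample of training inputs used as the
    masking baseline, fixed per fold by the seed."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y_train, dtype=int)
    half = max(1, size // 2)
    rows = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size == 0:
            continue
        take = min(half, idx.size)
        rows.append(rng.choice(idx, size=take, replace=False))
    return x_train[np.sort(np.concatenate(rows))]


def shap_layer(
    model: DualBranchModel,
    branch: str | None,
    layer: int,
    x_explain: np.ndarray,
    background: np.ndarray,
    *,
    n_perm: int = 16,
    background_size: int = 100,
    exact_max_width: int = 12,
    seed: int = 0,
) -> ShapResult:
    """Shapley attributions for one layer's nodes over the explained samples.

    ``background`` holds raw reference inputs; their activations at the target
    layer form the masking baseline.  Heads not downstream of the layer are
    held at each explained sample's actual value.
    """
    if background is None or len(background) == 0:
        raise ValueError("background reference set must be non-empty")
    rng = np.random.default_rng(seed)
    if len(background) > background_size:
        background = background[
            np.sort(rng.choice(len(background), size=background_size, replace=False))
        ]

    key = GENE_LAYER if layer == 0 else (branch, layer)
    acts_x = model.layer_activations(x_explain)[key]
    acts_bg = model.layer_activations(background)[key]
    node_ids = (
        list(model.gene_ids) if layer == 0
        else list(model.masks[branch][layer - 1].target_ids)
    )
    d = acts_x.shape[1]

    # per-sample fixed contribution of heads that are not downstream
    hw = dict(zip(model.head_keys(), model.head_weights()))
    cache = model.forward(x_explain)
    if layer == 0:
        fixed = np.zeros(len(x_explain))
    else:
        fixed = np.zeros(len(x_explain))
        for (br, l), w in hw.items():
            if br != branch or l < layer:
                fixed += w * cache["p"][(br, l)]

    exact = d <= exact_max_width
    phi = np.zeros((len(x_explain), d))
    base = np.zeros(len(x_explain))
    fx = np.zeros(len(x_explain))
    br_arg = None if layer == 0 else branch
    for i in range(len(x_explain)):
        def g(h, _fixed=fixed[i]):
            return model.forward_from_layer(br_arg, layer, h, _fixed)

        if exact:
            phi[i] = _exact_phi(g, acts_x[i], acts_bg)
        else:
            phi[i] = _sampled_phi(g, acts_x[i], acts_bg, n_perm, rng)
        base[i] = g(acts_bg).mean()
        fx[i] = g(acts_x[i:i + 1])[0]
    return ShapResult(
        branch="gene" if layer == 0 else branch,
        layer=layer, node_ids=node_ids, phi=phi, base=base, fx=fx,
        method="exact" if exact else "permutation",
    )


def explain_fold(
    model: DualBranchModel,
    x_explain: np.ndarray,
    background: np.ndarray,
    fold: int,
    **shap_kwargs,
) -> pd.DataFrame:
    """Node-level attribution table for every layer of one fold's model.

    Per-sample attributions are reduced to the mean absolute value per node.
    Columns: fold, branch, layer, node, phi.
    """
    rows = []
    layers = [(None, 0)] + [
        (br, l) for br in model.BRANCHES for l in range(1, model.n_layers + 1)
    ]
    for br, l in layers:
        res = shap_layer(model, br, l, x_explain, background, **shap_kwargs)
        node_phi = np.abs(res.phi).mean(axis=0)
        for node, p in zip(res.node_ids, node_phi):
            rows.append((fold, res.branch, l, node, float(p)))
    return pd.DataFrame(rows, columns=["fold", "branch", "layer", "node", "phi"])


def degree_normalize(attr: pd.DataFrame, degrees: dict[str, int]) -> pd.DataFrame:
    """Add ``phi_adjusted = phi / d_i``; degree-0 nodes keep phi unchanged
    (the normalization is undefined there) with a warning."""
    missing = sorted(set(attr["node"]) - set(degrees))
    if missing:
        raise KeyError(f"degree table missing node(s): {missing[:5]}")
    d = attr["node"].map(degrees).to_numpy(dtype=float)
    zero = d == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} attribution row(s) on degree-0 nodes left "
            "un-normalized", stacklevel=2,
        )
    out = attr.copy()
    out["phi_adjusted"] = np.where(zero, out["phi"], out["phi"] / np.where(zero, 1, d))
    return out


def aggregate_folds(attr: pd.DataFrame, value: str = "phi_adjusted") -> pd.DataFrame:
    """Arithmetic mean of per-fold attributions per node.

    A node absent from some folds is averaged over the folds where it is
    present and flagged with ``full_coverage = False``.
    """
    if attr.empty:
        raise ValueError("no attributions to aggregate")
    n_folds = attr["fold"].nunique()
    grouped = attr.groupby(["branch", "layer", "node"], sort=True)
    out = grouped.agg(
        phi_combined=(value, "mean"),
        n_folds_present=("fold", "nunique"),
    ).reset_index()
    out["full_coverage"] = out["n_folds_present"] == n_folds
    if not out["full_coverage"].all():
        warnings.warn(
            f"{int((~out['full_coverage']).sum())} node(s) missing from some folds",
            stacklevel=2,
        )
    return out


@dataclass
class RankedFeatures:
    features: list[tuple[str, float]]  # (node, signed combined score)
    top_fraction: float

    @property
    def ids(self) -> list[str]:
        return [n for n, _ in self.features]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.features, columns=["node", "phi_combined"])


def rank_top_fraction(
    combined: pd.DataFrame,
    fraction: float = 0.10,
    branch: str = "gene",
) -> RankedFeatures:
    """Top ``ceil(fraction * n)`` nodes of one layer kind by |phi_combined|,
    ties broken lexicographically by node id."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    sub = combined[combined["branch"] == branch]
    if sub.empty:
        raise ValueError(f"no nodes of branch {branch!r} to rank")
    sub = sub.assign(absphi=sub["phi_combined"].abs())
    sub = sub.sort_values(["absphi", "node"], ascending=[False, True], kind="mergesort")
    k = math.ceil(fraction * len(sub))
    top = sub.head(k)
    return RankedFeatures(
        features=list(zip(top["node"], top["phi_combined"])),
        top_fraction=fraction,
    )


def sankey_export(
    combined: pd.DataFrame,
    edges: list[tuple[str, str, int]],
    display_top_n: int = 10,
) -> dict:
    """Static Sankey JSON: per layer the top-n nodes by |phi_combined| are
    kept, the rest pooled into one residual node; each link carries the source
    node's |phi_combined| distributed over its outgoing edges proportionally
    to target scores (uniformly when all targets score zero)."""
    score = {
        (r.branch, r.layer, r.node): abs(r.phi_combined)
        for r in combined.itertuples()
    }
    node_layer = {}
    for r in combined.itertuples():
        node_layer[(r.branch, r.node)] = r.layer

    kept: dict[tuple[str, int], set[str]] = {}
    for (br, layer), grp in combined.groupby(["branch", "layer"]):
        grp = grp.assign(absphi=grp["phi_combined"].abs())
        grp = grp.sort_values(["absphi", "node"], ascending=[False, True], kind="mergesort")
        kept[(br, layer)] = set(grp.head(display_top_n)["node"])

    def display_id(branch: str, layer: int, node: str) -> str:
        if node in kept.get((branch, layer), ()):
            return node
        return f"residual::{branch}::L{layer}"

    # edge endpoints: resolve branch/layer of each node from the table
    by_node: dict[str, list[tuple[str, int]]] = {}
    for (br, layer, node) in score:
        by_node.setdefault(node, []).append((br, layer))

    out_edges: dict[str, list[str]] = {}
    edge_layers: dict[tuple[str, str], int] = {}
    for u, v, lv in edges:
        out_edges.setdefault(u, []).append(v)
        edge_layers[(u, v)] = lv

    links: dict[tuple[str, str], float] = {}
    for u, targets in out_edges.items():
        locs = by_node.get(u)
        if not locs:
            continue
        br_u, l_u = sorted(locs)[0]
        w_u = score[(br_u, l_u, u)]
        t_scores = []
        for v in targets:
            lv = edge_layers[(u, v)]
            locs_v = [bl for bl in by_node.get(v, []) if bl[1] == lv]
            br_v = locs_v[0][0] if locs_v else br_u
            t_scores.append(score.get((br_v, lv, v), 0.0))
        t_scores = np.asarray(t_scores, dtype=float)
        shares = t_scores / t_scores.sum() if t_scores.sum() > 0 else np.full(len(targets), 1 / len(targets))
        for v, share in zip(targets, shares):
            lv = edge_layers[(u, v)]
            locs_v = [bl for bl in by_node.get(v, []) if bl[1] == lv]
            br_v = locs_v[0][0] if locs_v else br_u
            src = display_id(br_u, l_u, u)
            dst = display_id(br_v, lv, v)
            links[(src, dst)] = links.get((src, dst), 0.0) + w_u * share

    nodes = []
    seen = set()
    for (br, layer, node), s in sorted(score.items()):
        did = display_id(br, layer, node)
        if did in seen:
            continue
        seen.add(did)
        if did.startswith("residual::"):
            res_score = sum(
                v for (b2, l2, n2), v in score.items()
                if b2 == br and l2 == layer and n2 not in kept.get((br, layer), ())
            )
            nodes.append({"id": did, "layer": layer, "score": res_score})
        else:
            nodes.append({"id": did, "layer": layer, "score": s})
    return {
        "nodes": nodes,
        "links": [
            {"source": s, "target": t, "value": v}
            for (s, t), v in sorted(links.items())
        ],
    }


def write_sankey(sankey: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(sankey, fh, indent=2)
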