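"""Masked dual-branch neural network compiled from knowledge-hierarchy masks.

The network shares one gene layer between two knowledge branches.  Ternary
CNV input is split into per-gene channels (A = duplication indicator,
D = deletion indicator) and fused by a *diagonal* layer: each gene node is a
linear combination of that gene's channels only, with no cross-gene terms.
A binary gene mask (tissue filtration) then zeroes genes not expressed in the
target tissue.  Each branch is a stack of masked dense layers whose weight
matrices are elementwise-multiplied by fixed binary connectivity masks in the
forward pass, so only biologically supported connections ever train or carry
gradient.  Every sparse layer has a scalar sigmoid auxiliary head; the model
output is a weighted mean of all head probabilities, which both combats
vanishing gradients and realizes multi-layer output extraction.

Implemented directly on numpy (forward, backward, Adam) so sparsity,
determinism and layer access are exact and inspectable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .hierarchy import ConnectivityMask

_DROPOUT_RANGE = (0.05, 0.1)


@dataclass
class ModelConfig:
    n_layers: int = 5
    dropout: float = 0.05
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 200
    seed: int = 0
    aux_head_weighting: list[float] | None = None  # None = uniform over heads
    class_weight: str | None = None                # None or "balanced"

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size <= 0:
            raise ValueError("epochs must be >= 0 and batch_size > 0")
        if not (_DROPOUT_RANGE[0] <= self.dropout <= _DROPOUT_RANGE[1]) and self.dropout != 0.0:
            warnings.warn(
                f"dropout {self.dropout} outside the default range {_DROPOUT_RANGE}",
                stacklevel=2,
            )
        if self.aux_head_weighting is not None:
            w = np.asarray(self.aux_head_weighting, dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("aux_head_weighting must be non-negative and sum to 1")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def channels(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a ternary matrix into duplication (A) and deletion (D) indicators."""
    x = np.asarray(x)
    return (x == 1).astype(float), (x == -1).astype(float)


class DualBranchModel:
    """Compiled masked network; see module docstring for the architecture."""

    BRANCHES = ("ontology", "pathway")

    def __init__(
        self,
        masks_ontology: list[ConnectivityMask],
        masks_pathway: list[ConnectivityMask],
        gene_mask: dict[str, int] | np.ndarray,
        config: ModelConfig | None = None,
    ):
        self.config = config or ModelConfig()
        go = masks_ontology[0].source_ids
        gp = masks_pathway[0].source_ids
        if go != gp:
            raise ValueError("the two branches must share one gene ordering")
        self.gene_ids: list[str] = list(go)
        n_genes = len(self.gene_ids)

        if isinstance(gene_mask, dict):
            missing = [g for g in self.gene_ids if g not in gene_mask]
            if missing:
                raise ValueError(f"gene mask missing {missing[:3]}...")
            gm = np.array([gene_mask[g] for g in self.gene_ids], dtype=float)
        else:
            gm = np.asarray(gene_mask, dtype=float)
            if gm.shape != (n_genes,):
                raise ValueError("gene mask length mismatch")
        self.gene_mask = gm

        self.masks = {"ontology": masks_ontology, "pathway": masks_pathway}
        for br, stack in self.masks.items():
            for l, cm in enumerate(stack, start=1):
                if cm.n_connections == 0:
                    raise ValueError(f"branch {br} layer {l} mask is all-zero (disconnected)")

        rng = np.random.default_rng(self.config.seed)
        self.params: dict[str, np.ndarray] = {}
        # diagonal fusion: per-gene channel weights
        self.params["fuse_wA"] = rng.normal(0, 0.5, n_genes)
        self.params["fuse_wD"] = rng.normal(0, 0.5, n_genes)
        self.params["fuse_b"] = np.zeros(n_genes)
        for br in self.BRANCHES:
            for l, cm in enumerate(self.masks[br], start=1):
                fan_in = np.maximum(cm.mask.sum(axis=0), 1)
                scale = 1.0 / np.sqrt(fan_in)
                w = rng.normal(0, 1.0, cm.mask.shape) * scale[None, :]
                self.params[f"{br}_W{l}"] = w * cm.mask
                self.params[f"{br}_b{l}"] = np.zeros(len(cm.target_ids))
                width = len(cm.target_ids)
                self.params[f"{br}_v{l}"] = rng.normal(0, 1.0 / np.sqrt(width), width)
                self.params[f"{br}_c{l}"] = np.zeros(1)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self._train_rng = np.random.default_rng(self.config.seed + 1)

    # -- structure ---------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.masks["ontology"])

    def head_keys(self) -> list[tuple[str, int]]:
        keys = []
        for br in self.BRANCHES:
            keys.extend((br, l) for l in range(1, len(self.masks[br]) + 1))
        return keys

    def head_weights(self) -> np.ndarray:
        keys = self.head_keys()
        if self.config.aux_head_weighting is None:
            return np.full(len(keys), 1.0 / len(keys))
        w = np.asarray(self.config.aux_head_weighting, dtype=float)
        if w.shape != (len(keys),):
            raise ValueError(f"aux_head_weighting must have {len(keys)} entries")
        return w

    def parameter_counts(self) -> dict[str, int]:
        """Trainable parameter count vs the dense equivalent."""
        mask_ones = sum(cm.n_connections for st in self.masks.values() for cm in st)
        biases = sum(len(cm.target_ids) for st in self.masks.values() for cm in st)
        heads = sum(len(cm.target_ids) + 1 for st in self.masks.values() for cm in st)
        fusion = 3 * len(self.gene_ids)
        dense_weights = sum(
            len(cm.source_ids) * len(cm.target_ids) for st in self.masks.values() for cm in st
        )
        return {
            "mask_ones": mask_ones,
            "biases": biases,
            "heads": heads,
            "fusion": fusion,
            "trainable": mask_ones + biases + heads + fusion,
            "dense_equivalent": dense_weights + biases + heads + fusion,
        }

    # -- forward -----------------------------------------------------------

    def _masked_w(self, br: str, l: int) -> np.ndarray:
        return self.params[f"{br}_W{l}"] * self.masks[br][l - 1].mask

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> dict:
        """Full forward pass; returns activations, head probabilities, output."""
        x = np.asarray(x)
        if x.ndim != 2 or x.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"input must be (n, {len(self.gene_ids)}), got {x.shape}"
            )
        A, D = channels(x)
        z0 = (A * self.params["fuse_wA"] + D * self.params["fuse_wD"] + self.params["fuse_b"])
        z0 = z0 * self.gene_mask
        h0 = np.tanh(z0)

        cache: dict = {"A": A, "D": D, "h0": h0, "h": {}, "drop": {}, "q": {}, "p": {}}
        p_drop = self.config.dropout if training else 0.0
        for br in self.BRANCHES:
            h = h0
            for l in range(1, len(self.masks[br]) + 1):
                if p_drop > 0:
                    dm = (rng.random(h.shape) >= p_drop) / (1.0 - p_drop)
                else:
                    dm = None
                a = h * dm if dm is not None else h
                cache["drop"][(br, l)] = dm
                z = a @ self._masked_w(br, l) + self.params[f"{br}_b{l}"]
                h = np.tanh(z)
                cache["h"][(br, l)] = h
                q = h @ self.params[f"{br}_v{l}"] + self.params[f"{br}_c{l}"][0]
                cache["q"][(br, l)] = q
                cache["p"][(br, l)] = _sigmoid(q)
        keys = self.head_keys()
        ps = np.stack([cache["p"][k] for k in keys])
        if self.config.aux_head_weighting is None:
            cache["output"] = ps.mean(axis=0)  # exact for identical heads
        else:
            cache["output"] = (self.head_weights()[:, None] * ps).sum(axis=0)
        return cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Aggregated probability of the positive class, in (0, 1)."""
        return self.forward(np.asarray(x), training=False)["output"]

    def layer_activations(self, x: np.ndarray) -> dict:
        """Post-nonlinearity activations keyed by ("gene", 0) and (branch, l)."""
        cache = self.forward(np.asarray(x), training=False)
        out = {("gene", 0): cache["h0"]}
        out.update(cache["h"])
        return out

    def forward_from_layer(
        self,
        branch: str | None,
        layer: int,
        h: np.ndarray,
        fixed_contribution: float = 0.0,
    ) -> np.ndarray:
        """Model output as a function of one layer's activations.

        ``h`` holds activations of ``layer`` in ``branch`` (or the shared gene
        layer when ``branch`` is None / layer == 0).  Heads not downstream of
        that layer contribute the per-sample constant ``fixed_contribution``.
        """
        keys = self.head_keys()
        hw = dict(zip(keys, self.head_weights()))
        out = np.full(h.shape[0], float(fixed_contribution))
        branches = self.BRANCHES if layer == 0 else (branch,)
        for br in branches:
            cur = h
            start = 1 if layer == 0 else layer
            for l in range(start, len(self.masks[br]) + 1):
                if l > layer:  # propagate one step (from l-1 activations)
                    cur = np.tanh(cur @ self._masked_w(br, l) + self.params[f"{br}_b{l}"])
                q = cur @ self.params[f"{br}_v{l}"] + self.params[f"{br}_c{l}"][0]
                out = out + hw[(br, l)] * _sigmoid(q)
        return out

    # -- training ----------------------------------------------------------

    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray, sample_weight=None, training: bool = True
    ) -> tuple[float, dict, dict]:
        """Mean head-weighted binary cross-entropy and its parameter gradients."""
        y = np.asarray(y, dtype=float)
        n = len(y)
        if sample_weight is None:
            sw = np.full(n, 1.0 / n)
        else:
            sw = np.asarray(sample_weight, dtype=float)
            sw = sw / sw.sum()
        cache = self.forward(x, training=training, rng=self._train_rng)
        keys = self.head_keys()
        hw = self.head_weights()
        eps = 1e-12
        per_head = {}
        loss = 0.0
        for w, k in zip(hw, keys):
            p = np.clip(cache["p"][k], eps, 1 - eps)
            lh = -np.sum(sw * (y * np.log(p) + (1 - y) * np.log(1 - p)))
            per_head[k] = float(lh)
            loss += w * lh

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        delta_h_prev: dict[str, np.ndarray] = {}
        for br in self.BRANCHES:
            L = len(self.masks[br])
            delta_h = None  # gradient wrt h_l flowing from layers above
            for l in range(L, 0, -1):
                w_head = hw[keys.index((br, l))]
                dq = w_head * sw * (cache["p"][(br, l)] - y)  # (n,)
                h = cache["h"][(br, l)]
                grads[f"{br}_v{l}"] += h.T @ dq
                grads[f"{br}_c{l}"] += np.array([dq.sum()])
                dh = np.outer(dq, self.params[f"{br}_v{l}"])
                if delta_h is not None:
                    dh = dh + delta_h
                dz = dh * (1 - h ** 2)
                a_prev = cache["h"][(br, l - 1)] if l > 1 else cache["h0"]
                dm = cache["drop"][(br, l)]
                a = a_prev * dm if dm is not None else a_prev
                grads[f"{br}_W{l}"] += (a.T @ dz) * self.masks[br][l - 1].mask
                grads[f"{br}_b{l}"] += dz.sum(axis=0)
                da = dz @ self._masked_w(br, l).T
                if dm is not None:
                    da = da * dm
                delta_h = da
            delta_h_prev[br] = delta_h

        dh0 = delta_h_prev["ontology"] + delta_h_prev["pathway"]
        dz0 = dh0 * (1 - cache["h0"] ** 2) * self.gene_mask
        grads["fuse_wA"] += (cache["A"] * dz0).sum(axis=0)
        grads["fuse_wD"] += (cache["D"] * dz0).sum(axis=0)
        grads["fuse_b"] += dz0.sum(axis=0)
        return float(loss), grads, per_head

    def adam_step(self, grads: dict, lr: float | None = None) -> None:
        lr = self.config.learning_rate if lr is None else lr
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1 ** t)
            vhat = self._adam_v[k] / (1 - b2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        # re-assert exact sparsity (gradient is already masked; this guards
        # against any accumulation drift in the optimizer state)
        for br in self.BRANCHES:
            for l, cm in enumerate(self.masks[br], start=1):
                self.params[f"{br}_W{l}"] *= cm.mask

    def max_masked_weight(self) -> float:
        """max |W o (1 - M)| over all sparse layers; must be exactly 0."""
        worst = 0.0
        for br in self.BRANCHES:
            for l, cm in enumerate(self.masks[br], start=1):
                off = np.abs(self.params[f"{br}_W{l}"] * (1 - cm.mask))
                if off.size:
                    worst = max(worst, float(off.max()))
        return worst

    # -- persistence -------------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(weights[k], dtype=float)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "config.json", "w") as fh:
            json.dump({"config": asdict(self.config), "gene_ids": self.gene_ids}, fh)
        np.savez(d / "weights.npz", gene_mask=self.gene_mask, **self.params)
        for br in self.BRANCHES:
            for l, cm in enumerate(self.masks[br], start=1):
                cm.write_triplets(d / f"mask_{br}_L{l}.tsv")

    @classmethod
    def load(cls, directory, masks_ontology, masks_pathway) -> "DualBranchModel":
        d = Path(directory)
        with open(d / "config.json") as fh:
            meta = json.load(fh)
        arrays = np.load(d / "weights.npz")
        model = cls(masks_ontology, masks_pathway, arrays["gene_mask"],
                    ModelConfig(**meta["config"]))
        model.set_weights({k: arrays[k] for k in model.params})
        return model


def build_model(
    masks_ontology: list[ConnectivityMask],
    masks_pathway: list[ConnectivityMask],
    gene_mask,
    config: ModelConfig | None = None,
) -> DualBranchModel:
    """Compile the dual-branch masked network from two mask stacks."""
    return DualBranchModel(masks_ontology, masks_pathway, gene_mask, config)
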