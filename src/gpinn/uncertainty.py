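"""Probability calibration, confidence scoring and selective-prediction gating.

Raw network probabilities are calibrated by isotonic regression (monotone
least squares, fitted on the validation fold and applied elsewhere).  The
confidence of a prediction is its distance from the decision boundary,
``2 * |y_prob - 0.5|``; predictions below a confidence threshold are
abstained on.  The threshold is chosen by scanning candidate confidence
cutoffs, computing Youden's index J = sensitivity + specificity - 1 and the
coverage C (fraction retained) at each, and picking the knee of the J curve
subject to a minimum coverage, with a composite score
S = w_J * N(J) + w_C * N(C) (min-max normalized over the candidates) as the
fallback selection rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression


@dataclass
class CalibrationModel:
    """Piecewise-constant monotone map from raw to calibrated probability."""

    breakpoints: np.ndarray
    fitted: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.fitted = np.asarray(self.fitted, dtype=float)
        if np.any(np.diff(self.fitted) < -1e-12):
            raise ValueError("fitted calibration values must be non-decreasing")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"breakpoints": self.breakpoints.tolist(),
                       "fitted": self.fitted.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["breakpoints"]), np.array(d["fitted"]))


def fit_isotonic(y_prob, y_true) -> CalibrationModel:
    """Monotone least-squares fit of outcomes on raw probabilities (PAVA)."""
    y_prob = np.asarray(y_prob, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_prob.shape != y_true.shape:
        raise ValueError("y_prob and y_true must have equal length")
    if y_prob.size == 0:
        raise ValueError("cannot fit on an empty sample")
    order = np.argsort(y_prob, kind="mergesort")
    iso = IsotonicRegression(out_of_bounds="clip")
    fitted = iso.fit_transform(y_prob[order], y_true[order])
    return CalibrationModel(breakpoints=y_prob[order], fitted=fitted)


def apply_calibration(model: CalibrationModel, y_prob) -> np.ndarray:
    """Stepwise-constant application; inputs outside the fitted range clamp to
    the first/last fitted value."""
    y_prob = np.asarray(y_prob, dtype=float)
    idx = np.searchsorted(model.breakpoints, y_prob, side="right") - 1
    idx = np.clip(idx, 0, len(model.fitted) - 1)
    return model.fitted[idx]


def confidence(y_prob) -> np.ndarray:
    """Distance from the decision boundary: 2 * |y_prob - 0.5| in [0, 1]."""
    y_prob = np.asarray(y_prob, dtype=float)
    if ((y_prob < 0) | (y_prob > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return 2.0 * np.abs(y_prob - 0.5)


def optimal_class_threshold(y_true, y_prob) -> float:
    """Accuracy-maximizing classification threshold th*.

    Candidates are the midpoints of consecutive sorted unique probabilities
    plus {0, 1}; a prediction is positive when y_prob > th.  Ties resolve to
    the smallest threshold.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(y_prob)
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.array([])
    candidates = np.unique(np.concatenate([[0.0], mids, [1.0]]))
    accs = np.array([
        np.mean((y_prob > th).astype(int) == y_true) for th in candidates
    ])
    return float(candidates[np.argmax(accs)])  # argmax returns first (smallest)


def gate(y_prob, confidence_threshold: float) -> tuple[np.ndarray, float]:
    """Indices of samples whose confidence strictly exceeds the threshold,
    plus the exact coverage fraction."""
    if not (0 <= confidence_threshold <= 1):
        raise ValueError("confidence threshold must lie in [0, 1]")
    conf = confidence(y_prob)
    retained = np.flatnonzero(conf > confidence_threshold)
    return retained, len(retained) / len(conf)


@dataclass
class GateResult:
    class_threshold: float
    confidence_threshold: float
    coverage: float
    youden: float
    composite: float
    knee_used: bool
    w_j: float
    w_c: float
    min_coverage: float
    candidates: pd.DataFrame = field(repr=False)

    def to_json(self, path) -> None:
        payload = {
            k: v for k, v in self.__dict__.items() if k != "candidates"
        }
        payload["candidates"] = self.candidates.to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _youden(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos = y_true == 1
    neg = ~pos
    sens = (y_pred[pos] == 1).mean() if pos.any() else 0.0
    spec = (y_pred[neg] == 0).mean() if neg.any() else 0.0
    return float(sens + spec - 1.0)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = np.min(v), np.max(v)
    if hi - lo < 1e-15:
        return np.ones_like(v)
    return (v - lo) / (hi - lo)


def select_confidence_threshold(
    y_true,
    y_prob,
    w_j: float = 0.5,
    w_c: float = 0.5,
    min_coverage: float = 0.70,
    class_threshold: float | None = None,
) -> GateResult:
    """Scan candidate confidence thresholds and pick the gating cutoff.

    Candidates are 0 plus every unique confidence value.  For each, Youden's J
    and the coverage are computed on the retained subset.  The chosen cutoff
    is the knee (maximum discrete concavity) of the J-vs-threshold curve among
    candidates meeting the coverage floor; if no knee exists the candidate
    maximizing the composite score S is returned.  All candidates are recorded
    for audit.
    """
    if w_j < 0 or w_c < 0 or w_j + w_c <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if class_threshold is None:
        class_threshold = optimal_class_threshold(y_true, y_prob)
    conf = confidence(y_prob)
    y_pred = (y_prob > class_threshold).astype(int)

    candidates = np.unique(np.concatenate([[0.0], np.unique(conf)]))
    rows = []
    for t in candidates:
        keep = conf > t
        cov = keep.mean()
        if keep.any():
            j = _youden(y_true[keep], y_pred[keep])
        else:
            j = 0.0
        rows.append((float(t), float(cov), j))
    table = pd.DataFrame(rows, columns=["threshold", "coverage", "youden"])
    table["n_j"] = _minmax(table["youden"].to_numpy())
    table["n_c"] = _minmax(table["coverage"].to_numpy())
    table["composite"] = w_j * table["n_j"] + w_c * table["n_c"]
    eligible = table[(table["coverage"] >= min_coverage) & (table["coverage"] > 0)]
    if eligible.empty:
        raise ValueError(
            f"no confidence threshold retains >= {min_coverage:.0%} of samples; "
            "lower min_coverage"
        )

    # knee of the J curve: maximum discrete concavity (difference of differences)
    knee_idx = None
    if len(eligible) >= 3:
        j = eligible["youden"].to_numpy()
        curv = j[:-2] - 2 * j[1:-1] + j[2:]
        if np.any(np.abs(curv) > 1e-12):
            knee_idx = eligible.index[1 + int(np.argmin(curv))]
    if knee_idx is None:
        knee_idx = eligible["composite"].idxmax()
        knee_used = False
    else:
        knee_used = True
    chosen = table.loc[knee_idx]
    return GateResult(
        class_threshold=float(class_threshold),
        confidence_threshold=float(chosen["threshold"]),
        coverage=float(chosen["coverage"]),
        youden=float(chosen["youden"]),
        composite=float(chosen["composite"]),
        knee_used=knee_used,
        w_j=w_j, w_c=w_c, min_coverage=min_coverage,
        candidates=table,
    )
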