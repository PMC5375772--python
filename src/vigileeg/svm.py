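"""Soft-margin SVM with RBF kernel, trained in the dual by SMO.

The classifier solves the usual soft-margin dual

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t.   0 <= a_i <= C,   sum_i a_i y_i = 0,

with K the RBF kernel exp(-g ||x - x'||^2) by default (linear and
polynomial kernels are also available). Decision values are
f(x) = sum_sv y_i a_i K(x_i, x) + b; the predicted label is the sign,
with the tie f(x) = 0 classified drowsy (-1) as the fail-safe choice for a
safety application. The optimiser is a pairwise coordinate-ascent (SMO)
scheme over a precomputed Gram matrix with an error cache; any solver
meeting the same KKT conditions would be interchangeable.

Hyperparameters C (error penalty) and g (RBF width) are selected by grid
search over powers of two under contiguous-block cross-validation — the
per-second features are serially dependent, so folds are time blocks, never
shuffled rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .features import FeatureMatrix, apply_scaling

#: libsvm-style default search grids (powers of two).
DEFAULT_GRID_C = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GRID_G = tuple(2.0 ** e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class KernelSpec:
    """Kernel function specification.

    kind: "rbf" (g >= 0), "linear", or "polynomial" ((x.x' + c)^d, c >= 0).
    """

    kind: str = "rbf"
    g: float = 2.0
    coef: float = 0.0
    degree: int = 3

    def __post_init__(self):
        if self.kind not in ("rbf", "linear", "polynomial"):
            raise ValueError(f"unknown kernel {self.kind!r}")
        if self.kind == "rbf" and self.g < 0:
            raise ValueError("RBF width g must be >= 0")
        if self.kind == "polynomial" and self.coef < 0:
            raise ValueError("polynomial offset c must be >= 0")


@dataclass
class TrainingConfig:
    """SVM training and model-selection settings.

    C is the soft-margin error penalty (> 0); g the RBF kernel width. The
    slack variables of the primal appear implicitly as the box constraint
    0 <= a_i <= C in the dual. ``tolerance`` is the KKT tolerance of the
    optimiser, ``max_passes`` the number of consecutive full sweeps without
    an update that ends training, ``max_iter`` a hard sweep bound.
    """

    C: float = 32.0
    g: float = 2.0
    kernel: str = "rbf"
    coef: float = 0.0
    degree: int = 3
    tolerance: float = 1e-3
    max_passes: int = 5
    max_iter: int = 200
    grid_C: Sequence[float] = DEFAULT_GRID_C
    grid_g: Sequence[float] = DEFAULT_GRID_G
    folds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if not len(self.grid_C) or not len(self.grid_g):
            raise ValueError("parameter grids must be non-empty")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def kernel_spec(self) -> KernelSpec:
        return KernelSpec(kind=self.kernel, g=self.g, coef=self.coef,
                          degree=self.degree)

    def with_params(self, C: float, g: float) -> "TrainingConfig":
        return TrainingConfig(
            C=C, g=g, kernel=self.kernel, coef=self.coef, degree=self.degree,
            tolerance=self.tolerance, max_passes=self.max_passes,
            max_iter=self.max_iter, grid_C=self.grid_C, grid_g=self.grid_g,
            folds=self.folds, seed=self.seed,
        )


def kernel_eval(x: np.ndarray, x_i: np.ndarray, spec: KernelSpec) -> float:
    """Evaluate the kernel on a single pair."""
    x = np.asarray(x, dtype=float)
    x_i = np.asarray(x_i, dtype=float)
    if x.shape != x_i.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {x_i.shape}")
    if spec.kind == "rbf":
        d = x - x_i
        return float(np.exp(-spec.g * np.dot(d, d)))
    if spec.kind == "linear":
        return float(np.dot(x, x_i))
    return float((np.dot(x, x_i) + spec.coef) ** spec.degree)


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, spec: KernelSpec) -> np.ndarray:
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("dimension mismatch")
    if spec.kind == "linear":
        return X1 @ X2.T
    if spec.kind == "polynomial":
        return (X1 @ X2.T + spec.coef) ** spec.degree
    sq = (
        np.sum(X1 ** 2, axis=1)[:, None]
        + np.sum(X2 ** 2, axis=1)[None, :]
        - 2.0 * (X1 @ X2.T)
    )
    return np.exp(-spec.g * np.maximum(sq, 0.0))


@dataclass
class SvmModel:
    """Trained classifier: support vectors, dual coefficients y_i a_i, bias b.

    ``scaling`` carries the feature min/max fitted on the training data so
    raw features can be mapped into the model's input space at predict time.
    """

    kernel: KernelSpec
    C: float
    support_vectors: np.ndarray
    dual_coefs: np.ndarray          # y_i * a_i per support vector
    bias: float
    scaling: Optional[np.ndarray] = None
    channel: Optional[str] = None
    label_map: dict = field(default_factory=lambda: {1: "alert", -1: "drowsy"})

    @property
    def n_support(self) -> int:
        return len(self.dual_coefs)

    def to_json_dict(self) -> dict:
        return {
            "format": "vigileeg-svm",
            "version": 1,
            "kernel": {
                "kind": self.kernel.kind, "g": self.kernel.g,
                "coef": self.kernel.coef, "degree": self.kernel.degree,
            },
            "C": self.C,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coefs": self.dual_coefs.tolist(),
            "bias": self.bias,
            "scaling": None if self.scaling is None else self.scaling.tolist(),
            "channel": self.channel,
            "label_map": {str(k): v for k, v in self.label_map.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SvmModel":
        if d.get("format") != "vigileeg-svm":
            raise ValueError("not a vigileeg SVM model document")
        k = d["kernel"]
        return cls(
            kernel=KernelSpec(kind=k["kind"], g=k["g"], coef=k["coef"],
                              degree=k["degree"]),
            C=d["C"],
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coefs=np.asarray(d["dual_coefs"], dtype=float),
            bias=d["bias"],
            scaling=None if d["scaling"] is None
            else np.asarray(d["scaling"], dtype=float),
            channel=d.get("channel"),
            label_map={int(k_): v for k_, v in d["label_map"].items()},
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SvmModel":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def dual_objective(K: np.ndarray, y: np.ndarray, alpha: np.ndarray) -> float:
    """Dual objective W(a) = sum a_i - 1/2 sum a_i a_j y_i y_j K_ij."""
    ay = alpha * y
    return float(np.sum(alpha) - 0.5 * ay @ K @ ay)


def _smo(K: np.ndarray, y: np.ndarray, C: float, tol: float,
         max_passes: int, max_iter: int, rng: np.random.Generator):
    """Platt-style SMO over a precomputed Gram matrix with an error cache.

    Alternates full sweeps with sweeps over the non-bound set; the joint
    partner is chosen by the |E1 - E2| heuristic with fall-through to the
    non-bound set and then the full set, so progress cannot stall on one
    unproductive pair. ``max_passes`` consecutive unproductive full sweeps
    (or ``max_iter`` sweeps in total) end training.
    """
    m = len(y)
    alpha = np.zeros(m)
    state = {"b": 0.0}
    # E_i = f(x_i) - y_i with f including the threshold; alpha = 0 -> f = b = 0
    E = -y.astype(float)
    eps = 1e-12

    def take_step(i1: int, i2: int) -> bool:
        nonlocal E
        if i1 == i2:
            return False
        a1, a2 = alpha[i1], alpha[i2]
        y1, y2 = y[i1], y[i2]
        s = y1 * y2
        if s < 0:
            L, H = max(0.0, a2 - a1), min(C, C + a2 - a1)
        else:
            L, H = max(0.0, a1 + a2 - C), min(C, a1 + a2)
        if H - L < eps:
            return False
        eta = K[i1, i1] + K[i2, i2] - 2.0 * K[i1, i2]
        if eta > eps:
            a2_new = a2 + y2 * (E[i1] - E[i2]) / eta
            a2_new = min(H, max(L, a2_new))
        else:
            # flat direction: move to whichever bound improves the objective
            f1 = y1 * E[i1] - a1 * K[i1, i1] - s * a2 * K[i1, i2]
            f2 = y2 * E[i2] - s * a1 * K[i1, i2] - a2 * K[i2, i2]
            L1 = a1 + s * (a2 - L)
            H1 = a1 + s * (a2 - H)
            psi_L = (L1 * f1 + L * f2 + 0.5 * L1 ** 2 * K[i1, i1]
                     + 0.5 * L ** 2 * K[i2, i2] + s * L * L1 * K[i1, i2])
            psi_H = (H1 * f1 + H * f2 + 0.5 * H1 ** 2 * K[i1, i1]
                     + 0.5 * H ** 2 * K[i2, i2] + s * H * H1 * K[i1, i2])
            if psi_L < psi_H - eps:
                a2_new = L
            elif psi_L > psi_H + eps:
                a2_new = H
            else:
                return False
        if abs(a2_new - a2) < eps * (a2_new + a2 + eps):
            return False
        a1_new = a1 + s * (a2 - a2_new)
        d1, d2 = a1_new - a1, a2_new - a2
        b = state["b"]
        b1 = b - E[i1] - y1 * d1 * K[i1, i1] - y2 * d2 * K[i1, i2]
        b2 = b - E[i2] - y1 * d1 * K[i1, i2] - y2 * d2 * K[i2, i2]
        if 0 < a1_new < C:
            b_new = b1
        elif 0 < a2_new < C:
            b_new = b2
        else:
            b_new = 0.5 * (b1 + b2)
        E += y1 * d1 * K[i1] + y2 * d2 * K[i2] + (b_new - b)
        alpha[i1], alpha[i2] = a1_new, a2_new
        state["b"] = b_new
        return True

    def examine(i2: int) -> bool:
        r2 = E[i2] * y[i2]
        if not ((r2 < -tol and alpha[i2] < C) or (r2 > tol and alpha[i2] > 0)):
            return False
        non_bound = np.flatnonzero((alpha > 0) & (alpha < C))
        if len(non_bound) > 1:
            i1 = int(non_bound[np.argmax(np.abs(E[non_bound] - E[i2]))])
            if take_step(i1, i2):
                return True
        start = int(rng.integers(m))
        for k in range(len(non_bound)):
            i1 = int(non_bound[(k + start) % len(non_bound)])
            if take_step(i1, i2):
                return True
        start = int(rng.integers(m))
        for k in range(m):
            if take_step((k + start) % m, i2):
                return True
        return False

    examine_all = True
    idle_full_sweeps = 0
    for _ in range(max_iter):
        changed = 0
        targets = range(m) if examine_all else \
            np.flatnonzero((alpha > 0) & (alpha < C))
        for i2 in targets:
            changed += examine(int(i2))
        if examine_all:
            idle_full_sweeps = 0 if changed else idle_full_sweeps + 1
            if idle_full_sweeps >= max_passes:
                break
            if changed:
                examine_all = False
        elif changed == 0:
            examine_all = True
    return alpha, state["b"]


def train(features: FeatureMatrix, config: TrainingConfig) -> SvmModel:
    """Train on (already scaled) features; returns the dual solution.

    Raises on single-class input or non-finite features. The bias b is the
    mean over free support vectors (0 < a_i < C); if there are none, the
    mean over all support vectors.
    """
    X, y = features.X, features.y.astype(float)
    if features.m < 2:
        raise ValueError("need at least two training rows")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training data")
    spec = config.kernel_spec()
    K = kernel_matrix(X, X, spec)
    rng = np.random.default_rng(config.seed)
    alpha, b = _smo(K, y, config.C, config.tolerance,
                    config.max_passes, config.max_iter, rng)
    sv = alpha > 1e-9
    if np.any(sv):
        # recompute b from the KKT conditions at the support vectors
        f_wo_b = (alpha * y) @ K
        free = sv & (alpha < config.C - 1e-9)
        pick = free if np.any(free) else sv
        b = float(np.mean(y[pick] - f_wo_b[pick]))
    return SvmModel(
        kernel=spec,
        C=config.C,
        support_vectors=X[sv].copy(),
        dual_coefs=(alpha * y)[sv].copy(),
        bias=float(b),
        scaling=None if features.scaling is None else features.scaling.copy(),
    )


def decision_values(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """Pre-sign decision function sum_sv y_i a_i K(x_i, x) + b, row-wise."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.n_support == 0:
        return np.full(X.shape[0], model.bias)
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError("dimension mismatch")
    K = kernel_matrix(X, model.support_vectors, model.kernel)
    return K @ model.dual_coefs + model.bias


def decision_value(model: SvmModel, x: np.ndarray) -> float:
    return float(decision_values(model, np.atleast_2d(x))[0])


def predict(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels: +1 (alert) where f > 0, else -1 (drowsy).

    The tie f = 0 goes to drowsy — for a safety system the ambiguous case
    raises the alarm.
    """
    f = decision_values(model, X)
    return np.where(f > 0, 1, -1).astype(int)


def contiguous_folds(m: int, folds: int) -> List[np.ndarray]:
    """Split row indices 0..m-1 into `folds` contiguous blocks."""
    return [idx for idx in np.array_split(np.arange(m), folds) if len(idx)]


def cross_validate(
    features: FeatureMatrix,
    config: TrainingConfig,
    folds: Optional[int] = None,
    return_details: bool = False,
):
    """Leave-one-block-out CV over contiguous time blocks.

    Feature scaling is fitted on the training blocks only and applied to the
    held-out block. Folds whose training portion is single-class are skipped
    with a warning. Returns the mean held-out accuracy, or (mean, details)
    where details is a per-fold list of dicts with test indices, truth,
    predictions and the fitted model.
    """
    from .features import scale_features  # local import avoids cycle noise

    folds = config.folds if folds is None else folds
    blocks = contiguous_folds(features.m, folds)
    accs = []
    details = []
    for k, test_idx in enumerate(blocks):
        train_idx = np.setdiff1d(np.arange(features.m), test_idx)
        tr = features.subset(train_idx)
        te = features.subset(test_idx)
        if len(np.unique(tr.y)) < 2:
            warnings.warn(
                f"fold {k}: training blocks contain a single class; skipped"
            )
            continue
        tr_s, te_s, _ = scale_features(tr, te)
        model = train(tr_s, config)
        pred = predict(model, te_s.X)
        acc = float(np.mean(pred == te.y))
        accs.append(acc)
        details.append({
            "fold": k, "test_idx": test_idx, "y_true": te.y,
            "y_pred": pred, "model": model, "accuracy": acc,
        })
    if not accs:
        raise ValueError("no usable folds (all single-class)")
    mean_acc = float(np.mean(accs))
    return (mean_acc, details) if return_details else mean_acc


def grid_search(
    features: FeatureMatrix,
    grid_C: Sequence[float] = DEFAULT_GRID_C,
    grid_g: Sequence[float] = DEFAULT_GRID_G,
    folds: int = 3,
    config: Optional[TrainingConfig] = None,
) -> Tuple[float, float, np.ndarray]:
    """Exhaustive (C, g) search by contiguous-block CV accuracy.

    Returns (best C, best g, accuracy surface of shape (|C|, |g|)); ties go
    to the smallest C, then the smallest g, favouring the smoother model.
    """
    if not len(grid_C) or not len(grid_g):
        raise ValueError("empty parameter grid")
    base = config or TrainingConfig()
    surface = np.zeros((len(grid_C), len(grid_g)))
    for i, C in enumerate(grid_C):
        for j, g in enumerate(grid_g):
            surface[i, j] = cross_validate(
                features, base.with_params(C=C, g=g), folds=folds
            )
    best_flat = int(np.argmax(surface))  # argmax returns first max: smallest C then g
    bi, bj = np.unravel_index(best_flat, surface.shape)
    return float(grid_C[bi]), float(grid_g[bj]), surface
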