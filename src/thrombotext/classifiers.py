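"""Binary Bernoulli Naïve Bayes and Maximum-Entropy classifiers.

Both operate on binary presence vectors given as sets of feature
indices.  They are written from scratch (training included) because the
classification model over annotation-derived features is the core of
the package; established libraries are used only as cross-checks in the
test suite.

Naïve Bayes uses the Bernoulli event model: a document is a vector of
independent per-feature Bernoulli draws, so an *absent* feature also
contributes evidence.  Conditional presence probabilities get add-alpha
smoothing on both presence and absence counts; class priors are the
training class frequencies (after any oversampling, so balancing the
training set balances the prior).

Maximum entropy is binary logistic regression maximizing the
elastic-net-penalized log-likelihood

    sum_i log p(y_i | x_i; w, b) - l1 ||w||_1 - (l2 / 2) ||w||^2

(bias unpenalized) by monotone proximal gradient descent with
backtracking line search, initialized at zero — deterministic by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

IndexSet = frozenset[int] | set[int]


class TrainingError(ValueError):
    pass


def _to_dense(
    vectors: Sequence[IndexSet], n_features: int
) -> np.ndarray:
    X = np.zeros((len(vectors), n_features))
    for i, v in enumerate(vectors):
        idx = list(v)
        if idx and (min(idx) < 0 or max(idx) >= n_features):
            raise ValueError("feature index out of range")
        X[i, idx] = 1.0
    return X


def _check_labels(labels: Sequence[int]) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise TrainingError(
            "training set must contain both classes (binary labels 0/1)"
        )
    return y


# ---------------------------------------------------------------------------
# Naïve Bayes

@dataclass
class NBModel:
    log_prior: np.ndarray          # shape (2,)
    log_p: np.ndarray              # shape (2, n_features), log P(f=1 | c)
    log_1mp: np.ndarray            # shape (2, n_features), log P(f=0 | c)
    alpha: float

    @property
    def n_features(self) -> int:
        return self.log_p.shape[1]


def train_nb(
    vectors: Sequence[IndexSet],
    labels: Sequence[int],
    n_features: int,
    alpha: float = 1.0,
) -> NBModel:
    y = _check_labels(labels)
    if len(vectors) != len(y):
        raise ValueError("vectors and labels length mismatch")
    counts = np.zeros((2, n_features))
    n_c = np.zeros(2)
    for v, c in zip(vectors, y):
        n_c[c] += 1
        counts[c, list(v)] += 1.0
    p = (counts + alpha) / (n_c[:, None] + 2.0 * alpha)
    return NBModel(
        log_prior=np.log(n_c / n_c.sum()),
        log_p=np.log(p),
        log_1mp=np.log1p(-p),
        alpha=alpha,
    )


def nb_joint_log_likelihood(model: NBModel, vector: IndexSet) -> np.ndarray:
    """log P(c) + log P(x | c) for c in {0, 1}, over ALL features."""
    idx = list(vector)
    base = model.log_prior + model.log_1mp.sum(axis=1)
    if idx:
        base = base + (model.log_p[:, idx] - model.log_1mp[:, idx]).sum(axis=1)
    return base


def predict_nb(model: NBModel, vector: IndexSet) -> tuple[int, float]:
    """Predicted label and its posterior probability; ties go positive."""
    jll = nb_joint_log_likelihood(model, vector)
    # normalize in log space
    m = jll.max()
    post = np.exp(jll - m)
    post /= post.sum()
    label = 1 if post[1] >= post[0] else 0
    return label, float(post[label])


def predict_nb_many(
    model: NBModel, vectors: Iterable[IndexSet]
) -> list[tuple[int, float]]:
    return [predict_nb(model, v) for v in vectors]


# ---------------------------------------------------------------------------
# Maximum entropy (penalized logistic regression)

@dataclass
class MaxEntModel:
    weights: np.ndarray
    bias: float
    l1: float
    l2: float
    tol: float
    max_iter: int
    n_iter: int = 0
    converged: bool = False
    objective_history: list[float] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable log sigma(z)
    return -np.logaddexp(0.0, -z)


def maxent_objective(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float,
    l1: float, l2: float,
) -> float:
    z = X @ w + b
    nll = -np.sum(y * _log_sigmoid(z) + (1 - y) * _log_sigmoid(-z))
    return float(nll + l1 * np.abs(w).sum() + 0.5 * l2 * w @ w)


def train_maxent(
    vectors: Sequence[IndexSet],
    labels: Sequence[int],
    n_features: int,
    l1: float = 0.0,
    l2: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> MaxEntModel:
    """Fit by monotone proximal gradient descent with backtracking."""
    y = _check_labels(labels).astype(float)
    X = _to_dense(vectors, n_features)
    w = np.zeros(n_features)
    b = 0.0

    def smooth(wv: np.ndarray, bv: float) -> float:
        z = X @ wv + bv
        return float(
            -np.sum(y * _log_sigmoid(z) + (1 - y) * _log_sigmoid(-z))
            + 0.5 * l2 * wv @ wv
        )

    def objective(wv: np.ndarray, bv: float) -> float:
        return smooth(wv, bv) + l1 * np.abs(wv).sum()

    f_cur = objective(w, b)
    history = [f_cur]
    # separate curvature bounds: the l2 penalty steepens the weight block
    # but leaves the (unpenalized) bias untouched
    n_docs = len(y)
    row_sum = np.abs(X).sum(axis=1).max() if n_docs else 1.0
    col_sum = np.abs(X).sum(axis=0).max() if n_features else 1.0
    base_w = 1.0 / max(1e-12, 0.25 * row_sum * col_sum + l2)
    base_b = 1.0 / max(1e-12, 0.25 * n_docs)
    t = 1.0
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        z = X @ w + b
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        resid = p - y
        gw = X.T @ resid + l2 * w
        gb = float(resid.sum())
        f_smooth = smooth(w, b)
        t = min(t * 2.0, 1e8)  # tentative growth, then backtrack
        while True:
            step_w, step_b = t * base_w, t * base_b
            w_new = w - step_w * gw
            if l1 > 0:
                w_new = np.sign(w_new) * np.maximum(
                    np.abs(w_new) - step_w * l1, 0.0
                )
            b_new = b - step_b * gb
            dw = w_new - w
            db = b_new - b
            quad = (f_smooth + gw @ dw + gb * db
                    + dw @ dw / (2.0 * step_w) + db * db / (2.0 * step_b))
            if smooth(w_new, b_new) <= quad + 1e-12:
                break
            t *= 0.5
            if t < 1e-18:
                break
        f_new = objective(w_new, b_new)
        if not np.isfinite(f_new):
            raise TrainingError("non-finite objective during training")
        if f_new > f_cur + 1e-10:  # safeguard: reject non-descent step
            break
        w, b = w_new, b_new
        history.append(f_new)
        if abs(f_cur - f_new) < tol:
            converged = True
            f_cur = f_new
            break
        f_cur = f_new

    return MaxEntModel(
        weights=w, bias=b, l1=l1, l2=l2, tol=tol, max_iter=max_iter,
        n_iter=n_iter, converged=converged, objective_history=history,
    )


def predict_maxent(model: MaxEntModel, vector: IndexSet) -> tuple[int, float]:
    """Predicted label and positive-class probability; ties go positive."""
    z = model.bias + sum(model.weights[i] for i in vector)
    p = float(1.0 / (1.0 + np.exp(-z)))
    return (1 if p >= 0.5 else 0), p


def predict_maxent_many(
    model: MaxEntModel, vectors: Iterable[IndexSet]
) -> list[tuple[int, float]]:
    return [predict_maxent(model, v) for v in vectors]


# ---------------------------------------------------------------------------
# plain-text model serialization

def write_nb_model(path, model: NBModel, names: Sequence[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("@model\tnaive_bayes\n")
        fh.write(f"@alpha\t{float(model.alpha)!r}\n")
        fh.write(f"@log_prior\t{float(model.log_prior[0])!r}\t"
                 f"{float(model.log_prior[1])!r}\n")
        for i, name in enumerate(names):
            fh.write(
                f"{name}\t{float(model.log_p[0, i])!r}\t"
                f"{float(model.log_p[1, i])!r}\n"
            )


def read_nb_model(path) -> tuple[NBModel, list[str]]:
    names: list[str] = []
    rows: list[tuple[float, float]] = []
    alpha = 1.0
    log_prior = np.zeros(2)
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "@model":
                continue
            if parts[0] == "@alpha":
                alpha = float(parts[1])
            elif parts[0] == "@log_prior":
                log_prior = np.array([float(parts[1]), float(parts[2])])
            else:
                names.append(parts[0])
                rows.append((float(parts[1]), float(parts[2])))
    log_p = np.array(rows).T if rows else np.zeros((2, 0))
    log_1mp = np.log1p(-np.exp(log_p))
    return NBModel(log_prior, log_p, log_1mp, alpha), names


def write_maxent_model(path, model: MaxEntModel, names: Sequence[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("@model\tmaxent\n")
        fh.write(f"@penalties\t{float(model.l1)!r}\t{float(model.l2)!r}\n")
        fh.write(f"@bias\t{float(model.bias)!r}\n")
        for name, wi in zip(names, model.weights):
            fh.write(f"{name}\t{float(wi)!r}\n")


def read_maxent_model(path) -> tuple[MaxEntModel, list[str]]:
    names: list[str] = []
    ws: list[float] = []
    bias = 0.0
    l1, l2 = 0.0, 1.0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "@model":
                continue
            if parts[0] == "@penalties":
                l1, l2 = float(parts[1]), float(parts[2])
            elif parts[0] == "@bias":
                bias = float(parts[1])
            else:
                names.append(parts[0])
                ws.append(float(parts[1]))
    return MaxEntModel(
        weights=np.array(ws), bias=bias, l1=l1, l2=l2, tol=0.0, max_iter=0
    ), names
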