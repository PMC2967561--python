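"""Weighted-cost binary SVM with an RBF kernel.

The decision function is f(x) = sgn(sum_i alpha_i y_i K(sv_i, x) + b)
with sgn(0) = +1 and K(x, z) = exp(-gamma ||x - z||^2).  Class
imbalance is handled with per-class box constraints related by
C+ = (n+/n-) C-, where n+ and n- are the positive and negative
training counts.

The dual problem is solved by libsvm via scikit-learn.  Because the
feature vectors here are extremely sparse (38 set bits of 15,200 for
the contact-map encoding), the Gram matrix is computed explicitly with
sparse linear algebra and libsvm is run on the precomputed kernel,
which is much faster than its internal row-wise kernel evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


def _row_sq_norms(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.multiply(X).sum(axis=1)).ravel()
    return np.einsum("ij,ij->i", X, X)


def squared_distances(X, Z) -> np.ndarray:
    """Dense matrix of squared Euclidean distances between rows of X and Z."""
    G = X @ Z.T
    if sp.issparse(G):
        G = G.toarray()
    D2 = _row_sq_norms(X)[:, None] + _row_sq_norms(Z)[None, :] - 2.0 * G
    np.maximum(D2, 0.0, out=D2)
    return D2


def rbf_kernel_matrix(X, Z, gamma: float) -> np.ndarray:
    """K(x, z) = exp(-gamma ||x - z||^2) for all row pairs."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"feature-length mismatch: {X.shape[1]} vs {Z.shape[1]}")
    return np.exp(-gamma * squared_distances(X, Z))


def rbf_kernel(x, z, gamma: float) -> float:
    """RBF kernel between two single vectors (dense or sparse rows)."""
    x = x.reshape(1, -1) if not sp.issparse(x) else x
    z = z.reshape(1, -1) if not sp.issparse(z) else z
    return float(rbf_kernel_matrix(x, z, gamma)[0, 0])


def weighted_costs(n_pos: int, n_neg: int, cost_neg: float = 1.0) -> tuple[float, float]:
    """Per-class costs (C+, C-) with C+ = (n+/n-) C-."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both classes must be present")
    return (n_pos / n_neg) * cost_neg, cost_neg


@dataclass
class SVMModel:
    """A trained RBF SVM in its kernel-expansion form.

    ``dual_coefs`` holds alpha_i * y_i for each support vector; the
    decision score of x is ``sum_i dual_coefs[i] * K(sv_i, x) + bias``.
    """

    gamma: float
    cost_neg: float
    cost_pos: float
    support_vectors: object  # ndarray or CSR matrix, one row per SV
    dual_coefs: np.ndarray
    bias: float
    n_pos: int
    n_neg: int

    def decision_scores(self, X) -> np.ndarray:
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError("feature-length mismatch with support vectors")
        K = rbf_kernel_matrix(X, self.support_vectors, self.gamma)
        return K @ self.dual_coefs + self.bias


def _fit_precomputed(K: np.ndarray, y: np.ndarray, C: float, class_weight, tol: float) -> SVC:
    svc = SVC(C=C, kernel="precomputed", class_weight=class_weight,
              tol=tol, shrinking=True, cache_size=500)
    svc.fit(K, y)
    return svc


def train(
    X,
    y,
    C: float = 1.0,
    gamma: float = 0.05,
    weighted: bool = True,
    tol: float = 1e-3,
) -> SVMModel:
    """Train the weighted-cost RBF SVM.

    ``C`` is the negative-class cost C-; when ``weighted`` the positive
    class uses C+ = (n+/n-) C-, otherwise both classes use ``C``.
    ``X`` may be a dense ndarray or a CSR matrix.
    """
    y = np.asarray(y)
    if X.shape[0] != len(y) or len(y) < 2:
        raise ValueError("X and y must agree and contain at least 2 samples")
    if not set(np.unique(y)) == {-1, 1}:
        raise ValueError("training requires both classes with labels in {-1, +1}")
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if weighted:
        cost_pos, cost_neg = weighted_costs(n_pos, n_neg, C)
        class_weight = {1: n_pos / n_neg, -1: 1.0}
    else:
        cost_pos = cost_neg = C
        class_weight = None

    K = rbf_kernel_matrix(X, X, gamma)
    svc = _fit_precomputed(K, y, C, class_weight, tol)
    support = svc.support_
    return SVMModel(
        gamma=gamma,
        cost_neg=cost_neg,
        cost_pos=cost_pos,
        support_vectors=X[support],
        dual_coefs=svc.dual_coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def decide(model: SVMModel, x) -> tuple[int, float]:
    """Classify one vector: label +1 when the score is >= 0 (sgn(0) = +1)."""
    x = x.reshape(1, -1) if not sp.issparse(x) else x
    score = float(model.decision_scores(x)[0])
    return (1 if score >= 0 else -1), score


def decide_batch(model: SVMModel, X) -> tuple[np.ndarray, np.ndarray]:
    scores = model.decision_scores(X)
    labels = np.where(scores >= 0, 1, -1)
    return labels, scores


DEFAULT_C_GRID = [2.0**k for k in range(-5, 16, 2)]
DEFAULT_GAMMA_GRID = [2.0**k for k in range(-15, 4, 2)]


@dataclass
class GridSearchResult:
    grid: list[tuple[float, float, float]]  # (C, gamma, mean CV ROC AUC)
    best: tuple[float, float]


def grid_search(
    X,
    y,
    C_grid: list[float] | None = None,
    gamma_grid: list[float] | None = None,
    folds: int = 5,
    seed: int = 0,
    weighted: bool = True,
    tol: float = 1e-3,
) -> GridSearchResult:
    """Exhaustive (C, gamma) search scored by stratified-CV mean ROC AUC.

    Ties are broken toward smaller C, then smaller gamma.  Squared
    distances are computed once and re-exponentiated per gamma.
    """
    from sklearn.metrics import roc_auc_score

    C_grid = sorted(C_grid or DEFAULT_C_GRID)
    gamma_grid = sorted(gamma_grid or DEFAULT_GAMMA_GRID)
    if not C_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    y = np.asarray(y)
    n_pos, n_neg = int((y == 1).sum()), int((y == -1).sum())
    if folds > min(n_pos, n_neg):
        raise ValueError(f"folds={folds} exceeds the smaller class size")
    class_weight = {1: n_pos / n_neg, -1: 1.0} if weighted else None

    D2 = squared_distances(X, X)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(np.zeros(len(y)), y))

    results = []
    best = None
    for gamma in gamma_grid:
        K = np.exp(-gamma * D2)
        for C in C_grid:
            aucs = []
            for tr, te in splits:
                svc = _fit_precomputed(K[np.ix_(tr, tr)], y[tr], C, class_weight, tol)
                scores = svc.decision_function(K[np.ix_(te, tr)])
                aucs.append(roc_auc_score(y[te], scores))
            mean_auc = float(np.mean(aucs))
            results.append((C, gamma, mean_auc))
            key = (mean_auc, -C, -gamma)
            if best is None or key > best[0]:
                best = (key, (C, gamma))
    results.sort(key=lambda t: (t[0], t[1]))
    return GridSearchResult(grid=results, best=best[1])


MODEL_FORMAT_VERSION = 1


def save_model(model: SVMModel, path: str | Path) -> None:
    """Serialize a model as versioned text (sparse index:value SV rows)."""
    sv = sp.csr_matrix(model.support_vectors)
    with open(path, "w") as fh:
        fh.write(f"pdzscan-svm v{MODEL_FORMAT_VERSION}\n")
        fh.write(f"gamma {model.gamma!r}\n")
        fh.write(f"cost_neg {model.cost_neg!r}\ncost_pos {model.cost_pos!r}\n")
        fh.write(f"bias {model.bias!r}\n")
        fh.write(f"n_pos {model.n_pos}\nn_neg {model.n_neg}\n")
        fh.write(f"n_features {sv.shape[1]}\nn_sv {sv.shape[0]}\n")
        for i in range(sv.shape[0]):
            row = sv.getrow(i)
            terms = " ".join(f"{j}:{float(v)!r}" for j, v in zip(row.indices, row.data))
            fh.write(f"{float(model.dual_coefs[i])!r} {terms}\n")


def load_model(path: str | Path) -> SVMModel:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("pdzscan-svm v"):
        raise ValueError(f"{path}: not a pdzscan model file")
    header = dict(line.split(None, 1) for line in lines[1:9])
    n_features = int(header["n_features"])
    n_sv = int(header["n_sv"])
    dual, rows, cols, data = [], [], [], []
    for i, line in enumerate(lines[9 : 9 + n_sv]):
        parts = line.split()
        dual.append(float(parts[0]))
        for term in parts[1:]:
            j, v = term.split(":")
            rows.append(i)
            cols.append(int(j))
            data.append(float(v))
    sv = sp.csr_matrix((data, (rows, cols)), shape=(n_sv, n_features))
    return SVMModel(
        gamma=float(header["gamma"]),
        cost_neg=float(header["cost_neg"]),
        cost_pos=float(header["cost_pos"]),
        support_vectors=sv,
        dual_coefs=np.array(dual),
        bias=float(header["bias"]),
        n_pos=int(header["n_pos"]),
        n_neg=int(header["n_neg"]),
    )
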