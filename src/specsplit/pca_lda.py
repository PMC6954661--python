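"""PCA-LDA classifier with pooled-covariance Mahalanobis scoring.

Spectra are decomposed by PCA; the scores feed a linear discriminant that
assigns each sample to the class minimizing the non-Bayesian score

    L_ik = (x_i - mean_k)^T  C_pooled^{-1}  (x_i - mean_k)

where ``C_pooled`` is the pooled within-class covariance of the training
scores (denominator N - K by default). The number of retained components is
chosen by venetian-blinds cross-validation: sample i goes to fold
``i mod n_splits``, PCA and LDA are refit on each fold complement (no
information leakage) and the smallest component count attaining the minimum
pooled misclassification fraction wins.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .data import SpectralDataset

logger = logging.getLogger("specsplit")

__all__ = [
    "PcaModel", "LdaModel", "CvCurve", "PcaLdaModel",
    "fit_pca", "project", "fit_lda", "lda_score", "classify",
    "venetian_blinds_cv", "select_n_pcs", "fit_pca_lda", "predict",
]

_COND_LIMIT = 1e12


@dataclass
class PcaModel:
    """Principal-component model: training mean, orthonormal loadings, EVR."""

    mean_spectrum: np.ndarray            # (n_variables,)
    loadings: np.ndarray                 # (n_variables, k), orthonormal columns
    explained_variance_ratio: np.ndarray # (k,), fractions of total variance

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def truncate(self, k: int) -> "PcaModel":
        """First *k* components of this model (nested by construction)."""
        if not 1 <= k <= self.n_components:
            raise ValueError(f"cannot truncate to {k} of {self.n_components} components")
        return PcaModel(self.mean_spectrum, self.loadings[:, :k],
                        self.explained_variance_ratio[:k])


@dataclass
class LdaModel:
    """Class means and pooled covariance in score space."""

    class_means: np.ndarray   # (K, d)
    pooled_cov: np.ndarray    # (d, d), symmetric positive definite
    class_order: list         # labels, column order of scores/confusions
    _cho: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self._cho is None:
            self._cho = linalg.cho_factor(self.pooled_cov)


@dataclass
class CvCurve:
    """Cross-validation misclassification fraction per component count."""

    n_pcs_grid: np.ndarray
    cv_error: np.ndarray
    n_splits: int = 10


@dataclass
class PcaLdaModel:
    """Fitted pipeline: PCA + LDA + the CV curve that chose ``n_pcs``."""

    pca: PcaModel
    lda: LdaModel
    n_pcs: int
    cv_curve: CvCurve
    training_accuracy: float   # percent
    cv_accuracy: float         # percent, 1 - cv_error at chosen n_pcs

    def to_dict(self) -> dict:
        return {
            "n_pcs": self.n_pcs,
            "training_accuracy": self.training_accuracy,
            "cv_accuracy": self.cv_accuracy,
            "pca": {
                "mean_spectrum": self.pca.mean_spectrum.tolist(),
                "loadings": self.pca.loadings.tolist(),
                "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
            },
            "lda": {
                "class_means": self.lda.class_means.tolist(),
                "pooled_cov": self.lda.pooled_cov.tolist(),
                "class_order": [str(c) for c in self.lda.class_order],
            },
            "cv_curve": {
                "n_pcs_grid": self.cv_curve.n_pcs_grid.tolist(),
                "cv_error": self.cv_curve.cv_error.tolist(),
                "n_splits": self.cv_curve.n_splits,
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "PcaLdaModel":
        return cls(
            pca=PcaModel(
                mean_spectrum=np.asarray(d["pca"]["mean_spectrum"]),
                loadings=np.asarray(d["pca"]["loadings"]),
                explained_variance_ratio=np.asarray(d["pca"]["explained_variance_ratio"]),
            ),
            lda=LdaModel(
                class_means=np.asarray(d["lda"]["class_means"]),
                pooled_cov=np.asarray(d["lda"]["pooled_cov"]),
                class_order=list(d["lda"]["class_order"]),
            ),
            n_pcs=int(d["n_pcs"]),
            cv_curve=CvCurve(
                n_pcs_grid=np.asarray(d["cv_curve"]["n_pcs_grid"], dtype=int),
                cv_error=np.asarray(d["cv_curve"]["cv_error"]),
                n_splits=int(d["cv_curve"]["n_splits"]),
            ),
            training_accuracy=float(d["training_accuracy"]),
            cv_accuracy=float(d["cv_accuracy"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PcaLdaModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_pca(X: np.ndarray, k: int) -> PcaModel:
    """Fit a k-component PCA of the rows of X.

    Columns of the loading matrix are the top right singular vectors of the
    centered data; each column's sign is fixed so its largest-magnitude
    element is positive, making the decomposition fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    kmax = min(n - 1, p)
    if not 1 <= k <= kmax:
        raise ValueError(f"k must lie in 1..min(n_samples-1, n_variables)={kmax}, got {k}")
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    total = float(np.sum(s**2))
    loadings = vt[:k].T.copy()
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings *= flip
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PcaModel(mean_spectrum=mean, loadings=loadings,
                    explained_variance_ratio=evr)


def project(m: PcaModel, X: np.ndarray) -> np.ndarray:
    """Project spectra onto the component space: (X - mean) @ loadings."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.mean_spectrum.size:
        raise ValueError(
            f"expected {m.mean_spectrum.size} variables, got {X.shape[1]}")
    return (X - m.mean_spectrum) @ m.loadings


def fit_lda(scores: np.ndarray, labels: np.ndarray,
            cov_denominator: str = "n-k") -> LdaModel:
    """Fit class means and pooled within-class covariance.

    C_pooled = sum_k sum_{i in k} (x_i - mean_k)(x_i - mean_k)^T / (N - K)
    (``cov_denominator="n"`` divides by N instead). Raises ``LinAlgError``
    when the pooled covariance is numerically singular, advising fewer PCs.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels, dtype=object)
    n, d = scores.shape
    order: list = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    if len(order) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int(np.sum(labels == c)) for c in order}
    if min(counts.values()) < 2:
        small = min(counts, key=counts.get)
        raise ValueError(f"class {small!r} has {counts[small]} sample(s); need >= 2")
    if d >= n - len(order):
        raise ValueError(
            f"score dimension {d} must be < n_samples - n_classes = {n - len(order)}")
    means = np.vstack([scores[labels == c].mean(axis=0) for c in order])
    scatter = np.zeros((d, d))
    for c, mu in zip(order, means):
        r = scores[labels == c] - mu
        scatter += r.T @ r
    denom = n - len(order) if cov_denominator == "n-k" else n
    pooled = scatter / denom
    if np.linalg.cond(pooled) > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            "pooled covariance is numerically singular; reduce the number of PCs")
    return LdaModel(class_means=means, pooled_cov=pooled, class_order=order)


def lda_score(m: LdaModel, x: np.ndarray) -> np.ndarray:
    """Per-class Mahalanobis scores L_ik for one vector or a matrix of rows."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != m.class_means.shape[1]:
        raise ValueError(
            f"expected dimension {m.class_means.shape[1]}, got {X.shape[1]}")
    K = m.class_means.shape[0]
    L = np.empty((X.shape[0], K))
    for k in range(K):
        diff = X - m.class_means[k]
        L[:, k] = np.einsum("ij,ji->i", diff, linalg.cho_solve(m._cho, diff.T))
    return L[0] if np.asarray(x).ndim == 1 else L


def classify(m: LdaModel, X: np.ndarray) -> np.ndarray:
    """Assign each row the class with minimal score; ties -> first class."""
    L = np.atleast_2d(lda_score(m, X))
    idx = np.argmin(L, axis=1)
    return np.asarray([m.class_order[i] for i in idx], dtype=object)


def _lda_kmax(labels: np.ndarray) -> int:
    """Largest usable score dimension for these labels (strict inequality)."""
    labels = np.asarray(labels, dtype=object)
    return labels.size - len(set(labels.tolist())) - 1


def venetian_blinds_cv(X: np.ndarray, labels: np.ndarray, max_pcs: int,
                       n_splits: int = 10) -> CvCurve:
    """Interleaved cross-validation of the PC count.

    Sample at row position i is held out in fold ``i mod n_splits``. For
    each candidate component count the full PCA+LDA pipeline is refit on
    every fold complement and the held-out predictions pooled; the curve
    reports the pooled misclassification fraction. Folds whose training part
    loses a class below 2 samples are skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    n = X.shape[0]
    if max_pcs < 1:
        raise ValueError("max_pcs must be >= 1")
    if n_splits > n:
        raise ValueError(f"n_splits={n_splits} exceeds n_samples={n}")
    folds = np.arange(n) % n_splits

    used_folds = []
    for f in range(n_splits):
        tr = labels[folds != f]
        if min(np.sum(tr == c) for c in set(labels.tolist())) < 2:
            warnings.warn(f"venetian blinds: fold {f} skipped "
                          "(a class drops below 2 training samples)")
            continue
        used_folds.append(f)
    if not used_folds:
        raise ValueError("no usable cross-validation folds")

    kmax = max_pcs
    for f in used_folds:
        n_tr = int(np.sum(folds != f))
        kmax = min(kmax, n_tr - 1, X.shape[1], _lda_kmax(labels[folds != f]))
    if kmax < 1:
        raise ValueError("training folds too small for even 1 component")

    grid = np.arange(1, kmax + 1)
    wrong = np.zeros(kmax)
    total = 0
    for f in used_folds:
        tr, te = folds != f, folds == f
        pca_full = fit_pca(X[tr], kmax)
        total += int(te.sum())
        for k in grid:
            pca = pca_full.truncate(int(k))
            lda = fit_lda(project(pca, X[tr]), labels[tr])
            pred = classify(lda, project(pca, X[te]))
            wrong[k - 1] += int(np.sum(pred != labels[te]))
    return CvCurve(n_pcs_grid=grid, cv_error=wrong / total, n_splits=n_splits)


def select_n_pcs(c: CvCurve) -> int:
    """Smallest component count attaining the minimum CV error."""
    if c.cv_error.size == 0:
        raise ValueError("empty cross-validation curve")
    return int(c.n_pcs_grid[int(np.argmin(c.cv_error))])


def fit_pca_lda(train: SpectralDataset, max_pcs: int = 20,
                n_splits: int = 10) -> PcaLdaModel:
    """Full training protocol: CV model selection then refit at the chosen k."""
    X, y = train.intensities, train.labels
    curve = venetian_blinds_cv(X, y, max_pcs, n_splits)
    k = select_n_pcs(curve)
    pca = fit_pca(X, k)
    lda = fit_lda(project(pca, X), y)
    train_pred = classify(lda, project(pca, X))
    train_acc = 100.0 * float(np.mean(train_pred == y))
    cv_acc = 100.0 * (1.0 - float(curve.cv_error[np.argmax(curve.n_pcs_grid == k)]))
    logger.info("fit_pca_lda: chose %d PCs (train acc %.1f%%, CV acc %.1f%%)",
                k, train_acc, cv_acc)
    return PcaLdaModel(pca=pca, lda=lda, n_pcs=k, cv_curve=curve,
                       training_accuracy=train_acc, cv_accuracy=cv_acc)


def predict(model: PcaLdaModel, ds: SpectralDataset) -> np.ndarray:
    """Predicted class labels for every sample of *ds*."""
    return classify(model.lda, project(model.pca, ds.intensities))
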