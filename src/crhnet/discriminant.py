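"""Maximum-likelihood discriminant (MLHD) classification and LOOCV fitness.

The classifier shared by every feature selector in this package: class-wise
Gaussians with a pooled within-class covariance and equal priors, which is
equivalent to classical linear discriminant analysis.  Samples are the 30
arrays of the time-course design (5 time points x 6 technical replicates);
features are small gene subsets ("chromosomes", typically 5 genes).

Leave-one-out cross-validation is the fitness measure of the wrapper
selectors, so :func:`loocv_predictions` avoids refitting from scratch: class
means and the pooled scatter matrix are downdated per held-out sample and all
30 fold-wise covariance inversions run as one batched operation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Relative ridge added to a singular pooled covariance before inversion.
RIDGE_EPS = 1e-8


@dataclass
class DiscriminantModel:
    """Fitted MLHD/LDA model with equal class priors.

    Attributes
    ----------
    classes : ndarray
        Sorted unique class labels.
    means : ndarray, shape (G, k)
        Per-class mean vectors.
    pooled_cov : ndarray, shape (k, k)
        Pooled within-class covariance, sum_g (n_g - 1) S_g / (n - G).
    precision : ndarray, shape (k, k)
        Inverse of the (possibly ridge-guarded) pooled covariance.
    ridged : bool
        True if the ridge guard was needed to invert the covariance.
    """

    classes: np.ndarray
    means: np.ndarray
    pooled_cov: np.ndarray
    precision: np.ndarray
    ridged: bool = False

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Linear discriminant scores d_g(x) = mu_g' P x - 1/2 mu_g' P mu_g."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lin = self.means @ self.precision @ X.T            # (G, n)
        const = 0.5 * np.einsum(
            "gk,kl,gl->g", self.means, self.precision, self.means
        )
        return (lin - const[:, None]).T                    # (n, G)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.decision_scores(X), axis=1)]


@dataclass
class FitnessResult:
    """LOOCV outcome for one gene subset."""

    genes: tuple
    accuracy: float
    predictions: np.ndarray
    true_labels: np.ndarray = field(repr=False, default=None)

    @property
    def error(self) -> float:
        """Classification error, 1 - accuracy, as a fraction."""
        return 1.0 - self.accuracy


@dataclass
class GeneralizationCurve:
    """Mean training and LOOCV test error as a function of subset size."""

    sizes: np.ndarray
    train_error: np.ndarray
    test_error: np.ndarray
    draws: int


def _batched_inv_pd(mats: np.ndarray) -> tuple[np.ndarray, bool]:
    """Invert a stack of symmetric matrices, ridge-guarding singular ones.

    Positive definiteness is probed with a batched Cholesky; on failure a
    ridge ``RIDGE_EPS * mean(diag)`` (with an absolute floor for all-zero
    matrices) is added to every matrix in the stack and the inversion retried.
    """
    try:
        np.linalg.cholesky(mats)
        return np.linalg.inv(mats), False
    except np.linalg.LinAlgError:
        pass
    diag_mean = np.einsum("...ii->...", mats) / mats.shape[-1]
    scale = np.where(diag_mean > 0, diag_mean, 1.0)
    k = mats.shape[-1]
    ridged = mats + RIDGE_EPS * scale[..., None, None] * np.eye(k)
    logger.debug("singular pooled covariance: ridge %.1e applied", RIDGE_EPS)
    try:
        np.linalg.cholesky(ridged)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance not invertible even after ridge guard"
        ) from exc
    return np.linalg.inv(ridged), True


def _class_stats(X: np.ndarray, y: np.ndarray):
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 training samples")
    sums = np.zeros((classes.size, X.shape[1]))
    np.add.at(sums, y_idx, X)
    means = sums / counts[:, None]
    return classes, y_idx, counts, means


def fit_mlhd(X: np.ndarray, y: np.ndarray) -> DiscriminantModel:
    """Fit the MLHD/LDA model on training data.

    Parameters
    ----------
    X : array, shape (n, k)
        Expression ratios, samples x genes.
    y : array, shape (n,)
        Class labels (the time-point factor in the intended design).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, k = X.shape
    classes, y_idx, counts, means = _class_stats(X, y)
    G = classes.size
    if k >= n - G:
        warnings.warn(
            f"subset size k={k} >= residual df n-G={n - G}; "
            "pooled covariance is rank deficient",
            stacklevel=2,
        )
    D = X - means[y_idx]
    pooled = (D.T @ D) / (n - G)
    precision, ridged = _batched_inv_pd(pooled[None])
    return DiscriminantModel(classes, means, pooled, precision[0], ridged)


def _loocv_core(
    X: np.ndarray, y_idx: np.ndarray, counts: np.ndarray, onehot: np.ndarray
) -> np.ndarray:
    """Vectorized LOOCV with precomputed label encoding; returns class
    indices.  See :func:`loocv_predictions` for the downdate algebra.

    Rather than inverting each fold covariance, one batched linear solve
    computes Sigma^-1 [x_i | mu_1 .. mu_G] per fold; a ridge guard handles
    exactly singular covariances.
    """
    n, k = X.shape
    G = counts.size
    means = (onehot @ X) / counts[:, None]
    D = X - means[y_idx]
    W = D.T @ D
    cg = counts[y_idx].astype(float)
    factor = cg / (cg - 1.0)
    W_stack = W[None] - factor[:, None, None] * (
        D[:, :, None] * D[:, None, :]
    )
    cov_stack = W_stack / (n - 1 - G)

    mu_stack = np.broadcast_to(means, (n, G, k)).copy()
    own = (counts[y_idx, None] * means[y_idx] - X) / (counts[y_idx, None] - 1)
    mu_stack[np.arange(n), y_idx] = own

    rhs = np.concatenate(
        [X[:, :, None], np.swapaxes(mu_stack, 1, 2)], axis=2
    )                                            # (n, k, 1 + G)
    try:
        sol = np.linalg.solve(cov_stack, rhs)
    except np.linalg.LinAlgError:
        diag_mean = np.einsum("...ii->...", cov_stack) / k
        scale = np.where(diag_mean > 0, diag_mean, 1.0)
        cov_stack = cov_stack + (
            RIDGE_EPS * scale[:, None, None] * np.eye(k)
        )
        logger.debug("singular fold covariance: ridge %.1e applied",
                     RIDGE_EPS)
        sol = np.linalg.solve(cov_stack, rhs)
    prec_x = sol[:, :, 0]                        # Sigma^-1 x_i
    prec_mu = sol[:, :, 1:]                      # Sigma^-1 mu_g (columns)
    lin = np.einsum("ngk,nk->ng", mu_stack, prec_x)
    quad = 0.5 * np.einsum("ngk,nkg->ng", mu_stack, prec_mu)
    return np.argmax(lin - quad, axis=1)


def loocv_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out predictions, one per sample, refit per fold.

    Implemented by rank-one downdates of the class means and pooled scatter:
    for held-out sample i of class g with deviation d_i = x_i - mu_g,

        W_(i) = W - n_g/(n_g - 1) * d_i d_i',
        mu_g_(i) = (n_g mu_g - x_i) / (n_g - 1),

    which reproduces the from-scratch refit exactly.  All fold covariances
    are inverted in one batched call.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx)
    if n < classes.size + 1:
        raise ValueError("need at least one more sample than classes")
    if np.any(counts < 2):
        raise ValueError("a class with a single sample cannot be left out")
    onehot = np.zeros((classes.size, n))
    onehot[y_idx, np.arange(n)] = 1.0
    return classes[_loocv_core(X, y_idx, counts, onehot)]


def loocv_accuracy(
    X: np.ndarray, y: np.ndarray, genes: tuple = ()
) -> FitnessResult:
    """LOOCV classification accuracy of a gene subset (the GA/SA fitness)."""
    y = np.asarray(y)
    preds = loocv_predictions(X, y)
    acc = float(np.mean(preds == y))
    return FitnessResult(tuple(genes), acc, preds, y)


def resubstitution_error(X: np.ndarray, y: np.ndarray) -> float:
    """Training (resubstitution) error of the model fit on all samples."""
    model = fit_mlhd(X, y)
    return float(np.mean(model.predict(X) != np.asarray(y)))


def generalization_curve(
    X: np.ndarray,
    y: np.ndarray,
    sizes=range(2, 31),
    draws: int = 1000,
    seed: int | None = None,
) -> GeneralizationCurve:
    """Overfitting diagnostic: error vs number of randomly drawn genes.

    For each subset size v, `draws` random gene subsets are scored by mean
    resubstitution (training) error and mean LOOCV (test) error.  On data
    without class signal the training error keeps falling with v while the
    test error rises once v approaches the sample count — the classical
    small-n-large-p overfitting signature.

    Parameters
    ----------
    X : array, shape (n_genes, n_samples)
        Ratio matrix, genes in rows (the package-wide orientation).
    """
    X = np.asarray(X, dtype=float)
    sizes = np.asarray(sorted(sizes))
    if draws < 1:
        raise ValueError("draws must be >= 1")
    if sizes[-1] > X.shape[0]:
        raise ValueError(
            f"largest subset size {sizes[-1]} exceeds available genes "
            f"{X.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    train = np.empty(sizes.size)
    test = np.empty(sizes.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank-deficiency warnings at large v
        for s, v in enumerate(sizes):
            tr = np.empty(draws)
            te = np.empty(draws)
            for d in range(draws):
                idx = rng.choice(X.shape[0], size=v, replace=False)
                sub = X[idx].T
                tr[d] = resubstitution_error(sub, y)
                te[d] = loocv_accuracy(sub, y).error
            train[s], test[s] = tr.mean(), te.mean()
    return GeneralizationCurve(sizes, train, test, draws)
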