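"""PCA diagnostics for feature matrices.

Covariance-mode PCA (optionally correlation-mode) of a samples x
features matrix, used to visualize how the per-event averaged sensor
features separate by class and to summarize the eigenvalue spectrum
(scree).  This is a diagnostic only — the classifier never consumes the
projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PCAResult:
    components: np.ndarray    # (p, p) rows are orthonormal loadings
    eigenvalues: np.ndarray   # (p,) descending, variance units
    scores: np.ndarray        # (n, p) projected coordinates
    mean: np.ndarray          # (p,) column means removed before projection


def pca_fit(X, mode: str = "covariance") -> PCAResult:
    """Eigendecomposition of the sample covariance of column-centered X.

    ``mode="correlation"`` standardizes columns first (zero-variance
    columns are left unscaled).  Components are sign-fixed so the
    largest-magnitude loading of each is positive; eigenvalues are
    sorted descending.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix must have no missing/non-finite values")
    if mode not in ("covariance", "correlation"):
        raise ValueError("mode must be 'covariance' or 'correlation'")
    mean = X.mean(axis=0)
    Xc = X - mean
    if mode == "correlation":
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    components = eigvecs[:, order].T
    for i, row in enumerate(components):
        if row[np.argmax(np.abs(row))] < 0:
            components[i] = -row
    scores = Xc @ components.T
    return PCAResult(components=components, eigenvalues=eigvals,
                     scores=scores, mean=mean)


def scree(X, mode: str = "covariance"):
    """Descending eigenvalues and the dominance ratio lambda1/lambda2.

    The ratio is infinite for rank-1 data (lambda2 = 0).
    """
    result = pca_fit(X, mode=mode)
    ev = result.eigenvalues
    # eigenvalues of rank-deficient data land at round-off, not exact zero
    if ev.size < 2 or ev[1] <= 1e-12 * max(ev[0], 1e-300):
        ratio = np.inf
    else:
        ratio = float(ev[0] / ev[1])
    return ev, ratio
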