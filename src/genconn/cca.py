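"""PCA reduction, canonical correlation analysis and mode summaries.

Both adjusted data blocks are reduced to their leading principal
components (100 by default) to avoid overfitting, then CCA finds paired
linear combinations — a genetic canonical score and a connectomic
canonical score per subject — maximizing their correlation.  Successive
modes are mutually uncorrelated within each block.

CCA is solved directly by SVD: with column-centered blocks U = Q_u R_u,
V = Q_v R_v (thin QR), the singular values of Q_u' Q_v are the canonical
correlations and the singular vectors give the weights.  On
well-conditioned PC scores no regularization is needed.

The CCA sign is arbitrary; by default modes are oriented so the mean
canonical connection strength is non-positive, matching the convention
that high canonical scores accompany reduced average connectivity.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA

from .datatypes import CCAMode, PCAReduction, VarianceExplained

logger = logging.getLogger(__name__)


def reduce_pca(X, n_components: int = 100,
               standardize: bool = False) -> PCAReduction:
    """Column-centered PCA keeping ``n_components`` components.

    Features stay on their native scale (dosages, fFA) unless
    ``standardize`` z-scores them first.  Zero-variance columns are
    tolerated (their centered values are identically zero).
    """
    values = np.asarray(X, float)
    n, p = values.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, p)="
            f"{min(n - 1, p)}")
    scale = None
    if standardize:
        scale = values.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        values = values / scale
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(values)
    return PCAReduction(loadings=pca.components_.T, scores=scores,
                        explained_variance_ratio=pca.explained_variance_ratio_,
                        mean=pca.mean_, scale=scale)


def fit_cca(U, V) -> list[CCAMode]:
    """Fit CCA between two aligned subjects x components blocks.

    Returns min(K_u, K_v) modes ordered by nonincreasing canonical
    correlation; canonical scores are unit-variance and, within each
    block, mutually uncorrelated across modes.  Zero-variance input
    columns raise before fitting.
    """
    U = np.asarray(U, float)
    V = np.asarray(V, float)
    if U.shape[0] != V.shape[0]:
        raise ValueError("U and V must have the same number of subjects")
    n = U.shape[0]
    for name, M in (("U", U), ("V", V)):
        if M.shape[1] > n - 1:
            raise ValueError(f"{name} has more columns than subjects - 1")
        if np.any(M.std(axis=0) == 0):
            raise ValueError(f"{name} contains zero-variance columns")
    Uc = U - U.mean(axis=0)
    Vc = V - V.mean(axis=0)
    Qu, Ru = np.linalg.qr(Uc)
    Qv, Rv = np.linalg.qr(Vc)
    W, s, Zt = linalg.svd(Qu.T @ Qv, full_matrices=False)
    s = np.clip(s, 0.0, 1.0)
    scale = np.sqrt(n - 1)
    x_scores = Qu @ W * scale       # unit variance, zero mean
    y_scores = Qv @ Zt.T * scale
    x_weights = linalg.solve_triangular(Ru, W) * scale
    y_weights = linalg.solve_triangular(Rv, Zt.T) * scale
    return [CCAMode(index=k, r=float(s[k]),
                    x_weights=x_weights[:, k], y_weights=y_weights[:, k],
                    x_scores=x_scores[:, k], y_scores=y_scores[:, k])
            for k in range(len(s))]


def canonical_strengths(X, score: np.ndarray) -> np.ndarray:
    """Per-feature Pearson correlation with a canonical score.

    Zero-variance features get NaN (flagged via log) rather than raising.
    """
    values = np.asarray(X, float)
    score = np.asarray(score, float)
    if values.shape[0] != len(score):
        raise ValueError("feature block and score lengths differ")
    Xc = values - values.mean(axis=0)
    sc = score - score.mean()
    denom = np.linalg.norm(Xc, axis=0) * np.linalg.norm(sc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ sc) / denom
    n_bad = int(np.sum(denom == 0))
    if n_bad:
        logger.info("canonical_strengths: %d zero-variance features "
                    "flagged as NaN", n_bad)
    return r


def orient_mode(mode: CCAMode, strengths: np.ndarray,
                reference: np.ndarray | None = None) -> CCAMode:
    """Fix the arbitrary CCA sign against a reference vector.

    Flips both score vectors (and weights) jointly so that the inner
    product of the canonical connection strengths with ``reference`` is
    >= 0.  The default reference is a vector of -1s, i.e. the mode is
    oriented so the mean connection strength is non-positive (high
    scores <-> reduced average connectivity).  An exactly zero inner
    product leaves the mode unflipped (logged).  Idempotent.
    """
    strengths = np.asarray(strengths, float)
    if reference is None:
        reference = -np.ones_like(strengths)
    reference = np.asarray(reference, float)
    if reference.shape != strengths.shape:
        raise ValueError("reference does not align with strengths")
    valid = np.isfinite(strengths)
    inner = float(strengths[valid] @ reference[valid])
    if inner == 0.0:
        logger.info("orient_mode: zero inner product, no flip applied")
        return mode
    return mode.flip() if inner < 0 else mode


def variance_explained(X, score: np.ndarray) -> tuple[float, int]:
    """Proportion of (standardized) feature variance a canonical score
    explains: the mean over features of the squared Pearson correlation
    between feature and score.  Zero-variance features are excluded from
    the mean; their count is returned alongside."""
    r = canonical_strengths(X, score)
    valid = np.isfinite(r)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("variance_explained: excluded %d zero-variance "
                    "features", n_excluded)
    if not valid.any():
        raise ValueError("no feature with nonzero variance")
    return float(np.mean(r[valid] ** 2)), n_excluded


def variance_explained_summary(observed: float,
                               null_values: np.ndarray) -> VarianceExplained:
    null_mean = float(np.mean(null_values))
    if null_mean == 0:
        raise ValueError("null variance-explained mean is zero")
    return VarianceExplained(observed=observed, null_mean=null_mean,
                             ratio=observed / null_mean)
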