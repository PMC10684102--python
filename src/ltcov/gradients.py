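"""Gradient embedding of covariance matrices and discrete clustering.

The continuous route sparsifies each row of a similarity matrix, builds a
normalized-angle affinity between the sparsified rows, and extracts
principal axes (PCA by default; diffusion maps and Laplacian eigenmaps as
alternatives). The discrete route clusters laminar profiles with k-means
and picks k at the elbow of the distortion curve.

Both are exposed as scikit-learn style estimators (`GradientEmbedding`,
`ElbowKMeans`) so they compose with sklearn pipelines; module-level
functions wrap them for one-shot use.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "sparsify_rows",
    "normalized_angle_affinity",
    "compute_gradients",
    "kmeans_elbow",
    "GradientEmbedding",
    "ElbowKMeans",
]


def sparsify_rows(matrix: np.ndarray, p: float = 0.9) -> np.ndarray:
    """Keep the ceil((1-p)(P-1)) largest off-diagonal values of each row.

    All other entries (including the diagonal) are zeroed; ties are broken
    by keeping the lower column index, so the result is deterministic. The
    output is generally asymmetric.
    """
    if not 0 <= p < 1:
        raise ValueError("sparsity p must be in [0, 1)")
    m = np.array(matrix, dtype=float)
    P = m.shape[0]
    np.fill_diagonal(m, np.nan)
    keep = int(np.ceil((1 - p) * (P - 1)))
    out = np.zeros_like(m)
    for i in range(P):
        row = m[i]
        finite = np.flatnonzero(np.isfinite(row))
        # sort by (-value, column index): ties keep the lower column
        order = finite[np.lexsort((finite, -row[finite]))]
        top = order[:keep]
        out[i, top] = row[top]
    return out


def normalized_angle_affinity(sparsified: np.ndarray) -> np.ndarray:
    """Affinity(i, j) = 1 - arccos(cosine(row_i, row_j)) / pi.

    1 for parallel rows, 0.5 for orthogonal, 0 for anti-parallel; the
    diagonal is exactly 1.
    """
    m = np.asarray(sparsified, dtype=float)
    norms = np.linalg.norm(m, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"all-zero sparsified row(s) at parcel(s) {zero.tolist()}")
    cos = np.clip((m @ m.T) / np.outer(norms, norms), -1.0, 1.0)
    # snap to +/-1: arccos loses half its digits near the poles, and exactly
    # (anti)parallel rows must map to exactly 1 (0)
    cos[cos > 1.0 - 1e-12] = 1.0
    cos[cos < -1.0 + 1e-12] = -1.0
    aff = 1.0 - np.arccos(cos) / np.pi
    np.fill_diagonal(aff, 1.0)
    return 0.5 * (aff + aff.T)


def _pca_embedding(affinity: np.ndarray, n_components: int):
    X = affinity - affinity.mean(axis=0, keepdims=True)  # column-center
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    ratio = var / var.sum()
    loadings = U[:, :n_components] * s[:n_components]
    return loadings, ratio[:n_components]


def _diffusion_embedding(affinity: np.ndarray, n_components: int, alpha: float = 0.5):
    W = np.asarray(affinity, dtype=float)
    d = W.sum(axis=1)
    W1 = W / np.outer(d**alpha, d**alpha)
    d1 = W1.sum(axis=1)
    # symmetric conjugate of the row-stochastic operator
    S = W1 / np.sqrt(np.outer(d1, d1))
    evals, evecs = eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(d1)[:, None]
    # skip the trivial constant eigenvector
    lam = evals[1 : n_components + 1]
    loadings = psi[:, 1 : n_components + 1] * lam[None, :]
    var = np.abs(lam)
    return loadings, var / np.abs(evals[1:]).sum()


def _laplacian_embedding(affinity: np.ndarray, n_components: int):
    W = np.asarray(affinity, dtype=float)
    d = W.sum(axis=1)
    L = np.eye(len(W)) - W / np.sqrt(np.outer(d, d))
    evals, evecs = eigh(L)
    lam = evals[1 : n_components + 1]
    loadings = evecs[:, 1 : n_components + 1] / np.sqrt(d)[:, None]
    inv = 1.0 / np.maximum(evals[1:], 1e-12)
    return loadings, (1.0 / np.maximum(lam, 1e-12)) / inv.sum()


class GradientEmbedding(BaseEstimator, TransformerMixin):
    """Principal-axis embedding of a parcel similarity matrix.

    Parameters
    ----------
    n_components : int
        Number of axes to retain.
    sparsity : float
        Row sparsification level p in [0, 1); the p lowest-ranking entries
        of each row are zeroed before the affinity kernel.
    kernel : {"normalized_angle", "none"}
        Affinity between sparsified rows.
    method : {"pca", "diffusion_map", "laplacian_eigenmap"}
        Decomposition applied to the affinity.
    reference : array, optional
        Per-parcel reference map; each component is sign-flipped to
        correlate positively with it (flips recorded in ``sign_flips_``).

    Attributes
    ----------
    gradients_ : (P, n_components) loadings over included parcels (NaN rows
        for parcels undefined in the input matrix).
    explained_variance_ratio_ : per-component variance fractions.
    affinity_ : the affinity matrix the decomposition ran on.
    """

    def __init__(self, n_components: int = 10, sparsity: float = 0.9,
                 kernel: str = "normalized_angle", method: str = "pca",
                 reference=None):
        self.n_components = n_components
        self.sparsity = sparsity
        self.kernel = kernel
        self.method = method
        self.reference = reference

    def fit(self, X, y=None):
        X = np.asarray(getattr(X, "values", X), dtype=float)
        P = X.shape[0]
        off = ~np.eye(P, dtype=bool)
        # a parcel is defined if it has any defined off-diagonal entry; the
        # submatrix over defined parcels must then be fully defined
        row_ok = np.array([np.isfinite(X[i, off[i]]).any() for i in range(P)])
        idx = np.flatnonzero(row_ok)
        sub_off = ~np.eye(len(idx), dtype=bool)
        if not np.isfinite(X[np.ix_(idx, idx)][sub_off]).all():
            raise ValueError("undefined entries among defined parcels")
        if self.n_components > len(idx):
            raise ValueError("n_components exceeds the number of defined parcels")
        sub = X[np.ix_(idx, idx)]

        sparsified = sparsify_rows(sub, self.sparsity)
        if self.kernel == "normalized_angle":
            affinity = normalized_angle_affinity(sparsified)
        elif self.kernel == "none":
            affinity = np.where(np.isfinite(sub), sub, 0.0)
        else:
            raise ValueError(f"unknown kernel {self.kernel!r}")

        if self.method == "pca":
            loadings, ratio = _pca_embedding(affinity, self.n_components)
        elif self.method == "diffusion_map":
            loadings, ratio = _diffusion_embedding(affinity, self.n_components)
        elif self.method == "laplacian_eigenmap":
            loadings, ratio = _laplacian_embedding(affinity, self.n_components)
        else:
            raise ValueError(f"unknown method {self.method!r}")

        flips = np.zeros(self.n_components, dtype=bool)
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)[idx]
            ok = np.isfinite(ref)
            for c in range(loadings.shape[1]):
                r = np.corrcoef(loadings[ok, c], ref[ok])[0, 1]
                if r < 0:
                    loadings[:, c] *= -1
                    flips[c] = True

        full = np.full((P, self.n_components), np.nan)
        full[idx] = loadings
        self.gradients_ = full
        self.explained_variance_ratio_ = ratio
        self.affinity_ = affinity
        self.included_ = idx
        self.sign_flips_ = flips
        return self

    def transform(self, X=None):
        check_is_fitted(self, "gradients_")
        return self.gradients_


class ElbowKMeans(BaseEstimator):
    """K-means over a range of k with elbow selection on the distortion curve.

    Distortion is the mean within-cluster sum of squared distances; the
    chosen k maximizes the distance of the (k, distortion) point to the
    chord joining the curve's endpoints (computed on min-max normalized
    axes, so the rule is scale-free).
    """

    def __init__(self, k_candidates=tuple(range(2, 11)), n_init: int = 10,
                 random_state: int = 0):
        self.k_candidates = k_candidates
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("profiles contain non-finite values")
        ks = list(self.k_candidates)
        if X.shape[0] <= max(ks):
            raise ValueError("need more samples than the largest candidate k")
        distortions = []
        labels_by_k = {}
        for k in ks:
            km = KMeans(n_clusters=k, n_init=self.n_init,
                        random_state=self.random_state).fit(X)
            distortions.append(km.inertia_ / X.shape[0])
            labels_by_k[k] = km.labels_
        distortions = np.asarray(distortions)

        kk = np.asarray(ks, dtype=float)
        kn = (kk - kk[0]) / (kk[-1] - kk[0])
        span = distortions[0] - distortions[-1]
        dn = (distortions - distortions[-1]) / (span if span > 0 else 1.0)
        # distance to the chord from (0, dn[0]) to (1, dn[-1])
        chord = dn[0] + (dn[-1] - dn[0]) * kn
        dist = (chord - dn) / np.sqrt(1 + (dn[-1] - dn[0]) ** 2)
        chosen = ks[int(np.argmax(dist))]

        self.distortions_ = distortions
        self.k_candidates_ = np.asarray(ks)
        self.chosen_k_ = int(chosen)
        self.labels_ = labels_by_k[chosen]
        self.labels_by_k_ = labels_by_k
        return self


def compute_gradients(matrix, n_components: int = 10, sparsity: float = 0.9,
                      method: str = "pca", reference=None) -> GradientEmbedding:
    """One-shot gradient embedding; returns the fitted estimator."""
    return GradientEmbedding(n_components=n_components, sparsity=sparsity,
                             method=method, reference=reference).fit(matrix)


def kmeans_elbow(profiles, k_candidates=tuple(range(2, 11)), seed: int = 0) -> ElbowKMeans:
    """One-shot elbow k-means; returns the fitted estimator."""
    return ElbowKMeans(k_candidates=k_candidates, random_state=seed).fit(profiles)
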