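"""Phylogenetically corrected spatial autocorrelation.

The trait is first residualised on the leading eigenvectors of the
double-centred patristic distance matrix (phylogenetic eigenvector
regression), absorbing phylogenetic structure; Moran's I of those
residuals under inverse-distance weights then measures purely spatial
clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tree import Phylogeny

__all__ = [
    "EigenvectorBasis",
    "SpatialWeights",
    "MoranResult",
    "phylo_eigenvectors",
    "residualize",
    "inverse_distance_weights",
    "morans_i",
]


@dataclass
class EigenvectorBasis:
    vectors: np.ndarray      # (n, k), unit columns
    eigenvalues: np.ndarray  # (k,), descending


@dataclass
class SpatialWeights:
    w: np.ndarray
    n_coincident: int = 0

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        self.w = w


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p: float

    def as_dict(self):
        return {"I": self.I, "expected": self.expected,
                "variance": self.variance, "z": self.z, "p": self.p}


def phylo_eigenvectors(tree: Phylogeny, k: int = 10) -> EigenvectorBasis:
    """Top-k eigenvectors of the PCoA-style transform of patristic distances.

    The distance matrix D is squared elementwise, double-centred as
    ``B = -1/2 * J (D o D) J`` with ``J = I - 11'/n``, and eigendecomposed;
    columns are the k eigenvectors with largest eigenvalues.
    """
    n = tree.n_tips
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, n-1], got {k} for n={n}")
    D = tree.patristic_matrix()
    B = -0.5 * (D ** 2)
    B = B - B.mean(axis=0, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:k]
    return EigenvectorBasis(vectors=evecs[:, order], eigenvalues=evals[order])


def residualize(y, basis: EigenvectorBasis) -> np.ndarray:
    """OLS residuals of y on [1 | eigenvectors]; rank-deficient columns are
    dropped with a warning.  Residuals sum to zero."""
    y = np.asarray(y, dtype=float)
    V = basis.vectors
    if len(y) != V.shape[0]:
        raise ValueError("response and basis are not aligned")
    X = np.column_stack([np.ones(len(y)), V])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient eigenvector basis; dropping columns")
        q, r, piv = _qr_pivot(X)
        X = X[:, piv[:rank]]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def _qr_pivot(X):
    from scipy.linalg import qr

    q, r, piv = qr(X, pivoting=True, mode="economic")
    return q, r, piv


def inverse_distance_weights(distances: np.ndarray) -> SpatialWeights:
    """w_ij = 1 / d_ij with a zero diagonal.

    Coincident pairs (d_ij = 0, i != j) receive the maximum finite weight in
    the matrix so that nearest pairs stay heaviest without infinities; the
    count of such pairs is recorded.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    off = ~np.eye(d.shape[0], dtype=bool)
    zero_off = off & (d == 0.0)
    n_coincident = int(zero_off.sum() // 2)
    with np.errstate(divide="ignore"):
        w = np.where(off & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    if n_coincident:
        w[zero_off] = w.max()
        warnings.warn(f"{n_coincident} coincident pair(s) assigned the "
                      "maximum finite weight")
    np.fill_diagonal(w, 0.0)
    return SpatialWeights(w=w, n_coincident=n_coincident)


def morans_i(z, weights: SpatialWeights, row_standardize: bool = False,
             assumption: str = "normality") -> MoranResult:
    """Global Moran's I with closed-form null moments.

    ``I = (n / S0) * sum_ij w_ij (z_i - zbar)(z_j - zbar) / sum_i (z_i - zbar)^2``;
    E[I] = -1/(n-1); the variance uses the standard S0/S1/S2 closed form
    (valid for asymmetric weights) under either the ``normality`` or the
    ``randomization`` (kurtosis-corrected) assumption, and the two-sided p
    comes from the normal approximation.  ``row_standardize`` divides each
    row by its sum first, the convention of several spatial packages.
    """
    if assumption not in ("normality", "randomization"):
        raise ValueError("assumption must be 'normality' or 'randomization'")
    z = np.asarray(z, dtype=float)
    w = weights.w
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        if np.any(rs == 0):
            raise ValueError("cannot row-standardize: a row sums to zero")
        w = w / rs
    n = len(z)
    if w.shape != (n, n):
        raise ValueError("weights do not match the data length")
    if n < 2:
        raise ValueError("need at least 2 observations")
    dev = z - z.mean()
    denom = float(dev @ dev)
    if denom == 0:
        raise ValueError("zero variance in the variable")
    S0 = float(w.sum())
    if S0 == 0:
        raise ValueError("all spatial weights are zero")
    num = float(dev @ w @ dev)
    I = (n / S0) * (num / denom)
    expected = -1.0 / (n - 1)
    if n < 3:
        return MoranResult(I=float(I), expected=expected, variance=np.nan,
                           z=np.nan, p=np.nan)
    S1 = 0.5 * float(((w + w.T) ** 2).sum())
    S2 = float(((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum())
    if assumption == "normality":
        var = ((n * n * S1 - n * S2 + 3.0 * S0 * S0)
               / (S0 * S0 * (n * n - 1.0))) - expected ** 2
    else:
        b2 = n * float((dev ** 4).sum()) / denom ** 2
        var = ((n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3.0 * S0 * S0)
                - b2 * ((n * n - n) * S1 - 2.0 * n * S2 + 6.0 * S0 * S0))
               / ((n - 1.0) * (n - 2.0) * (n - 3.0) * S0 * S0)) - expected ** 2
    from scipy import stats

    zscore = (I - expected) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(I=float(I), expected=expected, variance=float(var),
                       z=float(zscore), p=float(p))
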