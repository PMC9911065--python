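"""Genetic covariance tensor analysis across a set of matrices.

A set of m covariance matrices (here: two mutational matrices and one
standing-variation matrix, on a common phenotypic scale) is compared by
treating each n x n symmetric matrix as a point in the s = n(n+1)/2
dimensional space of its distinct elements.  The isometric
vectorization (diagonal elements as-is, each off-diagonal once times
sqrt(2)) makes Euclidean inner products equal Frobenius inner products.
The covariance matrix S of the vectorized matrices across the set is
eigen-decomposed; its eigenvectors map back to symmetric matrices — the
eigentensors E_1, E_2, ... — which are orthogonal "directions" of
variation among covariance matrices, with at most m - 1 carrying
variance.  Each eigentensor is itself spectrally decomposed into trait
axes (e11 = first eigenvector of E_1, the single phenotypic direction
explaining most of the differentiation).  Each matrix's coordinate in
E_i is its Frobenius inner product with E_i, and the sample variance of
coordinates in E_i equals the eigenvalue alpha_i.

Uncertainty attaches in two ways: permutation-null matrix sets run
through the identical analysis to give null alpha bands, and posterior
draws of the member matrices are projected onto the fixed observed
eigentensors to give credible intervals for alphas and coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .compare import EigenSummary, eigen_summary, equal_tailed_interval

_SQRT2 = np.sqrt(2.0)


@dataclass
class MatrixSet:
    """Labelled covariance matrices with optional posterior samples."""

    matrices: dict[str, np.ndarray]
    posteriors: Optional[dict[str, np.ndarray]] = None  # label -> (k, n, n)
    trait_labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if len(self.matrices) < 2:
            raise ValueError("a matrix set needs at least two matrices")
        dims = {m.shape for m in self.matrices.values()}
        if len(dims) != 1:
            raise ValueError("all matrices must share one dimension")

    @property
    def labels(self) -> list[str]:
        return list(self.matrices)

    @property
    def dim(self) -> int:
        return next(iter(self.matrices.values())).shape[0]

    def stacked(self) -> np.ndarray:
        return np.stack([self.matrices[k] for k in self.labels])


def vectorize(G: np.ndarray) -> np.ndarray:
    """Isometric half-vectorization of a symmetric matrix.

    Diagonal elements first (trait order), then the upper-triangle
    off-diagonals in row-major order, each multiplied by sqrt(2) so that
    vec(A) . vec(B) equals the Frobenius inner product sum_ij A_ij B_ij.
    """
    G = np.asarray(G, float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(G, G.T, atol=1e-10 * max(1.0, np.abs(G).max())):
        raise ValueError("matrix must be symmetric")
    n = G.shape[0]
    iu = np.triu_indices(n, k=1)
    return np.concatenate([np.diag(G), _SQRT2 * G[iu]])


def matricize(v: np.ndarray, n: Optional[int] = None) -> np.ndarray:
    """Inverse of :func:`vectorize` (bit-exact round trip)."""
    v = np.asarray(v, float)
    if n is None:
        n = int(round((np.sqrt(8 * v.size + 1) - 1) / 2))
    if n * (n + 1) // 2 != v.size:
        raise ValueError("vector length is not a triangular number")
    G = np.diag(v[:n]).astype(float)
    iu = np.triu_indices(n, k=1)
    off = v[n:] / _SQRT2
    G[iu] = off
    G[(iu[1], iu[0])] = off
    return G


def build_S(matrix_set: MatrixSet) -> np.ndarray:
    """Covariance of matrix elements across the set (divisor m - 1)."""
    vecs = np.stack([vectorize(m) for m in matrix_set.stacked()])
    if vecs.shape[0] < 2:
        raise ValueError("need at least two matrices")
    return np.atleast_2d(np.cov(vecs, rowvar=False, ddof=1))


@dataclass
class TensorDecomposition:
    """Eigentensor decomposition of the element-covariance matrix S."""

    S: np.ndarray
    alphas: np.ndarray  # descending eigenvalues of S
    eigentensors: np.ndarray  # (s, n, n) symmetric, unit Frobenius norm
    eigentensor_eigen: list[EigenSummary]  # spectral decomposition of each E_i
    dim: int

    @property
    def alpha_proportions(self) -> np.ndarray:
        """Each alpha as a proportion of the total (sums to 1)."""
        tot = self.alphas.sum()
        return self.alphas / tot if tot > 0 else np.zeros_like(self.alphas)

    def e_vector(self, i: int, j: int) -> np.ndarray:
        """j-th eigenvector of the i-th eigentensor (0-based; e11 = (0, 0))."""
        return self.eigentensor_eigen[i].eigenvectors[:, j]


def eigentensor_decomposition(S: np.ndarray, tol: float = 1e-8) -> TensorDecomposition:
    """Eigen-decompose S and map eigenvectors back to eigentensors.

    S must be symmetric PSD within tolerance; at most m - 1 eigenvalues
    are nonzero when S came from m matrices.  Every eigentensor has unit
    Frobenius norm because the vectorization is an isometry.
    """
    S = np.asarray(S, float)
    summ = eigen_summary(S)
    scale = max(1.0, float(np.abs(summ.eigenvalues).max()))
    if summ.eigenvalues.min() < -tol * scale:
        raise ValueError("S is not positive semi-definite within tolerance")
    alphas = np.clip(summ.eigenvalues, 0.0, None)
    n = int(round((np.sqrt(8 * S.shape[0] + 1) - 1) / 2))
    tensors = np.stack([matricize(summ.eigenvectors[:, k], n) for k in range(S.shape[0])])
    decomps = [eigen_summary(E) for E in tensors]
    return TensorDecomposition(
        S=S,
        alphas=alphas,
        eigentensors=tensors,
        eigentensor_eigen=decomps,
        dim=n,
    )


def coordinates(
    matrix_set: MatrixSet, decomposition: TensorDecomposition
) -> np.ndarray:
    """Frobenius coordinates of each matrix in each eigentensor.

    Rows follow the set's label order, columns the eigentensors.  The
    sample variance of column i across the set equals alpha_i.
    """
    if matrix_set.dim != decomposition.dim:
        raise ValueError("matrix set and decomposition dimensions differ")
    vecs = np.stack([vectorize(m) for m in matrix_set.stacked()])
    E_vecs = np.stack([vectorize(E) for E in decomposition.eigentensors])
    return vecs @ E_vecs.T


def tensor_analysis(matrix_set: MatrixSet) -> tuple[TensorDecomposition, np.ndarray]:
    """Convenience: build S, decompose, and return coordinates."""
    dec = eigentensor_decomposition(build_S(matrix_set))
    return dec, coordinates(matrix_set, dec)


def tensor_null(
    null_sets: Sequence[Mapping[str, np.ndarray] | np.ndarray],
    observed: TensorDecomposition,
) -> dict[str, np.ndarray]:
    """Null alpha distributions from randomized matrix sets.

    Each element of ``null_sets`` is one replicate set of matrices (same
    shape as the observed set); the full tensor analysis runs per
    replicate.  Returns the null alpha samples and their 95% bands.
    """
    alphas = []
    for rep in null_sets:
        mats = rep if isinstance(rep, Mapping) else {str(i): m for i, m in enumerate(rep)}
        dec, _ = tensor_analysis(MatrixSet(matrices=dict(mats)))
        alphas.append(dec.alphas)
    alphas = np.stack(alphas)
    bands = np.array(
        [equal_tailed_interval(alphas[:, k], 0.95) for k in range(alphas.shape[1])]
    )
    return {"null_alphas": alphas, "band95": bands}


def tensor_posterior(
    matrix_set: MatrixSet,
    decomposition: TensorDecomposition,
    levels: tuple[float, ...] = (0.83, 0.95),
) -> dict:
    """Credible intervals for alphas and coordinates from posterior draws.

    Eigentensors stay fixed at the point-estimate decomposition; for each
    posterior draw the drawn matrices are projected onto them, yielding a
    coordinate sample per matrix per eigentensor and, per draw, an
    alpha analogue (the across-matrix sample variance of coordinates).
    """
    if matrix_set.posteriors is None:
        raise ValueError("matrix set carries no posterior samples")
    missing = set(matrix_set.labels) - set(matrix_set.posteriors)
    if missing:
        raise ValueError(f"posterior samples missing for: {sorted(missing)}")
    n_draws = min(matrix_set.posteriors[k].shape[0] for k in matrix_set.labels)
    E_vecs = np.stack([vectorize(E) for E in decomposition.eigentensors])
    coord_draws = np.empty((n_draws, len(matrix_set.labels), E_vecs.shape[0]))
    for j, lab in enumerate(matrix_set.labels):
        draws = matrix_set.posteriors[lab][:n_draws]
        vecs = np.stack([vectorize(m) for m in draws])
        coord_draws[:, j, :] = vecs @ E_vecs.T
    alpha_draws = coord_draws.var(axis=1, ddof=1)  # (n_draws, s)
    out = {"coordinate_draws": coord_draws, "alpha_draws": alpha_draws}
    for lev in levels:
        key = f"ci{int(round(lev * 100))}"
        out[f"alpha_{key}"] = np.array(
            [equal_tailed_interval(alpha_draws[:, k], lev) for k in range(alpha_draws.shape[1])]
        )
        out[f"coordinate_{key}"] = np.array(
            [
                [
                    equal_tailed_interval(coord_draws[:, j, k], lev)
                    for k in range(coord_draws.shape[2])
                ]
                for j in range(coord_draws.shape[1])
            ]
        )
    return out
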