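"""Eigenanalysis and pairwise comparison of genetic covariance matrices.

The leading eigenvector of a mutational or standing covariance matrix
(m_max / g_max) is the phenotypic direction carrying the most genetic
variance.  Two matrices are compared through

* the folded angle between their leading eigenvectors (0-90 degrees;
  eigenvector sign is arbitrary, so angles above 90 are reflected),
  with a Monte-Carlo null from pairs of vectors drawn coordinate-wise
  uniform on (-1, 1);
* the projection statistic Pi = v' M v / (|v|^2 * lambda_max), the
  fraction of the matrix's maximal variance found along the other
  matrix's leading axis, with null expectation Pi0 = mean(lambda) /
  lambda_max;
* rotation of permutation-null matrices onto the observed eigenvectors,
  giving a per-eigentrait null band for the observed eigenvalues;
* the credible-interval overlap rule: two posterior distributions are
  declared different when their equal-tailed 83% intervals are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

_SYM_TOL = 1e-10
_TIE_TOL = 1e-8


@dataclass
class EigenSummary:
    """Descending spectral decomposition of a symmetric matrix."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, orthonormal, sign-fixed
    #: True when lambda1 - lambda2 < 1e-8 and mmax is ill-defined
    leading_tie: bool = False

    @property
    def mmax(self) -> np.ndarray:
        """Leading eigenvector (direction of maximal variance)."""
        return self.eigenvectors[:, 0]

    @property
    def lambda_max(self) -> float:
        return float(self.eigenvalues[0])


def eigen_summary(M: np.ndarray) -> EigenSummary:
    """Full spectral decomposition with descending eigenvalues.

    Eigenvector sign is fixed by making each vector's largest-magnitude
    coordinate positive, so reported directions are reproducible.
    """
    M = np.asarray(M, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, atol=_SYM_TOL * max(1.0, np.abs(M).max())):
        raise ValueError("matrix must be symmetric")
    w, v = np.linalg.eigh((M + M.T) / 2)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    for k in range(v.shape[1]):
        i = np.argmax(np.abs(v[:, k]))
        if v[i, k] < 0:
            v[:, k] = -v[:, k]
    tie = bool(w.size > 1 and (w[0] - w[1]) < _TIE_TOL)
    return EigenSummary(eigenvalues=w, eigenvectors=v, leading_tie=tie)


def angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Folded angle between two directions, in degrees within [0, 90]."""
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("angle undefined for a zero vector")
    c = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    theta = np.degrees(np.arccos(c))
    return float(180.0 - theta if theta > 90.0 else theta)


@dataclass
class NullAngles:
    """Monte-Carlo null for the folded angle between random directions."""

    samples: np.ndarray
    mean: float
    ci95: tuple[float, float]
    ci83: tuple[float, float]


def null_angle_samples(
    dim: int, n_pairs: int, rng: np.random.Generator
) -> NullAngles:
    """Folded angles between pairs of vectors uniform on (-1, 1)^dim.

    In dimension 2 the mean folded angle is exactly 45 degrees by the
    four-fold symmetry of the square; in higher dimensions it increases
    towards 90.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    a = rng.uniform(-1.0, 1.0, size=(n_pairs, dim))
    b = rng.uniform(-1.0, 1.0, size=(n_pairs, dim))
    dots = np.einsum("ij,ij->i", a, b)
    norms = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    theta = np.degrees(np.arccos(np.clip(dots / norms, -1.0, 1.0)))
    theta = np.where(theta > 90.0, 180.0 - theta, theta)
    return NullAngles(
        samples=theta,
        mean=float(theta.mean()),
        ci95=equal_tailed_interval(theta, 0.95),
        ci83=equal_tailed_interval(theta, 0.83),
    )


def project_variance(M: np.ndarray, v: np.ndarray) -> float:
    """Variance of M along direction v (Rayleigh quotient v'Mv/|v|^2)."""
    v = np.asarray(v, float)
    nv2 = float(v @ v)
    if nv2 == 0:
        raise ValueError("projection direction must be nonzero")
    return float(v @ np.asarray(M, float) @ v / nv2)


def pi_statistic(Mx: np.ndarray, y_mmax: np.ndarray) -> float:
    """Pi: variance along the other matrix's leading axis, as a fraction
    of this matrix's own maximal eigenvalue.  1 means aligned."""
    summ = eigen_summary(Mx)
    if summ.lambda_max <= 0:
        raise ValueError("Pi undefined: matrix has no positive variance")
    return project_variance(Mx, y_mmax) / summ.lambda_max


def pi_null(Mx: np.ndarray) -> float:
    """Null expectation Pi0 = mean eigenvalue / max eigenvalue."""
    summ = eigen_summary(Mx)
    if summ.lambda_max <= 0:
        raise ValueError("Pi0 undefined: matrix has no positive variance")
    return float(summ.eigenvalues.mean() / summ.lambda_max)


def equal_tailed_interval(samples: np.ndarray, level: float) -> tuple[float, float]:
    """Equal-tailed sample-quantile interval at the given level."""
    samples = np.asarray(samples, float)
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [tail, 1.0 - tail])
    return float(lo), float(hi)


@dataclass
class PiPosterior:
    """Posterior samples of Pi and Pi0 with 83% / 95% intervals."""

    pi_samples: np.ndarray
    pi0_samples: np.ndarray
    pi_ci83: tuple[float, float]
    pi_ci95: tuple[float, float]
    pi0_ci83: tuple[float, float]
    pi0_ci95: tuple[float, float]


def pi_posterior(
    posterior: np.ndarray,
    y_mmax: np.ndarray,
    n_draws: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PiPosterior:
    """Pi and Pi0 over posterior draws of a covariance matrix.

    ``posterior`` has shape (n_samples, d, d).  If ``n_draws`` is given,
    that many draws are resampled (with replacement) from the posterior.
    """
    posterior = np.asarray(posterior, float)
    if posterior.ndim != 3 or posterior.shape[0] < 2:
        raise ValueError("need at least two posterior samples")
    if n_draws is not None:
        rng = np.random.default_rng() if rng is None else rng
        idx = rng.integers(posterior.shape[0], size=n_draws)
        posterior = posterior[idx]
    pis = np.array([pi_statistic(m, y_mmax) for m in posterior])
    pi0s = np.array([pi_null(m) for m in posterior])
    return PiPosterior(
        pi_samples=pis,
        pi0_samples=pi0s,
        pi_ci83=equal_tailed_interval(pis, 0.83),
        pi_ci95=equal_tailed_interval(pis, 0.95),
        pi0_ci83=equal_tailed_interval(pi0s, 0.83),
        pi0_ci95=equal_tailed_interval(pi0s, 0.95),
    )


def rotate_null_eigenvalues(
    null_matrices: np.ndarray, observed: EigenSummary
) -> dict[str, np.ndarray]:
    """Rotate null matrices onto the observed eigentraits.

    For each null matrix N and observed eigenvector v_k the null
    eigenvalue analogue is v_k' N v_k.  Returns the per-eigentrait null
    samples and their equal-tailed 95% bands.
    """
    null_matrices = np.asarray(null_matrices, float)
    d = observed.eigenvectors.shape[0]
    if null_matrices.ndim != 3 or null_matrices.shape[1:] != (d, d):
        raise ValueError("null matrices do not match the observed dimension")
    V = observed.eigenvectors
    vals = np.einsum("ik,nij,jk->nk", V, null_matrices, V)
    bands = np.array(
        [equal_tailed_interval(vals[:, k], 0.95) for k in range(d)]
    )
    return {"null_samples": vals, "band95": bands}


def ci_compare(
    samples_a: np.ndarray, samples_b: np.ndarray, level: float = 0.83
) -> dict:
    """Overlap verdict between two posterior sample sets.

    The two are declared "different" exactly when their equal-tailed
    intervals at ``level`` are disjoint.
    """
    if level not in (0.83, 0.95):
        raise ValueError("level must be 0.83 or 0.95")
    samples_a = np.asarray(samples_a, float)
    samples_b = np.asarray(samples_b, float)
    if samples_a.size < 2 or samples_b.size < 2:
        raise ValueError("need at least two samples per set")
    ia = equal_tailed_interval(samples_a, level)
    ib = equal_tailed_interval(samples_b, level)
    different = ia[1] < ib[0] or ib[1] < ia[0]
    return {"interval_a": ia, "interval_b": ib, "level": level, "different": bool(different)}
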