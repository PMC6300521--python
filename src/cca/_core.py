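"""Array-level maxvar kernels shared by the estimation and simulation layers.

Everything here works on bare ndarrays and pre-computed block slices so the
Monte Carlo loops avoid per-call validation and labeling overhead.  The
labeled public API lives in :mod:`cca.estimation`.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg

from .errors import ConditioningError, DegenerateBlockError

EIG_TIE_TOL = 1e-9


def standardize_inplace_copy(x: np.ndarray) -> np.ndarray:
    """Column-standardize (mean 0, variance 1 with the 1/N denominator)."""
    x = x - x.mean(axis=0)
    sd = np.sqrt((x * x).mean(axis=0))
    if np.any(sd <= 0):
        bad = int(np.argmin(sd))
        raise DegenerateBlockError(f"column {bad} has zero variance")
    return x / sd


def corr_from_standardized(x: np.ndarray) -> np.ndarray:
    """Sample correlation matrix X'X / N of standardized data."""
    n = x.shape[0]
    return (x.T @ x) / n


def matrix_sqrt(m: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Symmetric (spectral) PD square root."""
    vals, vecs = np.linalg.eigh(m)
    if vals[0] <= rtol * max(vals[-1], 0.0):
        raise ConditioningError(
            f"matrix is not positive-definite: smallest eigenvalue {vals[0]:.3e} "
            f"(largest {vals[-1]:.3e})"
        )
    return (vecs * np.sqrt(vals)) @ vecs.T


def matrix_inverse_sqrt(m: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Symmetric PD inverse square root R with R @ m @ R = I."""
    vals, vecs = np.linalg.eigh(m)
    if vals[0] <= rtol * max(vals[-1], 0.0):
        raise ConditioningError(
            f"matrix is not positive-definite: smallest eigenvalue {vals[0]:.3e} "
            f"(largest {vals[-1]:.3e})"
        )
    return (vecs / np.sqrt(vals)) @ vecs.T


def _fix_sign(w: np.ndarray) -> np.ndarray:
    # Eigenvectors are sign-indeterminate; make the largest-magnitude entry
    # positive (argmax takes the first index on ties).
    if w[int(np.argmax(np.abs(w)))] < 0:
        return -w
    return w


def maxvar_core(
    S: np.ndarray,
    slices: list[slice],
    warn_ties: bool = True,
) -> tuple[list[np.ndarray], np.ndarray, float, np.ndarray]:
    """Maxvar weights from a correlation matrix and unified block slices.

    Builds the block-diagonal ``Sigma_D`` of intra-block matrices, takes the
    leading eigenvector ``a`` of ``Sigma_D^{-1/2} S Sigma_D^{-1/2}``,
    partitions it into per-block subvectors ``a_j`` and returns

        ``w_j = Sigma_jj^{-1/2} a_j / sqrt(a_j' a_j)``,

    so every composite has unit sample variance.

    Returns ``(weights, leading_eigenvector, leading_eigenvalue, whitened)``.
    """
    K = S.shape[0]
    R = np.zeros((K, K))
    inv_roots = []
    for sl in slices:
        r = matrix_inverse_sqrt(S[sl, sl])
        inv_roots.append(r)
        R[sl, sl] = r
    whitened = R @ S @ R
    vals, vecs = np.linalg.eigh(whitened)
    if warn_ties and K >= 2 and vals[-1] - vals[-2] < EIG_TIE_TOL:
        top = np.abs(vals - vals[-1]) < EIG_TIE_TOL
        cand = vecs[:, top]
        # Deterministic tie-break: lexicographically largest |eigenvector|.
        order = sorted(range(cand.shape[1]), key=lambda i: tuple(-np.abs(cand[:, i])))
        a = cand[:, order[0]]
        warnings.warn(
            "maxvar leading eigenvalue is (numerically) multiple; weights chosen "
            "by a deterministic tie-break",
            RuntimeWarning,
            stacklevel=2,
        )
    else:
        a = vecs[:, -1]
    weights = []
    for sl, r in zip(slices, inv_roots):
        aj = a[sl]
        norm = np.sqrt(aj @ aj)
        if norm < 1e-12:
            raise DegenerateBlockError(
                f"block at columns {sl.start}:{sl.stop} receives a zero eigenvector "
                "subvector; the composite is isolated"
            )
        weights.append(_fix_sign(r @ aj / norm))
    return weights, a, float(vals[-1]), whitened


def block_corr_from_weights(
    S: np.ndarray, slices: list[slice], weights: list[np.ndarray]
) -> np.ndarray:
    """Composite correlation matrix: entry (j, l) = w_j' S_jl w_l."""
    B = len(slices)
    c = np.empty((B, B))
    for j in range(B):
        for l in range(j, B):
            c[j, l] = c[l, j] = weights[j] @ S[slices[j], slices[l]] @ weights[l]
    return c


def sigma_hat_from_fit(
    S: np.ndarray,
    slices: list[slice],
    weights: list[np.ndarray],
    block_corr: np.ndarray,
) -> np.ndarray:
    """Estimated model-implied matrix: sample diagonal blocks, rank-one rest."""
    K = S.shape[0]
    lambdas = [S[sl, sl] @ w for sl, w in zip(slices, weights)]
    sigma = np.empty((K, K))
    for j, sj in enumerate(slices):
        sigma[sj, sj] = S[sj, sj]
        for l in range(j + 1, len(slices)):
            sl = slices[l]
            off = block_corr[j, l] * np.outer(lambdas[j], lambdas[l])
            sigma[sj, sl] = off
            sigma[sl, sj] = off.T
    return sigma


def fit_sigma_hat(S: np.ndarray, slices: list[slice]) -> np.ndarray:
    """One-call estimation of Sigma-hat from a correlation matrix."""
    weights, _, _, _ = maxvar_core(S, slices, warn_ties=False)
    c = block_corr_from_weights(S, slices, weights)
    return sigma_hat_from_fit(S, slices, weights, c)


def distances(S: np.ndarray, sigma_hat: np.ndarray) -> tuple[float, float, float]:
    """(dL, dG, SRMR) between a sample matrix and a model-implied matrix."""
    K = S.shape[0]
    resid = S - sigma_hat
    d_l = 0.5 * float(np.sum(resid * resid))
    # Eigenvalues of S^{-1} Sigma-hat via the generalized symmetric problem.
    phi = scipy.linalg.eigh(sigma_hat, S, eigvals_only=True)
    if np.any(phi <= 0):
        raise ConditioningError(
            "geodesic distance undefined: S^{-1} Sigma-hat has a non-positive eigenvalue"
        )
    d_g = float(np.sqrt(0.5 * np.sum(np.log(phi) ** 2)))
    d = np.sqrt(np.diag(S))
    std_resid = resid / np.outer(d, d)
    tri = np.tril_indices(K)
    srmr = float(np.sqrt(2.0 * np.sum(std_resid[tri] ** 2) / (K * (K + 1))))
    return d_l, d_g, srmr


def bootstrap_pvalues(
    X: np.ndarray,
    slices: list[slice],
    B: int,
    rng: np.random.Generator,
    max_fail_frac: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Bollen–Stine bootstrap reference distributions for (dL, dG, SRMR).

    Returns ``(observed, reference, n_failed)`` where ``observed`` has shape
    (3,) and ``reference`` shape (B_ok, 3).  Raises if more than
    ``max_fail_frac`` of the resamples fail estimation.
    """
    n = X.shape[0]
    Xs = standardize_inplace_copy(X)
    S = corr_from_standardized(Xs)
    sigma_hat = fit_sigma_hat(S, slices)
    observed = np.array(distances(S, sigma_hat))
    # Transform so the sample matrix of Y equals Sigma-hat exactly.
    Y = Xs @ matrix_inverse_sqrt(S) @ matrix_sqrt(sigma_hat)
    ref = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            Zb = standardize_inplace_copy(Y[idx])
            Sb = corr_from_standardized(Zb)
            ref.append(distances(Sb, fit_sigma_hat(Sb, slices)))
        except (ConditioningError, DegenerateBlockError, np.linalg.LinAlgError):
            failed += 1
    if failed > max_fail_frac * B:
        from .errors import FitTestError

        raise FitTestError(
            f"{failed}/{B} bootstrap resamples failed estimation; the reference "
            "distribution is unreliable"
        )
    return observed, np.asarray(ref), failed
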