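"""Overall model-fit assessment for composite models.

Three discrepancy measures between the sample correlation matrix S and the
estimated model-implied matrix Sigma-hat:

* squared Euclidean distance  ``dL = 1/2 * sum_ij (s_ij - sigma_ij)^2``
* geodesic distance           ``dG = sqrt(1/2 * sum_i log(phi_i)^2)`` with
  ``phi_i`` the eigenvalues of ``S^{-1} Sigma-hat``
* SRMR, the root of the average squared standardized residual over the lower
  triangle including the diagonal.

All three are zero exactly when the fit is perfect.  The overall test draws
its reference distribution with the Bollen–Stine device: the data are rotated
by ``X S^{-1/2} Sigma-hat^{1/2}`` (symmetric spectral roots) so the
transformed sample satisfies the null hypothesis exactly, and bootstrap
resamples of the transformed rows are re-standardized and re-estimated.  The
p-value per measure is the plain proportion of bootstrap distances at least
as large as the observed one; the model is rejected at level alpha when
p < alpha, equivalently when the observed distance exceeds the empirical
(1 - alpha) reference quantile.

Fit indices: SRMR (again), the normed fit index NFI relative to a baseline
model of mutually uncorrelated indicators (geodesic discrepancy by default),
and RMS_theta, the root mean square of the *cross-block* residual
correlations (within-block residuals are unconstrained, hence excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from . import _core
from .errors import ConditioningError, SpecificationError
from .estimation import DataMatrix
from .model import CompositeModelSpec

MEASURES = ("dL", "dG", "srmr")

__all__ = [
    "FitMeasures",
    "FitTestResult",
    "FitIndices",
    "euclidean_distance",
    "geodesic_distance",
    "srmr",
    "bollen_stine_transform",
    "bootstrap_fit_test",
    "nfi",
    "rms_theta",
    "fit_indices",
    "MEASURES",
]


def _pair(S, sigma_hat) -> tuple[np.ndarray, np.ndarray]:
    S = np.asarray(S, dtype=float)
    sh = np.asarray(sigma_hat, dtype=float)
    if S.shape != sh.shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise SpecificationError(
            f"matrices must be square and of equal shape, got {S.shape} and {sh.shape}"
        )
    return S, sh


def euclidean_distance(S, sigma_hat) -> float:
    """Squared Euclidean distance over all K^2 entries, halved."""
    S, sh = _pair(S, sigma_hat)
    r = S - sh
    return 0.5 * float(np.sum(r * r))


def geodesic_distance(S, sigma_hat) -> float:
    """Geodesic distance via the eigenvalues of ``S^{-1} Sigma-hat``."""
    S, sh = _pair(S, sigma_hat)
    phi = scipy.linalg.eigh(sh, S, eigvals_only=True)
    if np.any(phi <= 0):
        raise ConditioningError(
            "geodesic distance needs both matrices positive-definite"
        )
    return float(np.sqrt(0.5 * np.sum(np.log(phi) ** 2)))


def srmr(S, sigma_hat) -> float:
    """Standardized root mean square residual.

    Averages squared residuals, standardized by ``sqrt(s_ii s_jj)``, over the
    lower triangle including the diagonal (K(K+1)/2 cells).
    """
    S, sh = _pair(S, sigma_hat)
    d = np.diag(S)
    if np.any(d <= 0):
        raise SpecificationError("sample matrix has a non-positive diagonal entry")
    K = S.shape[0]
    rt = np.sqrt(d)
    std_resid = (S - sh) / np.outer(rt, rt)
    tri = np.tril_indices(K)
    return float(np.sqrt(2.0 * np.sum(std_resid[tri] ** 2) / (K * (K + 1))))


_MEASURE_FN: dict[str, Callable] = {
    "dL": euclidean_distance,
    "dG": geodesic_distance,
    "srmr": srmr,
}


@dataclass
class FitMeasures:
    """Observed discrepancies and the eigenvalues behind the geodesic one."""

    d_L: float
    d_G: float
    srmr: float
    eigenvalues: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {"dL": self.d_L, "dG": self.d_G, "srmr": self.srmr}


def fit_measures(S, sigma_hat) -> FitMeasures:
    S, sh = _pair(S, sigma_hat)
    phi = scipy.linalg.eigh(sh, S, eigvals_only=True)
    return FitMeasures(
        d_L=euclidean_distance(S, sh),
        d_G=geodesic_distance(S, sh),
        srmr=srmr(S, sh),
        eigenvalues=phi,
    )


def bollen_stine_transform(X, S, sigma_hat) -> np.ndarray:
    """Rotate the (standardized) data by ``S^{-1/2} Sigma-hat^{1/2}``.

    Symmetric spectral roots are used on both sides, so the transformed
    dataset's 1/N sample covariance equals Sigma-hat exactly and column means
    stay zero.
    """
    S, sh = _pair(S, sigma_hat)
    Xv = X.values.to_numpy() if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    if Xv.shape[1] != S.shape[0]:
        raise SpecificationError(
            f"data has {Xv.shape[1]} columns but matrices are {S.shape[0]}x{S.shape[0]}"
        )
    return Xv @ _core.matrix_inverse_sqrt(S) @ _core.matrix_sqrt(sh)


@dataclass
class FitTestResult:
    """Outcome of the bootstrap test of overall model fit."""

    observed: FitMeasures
    reference: dict[str, np.ndarray]
    p_values: dict[str, float]
    alpha: float
    rejected: dict[str, bool]
    quantiles: dict[str, float]
    n_bootstrap: int
    n_failed: int
    indices: "FitIndices | None" = None


@dataclass
class FitIndices:
    """Descriptive fit indices (no cut-off calibration is attempted)."""

    srmr: float
    nfi: float
    rms_theta: float
    residual_matrix: pd.DataFrame


def nfi(
    S,
    sigma_hat,
    baseline: np.ndarray | None = None,
    measure: Callable[[np.ndarray, np.ndarray], float] = geodesic_distance,
) -> float:
    """Normed fit index: ``1 - F(estimated) / F(baseline)``.

    The default baseline is the model of mutually uncorrelated indicators
    (identity correlation matrix); the default discrepancy F is the geodesic
    distance.
    """
    S, sh = _pair(S, sigma_hat)
    if baseline is None:
        baseline = np.eye(S.shape[0])
    f_base = measure(S, baseline)
    if f_base == 0:
        raise SpecificationError(
            "baseline discrepancy is zero; the NFI is undefined"
        )
    return 1.0 - measure(S, sh) / f_base


def rms_theta(S, sigma_hat, spec: CompositeModelSpec) -> float:
    """Root mean square cross-block residual correlation.

    Within-block residuals are excluded: intra-block correlations are free
    parameters and fit perfectly by construction.  Free variables count as
    their own (singleton) blocks, so indicator/free-variable residuals are
    included.
    """
    S, sh = _pair(S, sigma_hat)
    if S.shape[0] != spec.K:
        raise SpecificationError(
            f"matrices are {S.shape[0]}x{S.shape[0]} but the spec has K={spec.K}"
        )
    resid = S - sh
    slices = spec.block_slices()
    mask = np.ones((spec.K, spec.K), dtype=bool)
    for sl in slices:
        mask[sl, sl] = False
    mask &= np.tril(np.ones_like(mask), k=-1).astype(bool)
    m = int(mask.sum())
    if m == 0:
        raise SpecificationError(
            "no cross-block indicator pairs exist; RMS_theta is undefined"
        )
    return float(np.sqrt(np.mean(resid[mask] ** 2)))


def fit_indices(S, sigma_hat, spec: CompositeModelSpec) -> FitIndices:
    S, sh = _pair(S, sigma_hat)
    names = list(spec.indicator_names)
    return FitIndices(
        srmr=srmr(S, sh),
        nfi=nfi(S, sh),
        rms_theta=rms_theta(S, sh, spec),
        residual_matrix=pd.DataFrame(S - sh, index=names, columns=names),
    )


def bootstrap_fit_test(
    X,
    spec: CompositeModelSpec,
    B: int = 200,
    alpha: float = 0.05,
    measures: Sequence[str] = MEASURES,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    with_indices: bool = True,
) -> FitTestResult:
    """Bootstrap test of overall model fit (Beran–Srivastava / Bollen–Stine).

    Estimates the model on ``X``, computes the observed distances, rotates the
    standardized data so its sample matrix equals Sigma-hat, then draws ``B``
    row resamples with replacement; each resample is re-standardized and
    re-estimated and its distances are computed against its own Sigma-hat.
    Resamples failing estimation are dropped and counted (more than 5%
    failures aborts the test).
    """
    if B < 1:
        raise SpecificationError("B must be >= 1")
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise SpecificationError(f"unknown measures {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(X, (DataMatrix, pd.DataFrame)):
        dm = X if isinstance(X, DataMatrix) else DataMatrix(X)
        Xv = dm.ordered(spec).values.to_numpy()
    else:
        Xv = np.asarray(X, dtype=float)
    slices = spec.block_slices()
    observed_v, ref, failed = _core.bootstrap_pvalues(Xv, slices, B, rng)
    # Recompute labeled observed measures (incl. eigenvalues) once.
    Xs = _core.standardize_inplace_copy(Xv)
    S = _core.corr_from_standardized(Xs)
    sigma_hat = _core.fit_sigma_hat(S, slices)
    observed = fit_measures(S, sigma_hat)
    obs = observed.as_dict()
    p_values, rejected, quantiles, reference = {}, {}, {}, {}
    col = {"dL": 0, "dG": 1, "srmr": 2}
    for mname in measures:
        r = ref[:, col[mname]]
        reference[mname] = r
        p = float(np.mean(r >= obs[mname])) if r.size else float("nan")
        p_values[mname] = p
        quantiles[mname] = float(np.quantile(r, 1 - alpha)) if r.size else float("nan")
        rejected[mname] = bool(p < alpha)
    indices = fit_indices(S, sigma_hat, spec) if with_indices else None
    return FitTestResult(
        observed=observed,
        reference=reference,
        p_values=p_values,
        alpha=alpha,
        rejected=rejected,
        quantiles=quantiles,
        n_bootstrap=B,
        n_failed=failed,
        indices=indices,
    )
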