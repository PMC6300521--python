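"""Maxvar estimation of composite models.

Weights are estimated by Kettenring's *maxvar* generalized canonical
correlation criterion: with all composites constrained to unit variance, the
weights maximize the largest eigenvalue of the composite correlation matrix.
The closed-form solution whitens the sample correlation matrix block-wise and
takes its leading eigenvector (see :func:`maxvar_weights`).

Conventions
-----------
* Indicators are standardized to mean zero and unit variance with the 1/N
  denominator, so the sample correlation matrix is ``X'X / N``.  Under this
  convention the Bollen–Stine transform in :mod:`cca.fit` reproduces the
  estimated model-implied matrix exactly.
* Free observed variables participate as singleton blocks with weight 1, so a
  single code path covers composites and free variables.
* Eigenvector signs are fixed so each weight vector's largest-magnitude entry
  is positive (first index on ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _core
from .errors import DataError, DegenerateBlockError, SpecificationError
from .model import CompositeModelSpec, check_identification

__all__ = [
    "DataMatrix",
    "MaxvarSolution",
    "EstimationResult",
    "standardize",
    "inverse_sqrt",
    "maxvar_weights",
    "composite_scores",
    "composite_correlations",
    "estimate",
]


@dataclass
class DataMatrix:
    """An N x K numeric table with named columns.

    Requires N > K (so the sample correlation matrix can be invertible) and
    no missing entries.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.values)
        if df.isna().any().any():
            rows, cols = np.nonzero(df.isna().to_numpy())
            raise DataError(
                f"missing value at row {df.index[rows[0]]!r}, "
                f"column {df.columns[cols[0]]!r}"
            )
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise DataError(f"non-numeric data: {exc}") from exc
        if df.shape[0] <= df.shape[1]:
            raise DataError(
                f"need more observations than variables, got N={df.shape[0]}, "
                f"K={df.shape[1]}"
            )
        self.values = df

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(map(str, self.values.columns))

    def ordered(self, spec: CompositeModelSpec) -> "DataMatrix":
        """Columns reordered to spec order; raises on missing columns."""
        missing = [c for c in spec.indicator_names if c not in self.columns]
        if missing:
            raise DataError(f"data table lacks columns {missing}")
        out = object.__new__(DataMatrix)
        out.values = self.values.loc[:, list(spec.indicator_names)]
        return out


def standardize(data: DataMatrix | pd.DataFrame | np.ndarray):
    """Standardize columns to mean 0 and unit variance (1/N denominator).

    Returns the same container type it was given.  Constant columns raise
    :class:`~cca.errors.DegenerateBlockError`.
    """
    if isinstance(data, DataMatrix):
        out = object.__new__(DataMatrix)
        out.values = standardize(data.values)
        return out
    if isinstance(data, pd.DataFrame):
        arr = data.to_numpy(dtype=float)
        sd = arr.std(axis=0)
        if np.any(sd <= 0):
            bad = data.columns[int(np.argmin(sd))]
            raise DegenerateBlockError(f"column {bad!r} is constant")
        return pd.DataFrame(
            _core.standardize_inplace_copy(arr), index=data.index, columns=data.columns
        )
    return _core.standardize_inplace_copy(np.asarray(data, dtype=float))


def inverse_sqrt(matrix: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root R of a PD matrix: R @ M @ R = I."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-8):
        raise SpecificationError("inverse_sqrt needs a symmetric square matrix")
    return _core.matrix_inverse_sqrt(0.5 * (m + m.T), rtol=rtol)


@dataclass
class MaxvarSolution:
    """Ingredients of the closed-form maxvar solution.

    ``leading_eigenvector`` is the unit-length eigenvector of
    ``Sigma_D^{-1/2} S Sigma_D^{-1/2}`` associated with
    ``leading_eigenvalue``; its per-block subvectors, rescaled by
    ``Sigma_jj^{-1/2}`` and normalized, are the weights.
    """

    sample_corr: np.ndarray
    block_diag: np.ndarray
    leading_eigenvector: np.ndarray
    leading_eigenvalue: float
    weights: dict[str, np.ndarray]


def _sample_corr(data_or_S, spec: CompositeModelSpec) -> tuple[np.ndarray, DataMatrix | None]:
    """Accept a DataMatrix/DataFrame/ndarray of data, or a K x K matrix."""
    if isinstance(data_or_S, (DataMatrix, pd.DataFrame)):
        dm = data_or_S if isinstance(data_or_S, DataMatrix) else DataMatrix(data_or_S)
        dm = standardize(dm.ordered(spec))
        S = _core.corr_from_standardized(dm.values.to_numpy())
        return S, dm
    arr = np.asarray(data_or_S, dtype=float)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1] == spec.K and np.allclose(arr, arr.T, atol=1e-8):
        return 0.5 * (arr + arr.T), None
    # otherwise treat as raw data in spec column order
    dm = standardize(DataMatrix(pd.DataFrame(arr, columns=list(spec.indicator_names))))
    return _core.corr_from_standardized(dm.values.to_numpy()), dm


def maxvar_weights(S, spec: CompositeModelSpec) -> MaxvarSolution:
    """Closed-form maxvar weights from a K x K sample correlation matrix.

    Builds the block-diagonal ``Sigma_D`` from the diagonal blocks of ``S``
    (free variables as singleton blocks), whitens, and extracts the leading
    eigenvector.  Each returned weight vector gives its composite unit sample
    variance: ``w_j' S_jj w_j = 1``.
    """
    S = np.asarray(S, dtype=float)
    if S.shape != (spec.K, spec.K):
        raise SpecificationError(
            f"sample matrix is {S.shape}, expected ({spec.K}, {spec.K})"
        )
    slices = spec.block_slices()
    weights, a, lam, _ = _core.maxvar_core(S, slices)
    names = [name for name, _ in spec.unified_blocks()]
    block_diag = np.zeros_like(S)
    for sl in slices:
        block_diag[sl, sl] = S[sl, sl]
    return MaxvarSolution(
        sample_corr=S,
        block_diag=block_diag,
        leading_eigenvector=a,
        leading_eigenvalue=lam,
        weights=dict(zip(names, weights)),
    )


def composite_scores(
    data: DataMatrix | pd.DataFrame,
    weights: dict[str, np.ndarray],
    spec: CompositeModelSpec,
) -> pd.DataFrame:
    """Composite scores ``c_j = w_j' x_j`` from standardized data.

    One column per unified block (free variables score as themselves).
    """
    df = data.values if isinstance(data, DataMatrix) else pd.DataFrame(data)
    df = df.loc[:, list(spec.indicator_names)]
    out = {}
    for name, inds in spec.unified_blocks():
        w = np.asarray(weights[name], dtype=float).ravel()
        if w.size != len(inds):
            raise SpecificationError(
                f"block {name!r}: {w.size} weights for {len(inds)} indicators"
            )
        out[name] = df.loc[:, list(inds)].to_numpy() @ w
    return pd.DataFrame(out, index=df.index)


def composite_correlations(
    S, weights: dict[str, np.ndarray], spec: CompositeModelSpec
) -> pd.DataFrame:
    """Correlations ``rho_jl = w_j' S_jl w_l`` among all unified blocks."""
    S = np.asarray(S, dtype=float)
    slices = spec.block_slices()
    names = [name for name, _ in spec.unified_blocks()]
    wlist = [np.asarray(weights[name], dtype=float).ravel() for name in names]
    c = _core.block_corr_from_weights(S, slices, wlist)
    return pd.DataFrame(c, index=names, columns=names)


@dataclass
class EstimationResult:
    """Everything the maxvar fit produces.

    ``composite_corr`` covers the true composites only; ``block_corr`` extends
    it with the free variables (as singleton blocks), which is what the
    rank-one reassembly of ``sigma_hat`` uses.  ``sigma_hat``'s diagonal
    blocks equal the sample intra-block matrices (unconstrained parameters are
    fitted at their sample values).
    """

    spec: CompositeModelSpec
    weights: dict[str, np.ndarray]
    loadings: dict[str, np.ndarray]
    composite_corr: pd.DataFrame
    block_corr: pd.DataFrame
    sigma_hat: pd.DataFrame
    sample_corr: pd.DataFrame
    scores: pd.DataFrame | None
    solution: MaxvarSolution
    identification: object

    def sigma_hat_values(self) -> np.ndarray:
        return self.sigma_hat.to_numpy()


def estimate(data_or_S, spec: CompositeModelSpec) -> EstimationResult:
    """Fit a composite model by maxvar.

    Accepts either raw data (a :class:`DataMatrix`, DataFrame, or N x K array
    in spec column order; standardized internally) or a ready-made K x K
    sample correlation matrix.  The estimated model-implied matrix keeps the
    sample intra-block blocks and rebuilds every inter-block submatrix as
    ``rho_jl * lambda_j @ lambda_l'``.
    """
    S, dm = _sample_corr(data_or_S, spec)
    ident = check_identification(spec, S)
    if ident.isolated_blocks:
        raise SpecificationError(
            f"model not identified: isolated block(s) {list(ident.isolated_blocks)}"
        )
    sol = maxvar_weights(S, spec)
    slices = spec.block_slices()
    names = [name for name, _ in spec.unified_blocks()]
    wlist = [sol.weights[name] for name in names]
    c = _core.block_corr_from_weights(S, slices, wlist)
    sigma_hat = _core.sigma_hat_from_fit(S, slices, wlist, c)
    loadings = {
        name: S[sl, sl] @ w for name, sl, w in zip(names, slices, wlist)
    }
    ind_names = list(spec.indicator_names)
    block_corr = pd.DataFrame(c, index=names, columns=names)
    comp = list(spec.block_names)
    scores = None
    if dm is not None:
        scores = composite_scores(dm, sol.weights, spec)
    return EstimationResult(
        spec=spec,
        weights=sol.weights,
        loadings=loadings,
        composite_corr=block_corr.loc[comp, comp],
        block_corr=block_corr,
        sigma_hat=pd.DataFrame(sigma_hat, index=ind_names, columns=ind_names),
        sample_corr=pd.DataFrame(S, index=ind_names, columns=ind_names),
        scores=scores,
        solution=sol,
        identification=ident,
    )
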