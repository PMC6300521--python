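"""Composite-model specification, model-implied covariance, and identification.

A composite model partitions K observed indicators into J blocks; block j
forms a composite ``c_j = w_j' x_j``.  Intra-block correlation matrices
``Sigma_jj`` are unconstrained free parameters, while every inter-block
submatrix is constrained to rank one,

    ``Sigma_jl = rho_jl * lambda_j @ lambda_l'``,

with composite loadings ``lambda_j = Sigma_jj w_j`` and composite correlation
``rho_jl``.  Observed variables that do not form a composite ("free
variables") are handled internally as singleton blocks with weight 1, which
unifies both the covariance bookkeeping and the degrees-of-freedom count.

Everything here operates on the correlation scale: population and estimated
matrices are built from standardized indicators, and covariance-scale data
are standardized on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConditioningError, DegenerateBlockError, SpecificationError

# Positive-definiteness tolerance: smallest eigenvalue must exceed
# PD_RTOL * largest eigenvalue.
PD_RTOL = 1e-10

__all__ = [
    "CompositeModelSpec",
    "PopulationModelParams",
    "ModelImpliedCovariance",
    "IdentificationReport",
    "composite_loadings",
    "composite_variance",
    "rescale_weights",
    "model_implied_covariance",
    "degrees_of_freedom",
    "check_identification",
    "PD_RTOL",
]


def _check_square_symmetric(m: np.ndarray, what: str, tol: float = 1e-8) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise SpecificationError(f"{what} must be a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=tol):
        raise SpecificationError(f"{what} must be symmetric")
    return 0.5 * (m + m.T)


def is_positive_definite(m: np.ndarray, rtol: float = PD_RTOL) -> bool:
    """True if the symmetric matrix ``m`` is PD within the relative tolerance."""
    eig = np.linalg.eigvalsh(np.asarray(m, dtype=float))
    return bool(eig[0] > rtol * max(eig[-1], 0.0))


@dataclass(frozen=True)
class CompositeModelSpec:
    """Block structure of a composite model.

    Parameters
    ----------
    blocks
        Ordered mapping from block (composite) name to the ordered sequence of
        indicator names forming it.  Every block needs at least one indicator.
    free_variables
        Observed variables that do not form any composite but may freely
        correlate with the composites and with each other.
    """

    blocks: tuple[tuple[str, tuple[str, ...]], ...]
    free_variables: tuple[str, ...] = ()

    def __init__(
        self,
        blocks: Mapping[str, Sequence[str]] | Sequence[tuple[str, Sequence[str]]],
        free_variables: Sequence[str] = (),
    ):
        if isinstance(blocks, Mapping):
            items = tuple((str(k), tuple(map(str, v))) for k, v in blocks.items())
        else:
            items = tuple((str(k), tuple(map(str, v))) for k, v in blocks)
        object.__setattr__(self, "blocks", items)
        object.__setattr__(self, "free_variables", tuple(map(str, free_variables)))
        self._validate()

    def _validate(self) -> None:
        if len(self.blocks) < 1:
            raise SpecificationError("a composite model needs at least one block")
        seen: set[str] = set()
        for name, inds in self.blocks:
            if len(inds) < 1:
                raise SpecificationError(f"block {name!r} has no indicators")
            for ind in inds:
                if ind in seen:
                    raise SpecificationError(
                        f"indicator {ind!r} assigned more than once"
                    )
                seen.add(ind)
        for v in self.free_variables:
            if v in seen:
                raise SpecificationError(
                    f"variable {v!r} is both a block indicator and a free variable"
                )
            seen.add(v)
        block_names = [name for name, _ in self.blocks]
        if len(set(block_names)) != len(block_names):
            raise SpecificationError("block names must be unique")
        clash = set(block_names) & seen
        if clash:
            raise SpecificationError(
                f"block names clash with variable names: {sorted(clash)}"
            )

    # -- structure accessors -------------------------------------------------
    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.blocks)

    @property
    def J(self) -> int:
        """Number of composites (free variables not counted)."""
        return len(self.blocks)

    @property
    def n_free(self) -> int:
        return len(self.free_variables)

    @property
    def indicator_names(self) -> tuple[str, ...]:
        """All observed-variable names: block indicators in block order, then free."""
        names = [ind for _, inds in self.blocks for ind in inds]
        names.extend(self.free_variables)
        return tuple(names)

    @property
    def K(self) -> int:
        return len(self.indicator_names)

    def indicators_of(self, block: str) -> tuple[str, ...]:
        for name, inds in self.blocks:
            if name == block:
                return inds
        raise KeyError(block)

    def kj(self, block: str) -> int:
        return len(self.indicators_of(block))

    def unified_blocks(self) -> tuple[tuple[str, tuple[str, ...]], ...]:
        """Blocks with every free variable appended as a singleton pseudo-block."""
        return self.blocks + tuple((v, (v,)) for v in self.free_variables)

    def block_of(self, indicator: str) -> str:
        """Owning block name (a free variable owns itself)."""
        for name, inds in self.unified_blocks():
            if indicator in inds:
                return name
        raise KeyError(indicator)

    def block_slices(self) -> list[slice]:
        """Contiguous column slices of the unified blocks, in spec column order."""
        out, start = [], 0
        for _, inds in self.unified_blocks():
            out.append(slice(start, start + len(inds)))
            start += len(inds)
        return out


def composite_variance(weights: np.ndarray, intra_block_corr: np.ndarray) -> float:
    """Quadratic form ``w' Sigma_jj w`` — the variance of the composite."""
    w = np.asarray(weights, dtype=float).ravel()
    s = _check_square_symmetric(intra_block_corr, "intra-block matrix")
    if w.size != s.shape[0]:
        raise SpecificationError(
            f"weight vector of length {w.size} does not match "
            f"{s.shape[0]}x{s.shape[0]} intra-block matrix"
        )
    return float(w @ s @ w)


def composite_loadings(weights: np.ndarray, intra_block_corr: np.ndarray) -> np.ndarray:
    """Composite loadings ``lambda_j = Sigma_jj w_j``.

    Entry i is the covariance between the composite and its i-th indicator.
    """
    w = np.asarray(weights, dtype=float).ravel()
    s = _check_square_symmetric(intra_block_corr, "intra-block matrix")
    if w.size != s.shape[0]:
        raise SpecificationError(
            f"weight vector of length {w.size} does not match "
            f"{s.shape[0]}x{s.shape[0]} intra-block matrix"
        )
    return s @ w


def rescale_weights(weights: np.ndarray, intra_block_corr: np.ndarray) -> np.ndarray:
    """Rescale ``w`` so that the composite has unit variance, preserving direction."""
    v = composite_variance(weights, intra_block_corr)
    if v <= 0:
        raise DegenerateBlockError(
            f"composite variance w'Sw = {v:.3g} is not positive; "
            "weights cannot be normalized"
        )
    return np.asarray(weights, dtype=float).ravel() / np.sqrt(v)


@dataclass
class PopulationModelParams:
    """Population parameters of a composite model.

    ``weights[j]`` and ``intra_block_corr[j]`` are keyed by block name;
    ``composite_corr`` is J x J in spec block order with unit diagonal.
    ``free_composite_corr`` (n_free x J) holds correlations of each free
    variable with each composite; ``free_free_corr`` (n_free x n_free) the
    correlations among free variables.
    """

    spec: CompositeModelSpec
    weights: dict[str, np.ndarray]
    composite_corr: np.ndarray
    intra_block_corr: dict[str, np.ndarray]
    free_composite_corr: np.ndarray | None = None
    free_free_corr: np.ndarray | None = None
    unit_variance_tol: float = 1e-8

    def __post_init__(self) -> None:
        spec = self.spec
        self.weights = {k: np.asarray(v, dtype=float).ravel() for k, v in self.weights.items()}
        self.intra_block_corr = {
            k: _check_square_symmetric(v, f"intra-block matrix of {k!r}")
            for k, v in self.intra_block_corr.items()
        }
        for name in spec.block_names:
            if name not in self.weights:
                raise SpecificationError(f"no weights given for block {name!r}")
            if name not in self.intra_block_corr:
                raise SpecificationError(f"no intra-block matrix for block {name!r}")
            kj = spec.kj(name)
            if self.weights[name].size != kj:
                raise SpecificationError(
                    f"block {name!r}: {self.weights[name].size} weights for {kj} indicators"
                )
            s = self.intra_block_corr[name]
            if s.shape[0] != kj:
                raise SpecificationError(
                    f"block {name!r}: intra-block matrix is {s.shape[0]}x{s.shape[0]}, "
                    f"expected {kj}x{kj}"
                )
            if not np.allclose(np.diag(s), 1.0, atol=1e-8):
                raise SpecificationError(
                    f"block {name!r}: intra-block correlation diagonal must be 1"
                )
            if not is_positive_definite(s):
                raise ConditioningError(
                    f"block {name!r}: intra-block correlation matrix is not "
                    "positive-definite (condition (i) for a PD indicator matrix)"
                )
            v = composite_variance(self.weights[name], s)
            if abs(v - 1.0) > self.unit_variance_tol:
                raise SpecificationError(
                    f"block {name!r}: composite variance w'Sw = {v:.6g} != 1; "
                    "normalize the weights (rescale_weights)"
                )
        self.composite_corr = _check_square_symmetric(
            self.composite_corr, "composite correlation matrix"
        )
        if self.composite_corr.shape[0] != spec.J:
            raise SpecificationError(
                f"composite correlation matrix is {self.composite_corr.shape[0]}x"
                f"{self.composite_corr.shape[0]}, expected {spec.J}x{spec.J}"
            )
        if not np.allclose(np.diag(self.composite_corr), 1.0, atol=1e-8):
            raise SpecificationError("composite correlation diagonal must be 1")
        F = spec.n_free
        if F:
            if self.free_composite_corr is None:
                self.free_composite_corr = np.zeros((F, spec.J))
            self.free_composite_corr = np.asarray(self.free_composite_corr, dtype=float)
            if self.free_composite_corr.shape != (F, spec.J):
                raise SpecificationError(
                    f"free_composite_corr must be {F}x{spec.J}"
                )
            if self.free_free_corr is None:
                self.free_free_corr = np.eye(F)
            self.free_free_corr = _check_square_symmetric(
                self.free_free_corr, "free-variable correlation matrix"
            )
            if self.free_free_corr.shape[0] != F:
                raise SpecificationError(f"free_free_corr must be {F}x{F}")
        if not is_positive_definite(self.unified_composite_corr()):
            raise ConditioningError(
                "the covariance matrix of the composites (and free variables) is "
                "not positive-definite (condition (ii) for a PD indicator matrix)"
            )

    def unified_composite_corr(self) -> np.ndarray:
        """Correlation matrix over composites followed by free variables."""
        J, F = self.spec.J, self.spec.n_free
        if F == 0:
            return self.composite_corr
        c = np.empty((J + F, J + F))
        c[:J, :J] = self.composite_corr
        c[J:, :J] = self.free_composite_corr
        c[:J, J:] = self.free_composite_corr.T
        c[J:, J:] = self.free_free_corr
        return c

    def unified_weights(self) -> list[np.ndarray]:
        """Per unified block (free variables: weight one)."""
        out = [self.weights[name] for name in self.spec.block_names]
        out.extend(np.ones(1) for _ in self.spec.free_variables)
        return out

    def unified_intra(self) -> list[np.ndarray]:
        out = [self.intra_block_corr[name] for name in self.spec.block_names]
        out.extend(np.ones((1, 1)) for _ in self.spec.free_variables)
        return out


@dataclass
class ModelImpliedCovariance:
    """A K x K model-implied correlation matrix with named rows/columns."""

    sigma: np.ndarray
    names: tuple[str, ...]
    block_index: dict[str, str] = field(default_factory=dict)  # indicator -> block

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sigma, index=list(self.names), columns=list(self.names))

    def loc(self, row: str, col: str) -> float:
        return float(self.sigma[self.names.index(row), self.names.index(col)])


def assemble_sigma(
    blocks: Sequence[tuple[str, Sequence[str]]],
    weights: Sequence[np.ndarray],
    intra: Sequence[np.ndarray],
    block_corr: np.ndarray,
) -> np.ndarray:
    """Assemble a K x K matrix from per-block pieces under the rank-one rule.

    Diagonal blocks are the (unconstrained) ``intra`` matrices; the (j, l)
    off-diagonal block is ``block_corr[j, l] * lambda_j @ lambda_l'`` with
    ``lambda_j = intra[j] @ weights[j]``.
    """
    sizes = [len(inds) for _, inds in blocks]
    K = sum(sizes)
    lambdas = [np.asarray(s) @ np.asarray(w) for s, w in zip(intra, weights)]
    sigma = np.empty((K, K))
    starts = np.concatenate([[0], np.cumsum(sizes)])
    for j in range(len(blocks)):
        sj = slice(starts[j], starts[j + 1])
        sigma[sj, sj] = intra[j]
        for l in range(j + 1, len(blocks)):
            sl = slice(starts[l], starts[l + 1])
            off = block_corr[j, l] * np.outer(lambdas[j], lambdas[l])
            sigma[sj, sl] = off
            sigma[sl, sj] = off.T
    return sigma


def model_implied_covariance(
    params: PopulationModelParams,
    spec: CompositeModelSpec | None = None,
) -> ModelImpliedCovariance:
    """Build the model-implied indicator correlation matrix Sigma(theta).

    Free variables enter as singleton blocks with loading 1, so their
    covariance with the indicators of block j distributes as the composite
    loading ``lambda_j`` times the free-variable/composite correlation.

    Raises
    ------
    ConditioningError
        If the result cannot be positive-definite; the message names which of
        the two conditions failed (intra-block matrices PD, composite
        covariance matrix PD).
    """
    if spec is not None and spec is not params.spec:
        if spec.blocks != params.spec.blocks or spec.free_variables != params.spec.free_variables:
            raise SpecificationError("spec and params block structures disagree")
    spec = params.spec
    sigma = assemble_sigma(
        spec.unified_blocks(),
        params.unified_weights(),
        params.unified_intra(),
        params.unified_composite_corr(),
    )
    names = spec.indicator_names
    return ModelImpliedCovariance(
        sigma=sigma,
        names=names,
        block_index={ind: spec.block_of(ind) for ind in names},
    )


@dataclass
class IdentificationReport:
    """Degrees of freedom and identification status of a composite model.

    ``term_breakdown`` holds the seven counted terms, in order: non-redundant
    off-diagonal elements of the indicator matrix; free composite
    correlations; composite x free-variable covariances; free-variable pair
    covariances; intra-block off-diagonals; weights; number of blocks (added
    back, one per fixed composite variance).
    """

    df: int
    status: str  # "under-identified" | "just-identified" | "over-identified"
    isolated_blocks: tuple[str, ...]
    term_breakdown: dict[str, int]

    @property
    def terms(self) -> tuple[int, ...]:
        t = self.term_breakdown
        return (
            t["nonredundant_elements"],
            t["composite_correlations"],
            t["composite_free_covariances"],
            t["free_pair_covariances"],
            t["intra_block_elements"],
            t["weights"],
            t["blocks"],
        )


def _status(df: int, isolated: Sequence[str]) -> str:
    if isolated or df < 0:
        return "under-identified"
    return "just-identified" if df == 0 else "over-identified"


def degrees_of_freedom(spec: CompositeModelSpec) -> IdentificationReport:
    """Count degrees of freedom of a composite model.

    df equals the number of non-redundant off-diagonal elements of the
    indicator correlation matrix minus the free parameters: composite
    correlations, composite/free-variable covariances, free-variable pair
    covariances, intra-block off-diagonals and weights — plus one regained
    degree per block, because fixing each composite variance to one makes one
    weight per block redundant.
    """
    K, J, F = spec.K, spec.J, spec.n_free
    kj = [spec.kj(b) for b in spec.block_names]
    terms = {
        "nonredundant_elements": K * (K - 1) // 2,
        "composite_correlations": J * (J - 1) // 2,
        "composite_free_covariances": J * F,
        "free_pair_covariances": F * (F - 1) // 2,
        "intra_block_elements": sum(k * (k - 1) // 2 for k in kj),
        "weights": sum(kj),
        "blocks": J,
    }
    df = (
        terms["nonredundant_elements"]
        - terms["composite_correlations"]
        - terms["composite_free_covariances"]
        - terms["free_pair_covariances"]
        - terms["intra_block_elements"]
        - terms["weights"]
        + terms["blocks"]
    )
    isolated = _structurally_isolated(spec)
    return IdentificationReport(
        df=df, status=_status(df, isolated), isolated_blocks=isolated, term_breakdown=terms
    )


def _structurally_isolated(spec: CompositeModelSpec) -> tuple[str, ...]:
    # A composite with no other composite and no free variable to connect to
    # cannot satisfy the non-isolation condition, whatever the parameters.
    if spec.J == 1 and spec.n_free == 0:
        return (spec.block_names[0],)
    return ()


def check_identification(
    spec: CompositeModelSpec,
    params_or_sigma: PopulationModelParams | ModelImpliedCovariance | np.ndarray | None = None,
    zero_tol: float = 1e-12,
) -> IdentificationReport:
    """Combine the df count with the non-isolation condition.

    Each composite must be connected to at least one other composite or one
    free variable: with a parameter set or indicator matrix given, a block is
    flagged as isolated when every covariance between its indicators and all
    other observed variables is (numerically) zero.  Isolation is reported in
    the result, not raised.
    """
    report = degrees_of_freedom(spec)
    sigma: np.ndarray | None = None
    if isinstance(params_or_sigma, PopulationModelParams):
        sigma = model_implied_covariance(params_or_sigma).sigma
    elif isinstance(params_or_sigma, ModelImpliedCovariance):
        sigma = params_or_sigma.sigma
    elif params_or_sigma is not None:
        sigma = _check_square_symmetric(np.asarray(params_or_sigma, float), "indicator matrix")
        if sigma.shape[0] != spec.K:
            raise SpecificationError(
                f"indicator matrix is {sigma.shape[0]}x{sigma.shape[0]}, expected {spec.K}"
            )
    isolated = list(report.isolated_blocks)
    if sigma is not None:
        slices = spec.block_slices()
        names = [n for n, _ in spec.unified_blocks()]
        for name, sl in zip(names, slices):
            if name not in spec.block_names:
                continue  # free variables need not satisfy non-isolation
            mask = np.ones(spec.K, dtype=bool)
            mask[sl] = False
            if np.all(np.abs(sigma[sl, mask]) <= zero_tol) and name not in isolated:
                isolated.append(name)
    isolated_t = tuple(isolated)
    return IdentificationReport(
        df=report.df,
        status=_status(report.df, isolated_t),
        isolated_blocks=isolated_t,
        term_breakdown=report.term_breakdown,
    )
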