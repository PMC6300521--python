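"""Configuration files, data loading, and report serialization.

Model configuration is a single YAML document::

    blocks:
      c1: [x11, x12, x13]
      c2: [x21, x22, x23]
    free: [y, z]

Optionally, population parameters may accompany the structure::

    population:
      weights:            {c1: [0.6, 0.2, 0.4], c2: [0.4, 0.2, 0.6]}
      composite_corr:     [[1.0, 0.3], [0.3, 1.0]]
      intra_block_corr:   {c1: [[1, .5, .5], [.5, 1, .5], [.5, .5, 1]], ...}
      free_composite_corr: [[...]]       # rows: free variables, cols: blocks
      free_free_corr:      [[...]]

Data tables are delimited text (CSV/TSV) with a header row of indicator
names.  Reports are written as JSON (machine-readable) or plain text/CSV
(human-readable); every report echoes the configuration and seed so that
outputs are reproducible bit-for-bit from (inputs, config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, SpecificationError
from .estimation import DataMatrix, EstimationResult
from .fit import FitTestResult
from .model import CompositeModelSpec, PopulationModelParams
from .simulation import SimulationResult

_KNOWN_KEYS = {"blocks", "free", "population"}
_KNOWN_POP_KEYS = {
    "weights",
    "composite_corr",
    "intra_block_corr",
    "free_composite_corr",
    "free_free_corr",
}


def load_model_config(
    path: str | Path,
) -> tuple[CompositeModelSpec, PopulationModelParams | None]:
    """Parse a model configuration file; round-trips with `write_model_config`."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise SpecificationError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise SpecificationError(f"{path}: top level must be a mapping")
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        raise SpecificationError(f"{path}: unknown keys {sorted(unknown)}")
    blocks = doc.get("blocks")
    if not blocks or not isinstance(blocks, dict):
        raise SpecificationError(f"{path}: a non-empty 'blocks' mapping is required")
    for name, inds in blocks.items():
        if not isinstance(inds, list) or not inds:
            raise SpecificationError(
                f"{path}: block {name!r} must map to a non-empty list of indicators"
            )
    free = doc.get("free", []) or []
    if not isinstance(free, list):
        raise SpecificationError(f"{path}: 'free' must be a list")
    spec = CompositeModelSpec(blocks, free)
    pop = doc.get("population")
    params = None
    if pop is not None:
        if not isinstance(pop, dict):
            raise SpecificationError(f"{path}: 'population' must be a mapping")
        unknown = set(pop) - _KNOWN_POP_KEYS
        if unknown:
            raise SpecificationError(
                f"{path}: unknown population keys {sorted(unknown)}"
            )
        try:
            params = PopulationModelParams(
                spec=spec,
                weights={k: np.asarray(v, float) for k, v in pop["weights"].items()},
                composite_corr=np.asarray(pop["composite_corr"], float),
                intra_block_corr={
                    k: np.asarray(v, float) for k, v in pop["intra_block_corr"].items()
                },
                free_composite_corr=(
                    np.asarray(pop["free_composite_corr"], float)
                    if "free_composite_corr" in pop
                    else None
                ),
                free_free_corr=(
                    np.asarray(pop["free_free_corr"], float)
                    if "free_free_corr" in pop
                    else None
                ),
            )
        except KeyError as exc:
            raise SpecificationError(f"{path}: population section lacks {exc}") from exc
    return spec, params


def write_model_config(
    path: str | Path,
    spec: CompositeModelSpec,
    params: PopulationModelParams | None = None,
) -> None:
    doc: dict[str, Any] = {
        "blocks": {name: list(inds) for name, inds in spec.blocks},
    }
    if spec.free_variables:
        doc["free"] = list(spec.free_variables)
    if params is not None:
        pop: dict[str, Any] = {
            "weights": {k: np.asarray(v).tolist() for k, v in params.weights.items()},
            "composite_corr": np.asarray(params.composite_corr).tolist(),
            "intra_block_corr": {
                k: np.asarray(v).tolist() for k, v in params.intra_block_corr.items()
            },
        }
        if params.free_composite_corr is not None:
            pop["free_composite_corr"] = np.asarray(params.free_composite_corr).tolist()
        if params.free_free_corr is not None:
            pop["free_free_corr"] = np.asarray(params.free_free_corr).tolist()
        doc["population"] = pop
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_data(path: str | Path, spec: CompositeModelSpec | None = None) -> DataMatrix:
    """Read a delimited text table; columns reordered to spec order if given."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep)
    if raw.isna().any().any():
        rows, cols = np.nonzero(raw.isna().to_numpy())
        raise DataError(
            f"{path}: missing value at row {rows[0] + 2} (file line), "
            f"column {raw.columns[cols[0]]!r}"
        )
    dm = DataMatrix(raw)
    if spec is not None:
        dm = dm.ordered(spec)
        if dm.n <= spec.K:
            raise DataError(f"{path}: need N > K, got N={dm.n}, K={spec.K}")
    return dm


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.bool_):
            return bool(o)
        return super().default(o)


def _estimation_payload(r: EstimationResult) -> dict[str, Any]:
    return {
        "kind": "estimation",
        "weights": {k: np.asarray(v).tolist() for k, v in r.weights.items()},
        "loadings": {k: np.asarray(v).tolist() for k, v in r.loadings.items()},
        "composite_corr": {
            "names": list(r.composite_corr.columns),
            "values": r.composite_corr.to_numpy().tolist(),
        },
        "sigma_hat": {
            "names": list(r.sigma_hat.columns),
            "values": r.sigma_hat.to_numpy().tolist(),
        },
        "sample_corr": r.sample_corr.to_numpy().tolist(),
        "identification": {
            "df": r.identification.df,
            "status": r.identification.status,
            "isolated_blocks": list(r.identification.isolated_blocks),
            "term_breakdown": r.identification.term_breakdown,
        },
    }


def _fit_test_payload(r: FitTestResult) -> dict[str, Any]:
    payload: dict[str, Any] = {
        "kind": "fit_test",
        "alpha": r.alpha,
        "n_bootstrap": r.n_bootstrap,
        "n_failed": r.n_failed,
        "observed": r.observed.as_dict(),
        "p_values": r.p_values,
        "quantiles": r.quantiles,
        "rejected": {k: bool(v) for k, v in r.rejected.items()},
    }
    if r.indices is not None:
        payload["indices"] = {
            "srmr": r.indices.srmr,
            "nfi": r.indices.nfi,
            "rms_theta": r.indices.rms_theta,
        }
    return payload


def write_report(
    result: EstimationResult | FitTestResult | SimulationResult,
    path: str | Path,
    fmt: str = "json",
    config_echo: dict[str, Any] | None = None,
) -> None:
    """Serialize a result.

    JSON for estimation and fit-test results; simulation results additionally
    support ``fmt="csv"`` (the long-format rates table).  ``config_echo``
    (seed, input paths, flags) is embedded verbatim for reproducibility.
    """
    path = Path(path)
    if isinstance(result, SimulationResult):
        if fmt == "csv":
            result.rates.to_csv(path, index=False)
            return
        payload: dict[str, Any] = {
            "kind": "simulation",
            "seed": result.seed,
            "reps": result.reps,
            "B": result.B,
            "band_level": result.band_level,
            "rates": result.rates.to_dict(orient="records"),
        }
    elif isinstance(result, FitTestResult):
        payload = _fit_test_payload(result)
    elif isinstance(result, EstimationResult):
        payload = _estimation_payload(result)
    else:
        raise SpecificationError(f"cannot serialize {type(result).__name__}")
    if config_echo:
        payload["config"] = config_echo
    if fmt == "json":
        path.write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")
    elif fmt == "text":
        path.write_text(_render_text(payload))
    else:
        raise SpecificationError(f"unknown report format {fmt!r}")


def _render_text(payload: dict[str, Any]) -> str:
    lines = [f"# {payload['kind']} report"]
    for key, value in payload.items():
        if key == "kind":
            continue
        lines.append(f"{key}:")
        lines.append(json.dumps(value, indent=2, cls=_NumpyEncoder))
    return "\n".join(lines) + "\n"


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
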