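"""Result serialization: tidy CSV and JSON with a reproducibility header."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .kinetics import FluxResult, StateDistribution

_FLOAT_FMT = "%.12g"


def _metadata(extra: dict | None = None) -> dict:
    meta = {"package": "bc1dimer", "version": __version__}
    if extra:
        meta.update(extra)
    return meta


def parameter_file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (FluxResult,)) or dataclasses.is_dataclass(obj):
        return {
            k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()
        }
    if isinstance(obj, StateDistribution):
        return list(obj.probabilities)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(
    result: Any,
    path: str | Path,
    fmt: str = "json",
    metadata: dict | None = None,
) -> Path:
    """Write a result object (DataFrame, FluxResult, dataclass, dict) to
    CSV or JSON with a metadata header; 12-significant-digit floats give a
    lossless practical round-trip."""
    path = Path(path)
    if fmt == "json":
        payload = {"metadata": _metadata(metadata), "result": _jsonable(result)}
        path.write_text(json.dumps(payload, indent=1, default=str) + "\n")
    elif fmt == "csv":
        if isinstance(result, pd.DataFrame):
            df = result
        elif isinstance(result, FluxResult):
            df = pd.DataFrame([dataclasses.asdict(result)])
        elif dataclasses.is_dataclass(result):
            df = pd.DataFrame([_jsonable(result)])
        elif isinstance(result, dict):
            df = pd.DataFrame([result])
        else:
            raise TypeError(f"cannot serialize {type(result)} to CSV")
        with path.open("w") as fh:
            for k, v in _metadata(metadata).items():
                fh.write(f"# {k}: {v}\n")
            df.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_results(path: str | Path) -> pd.DataFrame | dict:
    """Read back a result file written by :func:`write_results`."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        return json.loads(text)
    return pd.read_csv(path, comment="#")
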