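"""CSV/JSON/YAML plumbing and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .simulation import IncompleteDataset

__all__ = ["read_table", "write_dataset", "read_config", "RunManifest"]

_DEFAULT_MISSING = ("", "NA", "NaN", "nan")


def read_table(
    path: str | Path,
    outcome: str = "y",
    missing_tokens: tuple[str, ...] = _DEFAULT_MISSING,
    binary_override: Mapping[str, bool] | None = None,
    truth: list[str] | None = None,
) -> IncompleteDataset:
    """Read an incomplete dataset from a headered CSV.

    Missing tokens become NaN; a column with at most two distinct observed
    values is treated as binary.  Columns with more than two levels that
    are not plain continuous numerics must be handled upstream: a non-
    numeric column raises rather than being silently coerced.
    """
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate column names: {dupes}")
    df = pd.read_csv(path, na_values=list(missing_tokens), keep_default_na=False)
    if outcome not in df.columns:
        raise ValueError(f"outcome column {outcome!r} not found")
    for c in df.columns:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise ValueError(
                f"column {c!r} is not numeric; encode categorical variables "
                "explicitly before loading"
            )
    y = df[outcome].astype(float)
    yv = y.dropna().unique()
    if not set(np.unique(yv)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1 after masking")
    X = df.drop(columns=[outcome]).astype(float)

    binary_cols = []
    override = dict(binary_override or {})
    for c in X.columns:
        if c in override:
            if override[c]:
                binary_cols.append(c)
            continue
        vals = X[c].dropna().unique()
        if len(vals) <= 2:
            if not set(vals) <= {0.0, 1.0}:
                raise ValueError(
                    f"column {c!r} has two levels but is not 0/1 coded; "
                    "recode or pass binary_override"
                )
            binary_cols.append(c)
    return IncompleteDataset(X=X, y=y.rename("y"), truth=truth,
                             binary_cols=binary_cols,
                             meta={"source": str(path)})


def write_dataset(data: IncompleteDataset, path: str | Path,
                  sidecar: bool = True) -> None:
    """Write a dataset as CSV (missing entries empty) plus a JSON sidecar
    with configuration, seed, truth set and realized missingness."""
    path = Path(path)
    df = data.X.copy()
    df["y"] = data.y
    df.to_csv(path, index=False, na_rep="")
    if sidecar:
        meta = {
            "truth": data.truth,
            "binary_cols": data.binary_cols,
            "n": int(len(data.y)),
            "overall_missingness": data.overall_missingness()
            if df.isna().to_numpy().any() else 0.0,
        }
        for key in ("config", "amputation", "seed", "realized_missingness",
                    "gamma_parameterization", "dependence_coefficients"):
            if key in data.meta:
                meta[key] = _jsonable(data.meta[key])
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) configuration file."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def _jsonable(obj: Any):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one CLI run, sufficient to reproduce it bit-for-bit."""

    command: str
    config: dict
    master_seed: int
    version: str = ""
    started: float = field(default_factory=time.time)
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        entry = {"stage": stage, "t": time.time() - self.started}
        for k, v in info.items():
            if isinstance(v, (str, Path)) and Path(str(v)).is_file():
                entry[k] = {"path": str(v), "sha256_16": _hash_file(Path(str(v)))}
            else:
                entry[k] = _jsonable(v)
        self.stages.append(entry)

    def write(self, path: str | Path) -> None:
        from . import __version__

        payload = {
            "command": self.command,
            "config": _jsonable(self.config),
            "master_seed": self.master_seed,
            "version": self.version or __version__,
            "elapsed_s": time.time() - self.started,
            "stages": self.stages,
        }
        Path(path).write_text(json.dumps(payload, indent=2))
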