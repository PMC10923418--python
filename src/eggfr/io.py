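"""Flat-file I/O: dataset CSV, generation manifests, fit outputs.

All outputs are plain CSV or JSON so that runs are diffable and every
file round-trips to its in-memory object.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .inference import FitResult
from .lifetime import DATASET_COLUMNS, ExperimentDataset

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_manifest",
    "write_manifest",
    "write_fit",
    "load_config",
]


def read_dataset(path) -> ExperimentDataset:
    """Read an experiment CSV (header ``female_id,day,n_offered,n_parasitized``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(
            f"could not read dataset {path}: {exc}; expected a CSV with header "
            f"{','.join(DATASET_COLUMNS)}"
        ) from exc
    return ExperimentDataset(df)


def write_dataset(dataset: ExperimentDataset, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dataset.df.to_csv(path, index=False)


def write_manifest(manifest: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_fit(fit: FitResult, outdir, prefix: str | None = None) -> dict[str, Path]:
    """Write posterior draws (CSV, one column per parameter) and a JSON
    summary.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or fit.model_name
    draws_path = outdir / f"{prefix}_draws.csv"
    summary_path = outdir / f"{prefix}_summary.json"
    fit.to_frame().to_csv(draws_path, index=False)
    with open(summary_path, "w") as fh:
        json.dump(fit.summary(), fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return {"draws": draws_path, "summary": summary_path}


def load_config(path) -> dict:
    """Load a YAML run-configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
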