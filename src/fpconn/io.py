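"""Delimited-text I/O for cohorts and pipeline artifacts.

Formats: per-subject time series as TSV (rows = time points, columns =
regions, header = region ids); atlas as TSV (region_id, region_name,
network); covariates and clinical scores as CSV; run manifests and reports
as JSON.  Floats are written at full precision so fixture sets round-trip
losslessly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortConfig, StabilityBlock
from .connectome import FPConnError, ParcellatedTimeSeries

_FLOAT_FMT = "%.17g"


def _ts_filename(ts: ParcellatedTimeSeries) -> str:
    return f"sub-{ts.subject_id}_timeseries.tsv"


def write_fixture_set(timeseries: Sequence[ParcellatedTimeSeries],
                      atlas: pd.DataFrame, covariates: pd.DataFrame,
                      clinical: pd.DataFrame | None,
                      config: CohortConfig, directory: str | Path) -> dict:
    """Write a cohort to disk and return its manifest.

    Produces one TSV per subject plus atlas/covariate/clinical tables and a
    JSON manifest recording the generating configuration and seed.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FPConnError(f"cannot create fixture directory {directory}: {exc}")
    files = []
    for ts in timeseries:
        name = _ts_filename(ts)
        df = pd.DataFrame(ts.data, columns=list(ts.region_ids))
        df.to_csv(directory / name, sep="\t", index=False,
                  float_format=_FLOAT_FMT)
        files.append(name)
    atlas.to_csv(directory / "atlas.tsv", sep="\t", index=False)
    covariates.to_csv(directory / "covariates.csv", index=False)
    if clinical is not None:
        clinical.to_csv(directory / "clinical.csv", index=False)
    manifest = {
        "config": config.as_dict(),
        "seed": config.seed,
        "subjects": [{"subject_id": ts.subject_id, "group": ts.group,
                      "file": _ts_filename(ts)} for ts in timeseries],
        "tables": {"atlas": "atlas.tsv", "covariates": "covariates.csv",
                   **({"clinical": "clinical.csv"} if clinical is not None
                      else {})},
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_fixture_set(directory: str | Path,
                     ) -> tuple[list[ParcellatedTimeSeries], pd.DataFrame,
                                pd.DataFrame, pd.DataFrame | None,
                                CohortConfig]:
    """Load a cohort written by :func:`write_fixture_set`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FPConnError(f"no manifest.json in {directory}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    cfg_dict["stability_diff_blocks"] = tuple(
        StabilityBlock(**b) for b in cfg_dict.get("stability_diff_blocks", []))
    cfg_dict["network_sizes"] = tuple(cfg_dict["network_sizes"])
    config = CohortConfig(**cfg_dict)
    atlas = pd.read_csv(directory / manifest["tables"]["atlas"], sep="\t")
    covariates = pd.read_csv(directory / manifest["tables"]["covariates"],
                             float_precision="round_trip")
    clinical = None
    if "clinical" in manifest["tables"]:
        clinical = pd.read_csv(directory / manifest["tables"]["clinical"],
                               float_precision="round_trip")
    timeseries = []
    for entry in manifest["subjects"]:
        df = pd.read_csv(directory / entry["file"], sep="\t",
                         float_precision="round_trip")
        timeseries.append(ParcellatedTimeSeries(
            entry["subject_id"], entry["group"],
            np.ascontiguousarray(df.to_numpy(dtype=float)),
            list(df.columns)))
    return timeseries, atlas, covariates, clinical, config


def write_square_matrix(values: np.ndarray, region_ids: Sequence[str],
                        path: str | Path) -> None:
    pd.DataFrame(values, columns=list(region_ids)).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
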