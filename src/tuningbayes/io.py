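"""File formats and run configuration.

Trial tables are plain CSV/JSON with columns (cell, angle_deg, trial,
response); trial-averaged tables use (cell, angle_deg, response_mean,
n_trials).  Posterior summaries round-trip through JSON (the default;
human-diffable, kilobytes per cell) or HDF5.  The raw joint posterior
is never written to disk — it is cheap to recompute and enormous to
store.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .grid import GridSpec, PosteriorSummary, ResponseData
from .noise import NoiseModel

__all__ = [
    "RunConfig",
    "read_responses",
    "write_responses",
    "write_summary",
    "read_summary",
]

TRIAL_COLUMNS = ("cell", "angle_deg", "trial", "response")
MEANS_COLUMNS = ("cell", "angle_deg", "response_mean", "n_trials")


@dataclass
class RunConfig:
    """Run-level settings shared by the CLI subcommands.

    ``modality`` picks the default production grid ("spiking" or
    "calcium"; the calcium grid ranges are derived per cell from its
    maximum mean response, which is recorded in the output).  Explicit
    ``grid`` ranges override the modality default.
    """

    modality: str = "spiking"
    grid: Optional[dict] = None
    noise: Optional[dict] = None
    seed: int = 0
    rpref_bins: Optional[list] = None
    joint2d_pairs: list = field(default_factory=list)

    def __post_init__(self):
        if self.modality not in ("spiking", "calcium"):
            raise ValueError(
                f"modality must be 'spiking' or 'calcium', got {self.modality!r}"
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls(**data)

    def noise_model(self) -> Optional[NoiseModel]:
        if self.noise is None:
            return None
        return NoiseModel(Cn=float(self.noise["Cn"]), K=float(self.noise["K"]),
                          S=float(self.noise["S"]))

    def grid_spec(self, data: Optional[ResponseData] = None) -> GridSpec:
        if self.grid is not None:
            return GridSpec.from_dict(self.grid)
        if self.modality == "calcium":
            if data is None:
                raise ValueError("calcium grids need the cell's data to derive MX")
            return GridSpec.calcium_default(float(np.max(np.abs(data.means))))
        return GridSpec.spiking_default()

    def digest(self) -> str:
        """Short hash of the configuration, embedded in outputs for provenance."""
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _fail_rows(mask: pd.Series, message: str):
    rows = list(np.flatnonzero(mask.to_numpy())[:10] + 2)  # 1-based incl. header
    raise ValueError(f"{message} (file rows {rows}{'...' if mask.sum() > 10 else ''})")


def read_responses(path, format: str | None = None) -> dict:
    """Read a trial table, grouped per cell.

    Returns an ordered dict mapping cell id to :class:`ResponseData`.
    Accepts trial-level tables (cell, angle_deg, trial, response) or
    trial-averaged ones (cell, angle_deg, response_mean, n_trials); the
    latter produce means-only ResponseData.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"response file not found: {path}")
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    if fmt == "csv":
        table = pd.read_csv(path)
    elif fmt == "json":
        table = pd.read_json(path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
    if table.empty:
        raise ValueError(f"empty response table: {path}")

    cols = set(table.columns)
    if set(TRIAL_COLUMNS) <= cols:
        return _from_trial_table(table)
    if set(MEANS_COLUMNS) <= cols:
        return _from_means_table(table)
    raise ValueError(
        f"missing columns in {path}: expected {TRIAL_COLUMNS} or {MEANS_COLUMNS}, "
        f"found {sorted(cols)}"
    )


def _check_numeric(table, columns):
    for col in columns:
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            _fail_rows(vals.isna(), f"non-numeric entries in column {col!r}")
        table[col] = vals
    return table


def _from_trial_table(table: pd.DataFrame) -> dict:
    table = _check_numeric(table.copy(), ["angle_deg", "trial", "response"])
    dup = table.duplicated(subset=["cell", "angle_deg", "trial"], keep=False)
    if dup.any():
        _fail_rows(dup, "duplicate (cell, angle, trial) entries")
    out = {}
    for cell, group in table.groupby("cell", sort=False):
        pivot = group.pivot(index="angle_deg", columns="trial", values="response")
        if pivot.isna().any().any():
            raise ValueError(
                f"cell {cell!r}: incomplete trials (every angle needs the same trial ids)"
            )
        out[cell] = ResponseData.from_trials(pivot.index.to_numpy(float),
                                             pivot.to_numpy(float))
    return out


def _from_means_table(table: pd.DataFrame) -> dict:
    table = _check_numeric(table.copy(), ["angle_deg", "response_mean", "n_trials"])
    dup = table.duplicated(subset=["cell", "angle_deg"], keep=False)
    if dup.any():
        _fail_rows(dup, "duplicate (cell, angle) entries")
    out = {}
    for cell, group in table.groupby("cell", sort=False):
        out[cell] = ResponseData.from_means(
            group["angle_deg"].to_numpy(float),
            group["response_mean"].to_numpy(float),
            group["n_trials"].to_numpy(float).astype(int),
        )
    return out


def write_responses(datasets: dict, path) -> None:
    """Write trial-level data for one or more cells as a tidy CSV."""
    rows = []
    for cell, data in datasets.items():
        if data.trials is None:
            raise ValueError(f"cell {cell!r} has no trial-level data to write")
        for i, angle in enumerate(data.angles):
            for t in range(data.trials.shape[1]):
                rows.append({"cell": cell, "angle_deg": angle, "trial": t,
                             "response": data.trials[i, t]})
    _atomic_write(path, pd.DataFrame(rows, columns=list(TRIAL_COLUMNS)).to_csv(index=False))


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_summary(summary: PosteriorSummary, path, format: str | None = None) -> None:
    """Store a posterior summary as JSON (default) or HDF5.

    Only the compact summaries are written; requests to export the full
    joint are refused (recompute it instead — the summary embeds the
    grid definition needed to do so).
    """
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "json")
    payload = summary.to_dict()
    if fmt == "json":
        _atomic_write(path, json.dumps(payload, indent=1))
    elif fmt == "hdf5":
        import h5py

        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            _dict_to_h5(f, payload)
    else:
        raise ValueError(f"unknown summary format {fmt!r}; expected 'json' or 'hdf5'")


def _dict_to_h5(group, d):
    for key, value in d.items():
        if isinstance(value, dict):
            _dict_to_h5(group.create_group(str(key)), value)
        elif isinstance(value, (list, np.ndarray)):
            group.create_dataset(str(key), data=np.asarray(value))
        elif value is None:
            group.attrs[str(key)] = "__none__"
        else:
            group.attrs[str(key)] = value


def _h5_to_dict(group):
    import h5py

    out = {}
    for key, value in group.items():
        if isinstance(value, h5py.Group):
            out[key] = _h5_to_dict(value)
        else:
            out[key] = np.asarray(value).tolist()
    for key, value in group.attrs.items():
        out[key] = None if (isinstance(value, str) and value == "__none__") else value
        if isinstance(out[key], np.generic):
            out[key] = out[key].item()
    return out


def read_summary(path, format: str | None = None) -> PosteriorSummary:
    """Load a stored posterior summary (inverse of :func:`write_summary`)."""
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "json")
    if fmt == "json":
        payload = json.loads(path.read_text())
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            payload = _h5_to_dict(f)
    else:
        raise ValueError(f"unknown summary format {fmt!r}")
    return PosteriorSummary.from_dict(payload)


def export_joint(*args, **kwargs):
    """Refused by design: the raw joint posterior is ~10 GB per cell.

    Recompute it from the stored grid definition with
    :func:`tuningbayes.grid.compute_posterior` (``return_joint=True``)
    when a downstream analysis genuinely needs the full joint.
    """
    raise NotImplementedError(
        "persisting the full joint posterior is unsupported by design; "
        "recompute it in memory via compute_posterior(..., return_joint=True)"
    )
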