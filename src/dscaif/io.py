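"""File formats: curve CSV, 4D NIfTI phantoms/series, configs and run
metadata.

CSV dialect: header row, '.' decimal, UTF-8. Curve files have one row per
voxel with columns id[, label, mix_weight], then one column per time point
named ``t<seconds>``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .preprocess import CurveSet
from .simulate import SimulationConfig, SyntheticDataset, TimeGrid

__all__ = [
    "write_curveset_csv",
    "read_curveset_csv",
    "write_dataset_csv",
    "read_dataset_csv",
    "write_phantom_nifti",
    "read_perfusion_nifti",
    "load_config",
    "save_config",
    "config_hash",
    "write_run_metadata",
]


def _time_columns(grid: TimeGrid) -> list[str]:
    return [f"t{t:g}" for t in grid.times]


def write_curveset_csv(curves: CurveSet, path) -> None:
    df = pd.DataFrame(curves.values, columns=_time_columns(curves.grid))
    df.insert(0, "id", curves.ids)
    df.to_csv(path, index=False)


def _grid_from_columns(cols) -> TimeGrid:
    times = np.array([float(c[1:]) for c in cols])
    if times.size < 2:
        raise ValueError("curve file has fewer than two time columns")
    dt = float(times[1] - times[0])
    return TimeGrid(float(times[0]), dt * times.size, dt)


def read_curveset_csv(path, kind: str = "signal") -> CurveSet:
    df = pd.read_csv(path)
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].replace(".", "", 1).isdigit()]
    grid = _grid_from_columns(tcols)
    return CurveSet(df["id"].to_numpy(), grid, df[tcols].to_numpy(float), kind)


def write_dataset_csv(ds: SyntheticDataset, path) -> None:
    """Curves with ground-truth labels and PVE mix weights."""
    df = pd.DataFrame(ds.signals, columns=_time_columns(ds.grid))
    df.insert(0, "mix_weight", [lab.mix_weight for lab in ds.labels])
    df.insert(0, "label", [lab.cls for lab in ds.labels])
    df.insert(0, "id", np.arange(ds.n_voxels))
    df.to_csv(path, index=False)


def read_dataset_csv(path) -> tuple[CurveSet, np.ndarray, np.ndarray]:
    """Returns (signal CurveSet, label array, mix-weight array)."""
    df = pd.read_csv(path)
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].replace(".", "", 1).isdigit()]
    grid = _grid_from_columns(tcols)
    cs = CurveSet(df["id"].to_numpy(), grid, df[tcols].to_numpy(float), "signal")
    return cs, df["label"].to_numpy(), df["mix_weight"].to_numpy()


def write_phantom_nifti(values: np.ndarray, path, dt: float = 1.0) -> None:
    """Write an (n_voxels, n_times) matrix as a 4D NIfTI phantom of shape
    (n_voxels, 1, 1, n_times); the time step is stored in the header zooms."""
    values = np.asarray(values, dtype=float)
    arr = values.reshape(values.shape[0], 1, 1, values.shape[1])
    img = nib.Nifti1Image(arr, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, dt))
    nib.save(img, str(path))


def read_perfusion_nifti(
    path, slice_index: int, dt: float = 1.0, n_discard: int = 2
) -> CurveSet:
    """Extract per-voxel signal curves from one slice of a 4D series.

    The first ``n_discard`` volumes are dropped (pre-steady-state frames;
    time 0 is assigned to the first retained volume). Voxel ids encode
    0-based (row, col) as ``r<row>c<col>``.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError("perfusion input must be a 4D NIfTI series")
    nz = img.shape[2]
    if not 0 <= slice_index < nz:
        raise ValueError(f"slice_index {slice_index} out of range [0, {nz})")
    data = np.asarray(img.dataobj)[:, :, slice_index, :]
    if n_discard < 0 or n_discard >= data.shape[-1] - 1:
        raise ValueError("n_discard leaves too few volumes")
    data = data[..., n_discard:]
    nr, nc, nt = data.shape
    ids = np.array([f"r{r}c{c}" for r in range(nr) for c in range(nc)])
    grid = TimeGrid(0.0, nt * dt, dt)
    return CurveSet(ids, grid, data.reshape(nr * nc, nt).astype(float), "signal")


def _config_to_dict(cfg: SimulationConfig) -> dict:
    return cfg.to_dict()


def save_config(cfg: SimulationConfig, path) -> None:
    path = Path(path)
    data = _config_to_dict(cfg)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_config(path) -> SimulationConfig:
    from .simulate import (
        AifModelParams, NoiseSpec, TissueClassSpec,
    )

    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return SimulationConfig(
        grid=TimeGrid(**data["grid"]),
        aif=AifModelParams(**data["aif"]),
        tissues=tuple(TissueClassSpec(**t) for t in data["tissues"]),
        n_true_arterial=data["n_true_arterial"],
        false_t0_values=tuple(data["false_t0_values"]),
        false_delay_values=tuple(data["false_delay_values"]),
        n_pve=data["n_pve"],
        s0=data["s0"],
        te=data["te"],
        gm_peak_drop=data["gm_peak_drop"],
        noise=NoiseSpec(**data["noise"]),
        residue_shape=data["residue_shape"],
        mtt_jitter=data["mtt_jitter"],
        mtt_floor=data["mtt_floor"],
    )


def config_hash(cfg: SimulationConfig) -> str:
    blob = json.dumps(_config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_metadata(path, cfg: SimulationConfig, seed: int, extra: dict | None = None) -> None:
    from . import __version__

    meta = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "config": _config_to_dict(cfg),
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2))
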