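"""Dataset, volume and result file formats.

HDF5 is the canonical container for trace datasets and 4D volumes (arrays
plus metadata, partial reads); CSV for tabular summaries and centerlines;
YAML for configs.  Every writer embeds a schema version and an echo of the
producing configuration so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .mapping import Vessel, VesselSet, Volume4D
from .simulate import HierarchicalDistConfig, TraceDataset, TraceRecipe

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_volume",
    "read_volume",
    "read_centerlines",
    "write_vessel_results",
    "load_config",
    "dump_config",
]

DATASET_SCHEMA = 1
VOLUME_SCHEMA = 1


def _recipe_to_row(r: TraceRecipe) -> dict:
    return {
        "flux_label": r.flux_label,
        "peak_times": r.peak_times,
        "peak_heights": r.peak_heights,
        "peak_fwhms": r.peak_fwhms,
        "noise_amplitude": r.noise_amplitude,
        "sine_freq": r.sine_freq,
        "sine_amp": r.sine_amp,
        "sine_phase": r.sine_phase,
    }


def write_dataset(dataset: TraceDataset, path, config: HierarchicalDistConfig | None = None,
                  seed: int | None = None) -> None:
    """Write a labeled trace dataset to HDF5 (lossless round-trip)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = DATASET_SCHEMA
        f.attrs["dt"] = dataset.dt
        f.attrs["duration"] = dataset.duration
        if seed is not None:
            f.attrs["seed"] = seed
        if config is not None:
            f.attrs["config_yaml"] = yaml.safe_dump(dataclasses.asdict(config))
        f.attrs["meta_json"] = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in dataset.meta.items()}
        )
        f.create_dataset("traces", data=np.asarray(dataset.traces, dtype=np.float32))
        f.create_dataset("labels", data=np.asarray(dataset.labels, dtype=np.float64))
        g = f.create_group("recipes")
        vfloat = h5py.vlen_dtype(np.float64)
        n = len(dataset.recipes)
        for name in ("peak_times", "peak_heights", "peak_fwhms"):
            d = g.create_dataset(name, (n,), dtype=vfloat)
            for i, r in enumerate(dataset.recipes):
                d[i] = getattr(r, name)
        for name in ("flux_label", "noise_amplitude", "sine_freq", "sine_amp", "sine_phase"):
            g.create_dataset(
                name, data=np.array([getattr(r, name) for r in dataset.recipes])
            )


def read_dataset(path) -> TraceDataset:
    """Read a dataset written by :func:`write_dataset`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != DATASET_SCHEMA:
            raise SchemaError(
                f"dataset schema version {version!r} does not match expected {DATASET_SCHEMA}"
            )
        for group in ("traces", "labels"):
            if group not in f:
                raise SchemaError(f"dataset file is missing the /{group} group")
        traces = f["traces"][...]
        labels = f["labels"][...]
        dt = float(f.attrs["dt"])
        duration = float(f.attrs["duration"])
        meta = json.loads(f.attrs.get("meta_json", "{}"))
        recipes = []
        if "recipes" in f:
            g = f["recipes"]
            n = g["flux_label"].shape[0]
            for i in range(n):
                recipes.append(
                    TraceRecipe(
                        flux_label=float(g["flux_label"][i]),
                        peak_times=g["peak_times"][i],
                        peak_heights=g["peak_heights"][i],
                        peak_fwhms=g["peak_fwhms"][i],
                        noise_amplitude=float(g["noise_amplitude"][i]),
                        sine_freq=float(g["sine_freq"][i]),
                        sine_amp=float(g["sine_amp"][i]),
                        sine_phase=float(g["sine_phase"][i]),
                        duration=duration,
                        dt=dt,
                    )
                )
    if "category_edges" in meta:
        meta["category_edges"] = tuple(meta["category_edges"])
    return TraceDataset(traces=traces, labels=labels, recipes=recipes, dt=dt, meta=meta)


def write_volume(volume: Volume4D, path) -> None:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, volume.intensity, photometric="minisblack")
        return
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = VOLUME_SCHEMA
        f.attrs["dt"] = volume.dt
        f.attrs["voxel_size_um"] = volume.voxel_size_um
        f.create_dataset("volume", data=volume.intensity)


def read_volume(path, dt: float | None = None) -> Volume4D:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        if dt is None:
            raise ValueError("dt must be given when reading a TIFF volume")
        return Volume4D(tifffile.imread(path), dt=dt)
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != VOLUME_SCHEMA:
            raise SchemaError("volume file has an unexpected schema version")
        if "volume" not in f:
            raise SchemaError("volume file is missing the /volume dataset")
        return Volume4D(
            f["volume"][...],
            dt=float(f.attrs["dt"]),
            voxel_size_um=tuple(f.attrs["voxel_size_um"]),
        )


def read_centerlines(path) -> VesselSet:
    """CSV with columns vessel_id, x, y, z (ordered along each vessel)."""
    df = pd.read_csv(path)
    required = {"vessel_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise SchemaError(f"centerline CSV must have columns {sorted(required)}")
    vessels = []
    for vid, sub in df.groupby("vessel_id", sort=True):
        vessels.append(
            Vessel(vessel_id=int(vid), centerline=sub[["x", "y", "z"]].to_numpy())
        )
    return VesselSet(vessels)


def write_vessel_results(vessels: VesselSet, path) -> None:
    rows = [
        {
            "vessel_id": v.vessel_id,
            "flux": v.flux,
            "sigma": v.sigma,
            "n_voxels": len(v.centerline),
        }
        for v in vessels
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("config file must contain a mapping")
    return cfg


def dump_config(obj, path) -> None:
    data = dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else dict(obj)
    with open(path, "w") as f:
        yaml.safe_dump(data, f)
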