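"""File formats: HDF5 phase-space containers, dose grids, configs, provenance.

Phase-space layout: one HDF5 file with datasets ``energy, x, y, u, v, w,
weight, history_id`` and attributes ``plane_z``, ``plane_direction``,
``plane_terminate``, ``n_primaries`` (plus any metadata the caller attaches).
Round-trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .pipeline import CaseConfig
from .transport import DoseGrid, PhaseSpaceBatch, PlaneSpec


def write_phase_space(path, batch: PhaseSpaceBatch) -> None:
    with h5py.File(path, "w") as f:
        for name in PhaseSpaceBatch.FIELDS:
            f.create_dataset(name, data=getattr(batch, name))
        if batch.plane is not None:
            f.attrs["plane_z"] = batch.plane.z
            f.attrs["plane_direction"] = batch.plane.direction
            f.attrs["plane_terminate"] = batch.plane.terminate
        f.attrs["n_primaries"] = batch.n_primaries
        for k, v in getattr(batch, "meta", {}).items():
            f.attrs[f"meta_{k}"] = v


def read_phase_space(path) -> PhaseSpaceBatch:
    with h5py.File(path, "r") as f:
        cols = [f[name][...] for name in PhaseSpaceBatch.FIELDS]
        plane = None
        if "plane_z" in f.attrs:
            plane = PlaneSpec(float(f.attrs["plane_z"]),
                              int(f.attrs["plane_direction"]),
                              bool(f.attrs["plane_terminate"]))
        batch = PhaseSpaceBatch(*cols, plane=plane,
                                n_primaries=int(f.attrs["n_primaries"]))
        meta = {k[5:]: (v.item() if hasattr(v, "item") else v)
                for k, v in f.attrs.items() if k.startswith("meta_")}
        if meta:
            batch.meta = {k: (v.decode() if isinstance(v, bytes) else v)
                          for k, v in meta.items()}
    return batch


def write_dose_grid(path, grid: DoseGrid) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sum_edep", data=grid.sum_grid)
        f.create_dataset("sum_edep_sq",
                         data=grid.s2.reshape(grid.sum_grid.shape))
        f.create_dataset("depth_edges_mm", data=grid.depth_edges())
        f.attrs["x_center_cm"] = grid.x_center
        f.attrs["z_top_cm"] = grid.z_top
        f.attrs["lateral_cm"] = grid.LATERAL
        f.attrs["n_primaries"] = grid.n_primaries


def read_dose_grid(path) -> DoseGrid:
    with h5py.File(path, "r") as f:
        grid = DoseGrid(float(f.attrs["x_center_cm"]),
                        float(f.attrs["z_top_cm"]))
        grid.s1 = f["sum_edep"][...].ravel()
        grid.s2 = f["sum_edep_sq"][...].ravel()
        grid.n_primaries = int(f.attrs["n_primaries"])
    return grid


def export_central_axis_csv(path, grid: DoseGrid) -> None:
    dose, se = grid.central_axis()
    rows = np.column_stack([grid.depth_centers(), dose, se])
    header = "depth_mm,dose_per_primary_mev,se"
    np.savetxt(path, rows, delimiter=",", header=header, comments="")


def load_case_config(path) -> CaseConfig:
    """Build a CaseConfig from a YAML/JSON run-config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    label = data.pop("case", data.pop("label", "custom"))
    if label != "custom" and not data:
        return CaseConfig.preset(label)
    if label != "custom":
        return CaseConfig.preset(label, **data)
    return CaseConfig(**data)


def save_provenance(path, provenance: dict) -> None:
    Path(path).write_text(json.dumps(provenance, indent=2, default=float))
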