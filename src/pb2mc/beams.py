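"""The per-beam training/inference unit and its HDF5 container.

One beam record bundles a CT volume, a pencil-beam (PB) dose, an optional
Monte-Carlo (MC) reference dose, body/CTV masks and the beam geometry.  All
grids of a record share one world frame and, as written by the simulator,
one lattice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .grids import BeamGeometry, FormatError, VolumeGrid

__all__ = ["BeamSample", "write_beam_h5", "read_beam_h5"]


@dataclass
class BeamSample:
    """One beam: CT, PB dose, optional MC dose, masks and geometry."""

    beam_id: str
    plan_id: str
    ct: VolumeGrid
    pb: VolumeGrid
    beam: BeamGeometry
    mc: VolumeGrid | None = None
    body: VolumeGrid | None = None
    ctv: VolumeGrid | None = None

    def __post_init__(self) -> None:
        for name in ("pb", "mc", "body", "ctv"):
            g = getattr(self, name)
            if g is not None and g.shape != self.ct.shape:
                raise ValueError(f"{name} shape {g.shape} != ct shape {self.ct.shape}")
        for m in (self.body, self.ctv):
            if m is not None:
                m.validate_mask()


_GRID_KEYS = ("ct", "pb", "mc", "body", "ctv")


def write_beam_h5(sample: BeamSample, path) -> None:
    with h5py.File(Path(path), "w") as f:
        f.attrs["beam_id"] = sample.beam_id
        f.attrs["plan_id"] = sample.plan_id
        for k, v in sample.beam.to_dict().items():
            f.attrs[k] = v
        for key in _GRID_KEYS:
            grid = getattr(sample, key)
            if grid is None:
                continue
            ds = f.create_dataset(
                key, data=grid.values, compression="gzip", track_times=False
            )
            ds.attrs["spacing"] = grid.spacing
            ds.attrs["origin"] = grid.origin


def read_beam_h5(path) -> BeamSample:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for key in ("ct", "pb"):
            if key not in f:
                raise FormatError(f"{path}: missing dataset '{key}'")
        grids: dict[str, VolumeGrid | None] = {}
        for key in _GRID_KEYS:
            if key not in f:
                grids[key] = None
                continue
            ds = f[key]
            spacing = tuple(float(s) for s in ds.attrs["spacing"])
            if any(s <= 0 for s in spacing):
                raise FormatError(f"{path}/{key}: non-positive spacing {spacing}")
            grids[key] = VolumeGrid(
                np.asarray(ds), spacing, tuple(float(o) for o in ds.attrs["origin"])
            )
        beam = BeamGeometry(
            gantry_deg=float(f.attrs["gantry_deg"]),
            couch_deg=float(f.attrs["couch_deg"]),
            isocenter=tuple(float(x) for x in f.attrs["isocenter"]),
            prescribed_dose=float(f.attrs["prescribed_dose"]),
        )
        beam_id = str(f.attrs["beam_id"])
        plan_id = str(f.attrs["plan_id"])
    try:
        return BeamSample(
            beam_id=beam_id, plan_id=plan_id, ct=grids["ct"], pb=grids["pb"],
            beam=beam, mc=grids["mc"], body=grids["body"], ctv=grids["ctv"],
        )
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e
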