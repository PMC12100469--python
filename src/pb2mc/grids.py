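"""Volumetric data types, coordinate transforms, resampling and file I/O.

Axis convention, fixed package-wide: array index axis 0 is patient
superior-inferior (SI), axis 1 anterior-posterior (AP), axis 2 right-left
(RL).  World coordinates are ordered the same way, in millimetres.  Voxel
*centres* carry coordinates: ``origin`` is the world position of the centre
of voxel (0, 0, 0), so ``world = origin + index * spacing`` on each axis.
Only axis-aligned grids are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "BeamGeometry",
    "FormatError",
    "world_to_voxel",
    "voxel_to_world",
    "resample",
    "read_volume",
    "write_volume",
]


class FormatError(ValueError):
    """A file could not be parsed as a valid volume (names the offending field)."""


@dataclass
class VolumeGrid:
    """A scalar 3D field on a regular, axis-aligned grid.

    ``values`` holds HU for CT, GyRBE for dose, or {0, 1} for masks.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite (no NaN/Inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy_with(self, values: np.ndarray) -> "VolumeGrid":
        return replace(self, values=values)

    def is_mask(self) -> bool:
        return bool(np.isin(self.values, (0, 1)).all())

    def validate_mask(self) -> None:
        if not self.is_mask():
            bad = np.setdiff1d(np.unique(self.values), [0, 1])
            raise ValueError(f"mask contains non-binary values {bad[:5]}")


@dataclass
class BeamGeometry:
    """Beam delivery geometry: gantry/couch angles, isocenter, prescription.

    Angles are degrees, normalised to [0, 360).  The isocenter is a world
    position in mm (SI, AP, RL).  ``prescribed_dose`` is GyRBE per beam.
    """

    gantry_deg: float
    couch_deg: float
    isocenter: tuple[float, float, float]
    prescribed_dose: float

    def __post_init__(self) -> None:
        self.gantry_deg = float(self.gantry_deg) % 360.0
        self.couch_deg = float(self.couch_deg) % 360.0
        self.isocenter = tuple(float(x) for x in self.isocenter)
        self.prescribed_dose = float(self.prescribed_dose)
        if self.prescribed_dose <= 0:
            raise ValueError("prescribed_dose must be > 0")

    def to_dict(self) -> dict:
        return {
            "gantry_deg": self.gantry_deg,
            "couch_deg": self.couch_deg,
            "isocenter": list(self.isocenter),
            "prescribed_dose": self.prescribed_dose,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeamGeometry":
        return cls(
            gantry_deg=d["gantry_deg"],
            couch_deg=d["couch_deg"],
            isocenter=tuple(d["isocenter"]),
            prescribed_dose=d["prescribed_dose"],
        )


def world_to_voxel(grid: VolumeGrid, point) -> np.ndarray:
    """Continuous voxel index of a world point (mm).  May be fractional,
    negative or beyond the array extent."""
    p = np.asarray(point, dtype=float)
    return (p - np.asarray(grid.origin)) / np.asarray(grid.spacing)


def voxel_to_world(grid: VolumeGrid, index) -> np.ndarray:
    """World position (mm) of a continuous voxel index."""
    i = np.asarray(index, dtype=float)
    return np.asarray(grid.origin) + i * np.asarray(grid.spacing)


def resample(
    grid: VolumeGrid,
    target_spacing,
    target_shape,
    target_origin,
    fill: float = 0.0,
    *,
    nearest: bool = False,
) -> VolumeGrid:
    """Resample onto a new axis-aligned lattice.

    Trilinear interpolation by default; ``nearest=True`` for masks.
    Voxels whose centre falls outside the source support take ``fill``.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    target_shape = tuple(int(n) for n in target_shape)
    if any(s <= 0 for s in target_spacing) or any(n <= 0 for n in target_shape):
        raise ValueError("target spacing and shape must be strictly positive")
    axes = [
        (float(target_origin[a]) + target_spacing[a] * np.arange(target_shape[a])
         - grid.origin[a]) / grid.spacing[a]
        for a in range(3)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        grid.values.astype(np.float64, copy=False),
        np.stack([c.ravel() for c in coords]),
        order=0 if nearest else 1,
        mode="constant",
        cval=fill,
        prefilter=False,
    ).reshape(target_shape)
    return VolumeGrid(out, target_spacing, tuple(float(o) for o in target_origin))


# ---------------------------------------------------------------------------
# File I/O: NRRD / NIfTI via SimpleITK, plus an HDF5 beam container.
# ---------------------------------------------------------------------------

_SITK_EXT = (".nrrd", ".nhdr", ".nii", ".nii.gz")


def _sitk_suffix(path: Path) -> str:
    name = path.name.lower()
    for ext in _SITK_EXT:
        if name.endswith(ext):
            return ext
    return path.suffix.lower()


def read_volume(path, *, mask: bool = False) -> VolumeGrid:
    """Read a volume from NRRD, NIfTI or the package HDF5 container.

    With ``mask=True`` the values are validated to be binary.
    """
    path = Path(path)
    ext = _sitk_suffix(path)
    if ext in _SITK_EXT:
        grid = _read_sitk(path)
    elif ext in (".h5", ".hdf5"):
        grid = _read_h5_single(path)
    else:
        raise FormatError(f"unknown volume extension {ext!r} for {path}")
    if mask:
        try:
            grid.validate_mask()
        except ValueError as e:
            raise FormatError(f"{path}: {e}") from e
    return grid


def write_volume(grid: VolumeGrid, path) -> None:
    path = Path(path)
    ext = _sitk_suffix(path)
    if ext in _SITK_EXT:
        _write_sitk(grid, path)
    elif ext in (".h5", ".hdf5"):
        _write_h5_single(grid, path)
    else:
        raise FormatError(f"unknown volume extension {ext!r} for {path}")


def _read_sitk(path: Path) -> VolumeGrid:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as e:  # pragma: no cover - sitk error text varies
        raise FormatError(f"cannot read {path}: {e}") from e
    arr = sitk.GetArrayFromImage(img)  # (z, y, x) = our (SI, AP, RL)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected 3 dimensions, got {arr.ndim}")
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if any(s <= 0 for s in spacing):
        raise FormatError(f"{path}: non-positive spacing {spacing}")
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{path}: values contain NaN/Inf")
    return VolumeGrid(np.asarray(arr), spacing, origin)


def _write_sitk(grid: VolumeGrid, path: Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values))
    img.SetSpacing(tuple(reversed(grid.spacing)))
    img.SetOrigin(tuple(reversed(grid.origin)))
    sitk.WriteImage(img, str(path))


def _read_h5_single(path: Path) -> VolumeGrid:
    import h5py

    with h5py.File(path, "r") as f:
        if "values" not in f:
            raise FormatError(f"{path}: missing dataset 'values'")
        ds = f["values"]
        values = np.asarray(ds)
        spacing = tuple(float(s) for s in ds.attrs.get("spacing", ()))
        origin = tuple(float(o) for o in ds.attrs.get("origin", (0, 0, 0)))
    if len(spacing) != 3:
        raise FormatError(f"{path}: attribute 'spacing' missing or malformed")
    if any(s <= 0 for s in spacing):
        raise FormatError(f"{path}: non-positive spacing {spacing}")
    if values.ndim != 3:
        raise FormatError(f"{path}: dataset 'values' must be 3D")
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: values contain NaN/Inf")
    return VolumeGrid(values, spacing, origin)


def _write_h5_single(grid: VolumeGrid, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        ds = f.create_dataset("values", data=grid.values)
        ds.attrs["spacing"] = grid.spacing
        ds.attrs["origin"] = grid.origin
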