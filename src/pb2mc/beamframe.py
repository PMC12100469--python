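"""Canonical beam-frame preprocessing.

Every proton field is rotated about its isocenter so that the beam is
virtually delivered at the canonical machine position (gantry 270°, couch
0°), cropped to a fixed tensor centred on the isocenter, and normalised:
CT to [0, 1] over a fixed HU window, doses by the maximum pencil-beam dose
inside the crop.  Model output is denormalised and rotated backward onto
the clinical lattice.

Conventions (fixed, asserted by tests rather than inferred):

* world/index axes are (SI, AP, RL); at gantry 270°, couch 0° the beam
  travels along +RL;
* the canonicalising rotation undoes the couch angle first (rotation about
  the AP axis through the isocenter), then the gantry offset from 270°
  (about the SI axis);
* rotation + crop are composed into a single affine resample so each
  volume is interpolated exactly once;
* zoom augmentation scales content isotropically about the isocenter in
  the canonical frame, leaving the lattice and dose values untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import BeamGeometry, VolumeGrid

__all__ = [
    "CanonicalConfig",
    "CanonicalSample",
    "beam_direction",
    "rotation_matrix",
    "rotate_about_isocenter",
    "zoom_about_isocenter",
    "to_canonical",
    "from_canonical",
    "augment_training_set",
]

CANONICAL_GANTRY = 270.0

# Zoom factors explored as the augmentation hyperparameter window.
ZOOM_MIN, ZOOM_MAX = 0.7, 1.3


def _rot_si(theta_deg: float) -> np.ndarray:
    """Rotation about the SI axis (acts on the AP-RL plane)."""
    c, s = np.cos(np.radians(theta_deg)), np.sin(np.radians(theta_deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_ap(theta_deg: float) -> np.ndarray:
    """Rotation about the AP axis (acts on the SI-RL plane)."""
    c, s = np.cos(np.radians(theta_deg)), np.sin(np.radians(theta_deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def rotation_matrix(beam: BeamGeometry, direction: str = "forward") -> np.ndarray:
    """Rotation carrying content into (forward) or out of (backward) the
    canonical frame: undo couch about AP, then gantry offset about SI."""
    fwd = _rot_si(-(beam.gantry_deg - CANONICAL_GANTRY)) @ _rot_ap(-beam.couch_deg)
    if direction == "forward":
        return fwd
    if direction == "backward":
        return fwd.T
    raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")


def beam_direction(beam: BeamGeometry) -> np.ndarray:
    """Unit beam-travel direction in the patient frame (SI, AP, RL)."""
    # forward rotation maps this onto +RL by construction
    return rotation_matrix(beam, "forward").T @ np.array([0.0, 0.0, 1.0])


def _affine_resample(
    grid: VolumeGrid,
    rot: np.ndarray,
    center,
    out_shape,
    out_spacing,
    out_origin,
    fill: float,
    nearest: bool = False,
) -> VolumeGrid:
    """Resample so that out(x) = in(center + rot^T (x - center)) on the
    requested output lattice.  One interpolation pass."""
    center = np.asarray(center, dtype=float)
    axes = [
        float(out_origin[a]) + float(out_spacing[a]) * np.arange(out_shape[a])
        for a in range(3)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1) - center
    src_world = pts @ rot + center  # rows: center + rot^T (x - center)
    src_idx = (src_world - np.asarray(grid.origin)) / np.asarray(grid.spacing)
    out = ndimage.map_coordinates(
        grid.values.astype(np.float64, copy=False),
        src_idx.T,
        order=0 if nearest else 1,
        mode="constant",
        cval=fill,
        prefilter=False,
    ).reshape(tuple(out_shape))
    return VolumeGrid(out, tuple(out_spacing), tuple(float(o) for o in out_origin))


def rotate_about_isocenter(
    grid: VolumeGrid,
    beam: BeamGeometry,
    direction: str = "forward",
    fill: float = 0.0,
    *,
    nearest: bool = False,
) -> VolumeGrid:
    """Rotate content about the isocenter into/out of the canonical frame,
    trilinearly resampled onto the *same* lattice."""
    rot = rotation_matrix(beam, direction)
    return _affine_resample(
        grid, rot, beam.isocenter, grid.shape, grid.spacing, grid.origin,
        fill, nearest=nearest,
    )


def zoom_about_isocenter(
    grid: VolumeGrid,
    factor: float,
    isocenter=None,
    fill: float = 0.0,
    *,
    nearest: bool = False,
) -> VolumeGrid:
    """Scale content isotropically by ``factor`` about the isocenter onto
    the same lattice.  Geometry only; values are not rescaled."""
    if not (ZOOM_MIN <= factor <= ZOOM_MAX):
        raise ValueError(
            f"zoom factor {factor} outside the explored window "
            f"[{ZOOM_MIN}, {ZOOM_MAX}]"
        )
    if isocenter is None:
        isocenter = tuple(
            grid.origin[a] + grid.spacing[a] * (grid.shape[a] - 1) / 2.0
            for a in range(3)
        )
    rot = np.eye(3) / factor  # out(x) = in(iso + (x - iso)/factor)
    return _affine_resample(
        grid, rot.T, isocenter, grid.shape, grid.spacing, grid.origin,
        fill, nearest=nearest,
    )


def _zoom_array(values: np.ndarray, factor: float) -> np.ndarray:
    """Zoom a canonical-frame array about the tensor centre voxel."""
    center = (np.asarray(values.shape) - 1) / 2.0
    axes = [np.arange(n, dtype=float) for n in values.shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = [center[a] + (mesh[a] - center[a]) / factor for a in range(3)]
    return ndimage.map_coordinates(
        values.astype(np.float64, copy=False),
        np.stack([c.ravel() for c in coords]),
        order=1, mode="constant", cval=0.0, prefilter=False,
    ).reshape(values.shape)


@dataclass
class CanonicalConfig:
    """Tensor geometry and normalisation for the model input frame."""

    tensor_shape: tuple[int, int, int] = (48, 80, 80)
    tensor_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    hu_window: tuple[float, float] = (-1000.0, 2000.0)
    rotate: bool = True  # False = ablation baseline (native beam angles)

    def to_dict(self) -> dict:
        return {
            "tensor_shape": list(self.tensor_shape),
            "tensor_spacing": list(self.tensor_spacing),
            "hu_window": list(self.hu_window),
            "rotate": self.rotate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CanonicalConfig":
        return cls(
            tensor_shape=tuple(d["tensor_shape"]),
            tensor_spacing=tuple(d["tensor_spacing"]),
            hu_window=tuple(d["hu_window"]),
            rotate=bool(d.get("rotate", True)),
        )


@dataclass
class CanonicalSample:
    """One beam in canonical tensor form.

    ``ct_norm`` lies in [0, 1]; doses are fractions of ``pb_max`` (the
    maximum PB dose inside the crop), so max(pb_norm) == 1 for freshly
    canonicalised beams.  ``mc_norm`` is normalised by ``pb_max`` too, not
    by its own maximum, so amplitude differences remain learnable.
    """

    ct_norm: np.ndarray
    pb_norm: np.ndarray
    mc_norm: np.ndarray | None
    pb_max: float
    beam: BeamGeometry
    tensor_shape: tuple[int, int, int]
    tensor_spacing: tuple[float, float, float]
    beam_id: str = ""
    plan_id: str = ""
    zoom_factor: float = 1.0


def _canonical_lattice(config: CanonicalConfig, isocenter):
    """Origin of the crop lattice placing the isocenter at voxel shape//2."""
    shape = config.tensor_shape
    sp = config.tensor_spacing
    return tuple(
        float(isocenter[a]) - sp[a] * (shape[a] // 2) for a in range(3)
    )


def to_canonical(
    ct: VolumeGrid,
    pb: VolumeGrid,
    mc: VolumeGrid | None,
    beam: BeamGeometry,
    config: CanonicalConfig,
    *,
    beam_id: str = "",
    plan_id: str = "",
) -> CanonicalSample:
    """Forward-rotate, crop to the tensor lattice and normalise one beam.

    Rotation and crop are one composed resample per volume.
    """
    rot = (
        rotation_matrix(beam, "forward") if config.rotate else np.eye(3)
    )
    origin = _canonical_lattice(config, beam.isocenter)
    shape, sp = config.tensor_shape, config.tensor_spacing

    def grab(grid: VolumeGrid, fill: float) -> np.ndarray:
        return _affine_resample(
            grid, rot, beam.isocenter, shape, sp, origin, fill
        ).values

    ct_c = grab(ct, -1000.0)
    pb_c = grab(pb, 0.0)
    pb_max = float(pb_c.max())
    if pb_max <= 0:
        raise ValueError("degenerate beam: PB dose is zero inside the crop")
    lo, hi = config.hu_window
    ct_norm = np.clip((ct_c - lo) / (hi - lo), 0.0, 1.0)
    mc_norm = grab(mc, 0.0) / pb_max if mc is not None else None
    return CanonicalSample(
        ct_norm=ct_norm.astype(np.float32),
        pb_norm=(pb_c / pb_max).astype(np.float32),
        mc_norm=None if mc_norm is None else mc_norm.astype(np.float32),
        pb_max=pb_max,
        beam=beam,
        tensor_shape=tuple(shape),
        tensor_spacing=tuple(sp),
        beam_id=beam_id,
        plan_id=plan_id,
    )


def from_canonical(
    dose_norm: np.ndarray,
    sample: CanonicalSample,
    target_grid: VolumeGrid,
    config: CanonicalConfig,
) -> VolumeGrid:
    """Denormalise a canonical-frame dose tensor and rotate it backward
    onto the lattice of ``target_grid``."""
    if tuple(dose_norm.shape) != tuple(sample.tensor_shape):
        raise ValueError(
            f"dose_norm shape {dose_norm.shape} != tensor shape {sample.tensor_shape}"
        )
    origin = _canonical_lattice(
        CanonicalConfig(
            tensor_shape=sample.tensor_shape,
            tensor_spacing=sample.tensor_spacing,
            rotate=config.rotate,
        ),
        sample.beam.isocenter,
    )
    canon = VolumeGrid(
        np.asarray(dose_norm, dtype=np.float64) * sample.pb_max,
        sample.tensor_spacing,
        origin,
    )
    rot = (
        rotation_matrix(sample.beam, "backward") if config.rotate else np.eye(3)
    )
    return _affine_resample(
        canon, rot, sample.beam.isocenter,
        target_grid.shape, target_grid.spacing, target_grid.origin,
        fill=0.0,
    )


def augment_training_set(
    samples: list[CanonicalSample],
    factors: tuple[float, ...] = (0.8, 1.2),
) -> list[CanonicalSample]:
    """Originals plus one zoomed copy per factor per sample.

    Output count = (1 + len(factors)) x input count; CT and dose channels
    are zoomed identically; originals are returned untouched.
    """
    out = list(samples)
    for factor in factors:
        if not (ZOOM_MIN <= factor <= ZOOM_MAX):
            raise ValueError(f"zoom factor {factor} outside [{ZOOM_MIN}, {ZOOM_MAX}]")
        for s in samples:
            out.append(
                CanonicalSample(
                    ct_norm=_zoom_array(s.ct_norm, factor).astype(np.float32),
                    pb_norm=_zoom_array(s.pb_norm, factor).astype(np.float32),
                    mc_norm=(
                        None if s.mc_norm is None
                        else _zoom_array(s.mc_norm, factor).astype(np.float32)
                    ),
                    pb_max=s.pb_max,
                    beam=s.beam,
                    tensor_shape=s.tensor_shape,
                    tensor_spacing=s.tensor_spacing,
                    beam_id=s.beam_id,
                    plan_id=s.plan_id,
                    zoom_factor=factor,
                )
            )
    return out
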