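"""Synthetic heterogeneous phantoms and paired PB-like / MC-like dose fields.

No public proton dataset exists for the dose-conversion task, so this
module manufactures the whole study: head-like CT phantoms (soft-tissue
ellipsoid with embedded air cavities and bone slabs), a spread-out Bragg
peak (SOBP) depth-dose model, and two ray-tracing dose engines that share
everything except the error the conversion model is meant to remove:

* the MC-like engine computes the water-equivalent depth (WED) of every
  ray independently and applies depth-dependent lateral scatter smearing;
* the PB-like engine replaces each ray's WED by the lateral average over a
  beamlet-width neighbourhood and applies no smearing, so the two agree in
  homogeneous media and diverge at distal edges behind heterogeneities —
  the classic failure mode of analytical pencil-beam algorithms.

Voxel dose is depth dose x aperture profile x local relative stopping
power (a dose-to-medium surrogate that also kills dose upstream in air).
Each field is normalised so the CTV median equals the prescription.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, special
from scipy.optimize import nnls

from .beams import BeamSample, write_beam_h5
from .beamframe import rotate_about_isocenter
from .grids import BeamGeometry, VolumeGrid

__all__ = [
    "PhantomSpec",
    "BeamSimSpec",
    "DepthDoseModel",
    "GenerationError",
    "SimulationError",
    "make_phantom",
    "hu_to_rsp",
    "build_sobp",
    "simulate_mc_like",
    "simulate_pb_like",
    "make_dataset",
]

HU_AIR, HU_SOFT, HU_BONE = -1000.0, 0.0, 700.0


class GenerationError(RuntimeError):
    """Phantom construction could not satisfy a placement constraint."""


class SimulationError(RuntimeError):
    """Beam geometry incompatible with the phantom (e.g. misses the body)."""


# ---------------------------------------------------------------------------
# CT phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Head-like phantom recipe: ellipsoidal body, air cavities, bone slabs."""

    shape: tuple[int, int, int] = (48, 80, 80)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    body_semiaxes: tuple[float, float, float] = (42.0, 70.0, 70.0)  # mm
    n_air_cavities: int = 2
    n_bone_slabs: int = 2
    cavity_semiaxis_range: tuple[float, float] = (6.0, 14.0)  # mm
    slab_thickness_range: tuple[float, float] = (4.0, 10.0)  # mm
    slab_extent_range: tuple[float, float] = (20.0, 50.0)  # mm
    ctv_semiaxis_range: tuple[float, float] = (10.0, 18.0)  # mm
    smooth_sigma_vox: float = 0.6  # Gaussian blur of the label CT, voxels
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "body_semiaxes": list(self.body_semiaxes),
            "n_air_cavities": self.n_air_cavities,
            "n_bone_slabs": self.n_bone_slabs,
            "cavity_semiaxis_range": list(self.cavity_semiaxis_range),
            "slab_thickness_range": list(self.slab_thickness_range),
            "slab_extent_range": list(self.slab_extent_range),
            "ctv_semiaxis_range": list(self.ctv_semiaxis_range),
            "smooth_sigma_vox": self.smooth_sigma_vox,
            "seed": self.seed,
        }


def _ellipsoid_mask(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    axes = [spacing[a] * np.arange(shape[a]) for a in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    q = sum(
        ((mesh[a] - center_mm[a]) / semiaxes_mm[a]) ** 2 for a in range(3)
    )
    return q <= 1.0


def make_phantom(spec: PhantomSpec):
    """Build (ct, body, ctv) deterministically from ``spec.seed``.

    The CTV is placed first; the first heterogeneity (cavity if any, else
    slab) is anchored within 20 mm of the CTV surface so that PB-vs-MC
    disagreement is guaranteed near the target.  Heterogeneities are kept
    strictly inside the body and pairwise disjoint (air cavities).
    """
    rng = np.random.default_rng(spec.seed)
    shape, sp = spec.shape, spec.spacing
    extent = np.array([sp[a] * (shape[a] - 1) for a in range(3)])
    body_center = extent / 2.0
    body_ax = np.asarray(spec.body_semiaxes, dtype=float)
    if np.any(body_ax * 2 > extent):
        raise GenerationError(
            f"body semi-axes {tuple(body_ax)} do not fit grid extent {tuple(extent)}"
        )
    body = _ellipsoid_mask(shape, sp, body_center, body_ax)

    def sample_inside_body(margin_mm, max_tries=200):
        for _ in range(max_tries):
            u = rng.uniform(-1, 1, size=3)
            c = body_center + u * (body_ax - margin_mm)
            if np.all(margin_mm < body_ax) and np.sum(
                ((c - body_center) / np.maximum(body_ax - margin_mm, 1e-9)) ** 2
            ) <= 1.0:
                return c
        raise GenerationError(
            f"could not place a component with margin {margin_mm} mm inside the body"
        )

    # CTV: modest ellipsoid away from the body surface
    ctv_ax = rng.uniform(*spec.ctv_semiaxis_range, size=3)
    ctv_center = sample_inside_body(np.max(ctv_ax) + 10.0)
    ctv = _ellipsoid_mask(shape, sp, ctv_center, ctv_ax)

    labels = np.full(shape, HU_AIR, dtype=np.float64)
    labels[body] = HU_SOFT

    placed_cavities: list[tuple[np.ndarray, float]] = []

    def near_ctv_center(size_mm):
        # anchor within 20 mm of the CTV surface, along a random direction;
        # components are clipped to the body, so only the centre must stay
        # comfortably inside
        margin = min(size_mm, 8.0)
        for _ in range(400):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            gap = rng.uniform(2.0, 18.0)
            c = ctv_center + d * (np.max(ctv_ax) + gap + 0.5 * size_mm)
            if np.sum(((c - body_center) / np.maximum(body_ax - margin, 1e-9)) ** 2) <= 1.0:
                return c
        raise GenerationError("could not anchor a heterogeneity near the CTV")

    # bone slabs first so cavities carved later stay air
    for i in range(spec.n_bone_slabs):
        thick = rng.uniform(*spec.slab_thickness_range)
        ext = rng.uniform(*spec.slab_extent_range, size=2)
        half = np.empty(3)
        axis = int(rng.integers(0, 3))
        half[axis] = thick / 2.0
        half[[a for a in range(3) if a != axis]] = ext / 2.0
        if i == 0:
            c = near_ctv_center(float(np.max(half)))
        else:
            c = sample_inside_body(np.max(half) + 4.0)
        axes_mm = [sp[a] * np.arange(shape[a]) for a in range(3)]
        mesh = np.meshgrid(*axes_mm, indexing="ij")
        box = np.ones(shape, dtype=bool)
        for a in range(3):
            box &= np.abs(mesh[a] - c[a]) <= half[a]
        labels[box & body & ~ctv] = HU_BONE

    for i in range(spec.n_air_cavities):
        for attempt in range(200):
            ax = rng.uniform(*spec.cavity_semiaxis_range, size=3)
            if i == 0:
                c = near_ctv_center(float(np.max(ax)))
            else:
                c = sample_inside_body(np.max(ax) + 4.0)
            # keep cavities pairwise disjoint so components stay countable
            if all(
                np.linalg.norm(c - pc) > np.max(ax) + pr + max(sp)
                for pc, pr in placed_cavities
            ):
                break
        else:
            raise GenerationError(f"could not place disjoint air cavity {i}")
        cav = _ellipsoid_mask(shape, sp, c, ax)
        labels[cav & body & ~ctv] = HU_AIR
        placed_cavities.append((c, float(np.max(ax))))

    ct_values = labels
    if spec.smooth_sigma_vox > 0:
        ct_values = ndimage.gaussian_filter(labels, spec.smooth_sigma_vox)
    ct = VolumeGrid(ct_values, sp, (0.0, 0.0, 0.0))
    body_grid = VolumeGrid(body.astype(np.uint8), sp, (0.0, 0.0, 0.0))
    ctv_grid = VolumeGrid(ctv.astype(np.uint8), sp, (0.0, 0.0, 0.0))
    return ct, body_grid, ctv_grid


# ---------------------------------------------------------------------------
# CT number -> relative stopping power
# ---------------------------------------------------------------------------

_RSP_HU = np.array([-1000.0, 0.0, 700.0])
_RSP_VAL = np.array([0.001, 1.00, 1.44])


def hu_to_rsp(hu):
    """Piecewise-linear stand-in calibration through
    (-1000 HU, 0.001), (0 HU, 1.00), (700 HU, 1.44); clamped outside."""
    return np.interp(np.asarray(hu, dtype=np.float64), _RSP_HU, _RSP_VAL)


# ---------------------------------------------------------------------------
# SOBP depth-dose model
# ---------------------------------------------------------------------------

@dataclass
class DepthDoseModel:
    """Weighted stack of range-shifted pristine Bragg-like peaks.

    The pristine curve has an entrance plateau rising from 0.35 to 0.45,
    a flat-topped unit peak between R - sigma_peak and R, and a Gaussian
    distal falloff of width sigma_distal.
    """

    R: float  # nominal (deepest) range, mm water-equivalent
    M: float  # modulation (SOBP width), mm
    ranges: np.ndarray  # per-peak ranges, mm
    weights: np.ndarray  # nonnegative peak weights
    sigma_peak: float = 3.0
    sigma_distal: float = 1.5
    plateau_level: float = 1.0  # mean SOBP dose over the modulation interval

    @staticmethod
    def pristine(d, R, sigma_peak=3.0, sigma_distal=1.5):
        d = np.asarray(d, dtype=np.float64)
        mu = R - sigma_peak
        rise = np.exp(-np.minimum(d - mu, 0.0) ** 2 / (2 * sigma_peak**2))
        fall = np.exp(-np.maximum(d - R, 0.0) ** 2 / (2 * sigma_distal**2))
        ramp_end = max(R - 3 * sigma_peak, 1e-6)
        plateau = 0.35 + 0.10 * np.clip(d / ramp_end, 0.0, 1.0)
        bump = rise * fall
        p = 8.0  # smooth-max blend exponent
        return (np.maximum(plateau * fall, 0.0) ** p + bump**p) ** (1.0 / p)

    def __call__(self, d):
        d = np.asarray(d, dtype=np.float64)
        out = np.zeros_like(d, dtype=np.float64)
        for w, r in zip(self.weights, self.ranges):
            if w > 0:
                out += w * self.pristine(d, r, self.sigma_peak, self.sigma_distal)
        return out


def build_sobp(R: float, M: float, K: int = 25, *,
               sigma_peak: float = 3.0, sigma_distal: float = 1.5,
               flatness_tol: float = 0.02) -> DepthDoseModel:
    """Fit nonnegative weights over K range-shifted pristine peaks so the
    summed depth dose is flat (within ±2%) across the modulation interval.

    The weights solve a nonnegative least squares problem against a unit
    target on a fine depth grid spanning the modulation interval.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if not (0 < M < R):
        raise ValueError(f"need 0 < M < R, got M={M}, R={R}")
    ranges = np.linspace(R - M, R, K)
    d_fit = np.arange(R - M + sigma_peak / 2, R - sigma_peak / 2, 0.25)
    A = np.stack(
        [DepthDoseModel.pristine(d_fit, r, sigma_peak, sigma_distal) for r in ranges],
        axis=1,
    )
    w, _ = nnls(A, np.ones_like(d_fit))
    model = DepthDoseModel(
        R=R, M=M, ranges=ranges, weights=w,
        sigma_peak=sigma_peak, sigma_distal=sigma_distal,
    )
    d_chk = np.arange(R - M + sigma_peak, R - sigma_peak, 0.1)
    plateau = model(d_chk)
    mean = float(plateau.mean())
    flat = float(np.max(np.abs(plateau - mean)) / mean)
    if flat > flatness_tol:
        raise GenerationError(
            f"SOBP flatness {flat:.3f} exceeds {flatness_tol}; increase K (got {K})"
        )
    model.plateau_level = mean
    return model


# ---------------------------------------------------------------------------
# Paired dose engines
# ---------------------------------------------------------------------------

@dataclass
class BeamSimSpec:
    """Geometry and beam-model parameters for one simulated field."""

    gantry_deg: float = 270.0
    couch_deg: float = 0.0
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    nominal_range: float = 100.0  # R, mm water-equivalent
    modulation: float = 40.0  # M, mm
    field_halfwidth_si: float = 20.0  # mm
    field_halfwidth_ap: float = 20.0  # mm
    prescribed_dose: float = 2.0  # GyRBE
    entrance_sigma: float = 4.0  # mm, lateral penumbra at the surface
    sigma_growth: float = 0.04  # mm penumbra per mm depth
    pb_beamlet_width: float = 10.0  # mm, PB lateral WED-averaging window
    sigma_peak: float = 3.0  # mm, pristine-peak width
    sigma_distal: float = 1.5  # mm, distal falloff width
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.modulation < self.nominal_range):
            raise ValueError("need 0 < modulation < nominal_range")
        if self.field_halfwidth_si <= 0 or self.field_halfwidth_ap <= 0:
            raise ValueError("field half-widths must be positive")

    def geometry(self) -> BeamGeometry:
        return BeamGeometry(
            gantry_deg=self.gantry_deg, couch_deg=self.couch_deg,
            isocenter=self.isocenter, prescribed_dose=self.prescribed_dose,
        )

    def to_dict(self) -> dict:
        return {
            "gantry_deg": self.gantry_deg, "couch_deg": self.couch_deg,
            "isocenter": list(self.isocenter),
            "nominal_range": self.nominal_range, "modulation": self.modulation,
            "field_halfwidth_si": self.field_halfwidth_si,
            "field_halfwidth_ap": self.field_halfwidth_ap,
            "prescribed_dose": self.prescribed_dose,
            "entrance_sigma": self.entrance_sigma,
            "sigma_growth": self.sigma_growth,
            "pb_beamlet_width": self.pb_beamlet_width,
            "sigma_peak": self.sigma_peak, "sigma_distal": self.sigma_distal,
            "seed": self.seed,
        }


def _edge(x, halfwidth, sigma):
    """Error-function aperture edge profile, 1 inside the field, ->0 outside."""
    s = np.sqrt(2.0) * np.maximum(sigma, 1e-6)
    return 0.5 * (special.erf((halfwidth - x) / s) + special.erf((halfwidth + x) / s))


def _canonical_inputs(ct: VolumeGrid, beam: BeamSimSpec,
                      body: VolumeGrid | None, ctv: VolumeGrid | None):
    geo = beam.geometry()
    ct_c = rotate_about_isocenter(ct, geo, "forward", fill=HU_AIR)
    body_c = (
        rotate_about_isocenter(body, geo, "forward", fill=0, nearest=True)
        if body is not None else None
    )
    ctv_c = (
        rotate_about_isocenter(ctv, geo, "forward", fill=0, nearest=True)
        if ctv is not None else None
    )
    return geo, ct_c, body_c, ctv_c


def _wed(ct_canonical: VolumeGrid) -> np.ndarray:
    """Cumulative water-equivalent depth along the canonical beam axis
    (+RL, array axis 2), midpoint rule, mm.  Nondecreasing along each ray."""
    rsp = hu_to_rsp(ct_canonical.values)
    ds = ct_canonical.spacing[2]
    return (np.cumsum(rsp, axis=2) - 0.5 * rsp) * ds


def _simulate(ct: VolumeGrid, beam: BeamSimSpec, dd: DepthDoseModel,
              body: VolumeGrid | None, ctv: VolumeGrid | None,
              pb_mode: bool) -> VolumeGrid:
    geo, ct_c, body_c, ctv_c = _canonical_inputs(ct, beam, body, ctv)
    shape, sp = ct_c.shape, ct_c.spacing
    rsp = hu_to_rsp(ct_c.values)
    wed = _wed(ct_c)

    # beam entry plane: first voxel along the axis where the body (or any
    # non-air tissue) appears in the aperture footprint
    iso_idx = (np.asarray(geo.isocenter) - np.asarray(ct_c.origin)) / np.asarray(sp)
    si = sp[0] * np.arange(shape[0]) - sp[0] * iso_idx[0]
    ap = sp[1] * np.arange(shape[1]) - sp[1] * iso_idx[1]
    tissue = body_c.values > 0 if body_c is not None else ct_c.values > -500
    foot = (
        (np.abs(si)[:, None] <= beam.field_halfwidth_si)
        & (np.abs(ap)[None, :] <= beam.field_halfwidth_ap)
    )
    col = tissue[foot]
    if not np.any(col):
        raise SimulationError("beam aperture does not intersect the body")
    k_entry = int(np.argmax(np.any(tissue[foot], axis=0)))
    depth = np.maximum(sp[2] * (np.arange(shape[2]) - k_entry), 0.0)
    sigma = beam.entrance_sigma + beam.sigma_growth * depth  # per-slice, mm

    if pb_mode and beam.pb_beamlet_width > max(sp[0], sp[1]):
        w_si = max(1, int(round(beam.pb_beamlet_width / sp[0])))
        w_ap = max(1, int(round(beam.pb_beamlet_width / sp[1])))
        wed = ndimage.uniform_filter(wed, size=(w_si, w_ap, 1), mode="nearest")

    dose = dd(wed)
    aperture = (
        _edge(si[:, None], beam.field_halfwidth_si, sigma[None, :])[:, None, :]
        * _edge(ap[:, None], beam.field_halfwidth_ap, sigma[None, :])[None, :, :]
    )
    dose *= aperture

    if not pb_mode:
        # depth-dependent in-slice smearing mimics accumulated scatter;
        # only the depth-grown part so the degenerate PB == MC limit holds
        for k in range(shape[2]):
            s_vox = beam.sigma_growth * depth[k]
            if s_vox > 1e-9:
                dose[:, :, k] = ndimage.gaussian_filter(
                    dose[:, :, k], (s_vox / sp[0], s_vox / sp[1])
                )

    dose *= rsp  # dose-to-medium surrogate; suppresses dose in air

    if ctv_c is not None and np.any(ctv_c.values > 0):
        med = float(np.median(dose[ctv_c.values > 0]))
        if med <= 0:
            raise SimulationError("CTV receives no dose; beam geometry invalid")
        dose *= beam.prescribed_dose / med

    dose_c = VolumeGrid(np.maximum(dose, 0.0), sp, ct_c.origin)
    out = rotate_about_isocenter(dose_c, geo, "backward", fill=0.0)
    return out.copy_with(np.maximum(out.values, 0.0))


def simulate_mc_like(ct: VolumeGrid, beam: BeamSimSpec, dd: DepthDoseModel,
                     body: VolumeGrid | None = None,
                     ctv: VolumeGrid | None = None) -> VolumeGrid:
    """Monte-Carlo-quality surrogate: per-ray WED, depth-grown scatter."""
    return _simulate(ct, beam, dd, body, ctv, pb_mode=False)


def simulate_pb_like(ct: VolumeGrid, beam: BeamSimSpec, dd: DepthDoseModel,
                     body: VolumeGrid | None = None,
                     ctv: VolumeGrid | None = None) -> VolumeGrid:
    """Pencil-beam surrogate: laterally averaged WED, no scatter smearing."""
    return _simulate(ct, beam, dd, body, ctv, pb_mode=True)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _beam_for_ctv(ct, body, ctv, gantry, couch, prescribed_dose, rng,
                  phantom_spacing, overrides=None) -> BeamSimSpec:
    """Choose R/M/aperture so the SOBP plateau covers the CTV for the
    given angles, from the WED of CTV rays in the canonical frame."""
    centroid_idx = np.array(np.nonzero(ctv.values)).mean(axis=1)
    iso = np.asarray(ctv.origin) + centroid_idx * np.asarray(ctv.spacing)
    geo = BeamGeometry(gantry, couch, tuple(iso), prescribed_dose)
    ct_c = rotate_about_isocenter(ct, geo, "forward", fill=HU_AIR)
    ctv_c = rotate_about_isocenter(ctv, geo, "forward", fill=0, nearest=True)
    wed = _wed(ct_c)
    inside = ctv_c.values > 0
    if not np.any(inside):
        raise SimulationError("CTV empty after rotation")
    wed_in = wed[inside]
    R = float(np.max(wed_in)) + 6.0
    M = float(np.clip(R - (np.min(wed_in) - 6.0), 15.0, R - 10.0))
    ii, jj, _ = np.nonzero(inside)
    sp = ctv_c.spacing
    hw_si = float(np.max(np.abs(sp[0] * ii - sp[0] * ((iso[0] - ct_c.origin[0]) / sp[0])))) + 8.0
    hw_ap = float(np.max(np.abs(sp[1] * jj - sp[1] * ((iso[1] - ct_c.origin[1]) / sp[1])))) + 8.0
    return BeamSimSpec(
        gantry_deg=gantry, couch_deg=couch, isocenter=tuple(iso),
        nominal_range=R, modulation=M,
        field_halfwidth_si=hw_si, field_halfwidth_ap=hw_ap,
        prescribed_dose=prescribed_dose,
        seed=int(rng.integers(0, 2**31 - 1)),
        **(overrides or {}),
    )


def make_dataset(
    n_train_beams: int,
    n_test_beams: int,
    out_dir,
    master_seed: int = 0,
    *,
    phantom_spec: PhantomSpec | None = None,
    beams_per_plan: int = 3,
    noncoplanar_fraction: float = 0.4,
    prescribed_dose: float = 2.0,
    beam_overrides: dict | None = None,
) -> dict:
    """Generate a per-beam HDF5 dataset plus JSON manifest.

    Beams are grouped into synthetic "plans" of ``beams_per_plan`` beams
    sharing one phantom; train and test plans use disjoint phantom seeds.
    About ``noncoplanar_fraction`` of beams receive a couch angle drawn
    from ±[10°, 30°].  Fully deterministic given ``master_seed``.
    """
    if n_train_beams < 1 or n_test_beams < 1:
        raise ValueError("beam counts must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = phantom_spec or PhantomSpec()
    ss = np.random.SeedSequence(master_seed)
    manifest = {"master_seed": int(master_seed), "beams": [],
                "phantom_spec": base.to_dict(), "beams_per_plan": beams_per_plan}

    def gen_split(split: str, n_beams: int, seed_offset: int):
        n_plans = int(np.ceil(n_beams / beams_per_plan))
        made = 0
        for p in range(n_plans):
            plan_rng = np.random.default_rng(
                np.random.SeedSequence([master_seed, seed_offset, p])
            )
            pseed = int(plan_rng.integers(0, 2**31 - 1))
            spec = PhantomSpec(**{**base.to_dict(), "seed": pseed})
            ct, body, ctv = make_phantom(spec)
            plan_id = f"{split}_plan{p:03d}"
            for b in range(beams_per_plan):
                if made >= n_beams:
                    break
                gantry = float(plan_rng.uniform(0.0, 360.0))
                if plan_rng.uniform() < noncoplanar_fraction:
                    couch = float(plan_rng.choice([-1, 1]) * plan_rng.uniform(10.0, 30.0))
                else:
                    couch = 0.0
                beam = _beam_for_ctv(ct, body, ctv, gantry, couch,
                                     prescribed_dose, plan_rng, spec.spacing,
                                     overrides=beam_overrides)
                dd = build_sobp(beam.nominal_range, beam.modulation,
                                sigma_peak=beam.sigma_peak,
                                sigma_distal=beam.sigma_distal)
                mc = simulate_mc_like(ct, beam, dd, body, ctv)
                pb = simulate_pb_like(ct, beam, dd, body, ctv)
                beam_id = f"{plan_id}_beam{b}"
                sample = BeamSample(
                    beam_id=beam_id, plan_id=plan_id, ct=ct, pb=pb,
                    beam=beam.geometry(), mc=mc, body=body, ctv=ctv,
                )
                fname = f"{beam_id}.h5"
                write_beam_h5(sample, out_dir / fname)
                manifest["beams"].append({
                    "beam_id": beam_id, "plan_id": plan_id, "split": split,
                    "file": fname, "phantom_seed": pseed,
                    "beam_spec": beam.to_dict(),
                })
                made += 1

    gen_split("train", n_train_beams, 1)
    gen_split("test", n_test_beams, 2)
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest
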