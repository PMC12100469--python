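"""Dose-distribution evaluation: 3D gamma, range maps, MAE, DSC, DVH.

All comparisons treat the MC-quality dose as the reference.  The gamma
analysis is *global*: the dose-difference criterion is a percentage of the
maximum reference dose inside the analysis mask, and voxels below the
(reference) low-dose threshold are excluded.  Range maps are beam's-eye
view: one distal threshold-crossing depth per lateral ray of the
canonical-frame dose, and the average range difference (ARD) over paired
rays is

    ARD = (100/n) * sum_i (R_ref(i) - R_eval(i)) / R_ref(i)   [%]

so an evaluated dose that overshoots (deeper range) gives a negative ARD.
DVH metrics D_x% (dose received by at least x% of the structure) use the
linearly interpolated inverse of the cumulative curve, and their relative
dose error is RDE = 100 * (D - D_ref) / D_ref.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .beamframe import CanonicalConfig, rotate_about_isocenter
from .grids import BeamGeometry, VolumeGrid

__all__ = [
    "GammaResult",
    "RangeMap",
    "DVHCurve",
    "EvalConfig",
    "EvalReport",
    "gamma_3d",
    "passing_rate",
    "range_map",
    "ard",
    "mae",
    "isodose_dsc",
    "dvh",
    "dvh_metric",
    "rde",
    "evaluate_beam",
    "evaluate_plan",
]


def _as_mask(mask) -> np.ndarray:
    if isinstance(mask, VolumeGrid):
        mask.validate_mask()
        return mask.values > 0
    return np.asarray(mask) > 0


def _check_lattice(a: VolumeGrid, b: VolumeGrid) -> None:
    if a.shape != b.shape:
        raise ValueError(f"lattice shape mismatch {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, atol=1e-6) or not np.allclose(
        a.origin, b.origin, atol=1e-6
    ):
        raise ValueError("lattice spacing/origin mismatch")


# ---------------------------------------------------------------------------
# gamma analysis
# ---------------------------------------------------------------------------

@dataclass
class GammaResult:
    gamma_values: np.ndarray  # NaN where excluded
    criteria: tuple[float, float]  # (dose %, DTA mm)
    normalization_dose: float  # GyRBE (max reference in mask)
    threshold_pct: float
    evaluated_mask: np.ndarray


def _search_offsets(dta_mm: float, spacing, search_factor: float,
                    step_fraction: float) -> np.ndarray:
    """Displacement vectors (mm) within the search sphere, sorted by norm."""
    radius = search_factor * dta_mm
    step = dta_mm * step_fraction
    n = int(np.floor(radius / step))
    axis = step * np.arange(-n, n + 1)
    mesh = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    d2 = (pts**2).sum(axis=1)
    pts = pts[d2 <= radius**2 + 1e-9]
    return pts[np.argsort((pts**2).sum(axis=1), kind="stable")]


def gamma_3d(
    reference: VolumeGrid,
    evaluated: VolumeGrid,
    dose_pct: float,
    dta_mm: float,
    threshold_pct: float = 10.0,
    mask=None,
    *,
    search_factor: float = 3.0,
    step_fraction: float = 1.0 / 3.0,
) -> GammaResult:
    """Global 3D gamma of ``evaluated`` against ``reference``.

    The evaluated dose is trilinearly interpolated on a sub-voxel search
    lattice (step ``dta * step_fraction``) inside a sphere of radius
    ``search_factor * dta`` around each voxel, with an exact early exit
    once the distance term alone exceeds every running minimum.
    """
    _check_lattice(reference, evaluated)
    m = _as_mask(mask) if mask is not None else np.ones(reference.shape, bool)
    if m.shape != reference.shape:
        raise ValueError("mask lattice mismatch")
    if not m.any():
        raise ValueError("empty analysis mask")
    ref = reference.values.astype(np.float64)
    norm = float(ref[m].max())
    if norm <= 0:
        raise ValueError("reference dose is nonpositive inside the mask")
    thresh = threshold_pct / 100.0 * norm
    evaluated_mask = m & (ref >= thresh)
    if not evaluated_mask.any():
        raise ValueError("no voxel passes the low-dose threshold")
    dd = dose_pct / 100.0 * norm
    spacing = np.asarray(reference.spacing)

    offsets = _search_offsets(dta_mm, spacing, search_factor, step_fraction)
    pad = int(np.ceil(search_factor * dta_mm / spacing.min())) + 2
    E = np.pad(evaluated.values.astype(np.float64), pad, constant_values=np.nan)
    iz, iy, ix = np.nonzero(evaluated_mask)
    iz, iy, ix = iz + pad, iy + pad, ix + pad
    dref = ref[evaluated_mask]

    gamma2 = np.full(dref.shape, np.inf)
    for v in offsets:
        dist2 = float((v**2).sum()) / dta_mm**2
        if dist2 >= gamma2.max():
            break
        s = v / spacing
        b = np.floor(s).astype(int)
        f = s - b
        dv = np.zeros_like(dref)
        for cz in (0, 1):
            wz = (1 - f[0]) if cz == 0 else f[0]
            if wz == 0:
                continue
            for cy in (0, 1):
                wy = (1 - f[1]) if cy == 0 else f[1]
                if wy == 0:
                    continue
                for cx in (0, 1):
                    wx = (1 - f[2]) if cx == 0 else f[2]
                    if wx == 0:
                        continue
                    dv = dv + (wz * wy * wx) * E[
                        iz + b[0] + cz, iy + b[1] + cy, ix + b[2] + cx
                    ]
        g2 = (dv - dref) ** 2 / dd**2 + dist2
        gamma2 = np.fmin(gamma2, g2)

    gamma_values = np.full(reference.shape, np.nan)
    gamma_values[evaluated_mask] = np.sqrt(gamma2)
    return GammaResult(
        gamma_values=gamma_values,
        criteria=(dose_pct, dta_mm),
        normalization_dose=norm,
        threshold_pct=threshold_pct,
        evaluated_mask=evaluated_mask,
    )


def passing_rate(result: GammaResult) -> float:
    """Percent of evaluated voxels with gamma <= 1 (boundary passes).

    A 1e-12 guard keeps voxels sitting exactly on the criterion boundary
    (e.g. a uniform 3% overdose under a 3% criterion) from failing by
    floating-point rounding.
    """
    g = result.gamma_values[result.evaluated_mask]
    if g.size == 0:
        raise ValueError("no evaluated voxels")
    return 100.0 * float(np.count_nonzero(g <= 1.0 + 1e-12)) / g.size


# ---------------------------------------------------------------------------
# range maps and ARD
# ---------------------------------------------------------------------------

@dataclass
class RangeMap:
    """Distal threshold-crossing depth (mm along +RL) per lateral ray."""

    ranges: np.ndarray  # (SI, AP), NaN where no crossing
    threshold_dose: float  # GyRBE
    spacing: tuple[float, float, float]


def range_map(dose: VolumeGrid, threshold_fraction: float,
              prescribed_dose: float) -> RangeMap:
    """Beam's-eye-view range map of a canonical-frame dose (beam = +RL).

    The range of a ray is the distal-most downward crossing of
    ``threshold_fraction * prescribed_dose``, linearly interpolated between
    the bracketing voxels; depth is measured from the k=0 voxel plane.
    Rays never reaching the threshold are NaN.
    """
    if prescribed_dose <= 0:
        raise ValueError("prescribed_dose must be > 0")
    thr = threshold_fraction * prescribed_dose
    vals = dose.values.astype(np.float64)
    ds = dose.spacing[2]
    K = vals.shape[2]
    above = vals >= thr
    has = above.any(axis=2)
    k_last = K - 1 - np.argmax(above[:, :, ::-1], axis=2)  # last index above
    k_safe = np.clip(k_last, 0, K - 2)
    i, j = np.meshgrid(*map(np.arange, vals.shape[:2]), indexing="ij")
    p0 = vals[i, j, k_safe]
    p1 = vals[i, j, k_safe + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(p0 > p1, (p0 - thr) / (p0 - p1), 0.0)
    depth = ds * (k_safe + np.clip(frac, 0.0, 1.0))
    depth = np.where(k_last == K - 1, ds * k_last, depth)  # crossing off-grid
    return RangeMap(
        ranges=np.where(has, depth, np.nan),
        threshold_dose=float(thr),
        spacing=dose.spacing,
    )


def ard(ref_map: RangeMap, eval_map: RangeMap) -> float:
    """Average range difference (%), over rays finite in both maps."""
    if ref_map.ranges.shape != eval_map.ranges.shape:
        raise ValueError("range maps are not congruent")
    both = np.isfinite(ref_map.ranges) & np.isfinite(eval_map.ranges)
    if not both.any():
        raise ValueError("no jointly finite rays")
    r_ref = ref_map.ranges[both]
    r_eval = eval_map.ranges[both]
    return float(100.0 * np.mean((r_ref - r_eval) / r_ref))


# ---------------------------------------------------------------------------
# MAE, isodose DSC
# ---------------------------------------------------------------------------

def mae(reference: VolumeGrid, evaluated: VolumeGrid, analysis_mask,
        threshold_fraction: float, prescribed_dose: float) -> float:
    """Mean |D_ref - D_eval| (GyRBE) over mask voxels with reference dose
    >= threshold_fraction * prescribed_dose."""
    _check_lattice(reference, evaluated)
    m = _as_mask(analysis_mask)
    sel = m & (reference.values >= threshold_fraction * prescribed_dose)
    if not sel.any():
        raise ValueError("empty voxel set for MAE")
    return float(np.mean(np.abs(reference.values[sel] - evaluated.values[sel])))


def isodose_dsc(reference: VolumeGrid, evaluated: VolumeGrid,
                band_low_pct: float, band_high_pct: float,
                prescribed_dose: float) -> float:
    """Dice overlap of the [low%, high%) isodose band of the prescription.

    The upper bound is exclusive; ``band_high_pct >= 100`` means unbounded.
    """
    _check_lattice(reference, evaluated)
    if band_low_pct >= band_high_pct:
        raise ValueError("band_low must be < band_high")

    def band(vals):
        rel = 100.0 * vals / prescribed_dose
        sel = rel >= band_low_pct
        if band_high_pct < 100.0:
            sel &= rel < band_high_pct
        return sel

    A = band(reference.values)
    B = band(evaluated.values)
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        raise ValueError("both isodose sets are empty")
    return 2.0 * int((A & B).sum()) / (na + nb)


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    dose: np.ndarray  # GyRBE, ascending
    volume_pct: np.ndarray  # nonincreasing, 100 -> 0
    structure: str = ""
    voxel_doses: np.ndarray = field(default_factory=lambda: np.array([]))


def dvh(dose: VolumeGrid, mask, structure: str = "") -> DVHCurve:
    m = _as_mask(mask)
    if not m.any():
        raise ValueError("empty structure mask")
    doses = np.sort(dose.values[m].astype(np.float64))
    n = doses.size
    # exact step curve: volume fraction receiving >= d
    axis = np.concatenate([[0.0], doses, [doses[-1] * (1 + 1e-9) + 1e-9]])
    vol = 100.0 * (n - np.searchsorted(doses, axis, side="left")) / n
    vol[0] = 100.0
    return DVHCurve(dose=axis, volume_pct=vol, structure=structure,
                    voxel_doses=doses)


def dvh_metric(curve: DVHCurve, x_pct: float) -> float:
    """D_x%: dose received by at least x% of the structure volume,
    the linearly interpolated inverse of the cumulative curve."""
    if curve.voxel_doses.size == 0:
        raise ValueError("curve carries no voxel doses")
    if not (0 < x_pct <= 100):
        raise ValueError("x_pct must be in (0, 100]")
    return float(np.percentile(curve.voxel_doses, 100.0 - x_pct))


def rde(metric_eval: float, metric_ref: float) -> float:
    """Relative dose error (%) of a DVH metric against the reference."""
    if metric_ref == 0:
        raise ValueError("reference metric is zero")
    return 100.0 * (metric_eval - metric_ref) / metric_ref


# ---------------------------------------------------------------------------
# beam / plan reports
# ---------------------------------------------------------------------------

@dataclass
class EvalConfig:
    beam_gamma: tuple[float, float] = (3.0, 3.0)
    plan_gamma: tuple[tuple[float, float], ...] = ((1.0, 1.0), (2.0, 2.0), (3.0, 3.0))
    threshold_pct: float = 10.0  # of max reference dose in body, for gamma
    mae_threshold_fraction: float = 0.10  # of prescription, on the reference
    dsc_bands: tuple[tuple[float, float], ...] = (
        (10.0, 30.0), (10.0, 50.0), (10.0, 70.0), (10.0, 90.0))
    dvh_x: tuple[float, ...] = (98.0, 95.0, 50.0, 2.0)
    range_thresholds: tuple[float, ...] = (0.90, 0.50)
    gamma_search_factor: float = 3.0
    gamma_step_fraction: float = 1.0 / 3.0


@dataclass
class EvalReport:
    """Flat metric dictionary with provenance, JSON round-trippable."""

    kind: str  # "beam" or "plan"
    subject_id: str
    metrics: dict[str, float]
    meta: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"kind": self.kind, "subject_id": self.subject_id,
             "metrics": self.metrics, "meta": self.meta},
            indent=2, sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "EvalReport":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(kind=d["kind"], subject_id=d["subject_id"],
                   metrics=d["metrics"], meta=d.get("meta", {}))


def _gamma_pass(ref, ev, crit, cfg, mask):
    res = gamma_3d(ref, ev, crit[0], crit[1], cfg.threshold_pct, mask,
                   search_factor=cfg.gamma_search_factor,
                   step_fraction=cfg.gamma_step_fraction)
    return passing_rate(res)


def evaluate_beam(
    mc: VolumeGrid,
    dl: VolumeGrid,
    pb: VolumeGrid,
    beam: BeamGeometry,
    body: VolumeGrid,
    config: EvalConfig | None = None,
    *,
    subject_id: str = "",
) -> EvalReport:
    """Single-field report: gamma (DL and PB vs MC) plus ARD of R90/R50
    from canonical-frame range maps with lateral-index-paired rays."""
    cfg = config or EvalConfig()
    metrics: dict[str, float] = {}
    for name, ev in (("dl", dl), ("pb", pb)):
        metrics[f"gamma_{cfg.beam_gamma[0]:g}_{cfg.beam_gamma[1]:g}_{name}"] = (
            _gamma_pass(mc, ev, cfg.beam_gamma, cfg, body)
        )
        metrics[f"mae_{name}"] = mae(
            mc, ev, body, cfg.mae_threshold_fraction, beam.prescribed_dose
        )
    maps = {}
    for name, grid in (("mc", mc), ("dl", dl), ("pb", pb)):
        canon = rotate_about_isocenter(grid, beam, "forward", fill=0.0)
        maps[name] = {
            tf: range_map(canon, tf, beam.prescribed_dose)
            for tf in cfg.range_thresholds
        }
    for tf in cfg.range_thresholds:
        label = f"r{int(round(tf * 100))}"
        for name in ("dl", "pb"):
            metrics[f"ard_{label}_{name}"] = ard(maps["mc"][tf], maps[name][tf])
    return EvalReport(
        kind="beam", subject_id=subject_id, metrics=metrics,
        meta={"prescribed_dose": beam.prescribed_dose,
              "threshold_pct": cfg.threshold_pct,
              "mae_threshold_on": "reference"},
    )


def evaluate_plan(
    mc: VolumeGrid,
    dl: VolumeGrid,
    pb: VolumeGrid,
    body: VolumeGrid,
    ctv: VolumeGrid,
    prescribed_dose: float,
    config: EvalConfig | None = None,
    *,
    subject_id: str = "",
) -> EvalReport:
    """Plan-level report: gamma at all criteria, MAE, isodose DSC bands and
    DVH metric RDEs, for DL-vs-MC and PB-vs-MC.  Plan doses are the
    voxelwise sums of the per-beam doses (done by the caller)."""
    cfg = config or EvalConfig()
    metrics: dict[str, float] = {}
    for crit in cfg.plan_gamma:
        for name, ev in (("dl", dl), ("pb", pb)):
            metrics[f"gamma_{crit[0]:g}_{crit[1]:g}_{name}"] = _gamma_pass(
                mc, ev, crit, cfg, body
            )
    for name, ev in (("dl", dl), ("pb", pb)):
        metrics[f"mae_{name}"] = mae(
            mc, ev, body, cfg.mae_threshold_fraction, prescribed_dose
        )
        for lo, hi in cfg.dsc_bands:
            metrics[f"dsc_{int(lo)}_{int(hi)}_{name}"] = isodose_dsc(
                mc, ev, lo, hi, prescribed_dose
            )
    curves = {
        name: dvh(grid, ctv, structure="ctv")
        for name, grid in (("mc", mc), ("dl", dl), ("pb", pb))
    }
    for x in cfg.dvh_x:
        ref_val = dvh_metric(curves["mc"], x)
        metrics[f"d{int(x)}_mc"] = ref_val
        for name in ("dl", "pb"):
            val = dvh_metric(curves[name], x)
            metrics[f"d{int(x)}_{name}"] = val
            metrics[f"rde_d{int(x)}_{name}"] = rde(val, ref_val)
    return EvalReport(
        kind="plan", subject_id=subject_id, metrics=metrics,
        meta={"prescribed_dose": prescribed_dose,
              "threshold_pct": cfg.threshold_pct,
              "mae_threshold_on": "reference"},
    )
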