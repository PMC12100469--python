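"""End-to-end experiment orchestration.

``run_experiment`` drives simulate -> preprocess -> train -> convert ->
evaluate for one ablation arm and writes a reproducible report bundle:

* ``baseline``      — beams enter the tensor at their native angles;
* ``rotation``      — beams are canonicalised to gantry 270°, couch 0°;
* ``rotation_zoom`` — canonicalised plus zoom augmentation (x0.8, x1.2).

One master seed fans out deterministically (via ``numpy.SeedSequence``) to
dataset generation, fold assignment, weight initialisation and batch
shuffling, so a rerun with the same seed reproduces the summary bit for
bit.  Every artifact embeds the resolved-config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beamframe import CanonicalConfig, augment_training_set, from_canonical, to_canonical
from .beams import read_beam_h5
from .dosemetrics import EvalConfig, EvalReport, evaluate_beam, evaluate_plan
from .grids import VolumeGrid
from .model import (FoldEnsemble, ModelConfig, TrainConfig, predict_ensemble,
                    split_folds, train_fold)
from .phantom import PhantomSpec, make_dataset

log = logging.getLogger("pb2mc")

ARMS = ("baseline", "rotation", "rotation_zoom")


@dataclass
class ExperimentConfig:
    """Resolved configuration of one ablation-arm experiment."""

    arm: str = "rotation_zoom"
    out_dir: str = "pb2mc_run"
    master_seed: int = 0
    # dataset
    n_train_beams: int = 18
    n_test_beams: int = 6
    beams_per_plan: int = 3
    prescribed_dose: float = 2.0
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    beam: dict = field(default_factory=dict)  # BeamSimSpec overrides
    dataset_dir: str | None = None  # reuse an existing dataset
    # preprocessing
    tensor_shape: tuple[int, int, int] = (48, 80, 80)
    tensor_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    hu_window: tuple[float, float] = (-1000.0, 2000.0)
    zoom_factors: tuple[float, ...] = (0.8, 1.2)
    # model / training
    model: dict = field(default_factory=dict)  # ModelConfig overrides
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    # evaluation
    eval: dict = field(default_factory=dict)  # EvalConfig overrides

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")

    def canonical_config(self) -> CanonicalConfig:
        return CanonicalConfig(
            tensor_shape=tuple(self.tensor_shape),
            tensor_spacing=tuple(self.tensor_spacing),
            hu_window=tuple(self.hu_window),
            rotate=self.arm != "baseline",
        )

    def model_config(self) -> ModelConfig:
        return ModelConfig(**self.model)

    def train_config(self) -> TrainConfig:
        seed = int(np.random.SeedSequence([self.master_seed, 20]).generate_state(1)[0]
                   % (2**31))
        return TrainConfig(**{"seed": seed, **self.train})

    def eval_config(self) -> EvalConfig:
        kw = dict(self.eval)
        for key in ("plan_gamma", "dsc_bands"):
            if key in kw:
                kw[key] = tuple(tuple(c) for c in kw[key])
        for key in ("beam_gamma", "dvh_x", "range_thresholds"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return EvalConfig(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("tensor_shape", "tensor_spacing", "hu_window", "zoom_factors"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("tensor_shape", "tensor_spacing", "hu_window", "zoom_factors"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def config_hash(self) -> str:
        """Hash of the study content; output locations are excluded so the
        same experiment run in two directories hashes identically."""
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("out_dir", "dataset_dir")}
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def micro_config(master_seed: int = 0, out_dir: str = "pb2mc_micro",
                 arm: str = "rotation") -> ExperimentConfig:
    """Desk-scale study conditions: a 16x24x24 tensor at 4 mm, a small
    HD U-Net (3 levels, 8 base/growth features) and a short training
    schedule, sized so the full three-arm ablation trains on one CPU in
    minutes.  18 training and 6 test beams, 3 beams per plan."""
    return ExperimentConfig(
        arm=arm,
        out_dir=out_dir,
        master_seed=master_seed,
        n_train_beams=18,
        n_test_beams=6,
        beams_per_plan=3,
        phantom={
            "shape": [16, 24, 24],
            "spacing": [4.0, 4.0, 4.0],
            "body_semiaxes": [26.0, 42.0, 42.0],
            "ctv_semiaxis_range": [6.0, 10.0],
            "n_air_cavities": 3,
            "n_bone_slabs": 4,
            "cavity_semiaxis_range": [6.0, 12.0],
            "slab_extent_range": [16.0, 40.0],
            "smooth_sigma_vox": 1.0,
        },
        beam={
            "entrance_sigma": 5.0,
            "sigma_growth": 0.15,
            "pb_beamlet_width": 28.0,
            "sigma_peak": 6.0,
            "sigma_distal": 4.0,
        },
        tensor_shape=(16, 24, 24),
        tensor_spacing=(4.0, 4.0, 4.0),
        model={"n_levels": 3, "base_features": 8, "growth_features": 8},
        train={"max_epochs": 12, "lr_patience": 3, "early_stop_patience": 5},
    )


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(status: dict, status_path: Path, name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            status[name] = "ok" if exc is None else f"failed: {exc}"
            status_path.write_text(json.dumps(status, indent=2, sort_keys=True))
            log.info("stage %s: %s (%.1f s)", name, status[name], dt)
            if exc is not None:
                raise StageFailure(name, exc) from exc
            return False

    return _Ctx()


def _load_split(dataset_dir: Path, split: str):
    with open(dataset_dir / "manifest.json") as f:
        manifest = json.load(f)
    recs = [b for b in manifest["beams"] if b["split"] == split]
    return [read_beam_h5(dataset_dir / r["file"]) for r in recs]


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one arm end to end; returns the summary dict (also written to
    ``summary.json`` / ``summary.csv`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict = {}
    status_path = out / "status.json"
    chash = config.config_hash()
    with open(out / "config.resolved.yaml", "w") as f:
        yaml.safe_dump({**config.to_dict(), "config_hash": chash}, f)

    with _stage(status, status_path, "simulate"):
        if config.dataset_dir:
            dataset_dir = Path(config.dataset_dir)
        else:
            dataset_dir = out / "dataset"
            if not (dataset_dir / "manifest.json").exists():
                phantom = PhantomSpec(**config.phantom) if config.phantom else None
                make_dataset(
                    config.n_train_beams, config.n_test_beams, dataset_dir,
                    master_seed=config.master_seed, phantom_spec=phantom,
                    beams_per_plan=config.beams_per_plan,
                    prescribed_dose=config.prescribed_dose,
                    beam_overrides=config.beam or None,
                )
        train_beams = _load_split(dataset_dir, "train")
        test_beams = _load_split(dataset_dir, "test")

    canon_cfg = config.canonical_config()
    with _stage(status, status_path, "preprocess"):
        canon_train = [
            to_canonical(b.ct, b.pb, b.mc, b.beam, canon_cfg,
                         beam_id=b.beam_id, plan_id=b.plan_id)
            for b in train_beams
        ]
        canon_test = [
            to_canonical(b.ct, b.pb, b.mc, b.beam, canon_cfg,
                         beam_id=b.beam_id, plan_id=b.plan_id)
            for b in test_beams
        ]

    train_cfg = config.train_config()
    model_cfg = config.model_config()
    with _stage(status, status_path, "train"):
        fold_seed = int(
            np.random.SeedSequence([config.master_seed, 10]).generate_state(1)[0]
            % (2**31)
        )
        folds = split_folds(
            [(s.beam_id, s.plan_id) for s in canon_train],
            train_cfg.n_folds, seed=fold_seed,
        )
        models, histories = [], []
        for k, val_ids in enumerate(folds):
            val = [s for s in canon_train if s.beam_id in set(val_ids)]
            tr = [s for s in canon_train if s.beam_id not in set(val_ids)]
            if config.arm == "rotation_zoom":
                tr = augment_training_set(tr, tuple(config.zoom_factors))
            model, hist = train_fold(tr, val, train_cfg, model_cfg, fold_index=k)
            models.append(model)
            histories.append(hist)
            log.info("fold %d: %d epochs, best val %.3e", k, len(hist),
                     min(h["val_loss"] for h in hist))
        ensemble = FoldEnsemble(models, histories, model_cfg, train_cfg)
        ensemble.save(out / "ensemble")

    with _stage(status, status_path, "convert"):
        dl_doses = {}
        for beam, sample in zip(test_beams, canon_test):
            dose_norm = predict_ensemble(ensemble, sample)
            dl_doses[beam.beam_id] = from_canonical(
                dose_norm, sample, beam.ct, canon_cfg
            )

    eval_cfg = config.eval_config()
    with _stage(status, status_path, "evaluate"):
        beam_reports = []
        for b in test_beams:
            rep = evaluate_beam(
                b.mc, dl_doses[b.beam_id], b.pb, b.beam, b.body,
                eval_cfg, subject_id=b.beam_id,
            )
            rep.meta["config_hash"] = chash
            rep.to_json(out / f"beam_{b.beam_id}.json")
            beam_reports.append(rep)
        plan_reports = []
        plans: dict[str, list] = {}
        for b in test_beams:
            plans.setdefault(b.plan_id, []).append(b)
        for plan_id, beams in sorted(plans.items()):
            mc = beams[0].mc.copy_with(sum(b.mc.values for b in beams))
            pb = beams[0].pb.copy_with(sum(b.pb.values for b in beams))
            dl = beams[0].pb.copy_with(
                sum(dl_doses[b.beam_id].values for b in beams)
            )
            rx = sum(b.beam.prescribed_dose for b in beams)
            rep = evaluate_plan(
                mc, dl, pb, beams[0].body, beams[0].ctv, rx,
                eval_cfg, subject_id=plan_id,
            )
            rep.meta["config_hash"] = chash
            rep.to_json(out / f"plan_{plan_id}.json")
            plan_reports.append(rep)

    summary = summarize(config, beam_reports, plan_reports)
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
    _summary_csv(summary, out / "summary.csv")
    return summary


def summarize(config: ExperimentConfig, beam_reports, plan_reports) -> dict:
    def stats(reports):
        keys = sorted(reports[0].metrics) if reports else []
        table = {}
        for k in keys:
            vals = np.array([r.metrics[k] for r in reports], dtype=float)
            table[k] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))
                        if len(vals) > 1 else 0.0}
        return table

    return {
        "arm": config.arm,
        "master_seed": config.master_seed,
        "config_hash": config.config_hash(),
        "n_test_beams": len(beam_reports),
        "per_beam": {r.subject_id: r.metrics for r in beam_reports},
        "per_plan": {r.subject_id: r.metrics for r in plan_reports},
        "beam_means": stats(beam_reports),
        "plan_means": stats(plan_reports),
    }


def _summary_csv(summary: dict, path: Path) -> None:
    rows = [{"beam_id": k, **v} for k, v in sorted(summary["per_beam"].items())]
    pd.DataFrame(rows).to_csv(path, index=False)


def compare_arms(summaries: list[dict]) -> dict:
    """Paired per-beam comparison across arms on the same test set.

    Emits per-metric mean ± SD per arm, a PB reference row (taken from the
    first summary's *_pb metrics), paired per-beam deltas against PB, and
    the ablation ordering checks (DL-vs-PB improvement; rotation >=
    baseline mean gamma passing).
    """
    if len(summaries) < 1:
        raise ValueError("need at least one summary")
    beam_sets = [tuple(sorted(s["per_beam"])) for s in summaries]
    if len(set(beam_sets)) != 1:
        raise ValueError("summaries cover different test beams")
    beams = beam_sets[0]

    def metric(s, beam, key):
        return s["per_beam"][beam][key]

    first = summaries[0]
    gamma_key_dl = next(k for k in first["per_beam"][beams[0]]
                        if k.startswith("gamma_") and k.endswith("_dl"))
    gamma_key_pb = gamma_key_dl[:-3] + "_pb"

    rows = {}
    rows["pb"] = {
        "gamma_mean": float(np.mean([metric(first, b, gamma_key_pb) for b in beams])),
        "gamma_sd": float(np.std([metric(first, b, gamma_key_pb) for b in beams], ddof=1))
        if len(beams) > 1 else 0.0,
    }
    deltas = {}
    for s in summaries:
        g = np.array([metric(s, b, gamma_key_dl) for b in beams])
        gp = np.array([metric(s, b, gamma_key_pb) for b in beams])
        rows[s["arm"]] = {
            "gamma_mean": float(g.mean()),
            "gamma_sd": float(g.std(ddof=1)) if len(beams) > 1 else 0.0,
        }
        deltas[s["arm"]] = {
            "per_beam_gamma_delta_vs_pb": dict(zip(beams, (g - gp).tolist())),
            "mean_gamma_delta_vs_pb": float((g - gp).mean()),
        }
    by_arm = {s["arm"]: rows[s["arm"]]["gamma_mean"] for s in summaries}
    checks = {}
    if "rotation" in by_arm:
        checks["rotation_beats_pb_gamma"] = by_arm["rotation"] > rows["pb"]["gamma_mean"]
    if "rotation" in by_arm and "baseline" in by_arm:
        checks["rotation_ge_baseline_gamma"] = (
            by_arm["rotation"] >= by_arm["baseline"]
        )
    return {
        "n_beams": len(beams),
        "gamma_metric": gamma_key_dl[:-3].rstrip("_"),
        "rows": rows,
        "deltas": deltas,
        "ordering_checks": checks,
    }
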