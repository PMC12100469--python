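"""Shared fixtures.

The expensive end-to-end study (three ablation arms on one shared synthetic
dataset) and the small determinism runs are session-scoped so several tests
can assert on one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from pb2mc.grids import BeamGeometry, VolumeGrid
from pb2mc.pipeline import ExperimentConfig, micro_config, run_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smooth_blob_grid():
    """A compactly supported smooth field on a 2 mm grid, resolved well
    enough (sigma = 12 mm) that trilinear resampling error stays small."""
    shape = (40, 48, 48)
    iso = tuple((s - 1) * 1.0 for s in shape)
    ax = [np.arange(n) * 2.0 for n in shape]
    mesh = np.meshgrid(*ax, indexing="ij")
    r2 = sum((mesh[a] - iso[a]) ** 2 for a in range(3))
    values = np.exp(-r2 / (2 * 12.0**2))
    return VolumeGrid(values, (2.0, 2.0, 2.0)), iso


def tiny_config(master_seed: int, out_dir: str, arm: str = "rotation") -> ExperimentConfig:
    """Minimal-but-complete experiment for smoke and determinism tests:
    3 training plans (the minimum for 3 folds), 1 test plan, 2 epochs."""
    cfg = micro_config(master_seed, out_dir, arm)
    cfg.n_train_beams = 9
    cfg.n_test_beams = 3
    cfg.model = {"n_levels": 2, "base_features": 4, "growth_features": 4}
    cfg.train = {"max_epochs": 2, "lr_patience": 1, "early_stop_patience": 2}
    return cfg


@pytest.fixture(scope="session")
def micro_ablation(tmp_path_factory):
    """The desk-scale three-arm ablation on one shared dataset.

    Returns {arm: summary dict}.  The qualitative ablation-ordering
    claims are checked against this study.
    """
    root = tmp_path_factory.mktemp("ablation")
    summaries = {}
    dataset_dir = None
    for arm in ("rotation", "baseline", "rotation_zoom"):
        cfg = micro_config(master_seed=1, out_dir=str(root / arm), arm=arm)
        if dataset_dir is not None:
            cfg.dataset_dir = dataset_dir
        summaries[arm] = run_experiment(cfg)
        if dataset_dir is None:
            dataset_dir = str(root / arm / "dataset")
    return {"summaries": summaries, "root": root}


@pytest.fixture(scope="session")
def tiny_repeat_runs(tmp_path_factory):
    """Two identical-seed tiny runs, for reproducibility checks."""
    root = tmp_path_factory.mktemp("repeat")
    out = []
    for i in range(2):
        cfg = tiny_config(master_seed=7, out_dir=str(root / f"run{i}"))
        out.append(run_experiment(cfg))
    return out
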