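"""Hierarchically dense U-Net for PB -> MC dose conversion.

The network maps the two-channel canonical tensor (normalised CT,
normalised PB dose) to the normalised MC dose.  Architecture contract:

* *dense convolution block*: two 3x3x3 convolution layers with ReLU, each
  layer's input being the concatenation of every previous feature map in
  the block;
* *dense down-sampling*: a stride-2 convolution with ReLU and a 2x
  max-pool of the incoming features, concatenated;
* *up-sampling*: 2x nearest-neighbour upsampling, a convolution with
  ReLU, concatenation with the same-level encoder features, then a dense
  convolution block;
* head: the raw input channels are concatenated back in (a global dense
  skip) and a 1-voxel convolution with ReLU produces the nonnegative
  single-channel output.

The head is initialised as a passthrough of the PB input channel, so an
untrained network reproduces the PB dose and training starts from the PB
baseline rather than from noise.

Training follows the usual plateau/early-stopping recipe: Adam at 1e-3,
learning rate x0.1 when validation loss stalls for ``lr_patience`` epochs,
stop after ``early_stop_patience`` stalled epochs, MSE loss, batch size 4,
3-fold cross-validation with plan-level folds; the best-validation weights
are kept and fold outputs are averaged at inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .beamframe import CanonicalSample

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "HDUNet",
    "FoldEnsemble",
    "build_model",
    "split_folds",
    "train_fold",
    "predict_ensemble",
]


@dataclass
class ModelConfig:
    n_levels: int = 4
    base_features: int = 16  # stride-conv / up-conv channels
    growth_features: int = 16  # channels added by each dense conv layer
    input_channels: int = 2  # (CT, PB)
    output_channels: int = 1  # (MC)

    def validate_shape(self, spatial_shape) -> None:
        div = 2 ** (self.n_levels - 1)
        for n in spatial_shape:
            if n % div:
                raise ValueError(
                    f"spatial dims {tuple(spatial_shape)} must be divisible by "
                    f"2^(n_levels-1) = {div}"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class TrainConfig:
    initial_lr: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_patience: int = 10
    early_stop_patience: int = 15
    max_epochs: int = 500
    batch_size: int = 4
    n_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr_patience, self.early_stop_patience, self.max_epochs,
               self.batch_size, self.n_folds) <= 0:
            raise ValueError("patience/epoch/batch/fold counts must be positive")
        if not (0 < self.lr_decay_factor < 1):
            raise ValueError("lr_decay_factor must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


class HDUNet:
    """The network: parameters plus a forward pass over the nn tape."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.params: dict[str, nn.Parameter] = {}
        g = config.growth_features
        base = config.base_features
        L = config.n_levels

        def conv3(name, cin, cout):
            self.params[name + ".w"] = nn.Parameter(
                nn.he_init(rng, (27, cin, cout), fan_in=27 * cin)
            )
            self.params[name + ".b"] = nn.Parameter(np.zeros(cout, np.float32))

        def conv1(name, cin, cout):
            self.params[name + ".w"] = nn.Parameter(
                nn.he_init(rng, (cin, cout), fan_in=cin)
            )
            self.params[name + ".b"] = nn.Parameter(np.zeros(cout, np.float32))

        def dense(name, cin):
            conv3(name + ".l1", cin, g)
            conv3(name + ".l2", cin + g, g)
            return cin + 2 * g

        c = config.input_channels
        self._enc_channels = []
        for lvl in range(L):
            c = dense(f"enc{lvl}", c)
            self._enc_channels.append(c)
            if lvl < L - 1:
                conv3(f"down{lvl}", c, base)  # stride-2 branch
                c = c + base  # concat with max-pool branch
        for lvl in reversed(range(L - 1)):
            comp = 2 * base
            conv1(f"up{lvl}.compress", c, comp)
            conv3(f"up{lvl}.conv", comp, base)
            c = base + self._enc_channels[lvl]
            c = dense(f"dec{lvl}", c)
        head_in = c + config.input_channels
        conv1("head", head_in, config.output_channels)
        # PB-passthrough head: weight ~0 except 1 on the PB input channel
        w = self.params["head.w"].data
        w *= 0.01
        w[c + 1, 0] = 1.0  # input channel order (CT, PB)

    # -- forward ----------------------------------------------------------

    def _dense(self, name, x):
        p = self.params
        l1 = nn.relu(nn.conv3d(x, p[name + ".l1.w"], p[name + ".l1.b"]))
        c1 = nn.concat([x, l1])
        l2 = nn.relu(nn.conv3d(c1, p[name + ".l2.w"], p[name + ".l2.b"]))
        return nn.concat([c1, l2])

    def forward(self, x_np: np.ndarray) -> nn.Tensor:
        """x_np: (N, D, H, W, 2) float32; returns the output tape node."""
        self.config.validate_shape(x_np.shape[1:4])
        p = self.params
        L = self.config.n_levels
        x = nn.Tensor(np.asarray(x_np, dtype=np.float32))
        inp = x
        skips = []
        for lvl in range(L):
            x = self._dense(f"enc{lvl}", x)
            skips.append(x)
            if lvl < L - 1:
                d = nn.relu(
                    nn.conv3d_stride2(x, p[f"down{lvl}.w"], p[f"down{lvl}.b"])
                )
                x = nn.concat([d, nn.maxpool2(x)])
        for lvl in reversed(range(L - 1)):
            t = nn.relu(
                nn.conv1x1(x, p[f"up{lvl}.compress.w"], p[f"up{lvl}.compress.b"])
            )
            u = nn.upsample2(t)
            r = nn.relu(nn.conv3d(u, p[f"up{lvl}.conv.w"], p[f"up{lvl}.conv.b"]))
            x = nn.concat([r, skips[lvl]])
            x = self._dense(f"dec{lvl}", x)
        x = nn.concat([x, inp])
        return nn.relu(nn.conv1x1(x, p["head.w"], p["head.b"]))

    def predict(self, x_np: np.ndarray) -> np.ndarray:
        return self.forward(x_np).data

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.asarray(state[k], dtype=p.data.dtype)

    def save(self, path) -> None:
        np.savez(Path(path), **self.state_dict())

    @classmethod
    def load(cls, path, config: ModelConfig, seed: int = 0) -> "HDUNet":
        model = cls(config, seed)
        with np.load(Path(path)) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


def build_model(config: ModelConfig, seed: int = 0) -> HDUNet:
    return HDUNet(config, seed)


def split_folds(beam_plan_pairs, n_folds: int, seed: int = 0):
    """Partition beams into folds at the plan level.

    ``beam_plan_pairs``: iterable of (beam_id, plan_id).  Returns a list of
    ``n_folds`` lists of beam_ids (the validation set of each fold); all
    beams of one plan land in the same fold and fold plan-counts differ by
    at most one.  Deterministic given ``seed``.
    """
    pairs = list(beam_plan_pairs)
    plans = sorted({p for _, p in pairs})
    if len(plans) < n_folds:
        raise ValueError(f"{len(plans)} plans < {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = [plans[i] for i in rng.permutation(len(plans))]
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    assign = {plan: i % n_folds for i, plan in enumerate(order)}
    for beam_id, plan_id in pairs:
        folds[assign[plan_id]].append(beam_id)
    return folds


def _stack(samples: list[CanonicalSample]):
    X = np.stack(
        [np.stack([s.ct_norm, s.pb_norm], axis=-1) for s in samples]
    ).astype(np.float32)
    Y = np.stack([s.mc_norm[..., None] for s in samples]).astype(np.float32)
    return X, Y


def _epoch_val_loss(model: HDUNet, Xv, Yv, batch_size) -> float:
    total, n = 0.0, 0
    for i in range(0, len(Xv), batch_size):
        xb, yb = Xv[i:i + batch_size], Yv[i:i + batch_size]
        pred = model.predict(xb)
        total += float(((pred - yb) ** 2).sum())
        n += yb.size
    return total / n


def train_fold(
    train_samples: list[CanonicalSample],
    val_samples: list[CanonicalSample],
    train_cfg: TrainConfig,
    model_cfg: ModelConfig,
    fold_index: int = 0,
):
    """Train one fold; returns (model-with-best-weights, history).

    History is a list of per-epoch dicts {epoch, train_loss, val_loss, lr}.
    Seeds for weight init and batch shuffling derive from
    ``train_cfg.seed`` and ``fold_index``.
    """
    if not train_samples or not val_samples:
        raise ValueError("need nonempty train and validation sample lists")
    init_seed = int(
        np.random.SeedSequence([train_cfg.seed, fold_index, 0]).generate_state(1)[0]
        % (2**31)
    )
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([train_cfg.seed, fold_index, 1])
    )
    model = HDUNet(model_cfg, seed=init_seed)
    X, Y = _stack(train_samples)
    Xv, Yv = _stack(val_samples)
    model_cfg.validate_shape(X.shape[1:4])
    opt = nn.Adam(list(model.params.values()), lr=train_cfg.initial_lr)

    history: list[dict] = []
    best_val = np.inf
    best_state = model.state_dict()
    stall = 0
    for epoch in range(train_cfg.max_epochs):
        perm = shuffle_rng.permutation(len(X))
        train_loss, nbatch = 0.0, 0
        for i in range(0, len(X), train_cfg.batch_size):
            idx = perm[i:i + train_cfg.batch_size]
            opt.zero_grad()
            out = model.forward(X[idx])
            loss = nn.mse_loss(out, Y[idx])
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"NaN/Inf training loss at epoch {epoch}, lr {opt.lr:g}, "
                    f"batch {i // train_cfg.batch_size}"
                )
            loss.backward()
            opt.step()
            train_loss += lval
            nbatch += 1
        val_loss = _epoch_val_loss(model, Xv, Yv, train_cfg.batch_size)
        history.append({
            "epoch": epoch, "train_loss": train_loss / max(nbatch, 1),
            "val_loss": val_loss, "lr": opt.lr,
        })
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            stall = 0
        else:
            stall += 1
            if stall >= train_cfg.early_stop_patience:
                break
            if stall > 0 and stall % train_cfg.lr_patience == 0:
                opt.lr *= train_cfg.lr_decay_factor
    model.load_state_dict(best_state)
    return model, history


@dataclass
class FoldEnsemble:
    """The n_folds trained networks plus their training provenance."""

    models: list[HDUNet]
    histories: list[list[dict]]
    model_cfg: ModelConfig
    train_cfg: TrainConfig

    def __post_init__(self) -> None:
        if len(self.models) != self.train_cfg.n_folds:
            raise ValueError(
                f"{len(self.models)} models != n_folds {self.train_cfg.n_folds}"
            )

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.models):
            m.save(out_dir / f"fold{i}.npz")
        with open(out_dir / "ensemble.json", "w") as f:
            json.dump({
                "model_cfg": self.model_cfg.to_dict(),
                "train_cfg": self.train_cfg.to_dict(),
                "histories": self.histories,
            }, f, indent=2)

    @classmethod
    def load(cls, out_dir) -> "FoldEnsemble":
        out_dir = Path(out_dir)
        with open(out_dir / "ensemble.json") as f:
            meta = json.load(f)
        model_cfg = ModelConfig.from_dict(meta["model_cfg"])
        train_cfg = TrainConfig.from_dict(meta["train_cfg"])
        models = [
            HDUNet.load(out_dir / f"fold{i}.npz", model_cfg)
            for i in range(train_cfg.n_folds)
        ]
        return cls(models, meta["histories"], model_cfg, train_cfg)


def predict_ensemble(ensemble: FoldEnsemble, sample: CanonicalSample) -> np.ndarray:
    """Arithmetic mean of the fold models' outputs for one canonical beam."""
    x = np.stack([sample.ct_norm, sample.pb_norm], axis=-1)[None].astype(np.float32)
    if tuple(x.shape[1:4]) != tuple(sample.tensor_shape):
        raise ValueError("sample tensor shape mismatch")
    preds = [m.predict(x)[0, ..., 0] for m in ensemble.models]
    return np.mean(preds, axis=0)
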