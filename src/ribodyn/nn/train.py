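"""Training loop (Adam + cosine decay + early stopping), prediction,
evaluation and checkpoint I/O."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from scipy import stats

from ..profiles import DatasetSplit, TransformError, WindowDataset
from .network import DensityModel, ModelConfig

CHECKPOINT_SCHEMA = "ribodyn-checkpoint-1"


def cosine_lr(step_fraction: float, start_lr: float = 0.0005) -> float:
    """start_lr * (1 + cos(pi * step)) / 2 over normalized progress [0, 1]."""
    if not 0.0 <= step_fraction <= 1.0:
        warnings.warn(
            f"step fraction {step_fraction} outside [0, 1]; clamping", stacklevel=2
        )
        step_fraction = min(max(step_fraction, 0.0), 1.0)
    return start_lr * (1.0 + np.cos(np.pi * step_fraction)) / 2.0


@dataclass
class TrainConfig:
    start_lr: float = 0.0005
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.start_lr <= 0:
            raise ValueError("start_lr must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


class EarlyStopper:
    """Stop when the monitored loss has not decreased for ``patience`` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self._since = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record an epoch loss; return True when training should stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self._since = 0
        else:
            self._since += 1
        return self._since >= self.patience


@dataclass
class TrainedModel:
    """A fitted model plus its training log and data-transform metadata."""

    model: DensityModel
    model_cfg: ModelConfig
    train_cfg: TrainConfig
    history: dict = field(default_factory=dict)  # train_mse, val_mse per epoch
    stop_epoch: int = 0
    best_epoch: int = 0
    mask_ref: bool = False
    ref_transform: str = "log"
    target_transform: str = "gene_mean_normalized"

    def predict_arrays(self, seq: np.ndarray, ref: np.ndarray) -> np.ndarray:
        """Deterministic (eval-mode) predictions for raw window arrays."""
        return self.model.forward(seq, ref, training=False, mask_ref=self.mask_ref)


def _batches(n, batch_size, rng=None):
    idx = rng.permutation(n) if rng is not None else np.arange(n)
    for s in range(0, n, batch_size):
        yield idx[s : s + batch_size]


def _mse_over(model: DensityModel, ds: WindowDataset, idx, mask_ref, batch_size=1024):
    se, cnt = 0.0, 0
    for b in _batches(len(idx), batch_size):
        sel = idx[b]
        pred = model.forward(ds.seq[sel], ds.ref[sel], training=False, mask_ref=mask_ref)
        se += float(((pred - ds.target[sel]) ** 2).sum())
        cnt += len(sel)
    return se / cnt


def train_model(
    ds: WindowDataset,
    split: DatasetSplit,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    mask_ref: bool = False,
    train_label="train",
    val_label="val",
) -> TrainedModel:
    """Fit the two-branch model with MSE loss, Adam and cosine decay.

    Returns the model restored to its best-validation epoch, with the full
    per-epoch loss history.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    tr_idx = split.indices(train_label)
    va_idx = split.indices(val_label)
    if len(tr_idx) == 0 or len(va_idx) == 0:
        raise ValueError("empty train or validation partition")
    if ds.W != model_cfg.window:
        raise TransformError(
            f"dataset W={ds.W} does not match model window={model_cfg.window}"
        )

    model = DensityModel(model_cfg, seed=train_cfg.seed)
    opt = Adam(model.params())
    stopper = EarlyStopper(train_cfg.patience)
    rng = np.random.default_rng(train_cfg.seed)
    model.seq_branch.attn._rng = rng
    model.ref_branch.attn._rng = rng

    n_batches = int(np.ceil(len(tr_idx) / train_cfg.batch_size))
    total_steps = max(train_cfg.max_epochs * n_batches, 1)
    history = {"train_mse": [], "val_mse": [], "lr": []}
    best_state = model.state_dict()
    step = 0
    stop_epoch = 0
    for epoch in range(1, train_cfg.max_epochs + 1):
        ep_se, ep_n = 0.0, 0
        for b in _batches(len(tr_idx), train_cfg.batch_size, rng):
            sel = tr_idx[b]
            pred = model.forward(
                ds.seq[sel], ds.ref[sel], training=True, mask_ref=mask_ref
            )
            err = pred - ds.target[sel]
            ep_se += float((err**2).sum())
            ep_n += len(sel)
            model.zero_grad()
            model.backward(2.0 * err / len(sel))
            lr = cosine_lr(step / total_steps, train_cfg.start_lr)
            opt.step(lr)
            step += 1
        val_mse = _mse_over(model, ds, va_idx, mask_ref)
        history["train_mse"].append(ep_se / ep_n)
        history["val_mse"].append(val_mse)
        history["lr"].append(cosine_lr(step / total_steps, train_cfg.start_lr))
        improved = val_mse < stopper.best
        stop = stopper.update(val_mse, epoch)
        if improved:
            best_state = model.state_dict()
        stop_epoch = epoch
        if stop:
            break
    model.load_state_dict(best_state)
    return TrainedModel(
        model=model,
        model_cfg=model_cfg,
        train_cfg=train_cfg,
        history=history,
        stop_epoch=stop_epoch,
        best_epoch=stopper.best_epoch,
        mask_ref=mask_ref,
        ref_transform=ds.ref_transform,
        target_transform=ds.target_transform,
    )


def predict(trained: TrainedModel, ds: WindowDataset, batch_size: int = 1024) -> np.ndarray:
    """Eval-mode predictions aligned with the dataset's instance order."""
    if ds.W != trained.model_cfg.window:
        raise TransformError(
            f"dataset W={ds.W} does not match model window={trained.model_cfg.window}"
        )
    if ds.ref_transform != trained.ref_transform:
        raise TransformError(
            f"reference transform {ds.ref_transform!r} != model's "
            f"{trained.ref_transform!r}"
        )
    out = np.empty(len(ds))
    for b in _batches(len(ds), batch_size):
        out[b] = trained.predict_arrays(ds.seq[b], ds.ref[b])
    return out


def evaluate(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Pearson/Spearman correlation and MSE; correlations are NaN when a
    vector has zero variance."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.size < 3:
        raise ValueError("pred and truth must share a length >= 3")
    mse = float(((pred - truth) ** 2).mean())
    if pred.std() == 0 or truth.std() == 0:
        return {"pearson": np.nan, "spearman": np.nan, "mse": mse}
    return {
        "pearson": float(stats.pearsonr(pred, truth).statistic),
        "spearman": float(stats.spearmanr(pred, truth).statistic),
        "mse": mse,
    }


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_model(trained: TrainedModel, directory) -> None:
    """Write config.json + params.npz under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cfg = {
        "schema": CHECKPOINT_SCHEMA,
        "model_cfg": trained.model_cfg.to_dict(),
        "train_cfg": asdict(trained.train_cfg),
        "history": trained.history,
        "stop_epoch": trained.stop_epoch,
        "best_epoch": trained.best_epoch,
        "mask_ref": trained.mask_ref,
        "ref_transform": trained.ref_transform,
        "target_transform": trained.target_transform,
        "init_seed": trained.train_cfg.seed,
    }
    (d / "config.json").write_text(json.dumps(cfg, indent=2))
    np.savez(d / "params.npz", **trained.model.state_dict())


def load_model(directory) -> TrainedModel:
    d = Path(directory)
    cfg = json.loads((d / "config.json").read_text())
    if cfg.get("schema") != CHECKPOINT_SCHEMA:
        raise ValueError(f"unsupported checkpoint schema {cfg.get('schema')!r}")
    model_cfg = ModelConfig.from_dict(cfg["model_cfg"])
    train_cfg = TrainConfig(**cfg["train_cfg"])
    model = DensityModel(model_cfg, seed=cfg["init_seed"])
    with np.load(d / "params.npz") as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return TrainedModel(
        model=model,
        model_cfg=model_cfg,
        train_cfg=train_cfg,
        history=cfg["history"],
        stop_epoch=cfg["stop_epoch"],
        best_epoch=cfg["best_epoch"],
        mask_ref=cfg["mask_ref"],
        ref_transform=cfg["ref_transform"],
        target_transform=cfg["target_transform"],
    )
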