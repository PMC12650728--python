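"""Training, evaluation and prediction pipeline.

The recipe: Adam (lr 1e-4, weight decay 1e-5), batch size 4, Dice-Focal
loss on the foreground channel, up to 300 epochs with early stopping
after 20 epochs without validation-Dice improvement, 256x256 random
crops during training, constant learning rate (optional cosine decay).
The best-validation-Dice parameters are kept.  A single master seed fixes
parameter initialization, batch order and the augmentation stream, so
two runs with the same seed are bitwise identical on one device.

Checkpoints are ``.npz`` archives of named parameter arrays with a JSON
sidecar carrying the network configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import AugmentationConfig, Sample, augment, write_mask
from .losses import LossConfig, combined_loss
from .metrics import evaluate_batch
from .network import NetworkConfig, SnakeSegNet, build_network, predict_mask
from .nn import Adam, Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainResult",
    "train",
    "evaluate",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-5
    epochs: int = 300
    early_stop_patience: int = 20
    batch_size: int = 4
    crop: int = 256
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0
    checkpoint_dir: str | None = None
    lr_schedule: str = "constant"  # or 'cosine'
    augmentation: AugmentationConfig | None = None
    max_steps: int | None = None   # optional hard cap on optimizer steps
    val_interval: int = 1          # epochs between validation passes
    target_val_dice: float | None = None  # stop once validation Dice reaches this

    def __post_init__(self):
        if min(self.lr, self.epochs, self.batch_size, self.crop) < 0 or self.weight_decay < 0:
            raise ValueError("training hyperparameters must be non-negative")
        if self.early_stop_patience > self.epochs:
            raise ValueError("patience must not exceed the epoch budget")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")


@dataclass
class TrainResult:
    history: list[dict]
    best_epoch: int
    best_val_dice: float
    model: SnakeSegNet
    checkpoint_path: Path | None


def _stack(samples: list[Sample]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image for s in samples]).astype(np.float32)[:, None]
    masks = np.stack([(s.mask > 0).astype(np.float32) for s in samples])
    return images, masks


def _foreground(probs: Tensor) -> Tensor:
    return probs[:, 1]


def _mean_dice(model: SnakeSegNet, samples: list[Sample], batch_size: int = 4) -> float:
    from .metrics import overlap_metrics

    scores = []
    for b0 in range(0, len(samples), batch_size):
        chunk = samples[b0 : b0 + batch_size]
        images, _ = _stack(chunk)
        preds = predict_mask(model(images))
        for p, s in zip(preds, chunk):
            scores.append(overlap_metrics(p, s.mask)[0])
    return float(np.mean(scores))


def train(
    train_set: list[Sample],
    val_set: list[Sample],
    cfg: TrainConfig = TrainConfig(),
    net_cfg: NetworkConfig = NetworkConfig(),
) -> TrainResult:
    """Train a network; returns the best model plus the per-epoch history."""
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be nonempty")
    ss = np.random.SeedSequence(cfg.seed)
    init_seed, order_seed, aug_seed = (int(s) for s in ss.generate_state(3) % (2**31))
    model = build_network(net_cfg, seed=init_seed)
    logger.info("built network with %d parameters", model.num_parameters())
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    order_rng = np.random.default_rng(order_seed)
    aug_rng = np.random.default_rng(aug_seed)

    history: list[dict] = []
    best_val = -np.inf
    best_epoch = 0
    best_state = model.state_dict()
    since_best = 0
    ckpt_path: Path | None = None
    steps = 0
    stop = False
    for epoch in range(1, cfg.epochs + 1):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.lr * 0.5 * (1.0 + np.cos(np.pi * (epoch - 1) / cfg.epochs))
        t0 = time.time()
        epoch_samples = list(train_set)
        if cfg.augmentation is not None:
            epoch_samples = [augment(s, cfg.augmentation, aug_rng) for s in epoch_samples]
        order = order_rng.permutation(len(epoch_samples))
        losses = []
        for b0 in range(0, len(order), cfg.batch_size):
            batch = [epoch_samples[i] for i in order[b0 : b0 + cfg.batch_size]]
            images, masks = _stack(batch)
            probs = model.forward_tensor(images)
            loss = combined_loss(_foreground(probs), masks, cfg.loss)
            lval = loss.item()
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss {lval} at epoch {epoch} step {steps}; "
                    "check learning rate and input normalization"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lval)
            del probs, loss  # release the autodiff graph before the next batch
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                stop = True
                break
        record = {"epoch": epoch, "train_loss": float(np.mean(losses)), "seconds": time.time() - t0}
        if epoch % cfg.val_interval == 0 or stop or epoch == cfg.epochs:
            val_dice = _mean_dice(model, val_set, cfg.batch_size)
            record["val_dice"] = val_dice
            logger.info("epoch %d: loss %.4f, val dice %.4f", epoch, record["train_loss"], val_dice)
            if val_dice > best_val:
                best_val = val_dice
                best_epoch = epoch
                best_state = model.state_dict()
                since_best = 0
                if cfg.checkpoint_dir is not None:
                    ckpt_path = Path(cfg.checkpoint_dir) / "best.npz"
                    save_checkpoint(model, ckpt_path)
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    history.append(record)
                    logger.info("early stop at epoch %d (best epoch %d)", epoch, best_epoch)
                    break
            if cfg.target_val_dice is not None and val_dice >= cfg.target_val_dice:
                history.append(record)
                logger.info("target dice %.3f reached at epoch %d", cfg.target_val_dice, epoch)
                break
        history.append(record)
        if stop:
            break
    model.load_state_dict(best_state)
    return TrainResult(history=history, best_epoch=best_epoch, best_val_dice=best_val,
                       model=model, checkpoint_path=ckpt_path)


# ------------------------------------------------------------------ checkpoints
def save_checkpoint(model: SnakeSegNet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(dataclasses.asdict(model.cfg), indent=2))
    return path


def load_checkpoint(path: str | Path) -> SnakeSegNet:
    path = Path(path)
    cfg_dict = json.loads(path.with_suffix(".json").read_text())
    model = build_network(NetworkConfig(**cfg_dict), seed=0)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


# -------------------------------------------------------------------- inference
def _resolve_model(model_or_path) -> SnakeSegNet:
    if isinstance(model_or_path, SnakeSegNet):
        return model_or_path
    return load_checkpoint(model_or_path)


def evaluate(model_or_path, test_set: list[Sample], csv_path: str | Path | None = None) -> pd.DataFrame:
    """Per-image and mean Dice/Precision/Recall/clDice/HD95 table."""
    model = _resolve_model(model_or_path)
    preds = []
    for s in test_set:
        out = model(s.image[None, None].astype(np.float32))
        preds.append(predict_mask(out)[0])
    return evaluate_batch(preds, [s.mask for s in test_set], [s.id for s in test_set], csv_path)


def predict(model_or_path, images: list[np.ndarray], ids: list[str] | None = None,
            out_dir: str | Path | None = None, threshold: float = 0.5):
    """Binary masks + probability maps for a list of grayscale images."""
    model = _resolve_model(model_or_path)
    if ids is None:
        ids = [f"image_{i:04d}" for i in range(len(images))]
    masks, probs = [], []
    for sid, img in zip(ids, images):
        out = model(np.asarray(img, dtype=np.float32)[None, None])
        fg = out.probabilities[0, 1]
        mask = predict_mask(out, threshold)[0]
        masks.append(mask)
        probs.append(fg)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_mask(out_dir / f"{sid}_mask.png", mask)
            np.save(out_dir / f"{sid}_prob.npy", fg)
    return masks, probs
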