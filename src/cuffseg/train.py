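"""Training recipe: binary cross-entropy, Adam, batch 2, lr 1e-4, 30 epochs.

The recipe is deliberately plain — no schedule, no weight decay, no early
stopping; the only model-selection step is keeping the checkpoint with the
best validation Dice alongside the last one.  Runs are reproducible: the
seed drives weight initialisation and the per-epoch shuffle, and the NumPy
backend is deterministic, so identical seeds give identical histories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import metrics as metrics_mod
from . import nn
from .dataio import to_model_input
from .errors import (CheckpointError, ConfigurationError, DataError,
                     TrainingDivergedError)
from .nets import ModelConfig, SegmentationNet, build_model
from .nn import functional as F

ADAM_BETAS = (0.9, 0.999)
ADAM_EPS = 1e-8
BCE_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 2
    epochs: int = 30
    seed: int = 0
    device: str = "cpu"
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ConfigurationError(
                f"threshold must lie strictly in (0, 1), got {self.threshold}")
        if self.device != "cpu":
            raise ConfigurationError(
                f"only the 'cpu' compute target is available, got {self.device!r}")


@dataclass
class History:
    """Per-epoch training loss and validation metrics, plus run metadata."""

    epochs: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def append(self, entry: dict) -> None:
        self.epochs.append(entry)

    @property
    def train_losses(self) -> list[float]:
        return [e["train_loss"] for e in self.epochs]

    def best_epoch(self) -> int:
        """1-based index of the epoch with the highest validation Dice."""
        dices = [e.get("val_dice", float("-inf")) for e in self.epochs]
        return int(np.argmax(dices)) + 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"metadata": self.metadata, "epochs": self.epochs}, indent=2))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.epochs).to_csv(path, index=False)


def bce_loss(pred, target) -> nn.Tensor:
    """Mean binary cross-entropy on probability maps (clamped at 1e-7)."""
    return F.bce_loss(pred, target, eps=BCE_EPS)


def _sample_arrays(sample) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(sample, "image"):
        return sample.image, sample.mask
    return sample


class Trainer:
    """Stateful training loop bound to one model and one config."""

    def __init__(self, model: SegmentationNet, cfg: TrainConfig):
        self.model = model
        self.cfg = cfg
        self.optimizer = nn.Adam(model.parameters(), lr=cfg.learning_rate,
                                 betas=ADAM_BETAS, eps=ADAM_EPS)
        self._shuffle_rng = np.random.default_rng(cfg.seed)
        self.history = History(metadata={
            "learning_rate": cfg.learning_rate,
            "batch_size": cfg.batch_size,
            "epochs": cfg.epochs,
            "seed": cfg.seed,
            "threshold": cfg.threshold,
            "optimizer": "adam",
            "adam_betas": list(ADAM_BETAS),
            "adam_eps": ADAM_EPS,
            "loss": "bce",
        })
        self._epoch = 0

    # -- one epoch -----------------------------------------------------------
    def train_epoch(self, train_set: Sequence) -> tuple[float, int]:
        """Run one epoch of seeded-shuffle minibatch SGD; return (mean loss, steps)."""
        if len(train_set) == 0:
            raise DataError("training set is empty")
        self.model.train()
        self._epoch += 1
        order = self._shuffle_rng.permutation(len(train_set))
        bs = self.cfg.batch_size
        losses = []
        for step, start in enumerate(range(0, len(order), bs)):
            idx = order[start:start + bs]
            imgs, masks = [], []
            for i in idx:
                image, mask = _sample_arrays(train_set[i])
                imgs.append(to_model_input(image))
                masks.append(mask[None].astype(np.float32))
            x = np.stack(imgs)
            t = np.stack(masks)
            pred = self.model(x)
            loss = bce_loss(pred, t)
            val = loss.item()
            if not np.isfinite(val):
                raise TrainingDivergedError(self._epoch, step, val)
            self.optimizer.zero_grad()
            loss.backward()
            self.optimizer.step()
            losses.append(val)
        return float(np.mean(losses)), len(losses)

    def validate(self, val_set: Sequence) -> metrics_mod.MetricsReport:
        return metrics_mod.evaluate(self.model, val_set, self.cfg.threshold)

    # -- full recipe ---------------------------------------------------------
    def fit(self, train_set: Sequence, val_set: Sequence,
            out_dir: Optional[str | Path] = None) -> History:
        if len(train_set) == 0 or len(val_set) == 0:
            raise DataError("training and validation sets must be non-empty")
        out = Path(out_dir) if out_dir is not None else None
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)
        best_dice = float("-inf")
        for _ in range(self.cfg.epochs):
            mean_loss, n_steps = self.train_epoch(train_set)
            report = self.validate(val_set)
            self.history.append({
                "epoch": self._epoch,
                "train_loss": mean_loss,
                "n_steps": n_steps,
                "val_precision": report.precision,
                "val_iou": report.iou,
                "val_dice": report.dice,
            })
            if out is not None:
                save_checkpoint(out / "last.npz", self.model,
                                seed=self.cfg.seed, epoch=self._epoch)
                if report.dice > best_dice:
                    best_dice = report.dice
                    save_checkpoint(out / "best.npz", self.model,
                                    seed=self.cfg.seed, epoch=self._epoch)
        if out is not None:
            self.history.to_json(out / "history.json")
            self.history.to_csv(out / "history.csv")
        return self.history


def train(model: SegmentationNet, train_set: Sequence, val_set: Sequence,
          cfg: TrainConfig, out_dir: Optional[str | Path] = None
          ) -> tuple[History, Trainer]:
    """Run the full recipe; returns the history and the trainer (with model)."""
    trainer = Trainer(model, cfg)
    history = trainer.fit(train_set, val_set, out_dir)
    return history, trainer


def predict(model: SegmentationNet, image: np.ndarray,
            threshold: float = 0.5) -> np.ndarray:
    """Segment one 8-bit (H, W, 3) image into a binary (H, W) mask."""
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError(
            f"threshold must lie strictly in (0, 1), got {threshold}")
    x = to_model_input(image)[None]
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            prob = model(x)
    finally:
        model.train(was_training)
    return (prob.numpy()[0, 0] >= threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: SegmentationNet,
                    seed: Optional[int] = None, **extra) -> None:
    """Serialise weights, buffers and the model config into one .npz file."""
    meta = {"model_config": _config_to_dict(model.config), "seed": seed, **extra}
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> tuple[SegmentationNet, dict]:
    """Rebuild the model from a checkpoint; returns (model, metadata)."""
    path = Path(path)
    if not path.exists():
        raise CheckpointError(f"checkpoint not found: {path}")
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
    except (OSError, ValueError, KeyError, json.JSONDecodeError) as e:
        raise CheckpointError(f"corrupted checkpoint {path}: {e}") from e
    config = ModelConfig(**meta["model_config"])
    model = build_model(config, seed=0)
    model.load_state_dict(state)
    model.eval()
    return model, meta


def _config_to_dict(config: ModelConfig) -> dict:
    return {
        "encoder_depth": config.encoder_depth,
        "use_attention": config.use_attention,
        "use_denseaspp": config.use_denseaspp,
        "attention_reduction": config.attention_reduction,
        "dilation_rates": list(config.dilation_rates),
        "in_channels": config.in_channels,
        "out_channels": config.out_channels,
        "aspp_reduce": config.aspp_reduce,
        "aspp_growth": config.aspp_growth,
    }
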