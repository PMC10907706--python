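"""Training, evaluation and prediction driver.

Optimization protocol: AdamW (lr 3e-4, weight decay 0.05), cosine learning
rate decay over the epoch schedule, mixed Focal + improved-Dice loss,
validation after every epoch, best-by-validation-DSC checkpointing. Defaults
target the full-scale protocol (50 epochs, 224 x 224 inputs); everything is
configurable for desk-scale runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn, preprocessing as pp
from .losses import LossConfig, mixed_loss
from .metrics import assd as assd_metric, dsc as dsc_metric
from .network import DSFNet, NetworkConfig, build_dsfnet
from .nn.tensor import Tensor, no_grad

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "lr_at",
    "load_phantom_dataset",
    "train",
    "evaluate",
    "predict_volume",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    learning_rate: float = 3e-4
    weight_decay: float = 0.05
    epochs: int = 50
    batch_size: int = 8
    seed: int = 0
    threshold: float = 0.5
    loss: LossConfig = field(default_factory=LossConfig)
    model: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate, epochs and batch size must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["loss"] = LossConfig(**d.get("loss", {}))
        d["model"] = NetworkConfig(**d.get("model", {}))
        return cls(**d)


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_dsc: list = field(default_factory=list)
    best_epoch: int = -1
    checkpoint: str | None = None

    def to_dict(self):
        return asdict(self)


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Cosine decay: lr0 at epoch 0, 0 at the final epoch."""
    E = cfg.epochs
    if not 0 <= epoch < E:
        raise ValueError(f"epoch {epoch} outside schedule [0, {E})")
    if E == 1:
        return cfg.learning_rate
    return cfg.learning_rate * 0.5 * (1.0 + math.cos(math.pi * epoch / (E - 1)))


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def load_phantom_dataset(manifest_path, size: int | None = None,
                         target_spacing: float | None = None) -> dict:
    """Load a generated NIfTI dataset through the preprocessing pipeline.

    Returns ``{volume_id: {"slices", "masks", "meta", "mask_volume",
    "spacing"}}`` with images clipped/normalized to [0, 1].
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    out = {}
    for entry in manifest["volumes"]:
        img = pp.load_volume(root / entry["image"])
        lbl = pp.load_volume(root / entry["label"])
        if target_spacing is not None:
            img = pp.resample(img, target_spacing)
            lbl = pp.resample(lbl, target_spacing, is_label=True)
        img = pp.clip_normalize(img)
        lbl = pp.binarize_labels(lbl)
        size_ = size or img.data.shape[0]
        slices, masks, meta = pp.make_slices(img, lbl, size=size_)
        out[entry["id"]] = {
            "slices": slices,
            "masks": masks,
            "meta": meta,
            "mask_volume": lbl.data.astype(np.uint8),
            "spacing": img.spacing,
        }
    return out


def _stack_split(dataset: dict, ids: list):
    xs = np.concatenate([dataset[i]["slices"] for i in ids], axis=0)
    ys = np.concatenate([dataset[i]["masks"] for i in ids], axis=0)
    return xs[:, None].astype(np.float32), ys[:, None].astype(np.float32)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: DSFNet, train_cfg: TrainConfig,
                    extra: dict | None = None) -> None:
    """Self-describing checkpoint: weights + config + metadata in one npz."""
    meta = {"config": train_cfg.to_dict(), "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(str(path), __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Returns ``(model, train_cfg, extra)`` reconstructed from the file."""
    with np.load(str(path), allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    cfg = TrainConfig.from_dict(meta["config"])
    model = build_dsfnet(cfg.model)
    model.load_state_dict(state)
    model.eval()
    return model, cfg, meta["extra"]


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def predict_slices(model: DSFNet, xs: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Probabilities for a (N, 1, S, S) stack, evaluation mode."""
    model.eval()
    out = []
    with no_grad():
        for i in range(0, len(xs), batch_size):
            out.append(model(Tensor(xs[i: i + batch_size])).data)
    return np.concatenate(out, axis=0)


def predict_volume(model: DSFNet, dataset_entry: dict, batch_size: int = 8,
                   threshold: float = 0.5) -> np.ndarray:
    """Predict every slice of a volume and restack to 3-D (H, W, Z)."""
    xs = dataset_entry["slices"][:, None].astype(np.float32)
    probs = predict_slices(model, xs, batch_size)[:, 0]
    binary = (probs >= threshold).astype(np.uint8)
    return pp.reassemble(binary, dataset_entry["meta"])


def _validation_scores(model, xs, ys, cfg):
    probs = predict_slices(model, xs, cfg.batch_size)
    vloss = float(mixed_loss(probs.astype(np.float64), ys.astype(np.float64),
                             cfg.loss))
    vdsc = dsc_metric((probs >= cfg.threshold).astype(np.uint8),
                      ys.astype(np.uint8))
    return vloss, vdsc


def train(cfg: TrainConfig, dataset: dict, manifest: pp.SplitManifest,
          out_dir, log=print) -> TrainHistory:
    """Run the training loop and persist the best-validation-DSC checkpoint."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not manifest.train or not manifest.val:
        raise ValueError("empty train or validation split")
    nn.seed_all(cfg.seed)
    model = build_dsfnet(cfg.model)
    opt = nn.AdamW(model.parameters(), lr=cfg.learning_rate,
                   weight_decay=cfg.weight_decay)
    xs, ys = _stack_split(dataset, manifest.train)
    vx, vy = _stack_split(dataset, manifest.val)
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    best_dsc = -1.0
    ckpt_path = out_dir / "best.npz"
    log_path = out_dir / "history.jsonl"
    with open(log_path, "w") as logf:
        for epoch in range(cfg.epochs):
            model.train()
            opt.lr = lr_at(epoch, cfg)
            order = rng.permutation(len(xs))
            losses = []
            for i in range(0, len(order), cfg.batch_size):
                idx = order[i: i + cfg.batch_size]
                pred = model(Tensor(xs[idx]))
                loss = mixed_loss(pred, Tensor(ys[idx]), cfg.loss)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, step {i // cfg.batch_size}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            vloss, vdsc = _validation_scores(model, vx, vy, cfg)
            history.train_loss.append(float(np.mean(losses)))
            history.val_loss.append(vloss)
            history.val_dsc.append(vdsc)
            if vdsc > best_dsc:
                best_dsc = vdsc
                history.best_epoch = epoch
                save_checkpoint(ckpt_path, model, cfg,
                                extra={"epoch": epoch, "val_dsc": vdsc})
            rec = {"epoch": epoch, "lr": opt.lr,
                   "train_loss": history.train_loss[-1],
                   "val_loss": vloss, "val_dsc": vdsc}
            logf.write(json.dumps(rec) + "\n")
            if log:
                log(f"epoch {epoch:3d}  lr {opt.lr:.2e}  "
                    f"train {rec['train_loss']:.4f}  val {vloss:.4f}  "
                    f"val DSC {vdsc:.4f}")
    history.checkpoint = str(ckpt_path)
    (out_dir / "history.json").write_text(json.dumps(history.to_dict(), indent=2))
    return history


def evaluate(model: DSFNet, dataset: dict, ids: list, batch_size: int = 8,
             threshold: float = 0.5) -> dict:
    """Volume-level test report: per-volume and mean DSC / ASSD (mm)."""
    rows = []
    for vid in ids:
        entry = dataset[vid]
        pred = predict_volume(model, entry, batch_size, threshold)
        truth = entry["mask_volume"]
        row = {"id": vid, "dsc": dsc_metric(pred, truth)}
        try:
            row["assd_mm"] = assd_metric(pred, truth, spacing=entry["spacing"])
        except ValueError as e:
            row["assd_mm"] = None
            row["assd_error"] = str(e)
        rows.append(row)
    valid_assd = [r["assd_mm"] for r in rows if r["assd_mm"] is not None]
    return {
        "volumes": rows,
        "mean_dsc": float(np.mean([r["dsc"] for r in rows])),
        "mean_assd_mm": float(np.mean(valid_assd)) if valid_assd else None,
    }
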