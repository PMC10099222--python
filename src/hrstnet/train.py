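"""Training and evaluation loops.

Optimisation follows the published recipe: AdamW with decoupled weight
decay, dice + cross-entropy loss, cosine learning-rate decay with a linear
warm-up (warm-up of 50 epochs and initial rate 1e-4 by default; 1e-3 is the
multi-organ setting), and the checkpoint with the best validation Dice is
kept.  Everything is seeded; two runs with the same seed produce identical
loss trajectories.
"""
from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._tensor import Tensor, no_grad
from .metrics import dice_ce_loss, dice_score, hausdorff95, region_masks
from .network import HRSTNet, save_checkpoint

__all__ = ["TrainConfig", "lr_at", "AdamW", "train", "evaluate", "predict"]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    min_lr: float = 0.0
    weight_decay: float = 0.01
    betas: tuple = (0.9, 0.999)
    warmup_epochs: int = 50
    epochs: int = 1000
    batch_size: int = 2
    seed: int = 0
    crop: int = 128

    def __post_init__(self):
        if self.warmup_epochs < 0 or self.epochs <= 0:
            raise ValueError("epochs must be positive, warmup_epochs >= 0")


def lr_at(step: int, cfg: TrainConfig, steps_per_epoch: int = 1) -> float:
    """Learning rate at an optimiser step: linear ramp 0 -> lr over the
    warm-up, then cosine decay lr -> min_lr over the remaining steps."""
    if step < 0:
        raise ValueError("step must be >= 0")
    warm = cfg.warmup_epochs * steps_per_epoch
    total = cfg.epochs * steps_per_epoch
    if warm > 0 and step < warm:
        return cfg.lr * step / warm
    if step >= total:
        return cfg.min_lr
    span = max(total - warm, 1)
    t = (step - warm) / span
    return cfg.min_lr + (cfg.lr - cfg.min_lr) * 0.5 * (1.0 + math.cos(math.pi * t))


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            update = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= np.float32(self.lr) * update


def _foreground_dice(pred_labels: np.ndarray, ref_labels: np.ndarray,
                     num_classes: int) -> float:
    """Mean Dice over foreground classes present in prediction or reference."""
    vals = []
    for c in range(1, num_classes):
        if (ref_labels == c).any() or (pred_labels == c).any():
            vals.append(dice_score(pred_labels == c, ref_labels == c))
    return float(np.mean(vals)) if vals else 1.0


def train(model: HRSTNet, train_data, cfg: TrainConfig, val_data=None,
          steps: int | None = None, out_dir=None, log_every: int = 10) -> dict:
    """Optimise ``model`` on ``train_data`` (a list of (image, labels) pairs,
    already preprocessed to the crop size).

    ``steps`` caps the number of optimiser steps (otherwise
    ``cfg.epochs * ceil(n/batch)`` are run).  Returns a history dict with the
    loss trajectory, per-evaluation Dice, and the best state.  Aborts with a
    diagnostic on NaN loss.
    """
    rng = np.random.default_rng(cfg.seed)
    params = list(model.parameters())
    opt = AdamW(params, lr=cfg.lr, betas=tuple(cfg.betas),
                weight_decay=cfg.weight_decay)
    n = len(train_data)
    steps_per_epoch = max(1, math.ceil(n / cfg.batch_size))
    total = steps if steps is not None else cfg.epochs * steps_per_epoch
    history = {"loss": [], "lr": [], "val": [], "config": asdict(cfg)}
    best = {"dice": -1.0, "step": -1, "state": None}
    ncls = model.cfg.num_classes
    step = 0
    while step < total:
        order = rng.permutation(n)
        for a in range(0, n, cfg.batch_size):
            if step >= total:
                break
            idx = order[a:a + cfg.batch_size]
            imgs = np.stack([train_data[i][0] for i in idx]).astype(np.float32)
            labs = np.stack([train_data[i][1] for i in idx])
            opt.lr = lr_at(step, cfg, steps_per_epoch)
            opt.zero_grad()
            scores = model(Tensor(imgs))
            loss = dice_ce_loss(scores, labs)
            lval = loss.item()
            if not math.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss {lval} at step {step} (lr={opt.lr:.2e}); "
                    "lower the learning rate or check the input scaling")
            loss.backward()
            opt.step()
            history["loss"].append(lval)
            history["lr"].append(opt.lr)
            if val_data is not None and (step + 1) % log_every == 0:
                d = validation_dice(model, val_data, ncls)
                history["val"].append({"step": step, "dice": d})
                if d > best["dice"]:
                    best.update(dice=d, step=step, state=model.state_dict())
            step += 1
    if val_data is not None and best["state"] is None:
        d = validation_dice(model, val_data, ncls)
        best.update(dice=d, step=step - 1, state=model.state_dict())
    history["best_dice"] = best["dice"]
    history["best_step"] = best["step"]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if best["state"] is not None:
            model.load_state_dict(best["state"])
        save_checkpoint(model, out_dir / "checkpoint.npz",
                        {"best_dice": best["dice"], "best_step": best["step"]})
        with open(out_dir / "train_log.jsonl", "w") as fh:
            for i, (l, lr) in enumerate(zip(history["loss"], history["lr"])):
                fh.write(json.dumps({"step": i, "loss": l, "lr": lr}) + "\n")
    history["best_state"] = best["state"]
    return history


def predict(model: HRSTNet, image: np.ndarray) -> np.ndarray:
    """Argmax label volume for one preprocessed image (K, D, H, W)."""
    with no_grad():
        scores = model(Tensor(image[None].astype(np.float32)))
    return np.argmax(scores.numpy()[0], axis=0).astype(np.uint8)


def validation_dice(model: HRSTNet, data, num_classes: int) -> float:
    vals = [
        _foreground_dice(predict(model, img), np.asarray(lab), num_classes)
        for img, lab in data]
    return float(np.mean(vals))


def evaluate(model: HRSTNet, data, scheme: str = "brats",
             spacing=(1.0, 1.0, 1.0), out_csv=None, out_json=None) -> dict:
    """Per-case and aggregate DSC / HD95 per region.

    ``data``: list of (case_id, image, labels).  Undefined HD95 values (one
    empty mask) are reported as NaN and excluded from the aggregate mean,
    with their count recorded.
    """
    rows = []
    for cid, img, lab in data:
        pred = predict(model, img)
        pred_regions = region_masks(pred, scheme)
        ref_regions = region_masks(np.asarray(lab), scheme)
        for name in ref_regions:
            P = pred_regions.get(name, np.zeros_like(lab, dtype=bool))
            G = ref_regions[name]
            rows.append({"case_id": cid, "region": name,
                         "dsc": dice_score(P, G),
                         "hd95": hausdorff95(P, G, spacing)})
    summary = {}
    for name in {r["region"] for r in rows}:
        sel = [r for r in rows if r["region"] == name]
        hds = [r["hd95"] for r in sel if not math.isnan(r["hd95"])]
        summary[name] = {
            "mean_dsc": float(np.mean([r["dsc"] for r in sel])),
            "mean_hd95": float(np.mean(hds)) if hds else float("nan"),
            "n_cases": len(sel),
            "n_hd95_undefined": len(sel) - len(hds),
        }
    report = {"per_case": rows, "summary": summary}
    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            wr = csv.DictWriter(fh, fieldnames=["case_id", "region", "dsc", "hd95"])
            wr.writeheader()
            wr.writerows(rows)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report, indent=1))
    return report
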