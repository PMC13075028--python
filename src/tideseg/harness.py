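"""Training loop, evaluation runner, ablations and parameter accounting.

Training follows the published recipe: AdamW (lr 6e-5, weight decay 0.01),
linear warmup followed by polynomial decay, batch augmentation on the train
split only, joint objective L_seg + lambda * L_bnd. Runs are seed-reproducible
on one device: the seed fixes weight init, batch sampling and augmentation
draws, so two runs with the same seed produce identical loss logs.

The reference recipe (512-px tiles, batch 8, 40k iterations) is a GPU-scale
profile; the configs used by the tests and ablation helpers run the same code
path at reduced tile size, depth and iteration count.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import metrics as M
from . import nn
from . import supervision as S
from .errors import ConfigError, InputError
from .model import EcaConfig, ModelConfig, SegmentationModel, normalize_composite
from .nn import functional as F
from .nn.tensor import Tensor
from .pipeline import AugmentPolicy, augment

__all__ = [
    "TrainConfig", "AblationSpec", "TrainResult", "train", "evaluate",
    "ablate_lambda", "ablate_eca_placement", "count_parameters",
    "save_checkpoint", "load_checkpoint", "ECA_PLACEMENTS",
]

# ECA placement ablation groups: (active stages, boundary branch on)
ECA_PLACEMENTS: dict[str, tuple[tuple[int, ...], bool]] = {
    "A1": ((1,), False),
    "A2": ((2,), False),
    "B1": ((3,), True),
    "B2": ((4,), True),
    "D1": ((3, 4), True),
    "D2": ((1, 2), True),
}


@dataclass(frozen=True)
class TrainConfig:
    input_size: int = 512
    iters: int = 40_000
    batch_size: int = 8
    lr: float = 6e-5
    weight_decay: float = 0.01
    warmup_iters: int = 1500
    poly_power: float = 1.0
    warmup_factor: float = 0.1
    lambda_bnd: float = 0.5
    seed: int = 0
    val_every: int | None = None  # default: every 10% of iters

    def __post_init__(self):
        if min(self.input_size, self.iters, self.batch_size) <= 0 and self.iters != 0:
            raise ConfigError("input_size, iters and batch_size must be positive")
        if self.lambda_bnd < 0:
            raise ConfigError("lambda_bnd must be non-negative")


@dataclass(frozen=True)
class AblationSpec:
    lambda_grid: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5, 0.7, 1.0)
    eca_placements: tuple[str, ...] = ("A1", "A2", "B1", "B2", "D1", "D2")
    repeats: int = 3

    def __post_init__(self):
        if not self.lambda_grid or self.repeats < 1:
            raise ConfigError("lambda grid must be non-empty and repeats >= 1")
        unknown = set(self.eca_placements) - set(ECA_PLACEMENTS)
        if unknown:
            raise ConfigError(f"unknown placement groups {sorted(unknown)}")


@dataclass
class TrainResult:
    model: SegmentationModel
    loss_log: pd.DataFrame       # iter, lr, l_seg, l_bnd, l_total
    val_log: pd.DataFrame        # iter, miou, bf_score, hd
    best_state: dict | None      # state dict at the best validation mIoU


def _batch_tensors(samples: list[tuple[np.ndarray, np.ndarray]]):
    xs = np.stack([normalize_composite(img) for img, _ in samples])
    masks = np.stack([m for _, m in samples]).astype(np.int64)
    bnd = np.stack([S.morphological_gradient(m) for _, m in samples]).astype(float)
    return Tensor(xs), masks, bnd[:, None]  # boundary target (N,1,H,W)


def train(model: SegmentationModel, data: dict[str, list], cfg: TrainConfig,
          policy: AugmentPolicy | None = AugmentPolicy(),
          log_path: str | None = None) -> TrainResult:
    """Optimise ``model`` on ``data`` = {"train": [(image, mask)...], "val": [...]}.

    Images are 8-bit (NIR, G, B) tiles; masks are {0,1} grids of the same
    side. Raises on divergence (non-finite loss).
    """
    train_set = data.get("train")
    if not train_set:
        raise InputError("data must contain a non-empty 'train' split")
    val_set = data.get("val", [])
    lam = cfg.lambda_bnd
    rng = np.random.default_rng(cfg.seed)
    sched = nn.WarmupPolySchedule(cfg.lr, max(cfg.iters, 1), cfg.warmup_iters,
                                  cfg.poly_power, cfg.warmup_factor)
    opt = nn.AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    val_every = cfg.val_every or max(cfg.iters // 10, 1)
    has_bnd = model.config.boundary_branch
    rows, val_rows = [], []
    best_miou, best_state = -1.0, None
    model.train()
    for it in range(cfg.iters):
        idx = rng.integers(0, len(train_set), size=cfg.batch_size)
        batch = []
        for i in idx:
            img, mask = train_set[int(i)]
            if policy is not None:
                img, mask = augment(img, mask, policy, rng, phase="train")
            batch.append((img, mask))
        x, masks, bnd_t = _batch_tensors(batch)
        pair = model(x)
        l_seg = F.cross_entropy(pair.seg_logits, masks)
        if has_bnd:
            if lam > 0:
                l_bnd = F.bce_with_logits(pair.boundary_logits, bnd_t)
                l_total = l_seg + lam * l_bnd
                l_bnd_val = l_bnd.item()
            else:
                # logged but not optimised
                l_bnd_val = S.boundary_loss(pair.boundary_logits.data, bnd_t)
                l_total = l_seg
        else:
            l_bnd_val = float("nan")
            l_total = l_seg
        lt = l_total.item()
        if not np.isfinite(lt):
            raise RuntimeError(
                f"training diverged at iteration {it}: total loss {lt}")
        opt.zero_grad()
        l_total.backward()
        lr = sched(it)
        opt.step(lr=lr)
        rows.append({"iter": it, "lr": lr, "l_seg": l_seg.item(),
                     "l_bnd": l_bnd_val, "l_total": lt})
        if val_set and ((it + 1) % val_every == 0 or it + 1 == cfg.iters):
            rep, _ = evaluate(model, val_set)
            val_rows.append({"iter": it, "miou": rep.miou,
                             "bf_score": rep.bf_score, "hd": rep.hd})
            if rep.miou > best_miou:
                best_miou, best_state = rep.miou, model.state_dict()
            model.train()
    loss_log = pd.DataFrame(rows, columns=["iter", "lr", "l_seg", "l_bnd", "l_total"])
    val_log = pd.DataFrame(val_rows, columns=["iter", "miou", "bf_score", "hd"])
    if log_path:
        loss_log.to_csv(log_path, index=False)
    return TrainResult(model, loss_log, val_log, best_state)


def evaluate(model: SegmentationModel, tiles: list,
             delta: float = M.DELTA_DEFAULT) -> tuple[M.MetricReport, pd.DataFrame]:
    """Argmax predictions over a split, per-image metrics + pooled aggregate."""
    if not tiles:
        raise InputError("empty evaluation split")
    reports, counts = [], []
    for img, mask in tiles:
        seg, _ = model.predict(img)
        pred = np.argmax(seg, axis=-1).astype(np.uint8)
        rep, cnt = M.evaluate_pair(pred, mask, delta)
        reports.append(rep)
        counts.append(cnt)
    agg = M.aggregate(reports, counts)
    frame = M.report_frame(reports)
    return agg, frame


# ----------------------------------------------------------------- ablations
def _run_once(model_cfg: ModelConfig, train_cfg: TrainConfig, data: dict,
              policy: AugmentPolicy | None) -> tuple[M.MetricReport, TrainResult]:
    model = SegmentationModel(model_cfg, seed=train_cfg.seed)
    result = train(model, data, train_cfg, policy=policy)
    split = data.get("val") or data["train"]
    rep, _ = evaluate(model, split)
    return rep, result


def ablate_lambda(spec: AblationSpec, base_cfg: TrainConfig,
                  model_cfg: ModelConfig, data: dict,
                  policy: AugmentPolicy | None = None) -> pd.DataFrame:
    """Boundary-weight sweep: one training run per (lambda, seed).

    Returns a table with per-lambda mean and sd of mIoU and BF-score across
    the repeated seeds, mirroring the usual lambda-ablation layout.
    """
    def sd(vals):
        return float(np.std(vals, ddof=1)) if spec.repeats > 1 else float("nan")

    rows = []
    for lam in spec.lambda_grid:
        mious, bfs, hds = [], [], []
        for r in range(spec.repeats):
            cfg = replace(base_cfg, lambda_bnd=float(lam),
                          seed=base_cfg.seed + 101 * r)
            rep, _ = _run_once(model_cfg, cfg, data, policy)
            mious.append(rep.miou)
            bfs.append(rep.bf_score)
            hds.append(rep.hd)
        rows.append({
            "lambda": lam,
            "miou_mean": float(np.mean(mious)), "miou_sd": sd(mious),
            "bf_mean": float(np.mean(bfs)), "bf_sd": sd(bfs),
            "hd_mean": float(np.mean(hds)), "hd_sd": sd(hds),
        })
    return pd.DataFrame(rows)


def ablate_eca_placement(spec: AblationSpec, base_cfg: TrainConfig,
                         model_cfg: ModelConfig, data: dict,
                         policy: AugmentPolicy | None = None) -> pd.DataFrame:
    """One scaled-down run per named ECA placement group."""
    rows = []
    for group in spec.eca_placements:
        stages, boundary_on = ECA_PLACEMENTS[group]
        eca = None
        if model_cfg.eca is not None:
            eca = replace(model_cfg.eca, active_stages=stages)
        else:
            eca = EcaConfig(active_stages=stages)
        mc = replace(model_cfg, eca=eca, boundary_branch=boundary_on)
        cfg = base_cfg if boundary_on else replace(base_cfg, lambda_bnd=0.0)
        rep, _ = _run_once(mc, cfg, data, policy)
        rows.append({"group": group,
                     "stages": ",".join(f"C{s}" for s in stages),
                     "boundary": boundary_on,
                     "miou": rep.miou, "f1": rep.f1,
                     "precision": rep.precision, "recall": rep.recall,
                     "bf_score": rep.bf_score, "hd": rep.hd})
    return pd.DataFrame(rows)


def count_parameters(model: SegmentationModel) -> pd.DataFrame:
    """Trainable parameter count per component; the rows sum to the total."""
    rows = []
    for name, module in model.components().items():
        rows.append({"module": name, "parameters": module.num_parameters()})
    table = pd.DataFrame(rows)
    total = int(table["parameters"].sum())
    assert total == model.num_parameters(), "component rows must sum to the total"
    table.loc[len(table)] = {"module": "total", "parameters": total}
    return table


# --------------------------------------------------------------- checkpoints
def save_checkpoint(path: str, model: SegmentationModel) -> None:
    """Single-file archive: weights + embedded config for exact graph rebuild."""
    payload = {"config": json.dumps(model.config.to_dict())}
    state = model.state_dict()
    arrays = {f"arr::{k}": v for k, v in state.items()}
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    np.savez(path, __config__=np.frombuffer(
        payload["config"].encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> SegmentationModel:
    with np.load(path) as z:
        cfg_json = bytes(z["__config__"]).decode()
        cfg = ModelConfig.from_dict(json.loads(cfg_json))
        model = SegmentationModel(cfg, seed=0)
        state = {k[len("arr::"):]: z[k] for k in z.files if k.startswith("arr::")}
    model.load_state_dict(state)
    model.eval()
    return model
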