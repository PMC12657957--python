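"""Training loop, evaluation harness, ensembling, and pseudo-label imputation.

Training minimizes the correlation-plus-MAE loss over the train split with
Adam under cosine learning-rate decay, batching samples bucketed by length
(padding is masked out of attention and of every loss term), and early-stops
on the macro-averaged validation DC Pearson correlation (the mean over
conditions of the mean per-sample correlation between predicted and observed
deprivation-condition profiles).

Pseudo-labeling: a seed-ensemble teacher's mean DC prediction fills the
missing training targets, and a fresh student is retrained on the completed
training split; validation and test targets are never touched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .core_io import CONDITION_INDEX, Dataset, Sample, annotated
from .model import DwellModel, ModelConfig, PredictionPair, maape, mse, pcc, sample_loss, scc

logger = logging.getLogger("ribodwell")


@dataclass
class TrainConfig:
    epochs: int = 15
    lr: float = 2e-3
    optimizer: str = "adam"
    patience: int = 4  # early stopping on macro val DC-PCC
    max_batch: int = 16
    max_batch_tokens: int = 4096
    seed: int = 0
    ensemble_seeds: tuple[int, ...] = (101, 102, 103, 104, 105)

    def __post_init__(self):
        if len(set(self.ensemble_seeds)) != len(self.ensemble_seeds) or not self.ensemble_seeds:
            raise ValueError("ensemble_seeds must be non-empty and distinct")


# ---------------------------------------------------------------------------
# batching


def _make_batches(samples: list[Sample], cfg: TrainConfig) -> list[list[int]]:
    order = sorted(range(len(samples)), key=lambda i: samples[i].seq.n)
    batches, cur = [], []
    for i in order:
        n = samples[i].seq.n
        width = max([samples[j].seq.n for j in cur] + [n])
        if cur and (len(cur) >= cfg.max_batch or (len(cur) + 1) * width > cfg.max_batch_tokens):
            batches.append(cur)
            cur = []
        cur.append(i)
    if cur:
        batches.append(cur)
    return batches


def _pad_batch(samples: list[Sample]):
    width = max(s.seq.n for s in samples)
    B = len(samples)
    tokens = np.zeros((B, width), dtype=np.int64)
    mask = np.zeros((B, width), dtype=bool)
    conds = np.zeros(B, dtype=np.int64)
    for b, s in enumerate(samples):
        tokens[b, : s.seq.n] = s.seq.token_ids()
        mask[b, : s.seq.n] = True
        conds[b] = CONDITION_INDEX[s.cond]
    return tokens, conds, mask


def predict_samples(model: DwellModel, samples: list[Sample], cfg: TrainConfig | None = None):
    """Batched inference; returns one PredictionPair per sample."""
    cfg = cfg or TrainConfig()
    out: list[PredictionPair | None] = [None] * len(samples)
    for batch in _make_batches(samples, cfg):
        group = [samples[i] for i in batch]
        tokens, conds, mask = _pad_batch(group)
        yc, yd = model.fast_forward(tokens, conds, mask)
        for b, i in enumerate(batch):
            n = group[b].seq.n
            out[i] = PredictionPair(yc[b, :n].astype(float), yd[b, :n].astype(float))
    return out


# ---------------------------------------------------------------------------
# evaluation


def evaluate(model: DwellModel, samples: list[Sample], cfg: TrainConfig | None = None) -> pd.DataFrame:
    """Per-condition mean metrics on the DC prediction, plus a macro row."""
    preds = predict_samples(model, samples, cfg)
    rows = {}
    for s, p in zip(samples, preds):
        r = pcc(s.y_dc, p.y_dc)
        rows.setdefault(s.cond, []).append(
            (r, scc(s.y_dc, p.y_dc), mse(s.y_dc, p.y_dc), maape(s.y_dc, p.y_dc))
        )
    table = []
    for cond, vals in sorted(rows.items()):
        arr = np.asarray(vals, dtype=float)
        with np.errstate(invalid="ignore"):
            table.append((cond, len(vals), *np.nanmean(arr, axis=0)))
    df = pd.DataFrame(table, columns=["condition", "n", "pcc", "scc", "mse", "maape"])
    macro = df[["pcc", "scc", "mse", "maape"]].mean()
    df.loc[len(df)] = ("MacroAvg", int(df["n"].sum()), *macro)
    return df


def macro_dc_pcc(model: DwellModel, samples: list[Sample], cfg: TrainConfig | None = None) -> float:
    df = evaluate(model, samples, cfg)
    return float(df.loc[df["condition"] == "MacroAvg", "pcc"].iloc[0])


# ---------------------------------------------------------------------------
# training


def train(
    dataset: Dataset,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    init_seed: int | None = None,
) -> tuple[DwellModel, pd.DataFrame]:
    """Train on the train split; return the checkpoint with best val DC-PCC.

    Fully reproducible: model init from ``init_seed`` (default the model
    config seed), batch shuffling from the train config seed.
    """
    train_samples = dataset.subset("train")
    val_samples = dataset.subset("val")
    if not train_samples or not val_samples:
        raise ValueError("train and val splits must be non-empty")
    if init_seed is not None:
        model_cfg = replace(model_cfg, seed=init_seed)
    model = DwellModel(model_cfg)
    opt = Adam(model.parameters(), lr=train_cfg.lr)
    rng = np.random.default_rng(train_cfg.seed)
    batches = _make_batches(train_samples, train_cfg)
    total_steps = max(1, train_cfg.epochs * len(batches))
    step = 0
    best = (-np.inf, None, -1)
    history = []
    since_best = 0
    for epoch in range(train_cfg.epochs):
        perm = rng.permutation(len(batches))
        epoch_loss = 0.0
        for bi in perm:
            group = [train_samples[i] for i in batches[bi]]
            tokens, conds, mask = _pad_batch(group)
            yc, yd = model.forward(tokens, conds, mask)
            losses = []
            for b, s in enumerate(group):
                n = s.seq.n
                losses.append(sample_loss(s.y_ctrl, s.y_delta, s.y_dc, yc[b, :n], yd[b, :n]))
            total = losses[0]
            for l in losses[1:]:
                total = total + l
            total = total * (1.0 / len(losses))
            if not np.isfinite(total.data):
                raise RuntimeError(f"non-finite loss in batch {bi} (epoch {epoch})")
            opt.zero_grad()
            total.backward()
            lr = train_cfg.lr * 0.5 * (1.0 + math.cos(math.pi * step / total_steps))
            opt.step(lr=lr)
            step += 1
            epoch_loss += float(total.data)
        val_pcc = macro_dc_pcc(model, val_samples, train_cfg)
        history.append((epoch, epoch_loss / len(batches), val_pcc))
        logger.info("epoch %d: train loss %.4f, val DC-PCC %.4f", epoch, history[-1][1], val_pcc)
        if val_pcc > best[0]:
            best = (val_pcc, model.state_dict(), epoch)
            since_best = 0
        else:
            since_best += 1
            if since_best > train_cfg.patience:
                break
    model.load_state(best[1])
    hist = pd.DataFrame(history, columns=["epoch", "train_loss", "val_dc_pcc"])
    hist.attrs["best_epoch"] = best[2]
    return model, hist


def train_ensemble(
    dataset: Dataset, model_cfg: ModelConfig, train_cfg: TrainConfig
) -> list[DwellModel]:
    """The pseudo-labeling teacher: one model per ensemble seed."""
    models = []
    for s in train_cfg.ensemble_seeds:
        m, _ = train(dataset, model_cfg, train_cfg, init_seed=int(s))
        models.append(m)
    return models


# ---------------------------------------------------------------------------
# ensembling and pseudo-label imputation


def _check_compatible(models: list[DwellModel]):
    ref = models[0].config
    for m in models[1:]:
        for f in ("d_model", "n_layers", "n_heads", "d_ff", "backbone"):
            if getattr(m.config, f) != getattr(ref, f):
                raise ValueError(f"ensemble member config mismatch on {f}")


def ensemble_predict(models: list[DwellModel], sample: Sample) -> PredictionPair:
    """Position-wise arithmetic mean of each head over the ensemble members."""
    _check_compatible(models)
    preds = [m.predict(sample.seq, sample.cond) for m in models]
    return PredictionPair(
        np.mean([p.y_ctrl for p in preds], axis=0),
        np.mean([p.y_delta for p in preds], axis=0),
    )


def impute_missing(dataset: Dataset, models: list[DwellModel], split: str = "train") -> int:
    """Fill missing train DC targets with the ensembled DC prediction.

    Only the train split may be imputed; predicted values are clipped at
    zero (profiles are non-negative by definition).  Control samples have
    the filled value written to both profiles so the control identity is
    preserved; the difference profile is recomputed and stays missing where
    the control profile is itself missing.  Returns the number of imputed
    positions.
    """
    if split != "train":
        raise ValueError("pseudo-label imputation is restricted to the train split")
    _check_compatible(models)
    n_imputed = 0
    by_len: dict = {}
    targets = dataset.subset("train")
    # batch ensemble inference per member for speed
    member_preds = [predict_samples(m, targets) for m in models]
    for i, s in enumerate(targets):
        gap = ~annotated(s.y_dc)
        if not gap.any():
            continue
        y_dc_hat = np.mean([member_preds[m][i].y_dc for m in range(len(models))], axis=0)
        fill = np.maximum(y_dc_hat[gap], 0.0)
        s.y_dc[gap] = fill
        if s.cond == "CTRL":
            s.y_ctrl[gap] = fill
        s.refresh_delta()
        n_imputed += int(gap.sum())
    return n_imputed


def retrain_pseudolabeled(
    dataset: Dataset, model_cfg: ModelConfig, train_cfg: TrainConfig, student_seed: int = 7919
) -> tuple[DwellModel, pd.DataFrame]:
    """Fresh training run on the imputed train split (the student model)."""
    return train(dataset, model_cfg, train_cfg, init_seed=student_seed)
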