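"""Ablation protocol: splits, repeated training, per-image test IoU.

Each experiment trains the network from the same starting conditions with
exactly one augmentation configuration (or none, the baseline) and evaluates
per-image IoU on a fixed test split.  Experiments are repeated (default ten
times) with fresh seeds to average out the randomness of the augmentation
draws; the data split itself never changes across experiments or
repetitions.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .losses import binarize, combined_loss, combined_loss_grad, jaccard_index
from .optim import Adam, lr_schedule
from .sample import ImageSample
from .transforms import TransformRange, apply_random_transform, spec_for
from .unet import UNet, UNetConfig, build_unet

__all__ = [
    "ExperimentConfig",
    "RESULT_COLUMNS",
    "split_dataset",
    "train_model",
    "per_image_iou",
    "run_ablation",
    "derive_seed",
]

RESULT_COLUMNS = ["experiment_id", "transform", "range", "repetition", "image_id", "iou"]


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the ablation plan.

    ``transform_name`` is "none" (baseline), one family name, or a list of
    (name, range_value) pairs for a combination; ``range_value`` is the
    family's range parameter (scalar or pair) and is ignored for
    combinations.
    """

    experiment_id: str
    transform_name: str | list = "none"
    range_value: object = None
    repetitions: int = 10
    epochs: int = 15
    batch_size: int = 4
    seed: int = 0
    base_lr: float = 1e-4
    model: UNetConfig = field(default_factory=UNetConfig)

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs/batch_size")

    @property
    def is_baseline(self) -> bool:
        return self.transform_name == "none"

    def transform_spec(self):
        if self.is_baseline:
            return None
        if isinstance(self.transform_name, (list, tuple)):
            return [spec_for(n, v) for n, v in self.transform_name]
        return spec_for(self.transform_name, self.range_value)


def derive_seed(seed: int, experiment_id: str, repetition: int) -> int:
    """Stable per-(experiment, repetition) seed below 2^31."""
    key = f"{seed}:{experiment_id}:{repetition}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def split_dataset(
    samples: list[ImageSample],
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[list[ImageSample], list[ImageSample], list[ImageSample]]:
    """Disjoint, exhaustive train/val/test split, deterministic under seed.

    Fractions must sum to 1.  Explicit predefined splits (datasets that ship
    their own division) can simply bypass this function.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(samples)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    return (
        [samples[i] for i in idx_train],
        [samples[i] for i in idx_val],
        [samples[i] for i in idx_test],
    )


def _batch_arrays(batch: list[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in batch]).astype(np.float32) / 255.0
    x = np.transpose(x, (0, 3, 1, 2))
    y = np.stack([s.mask for s in batch]).astype(np.float32)[:, None]
    return x, y


def train_model(
    model: UNet,
    train_set: list[ImageSample],
    val_set: list[ImageSample] | None,
    augmentation: TransformRange | list | None,
    config: ExperimentConfig,
    rng: np.random.Generator | None = None,
    log: callable = None,
) -> UNet:
    """Train with the combined BCE/Jaccard loss and the cyclic LR schedule.

    Augmentation parameters are re-drawn for every sample every time it is
    served (on-the-fly augmentation).  ``epochs = 0`` returns the model
    untouched.  Deterministic for a fixed rng seed.
    """
    if not train_set:
        raise ValueError("training set is empty")
    if config.epochs == 0:
        return model
    if rng is None:
        rng = np.random.default_rng(config.seed)
    opt = Adam(model.params())
    n = len(train_set)
    for epoch in range(config.epochs):
        opt.lr = lr_schedule(epoch, config.base_lr)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            batch = [
                apply_random_transform(train_set[i], augmentation, rng)
                for i in order[start:start + config.batch_size]
            ]
            x, y = _batch_arrays(batch)
            p = model.forward(x, train=True, rng=rng)
            loss, dprob = combined_loss_grad(y, p)
            model.backward(dprob)
            opt.step(model.grads())
            epoch_loss += loss
            n_batches += 1
        if log is not None:
            msg = f"epoch {epoch}: lr={opt.lr:.2e} train_loss={epoch_loss / n_batches:.4f}"
            if val_set:
                xv, yv = _batch_arrays(val_set)
                msg += f" val_loss={combined_loss(yv, model.forward(xv)):.4f}"
            log(msg)
    # precise batch-norm calibration over the (un-augmented) training set,
    # so eval-mode statistics reflect the trained network exactly
    model.calibrate_batchnorm(
        _batch_arrays(train_set[s:s + config.batch_size])[0]
        for s in range(0, n, config.batch_size)
    )
    return model


def per_image_iou(
    model: UNet,
    test_set: list[ImageSample],
    threshold: float = 0.5,
    exclude_void: bool = False,
) -> np.ndarray:
    """IoU of the binarized prediction against ground truth, per test image.

    With ``exclude_void`` the comparison is restricted to the valid (non-
    void) area of each frame.
    """
    ious = []
    for s in test_set:
        prob = model.predict_proba(s.image[None])[0]
        pred = binarize(prob, threshold)
        truth = s.mask
        if exclude_void:
            keep = (1 - s.void_mask).astype(bool)
            ious.append(jaccard_index(truth[keep], pred[keep]))
        else:
            ious.append(jaccard_index(truth, pred))
    return np.asarray(ious)


def run_ablation(
    configs: list[ExperimentConfig],
    samples: list[ImageSample],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    out_csv: str | None = None,
    exclude_void: bool = False,
    log: callable = None,
) -> pd.DataFrame:
    """Run every (config x repetition) cell and collect per-image test IoUs.

    Exactly one baseline ("none") config is required.  Each cell gets a
    fresh seed derived from (global seed, experiment_id, repetition), used
    for both weight initialization and augmentation draws, so queuing more
    experiments never perturbs the baseline's records.  When ``out_csv`` is
    given, records are appended after every cell and completed cells are
    skipped on re-run (crash-resumable, no duplicates).

    Within a repetition every experiment starts from the same initial
    weights (the analogue of finetuning a shared pretrained checkpoint), so
    with ``epochs = 0`` all experiments produce identical IoU vectors.
    """
    n_baseline = sum(c.is_baseline for c in configs)
    if n_baseline != 1:
        raise ValueError(f"expected exactly one baseline config, found {n_baseline}")
    ids = [c.experiment_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ValueError("experiment_id values must be unique")

    train_set, val_set, test_set = split_dataset(samples, fractions, seed)

    done: set[tuple[str, int]] = set()
    records: list[dict] = []
    if out_csv and os.path.exists(out_csv):
        prev = pd.read_csv(out_csv)
        records = prev.to_dict("records")
        done = set(zip(prev["experiment_id"], prev["repetition"]))

    for cfg in configs:
        spec = cfg.transform_spec()
        for rep in range(cfg.repetitions):
            if (cfg.experiment_id, rep) in done:
                continue
            # all experiments of a repetition share the initial weights
            # (mirroring a shared pretrained checkpoint); only augmentation
            # draws depend on the experiment
            init_seed = derive_seed(seed, "__init__", rep)
            cell_seed = derive_seed(seed, cfg.experiment_id, rep)
            model = build_unet(cfg.model, seed=init_seed)
            rng = np.random.default_rng(cell_seed)
            if cfg.epochs > 0:
                train_model(model, train_set, val_set, spec, cfg, rng=rng, log=log)
            ious = per_image_iou(model, test_set, exclude_void=exclude_void)
            rng_desc = cfg.range_value
            for s, iou in zip(test_set, ious):
                records.append(
                    {
                        "experiment_id": cfg.experiment_id,
                        "transform": str(cfg.transform_name),
                        "range": str(rng_desc),
                        "repetition": rep,
                        "image_id": s.id,
                        "iou": float(iou),
                    }
                )
            if out_csv:
                pd.DataFrame.from_records(records)[RESULT_COLUMNS].to_csv(out_csv, index=False)
            if log is not None:
                log(f"{cfg.experiment_id} rep {rep}: mean IoU {ious.mean():.3f}")
    return pd.DataFrame.from_records(records)[RESULT_COLUMNS]
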