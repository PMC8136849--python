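"""Training protocols: early-stopped, fixed-epoch, and combined two-library.

Models are trained with Adam (default parameters) on a mean-squared-error
loss.  Batches are padded on the 5' end to the longest sequence in the
batch, so fixed- and variable-length libraries train through the same path.
Two protocols are provided: early stopping on a withheld validation set
(stop after ``patience`` epochs without a strictly lower validation MSE,
return the best snapshot), and fixed-epoch training without a validation
set.  The combined protocol trains one shared trunk on two libraries at
once, with a per-library affine output scaling absorbing scale differences
between assays.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model_zoo import MRLPredictor, save_model
from .nn import Adam
from .seq_core import as_sequence, encode_batch

__all__ = [
    "MRLDataset",
    "TrainConfig",
    "split_validation",
    "train",
    "train_combined",
    "predict_dataset",
]

logger = logging.getLogger("framepool")


@dataclass(frozen=True)
class MRLDataset:
    """Sequences with MRL labels and per-sequence library indices."""

    sequences: tuple
    mrl: np.ndarray
    library: np.ndarray

    def __post_init__(self):
        n = len(self.sequences)
        if self.mrl.shape != (n,) or self.library.shape != (n,):
            raise ValueError("sequences, mrl and library must have equal length")
        if not np.all(np.isfinite(self.mrl)):
            raise ValueError("MRL labels must be finite")

    @staticmethod
    def from_arrays(sequences: Sequence, mrl, library=None) -> "MRLDataset":
        seqs = tuple(as_sequence(s) for s in sequences)
        mrl = np.asarray(mrl, dtype=np.float64)
        if library is None:
            library = np.zeros(len(seqs), dtype=np.int64)
        else:
            library = np.asarray(library, dtype=np.int64)
        return MRLDataset(seqs, mrl, library)

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, idx) -> "MRLDataset":
        idx = np.asarray(idx)
        return MRLDataset(
            tuple(self.sequences[i] for i in idx), self.mrl[idx], self.library[idx]
        )

    def concat(self, other: "MRLDataset") -> "MRLDataset":
        return MRLDataset(
            self.sequences + other.sequences,
            np.concatenate([self.mrl, other.mrl]),
            np.concatenate([self.library, other.library]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "utr": [str(s) for s in self.sequences],
                "mrl": self.mrl,
                "library": self.library,
            }
        )

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "MRLDataset":
        return MRLDataset.from_arrays(
            df["utr"].tolist(),
            df["mrl"].to_numpy() if "mrl" in df else np.zeros(len(df)),
            df["library"].to_numpy() if "library" in df else None,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  ``patience=None`` means fixed-epoch training."""

    max_epochs: int = 20
    patience: int | None = 3
    val_count: int = 0
    batch_size: int = 128
    seed: int = 0
    learning_rate: float = 1e-3
    bucket_by_length: bool = False

    def __post_init__(self):
        if self.patience is not None and self.val_count <= 0:
            raise ValueError("early stopping requires val_count > 0")


def split_validation(dataset: MRLDataset, val_count: int, seed: int):
    """Seeded random split into disjoint (train, validation) parts."""
    n = len(dataset)
    if val_count >= n:
        raise ValueError(f"val_count {val_count} must be < dataset size {n}")
    if val_count == 0:
        return dataset, None
    perm = np.random.default_rng(seed).permutation(n)
    return dataset.subset(perm[val_count:]), dataset.subset(perm[:val_count])


def predict_dataset(
    model: MRLPredictor, dataset: MRLDataset, batch_size: int = 256
) -> np.ndarray:
    """Batched inference over a dataset (order preserved).

    Sequences are grouped by length for efficiency; by the model's
    batch-composition invariance this does not change the predictions.
    """
    n = len(dataset)
    lengths = np.array([len(s) for s in dataset.sequences])
    order = np.argsort(lengths, kind="stable")
    preds = np.empty(n, dtype=np.float64)
    lib = dataset.library if model.config.n_libraries > 0 else None
    for start in range(0, n, batch_size):
        idx = order[start : start + batch_size]
        batch = encode_batch([dataset.sequences[i] for i in idx], dtype=model.dtype)
        preds[idx] = model.predict(
            batch, library=None if lib is None else lib[idx]
        )
    return preds


def _epoch_batches(n, lengths, batch_size, rng, bucket_by_length):
    perm = rng.permutation(n)
    if bucket_by_length:
        # stable length sort inside shuffled mega-chunks: batches are nearly
        # homogeneous in length but chunk membership is still random
        chunk = batch_size * 16
        parts = []
        for s in range(0, n, chunk):
            part = perm[s : s + chunk]
            parts.append(part[np.argsort(lengths[part], kind="stable")])
        perm = np.concatenate(parts)
    return [perm[s : s + batch_size] for s in range(0, n, batch_size)]


def train(
    model: MRLPredictor,
    dataset: MRLDataset,
    config: TrainConfig,
    run_dir=None,
):
    """Train ``model`` in place; returns ``(model, history)``.

    With ``patience`` set, training stops after that many consecutive epochs
    without a strictly lower validation MSE and the weights with the lowest
    validation error are restored.  With ``patience=None`` it runs exactly
    ``max_epochs`` epochs and keeps the final weights.  ``run_dir``
    optionally receives a config snapshot, per-epoch metrics and the best
    weights.
    """
    train_ds, val_ds = split_validation(dataset, config.val_count, config.seed)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.params, lr=config.learning_rate)
    lengths = np.array([len(s) for s in train_ds.sequences])
    lib_needed = model.config.n_libraries > 0
    logger.info(
        "training: n_train=%d n_val=%d params=%d seed=%d",
        len(train_ds), 0 if val_ds is None else len(val_ds),
        model.n_parameters, config.seed,
    )
    history = []
    best_val = np.inf
    best_params = None
    best_epoch = -1
    since_improve = 0
    for epoch in range(config.max_epochs):
        sq_sum = 0.0
        for idx in _epoch_batches(
            len(train_ds), lengths, config.batch_size, rng, config.bucket_by_length
        ):
            batch = encode_batch(
                [train_ds.sequences[i] for i in idx], dtype=model.dtype
            )
            lib = train_ds.library[idx] if lib_needed else None
            yhat, cache = model.forward(batch, library=lib, train=True, rng=rng)
            resid = yhat - train_ds.mrl[idx].astype(model.dtype)
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            sq_sum += float(np.sum(resid**2))
            grads, _ = model.backward((2.0 / len(idx)) * resid, cache)
            opt.step(model.params, grads)
        train_loss = sq_sum / len(train_ds)
        val_loss = np.nan
        if val_ds is not None:
            val_pred = predict_dataset(model, val_ds, batch_size=config.batch_size * 2)
            val_loss = float(np.mean((val_pred - val_ds.mrl) ** 2))
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        logger.info("epoch %d: train_mse=%.4f val_mse=%.4f", epoch, train_loss, val_loss)
        if config.patience is not None:
            if val_loss < best_val:
                best_val = val_loss
                best_params = copy.deepcopy(model.params)
                best_epoch = epoch
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= config.patience:
                    logger.info(
                        "early stop at epoch %d (best epoch %d, val_mse=%.4f)",
                        epoch, best_epoch, best_val,
                    )
                    break
    if config.patience is not None and best_params is not None:
        model.params.update(best_params)
    hist = pd.DataFrame(history)
    if run_dir is not None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "train_config.json").write_text(json.dumps(asdict(config), indent=2))
        hist.to_csv(run_dir / "history.csv", index=False)
        save_model(model, run_dir / "model.zip")
    return model, hist


def refit_library_scaling(
    model: MRLPredictor, dataset: MRLDataset, batch_size: int = 256
) -> None:
    """Set each library's (scale, bias) to its exact least-squares value.

    Given the trained trunk, the per-library affine head is a scalar linear
    regression of the labels on the trunk output, which has a closed-form
    optimum; gradient training leaves these four weights lagging behind the
    trunk, so they are refit in closed form at the end.  Never increases the
    training MSE.
    """
    preds = predict_dataset(model, dataset, batch_size=batch_size)
    scale = model.params["lib_scale"]
    bias = model.params["lib_bias"]
    libs = dataset.library
    raw = (preds - np.asarray(bias, dtype=np.float64)[libs]) / np.asarray(
        scale, dtype=np.float64
    )[libs]
    for lib in range(model.config.n_libraries):
        m = libs == lib
        if m.sum() < 2:
            continue
        A = np.vstack([raw[m], np.ones(int(m.sum()))]).T
        coef, *_ = np.linalg.lstsq(A, dataset.mrl[m], rcond=None)
        scale[lib] = coef[0]
        bias[lib] = coef[1]
    logger.info("refit library scaling: scale=%s bias=%s", scale, bias)


def train_combined(
    model: MRLPredictor,
    dataset_a: MRLDataset,
    dataset_b: MRLDataset | None,
    config: TrainConfig,
    run_dir=None,
    refit_scaling: bool = True,
):
    """Train a shared trunk on two libraries with per-library output scaling.

    Library labels index the scaling layer; examples from both libraries are
    shuffled together within each epoch.  After gradient training the
    scaling layer is refit in closed form (see
    :func:`refit_library_scaling`); pass ``refit_scaling=False`` for pure
    end-to-end weights.  With ``dataset_b=None`` this reduces to
    :func:`train`.
    """
    if dataset_b is None:
        return train(model, dataset_a, config, run_dir=run_dir)
    if model.config.n_libraries < 2:
        raise ValueError("combined training requires a model with n_libraries >= 2")
    combined = dataset_a.concat(dataset_b)
    if combined.library.max() >= model.config.n_libraries:
        raise ValueError("library label exceeds the model's n_libraries")
    result = train(model, combined, config, run_dir=run_dir)
    if refit_scaling:
        refit_library_scaling(model, combined, batch_size=max(config.batch_size, 256))
        if run_dir is not None:
            save_model(model, Path(run_dir) / "model.zip")
    return result
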