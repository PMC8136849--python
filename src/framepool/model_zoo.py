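"""Model architectures: frame-pooling predictor and frame-unaware baselines.

The main architecture is a stack of three same-length 1-D convolutions
(kernel 7, 128 filters, ReLU) with identity residual additions between
consecutive equal-width layers, followed by frame pooling (masked max and
average pooling within each reading-frame class, 3'-anchored), a 64-unit
ReLU dense layer with dropout 0.2, and a scalar linear output — 282,625
learnable weights.  Baselines swap frame pooling for conventional global
pooling, optionally with dilated convolutions to enlarge the receptive
field.  A per-library affine on the scalar output (2 extra weights per
library) accommodates training on libraries with different output scales.

Predictions are a deterministic function of (sequence, library, weights):
dropout is inactive at inference, and masked pooling makes the output of a
sequence independent of how much 5' padding its batch carries.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .seq_core import MIN_MODEL_LENGTH, PaddedOneHotBatch, encode_batch

__all__ = [
    "ModelConfig",
    "MRLPredictor",
    "PRESETS",
    "get_preset",
    "build_model",
    "count_parameters",
    "receptive_field",
    "predict_mrl",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Declarative description of a convolutional MRL architecture.

    ``conv_layers`` lists (filters, kernel, dilation) per layer; ``pooling``
    is ``"frame"`` (pooled width ``6 * filters``) or ``"global"`` (``2 *
    filters``); ``n_libraries = 0`` disables the output scaling layer.
    """

    conv_layers: tuple = ((128, 7, 1), (128, 7, 1), (128, 7, 1))
    residual: bool = True
    pooling: str = "frame"
    dense_units: int = 64
    dropout_rate: float = 0.2
    n_libraries: int = 0

    def __post_init__(self):
        if self.pooling not in ("frame", "global"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.conv_layers) == 0:
            raise ValueError("need at least one conv layer")
        for f, k, d in self.conv_layers:
            if k % 2 != 1:
                raise ValueError("kernel size must be odd (same-length output)")
            if f < 1 or d < 1:
                raise ValueError("filters and dilation must be >= 1")

    @property
    def pooled_width(self) -> int:
        last_filters = self.conv_layers[-1][0]
        return (6 if self.pooling == "frame" else 2) * last_filters

    def to_json(self) -> str:
        d = asdict(self)
        d["conv_layers"] = [list(t) for t in self.conv_layers]
        return json.dumps(d)

    @staticmethod
    def from_json(s: str) -> "ModelConfig":
        d = json.loads(s)
        d["conv_layers"] = tuple(tuple(t) for t in d["conv_layers"])
        return ModelConfig(**d)


PRESETS: dict[str, ModelConfig] = {
    # the frame-pooling architecture
    "framepool": ModelConfig(),
    # frame pooling with a two-library output scaling layer
    "framepool_combined": ModelConfig(n_libraries=2),
    # frame-unaware baselines
    "global_pool": ModelConfig(pooling="global"),
    "dilated": ModelConfig(
        conv_layers=((128, 7, 1), (128, 7, 2), (128, 7, 4)), pooling="global"
    ),
    "more_dilated": ModelConfig(
        conv_layers=((128, 7, 1), (128, 7, 2), (128, 7, 4), (128, 7, 8)),
        pooling="global",
    ),
}


def get_preset(name: str) -> ModelConfig:
    try:
        return PRESETS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def count_parameters(config: ModelConfig) -> int:
    """Closed-form count of all learnable weights and biases."""
    total = 0
    c_in = 4
    for f, k, _ in config.conv_layers:
        total += c_in * k * f + f
        c_in = f
    total += config.pooled_width * config.dense_units + config.dense_units
    total += config.dense_units + 1
    total += 2 * config.n_libraries
    return total


def receptive_field(config: ModelConfig) -> int:
    """Input span feeding one activation of the final conv layer:
    ``1 + sum((kernel - 1) * dilation)`` over layers."""
    return 1 + sum((k - 1) * d for _, k, d in config.conv_layers)


class MRLPredictor:
    """A (possibly trained) length-agnostic sequence -> MRL model.

    Accepts any sequence of length >= 3.  Use :func:`build_model` to create
    one; call :meth:`predict` (or :func:`predict_mrl`) for inference and
    :meth:`input_gradient` for contribution scores.
    """

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 4
        for li, (f, k, d) in enumerate(config.conv_layers):
            self.params[f"conv{li}_W"] = nn.glorot_uniform(
                rng, (k, c_in, f), fan_in=c_in * k, fan_out=f * k, dtype=dtype
            )
            self.params[f"conv{li}_b"] = np.zeros(f, dtype=dtype)
            c_in = f
        pw = config.pooled_width
        self.params["dense_W"] = nn.glorot_uniform(
            rng, (pw, config.dense_units), pw, config.dense_units, dtype
        )
        self.params["dense_b"] = np.zeros(config.dense_units, dtype=dtype)
        self.params["out_W"] = nn.glorot_uniform(
            rng, (config.dense_units, 1), config.dense_units, 1, dtype
        )
        self.params["out_b"] = np.zeros(1, dtype=dtype)
        if config.n_libraries > 0:
            # reference convention: every library starts at identity scaling
            self.params["lib_scale"] = np.ones(config.n_libraries, dtype=dtype)
            self.params["lib_bias"] = np.zeros(config.n_libraries, dtype=dtype)

    # -- plumbing ----------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _convs(self):
        for li, (_, _, d) in enumerate(self.config.conv_layers):
            yield li, nn.Conv1D(
                self.params[f"conv{li}_W"], self.params[f"conv{li}_b"], dilation=d
            )

    def _check_batch(self, batch: PaddedOneHotBatch, library):
        if int(batch.lengths.min()) < MIN_MODEL_LENGTH:
            raise ValueError(
                f"sequences must be >= {MIN_MODEL_LENGTH} nt "
                f"(got length {int(batch.lengths.min())})"
            )
        if self.config.n_libraries > 0:
            if library is None:
                raise ValueError("model has library scaling; a library label is required")
            lib = np.broadcast_to(
                np.asarray(library, dtype=np.int64), (batch.batch_size,)
            )
            if lib.min() < 0 or lib.max() >= self.config.n_libraries:
                raise ValueError(
                    f"library label out of range 0..{self.config.n_libraries - 1}"
                )
            return lib
        return None

    # -- forward / backward ------------------------------------------------

    def forward(self, batch: PaddedOneHotBatch, library=None, train=False, rng=None):
        """Full forward pass; returns (predictions, cache)."""
        lib = self._check_batch(batch, library)
        x = batch.values.astype(self.dtype, copy=False)
        maskf = batch.mask.astype(self.dtype)[:, :, None]
        h = x
        conv_caches = []
        for li, conv in self._convs():
            y, ccache = conv.forward(h)
            a, rcache = nn.relu_forward(y)
            a = a * maskf  # keep padded positions exactly zero
            prev = h
            if self.config.residual and li > 0 and prev.shape[2] == a.shape[2]:
                out = a + prev
                res = True
            else:
                out = a
                res = False
            conv_caches.append((ccache, rcache, res))
            h = out
        n_groups = 3 if self.config.pooling == "frame" else 1
        pooled, pcache = nn.masked_pool_forward(h, batch.mask, n_groups)
        dense = nn.Dense(self.params["dense_W"], self.params["dense_b"])
        z, dcache = dense.forward(pooled)
        a2, r2cache = nn.relu_forward(z)
        dropped, dropcache = nn.dropout_forward(
            a2, self.config.dropout_rate if train else 0.0, rng if train else None
        )
        out_layer = nn.Dense(self.params["out_W"], self.params["out_b"])
        yhat, ocache = out_layer.forward(dropped)
        yhat = yhat[:, 0]
        if lib is not None:
            raw = yhat
            yhat = self.params["lib_scale"][lib] * raw + self.params["lib_bias"][lib]
        else:
            raw = None
        cache = (conv_caches, pcache, dcache, r2cache, dropcache, ocache, lib, raw, maskf)
        return yhat, cache

    def backward(self, dpred: np.ndarray, cache):
        """Backprop; returns (grads dict, gradient w.r.t. the input batch)."""
        conv_caches, pcache, dcache, r2cache, dropcache, ocache, lib, raw, maskf = cache
        grads = {}
        if lib is not None:
            grads["lib_scale"] = np.zeros_like(self.params["lib_scale"])
            grads["lib_bias"] = np.zeros_like(self.params["lib_bias"])
            np.add.at(grads["lib_scale"], lib, dpred * raw)
            np.add.at(grads["lib_bias"], lib, dpred)
            dpred = dpred * self.params["lib_scale"][lib]
        out_layer = nn.Dense(self.params["out_W"], self.params["out_b"])
        dDrop, grads["out_W"], grads["out_b"] = out_layer.backward(
            dpred[:, None], ocache
        )
        dA2 = nn.dropout_backward(dDrop, dropcache)
        dZ = nn.relu_backward(dA2, r2cache)
        dense = nn.Dense(self.params["dense_W"], self.params["dense_b"])
        dPooled, grads["dense_W"], grads["dense_b"] = dense.backward(dZ, dcache)
        dH = nn.masked_pool_backward(dPooled, pcache)
        for li in reversed(range(len(self.config.conv_layers))):
            ccache, rcache, res = conv_caches[li]
            dA = dH * maskf
            dY = nn.relu_backward(dA, rcache)
            _, _, d = self.config.conv_layers[li]
            conv = nn.Conv1D(
                self.params[f"conv{li}_W"], self.params[f"conv{li}_b"], dilation=d
            )
            dX, grads[f"conv{li}_W"], grads[f"conv{li}_b"] = conv.backward(dY, ccache)
            dH = dX + dH if res else dX
        return grads, dH

    # -- inference ---------------------------------------------------------

    def predict(self, batch: PaddedOneHotBatch, library=None) -> np.ndarray:
        yhat, _ = self.forward(batch, library=library, train=False)
        return yhat

    def predict_sequences(self, seqs, library=None, frame_shift: int = 0) -> np.ndarray:
        """Convenience: encode, pad and predict a list of sequences.

        ``frame_shift`` appends that many masked zero positions at the 3'
        end (simulated frameshift).
        """
        batch = encode_batch(seqs, dtype=self.dtype)
        if frame_shift:
            batch = batch.with_3prime_padding(frame_shift)
        return self.predict(batch, library=library)

    def input_gradient(self, batch: PaddedOneHotBatch, library=None) -> np.ndarray:
        """d(prediction_b) / d(input_b) for every sequence, shape (B, L, 4).

        Each sequence's output depends only on its own input, so a single
        backward pass with unit output gradients yields per-sequence input
        gradients.
        """
        yhat, cache = self.forward(batch, library=library, train=False)
        _, dX = self.backward(np.ones_like(yhat), cache)
        return dX


def build_model(config: ModelConfig, seed: int = 0, dtype=np.float32) -> MRLPredictor:
    """Instantiate an untrained predictor with seeded initial weights."""
    return MRLPredictor(config, seed=seed, dtype=dtype)


def predict_mrl(model: MRLPredictor, batch: PaddedOneHotBatch, library=None) -> np.ndarray:
    """One finite MRL estimate per sequence in the batch."""
    return model.predict(batch, library=library)


# ---------------------------------------------------------------------------
# Persistence: one zip archive holding JSON config + npy weights
# ---------------------------------------------------------------------------

def save_model(model: MRLPredictor, path) -> None:
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", model.config.to_json())
        for name, arr in model.params.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(f"weights/{name}.npy", buf.getvalue())


def load_model(path) -> MRLPredictor:
    with zipfile.ZipFile(path, "r") as zf:
        config = ModelConfig.from_json(zf.read("config.json").decode())
        model = MRLPredictor(config, seed=0)
        for name in list(model.params):
            arr = np.load(io.BytesIO(zf.read(f"weights/{name}.npy")))
            model.params[name] = arr
            model.dtype = arr.dtype.type
    return model
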