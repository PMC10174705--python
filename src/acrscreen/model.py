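"""The anti-CRISPR classifier: CNN over one-hot channels fused with
evolutionary and language-model features, FCN head, 2- or 5-way output.

The network mirrors the standard two-branch fusion design for protein
classification. Variable-length one-hot channel matrices (sequence,
secondary structure, solvent accessibility) pass through a stack of
1-D convolutions with same-length padding and ReLU activations; a global
max pool along the sequence axis, restricted to mask-valid positions,
reduces each feature map to one number, making proteins of any length
batchable. The pooled vector is concatenated with the fixed-size
evolutionary descriptor and the protein-embedding vector, and a fully
connected stack with dropout produces the output units; softmax
probabilities are the public contract. Any subset of the three feature
blocks can be enabled ("variant features"): disabled blocks contribute
zero width.

The implementation is plain NumPy with hand-written backpropagation and
an Adam optimizer — the model is small (two conv layers, two hidden
layers by default) and trains in seconds on a CPU at the dataset sizes
this package targets. Binary output convention: index 0 = non-Acr,
index 1 = Acr, so ``probabilities[1]`` is P(Acr).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .encoders import ChannelMatrix

#: Output index of the positive (Acr) class in binary models.
POSITIVE_INDEX = 1

VALID_BLOCKS = ("onehot", "evolutionary", "embedding")


@dataclass
class ModelConfig:
    """Architecture and training-relevant hyperparameters.

    ``conv_layers`` is a list of (out_channels, kernel_width) pairs with
    odd kernel widths; ``fcn_widths`` the hidden widths of the fully
    connected head. ``n_outputs`` is 2 for Acr/non-Acr, 5 for the Acr-type
    task (6 for the joint variant with non-Acr as an extra class).
    """

    enabled_blocks: tuple[str, ...] = ("onehot", "evolutionary", "embedding")
    channel_width: int = 34
    evolutionary_dim: int = 1110
    embedding_dim: int = 1280
    conv_layers: tuple[tuple[int, int], ...] = ((64, 7), (128, 5))
    fcn_widths: tuple[int, ...] = (512, 128)
    dropout: float = 0.3
    n_outputs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.enabled_blocks = tuple(self.enabled_blocks)
        self.conv_layers = tuple(tuple(c) for c in self.conv_layers)
        self.fcn_widths = tuple(self.fcn_widths)
        unknown = set(self.enabled_blocks) - set(VALID_BLOCKS)
        if unknown:
            raise ValueError(f"unknown feature blocks: {sorted(unknown)}")
        if not self.enabled_blocks:
            raise ValueError("at least one feature block must be enabled")
        if self.n_outputs not in (2, 5, 6):
            raise ValueError("n_outputs must be 2, 5 or 6")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for out_ch, kernel in self.conv_layers:
            if kernel < 1 or kernel % 2 == 0:
                raise ValueError("kernel widths must be odd and >= 1")
            if out_ch < 1:
                raise ValueError("conv out_channels must be positive")

    @property
    def fused_width(self) -> int:
        width = 0
        if "onehot" in self.enabled_blocks:
            width += self.conv_layers[-1][0] if self.conv_layers else (
                self.channel_width
            )
        if "evolutionary" in self.enabled_blocks:
            width += self.evolutionary_dim
        if "embedding" in self.enabled_blocks:
            width += self.embedding_dim
        return width

    def to_dict(self) -> dict:
        return {
            "enabled_blocks": list(self.enabled_blocks),
            "channel_width": self.channel_width,
            "evolutionary_dim": self.evolutionary_dim,
            "embedding_dim": self.embedding_dim,
            "conv_layers": [list(c) for c in self.conv_layers],
            "fcn_widths": list(self.fcn_widths),
            "dropout": self.dropout,
            "n_outputs": self.n_outputs,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class FeatureBundle:
    """The model's input for one protein.

    Blocks that the model config disables may be ``None``.
    """

    id: str
    channels: ChannelMatrix | None = None
    evolutionary: np.ndarray | None = None
    embedding: np.ndarray | None = None


@dataclass
class Prediction:
    """Softmax output for one protein."""

    probabilities: np.ndarray
    predicted_index: int
    confidence: float

    @classmethod
    def from_probabilities(cls, p: np.ndarray) -> "Prediction":
        p = np.asarray(p, dtype=float)
        idx = int(np.argmax(p))  # ties resolve to the lowest index
        return cls(probabilities=p, predicted_index=idx, confidence=float(p[idx]))


@dataclass
class HierarchicalPrediction:
    """Two-level call: Acr/non-Acr, then the Acr class if positive."""

    label: str
    acr_class: int | None
    p_acr: float
    type_confidence: float | None = None
    type_probabilities: np.ndarray | None = None


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def pack_batch(
    bundles: Sequence[FeatureBundle], config: ModelConfig
) -> dict[str, np.ndarray]:
    """Pad a list of bundles into dense batch arrays with masks.

    Dimension mismatches raise errors naming the offending block and
    protein id.
    """
    if not bundles:
        raise ValueError("empty batch")
    arrays: dict[str, np.ndarray] = {}
    if "onehot" in config.enabled_blocks:
        for b in bundles:
            if b.channels is None:
                raise ValueError(f"{b.id}: onehot block enabled but missing")
            if b.channels.width != config.channel_width:
                raise ValueError(
                    f"{b.id}: onehot block has width {b.channels.width}, "
                    f"model expects {config.channel_width}"
                )
        max_len = max(b.channels.values.shape[0] for b in bundles)
        x = np.zeros((len(bundles), max_len, config.channel_width), dtype=np.float32)
        mask = np.zeros((len(bundles), max_len), dtype=bool)
        for i, b in enumerate(bundles):
            length = b.channels.values.shape[0]
            x[i, :length] = b.channels.values
            mask[i, :length] = b.channels.mask
        arrays["x"] = x
        arrays["mask"] = mask
    for key, attr, dim in (
        ("evo", "evolutionary", config.evolutionary_dim),
        ("emb", "embedding", config.embedding_dim),
    ):
        block = "evolutionary" if key == "evo" else "embedding"
        if block not in config.enabled_blocks:
            continue
        rows = []
        for b in bundles:
            vec = getattr(b, attr)
            if vec is None:
                raise ValueError(f"{b.id}: {block} block enabled but missing")
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (dim,):
                raise ValueError(
                    f"{b.id}: {block} block has shape {vec.shape}, "
                    f"model expects ({dim},)"
                )
            rows.append(vec)
        arrays[key] = np.stack(rows).astype(np.float32)
    return arrays


class Model:
    """CNN + FCN fusion network with seeded initialization.

    Use :func:`build_model` to construct one; ``forward`` returns softmax
    probabilities, ``loss_and_grads`` the cross-entropy loss and parameter
    gradients for one minibatch.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        # per-dimension standardization of the dense feature blocks,
        # fitted on the training set (identity until fitted)
        self.norm: dict[str, np.ndarray] = {}
        rng = np.random.Generator(np.random.PCG64(config.seed))
        if "onehot" in config.enabled_blocks:
            in_ch = config.channel_width
            for li, (out_ch, kernel) in enumerate(config.conv_layers):
                scale = np.sqrt(2.0 / (kernel * in_ch))
                self.params[f"conv{li}_w"] = rng.normal(
                    0.0, scale, size=(kernel * in_ch, out_ch)
                ).astype(np.float32)
                self.params[f"conv{li}_b"] = np.zeros(out_ch, dtype=np.float32)
                in_ch = out_ch
        width = config.fused_width
        for li, out_w in enumerate(config.fcn_widths):
            scale = np.sqrt(2.0 / width)
            self.params[f"fc{li}_w"] = rng.normal(
                0.0, scale, size=(width, out_w)
            ).astype(np.float32)
            self.params[f"fc{li}_b"] = np.zeros(out_w, dtype=np.float32)
            width = out_w
        scale = np.sqrt(2.0 / width)
        self.params["out_w"] = rng.normal(
            0.0, scale, size=(width, config.n_outputs)
        ).astype(np.float32)
        self.params["out_b"] = np.zeros(config.n_outputs, dtype=np.float32)

    # -- forward ----------------------------------------------------------

    def _conv_forward(
        self, x: np.ndarray, mask: np.ndarray
    ) -> tuple[np.ndarray, list]:
        """Conv stack + masked global max pool. Returns (pooled, caches)."""
        caches = []
        h = x
        valid = mask[:, :, None]
        for li, (_, kernel) in enumerate(self.config.conv_layers):
            w = self.params[f"conv{li}_w"]
            b = self.params[f"conv{li}_b"]
            pad = kernel // 2
            hp = np.pad(h, ((0, 0), (pad, pad), (0, 0)))
            # (B, L, C, K) -> (B, L, K*C) window columns
            cols = sliding_window_view(hp, kernel, axis=1)
            cols = cols.transpose(0, 1, 3, 2).reshape(
                h.shape[0], h.shape[1], -1
            )
            pre = cols @ w + b
            # zero padding positions so deeper layers see the same
            # context regardless of how much padding the batch carries
            post = _relu(pre) * valid
            caches.append((cols, (pre > 0) & mask[:, :, None], kernel))
            h = post
        # masked global max over the sequence axis
        neg = np.where(mask[:, :, None], h, -np.inf)
        pooled = neg.max(axis=1)
        argmax = neg.argmax(axis=1)
        caches.append((argmax, h.shape))
        return pooled, caches

    def fit_normalizer(self, arrays: dict[str, np.ndarray]) -> None:
        """Fit per-dimension standardization of the evolutionary and
        embedding blocks from (training) batch arrays.

        The two dense blocks arrive on very different scales (raw PSSM
        descriptor magnitudes vs unit-range embeddings); z-scoring each
        dimension on the training set puts them on a common footing
        before fusion. The one-hot branch is already in {0, 1}.
        """
        for key in ("evo", "emb"):
            if key in arrays:
                mu = arrays[key].mean(axis=0, dtype=np.float64)
                sd = arrays[key].std(axis=0, dtype=np.float64)
                self.norm[f"{key}_mu"] = mu.astype(np.float32)
                self.norm[f"{key}_sd"] = np.where(
                    sd < 1e-8, 1.0, sd
                ).astype(np.float32)

    def _normalized(self, arrays: dict[str, np.ndarray], key: str) -> np.ndarray:
        if f"{key}_mu" in self.norm:
            return (arrays[key] - self.norm[f"{key}_mu"]) / self.norm[
                f"{key}_sd"
            ]
        return arrays[key]

    def _fused_input(
        self,
        arrays: dict[str, np.ndarray],
        sample_scales: dict[str, np.ndarray] | None = None,
    ) -> tuple[np.ndarray, list | None]:
        """Concatenate the enabled blocks.

        ``sample_scales`` (training-time block dropout) maps block name
        to a per-sample scale vector: 0 silences the block for that
        sample, survivors carry the inverted-dropout 1/keep factor so
        evaluation-time magnitudes match training.
        """
        parts = []
        conv_caches = None
        if "onehot" in self.config.enabled_blocks:
            pooled, conv_caches = self._conv_forward(
                arrays["x"], arrays["mask"]
            )
            if sample_scales is not None:
                pooled = pooled * sample_scales["onehot"][:, None]
            parts.append(pooled)
        if "evolutionary" in self.config.enabled_blocks:
            evo = self._normalized(arrays, "evo")
            if sample_scales is not None:
                evo = evo * sample_scales["evolutionary"][:, None]
            parts.append(evo)
        if "embedding" in self.config.enabled_blocks:
            emb = self._normalized(arrays, "emb")
            if sample_scales is not None:
                emb = emb * sample_scales["embedding"][:, None]
            parts.append(emb)
        return np.hstack(parts), conv_caches

    def forward(
        self,
        batch: Sequence[FeatureBundle] | dict[str, np.ndarray],
    ) -> np.ndarray:
        """Inference pass: returns (B, n_outputs) softmax probabilities."""
        arrays = (
            batch
            if isinstance(batch, dict)
            else pack_batch(batch, self.config)
        )
        h, _ = self._fused_input(arrays)
        for li in range(len(self.config.fcn_widths)):
            h = _relu(h @ self.params[f"fc{li}_w"] + self.params[f"fc{li}_b"])
        logits = h @ self.params["out_w"] + self.params["out_b"]
        return _softmax(logits)

    def predict(self, batch: Sequence[FeatureBundle]) -> list[Prediction]:
        probs = self.forward(batch)
        return [Prediction.from_probabilities(p) for p in probs]

    # -- training pass ----------------------------------------------------

    def loss_and_grads(
        self,
        arrays: dict[str, np.ndarray],
        y: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
        block_dropout: float = 0.0,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Cross-entropy loss and gradients for one packed minibatch.

        ``dropout_rng`` draws the dropout masks; pass ``None`` to disable
        all dropout (evaluation-mode loss). ``block_dropout`` silences
        each feature block independently per sample with the given
        probability (at least one block always survives), forcing every
        branch to become predictive on its own.
        """
        cfg = self.config
        y = np.asarray(y, dtype=int)
        enabled = cfg.enabled_blocks
        sample_scales = None
        if (
            block_dropout > 0
            and len(enabled) > 1
            and dropout_rng is not None
        ):
            n_items = next(iter(arrays.values())).shape[0]
            keep = (
                dropout_rng.random((n_items, len(enabled))) >= block_dropout
            )
            dead = ~keep.any(axis=1)
            if dead.any():
                revive = dropout_rng.integers(
                    len(enabled), size=int(dead.sum())
                )
                keep[np.flatnonzero(dead), revive] = True
            sample_scales = {
                b: keep[:, i].astype(np.float32) / (1.0 - block_dropout)
                for i, b in enumerate(enabled)
            }
        fused, conv_caches = self._fused_input(arrays, sample_scales)
        batch_size = fused.shape[0]

        acts = [fused]
        relu_masks = []
        drop_masks = []
        h = fused
        keep = 1.0 - cfg.dropout
        for li in range(len(cfg.fcn_widths)):
            pre = h @ self.params[f"fc{li}_w"] + self.params[f"fc{li}_b"]
            h = _relu(pre)
            relu_masks.append(pre > 0)
            if dropout_rng is not None and cfg.dropout > 0:
                m = (
                    dropout_rng.random(h.shape) < keep
                ).astype(float) / keep
                h = h * m
                drop_masks.append(m)
            else:
                drop_masks.append(None)
            acts.append(h)
        logits = h @ self.params["out_w"] + self.params["out_b"]
        probs = _softmax(logits)
        eps = 1e-12
        loss = -float(
            np.log(probs[np.arange(batch_size), y] + eps).mean()
        )

        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(batch_size), y] -= 1.0
        dlogits /= batch_size
        grads["out_w"] = acts[-1].T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["out_w"].T
        for li in reversed(range(len(cfg.fcn_widths))):
            if drop_masks[li] is not None:
                dh = dh * drop_masks[li]
            dpre = dh * relu_masks[li]
            grads[f"fc{li}_w"] = acts[li].T @ dpre
            grads[f"fc{li}_b"] = dpre.sum(axis=0)
            dh = dpre @ self.params[f"fc{li}_w"].T
        # split fused gradient back into blocks
        offset = 0
        if "onehot" in cfg.enabled_blocks:
            n_pooled = cfg.conv_layers[-1][0]
            dpooled = dh[:, offset : offset + n_pooled]
            offset += n_pooled
            if sample_scales is not None:
                dpooled = dpooled * sample_scales["onehot"][:, None]
            self._conv_backward(arrays, conv_caches, dpooled, grads)
        # evolutionary / embedding inputs are leaves; nothing to propagate
        return loss, grads

    def _conv_backward(
        self,
        arrays: dict[str, np.ndarray],
        caches: list,
        dpooled: np.ndarray,
        grads: dict[str, np.ndarray],
    ) -> None:
        argmax, out_shape = caches[-1]
        batch, length, channels = out_shape
        dh = np.zeros(out_shape)
        b_idx = np.arange(batch)[:, None]
        c_idx = np.arange(channels)[None, :]
        dh[b_idx, argmax, c_idx] = dpooled
        for li in reversed(range(len(self.config.conv_layers))):
            cols, relu_mask, kernel = caches[li]
            w = self.params[f"conv{li}_w"]
            dpre = dh * relu_mask
            flat_cols = cols.reshape(-1, cols.shape[-1])
            flat_dpre = dpre.reshape(-1, dpre.shape[-1])
            grads[f"conv{li}_w"] = flat_cols.T @ flat_dpre
            grads[f"conv{li}_b"] = flat_dpre.sum(axis=0)
            if li == 0:
                break  # input gradient not needed
            dcols = flat_dpre @ w.T
            in_ch = w.shape[0] // kernel
            dcols = dcols.reshape(batch, length, kernel, in_ch)
            pad = kernel // 2
            dhp = np.zeros((batch, length + 2 * pad, in_ch))
            for k in range(kernel):
                dhp[:, k : k + length] += dcols[:, :, k]
            dh = dhp[:, pad : pad + length]

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: parameters plus the embedded config."""
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
            ),
            **self.params,
            **{f"__norm__{k}": v for k, v in self.norm.items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        with np.load(path) as data:
            config = ModelConfig.from_dict(
                json.loads(bytes(data["__config__"]).decode())
            )
            model = cls(config)
            for key in model.params:
                model.params[key] = data[key]
            for key in data.files:
                if key.startswith("__norm__"):
                    model.norm[key[len("__norm__"):]] = data[key]
        return model


def build_model(config: ModelConfig) -> Model:
    """Construct a model with parameters seeded from ``config.seed``."""
    return Model(config)


def predict_hierarchical(
    binary_model: Model,
    type_model: Model,
    bundle: FeatureBundle,
    threshold: float = 0.5,
) -> HierarchicalPrediction:
    """Two-level prediction: Acr screening, then Acr-class assignment.

    A protein is called Acr when P(Acr) >= ``threshold``; only Acr calls
    receive a class prediction from the 5-way model.
    """
    if binary_model.config.n_outputs != 2:
        raise ValueError("binary_model must have 2 outputs")
    p = binary_model.forward([bundle])[0]
    p_acr = float(p[POSITIVE_INDEX])
    if p_acr < threshold:
        return HierarchicalPrediction(
            label="non-Acr", acr_class=None, p_acr=p_acr
        )
    tp = type_model.forward([bundle])[0]
    pred = Prediction.from_probabilities(tp)
    return HierarchicalPrediction(
        label="Acr",
        acr_class=pred.predicted_index,
        p_acr=p_acr,
        type_confidence=pred.confidence,
        type_probabilities=pred.probabilities,
    )


def clone_config(config: ModelConfig, **overrides) -> ModelConfig:
    """Copy a config with field overrides (dataclass replace)."""
    return replace(config, **overrides)
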