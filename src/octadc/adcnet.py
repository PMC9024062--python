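"""Multichannel encoder-decoder restoration network for dispersion
compensation.

A modified UNet: the encoder stacks dense blocks (concatenative convolution
stages with intra-block skips) each followed by a channel-halving transition
block and 2x max pooling; the decoder mirrors it with 2x upsampling,
concatenation with the corresponding transition output, and convolution
stages.  Batch normalization + ReLU trail every convolution; a terminal
1-channel convolution with a sigmoid produces the restored B-scan in [0, 1].
The input is a stack of 1/3/5/7/9 partially compensated B-scans of the same
frame; the target is the stitched all-depth-compensated image.  Training
uses Adam with a soft dice loss.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

from . import nn
from .gtruth import TrainingPair
from .recon import BScan, CompensationStack, SUPPORTED_CHANNELS, log_display

__all__ = [
    "ModelConfig",
    "TrainingHistory",
    "ADCNet",
    "build_model",
    "dice_loss",
    "train",
    "predict",
    "predict_pairs",
    "predict_volume",
    "save_checkpoint",
    "load_checkpoint",
]

log = logging.getLogger(__name__)

_DICE_EPS = 1e-6


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters.

    Defaults: sigmoid terminal activation (SoftMax on a single-channel
    regression output is degenerate — it is constant one — but remains
    available for fidelity experiments), dice loss, and Adam at lr 1e-4.
    Capacity knobs (stages, filters, growth) are configuration, not canon.
    """

    n_channels: int = 5
    encoder_stages: int = 4
    base_filters: int = 16
    growth_per_block: int = 16
    layers_per_block: int = 2
    final_activation: str = "sigmoid"  # sigmoid | softmax | linear
    loss: str = "dice"  # dice | mae
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    epochs: int = 20
    batch_size: int = 8
    rng_seed: int = 0
    pretrained_encoder_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_channels not in SUPPORTED_CHANNELS:
            raise ValueError(f"n_channels must be one of {SUPPORTED_CHANNELS}")
        if self.final_activation not in ("sigmoid", "softmax", "linear"):
            raise ValueError("final_activation must be sigmoid, softmax or linear")
        if self.loss not in ("dice", "mae"):
            raise ValueError("loss must be 'dice' or 'mae'")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")

    def with_updates(self, **kw) -> "ModelConfig":
        return replace(self, **kw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def check_spatial(self, h: int, w: int) -> None:
        m = 2**self.encoder_stages
        if h % m or w % m:
            need_h = ((h + m - 1) // m) * m
            need_w = ((w + m - 1) // m) * m
            raise ValueError(
                f"input {h}x{w} not divisible by 2^{self.encoder_stages}={m}; "
                f"pad to {need_h}x{need_w}"
            )


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_ms_ssim: list[float] = field(default_factory=list)
    seed: int = 0
    config_hash: str = ""

    @property
    def epochs(self) -> int:
        return len(self.train_loss)


class _ConvBNReLU(nn.Module):
    def __init__(self, c_in, c_out, k, rng):
        self.conv = nn.Conv2d(c_in, c_out, k, rng)
        self.bn = nn.BatchNorm2d(c_out)

    def __call__(self, x):
        return nn.relu(self.bn(self.conv(x)))


class _DenseBlock(nn.Module):
    """Concatenative convolution stages with intra-block skip connections."""

    def __init__(self, c_in, growth, n_layers, rng):
        self.stages = []
        c = c_in
        for _ in range(n_layers):
            self.stages.append(_ConvBNReLU(c, growth, 3, rng))
            c += growth
        self.c_out = c

    def __call__(self, x):
        feats = [x]
        for stage in self.stages:
            y = stage(nn.concat_channels(feats) if len(feats) > 1 else feats[0])
            feats.append(y)
        return nn.concat_channels(feats)


class _Transition(nn.Module):
    """1x1 convolution halving the channel count (feature-map compression)."""

    def __init__(self, c_in, rng):
        self.c_out = max(c_in // 2, 1)
        self.block = _ConvBNReLU(c_in, self.c_out, 1, rng)

    def __call__(self, x):
        return self.block(x)


class _DecoderBlock(nn.Module):
    def __init__(self, c_in, c_skip, c_out, rng):
        self.conv1 = _ConvBNReLU(c_in + c_skip, c_out, 3, rng)
        self.conv2 = _ConvBNReLU(c_out, c_out, 3, rng)
        self.c_out = c_out

    def __call__(self, x, skip):
        x = nn.concat_channels([nn.upsample2(x), skip])
        return self.conv2(self.conv1(x))


class ADCNet(nn.Module):
    """The encoder-decoder restoration network."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        self.stem = _ConvBNReLU(config.n_channels, config.base_filters, 3, rng)
        c = config.base_filters
        self.enc_dense: list[_DenseBlock] = []
        self.enc_trans: list[_Transition] = []
        skip_channels = []
        for _ in range(config.encoder_stages):
            dense = _DenseBlock(c, config.growth_per_block, config.layers_per_block, rng)
            trans = _Transition(dense.c_out, rng)
            self.enc_dense.append(dense)
            self.enc_trans.append(trans)
            skip_channels.append(trans.c_out)
            c = trans.c_out
        self.bottleneck = _DenseBlock(c, config.growth_per_block, config.layers_per_block, rng)
        self.bottleneck_trans = _Transition(self.bottleneck.c_out, rng)
        c = self.bottleneck_trans.c_out
        self.dec_blocks: list[_DecoderBlock] = []
        for skip_c in reversed(skip_channels):
            block = _DecoderBlock(c, skip_c, max(skip_c, config.base_filters), rng)
            self.dec_blocks.append(block)
            c = block.c_out
        self.head = nn.Conv2d(c, 1, 1, rng)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        """Forward pass on a channels-last (N, H, W, C) tensor."""
        self.config.check_spatial(x.shape[1], x.shape[2])
        x = self.stem(x)
        skips = []
        for dense, trans in zip(self.enc_dense, self.enc_trans):
            t = trans(dense(x))
            skips.append(t)
            x = nn.maxpool2(t)
        x = self.bottleneck_trans(self.bottleneck(x))
        for block, skip in zip(self.dec_blocks, reversed(skips)):
            x = block(x, skip)
        x = self.head(x)
        if self.config.final_activation == "sigmoid":
            return nn.sigmoid(x)
        if self.config.final_activation == "softmax":
            # channel-wise softmax over a single channel: constant one
            return nn.Tensor(np.ones_like(x.data), (x,), lambda g: x._accumulate(np.zeros_like(g)))
        return x


def build_model(config: ModelConfig) -> ADCNet:
    """Instantiate the network; logs the parameter count."""
    model = ADCNet(config)
    if config.pretrained_encoder_path:
        _load_encoder_weights(model, config.pretrained_encoder_path)
    log.info("ADC network built: %d parameters", model.n_parameters())
    return model


def _load_encoder_weights(model: ADCNet, path: str) -> None:
    """Hook for externally pretrained encoder weights (npz of ordered arrays)."""
    data = np.load(path)
    arrays = [data[k] for k in sorted(data.files, key=lambda s: int(s.split("_")[1]))]
    enc_params = model.stem.parameters()
    for blk, tr in zip(model.enc_dense, model.enc_trans):
        enc_params += blk.parameters() + tr.parameters()
    for p, a in zip(enc_params, arrays):
        if p.data.shape != a.shape:
            raise ValueError("pretrained encoder weight shape mismatch")
        p.data[...] = a


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = _DICE_EPS) -> float:
    """Soft dice loss 1 - (2*sum(p*g)+eps)/(sum(p)+sum(g)+eps) for [0,1] images."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    num = 2.0 * float(np.sum(pred * target)) + eps
    den = float(np.sum(pred)) + float(np.sum(target)) + eps
    return 1.0 - num / den


def _dice_loss_t(pred: nn.Tensor, target: np.ndarray) -> nn.Tensor:
    t = nn.Tensor(target)
    num = (pred * t).sum() * 2.0 + nn.Tensor(_DICE_EPS)
    den = pred.sum() + nn.Tensor(float(target.sum()) + _DICE_EPS)
    return nn.Tensor(1.0) - num * den.reciprocal()


def _mae_loss_t(pred: nn.Tensor, target: np.ndarray) -> nn.Tensor:
    diff = pred - nn.Tensor(target)
    sign = np.sign(diff.data)

    def back(g):
        diff._accumulate(g * sign / diff.data.size)

    return nn.Tensor(np.mean(np.abs(diff.data)), (diff,), back)


def _loss_fn(pred: nn.Tensor, target: np.ndarray, kind: str) -> nn.Tensor:
    if kind == "dice":
        return _dice_loss_t(pred, target)
    return _mae_loss_t(pred, target)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield idx[i : i + batch_size]


def train(
    model: ADCNet,
    dataset: Sequence[TrainingPair],
    config: ModelConfig | None = None,
    val_pairs: Sequence[TrainingPair] | None = None,
) -> tuple[ADCNet, TrainingHistory]:
    """Seeded mini-batch training with Adam; retains the best-validation state.

    Validation defaults to the dataset's own 'test'-split pairs, falling back
    to the training pairs for toy runs.  Aborts with a diagnostic on NaN loss.
    """
    config = config or model.config
    train_pairs = [p for p in dataset if p.split == "train"] or list(dataset)
    if not train_pairs:
        raise ValueError("empty training dataset")
    if val_pairs is None:
        val_pairs = [p for p in dataset if p.split == "test"] or train_pairs
    # channels-last layout for the nn engine
    x_train = np.stack([p.inputs.transpose(1, 2, 0) for p in train_pairs])
    y_train = np.stack([p.target[:, :, None] for p in train_pairs])
    config.check_spatial(x_train.shape[1], x_train.shape[2])

    rng = np.random.default_rng([config.rng_seed, 0x7EA1])
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = TrainingHistory(seed=config.rng_seed, config_hash=config.config_hash())
    best_val = np.inf
    best_state = model.get_state()

    for epoch in range(config.epochs):
        model.set_training(True)
        losses = []
        for batch in _batches(len(train_pairs), config.batch_size, rng):
            xb = nn.Tensor(x_train[batch])
            yb = y_train[batch]
            opt.zero_grad()
            loss = _loss_fn(model(xb), yb, config.loss)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or check the data normalization"
                )
            loss.backward()
            opt.step()
            losses.append(value)
        history.train_loss.append(float(np.mean(losses)))

        val_loss, val_ms = _validate(model, val_pairs, config)
        history.val_loss.append(val_loss)
        history.val_ms_ssim.append(val_ms)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
        log.info(
            "epoch %d/%d train=%.4f val=%.4f ms-ssim=%.4f",
            epoch + 1,
            config.epochs,
            history.train_loss[-1],
            val_loss,
            val_ms,
        )

    model.set_state(best_state)
    return model, history


def _validate(model: ADCNet, pairs: Sequence[TrainingPair], config: ModelConfig):
    from .quality import ms_ssim

    model.set_training(False)
    losses, sims = [], []
    for p in pairs:
        pred = model(nn.Tensor(p.inputs.transpose(1, 2, 0)[None])).data[0, :, :, 0]
        losses.append(
            dice_loss(pred, p.target) if config.loss == "dice" else float(np.mean(np.abs(pred - p.target)))
        )
        try:
            sims.append(ms_ssim(pred.astype(float), p.target.astype(float)))
        except ValueError:
            sims.append(np.nan)
    return float(np.mean(losses)), float(np.nanmean(sims))


def _normalized_stack(stack: CompensationStack) -> np.ndarray:
    if stack.bscans[0].scale == "log":
        return stack.images().astype(np.float32)
    return np.stack([log_display(b).image for b in stack.bscans]).astype(np.float32)


def predict(model: ADCNet, stack: CompensationStack) -> BScan:
    """Restore one frame from its compensation stack (deterministic)."""
    if len(stack) != model.config.n_channels:
        raise ValueError(
            f"stack has {len(stack)} channels but the model expects "
            f"{model.config.n_channels}"
        )
    x = _normalized_stack(stack).transpose(1, 2, 0)
    model.set_training(False)
    out = model(nn.Tensor(x[None])).data[0, :, :, 0]
    out = np.clip(out, 0.0, 1.0)
    prov = dict(stack.bscans[0].provenance)
    prov.update(model="adc-net", n_channels=model.config.n_channels, config_hash=model.config.config_hash())
    prov.pop("a2", None)
    return BScan(out, scale="log", depth_pitch_um=stack.bscans[0].depth_pitch_um, provenance=prov)


def predict_pairs(model: ADCNet, pairs: Sequence[TrainingPair]) -> list[np.ndarray]:
    """Predictions for pre-normalized training pairs (arrays in [0, 1])."""
    model.set_training(False)
    out = []
    for p in pairs:
        out.append(
            np.clip(
                model(nn.Tensor(p.inputs.transpose(1, 2, 0)[None])).data[0, :, :, 0],
                0.0,
                1.0,
            )
        )
    return out


def predict_volume(model: ADCNet, stacks: Sequence[CompensationStack]) -> list[BScan]:
    """Order-preserving sequential restoration of a volume of stacks."""
    out = []
    for i, stack in enumerate(stacks):
        out.append(predict(model, stack))
        if (i + 1) % 25 == 0:
            log.info("predicted %d/%d frames", i + 1, len(stacks))
    return out


def save_checkpoint(model: ADCNet, path) -> None:
    """Model state + config as an npz (+'.json' config sidecar)."""
    state = model.get_state()
    np.savez(path, **{f"arr_{i}": a for i, a in enumerate(state)})
    with open(str(path) + ".json", "w") as fh:
        json.dump({"config": asdict(model.config), "hash": model.config.config_hash()}, fh, indent=2)


def load_checkpoint(path) -> ADCNet:
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    config = ModelConfig(**meta["config"])
    model = ADCNet(config)
    data = np.load(str(path) if str(path).endswith(".npz") else str(path))
    state = [data[f"arr_{i}"] for i in range(len(data.files))]
    model.set_state(state)
    return model
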