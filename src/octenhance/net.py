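"""Multi-frame B-scan enhancement network.

A compact U-net-style encoder-decoder that takes k repeated frames of one
location as input channels and emits a single enhanced frame.  After the
two-stage encoder comes a high-resolution representation stage: parallel
multi-resolution branches with repeated cross-resolution fusion, which keeps
fine retinal detail alive while context is aggregated at coarse scale.  A
side path concatenates decoder features across resolutions before the final
projection, and the output is a weighted sum of the mean of the input frames
and the restored map — a residual formulation in which the network only has
to learn the correction on top of plain frame averaging.

Training minimises w_ce * BCE + w_ssim * (1 - SSIM) with Adam, Xavier
initialisation, learning rate 0.001 decayed by 0.9 whenever the monitored
loss fails to decrease for 10 epochs, and offline augmentation by random
frame subsets.  All intensities live in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import metrics
from .nn import autodiff as ad
from .nn.layers import Adam, Conv2d, ConvAct, Module
from .nn.losses import combined_loss_tensor
from .phantom import FrameStack

_F32 = np.float32


@dataclass(frozen=True)
class NetConfig:
    n_input_frames: int = 5
    base_channels: int = 8
    n_hr_branches: int = 2
    n_hr_fusions: int = 2
    weighted_sum_mode: str = "learnable"  # "learnable" | "fixed"
    fixed_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_input_frames <= 20:
            raise ValueError("n_input_frames must be in [1, 20]")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.n_hr_branches not in (1, 2):
            raise ValueError("n_hr_branches must be 1 or 2")
        if self.n_hr_fusions < 1:
            raise ValueError("n_hr_fusions must be >= 1")
        if self.weighted_sum_mode not in ("learnable", "fixed"):
            raise ValueError("weighted_sum_mode must be 'learnable' or 'fixed'")


@dataclass(frozen=True)
class TrainConfig:
    lr_init: float = 1e-3
    decay_factor: float = 0.9
    patience_epochs: int = 10
    loss_weights: tuple[float, float] = (1.0, 1.0)  # (w_ce, w_ssim)
    batch_size: int = 4
    max_epochs: int = 30
    augmentation_draws: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.decay_factor < 1.0:
            raise ValueError("decay_factor must be in (0, 1)")
        w_ce, w_ssim = self.loss_weights
        if w_ce < 0 or w_ssim < 0 or (w_ce == 0 and w_ssim == 0):
            raise ValueError("loss weights must be non-negative and not both zero")


class _HRStage(Module):
    """Parallel multi-resolution branches with repeated cross fusion."""

    def __init__(self, channels: int, n_branches: int, n_fusions: int,
                 rng: np.random.Generator):
        self.n_branches = n_branches
        self.n_fusions = n_fusions
        if n_branches == 2:
            self.down_in = ConvAct(channels, channels, stride=2, rng=rng)
            self.fuse_a = [ConvAct(channels, channels, rng=rng) for _ in range(n_fusions)]
            self.fuse_b = [ConvAct(channels, channels, rng=rng) for _ in range(n_fusions)]
            self.cross_up = [Conv2d(channels, channels, rng=rng) for _ in range(n_fusions)]
            self.cross_down = [Conv2d(channels, channels, stride=2, rng=rng)
                               for _ in range(n_fusions)]
        else:
            self.fuse_a = [ConvAct(channels, channels, rng=rng) for _ in range(n_fusions)]

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        if self.n_branches == 1:
            for conv in self.fuse_a:
                x = conv(x)
            return x
        a, b = x, self.down_in(x)
        for i in range(self.n_fusions):
            ac = self.fuse_a[i](a)
            bc = self.fuse_b[i](b)
            a = ad.leaky_relu(ad.add(ac, ad.upsample2(self.cross_up[i](bc))))
            b = ad.leaky_relu(ad.add(bc, self.cross_down[i](ac)))
        return a


class EnhancementNet(Module):
    """Encoder (2 contracting blocks) + HR stage + decoder (2 expanding
    blocks) with a cross-resolution side path and residual output head."""

    def __init__(self, config: NetConfig):
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        k = config.n_input_frames
        self.config = config
        self.stem = ConvAct(k, c, rng=rng)
        self.enc1 = ConvAct(c, 2 * c, stride=2, rng=rng)
        self.enc1b = ConvAct(2 * c, 2 * c, rng=rng)
        self.enc2 = ConvAct(2 * c, 4 * c, stride=2, rng=rng)
        self.enc2b = ConvAct(4 * c, 4 * c, rng=rng)
        self.hr = _HRStage(4 * c, config.n_hr_branches, config.n_hr_fusions, rng)
        self.dec1 = ConvAct(4 * c + 2 * c, 2 * c, rng=rng)
        self.dec2 = ConvAct(2 * c + c, c, rng=rng)
        self.side = ConvAct(2 * c + c, c, kernel=1, rng=rng)
        self.head = Conv2d(c, 1, rng=rng)
        if config.weighted_sum_mode == "learnable":
            # w = sigmoid(rho); rho = 0 starts the blend at 0.5.
            self.rho = ad.Tensor(np.zeros(()), requires_grad=True)

    @property
    def residual_weight(self) -> float:
        if self.config.weighted_sum_mode == "fixed":
            return float(self.config.fixed_weight)
        return float(1.0 / (1.0 + math.exp(-float(self.rho.data))))

    def forward(self, frames: np.ndarray) -> ad.Tensor:
        """Forward pass on a (N, k, H, W) batch; H, W divisible by 8."""
        x = ad.Tensor(np.asarray(frames, dtype=_F32))
        mean_frames = ad.Tensor(x.data.mean(axis=1, keepdims=True))

        s = self.stem(x)
        e1 = self.enc1b(self.enc1(s))
        e2 = self.enc2b(self.enc2(e1))
        h = self.hr(e2)
        d1 = self.dec1(ad.concat([ad.upsample2(h), e1]))
        d2 = self.dec2(ad.concat([ad.upsample2(d1), s]))
        side = self.side(ad.concat([ad.upsample2(d1), d2]))
        decoded = ad.sigmoid(self.head(side))

        if self.config.weighted_sum_mode == "fixed":
            w = float(self.config.fixed_weight)
            return ad.add(ad.mul_const(mean_frames, w),
                          ad.mul_const(decoded, 1.0 - w))
        w = ad.sigmoid(self.rho)
        one_minus_w = ad.add_const(ad.mul_const(w, -1.0), 1.0)
        return ad.add(ad.scale(mean_frames, w), ad.scale(decoded, one_minus_w))


@dataclass
class TrainedModel:
    """A network plus its configuration and training history."""

    config: NetConfig
    net: EnhancementNet
    history: list[dict] = field(default_factory=list)

    @property
    def residual_weight(self) -> float:
        return self.net.residual_weight


def build_network(config: NetConfig) -> TrainedModel:
    """Construct an (untrained) enhancement network from a config."""
    return TrainedModel(config=config, net=EnhancementNet(config))


def combined_loss(prediction: np.ndarray, target: np.ndarray,
                  weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """w_ce * BCE(prediction, target) + w_ssim * (1 - SSIM(prediction, target)).

    The SSIM term uses the package's assessment SSIM, so the loss reduces
    exactly to BCE at weights (1, 0) and to 1 - SSIM at (0, 1).
    """
    prediction = np.asarray(prediction, dtype=float)
    target = np.asarray(target, dtype=float)
    if prediction.shape != target.shape:
        raise ValueError("prediction and target must share shape")
    for name, arr in (("prediction", prediction), ("target", target)):
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError(f"{name} values must lie in [0, 1]")
    w_ce, w_ssim = weights
    loss = 0.0
    if w_ce > 0:
        eps = 1e-12
        p = np.clip(prediction, eps, 1.0 - eps)
        loss += w_ce * float(
            -(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)).mean()
        )
    if w_ssim > 0:
        loss += w_ssim * (1.0 - metrics.ssim(prediction, target))
    return loss


def _pad_to_multiple(frames: np.ndarray, multiple: int = 8):
    h, w = frames.shape[-2:]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return frames, (0, 0)
    pad = [(0, 0)] * (frames.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(frames, pad, mode="reflect"), (ph, pw)


def _input_frames(model: TrainedModel, stack: FrameStack) -> np.ndarray:
    k = model.config.n_input_frames
    survivors = stack.surviving_indices()
    if len(survivors) < k:
        raise ValueError(
            f"stack provides {len(survivors)} surviving frames; "
            f"model needs {k}"
        )
    return stack.frames[survivors[:k]]


def enhance(model: TrainedModel, stack: FrameStack) -> np.ndarray:
    """Enhance one aligned stack with the model (first k surviving frames)."""
    frames = _input_frames(model, stack)
    padded, (ph, pw) = _pad_to_multiple(frames[None])
    out = model.net.forward(padded).data[0, 0]
    if ph or pw:
        out = out[: out.shape[0] - ph, : out.shape[1] - pw]
    return np.clip(out.astype(float), 0.0, 1.0)


def _build_samples(dataset, k: int, draws: int, rng: np.random.Generator):
    samples = []
    for stack, target in dataset:
        survivors = stack.surviving_indices()
        if len(survivors) < k:
            raise ValueError(
                f"stack provides {len(survivors)} surviving frames; need {k}"
            )
        target = np.asarray(target, dtype=_F32)
        for _ in range(draws):
            idx = rng.choice(survivors, size=k, replace=False)
            samples.append((stack.frames[idx].astype(_F32), target))
    return samples


def _epoch_loss(net: EnhancementNet, samples, batch_size: int,
                w_ce: float, w_ssim: float) -> float:
    """Forward-only mean loss over the samples (used for the baseline)."""
    total, count = 0.0, 0
    for lo in range(0, len(samples), batch_size):
        batch = samples[lo : lo + batch_size]
        x = np.stack([b[0] for b in batch])
        t = np.stack([b[1] for b in batch])
        out = net.forward(x)
        loss = combined_loss_tensor(out, t, w_ce, w_ssim)
        total += float(loss.data) * len(batch)
        count += len(batch)
    return total / count


def train(model: TrainedModel, dataset, tc: TrainConfig | None = None) -> TrainedModel:
    """Train the network on (FrameStack, target) pairs.

    Offline augmentation draws ``tc.augmentation_draws`` random
    ``n_input_frames``-subsets per stack.  Adam starts at ``lr_init``; when
    the monitored (training) loss has not decreased for ``patience_epochs``
    epochs the learning rate is multiplied by ``decay_factor`` and the
    patience counter resets.  Deterministic given the seeds.
    """
    tc = tc or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(tc.seed)
    w_ce, w_ssim = tc.loss_weights
    k = model.config.n_input_frames
    samples = _build_samples(dataset, k, tc.augmentation_draws, rng)

    params = model.net.parameters()
    opt = Adam(params, lr=tc.lr_init)
    # Baseline for the plateau rule: the loss before any update, so "did not
    # decrease within N epochs" is measured against the best loss seen so far
    # including the untrained state.
    best = _epoch_loss(model.net, samples, tc.batch_size, w_ce, w_ssim)
    stale = 0
    model.history = [{"epoch": 0, "loss": best, "lr": opt.lr}]

    order = np.arange(len(samples))
    for epoch in range(1, tc.max_epochs + 1):
        rng.shuffle(order)
        total = 0.0
        for lo in range(0, len(order), tc.batch_size):
            batch = [samples[i] for i in order[lo : lo + tc.batch_size]]
            x = np.stack([b[0] for b in batch])
            t = np.stack([b[1] for b in batch])
            opt.zero_grad()
            loss = combined_loss_tensor(model.net.forward(x), t, w_ce, w_ssim)
            loss.backward()
            opt.step()
            total += float(loss.data) * len(batch)
        epoch_loss = total / len(order)

        if epoch_loss < best - 1e-6:
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= tc.patience_epochs:
                opt.lr *= tc.decay_factor
                stale = 0
        model.history.append({"epoch": epoch, "loss": epoch_loss, "lr": opt.lr})
    return model
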