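"""Adversarial C-scan enhancement network.

A Pix2Pix-style pair of models trained on (synthetic degraded input,
averaged reference label) image pairs:

* **Generator** — U-shaped encoder/decoder. Every downsampling block is a
  4×4 / stride-2 / pad-1 convolution + batch-1 norm + LeakyReLU(0.2);
  every upsampling block is the mirror transposed convolution + norm +
  ReLU, with skip connections between mirror levels and a tanh head.
* **Discriminator** — a 4×4 / stride-2 / pad-1 convolution + LeakyReLU,
  five such blocks with norm, then a final 4×4 / stride-2 / pad-0
  convolution + sigmoid that reduces a 256×256 input to one probability.

Losses (batch size 1 throughout):

    G_loss = lambda * Content_loss + Adversarial_loss,   lambda = 1e3
    Content_loss = mean |I_label - G(I_input)|            (L1)
    Adversarial_loss = E[log(1 - D(G(I_input)))]          (minimized)
    D_loss = -E[log D(I_label)] - E[log(1 - D(G(I_input)))]

The discriminator is *unconditional* — it sees only the label image or the
generated image, exactly as the loss definitions above are written; a
``conditional`` flag is reserved for the input-conditioned variant.
Images enter in [0, 1] and are mapped to the tanh range [-1, 1] strictly
inside this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .exceptions import ValidationError
from .synthesis import TrainingPair, augment

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "TrainConfig",
    "LossRecord",
    "UNetGenerator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "content_loss",
    "adversarial_loss",
    "generator_loss",
    "discriminator_loss",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

EPS = 1e-7  # clamp inside every log


@dataclass(frozen=True)
class GeneratorSpec:
    """U-shaped generator architecture.

    ``n_levels`` stride-2 halvings take a ``2^n_levels``-divisible input
    down to the bottleneck; channels double from ``base_channels`` up to
    ``max_channels``. Default depth 8 gives a 1×1 bottleneck on 256×256.
    """

    n_levels: int = 8
    base_channels: int = 64
    max_channels: int = 512
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValidationError("n_levels must be >= 2")
        if self.base_channels < 1 or self.max_channels < self.base_channels:
            raise ValidationError("need 1 <= base_channels <= max_channels")

    def channels(self) -> list[int]:
        return [min(self.base_channels * 2**i, self.max_channels)
                for i in range(self.n_levels)]


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Discriminator stack: entry conv+LeakyReLU, ``n_blocks`` conv blocks
    with norm, then a 4×4/stride-2/pad-0 conv + sigmoid head."""

    base_channels: int = 64
    n_blocks: int = 5
    max_channels: int = 512
    in_channels: int = 1
    conditional: bool = False

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValidationError("n_blocks must be >= 1")
        if self.conditional:
            raise ValidationError("conditional discriminator is not implemented")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the published recipe
    (Adam, lr 1e-3, batch 1, 120 epochs, lambda = 1e3)."""

    learning_rate: float = 1e-3
    batch_size: int = 1
    epochs: int = 120
    lambda_content: float = 1e3
    betas: tuple[float, float] = (0.5, 0.999)
    seed: int = 0
    augment: bool = True
    checkpoint_every: int = 0  # epochs; 0 disables periodic checkpoints

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.lambda_content < 0:
            raise ValidationError("lambda_content must be >= 0")
        if self.batch_size != 1:
            raise ValidationError("the training scheme is defined for batch_size 1")


@dataclass(frozen=True)
class LossRecord:
    """Per-epoch mean losses; ``g_loss`` always equals
    ``lambda_content * content_loss + adversarial_loss`` exactly."""

    epoch: int
    g_loss: float
    content_loss: float
    adversarial_loss: float
    d_loss: float
    n_steps: int = 0


def _to_chw(image: np.ndarray, dtype) -> np.ndarray:
    x = np.asarray(image, dtype=dtype)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValidationError(f"expected a 2D image, got shape {image.shape}")
    return x


class UNetGenerator:
    """Encoder/decoder generator with skip connections (see module docs)."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0, dtype=np.float64) -> None:
        self.spec = spec
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        ch = spec.channels()
        n = spec.n_levels
        self.down: list[nn.Sequential] = []
        prev = spec.in_channels
        for i in range(n):
            layers: list[nn.Layer] = [nn.Conv2d(prev, ch[i], 4, 2, 1, rng=rng, dtype=dtype)]
            # no norm on the entry block (raw image statistics) nor on the
            # bottleneck, whose 1x1 maps have no spatial statistics
            if 0 < i < n - 1:
                layers.append(nn.ChannelNorm(ch[i], dtype=dtype))
            layers.append(nn.LeakyReLU(0.2))
            self.down.append(nn.Sequential(*layers))
            prev = ch[i]
        self.up: list[nn.Sequential] = []
        self._split: list[int] = []
        for k in range(n):
            in_ch = ch[n - 1] if k == 0 else 2 * ch[n - 1 - k]
            out_ch = ch[n - 2 - k] if k < n - 1 else spec.out_channels
            layers = [nn.ConvTranspose2d(in_ch, out_ch, 4, 2, 1, rng=rng, dtype=dtype)]
            if k < n - 1:
                layers.append(nn.ChannelNorm(out_ch, dtype=dtype))
                layers.append(nn.ReLU())
            else:
                layers.append(nn.Tanh())
            self.up.append(nn.Sequential(*layers))
            self._split.append(0 if k == 0 else ch[n - 1 - k])
        self._skips: list[np.ndarray] | None = None
        self._was_2d = True

    # -- parameter bookkeeping -------------------------------------------
    def modules(self) -> list[nn.Sequential]:
        return self.down + self.up

    def params(self) -> list[nn.Param]:
        return [p for m in self.modules() for p in m.params()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return _state_dict(self.modules())

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        _load_state_dict(self.modules(), state)

    # -- computation ------------------------------------------------------
    def _check_size(self, h: int, w: int) -> None:
        m = 2**self.spec.n_levels
        if h % m or w % m or h < m or w < m:
            raise ValidationError(
                f"generator with n_levels={self.spec.n_levels} requires spatial "
                f"sizes divisible by {m}, got {h}x{w}"
            )

    def forward(self, image: np.ndarray, train: bool = True) -> np.ndarray:
        x = _to_chw(image, self.dtype)
        self._was_2d = np.asarray(image).ndim == 2
        self._check_size(*x.shape[1:])
        h = 2.0 * x - 1.0
        skips: list[np.ndarray] = []
        for blk in self.down:
            h = blk.forward(h, train)
            skips.append(h)
        self._skips = skips
        n = self.spec.n_levels
        out = skips[-1]
        for k, blk in enumerate(self.up):
            inp = out if k == 0 else np.concatenate([out, skips[n - 1 - k]], axis=0)
            out = blk.forward(inp, train)
        y = (out + 1.0) / 2.0
        return y[0] if self._was_2d and y.shape[0] == 1 else y

    def backward(self, d_output: np.ndarray) -> np.ndarray:
        """Backpropagate a gradient w.r.t. the [0, 1]-scaled output image,
        accumulating parameter gradients; returns the input gradient."""
        dy = np.asarray(d_output, dtype=self.dtype)
        if dy.ndim == 2:
            dy = dy[None]
        dy = dy / 2.0  # through (out + 1) / 2
        n = self.spec.n_levels
        skip_grads: list[np.ndarray | None] = [None] * n
        g = dy
        for k in reversed(range(n)):
            dinp = self.up[k].backward(g)
            if k == 0:
                skip_grads[n - 1] = dinp if skip_grads[n - 1] is None else skip_grads[n - 1] + dinp
            else:
                c = dinp.shape[0] - self._split[k]
                g = dinp[:c]
                sg = dinp[c:]
                idx = n - 1 - k
                skip_grads[idx] = sg if skip_grads[idx] is None else skip_grads[idx] + sg
        gd = skip_grads[n - 1]
        for i in reversed(range(n)):
            gd = self.down[i].backward(gd)
            if i > 0 and skip_grads[i - 1] is not None:
                gd = gd + skip_grads[i - 1]
        dx = 2.0 * gd  # through 2x - 1
        return dx[0] if self._was_2d and dx.shape[0] == 1 else dx

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return self.forward(image, train=False)


class Discriminator:
    """Probability-of-real network (see module docs)."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0, dtype=np.float64) -> None:
        self.spec = spec
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        layers: list[nn.Layer] = [
            nn.Conv2d(spec.in_channels, spec.base_channels, 4, 2, 1, rng=rng, dtype=dtype),
            nn.LeakyReLU(0.2),
        ]
        prev = spec.base_channels
        for _ in range(spec.n_blocks):
            nxt = min(prev * 2, spec.max_channels)
            layers += [
                nn.Conv2d(prev, nxt, 4, 2, 1, rng=rng, dtype=dtype),
                nn.ChannelNorm(nxt, dtype=dtype),
                nn.LeakyReLU(0.2),
            ]
            prev = nxt
        layers += [nn.Conv2d(prev, 1, 4, 2, 0, rng=rng, dtype=dtype), nn.Sigmoid()]
        self.net = nn.Sequential(*layers)

    def modules(self) -> list[nn.Sequential]:
        return [self.net]

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def state_dict(self) -> dict[str, np.ndarray]:
        return _state_dict(self.modules())

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        _load_state_dict(self.modules(), state)

    def forward(self, image: np.ndarray, train: bool = True) -> np.ndarray:
        x = _to_chw(image, self.dtype)
        try:
            y = self.net.forward(2.0 * x - 1.0, train)
        except ValueError as exc:
            raise ValidationError(str(exc)) from exc
        return y[0]  # (h', w') probability map; 1x1 for 256x256 input

    def backward(self, d_prob: np.ndarray) -> np.ndarray:
        dy = np.asarray(d_prob, dtype=self.dtype)[None]
        dx = self.net.backward(dy)
        return 2.0 * dx[0] if dx.shape[0] == 1 else 2.0 * dx

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return self.forward(image, train=False)


def build_generator(spec: GeneratorSpec | None = None, seed: int = 0,
                    dtype=np.float64) -> UNetGenerator:
    return UNetGenerator(spec or GeneratorSpec(), seed=seed, dtype=dtype)


def build_discriminator(spec: DiscriminatorSpec | None = None, seed: int = 0,
                        dtype=np.float64) -> Discriminator:
    return Discriminator(spec or DiscriminatorSpec(), seed=seed, dtype=dtype)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def content_loss(label: np.ndarray, pred: np.ndarray) -> float:
    """L1 content loss: mean absolute difference over all pixels."""
    label = np.asarray(label, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if label.shape != pred.shape:
        raise ValidationError(f"shape mismatch: {label.shape} vs {pred.shape}")
    return float(np.mean(np.abs(label - pred)))


def adversarial_loss(d_on_generated: np.ndarray | float) -> float:
    """Mean of ``log(1 - D(G(input)))``; minimizing drives D(G) toward 1.
    Probabilities are clamped to ``[EPS, 1 - EPS]`` inside the log."""
    d = np.asarray(d_on_generated, dtype=np.float64)
    if np.any(d < 0) or np.any(d > 1):
        raise ValidationError("discriminator outputs must lie in [0, 1]")
    return float(np.mean(np.log(np.clip(1.0 - d, EPS, None))))


def generator_loss(content: float, adversarial: float, lambda_content: float) -> float:
    """Total generator objective ``lambda * content + adversarial``."""
    return lambda_content * content + adversarial


def discriminator_loss(d_on_label: np.ndarray | float,
                       d_on_generated: np.ndarray | float) -> float:
    """Binary cross-entropy: ``-E[log D(label)] - E[log(1 - D(G(input)))]``."""
    dr = np.asarray(d_on_label, dtype=np.float64)
    df = np.asarray(d_on_generated, dtype=np.float64)
    if np.any(dr < 0) or np.any(dr > 1) or np.any(df < 0) or np.any(df > 1):
        raise ValidationError("discriminator outputs must lie in [0, 1]")
    return float(-np.mean(np.log(np.clip(dr, EPS, None)))
                 - np.mean(np.log(np.clip(1.0 - df, EPS, None))))


# ---------------------------------------------------------------------------
# state (de)serialization
# ---------------------------------------------------------------------------

def _state_dict(modules: list[nn.Sequential]) -> dict[str, np.ndarray]:
    state: dict[str, np.ndarray] = {}
    for mi, mod in enumerate(modules):
        for li, layer in enumerate(mod.layers):
            key = f"m{mi}_l{li}"
            if isinstance(layer, (nn.Conv2d, nn.ConvTranspose2d)):
                state[f"{key}_w"] = layer.weight.data.copy()
                state[f"{key}_b"] = layer.bias.data.copy()
            elif isinstance(layer, nn.ChannelNorm):
                state[f"{key}_gamma"] = layer.gamma.data.copy()
                state[f"{key}_beta"] = layer.beta.data.copy()
                state[f"{key}_rmean"] = layer.running_mean.copy()
                state[f"{key}_rvar"] = layer.running_var.copy()
    return state


def _load_state_dict(modules: list[nn.Sequential], state: dict[str, np.ndarray]) -> None:
    for mi, mod in enumerate(modules):
        for li, layer in enumerate(mod.layers):
            key = f"m{mi}_l{li}"
            if isinstance(layer, (nn.Conv2d, nn.ConvTranspose2d)):
                layer.weight.data[...] = state[f"{key}_w"]
                layer.bias.data[...] = state[f"{key}_b"]
            elif isinstance(layer, nn.ChannelNorm):
                layer.gamma.data[...] = state[f"{key}_gamma"]
                layer.beta.data[...] = state[f"{key}_beta"]
                layer.running_mean[...] = state[f"{key}_rmean"]
                layer.running_var[...] = state[f"{key}_rvar"]


def save_checkpoint(path: str | Path, generator: UNetGenerator,
                    discriminator: Discriminator, g_opt: nn.Adam, d_opt: nn.Adam,
                    epoch: int) -> Path:
    """Write generator + discriminator weights, optimizer moments and the
    epoch counter to a single ``.npz``; :func:`train` can resume from it
    bit-for-bit (the per-epoch random streams are keyed by epoch index)."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for prefix, state in (("g", generator.state_dict()), ("d", discriminator.state_dict())):
        for k, v in state.items():
            arrays[f"{prefix}_{k}"] = v
    for prefix, opt in (("gopt", g_opt), ("dopt", d_opt)):
        st = opt.state_dict()
        arrays[f"{prefix}_t"] = np.array(st["t"])
        for i, (m, v) in enumerate(zip(st["m"], st["v"])):
            arrays[f"{prefix}_m{i}"] = m
            arrays[f"{prefix}_v{i}"] = v
    arrays["epoch"] = np.array(epoch)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path: str | Path, generator: UNetGenerator,
                    discriminator: Discriminator, g_opt: nn.Adam | None = None,
                    d_opt: nn.Adam | None = None) -> int:
    """Restore a checkpoint written by :func:`save_checkpoint` into the
    given models/optimizers; returns the stored epoch counter."""
    with np.load(Path(path)) as data:
        g_state = {k[2:]: data[k] for k in data.files if k.startswith("g_")}
        d_state = {k[2:]: data[k] for k in data.files if k.startswith("d_")
                   and not k.startswith("dopt_")}
        generator.load_state_dict(g_state)
        discriminator.load_state_dict(d_state)
        for prefix, opt in (("gopt", g_opt), ("dopt", d_opt)):
            if opt is None:
                continue
            n = len(opt.params)
            opt.load_state_dict({
                "t": int(data[f"{prefix}_t"]),
                "m": [data[f"{prefix}_m{i}"] for i in range(n)],
                "v": [data[f"{prefix}_v{i}"] for i in range(n)],
            })
        return int(data["epoch"])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(
    dataset: list[TrainingPair],
    config: TrainConfig,
    generator: UNetGenerator | None = None,
    discriminator: Discriminator | None = None,
    gen_spec: GeneratorSpec | None = None,
    disc_spec: DiscriminatorSpec | None = None,
    dtype=np.float64,
    checkpoint_dir: str | Path | None = None,
    resume_from: str | Path | None = None,
    step_records: list | None = None,
) -> tuple[UNetGenerator, list[LossRecord]]:
    """Adversarial training: one discriminator step and one generator step
    per sample (batch 1), with per-epoch re-augmentation of each pair.

    Fully seeded: sample order and augmentation draws are keyed by
    ``(config.seed, epoch)``, so resuming from an epoch checkpoint
    reproduces the continuation exactly. Returns the trained generator and
    one :class:`LossRecord` per epoch; if ``step_records`` is a list it
    additionally receives per-step ``(epoch, step, g, content, adv, d)``
    tuples with ``g = lambda*content + adv`` exact by construction.

    Raises ``RuntimeError`` naming the epoch/step if any loss goes
    non-finite.
    """
    if not dataset:
        raise ValidationError("dataset must be nonempty")
    generator = generator or build_generator(gen_spec, seed=config.seed, dtype=dtype)
    discriminator = discriminator or build_discriminator(disc_spec, seed=config.seed + 1,
                                                         dtype=dtype)
    g_opt = nn.Adam(generator.params(), lr=config.learning_rate, betas=config.betas)
    d_opt = nn.Adam(discriminator.params(), lr=config.learning_rate, betas=config.betas)
    start_epoch = 0
    if resume_from is not None:
        start_epoch = load_checkpoint(resume_from, generator, discriminator, g_opt, d_opt)
    lam = config.lambda_content
    records: list[LossRecord] = []
    for epoch in range(start_epoch, config.epochs):
        ep_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(epoch,)))
        order = ep_rng.permutation(len(dataset))
        aug_seeds = ep_rng.integers(0, 2**31, size=len(order))
        sum_c = sum_a = sum_d = 0.0
        for step, idx in enumerate(order):
            pair = dataset[int(idx)]
            if config.augment:
                pair = augment(pair, int(aug_seeds[step]))
            x, y = pair.input, pair.label

            # --- discriminator step: push D(label) -> 1, D(G(input)) -> 0
            fake = generator.forward(x, train=True)
            d_opt.zero_grad()
            p_real = discriminator.forward(y, train=True)
            n_real = p_real.size
            discriminator.backward(-1.0 / (n_real * np.clip(p_real, EPS, None)))
            p_fake = discriminator.forward(fake, train=True)
            n_fake = p_fake.size
            discriminator.backward(1.0 / (n_fake * np.clip(1.0 - p_fake, EPS, None)))
            d_val = discriminator_loss(p_real, p_fake)
            d_opt.step()

            # --- generator step: minimize lambda*L1 + log(1 - D(G(input)))
            g_opt.zero_grad()
            pred = generator.forward(x, train=True)
            c_val = content_loss(y, pred)
            d_grad_pred = np.sign(pred - y) / pred.size
            d_opt.zero_grad()  # D is only a critic here; discard its grads
            p_gen = discriminator.forward(pred, train=True)
            a_val = adversarial_loss(p_gen)
            dp = -1.0 / (p_gen.size * np.clip(1.0 - p_gen, EPS, None))
            adv_grad_pred = discriminator.backward(dp)
            generator.backward(lam * d_grad_pred + adv_grad_pred)
            g_opt.step()
            d_opt.zero_grad()

            g_val = generator_loss(c_val, a_val, lam)
            if not (np.isfinite(g_val) and np.isfinite(d_val)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}: "
                    f"g={g_val}, d={d_val}"
                )
            if step_records is not None:
                step_records.append((epoch, step, g_val, c_val, a_val, d_val))
            sum_c += c_val
            sum_a += a_val
            sum_d += d_val
        n = len(order)
        mean_c, mean_a = sum_c / n, sum_a / n
        records.append(LossRecord(
            epoch=epoch,
            g_loss=generator_loss(mean_c, mean_a, lam),
            content_loss=mean_c,
            adversarial_loss=mean_a,
            d_loss=sum_d / n,
            n_steps=n,
        ))
        if checkpoint_dir is not None and (
            (config.checkpoint_every and (epoch + 1) % config.checkpoint_every == 0)
            or epoch + 1 == config.epochs
        ):
            save_checkpoint(Path(checkpoint_dir) / f"epoch_{epoch + 1:04d}.npz",
                            generator, discriminator, g_opt, d_opt, epoch + 1)
    return generator, records


def save_loss_csv(records: list[LossRecord], path: str | Path) -> Path:
    """Write the per-epoch loss curve as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["epoch,g_loss,content_loss,adversarial_loss,d_loss,n_steps"]
    for r in records:
        lines.append(f"{r.epoch},{r.g_loss!r},{r.content_loss!r},"
                     f"{r.adversarial_loss!r},{r.d_loss!r},{r.n_steps}")
    path.write_text("\n".join(lines) + "\n")
    return path
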