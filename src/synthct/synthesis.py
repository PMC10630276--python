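"""Semantic image synthesis: encoder, SPADE generator, patch discriminators.

The generator turns a semantic annotation map plus a latent style code
into a slice that adheres to the map: every normalization stage re-injects
the label layout through spatially-adaptive scale/shift maps (SPADE), so
anatomy is dictated by the map while the latent code carries appearance
(scanner look, overall intensity).  The encoder is a VAE-style style
encoder producing the latent's mean and log-variance from an example
image; two patch discriminators at full and half resolution drive a hinge
adversarial loss with feature matching.

The architecture is resolution-parameterized.  The default ``desk``
profile (64x64, 16 base channels) is sized for CPU training; the ``full``
profile lays out the same architecture at 512x512 / 64 channels.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import labels as L
from .annotation import one_hot as _one_hot_single
from .errors import (
    BundleFormatError,
    ConfigError,
    DataError,
    TrainingDivergenceError,
)
from .nn import SPADE, Adam, Conv2d, Linear, Module, Tensor, instance_norm
from .preprocess import LUNG_WINDOW, denormalize

BUNDLE_FORMAT_VERSION = 1


def default_loss_weights() -> dict[str, float]:
    """Adversarial 1, feature matching 10, KL 0.05 (the conventional
    weighting for SPADE-style training).  The perceptual term is off by
    default because it needs a user-supplied feature extractor; in its
    place a pixel-space L1 reconstruction term (weight 10) supervises the
    label-to-intensity mapping directly, which at small training scales
    is what makes rare, small structures (nodules) render distinctly."""
    return {"adversarial": 1.0, "feature_matching": 10.0, "kl": 0.05,
            "reconstruction": 10.0, "perceptual": 0.0}


@dataclass
class GeneratorConfig:
    image_side: int = 64
    base_channels: int = 16
    n_upsample_stages: int = 4
    latent_dim: int = 64
    loss_weights: dict[str, float] = field(default_factory=default_loss_weights)
    # two-timescale rule (discriminator faster than generator); the desk
    # profile uses rates tuned for few-hundred-step CPU runs, the full
    # profile the conventional 1e-4 / 4e-4
    lr_g: float = 1e-3
    lr_d: float = 2e-3
    epochs: int = 3
    batch_size: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.image_side != 4 * 2**self.n_upsample_stages:
            raise ConfigError(
                f"image_side {self.image_side} inconsistent with "
                f"{self.n_upsample_stages} upsample stages "
                f"(expected {4 * 2 ** self.n_upsample_stages})"
            )
        if any(w < 0 for w in self.loss_weights.values()):
            raise ConfigError("loss weights must be >= 0")
        if self.latent_dim < 1 or self.base_channels < 1:
            raise ConfigError("latent_dim and base_channels must be >= 1")

    @property
    def initial_side(self) -> int:
        return self.image_side // 2**self.n_upsample_stages

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_json(cls, s: str) -> "GeneratorConfig":
        return cls(**json.loads(s))


def desk_profile(**overrides) -> GeneratorConfig:
    """64x64 CPU-trainable profile (the default)."""
    return GeneratorConfig(**overrides)


def full_profile(**overrides) -> GeneratorConfig:
    """512x512 layout matching the architecture at publication scale."""
    base = dict(image_side=512, base_channels=64, n_upsample_stages=7,
                latent_dim=256, lr_g=1e-4, lr_d=4e-4)
    base.update(overrides)
    return GeneratorConfig(**base)


@dataclass
class LatentCode:
    """Style distribution parameters from the encoder."""

    mean: np.ndarray
    logvar: np.ndarray

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        eps = rng.standard_normal(self.mean.shape).astype(np.float32)
        return self.mean + np.exp(0.5 * self.logvar) * eps


# ---------------------------------------------------------------------------
# Networks


class Generator(Module):
    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        c0 = config.base_channels * 8
        self.config = config
        self.c0 = c0
        self.fc = Linear(config.latent_dim, c0 * config.initial_side**2, rng=rng)
        chans = [c0]
        for i in range(config.n_upsample_stages):
            chans.append(max(config.base_channels // 2, c0 >> (i + 1)))
        self.spades = [
            SPADE(chans[i], L.N_LABELS, hidden=config.base_channels, rng=rng)
            for i in range(config.n_upsample_stages)
        ]
        self.convs = [
            Conv2d(chans[i], chans[i + 1], k=3, rng=rng)
            for i in range(config.n_upsample_stages)
        ]
        self.head_spade = SPADE(chans[-1], L.N_LABELS,
                                hidden=config.base_channels, rng=rng)
        self.head = Conv2d(chans[-1], 1, k=3, rng=rng)
        # direct style path: a global pre-activation bias predicted from
        # the latent; instance normalization strips global intensity from
        # the feature path, so without this the style code could not
        # steer overall brightness (scanner look)
        self.style_bias = Linear(config.latent_dim, 1, rng=rng, gain=0.1)
        # positive read-out of the encoder's luminance channel (unit 0)
        self.style_bias.weight.data[0, 0] = 0.5

    def __call__(self, seg: np.ndarray, z: Tensor) -> Tensor:
        s0 = self.config.initial_side
        x = self.fc(z).reshape(z.shape[0], self.c0, s0, s0)
        for spade, conv in zip(self.spades, self.convs):
            x = x.upsample2x()
            x = conv(spade(x, seg).relu())
        pre = self.head(self.head_spade(x, seg).relu())
        bias = self.style_bias(z).reshape(z.shape[0], 1, 1, 1)
        return (pre + bias).sigmoid()


class Encoder(Module):
    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.config = config
        chans = [1]
        for i in range(config.n_upsample_stages):
            chans.append(min(config.base_channels * 2**i, config.base_channels * 8))
        self.convs = [
            Conv2d(chans[i], chans[i + 1], k=3, stride=2, rng=rng)
            for i in range(config.n_upsample_stages)
        ]
        # +1: a global mean-intensity shortcut feature (see __call__)
        flat = chans[-1] * config.initial_side**2 + 1
        self.fc_mu = Linear(flat, config.latent_dim, rng=rng)
        self.fc_logvar = Linear(flat, config.latent_dim, rng=rng)
        # start with a tight posterior (sd ~ e^-1) so the style signal in
        # the latent mean is not drowned by sampling noise early on
        self.fc_logvar.bias.data[:] = -2.0
        # wire latent unit 0 as a luminance channel at init: it reads the
        # brightness shortcut directly (training refines the mapping
        # instead of having to discover its sign in few steps)
        self.fc_mu.weight.data[-1, :] = 0.0
        self.fc_mu.weight.data[-1, 0] = 1.0

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        # deliberately normalization-free: the latent must be able to
        # carry global intensity (scanner look), which instance norms
        # would strip
        from .nn import concat

        h = x
        for conv in self.convs:
            h = conv(h).leaky_relu(0.2)
        h = h.reshape(h.shape[0], -1)
        # global-pooling shortcut: overall image brightness is the single
        # strongest scanner-style cue, handed to the latent heads directly
        gm = x.mean(axis=(2, 3)).reshape(x.shape[0], 1) * 8.0
        h = concat([h, gm], axis=1)
        return self.fc_mu(h), self.fc_logvar(h)


class PatchDiscriminator(Module):
    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        b = config.base_channels
        self.c1 = Conv2d(1 + L.N_LABELS, b, k=4, stride=2, padding=1, rng=rng)
        self.c2 = Conv2d(b, 2 * b, k=4, stride=2, padding=1, rng=rng)
        self.c3 = Conv2d(2 * b, 4 * b, k=4, stride=2, padding=1, rng=rng)
        self.head = Conv2d(4 * b, 1, k=4, stride=1, padding=1, rng=rng)

    def __call__(self, img: Tensor, seg: Tensor):
        from .nn import concat

        h = concat([img, seg], axis=1)
        feats = []
        h = self.c1(h).leaky_relu(0.2)
        feats.append(h)
        h = instance_norm(self.c2(h)).leaky_relu(0.2)
        feats.append(h)
        h = instance_norm(self.c3(h)).leaky_relu(0.2)
        feats.append(h)
        return self.head(h), feats


class MultiScaleDiscriminator(Module):
    """Patch discriminators at full and half resolution."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.scales = [PatchDiscriminator(config, rng) for _ in range(2)]

    def __call__(self, img: Tensor, seg: Tensor):
        out = []
        for i, d in enumerate(self.scales):
            if i == 0:
                out.append(d(img, seg))
            else:
                out.append(d(img.avg_pool2x(), seg.avg_pool2x()))
        return out


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class ModelBundle:
    encoder: Encoder
    generator: Generator
    discriminator: MultiScaleDiscriminator
    config: GeneratorConfig
    training_manifest: dict = field(default_factory=dict)
    loss_history: list[dict] = field(default_factory=list)


def build_models(config: GeneratorConfig | None = None) -> ModelBundle:
    """Build an untrained encoder/generator/discriminator bundle.

    Parameter initialization is fully determined by ``config.seed``.
    """
    config = config or desk_profile()
    config.validate()
    rng = np.random.default_rng(config.seed)
    return ModelBundle(
        encoder=Encoder(config, rng),
        generator=Generator(config, rng),
        discriminator=MultiScaleDiscriminator(config, rng),
        config=config,
    )


# ---------------------------------------------------------------------------
# Training


def one_hot_batch(maps: np.ndarray) -> np.ndarray:
    """(N, H, W) uint8 label maps -> (N, 6, H, W) float32 one-hot."""
    m = np.asarray(maps)
    if m.ndim == 2:
        m = m[None]
    return (m[:, None] == np.arange(L.N_LABELS)[None, :, None, None]).astype(
        np.float32
    )


def _hinge_d(real_logits: Tensor, fake_logits: Tensor) -> Tensor:
    return (1.0 - real_logits).relu().mean() + (1.0 + fake_logits).relu().mean()


def train(
    bundle: ModelBundle,
    maps: np.ndarray,
    images: np.ndarray,
    config: GeneratorConfig | None = None,
    feature_extractor: Callable[[Tensor], list[Tensor]] | None = None,
    log: Callable[[str], None] | None = None,
) -> ModelBundle:
    """Adversarially train the bundle on (annotation map, image) pairs.

    ``images`` must be normalized to [0, 1] and aligned with ``maps``.
    Alternating updates: discriminator hinge step, then generator+encoder
    step with hinge adversarial, discriminator-feature L1 matching, and a
    KL penalty tying the style posterior to a standard normal.  A
    user-supplied ``feature_extractor`` enables the optional perceptual
    term.  Deterministic given ``config.seed`` (single-threaded BLAS);
    epoch-mean losses are recorded in ``bundle.loss_history`` and a
    non-finite loss aborts with :class:`TrainingDivergenceError`.
    """
    config = config or bundle.config
    config.validate()
    maps = np.asarray(maps)
    images = np.asarray(images, dtype=np.float32)
    if maps.ndim != 3 or images.shape != maps.shape:
        raise DataError(
            f"maps {maps.shape} and images {images.shape} must align as (N, H, W)"
        )
    if maps.shape[0] == 0:
        raise DataError("training set is empty")
    if maps.shape[1] != config.image_side:
        raise DataError(
            f"training side {maps.shape[1]} != config side {config.image_side}"
        )

    w = {**default_loss_weights(), **config.loss_weights}
    rng = np.random.default_rng(config.seed + 1)
    g_params = bundle.generator.parameters() + bundle.encoder.parameters()
    d_params = bundle.discriminator.parameters()
    opt_g = Adam(g_params, lr=config.lr_g)
    opt_d = Adam(d_params, lr=config.lr_d)

    n = maps.shape[0]
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        sums = {"d": 0.0, "g_adv": 0.0, "g_fm": 0.0, "g_kl": 0.0, "g_rec": 0.0}
        n_batches = 0
        for start in range(0, n - bs + 1, bs):
            idx = order[start : start + bs]
            seg_np = one_hot_batch(maps[idx])
            seg = Tensor(seg_np)
            real = Tensor(images[idx][:, None])

            mu, logvar = bundle.encoder(real)
            eps = Tensor(rng.standard_normal(mu.shape).astype(np.float32))
            z = mu + (logvar * 0.5).exp() * eps
            fake = bundle.generator(seg_np, z)

            # --- discriminator step
            fake_det = fake.detach()
            d_loss = Tensor(0.0)
            for logits_r, _ in bundle.discriminator(real, seg):
                d_loss = d_loss + (1.0 - logits_r).relu().mean()
            for logits_f, _ in bundle.discriminator(fake_det, seg):
                d_loss = d_loss + (1.0 + logits_f).relu().mean()
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            # --- generator + encoder step (through the updated D)
            real_out = bundle.discriminator(real.detach(), seg)
            fake_out = bundle.discriminator(fake, seg)
            g_adv = Tensor(0.0)
            g_fm = Tensor(0.0)
            n_feat = 0
            for (logits_f, feats_f), (_, feats_r) in zip(fake_out, real_out):
                g_adv = g_adv + (-1.0) * logits_f.mean()
                for ff, fr in zip(feats_f, feats_r):
                    g_fm = g_fm + (ff - fr.detach()).abs().mean()
                    n_feat += 1
            g_fm = g_fm * (1.0 / max(1, n_feat))
            kl = (-0.5) * (
                1.0 + logvar - mu * mu - logvar.exp()
            ).sum() * (1.0 / bs)
            g_rec = (fake - real.detach()).abs().mean()
            g_loss = (
                w["adversarial"] * g_adv
                + w["feature_matching"] * g_fm
                + w["kl"] * kl
                + w["reconstruction"] * g_rec
            )
            if feature_extractor is not None and w["perceptual"] > 0:
                p_loss = Tensor(0.0)
                for pf, pr in zip(feature_extractor(fake),
                                  feature_extractor(real.detach())):
                    p_loss = p_loss + (pf - pr.detach()).abs().mean()
                g_loss = g_loss + w["perceptual"] * p_loss
            opt_g.zero_grad()
            for p in d_params:
                p.grad = None
            g_loss.backward()
            opt_g.step()

            vals = {
                "d": float(d_loss.data),
                "g_adv": float(g_adv.data),
                "g_fm": float(g_fm.data),
                "g_kl": float(kl.data),
                "g_rec": float(g_rec.data),
            }
            if not all(np.isfinite(v) for v in vals.values()):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch}: {vals}", epoch=epoch
                )
            for k, v in vals.items():
                sums[k] += v
            n_batches += 1

        record = {"epoch": epoch} | {
            k: (s / max(1, n_batches)) for k, s in sums.items()
        }
        bundle.loss_history.append(record)
        if log is not None:
            log(
                f"epoch {epoch}: d={record['d']:.3f} adv={record['g_adv']:.3f} "
                f"fm={record['g_fm']:.3f} kl={record['g_kl']:.3f}"
            )
    return bundle


# ---------------------------------------------------------------------------
# Inference


def encode_style(bundle: ModelBundle, image: np.ndarray) -> LatentCode:
    """Encode a normalized [0, 1] image into a style latent distribution."""
    img = np.asarray(image, dtype=np.float32)
    if img.shape != (bundle.config.image_side,) * 2:
        raise DataError(
            f"image shape {img.shape} != configured side {bundle.config.image_side}"
        )
    mu, logvar = bundle.encoder(Tensor(img[None, None]))
    return LatentCode(mean=mu.data[0].copy(), logvar=logvar.data[0].copy())


def synthesize(
    bundle: ModelBundle,
    labels: np.ndarray,
    style: LatentCode | np.ndarray | str = "random",
    seed: int = 0,
    window: tuple[float, float] = LUNG_WINDOW,
) -> np.ndarray:
    """Generate a slice adhering to an annotation map.

    ``style`` selects the latent route: a :class:`LatentCode` is sampled
    (seeded); a guidance image (2D array) is encoded and its posterior
    mean used — example-guided synthesis; ``"random"`` draws a standard
    normal code.  The output is denormalized to HU inside ``window``.
    Deterministic given (bundle, labels, style, seed).
    """
    arr = L.validate_map(labels)
    side = bundle.config.image_side
    if arr.shape != (side, side):
        raise DataError(f"map shape {arr.shape} != configured side {side}")
    rng = np.random.default_rng(seed)
    if isinstance(style, LatentCode):
        z = style.sample(rng)
    elif isinstance(style, str):
        if style != "random":
            raise DataError(f"unknown style mode {style!r}")
        z = rng.standard_normal(bundle.config.latent_dim).astype(np.float32)
    else:
        z = encode_style(bundle, np.asarray(style)).mean
    seg = _one_hot_single(arr)[None]
    img = bundle.generator(seg, Tensor(z[None]))
    return denormalize(img.data[0, 0], window)


# ---------------------------------------------------------------------------
# Persistence


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Write a versioned single-file archive (params + config + manifest)."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for prefix, module in (
        ("enc", bundle.encoder),
        ("gen", bundle.generator),
        ("disc", bundle.discriminator),
    ):
        for i, a in enumerate(module.state_arrays()):
            arrays[f"{prefix}_{i:04d}"] = a
    header = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "config": bundle.config.__dict__,
        "training_manifest": bundle.training_manifest,
        "loss_history": bundle.loss_history,
    }
    buf = io.BytesIO()
    np.savez(buf, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)
    path.write_bytes(buf.getvalue())


def load_bundle(path: str | Path) -> ModelBundle:
    path = Path(path)
    try:
        with np.load(path) as npz:
            header = json.loads(bytes(npz["header"].tobytes()).decode())
            if header.get("format_version") != BUNDLE_FORMAT_VERSION:
                raise BundleFormatError(
                    f"bundle format {header.get('format_version')} unsupported "
                    f"(expected {BUNDLE_FORMAT_VERSION})"
                )
            config = GeneratorConfig(**header["config"])
            bundle = build_models(config)
            for prefix, module in (
                ("enc", bundle.encoder),
                ("gen", bundle.generator),
                ("disc", bundle.discriminator),
            ):
                keys = sorted(k for k in npz.files if k.startswith(prefix + "_"))
                module.load_state_arrays([npz[k] for k in keys])
            bundle.training_manifest = header["training_manifest"]
            bundle.loss_history = header["loss_history"]
            return bundle
    except BundleFormatError:
        raise
    except Exception as exc:  # corrupt zip, missing keys, bad json ...
        raise BundleFormatError(f"cannot read bundle {path}: {exc}") from exc
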