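"""Comparison augmentation strategies and training-set composition.

Implements standard data augmentation (SDA: random rotation within ±15°,
horizontal flip, brightness/contrast jitter — never vertical flips, which
would break ultrasound geometry), pixel-space Mixup (convex combination of
two images and their labels with ``λ ~ Beta(α, α)``), the manifold-mixing
training step (the same combination applied to hidden representations with
the model's current weights), and the composition rule that every
non-vanilla training set is the 600 originals plus a same-size augmented
set.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .data import DatasetManifest, ImageSample
from .nn.losses import softmax_cross_entropy
from .nn.models import ResNetClassifier
from .seeds import derive_seed

STRATEGIES = (
    "vanilla",
    "sda",
    "pixel_mixup",
    "manifold_mixup",
    "dreamon",
    "dreamon_sda",
    "dreamoff",
)


@dataclasses.dataclass
class SDAConfig:
    """Standard-data-augmentation parameters.

    Rotation is uniform in ``±rotation_range`` degrees with zero padding;
    brightness and contrast jitter are multiplicative, uniform in
    ``±brightness_range`` / ``±contrast_range``.
    """

    rotation_range: float = 15.0
    hflip_prob: float = 0.5
    brightness_range: float = 0.2
    contrast_range: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.rotation_range <= 180:
            raise ValueError("rotation_range must lie in [0, 180] degrees")
        if not 0 <= self.hflip_prob <= 1:
            raise ValueError("hflip_prob must be a probability")
        if not 0 <= self.brightness_range < 1 or not 0 <= self.contrast_range < 1:
            raise ValueError("jitter ranges must lie in [0, 1)")


@dataclasses.dataclass
class MixupConfig:
    """Mixup parameters: Beta shape α and the mixed fraction of the final set."""

    alpha: float = 0.8
    mixed_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0 <= self.mixed_fraction <= 0.5:
            raise ValueError(
                "mixed_fraction is the share of the final (doubled) training set that is "
                "mixed; the augmented half caps it at 0.5"
            )


def standard_augment(image: ImageSample, config: SDAConfig, seed: int) -> ImageSample:
    """Apply rotation → horizontal flip → brightness → contrast, then clip.

    The label passes through unchanged; the mask receives the same
    geometric transforms (nearest-neighbour).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    out = image.copy()
    x = out.pixels
    mask = out.mask
    angle = rng.uniform(-config.rotation_range, config.rotation_range)
    if angle != 0.0:
        x = ndimage.rotate(x, angle, reshape=False, order=1, mode="constant", cval=0.0)
        if mask is not None:
            mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="constant", cval=0)
    if rng.random() < config.hflip_prob:
        x = x[:, ::-1]
        if mask is not None:
            mask = mask[:, ::-1]
    x = x * (1.0 + rng.uniform(-config.brightness_range, config.brightness_range))
    mean = x.mean()
    x = (x - mean) * (1.0 + rng.uniform(-config.contrast_range, config.contrast_range)) + mean
    out.pixels = np.clip(x, 0.0, 1.0)
    out.mask = None if mask is None else np.ascontiguousarray(mask)
    out.source = "sda"
    return out


def sample_lambda(config: MixupConfig, rng: np.random.Generator) -> float:
    """One mixing weight ``λ ~ Beta(α, α)``."""
    return float(rng.beta(config.alpha, config.alpha))


def pixel_mixup(x: ImageSample, y: ImageSample, lam: float) -> ImageSample:
    """Convex combination of two images and their labels; the mask is dropped."""
    if x.pixels.shape != y.pixels.shape:
        raise ValueError("pixel_mixup requires images of identical shape")
    if not 0 <= lam <= 1:
        raise ValueError("lambda must lie in [0, 1]")
    return ImageSample(
        pixels=lam * x.pixels + (1 - lam) * y.pixels,
        label=lam * x.label + (1 - lam) * y.label,
        mask=None,
        source="pixel_mixup",
        parents=(x.path or "", y.path or ""),
    )


def manifold_mixup_step(
    model: ResNetClassifier,
    batch_a: tuple[np.ndarray, np.ndarray],
    batch_b: tuple[np.ndarray, np.ndarray],
    lam: float,
    layer_index: int,
    train: bool = True,
) -> float:
    """One manifold-mixing loss evaluation (with backward pass when training).

    Both batches are run forward to ``layer_index`` (0 = the input itself,
    ``k`` = output of the model's k-th stage), their hidden representations
    mixed with weight ``lam``, and the forward pass continued on the mix;
    the loss is soft-label cross-entropy against the λ-mixed labels.
    Executed with the model's current weights.  Returns the loss; when
    ``train``, parameter gradients are accumulated on the model.
    """
    if not 0 <= layer_index < model.n_mix_points:
        raise ValueError(
            f"layer_index {layer_index} out of range 0..{model.n_mix_points - 1}"
        )
    xa, ya = batch_a
    xb, yb = batch_b
    if xa.shape != xb.shape:
        raise ValueError("batches must have identical shapes")
    # one pass over the stacked batches keeps layer caches consistent
    stacked = np.concatenate([xa, xb], axis=0)
    h = model.forward_to(stacked, layer_index, train=train)
    n = xa.shape[0]
    h_mixed = lam * h[:n] + (1 - lam) * h[n:]
    logits = model.forward_from(h_mixed, layer_index, train=train)
    targets = lam * ya + (1 - lam) * yb
    loss, dlogits = softmax_cross_entropy(logits, targets)
    if train:
        g = model.backward_from(dlogits, layer_index)
        g_stacked = np.concatenate([lam * g, (1 - lam) * g], axis=0)
        model.backward_to(g_stacked, layer_index)
    return loss


def build_training_dataset(
    strategy: str,
    originals: DatasetManifest,
    generated: DatasetManifest | None = None,
    seed: int = 0,
    sda_config: SDAConfig | None = None,
    mixup_config: MixupConfig | None = None,
) -> DatasetManifest:
    """Compose the training set for a strategy: originals plus a same-size augmented set.

    * ``vanilla`` — the originals only.
    * ``sda`` — originals + one SDA-transformed copy of each.
    * ``pixel_mixup`` — originals + mixed pairs drawn from the originals
      (partner uniform over the split, cross-class allowed); any remainder
      of the augmented half beyond ``mixed_fraction`` of the final set is
      plain copies.
    * ``manifold_mixup`` — originals + copies flagged for in-training mixing.
    * ``dreamon`` / ``dreamoff`` — originals + the supplied generated set.
    * ``dreamon_sda`` — originals + SDA applied on top of the generated set.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    sda_config = sda_config or SDAConfig()
    mixup_config = mixup_config or MixupConfig()
    base = [s.copy() for s in originals]
    if strategy == "vanilla":
        return DatasetManifest(base, split="train")
    n = len(originals)
    if strategy in ("dreamon", "dreamoff", "dreamon_sda"):
        if generated is None:
            raise ValueError(f"strategy {strategy!r} requires a generated dataset")
        aug = [s.copy() for s in generated]
        if strategy == "dreamon_sda":
            aug = [
                standard_augment(s, sda_config, derive_seed(seed, "dream-sda", i))
                for i, s in enumerate(aug)
            ]
            for s, g in zip(aug, generated):
                s.label = g.label.copy()  # SDA never relabels
                s.source = "sda"
    elif strategy == "sda":
        aug = [
            standard_augment(s, sda_config, derive_seed(seed, "sda", i))
            for i, s in enumerate(originals)
        ]
    elif strategy == "pixel_mixup":
        rng = np.random.default_rng(derive_seed(seed, "pixel-mixup"))
        n_mixed = int(round(mixup_config.mixed_fraction * 2 * n))
        aug = []
        for i in range(n):
            if i < n_mixed:
                j = int(rng.integers(n - 1))
                j = j + 1 if j >= i else j  # partner != self, uniform over the rest
                lam = sample_lambda(mixup_config, rng)
                aug.append(pixel_mixup(originals[i], originals[j], lam))
            else:
                aug.append(originals[i].copy())
    else:  # manifold_mixup
        aug = []
        for s in originals:
            c = s.copy()
            c.source = "manifold_flag"
            aug.append(c)
    return DatasetManifest(base + aug, split="train")
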