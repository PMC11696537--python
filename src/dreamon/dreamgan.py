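"""The DreamOn generative pipeline.

Two adversarially trained networks produce the augmentation imagery:

* ``G_m`` — an unconditional *mask GAN* trained only on the binary lesion
  masks (blank masks from normal-class images are legitimate training
  samples, so the mask prior covers the lesion-free case);
* ``G_s`` — a conditional *image GAN* mapping ``(mask, class vector,
  noise vector)`` to a grayscale image.  Training uses only one-hot class
  vectors; class interpolation happens purely at synthesis time.

DreamOn samples are synthesized from 2-sparse class-weight vectors — two
strictly positive weights summing to 1 — drawn so the *average* weight per
class over a generated dataset matches the dataset proportions
(0.17 / 0.56 / 0.27 by default).  The emitted class vector doubles as the
soft ground-truth label.  DreamOff is the matched control: the same
generators driven by one-hot vectors, isolating interpolation from the
mere addition of synthetic data.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    DatasetManifest,
    ImageSample,
    as_weights,
    is_one_hot,
    largest_remainder_counts,
    one_hot,
)
from .nn import Adam, Discriminator, ImageGenerator, MaskGenerator, bce_with_logits
from .seeds import derive_seed

#: unordered class pairs in canonical order: (normal,benign), (normal,malignant), (benign,malignant)
CLASS_PAIRS = ((0, 1), (0, 2), (1, 2))

#: clamp interval keeping both weights strictly non-zero under floating point
WEIGHT_CLAMP = (1e-3, 1.0 - 1e-3)

#: training-set size at which the dataset-mean matching tolerance is defined
REFERENCE_SET_SIZE = 600


@dataclasses.dataclass
class GanConfig:
    """Architecture and training hyperparameters for both GANs.

    ``latent_dim`` defaults to the 400-dimensional standard-normal noise
    vector the image generator consumes.
    """

    image_size: int = 32
    latent_dim: int = 400
    width: int = 16
    learning_rate: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 16
    steps: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        size = self.image_size
        if size < 16 or (size & (size - 1)) != 0:
            raise ValueError("image_size must be a power of two >= 16")
        if self.batch_size < 1 or self.steps < 1:
            raise ValueError("batch_size and steps must be >= 1")


def _check_finite(step: int, **losses: float) -> None:
    for name, value in losses.items():
        if not np.isfinite(value):
            raise RuntimeError(f"non-finite {name} ({value}) at training step {step}")


def train_mask_gan(
    masks: Sequence[np.ndarray] | np.ndarray, config: GanConfig
) -> tuple[MaskGenerator, pd.DataFrame]:
    """Adversarially train the unconditional mask generator ``G_m``.

    *masks* is a collection of H×W binary arrays.  Returns the trained
    generator (outputs thresholded at 0.5 when sampling) and the per-step
    generator/discriminator loss history.  Deterministic per
    ``config.seed``.
    """
    masks = np.asarray(masks, dtype=float)
    if masks.ndim != 3 or masks.shape[0] < 1:
        raise ValueError("need at least one H x W mask")
    if masks.shape[1] != config.image_size or masks.shape[2] != config.image_size:
        raise ValueError(f"masks must be {config.image_size} px square")
    rng = np.random.default_rng(derive_seed(config.seed, "mask-gan"))
    gen = MaskGenerator(config.image_size, config.latent_dim, config.width, rng)
    disc = Discriminator(config.image_size, 1, config.width, rng)
    opt_g = Adam(gen.params(), lr=config.learning_rate, betas=config.betas)
    opt_d = Adam(disc.params(), lr=config.learning_rate, betas=config.betas)
    real_all = masks[:, None]  # (n, 1, H, W)
    history = []
    for step in range(config.steps):
        idx = rng.integers(len(masks), size=config.batch_size)
        real = real_all[idx]
        z = rng.standard_normal((config.batch_size, config.latent_dim))
        fake = gen.forward(z, train=True)
        # --- discriminator update
        opt_d.zero_grad()
        loss_r, g_r = bce_with_logits(disc.forward(real, train=True), 1.0)
        disc.backward(g_r)
        loss_f, g_f = bce_with_logits(disc.forward(fake, train=True), 0.0)
        disc.backward(g_f)
        opt_d.step()
        # --- generator update (non-saturating loss)
        opt_g.zero_grad()
        opt_d.zero_grad()
        loss_g, g_g = bce_with_logits(disc.forward(fake, train=True), 1.0)
        d_fake = disc.backward(g_g)
        gen.root.backward(d_fake)
        opt_g.step()
        opt_d.zero_grad()
        d_loss = loss_r + loss_f
        _check_finite(step, d_loss=d_loss, g_loss=loss_g)
        history.append({"step": step, "d_loss": d_loss, "g_loss": loss_g})
    gen.trained = True  # type: ignore[attr-defined]
    return gen, pd.DataFrame(history)


def train_image_gan(
    samples: DatasetManifest, config: GanConfig
) -> tuple[ImageGenerator, pd.DataFrame]:
    """Adversarially train the conditional image generator ``G_s``.

    Every training sample must carry a mask and a one-hot label; the
    discriminator is conditioned on ``(image, mask, class vector)`` via
    channel concatenation.  Interpolated class vectors are *never* seen
    during training.
    """
    if len(samples) < 1:
        raise ValueError("empty training manifest")
    for s in samples:
        if s.mask is None:
            raise ValueError("every image-GAN training sample needs a mask")
        if not is_one_hot(s.label):
            raise ValueError("image-GAN training labels must be one-hot")
    images = samples.pixels()[:, None]
    masks = np.stack([s.mask for s in samples]).astype(float)[:, None]
    labels = samples.labels()
    size = config.image_size
    if images.shape[-1] != size:
        raise ValueError(f"images must be {size} px square")
    rng = np.random.default_rng(derive_seed(config.seed, "image-gan"))
    gen = ImageGenerator(size, config.latent_dim, labels.shape[1], config.width, rng)
    disc = Discriminator(size, 1 + 1 + labels.shape[1], config.width, rng)
    opt_g = Adam(gen.params(), lr=config.learning_rate, betas=config.betas)
    opt_d = Adam(disc.params(), lr=config.learning_rate, betas=config.betas)

    def cond_input(img, msk, w):
        n, _, h, w_ = img.shape
        w_maps = np.broadcast_to(w[:, :, None, None], (n, w.shape[1], h, w_))
        return np.concatenate([img, msk, w_maps], axis=1)

    history = []
    for step in range(config.steps):
        idx = rng.integers(len(samples), size=config.batch_size)
        img, msk, w = images[idx], masks[idx], labels[idx]
        z = rng.standard_normal((config.batch_size, config.latent_dim))
        fake = gen.forward(msk, w, z, train=True)
        opt_d.zero_grad()
        loss_r, g_r = bce_with_logits(disc.forward(cond_input(img, msk, w), train=True), 1.0)
        disc.backward(g_r)
        loss_f, g_f = bce_with_logits(disc.forward(cond_input(fake, msk, w), train=True), 0.0)
        disc.backward(g_f)
        opt_d.step()
        opt_g.zero_grad()
        opt_d.zero_grad()
        loss_g, g_g = bce_with_logits(disc.forward(cond_input(fake, msk, w), train=True), 1.0)
        d_in = disc.backward(g_g)
        gen.backward(d_in[:, :1])  # image channel only; mask and class are inputs
        opt_g.step()
        opt_d.zero_grad()
        d_loss = loss_r + loss_f
        _check_finite(step, d_loss=d_loss, g_loss=loss_g)
        history.append({"step": step, "d_loss": d_loss, "g_loss": loss_g})
    gen.trained = True  # type: ignore[attr-defined]
    return gen, pd.DataFrame(history)


# -------------------------------------------------------- weight interpolation


def pair_beta_means(proportions: Sequence[float]) -> dict[tuple[int, int], float]:
    """Per-pair Beta means solving the proportion-matching linear system.

    With the three unordered class pairs chosen uniformly, the expected
    weight of class *c* over many draws is the average of its means across
    the two pairs containing it.  Requiring ``E[w] = proportions`` gives
    three equations for three means; the remaining degree of freedom is
    closed symmetrically (``mu_nb = mu_nm``), which for proportions
    (0.17, 0.56, 0.27) yields means (0.255, 0.255, 0.935).
    """
    p = as_weights(proportions)
    if np.any(p <= 0):
        raise ValueError("proportions must be strictly positive")
    mu_nb = mu_nm = 1.5 * p[0]
    mu_bm = 3.0 * p[1] - 1.0 + mu_nb
    mus = {(0, 1): mu_nb, (0, 2): mu_nm, (1, 2): mu_bm}
    for pair, mu in mus.items():
        if not 0.0 < mu < 1.0:
            raise ValueError(
                f"infeasible Beta mean {mu:.3f} for class pair {pair} under proportions "
                f"{tuple(p)}; reconfigure the pair probabilities"
            )
    return mus


def sample_interpolated_weights(
    proportions: Sequence[float],
    rng: np.random.Generator,
    concentration: float = 2.0,
) -> np.ndarray:
    """Draw one 2-sparse class-weight vector whose per-class expectation matches *proportions*.

    A class pair is chosen uniformly; given pair ``(i, j)`` the weight of
    class *i* is drawn from ``Beta(kappa * mu, kappa * (1 - mu))`` (mean
    ``mu`` from :func:`pair_beta_means`, concentration ``kappa``), clamped
    away from {0, 1} so both entries stay strictly positive.
    """
    mus = pair_beta_means(proportions)
    i, j = CLASS_PAIRS[int(rng.integers(len(CLASS_PAIRS)))]
    mu = mus[(i, j)]
    w_i = rng.beta(concentration * mu, concentration * (1.0 - mu))
    w_i = float(np.clip(w_i, *WEIGHT_CLAMP))
    out = np.zeros(3)
    out[i] = w_i
    out[j] = 1.0 - w_i
    return out


# ----------------------------------------------------------------- synthesis


def synthesize_image(
    g_m: MaskGenerator,
    g_s: ImageGenerator,
    weights: Sequence[float],
    rng: np.random.Generator,
) -> ImageSample:
    """Draw a mask from ``G_m``, a noise vector, and emit ``G_s(mask, weights, z)``.

    The class vector becomes the ground-truth label exactly; one-hot
    vectors are tagged ``dreamoff``, interpolated ones ``dreamon``.
    """
    for g in (g_m, g_s):
        if not getattr(g, "trained", False):
            raise ValueError("generator handles must be trained before synthesis")
    weights = as_weights(weights)
    mask = g_m.sample(rng, 1)
    z = rng.standard_normal((1, g_s.latent_dim))
    img = g_s.forward(mask[:, None].astype(float), weights[None], z, train=False)[0, 0]
    return ImageSample(
        pixels=np.clip(img, 0.0, 1.0),
        label=weights,
        mask=mask[0],
        source="dreamoff" if is_one_hot(weights) else "dreamon",
    )


def generate_dreamon_set(
    g_m: MaskGenerator,
    g_s: ImageGenerator,
    n: int,
    proportions: Sequence[float],
    seed: int = 0,
    mean_tolerance: float = 0.02,
    max_attempts: int = 10,
    concentration: float = 2.0,
) -> DatasetManifest:
    """Synthesize *n* DreamOn samples with dataset-mean weights matching *proportions*.

    The weight list is resampled (up to *max_attempts* times) until every
    per-class column mean is within tolerance of the target before any
    image is rendered.  *mean_tolerance* is defined at the reference
    dataset size of 600 and widens as ``sqrt(600 / n)`` for smaller sets,
    where sampling noise makes the fixed band unattainable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    target = as_weights(proportions)
    tol = mean_tolerance * max(1.0, np.sqrt(REFERENCE_SET_SIZE / n))
    rng = np.random.default_rng(derive_seed(seed, "dreamon-weights"))
    weights = None
    for _ in range(max_attempts):
        cand = np.stack(
            [sample_interpolated_weights(target, rng, concentration) for _ in range(n)]
        )
        achieved = cand.mean(axis=0)
        if np.all(np.abs(achieved - target) < tol):
            weights = cand
            break
    if weights is None:
        raise RuntimeError(
            f"dataset-mean weight matching failed after {max_attempts} attempts "
            f"(last achieved means {achieved.round(4).tolist()}, target {target.tolist()})"
        )
    render_rng = np.random.default_rng(derive_seed(seed, "dreamon-render"))
    samples = [synthesize_image(g_m, g_s, w, render_rng) for w in weights]
    return DatasetManifest(samples, split="generated")


def generate_dreamoff_set(
    g_m: MaskGenerator,
    g_s: ImageGenerator,
    n: int,
    proportions: Sequence[float],
    seed: int = 0,
) -> DatasetManifest:
    """Synthesize *n* one-hot-labelled control samples at the dataset proportions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = largest_remainder_counts(n, proportions)
    classes = np.repeat(np.arange(len(counts)), counts)
    order = np.random.default_rng(derive_seed(seed, "dreamoff-order")).permutation(n)
    render_rng = np.random.default_rng(derive_seed(seed, "dreamoff-render"))
    samples = [synthesize_image(g_m, g_s, one_hot(int(c)), render_rng) for c in classes[order]]
    return DatasetManifest(samples, split="generated")
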