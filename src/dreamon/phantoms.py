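"""Synthetic breast-ultrasound-like phantom datasets.

Generates speckle-textured grayscale images in three classes mimicking the
structure of public breast-ultrasound collections: *normal* (texture only,
blank lesion mask), *benign* (one smooth dark ellipse, mask = ellipse) and
*malignant* (one irregular jagged dark region with an acoustic-shadow
column beneath it, mask = region).  Class counts follow largest-remainder
apportionment of the configured proportions — (0.17, 0.56, 0.27) by
default, which at n = 780 yields (133, 437, 210).

No attempt is made at physical ultrasound simulation (no beamforming or
attenuation model); the phantoms exist to give every downstream stage a
learnable class signal and realistic binary mask shapes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from sklearn.model_selection import train_test_split

from .data import (
    DatasetManifest,
    ImageSample,
    as_weights,
    largest_remainder_counts,
    one_hot,
)
from .seeds import derive_seed

NORMAL, BENIGN, MALIGNANT = 0, 1, 2

#: default class proportions of the emulated dataset (normal, benign, malignant)
DEFAULT_PROPORTIONS = (0.17, 0.56, 0.27)


@dataclasses.dataclass
class PhantomSpec:
    """Configuration for one phantom dataset.

    Parameters
    ----------
    n_images:
        Number of samples to generate (>= 1).
    image_size:
        Side length in pixels of the square images (>= 16).
    class_proportions:
        Target class mix on the simplex; defaults to (0.17, 0.56, 0.27).
    speckle_contrast:
        Amplitude of the multiplicative speckle texture, in [0, 1].
    lesion_size_range:
        (min, max) lesion radius as a fraction of the image side.
    seed:
        Master seed; generation is a pure function of the spec.
    """

    n_images: int = 780
    image_size: int = 128
    class_proportions: Sequence[float] = DEFAULT_PROPORTIONS
    speckle_contrast: float = 0.35
    lesion_size_range: tuple[float, float] = (0.12, 0.28)
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_proportions = as_weights(self.class_proportions, atol=1e-9)
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not 0 <= self.speckle_contrast <= 1:
            raise ValueError("speckle_contrast must lie in [0, 1]")
        lo, hi = self.lesion_size_range
        if not 0 < lo <= hi < 0.5:
            raise ValueError("lesion_size_range fractions must satisfy 0 < lo <= hi < 0.5")
        if lo * self.image_size < 2:
            raise ValueError(
                f"image_size {self.image_size} too small to place the minimum lesion "
                f"(needs radius >= 2 px)"
            )


def _speckle_background(size: int, contrast: float, rng: np.random.Generator) -> np.ndarray:
    """Low-pass-filtered multiplicative noise over a mid-gray base."""
    base = 0.45 + 0.05 * rng.standard_normal()
    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=1.2)
    field = field / (np.abs(field).max() + 1e-12)
    img = base * (1.0 + contrast * field)
    return np.clip(img, 0.0, 1.0)


def _lesion_geometry(spec: PhantomSpec, rng: np.random.Generator) -> tuple[float, float, float]:
    size = spec.image_size
    lo, hi = spec.lesion_size_range
    radius = rng.uniform(lo, hi) * size
    margin = radius + 2
    cy = rng.uniform(margin, size * 0.7)  # keep room for the shadow below
    cx = rng.uniform(margin, size - margin)
    return cy, cx, radius


def _benign_sample(spec: PhantomSpec, rng: np.random.Generator) -> ImageSample:
    img = _speckle_background(spec.image_size, spec.speckle_contrast, rng)
    cy, cx, r = _lesion_geometry(spec, rng)
    ry, rx = r * rng.uniform(0.8, 1.0), r * rng.uniform(0.8, 1.0)
    rr, cc = skdraw.ellipse(cy, cx, ry, rx, shape=img.shape, rotation=rng.uniform(0, np.pi))
    mask = np.zeros(img.shape, dtype=np.uint8)
    mask[rr, cc] = 1
    # smooth hypoechoic interior: soften the edge before darkening
    soft = ndimage.gaussian_filter(mask.astype(float), sigma=1.0)
    img = img * (1.0 - 0.55 * soft)
    return ImageSample(np.clip(img, 0, 1), one_hot(BENIGN), mask=mask, source="original")


def _malignant_sample(spec: PhantomSpec, rng: np.random.Generator) -> ImageSample:
    img = _speckle_background(spec.image_size, spec.speckle_contrast, rng)
    cy, cx, r = _lesion_geometry(spec, rng)
    n_vert = 14
    angles = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
    radii = r * (1.0 + 0.4 * rng.uniform(-1, 1, size=n_vert))
    radii = np.clip(radii, 2.0, None)
    rr, cc = skdraw.polygon(cy + radii * np.sin(angles), cx + radii * np.cos(angles), shape=img.shape)
    mask = np.zeros(img.shape, dtype=np.uint8)
    mask[rr, cc] = 1
    img = img * (1.0 - 0.7 * mask)
    # posterior acoustic shadow: darken the column beneath the lesion
    cols = np.where(mask.any(axis=0))[0]
    bottom = int(np.where(mask.any(axis=1))[0].max())
    if bottom + 1 < img.shape[0] and cols.size:
        shade = np.ones(img.shape)
        shade[bottom + 1 :, cols] = 0.55
        img = img * shade
    return ImageSample(np.clip(img, 0, 1), one_hot(MALIGNANT), mask=mask, source="original")


def _normal_sample(spec: PhantomSpec, rng: np.random.Generator) -> ImageSample:
    img = _speckle_background(spec.image_size, spec.speckle_contrast, rng)
    mask = np.zeros(img.shape, dtype=np.uint8)
    return ImageSample(img, one_hot(NORMAL), mask=mask, source="original")


_MAKERS = {NORMAL: _normal_sample, BENIGN: _benign_sample, MALIGNANT: _malignant_sample}


def generate_phantom_dataset(spec: PhantomSpec) -> DatasetManifest:
    """Generate ``spec.n_images`` one-hot-labelled phantom samples.

    Per-class counts are the largest-remainder apportionment of
    ``n_images × class_proportions``; samples are emitted in interleaved
    deterministic order and each image is a pure function of
    ``(spec.seed, index)``.
    """
    counts = largest_remainder_counts(spec.n_images, spec.class_proportions)
    classes = np.repeat(np.arange(len(counts)), counts)
    # deterministic shuffle so classes are interleaved in the manifest
    order = np.random.default_rng(derive_seed(spec.seed, "phantom-order")).permutation(len(classes))
    samples = []
    for idx, cls in enumerate(classes[order]):
        rng = np.random.default_rng(derive_seed(spec.seed, "phantom", idx))
        sample = _MAKERS[int(cls)](spec, rng)
        sample.path = f"phantom_{idx:05d}.png"  # stable identity across splits/copies
        samples.append(sample)
    return DatasetManifest(samples, split="all")


def split_dataset(
    manifest: DatasetManifest,
    sizes: tuple[int, int, int],
    seed: int = 0,
    stratified: bool = True,
) -> tuple[DatasetManifest, DatasetManifest, DatasetManifest]:
    """Split a manifest into disjoint, exhaustive train/test/validation sets.

    With ``stratified=True`` (the default) per-class proportions in every
    split match the whole manifest within rounding.  Deterministic per seed.
    """
    n_train, n_test, n_val = sizes
    if min(sizes) < 0:
        raise ValueError("split sizes must be non-negative")
    if n_train + n_test + n_val != len(manifest):
        raise ValueError(
            f"split sizes {sizes} must sum to the manifest length {len(manifest)}"
        )
    indices = np.arange(len(manifest))
    strata = manifest.dominant_classes() if stratified else None
    if stratified:
        present = np.bincount(strata, minlength=1)
        n_nonempty_splits = sum(1 for s in sizes if s > 0)
        if np.any((present > 0) & (present < n_nonempty_splits)):
            raise ValueError(
                "stratified split requires at least as many samples per class as "
                "non-empty splits"
            )

    def _take(pool: np.ndarray, k: int, stage: str) -> tuple[np.ndarray, np.ndarray]:
        if k == 0:
            return np.array([], dtype=int), pool
        if k == len(pool):
            return pool, np.array([], dtype=int)
        taken, rest = train_test_split(
            pool,
            train_size=k,
            random_state=derive_seed(seed, "split", stage) % (2**32),
            stratify=strata[pool] if stratified else None,
        )
        return np.sort(taken), np.sort(rest)

    train_idx, rest = _take(indices, n_train, "train")
    test_idx, val_idx = _take(rest, n_test, "test")
    return (
        manifest.subset(train_idx, split="train"),
        manifest.subset(test_idx, split="test"),
        manifest.subset(val_idx, split="val"),
    )
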