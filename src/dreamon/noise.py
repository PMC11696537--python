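"""Parametric test-time noise: families, the doubling intensity ladder, and calibration.

Three noise families model common ultrasound distortions:

* ``gaussian`` — additive i.i.d. zero-mean normal noise (electronic interference),
* ``speckle``  — multiplicative granular noise, ``pixel + pixel * n`` with
  ``n ~ Normal(0, intensity^2)`` (coherent-imaging speckle),
* ``salt_pepper`` — impulse noise flipping random pixels to 0 or 1
  (transmission errors).

Intensities form a geometric ladder: level 0 is the clean condition and
``intensity(k) = base * 2**(k-1)`` for levels ``k >= 1``, i.e. each step up
doubles the noise.  The top level can be calibrated so a reference model
drops to chance accuracy (~1/3 for three balanced classes).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import DatasetManifest, ImageSample
from .seeds import derive_seed

FAMILIES = ("gaussian", "speckle", "salt_pepper")

#: defaults chosen so level 6 is severely degraded on [0,1] imagery
DEFAULT_BASE_INTENSITY = {"gaussian": 0.02, "speckle": 0.05, "salt_pepper": 0.005}


@dataclasses.dataclass
class NoiseSpec:
    """One noise family with its base intensity and ladder depth."""

    family: str
    base_intensity: float | None = None
    n_levels: int = 6

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}; expected one of {FAMILIES}")
        if self.base_intensity is None:
            self.base_intensity = DEFAULT_BASE_INTENSITY[self.family]
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be > 0")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.family == "salt_pepper" and self.base_intensity * 2 ** (self.n_levels - 1) > 1:
            raise ValueError(
                "salt_pepper corruption density at the top level exceeds 1; lower base_intensity"
            )


def intensity_for_level(spec: NoiseSpec, level: int) -> float:
    """Noise intensity at a ladder level: 0 at level 0, ``base * 2**(level-1)`` above."""
    if not 0 <= level <= spec.n_levels:
        raise ValueError(f"level {level} out of range 0..{spec.n_levels}")
    if level == 0:
        return 0.0
    return spec.base_intensity * 2 ** (level - 1)


def apply_noise(image: ImageSample, family: str, intensity: float, seed: int) -> ImageSample:
    """Corrupt one image; label and mask pass through unchanged."""
    if family not in FAMILIES:
        raise ValueError(f"unknown noise family {family!r}")
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    if family == "salt_pepper" and intensity > 1:
        raise ValueError("salt_pepper intensity is a pixel-corruption density and must be <= 1")
    out = image.copy()
    if intensity == 0:
        return out
    rng = np.random.default_rng(seed)
    x = out.pixels
    if family == "gaussian":
        x = x + rng.normal(0.0, intensity, size=x.shape)
    elif family == "speckle":
        x = x + x * rng.normal(0.0, intensity, size=x.shape)
    else:  # salt_pepper
        corrupt = rng.random(x.shape) < intensity
        salt = rng.random(x.shape) < 0.5
        x = np.where(corrupt, np.where(salt, 1.0, 0.0), x)
    out.pixels = np.clip(x, 0.0, 1.0)
    return out


def build_noise_test_sets(
    test_manifest: DatasetManifest,
    specs: list[NoiseSpec],
    seed: int = 0,
) -> dict[tuple[str, int], DatasetManifest]:
    """Materialize one corrupted copy of the test set per (family, level).

    Level 0 is the shared clean set (the same manifest object for every
    family).  Per-image seeds are derived deterministically from
    ``(seed, family, level, image index)``.
    """
    if len(test_manifest) == 0:
        raise ValueError("test manifest must be non-empty")
    out: dict[tuple[str, int], DatasetManifest] = {}
    clean = DatasetManifest([s.copy() for s in test_manifest], split=test_manifest.split)
    for spec in specs:
        out[(spec.family, 0)] = clean
        for level in range(1, spec.n_levels + 1):
            intensity = intensity_for_level(spec, level)
            samples = [
                apply_noise(s, spec.family, intensity, derive_seed(seed, spec.family, level, i))
                for i, s in enumerate(test_manifest)
            ]
            out[(spec.family, level)] = DatasetManifest(samples, split=test_manifest.split)
    if not specs:
        out[("clean", 0)] = clean
    return out


class CalibrationError(RuntimeError):
    """Chance band unreachable within the search bounds."""

    def __init__(self, message: str, closest_accuracy: float, closest_intensity: float):
        super().__init__(message)
        self.closest_accuracy = closest_accuracy
        self.closest_intensity = closest_intensity


def bisect_base_intensity(
    accuracy_at_base,
    chance_band: tuple[float, float],
    bounds: tuple[float, float] = (1e-4, 1.0),
    max_iter: int = 20,
    tol: float = 1e-3,
) -> tuple[float, float]:
    """Find a base intensity whose top-level accuracy falls inside *chance_band*.

    ``accuracy_at_base`` maps a base intensity to the accuracy of a reference
    model at the top ladder level; it is assumed non-increasing.  Returns
    ``(base_intensity, achieved_accuracy)``.
    """
    low, high = chance_band
    if not low < 1 / 3 < high:
        raise ValueError(f"chance_band {chance_band} must contain 1/3")
    lo, hi = bounds
    acc_lo = accuracy_at_base(lo)
    if acc_lo <= high:
        # already at or below chance at the weakest noise: nothing to search
        return lo, acc_lo
    acc_hi = accuracy_at_base(hi)
    if acc_hi > high:
        raise CalibrationError(
            f"accuracy {acc_hi:.3f} at the upper search bound still above the chance band",
            closest_accuracy=acc_hi,
            closest_intensity=hi,
        )
    closest = (acc_hi, hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        acc = accuracy_at_base(mid)
        if low <= acc <= high:
            return mid, acc
        if abs(acc - 1 / 3) < abs(closest[0] - 1 / 3):
            closest = (acc, mid)
        if acc > high:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    acc = accuracy_at_base(hi)
    if low <= acc <= high:
        return hi, acc
    raise CalibrationError(
        f"no base intensity inside the chance band after {max_iter} bisection steps "
        f"(closest accuracy {closest[0]:.3f})",
        closest_accuracy=closest[0],
        closest_intensity=closest[1],
    )


def calibrate_base_intensity(
    reference_model,
    clean_test: DatasetManifest,
    family: str,
    chance_band: tuple[float, float] = (0.28, 0.39),
    seed: int = 0,
    n_levels: int = 6,
    bounds: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Calibrate a family's base intensity so the top level sits at chance accuracy.

    Bisects the base intensity until the reference model's balanced accuracy
    on the test set corrupted at level ``n_levels`` lands inside
    *chance_band*.  Returns ``(base_intensity, achieved_balanced_accuracy)``.
    """
    from .evaluate import balanced_accuracy

    if bounds is None:
        bounds = (1e-4, 1.0 / 2 ** (n_levels - 1)) if family == "salt_pepper" else (1e-4, 1.0)
    truth = clean_test.dominant_classes()

    def accuracy_at_base(base: float) -> float:
        intensity = base * 2 ** (n_levels - 1)
        noisy = DatasetManifest(
            [
                apply_noise(s, family, intensity, derive_seed(seed, "calib", family, i))
                for i, s in enumerate(clean_test)
            ],
            split=clean_test.split,
        )
        probs = reference_model.predict(noisy)
        return balanced_accuracy(truth, probs)

    return bisect_base_intensity(accuracy_at_base, chance_band, bounds=bounds)
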