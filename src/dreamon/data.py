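"""Core in-memory containers: image samples, class-weight vectors, dataset manifests.

A dataset is a :class:`DatasetManifest` — an ordered collection of
:class:`ImageSample` records, each a grayscale image in ``[0, 1]`` with a
soft class-weight label on the 3-class probability simplex
(normal / benign / malignant), an optional binary lesion mask and a
provenance tag.  Manifests round-trip to a ``manifest.csv`` plus 8-bit PNG
(or lossless NPZ) image files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image

CLASSES = ("normal", "benign", "malignant")
N_CLASSES = len(CLASSES)

#: allowed provenance tags for a sample
SOURCES = ("original", "sda", "pixel_mixup", "manifold_flag", "dreamon", "dreamoff")

MANIFEST_COLUMNS = [
    "path",
    "mask_path",
    "split",
    "w_normal",
    "w_benign",
    "w_malignant",
    "source",
    "parents",
]


def as_weights(w: Sequence[float], *, atol: float = 1e-6) -> np.ndarray:
    """Validate and return a class-weight vector on the 3-class simplex."""
    arr = np.asarray(w, dtype=float)
    if arr.shape != (N_CLASSES,):
        raise ValueError(f"class-weight vector must have length {N_CLASSES}, got shape {arr.shape}")
    if np.any(arr < -atol):
        raise ValueError(f"class weights must be non-negative, got {arr}")
    if abs(arr.sum() - 1.0) > atol:
        raise ValueError(f"class weights must sum to 1, got sum {arr.sum()!r}")
    return np.clip(arr, 0.0, None)


def one_hot(class_index: int) -> np.ndarray:
    v = np.zeros(N_CLASSES)
    v[class_index] = 1.0
    return v


def is_one_hot(w: Sequence[float], *, atol: float = 1e-9) -> bool:
    arr = np.asarray(w, dtype=float)
    return int(np.sum(arr > atol)) == 1


def is_two_sparse(w: Sequence[float], *, atol: float = 1e-9) -> bool:
    arr = np.asarray(w, dtype=float)
    return int(np.sum(arr > atol)) == 2


def dominant_class(w: Sequence[float]) -> int:
    """Index of the largest class weight (ties broken toward lower index)."""
    return int(np.argmax(np.asarray(w, dtype=float)))


@dataclasses.dataclass
class ImageSample:
    """One grayscale image with a soft label, optional binary mask and provenance."""

    pixels: np.ndarray
    label: np.ndarray
    mask: np.ndarray | None = None
    source: str = "original"
    path: str | None = None
    mask_path: str | None = None
    parents: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        self.label = as_weights(self.label)
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask shape must match pixels")
            uniq = np.unique(self.mask)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be binary {0, 1}")
            self.mask = self.mask.astype(np.uint8)
        if self.source not in SOURCES:
            raise ValueError(f"unknown source tag {self.source!r}; expected one of {SOURCES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy(self) -> "ImageSample":
        return ImageSample(
            pixels=self.pixels.copy(),
            label=self.label.copy(),
            mask=None if self.mask is None else self.mask.copy(),
            source=self.source,
            path=self.path,
            mask_path=self.mask_path,
            parents=self.parents,
        )


class DatasetManifest:
    """Ordered record set defining a training / test / validation dataset."""

    def __init__(self, samples: Iterable[ImageSample], split: str = "all"):
        self.samples: list[ImageSample] = list(samples)
        self.split = split

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[ImageSample]:
        return iter(self.samples)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return DatasetManifest(self.samples[i], split=self.split)
        return self.samples[i]

    def labels(self) -> np.ndarray:
        """(n, 3) array of class-weight labels, manifest order."""
        return np.stack([s.label for s in self.samples])

    def pixels(self) -> np.ndarray:
        """(n, H, W) stacked image array; requires uniform shapes."""
        return np.stack([s.pixels for s in self.samples])

    def dominant_classes(self) -> np.ndarray:
        return np.array([dominant_class(s.label) for s in self.samples], dtype=int)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.dominant_classes(), minlength=N_CLASSES)

    def subset(self, indices: Sequence[int], split: str | None = None) -> "DatasetManifest":
        return DatasetManifest(
            [self.samples[int(i)] for i in indices],
            split=self.split if split is None else split,
        )

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.samples):
            rows.append(
                {
                    "path": s.path if s.path is not None else f"img_{i:05d}",
                    "mask_path": s.mask_path if s.mask_path is not None else "",
                    "split": self.split,
                    "w_normal": s.label[0],
                    "w_benign": s.label[1],
                    "w_malignant": s.label[2],
                    "source": s.source,
                    "parents": ";".join(s.parents) if s.parents else "",
                }
            )
        return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    def save(self, out_dir: str | Path, fmt: str = "png") -> Path:
        """Materialize images (+ masks) and a ``manifest.csv`` under *out_dir*.

        ``fmt='png'`` writes 8-bit grayscale PNGs (masks as {0, 255});
        ``fmt='npz'`` stores the float arrays losslessly.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, s in enumerate(self.samples):
            stem = f"{self.split}_{i:05d}"
            if fmt == "png":
                img_name = f"{stem}.png"
                Image.fromarray(
                    np.round(np.clip(s.pixels, 0, 1) * 255).astype(np.uint8)
                ).save(out / img_name)
                mask_name = ""
                if s.mask is not None:
                    mask_name = f"{stem}_mask.png"
                    Image.fromarray((s.mask * 255).astype(np.uint8)).save(out / mask_name)
            elif fmt == "npz":
                img_name = f"{stem}.npz"
                payload = {"pixels": s.pixels}
                mask_name = ""
                if s.mask is not None:
                    payload["mask"] = s.mask
                    mask_name = img_name
                np.savez(out / img_name, **payload)
            else:
                raise ValueError(f"unknown format {fmt!r}")
            rows.append(
                {
                    "path": img_name,
                    "mask_path": mask_name,
                    "split": self.split,
                    "w_normal": s.label[0],
                    "w_benign": s.label[1],
                    "w_malignant": s.label[2],
                    "source": s.source,
                    "parents": ";".join(s.parents) if s.parents else "",
                }
            )
        frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
        frame.to_csv(out / "manifest.csv", index=False)
        return out / "manifest.csv"

    @classmethod
    def load(cls, manifest_csv: str | Path) -> "DatasetManifest":
        manifest_csv = Path(manifest_csv)
        base = manifest_csv.parent
        frame = pd.read_csv(manifest_csv, keep_default_na=False)
        samples = []
        for _, row in frame.iterrows():
            path = base / str(row["path"])
            if path.suffix == ".npz":
                with np.load(path) as z:
                    pixels = z["pixels"]
                    mask = z["mask"] if "mask" in z and row["mask_path"] else None
            else:
                pixels = np.asarray(Image.open(path), dtype=float) / 255.0
                mask = None
                if row["mask_path"]:
                    mask = (np.asarray(Image.open(base / str(row["mask_path"]))) > 127).astype(
                        np.uint8
                    )
            parents = tuple(str(row["parents"]).split(";")) if row["parents"] else None
            samples.append(
                ImageSample(
                    pixels=pixels,
                    label=[row["w_normal"], row["w_benign"], row["w_malignant"]],
                    mask=mask,
                    source=str(row["source"]),
                    path=str(row["path"]),
                    mask_path=str(row["mask_path"]) or None,
                    parents=parents,  # type: ignore[arg-type]
                )
            )
        split = str(frame["split"].iloc[0]) if len(frame) else "all"
        return cls(samples, split=split)


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Apportion *n* units to classes by the largest-remainder (Hamilton) method.

    Ties on the fractional remainder are broken toward the lower class index,
    which reproduces the reference per-class counts (133, 437, 210) at
    n = 780 with proportions (0.17, 0.56, 0.27).
    """
    p = as_weights(proportions)
    quotas = n * p
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    # stable sort => lower index wins remainder ties
    order = np.argsort(-(quotas - counts), kind="stable")
    for k in range(remainder):
        counts[order[k]] += 1
    return counts
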