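"""Classifier training and multi-run robustness experiments.

The downstream model is a residual CNN trained from random initialization
with Adam and soft-target cross-entropy (epochs 100, batch size 20,
learning rate 1e-3, betas 0.9/0.999 by default, no schedule and no early
stopping).  After each epoch the balanced accuracy on the (one-hot
labelled) validation split is computed and the best checkpoint — earliest
epoch on ties — is the model used for testing.  Experiments repeat
training over several runs and evaluate every (noise family, level) test
condition.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .augment import MixupConfig, SDAConfig, build_training_dataset, manifold_mixup_step
from .data import DatasetManifest, largest_remainder_counts
from .dreamgan import GanConfig, generate_dreamoff_set, generate_dreamon_set, train_image_gan, train_mask_gan
from .evaluate import RobustnessReport, aggregate_report, balanced_accuracy, expected_calibration_error
from .nn import Adam, build_classifier, softmax, softmax_cross_entropy
from .nn.models import ResNetClassifier
from .noise import NoiseSpec, build_noise_test_sets
from .phantoms import PhantomSpec, generate_phantom_dataset, split_dataset
from .seeds import derive_seed


@dataclasses.dataclass
class TrainConfig:
    """Classifier training hyperparameters."""

    epochs: int = 100
    batch_size: int = 20
    learning_rate: float = 0.001
    adam_betas: tuple[float, float] = (0.9, 0.999)
    runs: int = 5
    seed: int = 0
    arch_scale: str = "full"
    mixup_alpha: float = 0.8

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.runs) < 1:
            raise ValueError("epochs, batch_size and runs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        b1, b2 = self.adam_betas
        if not (0 < b1 < 1 and 0 < b2 < 1):
            raise ValueError("adam_betas must lie in (0, 1)")
        if self.arch_scale not in ("full", "tiny"):
            raise ValueError("arch_scale must be 'full' or 'tiny'")


def _prepare(pixels: np.ndarray) -> np.ndarray:
    """Per-image min-max scaling, then centering to [-1, 1]; adds the channel axis."""
    x = pixels.astype(float)
    lo = x.min(axis=(1, 2), keepdims=True)
    span = x.max(axis=(1, 2), keepdims=True) - lo
    x = (x - lo) / np.maximum(span, 1e-8)
    return (x - 0.5)[:, None] * 2.0


class TrainedClassifier:
    """A trained model (best validation checkpoint) with its training history."""

    def __init__(self, model: ResNetClassifier, history: pd.DataFrame, best_epoch: int):
        self.model = model
        self.history = history
        self.best_epoch = best_epoch

    @property
    def best_val_balanced_accuracy(self) -> float:
        return float(self.history["val_balanced_accuracy"].iloc[self.best_epoch])

    def predict(self, manifest: DatasetManifest, batch_size: int = 64) -> np.ndarray:
        return predict(self, manifest, batch_size=batch_size)


def predict(
    model: TrainedClassifier | ResNetClassifier,
    manifest: DatasetManifest,
    batch_size: int = 64,
) -> np.ndarray:
    """Softmax class probabilities for every sample, manifest order preserved."""
    net = model.model if isinstance(model, TrainedClassifier) else model
    x = _prepare(manifest.pixels())
    rows = []
    for start in range(0, len(x), batch_size):
        logits = net.forward(x[start : start + batch_size], train=False)
        rows.append(softmax(logits))
    return np.concatenate(rows, axis=0)


def train_classifier(
    train: DatasetManifest,
    val: DatasetManifest,
    config: TrainConfig,
) -> TrainedClassifier:
    """Train a classifier and return the best-validation-epoch checkpoint.

    Records flagged ``manifold_flag`` are trained through mixed-hidden-state
    batches (representation mixing with the model's current weights, the
    mixing point drawn uniformly per batch from the eligible set: the raw
    input and each stage output); everything else uses plain soft-target
    cross-entropy batches.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("training and validation manifests must be non-empty")
    rng = np.random.default_rng(derive_seed(config.seed, "train"))
    model = build_classifier(config.arch_scale, train.labels().shape[1], rng)
    opt = Adam(model.params(), lr=config.learning_rate, betas=config.adam_betas)

    plain_idx = np.array([i for i, s in enumerate(train) if s.source != "manifold_flag"])
    mix_idx = np.array([i for i, s in enumerate(train) if s.source == "manifold_flag"])
    x_all = _prepare(train.pixels())
    y_all = train.labels()
    val_x = val.pixels()
    val_truth = val.dominant_classes()

    best_state = None
    best_acc = -np.inf
    best_epoch = -1
    history = []
    for epoch in range(config.epochs):
        epoch_losses = []
        order = rng.permutation(plain_idx) if len(plain_idx) else np.array([], dtype=int)
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            logits = model.forward(x_all[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_all[idx])
            model.root.backward(dlogits)
            opt.step()
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            epoch_losses.append(loss)
        if len(mix_idx):
            order_a = rng.permutation(mix_idx)
            order_b = rng.permutation(mix_idx)
            for start in range(0, len(order_a), config.batch_size):
                ia = order_a[start : start + config.batch_size]
                ib = order_b[start : start + config.batch_size]
                lam = float(rng.beta(config.mixup_alpha, config.mixup_alpha))
                layer = int(rng.integers(model.n_mix_points))
                opt.zero_grad()
                loss = manifold_mixup_step(
                    model, (x_all[ia], y_all[ia]), (x_all[ib], y_all[ib]), lam, layer
                )
                opt.step()
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite manifold-mixing loss at epoch {epoch}")
                epoch_losses.append(loss)
        val_probs = predict(model, val)
        val_acc = balanced_accuracy(val_truth, val_probs)
        history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(epoch_losses)) if epoch_losses else np.nan,
                "val_balanced_accuracy": val_acc,
            }
        )
        if val_acc > best_acc:  # strict: ties keep the earliest epoch
            best_acc = val_acc
            best_epoch = epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return TrainedClassifier(model, pd.DataFrame(history), best_epoch)


DREAM_STRATEGIES = ("dreamon", "dreamon_sda", "dreamoff")


def default_split_sizes(n: int) -> tuple[int, int, int]:
    """Scale the reference 600/90/90 split proportionally to *n* images."""
    sizes = largest_remainder_counts(n, (600 / 780, 90 / 780, 90 / 780))
    return int(sizes[0]), int(sizes[1]), int(sizes[2])


def run_experiment(
    strategies: Sequence[str],
    phantom_spec: PhantomSpec,
    noise_specs: Sequence[NoiseSpec],
    config: TrainConfig,
    gan_config: GanConfig | None = None,
    split_sizes: tuple[int, int, int] | None = None,
    sda_config: SDAConfig | None = None,
    mixup_config: MixupConfig | None = None,
    out_dir: str | Path | None = None,
) -> RobustnessReport:
    """Full benchmark: phantoms → (GANs) → strategy × run training → noise grid evaluation.

    Emits one metric cell (balanced accuracy + ECE) per
    (strategy, run, family, level); run seeds derive from ``config.seed``.
    Partial cells are flushed to ``out_dir/cells_partial.csv`` as runs
    finish so an interrupted experiment keeps its completed work.
    """
    phantoms = generate_phantom_dataset(phantom_spec)
    sizes = split_sizes or default_split_sizes(len(phantoms))
    train, test, val = split_dataset(phantoms, sizes, seed=derive_seed(config.seed, "split"))

    generated: dict[str, DatasetManifest] = {}
    if any(s in DREAM_STRATEGIES for s in strategies):
        gan_config = gan_config or GanConfig(image_size=phantom_spec.image_size)
        masks = np.stack([s.mask for s in train])
        g_m, _ = train_mask_gan(masks, gan_config)
        g_s, _ = train_image_gan(train, gan_config)
        dream_seed = derive_seed(config.seed, "dream-sets")
        if "dreamon" in strategies or "dreamon_sda" in strategies:
            on_set = generate_dreamon_set(
                g_m, g_s, len(train), phantom_spec.class_proportions, seed=dream_seed
            )
            generated["dreamon"] = on_set
            generated["dreamon_sda"] = on_set
        if "dreamoff" in strategies:
            generated["dreamoff"] = generate_dreamoff_set(
                g_m, g_s, len(train), phantom_spec.class_proportions, seed=dream_seed
            )

    noise_sets = build_noise_test_sets(test, list(noise_specs), seed=derive_seed(config.seed, "noise"))
    test_paths = {s.path for s in test}
    truth = test.dominant_classes()

    cells: list[dict] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for strategy, run in itertools.product(strategies, range(config.runs)):
        run_seed = derive_seed(config.seed, "run", strategy, run)
        training_set = build_training_dataset(
            strategy,
            train,
            generated=generated.get(strategy),
            seed=run_seed,
            sda_config=sda_config,
            mixup_config=mixup_config,
        )
        # train/test hygiene: no test-split image may leak into training
        overlap = {s.path for s in training_set if s.source == "original"} & test_paths
        assert not overlap, f"test images leaked into the {strategy} training set: {overlap}"
        run_config = dataclasses.replace(config, seed=run_seed)
        trained = train_classifier(training_set, val, run_config)
        for (family, level), manifest in sorted(noise_sets.items()):
            probs = trained.predict(manifest)
            cells.append(
                {
                    "strategy": strategy,
                    "run": run,
                    "family": family,
                    "level": level,
                    "balanced_accuracy": balanced_accuracy(truth, probs),
                    "ece": expected_calibration_error(probs, truth),
                }
            )
        if out_path is not None:
            pd.DataFrame(cells).to_csv(out_path / "cells_partial.csv", index=False)
    report = aggregate_report(cells, n_test=len(test))
    if out_path is not None:
        report.save(out_path)
    return report
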