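"""Network architectures: residual classifier and DCGAN-style generators/discriminators.

The classifier exposes its residual stages individually so hidden
representations can be mixed mid-forward (manifold mixing).  Generators
decode with nearest-neighbour upsampling followed by 3x3 convolutions —
the same DCGAN lineage as transposed convolution but with milder
checkerboard artifacts.  Model state (parameters plus batch-norm running
statistics) round-trips through NPZ checkpoints.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    Dense,
    Flatten,
    GlobalAvgPool,
    Layer,
    LeakyReLU,
    MaxPool2x2,
    Param,
    ReLU,
    Reshape,
    ResidualBlock,
    Sequential,
    Sigmoid,
    UpsampleNearest,
    iter_layers,
)


class Module:
    """A tree of layers with whole-model state save/restore."""

    root: Layer

    def params(self) -> list[Param]:
        return self.root.params

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params()):
            state[f"param_{i}"] = p.value.copy()
        for i, layer in enumerate(iter_layers(self.root)):
            if isinstance(layer, BatchNorm2d):
                state[f"bn_{i}_mean"] = layer.running_mean.copy()
                state[f"bn_{i}_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"param_{i}"]
        for i, layer in enumerate(iter_layers(self.root)):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"bn_{i}_mean"]
                layer.running_var[...] = state[f"bn_{i}_var"]

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path: str | Path) -> None:
        with np.load(path) as z:
            self.load_state_dict(dict(z))


# ------------------------------------------------------------------ classifier


class ResNetClassifier(Module):
    """Residual classifier with enumerable hidden mixing points.

    Mixing point 0 is the raw input; mixing point ``k`` (1-based) is the
    output of ``stages[k-1]``.  ``stages[0]`` is the convolutional stem;
    the remaining stages are residual.
    """

    def __init__(self, stages: list[Layer], head: Sequential):
        self.stages = stages
        self.head = head
        self.root = Sequential(list(stages) + [head])

    @property
    def n_mix_points(self) -> int:
        return len(self.stages) + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.root.forward(x, train=train)

    def forward_to(self, x: np.ndarray, mix_point: int, train: bool = True) -> np.ndarray:
        for stage in self.stages[:mix_point]:
            x = stage.forward(x, train=train)
        return x

    def forward_from(self, h: np.ndarray, mix_point: int, train: bool = True) -> np.ndarray:
        for stage in self.stages[mix_point:]:
            h = stage.forward(h, train=train)
        return self.head.forward(h, train=train)

    def backward_from(self, dlogits: np.ndarray, mix_point: int) -> np.ndarray:
        g = self.head.backward(dlogits)
        for stage in reversed(self.stages[mix_point:]):
            g = stage.backward(g)
        return g

    def backward_to(self, g: np.ndarray, mix_point: int) -> np.ndarray:
        for stage in reversed(self.stages[:mix_point]):
            g = stage.backward(g)
        return g


def build_classifier(
    arch_scale: str, n_classes: int, rng: np.random.Generator
) -> ResNetClassifier:
    """Build a classifier.

    ``arch_scale='full'`` is an 18-layer residual network (4 stages of 2
    basic blocks, widths 64/128/256/512); ``'tiny'`` is a reduced-depth
    variant (2 single-block stages, widths 16/32) for small inputs.
    """
    if arch_scale == "tiny":
        stem = Sequential([Conv2d(1, 8, 3, 1, 1, rng), BatchNorm2d(8), ReLU()])
        stages: list[Layer] = [
            stem,
            ResidualBlock(8, 16, 2, rng),
            ResidualBlock(16, 32, 2, rng),
        ]
        head = Sequential([GlobalAvgPool(), Dense(32, n_classes, rng)])
    elif arch_scale == "full":
        stem = Sequential(
            [Conv2d(1, 64, 7, 2, 3, rng), BatchNorm2d(64), ReLU(), MaxPool2x2()]
        )
        widths = (64, 128, 256, 512)
        stages = [stem]
        c_in = 64
        for i, c_out in enumerate(widths):
            stride = 1 if i == 0 else 2
            stages.append(
                Sequential(
                    [
                        ResidualBlock(c_in, c_out, stride, rng),
                        ResidualBlock(c_out, c_out, 1, rng),
                    ]
                )
            )
            c_in = c_out
        head = Sequential([GlobalAvgPool(), Dense(512, n_classes, rng)])
    else:
        raise ValueError(f"unknown arch_scale {arch_scale!r}; expected 'tiny' or 'full'")
    return ResNetClassifier(stages, head)


# ------------------------------------------------------------------------ GANs


def _n_ups(image_size: int) -> int:
    n = int(np.log2(image_size / 4))
    if 4 * 2**n != image_size or image_size < 16:
        raise ValueError("image_size must be a power of two >= 16")
    return n


class MaskGenerator(Module):
    """Unconditional generator of binary lesion masks."""

    def __init__(self, image_size: int, latent_dim: int, width: int, rng: np.random.Generator):
        n = _n_ups(image_size)
        c0 = width * 2 ** (n - 1)
        layers: list[Layer] = [Dense(latent_dim, c0 * 16, rng), Reshape((c0, 4, 4))]
        c = c0
        for _ in range(n):
            layers += [
                UpsampleNearest(),
                Conv2d(c, max(c // 2, width), 3, 1, 1, rng),
                BatchNorm2d(max(c // 2, width)),
                ReLU(),
            ]
            c = max(c // 2, width)
        layers += [Conv2d(c, 1, 3, 1, 1, rng), Sigmoid()]
        self.root = Sequential(layers)
        self.latent_dim = latent_dim
        self.image_size = image_size

    def forward(self, z: np.ndarray, train: bool = True) -> np.ndarray:
        return self.root.forward(z, train=train)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw *n* binary masks (probability maps thresholded at 0.5)."""
        z = rng.standard_normal((n, self.latent_dim))
        probs = self.forward(z, train=False)
        return (probs[:, 0] > 0.5).astype(np.uint8)


class ImageGenerator(Module):
    """Conditional generator: (mask, class vector, noise vector) -> image in [0, 1].

    The mask is encoded by strided convolutions down to a 4x4 grid; the
    noise and class vectors are fused by a dense layer into a parallel
    4x4 feature block; the concatenation is decoded back up to the image.
    """

    def __init__(
        self,
        image_size: int,
        latent_dim: int,
        n_classes: int,
        width: int,
        rng: np.random.Generator,
    ):
        n = _n_ups(image_size)
        enc: list[Layer] = []
        c = 1
        for i in range(n):
            c_out = width * 2 ** min(i, n - 1)
            enc += [Conv2d(c, c_out, 3, 2, 1, rng), LeakyReLU(0.2)]
            c = c_out
        self.encoder = Sequential(enc)
        c_enc = c
        c_z = width * 2 ** (n - 1)
        self.fuse = Sequential([Dense(latent_dim + n_classes, c_z * 16, rng), Reshape((c_z, 4, 4))])
        dec: list[Layer] = []
        c = c_enc + c_z
        for _ in range(n):
            c_out = max(c // 4, width)
            dec += [UpsampleNearest(), Conv2d(c, c_out, 3, 1, 1, rng), BatchNorm2d(c_out), ReLU()]
            c = c_out
        dec += [Conv2d(c, 1, 3, 1, 1, rng), Sigmoid()]
        self.decoder = Sequential(dec)
        self.root = Sequential([self.encoder, self.fuse, self.decoder])
        self.latent_dim = latent_dim
        self.image_size = image_size

    def forward(
        self, masks: np.ndarray, weights: np.ndarray, z: np.ndarray, train: bool = True
    ) -> np.ndarray:
        h_mask = self.encoder.forward(masks.astype(float), train=train)
        h_z = self.fuse.forward(np.concatenate([z, weights], axis=1), train=train)
        self._split = h_mask.shape[1]
        h = np.concatenate([h_mask, h_z], axis=1)
        return self.decoder.forward(h, train=train)

    def backward(self, grad: np.ndarray) -> None:
        g = self.decoder.backward(grad)
        self.encoder.backward(g[:, : self._split])
        self.fuse.backward(g[:, self._split :])


class Discriminator(Module):
    """Strided-convolution critic emitting one real/fake logit per sample."""

    def __init__(self, image_size: int, in_channels: int, width: int, rng: np.random.Generator):
        n = _n_ups(image_size)
        layers: list[Layer] = []
        c = in_channels
        for i in range(n):
            c_out = width * 2**i
            layers += [Conv2d(c, c_out, 3, 2, 1, rng), LeakyReLU(0.2)]
            c = c_out
        layers += [Flatten(), Dense(c * 16, 1, rng)]
        self.root = Sequential(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.root.forward(x, train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.root.backward(grad)
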