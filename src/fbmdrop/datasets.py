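"""Datasets for the benchmark experiments.

Two tasks are used to probe the regularizer:

* a 1-D noisy regression problem — ``n`` points with ``x`` uniform on
  ``[-1, 1]`` and ``y = x + 0.3 eps``, ``eps ~ N(0, 1)`` — small enough
  that an over-parameterized network overfits badly without dropout;
* 28x28 grayscale digit classification with 10 classes, either real MNIST
  (read from the standard IDX/ubyte files, with a reduced random subset)
  or a built-in synthetic glyph generator so every code path is testable
  without downloads.

The glyph generator renders ten class-distinct stroke patterns (ring, bars,
cross, diagonals, ...) with small random affine jitter and additive
Gaussian noise.  The skeletons are fixed per class; only jitter and noise
vary with the seed.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class RegressionData:
    """Scalar regression set: ``y = x + noise_scale * eps``."""

    x: np.ndarray  # shape (n, 1)
    y: np.ndarray  # shape (n, 1)
    seed: object = None

    @property
    def n_points(self) -> int:
        return self.x.shape[0]


@dataclass(frozen=True)
class ImageData:
    """Grayscale image classification set with labels 0-9.

    ``images`` are floats in [0, 1], shape ``(n, 28, 28)``; ``source`` is
    ``"mnist_files"`` or ``"synthetic_glyphs"``.
    """

    images: np.ndarray
    labels: np.ndarray
    source: str

    @property
    def n_samples(self) -> int:
        return self.images.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.images.reshape(self.n_samples, -1)


def make_regression_data(
    n_points: int = 50,
    noise_scale: float = 0.3,
    seed=None,
    rng: np.random.Generator | None = None,
) -> RegressionData:
    """Draw the noisy-line regression set used in the first benchmark."""
    if n_points < 2:
        raise ValueError(f"n_points must be at least 2, got {n_points}")
    if noise_scale < 0:
        raise ValueError(f"noise_scale must be non-negative, got {noise_scale}")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = rng.uniform(-1.0, 1.0, size=(n_points, 1))
    y = x + noise_scale * rng.standard_normal((n_points, 1))
    return RegressionData(x=x, y=y, seed=seed)


def _glyph_skeletons() -> np.ndarray:
    """Ten fixed 28x28 stroke patterns, one per class, values in [0, 1]."""
    yy, xx = np.mgrid[0:28, 0:28].astype(float)
    cx = cy = 13.5
    r = np.hypot(xx - cx, yy - cy)
    stroke = 2.0  # half-width of a stroke in pixels

    def band(d):
        return np.clip(1.0 - np.abs(d) / stroke, 0.0, 1.0)

    vbar = band(xx - cx) * (yy > 4) * (yy < 23)
    hbar = band(yy - cy) * (xx > 4) * (xx < 23)
    ring = band(r - 8.0)
    diag = band((xx - yy) / np.sqrt(2)) * (r < 12)
    anti = band((xx + yy - 27.0) / np.sqrt(2)) * (r < 12)
    box = np.clip(band(np.abs(xx - cx) - 8) * (np.abs(yy - cy) < 9.5)
                  + band(np.abs(yy - cy) - 8) * (np.abs(xx - cx) < 9.5), 0, 1)
    disk = np.clip((6.0 - r) / 2.0, 0.0, 1.0)
    twobars = band(yy - 8.0) * (xx > 4) * (xx < 23) + band(yy - 19.0) * (
        xx > 4
    ) * (xx < 23)
    ell = np.clip(band(xx - 8.0) * (yy > 5) * (yy < 22)
                  + band(yy - 20.0) * (xx > 7) * (xx < 21), 0, 1)
    cross = np.clip(vbar + hbar, 0, 1)
    glyphs = [ring, vbar, hbar, cross, np.clip(diag + anti, 0, 1),
              box, disk, diag, np.clip(twobars, 0, 1), ell]
    return np.stack(glyphs).astype(float)


def make_synthetic_glyphs(
    n_per_class: int,
    seed=None,
    jitter: bool = True,
    noise_sd: float = 0.10,
) -> ImageData:
    """Render a balanced synthetic 10-class glyph set.

    Each image is a fixed per-class skeleton, randomly rotated (up to ~10
    degrees), scaled (0.9-1.1) and shifted (up to 2 px), with additive
    Gaussian pixel noise, clipped to [0, 1].  Classes are linearly well
    separated, so a small network reaches high test accuracy quickly —
    a deliberately easy stand-in for handwritten digits.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be positive, got {n_per_class}")
    rng = np.random.default_rng(seed)
    skeletons = _glyph_skeletons()
    n = 10 * n_per_class
    images = np.empty((n, 28, 28))
    labels = np.repeat(np.arange(10), n_per_class)
    center = np.array([13.5, 13.5])
    for i, lab in enumerate(labels):
        img = skeletons[lab]
        if jitter:
            angle = rng.uniform(-0.17, 0.17)
            scale = rng.uniform(0.9, 1.1)
            shift = rng.uniform(-2.0, 2.0, size=2)
            c, s = np.cos(angle), np.sin(angle)
            mat = np.array([[c, -s], [s, c]]) / scale
            offset = center - mat @ (center + shift)
            img = ndimage.affine_transform(img, mat, offset=offset, order=1)
        img = img + noise_sd * rng.standard_normal((28, 28))
        images[i] = np.clip(img, 0.0, 1.0)
    perm = rng.permutation(n)
    return ImageData(
        images=images[perm], labels=labels[perm], source="synthetic_glyphs"
    )


def _read_idx(path) -> np.ndarray:
    """Read an IDX/ubyte file (the standard MNIST container format)."""
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic[:2] != b"\x00\x00":
            raise ValueError(f"{path}: not an IDX file (bad magic {magic!r})")
        dtype_code, n_dims = magic[2], magic[3]
        if dtype_code != 0x08:
            raise ValueError(f"{path}: only unsigned-byte IDX data supported")
        dims = struct.unpack(f">{n_dims}I", fh.read(4 * n_dims))
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    return data.reshape(dims)


def load_mnist_idx(images_path, labels_path) -> ImageData:
    """Load MNIST images and labels from IDX/ubyte files.

    Pixel values are scaled to [0, 1].
    """
    images = _read_idx(images_path).astype(float) / 255.0
    labels = _read_idx(labels_path).astype(np.int64)
    if images.shape[0] != labels.shape[0]:
        raise ValueError(
            f"image/label count mismatch: {images.shape[0]} vs {labels.shape[0]}"
        )
    return ImageData(images=images, labels=labels, source="mnist_files")


def subsample(data: ImageData, n_samples: int, seed=None) -> ImageData:
    """Randomly select ``n_samples`` images (the reduced-set protocol)."""
    if n_samples > data.n_samples:
        raise ValueError(
            f"cannot draw {n_samples} samples from a set of {data.n_samples}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(data.n_samples, size=n_samples, replace=False)
    return ImageData(
        images=data.images[idx], labels=data.labels[idx], source=data.source
    )
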