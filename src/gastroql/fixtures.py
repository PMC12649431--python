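"""Deterministic synthetic endoscopy-style fixtures.

Two generators emulate the statistical structure the pipeline assumes,
so every stage is testable without downloading the public endoscopy
benchmarks:

* classification: K texture/colour populations — each class has a
  distinct mean RGB (hue spaced around the colour wheel) plus a
  class-specific sinusoidal texture, with additive Gaussian pixel noise.
  Classes are separable from low-order statistics by construction, so a
  sound classifier's ceiling is 100%.
* segmentation: noisy textured backgrounds with 1-3 brighter elliptical
  "lesions" and the exact ellipse-indicator masks.  The ``contrast``
  knob sets the lesion/background intensity gap (on the [0, 1] scale),
  which monotonically controls difficulty.

The same spec and seed always reproduce bit-identical datasets.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "FixtureSpec",
    "classification_arrays",
    "segmentation_arrays",
    "make_classification_fixture",
    "make_segmentation_fixture",
]


@dataclass
class FixtureSpec:
    task: str = "classification"  # "classification" | "segmentation"
    num_classes: int = 4
    n_per_class: int = 50
    n_images: int = 200  # segmentation only
    image_size: int = 64
    noise_sd: float = 10.0  # pixel noise, [0, 255] scale
    texture_amplitude: float = 15.0
    lesion_axes_frac: tuple[float, float] = (1 / 16, 1 / 8)  # semi-axes / size
    lesion_contrast: float = 0.4  # lesion minus background, [0, 1] scale
    lesion_max_count: int = 3
    background_level: float = 0.35  # mean background, [0, 1] scale
    seed: int = 0

    def validate(self) -> None:
        if self.task not in ("classification", "segmentation"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == "classification" and self.num_classes < 2:
            raise ValueError("classification fixture needs K >= 2")
        if self.image_size < 8:
            raise ValueError("image_size too small")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.lesion_axes_frac
        if not 0 < lo <= hi or hi * self.image_size * 2 >= self.image_size:
            raise ValueError("lesion axes must fit inside the image")


def class_prototype(spec: FixtureSpec, label: int) -> np.ndarray:
    """Noise-free template image of one class (float in [0, 255])."""
    size, k = spec.image_size, spec.num_classes
    hue = label / k
    rgb = np.array(colorsys.hsv_to_rgb(hue, 0.55, 0.60)) * 255.0
    yy, xx = np.mgrid[0:size, 0:size] / size
    theta = np.pi * label / k
    freq = 3.0 + label
    wave = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)))
    img = rgb[None, None, :] + spec.texture_amplitude * wave[:, :, None]
    return np.clip(img, 0, 255)


def classification_arrays(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``(X, y)``: X uint8 (N, size, size, 3), y int labels."""
    spec.validate()
    if spec.task != "classification":
        raise ValueError("spec.task must be 'classification'")
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for label in range(spec.num_classes):
        proto = class_prototype(spec, label)
        for _ in range(spec.n_per_class):
            noise = rng.normal(0.0, spec.noise_sd, proto.shape) if spec.noise_sd > 0 else 0.0
            images.append(np.clip(proto + noise, 0, 255).astype(np.uint8))
            labels.append(label)
    return np.stack(images), np.array(labels, dtype=np.int64)


def _ellipse_mask(size: int, cy: float, cx: float, ay: float, ax: float,
                  angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    ry = dy * np.cos(angle) - dx * np.sin(angle)
    rx = dy * np.sin(angle) + dx * np.cos(angle)
    return (ry / ay) ** 2 + (rx / ax) ** 2 <= 1.0


def segmentation_arrays(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``(images, masks)``: uint8 (N, s, s, 3) and binary (N, s, s)."""
    spec.validate()
    if spec.task != "segmentation":
        raise ValueError("spec.task must be 'segmentation'")
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    lo, hi = (f * size for f in spec.lesion_axes_frac)
    images, masks = [], []
    for _ in range(spec.n_images):
        base = spec.background_level * 255.0
        # smooth low-frequency background texture
        coarse = rng.normal(0.0, 12.0, (size // 8 + 1, size // 8 + 1))
        yy, xx = np.mgrid[0:size, 0:size] / 8.0
        texture = _bilinear_sample(coarse, yy, xx)
        mask = np.zeros((size, size), dtype=bool)
        n_lesions = int(rng.integers(1, spec.lesion_max_count + 1))
        for _ in range(n_lesions):
            ay = rng.uniform(lo, hi)
            ax = rng.uniform(lo, hi)
            margin = max(ay, ax) + 1
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            mask |= _ellipse_mask(size, cy, cx, ay, ax, rng.uniform(0, np.pi))
        img = base + texture + mask * (spec.lesion_contrast * 255.0)
        img = img[:, :, None] + rng.normal(0.0, spec.noise_sd, (size, size, 3))
        images.append(np.clip(img, 0, 255).astype(np.uint8))
        masks.append(mask.astype(np.uint8))
    return np.stack(images), np.stack(masks)


def _bilinear_sample(grid: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    y0 = np.clip(np.floor(yy).astype(int), 0, grid.shape[0] - 2)
    x0 = np.clip(np.floor(xx).astype(int), 0, grid.shape[1] - 2)
    fy, fx = yy - y0, xx - x0
    return (grid[y0, x0] * (1 - fy) * (1 - fx) + grid[y0 + 1, x0] * fy * (1 - fx)
            + grid[y0, x0 + 1] * (1 - fy) * fx + grid[y0 + 1, x0 + 1] * fy * fx)


def _write_spec(spec: FixtureSpec, out_dir: Path) -> None:
    (out_dir / "fixture_spec.json").write_text(json.dumps(asdict(spec), indent=2))


def make_classification_fixture(spec: FixtureSpec, out_dir) -> list[Path]:
    """Write the classification fixture as a per-class-folder PNG tree."""
    x, y = classification_arrays(spec)
    out = Path(out_dir)
    written = []
    for label in range(spec.num_classes):
        class_dir = out / f"class_{label}"
        class_dir.mkdir(parents=True, exist_ok=True)
        for i in np.flatnonzero(y == label):
            path = class_dir / f"img_{i:05d}.png"
            Image.fromarray(x[i]).save(path)
            written.append(path)
    _write_spec(spec, out)
    return written


def make_segmentation_fixture(spec: FixtureSpec, out_dir) -> list[Path]:
    """Write the segmentation fixture as paired ``images/`` + ``masks/`` trees."""
    images, masks = segmentation_arrays(spec)
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    written = []
    for i in range(len(images)):
        ip = out / "images" / f"pair_{i:05d}.png"
        mp = out / "masks" / f"pair_{i:05d}.png"
        Image.fromarray(images[i]).save(ip)
        Image.fromarray((masks[i] * 255).astype(np.uint8)).save(mp)
        written.extend([ip, mp])
    _write_spec(spec, out)
    return written
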