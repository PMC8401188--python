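"""Seeded synthetic texture benchmark: a stand-in for multi-class
histopathology patch datasets.

Each class is a grayscale texture defined by an oriented sinusoidal
grating (spatial frequency + orientation) plus a random field of disk
"blobs" and Gaussian pixel noise.  The classes are separable by spatial
structure (frequency/orientation/blob statistics) but not by mean
intensity, which forces a classifier to use convolutional features —
loosely analogous to visually distinguishable tissue textures.  The whole
dataset is a pure function of its :class:`BenchmarkSpec`, and each patch's
seed is derived from (master seed, class, split, patch index) so any
single patch can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .data import ClassLabel, Patch, PatchDataset, make_labels, resize_patch

#: Skewed per-class test-count profile mirroring a realistic imbalanced
#: 24-class benchmark, including severely under-represented classes.
_TEST_COUNT_PROFILE = (64, 65, 65, 75, 15, 40, 70, 50, 60, 60, 70, 70,
                       70, 60, 60, 30, 45, 45, 25, 25, 65, 65, 65, 65)

_SPLIT_CODES = {"train": 0, "test": 1}


@dataclass
class TextureClassSpec:
    """Texture parameters of one synthetic class."""

    class_label: ClassLabel
    grating_frequency: float        # cycles per patch
    grating_orientation: float      # degrees in [0, 180)
    blob_density: float = 0.0       # blobs per 1000 px^2
    blob_radius: float = 2.0        # px
    contrast: float = 0.9           # in (0, 1]
    noise_sd: float = 0.05          # Gaussian pixel noise sd

    def __post_init__(self):
        if self.grating_frequency < 0 or self.blob_density < 0:
            raise ValueError("frequency and blob density must be >= 0")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.grating_orientation < 180.0:
            raise ValueError("orientation must be in [0, 180) degrees")


@dataclass
class BenchmarkSpec:
    """A full synthetic benchmark: class specs, counts, size, master seed."""

    class_specs: list[TextureClassSpec]
    train_counts: list[int]
    test_counts: list[int]
    patch_size: int = 32
    master_seed: int = 0
    supersample: int = 1  # generate at supersample*patch_size, then downsize

    def __post_init__(self):
        k = len(self.class_specs)
        if k < 2:
            raise ValueError("need at least 2 classes")
        if len(self.train_counts) != k or len(self.test_counts) != k:
            raise ValueError("one train and one test count per class")
        if any(c < 0 for c in self.train_counts + self.test_counts):
            raise ValueError("counts must be >= 0")
        if self.patch_size < 8:
            raise ValueError("patch_size must be >= 8")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "patch_size": self.patch_size,
            "master_seed": self.master_seed,
            "supersample": self.supersample,
            "train_counts": list(self.train_counts),
            "test_counts": list(self.test_counts),
            "classes": [
                {**{k: v for k, v in asdict(s).items() if k != "class_label"},
                 "name": s.class_label.name}
                for s in self.class_specs
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_benchmark(num_classes: int, seed: int,
                      patch_size: int = 32) -> BenchmarkSpec:
    """A deterministic K-class benchmark on a parameter grid.

    Orientations are spread as 180*k/K; frequencies alternate between a
    low and a high band; blob density and radius cycle so neighbouring
    classes differ in more than one statistic.  Test counts follow a
    skewed profile with at least one class of <= 15 test patches when
    K >= 8; train counts are 4x the test counts.
    """
    if not 2 <= num_classes <= 64:
        raise ValueError(f"num_classes must be in [2, 64], got {num_classes}")
    labels = make_labels(num_classes)
    specs = []
    for k, label in enumerate(labels):
        specs.append(TextureClassSpec(
            class_label=label,
            grating_orientation=180.0 * k / num_classes,
            grating_frequency=3.0 if k % 2 == 0 else 7.0,
            blob_density=(0.0, 1.5, 3.0)[k % 3],
            blob_radius=2.0 + (k % 2),
            contrast=0.9,
            noise_sd=0.05,
        ))
    if num_classes >= 8:
        test_counts = [
            _TEST_COUNT_PROFILE[k % len(_TEST_COUNT_PROFILE)]
            for k in range(num_classes)
        ]
        # keep the guaranteed minority class inside the first K entries
        if min(test_counts) > 15:
            test_counts[4 % num_classes] = 15
    else:
        test_counts = [30] * num_classes
    train_counts = [4 * c for c in test_counts]
    return BenchmarkSpec(class_specs=specs, train_counts=train_counts,
                         test_counts=test_counts, patch_size=patch_size,
                         master_seed=seed)


def _patch_seed(master_seed: int, class_index: int, split: str,
                patch_index: int) -> np.random.Generator:
    return np.random.default_rng(
        [master_seed, class_index, _SPLIT_CODES[split], patch_index]
    )


def generate_patch(spec: TextureClassSpec, size: int,
                   seed: int | np.random.Generator) -> np.ndarray:
    """One size x size texture patch in [0, 1].

    pixel(x, y) = clip(0.5 + 0.5*contrast*sin(2*pi*f*(x*cos(t) + y*sin(t))/size)
                       + blobs + N(0, noise_sd), 0, 1)

    with Poisson(blob_density * size^2 / 1000) disks of the given radius at
    uniform positions, each with amplitude +/- contrast/2.
    """
    if size < 8:
        raise ValueError(f"patch size must be >= 8, got {size}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    theta = np.deg2rad(spec.grating_orientation)
    phase = 2.0 * np.pi * spec.grating_frequency * (
        x * np.cos(theta) + y * np.sin(theta)) / size
    img = 0.5 + 0.5 * spec.contrast * np.sin(phase)
    n_blobs = rng.poisson(spec.blob_density * size * size / 1000.0)
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0, size, size=2)
        amp = spec.contrast / 2.0 * (1.0 if rng.random() < 0.5 else -1.0)
        mask = (x - cx) ** 2 + (y - cy) ** 2 <= spec.blob_radius ** 2
        img[mask] += amp
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def _quantize8(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """8-bit PNG grid and the float pixels that reload from it bit-exactly."""
    u8 = np.round(img * 255.0).astype(np.uint8)
    return u8, u8.astype(np.float64) / 255.0


def generate_dataset(
    spec: BenchmarkSpec, out_dir: str | Path | None = None
) -> tuple[PatchDataset, PatchDataset]:
    """Generate the (train, test) datasets defined by ``spec``.

    When ``out_dir`` is given, writes ``out_dir/train/cN/*.png`` and
    ``out_dir/test/cN/*.png`` plus a ``benchmark.yaml`` sidecar; the
    returned in-memory pixels are then quantized to the 8-bit PNG grid so
    that writing and re-loading round-trips bit-exactly.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        try:
            out.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {out}: {exc}") from exc
        spec.to_yaml(out / "benchmark.yaml")
    labels = [s.class_label for s in spec.class_specs]
    gen_size = spec.patch_size * spec.supersample
    datasets = {}
    for split, counts in (("train", spec.train_counts),
                          ("test", spec.test_counts)):
        by_class: dict[ClassLabel, list[Patch]] = {}
        for cls_spec, count in zip(spec.class_specs, counts):
            label = cls_spec.class_label
            patches = []
            for i in range(count):
                rng = _patch_seed(spec.master_seed, label.index, split, i)
                img = generate_patch(cls_spec, gen_size, rng)
                if spec.supersample > 1:
                    img = resize_patch(img, spec.patch_size)
                source = f"{split}/{label.name}/{label.name}_{i:05d}.png"
                if out is not None:
                    u8, img = _quantize8(img)
                    path = out / source
                    path.parent.mkdir(parents=True, exist_ok=True)
                    Image.fromarray(u8, mode="L").save(path)
                patches.append(Patch(pixels=img, label=label,
                                     index_in_class=i + 1, source=source))
            by_class[label] = patches
        datasets[split] = PatchDataset(classes=list(labels),
                                       patches_by_class=by_class)
    return datasets["train"], datasets["test"]
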