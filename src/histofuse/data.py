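"""Labeled grayscale patch datasets in the Kimia Path24 directory convention.

A dataset on disk is a directory with one subfolder per class, named
``c0`` ... ``c{K-1}``, each holding patch images (PNG/TIFF/JPEG).  Loading
converts every image to grayscale, resizes it to a square model input and
scales intensities into [0, 1].  In memory a dataset is the partition
:math:`\\Gamma_s` of patches by class, with per-class counts
:math:`n_{\\Gamma_s}` and total :math:`n_{tot}`.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

logger = logging.getLogger("histofuse")

#: Rec.601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
_CLASS_DIR_RE = re.compile(r"^c(\d+)$")


@dataclass(frozen=True, order=True)
class ClassLabel:
    """A class in the label set S = {c0, ..., c(K-1)}."""

    index: int
    name: str = ""

    def __post_init__(self):
        if self.index < 0:
            raise ValueError(f"class index must be >= 0, got {self.index}")
        if not self.name:
            object.__setattr__(self, "name", f"c{self.index}")
        elif self.name != f"c{self.index}":
            raise ValueError(
                f"class name {self.name!r} does not match index {self.index}"
            )


def make_labels(num_classes: int) -> list[ClassLabel]:
    """The ordered label set for ``num_classes`` contiguous classes."""
    if num_classes < 1:
        raise ValueError("need at least one class")
    return [ClassLabel(k) for k in range(num_classes)]


@dataclass
class Patch:
    """One labeled grayscale patch with intensities in [0, 1].

    ``index_in_class`` is the 1-based index i identifying the patch among
    all patches of its class.
    """

    pixels: np.ndarray
    label: ClassLabel
    index_in_class: int = 1
    source: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("patch pixels must be a non-empty 2-D array")
        if self.index_in_class < 1:
            raise ValueError("index_in_class is 1-based")


@dataclass
class PatchDataset:
    """The partition of patches by class (Gamma_s, n_Gamma_s, n_tot)."""

    classes: list[ClassLabel]
    patches_by_class: dict[ClassLabel, list[Patch]] = field(default_factory=dict)

    def __post_init__(self):
        for label in self.classes:
            self.patches_by_class.setdefault(label, [])
        for label, patches in self.patches_by_class.items():
            for p in patches:
                if p.label != label:
                    raise ValueError(
                        f"patch labeled {p.label.name} filed under {label.name}"
                    )

    @property
    def n_per_class(self) -> dict[ClassLabel, int]:
        return {c: len(self.patches_by_class[c]) for c in self.classes}

    @property
    def n_total(self) -> int:
        return sum(len(self.patches_by_class[c]) for c in self.classes)

    @property
    def num_classes(self) -> int:
        return len(self.classes)

    def __iter__(self) -> Iterator[Patch]:
        for c in self.classes:
            yield from self.patches_by_class[c]

    def __len__(self) -> int:
        return self.n_total

    def patches(self) -> list[Patch]:
        return list(self)

    def labels(self) -> np.ndarray:
        """Integer class index per patch, in iteration order."""
        return np.array([p.label.index for p in self], dtype=np.int64)

    def images(self) -> np.ndarray:
        """All patches stacked as an (n_total, H, W) array."""
        return np.stack([p.pixels for p in self])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an H x W x C intensity array to a single H x W channel.

    C = 1 passes through; C = 3 applies the fixed Rec.601 luma weights
    (0.299, 0.587, 0.114).  A bare 2-D array is already grayscale.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    if image.ndim != 3 or image.shape[2] not in (1, 3):
        raise ValueError(
            f"expected H x W x C with C in {{1, 3}}, got shape {image.shape}"
        )
    if image.shape[2] == 1:
        return image[:, :, 0]
    return image @ LUMA_WEIGHTS


def resize_patch(image: np.ndarray, target: int) -> np.ndarray:
    """Bilinear resize to ``target`` x ``target``, values clipped to [0, 1].

    No anti-aliasing filter is applied, so the mapping is the plain
    bilinear sample at output-pixel centers; resizing to the input size is
    the identity.
    """
    if target < 1:
        raise ValueError(f"target size must be >= 1, got {target}")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    if image.shape == (target, target):
        return image.copy()
    out = _sk_resize(
        image,
        (target, target),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def flatten_image(image: np.ndarray) -> np.ndarray:
    """Row-major flattening of an H x W patch to a length H*W vector."""
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    return image.reshape(-1).copy()


def _scale_intensities(arr: np.ndarray) -> np.ndarray:
    """Rescale raw codec intensities to [0, 1] by the dtype maximum."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def load_dataset(root_path: str | Path, image_size: int) -> PatchDataset:
    """Load a class-per-subfolder patch directory into a :class:`PatchDataset`.

    Every readable image is converted to grayscale, resized to
    ``image_size`` x ``image_size`` and scaled to [0, 1].  Patches within a
    class are ordered lexicographically by filename so loading is
    deterministic across machines.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    found: dict[int, Path] = {}
    for child in root.iterdir():
        m = _CLASS_DIR_RE.match(child.name)
        if child.is_dir() and m:
            found[int(m.group(1))] = child
    if not found:
        raise ValueError(f"no class subdirectories c0..c(K-1) under {root}")
    num_classes = max(found) + 1
    missing = sorted(set(range(num_classes)) - set(found))
    if missing:
        raise ValueError(
            f"class indices not contiguous: missing {['c%d' % i for i in missing]}"
        )
    classes = make_labels(num_classes)
    patches_by_class: dict[ClassLabel, list[Patch]] = {}
    for label in classes:
        class_dir = found[label.index]
        files = sorted(
            p for p in class_dir.iterdir()
            if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES
        )
        patches: list[Patch] = []
        for i, path in enumerate(files, start=1):
            try:
                with Image.open(path) as im:
                    arr = np.asarray(im)
            except Exception as exc:  # noqa: BLE001 - re-raised with file name
                raise ValueError(f"unreadable image file {path}: {exc}") from exc
            gray = to_grayscale(_scale_intensities(arr))
            pixels = resize_patch(gray, image_size)
            patches.append(
                Patch(
                    pixels=pixels,
                    label=label,
                    index_in_class=i,
                    source=str(path.relative_to(root)),
                )
            )
        patches_by_class[label] = patches
    return PatchDataset(classes=classes, patches_by_class=patches_by_class)


def stratified_split(
    dataset: PatchDataset, train_fraction: float, seed: int
) -> tuple[PatchDataset, PatchDataset]:
    """Split per class into train/validation at ``train_fraction``.

    Per class, round(train_fraction * n) patches (at least 1 when the class
    has >= 2 patches) go to the first output; the split is a deterministic
    function of ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    first: dict[ClassLabel, list[Patch]] = {}
    second: dict[ClassLabel, list[Patch]] = {}
    for label in dataset.classes:
        patches = dataset.patches_by_class[label]
        n = len(patches)
        if n == 0:
            raise ValueError(f"class {label.name} is empty; cannot split")
        # round-half-up, not banker's rounding
        n_train = int(math.floor(train_fraction * n + 0.5))
        if n >= 2:
            n_train = min(max(n_train, 1), n - 1)
        rng = np.random.default_rng([seed, label.index])
        order = rng.permutation(n)
        first[label] = [patches[i] for i in sorted(order[:n_train])]
        second[label] = [patches[i] for i in sorted(order[n_train:])]
    return (
        PatchDataset(classes=list(dataset.classes), patches_by_class=first),
        PatchDataset(classes=list(dataset.classes), patches_by_class=second),
    )


def write_manifest(
    dataset: PatchDataset, path: str | Path, split_tag: str = "train"
) -> None:
    """Write a TSV manifest: one row per patch (path, class, split tag)."""
    lines = ["path\tclass\tsplit"]
    for p in dataset:
        ref = p.source if p.source else f"{p.label.name}/{p.index_in_class:05d}"
        lines.append(f"{ref}\t{p.label.name}\t{split_tag}")
    Path(path).write_text("\n".join(lines) + "\n")
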