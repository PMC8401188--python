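"""Feature fusion: unit-normalized backbone features concatenated with the
unit-normalized image vector, re-normalized, and reshaped for
convolutional retraining.

The fused vector is

    v = normalize( [ normalize(f) , normalize(x) ] )

where f is the penultimate-layer activation of a frozen pre-trained
backbone and x is the flattened grayscale patch.  Because both halves are
unit vectors before concatenation, each half of v has L2 norm 1/sqrt(2),
so the two information sources enter training on the same Euclidean
scale regardless of their native magnitudes.  The fused vector is
zero-padded to the next perfect square and reshaped to a single-channel
square map so that the same convolutional architecture can be retrained
on it from scratch.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import ClassLabel, Patch, PatchDataset, flatten_image
from .nn import Sequential

logger = logging.getLogger("histofuse")

#: Vectors with L2 norm at or below this threshold pass through unchanged.
ZERO_NORM_EPS = 1e-12


@dataclass
class FeatureVector:
    """A penultimate-layer feature vector and the backbone that produced it."""

    values: np.ndarray
    source_backbone: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)
        if self.values.size == 0:
            raise ValueError("feature vector must be non-empty")


@dataclass
class FusedSample:
    """A unit-norm fused vector with its square conv map and label."""

    values: np.ndarray
    conv_map: np.ndarray
    label: ClassLabel | None = None


def unit_normalize(v: np.ndarray) -> np.ndarray:
    """v / ||v||2, with zero-norm vectors passed through (warned, not fatal).

    An all-black patch or a dead feature layer yields the zero vector;
    dividing by its norm would poison downstream arrays with NaN, so it is
    returned unchanged and a warning is logged.
    """
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("cannot normalize a vector with NaN or Inf entries")
    norm = float(np.linalg.norm(v))
    if norm <= ZERO_NORM_EPS:
        logger.warning("unit_normalize: zero-norm vector passed through")
        return v.copy()
    return v / norm


def vector_to_map(v: np.ndarray) -> np.ndarray:
    """Zero-pad to the next perfect square and reshape to a square map."""
    v = np.asarray(v, dtype=np.float64).reshape(-1)
    side = int(math.ceil(math.sqrt(v.size)))
    padded = np.zeros(side * side, dtype=np.float64)
    padded[:v.size] = v
    return padded.reshape(side, side)


def fuse(features: np.ndarray | FeatureVector,
         image_vec: np.ndarray,
         label: ClassLabel | None = None) -> FusedSample:
    """Build one fused training sample from backbone features and an image.

    Both inputs are unit-normalized, concatenated, and the concatenation is
    unit-normalized again; the result is reshaped to the square conv map.
    """
    if isinstance(features, FeatureVector):
        features = features.values
    features = np.asarray(features, dtype=np.float64).reshape(-1)
    image_vec = np.asarray(image_vec, dtype=np.float64).reshape(-1)
    if features.size == 0 or image_vec.size == 0:
        raise ValueError("fuse() requires non-empty feature and image vectors")
    fused = unit_normalize(
        np.concatenate([unit_normalize(features), unit_normalize(image_vec)])
    )
    return FusedSample(values=fused, conv_map=vector_to_map(fused), label=label)


def image_only_sample(image: np.ndarray,
                      label: ClassLabel | None = None) -> FusedSample:
    """The pixels-only counterpart: unit-normalized image vector, no features.

    Used as the baseline against which the fused representation is compared.
    """
    v = unit_normalize(flatten_image(image))
    return FusedSample(values=v, conv_map=vector_to_map(v), label=label)


def extract_features(backbone: Sequential,
                     patches: Sequence[Patch] | np.ndarray,
                     batch_size: int = 256) -> np.ndarray:
    """Penultimate-layer features for a batch of patches, (N, d).

    The backbone is used as a frozen extractor: its weights are read, never
    written.  Patches must already be preprocessed to the backbone's input
    size; a mismatch raises an error naming the expected size.
    """
    if isinstance(patches, np.ndarray):
        imgs = np.asarray(patches, dtype=np.float64)
        if imgs.ndim == 2:
            imgs = imgs[None]
    else:
        patches = list(patches)
        if not patches:
            return np.zeros((0, backbone.penultimate_width))
        imgs = np.stack([p.pixels for p in patches])
    side = backbone.input_side
    if imgs.shape[1] != side or imgs.shape[2] != side:
        raise ValueError(
            f"backbone {backbone.spec!r} expects {side}x{side} patches, "
            f"got {imgs.shape[1]}x{imgs.shape[2]}"
        )
    out = [backbone.features(imgs[i:i + batch_size])
           for i in range(0, imgs.shape[0], batch_size)]
    return np.concatenate(out, axis=0)


def fuse_dataset(features: np.ndarray,
                 dataset: PatchDataset) -> list[FusedSample]:
    """Fuse per-patch features with their patches, in dataset order."""
    patches = dataset.patches()
    if features.shape[0] != len(patches):
        raise ValueError("one feature row per patch required")
    return [
        fuse(features[i], flatten_image(p.pixels), label=p.label)
        for i, p in enumerate(patches)
    ]


def image_only_dataset(dataset: PatchDataset) -> list[FusedSample]:
    """Pixels-only samples for every patch, in dataset order."""
    return [image_only_sample(p.pixels, label=p.label) for p in dataset]


# ---------------------------------------------------------------------------
# on-disk feature cache


def backbone_weights_hash(backbone: Sequential) -> str:
    return backbone.checksum()[:16]


def cache_key(backbone: Sequential) -> str:
    return f"{backbone.spec}-{backbone_weights_hash(backbone)}"


def save_feature_cache(cache_dir: str | Path, backbone: Sequential,
                       split_tag: str, features: np.ndarray,
                       dataset: PatchDataset) -> Path:
    """Persist extracted features with a JSON index sidecar.

    The cache is keyed by (backbone spec, weights hash, split), and the
    sidecar records one patch reference per feature row, so reruns can
    verify they are reading features for the same inputs bit-exactly.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{cache_key(backbone)}-{split_tag}"
    npz_path = cache_dir / f"{stem}.npz"
    np.savez(npz_path, features=np.asarray(features, dtype=np.float64))
    index = {
        "backbone": backbone.spec,
        "weights_hash": backbone_weights_hash(backbone),
        "split": split_tag,
        "rows": [
            p.source if p.source else f"{p.label.name}/{p.index_in_class:05d}"
            for p in dataset
        ],
    }
    (cache_dir / f"{stem}.json").write_text(json.dumps(index, indent=1))
    return npz_path


def load_feature_cache(cache_dir: str | Path, backbone: Sequential,
                       split_tag: str) -> tuple[np.ndarray, dict] | None:
    """Load cached features for (backbone, split); None on cache miss."""
    cache_dir = Path(cache_dir)
    stem = f"{cache_key(backbone)}-{split_tag}"
    npz_path = cache_dir / f"{stem}.npz"
    json_path = cache_dir / f"{stem}.json"
    if not (npz_path.exists() and json_path.exists()):
        return None
    with np.load(npz_path) as data:
        feats = data["features"]
    return feats, json.loads(json_path.read_text())
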