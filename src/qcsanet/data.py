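"""Dataset manifest, preprocessing, splitting, balancing, augmentation,
and the synthetic chest-X-ray-like generator.

The on-disk convention mirrors the public pneumonia CXR dataset layout:

    <root>/{train,val,test}/{NORMAL,PNEUMONIA}/*.{png,jpeg,jpg}

The synthetic generator emulates that world offline: NORMAL images are a
dark thoracic background with two brighter elliptical lung fields plus
Gaussian noise; PNEUMONIA images add a handful of bright localized blobs
inside the lung fields (the radiological cue is focal opacities).  The two
classes differ only in the blobs, so a learner must find them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "LABEL_NAMES",
    "ManifestRecord",
    "DatasetManifest",
    "PreprocessConfig",
    "SynthConfig",
    "AugmentConfig",
    "load_manifest",
    "preprocess",
    "split_dataset",
    "balance",
    "augment",
    "generate_synthetic_dataset",
    "synthesize_image",
    "synthesize_arrays",
    "load_split_arrays",
]

logger = logging.getLogger(__name__)

# label encoding: the disease class is positive
LABEL_NAMES = {0: "NORMAL", 1: "PNEUMONIA"}
_NAME_LABELS = {v: k for k, v in LABEL_NAMES.items()}
_IMAGE_EXTS = {".png", ".jpeg", ".jpg", ".bmp"}
SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class ManifestRecord:
    path: str
    label: int  # 0 = NORMAL, 1 = PNEUMONIA
    split: str  # train / val / test / "" (unassigned)


@dataclass
class DatasetManifest:
    """Labeled image paths with split assignment."""

    records: list[ManifestRecord] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[int, int]:
        counts = {0: 0, 1: 0}
        for r in self.records:
            counts[r.label] += 1
        return counts

    def split_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.split] = counts.get(r.split, 0) + 1
        return counts

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.split == split])

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([r.__dict__ for r in self.records]).to_csv(path, index=False)

    @staticmethod
    def from_csv(path: str | Path) -> "DatasetManifest":
        df = pd.read_csv(path, keep_default_na=False)
        return DatasetManifest([
            ManifestRecord(str(row.path), int(row.label), str(row.split))
            for row in df.itertuples()
        ])


@dataclass(frozen=True)
class PreprocessConfig:
    """Target geometry and intensity scaling of the input images."""

    target_size: tuple[int, int] = (50, 50)
    rescale: bool = True  # divide 8-bit input by 255
    interpolation: str = "bilinear"
    enhancement: str | None = None  # identity hook by default

    def __post_init__(self) -> None:
        if min(self.target_size) < 1:
            raise ValueError("target_size must be positive")


@dataclass(frozen=True)
class AugmentConfig:
    """Seeded random flip / small rotation / small shift."""

    horizontal_flip: bool = True
    max_rotation_deg: float = 10.0
    max_shift_fraction: float = 0.1


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of the synthetic CXR-like world.

    Defaults give the desk-scale study set: 50x50 images, 2-6 bright blobs
    of peak intensity 0.5 on lung fields of brightness ~0.35 over a 0.12
    background, with pixel noise sd 0.05 — separable but not trivial.
    """

    n_per_class: int = 200
    image_size: int = 50
    blob_count_range: tuple[int, int] = (2, 6)
    blob_intensity: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.image_size < 8:
            raise ValueError("n_per_class >= 1 and image_size >= 8 required")
        lo, hi = self.blob_count_range
        if not (1 <= lo <= hi):
            raise ValueError("blob_count_range must satisfy 1 <= lo <= hi")


# ---------------------------------------------------------------------------
# manifest / preprocessing / splitting / balancing / augmentation
# ---------------------------------------------------------------------------

def load_manifest(root_dir: str | Path) -> DatasetManifest:
    """Scan the two-level directory layout into a manifest.

    Accepts either ``<root>/{train,val,test}/{NORMAL,PNEUMONIA}`` or an
    unsplit ``<root>/{NORMAL,PNEUMONIA}``.  Class-name matching is
    case-insensitive; files are ordered lexicographically; unreadable
    images are skipped with a logged warning.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    split_dirs = [d for d in root.iterdir()
                  if d.is_dir() and d.name.lower() in SPLITS]
    records: list[ManifestRecord] = []
    if split_dirs:
        for sd in sorted(split_dirs):
            records.extend(_scan_class_dirs(sd, sd.name.lower()))
    else:
        records.extend(_scan_class_dirs(root, ""))
    if not records:
        raise FileNotFoundError(f"no labeled images found under {root}")
    return DatasetManifest(records)


def _scan_class_dirs(parent: Path, split: str) -> list[ManifestRecord]:
    class_dirs = {d.name.upper(): d for d in parent.iterdir() if d.is_dir()}
    missing = [name for name in _NAME_LABELS if name not in class_dirs]
    if missing:
        raise FileNotFoundError(
            f"missing class subdirectories {missing} under {parent}")
    records = []
    for name, label in sorted(_NAME_LABELS.items()):
        for f in sorted(class_dirs[name].iterdir()):
            if f.suffix.lower() not in _IMAGE_EXTS:
                continue
            try:
                with Image.open(f) as img:
                    img.verify()
            except Exception:  # damaged file: skip, keep scanning
                logger.warning("skipping unreadable image %s", f)
                continue
            records.append(ManifestRecord(str(f), label, split))
    return records


def enhance_image(image: np.ndarray, method: str | None = None) -> np.ndarray:
    """Image-enhancement stage of the pipeline.

    The default (and currently only) method is the identity: the stage
    exists as an explicit hook so alternative enhancement schemes can slot
    in without touching the pipeline, but none is applied by default.
    """
    if method in (None, "identity"):
        return image
    raise ValueError(f"unknown enhancement method {method!r}")


def preprocess(image, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Path/PIL/array -> grayscale float array in [0, 1] at target size.

    3-channel input is reduced by luminance; 8-bit input is divided by 255
    (so 255 -> 1.0); the enhancement hook (identity by default) runs
    before resizing; already-conformant float input passes through
    unchanged (idempotence).
    """
    if isinstance(image, (str, Path)):
        try:
            with Image.open(image) as img:
                image = np.asarray(img.convert("L" if img.mode != "RGB" else "RGB"))
        except Exception as exc:
            raise OSError(f"cannot load image {image}: {exc}") from exc
    elif isinstance(image, Image.Image):
        image = np.asarray(image)
    arr = np.asarray(image)
    was_integer = np.issubdtype(arr.dtype, np.integer)
    arr = arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        arr = arr @ np.array([0.299, 0.587, 0.114])  # ITU-R 601 luminance
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D or HxWx3 image, got shape {arr.shape}")
    if was_integer:
        if cfg.rescale:
            arr = arr / 255.0
    elif arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("float images must already lie in [0, 1]")
    arr = enhance_image(arr, cfg.enhancement)
    if arr.shape != cfg.target_size:
        resample = {"bilinear": Image.BILINEAR, "nearest": Image.NEAREST,
                    "bicubic": Image.BICUBIC}[cfg.interpolation]
        img = Image.fromarray((arr * 255).astype(np.uint8), mode="L")
        th, tw = cfg.target_size
        arr = np.asarray(img.resize((tw, th), resample)) / 255.0
    return np.clip(arr, 0.0, 1.0)


def split_dataset(manifest: DatasetManifest,
                  fractions: tuple[float, float, float] = (0.75, 0.05, 0.20),
                  seed: int = 0) -> DatasetManifest:
    """Assign train/val/test splits, stratified by label.

    Overall sizes are ``train = round(f_train * N)``,
    ``val = floor(f_val * N)`` and ``test = remainder``; within that
    constraint each class is apportioned by the same rule, with any
    rounding slack moved between classes so the totals are exact.
    """
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = len(manifest)
    n_train = int(round(f_train * n))
    n_val = int(np.floor(f_val * n))
    n_test = n - n_train - n_val
    if n_test < 0:
        raise ValueError("fractions leave a negative test split")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[ManifestRecord]] = {0: [], 1: []}
    for r in manifest.records:
        by_class[r.label].append(r)
    # per-class targets by the same round/floor/remainder rule
    targets = {}
    for label, recs in by_class.items():
        nl = len(recs)
        tl = int(round(f_train * nl))
        vl = int(np.floor(f_val * nl))
        targets[label] = [tl, vl, nl - tl - vl]
    # reconcile per-class sums with the overall sizes
    for j, overall in enumerate([n_train, n_val]):
        drift = sum(targets[c][j] for c in targets) - overall
        order = sorted(targets, key=lambda c: -len(by_class[c]))
        k = 0
        while drift != 0:
            c = order[k % len(order)]
            step = -1 if drift > 0 else 1
            targets[c][j] += step
            targets[c][2] -= step
            drift += step
            k += 1
    new_records: list[ManifestRecord] = []
    for label, recs in by_class.items():
        idx = rng.permutation(len(recs))
        tl, vl, _ = targets[label]
        for pos, i in enumerate(idx):
            split = "train" if pos < tl else ("val" if pos < tl + vl else "test")
            r = recs[i]
            new_records.append(ManifestRecord(r.path, r.label, split))
    return DatasetManifest(new_records)


def balance(manifest: DatasetManifest, mode: str = "class-weights",
            seed: int = 0):
    """Counter class imbalance.

    ``class-weights`` returns ``{label: N / (2 * N_label)}``;
    ``oversample`` duplicates seeded random minority records until both
    classes are equally sized and returns the new manifest.
    """
    counts = manifest.class_counts
    if min(counts.values()) == 0:
        raise ValueError("both classes need at least one record")
    n = len(manifest)
    if mode == "class-weights":
        return {label: n / (2.0 * cnt) for label, cnt in counts.items()}
    if mode == "oversample":
        rng = np.random.default_rng(seed)
        minority = min(counts, key=counts.get)
        deficit = counts[1 - minority] - counts[minority]
        pool = [r for r in manifest.records if r.label == minority]
        extra = [pool[i] for i in rng.integers(0, len(pool), size=deficit)]
        return DatasetManifest(list(manifest.records) + extra)
    raise ValueError(f"unknown balance mode {mode!r}")


def augment(image: np.ndarray, cfg: AugmentConfig = AugmentConfig(),
            seed: int = 0) -> np.ndarray:
    """Seeded random flip, rotation (<= max deg) and shift (<= max frac).

    Output is re-clipped to [0, 1]; an all-off config is the identity.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    out = np.asarray(image, dtype=float)
    if cfg.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    if cfg.max_rotation_deg > 0:
        angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")
    if cfg.max_shift_fraction > 0:
        h, w = out.shape
        dy = rng.uniform(-cfg.max_shift_fraction, cfg.max_shift_fraction) * h
        dx = rng.uniform(-cfg.max_shift_fraction, cfg.max_shift_fraction) * w
        out = ndimage.shift(out, (dy, dx), order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

def _lung_fields(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of the two elliptical lung fields."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / (size - 1)
    left = (((xx - 0.32) / 0.17) ** 2 + ((yy - 0.52) / 0.32) ** 2) <= 1.0
    right = (((xx - 0.68) / 0.17) ** 2 + ((yy - 0.52) / 0.32) ** 2) <= 1.0
    return left, right


def synthesize_image(label: int, rng: np.random.Generator,
                     cfg: SynthConfig = SynthConfig()) -> np.ndarray:
    """One synthetic CXR-like image in [0, 1].

    label 0 (NORMAL): background 0.12 + lung fields at ~0.35 + noise.
    label 1 (PNEUMONIA): the same, plus 2-6 bright Gaussian blobs of peak
    ``blob_intensity`` centred inside the lung fields.
    """
    size = cfg.image_size
    left, right = _lung_fields(size)
    img = np.full((size, size), 0.12)
    brightness = 0.35 * rng.uniform(0.9, 1.1)
    img[left | right] = brightness
    if label == 1:
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        centers = np.argwhere(left | right)
        n_blobs = int(rng.integers(cfg.blob_count_range[0],
                                   cfg.blob_count_range[1] + 1))
        for _ in range(n_blobs):
            cy, cx = centers[rng.integers(0, len(centers))]
            sigma = rng.uniform(0.02, 0.05) * size
            bump = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2)
                            / (2.0 * sigma ** 2)))
            img += cfg.blob_intensity * rng.uniform(0.8, 1.2) * bump
    img += rng.normal(0.0, cfg.noise_sd, (size, size))
    return np.clip(img, 0.0, 1.0)


def synthesize_arrays(n_per_class: int, cfg: SynthConfig = SynthConfig(),
                      seed: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """In-memory synthetic set: (images (2n, H, W), labels (2n,)).

    Classes alternate (N, P, N, P, ...); fully determined by the seed
    (``cfg.seed`` unless overridden).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    images, labels = [], []
    for _ in range(n_per_class):
        for label in (0, 1):
            images.append(synthesize_image(label, rng, cfg))
            labels.append(label)
    return np.asarray(images), np.asarray(labels, dtype=int)


def generate_synthetic_dataset(cfg: SynthConfig, out_dir: str | Path,
                               fractions: tuple[float, float, float] | None
                               = (0.75, 0.05, 0.20)) -> DatasetManifest:
    """Write a synthetic dataset in the standard directory layout.

    ``n_per_class`` images per class are drawn, written as 8-bit grayscale
    PNGs under ``<out>/<split>/<CLASS>/`` (or ``<out>/<CLASS>/`` when
    ``fractions`` is None), and returned as a manifest.  Byte-identical
    under a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    records: list[ManifestRecord] = []
    for label, name in sorted(LABEL_NAMES.items()):
        n = cfg.n_per_class
        if fractions is None:
            splits = [""] * n
        else:
            n_train = int(round(fractions[0] * n))
            n_val = int(np.floor(fractions[1] * n))
            splits = (["train"] * n_train + ["val"] * n_val
                      + ["test"] * (n - n_train - n_val))
        for i in range(n):
            img = synthesize_image(label, rng, cfg)
            sub = out / splits[i] / name if splits[i] else out / name
            sub.mkdir(parents=True, exist_ok=True)
            path = sub / f"{name.lower()}_{i:05d}.png"
            Image.fromarray((img * 255).astype(np.uint8), mode="L").save(path)
            records.append(ManifestRecord(str(path), label, splits[i]))
    return DatasetManifest(records)


def load_split_arrays(manifest: DatasetManifest, split: str,
                      cfg: PreprocessConfig = PreprocessConfig()
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Load and preprocess every image of one split into arrays."""
    records = [r for r in manifest.records if r.split == split]
    if not records:
        warnings.warn(f"split {split!r} is empty", RuntimeWarning)
        th, tw = cfg.target_size
        return np.empty((0, th, tw)), np.empty(0, dtype=int)
    images = np.stack([preprocess(r.path, cfg) for r in records])
    labels = np.array([r.label for r in records], dtype=int)
    return images, labels
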