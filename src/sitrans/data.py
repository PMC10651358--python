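"""Datasets of images with (possibly missing) continuous attributes.

On disk a dataset is a directory of grayscale images (PNG, NPZ, or a
NIfTI volume from which one axial slice is extracted) plus a CSV of
attributes with columns ``id, attr1, ..., attrm`` where an empty cell
means the attribute is missing.  In memory it is an
:class:`ImageAttributeDataset`: an (N, H, W) image stack in [0, 1] and a
pandas DataFrame with NaN for missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class AttributeScaler:
    """Per-attribute affine normalization to zero mean / unit sd."""

    mean: np.ndarray
    sd: np.ndarray
    columns: list

    @classmethod
    def fit(cls, attrs: pd.DataFrame) -> "AttributeScaler":
        mean = attrs.mean(skipna=True).to_numpy(dtype=float)
        sd = attrs.std(skipna=True, ddof=0).to_numpy(dtype=float)
        sd = np.where((~np.isfinite(sd)) | (sd < 1e-12), 1.0, sd)
        mean = np.where(np.isfinite(mean), mean, 0.0)
        return cls(mean=mean, sd=sd, columns=list(attrs.columns))

    def transform(self, attrs: pd.DataFrame) -> pd.DataFrame:
        return (attrs - self.mean) / self.sd

    def inverse_transform(self, attrs) -> np.ndarray:
        return np.asarray(attrs, dtype=float) * self.sd + self.mean

    def to_dict(self):
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist(), "columns": self.columns}

    @classmethod
    def from_dict(cls, d):
        return cls(np.asarray(d["mean"], float), np.asarray(d["sd"], float), list(d["columns"]))


@dataclass
class ImageAttributeDataset:
    """In-memory image/attribute cohort.

    ``attributes`` holds normalized attribute values with NaN marking a
    missing entry; ``subjects`` ties scans to subjects (used for
    leakage-free splits and longitudinal pairing), ``timepoints`` is the
    scan time in years from the subject's baseline.
    """

    images: np.ndarray
    attributes: pd.DataFrame
    subjects: np.ndarray | None = None
    timepoints: np.ndarray | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("images must be an (N, H, W) stack")
        n = self.images.shape[0]
        if len(self.attributes) != n:
            raise ValueError("attribute table length does not match image count")
        if self.subjects is None:
            self.subjects = np.array([f"S{i:05d}" for i in range(n)])
        self.subjects = np.asarray(self.subjects)
        if self.timepoints is None:
            self.timepoints = np.zeros(n)
        self.timepoints = np.asarray(self.timepoints, dtype=float)

    def __len__(self):
        return self.images.shape[0]

    @property
    def m(self) -> int:
        return self.attributes.shape[1]

    @property
    def image_size(self) -> int:
        return self.images.shape[1]

    def attribute_arrays(self):
        """(values, mask) with missing entries zeroed."""
        vals = self.attributes.to_numpy(dtype=float)
        mask = np.isfinite(vals)
        return np.where(mask, vals, 0.0), mask

    def subset(self, idx) -> "ImageAttributeDataset":
        idx = np.asarray(idx, dtype=np.intp)
        return ImageAttributeDataset(
            images=self.images[idx],
            attributes=self.attributes.iloc[idx].reset_index(drop=True),
            subjects=self.subjects[idx],
            timepoints=self.timepoints[idx],
        )

    def split_by_subject(self, test_fraction: float = 0.2, seed: int = 0):
        """Train/test split with no subject in both halves."""
        rng = np.random.default_rng(seed)
        unique = np.unique(self.subjects)
        perm = rng.permutation(unique)
        n_test = max(1, int(round(test_fraction * unique.size)))
        test_subjects = set(perm[:n_test])
        test_idx = np.array(
            [i for i, s in enumerate(self.subjects) if s in test_subjects], dtype=np.intp
        )
        train_idx = np.array(
            [i for i, s in enumerate(self.subjects) if s not in test_subjects], dtype=np.intp
        )
        return self.subset(train_idx), self.subset(test_idx)

    # -- disk I/O ------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        import imageio.v3 as iio

        ids = []
        for i in range(len(self)):
            name = f"{i:05d}"
            ids.append(name)
            img16 = np.clip(self.images[i], 0, 1)
            iio.imwrite(directory / f"{name}.png", (img16 * 65535).astype(np.uint16))
        table = self.attributes.copy()
        table.insert(0, "id", ids)
        table.insert(1, "subject", self.subjects)
        table.insert(2, "timepoint", self.timepoints)
        table.to_csv(directory / "attributes.csv", index=False)

    @classmethod
    def load(cls, directory, slice_index: int | None = None) -> "ImageAttributeDataset":
        directory = Path(directory)
        table = pd.read_csv(directory / "attributes.csv", dtype={"id": str})
        subjects = table["subject"].to_numpy() if "subject" in table else None
        timepoints = table["timepoint"].to_numpy() if "timepoint" in table else None
        attr_cols = [c for c in table.columns if c not in ("id", "subject", "timepoint")]
        images = np.stack(
            [load_image(_find_image(directory, i), slice_index) for i in table["id"]]
        )
        return cls(
            images=images,
            attributes=table[attr_cols].astype(float),
            subjects=subjects,
            timepoints=timepoints,
        )


def _find_image(directory: Path, stem: str) -> Path:
    for ext in (".png", ".npz", ".npy", ".nii", ".nii.gz"):
        p = directory / f"{stem}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(f"no image found for id {stem!r} in {directory}")


def load_image(path, slice_index: int | None = None) -> np.ndarray:
    """Load one grayscale image in [0, 1] from PNG/NPZ/NPY/NIfTI."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".png"):
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path), dtype=np.float64)
        if arr.ndim == 3:
            arr = arr.mean(axis=-1)
        peak = 65535.0 if arr.max() > 255 else 255.0
        return arr / peak
    if name.endswith(".npz"):
        with np.load(path) as f:
            arr = f[list(f.files)[0]]
        return _normalize01(np.asarray(arr, dtype=np.float64))
    if name.endswith(".npy"):
        return _normalize01(np.asarray(np.load(path), dtype=np.float64))
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
        if vol.ndim == 3:
            k = vol.shape[2] // 2 if slice_index is None else slice_index
            vol = vol[:, :, k]
        return _normalize01(vol)
    raise ValueError(f"unsupported image format: {path}")


def _normalize01(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    return np.clip(arr, 0.0, 1.0)


# ----------------------------------------------------------------------
# training-time augmentation
# ----------------------------------------------------------------------

@dataclass
class AugmentationConfig:
    """Horizontal flips, small affine jitter and intensity rescaling.

    Applied to training batches only, never to evaluation inputs.
    """

    flip_probability: float = 0.5
    max_rotation_deg: float = 5.0
    max_translation_px: float = 3.0
    scale_range: tuple = (0.97, 1.03)
    intensity_range: tuple = (0.9, 1.1)
    enabled: bool = True


def augment_batch(
    images: np.ndarray, config: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply per-image random augmentation to an (N, H, W) stack."""
    if not config.enabled:
        return images
    out = np.empty_like(images)
    h, w = images.shape[1:]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    for i, img in enumerate(images):
        if rng.random() < config.flip_probability:
            img = img[:, ::-1]
        ang = np.deg2rad(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg))
        sc = rng.uniform(*config.scale_range)
        tr = rng.uniform(-config.max_translation_px, config.max_translation_px, size=2)
        ca, sa = np.cos(ang) / sc, np.sin(ang) / sc
        mat = np.array([[ca, -sa], [sa, ca]])
        offset = center - mat @ (center + tr)
        img = ndimage.affine_transform(img, mat, offset=offset, order=1, mode="nearest")
        img = img * rng.uniform(*config.intensity_range)
        out[i] = np.clip(img, 0.0, 1.0)
    return out
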