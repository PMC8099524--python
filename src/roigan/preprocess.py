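"""Data preparation: reading standard formats, lesion-area cropping, slice
extraction from labelled 3D volumes, max normalization, region images, and
the train/test split.

Conventions: 0-based indices, (row, column) axis order for 2D grids; 3D
volumes are stored (slice, row, column) and the NIfTI reader transposes the
on-disk (x, y, z) layout so the slice axis comes first.  Any geometric
operation applied to an image is applied identically to its mask.  PNG pairs
are written as 16-bit grayscale to limit quantization of [0,1] intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize as _resize

from .phantoms import PairedSample


@dataclass
class Volume3D:
    """3D intensity grid, axis order (slice, row, column)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class SplitResult:
    train: list[PairedSample]
    test: list[PairedSample]
    ratio: float
    seed: int


# ---------------------------------------------------------------------------
# core operations


def normalize_max(image: np.ndarray) -> np.ndarray:
    """Linearly scale to [0,1] by dividing by the image maximum.

    Idempotent on already-normalized images (max 1); order preserving.
    Raises on an all-zero (or non-positive) image, where x/max(x) is
    undefined.
    """
    image = np.asarray(image, dtype=np.float64)
    m = image.max()
    if m <= 0:
        raise ValueError("normalize_max: image maximum is not positive "
                         "(degenerate all-zero input)")
    return image / m


def compute_region_image(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Elementwise product of image and binary ROI mask: tumor intensities
    inside the mask, zeros outside."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} vs mask {mask.shape}")
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask must be binary")
    return image * mask


def crop_to_roi(image: np.ndarray, mask: np.ndarray, out_size: int,
                sample_id: str = "crop", group_label: str | None = None
                ) -> PairedSample:
    """Crop an out_size window centered on the lesion, mask cropped
    identically.

    The window is centered on the mask bounding-box center and clamped to the
    image bounds, so the full lesion lies inside the crop whenever its
    bounding box fits.  A lesion larger than the window is cropped to its
    bounding box and resized to out_size (bilinear image, nearest mask).
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    fg = np.argwhere(mask > 0)
    if fg.size == 0:
        raise ValueError("crop_to_roi: mask is empty")
    if out_size > min(image.shape):
        raise ValueError("out_size exceeds image dimensions")
    (r0, c0), (r1, c1) = fg.min(axis=0), fg.max(axis=0) + 1
    bh, bw = r1 - r0, c1 - c0
    if bh > out_size or bw > out_size:
        side = max(bh, bw)
        win_img, win_mask = _window(image, mask, r0, r1, c0, c1, side)
        img_out = _resize(win_img, (out_size, out_size), order=1,
                          preserve_range=True, anti_aliasing=True)
        mask_out = _resize(win_mask.astype(float), (out_size, out_size),
                           order=0, preserve_range=True,
                           anti_aliasing=False).astype(np.uint8)
        img_out = np.clip(img_out, 0.0, 1.0)
    else:
        win_img, win_mask = _window(image, mask, r0, r1, c0, c1, out_size)
        img_out, mask_out = win_img, win_mask
    return PairedSample(image=img_out, mask=mask_out, sample_id=sample_id,
                        group_label=group_label)


def _window(image, mask, r0, r1, c0, c1, size):
    """size x size window centered on the bbox center, clamped in-bounds."""
    h, w = image.shape
    size_r = min(size, h)
    size_c = min(size, w)
    cr = (r0 + r1) // 2
    cc = (c0 + c1) // 2
    top = int(np.clip(cr - size_r // 2, 0, h - size_r))
    left = int(np.clip(cc - size_c // 2, 0, w - size_c))
    return (image[top:top + size_r, left:left + size_c],
            mask[top:top + size_r, left:left + size_c])


def extract_slices(volume: Volume3D, mask_volume: Volume3D,
                   slice_indices: list[int],
                   group_label: str | None = None) -> list[PairedSample]:
    """Take paired (image, mask) slices at the given indices along the slice
    axis; pairs whose mask slice contains no foreground are excluded."""
    if volume.voxels.shape != mask_volume.voxels.shape:
        raise ValueError("volume and mask_volume shapes differ")
    out = []
    for idx in slice_indices:
        if not 0 <= idx < volume.n_slices:
            raise IndexError(
                f"slice index {idx} out of range [0, {volume.n_slices})")
        msk = (mask_volume.voxels[idx] > 0).astype(np.uint8)
        if msk.sum() == 0:
            continue
        img = np.asarray(volume.voxels[idx], dtype=np.float64)
        if img.max() > 1 or img.min() < 0:
            img = normalize_max(img - img.min()) if img.max() > img.min() else img * 0
        out.append(PairedSample(image=img, mask=msk,
                                sample_id=f"slice_{idx:03d}",
                                group_label=group_label))
    return out


def split_train_test(samples: list[PairedSample], ratio: float,
                     seed: int) -> SplitResult:
    """Random disjoint train/test split; the train count is the nearest
    integer to ratio * n (e.g. 107 samples at 0.7 -> 75/32)."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0,1)")
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(ratio * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train = [samples[i] for i in perm[:n_train]]
    test = [samples[i] for i in perm[n_train:]]
    return SplitResult(train=train, test=test, ratio=ratio, seed=seed)


# ---------------------------------------------------------------------------
# readers / writers

_PNG_MAX = 65535  # 16-bit grayscale


def _to_uint16(arr: np.ndarray) -> np.ndarray:
    return np.round(np.clip(arr, 0, 1) * _PNG_MAX).astype(np.uint16)


def write_pairs(samples: list[PairedSample], out_dir) -> pd.DataFrame:
    """Write image_###.png / mask_###.png pairs (16-bit grayscale) and a
    manifest.csv (sample_id, image_path, mask_path, group_label)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        ip = out_dir / f"image_{i:03d}.png"
        mp = out_dir / f"mask_{i:03d}.png"
        iio.imwrite(ip, _to_uint16(s.image))
        iio.imwrite(mp, _to_uint16(s.mask.astype(np.float64)))
        rows.append({"sample_id": s.sample_id, "image_path": ip.name,
                     "mask_path": mp.name,
                     "group_label": s.group_label if s.group_label else ""})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_pair_png(image_path, mask_path, sample_id: str | None = None,
                  group_label: str | None = None) -> PairedSample:
    """Read one PNG pair; intensities scaled by the dtype maximum, mask
    binarized at half range."""
    img = np.asarray(iio.imread(image_path), dtype=np.float64)
    msk = np.asarray(iio.imread(mask_path), dtype=np.float64)
    for a in (img, msk):
        if a.ndim != 2:
            raise ValueError("expected single-channel grayscale PNGs")
    img /= _PNG_MAX if img.max() > 255 else (255 if img.max() > 1 else 1)
    msk = (msk > msk.max() / 2).astype(np.uint8) if msk.max() > 0 else \
        msk.astype(np.uint8)
    return PairedSample(image=np.clip(img, 0, 1), mask=msk,
                        sample_id=sample_id or Path(image_path).stem,
                        group_label=group_label)


def read_manifest(manifest_path) -> list[PairedSample]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, keep_default_na=False)
    base = manifest_path.parent
    return [
        read_pair_png(base / r.image_path, base / r.mask_path,
                      sample_id=r.sample_id,
                      group_label=r.group_label or None)
        for r in df.itertuples()
    ]


def read_dicom(path) -> np.ndarray:
    """Single-frame grayscale DICOM -> 2D float array (raw stored values)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ValueError("expected a single-frame 2D DICOM image")
    return np.asarray(arr, dtype=np.float64)


def read_nifti(path) -> Volume3D:
    """NIfTI volume -> Volume3D with the slice axis (on-disk z) first."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError("expected a 3D NIfTI volume")
    zooms = img.header.get_zooms()[:3]
    return Volume3D(voxels=np.transpose(data, (2, 0, 1)),
                    spacing=(float(zooms[2]), float(zooms[0]), float(zooms[1])))
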