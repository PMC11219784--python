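"""Reading, writing and resizing fundus images, vessel masks and FOV masks.

Conventions: row-major arrays, origin top-left; masks are {0,1} with
1 = vessel (or 1 = inside the field of view). Images are RGB floats in
[0, 1]. TIFF/PPM/JPEG/PNG rasters are handled by imageio; resizing by
scikit-image (bilinear for images, nearest-neighbour for masks).
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

from .types import DatasetSpec, FundusSample, ValidationError

__all__ = [
    "read_image",
    "read_mask",
    "write_mask",
    "resize_to_input",
    "restore_resolution",
    "make_splits",
    "load_sample",
]

_SUPPORTED = {".tif", ".tiff", ".ppm", ".pgm", ".jpg", ".jpeg", ".png", ".bmp", ".gif"}


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Scale an integer raster to [0,1] by its format's full scale.

    uint8/uint16 use their dtype maximum; wider integer dtypes (e.g. the
    int32 that PPM/PGM decoders return) are scaled by the smallest
    conventional full scale (255 or 65535) that covers the data.
    """
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        scale = 255.0 if arr.max() <= 255 else 65535.0
        return np.clip(arr.astype(np.float64) / scale, 0.0, 1.0)
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:  # float file stored on a 0..255 scale
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a raster file as an HxWx3 RGB array in [0, 1].

    Grayscale inputs are replicated to three channels; an alpha channel,
    if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() not in _SUPPORTED:
        raise IOError(f"unsupported raster format {path.suffix!r} for {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the path
        raise IOError(f"cannot read {path} as {path.suffix!r}: {exc}") from exc
    arr = _to_unit_float(np.asarray(arr))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise IOError(f"unexpected image layout {arr.shape} in {path}")
    return arr


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a mask file as an HxW {0,1} array (threshold: >0.5 of full scale)."""
    arr = read_image(path)
    gray = arr.mean(axis=2)
    return (gray > 0.5).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary mask as a lossless PNG (0/255); round-trips exactly."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValidationError("write_mask requires a {0,1} mask")
    path = Path(path)
    try:
        iio.imwrite(path, (mask.astype(np.uint8) * 255), extension=".png")
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write mask to {path}: {exc}") from exc


def _resize_image(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if image.shape[:2] == shape:
        return image.copy()
    out = _sk_resize(image, shape, order=1, mode="edge", anti_aliasing=False,
                     preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def _resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if mask.shape == shape:
        return mask.copy()
    out = _sk_resize(mask.astype(np.float64), shape, order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def resize_to_input(sample: FundusSample, side: int) -> FundusSample:
    """Standardise a sample to ``side x side`` (e.g. 512x512).

    The image is resampled bilinearly; masks with nearest-neighbour and
    re-binarised. The original resolution is preserved on the sample so
    predictions can be mapped back.
    """
    if side <= 0 or side % 4 != 0:
        raise ValidationError(f"target side must be positive and divisible by 4, got {side}")
    shape = (side, side)
    return FundusSample(
        id=sample.id,
        image=_resize_image(sample.image, shape),
        vessel_mask=_resize_mask(sample.vessel_mask, shape),
        fov_mask=None if sample.fov_mask is None else _resize_mask(sample.fov_mask, shape),
        source_resolution=sample.source_resolution,
    )


def restore_resolution(mask_or_probs: np.ndarray, source_resolution: tuple[int, int],
                       binary: bool = True) -> np.ndarray:
    """Map a network-resolution mask or probability map back to the source size."""
    shape = tuple(source_resolution)
    if binary:
        return _resize_mask(np.asarray(mask_or_probs), shape)
    out = _sk_resize(np.asarray(mask_or_probs, dtype=np.float64), shape, order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def make_splits(spec: DatasetSpec) -> list[tuple[list[str], list[str]]]:
    """Expand a dataset spec into (train ids, test ids) pairs.

    fixed_train_test yields one pair (first ``n_train`` ids train, rest
    test); leave_one_out yields one pair per sample, testing that sample
    and training on the others.
    """
    ids = list(spec.sample_ids)
    if not ids:
        raise ValidationError("dataset has no samples")
    if spec.split_mode == "fixed_train_test":
        n_train = spec.n_train if spec.n_train is not None else len(ids) // 2
        if not 0 < n_train < len(ids):
            raise ValidationError(f"n_train={n_train} leaves an empty train or test set")
        return [(ids[:n_train], ids[n_train:])]
    if len(ids) < 2:
        raise ValidationError("leave_one_out needs at least 2 samples")
    return [([s for j, s in enumerate(ids) if j != i], [ids[i]]) for i in range(len(ids))]


def load_sample(sample_id: str, image_path, mask_path, fov_path=None) -> FundusSample:
    """Assemble a FundusSample from files; missing FOV means full-frame FOV."""
    image = read_image(image_path)
    mask = read_mask(mask_path)
    fov = read_mask(fov_path) if fov_path is not None else None
    return FundusSample(id=sample_id, image=image, vessel_mask=mask, fov_mask=fov,
                        source_resolution=image.shape[:2])
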