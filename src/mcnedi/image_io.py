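"""Image reading/writing, intensity normalization and integer shifts.

All images in this package are plain 2D ``numpy.ndarray`` of ``float64``,
indexed ``(row, col)``, 0-based, row-major.  Intensities are expected (but
not forced at load time) to live in ``[0, 1]``; :func:`normalize_unit`
performs the min-max mapping.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np

__all__ = ["load_image", "save_image", "normalize_unit", "shift_image"]

#: Shift direction -> (row step, col step) per pixel of shift.
_DIRECTIONS = {
    "slant": (1, 1),
    "anti-slant": (1, -1),
    "vertical": (1, 0),
    "horizontal": (0, 1),
}

_NIFTI_EXTS = (".nii", ".nii.gz")


def _is_nifti(path: str) -> bool:
    lowered = path.lower()
    return lowered.endswith(".nii") or lowered.endswith(".nii.gz")


def load_image(
    path: str | os.PathLike,
    *,
    slice_axis: Optional[int] = None,
    slice_index: Optional[int] = None,
    channel: Optional[int] = None,
) -> np.ndarray:
    """Load a 2D grayscale image from PNG/TIFF or a slice of a NIfTI volume.

    Parameters
    ----------
    path:
        File to read.  ``.nii``/``.nii.gz`` are read with nibabel, anything
        else with imageio.
    slice_axis, slice_index:
        Required for 3D NIfTI volumes: which axis to slice and which index
        to take.  Ignored for 2D inputs.
    channel:
        For multi-channel (color) rasters, which channel to take.  Without
        it, color input is rejected.

    Returns
    -------
    ndarray
        2D float64 array with the raw (unnormalized) intensities.

    Raises
    ------
    IOError
        If the file is missing or cannot be decoded.
    ValueError
        For color input without ``channel`` or 3D NIfTI without a slice
        specification.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")

    if _is_nifti(path):
        import nibabel as nib

        try:
            vol = np.asanyarray(nib.load(path).dataobj)
        except Exception as exc:  # nibabel raises many concrete types
            raise IOError(f"cannot decode NIfTI file {path}: {exc}") from exc
        if vol.ndim == 2:
            data = vol
        elif vol.ndim == 3:
            if slice_axis is None or slice_index is None:
                raise ValueError(
                    "3D NIfTI volume requires slice_axis and slice_index"
                )
            data = np.take(vol, slice_index, axis=slice_axis)
        else:
            raise ValueError(f"unsupported NIfTI dimensionality: {vol.ndim}")
    else:
        import imageio.v3 as iio

        try:
            data = iio.imread(path)
        except Exception as exc:
            raise IOError(f"cannot decode image file {path}: {exc}") from exc
        if data.ndim == 3:
            if channel is None:
                raise ValueError(
                    f"{path} has {data.shape[-1]} channels; pass channel=<int> "
                    "to select one"
                )
            data = data[..., channel]

    if data.ndim != 2:
        raise ValueError(f"expected a 2D raster, got shape {data.shape}")
    return np.asarray(data, dtype=np.float64)


def save_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write ``image`` to ``path``; format chosen by extension.

    ``[0, 1]`` floats are scaled to the full range of the integer format:
    8-bit for PNG, 16-bit for TIFF.  NIfTI keeps float values untouched.
    """
    path = os.fspath(path)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("only 2D images can be saved")

    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(image.astype(np.float64), np.eye(4)), path)
        return

    import imageio.v3 as iio

    clipped = np.clip(image, 0.0, 1.0)
    if path.lower().endswith((".tif", ".tiff")):
        iio.imwrite(path, np.round(clipped * 65535).astype(np.uint16))
    else:
        iio.imwrite(path, np.round(clipped * 255).astype(np.uint8))


def normalize_unit(image: np.ndarray) -> np.ndarray:
    """Min-max normalize intensities to ``[0, 1]``.

    A constant image maps to all zeros (documented convention: avoids a
    zero division while keeping the output well defined).  The input array
    is never modified.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    lo = image.min()
    hi = image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def shift_image(image: np.ndarray, direction: str, pixels: int) -> np.ndarray:
    """Translate an image by an integer number of pixels.

    Directions (``(drow, dcol)`` per pixel): ``slant`` ``(+1, +1)``,
    ``anti-slant`` ``(+1, -1)``, ``vertical`` ``(+1, 0)``, ``horizontal``
    ``(0, +1)``.  Vacated borders are filled by edge replication; the output
    has the same shape as the input.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(
            f"unknown direction {direction!r}; expected one of "
            f"{sorted(_DIRECTIONS)}"
        )
    pixels = int(pixels)
    if pixels < 0:
        raise ValueError("pixels must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if pixels == 0:
        return image.copy()
    h, w = image.shape
    if pixels >= min(h, w) / 2:
        raise ValueError("shift too large for image size")

    dr, dc = (pixels * s for s in _DIRECTIONS[direction])
    k = pixels
    padded = np.pad(image, k, mode="edge")
    # content moves by (+dr, +dc): out[r, c] = in[r - dr, c - dc]
    return padded[k - dr : k - dr + h, k - dc : k - dc + w].copy()
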