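"""Image readers and writers: NIfTI (.nii/.nii.gz) and PNG/TIFF grayscale.

Intensities are always exposed as float64 arrays.  NIfTI metadata (affine and
header) is preserved for round-tripping; 3D volumes are exposed as iterables
of 2D axial slices (a ``H x W x D`` volume yields ``D`` slices of ``H x W``).

PNG output quantisation rule (exact and documented): a float image scaled to
[0, 1] is written as ``round((2^bits - 1) * x)`` for 8- or 16-bit output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .exceptions import ImageFormatError, MetadataError

__all__ = ["LoadedImage", "read_image", "write_image"]

NIFTI_SUFFIXES = (".nii", ".nii.gz")
RASTER_SUFFIXES = (".png", ".tif", ".tiff")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


@dataclass(frozen=True)
class LoadedImage:
    """A loaded image plus the metadata needed to write it back.

    ``data`` is 2D (slice) or 3D (volume); ``affine``/``header`` are NIfTI
    metadata (``None`` for raster formats).
    """

    data: np.ndarray
    affine: np.ndarray | None = None
    header: object | None = None
    source_format: str = "array"

    @property
    def is_volume(self) -> bool:
        return self.data.ndim == 3

    def slices(self) -> Iterator[np.ndarray]:
        """Iterate 2D axial slices (the last axis of a volume)."""
        if self.data.ndim == 2:
            yield self.data
        else:
            for k in range(self.data.shape[2]):
                yield self.data[:, :, k]

    @property
    def n_slices(self) -> int:
        return 1 if self.data.ndim == 2 else int(self.data.shape[2])


def read_image(path: str | Path) -> LoadedImage:
    """Read a NIfTI or grayscale PNG/TIFF image as float64.

    Raises a not-found error for missing paths, a format error for unknown
    extensions, and a channel error (with guidance) for colour PNG/TIFF.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = _suffix(path)
    if suffix in NIFTI_SUFFIXES:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        return LoadedImage(data=data, affine=img.affine, header=img.header,
                           source_format="nifti")
    if suffix in RASTER_SUFFIXES:
        data = np.asarray(iio.imread(path))
        if data.ndim == 3:
            if data.shape[-1] in (3, 4) and np.all(
                data[..., :3] == data[..., :1]
            ):
                data = data[..., 0]
            else:
                raise ImageFormatError(
                    f"{path} is not grayscale (shape {data.shape}); convert "
                    "it to single-channel grayscale before processing"
                )
        return LoadedImage(data=data.astype(np.float64), source_format="raster")
    raise ImageFormatError(
        f"unsupported image extension {suffix!r} for {path}; supported: "
        f"{', '.join(NIFTI_SUFFIXES + RASTER_SUFFIXES)}"
    )


def write_image(
    image: np.ndarray,
    path: str | Path,
    like: LoadedImage | None = None,
    bits: int = 8,
) -> None:
    """Write an image as NIfTI or PNG/TIFF.

    NIfTI output copies the affine (and header) from ``like`` when given;
    a ``like`` whose data dimensions disagree with ``image`` is rejected.
    Float raster output maps [0, 1] to integers via ``round((2^bits - 1) x)``
    with ``bits`` in {8, 16}; values outside [0, 1] are clipped first.
    """
    path = Path(path)
    arr = np.asarray(image)
    if like is not None and like.data.shape != arr.shape:
        raise MetadataError(
            f"'like' metadata has shape {like.data.shape} but the image to "
            f"write has shape {arr.shape}"
        )
    suffix = _suffix(path)
    if suffix in NIFTI_SUFFIXES:
        affine = like.affine if (like is not None and like.affine is not None) \
            else np.eye(4)
        header = like.header if like is not None else None
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine, header)
        nib.save(img, str(path))
        return
    if suffix in RASTER_SUFFIXES:
        if np.issubdtype(arr.dtype, np.integer):
            iio.imwrite(path, arr)
            return
        if bits not in (8, 16):
            raise ImageFormatError(f"bits must be 8 or 16, got {bits}")
        peak = (1 << bits) - 1
        scaled = np.rint(np.clip(arr, 0.0, 1.0) * peak)
        iio.imwrite(path, scaled.astype(np.uint8 if bits == 8 else np.uint16))
        return
    raise ImageFormatError(
        f"unsupported image extension {suffix!r} for {path}"
    )
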