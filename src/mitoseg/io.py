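"""Reading and writing image/label stacks with physical voxel spacing.

Volumes are indexed ``(z, y, x)``; spacing is given in nanometers in the
same order and may be strongly anisotropic (serial block-face stacks
typically step 5-7x coarser in Z than the in-plane pixel size). On disk a
stack is either a multipage TIFF or a directory of equally sized
single-slice PNG/TIFF images whose lexicographic filename order is
ascending Z. Binary labels are stored as 8-bit 0/255 for viewer
compatibility and held in memory as 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = ["IntensityVolume", "LabelVolume", "read_stack", "read_labels", "write_stack"]

_SLICE_EXTS = {".png", ".tif", ".tiff"}


@dataclass
class IntensityVolume:
    """A 3D grayscale grid with physical voxel spacing.

    Parameters
    ----------
    data
        ``(z, y, x)`` array of gray values, 8-bit integers or reals.
    spacing
        ``(z_nm, y_nm, x_nm)`` physical voxel size in nanometers.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D (z, y, x), got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have extent >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        return tuple(s / 1000.0 for s in self.spacing)


@dataclass
class LabelVolume:
    """A binary 3D mask aligned voxel-for-voxel with an :class:`IntensityVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"labels must be 3D (z, y, x), got shape {data.shape}")
        vals = np.unique(data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"labels must be binary 0/1, found values {vals[:10]}")
        self.data = data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        return tuple(s / 1000.0 for s in self.spacing)


def _read_array(path: Path) -> np.ndarray:
    """Read a stack as a (z, y, x) array from a multipage TIFF or a directory."""
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTS and p.is_file()
        )
        if not files:
            raise FileNotFoundError(f"directory {path} contains no PNG/TIFF slices")
        slices = []
        for f in files:
            img = iio.imread(f)
            if img.ndim == 3:  # collapse redundant RGB(A) channels
                if not (img[..., 0] == img[..., 1]).all():
                    raise ValueError(f"{f} is not grayscale")
                img = img[..., 0]
            if img.ndim != 2:
                raise ValueError(f"{f} is not a single-slice 2D image")
            slices.append(img)
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice dimensions in {path}: {sorted(shapes)}")
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"{path} is not a 2D/3D grayscale TIFF (shape {data.shape})")
    if data.dtype.kind not in "ui" or data.dtype.itemsize > 2:
        raise ValueError(f"unsupported bit depth {data.dtype} in {path} (expect 8/16-bit)")
    return data


def read_stack(path: str | Path, spacing: tuple[float, float, float]) -> IntensityVolume:
    """Read an intensity stack; slices ordered by ascending Z.

    ``path`` is a multipage TIFF or a directory of equally sized
    single-slice images read in lexicographic filename order. 8-bit values
    are preserved bit-exactly.
    """
    return IntensityVolume(_read_array(Path(path)), spacing)


def read_labels(path: str | Path, spacing: tuple[float, float, float]) -> LabelVolume:
    """Read a label stack, re-binarizing any nonzero value to 1."""
    data = _read_array(Path(path))
    return LabelVolume((data > 0).astype(np.uint8), spacing)


def write_stack(volume: IntensityVolume | LabelVolume, path: str | Path) -> None:
    """Write a stack re-readable by :func:`read_stack` / :func:`read_labels`.

    A ``.tif``/``.tiff`` path produces a multipage TIFF; any other path is
    treated as a directory of per-slice PNGs named ``slice_0000.png`` etc.
    Labels are written as 8-bit 0/255.
    """
    path = Path(path)
    data = volume.data
    if isinstance(volume, LabelVolume):
        data = (data * 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, sl in enumerate(data):
            iio.imwrite(path / f"slice_{i:04d}.png", sl)
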