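"""Volumetric grid containers and MRC/TIFF input-output.

All grids are 3-D numpy arrays in ``(z, y, x)`` axis order with 0-based voxel
indices.  Physical coordinates are obtained only through ``voxel_size`` (edge
length per axis, in nanometres; soft X-ray tomograms of whole cells are
typically sampled at 35 nm isotropic).  Tomogram voxel intensities are in
arbitrary units numerically equal to the linear absorption coefficient (LAC).

On-disk formats are MRC2014 (modes 0, 1, 2, 6) and multi-page TIFF.  Integer
label grids are stored as unsigned 16-bit; instance counts in a single
tomogram are far below 65535.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

DEFAULT_VOXEL_SIZE_NM = 35.0

__all__ = [
    "Tomogram",
    "SemanticMask",
    "InstanceMask",
    "read_volume",
    "write_volume",
    "DEFAULT_VOXEL_SIZE_NM",
]


def _as_triple(value) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class _Volume:
    """Base grid type: 3-D data + voxel size (nm/axis) + voxel origin offset."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (
        DEFAULT_VOXEL_SIZE_NM,
        DEFAULT_VOXEL_SIZE_NM,
        DEFAULT_VOXEL_SIZE_NM,
    )
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all grid dimensions must be >= 1, got {self.data.shape}")
        self.voxel_size = _as_triple(self.voxel_size)
        if min(self.voxel_size) <= 0:
            raise ValueError(f"voxel_size components must be > 0, got {self.voxel_size}")
        self.origin = tuple(int(o) for o in self.origin)
        self._validate()

    def _validate(self) -> None:  # overridden by subclasses
        pass

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Tomogram(_Volume):
    """Grayscale tomogram; intensities are LAC-valued, finite floats."""

    def _validate(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("tomogram intensities must be finite")


@dataclass
class SemanticMask(_Volume):
    """Binary organelle-class mask: 1 marks organelle voxels, 0 background."""

    def _validate(self) -> None:
        data = np.asarray(self.data)
        if data.dtype.kind == "f":
            if not np.all(np.isin(data, (0.0, 1.0))):
                raise ValueError("semantic mask contains fractional values")
        elif not np.all(np.isin(data, (0, 1))):
            raise ValueError("semantic mask values must be in {0, 1}")
        self.data = data.astype(bool)

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


@dataclass
class InstanceMask(_Volume):
    """Integer label grid: 0 = background, k >= 1 = organelle instance k."""

    def _validate(self) -> None:
        data = np.asarray(self.data)
        if data.dtype.kind == "f":
            if not np.all(data == np.round(data)):
                raise ValueError("instance mask contains fractional values")
            data = data.astype(np.int64)
        if data.min() < 0:
            raise ValueError("instance labels must be non-negative")
        self.data = data.astype(np.int32)

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the grid."""
        vals = np.unique(self.data)
        return vals[vals > 0]

    @property
    def n_instances(self) -> int:
        return int(self.labels.size)


# ---------------------------------------------------------------------------
# MRC2014 codec (little-endian; modes 0=int8, 1=int16, 2=float32, 6=uint16)
# ---------------------------------------------------------------------------

_MRC_MODE_TO_DTYPE = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_DTYPE_TO_MRC_MODE = {
    np.dtype(np.int8): 0,
    np.dtype(np.int16): 1,
    np.dtype(np.float32): 2,
    np.dtype(np.uint16): 6,
}


def _read_mrc(path: Path) -> tuple[np.ndarray, tuple | None, tuple[int, int, int]]:
    raw = path.read_bytes()
    if len(raw) < 1024:
        raise IOError(f"{path}: truncated MRC header")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    nxstart, nystart, nzstart = struct.unpack_from("<3i", raw, 16)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    xlen, ylen, zlen = struct.unpack_from("<3f", raw, 40)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    if mode not in _MRC_MODE_TO_DTYPE:
        raise IOError(f"{path}: unsupported MRC mode {mode}")
    dtype = np.dtype(_MRC_MODE_TO_DTYPE[mode]).newbyteorder("<")
    count = nx * ny * nz
    offset = 1024 + nsymbt
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    data = data.reshape(nz, ny, nx).astype(_MRC_MODE_TO_DTYPE[mode])
    voxel = None
    if mx > 0 and my > 0 and mz > 0 and xlen > 0 and ylen > 0 and zlen > 0:
        # cell lengths are stored in angstroms; 10 A = 1 nm
        voxel = (zlen / mz / 10.0, ylen / my / 10.0, xlen / mx / 10.0)
    return data, voxel, (nzstart, nystart, nxstart)


def _write_mrc(path: Path, data: np.ndarray, voxel_size, origin) -> None:
    mode = _DTYPE_TO_MRC_MODE[np.dtype(data.dtype)]
    nz, ny, nx = data.shape
    vz, vy, vx = voxel_size
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 16, origin[2], origin[1], origin[0])
    struct.pack_into("<3i", header, 28, nx, ny, nz)
    struct.pack_into("<3f", header, 40, nx * vx * 10.0, ny * vy * 10.0, nz * vz * 10.0)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    dmin, dmax = float(data.min()), float(data.max())
    struct.pack_into("<3f", header, 76, dmin, dmax, float(data.mean()))
    struct.pack_into("<i", header, 88, 1)  # ispg: volume
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    path.write_bytes(bytes(header) + np.ascontiguousarray(data, dtype="<" + data.dtype.str[1:]).tobytes())


# ---------------------------------------------------------------------------
# TIFF codec (OME-TIFF metadata for voxel size; origin is not stored)
# ---------------------------------------------------------------------------


def _read_tiff(path: Path) -> tuple[np.ndarray, tuple | None]:
    import re

    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray().reshape(series.shape)
        if data.ndim < 3:  # leading singleton axes are squeezed on disk
            data = data.reshape((1,) * (3 - data.ndim) + data.shape)
        voxel = None
        if tif.ome_metadata:
            sizes = {}
            for axis in "XYZ":
                m = re.search(rf'PhysicalSize{axis}="([\d.eE+-]+)"', tif.ome_metadata)
                if m:
                    sizes[axis] = float(m.group(1)) * 1000.0  # micron -> nm
            if len(sizes) == 3:
                voxel = (sizes["Z"], sizes["Y"], sizes["X"])
        elif tif.imagej_metadata and "spacing" in tif.imagej_metadata:
            try:
                page = tif.pages[0]
                xres = page.tags["XResolution"].value  # pixels per micron
                yres = page.tags["YResolution"].value
                voxel = (float(tif.imagej_metadata["spacing"]) * 1000.0,
                         yres[1] / yres[0] * 1000.0,
                         xres[1] / xres[0] * 1000.0)
            except (KeyError, IndexError, ZeroDivisionError):
                voxel = None
    return data, voxel


def _write_tiff(path: Path, data: np.ndarray, voxel_size) -> None:
    vz, vy, vx = voxel_size  # stored in microns per OME convention
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": vx / 1000.0, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": vy / 1000.0, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": vz / 1000.0, "PhysicalSizeZUnit": "µm",
        },
    )


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

_KIND_TO_CLS = {
    "tomogram": Tomogram,
    "semantic": SemanticMask,
    "instance": InstanceMask,
}


def _sniff_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        return format_hint.lower()
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".map", ".rec"):
        return "mrc"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    raise IOError(f"cannot infer volume format from {path.name!r}; pass format_hint")


def read_volume(path, kind: str = "tomogram", format_hint: str | None = None):
    """Read a 3-D volume from MRC or multi-page TIFF.

    Parameters
    ----------
    path : path-like
        File to read.
    kind : {"tomogram", "semantic", "instance"}
        Which grid type to validate the content against.
    format_hint : {"mrc", "tiff"}, optional
        Override format sniffing by file suffix.

    Returns
    -------
    Tomogram | SemanticMask | InstanceMask
        Grid in (z, y, x) order.  When the file carries no voxel-size
        metadata, 35 nm isotropic is assumed and a warning logged.
    """
    path = Path(path)
    if kind not in _KIND_TO_CLS:
        raise ValueError(f"unknown volume kind {kind!r}")
    fmt = _sniff_format(path, format_hint)
    origin = (0, 0, 0)
    if fmt == "mrc":
        data, voxel, origin = _read_mrc(path)
    elif fmt == "tiff":
        data, voxel = _read_tiff(path)
    else:
        raise IOError(f"unsupported format {fmt!r}")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D content, got shape {data.shape}")
    if voxel is None:
        logger.warning(
            "%s carries no voxel-size metadata; assuming %.0f nm isotropic",
            path.name,
            DEFAULT_VOXEL_SIZE_NM,
        )
        voxel = (DEFAULT_VOXEL_SIZE_NM,) * 3
    return _KIND_TO_CLS[kind](data=data, voxel_size=voxel, origin=origin)


def write_volume(vol: _Volume, path, format: str | None = None) -> None:
    """Write a grid to MRC or TIFF; label grids are stored losslessly as uint16."""
    path = Path(path)
    fmt = _sniff_format(path, format)
    if isinstance(vol, Tomogram):
        data = vol.data.astype(np.float32)
    elif isinstance(vol, SemanticMask):
        data = vol.data.astype(np.uint16)
    elif isinstance(vol, InstanceMask):
        if vol.data.max() > np.iinfo(np.uint16).max:
            raise ValueError("instance labels exceed uint16 range")
        data = vol.data.astype(np.uint16)
    else:
        raise TypeError(f"unsupported volume type {type(vol).__name__}")
    if fmt == "mrc":
        _write_mrc(path, data, vol.voxel_size, vol.origin)
    elif fmt == "tiff":
        _write_tiff(path, data, vol.voxel_size)
    else:
        raise IOError(f"unsupported format {fmt!r}")
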