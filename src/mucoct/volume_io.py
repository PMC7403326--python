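"""Volumetric containers and file IO with explicit physical voxel spacing.

Axis convention used throughout the package: arrays are indexed ``(z, y, x)``
with ``z`` the axial, lumen-pointing direction.  The world coordinate of voxel
``(k, j, i)`` is ``origin + (k*sz, j*sy, i*sx)`` in micrometres.

Two on-disk formats are supported:

* NRRD (preferred, self-describing; spacing carried in the header), via
  SimpleITK.
* multi-page TIFF stacks, with spacing in a mandatory plain-text sidecar file
  ``<stem>.spacing.txt`` (TIFF resolution tags are too dialect-prone to trust
  for quantitative area work).

Spacing is never assumed: a file without resolvable spacing metadata raises
:class:`~mucoct.errors.MetadataError` rather than defaulting to 1 µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .errors import MetadataError, MucoctError

__all__ = [
    "VoxelVolume",
    "BinaryVolume",
    "read_volume",
    "write_volume",
]

_SIDECAR_KEYS = ("spacing_z_um", "spacing_y_um", "spacing_x_um")


def _check_geometry(values: np.ndarray, spacing, origin) -> tuple:
    if values.ndim != 3:
        raise MucoctError(f"volume must be 3-D, got ndim={values.ndim}")
    if any(d < 2 for d in values.shape):
        raise MucoctError(f"volume dims must be >= 2 per axis, got {values.shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise MucoctError(f"spacing must be three positive values (µm), got {spacing}")
    origin = tuple(float(o) for o in origin)
    if len(origin) != 3:
        raise MucoctError("origin must have three components (µm)")
    return spacing, origin


@dataclass
class VoxelVolume:
    """3-D scalar intensity grid with voxel spacing in µm.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Intensities, arbitrary units.
    spacing : tuple of float
        ``(sz, sy, sx)`` voxel spacing in µm.
    origin : tuple of float
        World position (µm) of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing, self.origin = _check_geometry(self.values, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the grid per axis (µm), span of voxel centres + 1 voxel."""
        return tuple(n * s for n, s in zip(self.values.shape, self.spacing))

    def voxel_volume_um3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx


@dataclass
class BinaryVolume:
    """Tissue/background occupancy grid sharing the VoxelVolume geometry contract.

    ``occupancy`` is boolean; True marks tissue.
    """

    occupancy: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy).astype(bool)
        self.spacing, self.origin = _check_geometry(self.occupancy, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.occupancy.shape, self.spacing))

    def voxel_volume_um3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    def to_voxel(self, tissue_level: int = 255, background_level: int = 0) -> VoxelVolume:
        vals = np.where(self.occupancy, np.uint8(tissue_level), np.uint8(background_level))
        return VoxelVolume(vals, self.spacing, self.origin)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tiff_stack", "nrrd"):
            raise MucoctError(f"unsupported format {fmt!r}; use 'tiff_stack' or 'nrrd'")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff_stack"
    if suffix in (".nrrd", ".nhdr"):
        return "nrrd"
    raise MucoctError(f"cannot infer volume format from suffix {suffix!r}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".spacing.txt")


def _nrrd_header_has_spacing(path: Path) -> bool:
    """Sniff the plain-text NRRD header for an explicit spacing field.

    SimpleITK fills absent spacing with 1.0, which would silently mis-scale
    every area in mm²; we therefore refuse headers without one.
    """
    with open(path, "rb") as fh:
        head = fh.read(16384)
    text = head.decode("ascii", errors="replace")
    for line in text.splitlines():
        if not line.strip():
            break  # end of NRRD header
        key = line.split(":", 1)[0].strip().lower()
        if key in ("spacings", "space directions"):
            return True
    return False


def read_volume(path, format: str | None = None) -> VoxelVolume:
    """Read a volume with spacing metadata from NRRD or a TIFF stack.

    Raises
    ------
    MetadataError
        If the spacing metadata is absent (TIFF sidecar missing a key, NRRD
        header without ``spacings``/``space directions``).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise MucoctError(f"no such file: {path}")
    if fmt == "nrrd":
        if not _nrrd_header_has_spacing(path):
            raise MetadataError(
                f"{path}: NRRD header lacks 'spacings'/'space directions'; "
                "refusing to assume 1 µm voxels"
            )
        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img)  # (z, y, x)
        sx, sy, sz = img.GetSpacing()
        ox, oy, oz = img.GetOrigin()
        return VoxelVolume(values, (sz, sy, sx), (oz, oy, ox))
    # TIFF stack + mandatory sidecar
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(
            f"{path}: missing spacing sidecar {sidecar.name} "
            f"(expected keys {', '.join(_SIDECAR_KEYS)})"
        )
    meta: dict[str, str] = {}
    for line in sidecar.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            continue
        k, v = line.split("=", 1)
        meta[k.strip()] = v.strip()
    for key in _SIDECAR_KEYS:
        if key not in meta:
            raise MetadataError(f"{sidecar}: missing required key {key!r}")
    spacing = tuple(float(meta[k]) for k in _SIDECAR_KEYS)
    origin = tuple(
        float(meta.get(k, "0.0")) for k in ("origin_z_um", "origin_y_um", "origin_x_um")
    )
    values = tifffile.imread(str(path))
    if values.ndim == 2:
        values = values[None]
    return VoxelVolume(values, spacing, origin)


def write_volume(vol: VoxelVolume | BinaryVolume, path, format: str | None = None) -> Path:
    """Write a volume to NRRD or TIFF stack (+ spacing sidecar).

    Binary volumes are stored as 0/255 uint8.  Integer grids round-trip
    bit-exactly; float grids are stored as float32.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if isinstance(vol, BinaryVolume):
        values = np.where(vol.occupancy, 255, 0).astype(np.uint8)
        spacing, origin = vol.spacing, vol.origin
    else:
        values = vol.values
        spacing, origin = vol.spacing, vol.origin
        if values.dtype == np.bool_:
            values = np.where(values, 255, 0).astype(np.uint8)
        elif values.dtype in (np.uint8, np.uint16, np.uint32, np.int16, np.int32):
            pass
        elif np.issubdtype(values.dtype, np.floating):
            values = values.astype(np.float32)
        else:
            raise MucoctError(f"unsupported dtype for volume IO: {values.dtype}")
    sz, sy, sx = spacing
    oz, oy, ox = origin
    if fmt == "nrrd":
        img = sitk.GetImageFromArray(values)
        img.SetSpacing((sx, sy, sz))
        img.SetOrigin((ox, oy, oz))
        sitk.WriteImage(img, str(path), useCompression=False)
        return path
    tifffile.imwrite(str(path), values, photometric="minisblack")
    lines = [
        "# voxel spacing sidecar (micrometres); axis order z, y, x",
        f"spacing_z_um = {sz!r}",
        f"spacing_y_um = {sy!r}",
        f"spacing_x_um = {sx!r}",
        f"origin_z_um = {oz!r}",
        f"origin_y_um = {oy!r}",
        f"origin_x_um = {ox!r}",
    ]
    _sidecar_path(path).write_text("\n".join(lines) + "\n")
    return path
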