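"""Stack I/O with physical metadata, plus the standard preprocessing steps.

Reads and writes TIFF / OME-TIFF through :mod:`tifffile`.  Physical voxel
spacing is required for every quantitative operation, so ``read_stack``
refuses to invent one: it must come from OME metadata, a JSON sidecar, or an
explicit override.

Sidecar schema (``<stem>.json`` next to the TIFF)::

    {"spacing_um": [dz, dy, dx], "axes": "tzyx"}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .geometry import VoxelSpacing

__all__ = ["VoxelGrid", "read_stack", "write_stack", "gaussian_blur_3d", "gamma_adjust"]


@dataclass
class VoxelGrid:
    """A scalar raster with anisotropic physical spacing.

    ``values`` is indexed (z, y, x) or (t, z, y, x); ``spacing`` applies to
    the trailing three axes.  ``origin_um`` is the physical position of
    voxel (0,0,0), so crops of a larger scene keep consistent coordinates.
    ``display_only`` marks grids that went through a visualization-only
    transform (gamma) and must not be quantified.
    """

    values: np.ndarray
    spacing: VoxelSpacing
    channel: str = ""
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    display_only: bool = field(default=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (3, 4):
            raise ValueError(f"expected a (z,y,x) or (t,z,y,x) raster, got ndim={self.values.ndim}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(np.isfinite(self.values)):
            raise ValueError("raster contains non-finite values")

    @property
    def is_timeseries(self) -> bool:
        return self.values.ndim == 4

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.values.shape[-3:])

    def frame(self, t: int) -> "VoxelGrid":
        """Extract one timepoint as a 3D grid."""
        if not self.is_timeseries:
            raise ValueError("not a time series")
        return replace(self, values=self.values[t])

    def physical_coords(self, voxel_zyx: np.ndarray) -> np.ndarray:
        """Map (…, 3) voxel indices to physical µm, honouring the origin."""
        return np.asarray(voxel_zyx, dtype=float) * self.spacing.as_array() + np.asarray(
            self.origin_um
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(path: str | Path, grid: VoxelGrid) -> None:
    """Write a grid as OME-TIFF with physical spacing plus a JSON sidecar."""
    path = Path(path)
    axes = "TZYX" if grid.is_timeseries else "ZYX"
    sp = grid.spacing
    tifffile.imwrite(
        path,
        grid.values,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": axes,
            "PhysicalSizeZ": sp.dz,
            "PhysicalSizeY": sp.dy,
            "PhysicalSizeX": sp.dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )
    _sidecar_path(path).write_text(
        json.dumps({"spacing_um": [sp.dz, sp.dy, sp.dx], "axes": axes.lower(), "channel": grid.channel})
    )


def _spacing_from_ome(tif: tifffile.TiffFile) -> VoxelSpacing | None:
    if not tif.is_ome or tif.ome_metadata is None:
        return None
    # minimal OME-XML scrape: Pixels PhysicalSize attributes
    import re

    m = {}
    for ax in ("Z", "Y", "X"):
        hit = re.search(rf'PhysicalSize{ax}="([0-9.eE+-]+)"', tif.ome_metadata)
        if hit:
            m[ax] = float(hit.group(1))
    if set(m) == {"Z", "Y", "X"}:
        return VoxelSpacing(m["Z"], m["Y"], m["X"])
    return None


def read_stack(
    path: str | Path,
    spacing: VoxelSpacing | None = None,
    channel: str = "",
) -> VoxelGrid:
    """Read a TIFF/OME-TIFF stack, normalizing axis order to (t,)z,y,x.

    Spacing resolution order: OME metadata, then JSON sidecar, then the
    explicit ``spacing`` override.  A stack whose spacing cannot be resolved
    is an error — never a silent default.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        meta_spacing = _spacing_from_ome(tif)
        axes = tif.series[0].axes if tif.series else ""

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        if meta_spacing is None and "spacing_um" in side:
            meta_spacing = VoxelSpacing(*side["spacing_um"])
        axes = axes or side.get("axes", "").upper()
        channel = channel or side.get("channel", "")

    resolved = meta_spacing or spacing
    if resolved is None:
        raise ValueError(f"{path}: no voxel spacing in OME metadata or sidecar and no override given")

    if values.ndim == 2:
        raise ValueError(f"{path}: 2D image — a z-stack is required")
    if values.ndim not in (3, 4):
        if axes:
            raise ValueError(f"{path}: unsupported axis layout {axes!r}")
        raise ValueError(f"{path}: ambiguous {values.ndim}D layout without axis metadata")
    # tifffile labels bare (non-OME) stack axes Q/S/I; anything ending in
    # YX with one (z) or two (t, z) leading axes is accepted as (t)zyx
    if axes and not axes.upper().endswith("YX"):
        raise ValueError(f"{path}: unsupported axis order {axes!r}; expected (t)zyx")
    return VoxelGrid(values, resolved, channel=channel)


def gaussian_blur_3d(
    grid: VoxelGrid, sigma_voxels: tuple[float, float, float] = (0.8, 0.8, 0.8)
) -> VoxelGrid:
    """Separable 3D Gaussian blur with sigma given in voxels, not µm.

    Default (0.8, 0.8, 0.8) voxels.  Reflective boundaries, so total
    intensity is conserved.  Applied per timepoint for 4D grids.
    """
    if any(s < 0 for s in sigma_voxels):
        raise ValueError(f"negative blur sigma {sigma_voxels}")
    vals = grid.values.astype(float, copy=False)
    if grid.is_timeseries:
        out = np.stack([ndimage.gaussian_filter(f, sigma_voxels, mode="reflect") for f in vals])
    else:
        out = ndimage.gaussian_filter(vals, sigma_voxels, mode="reflect")
    return replace(grid, values=out)


def gamma_adjust(grid: VoxelGrid, gamma: float = 0.75) -> VoxelGrid:
    """Gamma filter for display: rescale to [0, 1], then raise to ``gamma``.

    The result is flagged ``display_only`` — it must never feed a
    measurement operation.
    """
    vals = np.asarray(grid.values, dtype=float)
    if vals.min() < 0:
        raise ValueError("gamma adjustment requires nonnegative intensities")
    vmax = vals.max()
    scaled = vals / vmax if vmax > 0 else vals
    return replace(grid, values=scaled**gamma, display_only=True)
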