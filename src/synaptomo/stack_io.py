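"""Serial-section image containers, multi-page TIFF I/O and ROI cropping.

Array tomography images are acquired one ultrathin physical section at a
time; each channel of a ribbon is stored as one multi-page TIFF whose page
order is the section order.  In memory a channel becomes a 3D voxel grid
``(section, row, column)`` with strongly anisotropic calibration: in-plane
pixels of ~0.1 μm against a section thickness of 0.07 μm.

Coordinate conventions used everywhere in this package:

* voxel indices are 0-based; ``x`` maps to column, ``y`` to row, ``z`` to
  section;
* the physical centre of voxel ``(z, y, x)`` is
  ``((x + 0.5)·dx, (y + 0.5)·dy, (z + 0.5)·dz)`` in μm;
* crops are half-open ``[origin, origin + size)`` rectangles, applied to
  every section;
* a cropped stack remembers its origin offset so object centroids can be
  reported in the parent (pre-crop) frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import ConfigError, GridMismatchError

# Channel roles: what the channel's antibody labels, not the fluorophore.
ROLE_PRESYNAPSE = "presynapse"        # synaptophysin: all presynaptic terminals
ROLE_GFP = "gfp_presynapse"           # GFP: terminals of tau-expressing neurons
ROLE_POSTSYNAPSE = "postsynapse"      # PSD95: postsynaptic densities
ROLE_TAU = "tau"                      # Tau13: human tau

ALL_ROLES = (ROLE_PRESYNAPSE, ROLE_GFP, ROLE_POSTSYNAPSE, ROLE_TAU)


@dataclass
class SectionSeries:
    """Raw per-section, per-channel 2D images before alignment."""

    channels: dict[str, list[np.ndarray]]
    pixel_size_um: float
    section_thickness_um: float

    def __post_init__(self):
        if self.pixel_size_um <= 0 or self.section_thickness_um <= 0:
            raise ConfigError("calibration must be strictly positive")
        counts = {role: len(imgs) for role, imgs in self.channels.items()}
        if len(set(counts.values())) > 1:
            raise ConfigError(f"unequal section counts across channels: {counts}")
        shapes = {img.shape for imgs in self.channels.values() for img in imgs}
        if len(shapes) > 1:
            raise ConfigError(f"unequal in-plane shapes across sections: {shapes}")

    @property
    def n_sections(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(self.channels)


@dataclass
class VolumeStack:
    """Aligned 3D voxel grid for one channel, with physical calibration.

    ``origin_um`` is the (x, y) offset of this stack's voxel (.., 0, 0)
    corner in the parent coordinate frame; it starts at (0, 0) and is
    advanced by :func:`crop_roi`.
    """

    role: str
    data: np.ndarray  # (z, y, x)
    pixel_size_um: float
    section_thickness_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.size == 0:
            raise ConfigError("voxel grid must be 3D and non-empty")
        if self.pixel_size_um <= 0 or self.section_thickness_um <= 0:
            raise ConfigError("calibration must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um ** 2 * self.section_thickness_um

    @property
    def physical_volume_um3(self) -> float:
        nz, ny, nx = self.data.shape
        return nz * ny * nx * self.voxel_volume_um3

    def footprint_um(self) -> tuple[float, float]:
        """In-plane (x, y) extent in μm."""
        _, ny, nx = self.data.shape
        return nx * self.pixel_size_um, ny * self.pixel_size_um


def write_series(series: SectionSeries, paths: dict[str, str]) -> None:
    """Write one multi-page TIFF per channel; page order = section order."""
    for role, imgs in series.channels.items():
        if role not in paths:
            raise ConfigError(f"no output path for channel {role!r}")
        tifffile.imwrite(
            paths[role], np.stack(imgs, axis=0), photometric="minisblack"
        )


def read_series(
    paths: dict[str, str], pixel_size_um: float, section_thickness_um: float
) -> SectionSeries:
    """Read one multi-page TIFF per channel role into a :class:`SectionSeries`.

    Intensities are preserved exactly; an error names the offending channels
    when page counts disagree.
    """
    channels: dict[str, list[np.ndarray]] = {}
    for role, path in paths.items():
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None, ...]
        if arr.ndim != 3:
            raise ConfigError(f"channel {role!r}: expected 2D pages, got shape {arr.shape}")
        channels[role] = [arr[k] for k in range(arr.shape[0])]
    counts = {role: len(imgs) for role, imgs in channels.items()}
    if len(set(counts.values())) > 1:
        raise ConfigError(f"mismatched page counts across channels: {counts}")
    return SectionSeries(channels, pixel_size_um, section_thickness_um)


def series_to_stacks(series: SectionSeries) -> dict[str, VolumeStack]:
    """Stack each channel's sections into a (z, y, x) volume, unaligned."""
    return {
        role: VolumeStack(
            role=role,
            data=np.stack(imgs, axis=0),
            pixel_size_um=series.pixel_size_um,
            section_thickness_um=series.section_thickness_um,
        )
        for role, imgs in series.channels.items()
    }


def crop_roi(
    stack: VolumeStack, origin_um: tuple[float, float], size_um: tuple[float, float]
) -> VolumeStack:
    """Crop an in-plane ROI (all sections retained).

    The requested rectangle is rounded to whole voxels; the returned stack's
    ``origin_um`` is advanced so that parent-frame centroids are preserved.
    """
    dx = stack.pixel_size_um
    nz, ny, nx = stack.data.shape
    col0 = int(round(origin_um[0] / dx))
    row0 = int(round(origin_um[1] / dx))
    ncols = int(round(size_um[0] / dx))
    nrows = int(round(size_um[1] / dx))
    if ncols <= 0 or nrows <= 0:
        raise ConfigError(f"crop size must be positive, got {size_um} μm")
    if col0 < 0 or row0 < 0 or col0 + ncols > nx or row0 + nrows > ny:
        raise ConfigError(
            f"crop [{col0}:{col0 + ncols}) x [{row0}:{row0 + nrows}) px falls outside "
            f"the stack footprint [0:{nx}) x [0:{ny}) px"
        )
    return replace(
        stack,
        data=stack.data[:, row0 : row0 + nrows, col0 : col0 + ncols],
        origin_um=(stack.origin_um[0] + col0 * dx, stack.origin_um[1] + row0 * dx),
    )


def check_congruent(a, b) -> None:
    """Raise :class:`GridMismatchError` unless two grids share shape+calibration."""
    if a.data.shape != b.data.shape:
        raise GridMismatchError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if not (
        np.isclose(a.pixel_size_um, b.pixel_size_um)
        and np.isclose(a.section_thickness_um, b.section_thickness_um)
    ):
        raise GridMismatchError("calibration mismatch between grids")
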