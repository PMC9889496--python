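"""Oriented 3D scalar volumes with physical spacing.

All volumes in this package live in a single canonical frame: RAS axis
order ``(x, y, z)`` with x increasing toward the patient's right, y
anterior and z superior, voxel coordinates in millimetres.  NIfTI input
is reoriented to this frame on load, which removes an entire class of
left/right bookkeeping bugs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "load_nifti", "save_nifti"]


@dataclass
class Volume3D:
    """A scalar 3D image on a regular grid.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz)``; intensities or integer labels.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, all positive.
    origin
        Physical coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    @property
    def slice_zs(self) -> np.ndarray:
        """z coordinate (mm) of every axial slice centre."""
        return self.axis_coords(2)

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """New volume sharing this grid geometry."""
        return replace(self, data=data)


def resample_volume(volume: Volume3D, new_spacing_mm, order: int = 1) -> Volume3D:
    """Resample onto a new regular grid covering the same physical extent.

    ``order=1`` is trilinear (intensities), ``order=0`` nearest
    neighbour (labels).  The origin is preserved exactly.
    """
    from scipy import ndimage  # deferred; keeps module import light

    new_spacing = tuple(float(s) for s in new_spacing_mm)
    if any(s <= 0 for s in new_spacing):
        raise ValueError("new spacing must be positive")
    if new_spacing == volume.spacing:
        return Volume3D(volume.data.copy(), volume.spacing, volume.origin)
    idx = []
    for ax in range(3):
        extent = (volume.shape[ax] - 1) * volume.spacing[ax]
        n_new = int(np.floor(extent / new_spacing[ax])) + 1
        coords = volume.origin[ax] + new_spacing[ax] * np.arange(n_new)
        idx.append((coords - volume.origin[ax]) / volume.spacing[ax])
    grid = np.meshgrid(*idx, indexing="ij")
    data = volume.data if order == 0 else volume.data.astype(np.float32)
    out = ndimage.map_coordinates(data, grid, order=order, mode="nearest")
    return Volume3D(out, new_spacing, volume.origin)


def load_nifti(path) -> Volume3D:
    """Load a NIfTI file, reorienting to canonical RAS."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return Volume3D(np.asarray(data), tuple(map(float, zooms)), tuple(map(float, origin)))


def save_nifti(volume: Volume3D, path) -> None:
    data = volume.data
    if data.dtype == np.bool_:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
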