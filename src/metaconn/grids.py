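"""Voxel grids, masks, and scalar brain maps.

A :class:`BrainGrid` couples a 3D voxel lattice to world (mm) space through a
4x4 affine and carries the boolean in-brain mask on which every analysis in
this package operates (the "gray matter mask" role of coordinate-based
meta-analysis).  A :class:`VolumeMap` is a scalar field on that grid — a
modeled-activation (MA) map, an ALE map, a p/z map, or a connectivity map.

Conventions: voxel indices are 0-based, world coordinates are mm in the
right-handed axis convention of the affine, and mm -> voxel assignment snaps
to the nearest voxel center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "BrainGrid",
    "VolumeMap",
    "make_grid",
    "read_volume",
    "write_volume",
]

#: map kinds with their value constraints
_KINDS = ("MA", "ALE", "p", "z", "correlation", "tstat", "other")


class GridError(ValueError):
    """Raised for invalid grid construction or grid mismatches."""


@dataclass(frozen=True)
class BrainGrid:
    """A 3D voxel grid with a mm affine and an in-brain mask.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts per axis.
    affine : (4, 4) ndarray
        Voxel-index -> world-mm mapping (voxel centers).
    mask : ndarray of bool
        In-brain indicator, same shape as the grid.
    """

    shape: tuple
    affine: np.ndarray
    mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise GridError("affine must be 4x4")
        object.__setattr__(self, "affine", affine)
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != shape:
            raise GridError(f"mask shape {mask.shape} != grid shape {shape}")
        if not mask.any():
            raise GridError("mask is empty")
        if np.any(self.voxel_size <= 0):
            raise GridError("voxel_size must be positive on all axes")
        object.__setattr__(self, "mask", mask)

    # -- geometry ---------------------------------------------------------
    @property
    def voxel_size(self) -> np.ndarray:
        """mm per voxel along each axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def mask_indices(self) -> np.ndarray:
        """(N, 3) int array of in-mask voxel indices (C order)."""
        return np.argwhere(self.mask)

    @property
    def mask_coords_mm(self) -> np.ndarray:
        """(N, 3) world-mm coordinates of in-mask voxel centers."""
        return self.voxel_to_world(self.mask_indices)

    def voxel_to_world(self, idx) -> np.ndarray:
        """World-mm coordinates of voxel centers for integer indices."""
        arr = np.asarray(idx, dtype=float)
        single = arr.ndim == 1
        out = np.atleast_2d(arr) @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if single else out

    def world_to_voxel(self, coord_mm, strict: bool = True) -> np.ndarray:
        """Nearest-voxel-center index of world-mm coordinates.

        Raises :class:`GridError` naming the offending axis when a
        coordinate falls outside the grid extent (unless ``strict=False``,
        which clips instead).
        """
        coord = np.asarray(coord_mm, dtype=float)
        single = coord.ndim == 1
        coord = np.atleast_2d(coord)
        if not np.all(np.isfinite(coord)):
            raise GridError("non-finite world coordinate")
        inv = np.linalg.inv(self.affine)
        cont = coord @ inv[:3, :3].T + inv[:3, 3]
        idx = np.rint(cont).astype(int)
        if strict:
            for ax in range(3):
                bad = (idx[:, ax] < 0) | (idx[:, ax] >= self.shape[ax])
                if bad.any():
                    raise GridError(
                        f"coordinate out of grid extent on axis {ax}: "
                        f"{coord[bad][0].tolist()}"
                    )
        else:
            idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return idx[0] if single else idx

    def same_geometry(self, other: "BrainGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def check_same(self, other: "BrainGrid") -> None:
        if not self.same_geometry(other):
            raise GridError("grid mismatch between volumes")


@dataclass
class VolumeMap:
    """A scalar field on a :class:`BrainGrid`.

    ``data`` is a full 3D array (values outside the mask are carried but
    ignored by analyses); ``kind`` selects validation: MA/ALE maps must lie
    in [0, 1], p maps in (0, 1].
    """

    grid: BrainGrid
    data: np.ndarray
    kind: str = "other"

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; one of {_KINDS}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise GridError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        self.validate()

    def validate(self):
        vals = self.masked_values
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.kind} map contains non-finite in-mask values")
        if self.kind in ("MA", "ALE"):
            if vals.min() < 0 or vals.max() > 1:
                raise ValueError(f"{self.kind} values must lie in [0, 1]")
        elif self.kind == "p":
            if vals.min() <= 0 or vals.max() > 1:
                raise ValueError("p values must lie in (0, 1]")

    @property
    def masked_values(self) -> np.ndarray:
        """In-mask values as a 1D vector (C order over mask indices)."""
        return self.data[self.grid.mask]

    def with_data(self, data, kind=None) -> "VolumeMap":
        return VolumeMap(self.grid, data, kind or self.kind)

    def value_at_mm(self, coord_mm) -> float:
        i, j, k = self.grid.world_to_voxel(coord_mm)
        return float(self.data[i, j, k])


def make_grid(voxel_size_mm, extent_mm, mask_spec="full") -> BrainGrid:
    """Build a centered grid with a mask.

    Parameters
    ----------
    voxel_size_mm : float or 3-sequence
        Isotropic or per-axis voxel size in mm (> 0).
    extent_mm : float or 3-sequence
        Total extent covered per axis; the grid is centered on the origin.
    mask_spec : "full", ndarray, or dict
        ``"full"`` masks every voxel; a boolean array is used verbatim;
        ``{"type": "ellipsoid", "semi_axes_mm": [a, b, c]}`` masks voxel
        centers inside the origin-centered ellipsoid.
    """
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), 3).copy()
    ext = np.broadcast_to(np.asarray(extent_mm, dtype=float), 3).copy()
    if np.any(vs <= 0):
        raise GridError("voxel_size must be > 0")
    shape = tuple(int(np.floor(e / v + 1e-9)) for e, v in zip(ext, vs))
    if any(s < 1 for s in shape):
        raise GridError("extent smaller than one voxel")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    # centered origin: voxel centers symmetric about 0
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * vs

    if isinstance(mask_spec, str) and mask_spec == "full":
        mask = np.ones(shape, dtype=bool)
    elif isinstance(mask_spec, np.ndarray):
        mask = mask_spec.astype(bool)
    elif isinstance(mask_spec, dict) and mask_spec.get("type") == "ellipsoid":
        semi = np.asarray(mask_spec["semi_axes_mm"], dtype=float)
        idx = np.indices(shape).reshape(3, -1).T
        mm = idx * vs + affine[:3, 3]
        mask = ((mm / semi) ** 2).sum(axis=1) <= 1.0
        mask = mask.reshape(shape)
    else:
        raise GridError(f"unknown mask_spec {mask_spec!r}")
    return BrainGrid(shape=shape, affine=affine, mask=mask)


def write_volume(vmap: VolumeMap, path) -> None:
    """Write a map to NIfTI-1; the mask is not stored (carried by session grid)."""
    img = nib.Nifti1Image(vmap.data.astype(np.float64), vmap.grid.affine)
    nib.save(img, str(path))


def read_volume(path, grid: BrainGrid, kind: str = "other") -> VolumeMap:
    """Read a NIfTI-1 volume onto the session grid.

    Raises :class:`GridError` when the file's geometry does not match the
    session grid.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
    except Exception as exc:  # nibabel raises several header error types
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.shape != grid.shape or not np.allclose(img.affine, grid.affine, atol=1e-4):
        raise GridError(
            f"volume {path} geometry (shape {data.shape}) does not match "
            f"session grid (shape {grid.shape})"
        )
    return VolumeMap(grid, data, kind)


def mask_volume(grid: BrainGrid) -> VolumeMap:
    """The mask itself as a 0/1 map (for export)."""
    return VolumeMap(grid, grid.mask.astype(float), "other")
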