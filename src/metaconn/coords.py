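"""Stereotaxic coordinate-space conversion (Talairach <-> MNI).

Published foci come in either MNI/ICBM-152 or Talairach space.  Analyses in
this package run in MNI space; Talairach foci are converted with the pooled
Lancaster affine (vendored as JSON data in ``metaconn/data``), whose inverse
maps Talairach mm back to ICBM space.  A custom 4x4 can be supplied for any
other convention.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

__all__ = ["tal_to_mni", "mni_to_tal", "icbm2tal_matrix", "tal2icbm_matrix"]

_CACHE: dict = {}


def icbm2tal_matrix() -> np.ndarray:
    """The vendored pooled MNI->Talairach affine (4x4)."""
    if "icbm2tal" not in _CACHE:
        text = resources.files("metaconn.data").joinpath("tal2icbm.json").read_text()
        _CACHE["icbm2tal"] = np.asarray(json.loads(text)["icbm2tal_pooled"], float)
    return _CACHE["icbm2tal"].copy()


def tal2icbm_matrix() -> np.ndarray:
    """Talairach->MNI affine: matrix inverse of the pooled icbm2tal."""
    return np.linalg.inv(icbm2tal_matrix())


def _apply_affine(mat: np.ndarray, coord_mm) -> np.ndarray:
    coord = np.asarray(coord_mm, dtype=float)
    if not np.all(np.isfinite(coord)):
        raise ValueError("non-finite coordinate")
    single = coord.ndim == 1
    coord = np.atleast_2d(coord)
    if coord.shape[1] != 3:
        raise ValueError("coordinates must be 3-vectors (mm)")
    out = coord @ mat[:3, :3].T + mat[:3, 3]
    return out[0] if single else out


def tal_to_mni(coord_mm, matrix: np.ndarray | None = None) -> np.ndarray:
    """Convert Talairach mm coordinates to MNI space.

    Parameters
    ----------
    coord_mm : (3,) or (N, 3) array-like
        Finite Talairach coordinates in mm.
    matrix : (4, 4) ndarray, optional
        Override transform (applied as-is).  Default: inverse of the
        vendored pooled icbm2tal affine.
    """
    mat = tal2icbm_matrix() if matrix is None else np.asarray(matrix, float)
    return _apply_affine(mat, coord_mm)


def mni_to_tal(coord_mm, matrix: np.ndarray | None = None) -> np.ndarray:
    """Inverse of :func:`tal_to_mni` (pooled icbm2tal by default)."""
    mat = icbm2tal_matrix() if matrix is None else np.asarray(matrix, float)
    return _apply_affine(mat, coord_mm)
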