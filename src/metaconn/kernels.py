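"""Sample-size-dependent Gaussian kernels and modeled-activation (MA) maps.

Each reported focus is blurred with an isotropic 3D Gaussian whose full
width at half maximum (FWHM) reflects the spatial uncertainty of the peak:
a between-template component plus a between-subject component that shrinks
with sqrt(n).  The kernel is scaled as a probability per voxel (3D density
times voxel volume), so its values sum to ~1 over an unbounded grid and the
peak is < 1.  An experiment's MA map takes, per voxel, the MAXIMUM over
that experiment's focus kernels — the probability that the true activation
underlying at least the best-supported focus lies in that voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .grids import BrainGrid, VolumeMap

__all__ = [
    "kernel_fwhm_from_n",
    "build_kernel",
    "KernelProfile",
    "modeled_activation_map",
]

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # sd -> FWHM
#: relative truncation: kernel values below this fraction of the peak are zeroed
TRUNCATION = 1e-8


def _default_constants() -> dict:
    text = resources.files("metaconn.data").joinpath(
        "ale_kernel_constants.json"
    ).read_text()
    d = json.loads(text)
    return {
        "template_uncertainty_eud_mm": float(d["template_uncertainty_eud_mm"]),
        "subject_uncertainty_eud_mm": float(d["subject_uncertainty_eud_mm"]),
    }


def kernel_fwhm_from_n(n_subjects: int, constants: dict | None = None) -> float:
    """FWHM (mm) of the uncertainty kernel for an experiment with n subjects.

    The mean Euclidean displacement (EUD) of a 3D Gaussian with per-axis sd
    ``s`` is ``EUD = 2 s sqrt(2/pi)``; the vendored constants give the EUD
    attributable to template differences and (per subject) to between-subject
    variability, the latter divided by sqrt(n).  The two sd components add
    in quadrature and are converted to FWHM.  Strictly decreasing in n.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    c = constants or _default_constants()
    eud_to_sd = 1.0 / (2.0 * np.sqrt(2.0 / np.pi))
    sd_template = c["template_uncertainty_eud_mm"] * eud_to_sd
    sd_subject = c["subject_uncertainty_eud_mm"] * eud_to_sd / np.sqrt(n_subjects)
    return float(np.hypot(sd_template, sd_subject) * _FWHM_FACTOR)


@dataclass(frozen=True)
class KernelProfile:
    """A truncated, grid-sampled spherical Gaussian probability kernel.

    ``cube`` holds the kernel sampled at voxel-center offsets within the
    truncation radius (side ``2*halfwidth + 1`` voxels); values are the 3D
    Gaussian density times the voxel volume, zeroed below ``1e-8 * peak``.
    """

    fwhm_mm: float
    sigma_mm: float
    halfwidth: tuple
    cube: np.ndarray
    peak_value: float

    @property
    def radial_values(self) -> np.ndarray:
        """(distance_mm, value) pairs sorted by distance (non-increasing values)."""
        return self._radial

    def __post_init__(self):
        nz = self.cube > 0
        offs = np.argwhere(nz) - np.asarray(self.halfwidth)
        d = np.linalg.norm(offs * self._voxel_size, axis=1)
        order = np.argsort(d, kind="stable")
        object.__setattr__(
            self, "_radial", np.column_stack([d[order], self.cube[nz][order]])
        )

    _voxel_size: np.ndarray = None  # set by build_kernel


def build_kernel(fwhm_mm: float, grid: BrainGrid) -> KernelProfile:
    """Sample the spherical Gaussian kernel on the grid's voxel lattice."""
    if fwhm_mm <= 0:
        raise ValueError(f"fwhm must be > 0, got {fwhm_mm}")
    sigma = fwhm_mm / _FWHM_FACTOR
    vs = grid.voxel_size
    # truncation radius: density falls below TRUNCATION * peak
    r_trunc = sigma * np.sqrt(-2.0 * np.log(TRUNCATION))
    hw = tuple(int(np.ceil(r_trunc / v)) for v in vs)
    ax = [np.arange(-h, h + 1) * v for h, v in zip(hw, vs)]
    d2 = (
        ax[0][:, None, None] ** 2
        + ax[1][None, :, None] ** 2
        + ax[2][None, None, :] ** 2
    )
    peak_density = (2.0 * np.pi * sigma**2) ** -1.5
    cube = peak_density * np.exp(-d2 / (2.0 * sigma**2)) * grid.voxel_volume_mm3
    peak = float(cube.max())
    cube[cube < TRUNCATION * peak] = 0.0
    kp = KernelProfile(
        fwhm_mm=float(fwhm_mm),
        sigma_mm=float(sigma),
        halfwidth=hw,
        cube=cube,
        peak_value=peak,
        _voxel_size=vs,
    )
    return kp


def _place_max(acc_padded: np.ndarray, cube: np.ndarray, idx, hw) -> None:
    """Max-combine a kernel cube into the padded accumulator at voxel idx."""
    i, j, k = idx
    sl = (
        slice(i, i + 2 * hw[0] + 1),
        slice(j, j + 2 * hw[1] + 1),
        slice(k, k + 2 * hw[2] + 1),
    )
    np.maximum(acc_padded[sl], cube, out=acc_padded[sl])


def modeled_activation_map(
    foci_mm: np.ndarray,
    n_subjects: int | None,
    grid: BrainGrid,
    fwhm_mm: float | None = None,
    kernel: KernelProfile | None = None,
    constants: dict | None = None,
) -> VolumeMap:
    """MA map of one experiment: per-voxel max over its focus kernels.

    ``fwhm_mm`` (or a prebuilt ``kernel``) overrides the sample-size rule —
    used e.g. for the fixed 15-mm coactivation kernel.  Foci must convert
    to in-grid voxel positions; foci whose nearest voxel center is outside
    the mask still contribute to in-mask voxels through their kernel.
    """
    foci = np.atleast_2d(np.asarray(foci_mm, dtype=float))
    if foci.size == 0:
        raise ValueError("experiment with zero foci")
    if kernel is None:
        if fwhm_mm is None:
            fwhm_mm = kernel_fwhm_from_n(n_subjects, constants=constants)
        kernel = build_kernel(fwhm_mm, grid)
    hw = kernel.halfwidth
    padded = np.zeros(tuple(s + 2 * h for s, h in zip(grid.shape, hw)))
    idx = grid.world_to_voxel(foci)
    idx = np.atleast_2d(idx)
    for row in idx:
        _place_max(padded, kernel.cube, row, hw)
    data = padded[hw[0] : hw[0] + grid.shape[0],
                  hw[1] : hw[1] + grid.shape[1],
                  hw[2] : hw[2] + grid.shape[2]]
    return VolumeMap(grid, data, "MA")
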