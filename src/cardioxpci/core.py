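"""Core data containers shared across the pipeline.

Conventions
-----------
* Volumes are indexed ``(z, y, x)``; after long-axis alignment ``z`` runs
  apex to base.  Voxel indices are 0-based; physical coordinates are
  voxel-centre micrometres.
* Direction vectors are stored with components ordered ``(z, y, x)`` to
  match array axes, so ``(1, 0, 0)`` points along the z axis.
* Angles are degrees at every public interface; radians are internal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Planck * c in keV * m; lambda [m] = HC_KEV_M / energy [keV].
HC_KEV_M = 1.2398e-9


@dataclass
class Volume3D:
    """A 3D scalar image with isotropic voxel size.

    Parameters
    ----------
    data : ndarray, shape (z, y, x)
        Scalar voxel values.  Infinities are rejected; NaN is permitted
        as the documented not-a-value sentinel outside masks.
    voxel_size : float
        Isotropic voxel edge length in micrometres.
    origin : tuple of float
        Physical (z, y, x) coordinates of the centre of voxel (0, 0, 0),
        in micrometres.
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.data.dtype.kind == "f" and np.any(np.isinf(self.data)):
            raise ValueError("volume contains infinite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class AcquisitionConfig:
    """Propagation-based phase-contrast acquisition parameters.

    Defaults mirror the low-resolution whole-heart setup: 20 keV
    monochromatic beam, 3.33 m propagation distance, 5.8 um effective
    pixel size, delta/beta tuned to 56.9.  The high-resolution local
    setup uses 0.20 m and 0.65 um with the same energy and delta/beta.

    ``delta`` is the refractive-index decrement of the (assumed
    homogeneous) tissue; together with ``delta_beta`` it fixes the
    absorption coefficient ``mu = 4 pi beta / lambda``.
    """

    energy_kev: float = 20.0
    propagation_distance_m: float = 3.33
    pixel_size_um: float = 5.8
    delta_beta: float = 56.9
    delta: float = 5.76e-7  # soft tissue at 20 keV
    n_projections: int = 2501
    n_darks: int = 20
    n_flats: int = 50

    def __post_init__(self) -> None:
        if not self.energy_kev > 0:
            raise ValueError("energy_kev must be > 0")
        if self.propagation_distance_m < 0:
            raise ValueError("propagation_distance_m must be >= 0")
        if not self.delta_beta > 0:
            raise ValueError("delta_beta must be > 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.delta > 0:
            raise ValueError("delta must be > 0")

    @property
    def wavelength_m(self) -> float:
        """X-ray wavelength, lambda = hc / E."""
        return HC_KEV_M / self.energy_kev

    @property
    def beta(self) -> float:
        """Imaginary part of the refractive index decrement."""
        return self.delta / self.delta_beta

    @property
    def mu(self) -> float:
        """Linear attenuation coefficient in 1/m, mu = 4 pi beta / lambda."""
        return 4.0 * np.pi * self.beta / self.wavelength_m

    @property
    def paganin_coefficient_m2(self) -> float:
        """R * delta / mu, the Fourier-filter strength in m^2."""
        return self.propagation_distance_m * self.delta / self.mu


@dataclass
class ProjectionStack:
    """Detector-frame projection data with acquisition angles.

    ``data`` is ``(n_angles, n_rows, n_cols)`` intensity (or, after
    retrieval, projected thickness).  ``axis_offset`` is the signed
    distance in pixels of the rotation axis from the detector centre
    column ``n_cols // 2`` (positive = axis right of centre).
    """

    data: np.ndarray
    angles: np.ndarray
    darks: np.ndarray | None = None
    flats: np.ndarray | None = None
    axis_offset: float = 0.0
    corrected: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("projection data must be (n_angles, rows, cols)")
        if self.angles.shape != (self.data.shape[0],):
            raise ValueError("one angle per projection required")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        for name, f in (("darks", self.darks), ("flats", self.flats)):
            if f is not None and np.asarray(f).shape[-2:] != self.data.shape[1:]:
                raise ValueError(f"{name} do not match detector shape")

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    @property
    def detector_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def sinogram(self, row: int) -> "Sinogram":
        """Extract the single-row sinogram for detector row ``row``."""
        return Sinogram(self.data[:, row, :].copy(), self.angles.copy(),
                        axis_offset=self.axis_offset)


@dataclass
class Sinogram:
    """Angle x detector-column view of one reconstruction slice."""

    data: np.ndarray
    angles: np.ndarray
    axis_offset: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("sinogram data must be (n_angles, cols)")
        if self.angles.shape != (self.data.shape[0],):
            raise ValueError("one angle per row required")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")


@dataclass
class CardiacFrame:
    """Straight-long-axis cardiac coordinate frame.

    ``long_axis`` is a unit vector in (z, y, x) component order oriented
    base to apex; ``point`` is a point on the axis in voxel coordinates.
    The per-voxel radial direction points from the axis through the
    voxel; circumferential is ``long_axis x radial``; longitudinal is
    the long axis itself.  ``axis_ratio`` records the PCA elongation of
    the mask the frame was fitted to (< 1.1 flags an ill-defined axis).
    """

    long_axis: np.ndarray
    point: np.ndarray
    axis_ratio: float = float("inf")

    def __post_init__(self) -> None:
        self.long_axis = as_unit_vector(self.long_axis)
        self.point = np.asarray(self.point, dtype=float)


def as_unit_vector(v, tol: float = 1e-6) -> np.ndarray:
    """Validate that ``v`` is a 3-vector of unit norm (z, y, x order)."""
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError("direction must be a 3-vector (z, y, x)")
    n = np.linalg.norm(v)
    if abs(n - 1.0) > tol:
        raise ValueError(
            f"direction must have unit norm (|v| = {n:.6g}); "
            "normalize with v / np.linalg.norm(v)")
    return v


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
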