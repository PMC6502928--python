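"""Synthetic cardiac phantoms with exact ground truth.

Generates fibre-textured myocardium volumes, a cylindrical-annulus
"ventricular wall" with a prescribed linear transmural helical-angle
ramp, dual-rendering collagen phantoms at a controlled collagen volume
fraction, and linearised free-space-propagated projection stacks with
synthetic flat/dark fields.  Every generator returns the ground truth
(orientation field, helical angle, class labels, tissue mask) alongside
the rendered volume, so each downstream stage can be scored against a
known answer.

The propagation forward model is the linearised transport-of-intensity
form ``I_R = I_c - (R delta / mu) * laplacian(I_c)``, applied as the
Fourier multiplier ``1 + (R delta / mu) k^2``: single-distance phase
retrieval with the matching filter is then its exact inverse, which is
what makes the retrieval round trip testable to machine precision.
Full Fresnel diffraction (fringes) is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.transform import radon

from .core import (AcquisitionConfig, CardiacFrame, ProjectionStack, Volume3D,
                   as_unit_vector, warn)

# Rendering intensity levels (normalised units).
FIBER_LEVEL = 0.8
BACKGROUND_LEVEL = 0.2
WALL_MATRIX_LEVEL = 0.4

# Class labels.
LBL_BACKGROUND = 0
LBL_CARDIOMYOCYTE = 1
LBL_COLLAGEN = 2


@dataclass
class PhantomSpec:
    """Generative description of a synthetic cardiac volume.

    All lengths in micrometres.  ``noise_sigma`` is the standard
    deviation of additive Gaussian noise as a fraction of the unit
    dynamic range.  The same spec with the same seed always produces
    bit-identical output.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 5.8
    fiber_radius: float = 11.6       # ~2 voxels at LR scale
    fiber_spacing: float = 34.8      # ~6 voxels
    ha_endo: float = 60.0
    ha_epi: float = -60.0
    wall_inner_radius: float = 100.0
    wall_outer_radius: float = 330.0
    collagen_fraction: float = 0.05
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("voxel_size", "fiber_radius", "fiber_spacing",
                     "wall_inner_radius", "wall_outer_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError("shape must be three axes of at least 4 voxels")
        if not self.wall_inner_radius < self.wall_outer_radius:
            raise ValueError("wall_inner_radius must be < wall_outer_radius")
        for name in ("ha_endo", "ha_epi"):
            if not -90.0 <= getattr(self, name) <= 90.0:
                raise ValueError(f"{name} must lie in [-90, 90] degrees")
        if not 0.0 <= self.collagen_fraction <= 0.5:
            raise ValueError("collagen_fraction must lie in [0, 0.5]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    # voxel-unit conveniences
    @property
    def fiber_radius_vox(self) -> float:
        return self.fiber_radius / self.voxel_size

    @property
    def fiber_spacing_vox(self) -> float:
        return self.fiber_spacing / self.voxel_size


@dataclass
class GroundTruth:
    """Per-voxel truth carried by every phantom.

    ``orientation`` has shape (z, y, x, 3) with (z, y, x)-ordered unit
    vectors where ``tissue_mask`` is true (zeros elsewhere);
    ``helical_angle`` is degrees in [-90, 90] with NaN where undefined.
    """

    orientation: np.ndarray
    helical_angle: np.ndarray
    labels: np.ndarray
    tissue_mask: np.ndarray
    frame: CardiacFrame | None = None


def _grid_coords(shape):
    """Voxel-centre index grids as float32, (z, y, x) each of ``shape``."""
    return np.meshgrid(*(np.arange(s, dtype=np.float32) for s in shape),
                       indexing="ij")


def _poisson_disk_2d(rng, radius: float, spacing: float, n_attempts: int = 4000):
    """Dart-throwing Poisson-disk sample in a disk of given radius."""
    pts: list[np.ndarray] = []
    for _ in range(n_attempts):
        u = rng.uniform(-radius, radius, size=2)
        if u @ u > radius * radius:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - u, axis=1)) < spacing:
            continue
        pts.append(u)
    return np.array(pts) if pts else np.empty((0, 2))


def make_fiber_texture(spec: PhantomSpec, direction) -> tuple[Volume3D, GroundTruth]:
    """Quasi-parallel bright cylinders along ``direction``.

    Cylinder centrelines are Poisson-disk placed in the plane normal to
    ``direction`` at minimum spacing ``spec.fiber_spacing`` and rendered
    as bright (0.8) rods of radius ``spec.fiber_radius`` on a dark (0.2)
    background, plus additive Gaussian noise.  Ground-truth orientation
    equals ``direction`` at every cylinder voxel.
    """
    d = as_unit_vector(direction)
    if spec.fiber_spacing < 2.0 * spec.fiber_radius:
        raise ValueError(
            "fiber_spacing must be >= 2 * fiber_radius (fibres would overlap)")
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)

    # orthonormal basis of the plane normal to d
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    half_diag = 0.5 * float(np.linalg.norm(shape))
    centres = _poisson_disk_2d(rng, half_diag + spec.fiber_spacing_vox,
                               spec.fiber_spacing_vox)

    zz, yy, xx = _grid_coords(shape)
    c0 = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    rz, ry, rx = zz - c0[0], yy - c0[1], xx - c0[2]
    u = rz * e1[0] + ry * e1[1] + rx * e1[2]
    v = rz * e2[0] + ry * e2[1] + rx * e2[2]

    # exact nearest-centreline distance in the transverse plane
    tree = cKDTree(centres)
    pts = np.column_stack([u.ravel(), v.ravel()])
    dist, _ = tree.query(pts, k=1)
    mask = (dist.reshape(shape) <= spec.fiber_radius_vox)

    data = np.full(shape, BACKGROUND_LEVEL, dtype=np.float32)
    data[mask] = FIBER_LEVEL
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, shape).astype(np.float32)

    orientation = np.zeros(shape + (3,), dtype=np.float32)
    orientation[mask] = d.astype(np.float32)
    labels = np.where(mask, LBL_CARDIOMYOCYTE, LBL_BACKGROUND).astype(np.uint8)
    ha = np.full(shape, np.nan, dtype=np.float32)
    gt = GroundTruth(orientation=orientation, helical_angle=ha, labels=labels,
                     tissue_mask=mask,
                     frame=CardiacFrame(np.array([1.0, 0.0, 0.0]), c0))
    return Volume3D(data, spec.voxel_size), gt


def _annulus_frame_fields(spec: PhantomSpec):
    """Analytic wall mask, depth and tangent frame for the annulus phantom.

    Returns (wall, depth, circ, longit) with circ/longit unit fields of
    shape (z, y, x, 3).  Depth is 0 at the inner (endocardial) surface
    and 1 at the outer (epicardial) surface.
    """
    shape = tuple(spec.shape)
    zz, yy, xx = _grid_coords(shape)
    c0 = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    ry, rx = yy - c0[1], xx - c0[2]
    rho = np.sqrt(ry * ry + rx * rx) * spec.voxel_size  # um
    wall = (rho >= spec.wall_inner_radius) & (rho <= spec.wall_outer_radius)
    depth = (rho - spec.wall_inner_radius) / (
        spec.wall_outer_radius - spec.wall_inner_radius)

    with np.errstate(invalid="ignore", divide="ignore"):
        rho_vox = np.sqrt(ry * ry + rx * rx)
        ny = np.where(rho_vox > 0, ry / rho_vox, 0.0)
        nx = np.where(rho_vox > 0, rx / rho_vox, 0.0)
    # radial = (0, ny, nx); longitudinal = z; circumferential = L x R
    circ = np.stack([np.zeros_like(ny), nx, -ny], axis=-1)
    longit = np.zeros(shape + (3,), dtype=np.float32)
    longit[..., 0] = 1.0
    return wall, depth, circ.astype(np.float32), longit


def helical_ramp(depth, ha_endo: float, ha_epi: float):
    """Linear transmural helical-angle ramp HA(d) in degrees."""
    return ha_endo + (ha_epi - ha_endo) * np.asarray(depth)


def make_ventricle_phantom(spec: PhantomSpec) -> tuple[Volume3D, GroundTruth]:
    """Cylindrical-annulus ventricular wall with a linear HA ramp.

    The wall (inner/outer radius from the spec) around the z axis is
    filled with short bright fibre segments whose direction at each
    seed follows the analytic helical-angle field
    ``HA(d) = ha_endo + (ha_epi - ha_endo) * d`` in the local
    circumferential-longitudinal tangent plane, where ``d`` is the
    normalised transmural depth.  Ground truth carries the analytic
    orientation and HA at every wall voxel.
    """
    shape = tuple(spec.shape)
    max_r_um = (min(shape[1], shape[2]) - 1) / 2.0 * spec.voxel_size
    if spec.wall_outer_radius > max_r_um:
        raise ValueError(
            f"wall_outer_radius {spec.wall_outer_radius} um exceeds the "
            f"volume half-width {max_r_um:.1f} um")
    rng = np.random.default_rng(spec.seed)

    wall, depth, circ, longit = _annulus_frame_fields(spec)
    ha_true = np.where(wall, helical_ramp(depth, spec.ha_endo, spec.ha_epi),
                       np.nan).astype(np.float32)
    ha_rad = np.deg2rad(ha_true)
    orientation = np.zeros(shape + (3,), dtype=np.float32)
    cosha = np.cos(ha_rad)[..., None]
    sinha = np.sin(ha_rad)[..., None]
    ofield = cosha * circ + sinha * longit
    orientation[wall] = ofield[wall]

    # fibre texture: streamlines integrated through the analytic
    # direction field, so every texture voxel is tangent to the local
    # helical direction.  Density targets ~15-20% occupancy in the wall.
    wall_idx = np.argwhere(wall)
    n_wall = len(wall_idx)
    half_len = 12.0  # voxels each way from the seed
    n_sticks = max(1, int(0.0018 * n_wall))
    seeds = wall_idx[rng.integers(0, n_wall, size=n_sticks)].astype(np.float64)

    def field_at(pos):
        """Analytic helical direction at float positions (n, 3)."""
        ry = pos[:, 1] - c_yx[0]
        rx = pos[:, 2] - c_yx[1]
        r = np.sqrt(ry * ry + rx * rx)
        r = np.where(r > 0, r, 1.0)
        ny, nx = ry / r, rx / r
        dep = np.clip((r * spec.voxel_size - spec.wall_inner_radius)
                      / (spec.wall_outer_radius - spec.wall_inner_radius),
                      0.0, 1.0)
        ang = np.deg2rad(helical_ramp(dep, spec.ha_endo, spec.ha_epi))
        return np.stack([np.sin(ang), np.cos(ang) * nx, -np.cos(ang) * ny],
                        axis=1)

    c0 = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    c_yx = (c0[1], c0[2])
    step = 0.5
    pts = [seeds]
    for sign in (1.0, -1.0):
        pos = seeds.copy()
        for _ in range(int(half_len / step)):
            pos = pos + sign * step * field_at(pos)
            pts.append(pos.copy())
    idx = np.rint(np.concatenate(pts)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    fiber = np.zeros(shape, dtype=bool)
    fiber[tuple(idx[ok].T)] = True
    fiber = ndimage.binary_dilation(
        fiber, structure=ndimage.generate_binary_structure(3, 1))
    fiber &= wall

    data = np.full(shape, BACKGROUND_LEVEL, dtype=np.float32)
    data[wall] = WALL_MATRIX_LEVEL
    data[fiber] = FIBER_LEVEL
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, shape).astype(np.float32)

    labels = np.where(wall, LBL_CARDIOMYOCYTE, LBL_BACKGROUND).astype(np.uint8)
    c0 = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    frame = CardiacFrame(np.array([1.0, 0.0, 0.0]), c0)
    gt = GroundTruth(orientation=orientation, helical_angle=ha_true,
                     labels=labels, tissue_mask=wall, frame=frame)
    return Volume3D(data, spec.voxel_size), gt


def _collagen_strand(rng, shape, z_extent) -> np.ndarray:
    """Voxel indices of one jittered near-axial strand centreline."""
    z0 = rng.integers(0, max(1, shape[0] - z_extent))
    y = float(rng.uniform(2, shape[1] - 3))
    x = float(rng.uniform(2, shape[2] - 3))
    vy, vx = rng.normal(0.0, 0.15, size=2)
    pts = []
    for z in range(z0, min(shape[0], z0 + z_extent)):
        vy += rng.normal(0.0, 0.08)
        vx += rng.normal(0.0, 0.08)
        vy, vx = np.clip([vy, vx], -0.5, 0.5)
        y = float(np.clip(y + vy, 1, shape[1] - 2))
        x = float(np.clip(x + vx, 1, shape[2] - 2))
        pts.append((z, int(round(y)), int(round(x))))
    return np.array(pts, dtype=int)


def make_collagen_phantom(
    spec: PhantomSpec,
) -> tuple[Volume3D, Volume3D, GroundTruth]:
    """Cardiomyocyte texture plus thin bright collagen strands, rendered twice.

    Strands are jittered near-axial splines dilated to ~1 voxel radius,
    added by rejection until the collagen voxel count reaches
    ``collagen_fraction`` of the cardiomyocyte voxel count to within
    0.1 percentage points.  Two renderings of the single ground truth
    are returned:

    * *retrieved-style*: smoothed, high cell/background contrast but
      collagen barely brighter than cells;
    * *non-retrieved-style*: sharp, high collagen contrast, lower
      cell/background contrast and more noise.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)

    # cardiomyocyte rods along z
    zz_spec = PhantomSpec(shape=shape, voxel_size=spec.voxel_size,
                          fiber_radius=spec.fiber_radius,
                          fiber_spacing=spec.fiber_spacing,
                          noise_sigma=0.0, seed=spec.seed)
    _, cell_gt = make_fiber_texture(zz_spec, (1.0, 0.0, 0.0))
    cells = cell_gt.tissue_mask.copy()

    labels = np.where(cells, LBL_CARDIOMYOCYTE, LBL_BACKGROUND).astype(np.uint8)
    target = spec.collagen_fraction
    tol = 0.001  # +-0.1 percentage points
    struct = ndimage.generate_binary_structure(3, 1)

    if target > 0:
        for _ in range(10000):
            n_col = int((labels == LBL_COLLAGEN).sum())
            n_cell = int((labels == LBL_CARDIOMYOCYTE).sum())
            if n_cell == 0:
                raise ValueError(
                    "no cardiomyocyte voxels left; requested collagen "
                    f"fraction {target} unreachable in shape {shape} "
                    f"(achieved {n_col / max(n_col + n_cell, 1):.4f})")
            frac = n_col / n_cell
            if frac >= target - tol:
                break
            strand = ndimage.binary_dilation(
                _mask_from_points(_collagen_strand(rng, shape, shape[0] // 2),
                                  shape), structure=struct)
            new = np.argwhere(strand & (labels != LBL_COLLAGEN))
            # trim the last strand voxel-by-voxel to land inside tolerance
            for z, y, x in new:
                was_cell = labels[z, y, x] == LBL_CARDIOMYOCYTE
                labels[z, y, x] = LBL_COLLAGEN
                n_col += 1
                n_cell -= int(was_cell)
                if n_col / n_cell >= target:
                    break
            if n_col / n_cell >= target - tol:
                break
        else:
            raise ValueError(
                f"collagen fraction {target} unreachable in shape {shape}; "
                f"achieved {frac:.4f}")

    cells = labels == LBL_CARDIOMYOCYTE
    collagen = labels == LBL_COLLAGEN

    # retrieved-style: smooth, strong cell/background separation
    retr = np.full(shape, 0.2, dtype=np.float32)
    retr[cells] = 0.8
    retr[collagen] = 0.85
    retr = ndimage.gaussian_filter(retr, 1.0)
    if spec.noise_sigma > 0:
        retr = retr + rng.normal(0.0, spec.noise_sigma, shape).astype(np.float32)

    # non-retrieved-style: sharp, strong collagen contrast, noisier
    nonretr = np.full(shape, 0.45, dtype=np.float32)
    nonretr[cells] = 0.55
    nonretr[collagen] = 0.95
    nonretr = ndimage.gaussian_filter(nonretr, 0.3)
    if spec.noise_sigma > 0:
        nonretr = nonretr + rng.normal(
            0.0, 1.5 * spec.noise_sigma, shape).astype(np.float32)

    orientation = np.zeros(shape + (3,), dtype=np.float32)
    orientation[cells] = np.array([1.0, 0.0, 0.0], dtype=np.float32)
    ha = np.full(shape, np.nan, dtype=np.float32)
    gt = GroundTruth(orientation=orientation, helical_angle=ha, labels=labels,
                     tissue_mask=cells | collagen, frame=None)
    return (Volume3D(retr, spec.voxel_size),
            Volume3D(nonretr, spec.voxel_size), gt)


def _mask_from_points(pts: np.ndarray, shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    if len(pts):
        m[tuple(pts.T)] = True
    return m


# ---------------------------------------------------------------------------
# forward projection model
# ---------------------------------------------------------------------------

def propagation_multiplier(shape, acq: AcquisitionConfig) -> np.ndarray:
    """Fourier multiplier ``1 + (R delta / mu) k^2`` on the detector grid.

    Angular spatial frequencies ``k = 2 pi * fftfreq / pixel_size`` in
    rad/m; the multiplier acts on the 2D FFT of a (rows, cols) frame.
    """
    px_m = acq.pixel_size_um * 1e-6
    kr = 2.0 * np.pi * np.fft.fftfreq(shape[0], d=px_m)
    kc = 2.0 * np.pi * np.fft.fftfreq(shape[1], d=px_m)
    k2 = kr[:, None] ** 2 + kc[None, :] ** 2
    return 1.0 + acq.paganin_coefficient_m2 * k2


def _propagate_linearized(frames: np.ndarray, acq: AcquisitionConfig) -> np.ndarray:
    """Apply ``I - (R delta/mu) lap(I)`` per frame via the FFT multiplier."""
    mult = propagation_multiplier(frames.shape[1:], acq)
    out = np.fft.ifft2(np.fft.fft2(frames) * mult).real
    return out


def project_thickness(volume: Volume3D, angles) -> np.ndarray:
    """Parallel-beam projected thickness maps, metres, centred axis.

    ``volume.data`` is a material-fraction map; each z slice is radon
    transformed and scaled by the voxel size.  The output detector width
    is the padded (diagonal) width used by ``skimage.transform.radon``
    with ``circle=False``, with the rotation axis at column ``W // 2``.
    """
    angles = np.asarray(angles, dtype=float)
    vol = np.asarray(volume.data, dtype=float)
    sinos = [radon(vol[z], theta=angles, circle=False) for z in range(vol.shape[0])]
    # radon returns (det, n_angles); stack to (n_angles, z, det)
    s = np.stack(sinos, axis=0)            # (z, det, n_angles)
    s = np.moveaxis(s, 2, 0)               # (n_angles, z, det)
    return s * (volume.voxel_size * 1e-6)


def simulate_projections(
    obj,
    acq: AcquisitionConfig,
    n_angles: int = 64,
    axis_offset: float = 0.0,
    angular_span: float = 180.0,
    detector_width: int | None = None,
    flat_gain_amplitude: float = 0.1,
    dark_level: float = 0.02,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ProjectionStack:
    """Simulate a propagation-based phase-contrast projection stack.

    Parameters
    ----------
    obj : Volume3D or ndarray
        Either an object volume (material fraction; line integrals give
        projected thickness) or a pre-computed thickness map in metres:
        a 2D array (one frame, replicated per angle) or a 3D
        ``(n_angles, rows, cols)`` stack.
    acq : AcquisitionConfig
        Beam energy, propagation distance, pixel size and delta/beta.
    n_angles : int
        Number of equispaced projection angles over ``angular_span``.
    axis_offset : float
        Signed rotation-axis displacement from the detector centre
        column, in pixels; used for 360-degree extended-FoV emulation.
    angular_span : float
        180 for a standard scan, 360 for an offset scan.
    detector_width : int, optional
        Detector column count.  Defaults to the full (padded) projection
        width for volume input, or the frame width for thickness input.
    flat_gain_amplitude, dark_level : float
        Amplitude of the smooth multiplicative flat-field gain pattern
        and the additive dark offset.
    noise_sigma : float
        Additive Gaussian noise (fraction of I0) on projections, flats
        and darks; 0 gives the exact linearised model.

    Notes
    -----
    Contact intensity is ``I_c = I0 exp(-mu T)``; the propagated frame
    is ``I_R = I_c - (R delta/mu) lap(I_c)`` applied as a periodic
    Fourier multiplier, making single-distance retrieval (unpadded) its
    exact inverse.  Negative intensities after propagation are clipped
    to zero with a warning (validity limit of the linearised model).
    """
    if n_angles < 2:
        raise ValueError("n_angles must be >= 2")
    rng = np.random.default_rng(seed)
    angles = np.linspace(0.0, angular_span, n_angles, endpoint=False)

    if isinstance(obj, Volume3D):
        thick = project_thickness(obj, angles)       # (n_angles, z, det_full)
        full_w = thick.shape[2]
        cen = full_w // 2
        if detector_width is None:
            detector_width = full_w
        w = detector_width
        # detector column s samples centred coordinate t = s - w//2 - offset
        lo = cen - w // 2 - int(round(axis_offset))
        if lo < 0 or lo + w > full_w:
            pad = max(-lo, lo + w - full_w)
            thick = np.pad(thick, ((0, 0), (0, 0), (pad, pad)))
            lo += pad
        thick = thick[:, :, lo:lo + w]
    else:
        thick = np.asarray(obj, dtype=float)
        if thick.ndim == 2:
            thick = np.broadcast_to(thick, (n_angles,) + thick.shape).copy()
        elif thick.ndim == 3:
            if thick.shape[0] != n_angles:
                raise ValueError("thickness stack length must equal n_angles")
        else:
            raise ValueError("thickness input must be 2D or 3D")

    contact = np.exp(-acq.mu * thick)
    frames = _propagate_linearized(contact, acq)
    if np.any(frames < 0):
        warn("negative intensities after linearised propagation were clipped "
             "(model validity limit)")
        frames = np.clip(frames, 0.0, None)

    det_shape = frames.shape[1:]
    # smooth multiplicative gain pattern for the flats
    gain = np.ones(det_shape)
    if flat_gain_amplitude > 0:
        g = np.random.default_rng(seed + 1).normal(size=det_shape)
        g = ndimage.gaussian_filter(g, sigma=max(det_shape) / 8.0)
        g /= max(np.abs(g).max(), 1e-12)
        gain = 1.0 + flat_gain_amplitude * g

    darks = np.full((acq.n_darks,) + det_shape, dark_level)
    flats = np.broadcast_to(gain + dark_level,
                            (acq.n_flats,) + det_shape).copy()
    data = frames * gain[None] + dark_level
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, data.shape)
        flats = flats + rng.normal(0.0, noise_sigma, flats.shape)
        darks = darks + rng.normal(0.0, noise_sigma / 4.0, darks.shape)

    return ProjectionStack(data=data, angles=angles, darks=darks, flats=flats,
                           axis_offset=float(axis_offset))
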