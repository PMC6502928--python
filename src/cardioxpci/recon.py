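"""Projection processing and tomographic reconstruction.

Flat/dark-field correction, single-distance phase retrieval, conversion
of 360-degree offset-axis scans to centred 180-degree sinograms,
slice-by-slice parallel-beam filtered back-projection, and vertical
stitching of overlapping reconstructed volumes.

The retrieval filter divides the 2D Fourier transform of each
normalised projection by ``1 + (R delta / mu) (k_x^2 + k_y^2)`` with
angular frequencies ``k = 2 pi fftfreq / pixel_size`` and returns
projected thickness ``T = -(1/mu) ln(filtered I / I0)``.  Filtered
back-projection replaces the Fourier-regridding reconstructor used on
beamline clusters; at desk scale they target the same reconstruction.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal
from skimage.transform import iradon

from .core import AcquisitionConfig, ProjectionStack, Sinogram, Volume3D, warn

#: floor applied to normalised intensity before the logarithm
INTENSITY_FLOOR = 1e-6

_FILTERS = {"ramlak": "ramp", "ramp": "ramp",
            "shepp": "shepp-logan", "shepp-logan": "shepp-logan",
            "hann": "hann"}


def flat_field_correct(stack: ProjectionStack) -> ProjectionStack:
    """Normalise projections by dark/flat fields.

    Output data are ``(I - mean(darks)) / (mean(flats) - mean(darks))``,
    clipped below at a small positive floor.  Pixels where the mean flat
    does not exceed the mean dark are imputed from their nearest valid
    neighbour before the division.
    """
    if stack.darks is None or stack.flats is None:
        raise ValueError("at least one dark and one flat field are required")
    det = stack.detector_shape
    dark = np.mean(np.asarray(stack.darks).reshape((-1,) + det), axis=0)
    flat = np.mean(np.asarray(stack.flats).reshape((-1,) + det), axis=0)
    denom = flat - dark
    bad = denom <= 0
    if np.any(bad):
        warn(f"{int(bad.sum())} detector pixels have flat <= dark; "
             "imputed from nearest valid neighbours")
        idx = ndimage.distance_transform_edt(bad, return_distances=False,
                                             return_indices=True)
        denom = denom[tuple(idx)]
        dark = np.where(bad, dark[tuple(idx)], dark)
    corrected = (stack.data - dark[None]) / denom[None]
    corrected = np.clip(corrected, INTENSITY_FLOOR, None)
    return ProjectionStack(data=corrected, angles=stack.angles.copy(),
                           darks=None, flats=None,
                           axis_offset=stack.axis_offset, corrected=True)


def paganin_retrieve(stack: ProjectionStack, acq: AcquisitionConfig,
                     pad: bool = True) -> ProjectionStack:
    """Single-distance phase retrieval of projected thickness.

    Per projection, ``T = -(1/mu) ln( IFFT[ FFT(I/I0) /
    (1 + R delta/mu (k_x^2 + k_y^2)) ] )`` on the detector grid.  The
    filter has unit DC gain, so the mean transmission (hence mean
    log-transmission) of each frame is preserved.

    Parameters
    ----------
    stack : ProjectionStack
        Flat-field-corrected projections (``I/I0``).
    acq : AcquisitionConfig
        Supplies wavelength, ``R``, ``delta/beta`` and ``mu``.
    pad : bool
        Edge-pad each projection to twice its size before the FFT to
        suppress wraparound (default, appropriate for measured data).
        With ``pad=False`` the unpadded periodic transform is used,
        which is the exact inverse of the linearised forward model.

    Returns
    -------
    ProjectionStack
        Retrieved projected-thickness frames in metres.
    """
    if not stack.corrected:
        raise ValueError("stack must be flat-field corrected before retrieval")
    from .phantom import propagation_multiplier  # shared grid convention

    frames = np.asarray(stack.data, dtype=float)
    n, rows, cols = frames.shape
    if pad:
        pr, pc = rows // 2, cols // 2
        work = np.pad(frames, ((0, 0), (pr, pr), (pc, pc)), mode="edge")
    else:
        work = frames
    mult = propagation_multiplier(work.shape[1:], acq)
    filt = np.fft.ifft2(np.fft.fft2(work) / mult).real
    if pad:
        filt = filt[:, pr:pr + rows, pc:pc + cols]

    n_floored = int(np.count_nonzero(filt < INTENSITY_FLOOR))
    if n_floored:
        warn(f"{n_floored} non-positive intensities floored before log")
    filt = np.clip(filt, INTENSITY_FLOOR, None)
    thickness = -np.log(filt) / acq.mu
    return ProjectionStack(data=thickness, angles=stack.angles.copy(),
                           darks=None, flats=None,
                           axis_offset=stack.axis_offset, corrected=True)


def negative_log(stack: ProjectionStack) -> ProjectionStack:
    """Line integrals ``-ln(I/I0)`` of a corrected stack (absorption mode)."""
    if not stack.corrected:
        raise ValueError("stack must be flat-field corrected first")
    data = -np.log(np.clip(stack.data, INTENSITY_FLOOR, None))
    return ProjectionStack(data=data, angles=stack.angles.copy(),
                           axis_offset=stack.axis_offset, corrected=True)


# ---------------------------------------------------------------------------
# 360-degree offset scans
# ---------------------------------------------------------------------------

def estimate_axis_offset(s: Sinogram, n_pairs: int = 8) -> float:
    """Rotation-axis offset (px) from mirrored theta / theta+180 rows.

    Cross-correlates each row with the column-reversed row half a turn
    later; the correlation peak, refined to sub-pixel resolution by
    parabolic interpolation, locates the axis.  Averaged over
    ``n_pairs`` angle pairs.
    """
    angles = s.angles
    w = s.data.shape[1]
    step = np.median(np.diff(angles))
    span = angles[-1] - angles[0] + step
    if span < 360.0 - step / 2:
        raise ValueError("axis estimation needs a full 360-degree scan")
    half = len(angles) // 2
    offsets = []
    for i in np.linspace(0, half - 1, n_pairs).astype(int):
        j = int(np.argmin(np.abs(angles - (angles[i] + 180.0))))
        r1 = s.data[i] - s.data[i].mean()
        r2r = s.data[j][::-1] - s.data[j].mean()
        cc = signal.correlate(r1, r2r, mode="full")
        p = int(np.argmax(cc))
        lag = float(p - (w - 1))
        if 0 < p < len(cc) - 1:  # parabolic sub-pixel refinement
            y0, y1, y2 = cc[p - 1], cc[p], cc[p + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                lag += 0.5 * (y0 - y2) / denom
        a = (lag + w - 1) / 2.0          # axis column
        offsets.append(a - w // 2)
    return float(np.mean(offsets))


def sino_360_to_180(s: Sinogram, axis_offset: float | None = None) -> Sinogram:
    """Convert a 360-degree offset-axis sinogram to a centred 180-degree one.

    Rows at ``theta`` and ``theta + 180`` view the same rays mirrored
    about the rotation axis; they are resampled onto a common widened
    detector grid centred on the axis and blended with linear feathering
    across the overlap.  The output ``axis_offset`` is 0.

    If the offset is neither given nor stored on the sinogram it is
    estimated by mirrored cross-correlation and logged via a warning.
    """
    angles = s.angles
    step = np.median(np.diff(angles))
    if angles[-1] - angles[0] + step < 360.0 - step / 2:
        raise ValueError("input must span (close to) 360 degrees")
    if axis_offset is None:
        axis_offset = s.axis_offset
        if axis_offset == 0.0:
            axis_offset = estimate_axis_offset(s)
            warn(f"rotation-axis offset estimated at {axis_offset:+.2f} px")

    w = s.data.shape[1]
    a = w // 2 + axis_offset                     # axis column (float)
    half = len(angles) // 2
    out_angles = angles[:half].copy()

    half_w = max(a, (w - 1) - a)
    wout = 2 * int(np.floor(half_w)) + 1
    t = np.arange(wout, dtype=float) - wout // 2  # signed distance from axis

    s1 = t + a          # sample positions in the theta rows
    s2 = a - t          # mirrored sample positions in the theta+180 rows
    in1 = (s1 >= 0) & (s1 <= w - 1)
    in2 = (s2 >= 0) & (s2 <= w - 1)
    # feather weights: distance to the nearest edge of each row's support
    w1 = np.where(in1, np.minimum(s1, (w - 1) - s1) + 1.0, 0.0)
    w2 = np.where(in2, np.minimum(s2, (w - 1) - s2) + 1.0, 0.0)
    tot = w1 + w2
    tot[tot == 0] = 1.0
    w1, w2 = w1 / tot, w2 / tot

    out = np.zeros((half, wout))
    cols = np.arange(w, dtype=float)
    for i in range(half):
        j = int(np.argmin(np.abs(angles - (angles[i] + 180.0))))
        r1 = np.interp(s1, cols, s.data[i], left=0.0, right=0.0)
        r2 = np.interp(s2, cols, s.data[j], left=0.0, right=0.0)
        out[i] = w1 * r1 + w2 * r2
    return Sinogram(data=out, angles=out_angles, axis_offset=0.0)


# ---------------------------------------------------------------------------
# filtered back-projection
# ---------------------------------------------------------------------------

def fbp_reconstruct_sinogram(s: Sinogram, filter_name: str = "ramlak",
                             output_size: int | None = None) -> np.ndarray:
    """FBP of a single centred sinogram; returns a (N, N) slice."""
    if filter_name not in _FILTERS:
        raise ValueError(f"unknown filter {filter_name!r}; "
                         f"choose from {sorted(set(_FILTERS))}")
    if abs(s.axis_offset) > 0.01:
        raise ValueError("sinogram must be centred (run sino_360_to_180 first)")
    if np.any(~np.isfinite(s.data)):
        raise ValueError("NaNs/inf in sinogram")
    if len(s.angles) < 16:
        warn("fewer than 16 angles: expect severe streaking")
    step = np.median(np.diff(s.angles))
    if s.angles[-1] - s.angles[0] + step < 180.0 - step / 2:
        raise ValueError("angles must cover at least 180 degrees")
    size = output_size or s.data.shape[1]
    return iradon(s.data.T, theta=s.angles, filter_name=_FILTERS[filter_name],
                  circle=False, output_size=size)


def fbp_reconstruct(stack: ProjectionStack, filter_name: str = "ramlak",
                    voxel_size_um: float | None = None,
                    scale: float = 1.0) -> Volume3D:
    """Slice-by-slice parallel-beam FBP of a line-integral stack.

    ``stack.data`` must already be in line-integral form (retrieved
    thickness or ``-ln(I/I0)``).  ``scale`` multiplies the output, e.g.
    ``1 / pixel_size_m`` to convert thickness integrals in metres back
    to a material-fraction map.  The output voxel size equals the
    detector pixel size.
    """
    if np.any(~np.isfinite(stack.data)):
        raise ValueError("NaNs/inf in projection data")
    n_rows = stack.data.shape[1]
    slices = [fbp_reconstruct_sinogram(stack.sinogram(r), filter_name)
              for r in range(n_rows)]
    vol = np.stack(slices, axis=0) * scale
    return Volume3D(vol, voxel_size=voxel_size_um or 1.0)


# ---------------------------------------------------------------------------
# vertical stitching
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def fit_overlap(a: np.ndarray, b: np.ndarray, nominal: int,
                margin: int = 10) -> tuple[int, float]:
    """Best integer z-overlap between the bottom of ``a`` and top of ``b``.

    Searches ``nominal +- margin`` maximising normalised cross
    correlation of the overlapping slabs; returns (overlap, ncc).
    """
    zmax = min(a.shape[0], b.shape[0])
    best, best_c = nominal, -np.inf
    for o in range(max(1, nominal - margin), min(zmax, nominal + margin) + 1):
        c = _ncc(a[-o:], b[:o])
        if c > best_c:
            best, best_c = o, c
    return best, best_c


def stitch_vertical(volumes: list[Volume3D], nominal_overlap: int,
                    search_margin: int = 10,
                    corr_threshold: float = 0.5) -> Volume3D:
    """Stitch vertically overlapping volumes into one.

    Consecutive pairs are registered by maximising normalised cross
    correlation of their overlap slabs within ``nominal_overlap +-
    search_margin`` and blended with a linear ramp across the fitted
    overlap.  If the correlation peak falls below ``corr_threshold``
    the nominal overlap is used with a warning.
    """
    if not volumes:
        raise ValueError("no volumes to stitch")
    if len(volumes) == 1:
        return volumes[0]
    if nominal_overlap <= 0:
        raise ValueError("nominal_overlap must be > 0")
    vs = volumes[0].voxel_size
    lat = volumes[0].data.shape[1:]
    for v in volumes[1:]:
        if v.data.shape[1:] != lat or v.voxel_size != vs:
            raise ValueError("volumes must share lateral shape and voxel size")

    out = np.asarray(volumes[0].data, dtype=float)
    for v in volumes[1:]:
        b = np.asarray(v.data, dtype=float)
        o, c = fit_overlap(out, b, nominal_overlap, search_margin)
        if c < corr_threshold:
            warn(f"overlap correlation {c:.2f} below {corr_threshold}; "
                 f"falling back to nominal overlap {nominal_overlap}")
            o = nominal_overlap
        wgt = np.linspace(0.0, 1.0, o + 2)[1:-1][:, None, None]
        blended = (1.0 - wgt) * out[-o:] + wgt * b[:o]
        out = np.concatenate([out[:-o], blended, b[o:]], axis=0)
    return Volume3D(out, voxel_size=vs, origin=volumes[0].origin)
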