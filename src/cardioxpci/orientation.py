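"""Myofibre orientation by the gradient structure-tensor method.

The structure tensor at each voxel is the Gaussian-windowed outer
product of Gaussian-derivative gradients,

    J = G_rho * (grad_sigma I . grad_sigma I^T),

with derivative scale ``sigma`` and integration scale ``rho``.  The
eigenvector of the smallest eigenvalue spans the direction of least
intensity variation and is taken as the local fibre axis (the
orientation is sign-ambiguous: v and -v are the same fibre).

Helical angle (HA) is the angle between the fibre direction projected
onto the local circumferential-longitudinal wall plane and the
circumferential direction: ~0 deg for circumferential fibres, +-90 deg
for longitudinal ones, folded into (-90, 90] because of the sign
ambiguity.  Transmural profiles sample HA along a line from one
endocardial surface to the other with circular-aware averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CardiacFrame, Volume3D, warn
from .mask import TissueMask

_TRIU = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


@dataclass
class StructureTensorParams:
    """Scales of the structure tensor, in micrometres.

    ``sigma_gradient`` (derivative scale) should sit below the width of
    a myocyte bundle; ``sigma_window`` (integration scale) should span
    several bundles.  Defaults correspond to 2 and 6 voxels at the
    5.8 um whole-heart scale.
    """

    sigma_gradient: float = 11.6
    sigma_window: float = 34.8

    def __post_init__(self) -> None:
        if not (self.sigma_gradient > 0 and self.sigma_window > 0):
            raise ValueError("structure-tensor scales must be > 0")
        if self.sigma_window < self.sigma_gradient:
            raise ValueError("sigma_window must be >= sigma_gradient")


@dataclass
class StructureTensorField:
    """Per-voxel symmetric 3x3 tensor, upper triangle stored as 6 planes.

    Component order: (zz, zy, zx, yy, yx, xx).
    """

    data: np.ndarray  # (z, y, x, 6)
    params: StructureTensorParams

    @property
    def shape(self):
        return self.data.shape[:3]

    def full_tensor(self) -> np.ndarray:
        """Assemble the dense (z, y, x, 3, 3) symmetric tensor."""
        out = np.empty(self.shape + (3, 3), dtype=self.data.dtype)
        for k, (i, j) in enumerate(_TRIU):
            out[..., i, j] = self.data[..., k]
            out[..., j, i] = self.data[..., k]
        return out


@dataclass
class OrientationField:
    """Per-voxel unit fibre direction (sign-ambiguous) and confidence.

    ``vectors`` has (z, y, x)-ordered components; undefined voxels are
    NaN.  ``confidence`` is ``1 - l1/l2`` (eigenvalues l1 <= l2 <= l3),
    in [0, 1]: 0 for isotropic neighbourhoods, ->1 for clean fibres.
    """

    vectors: np.ndarray      # (z, y, x, 3)
    confidence: np.ndarray   # (z, y, x)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.vectors[..., 0])


@dataclass
class HelicalAngleMap:
    """Per-voxel helical angle in degrees, NaN outside tissue."""

    data: np.ndarray
    voxel_size: float = 1.0


@dataclass
class TransmuralProfile:
    """HA sampled along a transmural segment.

    ``depth`` runs 0 (first endpoint, endocardial) to 1 (second
    endpoint); ``ha_deg`` is NaN where no defined voxels fell inside the
    averaging window (gaps are recorded, never interpolated).
    """

    depth: np.ndarray
    ha_deg: np.ndarray
    n_voxels: np.ndarray
    endpoints: tuple = ()


def structure_tensor(v: Volume3D, p: StructureTensorParams) -> StructureTensorField:
    """Gradient structure tensor of a volume.

    Gaussian-derivative gradients at scale ``sigma_gradient`` followed
    by componentwise Gaussian windowing at ``sigma_window``; scales are
    given in micrometres and converted to voxels internally.
    """
    sig = p.sigma_gradient / v.voxel_size
    rho = p.sigma_window / v.voxel_size
    data = np.asarray(v.data, dtype=np.float32)
    grads = [ndimage.gaussian_filter(data, sig, order=tuple(int(a == i) for a in range(3)))
             for i in range(3)]
    out = np.empty(data.shape + (6,), dtype=np.float32)
    for k, (i, j) in enumerate(_TRIU):
        out[..., k] = ndimage.gaussian_filter(grads[i] * grads[j], rho)
    return StructureTensorField(out, p)


def _chunked_eigh(tensors: np.ndarray, chunk: int = 1 << 18):
    """Eigendecomposition of (N, 3, 3) symmetric tensors in chunks."""
    n = tensors.shape[0]
    vals = np.empty((n, 3), dtype=np.float32)
    vecs = np.empty((n, 3, 3), dtype=np.float32)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        w, q = np.linalg.eigh(tensors[lo:hi])
        vals[lo:hi] = w
        vecs[lo:hi] = q
    return vals, vecs


def principal_fiber_direction(t: StructureTensorField,
                              confidence_floor: float = 0.05) -> OrientationField:
    """Fibre direction as the smallest-eigenvalue eigenvector.

    Confidence is ``1 - l1/l2``; voxels below ``confidence_floor`` —
    isotropic or degenerate (l1 ~ l2) neighbourhoods — are marked
    undefined (NaN) rather than guessed.  Vector signs are canonicalised
    so the largest-magnitude component is positive.
    """
    shape = t.shape
    full = t.full_tensor().reshape(-1, 3, 3)
    vals, vecs = _chunked_eigh(full)
    l1, l2 = vals[:, 0], vals[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        conf = np.where(l2 > 0, 1.0 - l1 / np.maximum(l2, 1e-30), 0.0)
    conf = np.clip(conf, 0.0, 1.0).astype(np.float32)
    v = vecs[:, :, 0]

    # sign canonicalisation: largest |component| made positive
    lead = np.take_along_axis(v, np.argmax(np.abs(v), axis=1)[:, None], axis=1)
    v = v * np.sign(np.where(lead == 0, 1.0, lead))

    undef = conf < confidence_floor
    v[undef] = np.nan
    return OrientationField(v.reshape(shape + (3,)),
                            conf.reshape(shape))


def estimate_long_axis(m: TissueMask) -> CardiacFrame:
    """Long axis as the principal axis of the mask voxel cloud.

    The axis is the largest-variance eigenvector of the coordinate
    covariance, oriented base to apex by the heavier-mass convention
    (positive skewness of the projected coordinates points toward the
    apex).  The frame point is the mask centroid.
    """
    coords = np.argwhere(m.data).astype(float)
    if len(coords) < 2:
        raise ValueError("mask has fewer than 2 voxels; no axis definable")
    centroid = coords.mean(axis=0)
    rel = coords - centroid
    cov = rel.T @ rel / len(rel)
    w, q = np.linalg.eigh(cov)
    axis = q[:, -1]
    ratio = float(np.sqrt(w[-1] / max(w[-2], 1e-30)))
    if ratio < 1.1:
        warn(f"near-spherical mask (axis ratio {ratio:.3f}); "
             "long axis is ill-defined")
    proj = rel @ axis
    skew = np.mean(proj ** 3)
    if abs(skew) > 1e-9:
        axis = axis * np.sign(skew)
    else:
        lead = axis[np.argmax(np.abs(axis))]
        axis = axis * np.sign(lead if lead != 0 else 1.0)
    return CardiacFrame(long_axis=axis, point=centroid, axis_ratio=ratio)


def _cross_zyx(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product for vectors stored in (z, y, x) component order."""
    return np.cross(a[..., ::-1], b[..., ::-1])[..., ::-1]


def local_frame_fields(shape, f: CardiacFrame, eps: float = 1e-6):
    """Per-voxel radial and circumferential unit fields for a frame.

    Returns ``(radial, circ, on_axis)``; ``on_axis`` marks voxels whose
    distance to the long axis is below ``eps`` voxels.
    """
    grids = np.meshgrid(*(np.arange(s, dtype=np.float32) for s in shape),
                        indexing="ij")
    rel = np.stack(grids, axis=-1) - f.point.astype(np.float32)
    L = f.long_axis.astype(np.float32)
    axial = rel @ L
    radial = rel - axial[..., None] * L
    r = np.linalg.norm(radial, axis=-1)
    on_axis = r < eps
    with np.errstate(invalid="ignore", divide="ignore"):
        radial = radial / np.where(r[..., None] > 0, r[..., None], 1.0)
    circ = _cross_zyx(np.broadcast_to(L, radial.shape), radial)
    return radial, circ, on_axis


def helical_angle(o: OrientationField, f: CardiacFrame) -> HelicalAngleMap:
    """Helical angle of an orientation field in a cardiac frame.

    At each voxel the fibre vector is projected onto the tangent
    (circumferential-longitudinal) plane; ``HA = atan2(v.L, v.C)``
    folded into (-90, 90] degrees, identical for v and -v.  Voxels on
    the axis, with undefined orientation, or with (numerically) purely
    radial fibres get the NaN sentinel.
    """
    shape = o.vectors.shape[:3]
    _, circ, on_axis = local_frame_fields(shape, f)
    L = f.long_axis.astype(np.float32)
    v = o.vectors
    comp_l = v @ L
    comp_c = np.einsum("...i,...i->...", v, circ)
    ha = np.degrees(np.arctan2(comp_l, comp_c))
    ha = np.where(ha > 90.0, ha - 180.0, ha)
    ha = np.where(ha <= -90.0, ha + 180.0, ha)
    bad = on_axis | ~o.defined
    bad |= (np.abs(comp_l) < 1e-9) & (np.abs(comp_c) < 1e-9)  # purely radial
    ha = np.where(bad, np.nan, ha).astype(np.float32)
    return HelicalAngleMap(ha)


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Mean of axial (180-degree-periodic) angles via angle doubling."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float) * 2.0)
    m = 0.5 * np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))
    out = np.degrees(m)
    return float(out + 180.0) if out <= -90.0 else float(out)


def average_transmural_profiles(profiles) -> TransmuralProfile:
    """Circular-aware mean of transmural profiles sampled on a common grid.

    The original wall analysis averages a region (several transmural
    rays), not a single line; this combines per-ray profiles with the
    doubled-angle mean at each depth, skipping recorded gaps.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    depth = profiles[0].depth
    for p in profiles[1:]:
        if not np.array_equal(p.depth, depth):
            raise ValueError("profiles must share their depth grid")
    arr = np.array([p.ha_deg for p in profiles])
    doubled = np.deg2rad(arr * 2.0)
    with np.errstate(invalid="ignore"):
        mean = 0.5 * np.degrees(np.arctan2(np.nanmean(np.sin(doubled), 0),
                                           np.nanmean(np.cos(doubled), 0)))
    counts = np.sum([p.n_voxels for p in profiles], axis=0)
    mean = np.where(np.all(np.isnan(arr), axis=0), np.nan, mean)
    return TransmuralProfile(depth=depth, ha_deg=mean, n_voxels=counts,
                             endpoints=profiles[0].endpoints)


def transmural_profile(ha: HelicalAngleMap, endpoints, n_samples: int = 20,
                       averaging_radius: float = 17.4) -> TransmuralProfile:
    """Sample HA along a transmural segment.

    ``endpoints`` are two (z, y, x) voxel-coordinate points (endocardial
    on each side of the wall); at each of ``n_samples`` equispaced
    points the circular-aware mean of defined HA voxels within
    ``averaging_radius`` (micrometres) is taken.  Windows with no
    defined voxels yield NaN.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    p0, p1 = (np.asarray(p, dtype=float) for p in endpoints)
    r_vox = averaging_radius / ha.voxel_size
    shape = ha.data.shape
    depth = np.linspace(0.0, 1.0, n_samples)
    out = np.full(n_samples, np.nan)
    counts = np.zeros(n_samples, dtype=int)

    rad = int(np.ceil(r_vox))
    offs = np.argwhere(np.ones((2 * rad + 1,) * 3)) - rad
    offs = offs[np.linalg.norm(offs, axis=1) <= r_vox]
    for k, d in enumerate(depth):
        p = p0 + d * (p1 - p0)
        idx = np.rint(p).astype(int) + offs
        ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
        vals = ha.data[tuple(idx[ok].T)]
        vals = vals[np.isfinite(vals)]
        counts[k] = len(vals)
        if len(vals):
            out[k] = circular_mean_deg(vals)
    return TransmuralProfile(depth=depth, ha_deg=out, n_voxels=counts,
                             endpoints=(tuple(p0), tuple(p1)))
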