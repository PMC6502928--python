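# Methods

This note records the models, parameter choices and numerical
conventions behind `cardioxpci`, and what the synthetic validation does
and does not establish about real beamline data.

## Conventions

Volumes are indexed `(z, y, x)` with isotropic voxel size in
micrometres; physical coordinates are voxel-centre micrometres.
Direction vectors store components in `(z, y, x)` order, so `(1, 0, 0)`
points along the rotation / long axis. Angles are degrees at every
public interface and radians internally. All randomness flows through
`numpy.random.default_rng(seed)`; identical seeds give bit-identical
phantoms and artifacts.

## Forward model and phase retrieval

The simulator implements the linearised (transport-of-intensity
consistent) propagation model: contact intensity `I_c = I₀ exp(−µT)`
followed by `I_R = I_c − (Rδ/µ)∇²I_c`, applied as the periodic Fourier
multiplier `1 + (Rδ/µ)k²` with `k = 2π·fftfreq/pixel_size` (rad/m).
This model is chosen deliberately so that the single-distance retrieval
filter is its *exact* inverse, giving a machine-precision round-trip
test of both implementations. Full Fresnel diffraction (edge fringes)
is out of scope: the simulator validates the processing chain, not the
optics.

Consequences worth knowing:

* Retrieval offers `pad=True` (default; edge-pads each projection to
  twice its size before the FFT, standard practice for measured data)
  and `pad=False`, the unpadded periodic transform that exactly inverts
  the simulator. The round-trip validation uses `pad=False`.
* The periodic forward model assumes negligible thickness at the frame
  border; objects touching the border wrap around, ring under the
  `1 + αk²` amplification, and may clip at zero intensity (a warning is
  emitted — this is the validity limit of the linearised model, not a
  bug).
* The attenuation coefficient needs an absolute `δ`, not only `δ/β`;
  the default `δ = 5.76e−7` is representative of soft tissue at 20 keV.
  With the tuned `δ/β = 56.9` this yields `µ ≈ 2050 m⁻¹`. The ratio is
  an empirically tuned retrieval parameter rather than a physical
  constant, so `µ` should be read as a model parameter; every
  validation quantity here is either relative or scale-free.
* Intensities are floored at `1e−6·I₀` before logarithms.

## Reconstruction

Filtered back-projection (`skimage.transform.iradon`, filters ram-lak /
shepp-logan / hann) reconstructs each detector row independently. The
Fourier-regridding reconstructor used on beamline clusters targets the
same inversion; at package scale direct FBP is simpler and fast enough.

Offset (extended-FoV) scans: a 360° scan with the rotation axis
displaced by `o` pixels from the detector centre is converted to a
centred 180° sinogram. Rows at θ and θ+180° are resampled by linear
interpolation onto a common axis-centred grid of width `≈ W + 2|o|` and
blended with weights proportional to each row's distance from its own
detector edge — a linear feather across the overlap that degrades
gracefully for any offset sign or magnitude. The axis position is
estimated from the cross-correlation of each row with the
column-reversed row half a turn later, with parabolic sub-pixel peak
refinement, averaged over eight angle pairs; on noiseless phantoms the
recovery is accurate to well under 0.1 px (the package commits to
±0.5 px).

Vertical stitching fits the integer overlap between consecutive volumes
by maximising normalised cross-correlation within
`nominal ± search_margin` (default margin 10), then blends with a
linear ramp. Ramp blending of identical data is the identity, so a
volume split and restitched is recovered to machine precision; a
correlation peak below 0.5 falls back to the nominal overlap with a
warning.

For orientation analysis the pipeline reconstructs in *absorption*
mode (`−ln(I/I₀)`, no retrieval) by default: at the whole-organ
settings the retrieval filter is a ~5-pixel low-pass that visibly
washes out the fibre texture the structure tensor needs. Retrieved-mode
reconstruction (`recon: {mode: paganin}`) remains available and is what
the collagen branch emulates at high resolution.

## Tissue mask

Gaussian smoothing (default 11.6 µm), Otsu threshold, binary closing
with a radius-2 ball, per-slice hole filling, largest 3-D connected
component. The threshold is histogram-derived, so the mask is invariant
under positive intensity rescaling. Per-slice hole filling closes
chamber cross-sections — intended for whole-heart masks; note it also
fills the cavity of the annulus phantom, which is why the demo pipeline
derives its transmural ray from thresholded intensity rather than from
the filled mask.

## Structure tensor, helical angle, profiles

`J = G_ρ ∗ (∇_σ I · ∇_σ Iᵀ)` with Gaussian-derivative gradients.
Defaults σ = 11.6 µm, ρ = 34.8 µm (2 and 6 voxels at 5.8 µm): σ below a
myocyte-bundle width, ρ spanning several bundles. Both are config
parameters; the 64³ demo uses 1 and 3 voxels because its wall is only
~20 voxels thick. The fibre axis is the smallest-eigenvalue
eigenvector; confidence is `1 − ℓ₁/ℓ₂` (eigenvalues ℓ₁ ≤ ℓ₂ ≤ ℓ₃) and
voxels below the confidence floor (default 0.05) — isotropic or
degenerate neighbourhoods — are marked undefined rather than guessed.
Eigen-decomposition runs in 2¹⁸-voxel chunks; tensors are stored as six
upper-triangle planes in float32.

The cardiac frame uses a straight long axis: the largest-variance
eigenvector of the mask coordinate covariance, oriented so positive
skewness of the projected coordinates points to the apex (the heavier
end is the base); a curved centreline is out of scope. Helical angle is
`atan2(v·L̂, v·Ĉ)` folded to (−90°, 90°]; the fold makes HA identical
for `v` and `−v`, with the single convention that −90° is reported
as +90°. Profiles average defined HA voxels in a ball (default radius
~2 voxels) at equispaced points between two endpoints, using the
doubled-angle circular mean to avoid wraparound bias near ±90°; windows
with no defined voxels are recorded as gaps, never interpolated.
`average_transmural_profiles` combines rays at several azimuths the way
a wall-region profile is measured in practice.

## Phantoms (what they emulate, what they do not)

* **Fibre texture** — parallel bright cylinders (radius ~2 voxels,
  Poisson-disk spacing ~6 voxels, intensity 0.8 on 0.2) along an
  arbitrary direction; nearest-centreline distances are exact (k-d
  tree). Emulates aligned myocyte bundles for orientation validation.
* **Ventricular wall** — a cylindrical annulus around z filled with
  short fibre *streamlines integrated through the analytic helical
  field*, so every texture voxel is tangent to the prescribed
  direction; the helical angle ramps linearly with normalised
  transmural depth from `ha_endo` to `ha_epi`. Default wall
  100–330 µm (128³); the 160³ validation uses 120–440 µm. The wall is
  deliberately thick relative to ρ: when the wall is only ~5ρ across,
  one-sided windows at the surfaces mix depths asymmetrically and
  compress the recovered ramp — visible in the 64³ demo and quantified
  below.
* **Collagen subvolume** — cardiomyocyte rods along z plus jittered
  near-axial strands dilated to ~1-voxel radius, added (and trimmed
  voxel-wise) until the collagen/cardiomyocyte count ratio matches the
  requested fraction within 0.1 percentage points. Two renderings of
  the single truth: retrieved-style (smoothed σ=1, cell 0.8 vs
  background 0.2, collagen barely brighter than cells) and
  non-retrieved-style (sharp, collagen 0.95 vs cell 0.55, 1.5× noise) —
  reproducing the contrast trade-off that motivates dual-reconstruction
  fusion.
* **Noise** — additive Gaussian on normalised intensity (default
  σ = 0.05 of the dynamic range); Poisson counting noise, detector PSF,
  ring artifacts and beam hardening are not modelled.

Passing tests on these phantoms establishes that the *processing* is
correct and well-conditioned at realistic contrasts and noise; it does
not establish robustness to optics and detector effects absent from the
generator.

## Voxel classification and fusion

Features: raw intensity plus, per scale (default 1, 2, 4 voxels),
Gaussian-smoothed intensity, gradient magnitude, Laplacian of Gaussian
and the three Hessian eigenvalues — float32, deterministic. Classifier:
`RandomForestClassifier` (100 trees, `min_samples_leaf=2`, fixed seed,
single-threaded for reproducibility), retrainable with added labels to
mirror the iterative annotate–train–correct loop. The annotation
emulator draws uniform per-class samples *plus* samples from the
2-voxel shell around collagen: annotators concentrate labels around the
structures of interest, and without near-strand negatives the
classifier dilates thin strands — at 1% collagen that alone moves the
Dice from ~0.78 to ~0.99.

Fusion: a voxel is collagen iff the non-retrieved segmentation says so;
otherwise the retrieved volume's cell/background call stands. A
retrieved collagen call without non-retrieved support takes the
retrieved volume's more likely non-collagen class (cardiomyocyte when
probabilities are unavailable). The collagen fraction defaults to the
cardiomyocyte-only denominator with the convention recorded in every
report; the cardiomyocyte-plus-collagen variant is a flag away, since
"with respect to cellular area" is ambiguous between the two.

Sparse-plane interpolation blends per-class signed distance fields
linearly between labelled planes (labelled planes are reproduced
exactly); an object present in a single plane is extruded halfway to
its neighbours with a warning.

## Validation problem sizes and measured behaviour

The self-validation (`scripts/acceptance.py`, mirrored in
`tests/test_acceptance.py`) uses: 128²-pixel, 64-angle stacks for the
retrieval round trip (error ~1e−15); 128-pixel discs at 512/720 angles
for FBP fidelity, extended-FoV agreement and axis recovery; 24³ volumes
with 11³ windows for the brute-force structure-tensor oracle (~1e−9);
64³ fibre phantoms at five orientations (mean error ~0.3°, rotation
equivariance ~0.8°); a 160³ ventricle for the ramp (slope within a few
percent of −120°/depth, region-averaged RMSE ~3°); 128³ collagen
phantoms at 1/5/10% (fraction error < 0.1 pp, Dice > 0.99); and the 64³
demo pipeline for byte-level determinism. These sizes keep the full
validation within a few minutes on one CPU.

## Known limitations

* The structure tensor carries a curvature-coupling bias on strongly
  curved, thin-walled geometry: with ρ = 6 voxels and wall radii of a
  few tens of voxels, recovered HA can deviate systematically by 2–5°,
  and much more when the wall is thinner than ~5ρ. At real whole-heart
  scale (walls hundreds of voxels thick) the effect is negligible; at
  phantom scale it is the dominant error term and is why ramp recovery
  is validated at 160³ with a thick wall.
* The frame assumes a straight long axis; apex geometry and curved
  centrelines are not modelled.
* The linearised propagation model excludes Fresnel fringes, so the
  retrieval exactness result is a statement about the inverse filter,
  not about full-diffraction data.
* Collagen separability in the phantom is intentionally clean
  (strand/cell contrast ≫ noise); infarct-zone scar tissue, where
  classes genuinely overlap, is out of scope.
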