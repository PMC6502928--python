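# cardioxpci

Multiscale propagation-based X-ray phase-contrast (PB-X-PCI) cardiac
image analysis: single-distance phase retrieval, tomographic
reconstruction with extended-field-of-view support and vertical
stitching, gradient structure-tensor myofibre orientation with
helical-angle mapping, and dual-reconstruction collagen quantification —
all exercised end to end on synthetic phantoms with exact ground truth.

## Who this is for

Synchrotron tomography of excised hearts images the whole organ at
~5.8 µm (overall shape, chambers, myofibre architecture) and local
regions at ~0.65 µm (cardiomyocytes, collagen strands, microvessels).
`cardioxpci` packages the downstream analysis of such scans for
researchers who want a tested, scriptable version of that processing
chain — and, because beamline data are rarely redistributable, ships a
first-class synthetic-phantom module so every stage can be validated
without beamline access.

## The methods at its core

**Phase retrieval.** In free-space propagation mode the measured frame
is modelled (to first order) as
`I_R = I_c − (Rδ/µ)∇²I_c`, where `I_c = I₀ exp(−µT)` is the contact
intensity, `T` the projected thickness, `R` the propagation distance,
`δ/β` the refractive-index ratio and `µ = 4πβ/λ`. The single-distance
retrieval filter divides the 2-D Fourier transform of `I/I₀` by
`1 + (Rδ/µ)(k_x² + k_y²)` and returns
`T = −(1/µ) ln(filtered)`. Because the simulator uses exactly this
linearised forward model, retrieval inverts it to machine precision —
a property the test suite asserts. Defaults mirror a two-microscope
setup: 20 keV, `δ/β = 56.9`, 3.33 m / 5.8 µm (whole-organ) and
0.20 m / 0.65 µm (local).

**Reconstruction.** Projections are flat/dark corrected, optionally
retrieved, and reconstructed slice-by-slice by parallel-beam filtered
back-projection. Scans acquired over 360° with the rotation axis offset
from the detector centre (to cover an object wider than the field of
view) are converted to centred 180° sinograms by mirroring about the
axis with linear feathering; the axis position is recovered to sub-pixel
precision from mirrored cross-correlation. Vertically overlapping scans
are stitched by normalised cross-correlation and ramp blending.

**Fibre orientation.** The gradient structure tensor
`J = G_ρ ∗ (∇_σ I · ∇_σ Iᵀ)` is computed with Gaussian-derivative
gradients at scale σ and a Gaussian integration window ρ. The
eigenvector of the smallest eigenvalue — the direction of least
intensity variation — is the local fibre axis. In a cardiac frame
(straight long axis `L̂` fitted by PCA of the tissue mask, per-voxel
radial `R̂` and circumferential `Ĉ = L̂ × R̂`), the helical angle is
`HA = atan2(v·L̂, v·Ĉ)` folded into (−90°, 90°]: ~0° circumferential,
±90° longitudinal. Transmural profiles sample HA from endocardium to
epicardium with circular-aware (doubled-angle) averaging.

**Collagen quantification.** Cardiomyocytes, collagen and background
are segmented by a seeded random-forest voxel classifier over a
multi-scale feature bank (smoothed intensity, gradient magnitude,
Laplacian, Hessian eigenvalues), trained from sparse annotations in the
iterative label–train–correct workflow. Segmentations of the two
reconstructions of the same subvolume are fused by a fixed rule — the
collagen label is kept from the sharper non-retrieved reconstruction,
the cell/background call from the higher-cell-contrast retrieved one —
and the collagen fraction is reported as
`f_c = 100 · N_collagen / N_cardiomyocyte` (the
cardiomyocyte-plus-collagen denominator is also available). Sparse 2-D
slice annotations are lifted to 3-D by linear signed-distance-field
interpolation.

## Worked example

Run the full demo pipeline (64³ annulus phantom with a +60° → −60°
transmural helical-angle ramp, plus a 48³ collagen subvolume at 5%
collagen):

```python
from cardioxpci.pipeline import run_pipeline

result = run_pipeline(out_dir="demo_out", seed=42)
profile = result.artifacts["profile"]
for d, ha in zip(profile.depth, profile.ha_deg):
    print(f"{d:.2f}  {ha:6.1f}")
print(result.artifacts["collagen_report"].to_dict())
```

which prints (abbreviated):

```
0.00    44.4
0.27    34.3
0.53    24.2
0.80     8.0
1.00    -1.5
{'region': 'demo_subvolume',
 'counts': {'background': 85028, 'cardiomyocyte': 24345, 'collagen': 1219},
 'collagen_fraction_pct': 5.007, 'denominator': 'cardiomyocyte'}
```

The profile descends monotonically across the wall — the generated
ramp, compressed by the structure-tensor window at this deliberately
tiny demo scale (see `docs/methods.md`) — and the collagen fraction of
the 5%-collagen phantom is recovered at 5.01%. At the 160³ validation
scale the fitted ramp slope is within a few percent of the generated
−120°/unit-depth. `demo_out/` receives the phantom, reconstruction,
mask, HA map (TIFF), profile (CSV), collagen report (JSON) and a
provenance record; reruns with the same config and seed are
byte-identical.

The same stages are scriptable from the shell:

```bash
cardioxpci run --seed 42 --out demo_out
cardioxpci mask segment volume.tif mask.tif
cardioxpci orient ha volume.tif mask.tif ha.tif --profile-csv profile.csv
```

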