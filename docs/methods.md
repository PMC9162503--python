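# Methods

## Optics model

The imaging chain is a microscope objective (focal length `fMO`) followed by
an EFTL at distance `d` from the objective's back principal plane and a
sensor at distance `D` from the EFTL. EFTL optical power `P` is taken as
affine in the drive current through two calibration endpoints (stock values:
+3 diopters at +270 mA, −2 diopters at −230 mA, i.e. 0.01 diopter/mA); the
linearity assumption is the same one that makes the blur radius linear in
the current difference. The equivalent power of the doublet is

    feq⁻¹ = fMO⁻¹ + P − fMO⁻¹ P d ,

the lateral magnification and focus shift are

    M(P) = P⁻¹ fMO⁻¹ + (D − P⁻¹) feq⁻¹ ,
    z(P) = − fMO P (D − P⁻¹) / M(P) .

This grouping of terms was chosen because it simultaneously reproduces the
two aggregate figures of the stock configuration (fMO = 9 mm, D = 10 cm,
d = 5 cm): an axial focusing range of ≈ 211 µm and a maximum relative
magnification change of ≈ 15.9% across the −2..+3 diopter sweep. All
computation is in SI; the public API takes mm/cm/µm/mA as documented.
`P = 0` makes `P⁻¹` singular and is rejected with a dedicated error; `z` is
continuous through that point in the limit, but the parametrization is not,
and no acquisition current in practice maps to exactly zero power.

## Registration

Because the EFTL does not sit in the illumination path, total collected
energy is slice-independent; only the magnification (hence field of view)
varies with current. `register_stack` therefore equalizes slice energies
against a reference slice. The geometric scale applied about the image
center comes either from the optics model (`mode="model"`, default:
`M(j_ref)/M(j_k)`, deterministic) or from the energy ratio itself
(`mode="energy"`, scale `√(E_ref/E_k)`, using that magnifying interior
content by `s` multiplies its in-frame energy by `s²`). In both modes a
final multiplicative intensity factor makes the energy match exact, so the
0.1% equalization contract holds regardless of interpolation error.
Interpolation is bicubic with the output clipped at zero (cubic undershoot
around sharp structures would otherwise create negative intensities); the
output canvas keeps the input dimensions. Registering an already registered
stack is a no-op, which makes the operation idempotent. Scales outside
[0.5, 2] trigger a warning — such zooms indicate wrong current metadata,
not a real field-of-view change.

## Forward model and phantom

The defocus PSF is a unit-mass pillbox of radius `r_kk' = R0·|j_k − j_k'|`
px. Two representations are deliberately distinct:

- the **spatial simulator** rasterizes the pillbox on the pixel grid with
  area-weighted antialiasing (each rim pixel weighted by 8×8-subsample
  coverage) and convolves by FFT on a canvas zero-padded by the maximum
  blur radius, then crops — blur spilling past the frame is lost exactly as
  on a finite sensor;
- the **solver** uses the continuous closed form `2·J1(2πrρ)/(2πrρ)`.

A rasterized kernel is the continuous disc seen through the square pixel
aperture, so its DFT differs from the closed form by a pixel-sinc factor:
the maximum deviation on a 256² grid is ≈ 0.055 at r = 2 px, ≈ 0.023 at
r = 5, ≈ 0.009 at r = 10, concentrated near the Nyquist corner. This
mismatch is kept intentionally — round-trip tests that simulate with the
raster and invert with the closed form do not commit an inverse crime.

The bead phantom emulates a layered fluorescent test scene: `n` rings of
antialiased disc "beads", each ring on its own focal plane. Defaults: three
layers at currents 50/33.3/0 mA, 256×256 canvas, ring radii 40/65/90 px,
12 beads per ring of radius 3 px at intensity 200 on an 8-bit-like scale,
seeded angular jitter of 0.05 rad. Ring spacing makes the layers' supports
disjoint; zero jitter makes the phantom exactly mirror-symmetric about the
vertical axis (used by the symmetry checks). The default pipeline blur
coefficient is `R0 = 0.2` px/mA, giving adjacent-plane blur radii of 3.3
and 6.7 px on this phantom — strong enough to decorrelate the transfer
matrix at moderate frequencies, small enough that blur stays far from the
canvas edge. The optional noise model is additive Gaussian only (clipped at
zero against the dark background), default off.

What the phantom does *not* emulate: occlusion (layers add, as in the
additive fluorescence model), continuous depth (the scene is piecewise
planar by construction), photon/Poisson statistics, chromatic effects, and
magnification-dependent field-of-view changes (simulated stacks are born
registered). Passing tests on the phantom therefore validate the inversion
and rendering machinery, not robustness to those real-data effects.

## Layer separation

Slices are Fourier-transformed once; for each frequency bin the symmetric
unit-diagonal transfer matrix `H(ρ)` is pseudoinverted and applied. Since
`H` depends on the bin only through `ρ`, bins are grouped: by default `ρ` is
rounded to 12 decimals, which merges only bins whose `ρ` coincide to
machine precision, so the grouped solver is bit-compatible with the naive
per-bin solver (kept as `method="naive"` for cross-checking) while doing
thousands instead of tens of thousands of SVDs. The rounding quantum is
exposed purely as a performance knob; coarsening it trades accuracy for
speed because the jinc varies with slope up to `2πr` in `ρ`.

The pseudoinverse truncates singular values below `rcond·σ_max`, default
`rcond = 1e−3`. At DC, `H` is the all-ones matrix and `H† = H/N²`: each
layer receives `1/N` of the mean slice DC, which fixes the total intensity
of every reconstruction at the mean slice energy. For `ρ ≲ 0.6/r` the
off-diagonal transfer values are all close to 1 and `H` is nearly rank one:
the *per-layer* split of low-frequency content is fundamentally
unidentifiable there, and the minimal-norm solution spreads it evenly
across layers. Consequently individual recovered layers carry 10–20%
relative error concentrated at low frequencies (their energy still
concentrates > 95% on the true layer support), while every rendered output
— which sums the layers with phase ramps that are near-identity at low
frequency — is accurate to unit-scale MSE ~1e−6 on the phantom. Raising
`rcond` suppresses noise amplification at the cost of more low-frequency
mixing; lowering it below ~1e−4 lets the pillbox/jinc mismatch blow up and
degrades the layers again.

An optional Tukey edge taper (`taper_alpha`) is available to damp
wrap-around ringing from the periodic-convolution assumption on real
stacks with bright borders; it darkens the frame edge and is off by
default.

## Viewpoint synthesis and stereo

Views are synthesized purely with Fourier phase ramps, so shifts are
circular. The stack-level helpers (`stereo_pair`, `sweep_viewpoints`)
default to `pad="auto"`: slices are zero-padded by the maximum expected
disparity `⌈max|β|·R0·max|j|⌉` before solving and cropped after rendering,
which prevents content from wrapping across the frame for large `β·R0·j`
products. The DC bin carries no phase, so every viewpoint has exactly the
same total intensity as the β = 0 reconstruction.

Conventions: x = columns, y = rows, origin top-left. `β_x > 0` shifts
layers with positive current to the right (`d_k = β_x R0 j_k`); `β_y`
applies the same law along rows. The stereo pair assigns the view at
`β_x = +B/(2R)` to the left eye and `−B/(2R)` to the right eye;
`render_stereo` places the left-eye view on the right panel for cross-eyed
viewing (`parallel` swaps the panels, `anaglyph` encodes left in red,
right in green+blue). The global magnification-at-zero-current factor in
the disparity law is a `k`-independent constant and is dropped: views live
on the registered pixel grid.

## Evaluation

`evaluate_viewpoints` compares full-pipeline reconstructions against
analytic ground truth (sharp layers shifted by their exact disparities and
summed). The ground-truth shift uses the same phase-ramp operator as the
reconstruction, so the metric measures inversion error, not differences
between interpolation schemes. MSE is computed on luminance (Rec. 601
weights for RGB) and reported on both the raw intensity scale and a unit
scale (divided by the dtype maximum, default 255); absolute MSE values
from other bead scenes are not comparable unless canvas, bead intensity
and normalization match, so cross-study comparisons should be qualitative.

A counterintuitive but robust property of the method, verified in the test
suite: reconstruction fidelity of off-axis viewpoints *improves* with
stronger defocus coupling (larger `R0`), because separating layers —
a prerequisite for shifting them individually — requires the transfer
matrix to decorrelate away from the all-ones matrix. As `R0 → 0` the
slices become identical, only their sum is determined, and β ≠ 0 views
degrade.

## Problem sizes

All tests and the evaluation pipeline run on the 256×256, N = 3 phantom
(the solver groups ~8000 distinct radial frequencies and completes in well
under a second); solver-equivalence checks use 32×32 stacks where the naive
per-bin pseudoinverse is affordable. These sizes were chosen as the
smallest on which every contract — conservation to 1e−6, sub-pixel
parallax slopes to 2%, MSE below 1e−3 — is meaningfully exercised.

## Known limitations

- The pseudoinverse is the only inversion offered (no Tikhonov or
  iterative solvers); `rcond` is the single regularization knob.
- The PSF is an isotropic pillbox with a single global `R0`; no spatially
  varying or aberrated PSFs. How to calibrate `R0` for a given instrument
  is outside the package's scope — it is a required input.
- Registration corrects isotropic scale only (no rotation/translation),
  as appropriate for an EFTL that changes magnification but not alignment.
- Stereo/viewpoint rendering is additive: no occlusion handling beyond the
  layered fluorescence model.
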