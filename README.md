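# multifocus

Computational multifocus fluorescence microscopy: recover every in-focus
plane of a thick sample from a focus-swept z-stack, and re-render the scene
as an extended depth-of-field image, from arbitrary virtual-pinhole
viewpoints, or as a stereoscopic pair.

The package is written for microscopists who acquire multifocus stacks with
an electrically focus-tunable lens (EFTL) — e.g. to visualize DAPI-stained
multicellular tumor spheroids — and for anyone who wants a fully synthetic,
ground-truth-checked testbed for focal-stack fusion algorithms.

## The model

An EFTL driven with control current `j` changes focus without moving any
optics. Slice `k` of a stack taken at current `j_k` contains its own sharp
layer `f_k` plus every other layer blurred by a geometric-defocus pillbox
PSF whose radius grows linearly with the current difference:

    i_k = f_k + Σ_{k'≠k} h_kk' * f_k' ,     r_kk' = R0 · |j_k − j_k'|  [px]

with a single effective coefficient `R0` (px/mA). In the Fourier domain this
is, at every spatial frequency `(u, v)`, an `N×N` linear system
`I(u,v) = H(u,v) F(u,v)` with a symmetric unit-diagonal transfer matrix
whose entries are the pillbox transfer values `2·J1(2πrρ)/(2πrρ)`,
`ρ = √(u²+v²)`. The sharp layer spectra are recovered per frequency with
the Moore–Penrose pseudoinverse,

    F(u,v) = H†(u,v) · I(u,v),

which handles the rank-deficient DC bin (H is all ones there) and
near-singular low frequencies by minimal-norm least squares. A virtual
pinhole displaced a fraction `β` of the pupil radius sees layer `k` shifted
by the disparity `d_k = β·R0·j_k` px, applied as a per-layer Fourier phase
ramp:

    S_β(u,v) = Σ_k exp(−i2π j_k R0 (β_x u + β_y v)) · F_k(u,v).

`β = 0` is the all-in-focus image; a stereo pair is the two views at
`β_x = ±B/(2R)` for a baseline `B ≤ 2R`. No depth map or in-focus
segmentation is ever computed.

Registration of real stacks uses conservation of energy: the EFTL sits in
the imaging path, so total collected intensity is constant across the stack
and each slice is rescaled (geometrically, about the image center) to match
the energy and field of view of a reference slice.

## Worked example

```python
import multifocus as mf

# optics of a 20x/0.5NA objective with an EFTL spanning -2..+3 diopters
cfg = mf.OpticsConfig()
print(f"focusing range: {mf.focusing_range(cfg)[2]:.1f} um")

# synthetic ground truth: three rings of fluorescent beads on three planes
scene = mf.generate_bead_scene(angular_jitter_rad=0.0, seed=0)
blur = mf.BlurModel(R0=0.2)                    # px of blur per mA
stack = mf.simulate_stack(scene, blur)         # the stack a camera would see
print(f"stack: N={stack.n_slices}, slice energies {stack.slice_energies().round(1)}")

# full pipeline: solve layers, re-render viewpoints, compare to ground truth
report = mf.evaluate_viewpoints(scene, blur, [-0.5, 0.0, 0.5])
print(report)
```

prints

```
focusing range: 210.9 um
stack: N=3, slice energies [204465. 204465. 204465.]
 beta_x  beta_y   mse_raw    mse_unit
   -0.5       0 0.0378803  5.8255e-07
      0       0 0.0456297 7.01725e-07
    0.5       0 0.0378803  5.8255e-07
```

The focusing range is the axial span the EFTL sweep reaches (~211 µm for
the stock optics). The identical slice energies confirm the forward model
conserves intensity — the property registration relies on. The MSE rows
compare full-pipeline reconstructions of three virtual viewpoints
(βx = −0.5, 0, +0.5) against analytically shifted ground truth on a 0–1
intensity scale: errors below 1e−6 mean the rendered views are visually
indistinguishable from the truth, and the ±0.5 symmetry reflects the
mirror-symmetric phantom.

The same pipeline is scriptable from the shell:

```
multifocus simulate --out stack.tif --seed 0
multifocus edof stack.tif --out allinfocus.png
multifocus stereo stack.tif --out stereo.png --baseline-frac 0.5
multifocus sweep stack.tif --out sweep.gif --steps 5
multifocus evaluate --out mse.csv
```

## Layout

- `multifocus.optics` — EFTL current → power, focus shift, magnification
- `multifocus.stack` / `multifocus.io` — stack container, TIFF + YAML sidecar I/O
- `multifocus.registration` — energy-conservation field-of-view registration
- `multifocus.forward` — pillbox PSF forward simulator and bead phantom
- `multifocus.separation` — per-frequency pseudoinverse layer solver
- `multifocus.viewpoint` — viewpoint synthesis, extended DoF, stereo
- `multifocus.evaluation` — MSE-against-ground-truth reporting
- `multifocus.cli` — `multifocus` command-line tool

See `docs/methods.md` for the numerical choices, parameter defaults and
known limitations.
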