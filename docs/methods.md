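# Methods

This note documents the models, conventions and numerical choices behind
`emva`, what the synthetic fixtures do and do not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The map object and units

A `DensityMap` is a 3D scalar grid with per-axis sampling (Å/voxel), an
origin (Å position of voxel (0,0,0) in the model frame), and values stored
in canonical x-fastest order. Internal lengths are Å and raw volumes Å³ —
the archive convention for sampling — while report-level volumes are
converted to nm³, the natural scale for molecular volumes.

**MRC dialects.** Deposited maps carry the origin in two ways; `read_map`
prefers the MRC origin record when any component is non-zero and otherwise
derives it from `nxstart/nystart/nzstart × voxel_size`. Axis permutations
declared by `mapc/mapr/maps` are undone at read time so no downstream
operation needs to branch on axis order. Modes 0/1/2 (int8/int16/float32)
are read; the writer always emits mode 2 in canonical axis order. A
truncated data block or malformed header raises an error naming the
offending header field; gemmi is used in the test suite as an independent
reader to confirm the writer's output, never as the implementation.

**8-bit quantization.** Bytes are `round((ρ − min)/scale)` with
`scale = (max − min)/255`, which guarantees a dequantization error of at
most half a step everywhere and uses the full byte range unless the map is
constant. A constant map quantizes to all-zero bytes with scale 1 and
offset equal to the constant, keeping the round trip exact without a
divide-by-zero. Global min/max scaling (rather than robust percentiles) is
deliberate: it is lossless-in-range and reproducible, at the cost of
sensitivity to a single extreme voxel.

**Brix layout.** The 512-byte text header carries origin, extent, grid,
cell and the `prod`/`plus` scaling with the convention
`density = (byte − plus)/prod`. Data follow as 8×8×8 bricks, x-fastest both
across the brick grid and within each brick, partial bricks zero-padded —
hence the payload is exactly `512·⌈nx/8⌉⌈ny/8⌉⌈nz/8⌉` bytes.

## Down-sampling

Maps above the cap (default `max_dim = 160`, the compromise between detail
retention and viewer memory) are reduced with one isotropic factor
`s = max_dim / max(dims)` so anisotropic grids keep their aspect ratio and
cubic voxels stay cubic; per-axis capping would distort voxel shape. The
operation never up-samples.

Output sample `i` along an axis maps to input voxel coordinate
`i·(Nin−1)/(Nout−1)` (endpoints aligned). This fixes the boundary-handling
question when the isotropic factor leaves an axis fractionally short, keeps
the bounding box invariant to within one output voxel, and makes trilinear
interpolation *exact* on trilinear fields — which the tests exploit by
comparing against direct evaluation of `ρ = 2x + 3y − z`. Interpolation
delegates to `scipy.ndimage.map_coordinates(order=1)` in the input dtype:
float64 maps interpolate at full precision; float32 maps avoid a
full-precision copy (relevant at 512³).

## Slice extraction

One Z plane is linearly mapped onto pixels 0–255. The automatic window is
the 1st/99th percentile of the plane — a robust "best guess" that tolerates
hot pixels and saturates about 1% of pixels at each end; a constant plane
renders as uniform mid-gray 128. An explicit window clips below/above to
0/255 and is monotone in density.

## Density statistics

* **Histogram** — 128 equal-width bins spanning exactly [min, max]; the
  maximum is assigned to the last bin; a constant map degenerates to a
  flagged single bin. 128 bins resolves masking spikes without emptying
  bins on typical grids.
* **Contour level** — supplied level verbatim, else μ + 1σ computed in
  float64. The fallback inherits the map's padding/masking sensitivity,
  which is precisely why a supplied level takes precedence.
* **Enclosed volume** — "above the threshold" is implemented as ρ ≥ ℓ so
  that the recommended level itself encloses the surface it defines; the
  curve reuses the histogram's 128 bin left edges so the two plots share a
  density axis. Counting uses a single sort plus `searchsorted`, verified
  against brute-force per-voxel counting on all 2³–8³ grids.
* **MW → volume** — `V = MW/(ρₘ·N_A)` with ρₘ = 1.5 g/cm³ by default, a
  deliberate round figure between protein (~1.2) and nucleic-acid (~2)
  densities; the estimate is rough by construction and linear in MW.
* **FSC** — full complex FFTs of both maps; shells are spherical in
  reciprocal space, one Fourier pixel wide (sampling interval of the
  largest axis), real part of the normalized cross-correlation reported at
  shell-center frequencies up to Nyquist. This is the field-standard shell
  geometry; no masking correction or resolution threshold (0.143/0.5) is
  applied — the full curve is the product. Externally computed curves can
  be imported from two-column text since deposited-curve conventions vary.

## Models, trace atoms, backbone

Parsing uses gemmi (PDB format, first model of multi-model files), with
residue classes from its tabulated chemical components. The trace atom is
CA (amino), P (nucleotide), or the residue's first atom (other compounds),
falling back to the first atom when the designated one is missing, so
simplification is total. The amino backbone set is {N, CA, C, O}: the
carbonyl-oxygen spelling "CO" is not a PDB atom name, but a literal "CO" is
also matched for robustness. Nucleotide backbone names accept the prime,
Unicode-prime and legacy asterisk dialects (C3′ ≡ C3').

## Symmetry expansion

Operators are proper rigid transforms (orthonormality and det +1 validated
to 1e−6). Expansion rules:

* **virus** — exactly the 5 copies of a supplied C5 operator set (angles
  validated as multiples of 72° about a common axis); selecting one 5-fold
  axis out of a full icosahedral set is the caller's choice, since no
  canonical selection rule exists.
* **helical** — instance k is k applications of the screw operator (twist
  about the axis, rise along it), identity first, 5 instances by default so
  the deposited copy counts as one of the five.
* **2D crystal** — one instance per plane-group operator (p1, p2, p121,
  p222, p4, p6 as pure in-plane rotation groups; p121/p222 include the
  in-plane 2-fold about b in the two-sided convention), each copy
  translated by whole cell vectors into the reference unit cell. The
  group's copies tile the cell, not the asymmetric unit, so "all copies"
  is implemented per unit cell.

Instances are shifted by integer multiples of the map's box edges until
their centroid lies inside the box, and the display filter keeps an
instance only when at least half of its *trace* positions (the viewer
operates on simplified models) have interpolated density ≥ the contour
level, boundary inclusive.

## Atom inclusion

Inside-ness is trilinear interpolation at the atom position with an
inclusive threshold, matching the isosurface a viewer renders; a
nearest-voxel mode exists for cross-checks. Positions outside the grid
return −∞ (outside any surface). The inclusion curve reuses the map's 128
histogram levels; the reduced series uses backbone atoms when any residue
carries a full backbone set and trace atoms otherwise. Per-residue
fractions count all available atoms (binary for trace-only models) and are
coloured on a piecewise-linear red→yellow→green ramp — (255,0,0) at 0,
(255,255,0) at ½, (0,255,0) at 1 — chosen over a single linear RGB blend
because the latter passes through olive rather than yellow at the midpoint.
Residues are chunked into display segments of at most 200 in model order.
The 40% default-display filter counts **all** model atoms (recorded as
`inclusion_atom_set` in the report) and is boundary-inclusive.

## The report

`analyze_entry` contains exactly the blocks whose inputs were supplied and
delegates every computation to the modules above; failures propagate with
the failing component named (`mask[0]`, `model[1]`, ...). Serialization is
sorted-key JSON with a units label on every numeric field; there is no
timestamp, so re-running on identical inputs is byte-identical. Orthogonal
projections (sum) and central sections are exposed as raw 2D arrays —
rendering is presentation, not computation, and stays out of the report.

## Synthetic fixtures: what they do and do not show

The generators produce controllable ground truth, not realistic data:
unit-amplitude Gaussian atoms with no element weighting or B-factors, white
noise with no spectral colouring, masks as exact-zero backgrounds, no CTF,
no tomographic missing wedge. Passing tests therefore demonstrate the
*correctness of the computations* (binning, counting, interpolation,
transforms, format round trips) under known conditions — not robustness to
experimental artefacts such as non-uniform solvent background, sharpening,
or model/map frame mismatches, which real deposited entries exhibit.
`make_inclusion_pair` places atoms exactly on voxel centers (where the
trilinear interpolant equals the voxel value) so the advertised inside
fraction is recovered exactly; all generators are seeded and
spec-deterministic.

## Problem sizes and numerical tolerances

The test suite exercises the down-sampling cap at 512³ (float32) with
trilinear exactness asserted at 1e−9 on a 200³ float64 linear field; FSC
identities on 64³ grids (self-correlation 1 and sign-flip −1 to 1e−9,
noise-null within 3/√(shell count)); brute-force volume equality on all
2³–8³ grids; rigidity of symmetry expansion to 1e−9. These sizes make the
suite complete in well under a minute on one CPU while still covering the
cap constant at full scale.

## Known limitations

* MRC modes 6/12/float16, compressed containers and in-map symmetry
  records are not read; mmCIF models are not parsed (PDB only).
* Resolution estimation from FSC thresholds, map sharpening and
  masking-aware FSC corrections are out of scope.
* Plane-group support covers the six rotation groups listed above; mirror
  and glide groups are not implemented.
* The Brix `prod`/`plus` scaling is derived from the global min/max; robust
  percentile scaling is not offered.
* `expand_virus` validates a supplied C5 set rather than choosing a 5-fold
  axis from a full icosahedral operator set automatically.
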