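# Methods

This note documents the models, conventions, numerical choices and known
limitations of `anisocell`, in the spirit of the methods documentation of
mature modelling packages.

## Synthetic tissue model

The generator (`anisocell.synthetic`) emulates a segment of a germinating
embryonic axis as a cylinder of concentric cell shells around a central
axis: layer 1 is the epidermis (outermost), layers 2…n are cortex,
numbered inward; the core inside the innermost shell stands for the stele
and is left unlabelled (the Bezier axis runs through it). Each shell is
tiled into longitudinal slabs of height ≈ the layer's target longitudinal
dimension and angular sectors of arc ≈ its circumferential target, with a
seeded random angular phase per ring so walls do not align radially.

Because every cell is an annular sector of known bounds (r_in, r_out,
height h, angle θ), its organ-frame quantities are known in closed form
and stored as ground truth:

- longitudinal extent = h,
- radial extent = r_out − r_in·cos(θ/2) (spread of the sector along its
  bisector),
- circumferential extent = 2·r_out·sin(θ/2) (chord width),
- volume = h·(θ/2)·(r_out² − r_in²),
- centroid radius = (2/3)·(r_out³ − r_in³)/(r_out² − r_in²)·sin(θ/2)/(θ/2).

The default organ has 12 shells (epidermis + 11 cortical layers) with
per-layer target dimensions following a triangular profile peaking in
mid-cortex (radial 4–10 µm, longitudinal 12–20 µm, circumferential
6–12 µm), reproducing the unimodal radial cell-size gradient of a thick
embryonic axis. The experiment layout defaults to two time points (4 and
18 hours after imbibition), two axial positions (H1 below t = 0.5, nearer
the radicle; H2 above), and four replicates per condition pooled for
analysis.

**Growth** is multiplicative per (layer, position, direction): each
directional dimension is multiplied by its true ratio times a lognormal
factor exp(N(0, σ²)), σ = 0.1 by default (cell sizes are positive and the
analysis works on log-scale ratios, so multiplicative lognormal noise is
the natural error model). Volume is multiplied by the product of the
three realised directional factors, so volumetric and directional growth
are mutually consistent by construction. Growth acts on the ground-truth
records; the label volume is carried over unchanged. This keeps each
stage's oracle exact: the statistics pipeline is validated on records
with known ratios, the image pipeline on rasterized volumes with known
geometry. The pipeline's `measured` route composes the two by applying
the growth spec to the *measured* per-cell table.

**Rendering** marks label–label and label–background interface voxels
(cell walls, as a membrane stain would) at intensity 1, Gaussian-blurs
with σ = 0.7 voxels by default, and adds Gaussian noise (sd 0.05 by
default, i.e. 5% of the wall signal). No anisotropic point-spread
function, attenuation with depth, or stain-penetration gradient is
simulated — so passing segmentation tests demonstrate correctness of the
watershed machinery on idealised wall signal, not robustness to the full
artefact spectrum of deep-tissue confocal imaging.

## Segmentation

The segmentation stage mirrors the standard interactive plant-tissue
workflow, made scriptable:

- Gaussian blur, σ = radius voxels (default 0.5) — the light smoothing
  conventionally applied before seeding on wall-stained stacks.
- Autoseeded watershed: seeds are connected h-minima of the blurred
  intensity (depth 0.15 by default, in units of the wall signal); the
  watershed floods intensity until every voxel is labelled.
- Over-segmentation fusion: adjacent labels whose mean interface
  intensity falls below a threshold merge transitively (union-find);
  an explicit pair list is accepted as the scripted equivalent of manual
  curation, making that step reproducible.
- Boundary clipping: any label owning a voxel on a stack face is removed
  (its 3D shape was not fully captured). Idempotent by construction.
- Air-space filtering: segments smaller than `min_volume` (default
  50 µm³; the choice is exposed in the config since no principled value
  exists) are dropped from the per-cell table — these slivers between
  cortical layers are not cells.
- Meshing: per-label marching cubes on a grid resampled to
  `mesh_cube_size` (default 0.3 µm) with optional Laplacian smoothing
  (0 passes by default); mesh volume is the divergence-theorem volume and
  agrees with voxel-count volume within 10% for cells of ≥ 100 voxels.

## Organ geometry and measurement

- **Axis.** Cubic Bezier by default. The initial fit is linear least
  squares on chord-length parameters; a joint Levenberg–Marquardt polish
  of control points and interior parameters follows (default on). The
  polish was added because chord-length-only fitting leaves O(10⁻² µm)
  residuals on curves whose speed is non-uniform, and the package
  guarantees that points sampled from a fitted curve refit to machine
  precision. Nearest-point queries use dense sampling (256 parameters)
  plus bounded scalar minimisation.
- **Frames.** Longitudinal = tangent at the nearest axis point; radial =
  centroid offset orthogonalised against it; circumferential = cross
  product. Frames are orthonormal to 1e-9 and right-handed; a centroid
  within 1e-6 µm of the axis is rejected (radial direction undefined).
  The longitudinal direction points from the radicle end (t = 0) upward.
- **Lengths.** Directional length is the projection extent of the cell's
  voxel centres onto each frame axis, plus *half* the projection width of
  one voxel. Voxel centres under-reach the true cell boundary by about
  half a sampling step per side on oblique directions, so the half-width
  correction is approximately unbiased there, while frame-aligned boxes
  stay within half a voxel per side. Whether interactive tools measure
  lengths as centroid-ray surface intersections instead of projection
  extents is not settled; the projection extent is the simplest
  well-defined choice and is used consistently for truth and measurement.
- **Layers.** Radial distances (normalised per axial slab by the slab
  maximum when the organ tapers or bends) are clustered by a
  deterministic 1-D k-means (quantile initialisation, Lloyd updates),
  cluster centres sorted outer → inner. An `alternating_layer_selection`
  helper returns the standard analysis subset — epidermis, first cortical
  layer, then alternating layers inward; for a 12-shell organ that is
  layers {1, 2, 4, 6, 8, 10, 12}, i.e. seven layers.
- **Coordinates.** Arrays are (z, y, x); world position = index ×
  spacing; voxel i occupies the half-open box [i·s, (i+1)·s). Volume is
  conserved exactly: cell volumes + background volume = stack volume.

## Statistics

The estimator implemented is deliberately the literal log-scale form:

- point estimate exp(ln x̄ − ln ȳ), algebraically x̄/ȳ (the identity is
  asserted at runtime to 1e-12);
- interval halfwidth t_{level, nx+ny−2}·√(S²ln(x)/nx + S²ln(y)/ny),
  exponentiated around the log ratio.

Note the asymmetry: the point estimate uses the log of the arithmetic
mean while the interval uses variances of the logs. A geometric-mean
ratio (mean of logs) would pair naturally with that interval but is *not*
what is computed; the mixed form is implemented as specified, not
"corrected". Simulation shows its 95% CI covers the true ratio of means
in 92–98% of replicates at the noise levels of interest (σ ≤ 0.2), so the
approximation is serviceable there; coverage degrades for large σ where
arithmetic and geometric means diverge.

Other choices:

- Bonferroni correction as a corrected confidence level 1 − α/m
  (m defaults to the number of analysed layers; 99.3% at α = 0.05,
  m = 7). Reported ratio CIs default to the corrected level; pass
  `ci_level=0.95` for uncorrected intervals — both are legitimate
  reporting conventions and the package does not privilege one in
  figures.
- t-tests are pooled-variance two-tailed Student's t (df = nx + ny − 2,
  the same df convention as the ratio interval). Zero pooled variance
  with equal means returns t = 0, p = 1.
- The ANOVA fits the full two-factor time × position model with
  interaction and tests the interaction term only. Balanced designs use
  the classical closed-form decomposition (noiseless additive data give
  interaction SS exactly 0); unbalanced data fall back to an OLS fit with
  Type II sums of squares, which coincides with the classical
  decomposition when balanced. The response is log-transformed by
  default, consistent with the multiplicative growth model; raw-scale
  analysis is a switch.
- Bootstrap CIs use the percentile method with 1000 resamples by default,
  fully seeded.
- Cells are the observational units, pooled across replicates.
  Replicate-level mixed-effects modelling is out of scope; p-values are
  therefore anti-conservative to the extent that cells within a replicate
  are correlated.

## Pipeline sizing and determinism

The default scene (four layers, ~64³ voxels at 0.7 µm, ~230 cells per
replicate, 4 replicates × 2 time points) runs end to end — generation,
rendering, watershed, measurement, statistics — in well under a minute on
one CPU; it is sized as the smallest scene that still exercises a
multi-layer, two-position, replicated design. All randomness descends
from one master seed via `numpy.random.SeedSequence` spawning, recorded
per stage in the run manifest together with a SHA-256 of the config;
reruns with the same config produce byte-identical result tables.

## Known limitations

- The generator's cells are annular sectors: real cortical cells are
  rounded, interlocked, and vary in size within a layer; segmentation
  performance on the synthetic walls should be read as an upper bound.
- The membrane renderer has no depth-dependent signal loss, the dominant
  failure mode in deep whole-mount stacks.
- The watershed's h-minima depth is a free parameter; there is no
  auto-calibration against wall-signal statistics.
- Layer clustering assumes shells are concentric and radially separated;
  heavily deformed organs would need the per-cell override table.
- The ratio estimator's CI is approximate (see above); for strongly
  skewed data at small n, the bootstrap interval is the safer summary.
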