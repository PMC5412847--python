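# Methods

This note documents the models, conventions and numerical choices behind
`trabtex`, and what its synthetic validation does and does not show.

## Coordinate and intensity conventions

The third array axis (index 2) is the distal-proximal (longitudinal) axis
everywhere; TIFF stacks map one transverse slice per page onto that axis.
Voxels are isotropic, with the edge length carried in micrometres.
Intensities are analyzed as given; the canonical thresholds assume an
8-bit reconstruction and the default pre-threshold is rescaled
proportionally (60/255 of full scale) for 16-bit data.

## Segmentation

Binarization is two-stage: a fixed pre-threshold (default 60, inclusive)
removes marrow/background, then a voxel is kept only if its intensity
reaches the local midrange `(min + max)/2` of a window centred on it
(default: 3D ball of radius 5 voxels; an 11³ cube and a slice-wise 2D
window are options).  Windows are clipped at the volume boundary, and a
voxel exactly at the midrange is foreground — this keeps constant volumes
stable and makes the rule invariant under adding a constant to both the
image and the pre-threshold.  "Radius" is read as a spherical window; the
shape is configurable because vendor implementations differ.

## 3D local binary patterns

26 neighbors are placed on a sphere of radius `r` voxels (default 1.0)
along the normalized 3×3×3 directions, in a fixed lexicographic order
(distal-proximal component most significant).  Neighbor values come from
trilinear interpolation; a neighbor with value ≥ centre is a marker, and
the 26 marker bits form the pattern code.  Analysis is restricted to
voxels with at least one interpolated neighbor strictly above a fixed
threshold (default: the binarization pre-threshold), so empty space
contributes nothing; voxels within `ceil(r)` of a volume face are never
analyzed (no extrapolation).  LBP runs on the *grayscale* volume — the
gradient information in gray values is what orients the patterns —
although binarized input is accepted.

Pattern statistics are the Shannon entropy (bits) of the pattern
proportions, the number of distinct patterns, and the count-weighted mean
marker count.  Histograms are stored sparsely; 2²⁶ dense bins would be
wasteful and the number of observed patterns is itself an outcome.

### Numerical tie handling

The trilinear sample is computed relative to the base corner of the
sampling cell, `v000 + Σ w_c (v_c − v000)`, with corners accumulated in a
fixed lexicographic order.  The naive accumulation `Σ w_c v_c` makes the
marker tie rule (`sample ≥ centre`) depend on rounding of the weight sum
(≈ 1 ± 1 ulp): on a linear ramp it fractures the single true pattern into
several, because `W·v ≥ v` flips with the magnitude of `v`.  The relative
form is exactly equal to the voxel value whenever all contributing corners
share one value, so flat and ramp-like fields behave deterministically.
Pattern codes are invariant under positive affine intensity maps (with the
eligibility threshold co-mapped), up to exact ties that such maps cannot
preserve in floating point; the test suite checks the invariance on
continuous-valued volumes where ties have measure zero.

## Pattern orientation

A valid pattern's markers, taken as points on the sampling sphere, are
reduced by principal component analysis: positions are centred on the
marker centroid and the top eigenvector of their covariance is the pattern
axis.  Elevation is `arcsin(|axis·ẑ|)` in degrees — 0° transverse, 90°
longitudinal.  This convention flips correlation signs relative to the
opposite choice, so it is stated prominently.  The sign of the axis and
the azimuth carry no information (the acquisition fixes no transverse
reference), which also makes elevation invariant under volume flips in
any axis.

Patterns are discarded as orientation-inconsistent when:

- fewer than 3 or more than 24 markers;
- the markers' mean distance to their own centroid exceeds the
  non-markers' mean distance to that same centroid (dispersed/ring-like
  sets).  The dispersion criterion is operationalized as a mean-distance
  comparison; discarding sets that spread *around* rather than *along* is
  the intent;
- the top two covariance eigenvalues agree within 1e−9 relative tolerance
  (no unique principal axis — e.g. the all-markers pattern of a constant
  region).

Elevation is a pure function of the code, so it is computed once per
distinct observed code (vectorized, chunked eigendecomposition) and
broadcast to the field.

### Elevation statistics

Elevations are binned in 5° bins over [0°, 90°] (18 bins, configurable;
90° falls in the last bin).  The field summary reports the per-voxel mean,
the entropy of the binned distribution, and the fraction of analyzed
voxels that carried a valid orientation.  The angle-level co-occurrence
matrix (ALCM) counts every ordered pair of 26-adjacent valid voxels
("one voxel-size radius" is read as including diagonals; 6-adjacency is an
option), making it symmetric by construction, and is normalized to sum
to 1.  Homogeneity of elevation is `Σ ALCM(i,j)/(1+|i−j|)` over bin
indices: exactly 1 when all co-occurring pairs share a bin, strictly
decreasing as mass moves off the diagonal.

### Scale matching

The sampling sphere reads orientation at its own scale.  For structural
elements much thicker than the sphere radius the local surface looks
planar and the marker set degenerates to a half-space whose in-plane axis
is only weakly determined by curvature; recovered orientations then
scatter within the surface plane.  Orientation is read reliably when the
sphere radius is on the order of the element half-thickness.  The radius
is therefore a first-class parameter (CLI `--radius`), with 1.0 voxel as
the default smallest neighborhood.

## Morphometry

- **BV/TV**: foreground voxels over ROI voxels.
- **BS/BV**: marching-cubes area of the 0.5 iso-surface of the binary
  field smoothed with a 0.8-voxel Gaussian, divided by foreground volume.
  Meshing the raw binary field overestimates areas by ~10% (staircase
  facets) and voxel-face counting by up to 1.5×.  Surface crossing the
  volume faces is a volume-of-interest cut, not bone surface, and is not
  counted (smoothing uses edge replication so the field stays flat across
  the faces).
- **Local thickness** (Tb.Th on the foreground, Tb.Sp on the background,
  2D mode for histological sections): maximal-inscribed-sphere thickness
  computed by sphere covering on the Euclidean distance transform.  A
  voxel p is covered by the sphere of q when `|p−q| ≤ D(q)`; distances are
  centre-to-centre, which overstates the inscribed diameter by one voxel,
  so thickness is reported as `2·max D − 1` voxels — an isolated voxel
  measures exactly 1 voxel, an even-thickness slab t−1, an odd one t.
  The covering loop runs over at most 64 distance levels (evenly
  subsampled when there are more distinct values).  Structures touching
  the volume boundary are treated as continuing beyond it (the transform
  sees no background there), consistent with analyzing an excised core.
- **Tb.N**: BV/TV ÷ Tb.Th (plate-model identity; exact for plate stacks,
  a convention for other geometries — vendor software may differ).
- **Fractal dimension**: box-counting slope of log N vs log(1/s) over a
  ladder of box sizes spanning at least three octaves.  Sizes that divide
  the image edge are preferred — they keep the box grid aligned with
  regular self-similar structures (a dyadic ladder on a triadic sponge
  underestimates its dimension by ~0.4) — with a dyadic fallback over a
  zero-padded grid otherwise.
- **Plate thickness**: mean of the local-thickness map over the bone
  voxels inside the plate mask.  Plate vs trabecular compartments are
  supplied as masks; no automatic plate segmentation is attempted.

SMI, connectivity, connectivity density, trabecular pattern factor and
degree of anisotropy are not implemented; the pipeline report reserves
their keys so values from external tools can be merged into one record.

## Statistics

Samples from one donor are pseudoreplicates, so correlation against the
severity grade weights each sample by 1/(its donor's sample count): every
donor contributes one unit of weight, and duplicating a donor's rows
provably leaves r unchanged.  Significance uses a t statistic with
(donors − 2) degrees of freedom — the donor count, not the sample count,
is the effective N.  Collapsing donors to their means before an
unweighted correlation is available as `method="donor_mean"`; the
weighted form is the default because it preserves within-donor spread of
grade and metric.  Rows with missing values are dropped pairwise and
logged.  CV% is 100 · sample SD / mean of repeated measures.

## Synthetic phantoms

The generator voxelizes continuous geometry at voxel centres (so analytic
volume fractions hold to discretization error), assigns two intensity
levels, and degrades the result with a Gaussian blur and additive Gaussian
noise clipped to the intensity range.  Defaults emulate an 8-bit
trabecular μCT reconstruction: bone 200, marrow 40, blur σ = 0.8 voxel
(a ~2-voxel FWHM point-spread), noise SD 5 (a conservative detector noise
at typical exposures).  All randomness derives from the integer seed in
the spec; no global random state is used.

Kinds: tilted rod lattices (BV/TV = πr²/s², elevation as specified),
plate stacks (BV/TV = t/s, transverse), simple-cubic sphere packs
(BV/TV = 4πr³/3s³), strictly increasing ramps (exactly one local
pattern), and smoothed-noise two-phase fields at a controlled volume
fraction.  `mixed_rod_phantom` stacks rod blocks of different elevations
to produce controlled orientation heterogeneity.

### Validation fixtures and their limits

Orientation-recovery fixtures use thin rods (radius 1.2 voxels, spacing
8) analyzed at sampling radius 1.5 — the scale-matched regime above — and
are noise-free: the analytic elevation is the ground truth of the clean
structure only, and under voxel-scale noise eligible flat regions emit
patterns with random orientations that dilute the mean toward 45°.  Tests
at 0/30/60/90° recover the mean elevation within one 5° bin, and
homogeneity decreases strictly across one-, two- and four-block
orientation mixtures.  Morphometry fixtures (spheres, slabs, cylinders,
wedges, sponges) are placed clear of the volume faces where their
geometry requires background on all sides.

Phantoms do not emulate beam hardening, ring artifacts, partial-volume
mineral gradients, or anatomically realistic trabecular networks.
Passing tests therefore demonstrate the correctness of the operators and
their tolerances on idealized structures, not end-to-end accuracy on
clinical scans.

## Pipeline

`run_pipeline` composes the chain — read, binarize, split compartments by
mask, LBP, orientation, morphometry — into a versioned JSON report with
full provenance (package version, parameters, SHA-256 of inputs) and
units on every key.  The run is deterministic for fixed configuration and
inputs; reports are written with sorted keys so reruns are byte-identical.
Configuration comes from YAML with CLI override precedence; referenced
paths are validated before any computation.

## Known limitations

- Local thickness carries the ±0.5-voxel parity effect of the
  centre-to-centre distance correction and inherits the maximal-sphere
  definition's behavior on wedges (read thicker than the perpendicular
  width on steep slopes).
- BS/BV of structures thinner than ~2 voxels is attenuated by the
  pre-mesh smoothing.
- The eligibility threshold and the sphere radius are analysis choices;
  comparisons across studies must hold them fixed.
- Mean elevation is a per-voxel average; with heavy noise it regresses
  toward 45° as random-orientation patterns enter the valid set.
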