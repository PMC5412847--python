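# trabtex

Volumetric texture and morphometry analysis of trabecular and subchondral
bone in micro-CT images.

Osteoarthritis remodels the bone beneath the cartilage: the subchondral
plate thickens, trabeculae change number and orientation, and the local
architecture becomes more heterogeneous.  Conventional morphometry (BV/TV,
Tb.Th, Tb.Sp, ...) summarizes how much bone there is and how thick it is;
`trabtex` adds a 3D local-binary-pattern (LBP) description of *how the bone
is locally arranged* — the randomness of local patterns and the orientation
of structures relative to the distal-proximal axis — together with the
segmentation recipe and phantom generators needed to validate the whole
chain on synthetic data.  It is aimed at researchers quantifying bone
micro-architecture from isotropic μCT volumes (TIFF stacks or NIfTI).

## Method

For every eligible voxel, 26 neighbors are fitted on a sphere centred on
the voxel (the normalized 3×3×3 directions) and sampled by trilinear
interpolation.  Neighbors with gray value ≥ the centre are *markers*; the
26 marker bits form the voxel's pattern code.  A voxel is eligible when at
least one neighbor exceeds a fixed threshold, restricting analysis to bone
and its surroundings.  Over a volume of interest this yields:

- **Pattern entropy** `E = −Σᵢ Pᵢ log₂ Pᵢ` over the pattern proportions
  (0 bits when the volume contains a single local pattern), the number of
  distinct patterns, and the mean marker count.
- **Elevation** of each valid pattern: the first principal axis of the
  marker positions, expressed as the angle against the transverse plane
  (0° = transverse, 90° = longitudinal/distal-proximal; the azimuth is
  ignored).  Patterns with < 3 or > 24 markers, dispersed marker sets
  (centroid rule), or no unique principal axis are discarded.
- **Homogeneity of elevation** `H = Σᵢⱼ ALCM(i,j)/(1+|i−j|)` from the
  angle-level co-occurrence matrix of adjacent valid voxels; `H = 1` when
  neighboring voxels always share an elevation bin.
- **Morphometry**: BV/TV, BS/BV (marching-cubes surface), Tb.Th/Tb.Sp
  (maximal-inscribed-sphere local thickness, 3D and 2D section modes),
  Tb.N = BV/TV ÷ Tb.Th, box-counting fractal dimension, and subchondral
  plate thickness within a plate mask.
- **Segmentation**: fixed pre-threshold (60 on 8-bit) followed by local
  adaptive midrange thresholding (ball window, radius 5 voxels).
- **Statistics**: Pearson correlation against a severity grade with donors
  weighted equally (each sample weighted 1/its donor's sample count), and
  CV% precision of repeated measures.

## Worked example

Generate a phantom of longitudinal rods, then measure its texture and
orientation:

```python
import trabtex as tt
from trabtex.phantoms import PhantomSpec, generate

spec = PhantomSpec(kind="rod_lattice", elevation_deg=90.0,
                   element_radius_vox=1.2, spacing_vox=8.0,
                   size_vox=(64, 64, 64), noise_sd=0.0, seed=5)
vol, truth = generate(spec)

nbhd = tt.build_neighborhood(radius_vox=1.5)
mask = tt.analysis_mask(vol, nbhd, fixed_threshold=60.0)
hist = tt.lbp_histogram(vol, mask, nbhd)
field = tt.elevation_field(vol, mask, nbhd)
summary = tt.orientation_summary(field)

print(f"pattern entropy  {tt.pattern_entropy(hist):.2f} bits")
print(f"mean elevation   {summary.mean_elevation_deg:.1f} deg "
      f"(ground truth {truth.elevation_deg:.0f})")
print(f"homogeneity      {summary.homogeneity:.3f}")
```

prints

```
pattern entropy  4.73 bits
mean elevation   90.0 deg (ground truth 90)
homogeneity      1.000
```

The rods are perfectly aligned with the distal-proximal axis, so every
valid pattern points longitudinally (mean elevation 90°, homogeneity 1);
the entropy reflects the variety of surface patterns around the rods.  The
same functions are exposed on the command line (`trabtex phantom`,
`trabtex binarize`, `trabtex lbp`, `trabtex orient`, `trabtex morpho`,
`trabtex correlate`, `trabtex run --config run.yml`).

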