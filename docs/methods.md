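# Methods

## Chamber volumetry from sparse plane segmentations

### Plane geometry and oriented points

Each segmentation mask lives on an imaging plane whose placement in the
patient coordinate system is given by the DICOM Image Position (Patient),
Image Orientation (Patient), and Pixel Spacing attributes.  We use the
DICOM pixel-center convention with 0-based indices:

    P(r, c) = S + c·Δc·X + r·Δr·Y

with X the first orientation triplet (direction of increasing column), Y
the second, Δr = PixelSpacing[0], Δc = PixelSpacing[1].

The perimeter of a mask is the mask minus its binary erosion with a 3×3
cross (the erosion default of scipy/scikit-image; configurable).  Each
perimeter pixel becomes a 3-D point whose normal is the unit vector from
the center of gravity of the *full* mask (not the perimeter) to the point;
it lies in the view plane by construction.  Points that coincide with the
centroid have no direction and are dropped with a warning rather than
zero-filled, so the reconstruction never sees non-unit normals.

**Sub-pixel bias correction.**  A binary mask contains the pixels whose
centers fall inside the structure, so perimeter pixel centers sit on
average half a pixel inside the true contour.  At the 1.83-mm in-plane
spacing of long-axis CINEs this inward bias is ≈0.9 mm, which for a 30-mm
chamber radius is an ≈8 % volume deficit.  `fragment_from_mask` therefore
offsets each perimeter point outward along its normal by 0.5 pixel
(configurable, `subpixel_offset_px`); with the correction the sphere and
ellipsoid phantoms are recovered within 5 % (typically 0.3–3 %).

### Poisson indicator solve

The surface is recovered through the indicator function χ (≈1 inside the
chamber, ≈0 outside).  The smoothed field V⃗ of splatted outward normals
approximates the surface-delta-weighted gradient of χ up to sign, giving
the Poisson problem ∇²χ = −∇·V⃗ (the sign because our normals point
outward while ∇χ points inward at the boundary).

We deliberately use a regular grid instead of the adaptive octree of the
classical implementation: at chamber scale a 96³ grid resolves the surface
comfortably, and the zero-Dirichlet 7-point Laplacian is diagonal in the
type-I discrete sine basis, so the solve is three DSTs and a pointwise
division — exact, deterministic, and fast (≈0.1 s per frame at 96³).
Defaults and their rationale:

| parameter | default | meaning |
|---|---|---|
| `grid_res` | 96 | isotropic grid size; 96 puts ≈1 mm voxels on a 100-mm box |
| `smoothing_sigma_vox` | 1.5 | Gaussian width applied to V⃗, in voxels; bridges the ≈2-mm gaps between perimeter points of neighbouring planes |
| `padding_frac` | 0.25 | bounding-box padding per side, so the Dirichlet boundary (χ = 0) stays clear of the surface |
| iso-value | mean of χ at the input points | the standard Poisson-reconstruction convention; configurable |

Marching cubes extracts the iso-surface; only the largest connected
component is kept (multi-component segmentations are separately a QC
flag), the orientation is fixed so the signed volume is positive, and the
volume is the divergence-theorem sum of signed tetrahedra, mm³ → mL.
A cloud confined to one plane cannot bound a volume, so assembly rejects
clouds whose centered points have rank < 3 (third singular value below
max(1e-8·σ₁, 1e-6 mm)).  Frames that fail to reconstruct carry NaN and a
status string; phenotype extraction refuses incomplete traces, mirroring
study-level exclusion by QC.

### Phenotypes

LAmax and LAmin are the extrema of the 50-frame trace, LASV their
difference, LAEF = LASV/LAmax.  BSA indexing divides volumes by the Du
Bois body surface area 0.007184·W^0.425·H^0.725 (Mosteller available);
the Du Bois form is the prevailing cardiology convention.  The 50×8
filling tensor normalizes each chamber-area channel by its own maximum, so
only relative size changes remain; studies missing any of the 8 channels
(4ch LA/RA/LV/RV, 3ch LA/LV, 2ch LA/LV) are excluded, as is any channel
with zero maximum.  The per-channel maximum is taken over the 50 frames of
that channel only.  The filling-pattern classifier is a pluggable
interface; the shipped heuristic (a late-cycle dip-and-rebound of the mean
LA channel of at least 5 % of its range) is a reference stand-in for a
trained time-series model, not a claim about clinical sensitivity.

### Quality control

Per study: (a) >1 connected component in any frame (8-connected by
default; configurable), (b) a maximum frame-to-frame change in segmented
pixel count exceeding the cohort mean by more than five cohort SDs,
(c) any empty frame, (d) frame count ≠ 50.  Cohort statistics are computed
over the batch passed in and persisted to JSON.  Mask-quality metrics are
the Sørensen–Dice coefficient (defined as 1 when both masks are empty),
the *directed* Hausdorff distance between perimeters, and the directed
mean contour distance, all between pixel centers in mm assuming isotropic
in-plane spacing; a symmetrized Hausdorff is available but the directed
form is the primary definition.

## Locus definition, overlap, and Hardy–Weinberg

Distinct loci are defined greedily: take the remaining SNP with the
smallest P, absorb every SNP within the window (default 500 kb,
boundary-inclusive |Δbp| ≤ 500,000; inclusive because "within" is
boundary-ambiguous and the choice is configurable) on the same chromosome,
iterate.  Ties on P break by (chromosome, position), making the result
independent of input row order.  Cross-trait "distinct loci" pool all
rows first and then merge — this pool-then-merge procedure reproduces
every per-trait, shared, and pooled count on the packaged lead-SNP table.
Distance-only merging deliberately stands in for LD-based clumping: no LD
panel ships with the package, and at these window sizes the two coincide
for well-separated association signals.

Overlap of a locus set with a reference lead list counts loci having ≥1
reference lead within the window (each locus counts once).  The
permutation test compares the observed count with counts from matched null
SNP sets supplied by a pluggable provider — covariate-matched set
generation (allele frequency, LD, gene density) is out of scope, so the
default provider samples uniformly from a user-supplied panel.  The
one-tailed p carries the +1 correction, p = (1 + #{null ≥ obs})/(1 + N),
whose floor at N = 10,000 is ≈1E-04.

The Hardy–Weinberg test is exact: conditioning on allele counts, all
heterozygote counts of matching parity are enumerated in log space and the
probabilities not exceeding that of the observed count are summed.

## Two-sample Mendelian randomization

Instruments: P < 1e-6 filter then distance clumping with a 5-Mb window
(both configurable).  Harmonization removes palindromic (A/T, C/G)
variants, flips the outcome beta when the allele pair is swapped, and
drops non-matching pairs with a warning.

* **IVW** — weighted regression of βy on βx through the origin, weights
  1/σy².  The default is multiplicative random effects: SE scaled by
  max(1, √(Q/(k−1))), appropriate when instrument heterogeneity is
  expected; fixed effects by flag.
* **MR-Egger** — WLS with intercept after orienting instruments to
  βx ≥ 0 (required for identifiability).  The intercept estimates
  directional pleiotropy under InSIDE.  SEs are analytic with the same
  multiplicative scaling, or instrument-level bootstrap on request.
  Note the slope carries the usual weak-instrument (NOME) attenuation of
  ≈ mean(σx²)/var(|βx|); with the synthetic generator's sample sizes this
  is ≈2 %.
* **Medians** — per-SNP Wald ratios βy/βx; the simple median and the
  weighted median with first-order inverse-variance weights of the ratio.
  The weighted median is the classical crossing definition (smallest ratio
  at cumulative weight ≥ ½, midpoint on an exact split), so an instrument
  holding >50 % of the weight returns its own ratio.  SEs come from a
  parametric bootstrap (betas perturbed by their SEs): an instrument-level
  resampling bootstrap under-covered (0.90 at nominal 0.95 over 500
  replicates) for this non-smooth estimator, while the parametric form
  covers at 0.95.
* **Cochran's Q** on Wald ratios with first-order weights; χ²(k−1).
* **Pleiotropy screen** — OLS of each risk factor on each instrument
  dosage plus covariates; flags below the family-wise Bonferroni threshold
  α/(k·m) mark instruments for a leave-out sensitivity rerun.

MR-PRESSO and the contamination-mixture model are documented sensitivity
analyses elsewhere; the report schema reserves their method labels so
externally computed rows can be merged.

## Synthetic data: what it emulates, and what it does not

`make_phantom` rasterizes a time-varying sphere/ellipsoid/two-lobe shape
onto the standard acquisition plan — three long-axis planes 60° apart
about the long axis plus a 6-slice short-axis stack (8-mm slices, 2-mm
gaps), 1.83/1.86-mm pixels, 50 frames — with closed-form volume as ground
truth, optional boundary pixel-flip jitter emulating segmentation noise.
It does **not** emulate atrial anatomy (appendage, pulmonary veins),
through-plane motion, or imaging physics; passing the recovery tests shows
the reconstruction machinery is accurate for convex chambers at study
geometry, not that real LA volumes carry no segmentation-driven error.
`make_filling_curves` produces smooth two-phase atrial/ventricular area
curves whose only degree of freedom of interest is the presence of a
late-cycle atrial-kick dip.  `make_leadsnp_table` plants distance-separated
clusters so locus counts are known by construction.  `make_mr_dataset`
draws per-SNP effects around ±0.08 (SD 0.02) with standard errors
1/√(2·N·f(1−f)) at N = 300,000 per study — instrument strengths typical of
a large volumetric GWAS — and supports balanced or directional pleiotropy
(directional effects aligned with the exposure-increasing allele) and an
InSIDE-violating mode where pleiotropy scales with instrument strength.
All generators are pure functions of spec + seed.

## Problem sizes used by the tests and acceptance script

Phantom recovery runs single frames at grid 96 across 20–60-mm semi-axes;
full-trace tests use grid 64 (50 frames) and 48, where reconstruction
noise is ≈2 %.  Estimator calibration uses 500 replicate instrument sets
of k = 50 with 200 bootstrap draws.  The permutation floor uses the full
10,000 null sets.  These sizes keep the whole suite under a minute apart
from the imaging tests while leaving every statistical tolerance
binomially justified.

## Known limitations

* The unscreened regular-grid solve trades the octree's adaptivity for
  exactness and simplicity; very thin or highly concave chambers would
  need finer grids than 96³.
* Volumes are calibrated for convex phantoms; concave anatomy with the
  same plane plan is under-determined and the reconstruction interpolates.
* Distance clumping ignores LD structure; two independent signals within
  one window merge, and long-range LD can split.
* The uniform null-set provider does not match allele frequency or gene
  density; enrichment p values against it are optimistic relative to a
  matched provider, which is why the provider is an interface.
* Egger's slope is reported without NOME/I²GX correction.
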