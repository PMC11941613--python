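# Methods

## Scope and data model

The pipeline mirrors how en face diaphragm NMJs are quantified from
two-channel confocal stacks: binarize each channel, clean the 3D masks,
take volumes and MIP shape descriptors, compute the 3D apposition of the
pre-synaptic terminal against the motor end-plate, and classify
denervation from projected overlap. Stacks are `(channel, z, y, x)`
grids of 12-bit intensities with voxel size (dz, dy, dx) =
(1.0, 0.5, 0.5) µm by default; all physical quantities are derived from
the voxel size, never from pixel counts alone.

## Segmentation

**Thresholding.** The default is Otsu's method on the full 3D histogram
of a channel (256 bins), applied identically to the MIP so that 2D and
3D descriptors share one calibration per channel. Foreground is
intensity ≥ threshold; because the common library convention marks
strictly-greater pixels, the Otsu value is stepped to the next
representable float before use. Fixed thresholds (`fixed:N`) are
available, and every threshold actually applied is logged — automatic
thresholding trades a small, quantified bias (below) for exact
reproducibility, which interactive manual thresholding cannot offer.

**Cleaning.** 26-connected components smaller than 5 µm³ are removed
(speckle). For the pre-synaptic channel a reference-linking rule
additionally keeps only components that come within 2 µm of the
end-plate mask; this excludes stray axonal synaptophysin label from
terminal volume. Both cutoffs are configuration. The operation is
idempotent. Whether apposition uses the cleaned or raw pre-synaptic
mask is a config switch (cleaned by default).

## Shape descriptors

The **axes box** is the bounding box aligned to the principal axes
(second-moment eigenvectors) of the foreground pixel cloud; each extent
is the span between extreme pixel centers plus one pixel width, and a
degenerate (collinear) mask gets a one-pixel minor extent. This
convention makes an axis-aligned rectangle score a relative planar area
of exactly 100 %. Its cost is a discretization bias for non-aligned
shapes: extents can overshoot by up to one pixel width per axis, so a
filled ellipse with semi-axes a, b approaches the analytic ratio
πab / (2a · 2b) = π/4 ≈ 78.5 % from below as resolution grows (75.5 %
at 40 × 20 px, 77.8 % at 160 × 80 px). An alternative reading of "main
orthogonal axes" via a convex-hull minimal box would behave similarly
and is not implemented.

**Denervation classification** replaces the visual call with a
quantitative rule on the binarized MIPs: f = |pre ∩ post| / |post|, with
category cutpoints (0.10, 0.80) and boundaries classifying upward
(f = 0.80 is innervated). The cutpoints are configuration and a
sensitivity sweep is part of the test suite; the defaults were fixed
before any cohort-level result was computed and are not tuned per
dataset.

## Synthetic NMJs

The generator emulates the study conditions so every stage can be
validated against exact truth:

1. **End-plate**: `branch_count` (4–6) smooth random-walk arms radiate
   from a centre on a gently curved surface patch (bowl curvature
   0.004 µm⁻¹), giving a branched "pretzel" skeleton. The mask is the
   set of the N grid voxels nearest the skeleton (Euclidean distance
   transform with anisotropic sampling), N = target volume / voxel
   volume — realized volume therefore matches the target to one voxel,
   and ties in distance are broken deterministically.
2. **Terminal**: the same construction on a sub-length of every arm
   (arc-length fraction = volume ratio), which keeps the terminal tube
   as thick as the end-plate tube at its smaller volume. The sub-skeleton
   is translated along a fixed oblique direction; the translation
   magnitude is bisected (≤ 14 iterations, tolerance 0.01) until the
   voxel overlap fraction with the end-plate matches the target
   apposition. Realized apposition is recorded exactly; targets outside
   the geometrically achievable range are clamped with a warning.
3. **Axon**: an optional thin filament in the pre-synaptic channel,
   placed ≥ 4.5 µm clear of both structures so that reference-linked
   cleaning should remove it; it is rendered but never counted in the
   true terminal volume. It is on by default to force the segmentation
   stage to handle non-terminal label.
4. **Optics**: Gaussian PSF blur (σ = 0.6 µm lateral, 1.2 µm axial by
   default), additive Poisson photon noise scaled by `noise_level`
   (0 disables it; 1 is pure Poisson), and 12-bit quantization in a
   16-bit container. With σ = 0 and noise 0, any threshold strictly
   between background (100) and foreground (3100) recovers the true
   masks exactly — the basis of the exact-recovery tests.

Tube radius (2.6 µm) and arm curl (0.07 rad/µm, jitter 0.15) were
calibrated once so that measured relative planar area of
branch-count-5 end-plates lands in the mid-40s percent, matching the
branched morphology the study describes; the same geometry keeps
structures thick relative to the PSF.

Population draws use zero-truncated normals for volumes and clamped
normals for apposition — the distributional choice consistent with the
ANOVA analyses. Cohorts alternate sexes within groups, draw per-animal
NMJ counts (floored at 35), and draw body masses from sex-specific
normals (males 32.0 ± 3.0 g, females 22.7 ± 1.5 g, 7-day change
−0.3 ± 1.0 g) matching the cohort's reported mass table. Fast mode
emits the draws directly as measurements for statistics-only runs;
image mode renders every NMJ. Everything is deterministic given the
seed (child seeds via `SeedSequence.spawn`).

**What the generator does not emulate**: antibody penetration gradients,
depth-dependent attenuation, detector read noise, end-plate
fragmentation, spatially correlated NMJ placement, or a mechanistic link
between the drawn denervation category and the rendered apposition (the
two are sampled independently from their marginal distributions).
Passing recovery tests therefore demonstrate correctness of the
measurement chain under idealized optics, not robustness to every
property of real microscopy.

## Measurement accuracy under the default optics

Otsu on a histogram dominated by background places the threshold on the
blur skirt, dilating masks slightly: at the default geometry the
volume bias is about +5 to +9 % (compact canvas; slightly larger on the
full 600 × 800 field) with per-NMJ spread of a few percent, while
apposition — a ratio of similarly biased masks — is recovered within
~1 point. The validation suite asserts mean absolute volume error
< 10 % and apposition error < 5 points on a 50-NMJ two-group batch, and
exact recovery on blur-free renders.

## Statistics

* **One-way ANOVA** is computed from the between/within decomposition
  directly (the decomposition is asserted exact to 1e-9 relative);
  degenerate zero-within-variance inputs report an infinite F with
  p = 0, and F = 0 with p = 1 when groups are identical.
* **Two-way ANOVA** uses Type-II sums of squares via nested
  least-squares fits — the standard main-effects choice for the
  unbalanced per-animal proportion table; the implementation is
  cross-checked against statsmodels' `anova_lm(typ=2)` in the test
  suite. Empty cells drop the interaction with a warning. Note that a
  treatment main effect on complete compositional proportions is
  identically zero (each animal's proportions sum to 1); the meaningful
  treatment signal appears in the interaction, which is how the report
  should be read.
* **Chi-square** is the Pearson statistic on the treatment × category
  count table (no continuity correction); all-zero categories are
  dropped from the table with a warning before testing.
* **Tukey–Kramer HSD** uses the studentized-range test with the
  unequal-n correction (scipy's implementation) behind a thin pairwise
  interface.
* **Paired t-tests** compare pre/post body mass per group; zero-variance
  differences are flagged degenerate rather than erroring.
* **Effect sizes** are percent changes relative to the vehicle mean
  (100 · (veh − chl)/veh), a fold change for the partial-denervation
  proportion (chl/veh), and the male/female mass difference
  (100 · (m − f)/f); a `rounded()` view reports them at integer-percent
  / one-decimal-fold precision. Proportions are analyzed untransformed
  by default (an arcsine transform is a config option left off).
* **Power**: a Monte-Carlo check of the one-way ANOVA on per-animal
  means under the nested variance model (between-animal CV 5 %,
  within-animal CV 17 %, 40 NMJs/animal). At this profile, 4 animals
  per group exceed 80 % power for a 20 % effect at α = 0.05, consistent
  with the design rationale of studies at this scale. Tests are
  two-sided at α = 0.05 throughout.

All tests' type-I error rates are verified by null simulation (10⁴
replicates each) to sit within two binomial standard errors of 0.05.

## Replication run and problem sizes

The shipped calibration (`configs/replication.yaml`,
`nmjmorph.REFERENCE_STUDY`) encodes the study design: 6 animals per
group, sexes balanced, per-group NMJ-count means 45/37 (SD 11, floor
35) reproducing ~270 vehicle and ~221 chloroquine NMJs, pre-synaptic
volume 1411 ± 236 vs 1248 ± 274 µm³, end-plate volume 1792 ± 259 vs
1804 ± 269 µm³, apposition 66 ± 11 vs 56 ± 10 %, category probabilities
(0.93, 0.07, 0) vs (0.78, 0.19, 0.03). Replication verdicts are bracket
checks (value ± tolerance) because cohorts are stochastic and the
original per-NMJ data are not published; the package does not attempt
to equal the study's own F statistics beyond the study-scale mean-F
recomputation in `scripts/acceptance.py` (300 Monte-Carlo replicates at
n = 491). Image-mode replication defaults to a reduced scale (3 animals
per group, 12 NMJs each, compact canvas) sized for interactive runs;
the statistics replicate at full scale in fast mode.

## Known limitations

* NMJs are analyzed as independent units in the per-NMJ ANOVAs,
  mirroring the study design; a mixed-effects model accounting for
  animal-level clustering would be more conservative and is not
  implemented.
* The printed degrees of freedom of some published category-proportion
  ANOVAs are inconsistent with a conventional two-factor layout; the
  package reports conventional df and makes no attempt to match those
  F values.
* Otsu's threshold depends on the foreground fraction of the field, so
  measured volumes carry a canvas-size-dependent bias of a few percent;
  fixed thresholds remove this at the cost of manual calibration.
* The generator's category draw and rendered apposition are coupled only
  through their group-level distributions, so image-mode category
  proportions emerge from the MIP-overlap rule rather than reproducing
  the drawn categories NMJ-by-NMJ.
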