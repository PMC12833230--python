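# Methods

## The mapping model

The pipeline treats each included study as a noisy pointer to an
underlying functional system. A study's reported peak coordinates are
expanded into a union of 4 mm spheres (the *contrast seed*); the seed's
mean time series in each normative-connectome subject is correlated with
every brain voxel, Fisher z-transformed (z = atanh(r), with r clipped to
±(1 − 1e−7) to keep z finite; clipped voxels are flagged), and the
per-subject z maps enter a voxel-wise one-sample t-test. The group map
is thresholded at P < 0.01 with Benjamini–Hochberg FDR computed over
brain-mask voxels only, restricted to positive t (negative-connectivity
networks are deliberately out of scope), and binarized. Binary maps are
averaged across studies into a probability map and thresholded
inclusively at 60% — with 14 studies a voxel needs 9 (9/14 ≈ 0.643),
with 4 studies it needs 3.

Design choices where the procedure is genuinely underdetermined:

- **t-test sidedness.** The t-test is two-sided with a post-hoc positive
  restriction (t > 0); a one-sided mode is available via
  `PipelineConfig(two_sided=False)`. Both orderings give identical
  networks whenever the voxel-wise p is monotone in |t|, which holds
  here; the default is the more conservative published convention.
- **Aggregation unit.** One seed per *study* (pooling its contrasts) is
  the default, since the probability map's denominator is a study count;
  per-contrast mode (`unit="contrast"`) is provided.
- **Sphere membership.** A voxel belongs to a sphere iff its center is
  within the radius (Euclidean mm), plus a containing-voxel rule so that
  1 mm seeds on a 3 mm grid are the single enclosing voxel rather than
  empty. Rounding of mm→voxel coordinates is half-away-from-zero to be
  platform-stable.
- **Talairach conversion.** The Lancaster icbm-spm affine (inverted
  icbm_spm2tal matrix) is the default; the Brett piecewise transform is
  selectable. Which conversion (if any) applies to a given literature
  table is input metadata, not something the pipeline guesses.
- **Probability threshold inclusive (≥).** With 4 studies inclusive and
  exclusive rules coincide at 3/4; inclusivity keeps a threshold of 1.0
  attainable.
- **FDR implementation.** `fdr_select` delegates to statsmodels'
  `multipletests(method="fdr_bh")`; the test suite checks it against a
  direct max-k implementation of the step-up definition, ties included.

## Canonical-network annotation

Overlap proportions are network-relative: |network ∩ label| / |network|,
so proportions plus the unassigned (background) fraction sum to one.
"Subcortical" is a single aggregate of thalamus, caudate, putamen,
pallidum, hippocampus, amygdala and nucleus accumbens labels, with a
per-structure breakdown retained. The atlas is a hard parcellation on
the session grid; probabilistic atlases must be argmax-reduced and
grid-mismatched atlases resampled upstream (a mismatch is an error, not
a silent resample).

## Molecular association

Maps are reduced to parcel means on a contiguous 1..R labeling
(R = 119 by default, mirroring the Neuromorphometrics convention). The
association statistic is a partial Spearman correlation: rank-transform
x, y and the gray-matter covariate over jointly non-missing parcels
(average ranks on ties), residualize the x and y ranks on the covariate
ranks with an intercept, and Pearson-correlate the residuals;
rho_z = atanh(rho). Inference is by exact permutation: the
neurotransmitter map's parcel values are shuffled uniformly
(n_perm = 10,000 by default), and the two-sided p is
(1 + #{|rho_null| ≥ |rho_obs|}) / (n_perm + 1), so the smallest
attainable p is 1/(n_perm + 1). BH-FDR at α = 0.05 is applied across
the 16-map catalogue.

The permutation null assumes exchangeability of parcels and therefore
ignores spatial autocorrelation; an autocorrelation-preserving null is a
known limitation, partially mitigated by the gray-matter covariate.
Two screening modes exist: single-map (default; one rho for the final
network) and subject-level (per-subject FC-map rhos, Fisher z, one-sample
t against zero with a shared permutation null), since published reports
are ambiguous about which units enter the group test.

## Validation

Dice = 2|A∩B| / (|A|+|B|) on exact voxel sets. Radius sensitivity reruns
the entire pipeline at 1 and 7 mm and compares each to the 4 mm
reference. The test against the 0.5 benchmark is a one-sample t with
one-sided alternative "mean < 0.5"; because it is typically applied to
very few values, the raw Dice values are always reported alongside the
test, and a zero-variance input yields a sign-based verdict instead of a
t statistic.

## The synthetic generator

`synthetic_data` emulates the statistical structure the method assumes,
not BOLD physiology. Per subject, each acupoint's latent signal u(t) is
AR(1) with coefficient φ = 0.3 and unit marginal variance; every voxel of
that acupoint's seed region and planted network receives
x_v(t) = λ·u(t) + ε_v(t) with ε ~ N(0, σ²) i.i.d., so any two driven
voxels correlate at λ²/(λ² + σ²) in expectation and off-network voxels
are pure noise. Defaults: λ = √(2/3), σ = 1 (driven-pair correlation
0.4 — a realistic within-network resting-state coupling), 40 subjects,
T = 120 timepoints, a 20×24×20 voxel grid at 3 mm with an ellipsoidal
brain mask, and two disjoint planted systems with 14 and 4 simulated
studies of 1–5 jittered coordinates each (σ_jitter = 1 mm), mirroring the
two-acupoint study scenario. Atlases and parcellations are Voronoi
labelings of the mask; a designated canonical label can be planted to
dominate a network's composition. Neurotransmitter catalogues are drawn
by Gaussian-copula mixing against the target pattern's normal scores with
ρ_gauss = 2·sin(π·ρ_spearman/6), so a requested Spearman association is
realized on average; heavy ties in the target (e.g. sparse binary-network
coverage vectors) compress the realized correlation below the nominal
target, which matches how sparse empirical maps behave. All generators
derive per-subject/unit/map streams by seed-sequence spawning, so scenes
are bit-reproducible and sub-streams independent.

What the generator does **not** simulate: head motion, physiological
noise, smoothing, spatial autocorrelation of noise, hemodynamics, or
between-subject anatomical variability. Passing tests therefore
demonstrate the statistical machinery (error control, recovery,
calibration, reproducibility) — they do not certify performance on real
fMRI, where preprocessing quality and spatial autocorrelation matter.

## Error control measurement

In a pure-noise connectome the voxels of a seed still correlate with
their own seed mean (r ≈ 1/√k for a k-voxel seed), so they are not null
hypotheses and survive FDR legitimately. False-positive control is
therefore measured over the true-null family — brain-mask voxels outside
the unit's seed — where the surviving fraction at q = 0.01 is ~2·10⁻⁵ in
the shipped null simulation (bound checked: < 0.5%).

## Problem sizes

The default test and acceptance scenes use the 20×24×20 grid
(≈ 4,300 mask voxels), 40 subjects × 120 timepoints for recovery and
robustness runs, 50 units for null calibration, 200 replicates × 999
permutations for permutation calibration, and 500 replicates for copula
calibration — sizes chosen so a full verification pass completes in
minutes on one CPU while keeping Monte-Carlo error well inside the
asserted tolerances.
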