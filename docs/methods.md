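# Methods

## The analysis

The pipeline treats each lesion as a point in a three-dimensional intensity
space: its median voxel intensity on FSPGR, SE and FLAIR. Three constructions
sit on top of that.

**Standardized intensity.** A lesion median divided by the subject's tissue
median (WM, GM or CSF) on the same sequence. The ratio is dimensionless and
scale-invariant: multiplying a volume by any c > 0 changes lesion and tissue
medians by c and leaves the ratio fixed. A WM-ratio of 1 means the lesion is
indistinguishable from surrounding white matter; T1-hypointense lesions have
WM-ratios below 1 and GM/CSF-ratios above 1.

**Two-cluster typing.** K-means with K = 2 on the raw median triplets pooled
across subjects, unscaled. Not rescaling features is deliberate: intensities
on FSPGR span a much wider range between the two lesion types than on SE or
FLAIR, so the FSPGR median dominates the partition, and the per-feature
one-way ANOVA F across the final labels (between-cluster mean square over
within-cluster mean square, df (1, n−2)) makes that dominance explicit.
Labels are canonicalized so cluster 1 has the lower FSPGR center.

**Standardized lesion distance.** For reference intensity r and WM voxel
intensities w₁…w_m, the mean distance d(r) = (1/m) Σ wᵢ/r, which collapses to
mean(WM)/r because r is constant across the sum (both forms are computed and
tested against each other). A null distribution per subject and sequence is
the multiset {d(r₁)…d(r₅₀₀₀)} for 5,000 reference voxels drawn with
replacement from the subject's own lesion-free WM; a lesion's z is
(d(lesion median) − null mean) / null sd, with the sd using the n−1
denominator. Because the null is built per subject, z adapts to individual
WM intensity profiles; because d is a ratio, z is scale-invariant; and
because d decreases in r, darker lesions get larger z. The summary statistic
is the percentage of lesions in each cluster × sequence with z > 2.3
(one-sided — hypointensity is directional).

Design points that were genuinely open, and the choices made:

- *Ratio direction.* "Average ratio of WM intensities and the reference" can
  be read either way; `wm_over_ref` is the default so that hypointense
  lesions get positive z and "exceeding 2.3" flags conspicuous lesions. The
  reciprocal is available via `NullConfig.ratio_direction`.
- *Z conversion.* Moment standardization against the empirical null (not a
  percentile transform); "converted to Z-scores" is read literally.
- *Bootstrap sampling.* With replacement; WM voxel counts can fall below
  5,000 on coarse grids.
- *K-means initialization.* The fit must be deterministic. For tables of at
  most 64 rows, every observation pair is tried as initial centers and the
  lowest final within-cluster sum of squares wins — at these sizes that
  reliably coincides with the exhaustive optimum over all 2-partitions (it
  matched brute force in 500/500 random trials, where a single farthest-pair
  start missed in ~54%). Larger tables use the single farthest-pair start;
  with the separated structure this analysis targets, Lloyd converges to the
  same partition either way, in far fewer than the 10-iteration cap.
- *Multiple comparisons.* Bonferroni, with the family defined as all valid
  cells of the burden × clinical grid produced in one run (constant
  variables are flagged and excluded from the family size). p-values are
  capped at 1.

## Preprocessing

Intensity standardization maps each volume onto a per-sequence standard
scale: decile landmarks (p10…p90 of strictly-positive voxels) are averaged
over the cohort, and each volume's own landmarks are matched to them by a
piecewise-linear, monotone map with linear extrapolation at the tails. The
method follows the classical two-stage histogram-landmark approach for MR
intensity standardization; a passthrough mode exists
(`standardization_enabled=False`).

Lesion masks are conditioned in three steps, with the stated conventions:
trilinear resampling onto the target grid followed by thresholding at 0.5
(values ≥ 0.5 kept, so a mask does not grow through interpolation);
connected-component labelling with 26-connectivity; and a strict size filter
(components must exceed 100 voxels, applied in the mask's native space so
the count does not depend on the resampling). Tissue membership uses the
majority rule (partial volume > 0.5); WM membership excludes every lesion
voxel, both for the WM median and for the bootstrap multiset. Medians of
even-sized sets are the mean of the two middle values throughout.

## The phantom cohort

The generator emulates the statistical structure the analysis assumes, not
MR physics. Each subject is a concentric-ellipsoid head — CSF rim and a
small central ventricle, a GM shell, a WM core — on a 64³ grid of 1 mm
voxels. Per sequence, tissue voxels get Gaussian noise with sd equal to 3%
of the tissue location; the locations (FSPGR 4800/3000/800, SE
2000/1400/600, FLAIR 2200/2400/300 for WM/GM/CSF) are chosen to satisfy the
qualitative contrasts: CSF < GM < WM on the T1-weighted sequences, GM > WM
and suppressed CSF on FLAIR.

Lesions are axis-aligned ellipsoids placed by rejection sampling wholly
inside WM-dominant voxels (largest first), with voxel counts log-uniform on
[60, 2000] so the 100-voxel filter genuinely bites (~15% of lesions fall
below it). Each lesion belongs to class 1 (probability 1 − 470/694) or
class 2, and its per-sequence median is drawn from the class distribution —
locations at the published-scale cluster centers (FSPGR 3525.20 / 4280.42,
SE 1701.23 / 1887.77, FLAIR 2575.23 / 2555.67), spreads (140/120, 140/80,
210/210) set so the classes are essentially disjoint on FSPGR, overlapping
on SE, and coincident on FLAIR, truncated to lie strictly between the GM
and WM locations on the T1 sequences. The expected cohort is 79 subjects ×
8.78 lesions ≈ 694 lesions.

Clinical covariates are coupled to class-2 burden with a Gaussian copula:
for a target Spearman ρ, the latent Pearson correlation is r = 2 sin(πρ/6),
the latent normal is r·score(burden) + √(1−r²)·noise (van der Waerden scores
with average ranks), and the result is pushed through the marginal quantile
function — EDSS a truncated normal on [0, 6] with median 2 rounded to 0.5
steps, disease duration a truncated normal (mean 12.34 y, sd 7.44 y, ≥ 0),
NBV Normal(1500, 75). Defaults inject ρ = +0.30 (class-2 count ↔ EDSS),
+0.33 (class-2 count ↔ duration) and −0.51 (class-2 volume ↔ NBV); relapse
counts are independent Poisson draws. Discrete marginals attenuate the
realized Spearman by a few hundredths, which the replicate studies show.

Everything derives from one master seed: subject i uses
`SeedSequence(master_seed, spawn_key=(i,))`, the clinical table
`spawn_key=(n_subjects,)`, and the pipeline's per-subject bootstrap nulls
`spawn_key=(1000, subject, sequence)`; identical configurations reproduce
identical bytes.

What the phantom does **not** emulate — and hence what passing tests do not
show about real data: acquisition physics (TE/TR, flip angles), bias fields
and registration misalignment (volumes are generated pre-aligned; only the
threshold/binarize step of mask transfer is retained), segmentation error
(ground-truth partial volumes are supplied), realistic lesion anatomy
(placement is uniform in WM, shapes are ellipsoids), contrast-enhancing
acute lesions, and non-RRMS subpopulations. Results on the phantom validate
the machinery — calibration of the Z statistic, exactness of the clustering,
recovery of injected effects — not the clinical conclusions themselves.

## Problem sizes and numerics

Default runs use the full 79-subject cohort on 64³ grids (~40k WM voxels per
subject), 5,000 bootstrap references per subject × sequence, 2,000
pseudo-lesions × 10 seeds for null calibration, and 20 replicate cohorts for
effect recovery; the whole acceptance computation completes in well under a
minute on one CPU. Tests use coarser grids (40³) with lesion sizes capped at
300 voxels so placement stays feasible. Lloyd iterations stop on unchanged
labels or a center shift below 1e-9; K-means ties in assignment go to the
lower-indexed center, and ties in the farthest-pair search to the
lexicographically smallest row pair. Volumes are stored float32; medians and
ratios are computed in float64. Degenerate inputs fail loudly rather than
silently: constant-intensity volumes (landmarks collapse), empty tissue
classes, all-identical WM (zero-spread null), clusters with fewer than two
members, and all-unity ratio sets each raise a specific error.

## Known limitations

The standardized-lesion-distance null is exchangeable only against the
subject's own WM distribution; comparing z across subjects assumes their WM
noise profiles are comparable after standardization. The exceedance
percentages depend on the phantom's 3% noise level — they reproduce the
qualitative ordering (FSPGR ≫ SE; cluster 1 ≫ cluster 2 on SE) rather than
any particular printed percentage. Bonferroni over the full grid is
conservative; with 34 cells, moderate true effects (|ρ| ≈ 0.3 at n = 79) are
often non-significant after correction even though the point estimate is
recovered.
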