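# bhtyper — intensity-based typing of T1-hypointense MS lesions

Hypointense lesions on T1-weighted MRI ("black holes") mark axonal loss in
multiple sclerosis, and have traditionally been assessed on spin-echo (SE)
images. Fast spoiled gradient-echo (FSPGR) images show the same lesions with
more contrast, and the two sequences do not agree on which lesions stand out.
`bhtyper` implements an analysis pipeline that types T1-hypointense lesions
by their intensity profile across sequences and asks which type carries
clinical meaning:

1. **Per-lesion features.** For every lesion (connected component > 100
   voxels), the median voxel intensity on FSPGR, SE and FLAIR, plus
   *standardized intensities* — the lesion median divided by the subject's
   white-matter (or GM/CSF) median on the same sequence, so a value of 1
   means the lesion does not stand out from that tissue.
2. **Two-cluster typing.** K-means (K = 2, at most 10 Lloyd iterations, then
   a final classification pass) on the raw (FSPGR, SE, FLAIR) median triplets,
   pooled across subjects. Cluster 1 is canonically the darker-on-FSPGR type.
   One-way ANOVA F per feature quantifies each sequence's influence on the
   partition.
3. **Standardized lesion distance (Z).** For a reference intensity r and WM
   voxels w₁…w_m, the mean distance is d(r) = (1/m) Σᵢ wᵢ/r = mean(WM)/r.
   A per-subject, per-sequence null is built by sampling 5,000 reference
   voxels from the subject's own WM; a lesion's z = (d(median) − null mean) /
   null sd. The fraction of lesions with z > 2.3 per cluster and sequence
   measures how visible each lesion type is.
4. **Clinical relevance.** One-sample Wilcoxon of standardized intensities
   against 1, Mann-Whitney U between sequences, and Spearman correlations of
   cluster-wise lesion burden (count, volume) with EDSS, disease duration,
   relapse counts and normalized brain volume, Bonferroni-corrected.

The cohort the analysis was designed for is not publicly deposited, so the
package ships a calibrated synthetic phantom generator (`bhtyper.phantom`):
79 subjects, ~8.8 lesions each, two lesion intensity classes whose locations
match the published cluster centers, ground-truth tissue maps, and clinical
covariates coupled to class-2 burden through a Gaussian copula with known
target rank correlations. See `docs/methods.md` for what the phantom does and
does not emulate.

## Worked example

```bash
python analysis/02_run_pipeline.py --seed 1
```

runs the whole pipeline on the default 79-subject phantom and prints:

```
600 lesions clustered: 183 in cluster 1, 417 in cluster 2
  cluster 1: FSPGR center 3515.9, SE 1707.2, FLAIR 2590.7
  cluster 2: FSPGR center 4292.5, SE 1880.9, FLAIR 2584.3
feature influence F: {'fspgr': 4114.18, 'se': 459.03, 'flair': 0.14}
lesions exceeding Z = 2.3 (%): {'cluster1_fspgr': 100.0, 'cluster1_se': 90.2,
                                'cluster2_fspgr': 94.5, 'cluster2_se': 41.7}
```

Reading this: the 600 surviving lesions split into a darker type (cluster 1)
and a brighter type (cluster 2); the FSPGR median dominates cluster formation
(F ≈ 4114) while FLAIR is irrelevant (F ≈ 0.1), because the two classes
coincide on FLAIR by construction. Every cluster-1 lesion stands out from
white matter on FSPGR (100% above Z = 2.3) and most do on SE, whereas
cluster-2 lesions are far less conspicuous on SE (41.7%) than on FSPGR
(94.5%) — the brighter type hides on spin-echo images. The correlation stage
then reports that class-2 burden (not class-1) tracks EDSS, disease duration
and brain atrophy, which is the injected clinical structure.

The other drivers: `analysis/01_simulate_cohort.py` (cohort + clinical
table), `analysis/03_null_calibration.py` (false-positive rate of the
Z > 2.3 rule on WM-drawn pseudo-lesions; ~1.4%, comfortably below 5%), and
`analysis/04_effect_recovery.py` (mean recovered Spearman over 20 replicate
cohorts vs the injected targets). Stage artifacts (feature tables, cluster
summary, exceedance report, Table-3-style correlation grid, checksummed
manifest) land under `results/`.

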