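# Methods

`replocal` implements an inclusive, multivariate approach to localizing
language-relevant cortex from word-level fMRI activity patterns, together
with the partial-correlation representational similarity analysis (RSA) the
localizer is designed to serve, and a generative simulator that provides
ground truth for every stage. This note records the models, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
benchmarks do and do not establish.

## Representational dissimilarity matrices

The atom of all analyses is the RDM: a symmetric, zero-diagonal
condition-by-condition matrix of pairwise dissimilarities. Observed (neural)
RDMs are built from stimulus-by-voxel pattern matrices using correlation
distance, `D(i,j) = 1 − r(pattern_i, pattern_j)`; Euclidean distance is
available via `metric="euclidean"`. Correlation distance is the dominant
convention in the RSA literature and is insensitive to regional mean
activation and scaling. Predicted RDMs come from three sources:

- **semantic** — absolute pairwise difference of a rated word property
  (concreteness or imageability), `D(i,j) = |v_i − v_j|`;
- **orthographic** — Levenshtein distance over letters (unit
  insertion/deletion/substitution costs, case folded);
- **phonological** — the same dynamic program over phoneme sequences, with
  substitution between same-class phonemes costing the fraction of
  mismatching phonetic features: place and manner of articulation for
  consonants, height and backness for vowels (so velar-stop /k/ vs
  bilabial-stop /b/ costs 0.5). Cross-class substitutions cost 1. Voicing is
  excluded by default (`include_voicing=True` adds it as a third feature).
  The exact weighting of published feature-based schemes varies; the
  mismatch-fraction rule over a two-feature set is this package's documented
  choice, and `unit_substitution=True` recovers plain phoneme Levenshtein.

The phoneme inventory ships as a packaged ARPABET feature table
(`replocal/data/phoneme_features.tsv`) and can be overridden by path.
Behavioral familiarity RDMs average each word's binary judgments over its
available presentations and take absolute differences of the means, one RDM
per subject.

RDM vectors use the strictly-lower-triangle, row-major order
(`numpy.tril_indices(n, -1)`), fixed across the package.

## Searchlight

A sphere of voxels is swept over the analysis mask so that every in-mask
voxel is a center exactly once; the statistic computed on the sphere's
patterns is assigned to the center. The default radius is **3.0 voxels**,
which on the integer lattice contains exactly **123 voxels** — the canonical
neighborhood size for this analysis family; the offset count is constant for
any radius in [3, √10), and `--radius` overrides it. Edge neighborhoods are
truncated rather than dropped (whole-mask coverage); neighborhoods smaller
than `min_members` (default 10) are flagged but still evaluated. Voxels
flagged invalid (e.g. zero variance after z-scoring) are excluded from
membership. The engine is deterministic and its output at any center is
identical to calling the statistic directly on the extracted submatrix
(tested).

## Representational fidelity and the mROI

Representational fidelity (RF) asks whether a neighborhood's geometry is
*shared across people*: for each subject s, correlate the vectorized RDM of
s with the elementwise mean of all other subjects' RDMs (leave-one-out).
Pearson correlation on RDM vectors is the default; Spearman is selectable.
RF uses per-word presentation-averaged betas without z-scoring (z-scoring is
an RSA convention; a flag enables it for RF as well).

Group inference for the RF map Fisher z-transforms the per-subject fidelity
values and applies a **one-sided** one-sample t-test against zero per voxel —
one-sided because only positive reproducibility defines a localizer. Voxels
with p < 0.05 are kept and connected components smaller than 120 voxels
(26-connectivity, corner-touching, configurable) are discarded, yielding the
multivariate ROI (mROI). Caveat: leave-one-out values are not independent
across subjects, so the t-test is a pragmatic convention mirroring common
practice; a sign-flip permutation alternative is available
(`method="signflip"`).

**Recovery is scored against the searchlight footprint.** A center-assigned
searchlight statistic carries signal wherever the sphere intersects a
signal-bearing region, so a perfectly recovered map is the planted region
*dilated by the searchlight radius* (clipped to the mask) — empirically the
group RF signal decays from ~0.74 just outside a planted region to ~0.00
beyond one radius. `searchlight_footprint` builds this reference set and
Dice overlap is computed against it; against the undilated region the same
perfect map would score Dice ≈ 0.4 purely from geometry.

## Partial-correlation RSA

Words that differ in meaning also differ in spelling and sound, so a
semantic RSA must control form. At each searchlight center, betas are
z-scored across stimuli within voxel (mean 0, sample SD 1; exactly-constant
voxels are flagged and excluded), the neural RDM vector is rank-transformed
(average ranks for ties), and both it and the rank-transformed semantic
predictor are residualized on the rank-transformed orthographic and
phonological control RDMs by least squares with an intercept; the Pearson
correlation of the residuals is the partial Spearman coefficient. With no
controls this reduces exactly to Spearman's rho, and with k controls it
equals the recursive partial-correlation closed form (both tested). A
rank-deficient control set raises an error; pairwise predictor |r| ≥ 0.7
triggers a collinearity warning (the conventional multicollinearity bound
for linear-model-based analyses).

Group inference: subject coefficient maps are Fisher z-transformed, then
smoothed with a 5 mm FWHM Gaussian (mask-normalized: kernel weights are
renormalized over in-mask finite voxels so the mask edge does not attenuate
values; a constant map is preserved exactly), then entered into a two-tailed
one-sample t-test. z-before-smoothing is the statistically standard order;
the literal smooth-then-z order is available via
`fisher_before_smooth=False`. Voxels at p < 0.005 are clustered (|t|
suprathreshold, 26-connectivity) and cluster extent is corrected by a
sign-flip permutation null of the maximum cluster size (default 1000
permutations, seeded); clusters with corrected p ≤ 0.05 survive. The
correction is assumption-light and, by construction, equivariant under a
global sign flip of all subject maps (tested). Null simulations with 20
subjects keep the family-wise positive rate at the nominal level (0/10
replicates in the acceptance run).

Peak tables report, within each cluster, local extrema selected greedily in
descending |value| with a minimum world-distance separation of 11 mm (ties
broken by ascending linear voxel index).

## ROI statistics

- **Top-fraction querying:** within each ROI the top 20 % most active
  voxels of the *group* statistic map are selected (k = max(1,
  round(fraction·|ROI|)), round half away from zero, ties by linear index),
  and per-subject mean parameter estimates are extracted from the selected
  voxels. Group-level selection keeps the voxel set identical across
  subjects; per-subject selection is available via `per_subject_li`-style
  helpers.
- **ROI comparisons** use paired two-tailed t-tests (the same subjects
  contribute to every ROI); subjects with no valid voxels are dropped
  pairwise.
- **Overlap accounting** reports |A|, |B|, |A∩B|, per-hemisphere
  intersection counts, and percentages of each ROI's volume to one decimal.
- **Laterality:** LI = (V_left − V_right)/(V_left + V_right) over
  significant voxel counts, with world x < 0 = left (RAS affine
  convention), x = 0 midline (excluded), undefined (NaN) when no
  lateralized voxels exist. Per-subject LIs threshold each subject's map at
  its own top 20 % within the analysis ROI before counting.
- **Stimulus matching** uses pooled-variance two-sample t-tests on group
  summaries (df = n1 + n2 − 2, |mean difference| in the numerator); pooled
  rather than Welch variance because it reproduces the reference matching
  tables exactly.

## Synthetic data generator

The generator emulates the study design the analyses assume: a cohort
reading abstract and concrete words, three presentations each, with
designated regions carrying representational geometry shared across
subjects.

**Stimuli.** Concreteness is drawn per group from normals matching the
reference stimulus characteristics (abstract 2.45 ± 0.59, concrete
4.79 ± 0.19, clipped to [1, 5]); log10 frequency is group-matched (6.20 ±
1.87 vs 6.03 ± 1.44); imageability correlates ~0.87 with concreteness.
Transcriptions are random pronounceable C-V(-C) syllable strings (1–5
syllables) over the packaged ARPABET inventory, and spellings are sampled
from many-to-one grapheme variants per phoneme, so orthographic and
phonological distances covary realistically but not deterministically.

**Patterns.** For each planted region, stimulus scores F are the
standardized generating property: concreteness for semantic regions;
classical (Torgerson) MDS coordinates of the respective edit-distance RDM,
3 components, for orthographic/phonological regions (edit distances are not
coordinates; the generator needs low-rank stimulus scores); a shared random
vector otherwise. Region voxel loadings L ~ N(0,1) are drawn **once and
shared across subjects** — this is what makes fidelity positive. Each
subject additionally receives nuisance structure `(latent_sd/√n_latent) ·
GᵀM` with subject-specific stimulus scores G and loadings M, which inflates
each subject's RDM without contributing to across-subject agreement — the
minimal model under which RF and RSA dissociate. Presentations are
independent Gaussian replicates (sd `noise_sd`) around the word's mean
pattern. All randomness flows from one seed through named child streams;
identical configs are bit-identical.

Defaults: `noise_sd = 0.5`, `effect = 1.0`, `n_latent = 16`,
`latent_sd = 0.5`. The nuisance rank matters: a very low-rank idiosyncratic
covariance (rank ≈ 4 against 24–96 words) produces heavy-tailed, low-rank
RDM geometry whose leave-one-out correlation carries a small positive bias
(~+0.03 at rank 4, ~+0.005 at rank 16 in null simulations); rank comparable
to the stimulus count keeps the null fidelity centered on zero, which is
also the realistic regime for cortical covariance.

**Fixtures.** `tiny` (4 subjects, 12³ grid at 3 mm, 24 words, one semantic
region, ~360 mask voxels) backs the unit tests; `demo` (12 subjects, 24³
grid, 96 words, a left-hemisphere semantic region of ~310 voxels and a
right-hemisphere phonological region of ~195 voxels inside a ~3500-voxel
spherical mask) backs the end-to-end recovery runs. These sizes keep a full
five-seed recovery suite in the low minutes on one CPU while leaving the
123-voxel searchlight meaningfully smaller than the mask.

**What passing recovery tests show — and what they do not.** The demo
recovery (mROI vs footprint Dice ≥ 0.5 in ≥4/5 seeds; semantic partial
coefficient centered on zero across seeds in a phonological-only region)
establishes that the statistics and thresholds behave as designed under the
generative model. Real fMRI data differ in ways the generator deliberately
omits: spatial autocorrelation of noise (an optional smoothing flag exists
but no hemodynamic model), between-run variance, anatomical variability
across subjects, non-Gaussian artifacts, and a much lower signal fraction.
The synthetic pseudo-lexicon is also more transparent than English: its
orthographic and phonological RDMs correlate at ~0.8 (letter and phoneme
counts are nearly collinear), above the ~0.34–0.46 typical of curated real
stimulus sets, so the collinearity warning fires on the demo model by
design; the control design matrix remains full-rank and the partialling is
unaffected, but the two controls' individual contributions are not
interpretable there.

## Numerical conventions and degenerate inputs

- Correlations are clipped to [−1, 1]; Fisher z clips its argument to
  ±(1 − 1e−7) before arctanh.
- Zero-variance RDM vectors make a correlation undefined: returned as NaN
  and flagged, never silently zeroed — except in partialling, where a
  predictor fully explained by the controls (residual norm ≤ 1e−8 of its
  centered norm) correctly yields 0.
- Searchlight centers where the statistic fails produce NaN with a logged
  center coordinate; group stages exclude voxels any subject is missing.
- Volumes are written float32, masks uint8; stimulus tables and reports are
  TSV; provenance (thresholds, seeds, versions) is embedded in the pipeline
  manifest JSON.
- An empty mROI after thresholding raises an explicit error; an empty
  RSA group mask is a legitimate result and is returned with provenance.

## Known limitations

- The extent threshold counts voxels on the analysis grid only; no
  resampling across grids.
- No noise-ceiling estimation, crossnobis distances, TFCE, surface-based
  searchlights, or grapheme-to-phoneme conversion (transcriptions must be
  supplied).
- The univariate sentences>pseudowords localizer is consumed as an external
  mask file only; its derivation is out of scope.
- Leave-one-out fidelity values are statistically dependent across
  subjects; group p-values for the RF map are approximate (see above).
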