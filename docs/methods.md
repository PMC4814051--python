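# Methods

This note documents the models, conventions and numerical choices behind
`txconcord`, and what the synthetic cohorts do and do not establish about
real data.

## Feature construction

**Normalization to controls.** Per-gene logFC is the mean log intensity over
2–5 treated arrays minus the mean over controls, always time-matched. The
package operates downstream of array summarization; raw CEL processing and
MAS5/RMA are out of scope.

**Expressed/inducible filter.** A gene is *expressed* if it exceeds the
per-array median intensity on ≥ 10 % of control arrays, *inducible*
analogously on treatment arrays; the retained set is the union. "Above
median" is strict (`>`), the median of an even number of features is the
midpoint of the central order statistics, and the 10 % threshold is an
inclusive fraction (`≥ fraction`, so 1 of 10 arrays qualifies). Because the
comparison is rank-based per array, the filter is invariant to any monotone
per-array transform. Representative probe sets are chosen per gene by
highest mean control intensity, after discarding probes that map to more
than one gene; ties break on lexicographic probe id for determinism.

**Gene-set z-scores.** For a profile x and set S of size m,
`z = (mean(x[S]) − mean(x)) · √m / sd(x)`, with `sd` the sample (n−1)
standard deviation over *all* profiled genes, not only the expressed set.
Two-sided normal p-values are BH-adjusted within each experiment
(statsmodels `fdr_bh`). Set members absent from the profile are dropped
before m is computed; a set with fewer than 3 present members yields a
missing result, never a zero. Collections are size-filtered to [3, 5000]
members at load. Pruning keeps sets with adjusted p ≤ 0.01 in ≥ 1 % of a
cohort's experiments, then unions in an explicit rescue list of
domain-relevant sets.

## Co-expression modules

The network is built on a training logFC matrix (genes × experiments):
unsigned soft-thresholded adjacency `a_ij = |cor|^8` (anti-correlated genes
are fully adjacent, so a module can contain induced and repressed genes),
unsigned topological overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, and
average-linkage clustering of `1 − TOM`.

**Branch cut.** Modules come from a height-adaptive branch decomposition:
maximal branches fully merged below a static cut (0.99 × the tallest merge)
are split recursively at any merge whose height exceeds the taller child's
merge height by a relative gap (default 5 %), provided both children hold at
least the minimum module size (5 genes). This is a deliberate
simplification of the dynamic tree cut family: it omits the PAM-style
relabeling stage, which adds substantial machinery while planted-structure
recovery is already essentially perfect without it. Consequently module
counts on real data would not match a PAM-enabled cut exactly; the
derivation is intended to be faithful in structure, not bit-compatible with
any particular toolkit.

**Calibration.** Member genes are z-scored across training experiments
(center and scale, sample sd); the first principal component (via SVD) gives
gene loadings; raw training scores are the projections, and their sample sd
(`raw_score_sd`) normalizes all later scoring, which forces the training
final-score sd to be exactly 1 per module. The PCA sign ambiguity is
resolved by making the loadings sum positive, falling back to a positive
largest-|loading| gene in the (measure-zero) tie. Genes with zero training
sd are excluded from module membership (division guard); correlations use
complete observations.

**Merging.** Modules whose training eigengene scores correlate R ≥ 0.8 are
grouped by connected components of the threshold graph — transitive chains
merge into one group. Each multi-module component is recalibrated on the
union gene set as a *merged* module; merged modules plus modules outside any
component are flagged *base*, and constituents of merges lose base status.
Component merging is one reading of "grouping together"; re-clustering
eigengenes would be an alternative, and the bookkeeping (derived − merging +
groups = base) is independent of that choice.

**Scoring (scale, don't center).** A new experiment's raw score is
`Σ_g loading_g · (logFC_g / sd_g)` over present members, divided by
`raw_score_sd`. No mean subtraction happens at scoring time: many genes in a
toxicology training cohort have nonzero mean logFC, and centering would give
near-null experiments spurious nonzero module scores. The all-zero profile
therefore scores exactly 0 on every module, and scoring is linear in the
profile. Member coverage is reported alongside; scores with < 60 % coverage
are flagged low-confidence (our threshold), and zero coverage yields a
missing score. For cross-system scoring the default keeps training loadings
and training gene sds; per-gene sds from the target system may be
substituted (rescaling), or the module fully recalibrated — three
alternatives ordered by how much target-system data they require. Scores
are stable under rescaling when per-gene sds correlate well across systems.

**Activity.** avg. abs. EG — the mean absolute score over base modules —
is the scalar measure of an experiment's overall transcriptional activity;
restricting to base modules avoids double-counting merged constituents.

**Preservation.** The preservation statistic is the mean absolute pairwise
correlation of member genes in a test cohort, Z-normalized against 200
size-matched random gene selections. This is a density-only permutation Z, a
simplification of composite preservation summaries that also include
connectivity terms; it ranks strongly co-expressed modules far above random
selections (Z ≫ 5) but its absolute scale is not comparable to composite
Z-summaries.

## Concordance, null model, decomposition

**Metrics.** Pearson correlation over the intersection of feature ids
(missing when a profile is constant; ≥ 3 shared features required); percent
overlap of the top-k lists with matching direction, k = round-half-up of
5 % of the feature count (this rule reproduces both printed list sizes,
454 of 9071 and 21 of 415; with fewer than 10 features k is floored at 1);
Euclidean distance over shared features. Top-list ties at the boundary break
on feature id; a zero value counts as positive direction (zeros essentially
never reach the top 5 %).

**Stringency matching.** Nested levels L1 (same time — optionally within
1.15-fold for across-study day-grid mismatches — and ≤ 5-fold dose), L2
(≤ 2-fold time, ≤ 10-fold dose), L3 (unconstrained). Best-match selection
maximizes the metric (minimizes distance) over eligible same-drug reference
experiments, independently per metric and feature space; nestedness makes
the best value non-decreasing from L1 to L3.

**Null model.** Pair activity is the *smaller* of the two experiments'
avg. abs. EG — the least perturbing treatment governs how much shared signal
a pair can show. Activity bins are left-closed intervals with edges 0.2,
0.3, 0.4, 0.5, 0.6, 0.8 (7 bins). For each bin, up to 1000 different-drug
pairs are drawn; all eligible pairs are enumerated and sampled without
replacement (experiments may recur across pairs), which is deterministic
under the seed and equivalent in distribution to rejection sampling. Bins
with fewer available pairs use them all with a warning; an empty bin is an
error by default, though the pipeline tolerates it (pairs falling in an
empty bin get a missing probability) since realistic cohorts need not
populate the lowest activity interval. The self-ID probability counts null
values ≥ the observed concordance (≤ for distances) in the pair's bin;
success requires strictly < 0.05.

**Variance decomposition.** OLS forward selection over covariate groups:
log10 dose ratio, log10 time ratio, schedule difference (3-level factor as
two indicators entering together), and the min/max pair activity. No entry
threshold — every non-degenerate group eventually enters, so the stepwise
total equals the full-model R²; each step's R² increase is reported in
percent, in both entry order and a fixed canonical order (displayed
orderings of such tables are ambiguous, so both are emitted). Constant or
collinear groups (condition number guard at 1e8) are dropped with a
warning. At least 10 pairs per design column are required.

## Synthetic cohorts

The generator emulates the structure of a toxicogenomics fold-change
compendium: `logFC = W s + caw · c a' + ε`. W plants disjoint modules
(default 40 modules of 10–30 genes among 2000, loading magnitudes
|N(1, 0.25)| with 30 % negative members); s are sparse heavy-tailed module
activities — per drug, each module is active with probability 0.3 with an
Exponential(1) scale, so most modules are quiescent in any one experiment;
c is a fixed stress-response axis whose per-experiment weight is the mean
|s|, so strongly perturbing treatments share a common component and random
different-drug pairs grow more alike with activity; ε is N(0, 0.3).
Within a drug, latents follow a Gaussian process over the dose/time grid
with correlation `exp(−time_decay·|Δlog10 t| − dose_decay·|Δlog10 d|)`
(defaults 1.0 and 0.02: strong time decay, weak dose decay). The default
cohort is 60 drugs × 5 conditions drawn from 3 doses × {3, 6, 9, 24, 96,
192} h, with times > 24 h labelled repeat-dose. The cross-system cohort
multiplies shared latents by an attenuation factor (default 0.5), redraws
noise, and adds a fixed baseline-shift profile built in module space with
magnitude 2.5 training-sd units — mirroring the observation that the
culture-versus-tissue state change rivals strongly toxic treatments in
avg. abs. EG.

A calibration mode (`fixed_same_drug_rho`) replaces the decay model with a
constant equicorrelation and draws dense homogeneous latents (no gating).
At ρ = 0 same-drug pairs are then genuinely exchangeable with
different-drug pairs, which is what a calibration test of the self-ID rule
requires; at ρ > 0 it plants a tunable signal whose detection rate must
grow monotonically.

**What passing tests show — and don't.** The generator is linear-Gaussian
with exactly disjoint planted modules and a single shared axis. Real
compendia have correlated module structure, batch and platform effects,
dose-dependent effect magnitudes, and probe-level artifacts, none of which
are emulated (probe intensities and compound identities are explicit
non-goals). Recovery and calibration results on synthetic cohorts validate
the implementation and the internal consistency of the method, not its
field performance on any particular dataset.

## Problem sizes and reproducibility

All stochastic stages consume named substreams (CRC32-keyed
`SeedSequence`s) of a single seed, so any stage reproduces in isolation and
pipeline reruns are byte-identical. Test and acceptance runs use scaled
cohorts chosen for statistical adequacy: module recovery on the default
2000-gene / 300-experiment cohort; self-ID calibration on 2100 exchangeable
pairs against a 5000-draw null (the larger null shrinks the shared
sampling error of the 95th-percentile threshold); the ρ ladder at 900 pairs
per level; the variance decomposition on 4680 pairs (at this size the
added-R² sampling floor ≈ 1/n sits well below the 0.1 % dose bound being
tested, with `time_decay = 2.0` to make the time effect dominate activity
as the leading covariate). The full pipeline on the default cohort runs in
well under 10 minutes on one CPU.

## Known limitations

* The branch cut omits PAM relabeling; module counts on real data will
  differ from PAM-enabled cuts.
* Preservation Z is density-only, not a composite Z-summary.
* The GO graph is not expanded internally; collections arrive pre-expanded
  as GMT.
* Euclidean distance is implemented for completeness but treats shared
  absence of response as similarity; the similarity metrics are preferred
  for library lookups.
* Ortholog maps are applied eagerly at load so downstream stages work in a
  single reference gene space; many-to-many relations resolve to the last
  mapping read.
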