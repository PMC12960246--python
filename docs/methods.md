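# Methods

`acrotype` re-implements, as a tested and reusable library, the analysis
stack of an acral-melanoma cohort study: consensus somatic-variant calling
and driver classification, purity/ploidy-aware copy-number scoring and
homozygous-deletion calling, a melanocytic-origin gene-signature score,
consensus transcriptomic clustering with a two-level signature analysis,
and the exact/asymptotic inference those analyses rest on. Because the
original patient data are controlled-access, the package ships a
synthetic-cohort generator whose planted parameters mirror the cohort's
published summary statistics; every downstream stage is validated as a
recovery experiment against that planted truth, plus the handful of
contingency tables that can be reconstructed from printed group sizes and
percentages.

## The synthetic cohort generator

The generator is first-class, tested code, not a fixture. Its defaults are
the study conditions:

- **Cohort size.** 92 patients (123 samples in the original study; one
  index sample per patient is what every association analysis uses).
- **Ancestry.** Per-patient (AMR, EUR, AFR) fractions are Dirichlet with
  concentrations (8.33, 1.66, 0.52), calibrated numerically so the
  component medians reproduce the cohort's 81% / 13.6% / 2.5%. Medians of
  a Dirichlet are not closed-form, so the calibration was done once by
  simulated moment matching and frozen in the defaults.
- **Drivers.** A two-stage model. Stage one draws carrier status (any
  mutation in BRAF/NRAS/KIT/NF1) as a Bernoulli whose female-vs-male odds
  ratio is exactly the planted 3.83, with the marginal carrier rate held
  at 42/85. Stage two assigns the gene: the BRAF share among carriers is a
  logistic function of the EUR fraction (slope 4.0 on the log-odds scale,
  intercept calibrated by numerical integration over the EUR Beta marginal
  so that the marginal gene frequencies are NRAS 14%, KIT 14%, BRAF 13%,
  NF1 9%). This factorization makes both planted effects exactly
  recoverable: the sex OR by a saturated logistic fit of carrier status on
  sex, the EUR slope by a carrier-conditional logistic fit of BRAF status
  on EUR. A multi-hit probability of 1/92 adds a second distinct driver
  (the cohort had one such patient). Mutual exclusivity otherwise holds by
  construction.
- **Mutation burden.** Per-patient mutation counts are Poisson with a
  lognormal rate centred at 0.95 mutations/Mb over a 50 Mb capture. The
  lognormal sd (0.42) is pinned by the published mean/median ratio
  (0.95/0.87). Each true variant is seen by each of three callers
  independently (sensitivity 0.92) and each caller adds ~1 false call per
  sample, so the 2-of-3 consensus stage has real work to do; BRAF V600E
  calls can survive as single-caller calls only through the rescue rule.
- **Expression.** Negative-binomial counts (dispersion 0.15) with log2
  mean = gene baseline + lineage effect + cluster-module effect +
  oncogene-program effect + library-size offset. Two disjoint 10-gene
  lineage programs emulate the volar (v-type) and cutaneous (c-type)
  melanocyte signatures (log2 fold 3.0); BRAF-flagged acral samples are
  shifted a fraction 0.6 of the way toward the cutaneous program. Three
  disjoint 100-gene modules define the transcriptional clusters
  (proportions 14:16:14, matching the study's cluster sizes); a separate
  10-gene "oncogene" program is activated by BRAF and deliberately
  disjoint from the lineage panel, so the claim that the origin score does
  not simply read out BRAF signalling is testable. A zero-noise mode
  returns exact means for closed-form checks.
- **Copy number.** Integer allele-specific copy numbers per arm
  (whole-arm gains/losses, focal events layered on top, whole-genome
  duplication probability 0.23), purity U(0.35, 0.95), and bin-level log2
  ratios from the tumour/normal mixture
  log2((ρc + 2(1−ρ)) / (ρψ + 2(1−ρ))) + N(0, 0.15). Homozygous deletions
  of CDKN2A and NF1 are planted in 25% of samples each and recorded in the
  truth block. A latent per-sample instability factor couples the
  copy-number event rates to the mutation rate; its cross-correlation
  (0.88) was calibrated once so the realized Pearson correlation between
  the computed global copy-number score and TMB is ~0.72, the published
  value. A small fraction (6%) of samples is planted with the
  extreme purity-disagreement pattern to exercise the QC stage.
- **Outcomes.** Recurrence is logistic with driver log-OR ln(5.31) and a
  QWT baseline rate of 37.2%; death times are exponential
  proportional-hazards with driver log-HR ln(3.19), baseline solved
  numerically so ~17.6% of the cohort dies within the 8-year
  administrative horizon. A recruitment-lag column (exponential, mean 2.01
  years) emulates the delay between diagnosis and study entry; actual
  left-truncation correction is available in the Cox fit (`entry=`) but
  off by default, since the original analysis adjusted for diagnosis date
  rather than using delayed-entry risk sets.

**Determinism.** One master seed is split with
`numpy.random.SeedSequence.spawn` into child seeds for ancestry, clinical,
drivers, variants, expression, copy number and outcomes, in that fixed
order. Identical (config, seed) pairs reproduce byte-identical cohorts.

**What the generator does not emulate:** read-level data, germline
genotypes, mutational-signature spectra, immune deconvolution ground
truth, FFPE artefact structure, and realistic linkage between clinical
covariates. Passing recovery tests therefore demonstrates the estimators
are correct under the stated models, not that the pipeline is robust to
every artefact of real FFPE exomes.

## Variant consensus

Sites are keyed by (sample, chrom, pos, ref, alt) after indel
left-alignment and trimming, so the same event from different callers
compares equal. A site is kept when called by ≥2 of the 3 declared
callers, or by ≥1 caller when its (gene, HGVS p.) annotation matches the
rescue whitelist (default BRAF p.V600E); matching rescue entries by
protein change rather than coordinates survives transcript-version
differences. Base-quality filtering keeps calls at Phred ≥ 30 (boundary
keeps); a missing quality is retained, a strand-bias flag drops the call
when the filter is enabled. Driver categories are
{BRAF, NRAS, KIT, NF1, multi-hit, QWT}; multi-hit means ≥2 distinct driver
genes, QWT none. TMB is (SNVs + indels) / capture Mb. Index-sample
selection prefers primaries, then the earliest collection date, then the
lexicographically smallest sample id.

## Copy number

Purity QC fails a sample when its two purity estimates differ by more than
0.5, when they show the extreme pattern (one < 0.15 while the other
≥ 0.95), or when goodness of fit is below 95 (boundary keeps); a missing
estimate is "unassessable", never a silent pass. Segment means are
log2(cn/ψ) with copy number 0 capped at −5. Region values classify as
high-level amplification (> 0.9), low-level (0.25–0.9), neutral
([−0.25, 0.25]), low-level deletion (−1.3 to −0.25) and high-level
(< −1.3).

The burden score first coalesces contiguous equal-copy-number segments
(making it invariant to how a constant region was split), then computes
BCS = Σ|arm-level length-weighted mean seg_mean| over arms whose |mean|
exceeds 0.2, and FCS = Σ|seg_mean|·(segment length/arm length) over
sub-arm segments. Each component is min–max normalized to [0, 50] across
the cohort and GCS is their sum. The upstream tool's exact normalization
is unpublished, so only orderings and monotonicity are asserted, never
absolute GCS values; the broad threshold 0.2 sits deliberately below the
low-amplification cut (0.25).

The expected homozygous-deletion log2 ratio is
log2(2(1−ρ)/(ρψ + 2(1−ρ))), floored at −5 for pure tumours. The
large-gene rule (NF1) calls a deletion when ≥2 contiguous in-gene bins are
at or below that threshold or a full in-gene bin has zero coverage. The
small-gene rule (CDKN2A) requires ≥1 bin at or below threshold, ≥2
further bins within 0.3 of it, and an in-gene mean at least 0.5 below the
flanking mean — explicit numeric margins standing in for the original
manual scrutiny, which is not reproducible.

## Origin score

Panel-style counts are normalized by the housekeeping geometric mean
(each sample scaled by cohort-mean geomean / sample geomean), floored at a
background of 20, then log2-transformed; RNA-seq counts by median-of-ratios
size factors, log2(x+1), optional per-batch mean-centring, floored just
above 1 (1 + 2⁻¹⁰) so the log2 values used by the score stay positive.

Training runs PCA with genes as variables and samples as observations
(column-centred, unscaled) and selects the component whose sample scores
maximize |point-biserial correlation| with the acral/cutaneous label —
recording its index rather than hard-coding the second component, which is
where the published training data happened to carry the class split. The
top and bottom ten genes by loading form the two panel sides, oriented so
acral samples score high. The A:C score is the ratio of products of the
floored log2 expression values of the two sides; "multiplicative score"
admits two readings (product of log2 values vs sum), and the product
reading is adopted — the group orderings every test asserts hold under
either. A log-score is exposed for numerical stability. With equal panel
sizes the score is invariant to any sample-wide multiplicative factor that
normalization has already removed. Group comparisons delegate to the
Mann-Whitney test; the one-sided direction (BRAF-activating scores lower)
follows the direction of the published group medians and is asserted only
on synthetic data.

## Consensus clustering

Read-level sample QC drops samples with < 25M total reads or with
ambiguous + no-feature counts strictly exceeding gene counts. Matrix
preprocessing applies, in order: removal of rows with > 25% missing
values, row-median imputation of the rest, per-row winsorization at the
5th/95th percentiles, zero-variance removal, and bottom-5%-variance
removal.

Consensus partitioning keeps the top 2,000 features by the chosen score
(sd, MAD or CV), draws 50 subsamples of 80% of samples, partitions each
(k-means, PAM — implemented as Voronoi-iteration k-medoids — or Ward
hierarchical clustering), and sets consensus(i,j) to the co-clustering
fraction among co-sampled pairs. Final labels cut the average-linkage tree
of 1 − consensus. Stability per k: 1-PAC with ambiguity interval
(0.1, 0.9); pair-concordance of resample partitions with the final
labels; Jaccard similarity of the k vs k−1 co-clustered pair sets; and the
mean silhouette on 1 − consensus. The best method/k maximizes 1-PAC with
silhouette as the tie-break — the subjective "biological
interpretability" step of the original selection is dropped. The PAC
interval and the resampling defaults are package conventions (the
originals are unpublished), all configurable.

Signature genes use per-gene one-way fixed-effects F tests with BH
correction (q < 0.05) and are assigned to their argmax-mean cluster; a
gene with zero within-group variance but real between-group spread is
treated as exactly separated (p = 0). Gene modules are k-means (k = 3,
25 starts, fixed seed) on row-standardized cluster-mean profiles, labelled
M1–M3 by their peak cluster for stable naming. Over-representation uses
the upper-tail hypergeometric p with BH correction over the tested sets.

## Statistics

All procedures are implemented in the package and cross-checked in the
test suite against independent oracles (enumeration, closed forms,
scipy/statsmodels/lifelines):

- Pearson χ² without continuity correction — the variant that reproduces
  the published table p-values.
- Fisher exact tests (2×2 and Freeman–Halton r×c) by exhaustive
  enumeration of the margin-constrained lattice in exact rational
  arithmetic, two-sided by the probability-mass rule; an enumeration guard
  (total ≤ 200) fails loudly rather than silently approximating.
- Mann–Whitney U with midranks; exact enumerated null for untied samples
  of at most 12 each, otherwise the tie-corrected normal approximation
  with continuity correction.
- Logistic regression by IRLS (convergence when max |score| < 1e-8, 50
  iterations max, step-halving), Wald standard errors from observed
  information, separation detected and flagged rather than iterated to
  divergence.
- Kaplan–Meier with Greenwood variance and log(−log) confidence bands;
  the product-limit form serves as the life-table descriptor (interval
  widths were unpublished).
- Multi-group log-rank with multivariate-hypergeometric variance.
- Cox proportional hazards by Newton–Raphson on the Efron-tie partial
  likelihood (Breslow by flag, since the original software's tie handling
  is unstated; the pipeline reports both), optional delayed entry.
- Wald (not profile) confidence intervals throughout, matching the
  published symmetric-on-log-scale intervals.

## Problem sizes and reproducibility

The test suite and the acceptance script run entirely on synthetic data at
desk scale: cohorts of 92–123 patients for pipeline stages, 300–600
samples for hom-del recovery, 50–200 replicates of n = 300–400 for CI-coverage
experiments, 8 replicates of n = 2,000 for the hazard-ratio recovery, and
n = 5,000 draws for ancestry/driver marginals. `scripts/acceptance.py
--seed S --out results/acceptance.json` recomputes every headline quantity
from scratch; all randomness derives from the single seed.

## Known limitations

- Absolute GCS values are a package convention; only orderings transfer
  across tools.
- The exact tests' enumeration guard limits Freeman–Halton to small
  tables; no Monte-Carlo fallback is implemented.
- Separation in logistic models is flagged, not penalized (no Firth
  correction).
- The large-gene hom-del rule at exactly-threshold signal has ~89% per-
  sample sensitivity by construction (two contiguous sub-threshold bins
  among symmetric noise); the small-gene rule, which the CDKN2A recovery
  experiment exercises, is the sensitive one.
- Left truncation is modelled in the generator but not corrected by
  default, mirroring the original covariate-adjustment approach.
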