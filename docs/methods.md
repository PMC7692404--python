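# Methods

## Model and procedure

The package measures, per sample and per pathway, the perturbation of
pairwise co-expression relative to a normal-sample reference.

1. **Gene filter.** Genes with exactly-zero values in strictly more than a
   fraction `zero_fraction_threshold` (default 0.75) of *all* cohort samples
   — normal and tumor jointly — are removed. The boundary case (exactly the
   threshold) is retained; the rule is deliberately strict-inequality.
2. **Reference network.** For every unique pathway edge (g₁, g₂), the
   Pearson correlation `PCC_n` over the n normal samples. Edges with zero
   reference variance in either gene are flagged undefined and excluded
   globally — for every sample — so all samples' scores average over the
   same edge set and remain comparable.
3. **Single-sample perturbation.** Adding one sample gives `PCC_{n+1}` per
   edge and `ΔPCC = PCC_{n+1} − PCC_n ∈ [−2, 2]`.
4. **Pathway score.** `iPS = mean over the pathway's retained edges of
   |ΔPCC|`, hence `iPS ∈ [0, 2]`. Pathways with fewer than `min_edges`
   (default 3) defined edges are carried as explicitly unscored; a one- or
   two-edge "pathway mean" is too noisy for the downstream 2-SD rule.
5. **Classification.** Per pathway, μ and σ are the mean and sample
   (n−1 denominator) SD of the normal samples' iPS. A tumor is
   *perturbed-strong* iff `|iPS − μ| > k·σ` (default k = 2, strictly);
   boundary ties are weak. The rule is two-sided by default — iPS is a
   nonnegative deviation measure, so "distance from the normal mean" is the
   non-degenerate reading — with a one-sided upper variant behind a flag.
6. **Prognosis screen.** Stage 1: per pathway, two-sided Wilcoxon rank-sum
   on the iPS of strong vs weak tumors, Benjamini–Hochberg FDR across all
   tested pathways, keep q < 0.05. Because the groups are themselves defined
   by an iPS threshold this stage is nearly tautological whenever both arms
   are large; it is retained for fidelity to the published procedure and can
   be disabled (`skip_wilcoxon`). Stage 2: Kaplan–Meier log-rank test
   between arms; a pathway is prognosis-related iff log-rank p < 0.005
   (strict) *and* the strong arm has worse prognosis. "Worse" is
   operationalized as a lower restricted mean survival time (RMST) with
   horizon at the largest observed time in either arm — well-defined under
   censoring, unlike median survival. Arms need `min_group` (default 10)
   samples with clinical data at both stages; no correction beyond the fixed
   0.005 cutoff is applied at the survival stage.

## Normal-sample scoring mode

How a normal sample's own iPS enters the null is genuinely open: scoring it
against a reference that contains it (`pooled`) shrinks its ΔPCC and
deflates the null spread. Both modes are implemented; the default is
`leave_one_out`, where the reference statistics are downdated to the other
n−1 normals (an O(1) inverse of the update, verified against rebuild to
1e−10). The mode used is recorded in the iPS matrix metadata.

## Numerical choices

- Edge statistics are kept **centered** (per-gene means plus centered
  second-moment sums, Welford-style) rather than as raw power sums: the
  update and downdate stay O(1) per edge while avoiding the cancellation
  raw sums suffer when the mean dominates the spread. Property tests pin the
  incremental path to a from-scratch Pearson computation at 1e−10.
- Zero variance is declared when a centered sum of squares falls below
  `1e−24 · n · mean²` (absolute floor 1e−300). Accumulated rounding sits
  orders of magnitude below this for any realistic expression scale; a true
  variance below it is numerically meaningless anyway.
- If the *augmented* set is degenerate (all n+1 values of a gene coincide),
  `PCC_{n+1}` is defined as `PCC_n`, i.e. ΔPCC = 0: the added sample carries
  no correlation evidence. A degenerate leave-one-out reference for a normal
  sample is handled the same way (its edge contributes 0).
- Correlations are clipped to [−1, 1] after the closed form; p-values from
  the rank-sum test use the exact distribution when both arms have ≤ 25
  tie-free observations, otherwise the normal approximation with tie
  correction.
- All arithmetic is double precision without compensated summation;
  references of up to a few hundred samples keep cancellation benign. This
  is a known limit for extreme value scales (mean/SD ratios beyond ~1e6).
- `build_reference` requires ≥ 3 reference samples and warns below 20, where
  the null statistics stop being representative.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
any particular dataset:

- **Expression.** Each pathway owns a disjoint block of
  `genes_per_pathway` genes (default 10; edges are all within-block pairs).
  A latent Gaussian field has compound-symmetric correlation ρ (default 0.8)
  within each block; emitted expression is `exp(log_mean + latent_sigma·z)`,
  log-normal, matching the nonnegativity and right skew of normalized
  RNA-seq. `latent_sigma` defaults to 0.5, which keeps the realized
  (post-transform) Pearson correlation within ~0.02 of the latent ρ; the
  truth table records the realized within-block correlation, since that is
  what the pipeline sees.
- **Perturbation.** A fraction of tumors (default 0.5), drawn independently
  per perturbed pathway, are carriers: their block is drawn with independent
  genes (`decorrelate`) or with alternate genes' latent values negated
  (`sign_flip`), which flips the correlation sign on every edge crossing the
  two halves of the block. A full block of pairwise −ρ is not a valid
  covariance for more than two genes, so the half-block construction is the
  PSD-respecting way to plant sign flips.
- **Survival.** Tumor survival is exponential with hazard
  `baseline_hazard · hazard_ratio^carrier` (defaults 1/1000 per day and 3),
  where carrier means carrying the perturbation on at least one designated
  survival pathway. A randomly chosen `censoring_fraction` (default 0.2) of
  tumors is censored at a uniform time before their event, independent of
  the covariates.
- Cohort sizes default to 50 normals / 100 tumors (200 tumors in the
  standard planted configuration); the calibration cohort uses 100 six-gene
  pathways. These sizes were chosen so full-pipeline runs complete in
  seconds while keeping per-pathway group sizes realistic for the test
  stages.

What passing tests on these cohorts show: the score separates planted
decorrelation from background, the 2-SD rule is calibrated near its nominal
~5% false-positive rate under the null, and the two-step screen recovers a
planted hazard effect while rejecting perturbed-but-survival-neutral
pathways. What they do not show: behavior under batch effects, overlapping
pathways, subtype mixtures, or real pathway topologies — the generator's
blocks are disjoint and single-factor by design so that truth attribution
is unambiguous.

## Known limitations

- **Carrier sensitivity under single-factor blocks.** In a
  compound-symmetric block, a *normal* sample whose shared-factor deviation
  w is large perturbs every edge coherently (per-edge influence
  ≈ ρ(1−ρ)(w²−1)/n), so the null iPS spread cannot be averaged away by
  adding edges and its SD is comparable to its mean. The μ+2σ threshold
  therefore sits near the typical carrier score
  (E|ΔPCC| ≈ E|z₁z₂ − ρ(z₁²+z₂²)/2|/n ≈ 1.1/n for a decorrelated carrier at
  ρ = 0.8), and per-pathway carrier sensitivity on the planted cohort is
  ~30–55% rather than near-complete — largely independent of block size,
  reference size, or the emission transform, since signal and threshold
  both scale as 1/n. Real pathways are not single-factor, so this is a
  property of the stress-test geometry as much as of the score; the
  prognosis screen still recovers the planted survival pathway because it
  needs group separation, not per-sample completeness.
- The score is unsigned; decorrelation and sign reversal are
  indistinguishable in iPS, and perturbation direction is out of scope.
- The Wilcoxon stage inherits the circularity noted above.
- Gene identifiers are opaque strings; no aliasing, no missing-value
  support (a blank cell is an error, never imputed, because imputation
  would silently change edge correlations).
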