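# Methods

## The measurement model

An IgG-Seq experiment stains stool microbes with a fluorescent DNA dye and
an anti-IgG antibody, then sorts single cells into three gates: `all`
(SYBR+ total population), `igg_pos` (antibody-bound) and `igg_neg`
(unbound). Each gate is shotgun-sequenced and taxonomically profiled
upstream of this package (Kraken2/Bracken for taxa, HUMAnN for gene
families); `iggseq` consumes those count tables together with per-sample
flow summaries: the two sorted-gate sizes as proportions of SYBR+ events,
the isotype-control background percentage, and the total microbial load in
cells per gram.

We model coating as per-cell Bernoulli with a taxon-specific probability
theta_i, i.i.d. across the cells of a taxon. A cell of taxon *i* therefore
lands in the bound gate with joint probability RA_i * theta_i, giving gate
sizes S+ = sum_i RA_i*theta_i and S- = 1 - S+ and gate compositions
proportional to RA_i*theta_i and RA_i*(1-theta_i).

## The probability-ratio score

For taxon *i* in sample *j*:

    ratio_ij = log2( (pos_ij * S+_j + c) / (neg_ij * S-_j + c) )

`pos_ij * S+_j` estimates P(cell is taxon i AND coated); dividing by the
unbound analogue and discarding the shared RA_i factor leaves the coating
odds, so as sequencing depth grows and c -> 0 the score converges to
log2(theta_i / (1 - theta_i)) for every taxon, independent of the taxon's
relative abundance. Scores are reported in log2 units and never
back-transformed.

Numerical choices:

- With `scale=True` (default) both gate sizes are divided by the larger of
  the two within each sample. The rescaling cancels in the c -> 0 limit,
  makes the score exactly invariant to a common rescaling of both sizes,
  and keeps the pseudocount comparable in magnitude across samples.
- The pseudocount is added after multiplying abundance by gate size
  (c competes with a joint probability, not a composition). Defaults:
  1e-5 for taxa, 6e-10 for gene families — gene-family relative abundances
  are orders of magnitude smaller because there are tens of thousands of
  families.
- The ratio is computed as log2(numerator) - log2(denominator) rather than
  log2 of the quotient so that swapping the two fractions is an exact
  floating-point negation.
- A zero numerator or denominator cell combined with c = 0 raises rather
  than returning an infinity.

## Thresholds and filtering

All detection rules are strictly greater-than: a value exactly equal to a
cutoff is removed. Defaults follow the profiling conventions for this assay
type and are configurable everywhere:

- RMP: total-sum scaling, cutoff 1e-6 on relative abundance, pseudocount
  1e-7 added to every cell (zeroed and surviving alike) after zeroing.
- QMP: absolute abundance = RA * microbial load (cells/gram). Because QMP
  is computed on the thresholded, pseudocounted RMP, column sums deviate
  slightly from the measured load; `renormalise=True` rescales first and
  restores exact conservation.
- IgG binding: cutoff 1e-5. Taxa not detected above the cutoff in a
  sample's `all` fraction are zeroed in that sample's sorted fractions
  (per-sample, not cohort-wide — the spec-level wording is per-participant,
  and per-sample is the faithful reading). Scores are then restricted to
  taxa detected in every sample, mirroring common-feature selection in
  small paired cohorts.
- Gene families: only community-level rows are used (taxon-stratified rows
  are dropped at read time). Families with zero reads-per-kilobase in a
  participant's `all` fraction are zeroed in that participant's sorted
  fractions ("present" is taken as RPK > 0, not above the relative
  threshold — the stricter reading would also remove borderline families
  and is available by thresholding first). Columns are then total-sum
  scaled, the 1e-6 cutoff applied, and families below the cutoff in >= 7
  samples (of 10, both values configurable) discarded. Gene families with
  no signal in either sorted fraction of some sample have no defined ratio
  there and are dropped from the ratio matrix.
- Isotype normalisation subtracts the isotype-control background from
  measured bound percentages, floored at 0; the pipeline applies the same
  correction to the bound-gate size before scoring.

## Diversity

Shannon entropy uses natural log by default (base configurable); inverse
Simpson is 1 / sum p_i^2. Rarefied observed richness is the analytic
hypergeometric expectation of the species count in a without-replacement
subsample,

    E[S_d] = sum_i [ 1 - C(N - N_i, d) / C(N, d) ],

evaluated via log-gamma for numeric range; this is deterministic and
unbiased, with a seeded Monte-Carlo mode retained as a cross-check. The
default rarefaction depth is the cohort-wide minimum sample depth (a
per-fraction option exists). Bray–Curtis dissimilarity is computed on
relative abundances (scipy's implementation of the standard formula), and
NMDS runs SMACOF with monotone regression from 20 random starts (default),
reporting Kruskal stress-1 for the best start. NMDS finds local optima;
quality should be judged by stress, not by coordinate values, and the run
is flagged converged when at least two starts agree with the best stress to
1e-3.

## Compositional functional analysis

The CLR transform maps each sample's composition to log-ratio space:
clr(x)_i = log x_i - mean(log x). No pseudocount convention is inherent to
the `all`-fraction analysis, so half the smallest non-zero value in the
table is used by default (configurable; pass 0 to require strictly positive
input). PCA centres samples internally, orders components by decreasing
variance, and fixes each component's sign so its largest-magnitude loading
is positive — making results deterministic across runs. Patients and
controls enter PCA unpaired.

## Paired statistics

Patient-control comparisons use a two-tailed paired t-test. "Evidence for
non-normality" triggering a log-transform is operationalised as Shapiro-
Wilk on the paired differences at alpha = 0.05, applied only when
`auto_log` is enabled, all values are strictly positive and n >= 3; the
decision is recorded in the output. Identical vectors return t = 0, p = 1;
constant non-zero differences raise a degenerate-test error rather than
reporting an infinite statistic. Pearson correlation uses the two-sided
t-based p-value on n-2 degrees of freedom. No multiple-testing correction
is applied by default (a Benjamini-Hochberg helper exists).

## The synthetic cohort generator

The generator emulates the study design the package targets: a small cohort
of household pairs, one patient and one control each.

| parameter | default | meaning |
| --- | --- | --- |
| `n_pairs` | 5 | household pairs (10 samples), the target study size |
| `n_taxa` | 120 | species shared cohort-wide |
| `abundance_sigma` | 2.0 | lognormal shape of species abundances; spans ~4-5 decades across ~100 taxa, matching gut metagenome profiles |
| `theta_alpha`, `theta_beta` | 2, 2 | Beta prior of coating probabilities — a modelling choice (no empirical distribution is available), symmetric and mildly concentrated |
| `patient_theta_scale` | 1.0 | multiplier on patients' coating odds; 0.25 plants a "reduced IgG reactivity" effect of exactly -2 log2 units |
| `household_similarity` | 0.7 | correlation of patient/control log-abundances within a pair |
| `load_median`, `load_sigma` | 1.5e11, 0.35 | lognormal microbial load, spanning roughly 6e10-2.6e11 cells/gram |
| `n_gene_families`, `gene_incidence_prob` | 150, 0.3 | binary taxon-to-gene-family map shared cohort-wide |
| `read_depth` | 200,000 | multinomial reads per fraction |
| `gating_gap` | 0.05 | SYBR+ events sorted into neither gate |
| `isotype_background` | 0.01 | non-specific staining added to the reported bound-gate size and recorded as `isotype_pct`, so downstream normalisation removes it |

Sequencing is multinomial at fixed depth with no taxon-specific genome-size
or amplification bias — deliberately, so estimator-recovery tests are not
confounded. The generator does **not** emulate whole-genome-amplification
bias, classifier misassignment, contamination, overdispersion beyond
multinomial, or within-taxon coating heterogeneity; passing tests therefore
validate the statistical machinery, not robustness to those real-data
artefacts. All randomness derives from explicit integer seeds via spawned
seed sequences, so cohorts are bit-reproducible.

## Validation strategy and problem sizes

The test suite checks closed forms (Shannon, inverse Simpson, Bray–Curtis,
CLR, rarefaction against exhaustive enumeration and against an independent
R implementation), exact equivalence of the vectorised score with a direct
cell-by-cell transcription of the formula, antisymmetry and
scale-invariance, the published fraction-presence proportions from their
count triples, and Monte-Carlo properties of the generator. Estimator
recovery is tested on a 50-taxon community at depth 1e6 and c = 1e-8 with
per-taxon ratios averaged over 16 independent sequencing replicates: a
taxon at the 1e-3 abundance cutoff has a single-replicate sampling SD of
~0.065 log2 units, so averaging is what makes a 0.1 deviation bound a
~6-sigma statement rather than a coin flip. Effect-direction recovery uses
50 replicate cohorts of 20 pairs at depth 20,000 with quartered patient
coating odds; null calibration uses 200 five-pair cohorts at the same
depth. These sizes keep the whole suite fast while leaving every stochastic
bound several standard errors wide.

## Known limitations

- The probability ratio is a plug-in estimator; no uncertainty is attached
  to individual scores (the study design compares per-sample summaries).
- Copy-number (16S) correction and flow-independent load estimation are out
  of scope for QMP.
- NMDS is not guaranteed the global optimum; stress is the quality measure.
- The generator's idealised sequencing model understates real technical
  variance (see above).
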