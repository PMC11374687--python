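# Methods

`crcmetrics` re-implements, as a reusable library, the cohort-level analytic
procedures used in population-scale colorectal-cancer (CRC) whole-genome and
transcriptome studies: burden-based hypermutation classification, an
allele-specific copy-number state taxonomy with genome-altered density
metrics, mitochondrial somatic-variant filtering against NuMT artifacts,
transcriptomic hypoxia scoring with a nested-model association framework,
mutational-signature comparison, co-mutation testing, and survival
endpoint/cutpoint machinery. Because the cohorts such procedures were
designed for are access-restricted, the package ships a synthetic cohort
generator that plants every statistical structure the downstream stages
assume, and the test suite exercises the whole chain against that planted
truth.

## Hypermutation classification

A tumour is hypermutated (HM) when its total somatic short-variant count
exceeds the cohort median plus 1.5 times the interquartile range. The rule
is applied iteratively: every flagged sample is replaced in the pool by two
artificial samples of half its count (floor/ceil halves for odd counts, so
the total is conserved), the median and IQR are recomputed on the updated
pool, and the procedure repeats until no sample is flagged. A tumour is HM
if it or any artificial descendant was ever flagged; its *outlier times* is
the number of rounds in which that happened.

Numerical choices, pinned so that worked examples are exact:

- Quantiles use linear interpolation of order statistics at positions
  `(n - 1) * p` — the numpy/R type-7 default.
- Flagging uses strict `>`, as the rule's formula is written.
- Thresholds are recomputed on the full updated pool, artificial samples
  included, nothing excluded.
- Termination: each split at least halves a count, and the pool maximum is
  non-increasing, so the procedure converges within
  `ceil(log2(max count)) + 1` rounds. In the degenerate case of a zero-IQR
  pool where only counts below 2 are flagged (splitting cannot reduce
  them), the procedure is declared converged; real burden data never
  reaches this state.

Tumour mutation burden (TMB) is the count divided by a callable genome size
in megabases (default 2,859 Mb, GRCh38 non-gap autosomes plus X; always
configurable). The HM TMB cut-off reported for a cohort is the minimum TMB
among HM samples. Microsatellite instability is called from a
paired-sample instability score at the conventional threshold 3.5,
boundary inclusive.

Pairwise co-mutation and mutual exclusivity use two-sided Fisher exact
tests per gene pair (two-sided p as the sum of hypergeometric outcome
probabilities not exceeding the observed table's), Benjamini–Hochberg
adjustment across pairs, and the sample odds ratio `(both*neither)/
(a_only*b_only)`; a pair is co-occurring when the odds ratio exceeds 1.

## Copy-number states and density metrics

Allele-specific segments carry total (tcn) and minor (lcn) copy number.
The eight-class taxonomy: wild type (2,1), homozygous deletion (0,0),
LOH (1,0), copy-neutral LOH (2,0), gain-LOH (tcn 3–4, lcn 0), gain
(tcn 3–4, lcn ≥ 1), amp-LOH (tcn ≥ 5, lcn 0), amp (tcn ≥ 5, lcn ≥ 1).
When lcn is missing (common at low coverage), the segment is given a
coarse tcn-only label with an LOH-indeterminate flag rather than being
dropped, which would bias genome-altered fractions; tcn = 2 without lcn is
labelled `indeterminate` because wild type and copy-neutral LOH cannot be
distinguished. Focal calls from the tumour/control log2 ratio use strict
thresholds: amplification above 0.9, deletion below −0.3.

Eight density metrics per sample: fraction of genome altered (PGA) total,
gain (tcn > 2) and loss (tcn < 2), their ratio, and average aberrant
segment lengths with the gain:loss ratio. The aberration baseline is
diploid tcn = 2 rather than sample ploidy (the simplest reading of "total
copy-number aberration"; a ploidy-relative baseline is exposed via the
`baseline_tcn` argument). Ratios with zero denominators are reported as
missing, not zero. PGA is invariant to splitting segments into adjacent
equal-tcn pieces; average lengths are segment-definition-dependent and
documented as such. Coordinates are 1-based inclusive internally; BED
input is converted on read. Gene-level states take the overlapping segment
with the largest overlap (leftmost on ties).

## Mitochondrial filter and copy number

NuMT-derived false calls are low-heteroplasmy, supported in the matched
control, and recurrent across unrelated tumours. The filter retains a
candidate when all of the following hold:

1. control VAF < 0.0034;
2. the control/tumour rate ratio
   `r = (Nc/RDc) / (Nc/RDc + Nt/RDt)` < 0.0629 (undefined when both
   mutant counts are zero; such candidates trivially pass);
3. for low-heteroplasmy candidates only (tumour VAF < 0.10), the variant's
   cohort carrier frequency < 0.023 (denominator: number of tumours);
   higher-VAF variants bypass this rule so recurrent true hotspots are not
   deleted;
4. tumour VAF strictly inside (0.01, 0.95).

A rescue step guards against false negatives of the recurrence rule: a
variant with cohort VAF maximum < 0.1 and median < 0.05 is re-adjudicated
per carrier — the recurrence rule is waived and retention restricted to
carriers with tumour VAF > 0.05, with the control-based rules and the
heteroplasmy window still applying. Variant identity for cohort frequency
is the exact (position, ref, alt) triple.

The two rate cutoffs can be re-derived from data as
`median + 2 × IQR` of the statistic over all candidates (same quantile
convention as the burden rule). On synthetic cohorts this derivation
lands between the planted artifact and somatic distributions.

Heteroplasmy banding calls a variant near-homoplasmic when tumour VAF is
strictly above 0.60. Raw mitochondrial copy number is
`2 × mtDNA depth / autosomal depth`; when tumour purity and the matched
control's raw copy number are available, the tumour-cell value is
recovered as `(raw − (1 − purity) × control) / purity` — a standard
two-component mixture inversion, isolated in one function so an
alternative normalisation can be substituted.

## Hypoxia score and association framework

The Buffa score sums, over a hypoxia signature gene set, +1 if a sample's
abundance is strictly above that gene's median across tumour samples and
−1 otherwise (ties score −1; "above the median" is read strictly).
Reference medians always come from tumour samples, also when scoring
controls. Because only comparison signs enter, the score is invariant
under monotone per-gene transformations whenever the tumour count is odd
(the median is then an order statistic); with an even count the
interpolated median is not rank-equivariant, a property the tests
respect. Scores lie in [−G, +G] with the parity of G for G signature
genes. The signature list is user-supplied (one gene per line), e.g. the
published 52-gene Buffa set.

Associations between hypoxia and a mutational feature compare nested
least-squares models — `hypoxia ~ feature + age + sex + purity` against
the same model without the feature — with the exact F test, on complete
cases (≥ 10 required; exclusion counts logged). The feature's direction
is the sign of its coefficient in the full model. Across features,
p values are Bonferroni-adjusted when fewer than 20 tests were run and
Benjamini–Hochberg-adjusted otherwise, with calls at adjusted p < 0.1.
The feature set comprises 22 mutational-density metrics (10 variant
counts: all, coding, non-coding, nonsynonymous, SNV, DNV, TNV, DEL, INS,
INDEL; the 8 CNV metrics above; 4 SV-type counts), plus clonal/subclonal
counts when clonality annotations exist; decile bins of every metric are
emitted alongside, with constant metrics flagged degenerate rather than
binned.

Model adequacy is checked with a parametric-simulation residual test:
250 response vectors (configurable, ≥ 20) are simulated from the fitted
Gaussian model, each observation is placed as a quantile within its
simulated distribution (`(rank + 0.5)/(n_sim + 1)`), and the quantiles are
tested against Uniform(0, 1) by Kolmogorov–Smirnov. A correctly specified
model yields approximately uniform KS p values over replications; gross
heteroscedasticity drives them to zero.

## Signature comparison

Profiles are probability vectors over a fixed channel set; they are
re-indexed by channel label before comparison, never matched by position.
A de novo signature is novel when its best cosine similarity within
*each* of two reference catalogues is strictly below 0.85; otherwise the
best match is reported. Novelty is monotone in the threshold. Activity
matrices are correlated pairwise with Spearman's rank correlation
(average ranks for ties); p values are exact permutation enumerations for
cohorts below 10 samples and the t approximation otherwise, with BH
adjustment across pairs and significance at FDR < 0.05.

## Survival machinery

Endpoints, in years (365.25 days): overall survival (OS) from diagnosis to
death, censored at last follow-up; recurrence-free survival (RFS) from
surgery to the earliest of recurrence or death, censored at last
follow-up, with stage IV at diagnosis ineligible; survival after
recurrence (SAR) from recurrence to death. Every patient receives every
endpoint row with an eligibility flag and reason; derivation is total and
idempotent, and recurrence preceding surgery is a record-level error.

The maximally selected rank statistic dichotomises a continuous marker.
Log-rank (Savage) scores `a_i = δ_i − Λ̂(t_i)` are computed from the
Nelson–Aalen cumulative hazard; for a candidate cutpoint the statistic is
the score sum of the low group standardised by the conditional
permutation mean and variance. Candidates are midpoints between
consecutive distinct marker values keeping at least 10% of subjects on
each side (boundary fractions admissible; ties in the statistic resolve
to the smallest cutpoint). Being rank-based, the statistic is invariant
under monotone marker transformations. No small-sample correction is
applied to the p value at the selected cutpoint; the statistic is
reported, not an adjusted significance. Below 20 events the function
warns rather than refuses, so small worked examples remain runnable.

The Cox workflow applies the two-stage contract: univariable screening of
each feature at p < 0.05, then multivariable refit of survivors with
clinical covariates (tumour site, pretreatment, stage, age group, grade;
hypermutation status optional and off by default). Fits are delegated to
lifelines; binary features with fewer than 5 carriers are skipped with a
warning, and rank-deficient covariate designs drop collinear columns with
a warning.

## Synthetic cohort generator

The generator plants, from a single seeded `numpy.random.Generator`:

- **Burden**: baseline counts from a log-normal (default median 200)
  with log-scale tails truncated at −2.5σ/+1.2σ; HM samples (default 23%
  of the cohort) multiply a baseline draw by 20. The log-normal body
  gives realistic overdispersion; the truncation reproduces the clean
  burden gap between nHM and HM tumours that population cohorts show and
  that a quantile threshold relies on. Counts are materialised as a
  MAF-like table on a down-scaled 40 Mb genome so whole cohorts generate
  in under a second while keeping per-megabase burden on a realistic
  scale.
- **Copy number**: per-chromosome segment partitions, 30% of segments
  drawn from gain/loss/LOH states, log2 ratios consistent with tcn plus
  noise.
- **Mitochondria**: private true somatic variants (mean 5 per tumour,
  matching the per-tumour mtDNA mutation burden of large CRC cohorts) at
  VAF 0.06–0.92 with at most trace control contamination; a panel of
  recurrent artifact sites (default 8) each carried by ~15% of tumours at
  VAF < 0.08 with genuine control support; and a few shared low-frequency
  true hotspots. Depths are uniform on [500, 30000], spanning the
  ultra-deep mtDNA coverage regime of tumour WGS.
- **Expression**: Gaussian log-abundances with the signature genes
  shifted by the hypoxia effect (default +1.2) in a planted high-hypoxia
  subgroup (30% of tumours) and lowered in controls.
- **Survival**: exponential times with the hazard tripled above the 40th
  percentile of a standard-normal risk marker; administrative censoring
  at 10 years; dates are consistent (diagnosis ≤ surgery ≤ recurrence ≤
  death/censor).

What the generator does **not** emulate: read-level data, trinucleotide
context, linkage between tables (e.g. HM status does not alter copy-number
or SV profiles), non-administrative censoring, or batch structure. Passing
tests therefore demonstrate correctness of the procedures under the
assumed statistical structure, not robustness to every real-data pathology.

## Problem sizes

Simulation-based checks use cohorts of n = 200 (20 seeds) for burden and
mitochondrial recovery, 1000/500 replications for type-I error and power
of the association framework, and 100 replications at n = 500 for
cutpoint recovery — sizes at which the binomial uncertainty of the
measured rates is well inside the asserted bands while the full suite
runs in well under a minute per module.

## Known limitations

- The mtDNA copy-number normalisation formula is a declared stand-in for
  an external method published without equations.
- PGA is diploid-relative by default; ploidy-relative analyses must set
  the baseline explicitly.
- The recurrence-filter denominator counts tumours, not candidates.
- Fisher odds ratios are sample odds ratios (infinite when a
  discordant-cell count is zero), not conditional MLEs.
- The CLI's signatures stage on synthetic cohorts correlates per-sample
  variant-class counts as the activity matrix, since signature extraction
  itself is out of scope.
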