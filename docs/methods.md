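# Methods

This note records the models, rules and numerical choices behind
`mocprog`, and what the synthetic cohort does and does not establish.

## Somatic filter cascade

Variants arrive as multi-caller calls with quality, depth, allele
fraction and annotation evidence, and pass through twelve conjunctive
rules (module docstring of `mocprog.filtering` lists them in order).
Points that required a decision:

- **Population-frequency rule.** A variant is excluded when its maximum
  allele frequency across the population resources (ExAC-minus-TCGA,
  ExAC-NFE, EVS) exceeds 1e-4, unless ClinVar lists it as (potentially)
  pathogenic. The maximum is used because exclusion should trigger if
  *any* resource reports the variant as common; the ClinVar rescue only
  makes sense in the exclude-if-common direction.
- **Absent evidence fails.** A missing QUAL (or any quantitative field)
  fails its rule rather than passing silently: the cascade defines a
  *high-confidence* set, and unknown quality is not high confidence.
- **Panel of normals.** "Present in more than one" germline exome means
  rejection at ≥ 2 hits.
- **Caller concordance.** VarScan-only calls are always excluded;
  UnifiedGenotyper-only calls are additionally excluded for unpaired
  exomes and panel data, where no matched normal backstops the call.
  WGS uses the paired-exome rule set.
- **Cohort recurrence.** Identity is (chrom, pos, ref, alt), computed in
  a first pass over the raw cohort; recurrence > 20% rejects unless the
  site is a known hotspot. The hotspot table ships as an editable
  constant (`KRAS` 12/13/61, `BRAF` 600, `PIK3CA` 542/545/1047, `TP53`
  common codons); the gene blacklist defaults to empty and accepts a
  user list.
- The cascade is conjunctive, so rule order never changes keep/reject,
  only the order of reported reasons; re-filtering a kept set is a
  no-op because recurrence can only fall when recomputed on kept
  variants.

Mutation burden counts kept coding and splice-site variants restricted
to the validation-panel gene set, divided by the capture target size
(2.07 Mb), yielding variants/Mb comparable across platforms.

## Mutational signatures

Catalogs use the canonical 96-channel layout (six pyrimidine-strand
substitution classes × 16 trinucleotide contexts); purine-reference SNVs
are reverse-complement folded. Refitting is greedy forward selection:
at each step the candidate signature whose admission most reduces the
squared reconstruction error of the count-normalized catalog (weights by
nonnegative least squares) joins the model; selection stops when the
relative improvement drops below 1e-3. Weights below the sparsity
cutoff (0.06, the refitting tool's conventional default) are zeroed and
the survivors rescaled to the pre-zeroing total. No exome/genome
trinucleotide-frequency renormalization is applied by default; the
catalogs compared here are built against the same reference.

De novo discovery is Lee–Seung multiplicative-update NMF on the
96 × cases count matrix (Frobenius objective, monotonicity asserted at
every iteration), best of 50 seeded restarts, 500 iterations each —
dimensions small enough that restarts cost little. The restart count is
a free choice; 50 gives byte-identical optima across nearby seeds in our
tests.

The bundled reference signature set is **synthetic**
(`synthetic_reference_signatures`): five parametric profiles echoing
well-known processes — age-like C>T at CpG, the two APOBEC-like TpC
processes, a broad C>A process, and a near-flat background. It is
constructed in code, not fitted to any external catalog, and exists so
refitting and recovery contracts can be tested self-contained; users
with the published reference matrix can load it as a `SignatureSet` from
TSV and use it identically.

## Copy number

Discrete calls from log2 ratios: homozygous deletion < −1, loss
[−1, −0.2], neutral (−0.2, 0.2), gain [0.2, 0.6], amplification > 0.6.
The boundary values ±0.2 are assigned to gain/loss, and the
amplification/homozygous-deletion thresholds are strict, matching the
way the thresholds are conventionally quoted.

**FGA** is the fraction of bases affected by copy-number change per
chromosome, averaged over *all* chromosomes of the build (hg19 autosomes
+ X, 23 chromosomes; chromosomes without segments contribute zero). The
X chromosome is included (the cohort modelled is female) and Y excluded;
both are configurable through the build. Copy-neutral LOH does not
count: the definition is change in copy number.

**Profile types.** The five global profile labels are defined here by
explicit rules (the qualitative taxonomy is established; the cutoffs are
this package's):
amps on ≥ 2 chromosomes → `complex_multi_amp` (highest precedence, so a
few-event multi-amplified genome still counts as multi-amp);
otherwise < 10 altered autosomal events (adjacent same-call segments
coalesced first, making the label invariant to segment splitting) →
`simple`, or `simple_one_amp` when exactly one chromosome bears an amp;
otherwise `complex_whole_chr` when ≥ 80% of altered bases come from
whole-chromosome events (≥ 95% of their chromosome), else `complex`.
All cutoffs are keyword parameters.

**Group comparison.** The genome is partitioned at the union of all
segment breakpoints; per minimal interval and direction (gain∪amp,
loss∪homdel) a 2×2 Fisher's exact test compares aberrant counts between
groups. Fisher's exact is used because per-region counts are small. A
region is reported significant when p < 0.002 (0.05 divided by the
build's 23 chromosomes, since intra-chromosomal segments are not
independent, quoted to one significant figure), the absolute frequency
difference is ≥ 15%, the interval does not touch a platform-artifact
region, and its copy-number-polymorphism overlap is ≤ 90%. Regions
covered by segments but aberrant in no case are emitted with p = 1;
gaps with no segment coverage are not regions.

**Minimal overlap.** The shared amplicon core across cases is the
intersection of each case's union of amplified segments on the target
chromosome (optionally an arm window); a case without an amp there is an
error naming the case, and an empty intersection is reported explicitly.

## Structural variants

Deletions, duplications and inversions are intra-chromosomal with
size = |pos_b − pos_a|; small means < 1 Mb strictly, and inversions
< 30 kb are fold-back inversions — the size-only convention; breakend
orientation is recorded when present but not required. Anything joining
two chromosomes is an inter-chromosomal translocation. Summaries report
proportions of all breakpoint pairs, with fold-backs also given as a
share of inversions, and an empty input yields absent proportions rather
than zeros.

## Taxonomy

A gene event is a qualifying mutation (per-gene rule; default: any
non-synonymous effect, with `KRAS`/`BRAF`/`PIK3CA` missense-only and
`CDKN2A` inactivating-only) or a qualifying copy-number call overlapping
the gene locus — only amplifications and homozygous deletions are
eligible. The rule table and gene loci are user-editable dictionaries;
external tumor-type frequency columns are consumed as plain TSV, never
downloaded. Clustering is Euclidean distance on frequency columns with
complete linkage; dendrogram leaves are reordered by mean column value
(subtree with the smaller mean leaf weight first), which pins the leaf
order deterministically so other implementations can match it.

## Cohort statistics

- Fisher co-occurrence reports the two-sided exact p (hypergeometric
  tail sum), the conditional maximum-likelihood odds ratio and an exact
  confidence interval inverting the noncentral hypergeometric tails —
  the `fisher.test` convention, so zero cells give OR 0/∞ with a finite
  one-sided bound and no continuity corrections. The reported
  orientation (rows = event A yes/no, columns = event B yes/no) is
  carried in the result metadata because the OR inverts under row
  exchange. No multiple-testing correction is applied across
  co-occurrence tests (they are single targeted hypotheses); callers can
  adjust downstream.
- ANOVA is an ordinary linear-model two-factor analysis (group +
  sequencing platform), type-II sums of squares, with Tukey HSD
  (studentized range) on the group factor.
- Survival is disease-specific: only death-of-disease is an event,
  other deaths censor. FGA is dichotomized at the cohort median by
  default — the cut point is returned so it can be logged — and the
  logrank test is the k-sample score test with k−1 df. A multivariable
  Cox fit is provided as a convenience only.
- Profile-by-grade tables use Pearson chi-square without continuity
  correction and warn when any expected count is below 5.

## Synthetic cohort generator

The generator (`mocprog.simulate`) emulates the statistical structure
the analyses assume, with oracle truth labels riding along in
`CaseRecord.truth` that no analysis stage reads:

- **Composition.** Default group sizes 22 BEN, 39 MBT, 87 G1, 79 G2,
  24 G3, 23 EOM; platform mix 20% paired exome, 4% unpaired exome,
  4% WGS, 72% panel.
- **Drivers.** Per-group event probabilities default to the MOC
  literature values (CDKN2A inactivation 0.76 split between deletion and
  mutation, KRAS 0.64, TP53 0.64, ERBB2 amplification 0.26, RNF43 0.12,
  BRAF 0.10, PIK3CA 0.09, ARID1A 0.08; MBT with TP53 at 0.18; benign
  tumors mostly KRAS/CDKN2A only). They are configuration, not
  constants: the published frequencies are estimates, not mechanisms.
- **Reads.** Alt support is Binomial(depth, VAF) with true VAF ~
  Beta(14, 21) (clonal-ish, mean 0.4) and Poisson depth around platform
  means (80× exome, 60× WGS, 400× panel), rejection-resampled so a true
  clonal variant always clears the quantitative minimums — which is why
  clean synthetic data yields sensitivity = specificity = 1 and real
  data would not.
- **Artifacts.** Each artifact class violates exactly one cascade rule
  (population frequency, low QUAL, low depth, VarScan-only,
  UnifiedGenotyper-only in unpaired/panel, germline leakage in paired
  modes, and cohort-recurrent sites injected at 30% prevalence).
  Hotspot status is positional: any variant landing on a hotspot site is
  flagged, whichever simulation path drew it.
- **Copy number.** A per-case FGA target is Beta-distributed around the
  group mean (concentration 60), with means 0.01 → 0.04 → 0.10 → 0.16 →
  0.24 across BEN → G3 (0.18 for EOM), realized by placing
  non-overlapping altered segments under a sampled profile archetype
  with grade-dependent weights. Driver deletions/amplifications are
  planted at the CDKN2A and ERBB2 loci. Amplified chromosomes acquire
  fold-back-sized inversions.
- **Survival.** Exponential with hazard λ0·exp(link·(FGA − 0.1)),
  λ0 = ln2/100 per month, administrative censoring uniform over 12–120
  months and a slow independent other-cause process. The default link of
  7 per unit FGA was set so the expected logrank chi-square of a
  ~200-case invasive cohort split at median FGA is ≈ 12, the magnitude
  reported for real MOC cohorts of that size.
- **Sequence context.** SNVs are placed on a small generated
  multi-chromosome reference (3 × 30 kb) so trinucleotide contexts are
  real lookups; copy-number coordinates live on hg19. The two coordinate
  systems never mix within an analysis.

What the generator does **not** emulate: subclonal architecture and
clonal phylogenies, mapping artifacts with locus structure, FFPE damage
spectra, segmentation noise and wavy-baseline artifacts, germline CNVs,
or inter-site metastatic evolution. Passing the oracle suites therefore
shows the *rules* are implemented exactly, not that the cascade's error
rates on real tumors are 0/1.

## Problem sizes in tests

The shipped suites use a 600-case cohort for the cascade oracle, 1,000
random profiles (six 100 kb toy chromosomes) for the per-base FGA
oracle, 500 random 2×2 tables (n ≤ 40) against full hypergeometric
enumeration, 60 catalogs for planted-signature NMF recovery, 10,000
random breakpoint pairs for the SV partition, and 100 replicates of a
200-case invasive cohort for logrank power (observed ≈ 0.93–0.95 at the
default link; null rejection ≈ 0.04). These sizes make every check
sharp while keeping the default suite quick on a laptop.

## Known limitations

- The cascade treats QUAL as one scale across callers and platforms.
- Region comparison tests minimal intervals independently; no
  segment-level multiple-testing control beyond the 0.05/23 level.
- The conditional-MLE odds ratio solver targets the distribution mean
  (as `fisher.test` does); for extreme tables the CI endpoints can
  differ from other exact conventions in the third significant figure.
- Tukey HSD is computed on the group factor without covariate
  adjustment of the pairwise contrasts.
- The synthetic reference signatures are stand-ins; exposures refit
  against them are not comparable to published signature exposures.
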