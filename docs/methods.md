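# Methods

This note records the models, formulas, defaults and design choices
behind quartet-qc, including the points where a published metric is
named conceptually but its operational definition had to be fixed here.

## The quartet design

Four related donors — father F7, mother M8 and monozygotic twin
daughters D5 and D6 — are profiled as reference materials alongside
study samples, typically three technical replicates per donor per
batch. Two kinds of truth follow from the design and anchor the
metrics: *pedigree truth* (twins share genotypes; every child allele
must come from a parent), which is reference-free, and *reference
datasets* (benchmark variants, ratio-to-D6 profiles, differential
feature lists) distilled from historical batches.

## Genomics scoring

**Variant model.** Records are biallelic after multi-allelic splitting;
genotypes are unphased diploid over {0/0, 0/1, 1/1, ./.}. Left-alignment
and decomposition are *not* performed: benchmark matching is by exact
(chrom, pos, ref, alt) key, and the bundled simulator emits normalized
records. Real call sets should be normalized (e.g. `bcftools norm`)
before scoring; this is a documented limitation. Only autosomes are
scored — hemizygous sex-chromosome transmission needs a different
Mendelian model and is out of scope. Records with a FILTER other than
PASS/"." are dropped by default (configurable).

**Benchmark comparison.** Inside the merged confident regions, a donor
"call" is a non-missing, non-reference genotype. Default matching is
allele-presence: a call is a true positive iff a truth record with the
identical key exists and the truth donor carries the alternate allele.
The stricter genotype-exact mode (`genotype_match=True`) additionally
requires the genotypes to agree, demoting genotype discordances to
FP + FN pairs. Allele-presence is the default because genotype fidelity
is already measured — more sensitively — by the Mendelian component,
and double-counting it makes precision/recall conflate two error
processes; the choice is exposed so users can mirror either convention.
Precision/recall are computed per donor and arithmetically averaged
over the donors supplied.

**Mendelian concordance.** A site is *evaluable* iff no donor genotype
is missing and at least one is non-reference. Classification order:
missing → unevaluable; D5 ≠ D6 → twin-discordant; twin genotype not
producible as one paternal plus one maternal allele → trio violation;
otherwise concordant. MCR = concordant / evaluable, per variant type;
twin-discordant and trio-violating sites stay in the denominator, while
sites with any missing genotype are excluded from both numerator and
denominator (concordance is defined only over called genotypes).

**Combination.** Each component (precision, recall, MCR) is combined
across SNV/indel with F_β = (1+β²)ab/(β²a+b), β = 0.5, with the SNV
value in the β-favoured first slot — SNVs dominate call sets, so the
combined score should track them more closely; this slot assignment is
a package choice, as is returning the defined value verbatim (with a
warning) when one variant type is absent. Both-zero inputs return 0 by
the limit convention. The total is the arithmetic mean of the defined
combined components.

## Quantitative-omics scoring

**Scales.** Raw abundances are transformed as log2(x+1) for ratios,
correlations, t-tests and SNR. CV is computed on the raw scale (it is
scale-relative); when a profile arrives already log-transformed the
inverse transform 2^x − 1 is applied for CV rather than refusing, so a
single profile object serves every metric. Missing values are explicit
NaN; an option coerces zeros to missing on read for assays (commonly
proteomics) that encode absence as 0 (default off).

**SNR.** Features with any missing value are dropped; samples are
centred and projected onto the first two principal components; each
coordinate is multiplied by that component's explained-variance
fraction, so a nearly one-dimensional separation is not diluted by a
noise axis. Signal = mean squared Euclidean distance over all
cross-donor sample pairs, noise = the same over within-donor pairs, and
SNR = 10·log10(signal/noise) dB, capped at 100 dB when noise < 1e−12
(and undefined, raising, when signal also vanishes). The two-component,
variance-weighted, decibel form is this package's concrete definition
of the published signal/noise concept and is pinned by a test against
an independent SVD-based computation to 1e−9.

**Ratios and RC.** Donor means are taken over non-missing replicates on
log2 scale *before* differencing (not per-replicate ratios); features
with no D6 measurement are excluded. RC concatenates the three pair
columns over features shared with the reference into one vector per
side and reports their Pearson correlation; ≥3 overlapping entries are
required and a constant reference is an error. RC is therefore
invariant to affine rescalings of the query, which is intended — it
measures relative, not absolute, agreement.

**CV.** Per (feature, donor) cell with ≥2 non-missing replicates and a
positive mean, CV = sample sd (ddof = 1) / mean; the reported value is
the median over cells. The sample-sd convention is documented because
at n = 3 the population convention differs appreciably.

**Differential abundance.** Per feature and pair (D5, F7, M8 each vs
D6): two-sided Welch t-test on log2 values, significant at raw
p < 0.05 — no multiple-testing correction, deliberately, because the
recall metric asks whether *known* differential features reappear, not
whether discoveries are controlled. Degenerate zero-variance cases: p
= 1 when the means also agree, p = 0 otherwise. DAM recall divides the
rediscovered reference (feature, pair) entries by the reference entries
measurable in the profile (configurable to all reference entries).

**Total scores.** SNR enters every total through
scale01(SNR) = clip(SNR/100, 0, 1); RC enters clamped at 0. The raw
dB × r product is reported alongside the transcriptomics total because
the bounded form is an interpretation: the raw product is unbounded and
sign-unstable, unusable as a [0,1] score. The proteomics total is the
geometric mean of six metrics (feature count, missing fraction,
replicate correlation, median CV, SNR, RC), each min–max scaled against
its historical distribution to [0.01, 1], with missingness and CV
inverted first since lower is better; the 0.01 floor keeps the
geometric mean defined and makes any single catastrophic metric cost at
most a factor 0.01^(1/6). "Replicate correlation" is defined here as
the mean pairwise Pearson correlation of log2 abundances between
technical replicates within a donor (reference-independent). The
metabolomics total is the geometric mean of DAM recall, scaled SNR and
clamped RC with the same floor. All totals lie in [0, 1] by
construction.

## Ranking and reporting

Percentile = 100·(#{h < s} + ½·#{h = s})/N over the historical scores
(midrank ties), requiring N ≥ 5 — quartile categories are meaningless
below that. Category cut points are ≥80 great, ≥50 good, ≥20 fair,
else bad; the published ranges name no boundary rule, so inclusive
lower bounds are fixed here and tested. Reports are pydantic-validated
JSON (schema export shipped) rendered to HTML by a stdlib template;
regeneration from identical inputs is byte-identical apart from the
optional timestamp. Historical scores ship as small versioned JSON
fixtures produced by the simulator (`scripts/make_historical.py`);
users substitute their own by passing `--historical`.

## Metadata Data Packages

A package is a directory of CSV tables governed by one JSON descriptor
assigning each table typed fields (string, integer, number, ISO date,
enum) with required flags, ranges, enumerations and `table.field`
foreign keys. Findings are coded (MISSING_TABLE, MISSING_COLUMN,
MISSING_REQUIRED, TYPE_ERROR, ENUM_VIOLATION, RANGE_VIOLATION,
DANGLING_FOREIGN_KEY) and located by (table, row, field). Per cell, the
first failed check wins, so one defect yields exactly one finding. A
malformed descriptor raises a schema error rather than producing data
findings. The dialect is intentionally minimal; ontology resolution of
field names is out of scope.

## The simulator

**Variants.** Positions are drawn without replacement on a synthetic
contig chrS1 (declared autosomal; span 50 bp per requested variant) so
no real genome coordinates appear. Site allele frequencies follow
Beta(1.5, 1.5) rescaled to (0.05, 0.95) — bell-shaped, bounded away
from fixation so all-reference quartets are rare. Parents draw two
Bernoulli(af) alleles; the child draws one allele per parent; D6 copies
D5 (monozygosity), so every truth record is Mendelian-concordant by
construction. Indels (default 20 % of sites) are 1–3 bp
insertions/deletions. Defect injection: records are deleted at
`fn_rate`; each retained genotype is independently resampled from the
site allele frequency at `genotype_error_rate` (biologically shaped, and
chosen over a uniform genotype flip so that genotype errors degrade
MCR strongly while perturbing allele-presence precision/recall only
mildly — keeping the two genomics metrics separately exercisable);
false records are injected at unused positions with count
Binomial(n_retained, fp/(1−fp)) so the expected false fraction of calls
is `fp_rate`, and each injected record is made pedigree-inconsistent
with probability 0.5 by perturbing one twin. Benchmark regions are one
interval spanning the contig.

**Profiles.** Feature baselines are N(8, 2²) log2 units; per-donor
effects N(0, 0.5²) create the between-donor signal; for a `dam_fraction`
of features per pair the donor effect is pinned to the D6 effect ±
`dam_log2fc` exactly, and those entries are flagged in the returned
reference, whose ratios are the true donor-mean differences — hence a
noiseless profile reproduces the reference exactly (RC = 1, SNR at
cap). Replicates add N(0, noise_sd²); cells go missing completely at
random at `missing_rate`; an optional constant batch shift exercises
the shift-invariance of SNR and RC. Defaults (3 replicates, 0.2 sd
noise, 10 % DAMs at |log2FC| = 2) represent a competent batch.

**What the simulator does not emulate** — and hence what passing tests
do not demonstrate about real data: linkage disequilibrium, variant
representation ambiguity (the exact-key matcher is only as good as
upstream normalization), sequencing-depth-dependent genotype error,
heavy-tailed or intensity-dependent abundance noise,
missing-not-at-random dropout, and correlated features (real proteomes
are strongly co-regulated, which inflates effective SNR). The loop
validates the *metrics*, not any particular assay.

## Problem sizes and numerical tolerances

The test suite runs simulations at 200–2,000 variants/features with
20-seed averages for trend checks, and one 10,000-variant batch for
error-rate recovery (3-binomial-SD bands); `scripts/acceptance.py` uses
10,000 variants and 1,000 features — sizes at which the binomial noise
on recovered rates is well below the injected effects while the whole
script completes in seconds. Oracle comparisons are pinned at 1e−9
(SNR, Welch p-values) and 1e−12 (score algebra, RC identity);
interval arithmetic, percentiles and category boundaries are exact.
Seeds are fixed in tests; all simulator draws flow from a single
`numpy.random.default_rng(seed)`.

## Known limitations

- Exact-key variant matching (no haplotype-aware or left-aligned
  comparison); complex indel representations will miscount.
- Autosomes only; no structural-variant or methylation scoring.
- The SNR definition, the proteomics scaling recipe, the
  "replicate correlation" operationalization and the bounded
  transcriptomics product are this package's documented concretizations
  of metrics that are published as concepts; alternative portals may
  differ in detail while agreeing in ordering.
- Batch-effect *correction* is out of scope (only detection-adjacent
  metrics are provided).
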