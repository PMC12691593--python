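# Methods

## Model and assumptions

`mutkit` analyzes mutation-accumulation (MA) experiments under the standard
neutral model: replicate lines descend from one ancestor through repeated
single-cell bottlenecks, so within-line effective size is tiny (harmonic
mean of the doubling ladder between bottlenecks, ≈ g/2 for g generations
per cycle), selection is powerless against mutations with |s| < 1/Ne, and
observed mutations accumulate as independent events. Under that model a
line's count of events of a class is Poisson with mean rate × eligible
sites × generations; all estimators are moment/ML estimators of that law.

Rates are *conditional*: a G:C→A:T rate divides by the ancestor's G+C site
count, because only G:C pairs can host that event. Denominators always use
the ancestral composition — the mutations accumulated during an experiment
(< 0.2% of sites even in the fastest-mutating species analyzed) cannot
shift composition enough to matter.

## Coordinates and conventions

- 1-based coordinates throughout (VCF/GFF habits); bins are closed
  intervals `[start, end]` with the next bin starting at `end + 1`; a
  mutation belongs to the unique bin containing its position.
- The chromosome is circular for distances (two replichores run from
  *oriC*) but linear for binning: bins never wrap.
- Ambiguous bases (N) count toward total length but are excluded from
  class-specific denominators: an unclassifiable site cannot host a
  classified mutation.
- Strand collapsing: type(X→Y) = type(complement(X)→complement(Y)),
  giving the six canonical SNM classes.

## Filtering

Hard filters use the conventional inclusive thresholds for haploid
short-read calls (QD ≥ 2, SOR ≤ 5, FS ≤ 60, MQ ≥ 40, MQRankSum ≥ −20,
ReadPosRankSum ≥ −8, QUAL ≥ 30, F_MISSING = 0). They are opt-in, and
records lacking a requested field are retained: the package's primary
inputs are post-filter call tables or synthetic data, so filters must be
no-ops on QC-less input. Ancestral differences are removed by exact
(position, ref, alt) match — cross-line recurrence is only warned about,
since the ancestor comparison is the user's explicit mechanism.

Mutations closer than 50 bp (strict adjacent-gap rule, measured between
consecutive positions within one line) are collapsed into a single
complex/multi-nucleotide event; chains may mix SNMs and indels and count
once, in their own category, excluded from SNM and indel numerators. The
alternative span-of-pair reading of the proximity rule would differ only
for chains of ≥ 3 events spread over > 50 bp; the adjacent-gap rule is the
implemented and tested one.

## Estimators and uncertainty

Species rates are means of per-line rates; with uniform generations this
equals the pooled m/(nTl) identically (asserted in tests). The default SE
is s/√N across lines — the empirical standard error of the mean — with a
model-based Poisson SE (√m / nTl) available as `RateEstimate.poisson_se`.
95% CIs are mean ± 1.96·SE. Both SEs are asymptotic: for classes with
fewer than ~30 total events the ±3·SE interval's true coverage falls to
≈97–98.5% rather than the nominal 99.7% (a property of the interval, not a
bias of the estimator; the mean itself is exactly unbiased). The parameter-
recovery acceptance test documents this regime deliberately: its rarest
simulated classes carry ~9–11 expected events.

The AT mutation bias β uses conditional class *rates*, not raw counts, so
genome composition cancels; the default numerator is the transition class
only (G:C→A:T over A:T→G:C), with an all-GC-origin/all-AT-origin variant
behind `numerator="all"` — the two differ only through transversion rates,
and both are exposed because the convention is ambiguous in common usage.
Ts/Tv is count-based by default with a rate-based variant.

Fourfold-site eligibility requires the first two codon positions to be
gap-free and monomorphic across *all* sequences and to form a
fourfold-degenerate prefix of the standard code. This is conservative — a
polymorphic-context site whose observed states happen to be synonymous is
discarded — but it guarantees synonymy of every counted third-position
state. π is the unbiased pairwise average (differences / valid pairwise
comparisons, gaps excluded pairwise). The drift-barrier fit is OLS in
log10–log10 space (the rate–Ne scaling is a power law), always excluding
the focal species so their deviations are out-of-sample.

## Tests

The dispersion test fits a negative binomial by maximum likelihood (mean
fixed at the sample mean; size parameter optimized from a
method-of-moments start) and falls back to Poisson when the sample
variance does not exceed the mean. Goodness of fit is χ² on count
categories pooled — first from the tails, then any interior cell — until
every expected count is ≥ 5 (Cochran's rule), with df = categories − 1 −
fitted parameters; if fewer than two effective categories remain the
p-value is reported as unavailable with a warning rather than fabricated.

The coding-enrichment test is a two-cell χ² (coding vs noncoding, 1 df)
with expectation proportional to merged interval lengths.

Spearman correlations of per-bin rate against origin distance use average
ranks on ties, an exact permutation null for ≤ 9 bins and the
t-approximation otherwise, and Bonferroni correction defaulting to 6 tests
(one per SNM type).

## The simulator

The generator emulates exactly the process the estimators assume — iid
ancestral bases at a target GC fraction, Poisson (or mean-matched negative
binomial) per-line per-type counts, placement on eligible sites without
replacement within a line, indels placed uniformly with geometric lengths
— plus one deliberate deviation available for power studies: an
origin-proximal placement gradient f(d) = 1 + (k−1)·max(0, 1 − d/w), a
linear decay from k-fold at *oriC* to flat beyond window w. The linear
one-parameter shape is the minimal model of an origin-centred enrichment
of the kind reported in MMR-deficient lines (~3× within ~250 kb).

Default conditions mirror the largest experiment the stack is sized for:
66 lines, T = 1171 generations, 2 Mb at 34.7% GC, a transition-dominated
spectrum (G:C→A:T 1.2×10⁻⁸ and A:T→G:C 8×10⁻⁹ per site per generation
conditional, transversions 1–2×10⁻¹⁰, giving Ts/Tv ≈ 30), insertion and
deletion rates 2.4×10⁻⁹ and 4.5×10⁻⁹ with mean lengths 1.0 and 1.5 bp, and
85% coding density laid down as 1 kb blocks. Codon alignments are built
from fourfold-degenerate codon families with third-position allele
frequencies solving 2p(1−p) = π (two alleles, π ≤ 0.5) or a symmetric
four-allele scheme (π ≤ 0.75).

What the simulator does *not* emulate: within-colony genealogy and drift,
sequencing error and coverage variation, selection during MA, mutation
rate heterogeneity beyond the NB option and the origin gradient, and
context effects (e.g. neighboring-base dependence). Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
generating law, not robustness to those real-data complications.

All randomness flows through a single `numpy.random.Generator`; a config
plus seed reproduces byte-identical outputs.

## Problem sizes in the test suite

The statistical acceptance checks run at study scale but modest replicate
counts chosen as a sensible compute budget for a CI-style run: 100
replicates for rate recovery (64 lines, T = 1084, 2.24 Mb at 37% GC, six
nonzero conditional rates summing to ≈10⁻⁹), 20 gradient + 20 control
replicates for positional-bias recovery (66 lines, T = 1171, 2 Mb, k = 3,
w = 250 kb, 10 kb bins), 200 Poisson nulls for dispersion-test calibration
and 1,000 uniform-placement nulls for the coding test.

## Known limitations

- The NB goodness-of-fit flavor (categories, pooling, df) follows
  Cochran's rule; other reasonable binning policies give slightly
  different p-values.
- Ne during MA uses a ceiling on fractional generations per cycle
  (population sizes are integer generations); the difference is < 3% for
  g > 20.
- Per-line generation counts default to the species value; per-line
  overrides are supported but SE formulas still assume exchangeable lines.
- VCF import expects haploid genotypes and the GATK-style INFO keys; it is
  an import path, not a re-implementation of variant calling or filtering
  upstream of those fields.
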