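# Methods notes

This note records the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic data does and does not
emulate, and the design decisions taken where more than one reasonable
convention exists.

## Assays and in-silico PCR

An assay is a degenerate forward/reverse primer pair plus optional
accessories: a blocking primer and the four spacer sets (E–H) of the
two-step library construct.  Two assays are built in: the broad mollusc
16S mini-barcode (forward `RRWRGACRAGAAGACCCT`, reverse
`ARTCCAACATCGAGGT`, fish blocking primer `AGGTCGTAACCCCCTRG` with a C3
spacer blocking 3' extension) and the sphaeriid-specific 16S assay
(forward `TAGGGGAAGGTATGAATGGTTTG`, reverse `ACATCGAGGTCGCAACC`).

IUPAC semantics: a primer code matches a template base iff the base is in
the code's expansion; an `N` in the template matches nothing (an uncalled
base is no evidence of annealing).  Degenerate positions are full matches
when covered — there is no partial scoring.

In-silico PCR scans both strands for a forward site and a downstream
reverse-complemented reverse site, applying a mismatch budget
(default 0 — reference predictions are exact-site based; the trimmer and
specificity screens may raise it) and a length window (default
100–500 bp, wide enough for the 183–310 bp broad-assay amplicons while
excluding spurious distant pairings).  **Amplicon length is
primer-inclusive** (forward primer start to reverse primer end), the
convention amplicon sizes are quoted in; the primer-free *insert* is kept
alongside because that is the region a primer-trimmed read covers.
Coordinates are 0-based half-open on the plus strand throughout.

Blocking-primer overlap is the longest k for which the last k reverse-
primer codes are IUPAC-compatible with the first k blocking-primer codes
(both oligos anneal to the same strand, the blocker's 5' end overlapping
the reverse primer's 3' end).  For the built-in mollusc assay this
overlap is 4 nt.

## Reference database and amplicon OTUs

References are uppercase-normalised nucleotide sequences keyed by unique
accession, joined to species/higher-taxon labels through a minimal
tab-delimited taxonomy table (no machine-readable format is standard for
this; two mandatory columns plus optional higher taxon and source).
Collapsing references by byte-identical amplicon produces *amplicon
OTUs*: the unit an exact-matching read can actually discriminate.  A
multi-species amplicon OTU preserves the ambiguity as a species set
rather than resolving it — downstream exact assignment counts such reads
as ambiguous instead of fabricating per-species splits.  Records whose
amplicon contains `N` are kept but flagged; under exact string equality
they can never match an error-free read, which is the intended
conservative behaviour.

## Competitive-PCR quantification

Model: with equal NT/IS amplification efficiency the product molarity
ratio equals the template input ratio, so
`log10(NT/IS molarity) = log10(NT copies) − log10(IS copies)` — a line of
slope −1 in `log10(IS copies)` whose intercept is `log10(NT copies)`.
The estimator is OLS with `NT = 10^intercept`; this rule is exact only at
slope −1, so a warning flags fits with `|slope + 1| > 0.15` (default),
and the root-solving alternative `10^(−intercept/slope)` is reported as a
diagnostic.  Points with zero NT molarity (NT fully out-competed at high
IS input) are excluded and counted, not imputed: the log of zero is
undefined and no imputation rule is defensible.  At least 3 usable points
are required.

The internal-standard designer removes `round(fraction × amplicon
length)` bases (default 10%) from the centre of the insert, leaving both
primer annealing sites untouched — enough size difference for
electrophoretic separation without measurably changing PCR efficiency.

Simulated dilution series apply multiplicative lognormal noise to the
molarity ratio; recovery tests use σ = 0.05 (a ~5% coefficient of
variation, typical of chip-electrophoresis molarity estimates) over six
points spanning 10²–10⁵ copies.

## Mock communities and expected fractions

The five packaged recipes place eleven species (three sphaeriid clams,
seven other molluscs and walleye as the non-target fish) at copy numbers from 14 to 9090, with one
species fixed at 18 copies in every community as a low-abundance
constant.  Expected read fractions condition on amplifiability:
`100 × copies / Σ copies` over the amplifiable set, zero otherwise.  The
amplifiable set defaults to what in-silico PCR predicts against the
reference database, with a manual override available — necessary because
the fish is amplifiable by the broad assay yet suppressed by the blocking
primer, and suppression affects *observed*, not *expected*, values.

## Read simulator

The simulator emulates what reaches the sequencer after the two-step
library build, reduced to the parts that matter downstream:

* **Construct**: forward spacer + primer-inclusive amplicon +
  reverse-complemented reverse spacer.  Sequencing primer regions and
  P5/P7 adaptors are outside the read start and are not emitted.
* **Template choice** per pair is multinomial with weight
  `copies × efficiency_bias × (1 − blocking_efficiency  if blocked)`.
  Bias defaults to 1 (the validation condition); a lognormal per-species
  bias mode exists to emulate the over/under-representation real
  libraries show.
* **Reads**: 2 × 300 bp (truncated at the construct end), substitution
  errors only by default — indels would blur the exact-match semantics
  the validation path depends on.  Qualities follow a linear mean-Q decay
  (Q38 start, 0.02/cycle) with Gaussian jitter (SD 2), clipped to
  [2, 41]; nothing downstream is calibrated to these values, they only
  exercise the quality-aware merge rules.
* **Chimeras** splice two parent inserts at uniform interior breakpoints;
  such hybrids are never byte-identical to any single reference, so exact
  assignment drops them by construction (the clustering path inherits
  them, a documented limitation of the survey-mode analysis).
* **Decoys**: a configurable fraction of random-sequence pairs stands in
  for the PhiX spike-in / unindexed cluster fraction; they carry no
  primer sites and fall out at trimming.

Everything is driven by one integer seed; a fixed configuration gives
byte-identical FASTQ output.

What the generator does **not** emulate: PCR-cycle-level error
accumulation, index hopping, quality-dependent error rates, per-cycle
error profiles and real 16S secondary-structure context.  Passing
validation therefore demonstrates the correctness of the pipeline's
bookkeeping and statistics under controlled conditions — not the
biological fidelity of any particular sequencing run.

The synthetic reference database plants concretely-realised primer sites
around random species-specific inserts (149–276 nt for the broad assay;
the sphaeriid amplicon fixed at 299 bp on clam templates only), so assay
specificity emerges from sequence content, not from labels.  Random
inserts are effectively unrelated (~25% pairwise identity), which makes
them well-separated for clustering tests; real congeners are far closer,
so clustering resolution on real data is not established by these tests.

## Read processing

* **Merging**: read 2 is reverse-complemented and slid along read 1;
  candidate offsets come from exact 16-mer seeds at several read-2
  positions (a brute-force offset scan is the fallback), the winner
  minimising mismatch rate over an overlap ≥ 20 nt, ties to the longer
  overlap.  Pairs whose best overlap exceeds a 10% mismatch rate are
  rejected.  Disagreements take the higher-quality base and keep the
  *lower* quality; agreements keep the higher quality capped at Q41.
  The merge parameters are exposed because no published values exist for
  this step.
* **Trimming** is anchored: the forward primer must start within the
  first 25 nt (longest spacer 17 nt + slack) and the reverse-complemented
  reverse primer must end within the last 25 nt — a primer-like match in
  the read interior never triggers trimming.  Primer location tolerates
  1 mismatch by default (undocumented in the original tooling; exposed).
* **Retention**: inserts shorter than 100 bp are dropped (boundary
  inclusive: 100 bp is retained); singletons are exact-sequence
  multiplicity-1 reads within one sample, counted after the length
  filter.  Singleton removal is sequence-level, not cluster-level,
  matching its application before/independently of clustering; the
  cluster-level >1-read filter exists separately in identification, and
  the two are independently switchable.

Every stage's ledger satisfies `n_in = n_out + Σ rejections`.

## Taxonomic assignment

**Exact path** (validation): a read counts for a species iff its insert
equals a single-species amplicon OTU byte-for-byte; multi-species OTU
matches are ambiguous; everything else is unassigned.  This deliberately
sacrifices sensitivity for an error-free retained set.

**Survey path**: greedy centroid clustering over unique sequences in
abundance order (desc), then length (desc), then lexicographic; a
sequence joins the first centroid at ≥97% identity, else founds a new
centroid.  Identity is matches over all columns of a global alignment
with free terminal gaps — an exactly-specifiable approximation of the
usual heuristic centroid clusterer.  At threshold 1.0 the procedure
degenerates to exact deduplication.

Identification aligns representatives locally against the reference
collection with megablast-like scoring (match +2, mismatch −3, gap open
−5, extend −2; a gap of length L costs `open + (L−1)·extend`), replacing
a live remote database search with a deterministic local one.  Identity =
matches / alignment columns, coverage = aligned query span / query
length.  E-values are not computed; the retention rules never used them.
Best hit maximises identity, then coverage, then takes the smallest
accession — a deterministic substitute for irreproducible
database-order-dependent "first hit" behaviour.  Filters: coverage ≥80%,
reads ≥2; retained clusters sharing a best-hit accession are pooled with
summed counts.  Identity ≥97% marks species level.  Pairwise alignment is
computed with biotite; the test suite verifies identity/coverage against
an independent quadratic-time Gotoh implementation.

## Statistics

Observed percentages are computed from raw counts and rounded only at
presentation.  Log-log OLS (scipy) reports slope, intercept, R² and the
two-sided t-test p-value for slope ≠ 0; no multiple-testing correction is
applied (none is standard for this handful of planned comparisons).
Zero observed percentages are excluded by default (with the exclusion
counted) rather than floored: the alternative ε-floor is available but
makes the fit depend on an arbitrary constant.  Zero *expected*
percentages are always excluded (no defined log expectation).  Whether
the original analyses regressed rounded table percentages or raw
fractions is unknowable; this pipeline uses raw count-derived fractions,
which reproduces the published significance pattern.  Regressions run
both across species within a community and across communities within a
species; a species with constant expectation across communities has no
defined slope and is reported as NaN.

Blocking-primer efficacy is `100 × (1 − with/without)` on the blocked
taxon's read percentages, negative when the share increased, and
undefined (None) when the without-block share is zero.

## Problem sizes

Default test and acceptance runs use 10³–2×10⁴ simulated pairs per case
and one 10⁵-pair end-to-end run, sizes at which binomial sampling noise
on the rarest community member (~0.09% expected) is small enough for the
1%-absolute consistency checks while the whole suite stays fast.  The
competitive-PCR recovery study uses 100 replicate series.

## Known limitations

* The clustering path carries chimeras into OTUs (no chimera detector);
  the exact path drops them implicitly.
* Greedy clustering quality depends on abundance ordering; rare true
  variants within 97% of an abundant centroid are absorbed.
* The simulator's substitution-only default cannot exercise
  indel-tolerant merging/trimming paths (an indel mode is not provided).
* Competitive-PCR estimates rely on the slope ≈ −1 competition model; a
  strongly deviating slope invalidates `10^intercept` and is only
  warned about, not corrected.
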