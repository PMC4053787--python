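# Methods

## Variant hard-filter cascade

The model of the data is a comparison of two fully inbred genomes against
one reference assembly.  Under that model every genuine sub-strain variant
is homozygous, so three artifact classes dominate a raw call set: calls
that reflect errors in the reference assembly rather than sub-strain
differences (identified because they recur in an independent re-sequencing
of the reference strain), heterozygous-looking calls from mismapped or
paralogous reads, and calls at abnormal read depth (collapsed repeats,
dropout).  The cascade removes, in order:

1. calls whose (chrom, pos, ref, alt) key appears in the reference-strain
   call set;
2. calls with alternate-allele ratio < 0.8 (reason `heterozygous`);
3. calls with depth < 3 or > 150 (`low_depth` / `high_depth`).

All three cutoffs are strict inequalities, so 0.8, 3 and 150 themselves
pass.  The removal reason records the first failing rule, allele ratio
before depth; the choice of precedence is arbitrary but fixed.  The two
cascade stages commute — subtraction-then-filter equals
filter-then-subtraction — which the suite asserts on random inputs.

Variant identity trims alleles to their minimal representation (shared
trailing, then leading, bases removed with the position advanced), so
differently padded spellings of one indel compare equal;
`left_normalize()` additionally shifts an indel to its smallest start when
the flanking sequence is available.  A single allele-ratio cutoff is
applied to SNVs and indels alike.

An optional manual-curation rule flags calls inside a homopolymer run of
≥ 8 bases or in a 50-bp window with GC fraction > 0.8; it is off by
default because it models a human inspection step rather than a measured
property of the data.

## Consequence classification

Transcripts are minimal models: ordered exon intervals, a CDS span, and
the spliced coding-strand CDS sequence (BED12 + FASTA loader provided; the
CDS length must be divisible by 3).  An SNV inside the CDS is translated
codon-wise, strand-aware: stop gained → nonsense, amino-acid change →
missense, else synonymous.  Any variant touching the 2 intronic bases
flanking a coding exon (the canonical donor/acceptor dinucleotides) is a
splice variant; the window width is a declared choice.  A CDS indel is a
frameshift when |len(ref) − len(alt)| is not divisible by 3, otherwise an
in-frame indel.  Everything else, including positions outside the
transcript span, is non-coding.  The classifier is verified against a
brute-force oracle that rebuilds the mutated genome, re-splices, and
translates both haplotypes, over 1,000 random SNVs on random transcripts
of both strands.

## Validation adjudication

Each candidate variant is genotyped on four samples per sub-strain.  The
status precedence is: any missing call → PCR failure; any heterozygous
call → heterozygous; within-strain disagreement → inconsistent; identical
homozygous genotype in both strains → not a variant; otherwise confirmed.
The published campaign reports only aggregate counts (931 assayed, 363
eliminated, 568 remaining, 236 confirmed split 34/2/146/54 by coding ×
SNP/indel), not per-assay genotypes, so the ledger replay synthesizes one
deterministic panel per assay — eliminations split evenly across the three
failure modes — and recomputes the aggregates through the real
adjudication and summary code paths.

## SV triage and annotation

Candidates from several detectors merge when they share chromosome and
type and meet 50 % reciprocal overlap (a standard benchmark default; the
merged span is the union and supporting methods accumulate).  The state
machine allows only predicted → {false_pe_error, retained} and retained →
{reference_error, validated}; anything else raises, so no candidate can
reach `validated` unvetted.  The 551 → 81 → 43 ledger is replayed with the
43 published candidates plus synthetic stand-ins for the 508 rejected
predictions, whose intervals were never published.

Gene overlap: `entire` requires containment of the gene's whole
transcribed span; `exon` any exon base; `intron` an intersection with the
gene span touching no exon — implemented as "intersects the span" rather
than "contained in it", so an SV straddling a gene edge through an intron
still reports intron.  With several genes hit the most severe label wins
(entire > exon > intron), reporting the strongest functional consequence.

Ancestral events: the derived allele is the one absent from the outgroup
(rat); both alleles present is an ambiguity error, neither present is
invalid.  A derived gain whose sequence matches a mobile-element class
(LINE, SINE, IAP, MaLR, MTA) is a retrotransposition ("LINE Ins", ...);
a plain gain is "Ins" (same rollup), a derived loss "Del", a tandem-array
copy-number change "VNTR".  On the packaged table the rollup is 27
insertions / 15 deletions / 1 VNTR.

## Phenotype statistics

Comparisons are within-center only; centers differ in equipment, diet and
unrecognized environment, so a pooled model would confound center with
strain.  Replication across centers, not pooling, provides the power.

- Group selection: when metadata splits a (parameter, center) stratum into
  several comparable groups, the group maximizing min(n_N, n_J) is used,
  ties broken by larger total then list order.
- Time courses are averaged into one scalar per animal (missing points
  skipped; an animal with no valid points is dropped with a warning).
- Numeric: two-sided Mann-Whitney U.  Exact enumeration when
  min(n) ≤ 8 and the pooled sample is tie-free — where enumeration is
  cheap and exactness free — otherwise the normal approximation with tie
  correction and continuity correction.  Direction is the sign of
  mean(N) − mean(J); the rank-biserial correlation 2U/(n₁n₂) − 1 is
  reported alongside as a rank-based effect size.
- Categorical: Fisher's exact test for 2×2 (two-sided as the sum of
  hypergeometric point probabilities ≤ the observed one), Pearson χ² with
  (r−1)(c−1) df for larger tables.  For binary outcomes the direction
  orders strains by the proportion of a configured "affected" level
  (the affected level is not derivable from the data and must be named
  per parameter); multi-level tables are unordered.
- No multiple-testing correction across parameters: multiplicity is
  handled by the cross-center randomization null instead.

Cell encoding: p ≥ 0.05 → no call (null, shade 0); otherwise shade 1–3 as
p falls below 0.05 / 0.01 / 0.001 (conventional levels; the original key
is graphical), hue red for N > J, green for J > N, blue for unordered
categorical differences.  A significant result with exactly equal means
has no direction and is encoded null.  Encoding is monotone: smaller p
never gives a lighter shade.

## Concordance classes and the randomization null

Each parameter is evaluated per sex over its centers' non-null hues and
classed with precedence contradictory (≥ 2 centers of one ordered hue and
≥ 1 of the opposite) > concordant_3plus (≥ 3 same-hue centers) >
concordant_2 (exactly 2 same-hue centers, all others null) >
no_difference.  Sexes aggregate by "any sex".  Null cells never match
each other, and blue matches only blue — otherwise mostly-empty maps would
trivially concord.

The null: each repeat permutes the observed hue multiset (nulls included,
shades ignored) over all present cell positions without replacement —
conditioning on the observed color composition; resampling with
replacement is available behind a flag — and counts parameters with ≥ k
same-hue centers within some sex.  The estimate is total count / (P · R).
The observed rate uses the identical counting rule, so observed and null
are directly comparable; the four-class roster (with its contradictory
precedence) is reported separately.  For maps of ≤ 16 cells an exact
expectation is computed by enumerating all distinct assignments of the
multiset (capped at 500,000 arrangements); the Monte-Carlo estimate is
required to agree within 3 standard errors at 10⁵ repeats.  Whether the
original procedure shuffled within sexes or centers is not stated; the
global shuffle is the default and the chosen reading.

## Synthetic data

The phenotype generator emulates a standardized multi-center pipeline:
per parameter, independent cohorts of both strains at each center and sex,
Gaussian noise, a center-specific baseline offset, and a strain effect
given as a standardized shift d (numeric, time course) or a prevalence
pair (categorical, Bernoulli), optionally per center.  The default study
is parameterized from the published summaries: visual acuity 0.314 vs
0.399 cycles/degree (sd ≈ 0.043 → d ≈ −2), vein count 4.8 vs 5.3
(sd ≈ 1.1 → d ≈ −0.45), pulse rate elevated in N (d = +1, center offsets),
a glucose-tolerance time course (d = −1), fundus flecking at 69.2 / 44.6 /
23.0 % in N versus 0 % in J depending on center, and a null lens-opacity
parameter (the published lens measurements found no difference).  Group
size defaults to 20 per strain per sex per center, a typical primary-
screen cohort.

The variant generator plants disjoint classes at distinct positions:
true variants (allele ratio ≥ 0.9, depth inside [3, 150]),
reference-shared calls (clean metrics, present in both call sets),
heterozygous artifacts (ratio uniform in [0.3, 0.8)), and depth artifacts
(below 3 or in (150, 250]).  Filter recovery is therefore perfect by
construction, and the suite asserts exactly that over 20 seeds.

What the simulators do not model: correlated parameters, batch effects
within a center, non-Gaussian measurement error, missing-not-at-random
dropout, linkage between variants, and read-level error processes.
Passing tests show the pipeline's logic is correct under its stated
assumptions, not that real studies meet those assumptions.

## Numerical and design notes

- Both generators and the Monte-Carlo null are bit-reproducible under a
  fixed seed (single `numpy` Generator, fixed draw order); pipeline
  outputs embed the package version, a config hash, and the seed, and
  reruns are byte-identical.
- The analysis drivers use 10⁵ null repeats on small maps, 2,000 on the
  default study, 200 replicate studies for effect recovery, and 20 seeds
  for cascade recovery — sizes chosen so each driver completes in seconds
  while Monte-Carlo error stays well below the margins being tested.
- Degenerate inputs: empty comparison groups, all-zero contingency
  tables, unadjudicated assays, maps with fewer than k centers, and
  illegal triage transitions all raise informative errors rather than
  returning defaults.
- Known limitations: the published heat-map cell matrix exists only as
  figure images, so the printed concordance rates (0.213/0.074,
  0.102/0.388, 0.181/0.183) are not re-derivable from deposited data;
  the package instead proves the machinery on synthetic maps with known
  truth and exact oracles.  Transcript ingestion supports BED12 + FASTA
  (not GFF3), and SV detector outputs are inputs — the detectors
  themselves are out of scope.
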