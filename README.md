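# b6compare

Genomic and multi-center phenotypic comparison of the two most widely used
C57BL/6 mouse sub-strains, C57BL/6J (J) and C57BL/6N (N).

Although both descend from the same inbred line, roughly 220 generations of
separate breeding have left the sub-strains measurably different: a short
list of validated coding variants (including the *Nnt* deletion and the
*Crb1*<sup>rd8</sup> mutation), 43 structural variants, and reproducible
phenotypic differences in metabolism, behavior, and vision.  Because most
knockout mouse lines are made on an N background while much of the
literature's baseline data comes from J, these differences matter to anyone
interpreting mouse phenotypes.  This package re-implements the comparative
analysis as a reusable, fully tested pipeline:

- **Variant filter cascade** — in an inbred-vs-inbred comparison every true
  variant is homozygous, so a call is removed when it is shared with an
  independent re-sequencing of the reference strain, when its alternate
  allele ratio is < 0.8 (heterozygous artifact), or when its read depth is
  < 3 or > 150 (boundaries pass).  Retained coding calls are classified
  (missense / nonsense / splice / frameshift / inframe / synonymous) by
  strand-aware codon translation against transcript models, checked for
  privacy against a panel of other inbred strains, and adjudicated with a
  4 + 4 genotyping panel per sub-strain.
- **SV triage ledger** — structural-variant candidates from multiple
  detectors are merged at ≥ 50 % reciprocal overlap and driven through an
  audited state machine (predicted → retained/false → validated/reference
  error), annotated with gene overlap (entire > exon > intron), and
  assigned an ancestral event against the rat outgroup (the derived allele
  is the one absent from the outgroup).
- **Multi-center phenotype concordance** — strain comparisons are run
  within, never between, centers: two-sided Mann-Whitney *U* for numeric
  parameters (exact enumeration when min(n) ≤ 8 without ties), Fisher's
  exact test or Pearson's χ² for categorical ones, time courses averaged
  per animal first.  Each parameter × center × sex cell becomes a heat-map
  color (red N > J, green J > N, blue unordered; shade darkens at
  p < 0.05, 0.01, 0.001).  Parameters are classed as concordant in ≥ 3
  centers, concordant in exactly 2, contradictory, or no difference, and
  the chance rate of ≥ k-center concordance is estimated by randomizing
  all heat-map squares (permuting the observed color multiset), with an
  exact enumeration oracle for small maps:

  p̂₀ = (Σ over repeats of concordant parameters) / (P · R).

The published Table 1 (36 coding SNPs/indels), Table 2 (43 SVs), and the
validation bookkeeping counts ship as packaged TSV fixtures; synthetic
generators provide multi-center studies and variant call sets with known
ground truth for everything the published tables cannot test.

## Worked example

```sh
python analysis/03_phenotype_concordance.py
```

simulates the default four-center study (visual acuity, fundus vein
counts, pulse rate, a glucose-tolerance time course, fundus-flecking
prevalence, and a deliberately null lens-opacity parameter) and prints:

```
study: 1920 measurements, 6 parameters x 4 centers x 2 sexes
  fundus_flecking    concordant_3plus
  glucose_auc        concordant_3plus
  lens_opacity       no_difference
  pulse_rate         concordant_3plus
  vein_count         no_difference
  visual_acuity      concordant_3plus
observed >=3-center concordance rate 0.667 vs randomization null 0.367
concordant_3plus: observed 0.667, randomized 0.107 (ratio 6.2)
```

The four parameters simulated with real strain effects land in the
≥ 3-center concordant class; the null parameter does not; the small
vein-count shift (d ≈ −0.45 at n = 20) is under-powered per center, which
is exactly the situation the cross-center design exists to flag.  The
`concordant_3plus` class is ~6× over-represented relative to
color-randomized maps — the same qualitative signature the real study
reports.  Equivalent drivers replicate the printed variant tables
(`analysis/01_replicate_tables.py`), exercise the filter cascade on planted
artifacts (`analysis/02_variant_cascade.py`), and calibrate the
Monte-Carlo null against exact enumeration
(`analysis/04_null_calibration.py`).

A `b6compare` console script exposes the same pipelines
(`b6compare simulate | variants | concord | replicate`).

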