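# Methods

This document records the model implemented by `neoscreen`, its parameter
defaults, the design of the synthetic generators, the numerical choices,
and the known limitations. No empirical performance claims are made here
beyond what the shipped test suite computes.

## 1. Screening model

The toolkit models a targeted-sequencing newborn screen as a deterministic
decision pipeline over a single sample's small-variant calls:

1. **Panel filter.** A call is on-panel when its full reference span lies
   inside the (merged) regions of at least one panel gene. A span
   overlapping two genes' regions is kept and flagged `ambiguous-gene` in
   the audit trail; gene assignment stays with both genes.
2. **Caller-scope filter.** Indels with a REF/ALT length difference above
   15 bp fall outside the validated scope of a panel small-variant caller
   and are excluded from interpretation (and from benchmarking).
3. **Quality filter.** Sample depth DP ≥ 30 and quality-by-depth
   QD ≥ 2.0. Missing DP or QD *fails closed*: a screen must not report a
   variant it cannot quality-assess.
4. **Frequency filter.** Population allele frequency must be < 0.01.
   Genes marked `frequent_gene` (conditions with common pathogenic
   founder alleles) bypass the cutoff. A variant with no frequency record
   is treated as rare and kept — absence of evidence is not evidence of
   commonness for a screen whose purpose is detecting rare disease.
5. **Knowledge-base classification.** Four assertion sources: a curated
   managed variant list (MVL), a ClinVar-like public archive, and two
   auxiliary databases. Consensus rules:
   - reportable ⇔ P or LP in MVL or ClinVar-like, **and** no benign/likely
     benign assertion and no unresolved conflict in any of the three
     consensus sources (ClinVar-like and the two auxiliaries);
   - a variant absent from both MVL and ClinVar-like is `NOT_IN_DB` and
     unreportable, whatever the auxiliaries say;
   - a missing auxiliary assertion counts as non-dissent;
   - VUS are stored per sample but never reported;
   - benign-consensus and conflicting variants are dropped with reasons.
6. **Zygosity resolution**, per gene, against the declared inheritance:
   - **AR**: a homozygous call is an event (`homozygous`); two or more
     distinct heterozygous calls form one `possible_compound_het` event
     (calls are unphased — phase confirmation is downstream wet-lab
     work); a single het is a carrier, suppressed by design.
   - **AD**: every surviving variant is an event (`dominant_het`).
   - **XL, male**: any variant outside the pseudoautosomal regions is an
     event (`hemizygous`); diploid callers typically emit `0/1` on male
     X, so het-called X variants are treated as hemizygous. Variants in
     PAR1/PAR2 follow diploid AR rules.
   - **XL, female**: AR rules.
   - **Unknown sex** on an X-linked gene *fails open*: an event with
     `mechanism = None` forces human review rather than silently applying
     either rule.

A sample with ≥ 1 event is `review_required` (confirmation-rerun
candidate); otherwise `auto_closed`. Every input variant receives exactly
one terminal audit entry (the stage that dropped it, or its zygosity
outcome), plus optional non-terminal flags.

### Assumptions

- Calls are normalized and biallelic after read-time decomposition;
  matching and knowledge-base lookup use the exact
  (chrom, pos, ref, alt) key.
- No phasing information; compound heterozygosity is "possible" only.
- CNVs/SVs are out of scope; panel genes may carry a `cnv_flagged`
  annotation for reporting completeness, but no CNV calling is modelled.
- hg19 PAR coordinates (0-based): X:60000–2699520 and
  X:154931043–155260560.

## 2. Quality control

Per-sample metrics are judged against a threshold set combining:

- **Fixed thresholds** (panel v1 / v2): Q30 ≥ 85 / 90 %, target bases at
  30× ≥ 93 %, mean target coverage ≥ 100, selected (on/near-bait) bases
  ≥ 40 / 78 %, SNP reference bias ≤ 0.56.
- **Derived thresholds**: median ± 1.5·IQR computed from run history with
  `numpy.quantile(..., method="linear")` (a classical Tukey-style fence
  around the quartiles is available as an option). At least 8 historical
  samples are required.

Boundary values pass (thresholds are inclusive). A missing metric fails
closed. Q30, target-bases-30× and reference bias are *VIP* metrics: any
VIP failure forces a full wet-lab `repeat`; other failures yield `review`;
otherwise `pass`.

The internal control sample (plate position H12) must carry its expected
variants with matching genotype at DP ≥ 30; a missing or failing control
fails the batch. Longitudinal monitoring uses Levey–Jennings series with
mean ± 1/2/3 SD bands (sample SD, `ddof=1`, optionally over a trailing
window); points beyond 3 SD are flagged.

## 3. Benchmarking

Test and truth call sets are restricted to the targets of interest
intersected with the high-confidence regions at DP ≥ 30; truth records
without a DP annotation are retained (truth sets commonly lack per-site
depth), test records fail closed. Matching is exact on the normalized key
*and* genotype: a genotype mismatch at a shared site counts as one FP plus
one FN. Counts are stratified into SNP / INDEL / ALL. Metrics:
sensitivity TP/(TP+FN), precision TP/(TP+FP), concordance C/(A+B+C) with
C shared and A/B the test-/truth-only counts (symmetric). Ratios with a
zero denominator are reported as absent (`None`/`NA`), never coerced to 0
or 1.

## 4. Synthetic generators

The generators are the study conditions: their defaults define what the
tests and the acceptance script measure, and they return the ground truth
they plant.

- **Determinism.** Every generator derives sub-generators from
  `numpy.random.SeedSequence([seed, crc32(purpose), ...])`, so outputs
  are byte-identical for a fixed seed and independent across purposes.
- **Panels.** Genes of 3–8 exons (80–300 bp with ±50 bp intronic flanks),
  placed without overlap on autosomes and X; X-linked genes start at
  ≥ 10 Mb, clear of PAR1. A fixed five-gene roster (two AR control genes,
  a frequent AR gene, an AD gene, an XL gene) heads every default panel.
  Panel redesign removes non-roster genes and adds new ones at an offset
  that cannot collide with existing regions.
- **Knowledge base.** Per gene, five planted variants inside the first
  exon: two reportable P/LP (one an insertion for alternating genes), a
  VUS (AF 10⁻³), a common benign variant (AF 5 %), and a conflicting
  variant (LP with a benign dissent). The returned ledger maps every key
  to its intended consensus class.
- **Scenario samples.** Eleven scenarios (negative, AR carrier, AR
  homozygote, AR compound het, AD het, XL hemizygous male, XL female
  compound het, VUS-only, conflicting, off-panel, low-depth) plus an H12
  control sample. Background depth is lognormal around 150× (floor 40),
  QD ~ N(15, 3) clipped to [5, 40]; every sample carries two common
  benign calls from other genes and one off-panel call as noise.
- **Truth pairs.** Planted (shared, test-only, truth-only) counts on
  non-colliding slots inside the panel targets, DP ≥ 31, ~20 % small
  indels, so benchmark counts are exactly predictable.
- **QC cohorts.** Safe metric values are uniform inside bands that sit
  strictly within the fixed thresholds; planted failures are uniform in
  bands decisively outside them, with the failing metric drawn by weights
  dominated by the on-bait fraction. Because a uniform[a, b] sample has
  median − 1.5·IQR = a − 0.25(b − a) < a, the derived PF_BASES fence can
  never cut into safe draws: planted verdicts are exactly the expected
  verdicts.

Realism boundaries: no reads or alignment are simulated, no reference
FASTA is used (normalization is string-based, so none is needed), and
coordinates are plausible rather than real gene coordinates.

## 5. Numerical and representation choices

- Quantiles use linear interpolation of order statistics
  (`numpy.quantile`, `method="linear"`); the derived-threshold oracle in
  the tests recomputes this independently.
- Thresholds are inclusive at the boundary in the direction of passing.
- Levey–Jennings uses the sample standard deviation (`ddof=1`).
- htslib stores INFO `Float` fields as 32-bit floats; QD is rounded to
  4 decimals on read so round trips are exact and representation noise
  never crosses the QD ≥ 2.0 boundary.
- Normalization right-trims shared suffixes, then left-trims shared
  prefixes keeping one anchor base for indels; it is idempotent and never
  consults a reference genome.
- Chromosome labels are harmonized by stripping any `chr` prefix at read
  time; files are written `chr`-prefixed.
- 1-based VCF positions are converted to 0-based half-open spans for all
  interval arithmetic; a variant's span covers its full REF allele.

## 6. Limitations

- Matching is exact-key and genotype-aware but not haplotype-aware:
  complex representation differences that a haplotype comparison engine
  would reconcile appear here as paired FP/FN.
- Compound heterozygosity is inferred from counts of distinct hets, not
  phase; true cis pairs are over-called by design (screening errs toward
  review).
- The knowledge base is a snapshot keyed on exact normalized alleles; no
  transcript-level or region-level (e.g. loss-of-function) rules.
- QC thresholds assume the metric semantics of hybrid-capture panels
  (HsMetrics-style); other assay types need different rules.
- Synthetic cohorts are designed for exactness, not distributional
  realism: they validate logic, not caller performance on real data, and
  headline sequencing-accuracy figures from real benchmark genomes are
  out of scope at desk scale.
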