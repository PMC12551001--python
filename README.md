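# neoscreen

A desk-scale toolkit for the analytical software stack of a gene-panel
**genomic newborn screen**: deterministic variant triage against a curated
knowledge base, sequencing-run quality control with derived and fixed
thresholds, truth-set benchmarking, and fully self-describing synthetic
fixtures with planted ground truth.

Newborn screening by targeted sequencing differs from diagnostic testing in
one crucial way: decisions must be *automatable and auditable*. A screen
reports only known pathogenic / likely pathogenic (P/LP) variants that fit
the gene's inheritance mode; everything else — carriers, variants of
uncertain significance (VUS), conflicting assertions, common variants — is
deliberately suppressed or merely stored. `neoscreen` implements that flow
as a pipeline of pure, testable stages, each of which appends to a
per-variant audit trail.

## What it does

- **`genomic_io`** — VCF reading via [pysam] with multiallelic
  decomposition, genotype labelling (`het` / `hom_alt` / `hemi`),
  string-based variant normalization (right-trim then left-trim with one
  anchor base; idempotent), and BED interval I/O.
- **`knowledge`** — gene panel (inheritance mode, regions, frequent-gene
  and CNV flags, versioned revisions) and a four-source variant knowledge
  base (an internally curated managed variant list, a ClinVar-like public
  source, and two auxiliary sources). A variant is *reportable* only when
  the curated or public source asserts P/LP **and** no consensus source
  dissents (benign assertion or unresolved conflict). Variants absent from
  both reporting sources are not reportable regardless of auxiliary
  content.
- **`triage`** — the decision tree: panel filter → caller-scope filter
  (indels ≤ 15 bp) → quality filter (DP ≥ 30, QD ≥ 2.0, missing fails
  closed) → population-frequency filter (AF < 1%, frequent-gene bypass,
  missing AF treated as rare) → knowledge-base classification → per-gene
  zygosity resolution: AR homozygous or possible compound heterozygous
  (≥ 2 distinct hets, unphased), AD any single variant, X-linked male
  hemizygous outside the pseudoautosomal regions, X-linked female under AR
  rules, unknown sex fails open to human review. Single-het AR findings
  are carriers and never reported.
- **`qc`** — per-sample verdicts against fixed thresholds plus
  median ± 1.5·IQR fences derived from run history; failures on *VIP*
  metrics force a wet-lab repeat, others a manual review. Internal-control
  verification (plate position H12) and Levey–Jennings series with
  ±1/2/3 SD bands complete the monitor.
- **`benchmark`** — genotype-aware exact matching of a test call set
  against a truth set inside targets-of-interest ∩ high-confidence
  regions at DP ≥ 30, stratified into SNPs and indels, reporting
  sensitivity, precision and pairwise concordance (0/0 ratios reported as
  absent, never coerced).
- **`synth`** — deterministic generators for panels, knowledge bases,
  scenario VCFs, truth/test pairs with planted discordance counts, and QC
  metric cohorts with planted failure plans. Every generator returns the
  ground truth it planted, so the toolkit can be validated end to end
  without any external data.
- **`batch` / `cli`** — one `nbs` entry point wiring QC gate → triage →
  control check over a batch directory.

## Worked example

Generate a self-contained fixture bundle (panel, knowledge base, one VCF
per triage scenario plus a control sample, QC metrics, ground truth) and
run the full batch flow over it:

```console
$ nbs synth bundle --genes 12 --seed 42 --out demo/bundle
wrote bundle with 12 samples to demo/bundle

$ nbs run --bundle demo/bundle --out demo/results
12 samples; repeat=0; confirmation=5; control=PASS
```

Five samples carry planted reportable configurations and are flagged as
confirmation candidates (`NB002`–`NB006`: homozygous AR, compound-het AR,
dominant AD, hemizygous X-linked male, and X-linked female compound het);
the internal control at plate position H12 passes. The per-sample triage
JSON names the event exactly:

```console
$ python -c "import json; r = json.load(open('demo/results/batch_report.json')); \
             print(json.dumps(r['triage']['NB003']['events'], indent=2))"
[
  {
    "gene": "ALDOB",
    "mechanism": "possible_compound_het",
    "variants": [
      ["9", 1000011, "G", "A", "het"],
      ["9", 1000021, "T", "TCT", "het"]
    ]
  }
]
```

and the audit trail records one terminal decision per input variant:

```console
$ head -6 demo/results/NB003.audit.tsv
chrom	pos	ref	alt	stage	decision	reason	genes
2	1000998	C	G	panel	dropped	off-panel	.
11	1000041	C	A	frequency	dropped	common-af=0.05	GENE0005
16	1000041	C	T	frequency	dropped	common-af=0.05	GENE0001
9	1000011	G	A	zygosity	kept	reported	ALDOB
9	1000021	T	TCT	zygosity	kept	reported	ALDOB
```

Individual stages are exposed as `nbs triage run`, `nbs qc
thresholds|evaluate|control|lj`, and `nbs bench compare`.

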