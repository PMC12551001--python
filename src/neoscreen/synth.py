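"""Synthetic fixture generation with full ground truth.

Everything the toolkit consumes can be generated here: gene panels
(TSV + BED4), knowledge-base tables, per-sample VCFs with planted triage
scenarios, truth/test VCF pairs with controlled discordance, and QC metric
histories with planted failures. Every generator is deterministic for a
fixed seed (sub-seeds are derived from the master seed plus a purpose
string), and each returns the ground truth it planted so tests and
integration checks can verify the toolkit end to end.

The generators emulate the study conditions of a panel-based newborn
screen: exons of 80-300 bp carrying +/-50 bp intronic flanks, background
sequencing depth lognormal around 150x, reportable variants planted per
inheritance mode, a per-plate internal control sample at position H12 with
two known pathogenic variants, and a QC cohort whose planted failure plan
mirrors routine operations. No reads are simulated and coordinates live on
real chromosome labels without a reference FASTA; normalization is
string-based so none is needed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ScenarioError
from .genomic_io import PathLike, VariantCall, VariantKey, write_bed, write_vcf
from .intervals import GenomicInterval, IntervalSet
from .knowledge import KnowledgeBase, Panel, PanelGene, revise_panel
from .qc import DEFAULT_RULES, VIP_METRICS, QCRecord
from .triage import SampleMeta

BASES = ("A", "C", "G", "T")
AUTOSOMES = tuple(str(c) for c in range(1, 23))

#: fixed roster heading every generated panel: two control genes, a
#: frequent gene, a dominant gene and an X-linked gene.
_ROSTER = (
    ("SERPINA1", "14", "AR", False),
    ("ALDOB", "9", "AR", False),
    ("PAH", "12", "AR", True),
    ("ELN", "7", "AD", False),
    ("OTC", "X", "XL", False),
)

SCENARIOS = (
    "negative",
    "carrier_AR",
    "hom_AR",
    "compound_het_AR",
    "dominant_AD",
    "hemi_XL_male",
    "xl_female_comp_het",
    "vus_only",
    "conflicting",
    "off_panel",
    "low_depth",
)

#: scenarios whose expected triage outcome contains at least one event
POSITIVE_SCENARIOS = ("hom_AR", "compound_het_AR", "dominant_AD", "hemi_XL_male",
                      "xl_female_comp_het")

_SCENARIO_INHERITANCE = {
    "carrier_AR": "AR",
    "hom_AR": "AR",
    "compound_het_AR": "AR",
    "dominant_AD": "AD",
    "hemi_XL_male": "XL",
    "xl_female_comp_het": "XL",
    "low_depth": "AR",
}

#: analytical validation plate composition: eight positives in triplicate on
#: two 96-sample runs, in duplicate on one 48-sample run, the negatives of
#: those plates, and eight revalidation positives on two further runs.
VALIDATION_DESIGN = {
    "positive_triplicates_novaseq": 48,
    "positive_duplicates_nextseq": 16,
    "negative_novaseq": 112,
    "negative_nextseq": 24,
    "revalidation_positives": 16,
}


def validation_total(design: Mapping[str, int] = VALIDATION_DESIGN) -> int:
    return sum(design.values())


def _rng(seed: int, *purpose: str) -> np.random.Generator:
    """Deterministic sub-generator derived from the master seed and a
    purpose key."""
    entropy = [int(seed)] + [zlib.crc32(p.encode()) for p in purpose]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------


def make_panel(
    n_genes: int = 12,
    seed: int = 0,
    version: str = "v1",
    n_cnv_flagged: int = 0,
    prefix: str = "GENE",
    include_roster: bool = True,
    base_offset: int = 0,
) -> Panel:
    """Generate a panel of ``n_genes`` genes with 3-8 exons each (80-300 bp,
    +/-50 bp flanks), spread over autosomes and X, regions non-overlapping
    between genes. X-linked genes are placed outside the pseudoautosomal
    regions."""
    if n_genes < 3:
        raise ScenarioError("a panel needs at least 3 genes")
    rng = _rng(seed, "panel", version, prefix)
    cursors: Dict[str, int] = {}
    genes: Dict[str, PanelGene] = {}

    def _place(symbol: str, chrom: str, inheritance: str, frequent: bool) -> None:
        # X placement clears PAR1 (ends at 2.7 Mb on hg19)
        start_floor = (10_000_000 if chrom == "X" else 1_000_000) + base_offset
        cursor = cursors.get(chrom, start_floor)
        n_ex = int(rng.integers(3, 9))
        regions = []
        pos = cursor
        for _ in range(n_ex):
            length = int(rng.integers(80, 301))
            regions.append(GenomicInterval(chrom, pos - 50, pos + length + 50))
            pos += length + int(rng.integers(500, 5001))
        cursors[chrom] = pos + 100_000
        genes[symbol] = PanelGene(
            symbol=symbol,
            inheritance=inheritance,
            regions=IntervalSet(regions),
            frequent_gene=frequent,
            panel_version=version,
        )

    roster = _ROSTER if include_roster else ()
    for symbol, chrom, inheritance, frequent in roster[:n_genes]:
        _place(symbol, chrom, inheritance, frequent)
    i = 0
    while len(genes) < n_genes:
        i += 1
        symbol = f"{prefix}{i:04d}"
        if symbol in genes:
            continue
        if i % 9 == 0:
            chrom, inheritance = "X", "XL"
        else:
            chrom = str(AUTOSOMES[int(rng.integers(0, len(AUTOSOMES)))])
            inheritance = "AD" if rng.random() < 0.2 else "AR"
        _place(symbol, chrom, inheritance, False)

    if n_cnv_flagged:
        if n_cnv_flagged > n_genes:
            raise ScenarioError("cannot flag more genes than the panel holds")
        flagged = rng.choice(sorted(genes), size=n_cnv_flagged, replace=False)
        for symbol in flagged:
            genes[symbol].cnv_flagged = True
    return Panel(version=version, genes=genes)


def write_panel(panel: Panel, table_path: PathLike, bed_path: PathLike) -> None:
    """Write the gene table (TSV) and region file (BED4, chr-prefixed)."""
    with open(table_path, "w") as fh:
        fh.write("symbol\tinheritance\tfrequent_gene\tcnv_flagged\n")
        for symbol in sorted(panel.genes):
            g = panel.genes[symbol]
            fh.write(
                f"{symbol}\t{g.inheritance}\t{int(g.frequent_gene)}"
                f"\t{int(g.cnv_flagged)}\n"
            )
    names = {}
    intervals = []
    for symbol in sorted(panel.genes):
        for iv in panel.genes[symbol].regions:
            intervals.append(iv)
            names[(iv.chrom, iv.start, iv.end)] = symbol
    write_bed(IntervalSet(intervals), bed_path, chrom_prefix="chr", names=names)


def make_redesigned_panel(
    panel: Panel,
    n_removed: int,
    n_added: int,
    seed: int = 0,
    version: str = "v2",
    n_cnv_flagged: int = 0,
) -> Panel:
    """Emulate a panel redesign: drop ``n_removed`` non-roster genes, add
    ``n_added`` freshly generated ones, and optionally mark
    ``n_cnv_flagged`` genes as carrying reported CNVs/SVs."""
    rng = _rng(seed, "redesign")
    roster_syms = {r[0] for r in _ROSTER}
    removable = sorted(s for s in panel.genes if s not in roster_syms)
    removed = list(rng.choice(removable, size=n_removed, replace=False))
    # offset keeps added-gene regions clear of the original panel's
    extra = make_panel(
        max(3, n_added), seed=seed + 1, version=version, prefix="NEW",
        include_roster=False, base_offset=50_000_000,
    )
    added = [extra.genes[s] for s in sorted(extra.genes)][:n_added]
    revised = revise_panel(panel, removed, added, version=version)
    if n_cnv_flagged:
        for symbol in rng.choice(sorted(revised.genes), size=n_cnv_flagged, replace=False):
            revised.genes[symbol].cnv_flagged = True
    return revised


# ---------------------------------------------------------------------------
# knowledge base
# ---------------------------------------------------------------------------


def _first_region(gene: PanelGene) -> GenomicInterval:
    return next(iter(gene.regions))


def _snv(rng: np.random.Generator, chrom: str, pos: int) -> Tuple[str, str]:
    ref = BASES[int(rng.integers(0, 4))]
    alt = BASES[int(rng.integers(0, 4))]
    while alt == ref:
        alt = BASES[int(rng.integers(0, 4))]
    return ref, alt


def make_kb(panel: Panel, seed: int = 0) -> Tuple[KnowledgeBase, dict]:
    """Plant, per gene, two reportable P/LP variants, one VUS, one common
    benign variant (AF 5%) and one conflicting variant (LP vs benign
    dissent), all inside the gene's first exon. Returns the knowledge base
    plus a ground-truth ledger mapping every key to its intended consensus
    and listing the internal-control variant keys."""
    rng = _rng(seed, "kb")
    kb = KnowledgeBase()
    ledger: dict = {"classifications": {}, "genes": {}, "control_variants": {}}
    for idx, symbol in enumerate(sorted(panel.genes)):
        gene = panel.genes[symbol]
        region = _first_region(gene)
        base = region.start + 60  # clear the 50 bp flank, sit inside the exon
        keys: Dict[str, VariantKey] = {}

        def _key(offset: int, indel: bool = False) -> VariantKey:
            pos = base + offset + 1  # 1-based
            ref, alt = _snv(rng, region.chrom, pos)
            if indel:
                ins = "".join(BASES[int(rng.integers(0, 4))] for _ in range(2))
                alt = ref + ins
            return (region.chrom, pos, ref, alt)

        keys["P1"] = _key(0)
        keys["P2"] = _key(10, indel=idx % 2 == 0)
        keys["VUS"] = _key(20)
        keys["BENIGN_COMMON"] = _key(30)
        keys["CONFLICTING"] = _key(40)

        kb.add_assertion(keys["P1"], "MVL", "P")
        kb.add_assertion(keys["P1"], "CLINVAR", "P")
        kb.add_assertion(keys["P1"], "AUX1", "P")
        kb.add_assertion(keys["P1"], "AUX2", "LP")
        kb.add_assertion(keys["P2"], "CLINVAR", "LP")
        kb.add_assertion(keys["VUS"], "CLINVAR", "VUS")
        kb.add_assertion(keys["BENIGN_COMMON"], "CLINVAR", "B")
        kb.add_assertion(keys["CONFLICTING"], "CLINVAR", "LP")
        kb.add_assertion(keys["CONFLICTING"], "AUX1", "B")

        kb.add_frequency(keys["P1"], 0.0002)
        kb.add_frequency(keys["VUS"], 0.001)
        kb.add_frequency(keys["BENIGN_COMMON"], 0.05)
        kb.add_frequency(keys["CONFLICTING"], 0.003)

        expected = {
            "P1": "REPORTABLE_P_LP",
            "P2": "REPORTABLE_P_LP",
            "VUS": "VUS",
            "BENIGN_COMMON": "BENIGN",
            "CONFLICTING": "CONFLICTING",
        }
        for role, key in keys.items():
            ledger["classifications"][key] = expected[role]
        ledger["genes"][symbol] = keys

    for symbol in ("SERPINA1", "ALDOB"):
        if symbol in ledger["genes"]:
            ledger["control_variants"][ledger["genes"][symbol]["P1"]] = "het"
    return kb, ledger


# ---------------------------------------------------------------------------
# per-sample scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    scenario: str
    gene: str
    sample_id: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ScenarioError(f"unknown scenario {self.scenario!r}")


@dataclass
class SampleBundle:
    spec: ScenarioSpec
    meta: SampleMeta
    calls: List[VariantCall]
    expected_status: str
    expected_events: List[dict] = field(default_factory=list)

    def expected(self) -> dict:
        return {
            "sample_id": self.meta.sample_id,
            "scenario": self.spec.scenario,
            "status": self.expected_status,
            "events": self.expected_events,
        }


def _depth(rng: np.random.Generator) -> int:
    return max(40, int(rng.lognormal(np.log(150.0), 0.25)))


def _qd(rng: np.random.Generator) -> float:
    return float(np.clip(rng.normal(15.0, 3.0), 5.0, 40.0))


def _call_from_key(
    key: VariantKey,
    genotype: str,
    rng: np.random.Generator,
    sample_id: str,
    depth: Optional[int] = None,
) -> VariantCall:
    dp = depth if depth is not None else _depth(rng)
    if genotype == "het":
        alt_ad = int(round(dp * float(rng.uniform(0.4, 0.6))))
    else:
        alt_ad = dp
    return VariantCall(
        chrom=key[0],
        pos=key[1],
        ref=key[2],
        alt=key[3],
        genotype=genotype,
        depth=dp,
        allele_depths=(dp - alt_ad, alt_ad),
        qd=round(_qd(rng), 2),
        sample_id=sample_id,
    )


def _off_panel_key(panel: Panel, rng: np.random.Generator, i: int) -> VariantKey:
    chrom = "2"
    toi = panel.toi
    floor = 1
    for iv in toi:
        if iv.chrom == chrom:
            floor = max(floor, iv.end)
    pos = floor + 1_000_000 + i * 997
    ref, alt = _snv(rng, chrom, pos)
    return (chrom, pos, ref, alt)


def make_sample(
    panel: Panel,
    kb_ledger: dict,
    spec: ScenarioSpec,
) -> SampleBundle:
    """Build one sample's call set for a triage scenario, plus the expected
    triage outcome. Background noise: two common benign variants from other
    genes, one off-panel call."""
    gene = panel.genes.get(spec.gene)
    if gene is None:
        raise ScenarioError(f"gene {spec.gene!r} not in panel")
    need = _SCENARIO_INHERITANCE.get(spec.scenario)
    if need is not None and gene.inheritance != need:
        raise ScenarioError(
            f"scenario {spec.scenario} needs a {need} gene, "
            f"{spec.gene} is {gene.inheritance}"
        )
    rng = _rng(spec.seed, "sample", spec.sample_id, spec.scenario)
    keys = kb_ledger["genes"][spec.gene]
    sid = spec.sample_id
    sex = "male" if spec.scenario == "hemi_XL_male" else "female"
    calls: List[VariantCall] = []
    events: List[dict] = []

    if spec.scenario == "carrier_AR":
        calls.append(_call_from_key(keys["P1"], "het", rng, sid))
    elif spec.scenario == "hom_AR":
        calls.append(_call_from_key(keys["P1"], "hom_alt", rng, sid))
        events.append({"gene": spec.gene, "mechanism": "homozygous", "n_variants": 1})
    elif spec.scenario == "compound_het_AR":
        calls.append(_call_from_key(keys["P1"], "het", rng, sid))
        calls.append(_call_from_key(keys["P2"], "het", rng, sid))
        events.append(
            {"gene": spec.gene, "mechanism": "possible_compound_het", "n_variants": 2}
        )
    elif spec.scenario == "dominant_AD":
        calls.append(_call_from_key(keys["P1"], "het", rng, sid))
        events.append({"gene": spec.gene, "mechanism": "dominant_het", "n_variants": 1})
    elif spec.scenario == "hemi_XL_male":
        # diploid callers emit 0/1 on male X; triage treats it as hemizygous
        calls.append(_call_from_key(keys["P1"], "het", rng, sid))
        events.append({"gene": spec.gene, "mechanism": "hemizygous", "n_variants": 1})
    elif spec.scenario == "xl_female_comp_het":
        calls.append(_call_from_key(keys["P1"], "het", rng, sid))
        calls.append(_call_from_key(keys["P2"], "het", rng, sid))
        events.append(
            {"gene": spec.gene, "mechanism": "possible_compound_het", "n_variants": 2}
        )
    elif spec.scenario == "vus_only":
        calls.append(_call_from_key(keys["VUS"], "het", rng, sid))
    elif spec.scenario == "conflicting":
        calls.append(_call_from_key(keys["CONFLICTING"], "het", rng, sid))
    elif spec.scenario == "off_panel":
        calls.append(_call_from_key(_off_panel_key(panel, rng, 0), "het", rng, sid))
    elif spec.scenario == "low_depth":
        calls.append(_call_from_key(keys["P1"], "hom_alt", rng, sid, depth=15))
    # "negative": no planted variant

    # background noise shared by every scenario
    others = [s for s in sorted(panel.genes) if s != spec.gene]
    noise_genes = [others[int(i)] for i in rng.choice(len(others), 2, replace=False)]
    for g in noise_genes:
        calls.append(
            _call_from_key(kb_ledger["genes"][g]["BENIGN_COMMON"], "het", rng, sid)
        )
    calls.append(_call_from_key(_off_panel_key(panel, rng, 1), "het", rng, sid))

    return SampleBundle(
        spec=spec,
        meta=SampleMeta(sample_id=sid, sex=sex),
        calls=calls,
        expected_status="review_required" if events else "auto_closed",
        expected_events=events,
    )


def default_scenario_plan(panel: Panel) -> List[Tuple[str, str]]:
    """One sample per scenario on a compatible roster gene."""
    ar, ad, xl = "SERPINA1", "ELN", "OTC"
    return [
        ("negative", ar),
        ("carrier_AR", ar),
        ("hom_AR", ar),
        ("compound_het_AR", "ALDOB"),
        ("dominant_AD", ad),
        ("hemi_XL_male", xl),
        ("xl_female_comp_het", xl),
        ("vus_only", ar),
        ("conflicting", ar),
        ("off_panel", ar),
        ("low_depth", "PAH"),
    ]


def make_control_sample(
    kb_ledger: dict, seed: int = 0, sample_id: str = "CTRL-H12"
) -> SampleBundle:
    """Internal control sample: both expected pathogenic control variants,
    heterozygous, at high depth, placed at plate position H12."""
    rng = _rng(seed, "control", sample_id)
    calls = [
        _call_from_key(key, genotype, rng, sample_id, depth=100)
        for key, genotype in sorted(kb_ledger["control_variants"].items())
    ]
    spec = ScenarioSpec("negative", "SERPINA1", sample_id, seed)
    return SampleBundle(
        spec=spec,
        meta=SampleMeta(sample_id=sample_id, sex="unknown", plate_position="H12"),
        calls=calls,
        # both control variants are single-het AR pathogenic: carriers,
        # so the control sample itself auto-closes
        expected_status="auto_closed",
        expected_events=[],
    )


# ---------------------------------------------------------------------------
# truth/test pairs for benchmarking
# ---------------------------------------------------------------------------


def make_truth_pair(
    panel: Panel,
    seed: int = 0,
    a_fp: int = 3,
    b_fn: int = 2,
    c_shared: int = 95,
    indel_fraction: float = 0.2,
) -> dict:
    """Generate a (test, truth) call-set pair with exactly ``a_fp`` test-only,
    ``b_fn`` truth-only and ``c_shared`` shared variants, all inside the
    panel targets with DP >= 31. Returns a dict with both call lists, the
    TOI/HCR region sets and the expected counts."""
    rng = _rng(seed, "truthpair")
    toi = panel.toi
    slots: List[Tuple[str, int]] = []  # (chrom, 1-based pos) with room for indels
    for iv in toi:
        for off in range(5, iv.length - 20, 9):
            slots.append((iv.chrom, iv.start + off + 1))
    total = a_fp + b_fn + c_shared
    if total > len(slots):
        raise ScenarioError(f"panel too small for {total} planted variants")
    chosen = rng.choice(len(slots), size=total, replace=False)

    def _variant(i: int, sample_id: str) -> VariantCall:
        chrom, pos = slots[int(i)]
        ref, alt = _snv(rng, chrom, pos)
        if rng.random() < indel_fraction:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                alt = ref + "".join(
                    BASES[int(rng.integers(0, 4))] for _ in range(size)
                )
            else:
                ref = ref + "".join(
                    BASES[int(rng.integers(0, 4))] for _ in range(size)
                )
        genotype = "het" if rng.random() < 0.7 else "hom_alt"
        dp = int(rng.integers(31, 201))
        ad = dp if genotype == "hom_alt" else dp // 2
        return VariantCall(
            chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=genotype,
            depth=dp, allele_depths=(dp - ad, ad), qd=round(_qd(rng), 2),
            sample_id=sample_id,
        )

    shared = [_variant(i, "shared") for i in chosen[:c_shared]]
    test_only = [_variant(i, "test") for i in chosen[c_shared:c_shared + a_fp]]
    truth_only = [_variant(i, "truth") for i in chosen[c_shared + a_fp:]]

    def _as(sample_id: str, vs: Sequence[VariantCall]) -> List[VariantCall]:
        from dataclasses import replace

        return [replace(v, sample_id=sample_id) for v in vs]

    return {
        "test": _as("TEST", shared) + _as("TEST", test_only),
        "truth": _as("TRUTH", shared) + _as("TRUTH", truth_only),
        "toi": toi,
        "hcr": toi.pad(25),
        "expected": {"tp": c_shared, "fp": a_fp, "fn": b_fn},
    }


# ---------------------------------------------------------------------------
# QC histories
# ---------------------------------------------------------------------------

# safe generation bands sit well inside the routine thresholds; failing
# bands sit decisively outside. Uniform safe bands also guarantee the
# IQR-derived PF_BASES fence falls below every safe draw.
_SAFE_BANDS = {
    "v1": {
        "PF_BASES": (4.0e9, 6.0e9),
        "Q30_pct": (92.0, 99.0),
        "TARGET_BASES_30X_pct": (96.0, 99.5),
        "MEAN_TARGET_COVERAGE": (150.0, 400.0),
        "SELECTED_BASES_pct": (55.0, 80.0),
        "SNP_REFERENCE_BIAS": (0.48, 0.54),
    },
    "v2": {
        "PF_BASES": (4.0e9, 6.0e9),
        "Q30_pct": (93.5, 99.0),
        "TARGET_BASES_30X_pct": (96.0, 99.5),
        "MEAN_TARGET_COVERAGE": (150.0, 400.0),
        "SELECTED_BASES_pct": (85.0, 95.0),
        "SNP_REFERENCE_BIAS": (0.48, 0.54),
    },
}

_FAIL_BANDS = {
    "v1": {
        "Q30_pct": (70.0, 80.0),
        "TARGET_BASES_30X_pct": (80.0, 90.0),
        "MEAN_TARGET_COVERAGE": (40.0, 80.0),
        "SELECTED_BASES_pct": (20.0, 35.0),
        "SNP_REFERENCE_BIAS": (0.60, 0.80),
    },
    "v2": {
        "Q30_pct": (80.0, 87.0),
        "TARGET_BASES_30X_pct": (80.0, 90.0),
        "MEAN_TARGET_COVERAGE": (40.0, 80.0),
        "SELECTED_BASES_pct": (55.0, 70.0),
        "SNP_REFERENCE_BIAS": (0.60, 0.80),
    },
}

#: which metric fails, weighted so the on-bait fraction dominates as in
#: routine operations
_FAIL_WEIGHTS = {
    "SELECTED_BASES_pct": 0.60,
    "MEAN_TARGET_COVERAGE": 0.15,
    "Q30_pct": 0.10,
    "TARGET_BASES_30X_pct": 0.10,
    "SNP_REFERENCE_BIAS": 0.05,
}


def make_qc_history(
    n_samples: int = 2600,
    failure_plan: Optional[Mapping[int, int]] = None,
    seed: int = 0,
    panel_version: str = "v1",
    batch_size: int = 96,
) -> Tuple[List[QCRecord], List[dict]]:
    """Generate a per-sample metric table with a planted failure plan
    ``{k_metrics_failed: n_samples}`` against the shipped fixed thresholds
    (PF_BASES never fails: its fence is derived). Returns records plus the
    expected verdicts."""
    failure_plan = dict(failure_plan or {})
    n_failing = sum(failure_plan.values())
    if n_failing > n_samples:
        raise ScenarioError("failure plan exceeds cohort size")
    rng = _rng(seed, "qc", panel_version)
    safe = _SAFE_BANDS[panel_version]
    fail = _FAIL_BANDS[panel_version]
    fail_metrics = list(_FAIL_WEIGHTS)
    weights = np.array([_FAIL_WEIGHTS[m] for m in fail_metrics])
    weights = weights / weights.sum()

    failing_idx = rng.choice(n_samples, size=n_failing, replace=False)
    plan_per_sample: Dict[int, int] = {}
    cursor = 0
    for k in sorted(failure_plan):
        for _ in range(failure_plan[k]):
            plan_per_sample[int(failing_idx[cursor])] = k
            cursor += 1

    records: List[QCRecord] = []
    expected: List[dict] = []
    base_date = np.datetime64("2022-01-03")
    for i in range(n_samples):
        batch = i // batch_size
        sample_id = f"S{i:05d}"
        metrics = {
            m: float(rng.uniform(lo, hi)) for m, (lo, hi) in safe.items()
        }
        k = plan_per_sample.get(i, 0)
        failed: List[str] = []
        if k:
            picked = rng.choice(len(fail_metrics), size=k, replace=False, p=weights)
            failed = [fail_metrics[int(j)] for j in picked]
            for m in failed:
                lo, hi = fail[m]
                metrics[m] = float(rng.uniform(lo, hi))
        records.append(
            QCRecord(
                sample_id=sample_id,
                batch_id=f"B{batch:03d}",
                run_date=str(base_date + 3 * batch),
                metrics=metrics,
            )
        )
        if any(m in VIP_METRICS for m in failed):
            status = "repeat"
        elif failed:
            status = "review"
        else:
            status = "pass"
        expected.append(
            {"sample_id": sample_id, "status": status,
             "failed_metrics": sorted(failed)}
        )
    return records, expected


# ---------------------------------------------------------------------------
# full bundles
# ---------------------------------------------------------------------------


def make_bundle(
    out_dir: PathLike,
    n_genes: int = 12,
    seed: int = 42,
    scenario_plan: Optional[Sequence[Tuple[str, str]]] = None,
    panel_version: str = "v1",
) -> dict:
    """Write a complete fixture bundle: panel TSV/BED, knowledge-base tables,
    per-sample VCFs (+ the H12 control), sample metadata, a QC metric table
    and a ground-truth JSON. Returns the ground truth as a dict."""
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)

    panel = make_panel(n_genes=n_genes, seed=seed, version=panel_version)
    write_panel(panel, out / "panel.tsv", out / "panel.bed")
    kb, ledger = make_kb(panel, seed=seed)
    kb.save(out / "assertions.tsv", out / "frequencies.tsv")

    plan = list(scenario_plan or default_scenario_plan(panel))
    bundles: List[SampleBundle] = []
    for i, (scenario, gene) in enumerate(plan):
        spec = ScenarioSpec(scenario, gene, f"NB{i:03d}", seed=seed + i)
        bundles.append(make_sample(panel, ledger, spec))
    control = make_control_sample(ledger, seed=seed)
    bundles.append(control)

    rows = ["sample_id\tsex\tplate_position\tbatch_id"]
    qc_records: List[QCRecord] = []
    rng = _rng(seed, "bundle-qc")
    safe = _SAFE_BANDS[panel_version]
    for i, b in enumerate(bundles):
        write_vcf(b.calls, out / "vcf" / f"{b.meta.sample_id}.vcf", b.meta.sample_id)
        plate = b.meta.plate_position or f"{'ABCDEFGH'[i % 8]}{i // 8 + 1}"
        rows.append(f"{b.meta.sample_id}\t{b.meta.sex}\t{plate}\tBATCH01")
        qc_records.append(
            QCRecord(
                sample_id=b.meta.sample_id,
                batch_id="BATCH01",
                run_date="2022-01-03",
                metrics={m: float(rng.uniform(lo, hi)) for m, (lo, hi) in safe.items()},
            )
        )
    (out / "samples.tsv").write_text("\n".join(rows) + "\n")
    from .qc import write_qc_table

    write_qc_table(qc_records, out / "metrics.tsv")

    control_expected = {
        "min_depth": 30,
        "variants": [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "genotype": g}
            for k, g in sorted(ledger["control_variants"].items())
        ],
    }
    (out / "control.json").write_text(json.dumps(control_expected, indent=2))

    truth = {
        "seed": seed,
        "panel_version": panel_version,
        "n_genes": len(panel),
        "control_sample": control.meta.sample_id,
        "samples": [b.expected() for b in bundles],
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return truth
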