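"""Variant interpretation decision tree for asymptomatic newborns.

Filters a sample's normalized calls in a fixed order — gene panel, caller
scope (SNVs and 1-15 bp indels only), depth/quality, population frequency
(with the frequent-gene exception), knowledge-base consensus — and then
resolves zygosity against each gene's inheritance mode:

* AR: report homozygotes and possible compound heterozygotes (two or more
  distinct heterozygous reportable variants, phase unknown); single-het
  carriers are never reported.
* AD: one reportable variant suffices, regardless of zygosity.
* XL: hemizygous in males for variants outside the pseudoautosomal regions
  (diploid callers often emit 0/1 on male X, so a het-called genotype
  counts); homozygous / possible compound het in females; unknown sex fails
  open to manual review.

Variants of uncertain significance are retained in a separate store —
recorded, never reported. Conflicting and not-in-database variants never
produce events. A sample with no events auto-closes; any event flags the
sample for manual review (and, operationally, a confirmation rerun).

Every input variant receives exactly one audit entry at the stage where its
fate was decided; filters short-circuit, so the entry names the first stage
that dropped it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .genomic_io import VariantCall, VariantKey, contains
from .intervals import IntervalSet
from .knowledge import (
    BENIGN_CONSENSUS,
    CONFLICTING,
    NOT_IN_DB,
    REPORTABLE_P_LP,
    VUS,
    ClassifyResult,
    KnowledgeBase,
    Panel,
    PanelGene,
)

_PLATE_RE = re.compile(r"^[A-H](1[0-2]|[1-9])$")

#: hg19 pseudoautosomal regions on X, 0-based half-open
HG19_PAR = IntervalSet.from_tuples(
    [("X", 60000, 2699520), ("X", 154931043, 155260560)]
)


def default_par() -> IntervalSet:
    return HG19_PAR


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    sex: str = "unknown"  # male | female | unknown
    plate_position: Optional[str] = None
    batch_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"bad sex {self.sex!r}")
        if self.plate_position is not None and not _PLATE_RE.match(self.plate_position):
            raise ValueError(f"bad plate position {self.plate_position!r}")


@dataclass
class TriageConfig:
    """Tunable filter parameters.

    ``dp_min`` mirrors the benchmark restriction (DP >= 30); ``qd_min`` 2.0
    follows common short-read caller practice; ``af_max`` 0.01 encodes the
    "<1 %" population-frequency rule (strict less-than).
    """

    dp_min: int = 30
    qd_min: float = 2.0
    af_max: float = 0.01
    par: IntervalSet = field(default_factory=default_par)


@dataclass(frozen=True)
class AuditEntry:
    key: VariantKey
    stage: str
    kept: bool
    reason: str
    genes: Tuple[str, ...] = ()

    def as_row(self) -> str:
        chrom, pos, ref, alt = self.key
        return "\t".join(
            [chrom, str(pos), ref, alt, self.stage,
             "kept" if self.kept else "dropped", self.reason,
             ",".join(self.genes) or "."]
        )


@dataclass
class ReportableEvent:
    gene: str
    mechanism: Optional[str]  # homozygous | possible_compound_het | dominant_het | hemizygous
    variants: List[VariantCall]
    classifications: Dict[VariantKey, ClassifyResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("event without variants")
        if self.mechanism == "possible_compound_het":
            distinct = {v.key for v in self.variants}
            if len(distinct) < 2:
                raise ValueError("compound het event needs >= 2 distinct variants")


@dataclass
class TriageResult:
    sample_id: str
    status: str  # auto_closed | review_required
    events: List[ReportableEvent]
    vus_store: List[VariantCall]
    audit: List[AuditEntry]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "status": self.status,
            "events": [
                {
                    "gene": e.gene,
                    "mechanism": e.mechanism,
                    "variants": [list(v.key) + [v.genotype] for v in e.variants],
                }
                for e in self.events
            ],
            "vus": [list(v.key) for v in self.vus_store],
            "n_audited": len(self.audit),
        }


@dataclass(frozen=True)
class _Annotated:
    call: VariantCall
    genes: Tuple[str, ...]


def _vkey(v: VariantCall) -> Tuple:
    return (v.chrom, v.pos, v.ref, v.alt, v.genotype)


# ---------------------------------------------------------------------------
# individual filter stages (each returns survivors + audit entries for drops)
# ---------------------------------------------------------------------------


def filter_panel(
    variants: Sequence[VariantCall], panel: Panel
) -> Tuple[List[_Annotated], List[AuditEntry]]:
    """Keep variants whose span lies inside some panel gene's regions,
    annotating each survivor with the owning gene(s)."""
    kept: List[_Annotated] = []
    audit: List[AuditEntry] = []
    for v in variants:
        genes = tuple(sorted(panel.genes_overlapping(v)))
        if genes:
            kept.append(_Annotated(v, genes))
            if len(genes) > 1:
                audit.append(AuditEntry(v.key, "panel", True, "ambiguous-gene", genes))
        else:
            audit.append(AuditEntry(v.key, "panel", False, "off-panel"))
    return kept, audit


def filter_scope(
    variants: Sequence[_Annotated],
) -> Tuple[List[_Annotated], List[AuditEntry]]:
    kept, audit = [], []
    for av in variants:
        if av.call.in_caller_scope:
            kept.append(av)
        else:
            audit.append(
                AuditEntry(av.call.key, "scope", False, "indel-over-15bp", av.genes)
            )
    return kept, audit


def filter_quality(
    variants: Sequence[_Annotated], dp_min: int, qd_min: float
) -> Tuple[List[_Annotated], List[AuditEntry]]:
    """Depth and quality-by-depth filter; missing annotations fail closed."""
    kept, audit = [], []
    for av in variants:
        v = av.call
        if v.depth is None:
            audit.append(AuditEntry(v.key, "quality", False, "no-DP", av.genes))
        elif v.depth < dp_min:
            audit.append(AuditEntry(v.key, "quality", False, "low-depth", av.genes))
        elif v.qd is None:
            audit.append(AuditEntry(v.key, "quality", False, "no-QD", av.genes))
        elif v.qd < qd_min:
            audit.append(AuditEntry(v.key, "quality", False, "low-QD", av.genes))
        else:
            kept.append(av)
    return kept, audit


def filter_frequency(
    variants: Sequence[_Annotated], panel: Panel, kb: KnowledgeBase, af_max: float
) -> Tuple[List[_Annotated], List[AuditEntry]]:
    """Drop common variants (AF >= af_max) unless the gene carries the
    frequent-gene flag; variants with no frequency record count as rare."""
    kept, audit = [], []
    for av in variants:
        af = kb.frequency(av.call.key)
        frequent = any(panel.genes[g].frequent_gene for g in av.genes if g in panel.genes)
        if af is None or af < af_max or frequent:
            kept.append(av)
        else:
            audit.append(
                AuditEntry(av.call.key, "frequency", False, f"common-af={af:g}", av.genes)
            )
    return kept, audit


def classify_stage(
    variants: Sequence[_Annotated], kb: KnowledgeBase
) -> Tuple[List[Tuple[_Annotated, ClassifyResult]], List[VariantCall], List[AuditEntry]]:
    """Knowledge-base consensus: reportable P/LP survive, VUS go to the
    retained-but-unreported store, everything else terminates here."""
    survivors: List[Tuple[_Annotated, ClassifyResult]] = []
    vus_store: List[VariantCall] = []
    audit: List[AuditEntry] = []
    for av in variants:
        res = kb.classify(av.call)
        if res.consensus == REPORTABLE_P_LP:
            survivors.append((av, res))
        elif res.consensus == VUS:
            vus_store.append(av.call)
            audit.append(
                AuditEntry(av.call.key, "classification", False, "vus-stored", av.genes)
            )
        else:
            reason = {
                BENIGN_CONSENSUS: "benign",
                NOT_IN_DB: "not-in-db",
                CONFLICTING: "conflicting-assertions",
            }[res.consensus]
            audit.append(
                AuditEntry(av.call.key, "classification", False, reason, av.genes)
            )
    return survivors, vus_store, audit


def resolve_zygosity(
    variants: Sequence[VariantCall],
    gene: PanelGene,
    meta: SampleMeta,
    par: IntervalSet,
    classifications: Optional[Dict[VariantKey, ClassifyResult]] = None,
) -> List[ReportableEvent]:
    """Apply the inheritance-mode reporting rules to one gene's reportable
    P/LP variants."""
    classifications = classifications or {}
    events: List[ReportableEvent] = []

    def _event(mechanism: Optional[str], vs: List[VariantCall]) -> None:
        events.append(
            ReportableEvent(
                gene=gene.symbol,
                mechanism=mechanism,
                variants=sorted(vs, key=_vkey),
                classifications={v.key: classifications.get(v.key) for v in vs},
            )
        )

    def _recessive(vs: Sequence[VariantCall]) -> None:
        for v in vs:
            if v.genotype == "hom_alt":
                _event("homozygous", [v])
        hets = {v.key: v for v in vs if v.genotype == "het"}
        if len(hets) >= 2:
            _event("possible_compound_het", list(hets.values()))

    if gene.inheritance == "AD":
        for v in sorted(variants, key=_vkey):
            _event("dominant_het", [v])
    elif gene.inheritance == "AR":
        _recessive(variants)
    elif gene.inheritance == "XL":
        if meta.sex == "male":
            for v in sorted(variants, key=_vkey):
                start, end = v.span
                if par.contains_span(v.chrom, start, end):
                    # pseudoautosomal: effectively diploid, recessive rules
                    continue
                _event("hemizygous", [v])
            par_vs = [
                v for v in variants if par.contains_span(v.chrom, *v.span)
            ]
            _recessive(par_vs)
        elif meta.sex == "female":
            _recessive(variants)
        else:
            # sex unknown on an X-linked gene: fail open to manual review
            for v in sorted(variants, key=_vkey):
                _event(None, [v])
    return events


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_decision_tree(
    variants: Sequence[VariantCall],
    panel: Panel,
    kb: KnowledgeBase,
    meta: SampleMeta,
    config: Optional[TriageConfig] = None,
) -> TriageResult:
    """Run the full decision tree on one sample's normalized calls."""
    config = config or TriageConfig()
    ordered = sorted(variants, key=_vkey)
    audit: List[AuditEntry] = []

    annotated, a = filter_panel(ordered, panel)
    audit.extend(a)
    annotated, a = filter_scope(annotated)
    audit.extend(a)
    annotated, a = filter_quality(annotated, config.dp_min, config.qd_min)
    audit.extend(a)
    annotated, a = filter_frequency(annotated, panel, kb, config.af_max)
    audit.extend(a)
    survivors, vus_store, a = classify_stage(annotated, kb)
    audit.extend(a)

    by_gene: Dict[str, List[Tuple[VariantCall, ClassifyResult]]] = {}
    for av, res in survivors:
        for g in av.genes:
            by_gene.setdefault(g, []).append((av.call, res))

    events: List[ReportableEvent] = []
    reported_keys = set()
    for g in sorted(by_gene):
        gene = panel.genes[g]
        calls = [v for v, _ in by_gene[g]]
        cls = {v.key: res for v, res in by_gene[g]}
        gene_events = resolve_zygosity(calls, gene, meta, config.par, cls)
        events.extend(gene_events)
        for e in gene_events:
            reported_keys.update(v.key for v in e.variants)

    # terminal audit entries for classification survivors
    for av, _res in survivors:
        if av.call.key in reported_keys:
            audit.append(
                AuditEntry(av.call.key, "zygosity", True, "reported", av.genes)
            )
        else:
            audit.append(
                AuditEntry(av.call.key, "zygosity", False, "carrier", av.genes)
            )

    status = "review_required" if events else "auto_closed"
    return TriageResult(
        sample_id=meta.sample_id,
        status=status,
        events=events,
        vus_store=vus_store,
        audit=audit,
    )


def write_audit(result: TriageResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tstage\tdecision\treason\tgenes\n")
        for entry in result.audit:
            fh.write(entry.as_row() + "\n")
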