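"""Gene panel and variant-classification knowledge base.

The panel models a targeted newborn-screening capture design: each gene has
one inheritance mode (autosomal recessive, autosomal dominant or X-linked),
a merged set of targeted regions (exons with ~50 bp intronic flanks) and an
optional *frequent gene* flag that bypasses the population-frequency filter
during triage.

Variant classifications are consumed, never computed: four local assertion
tables stand in for the laboratory's managed variant list (MVL) and for
ClinVar-style plus two auxiliary public classifiers. ACMG classes 4 and 5
map to {LP, P}. The consensus rule for reportability: the variant must be
asserted P or LP in the MVL or the ClinVar-like table, no consensus source
(ClinVar-like or either auxiliary) may dissent with a benign/likely-benign
assertion, and none may carry a conflicting assertion. A variant absent from
both the MVL and the ClinVar-like table is never reportable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .errors import FormatError, PanelError
from .genomic_io import PathLike, VariantCall, VariantKey, read_bed4
from .intervals import GenomicInterval, IntervalSet, union_all

INHERITANCE_MODES = ("AR", "AD", "XL")

#: source-level classifications (ACMG classes 5..1 plus an unresolved state)
CLASSIFICATIONS = ("P", "LP", "VUS", "LB", "B", "CONFLICTING")
PATHOGENIC = frozenset({"P", "LP"})
BENIGN = frozenset({"B", "LB"})

SOURCES = ("MVL", "CLINVAR", "AUX1", "AUX2")
#: sources participating in the three-way consensus check
CONSENSUS_SOURCES = ("CLINVAR", "AUX1", "AUX2")
#: sources whose P/LP assertion can initiate reporting
REPORTING_SOURCES = ("MVL", "CLINVAR")

# consensus outcomes
REPORTABLE_P_LP = "REPORTABLE_P_LP"
VUS = "VUS"
BENIGN_CONSENSUS = "BENIGN"
NOT_IN_DB = "NOT_IN_DB"
CONFLICTING = "CONFLICTING"


@dataclass
class PanelGene:
    symbol: str
    inheritance: str
    regions: IntervalSet
    frequent_gene: bool = False
    cnv_flagged: bool = False
    panel_version: str = "v1"

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise PanelError(f"{self.symbol}: bad inheritance {self.inheritance!r}")
        if not self.regions:
            raise PanelError(f"{self.symbol}: gene has no targeted regions")


@dataclass
class Panel:
    version: str
    genes: Dict[str, PanelGene]
    _toi: Optional[IntervalSet] = field(default=None, repr=False, compare=False)

    @property
    def toi(self) -> IntervalSet:
        """Union of all gene regions (the targets of interest)."""
        if self._toi is None:
            self._toi = union_all(g.regions for g in self.genes.values())
        return self._toi

    def __len__(self) -> int:
        return len(self.genes)

    def genes_overlapping(self, v: VariantCall) -> List[str]:
        start, end = v.span
        return [
            g.symbol
            for g in self.genes.values()
            if g.regions.contains_span(v.chrom, start, end)
        ]

    @property
    def cnv_flagged_fraction(self) -> float:
        if not self.genes:
            return 0.0
        return sum(g.cnv_flagged for g in self.genes.values()) / len(self.genes)


def _read_tsv(path: PathLike) -> List[Dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_panel(table_path: PathLike, bed_path: PathLike, version: str = "v1") -> Panel:
    """Build a Panel from a gene table (symbol, inheritance, frequent_gene
    [, cnv_flagged]) plus a BED4 region file whose name column carries the
    gene symbol. Every table gene must own at least one region and every BED
    region must reference a declared gene."""
    rows = _read_tsv(table_path)
    if not rows:
        raise FormatError(f"empty panel table: {table_path}")
    declared: Dict[str, Dict[str, str]] = {}
    for row in rows:
        sym = row.get("symbol", "").strip()
        if not sym:
            raise FormatError(f"{table_path}: missing gene symbol")
        if sym in declared:
            raise FormatError(f"{table_path}: duplicate gene symbol {sym}")
        declared[sym] = row
    regions: Dict[str, List[GenomicInterval]] = {s: [] for s in declared}
    for chrom, start, end, name in read_bed4(bed_path):
        if name not in declared:
            raise PanelError(f"{bed_path}: region gene {name!r} not in panel table")
        regions[name].append(GenomicInterval(chrom, start, end))
    genes: Dict[str, PanelGene] = {}
    for sym, row in declared.items():
        if not regions[sym]:
            raise PanelError(f"panel gene {sym} has no BED regions")
        genes[sym] = PanelGene(
            symbol=sym,
            inheritance=row["inheritance"].strip(),
            regions=IntervalSet(regions[sym]),
            frequent_gene=row.get("frequent_gene", "0").strip() in ("1", "true", "True"),
            cnv_flagged=row.get("cnv_flagged", "0").strip() in ("1", "true", "True"),
            panel_version=version,
        )
    return Panel(version=version, genes=genes)


def revise_panel(
    panel: Panel,
    remove: Sequence[str],
    add: Sequence[PanelGene],
    version: str = "v2",
) -> Panel:
    """Derive a redesigned panel: drop ``remove`` genes, add ``add`` genes.
    Resulting size is |panel| - |remove| + |add|."""
    missing = [s for s in remove if s not in panel.genes]
    if missing:
        raise PanelError(f"cannot remove absent genes: {missing}")
    genes = {s: g for s, g in panel.genes.items() if s not in remove}
    for g in add:
        if g.symbol in genes:
            raise PanelError(f"added gene {g.symbol} already in panel")
        genes[g.symbol] = g
    return Panel(version=version, genes=genes)


@dataclass(frozen=True)
class ClassifyResult:
    consensus: str
    per_source: Dict[str, str]


class KnowledgeBase:
    """Assertion tables plus population allele frequencies, keyed by the
    normalized variant key (chrom, pos, ref, alt)."""

    def __init__(
        self,
        assertions: Optional[Dict[VariantKey, Dict[str, str]]] = None,
        frequencies: Optional[Dict[VariantKey, float]] = None,
    ) -> None:
        self.assertions: Dict[VariantKey, Dict[str, str]] = assertions or {}
        self.frequencies: Dict[VariantKey, float] = frequencies or {}

    # -- construction -------------------------------------------------------

    def add_assertion(self, key: VariantKey, source: str, classification: str) -> None:
        if source not in SOURCES:
            raise FormatError(f"unknown assertion source {source!r}")
        if classification not in CLASSIFICATIONS:
            raise FormatError(f"unknown classification {classification!r}")
        self.assertions.setdefault(key, {})[source] = classification

    def add_frequency(self, key: VariantKey, af: float) -> None:
        if not 0.0 <= af <= 1.0:
            raise FormatError(f"allele frequency out of [0,1]: {af}")
        self.frequencies[key] = af

    @classmethod
    def load(
        cls, assertions_path: PathLike, frequencies_path: Optional[PathLike] = None
    ) -> "KnowledgeBase":
        """Load tab-delimited tables: assertions (chrom, pos, ref, alt,
        source, classification) and frequencies (chrom, pos, ref, alt, af)."""
        kb = cls()
        for row in _read_tsv(assertions_path):
            key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            kb.add_assertion(key, row["source"], row["classification"])
        if frequencies_path is not None:
            for row in _read_tsv(frequencies_path):
                key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
                kb.add_frequency(key, float(row["af"]))
        return kb

    def save(
        self, assertions_path: PathLike, frequencies_path: Optional[PathLike] = None
    ) -> None:
        with open(assertions_path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tsource\tclassification\n")
            for key in sorted(self.assertions):
                for source in SOURCES:
                    if source in self.assertions[key]:
                        fh.write(
                            "\t".join(
                                [key[0], str(key[1]), key[2], key[3], source,
                                 self.assertions[key][source]]
                            )
                            + "\n"
                        )
        if frequencies_path is not None:
            with open(frequencies_path, "w") as fh:
                fh.write("chrom\tpos\tref\talt\taf\n")
                for key in sorted(self.frequencies):
                    fh.write(
                        "\t".join(
                            [key[0], str(key[1]), key[2], key[3],
                             f"{self.frequencies[key]:.6g}"]
                        )
                        + "\n"
                    )

    # -- queries ------------------------------------------------------------

    def frequency(self, key: VariantKey) -> Optional[float]:
        return self.frequencies.get(key)

    def classify(self, v: Union[VariantCall, VariantKey]) -> ClassifyResult:
        """Consensus classification for a normalized variant.

        Pure function of the variant key and the loaded tables.
        """
        key = v.key if isinstance(v, VariantCall) else v
        per = dict(self.assertions.get(key, {}))
        if not any(s in per for s in REPORTING_SOURCES):
            return ClassifyResult(NOT_IN_DB, per)
        has_plp = any(per.get(s) in PATHOGENIC for s in REPORTING_SOURCES)
        dissent = any(per.get(s) in BENIGN for s in CONSENSUS_SOURCES)
        unresolved = any(per.get(s) == CONFLICTING for s in CONSENSUS_SOURCES)
        if has_plp:
            if dissent or unresolved:
                return ClassifyResult(CONFLICTING, per)
            return ClassifyResult(REPORTABLE_P_LP, per)
        if unresolved or per.get("MVL") == CONFLICTING:
            return ClassifyResult(CONFLICTING, per)
        if any(per.get(s) == "VUS" for s in REPORTING_SOURCES):
            return ClassifyResult(VUS, per)
        return ClassifyResult(BENIGN_CONSENSUS, per)
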