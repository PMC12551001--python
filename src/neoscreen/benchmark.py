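"""Truth-set comparison: TP/FP/FN, sensitivity, precision, concordance.

Both call sets are restricted to the targets of interest intersected with
the high-confidence regions, at a minimum depth of 30 reads; the depth
filter applies to truth records only when they carry a DP annotation (truth
sets frequently lack per-site depth). Matching is exact on the normalized
(chrom, pos, ref, alt) key *and* the genotype: a genotype mismatch at a
shared site counts as one FP plus one FN, with no half credit. This is a
deliberate desk-scale simplification relative to haplotype-aware comparison
engines; complex representation differences can therefore surface as paired
FP/FN.

Counts are stratified into SNPs (single-base ref and alt) and indels
(length difference 1-15 bp; longer events fall outside the caller's
validated scope and are excluded). Metrics: sensitivity TP/(TP+FN),
precision TP/(TP+FP), and pairwise concordance C/(A+B+C) where C is the
shared count and A/B the test-/truth-only counts. Undefined ratios (0/0)
are reported as absent, never coerced to 0 or 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .genomic_io import PathLike, VariantCall, contains
from .intervals import IntervalSet

STRATA = ("SNP", "INDEL", "ALL")


def stratum_of(v: VariantCall) -> str:
    return "SNP" if v.is_snp else "INDEL"


@dataclass(frozen=True)
class ComparisonCounts:
    tp: int
    fp: int
    fn: int
    stratum: str = "ALL"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("negative count")

    def __add__(self, other: "ComparisonCounts") -> "ComparisonCounts":
        return ComparisonCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, "ALL"
        )


def sensitivity(c: ComparisonCounts) -> Optional[float]:
    """TP/(TP+FN); absent when no truth variants exist."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else None


def precision(c: ComparisonCounts) -> Optional[float]:
    """TP/(TP+FP); absent when no test variants exist."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else None


def concordance(c: ComparisonCounts) -> Optional[float]:
    """C/(A+B+C) with C = shared (TP), A = test-only (FP), B = truth-only
    (FN); symmetric in the two samples."""
    denom = c.tp + c.fp + c.fn
    return c.tp / denom if denom else None


def restrict(
    calls: Sequence[VariantCall],
    toi: IntervalSet,
    hcr: IntervalSet,
    dp_min: int = 30,
    missing_depth_passes: bool = False,
) -> List[VariantCall]:
    """Keep calls inside toi intersect hcr with depth >= dp_min.

    ``missing_depth_passes`` retains records without a DP annotation (used
    for truth sets); test calls fail closed.
    """
    region = toi.intersect(hcr)
    kept = []
    for v in calls:
        if not contains(region, v):
            continue
        if v.depth is None:
            if missing_depth_passes:
                kept.append(v)
        elif v.depth >= dp_min:
            kept.append(v)
    return kept


def _dedup(calls: Sequence[VariantCall], label: str) -> List[VariantCall]:
    seen = set()
    out = []
    dupes = 0
    for v in calls:
        k = (v.key, v.genotype)
        if k in seen:
            dupes += 1
            continue
        seen.add(k)
        out.append(v)
    if dupes:
        warnings.warn(f"{label}: dropped {dupes} duplicate record(s)", stacklevel=3)
    return out


def match(
    test_calls: Sequence[VariantCall], truth_calls: Sequence[VariantCall]
) -> Dict[str, ComparisonCounts]:
    """Genotype-aware exact matching of two normalized, restricted call sets.

    Returns per-stratum counts; the ALL stratum is the component-wise sum of
    SNP and INDEL. Indels beyond the 15 bp scope are excluded entirely.
    """
    test = [v for v in _dedup(test_calls, "test") if v.in_caller_scope]
    truth = [v for v in _dedup(truth_calls, "truth") if v.in_caller_scope]
    truth_keys = {(v.key, v.genotype) for v in truth}
    test_keys = {(v.key, v.genotype) for v in test}
    counts = {s: [0, 0, 0] for s in ("SNP", "INDEL")}  # tp, fp, fn
    for v in test:
        s = stratum_of(v)
        if (v.key, v.genotype) in truth_keys:
            counts[s][0] += 1
        else:
            counts[s][1] += 1
    for v in truth:
        if (v.key, v.genotype) not in test_keys:
            counts[stratum_of(v)][2] += 1
    out = {
        s: ComparisonCounts(tp, fp, fn, s) for s, (tp, fp, fn) in counts.items()
    }
    out["ALL"] = out["SNP"] + out["INDEL"]
    return out


@dataclass
class ComparisonReport:
    counts: Dict[str, ComparisonCounts]
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def metrics(self) -> Dict[str, Dict[str, Optional[float]]]:
        return {
            s: {
                "sensitivity": sensitivity(c),
                "precision": precision(c),
                "concordance": concordance(c),
            }
            for s, c in self.counts.items()
        }

    def to_dict(self) -> dict:
        return {
            "counts": {
                s: {"tp": c.tp, "fp": c.fp, "fn": c.fn}
                for s, c in self.counts.items()
            },
            "metrics": self.metrics,
            "provenance": self.provenance,
        }

    def to_json(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compare(
    test_calls: Sequence[VariantCall],
    truth_calls: Sequence[VariantCall],
    toi: IntervalSet,
    hcr: IntervalSet,
    dp_min: int = 30,
) -> ComparisonReport:
    """Full comparison: region/depth restriction, genotype-aware matching,
    per-stratum metrics, with restriction provenance recorded."""
    test = restrict(test_calls, toi, hcr, dp_min, missing_depth_passes=False)
    truth = restrict(truth_calls, toi, hcr, dp_min, missing_depth_passes=True)
    counts = match(test, truth)
    return ComparisonReport(
        counts=counts,
        provenance={
            "dp_min": dp_min,
            "toi_bp": toi.total_length,
            "hcr_bp": hcr.total_length,
            "restricted_bp": toi.intersect(hcr).total_length,
            "n_test_restricted": len(test),
            "n_truth_restricted": len(truth),
        },
    )
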