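"""Sequencing QC: threshold derivation, sample verdicts, control monitoring.

Per-sample metrics (Picard CollectHsMetrics style) are checked against a
resolved threshold set. Thresholds are either fixed (the routine values:
Q30_pct >= 85 for panel v1 / 90 for v2, TARGET_BASES_30X_pct >= 93,
MEAN_TARGET_COVERAGE >= 100, SELECTED_BASES_pct >= 40 v1 / 78 v2,
SNP_REFERENCE_BIAS <= 0.56) or derived from historical runs as an IQR
fence: median -/+ 1.5 x IQR for lower/upper bounds. Quartiles use linear
interpolation between order statistics; a classical Tukey fence
(Q1/Q3 -/+ 1.5 x IQR) is available behind ``fence="tukey"``.

Three metrics are "very important" (VIP): Q30_pct, TARGET_BASES_30X_pct and
SNP_REFERENCE_BIAS. A VIP failure forces the whole wet+dry workflow to be
repeated for the sample (verdict ``repeat``); any other failure flags the
sample for ``review``; otherwise ``pass``. Boundary values pass: printed
thresholds are read as attainable minima/maxima.

The per-plate internal control sample (position H12) carries known
pathogenic variants in two genes; every batch verifies their presence,
genotype and depth, and a Levey-Jennings series tracks any monitored value
across batches with mean +/- 1/2/3 SD bands.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import FormatError, InsufficientHistoryError
from .genomic_io import PathLike, VariantCall, VariantKey

VIP_METRICS = ("Q30_pct", "TARGET_BASES_30X_pct", "SNP_REFERENCE_BIAS")

PERCENT_METRICS = {"Q30_pct", "TARGET_BASES_30X_pct", "SELECTED_BASES_pct"}


@dataclass
class QCRecord:
    sample_id: str
    batch_id: str
    run_date: str  # ISO-8601
    metrics: Dict[str, float]

    def __post_init__(self) -> None:
        for name, value in self.metrics.items():
            if name in PERCENT_METRICS and not 0.0 <= value <= 100.0:
                raise FormatError(f"{self.sample_id}: {name}={value} outside [0,100]")
            if name == "SNP_REFERENCE_BIAS" and not 0.0 <= value <= 1.0:
                raise FormatError(f"{self.sample_id}: {name}={value} outside [0,1]")
            if name == "PF_BASES" and value < 0:
                raise FormatError(f"{self.sample_id}: PF_BASES < 0")


@dataclass(frozen=True)
class MetricRule:
    metric: str
    direction: str  # lower_bound | upper_bound
    mode: str = "iqr_derived"  # fixed | iqr_derived
    fixed_value: Optional[float] = None
    vip: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("lower_bound", "upper_bound"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.mode not in ("fixed", "iqr_derived"):
            raise ValueError(f"bad mode {self.mode!r}")
        if self.mode == "fixed" and self.fixed_value is None:
            raise ValueError(f"{self.metric}: fixed rule without fixed_value")


#: routine metric rules per panel version; the registry is open — any metric
#: with a rule participates, unnamed metrics are configuration, not code.
DEFAULT_RULES: Dict[str, Tuple[MetricRule, ...]] = {
    "v1": (
        MetricRule("PF_BASES", "lower_bound", "iqr_derived"),
        MetricRule("Q30_pct", "lower_bound", "fixed", 85.0, vip=True),
        MetricRule("TARGET_BASES_30X_pct", "lower_bound", "fixed", 93.0, vip=True),
        MetricRule("MEAN_TARGET_COVERAGE", "lower_bound", "fixed", 100.0),
        MetricRule("SELECTED_BASES_pct", "lower_bound", "fixed", 40.0),
        MetricRule("SNP_REFERENCE_BIAS", "upper_bound", "fixed", 0.56, vip=True),
    ),
    "v2": (
        MetricRule("PF_BASES", "lower_bound", "iqr_derived"),
        MetricRule("Q30_pct", "lower_bound", "fixed", 90.0, vip=True),
        MetricRule("TARGET_BASES_30X_pct", "lower_bound", "fixed", 93.0, vip=True),
        MetricRule("MEAN_TARGET_COVERAGE", "lower_bound", "fixed", 100.0),
        MetricRule("SELECTED_BASES_pct", "lower_bound", "fixed", 78.0),
        MetricRule("SNP_REFERENCE_BIAS", "upper_bound", "fixed", 0.56, vip=True),
    ),
}


def derive_threshold(
    values: Sequence[float],
    direction: str,
    k: float = 1.5,
    min_n: int = 8,
    fence: str = "median",
) -> float:
    """IQR outlier fence from historical values.

    ``median`` fence: median -/+ k*IQR (the routine convention);
    ``tukey`` fence: Q1 - k*IQR / Q3 + k*IQR. Quartiles by linear
    interpolation. Duplicate samples should be excluded upstream.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < min_n:
        raise InsufficientHistoryError(
            f"need >= {min_n} values to derive a threshold, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise FormatError("non-finite value in threshold history")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    if fence == "median":
        lo, hi = med - k * iqr, med + k * iqr
    elif fence == "tukey":
        lo, hi = q1 - k * iqr, q3 + k * iqr
    else:
        raise ValueError(f"unknown fence {fence!r}")
    return float(lo if direction == "lower_bound" else hi)


@dataclass(frozen=True)
class Threshold:
    metric: str
    value: float
    direction: str
    vip: bool
    provenance: str  # "fixed" | "derived from n samples"

    def passes(self, value: Optional[float]) -> bool:
        if value is None or not math.isfinite(value):
            return False
        if self.direction == "lower_bound":
            return value >= self.value
        return value <= self.value


@dataclass
class ThresholdSet:
    panel_version: str
    thresholds: Dict[str, Threshold]

    def to_json(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "panel_version": self.panel_version,
                    "thresholds": {
                        m: {
                            "value": t.value,
                            "direction": t.direction,
                            "vip": t.vip,
                            "provenance": t.provenance,
                        }
                        for m, t in self.thresholds.items()
                    },
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: PathLike) -> "ThresholdSet":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            panel_version=data["panel_version"],
            thresholds={
                m: Threshold(m, d["value"], d["direction"], d["vip"], d["provenance"])
                for m, d in data["thresholds"].items()
            },
        )


def build_threshold_set(
    history: Sequence[QCRecord],
    rules: Sequence[MetricRule],
    panel_version: str,
    min_n: int = 8,
    fence: str = "median",
) -> ThresholdSet:
    """Resolve every rule to a concrete threshold: fixed rules use their
    shipped value, IQR-derived rules use the historical distribution."""
    thresholds: Dict[str, Threshold] = {}
    for rule in rules:
        if rule.mode == "fixed":
            thresholds[rule.metric] = Threshold(
                rule.metric, float(rule.fixed_value), rule.direction, rule.vip, "fixed"
            )
        else:
            values = [
                r.metrics[rule.metric] for r in history if rule.metric in r.metrics
            ]
            value = derive_threshold(values, rule.direction, min_n=min_n, fence=fence)
            thresholds[rule.metric] = Threshold(
                rule.metric, value, rule.direction, rule.vip,
                f"derived from {len(values)} samples",
            )
    return ThresholdSet(panel_version=panel_version, thresholds=thresholds)


@dataclass(frozen=True)
class MetricCheck:
    metric: str
    value: Optional[float]
    threshold: float
    direction: str
    vip: bool
    passed: bool


@dataclass
class SampleQCVerdict:
    sample_id: str
    checks: List[MetricCheck]
    status: str  # pass | review | repeat

    @property
    def failed_metrics(self) -> List[str]:
        return [c.metric for c in self.checks if not c.passed]


def evaluate_sample(record: QCRecord, thresholds: ThresholdSet) -> SampleQCVerdict:
    """Check every configured metric; a metric missing from the record fails.
    Any VIP failure -> repeat; any other failure -> review; else pass."""
    checks: List[MetricCheck] = []
    for metric, th in thresholds.thresholds.items():
        value = record.metrics.get(metric)
        checks.append(
            MetricCheck(metric, value, th.value, th.direction, th.vip, th.passes(value))
        )
    if any(not c.passed and c.vip for c in checks):
        status = "repeat"
    elif any(not c.passed for c in checks):
        status = "review"
    else:
        status = "pass"
    return SampleQCVerdict(record.sample_id, checks, status)


# ---------------------------------------------------------------------------
# internal control sample
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ControlVariantCheck:
    key: VariantKey
    found: bool
    genotype_match: bool
    depth: Optional[int]
    depth_ok: bool
    allele_depth_fraction: Optional[float]


@dataclass
class ControlCheck:
    batch_id: str
    variants: List[ControlVariantCheck]
    overall_pass: bool


def check_internal_control(
    calls: Sequence[VariantCall],
    expected: Mapping[VariantKey, str],
    min_depth: int = 30,
    batch_id: str = "",
) -> ControlCheck:
    """Verify that the control sample carries every expected variant with the
    expected genotype and sufficient depth."""
    by_key = {c.key: c for c in calls}
    results: List[ControlVariantCheck] = []
    for key, genotype in expected.items():
        call = by_key.get(key)
        if call is None:
            results.append(ControlVariantCheck(key, False, False, None, False, None))
            continue
        depth_ok = call.depth is not None and call.depth >= min_depth
        results.append(
            ControlVariantCheck(
                key=key,
                found=True,
                genotype_match=call.genotype == genotype,
                depth=call.depth,
                depth_ok=depth_ok,
                allele_depth_fraction=call.alt_fraction,
            )
        )
    overall = all(r.found and r.genotype_match and r.depth_ok for r in results)
    return ControlCheck(batch_id=batch_id, variants=results, overall_pass=overall)


# ---------------------------------------------------------------------------
# Levey-Jennings longitudinal series
# ---------------------------------------------------------------------------


@dataclass
class LeveyJenningsSeries:
    metric: str
    labels: List[str]
    values: List[float]
    mean: Optional[float]
    sd: Optional[float]
    flagged: List[str] = field(default_factory=list)

    def bands(self) -> Optional[Dict[str, Tuple[float, float]]]:
        if self.mean is None or self.sd is None:
            return None
        return {
            f"{k}sd": (self.mean - k * self.sd, self.mean + k * self.sd)
            for k in (1, 2, 3)
        }

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "labels": self.labels,
            "values": self.values,
            "mean": self.mean,
            "sd": self.sd,
            "bands": self.bands(),
            "flagged": self.flagged,
        }


def levey_jennings(
    points: Sequence[Tuple[str, float]],
    metric: str,
    window: Optional[int] = None,
) -> LeveyJenningsSeries:
    """Control-chart series ordered as given (callers sort by run date).

    Bands use the sample SD (ddof=1) over all points, or over the trailing
    ``window`` points when set; values beyond +/- 3 SD are flagged. A series
    of one point has no bands and flags nothing.
    """
    labels = [p[0] for p in points]
    values = [float(p[1]) for p in points]
    scope = values[-window:] if window else values
    if len(scope) < 2:
        return LeveyJenningsSeries(metric, labels, values, None, None, [])
    mean = float(np.mean(scope))
    sd = float(np.std(scope, ddof=1))
    flagged = [
        lab
        for lab, val in zip(labels, values)
        if sd > 0 and abs(val - mean) > 3 * sd
    ]
    return LeveyJenningsSeries(metric, labels, values, mean, sd, flagged)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_ID_COLUMNS = ("sample_id", "batch_id", "run_date")


def read_qc_table(path: PathLike) -> List[QCRecord]:
    """Read a tab-delimited metric table: sample_id, batch_id, run_date plus
    one numeric column per metric."""
    records: List[QCRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or any(
            c not in reader.fieldnames for c in _ID_COLUMNS
        ):
            raise FormatError(f"{path}: expected columns {_ID_COLUMNS} + metrics")
        for row in reader:
            metrics = {
                k: float(v)
                for k, v in row.items()
                if k not in _ID_COLUMNS and v not in (None, "", ".")
            }
            records.append(
                QCRecord(row["sample_id"], row["batch_id"], row["run_date"], metrics)
            )
    return records


def write_qc_table(records: Sequence[QCRecord], path: PathLike) -> None:
    metric_names: List[str] = []
    for r in records:
        for m in r.metrics:
            if m not in metric_names:
                metric_names.append(m)
    with open(path, "w") as fh:
        fh.write("\t".join(list(_ID_COLUMNS) + metric_names) + "\n")
        for r in records:
            row = [r.sample_id, r.batch_id, r.run_date] + [
                f"{r.metrics[m]:.6g}" if m in r.metrics else "." for m in metric_names
            ]
            fh.write("\t".join(row) + "\n")


def write_verdicts(verdicts: Sequence[SampleQCVerdict], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstatus\tfailed_metrics\n")
        for v in verdicts:
            fh.write(f"{v.sample_id}\t{v.status}\t{','.join(v.failed_metrics) or '.'}\n")
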