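"""Variant and region I/O plus representation normalization.

VCF positions are 1-based; everything else in the toolkit is 0-based
half-open. Multiallelic sites are decomposed into one record per called
alternate allele at read time, and every record is normalized (shared
right suffix trimmed, then shared left prefix trimmed down to the single
anchor base indels need) so that downstream matching and knowledge-base
lookups are representation-independent. Normalization is pure string
trimming: no reference FASTA is consulted, so left-alignment across
repeat tracts is out of scope.

Chromosome labels are harmonized at read time; the default convention
strips a leading ``chr``.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import pysam

from .errors import DegenerateVariantError, FormatError, MissingSampleError
from .intervals import GenomicInterval, IntervalSet, _chrom_sort_key

PathLike = Union[str, Path]

SEX_CHROMOSOMES = {"X", "Y"}

#: indel span (|len(ref) - len(alt)|) beyond which a call is flagged
#: out-of-scope for triage and benchmarking; the upstream caller is
#: validated for 1-15 bp indels only.
MAX_INDEL_BP = 15


def harmonize_chrom(chrom: str, style: str = "strip") -> str:
    """Harmonize chromosome naming. ``strip`` removes a leading 'chr',
    ``prefix`` ensures one, ``keep`` leaves labels untouched."""
    if style == "strip":
        return chrom[3:] if chrom.lower().startswith("chr") else chrom
    if style == "prefix":
        return chrom if chrom.lower().startswith("chr") else f"chr{chrom}"
    if style == "keep":
        return chrom
    raise ValueError(f"unknown chromosome naming style: {style!r}")


VariantKey = Tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantCall:
    """One normalized alternate-allele observation in one sample.

    ``pos`` is the 1-based VCF coordinate. ``depth`` (DP), ``allele_depths``
    (AD as ``(ref, alt)``) and ``qd`` (quality by depth) are ``None`` when the
    annotation is absent from the file — absent, not zero, so depth-based
    filters can fail closed.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # "het" | "hom_alt" | "hemi"
    depth: Optional[int] = None
    allele_depths: Optional[Tuple[int, int]] = None
    qd: Optional[float] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise DegenerateVariantError(
                f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}"
            )
        if self.genotype not in ("het", "hom_alt", "hemi"):
            raise ValueError(f"bad genotype {self.genotype!r}")
        if self.genotype == "hemi" and self.chrom not in SEX_CHROMOSOMES:
            raise ValueError(
                f"hemizygous call on non-sex chromosome {self.chrom!r}"
            )
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")

    # -- derived views ------------------------------------------------------

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_size(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def in_caller_scope(self) -> bool:
        """SNVs and 1-15 bp indels; longer events are retained in I/O but
        excluded from triage and benchmarking."""
        return self.is_snp or 1 <= self.indel_size <= MAX_INDEL_BP

    @property
    def span(self) -> Tuple[int, int]:
        """0-based half-open reference span affected by the call."""
        start = self.pos - 1
        return (start, start + len(self.ref))

    @property
    def alt_fraction(self) -> Optional[float]:
        if self.allele_depths is None:
            return None
        total = sum(self.allele_depths)
        return self.allele_depths[1] / total if total else None


def normalize_variant(v: VariantCall) -> VariantCall:
    """Trim shared right suffix, then shared left prefix (keeping one anchor
    base for indels), adjusting ``pos``. Idempotent."""
    ref, alt, pos = v.ref, v.alt, v.pos
    if ref == alt:
        raise DegenerateVariantError(f"degenerate variant at {v.chrom}:{v.pos}")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise DegenerateVariantError(f"degenerate variant at {v.chrom}:{v.pos}")
    if (ref, alt, pos) == (v.ref, v.alt, v.pos):
        return v
    return replace(v, ref=ref, alt=alt, pos=pos)


def contains(regions: IntervalSet, v: VariantCall) -> bool:
    """True iff the variant's reference-affected span lies fully inside
    ``regions``."""
    start, end = v.span
    return regions.contains_span(v.chrom, start, end)


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------


def _genotype_label(gt: Sequence[Optional[int]], alt_index: int, chrom: str) -> Optional[str]:
    called = [a for a in gt if a is not None]
    if alt_index not in called:
        return None
    if len(called) == 1:
        return "hemi" if chrom in SEX_CHROMOSOMES else "hom_alt"
    return "hom_alt" if called.count(alt_index) == len(called) else "het"


def read_vcf(
    path: PathLike,
    sample_id: str,
    chrom_style: str = "strip",
) -> List[VariantCall]:
    """Read one sample's calls, decomposed to one alternate per record and
    normalized.

    Records without a called alternate allele (0/0, ./.) yield nothing.
    Symbolic and spanning-deletion alternates are skipped. QD is taken from
    INFO, falling back to the sample FORMAT field; a missing QD stays
    ``None``.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read VCF {path}: {exc}") from exc
    calls: List[VariantCall] = []
    with vf:
        if sample_id not in list(vf.header.samples):
            raise MissingSampleError(f"sample {sample_id!r} not in {path}")
        try:
            for rec in vf:
                sample = rec.samples[sample_id]
                gt = sample.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                depth = sample.get("DP")
                ad = sample.get("AD")
                qd = rec.info.get("QD", None)
                if qd is None:
                    qd = sample.get("QD")
                if isinstance(qd, tuple):
                    qd = qd[0]
                chrom = harmonize_chrom(rec.chrom, chrom_style)
                alts = rec.alts or ()
                for i, alt in enumerate(alts, start=1):
                    if alt is None or alt == "*" or alt.startswith("<"):
                        continue
                    label = _genotype_label(gt, i, chrom)
                    if label is None:
                        continue
                    allele_depths = None
                    if ad is not None and len(ad) > i and ad[0] is not None and ad[i] is not None:
                        allele_depths = (int(ad[0]), int(ad[i]))
                    calls.append(
                        normalize_variant(
                            VariantCall(
                                chrom=chrom,
                                pos=rec.pos,
                                ref=rec.ref,
                                alt=alt,
                                genotype=label,
                                depth=int(depth) if depth is not None else None,
                                allele_depths=allele_depths,
                                # htslib stores Float as float32; round away
                                # the representation noise
                                qd=round(float(qd), 4) if qd is not None else None,
                                sample_id=sample_id,
                            )
                        )
                    )
        except (OSError, ValueError) as exc:
            raise FormatError(f"malformed VCF {path}: {exc}") from exc
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence by depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""

_GT_STRING = {"het": "0/1", "hom_alt": "1/1", "hemi": "1"}


def write_vcf(
    calls: Sequence[VariantCall],
    path: PathLike,
    sample_id: str,
    chrom_prefix: str = "chr",
) -> None:
    """Write single-sample VCF 4.2 text, sorted by position.

    Contig header lines are emitted for every chromosome present so the file
    parses under strict readers. Plain text only; compression is the caller's
    concern.
    """
    rows = sorted(calls, key=lambda v: (_chrom_sort_key(v.chrom), v.pos, v.ref, v.alt))
    chroms: List[str] = []
    for v in rows:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    chroms.sort(key=_chrom_sort_key)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={chrom_prefix}{c},length=250000000>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for v in rows:
            info = f"QD={v.qd:g}" if v.qd is not None else "."
            dp = str(v.depth) if v.depth is not None else "."
            ad = (
                f"{v.allele_depths[0]},{v.allele_depths[1]}"
                if v.allele_depths is not None
                else "."
            )
            fh.write(
                f"{chrom_prefix}{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t100\tPASS\t"
                f"{info}\tGT:DP:AD\t{_GT_STRING[v.genotype]}:{dp}:{ad}\n"
            )


# ---------------------------------------------------------------------------
# BED reading / writing
# ---------------------------------------------------------------------------


def _open_text(path: PathLike) -> io.TextIOBase:
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p, "r")


def _parse_bed_line(line: str, lineno: int, path: PathLike) -> Optional[List[str]]:
    line = line.rstrip("\n")
    if not line or line.startswith(("#", "track", "browser")):
        return None
    fields = line.split("\t")
    if len(fields) < 3:
        raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
    return fields


def read_bed(path: PathLike, chrom_style: str = "strip") -> IntervalSet:
    """Read a 3+ column BED file into a merged IntervalSet."""
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = _parse_bed_line(line, lineno, path)
            if fields is None:
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            intervals.append(
                GenomicInterval(harmonize_chrom(fields[0], chrom_style), start, end)
            )
    return IntervalSet(intervals)


def read_bed4(
    path: PathLike, chrom_style: str = "strip"
) -> List[Tuple[str, int, int, str]]:
    """Read a BED4 file keeping the name column (used for panel regions)."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = _parse_bed_line(line, lineno, path)
            if fields is None:
                continue
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED4 requires a name column")
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            rows.append(
                (harmonize_chrom(fields[0], chrom_style), start, end, fields[3])
            )
    return rows


def write_bed(
    intervals: IntervalSet,
    path: PathLike,
    chrom_prefix: str = "",
    names: Optional[dict] = None,
) -> None:
    """Write an IntervalSet as BED3 (or BED4 when ``names`` maps
    (chrom, start, end) -> label)."""
    with open(path, "w") as fh:
        for iv in intervals:
            row = f"{chrom_prefix}{iv.chrom}\t{iv.start}\t{iv.end}"
            if names is not None:
                row += f"\t{names.get((iv.chrom, iv.start, iv.end), '.')}"
            fh.write(row + "\n")
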