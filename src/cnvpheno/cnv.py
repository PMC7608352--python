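"""CNV call ingestion, per-sample QC and locus-deletion genotyping.

Coordinates are 1-based and inclusive at both ends (PennCNV convention), so
the length of an interval [start, end] is ``end - start + 1``.

A sample is genotyped as a deletion carrier when the union of its
copy-number-1 segments covers at least ``min_fraction`` (default 95%) of the
probe-bounded locus interval. The default locus is the 15q11.2 BP1-BP2
region between the outermost array probes covering NIPA1/NIPA2/CYFIP1/
TUBGCP5 on GRCh37: chr15:22,819,338-23,093,090.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

__all__ = [
    "BP1_BP2_LOCUS",
    "CNVCall",
    "SampleCNVStats",
    "GenomicInterval",
    "DeletionStatus",
    "QCResult",
    "CNVParseError",
    "parse_cnv_calls",
    "sample_qc",
    "detect_locus_deletion",
]


class CNVParseError(ValueError):
    """Malformed CNV call input; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _normalize_chrom(label: str) -> str:
    label = label.strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully closed genomic interval."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "chromosome", _normalize_chrom(self.chromosome))
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: Outermost array probes covering the four BP1-BP2 genes (GRCh37).
BP1_BP2_LOCUS = GenomicInterval("15", 22_819_338, 23_093_090)


@dataclass(frozen=True)
class CNVCall:
    """One copy-number segment called for one sample.

    ``copy_number`` 2 is diploid and therefore not a variant call; the
    parser rejects such lines.
    """

    sample_id: str
    chromosome: str
    start: int
    end: int
    copy_number: int
    n_probes: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "chromosome", _normalize_chrom(self.chromosome))
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


@dataclass(frozen=True)
class SampleCNVStats:
    """Per-sample QC metrics from genome-wide CNV calling."""

    sample_id: str
    waviness_factor: float
    n_cnvs: int

    def __post_init__(self):
        if self.n_cnvs < 0:
            raise ValueError("n_cnvs must be >= 0")


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str | None = None  # "waviness" or "cnv_count" when failed


@dataclass(frozen=True)
class DeletionStatus:
    """Locus genotype for one sample."""

    sample_id: str
    carrier: bool
    overlap_fraction: float
    anomaly: str | None = None  # "homozygous_deletion_at_locus"


# PennCNV rawcnv line, e.g.
# chr15:22819338-23093090  numsnp=50  length=273,753  state2,cn=1  S1  startsnp=rs1  endsnp=rs2
_RAWCNV_COORD = re.compile(r"^(?P<chrom>[\w]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")
_RAWCNV_STATE = re.compile(r"^state\d+,cn=(?P<cn>\d+)$")


def _parse_rawcnv_line(fields: list[str], lineno: int) -> CNVCall:
    if len(fields) < 5:
        raise CNVParseError(
            f"expected at least 5 whitespace-separated fields, got {len(fields)}", lineno
        )
    m = _RAWCNV_COORD.match(fields[0])
    if not m:
        raise CNVParseError(f"malformed coordinate field {fields[0]!r}", lineno)
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if start > end:
        raise CNVParseError(f"start {start} > end {end}", lineno)
    n_probes = None
    state_field = None
    sample = None
    for f in fields[1:]:
        if f.startswith("numsnp="):
            try:
                n_probes = int(f.split("=", 1)[1])
            except ValueError:
                raise CNVParseError(f"malformed numsnp field {f!r}", lineno) from None
        elif f.startswith("state"):
            state_field = f
        elif "=" not in f and sample is None:
            sample = f
    if state_field is None:
        raise CNVParseError("missing stateK,cn=N field", lineno)
    ms = _RAWCNV_STATE.match(state_field)
    if not ms:
        raise CNVParseError(f"malformed state/cn field {state_field!r}", lineno)
    cn = int(ms.group("cn"))
    if sample is None:
        raise CNVParseError("missing sample identifier field", lineno)
    if cn == 2:
        raise CNVParseError("copy_number 2 is diploid, not a variant call", lineno)
    return CNVCall(sample, m.group("chrom"), start, end, cn, n_probes)


def _parse_tsv(lines: Iterator[tuple[int, list[str]]]) -> Iterator[CNVCall]:
    header = None
    for lineno, fields in lines:
        if header is None:
            header = fields
            required = {"sample_id", "chromosome", "start", "end", "copy_number"}
            missing = required - set(header)
            if missing:
                raise CNVParseError(
                    f"missing required columns: {sorted(missing)}", lineno
                )
            continue
        row = dict(zip(header, fields))
        try:
            cn = int(row["copy_number"])
            start, end = int(row["start"]), int(row["end"])
        except (KeyError, ValueError) as exc:
            raise CNVParseError(f"malformed row: {exc}", lineno) from None
        if cn == 2:
            raise CNVParseError("copy_number 2 is diploid, not a variant call", lineno)
        if start > end:
            raise CNVParseError(f"start {start} > end {end}", lineno)
        n_probes = row.get("n_probes")
        yield CNVCall(
            row["sample_id"],
            row["chromosome"],
            start,
            end,
            cn,
            int(n_probes) if n_probes not in (None, "", "NA") else None,
        )


def parse_cnv_calls(
    stream: TextIO | Iterable[str], dialect: str = "penncnv_rawcnv"
) -> list[CNVCall]:
    """Parse CNV calls from text in the named dialect.

    Parameters
    ----------
    stream:
        Open text file or iterable of lines.
    dialect:
        ``"penncnv_rawcnv"`` for PennCNV whitespace-separated output, or
        ``"tsv"`` for a tab-separated file with header columns
        sample_id/chromosome/start/end/copy_number[/n_probes].

    Raises
    ------
    CNVParseError
        On any malformed line, naming the 1-based line number. Diploid
        (copy-number 2) records are rejected: they are not variant calls.
    """
    numbered = (
        (i, line.split()) for i, line in enumerate(stream, start=1) if line.strip()
    )
    if dialect == "penncnv_rawcnv":
        return [_parse_rawcnv_line(fields, lineno) for lineno, fields in numbered]
    if dialect == "tsv":
        numbered = (
            (i, line.rstrip("\n").split("\t"))
            for i, line in enumerate(stream, start=1)
            if line.strip()
        )
        return list(_parse_tsv(numbered))
    raise ValueError(f"unknown dialect {dialect!r}")


def sample_qc(
    stats: SampleCNVStats, wf_limit: float = 0.03, max_cnvs: int = 40
) -> QCResult:
    """Apply per-sample CNV-calling QC.

    A sample fails if its waviness factor lies strictly outside
    [-wf_limit, +wf_limit] or it carries strictly more than ``max_cnvs``
    genome-wide calls. Boundary values (waviness exactly +/-0.03, exactly 40
    CNVs) are retained: the exclusion rules are strict inequalities, chosen
    deliberately to keep high-CNV-burden samples in the cohort.
    """
    if abs(stats.waviness_factor) > wf_limit:
        return QCResult(False, "waviness")
    if stats.n_cnvs > max_cnvs:
        return QCResult(False, "cnv_count")
    return QCResult(True)


def _union_overlap_bp(
    calls: Iterable[CNVCall], locus: GenomicInterval, copy_number: int
) -> int:
    """Total bases of the locus covered by the union of calls at the given CN."""
    clipped = []
    for c in calls:
        if c.copy_number != copy_number or c.chromosome != locus.chromosome:
            continue
        s, e = max(c.start, locus.start), min(c.end, locus.end)
        if s <= e:
            clipped.append((s, e))
    if not clipped:
        return 0
    clipped.sort()
    total = 0
    cur_s, cur_e = clipped[0]
    for s, e in clipped[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def detect_locus_deletion(
    calls: list[CNVCall],
    locus: GenomicInterval = BP1_BP2_LOCUS,
    min_fraction: float = 0.95,
) -> DeletionStatus:
    """Genotype one sample's heterozygous deletion status at a locus.

    The overlap fraction is the length of the union of the sample's CN=1
    segments intersected with the locus, divided by the locus length
    (1-based inclusive arithmetic). The sample is a carrier when that
    fraction is at least ``min_fraction``. A CN=0 call overlapping the
    locus is flagged as a homozygous-deletion anomaly and the sample is not
    called a (heterozygous) carrier.

    All calls must belong to a single sample; an empty call list genotypes
    a sample with no variant calls (fraction 0, non-carrier) but yields an
    empty sample id.
    """
    samples = {c.sample_id for c in calls}
    if len(samples) > 1:
        raise ValueError(f"calls span multiple samples: {sorted(samples)}")
    sample_id = samples.pop() if samples else ""

    hom_bp = _union_overlap_bp(calls, locus, copy_number=0)
    if hom_bp > 0:
        frac = _union_overlap_bp(calls, locus, copy_number=1) / locus.length
        return DeletionStatus(sample_id, False, frac, "homozygous_deletion_at_locus")

    overlap = _union_overlap_bp(calls, locus, copy_number=1)
    frac = overlap / locus.length
    return DeletionStatus(sample_id, frac >= min_fraction, frac)
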