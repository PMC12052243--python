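"""SAM/BAM ingest, record filtering, and CIGAR segmentation.

Alignments are reduced to typed *segments* — match, insertion, deletion,
clip — each carrying dual (reference, read) half-open coordinates. Indels
shorter than ``min_svlen`` (default 50 bp, the conventional SV size floor)
are treated as alignment noise: they advance the corresponding cursor but
are fused into the surrounding match context instead of emitting a variant
segment.

All internal coordinates are 0-based half-open; SAM's 1-based ``POS`` is
converted on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple

import pysam

# CIGAR ops that consume the read / the reference
_READ_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")
_VALID_OPS = frozenset("MIDNSHP=X")

#: segment op codes: match 0, insertion 1, deletion 2, clip 3
OP_MATCH, OP_INS, OP_DEL, OP_CLIP = 0, 1, 2, 3

DEFAULT_MIN_SVLEN = 50


class CigarError(ValueError):
    """Malformed CIGAR string."""


@dataclass(frozen=True)
class CigarOp:
    kind: str  # one of MIDNSHP (= and X are normalized to M on ingest)
    length: int

    def __post_init__(self) -> None:
        if self.kind not in _VALID_OPS:
            raise CigarError(f"illegal CIGAR op {self.kind!r}")
        if self.length <= 0:
            raise CigarError(f"non-positive CIGAR length {self.length}")


@dataclass
class AlignmentRecord:
    """One SAM alignment, with the CIGAR parsed and =/X collapsed to M.

    ``pos`` is 0-based (converted from SAM's 1-based storage).
    """

    qname: str
    flag: int
    chrom: Optional[str]
    pos: int
    mapq: int
    cigar: List[CigarOp] = field(default_factory=list)

    @property
    def read_len(self) -> int:
        return sum(op.length for op in self.cigar if op.kind in _READ_OPS)

    @property
    def ref_span(self) -> int:
        return sum(op.length for op in self.cigar if op.kind in _REF_OPS)


@dataclass(frozen=True)
class Segment:
    """A typed alignment segment with dual half-open coordinates.

    Deletions consume reference only (``read_start == read_end``);
    insertions and clips consume read only (``ref_start == ref_end``).
    A match segment may have absorbed sub-threshold indels, so its read
    span can differ from its reference span; ``length`` is the reference
    span for matches and deletions, the read span for insertions/clips.
    """

    op_code: int
    length: int
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int


def parse_cigar(cigar: str) -> List[CigarOp]:
    """Parse a CIGAR string, normalizing ``=``/``X`` runs to ``M``."""
    if cigar in ("*", ""):
        return []
    ops: List[CigarOp] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        if not num:
            raise CigarError(f"CIGAR op {ch!r} without a length in {cigar!r}")
        kind = "M" if ch in "=X" else ch
        if kind not in _VALID_OPS:
            raise CigarError(f"illegal CIGAR op {ch!r} in {cigar!r}")
        length = int(num)
        if ops and ops[-1].kind == kind:
            ops[-1] = CigarOp(kind, ops[-1].length + length)
        else:
            ops.append(CigarOp(kind, length))
        num = ""
    if num:
        raise CigarError(f"trailing length in CIGAR {cigar!r}")
    return ops


_NUM2OP = "MIDNSHP=X"  # pysam integer op codes


def _record_from_pysam(aln: pysam.AlignedSegment) -> AlignmentRecord:
    if aln.cigartuples is None:
        cigar: List[CigarOp] = []
    else:
        cigar = parse_cigar(
            "".join(f"{ln}{_NUM2OP[op]}" for op, ln in aln.cigartuples)
        )
    return AlignmentRecord(
        qname=aln.query_name or "*",
        flag=aln.flag,
        chrom=aln.reference_name,
        pos=aln.reference_start if aln.reference_start >= 0 else 0,
        mapq=aln.mapping_quality,
        cigar=cigar,
    )


def read_alignments(
    path: str, region: Optional[str] = None
) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM/BAM file in coordinate order.

    ``region`` uses the samtools dialect (``chrom:start-end``, 1-based
    inclusive) and requires an index.
    """
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
            it = fh.fetch(region=region) if region else fh
            for aln in it:
                yield _record_from_pysam(aln)
    finally:
        pysam.set_verbosity(save)


def keep_record(rec: AlignmentRecord) -> bool:
    """Primary-alignment gate: drop unmapped (FLAG bit 4) and any record
    with FLAG >= 256 (secondary, supplementary, duplicate, QC-fail)."""
    return not (rec.flag & 4) and rec.flag < 256


def filter_records(
    records: Sequence[AlignmentRecord],
) -> List[AlignmentRecord]:
    return [r for r in records if keep_record(r)]


def segment_ops(
    record: AlignmentRecord, min_svlen: int = DEFAULT_MIN_SVLEN
) -> List[Segment]:
    """Decompose a filtered alignment into typed segments.

    I/D ops shorter than ``min_svlen`` advance their cursor but emit no
    segment; the match context around them is coalesced into a single
    match segment. S always emits a clip; H and P emit nothing; N
    consumes reference like an absorbed deletion (splice semantics are
    out of scope).
    """
    if min_svlen < 1:
        raise ValueError(f"min_svlen must be >= 1, got {min_svlen}")
    segs: List[Segment] = []
    ref = record.pos
    read = 0
    # pending coalesced match context: (ref_start, read_start) or None
    pending: Optional[Tuple[int, int]] = None

    def flush() -> None:
        nonlocal pending
        if pending is not None:
            rs, qs = pending
            if ref > rs or read > qs:
                segs.append(
                    Segment(OP_MATCH, ref - rs, rs, ref, qs, read)
                )
            pending = None

    for op in record.cigar:
        k, n = op.kind, op.length
        if k == "M":
            if pending is None:
                pending = (ref, read)
            ref += n
            read += n
        elif k == "D":
            if n >= min_svlen:
                flush()
                segs.append(Segment(OP_DEL, n, ref, ref + n, read, read))
            elif pending is None:
                pending = (ref, read)
            ref += n
        elif k == "I":
            if n >= min_svlen:
                flush()
                segs.append(Segment(OP_INS, n, ref, ref, read, read + n))
            elif pending is None:
                pending = (ref, read)
            read += n
        elif k == "N":
            # reference gap, never a variant segment
            if pending is None:
                pending = (ref, read)
            ref += n
        elif k == "S":
            flush()
            segs.append(Segment(OP_CLIP, n, ref, ref, read, read + n))
            read += n
        # H, P: no cursor movement on either sequence we track
    flush()
    return segs
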