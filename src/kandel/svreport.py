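"""VCF emission and benchmark scoring for deletion calls.

Scoring follows common SV-benchmarking practice: a predicted call
matches a truth deletion when both breakpoints agree within ``bp_tol``
(default 1000 bp) and the reciprocal overlap (overlap length divided by
the longer interval) is at least ``min_ro`` (default 0.7). Matching is
one-to-one and greedy by descending reciprocal overlap. Metrics are
reported overall and within the five standard length bins
[50,200), [200,500), [500,1000), [1000,5000), [5000, inf).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

LENGTH_BINS: Tuple[Tuple[float, float], ...] = (
    (50, 200),
    (200, 500),
    (500, 1000),
    (1000, 5000),
    (5000, float("inf")),
)


class ReferenceMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class SVCall:
    """A consensus deletion call, 0-based half-open."""

    chrom: str
    start: int
    end: int
    support: int = 1
    score: float = 1.0

    @property
    def svlen(self) -> int:
        return self.end - self.start


def bin_index(svlen: int) -> int:
    for i, (lo, hi) in enumerate(LENGTH_BINS):
        if lo <= svlen < hi:
            return i
    return 0  # svlen < 50 only arises from user-supplied call sets


@dataclass
class BinMetrics:
    """Per-bin counts: recall side bins by truth length (``tp``/``fn``),
    precision side by predicted length (``tp_pred``/``fp``)."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tp_pred: int = 0

    @property
    def precision(self) -> float:
        d = self.tp_pred + self.fp
        return self.tp_pred / d if d else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    per_bin: Dict[Tuple[float, float], BinMetrics]
    matches: List[Tuple[SVCall, SVCall]] = field(default_factory=list)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def summary(self) -> str:
        lines = [
            f"TP={self.tp} FP={self.fp} FN={self.fn}",
            f"precision={self.precision:.4f} recall={self.recall:.4f} "
            f"f1={self.f1:.4f}",
        ]
        for (lo, hi), bm in self.per_bin.items():
            hi_s = "inf" if hi == float("inf") else f"{hi:g}"
            lines.append(
                f"  [{lo:g},{hi_s}) P={bm.precision:.3f} "
                f"R={bm.recall:.3f} F1={bm.f1:.3f} "
                f"(tp={bm.tp} fp={bm.fp} fn={bm.fn})"
            )
        return "\n".join(lines)


def _reciprocal_overlap(a: SVCall, b: SVCall) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return ov / max(a.svlen, b.svlen)


def evaluate_calls(
    pred: Sequence[SVCall],
    truth: Sequence[SVCall],
    bp_tol: int = 1000,
    min_ro: float = 0.7,
) -> EvalResult:
    """Score predicted calls against a truth set.

    ``truth`` items only need chrom/start/end (``TruthSV`` works).
    Precision bins by predicted length, recall bins by truth length.
    """
    truth = sorted(
        (SVCall(t.chrom, t.start, t.end) for t in truth),
        key=lambda t: (t.chrom, t.start),
    )
    for a, b in zip(truth, truth[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                f"overlapping truth records at {a.chrom}:{a.start}-{a.end}"
            )
    pred = sorted(pred, key=lambda p: (p.chrom, p.start, p.end))

    pairs: List[Tuple[float, int, int, int]] = []
    for pi, p in enumerate(pred):
        for ti, t in enumerate(truth):
            if p.chrom != t.chrom:
                continue
            if abs(p.start - t.start) > bp_tol or abs(p.end - t.end) > bp_tol:
                continue
            ro = _reciprocal_overlap(p, t)
            if ro >= min_ro:
                pairs.append((ro, p.start, pi, ti))
    # greedy one-to-one: best reciprocal overlap first, ties leftmost
    pairs.sort(key=lambda x: (-x[0], x[1], x[2], x[3]))
    used_p: set = set()
    used_t: set = set()
    matches: List[Tuple[SVCall, SVCall]] = []
    for ro, _, pi, ti in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        matches.append((pred[pi], truth[ti]))

    per_bin = {b: BinMetrics() for b in LENGTH_BINS}
    for pi, p in enumerate(pred):
        if pi not in used_p:
            per_bin[LENGTH_BINS[bin_index(p.svlen)]].fp += 1
    for ti, t in enumerate(truth):
        if ti not in used_t:
            per_bin[LENGTH_BINS[bin_index(t.svlen)]].fn += 1
    for p, t in matches:
        per_bin[LENGTH_BINS[bin_index(p.svlen)]].tp_pred += 1
        per_bin[LENGTH_BINS[bin_index(t.svlen)]].tp += 1
    result = EvalResult(
        tp=len(matches),
        fp=len(pred) - len(matches),
        fn=len(truth) - len(matches),
        per_bin=per_bin,
        matches=matches,
    )
    return result


def write_vcf(
    calls: Sequence[SVCall], ref_lengths: Dict[str, int], path: str
) -> None:
    """Write calls as VCFv4.2 DEL records."""
    header = pysam.VariantHeader()
    header.add_line(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">'
    )
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End">')
    header.add_line(
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">'
    )
    header.add_line(
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,'
        'Description="Supporting reads">'
    )
    for name, length in ref_lengths.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    for c in calls:
        if c.chrom not in ref_lengths:
            raise ReferenceMismatchError(
                f"call chromosome {c.chrom!r} absent from reference"
            )
        if c.end > ref_lengths[c.chrom]:
            raise ReferenceMismatchError(
                f"call end {c.end} beyond {c.chrom} length "
                f"{ref_lengths[c.chrom]}"
            )
    # silence htslib's transient END=0 warning (END derives from SVLEN)
    verbosity = pysam.set_verbosity(0)
    try:
        with pysam.VariantFile(path, "w", header=header) as out:
            for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.end)):
                # padding-base convention for symbolic ALTs (VCF
                # standard); htslib derives END as POS + |SVLEN|
                rec = out.new_record(
                    contig=c.chrom, start=max(c.start - 1, 0),
                    alleles=("N", "<DEL>"),
                )
                rec.qual = round(100 * c.score)
                rec.info["SVTYPE"] = "DEL"
                rec.info["SVLEN"] = -c.svlen
                rec.info["SUPPORT"] = c.support
                out.write(rec)
    finally:
        pysam.set_verbosity(verbosity)


def read_vcf(path: str) -> List[SVCall]:
    out: List[SVCall] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            support = int(rec.info.get("SUPPORT", 1))
            score = (rec.qual or 100.0) / 100.0
            svlen = abs(int(rec.info["SVLEN"]))
            out.append(
                SVCall(rec.chrom, rec.stop - svlen, rec.stop, support, score)
            )
    return sorted(out, key=lambda c: (c.chrom, c.start, c.end))
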