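"""Synthetic long-read datasets with implanted deletions.

The generator produces a small multi-chromosome reference, implants
non-overlapping deletions (>= 50 bp, log-uniform lengths spanning the
five standard SV length bins), and emits long reads sampled from the
donor with *analytically computed* alignments: because the donor-to-
reference coordinate map is known exactly, every read crossing a
deletion junction carries the deletion as a single ``D`` CIGAR op of
exactly the implanted length, with no aligner in the loop. Sequencing
noise is injected as substitutions and small (< 50 bp) insertions and
deletions, so every >= 50 bp ``D`` op in the output corresponds to
exactly one truth deletion. Decoy records (secondary/supplementary
duplicates, unmapped reads) exercise downstream FLAG filtering.

Outputs are standard formats: FASTA (reference, donor), coordinate-
sorted SAM, truth VCFv4.2 plus a BED mirror.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX",
]


class ConfigurationError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


class ReferenceMismatchError(ValueError):
    pass


def chrom_name(i: int) -> str:
    return f"chr{_ROMAN[i]}" if i < len(_ROMAN) else f"chr{i + 1}"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate an ONT-like microbial benchmark: ~10 kb reads at
    30x depth with ~8% error split over substitutions and small indels,
    and 50 deletions with log-uniform lengths on [50, 20000] bp.
    """

    n_chroms: int = 2
    chrom_length: int = 1_200_000
    n_deletions: int = 50
    del_len_range: Tuple[int, int] = (50, 20_000)  # log-uniform
    coverage: float = 30.0
    read_len_median: int = 10_000
    read_len_sigma: float = 0.25  # lognormal shape
    read_len_range: Tuple[int, int] = (2_000, 15_000)
    sub_rate: float = 0.054
    small_ins_rate: float = 0.013
    small_del_rate: float = 0.013
    small_err_max_len: int = 20
    frac_clipped: float = 0.1
    clip_len_range: Tuple[int, int] = (20, 300)
    frac_secondary: float = 0.05
    frac_unmapped: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sub_rate", "small_ins_rate", "small_del_rate",
            "frac_clipped", "frac_secondary", "frac_unmapped",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not (1 <= self.small_err_max_len < 50):
            raise ConfigurationError(
                "small_err_max_len must be in [1, 50) so that noise ops "
                "never reach the SV size floor"
            )
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ConfigurationError("non-positive reference dimensions")
        if self.del_len_range[0] < 50:
            raise ConfigurationError("deletions must be >= 50 bp")
        if self.chrom_length <= 3 * self.del_len_range[1]:
            raise ConfigurationError(
                "chrom_length must exceed 3x the maximum deletion length"
            )
        if self.coverage <= 0:
            raise ConfigurationError("coverage must be positive")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True, order=True)
class TruthSV:
    """An implanted deletion, 0-based half-open on the reference."""

    chrom: str
    start: int
    end: int

    @property
    def svlen(self) -> int:
        return self.end - self.start


# A genome is an ordered mapping chrom -> uint8 array of ACGT codes.
Genome = Dict[str, np.ndarray]


def genome_to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def write_fasta(genome: Genome, path: str) -> None:
    records = [
        SeqRecord(Seq(genome_to_str(seq)), id=name, description="")
        for name, seq in genome.items()
    ]
    SeqIO.write(records, path, "fasta")


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def gen_reference(cfg: SimConfig) -> Genome:
    """Uniform-composition random reference, deterministic per seed."""
    rng = _rng(cfg, 0)
    return {
        chrom_name(i): rng.integers(0, 4, cfg.chrom_length, dtype=np.uint8)
        for i in range(cfg.n_chroms)
    }


def _draw_del_lengths(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.del_len_range
    u = rng.uniform(np.log(lo), np.log(hi), cfg.n_deletions)
    return np.exp(u).astype(np.int64)


def implant_deletions(
    ref: Genome, cfg: SimConfig
) -> Tuple[Genome, List[TruthSV]]:
    """Remove non-overlapping deletions from the reference.

    Deletions are spaced by at least twice the maximum read length (and
    kept one read length away from chromosome ends) so that no read can
    span two events and evaluation stays unambiguous.
    """
    rng = _rng(cfg, 1)
    lengths = _draw_del_lengths(cfg, rng)
    chroms = list(ref.keys())
    # balanced assignment: counts per chromosome differ by at most one
    assign = rng.permutation(cfg.n_deletions) % len(chroms)

    min_gap = 2 * cfg.read_len_range[1]
    margin = cfg.read_len_range[1]
    truth: List[TruthSV] = []
    donor: Genome = {}
    for ci, chrom in enumerate(chroms):
        lens = lengths[assign == ci]
        n = len(lens)
        L = len(ref[chrom])
        required = int(lens.sum()) + max(n - 1, 0) * min_gap + 2 * margin
        if n and required > L:
            raise PlacementError(
                f"cannot place {n} deletions totalling {int(lens.sum())} bp "
                f"on {chrom} ({L} bp) with gap {min_gap} and margin {margin}"
            )
        slack = L - required
        extras = np.sort(rng.uniform(0.0, max(slack, 0), n)).astype(np.int64)
        cum = 0
        chrom_truth: List[TruthSV] = []
        for i, ln in enumerate(lens):
            start = margin + int(extras[i]) + cum + i * min_gap
            chrom_truth.append(TruthSV(chrom, start, start + int(ln)))
            cum += int(ln)
        truth.extend(chrom_truth)
        if chrom_truth:
            keep = []
            prev = 0
            for t in chrom_truth:
                keep.append(ref[chrom][prev : t.start])
                prev = t.end
            keep.append(ref[chrom][prev:])
            donor[chrom] = np.concatenate(keep)
        else:
            donor[chrom] = ref[chrom].copy()
    truth.sort()
    return donor, truth


@dataclass
class SimRead:
    """One SAM record of the simulated dataset."""

    qname: str
    flag: int
    chrom: Optional[str]
    pos: int  # 0-based; ignored for unmapped
    mapq: int
    cigar: str
    seq: str


def _junction_map(
    truth: Sequence[TruthSV], chrom: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Donor-coordinate junction positions and deletion lengths."""
    events = [t for t in truth if t.chrom == chrom]
    pos, lens = [], []
    removed = 0
    for t in events:
        pos.append(t.start - removed)
        lens.append(t.svlen)
        removed += t.svlen
    return np.asarray(pos, dtype=np.int64), np.asarray(lens, dtype=np.int64)


def _mutate_block(
    block: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> Tuple[List[Tuple[str, int]], List[np.ndarray]]:
    """Apply small-indel + substitution noise to one aligned M block.

    Returns CIGAR ops (M/I/D only) and read-sequence chunks. The block
    consumes exactly ``len(block)`` reference bases regardless of noise.
    """
    m = len(block)
    block = block.copy()
    n_sub = rng.binomial(m, cfg.sub_rate) if cfg.sub_rate > 0 else 0
    if n_sub:
        at = rng.choice(m, size=n_sub, replace=False)
        block[at] = (block[at] + rng.integers(1, 4, n_sub)) % 4

    mean_len = (1 + cfg.small_err_max_len) / 2.0
    events: List[Tuple[int, int, str]] = []  # (offset, length, kind)
    for rate, kind in (
        (cfg.small_ins_rate, "I"),
        (cfg.small_del_rate, "D"),
    ):
        if rate <= 0 or m < 4:
            continue
        k = rng.poisson(m * rate / mean_len)
        if k:
            offs = rng.integers(1, m - 1, k)
            lens = rng.integers(1, cfg.small_err_max_len + 1, k)
            events.extend(zip(offs.tolist(), lens.tolist(), [kind] * k))
    events.sort()

    ops: List[Tuple[str, int]] = []
    chunks: List[np.ndarray] = []
    cur = 0
    for off, ln, kind in events:
        if off <= cur:
            continue
        if kind == "D" and off + ln >= m:
            continue
        ops.append(("M", off - cur))
        chunks.append(block[cur:off])
        if kind == "I":
            ops.append(("I", ln))
            chunks.append(rng.integers(0, 4, ln, dtype=np.uint8))
            cur = off
        else:
            ops.append(("D", ln))
            cur = off + ln
    if cur < m:
        ops.append(("M", m - cur))
        chunks.append(block[cur:])
    return ops, chunks


def _merge_ops(ops: List[Tuple[str, int]]) -> List[Tuple[str, int]]:
    out: List[Tuple[str, int]] = []
    for k, n in ops:
        if n <= 0:
            continue
        if out and out[-1][0] == k:
            out[-1] = (k, out[-1][1] + n)
        else:
            out.append((k, n))
    return out


def simulate_reads(
    donor: Genome,
    truth: Sequence[TruthSV],
    cfg: SimConfig,
) -> List[SimRead]:
    """Sample error-injected long reads with exact analytic CIGARs.

    Read count per chromosome targets ``coverage`` x donor length in
    total sequenced bases. Records are returned coordinate-sorted with
    secondary/supplementary decoys interleaved and unmapped decoys last.
    """
    rng = _rng(cfg, 2)
    reads: List[SimRead] = []
    lo_len, hi_len = cfg.read_len_range
    for chrom, dseq in donor.items():
        dlen = len(dseq)
        jpos, jlen = _junction_map(truth, chrom)
        target = cfg.coverage * dlen
        sequenced = 0
        idx = 0
        chrom_reads: List[SimRead] = []
        while sequenced < target:
            L = int(
                np.clip(
                    np.exp(rng.normal(np.log(cfg.read_len_median),
                                      cfg.read_len_sigma)),
                    lo_len, hi_len,
                )
            )
            L = min(L, dlen)
            s = int(rng.integers(0, dlen - L + 1))
            sequenced += L
            # optional soft clips at the ends (aligner-like truncation)
            cl = cr = 0
            if cfg.frac_clipped > 0 and rng.random() < cfg.frac_clipped:
                c = int(rng.integers(*cfg.clip_len_range))
                c = min(c, L // 4)
                if rng.random() < 0.5:
                    cl = c
                else:
                    cr = c
            a, b = s + cl, s + L - cr  # aligned donor interval
            # reference position of donor coordinate a
            pos = int(a + jlen[: np.searchsorted(jpos, a, side="right")].sum())
            ops: List[Tuple[str, int]] = []
            chunks: List[np.ndarray] = []
            if cl:
                ops.append(("S", cl))
                chunks.append(dseq[s : s + cl])
            prev = a
            lo_j = np.searchsorted(jpos, a, side="right")
            hi_j = np.searchsorted(jpos, b, side="left")
            for j in range(lo_j, hi_j):
                block_ops, block_chunks = _mutate_block(
                    dseq[prev : jpos[j]], cfg, rng
                )
                ops.extend(block_ops)
                chunks.extend(block_chunks)
                ops.append(("D", int(jlen[j])))
                prev = int(jpos[j])
            block_ops, block_chunks = _mutate_block(dseq[prev:b], cfg, rng)
            ops.extend(block_ops)
            chunks.extend(block_chunks)
            if cr:
                ops.append(("S", cr))
                chunks.append(dseq[s + L - cr : s + L])
            ops = _merge_ops(ops)
            seq = genome_to_str(np.concatenate(chunks))
            flag = 16 if rng.random() < 0.5 else 0
            chrom_reads.append(
                SimRead(
                    qname=f"read_{chrom}_{idx}",
                    flag=flag,
                    chrom=chrom,
                    pos=pos,
                    mapq=60,
                    cigar="".join(f"{n}{k}" for k, n in ops),
                    seq=seq,
                )
            )
            idx += 1
        # secondary / supplementary decoys: duplicates of primaries
        n_sec = int(round(cfg.frac_secondary * len(chrom_reads)))
        if n_sec:
            picks = rng.choice(len(chrom_reads), size=n_sec, replace=False)
            for j, pi in enumerate(sorted(picks.tolist())):
                src = chrom_reads[pi]
                decoy_flag = src.flag | (256 if j % 2 == 0 else 2048)
                chrom_reads.append(
                    SimRead(src.qname, decoy_flag, src.chrom, src.pos,
                            src.mapq, src.cigar, src.seq)
                )
        chrom_reads.sort(key=lambda r: r.pos)
        reads.extend(chrom_reads)
        # unmapped decoys
        n_un = int(round(cfg.frac_unmapped * idx))
        for j in range(n_un):
            seq = genome_to_str(rng.integers(0, 4, 1000, dtype=np.uint8))
            reads.append(
                SimRead(f"unmapped_{chrom}_{j}", 4, None, 0, 0, "*", seq)
            )
    mapped = [r for r in reads if r.chrom is not None]
    unmapped = [r for r in reads if r.chrom is None]
    order = {c: i for i, c in enumerate(donor)}
    mapped.sort(key=lambda r: (order[r.chrom], r.pos))
    return mapped + unmapped


def write_sam(
    reads: Sequence[SimRead], ref_lengths: Dict[str, int], path: str
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in ref_lengths.items()
        ],
    }
    names = list(ref_lengths)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.qname
            a.flag = r.flag
            if r.chrom is None:
                a.reference_id = -1
                a.reference_start = -1
            else:
                a.reference_id = names.index(r.chrom)
                a.reference_start = r.pos
                a.cigarstring = r.cigar
            a.mapping_quality = r.mapq
            a.query_sequence = r.seq
            out.write(a)


# ------------------------------------------------------------- truth I/O


def _vcf_header(ref_lengths: Dict[str, int]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    h.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">')
    h.add_line(
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">'
    )
    for name, length in ref_lengths.items():
        h.add_line(f"##contig=<ID={name},length={length}>")
    return h


def write_truth(
    truth: Sequence[TruthSV], ref_lengths: Dict[str, int], path: str,
    bed_path: Optional[str] = None,
) -> None:
    """Write truth deletions as VCFv4.2 (plus an optional BED mirror)."""
    for t in truth:
        if t.chrom not in ref_lengths:
            raise ReferenceMismatchError(
                f"truth chromosome {t.chrom!r} absent from reference"
            )
    header = _vcf_header(ref_lengths)
    # htslib warns about the transient END=0 between record creation and
    # the SVLEN assignment it derives END from; silence it
    verbosity = pysam.set_verbosity(0)
    try:
        with pysam.VariantFile(path, "w", header=header) as out:
            for t in sorted(truth):
                # symbolic-ALT records carry the padding base before the
                # event (VCF standard); htslib derives END = POS + |SVLEN|
                rec = out.new_record(
                    contig=t.chrom, start=max(t.start - 1, 0),
                    alleles=("N", "<DEL>"),
                )
                rec.info["SVTYPE"] = "DEL"
                rec.info["SVLEN"] = -t.svlen
                out.write(rec)
    finally:
        pysam.set_verbosity(verbosity)
    if bed_path:
        with open(bed_path, "w") as fh:
            for t in sorted(truth):
                fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")


def read_truth(path: str) -> List[TruthSV]:
    out: List[TruthSV] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            svlen = abs(int(rec.info["SVLEN"]))
            out.append(TruthSV(rec.chrom, rec.stop - svlen, rec.stop))
    return sorted(out)


# ------------------------------------------------------------ convenience


@dataclass
class SimDataset:
    cfg: SimConfig
    ref: Genome
    donor: Genome
    truth: List[TruthSV]
    reads: List[SimRead]

    @property
    def ref_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.ref.items()}


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Run the full generator pipeline in memory."""
    ref = gen_reference(cfg)
    donor, truth = implant_deletions(ref, cfg)
    reads = simulate_reads(donor, truth, cfg)
    return SimDataset(cfg, ref, donor, truth, reads)


def write_dataset(ds: SimDataset, outdir: str) -> Dict[str, str]:
    """Write FASTA/SAM/VCF/BED artifacts; returns the path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "ref": os.path.join(outdir, "ref.fasta"),
        "donor": os.path.join(outdir, "donor.fasta"),
        "sam": os.path.join(outdir, "reads.sam"),
        "vcf": os.path.join(outdir, "truth.vcf"),
        "bed": os.path.join(outdir, "truth.bed"),
    }
    write_fasta(ds.ref, paths["ref"])
    write_fasta(ds.donor, paths["donor"])
    write_sam(ds.reads, ds.ref_lengths, paths["sam"])
    write_truth(ds.truth, ds.ref_lengths, paths["vcf"], paths["bed"])
    return paths
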