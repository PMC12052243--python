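"""Consolidate per-node deletion evidence into consensus SV intervals.

Each read crossing a deletion contributes one candidate interval, so a
true event at 30x depth appears as ~30 near-identical candidates with
breakpoint jitter from sequencing error and alignment ambiguity. The
consolidation runs per chromosome:

1. density clustering (DBSCAN) of candidates as 3-vectors
   ``(svlen, start, end)`` under unscaled Euclidean distance;
2. a fragment-merging rule applied to candidates the first pass left as
   noise — adjacent fragments merge when the gap between them is below
   ``alpha`` (default 3000 bp) or their lengths agree within ``ratio``
   (default 0.7), the disjunctive gate being configurable to a
   conjunction;
3. secondary clustering of the merged fragments and a final conjunctive
   adjacency pass, so sub-clusters of one long fragmented event fuse
   into a single call while distinct events stay apart.

Each surviving group becomes one call with member-wise median
breakpoints, read support, and the mean classifier probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import DBSCAN

from .alignio import OP_DEL
from .hetgraph import ReadGraph
from .svreport import SVCall

DEFAULT_EPS = 500.0
DEFAULT_MIN_SAMPLES = 2
DEFAULT_ALPHA = 3000
DEFAULT_RATIO = 0.7
DEFAULT_MIN_SUPPORT = 2


@dataclass(frozen=True)
class CandidateSV:
    """One positive deletion node's reference interval."""

    chrom: str
    start: int
    end: int
    prob: float
    qname: str

    @property
    def svlen(self) -> int:
        return self.end - self.start


@dataclass
class Fragment:
    """A candidate group with a consensus or hull interval."""

    chrom: str
    start: int
    end: int
    members: List[CandidateSV]

    @property
    def svlen(self) -> int:
        return self.end - self.start


def extract_candidates(
    graphs: Sequence[ReadGraph],
    hard_labels: np.ndarray,
    probs: Optional[np.ndarray] = None,
) -> List[CandidateSV]:
    """One candidate per positive, deletion-typed, ref-side node.

    ``hard_labels``/``probs`` are concatenated over graphs in order
    (the classifier's output layout). Non-deletion nodes never emit a
    candidate regardless of their label.
    """
    out: List[CandidateSV] = []
    off = 0
    for g in graphs:
        for node in g.nodes:
            i = off + node.node_id
            if (
                hard_labels[i] == 1
                and node.op_code == OP_DEL
                and node.side == "ref"
            ):
                out.append(
                    CandidateSV(
                        g.chrom,
                        node.segment.ref_start,
                        node.segment.ref_end,
                        float(probs[i, 1]) if probs is not None else 1.0,
                        g.qname,
                    )
                )
        off += g.n_nodes
    out.sort(key=lambda c: (c.chrom, c.start, c.end))
    return out


def _dbscan_groups(
    cands: Sequence, eps: float, min_samples: int
) -> Tuple[List[List], List]:
    """DBSCAN over (svlen, start, end); returns (clusters, noise)."""
    pts = np.array([[c.svlen, c.start, c.end] for c in cands], dtype=float)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(pts)
    clusters: Dict[int, List] = {}
    noise: List = []
    for c, lab in zip(cands, labels):
        if lab < 0:
            noise.append(c)
        else:
            clusters.setdefault(int(lab), []).append(c)
    return [clusters[k] for k in sorted(clusters)], noise


def cluster_candidates(
    cands: Sequence[CandidateSV],
    eps: float = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> Tuple[List[List[CandidateSV]], List[CandidateSV]]:
    """Per-chromosome density clustering of candidate intervals."""
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    clusters: List[List[CandidateSV]] = []
    noise: List[CandidateSV] = []
    for chrom in sorted({c.chrom for c in cands}):
        sub = [c for c in cands if c.chrom == chrom]
        cl, nz = _dbscan_groups(sub, eps, min_samples)
        clusters.extend(cl)
        noise.extend(nz)
    return clusters, noise


def _should_merge(
    left_end: int, left_len: int, right: "Fragment | CandidateSV",
    alpha: int, ratio: float, mode: str,
) -> bool:
    gap = right.start - left_end
    lens = sorted((left_len, right.svlen))
    cond_gap = gap < alpha
    cond_len = lens[1] > 0 and lens[0] / lens[1] > ratio
    return (cond_gap or cond_len) if mode == "any" else (cond_gap and cond_len)


def merge_fragments(
    noise_cands: Sequence[CandidateSV],
    alpha: int = DEFAULT_ALPHA,
    ratio: float = DEFAULT_RATIO,
    mode: str = "any",
) -> List[Fragment]:
    """Merge adjacent unclustered fragments within a chromosome.

    A left-to-right scan accumulates fragments: the current hull merges
    the next fragment when the inter-fragment gap is below ``alpha``
    and/or the shorter-to-longer length ratio exceeds ``ratio``
    (``mode`` selects or/and). Merged fragments span the hull of their
    members.
    """
    if alpha <= 0 or not (0.0 < ratio < 1.0):
        raise ValueError("require alpha > 0 and 0 < ratio < 1")
    if mode not in ("any", "all"):
        raise ValueError(f"unknown merge mode {mode!r}")
    key = [(c.chrom, c.start) for c in noise_cands]
    if key != sorted(key):
        raise ValueError("noise candidates must be sorted by (chrom, start)")
    out: List[Fragment] = []
    for c in noise_cands:
        cur = out[-1] if out else None
        if (
            cur is not None
            and cur.chrom == c.chrom
            and _should_merge(cur.end, cur.svlen, c, alpha, ratio, mode)
        ):
            cur.end = max(cur.end, c.end)
            cur.start = min(cur.start, c.start)
            cur.members.append(c)
        else:
            out.append(Fragment(c.chrom, c.start, c.end, [c]))
    return out


def _merge_fragment_list(
    frags: List[Fragment], alpha: int, ratio: float, mode: str
) -> List[Fragment]:
    """Adjacency merge pass over already-built fragments."""
    frags = sorted(frags, key=lambda f: (f.chrom, f.start, f.end))
    out: List[Fragment] = []
    for f in frags:
        cur = out[-1] if out else None
        if (
            cur is not None
            and cur.chrom == f.chrom
            and _should_merge(cur.end, cur.svlen, f, alpha, ratio, mode)
        ):
            cur.start = min(cur.start, f.start)
            cur.end = max(cur.end, f.end)
            cur.members.extend(f.members)
        else:
            out.append(Fragment(f.chrom, f.start, f.end, list(f.members)))
    return out


def _consensus_fragment(members: List[CandidateSV]) -> Fragment:
    start = int(np.median([m.start for m in members]))
    end = int(np.median([m.end for m in members]))
    return Fragment(members[0].chrom, start, end, list(members))


def finalize_calls(
    clusters: Sequence[List[CandidateSV]],
    merged_fragments: Sequence[Fragment],
    min_support: int = DEFAULT_MIN_SUPPORT,
    eps: float = DEFAULT_EPS,
    alpha: int = DEFAULT_ALPHA,
    ratio: float = DEFAULT_RATIO,
) -> List[SVCall]:
    """Secondary clustering and call emission.

    First-pass clusters become median-consensus fragments; merged noise
    fragments are density-clustered once more (``min_samples=1`` — a
    lone merged hull is already consolidated evidence) and fused by
    hull. The union then passes through one conjunctive adjacency merge
    so sub-clusters of a single fragmented long event join. Calls with
    fewer than ``min_support`` distinct supporting reads are dropped.
    """
    frags: List[Fragment] = [
        _consensus_fragment(members) for members in clusters if members
    ]
    merged = list(merged_fragments)
    if merged:
        by_chrom: Dict[str, List[Fragment]] = {}
        for f in merged:
            by_chrom.setdefault(f.chrom, []).append(f)
        for chrom in sorted(by_chrom):
            groups, _ = _dbscan_groups(by_chrom[chrom], eps, 1)
            for grp in groups:
                frags.append(
                    Fragment(
                        chrom,
                        min(f.start for f in grp),
                        max(f.end for f in grp),
                        [m for f in grp for m in f.members],
                    )
                )
    frags = _merge_fragment_list(frags, alpha, ratio, mode="all")
    calls: List[SVCall] = []
    for f in frags:
        support = len({m.qname for m in f.members})
        if support < min_support:
            continue
        score = float(np.mean([m.prob for m in f.members]))
        calls.append(SVCall(f.chrom, f.start, f.end, support, score))
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    return calls


def consolidate(
    cands: Sequence[CandidateSV],
    eps: float = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    alpha: int = DEFAULT_ALPHA,
    ratio: float = DEFAULT_RATIO,
    mode: str = "any",
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> List[SVCall]:
    """Full candidate-to-call pipeline (cluster, merge, finalize)."""
    clusters, noise = cluster_candidates(cands, eps, min_samples)
    merged = merge_fragments(noise, alpha, ratio, mode)
    return finalize_calls(
        clusters, merged, min_support=min_support, eps=eps,
        alpha=alpha, ratio=ratio,
    )
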