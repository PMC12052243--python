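"""End-to-end stage wiring: SAM -> graphs -> predictions -> calls.

These helpers are what the CLI subcommands and the test/benchmark
harnesses call; each stage is importable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import alignio, hetgraph, svcluster
from .hetgraph import DEFAULT_LENGTH_SCALE, ReadGraph
from .model import DeletionNodeClassifier
from .simgen import TruthSV
from .svreport import SVCall


@dataclass
class StageStats:
    n_records: int = 0
    n_removed_flag: int = 0
    n_graphs: int = 0
    n_candidates: int = 0
    n_clusters: int = 0
    n_noise: int = 0
    n_calls: int = 0


def sam_to_graphs(
    path: str,
    min_svlen: int = alignio.DEFAULT_MIN_SVLEN,
    length_scale: float = DEFAULT_LENGTH_SCALE,
    region: Optional[str] = None,
    chroms: Optional[Sequence[str]] = None,
) -> Tuple[List[ReadGraph], StageStats]:
    """Read, FLAG-filter, segment and graph every primary alignment."""
    stats = StageStats()
    graphs: List[ReadGraph] = []
    for rec in alignio.read_alignments(path, region=region):
        stats.n_records += 1
        if not alignio.keep_record(rec):
            stats.n_removed_flag += 1
            continue
        if chroms is not None and rec.chrom not in chroms:
            continue
        segs = alignio.segment_ops(rec, min_svlen=min_svlen)
        if not segs:
            continue
        graphs.append(
            hetgraph.build_graph(
                segs, rec.chrom, rec.qname, length_scale=length_scale
            )
        )
    stats.n_graphs = len(graphs)
    return graphs, stats


def label_graphs(
    graphs: Sequence[ReadGraph],
    truth: Sequence[TruthSV],
    min_overlap: float = 0.5,
) -> List[ReadGraph]:
    return [hetgraph.label_nodes(g, truth, min_overlap) for g in graphs]


def call_graphs(
    graphs: Sequence[ReadGraph],
    model: DeletionNodeClassifier,
    eps: float = svcluster.DEFAULT_EPS,
    min_samples: int = svcluster.DEFAULT_MIN_SAMPLES,
    alpha: int = svcluster.DEFAULT_ALPHA,
    ratio: float = svcluster.DEFAULT_RATIO,
    mode: str = "any",
    min_support: int = svcluster.DEFAULT_MIN_SUPPORT,
    stats: Optional[StageStats] = None,
) -> Tuple[List[SVCall], List[svcluster.CandidateSV]]:
    """Classify nodes and consolidate positives into consensus calls."""
    if not graphs:
        return [], []
    probs = model.predict_proba(graphs)
    hard = (probs[:, 1] > probs[:, 0]).astype(np.int64)
    cands = svcluster.extract_candidates(graphs, hard, probs)
    clusters, noise = svcluster.cluster_candidates(cands, eps, min_samples)
    merged = svcluster.merge_fragments(noise, alpha, ratio, mode)
    calls = svcluster.finalize_calls(
        clusters, merged, min_support=min_support, eps=eps,
        alpha=alpha, ratio=ratio,
    )
    if stats is not None:
        stats.n_candidates = len(cands)
        stats.n_clusters = len(clusters)
        stats.n_noise = len(noise)
        stats.n_calls = len(calls)
    return calls, cands
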