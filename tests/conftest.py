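"""Shared fixtures: crafted SAM writing, random graphs, brute-force oracles."""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pysam
import pytest

from kandel.hetgraph import RELATIONS


def write_sam(
    path: str,
    records: Sequence[Tuple[str, int, str, int, str]],
    ref_lengths: Dict[str, int],
) -> str:
    """Write (qname, flag, chrom, pos0, cigar) tuples as a SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in ref_lengths.items()],
    }
    names = list(ref_lengths)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for qname, flag, chrom, pos, cigar in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.flag = flag
            if flag & 4:
                a.reference_id = -1
                a.reference_start = -1
            else:
                a.reference_id = names.index(chrom)
                a.reference_start = pos
                a.cigarstring = cigar
            a.mapping_quality = 60
            a.query_sequence = None
            out.write(a)
    return path


@pytest.fixture
def sam_writer():
    return write_sam


def random_multirelation_graph(
    rng: np.random.Generator, max_nodes: int = 20, d: int = 5
) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """A random feature matrix and random directed edges per relation."""
    n = int(rng.integers(1, max_nodes + 1))
    X = rng.normal(size=(n, d))
    edges = {}
    for rel in RELATIONS:
        m = int(rng.integers(0, 3 * n))
        edges[rel] = (
            rng.integers(0, n, size=(m, 2)).astype(np.int64)
            if m
            else np.zeros((0, 2), dtype=np.int64)
        )
    return X, edges


def rgcn_brute_force(
    H: np.ndarray,
    edges: Dict[str, np.ndarray],
    Wr: Dict[str, np.ndarray],
    W0: np.ndarray,
    b: np.ndarray | None = None,
) -> np.ndarray:
    """Per-node double-loop evaluation of the relational conv layer."""
    n = H.shape[0]
    out = np.zeros((n, W0.shape[1]))
    for i in range(n):
        acc = H[i] @ W0
        if b is not None:
            acc = acc + b
        for rel, E in edges.items():
            nbrs = [int(src) for src, dst in E if int(dst) == i]
            if not nbrs:
                continue
            msg = np.zeros(W0.shape[1])
            for j in nbrs:
                msg += H[j] @ Wr[rel]
            acc = acc + msg / len(nbrs)
        out[i] = np.maximum(acc, 0.0)
    return out


@pytest.fixture
def rgcn_oracle():
    return rgcn_brute_force


@pytest.fixture
def random_graph_factory():
    return random_multirelation_graph
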