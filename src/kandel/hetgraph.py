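"""Heterogeneous per-read graphs over alignment segments.

Each primary alignment becomes one small graph with two node classes:

* **read-side** nodes — one per segment, carrying read coordinates;
* **ref-side** nodes — one per reference-consuming segment (match,
  deletion), carrying reference coordinates anchored to the alignment
  start.

Three edge relations connect them: ``ref-ref`` chains consecutive
ref-side nodes in reference order, ``read-read`` chains consecutive
read-side nodes in read order, and ``ref-read`` joins the two copies of
each segment (insertion/clip nodes, which have no ref-side copy, attach
to the ref-side node of the nearest preceding reference-consuming
segment, or the following one at the left edge). Every relation is
stored as directed pairs in both directions; self-loops are implicit in
the classifier's self-weight term.

Node features are 6-vectors ``(v1, v2, v3, v4, start, end)``: a one-hot
over the four segment types scaled by segment length, plus the node's
(anchored) start/end coordinates; all six entries are multiplied by
``length_scale`` so genomic magnitudes do not swamp the feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alignio import OP_DEL, OP_MATCH, Segment

RELATIONS = ("ref-ref", "ref-read", "read-read")
DEFAULT_LENGTH_SCALE = 1e-3
N_FEATURES = 6


class GraphError(ValueError):
    pass


@dataclass
class SegmentNode:
    node_id: int
    side: str  # "ref" | "read"
    op_code: int
    feat: np.ndarray  # (6,)
    segment: Segment  # source segment (unscaled coordinates)


@dataclass
class ReadGraph:
    """Heterogeneous graph for one alignment."""

    chrom: str
    anchor: int  # alignment reference start (bp)
    qname: str
    nodes: List[SegmentNode]
    edges: Dict[str, List[Tuple[int, int]]]
    length_scale: float = DEFAULT_LENGTH_SCALE
    labels: Optional[np.ndarray] = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def feature_matrix(self) -> np.ndarray:
        if not self.nodes:
            return np.zeros((0, N_FEATURES))
        return np.stack([n.feat for n in self.nodes])


def _node_feat(
    op_code: int, length: int, start: int, end: int, scale: float
) -> np.ndarray:
    feat = np.zeros(N_FEATURES)
    feat[op_code] = length * scale
    feat[4] = start * scale
    feat[5] = end * scale
    return feat


def build_graph(
    segments: Sequence[Segment],
    chrom: str,
    qname: str,
    length_scale: float = DEFAULT_LENGTH_SCALE,
) -> ReadGraph:
    """Build the per-read heterogeneous graph from ordered segments."""
    if not segments:
        raise GraphError(f"no segments for read {qname!r}: empty graph")
    anchor = min(s.ref_start for s in segments)

    nodes: List[SegmentNode] = []
    edges: Dict[str, List[Tuple[int, int]]] = {r: [] for r in RELATIONS}
    ref_ids: List[int] = []  # ref-side node ids in reference order
    read_ids: List[int] = []
    # per segment index: id of its ref-side node, if any
    seg_ref_id: List[Optional[int]] = []

    for seg in segments:
        rid: Optional[int] = None
        if seg.op_code in (OP_MATCH, OP_DEL):
            rid = len(nodes)
            nodes.append(
                SegmentNode(
                    rid,
                    "ref",
                    seg.op_code,
                    _node_feat(
                        seg.op_code,
                        seg.length,
                        seg.ref_start - anchor,
                        seg.ref_end - anchor,
                        length_scale,
                    ),
                    seg,
                )
            )
            ref_ids.append(rid)
        seg_ref_id.append(rid)
        qid = len(nodes)
        nodes.append(
            SegmentNode(
                qid,
                "read",
                seg.op_code,
                _node_feat(
                    seg.op_code, seg.length, seg.read_start, seg.read_end,
                    length_scale,
                ),
                seg,
            )
        )
        read_ids.append(qid)

    def link(rel: str, a: int, b: int) -> None:
        edges[rel].append((a, b))
        edges[rel].append((b, a))

    for a, b in zip(ref_ids, ref_ids[1:]):
        link("ref-ref", a, b)
    for a, b in zip(read_ids, read_ids[1:]):
        link("read-read", a, b)

    for i, seg in enumerate(segments):
        rid = seg_ref_id[i]
        if rid is None:
            # insertion/clip: attach to nearest preceding ref-consuming
            # segment's ref node; at the left edge, the following one
            for j in range(i - 1, -1, -1):
                if seg_ref_id[j] is not None:
                    rid = seg_ref_id[j]
                    break
            else:
                for j in range(i + 1, len(segments)):
                    if seg_ref_id[j] is not None:
                        rid = seg_ref_id[j]
                        break
        if rid is not None:
            link("ref-read", rid, read_ids[i])

    return ReadGraph(chrom, anchor, qname, nodes, edges, length_scale)


def label_nodes(
    graph: ReadGraph, truth: Sequence, min_overlap: float = 0.5
) -> ReadGraph:
    """Attach 0/1 node labels from a truth deletion set.

    A node is positive iff it is deletion-typed and its reference
    interval has reciprocal overlap >= ``min_overlap`` with a truth
    deletion on the same chromosome; both the ref-side and read-side
    copies of that segment are labeled. ``truth`` items need ``chrom``,
    ``start``, ``end`` attributes.
    """
    intervals = [
        (t.start, t.end) for t in truth if t.chrom == graph.chrom
    ]
    labels = np.zeros(graph.n_nodes, dtype=np.int64)
    for node in graph.nodes:
        if node.op_code != OP_DEL:
            continue
        a, b = node.segment.ref_start, node.segment.ref_end
        for s, e in intervals:
            ov = min(b, e) - max(a, s)
            if ov > 0 and ov / max(b - a, e - s) >= min_overlap:
                labels[node.node_id] = 1
                break
    graph.labels = labels
    return graph


@dataclass
class GraphBatch:
    """Disjoint union of read graphs, ready for the classifier."""

    X: np.ndarray  # (N, 6) float
    edges: Dict[str, np.ndarray]  # relation -> (E, 2) int (src, dst)
    offsets: np.ndarray  # (n_graphs + 1,) node offset of each graph
    graphs: List[ReadGraph]
    labels: Optional[np.ndarray] = None  # (N,) or None

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    def node_slice(self, g: int) -> slice:
        return slice(int(self.offsets[g]), int(self.offsets[g + 1]))


def save_batch(batch: GraphBatch, path: str) -> None:
    """Serialize a batch to a JSON container (features, per-relation
    edge pairs, offsets, labels, per-graph provenance)."""
    import json

    blob = {
        "format": "kandel-graphbatch-v1",
        "X": batch.X.tolist(),
        "edges": {r: e.tolist() for r, e in batch.edges.items()},
        "offsets": batch.offsets.tolist(),
        "labels": None if batch.labels is None else batch.labels.tolist(),
        "graphs": [
            {
                "chrom": g.chrom,
                "anchor": g.anchor,
                "qname": g.qname,
                "length_scale": g.length_scale,
            }
            for g in batch.graphs
        ],
    }
    with open(path, "w") as fh:
        json.dump(blob, fh)


def load_batch(path: str) -> GraphBatch:
    """Load a batch written by :func:`save_batch`.

    Node-level metadata (source segments) is not serialized, so loaded
    batches support classification but not candidate extraction.
    """
    import json

    with open(path) as fh:
        blob = json.load(fh)
    offsets = np.asarray(blob["offsets"], dtype=np.int64)
    X = np.asarray(blob["X"], dtype=float)
    graphs = [
        ReadGraph(
            chrom=g["chrom"],
            anchor=g["anchor"],
            qname=g["qname"],
            nodes=[],
            edges={r: [] for r in RELATIONS},
            length_scale=g["length_scale"],
        )
        for g in blob["graphs"]
    ]
    labels = (
        None
        if blob["labels"] is None
        else np.asarray(blob["labels"], dtype=np.int64)
    )
    edges = {
        r: np.asarray(e, dtype=np.int64).reshape(-1, 2)
        for r, e in blob["edges"].items()
    }
    return GraphBatch(X, edges, offsets, graphs, labels)


def batch_graphs(graphs: Sequence[ReadGraph]) -> GraphBatch:
    """Stack graphs into one disjoint-union batch with node offsets."""
    if not graphs:
        raise ValueError("batch_graphs requires at least one graph")
    offsets = np.zeros(len(graphs) + 1, dtype=np.int64)
    for i, g in enumerate(graphs):
        offsets[i + 1] = offsets[i] + g.n_nodes
    X = np.concatenate([g.feature_matrix() for g in graphs], axis=0)
    edges: Dict[str, np.ndarray] = {}
    for rel in RELATIONS:
        pairs = [
            np.asarray(g.edges[rel], dtype=np.int64).reshape(-1, 2) + off
            for g, off in zip(graphs, offsets[:-1])
        ]
        edges[rel] = (
            np.concatenate(pairs, axis=0)
            if pairs
            else np.zeros((0, 2), dtype=np.int64)
        )
    labels = None
    if all(g.labels is not None for g in graphs):
        labels = np.concatenate([g.labels for g in graphs])
    scales = {g.length_scale for g in graphs}
    if len(scales) != 1:
        raise GraphError(f"mixed length scales in batch: {scales}")
    return GraphBatch(X, edges, offsets, list(graphs), labels)
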