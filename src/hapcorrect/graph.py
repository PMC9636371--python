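"""Partial-order variation graphs over window subreads.

The graph is a base-labeled DAG: nodes carry single nucleotides, edges mean
that two nucleotides appeared consecutively in at least one subread at that
position of the pile, and every subread is recorded as a path (one node per
read base).  The first sequence -- the target subread -- is laid down as a
linear backbone; each further sequence is aligned against the current graph
(banded semi-global DP over the topological order) and fused: matches reuse
existing nodes, mismatches and insertions create fresh nodes, deletions
connect across skipped nodes.

Nodes carry an approximate window coordinate (inherited from the backbone
or from the fusion context) used only to center the alignment band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._align import (NEG, OP_DEL, OP_INS, OP_MATCH, OP_MISMATCH,
                     build_csr_kernel, sg_align_kernel, sg_traceback_kernel)

_ENC_TABLE = np.full(256, -1, dtype=np.int8)
for _ch, _co in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
    _ENC_TABLE[ord(_ch)] = _co

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


@dataclass
class AlignScoring:
    """Semi-global alignment scores (free leading/trailing graph nodes)."""

    match: int = 3
    mismatch: int = -4
    gap: int = -4

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch and self.gap < 0):
            raise ValueError("require match > 0 > mismatch, gap")


DEFAULT_SCORING = AlignScoring()


@dataclass
class GraphAlignment:
    """A sequence-to-graph alignment: parallel op/node/qpos arrays.

    ``ops[k]`` is one of OP_MATCH/OP_MISMATCH (node consumed with a sequence
    base), OP_INS (sequence base only) or OP_DEL (node consumed without a
    base); ``nodes[k]`` is the graph node id or -1; ``qpos[k]`` the sequence
    position or -1.
    """

    ops: np.ndarray
    nodes: np.ndarray
    qpos: np.ndarray
    score: int

    def walk(self) -> np.ndarray:
        """Consumed graph nodes, in order (match, mismatch and deletion ops)."""
        return self.nodes[self.ops != OP_INS]


class VariationGraph:
    """Base-labeled DAG with per-read paths.

    Node ids are stable across pruning; removed nodes are tombstoned.
    ``paths`` maps read id to (node id array, per-node error probability
    array) -- the probabilities are the Phred-derived p_{r,v} (zero for
    FASTA input).
    """

    def __init__(self) -> None:
        self.base: List[int] = []
        self.pos: List[int] = []
        self.alive: List[bool] = []
        self.succ: List[set] = []
        self.pred: List[set] = []
        self.paths: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        self._topo_cache: Optional[List[int]] = None
        self._version = 0
        self._csr_cache: Optional[tuple] = None
        self._csr_version = -1

    # -- construction -------------------------------------------------------

    def add_node(self, base_code: int, pos: int) -> int:
        self.base.append(base_code)
        self.pos.append(pos)
        self.alive.append(True)
        self.succ.append(set())
        self.pred.append(set())
        self._topo_cache = None
        self._version += 1
        return len(self.base) - 1

    def add_edge(self, u: int, v: int) -> None:
        if v not in self.succ[u]:
            self.succ[u].add(v)
            self.pred[v].add(u)
            self._topo_cache = None
            self._version += 1

    def remove_edge(self, u: int, v: int) -> None:
        self.succ[u].discard(v)
        self.pred[v].discard(u)
        self._topo_cache = None
        self._version += 1

    def remove_isolated_nodes(self) -> List[int]:
        """Tombstone nodes without incident edges; returns their ids."""
        removed = []
        for v in range(len(self.base)):
            if self.alive[v] and not self.succ[v] and not self.pred[v]:
                self.alive[v] = False
                removed.append(v)
        if removed:
            self._topo_cache = None
            self._version += 1
        return removed

    # -- queries ------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return sum(self.alive)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for v, s in enumerate(self.succ) if self.alive[v])

    def edges(self) -> List[Tuple[int, int]]:
        out = []
        for u in range(len(self.base)):
            if self.alive[u]:
                out.extend((u, v) for v in sorted(self.succ[u]))
        return out

    def node_base(self, v: int) -> str:
        return _CODE_BASE[self.base[v]]

    def topo_order(self) -> List[int]:
        """Topological order (Kahn), deterministic: min node id first."""
        if self._topo_cache is None:
            order = self._csr()[0]
            self._topo_cache = [int(v) for v in order]
        return self._topo_cache

    def is_dag(self) -> bool:
        try:
            self.topo_order()
            return True
        except RuntimeError:
            return False

    # -- array export for the DP kernel -------------------------------------

    def _csr(self):
        """(order, rank, bases, pos, pred_ptr, pred_idx), cached per version."""
        if self._csr_cache is not None and self._csr_version == self._version:
            return self._csr_cache
        n = len(self.base)
        eu: List[int] = []
        ev: List[int] = []
        for u in range(n):
            if self.alive[u]:
                for v in self.succ[u]:
                    eu.append(u)
                    ev.append(v)
        eu_a = np.asarray(eu, dtype=np.int32)
        ev_a = np.asarray(ev, dtype=np.int32)
        alive = np.asarray(self.alive, dtype=np.uint8)
        bases_all = np.asarray(self.base, dtype=np.int8)
        pos_all = np.asarray(self.pos, dtype=np.int32)
        order, rank, bases, pos, pred_ptr, pred_idx = build_csr_kernel(
            n, alive, eu_a, ev_a, bases_all, pos_all)
        if order.size and order[0] == -1:
            raise RuntimeError("graph contains a cycle")
        self._csr_cache = (order, rank, bases, pos, pred_ptr, pred_idx)
        self._csr_version = self._version
        return self._csr_cache


def _encode_seq(seq: str) -> np.ndarray:
    codes = _ENC_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT letters")
    return codes


def align_to_graph(
    graph: VariationGraph,
    seq: str,
    scoring: AlignScoring = DEFAULT_SCORING,
    offset: int = 0,
    band: Optional[int] = None,
    prefer_ins: bool = False,
) -> GraphAlignment:
    """Optimal semi-global alignment of ``seq`` against the graph.

    ``offset`` is the sequence's start coordinate in window space (used to
    center the band); ``band=None`` computes the full, unbanded DP.  The
    sequence is consumed entirely; unconsumed graph prefix/suffix is free.
    ``prefer_ins`` resolves score ties toward insertions, pushing
    unaligned sequence to the walk ends.
    """
    m = len(seq)
    if m == 0:
        empty = np.empty(0, dtype=np.int8)
        return GraphAlignment(ops=empty,
                              nodes=np.empty(0, dtype=np.int32),
                              qpos=np.empty(0, dtype=np.int32), score=0)
    if graph.n_nodes == 0:
        return _all_insertion(seq, scoring)
    order, _rank, bases, pos, pred_ptr, pred_idx = graph._csr()
    sq = _encode_seq(seq)
    if band is None:
        lo = np.zeros(len(order), dtype=np.int32)
        W = m + 1
    else:
        lo = np.clip(pos - offset - band, 0, m).astype(np.int32)
        W = 2 * band + 2
    ma, mi, ga = (np.int16(scoring.match), np.int16(scoring.mismatch),
                  np.int16(scoring.gap))
    H, best_end, ei = sg_align_kernel(bases, pred_ptr, pred_idx, lo, W, sq,
                                      ma, mi, ga)
    all_ins_score = m * scoring.gap
    if ei < 0 and band is not None:
        # band missed the final column entirely; fall back to the full DP
        return align_to_graph(graph, seq, scoring, offset, band=None,
                              prefer_ins=prefer_ins)
    if ei < 0 or best_end < all_ins_score:
        return _all_insertion(seq, scoring)
    code, node_ranks, qpos = sg_traceback_kernel(
        H, bases, pred_ptr, pred_idx, lo, W, sq, ma, mi, ga, ei, prefer_ins)
    node_ids = np.full(node_ranks.size, -1, dtype=np.int32)
    sel = node_ranks >= 0
    node_ids[sel] = order[node_ranks[sel]]
    return GraphAlignment(ops=code, nodes=node_ids, qpos=qpos, score=int(best_end))


def _all_insertion(seq: str, scoring: AlignScoring) -> GraphAlignment:
    m = len(seq)
    return GraphAlignment(
        ops=np.full(m, OP_INS, dtype=np.int8),
        nodes=np.full(m, -1, dtype=np.int32),
        qpos=np.arange(m, dtype=np.int32),
        score=m * scoring.gap)


def _quals_to_p(seq_len: int, quals: Optional[Sequence[int]]) -> np.ndarray:
    if quals is None:
        return np.zeros(seq_len)
    q = np.asarray(quals, dtype=np.float64)
    if (q < 0).any():
        raise ValueError("negative Phred score")
    return np.minimum(1.0, 10.0 ** (-q / 10.0))


def fuse_sequence(
    graph: VariationGraph,
    read_id: str,
    seq: str,
    quals: Optional[Sequence[int]],
    aln: GraphAlignment,
    offset: int = 0,
) -> None:
    """Fuse an aligned sequence into the graph and record its path.

    Matches reuse the aligned node; mismatches and insertions create new
    nodes; deleted graph nodes are skipped (the read path connects across
    them).  All new edges point forward in topological order, so the DAG
    property is preserved by construction.
    """
    p = _quals_to_p(len(seq), quals)
    path_nodes: List[int] = []
    path_p: List[float] = []
    prev = -1
    for k in range(aln.ops.size):
        op = aln.ops[k]
        if op == OP_DEL:
            continue
        q = int(aln.qpos[k])
        if op == OP_MATCH:
            cur = int(aln.nodes[k])
        elif op == OP_MISMATCH:
            cur = graph.add_node(_BASE_CODE[seq[q]], graph.pos[int(aln.nodes[k])])
        else:  # OP_INS
            pos = graph.pos[prev] if prev >= 0 else offset + q
            cur = graph.add_node(_BASE_CODE[seq[q]], pos)
        if prev >= 0:
            graph.add_edge(prev, cur)
        path_nodes.append(cur)
        path_p.append(p[q])
        prev = cur
    graph.paths[read_id] = (np.asarray(path_nodes, dtype=np.int32),
                            np.asarray(path_p))


def poa_build(
    sequences: Sequence[Tuple[str, str, Optional[Sequence[int]], int]],
    scoring: AlignScoring = DEFAULT_SCORING,
    band: Optional[int] = None,
) -> VariationGraph:
    """Progressively build a variation graph from (id, seq, quals, offset).

    The first sequence (the target subread, offset 0) becomes the linear
    backbone; the rest are fused in the given order.  Empty sequences are
    skipped.
    """
    if not sequences:
        raise ValueError("poa_build needs at least one sequence")
    graph = VariationGraph()
    first = True
    for rid, seq, quals, offset in sequences:
        if not seq:
            continue
        if first:
            p = _quals_to_p(len(seq), quals)
            prev = -1
            nodes = []
            for i, ch in enumerate(seq):
                cur = graph.add_node(_BASE_CODE[ch], offset + i)
                if prev >= 0:
                    graph.add_edge(prev, cur)
                nodes.append(cur)
                prev = cur
            graph.paths[rid] = (np.asarray(nodes, dtype=np.int32), p)
            first = False
            continue
        aln = align_to_graph(graph, seq, scoring, offset=offset, band=band)
        fuse_sequence(graph, rid, seq, quals, aln, offset=offset)
    return graph


def extract_path_sequence(graph: VariationGraph, aln: GraphAlignment) -> str:
    """Spell the graph walk of an alignment.

    Consumed nodes (matches, mismatches, deletions) contribute their graph
    base; sequence insertions contribute nothing.  Aligning an erroneous
    subread against a clean graph therefore yields the clean sequence.
    """
    walk = aln.walk()
    for k in range(walk.size - 1):
        u, v = int(walk[k]), int(walk[k + 1])
        if v not in graph.succ[u]:
            raise ValueError(f"alignment walk uses missing edge ({u},{v})")
    return "".join(graph.node_base(int(v)) for v in walk)


def heaviest_bundle(
    graph: VariationGraph,
    edge_weights: Dict[Tuple[int, int], float],
) -> str:
    """Maximum-weight source-to-sink path (consensus) by DP over topo order.

    Edge weights default to 0 for edges missing from ``edge_weights``.
    Deterministic: ties resolve to the predecessor encountered first in
    ascending node id.  Returns the concatenated bases of the best path;
    empty graph gives the empty string.
    """
    order = graph.topo_order()
    if not order:
        return ""
    best: Dict[int, float] = {}
    back: Dict[int, int] = {}
    for v in order:
        preds = sorted(graph.pred[v])
        if not preds:
            best[v] = 0.0
            back[v] = -1
            continue
        b = -float("inf")
        bk = preds[0]
        for u in preds:
            cand = best[u] + edge_weights.get((u, v), 0.0)
            if cand > b:
                b, bk = cand, u
        best[v] = b
        back[v] = bk
    # best sink
    sinks = [v for v in order if not graph.succ[v]]
    end = max(sinks, key=lambda v: (best[v], -v))
    path = []
    v = end
    while v != -1:
        path.append(v)
        v = back[v]
    path.reverse()
    return "".join(graph.node_base(v) for v in path)
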