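"""Frequent-itemset pruning of variation graphs.

Reads are baskets, nodes are items, edges are the 2-itemsets of interest.
For a node v covered by reads R(v), the node weight
``w(v) = sum_{r in R(v)} (1 - p_{r,v})`` is the expected number of reads
covering it, with p_{r,v} the Phred-derived error probability (0 for FASTA
input, so weights are exact read counts).  For an edge e = (v_i, v_j),

    w(e)          = sum_{r in R(e)} (1 - p_{r,v_i}/2 - p_{r,v_j}/2)
    Support(e)    = w(e)
    Confidence(e) = max( w(e) / sum_{v' in S(v_i)} w(v_i, v'),
                         w(e) / sum_{v' in P(v_j)} w(v', v_j) )

The edge-weight sum is the fast approximation of the exact product
(1-p_i)(1-p_j); for FASTA input it equals the traversal count exactly.
Edges with Support < s or Confidence < c are pruned (strict inequality:
edges exactly at threshold survive), where s = s_factor * C and
C = sum_v w(v) / L is the average per-position coverage of the window.
After each pruning round all window subreads are realigned against the
smaller graph -- read-only, never adding nodes or edges -- and the
statistics are recomputed from the new paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._align import OP_INS
from .graph import (AlignScoring, DEFAULT_SCORING, GraphAlignment,
                    VariationGraph, align_to_graph)


@dataclass
class PruneConfig:
    """Pruning thresholds.

    ``c``: confidence threshold.  ``s_factor``: support threshold as a
    fraction of the window's average per-position coverage C.  ``L``: the
    window length used for the coverage normalization (set per window).
    """

    c: float = 0.2
    s_factor: float = 0.2
    iterations: int = 3
    L: int = 500

    def __post_init__(self) -> None:
        if not (0.0 < self.c < 1.0 and 0.0 < self.s_factor < 1.0):
            raise ValueError("c and s_factor must be in (0,1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


# ---------------------------------------------------------------------------
# elementary statistics (the per-node / per-edge definitions)

def node_weight(p_values: Sequence[float]) -> float:
    """w(v) = sum over covering reads of (1 - p_{r,v})."""
    total = 0.0
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"error probability {p} outside [0,1]")
        total += 1.0 - p
    return total


def edge_weight(p_pairs: Sequence[Tuple[float, float]]) -> float:
    """w(e) = sum over covering reads of (1 - p_i/2 - p_j/2)."""
    total = 0.0
    for pi, pj in p_pairs:
        if not (0.0 <= pi <= 1.0 and 0.0 <= pj <= 1.0):
            raise ValueError("error probability outside [0,1]")
        total += 1.0 - 0.5 * pi - 0.5 * pj
    return total


def edge_support(w_e: float) -> float:
    """Support(e) is just the edge weight."""
    return w_e


@dataclass
class GraphStats:
    """Vectorized Support/Confidence statistics for one graph state."""

    w_node: np.ndarray                 # indexed by node id
    cov_node: np.ndarray               # |R(v)| per node id
    edge_u: np.ndarray
    edge_v: np.ndarray
    w_edge: np.ndarray
    conf_fwd: np.ndarray
    conf_bwd: np.ndarray
    edge_index: Dict[Tuple[int, int], int] = field(repr=False, default_factory=dict)

    @property
    def support(self) -> np.ndarray:
        return self.w_edge

    @property
    def confidence(self) -> np.ndarray:
        return np.maximum(self.conf_fwd, self.conf_bwd)

    def coverage(self, L: int) -> float:
        """C = sum_v w(v) / L, the average per-position coverage."""
        return float(self.w_node.sum()) / L

    def edge_weight_dict(self) -> Dict[Tuple[int, int], float]:
        return {(int(u), int(v)): float(w) for u, v, w in
                zip(self.edge_u, self.edge_v, self.w_edge)}


def compute_stats(
    graph: VariationGraph,
    paths: Optional[Dict[str, tuple]] = None,
) -> GraphStats:
    """Accumulate node/edge weights and confidences from read paths.

    ``paths`` maps read id to (nodes, p) or (nodes, p, adj) records; the
    optional boolean ``adj`` mask restricts edge support to consecutive
    path entries the read spells adjacently.
    """
    if paths is None:
        paths = graph.paths
    n = len(graph.base)
    w_node = np.zeros(n)
    cov_node = np.zeros(n, dtype=np.int64)
    keys_all: List[np.ndarray] = []
    wts_all: List[np.ndarray] = []
    M = np.int64(max(n, 1))
    for rid in sorted(paths):
        rec = paths[rid]
        nodes, p = rec[0], rec[1]
        adj = rec[2] if len(rec) > 2 else None
        if nodes.size == 0:
            continue
        np.add.at(w_node, nodes, 1.0 - p)
        np.add.at(cov_node, nodes, 1)
        if nodes.size >= 2:
            u = nodes[:-1].astype(np.int64)
            v = nodes[1:].astype(np.int64)
            wt = 1.0 - 0.5 * p[:-1] - 0.5 * p[1:]
            if adj is not None:
                u, v, wt = u[adj], v[adj], wt[adj]
            keys_all.append(u * M + v)
            wts_all.append(wt)
    if keys_all:
        keys = np.concatenate(keys_all)
        wts = np.concatenate(wts_all)
        ukeys, inv = np.unique(keys, return_inverse=True)
        w_edge = np.bincount(inv, weights=wts)
        edge_u = (ukeys // M).astype(np.int64)
        edge_v = (ukeys % M).astype(np.int64)
    else:
        edge_u = edge_v = np.empty(0, dtype=np.int64)
        w_edge = np.empty(0)
    out_sum = np.zeros(n)
    in_sum = np.zeros(n)
    np.add.at(out_sum, edge_u, w_edge)
    np.add.at(in_sum, edge_v, w_edge)
    with np.errstate(divide="ignore", invalid="ignore"):
        conf_fwd = np.where(out_sum[edge_u] > 0, w_edge / out_sum[edge_u], 0.0)
        conf_bwd = np.where(in_sum[edge_v] > 0, w_edge / in_sum[edge_v], 0.0)
    edge_index = {(int(u), int(v)): i for i, (u, v) in
                  enumerate(zip(edge_u, edge_v))}
    return GraphStats(w_node=w_node, cov_node=cov_node,
                      edge_u=edge_u, edge_v=edge_v, w_edge=w_edge,
                      conf_fwd=conf_fwd, conf_bwd=conf_bwd,
                      edge_index=edge_index)


def edge_confidence(stats: GraphStats, edge: Tuple[int, int]) -> Tuple[float, float, float]:
    """(conf_fwd, conf_bwd, confidence) for one edge; 0 if uncovered."""
    i = stats.edge_index.get(edge)
    if i is None:
        return 0.0, 0.0, 0.0
    return (float(stats.conf_fwd[i]), float(stats.conf_bwd[i]),
            float(max(stats.conf_fwd[i], stats.conf_bwd[i])))


# ---------------------------------------------------------------------------
# pruning

def prune_once(
    graph: VariationGraph,
    stats: GraphStats,
    cfg: PruneConfig,
) -> Tuple[List[Tuple[int, int]], List[int]]:
    """Remove every edge with Support < s or Confidence < c.

    s = s_factor * C with C the average window coverage.  Edges present in
    the graph but traversed by no current path have Support 0 and are
    removed.  Nodes left without incident edges are removed afterwards.
    Returns (removed edges, removed nodes).
    """
    C = stats.coverage(cfg.L)
    s = cfg.s_factor * C
    removed: List[Tuple[int, int]] = []
    for (u, v) in graph.edges():
        i = stats.edge_index.get((u, v))
        if i is None:
            support, conf = 0.0, 0.0
        else:
            support = float(stats.w_edge[i])
            conf = float(max(stats.conf_fwd[i], stats.conf_bwd[i]))
        if support < s or conf < cfg.c:
            removed.append((u, v))
    for u, v in removed:
        graph.remove_edge(u, v)
    removed_nodes = graph.remove_isolated_nodes()
    return removed, removed_nodes


def realign_path(
    aln: GraphAlignment,
    quals: Optional[Sequence[int]],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert a read-only realignment into a (nodes, p, adj) path record.

    Only nodes the read actually spells (matches and mismatches) enter its
    basket; nodes consumed as deletions are not covered by the read.
    ``adj[k]`` marks whether path entries k and k+1 are spelled adjacently
    by the read (no insertion in between): only adjacently spelled pairs
    support an edge, exactly as in the paths recorded at construction.
    """
    sel = (aln.ops == 0) | (aln.ops == 1)
    nodes = aln.nodes[sel].astype(np.int32)
    qp = aln.qpos[sel].astype(np.int64)
    adj = (np.diff(qp) == 1) if qp.size else np.zeros(0, dtype=bool)
    if quals is None or nodes.size == 0:
        return nodes, np.zeros(nodes.size), adj
    p_seq = np.minimum(1.0, 10.0 ** (-np.asarray(quals, dtype=np.float64) / 10.0))
    return nodes, p_seq[qp], adj


def prune_iterative(
    graph: VariationGraph,
    window_reads: Sequence[Tuple[str, str, Optional[Sequence[int]], int]],
    scoring: AlignScoring = DEFAULT_SCORING,
    cfg: Optional[PruneConfig] = None,
    band: Optional[int] = None,
    realign_first: bool = False,
) -> List[int]:
    """Iterate prune -> realign -> recompute for ``cfg.iterations`` rounds.

    ``window_reads`` are the (id, seq, quals, offset) tuples the graph was
    built from (target subread first).  Realignment is read-only (no new
    nodes or edges).  Stops early when a round removes nothing or empties
    the graph; a round that disconnects the graph (most read bases can no
    longer be aligned to it) is rolled back.  Returns the number of edges
    removed per round.
    """
    cfg = cfg if cfg is not None else PruneConfig()
    paths = dict(graph.paths)
    if realign_first:
        for rid, seq, quals, offset in window_reads:
            aln = align_to_graph(graph, seq, scoring, offset=offset, band=band)
            paths[rid] = realign_path(aln, quals)
    removed_per_round: List[int] = []
    for it in range(cfg.iterations):
        stats = compute_stats(graph, paths)
        removed_edges, removed_nodes = prune_once(graph, stats, cfg)
        removed_per_round.append(len(removed_edges))
        if not removed_edges or graph.n_nodes == 0:
            break
        if it == cfg.iterations - 1 and \
                len(removed_edges) < 0.15 * (graph.n_edges + len(removed_edges)):
            break  # small final trim cannot disconnect the graph
        new_paths = {}
        consumed = total = 0
        for rid, seq, quals, offset in window_reads:
            aln = align_to_graph(graph, seq, scoring, offset=offset, band=band)
            new_paths[rid] = realign_path(aln, quals)
            consumed += new_paths[rid][0].size
            total += max(1, len(seq))
        if consumed < MIN_REALIGN_FRACTION * total:
            # this round disconnected the graph: most reads can no longer
            # walk it; roll the round back and stop iterating
            for v in removed_nodes:
                graph.alive[v] = True
            for u, v in removed_edges:
                graph.add_edge(u, v)
            removed_per_round[-1] = 0
            break
        paths = new_paths
        if it == cfg.iterations - 1:
            break
    graph.paths = paths
    return removed_per_round


#: below this fraction of walk-consumed target bases the pruned graph is
#: considered collapsed and the raw subread passes through whole
MIN_WALK_FRACTION = 0.5

#: a pruning round after which the window reads align fewer than this
#: fraction of their bases to the graph has disconnected it; the round is
#: rolled back (erroneous reads at ~15% error still consume >>80%)
MIN_REALIGN_FRACTION = 0.8


def correct_subread(
    graph: VariationGraph,
    target_subread: str,
    target_quals: Optional[Sequence[int]] = None,
    scoring: AlignScoring = DEFAULT_SCORING,
    band: Optional[int] = None,
) -> Tuple[str, bool]:
    """Realign the target subread against the pruned graph and spell the path.

    Consumed nodes contribute their graph base.  Interior insertions --
    target bases flanked by aligned context -- are the target's own excess
    bases and are dropped.  Leading and trailing unaligned bases pass
    through as raw sequence: the graph ends where fragment support ends, a
    few bases short of the target's own ends, and clean terminal sequence
    must never be truncated.  Returns (sequence, False) only when the
    whole window passed through raw (empty graph, collapsed graph, or no
    usable walk).
    """
    if graph.n_nodes == 0 or not target_subread:
        return target_subread, False
    aln = align_to_graph(graph, target_subread, scoring, offset=0, band=band,
                         prefer_ins=True)
    # anchor the walk on target evidence: its first/last match or mismatch
    anchored = np.nonzero((aln.ops == 0) | (aln.ops == 1))[0]
    if anchored.size == 0:
        return target_subread, False
    first, last = int(anchored[0]), int(anchored[-1])
    parts: List[str] = [target_subread[:int(aln.qpos[first])]]
    n_corrected = 0
    for k in range(first, last + 1):
        if aln.ops[k] == OP_INS:
            continue
        parts.append(graph.node_base(int(aln.nodes[k])))
        n_corrected += 1
    parts.append(target_subread[int(aln.qpos[last]) + 1:])
    corrected = "".join(parts)
    if n_corrected < MIN_WALK_FRACTION * len(target_subread) or not corrected:
        # the graph collapsed over most of the window; its remnants are not
        # trustworthy either, so the whole raw subread passes through
        return target_subread, False
    return corrected, True
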