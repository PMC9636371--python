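"""Numba kernels for banded sequence-to-DAG alignment.

The dynamic program runs over graph nodes in topological order; for each
node only a band of sequence columns around the node's expected position is
evaluated, which bounds the cost at O(|V| * band) instead of O(|V| * m).
The alignment is semi-global with free ends on the graph side: the aligned
walk may start and end at any node, the sequence is consumed entirely, and
interior gaps are penalized linearly.

Scores are integers.  Tie-breaking is fixed, so alignments -- and
therefore corrections -- are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(2 ** 30))

# op codes shared with the graph module
OP_MATCH = 0
OP_MISMATCH = 1
OP_INS = 2      # sequence base not aligned to any node
OP_DEL = 3      # node consumed without a sequence base


@njit(cache=True, nogil=True)
def sg_align_kernel(bases, pred_ptr, pred_idx, lo, W, seq, match, mismatch, gap):
    """Fill the banded DP score matrix.

    ``H[i, j-lo[i]]`` is the best score of a walk whose last consumed node
    has topological rank ``i`` after consuming ``j`` sequence characters.
    Every in-band cell has at least the fresh-start candidates, so all
    in-band cells hold valid scores.  Returns (H, best_end_score, end_rank).
    """
    n = bases.shape[0]
    m = seq.shape[0]
    H = np.empty((n, W), dtype=np.int16)
    for i in range(n):
        li = lo[i]
        hi = li + W - 1
        if hi > m:
            hi = m
        b = bases[i]
        p0 = pred_ptr[i]
        p1 = pred_ptr[i + 1]
        for j in range(li, hi + 1):
            if j >= 1:
                sub = match if seq[j - 1] == b else mismatch
                best = (j - 1) * gap + sub   # fresh start with leading ins
            else:
                sub = 0
                best = gap                    # fresh start consuming node as del
            cand = j * gap + gap
            if cand > best:
                best = cand
            for pp in range(p0, p1):
                p = pred_idx[pp]
                lp = lo[p]
                hp = lp + W - 1
                if hp > m:
                    hp = m
                if j >= 1 and lp <= j - 1 <= hp:
                    cand = H[p, j - 1 - lp] + sub
                    if cand > best:
                        best = cand
                if lp <= j <= hp:
                    cand = H[p, j - lp] + gap
                    if cand > best:
                        best = cand
            if j - 1 >= li:
                cand = H[i, j - 1 - li] + gap
                if cand > best:
                    best = cand
            H[i, j - li] = best
    best_end = np.int32(NEG)
    ei = np.int32(-1)
    for i in range(n):
        li = lo[i]
        if li <= m <= li + W - 1:
            v = np.int32(H[i, m - li])
            if v > best_end:
                best_end = v
                ei = np.int32(i)
    return H, best_end, ei


@njit(cache=True, nogil=True)
def sg_traceback_kernel(H, bases, pred_ptr, pred_idx, lo, W, seq,
                        match, mismatch, gap, ei, prefer_ins):
    """Recover (op, node rank, seq position) triples, in alignment order.

    Moves are re-derived by scanning candidates in a fixed order (fresh
    starts, insertion, then predecessors ascending with substitution
    before deletion) and taking the first one that reproduces the cell
    score; any such walk is score-optimal, and the fixed order makes the
    choice deterministic.  With ``prefer_ins`` insertion wins ties against
    node moves, so unaligned sequence collects at the walk ends (used for
    the final target extraction; construction and statistics alignments
    keep node moves first).
    """
    m = seq.shape[0]
    max_ops = H.shape[0] + m + 2
    code = np.empty(max_ops, dtype=np.int8)
    node = np.empty(max_ops, dtype=np.int32)
    qpos = np.empty(max_ops, dtype=np.int32)
    k = 0
    i = ei
    j = m
    while True:
        v = H[i, j - lo[i]]
        b = bases[i]
        if j >= 1:
            sub = match if seq[j - 1] == b else mismatch
        else:
            sub = 0
        # fresh starts are the first candidates in forward order
        if j >= 1 and v == (j - 1) * gap + sub:
            code[k] = OP_MATCH if seq[j - 1] == b else OP_MISMATCH
            node[k] = i
            qpos[k] = j - 1
            k += 1
            j -= 1
            while j > 0:
                j -= 1
                code[k] = OP_INS
                node[k] = -1
                qpos[k] = j
                k += 1
            break
        if j >= 1 and v == gap and j == 0:
            pass  # unreachable; kept for symmetry
        if v == j * gap + gap or (j == 0 and v == gap):
            code[k] = OP_DEL
            node[k] = i
            qpos[k] = -1
            k += 1
            while j > 0:
                j -= 1
                code[k] = OP_INS
                node[k] = -1
                qpos[k] = j
                k += 1
            break
        # optionally prefer insertion among tied moves: unaligned sequence
        # drifts to the walk ends, where callers keep it as raw sequence
        if prefer_ins and j >= 1 and j - 1 >= lo[i] and v == H[i, j - 1 - lo[i]] + gap:
            code[k] = OP_INS
            node[k] = -1
            qpos[k] = j - 1
            k += 1
            j -= 1
            continue
        moved = False
        for pp in range(pred_ptr[i], pred_ptr[i + 1]):
            p = pred_idx[pp]
            lp = lo[p]
            hp = lp + W - 1
            if hp > m:
                hp = m
            if j >= 1 and lp <= j - 1 <= hp and v == H[p, j - 1 - lp] + sub:
                code[k] = OP_MATCH if seq[j - 1] == b else OP_MISMATCH
                node[k] = i
                qpos[k] = j - 1
                k += 1
                i = p
                j -= 1
                moved = True
                break
            if lp <= j <= hp and v == H[p, j - lp] + gap:
                code[k] = OP_DEL
                node[k] = i
                qpos[k] = -1
                k += 1
                i = p
                moved = True
                break
        if moved:
            continue
        # insertion
        code[k] = OP_INS
        node[k] = -1
        qpos[k] = j - 1
        k += 1
        j -= 1
    return code[:k][::-1].copy(), node[:k][::-1].copy(), qpos[:k][::-1].copy()


@njit(cache=True, nogil=True)
def build_csr_kernel(n, alive, eu, ev, bases_all, pos_all):
    """Topological order (Kahn, min node id first) and predecessor CSR.

    Returns (order, rank, bases, pos, pred_ptr, pred_idx) over alive nodes,
    with predecessors listed in ascending topological rank.  rank[v] == -1
    for dead nodes; raises via a sentinel (order[0] == -1) on cycles.
    """
    m = eu.size
    indeg = np.zeros(n, dtype=np.int32)
    outdeg = np.zeros(n, dtype=np.int32)
    for e in range(m):
        indeg[ev[e]] += 1
        outdeg[eu[e]] += 1
    # successor CSR by node id
    sptr = np.zeros(n + 1, dtype=np.int32)
    for u in range(n):
        sptr[u + 1] = sptr[u] + outdeg[u]
    sidx = np.empty(m, dtype=np.int32)
    fill = sptr[:n].copy()
    for e in range(m):
        u = eu[e]
        sidx[fill[u]] = ev[e]
        fill[u] += 1
    # min-heap of ready nodes
    heap = np.empty(n, dtype=np.int32)
    hn = 0
    for v in range(n):
        if alive[v] and indeg[v] == 0:
            heap[hn] = v
            i = hn
            hn += 1
            while i > 0 and heap[(i - 1) // 2] > heap[i]:
                heap[(i - 1) // 2], heap[i] = heap[i], heap[(i - 1) // 2]
                i = (i - 1) // 2
    n_alive = 0
    for v in range(n):
        if alive[v]:
            n_alive += 1
    order = np.empty(n_alive, dtype=np.int32)
    rank = np.full(n, -1, dtype=np.int32)
    k = 0
    while hn > 0:
        v = heap[0]
        hn -= 1
        heap[0] = heap[hn]
        i = 0
        while True:
            l = 2 * i + 1
            r = l + 1
            small = i
            if l < hn and heap[l] < heap[small]:
                small = l
            if r < hn and heap[r] < heap[small]:
                small = r
            if small == i:
                break
            heap[small], heap[i] = heap[i], heap[small]
            i = small
        order[k] = v
        rank[v] = k
        k += 1
        for s in range(sptr[v], sptr[v + 1]):
            w = sidx[s]
            indeg[w] -= 1
            if indeg[w] == 0:
                heap[hn] = w
                i = hn
                hn += 1
                while i > 0 and heap[(i - 1) // 2] > heap[i]:
                    heap[(i - 1) // 2], heap[i] = heap[i], heap[(i - 1) // 2]
                    i = (i - 1) // 2
    if k != n_alive:
        order = np.full(1, -1, dtype=np.int32)  # cycle sentinel
        return (order, rank, np.empty(0, dtype=np.int8),
                np.empty(0, dtype=np.int32), np.empty(0, dtype=np.int32),
                np.empty(0, dtype=np.int32))
    bases = np.empty(n_alive, dtype=np.int8)
    pos = np.empty(n_alive, dtype=np.int32)
    for i in range(n_alive):
        bases[i] = bases_all[order[i]]
        pos[i] = pos_all[order[i]]
    # predecessor CSR in rank space
    pcnt = np.zeros(n_alive + 1, dtype=np.int32)
    for e in range(m):
        pcnt[rank[ev[e]] + 1] += 1
    for i in range(n_alive):
        pcnt[i + 1] += pcnt[i]
    pred_idx = np.empty(m, dtype=np.int32)
    fill2 = pcnt[:n_alive].copy()
    for e in range(m):
        rv = rank[ev[e]]
        pred_idx[fill2[rv]] = rank[eu[e]]
        fill2[rv] += 1
    # ascending ranks within each node's segment (insertion sort, tiny runs)
    for i in range(n_alive):
        lo2 = pcnt[i]
        hi2 = pcnt[i + 1]
        for a in range(lo2 + 1, hi2):
            key = pred_idx[a]
            b = a - 1
            while b >= lo2 and pred_idx[b] > key:
                pred_idx[b + 1] = pred_idx[b]
                b -= 1
            pred_idx[b + 1] = key
    return order, rank, bases, pos, pcnt, pred_idx
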