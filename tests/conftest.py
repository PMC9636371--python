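"""Shared fixtures: tiny deterministic read sets and window builders."""

from __future__ import annotations

import numpy as np
import pytest

from hapcorrect.graph import VariationGraph, poa_build
from hapcorrect.io import Read


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


def mutate_one(seq: str, pos: int, base: str) -> str:
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1:]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_window(rng):
    """A 120-bp window: clean truth plus reads; builder for noisy variants."""
    truth = random_seq(rng, 120)
    return truth


def build_window_graph(seqs, **kwargs):
    """POA graph over (id, seq) pairs, FASTA-style (no quals, offset 0)."""
    return poa_build([(rid, s, None, 0) for rid, s in seqs], **kwargs)


def enumerate_walks(graph: VariationGraph):
    """Every directed walk (any start node, any end node) in a small DAG."""
    walks = []
    nodes = [v for v in range(len(graph.base)) if graph.alive[v]]

    def extend(path):
        walks.append(list(path))
        for nxt in sorted(graph.succ[path[-1]]):
            path.append(nxt)
            extend(path)
            path.pop()

    for v in nodes:
        extend([v])
    return walks


def spell(graph: VariationGraph, walk) -> str:
    return "".join(graph.node_base(v) for v in walk)


def global_align_score(a: str, b: str, match: int, mismatch: int, gap: int) -> int:
    """Plain quadratic global alignment score (independent oracle)."""
    n, m = len(a), len(b)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    H[0, :] = np.arange(m + 1) * gap
    H[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(H[i - 1, j - 1] + s, H[i - 1, j] + gap,
                          H[i, j - 1] + gap)
    return int(H[n, m])


def edit_distance_dp(a: str, b: str) -> int:
    """Plain quadratic unit-cost edit distance (independent oracle)."""
    n, m = len(a), len(b)
    D = np.empty((n + 1, m + 1), dtype=np.int64)
    D[0, :] = np.arange(m + 1)
    D[:, 0] = np.arange(n + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = 0 if a[i - 1] == b[j - 1] else 1
            D[i, j] = min(D[i - 1, j - 1] + c, D[i - 1, j] + 1, D[i, j - 1] + 1)
    return int(D[n, m])
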