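"""Variation graph construction, sequence-to-graph alignment, consensus.

The alignment and consensus operations are checked against brute-force
oracles: exhaustive enumeration of all directed walks in small DAGs.
"""

import numpy as np
import pytest

from hapcorrect.graph import (AlignScoring, VariationGraph, align_to_graph,
                              extract_path_sequence, heaviest_bundle,
                              poa_build)
from hapcorrect.pruning import compute_stats

from conftest import (build_window_graph, enumerate_walks, global_align_score,
                      mutate_one, random_seq, spell)

S = AlignScoring()


class TestPoaBuild:
    def test_single_sequence_chain(self):
        g = build_window_graph([("a", "ACGT")])
        assert g.n_nodes == 4 and g.n_edges == 3
        assert list(g.paths) == ["a"]
        assert spell(g, g.paths["a"][0]) == "ACGT"

    def test_identical_sequences_share_chain(self):
        g = build_window_graph([("a", "ACGT"), ("b", "ACGT")])
        assert g.n_nodes == 4 and g.n_edges == 3
        st = compute_stats(g)
        assert np.all(st.w_edge == 2)

    def test_substitution_makes_width_one_bubble(self):
        g = build_window_graph([("a", "ACGT"), ("b", "AGGT")])
        # expected: backbone A-C-G-T plus one new G node branching around C
        assert g.n_nodes == 5
        pa, pb = g.paths["a"][0], g.paths["b"][0]
        assert pa[0] == pb[0] and tuple(pa[2:]) == tuple(pb[2:])
        new = int(pb[1])
        assert g.node_base(new) == "G"
        assert g.pred[new] == {int(pa[0])}
        assert g.succ[new] == {int(pa[2])}

    def test_refusing_empty_input(self):
        with pytest.raises(ValueError):
            poa_build([])

    def test_existing_path_adds_no_nodes(self, rng):
        seq = random_seq(rng, 60)
        noisy = mutate_one(seq, 30, "A" if seq[30] != "A" else "C")
        g = build_window_graph([("a", seq), ("b", noisy)])
        n_before = g.n_nodes
        g2 = build_window_graph([("a", seq), ("b", noisy), ("c", noisy)])
        assert g2.n_nodes == n_before

    def test_dag_preserved_under_fusion(self, rng):
        seqs = [(f"r{i}", random_seq(rng, 40)) for i in range(6)]
        g = build_window_graph(seqs)
        assert g.is_dag()
        order = g.topo_order()
        rank = {v: i for i, v in enumerate(order)}
        for u, v in g.edges():
            assert rank[u] < rank[v]


class TestAlignToGraph:
    def test_existing_path_scores_full_match(self, rng):
        seq = random_seq(rng, 30)
        g = build_window_graph([("a", seq)])
        aln = align_to_graph(g, seq, S)
        assert aln.score == S.match * len(seq)
        assert np.all(aln.ops == 0)

    def test_empty_sequence(self):
        g = build_window_graph([("a", "ACGT")])
        aln = align_to_graph(g, "", S)
        assert aln.score == 0 and aln.ops.size == 0

    def test_empty_graph_all_insertion(self):
        g = VariationGraph()
        aln = align_to_graph(g, "ACGT", S)
        assert aln.score == 4 * S.gap
        assert np.all(aln.ops == 2)

    @pytest.mark.parametrize("trial", range(8))
    def test_score_matches_walk_enumeration(self, trial):
        # oracle: max over all walks of the global pairwise score, vs the
        # pure-insertion fallback
        rng = np.random.default_rng(100 + trial)
        base = random_seq(rng, 5)
        variant = base[:2] + "".join(rng.choice(list("ACGT"), 2)) + base[3:]
        g = build_window_graph([("a", base), ("b", variant)])
        assert g.n_nodes <= 8
        query = random_seq(rng, int(rng.integers(3, 8)))
        best = len(query) * S.gap  # consume everything as insertions
        for walk in enumerate_walks(g):
            best = max(best, global_align_score(query, spell(g, walk),
                                                S.match, S.mismatch, S.gap))
        aln = align_to_graph(g, query, S)
        assert aln.score == best

    def test_banded_equals_full_on_window_like_input(self, rng):
        seqs = [(f"r{i}", random_seq(rng, 200)) for i in range(2)]
        g = poa_build([(rid, s, None, 0) for rid, s in seqs])
        q = seqs[0][1][:150] + "ACGT"
        full = align_to_graph(g, q, S, band=None)
        banded = align_to_graph(g, q, S, offset=0, band=75)
        assert banded.score == full.score

    def test_walk_is_directed_path(self, rng):
        seqs = [(f"r{i}", random_seq(rng, 50)) for i in range(4)]
        g = build_window_graph(seqs)
        aln = align_to_graph(g, random_seq(rng, 45), S)
        walk = aln.walk()
        for u, v in zip(walk[:-1], walk[1:]):
            assert int(v) in g.succ[int(u)]


class TestExtractPathSequence:
    def test_chain(self):
        g = build_window_graph([("a", "ACG")])
        aln = align_to_graph(g, "ACG", S)
        assert extract_path_sequence(g, aln) == "ACG"

    def test_empty_alignment(self):
        g = build_window_graph([("a", "ACG")])
        aln = align_to_graph(g, "", S)
        assert extract_path_sequence(g, aln) == ""

    def test_error_correction_via_extraction(self, rng):
        # an erroneous subread aligned to a clean graph spells the clean seq
        truth = random_seq(rng, 80)
        g = build_window_graph([(f"r{i}", truth) for i in range(5)])
        noisy = mutate_one(truth, 40, "A" if truth[40] != "A" else "C")
        aln = align_to_graph(g, noisy, S)
        assert extract_path_sequence(g, aln) == truth

    def test_deleted_base_restored(self, rng):
        truth = random_seq(rng, 80)
        g = build_window_graph([(f"r{i}", truth) for i in range(5)])
        noisy = truth[:40] + truth[41:]
        aln = align_to_graph(g, noisy, S)
        assert extract_path_sequence(g, aln) == truth

    def test_inserted_base_dropped(self, rng):
        truth = random_seq(rng, 80)
        g = build_window_graph([(f"r{i}", truth) for i in range(5)])
        noisy = truth[:40] + "A" + truth[40:]
        aln = align_to_graph(g, noisy, S)
        assert extract_path_sequence(g, aln) == truth


class TestHeaviestBundle:
    def test_identical_reads(self, rng):
        seq = random_seq(rng, 50)
        g = build_window_graph([(f"r{i}", seq) for i in range(4)])
        st = compute_stats(g)
        assert heaviest_bundle(g, st.edge_weight_dict()) == seq

    def test_linear_chain_any_weights(self, rng):
        seq = random_seq(rng, 20)
        g = build_window_graph([("a", seq)])
        weights = {e: float(rng.random()) for e in g.edges()}
        assert heaviest_bundle(g, weights) == seq

    def test_empty_graph(self):
        assert heaviest_bundle(VariationGraph(), {}) == ""

    def test_majority_wins_bubble(self, rng):
        seq = random_seq(rng, 40)
        var = mutate_one(seq, 20, "A" if seq[20] != "A" else "C")
        g = build_window_graph([("a", seq), ("b", seq), ("c", seq),
                                ("d", var)])
        st = compute_stats(g)
        assert heaviest_bundle(g, st.edge_weight_dict()) == seq

    @pytest.mark.parametrize("trial", range(8))
    def test_weight_matches_exhaustive_maximum(self, trial):
        rng = np.random.default_rng(300 + trial)
        base = random_seq(rng, 6)
        var = base[:2] + "".join(rng.choice(list("ACGT"), 2)) + base[3:]
        g = build_window_graph([("a", base), ("b", var)])
        assert g.n_nodes <= 10
        weights = {e: float(np.round(rng.random(), 3)) for e in g.edges()}
        sources = [v for v in range(len(g.base)) if g.alive[v]
                   and not g.pred[v]]
        sinks = {v for v in range(len(g.base)) if g.alive[v]
                 and not g.succ[v]}
        best = -1.0
        best_seq = ""
        for walk in enumerate_walks(g):
            if walk[0] in sources and walk[-1] in sinks:
                w = sum(weights[(u, v)] for u, v in zip(walk, walk[1:]))
                if w > best:
                    best, best_seq = w, spell(g, walk)
        got = heaviest_bundle(g, weights)
        got_w = _path_weight(g, got, weights)
        assert got_w == pytest.approx(best)

    def test_weight_at_least_any_read_path(self, rng):
        seqs = [(f"r{i}", random_seq(rng, 30)) for i in range(3)]
        g = build_window_graph(seqs)
        st = compute_stats(g)
        wd = st.edge_weight_dict()
        hb = heaviest_bundle(g, wd)
        hb_w = _path_weight(g, hb, wd)
        for rid in g.paths:
            nodes = g.paths[rid][0]
            w = sum(wd.get((int(u), int(v)), 0.0)
                    for u, v in zip(nodes[:-1], nodes[1:]))
            assert hb_w >= w - 1e-9


def _path_weight(g, seq, weights):
    # recompute the weight of the returned consensus by following its walk
    # (re-derive the best path with the same DP to get the node walk)
    from hapcorrect.graph import heaviest_bundle as _hb  # noqa
    # brute force: find a source-sink walk spelling seq with max weight
    best = None
    for walk in enumerate_walks(g):
        if g.pred[walk[0]] or g.succ[walk[-1]]:
            continue
        if spell(g, walk) == seq:
            w = sum(weights.get((u, v), 0.0) for u, v in zip(walk, walk[1:]))
            best = w if best is None else max(best, w)
    assert best is not None, "consensus does not spell a source-sink walk"
    return best
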