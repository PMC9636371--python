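"""Support/Confidence statistics and graph pruning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hapcorrect.graph import AlignScoring, align_to_graph, poa_build
from hapcorrect.pruning import (PruneConfig, compute_stats, correct_subread,
                                edge_confidence, edge_support, edge_weight,
                                node_weight, prune_iterative, prune_once)

from conftest import build_window_graph, mutate_one, random_seq

S = AlignScoring()


class TestElementaryWeights:
    def test_node_weight_fasta(self):
        assert node_weight([0.0, 0.0, 0.0]) == 3.0

    def test_node_weight_fastq_q10(self):
        assert node_weight([0.1, 0.1]) == pytest.approx(1.8)

    def test_node_weight_empty(self):
        assert node_weight([]) == 0.0

    def test_node_weight_domain(self):
        with pytest.raises(ValueError):
            node_weight([1.5])

    def test_edge_weight_fasta(self):
        assert edge_weight([(0.0, 0.0)] * 4) == 4.0

    def test_edge_weight_fastq(self):
        assert edge_weight([(0.1, 0.01)]) == pytest.approx(0.945)

    def test_edge_support_is_weight(self):
        assert edge_support(4.0) == 4.0
        assert edge_support(0.0) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 0.5), st.floats(0, 0.5)),
                    min_size=1, max_size=20))
    def test_approximation_gap_closed_form(self, pairs):
        # the half-weight sum deviates from the exact product sum by
        # exactly sum((p_i + p_j)/2 - p_i p_j), hence at most sum(p_i+p_j)/2
        approx = edge_weight(pairs)
        exact = sum((1 - pi) * (1 - pj) for pi, pj in pairs)
        gap = sum((pi + pj) / 2 - pi * pj for pi, pj in pairs)
        assert approx - exact == pytest.approx(gap)
        assert abs(approx - exact) <= sum(pi + pj for pi, pj in pairs) / 2 + 1e-12


class TestComputeStats:
    def _toy(self):
        # graph a->b (8 reads), a->c (2 reads), b->d, c->d
        g = build_window_graph([("r0", "AC"), ("x", "AG")])
        # nodes: 0:A 1:C (backbone), 2:G; paths recorded by build
        paths = {}
        for i in range(8):
            paths[f"p{i}"] = (np.array([0, 1], dtype=np.int32), np.zeros(2))
        for i in range(2):
            paths[f"q{i}"] = (np.array([0, 2], dtype=np.int32), np.zeros(2))
        return g, paths

    def test_hand_computed_confidences(self):
        g, paths = self._toy()
        stats = compute_stats(g, paths)
        i_ab = stats.edge_index[(0, 1)]
        i_ac = stats.edge_index[(0, 2)]
        assert stats.w_edge[i_ab] == 8
        assert stats.w_edge[i_ac] == 2
        # conf_fwd(a,b) = 8/10; conf_bwd(a,b) = 8/8 (b's only pred is a)
        assert stats.conf_fwd[i_ab] == pytest.approx(0.8)
        assert stats.conf_bwd[i_ab] == pytest.approx(1.0)
        assert edge_confidence(stats, (0, 2)) == pytest.approx((0.2, 1.0, 1.0))
        assert edge_confidence(stats, (5, 6)) == (0.0, 0.0, 0.0)

    def test_symmetric_bubble_confidence_half(self, rng):
        seq = random_seq(rng, 30)
        var = mutate_one(seq, 15, "A" if seq[15] != "A" else "C")
        g = build_window_graph([("a", seq), ("b", var), ("c", seq), ("d", var)])
        stats = compute_stats(g)
        u = int(g.paths["a"][0][14])
        va, vb = int(g.paths["a"][0][15]), int(g.paths["b"][0][15])
        assert stats.conf_fwd[stats.edge_index[(u, va)]] == pytest.approx(0.5)
        assert stats.conf_fwd[stats.edge_index[(u, vb)]] == pytest.approx(0.5)

    def test_fasta_weights_are_traversal_counts(self, rng):
        # oracle: recount traversals directly from the recorded paths
        seqs = [(f"r{i}", random_seq(rng, 40)) for i in range(5)]
        g = build_window_graph(seqs)
        stats = compute_stats(g)
        counts = {}
        for rid, (nodes, _p) in g.paths.items():
            for u, v in zip(nodes[:-1], nodes[1:]):
                counts[(int(u), int(v))] = counts.get((int(u), int(v)), 0) + 1
        for (u, v), n in counts.items():
            i = stats.edge_index[(u, v)]
            assert stats.w_edge[i] == n
            assert float(stats.w_edge[i]).is_integer()

    def test_confidence_in_unit_interval_and_normalized(self, rng):
        seqs = [(f"r{i}", random_seq(rng, 50)) for i in range(6)]
        g = build_window_graph(seqs)
        stats = compute_stats(g)
        assert np.all(stats.confidence >= 0) and np.all(stats.confidence <= 1)
        # per source node, conf_fwd terms sum to 1
        for u in set(stats.edge_u.tolist()):
            sel = stats.edge_u == u
            assert stats.conf_fwd[sel].sum() == pytest.approx(1.0)


class TestPruneOnce:
    def test_clean_window_nothing_removed(self, rng):
        truth = random_seq(rng, 100)
        g = build_window_graph([(f"r{i}", truth) for i in range(10)])
        stats = compute_stats(g)
        removed, removed_nodes = prune_once(g, stats, PruneConfig(L=100))
        assert removed == [] and removed_nodes == []

    def test_private_error_bubble_pruned(self, rng):
        truth = random_seq(rng, 100)
        noisy = mutate_one(truth, 50, "A" if truth[50] != "A" else "C")
        seqs = [(f"r{i:02d}", truth) for i in range(29)] + [("zz", noisy)]
        g = build_window_graph(seqs)
        err_node = int(g.paths["zz"][0][50])
        stats = compute_stats(g)
        removed, removed_nodes = prune_once(g, stats, PruneConfig(L=100))
        assert err_node in removed_nodes
        assert all(err_node in (u, v) for u, v in removed)

    def test_balanced_haplotype_bubble_retained(self, rng):
        # 15/15 split: support 15 >= s = 0.2*30 = 6, confidence 0.5 >= 0.2
        truth = random_seq(rng, 100)
        var = mutate_one(truth, 50, "A" if truth[50] != "A" else "C")
        seqs = [(f"a{i:02d}", truth) for i in range(15)] + \
               [(f"b{i:02d}", var) for i in range(15)]
        g = build_window_graph(seqs)
        stats = compute_stats(g)
        va = int(g.paths["a00"][0][50])
        vb = int(g.paths["b00"][0][50])
        removed, _ = prune_once(g, stats, PruneConfig(L=100))
        assert removed == []
        assert g.alive[va] and g.alive[vb]

    def test_coverage_scale_invariance(self, rng):
        # duplicating every read doubles C and all supports; decisions equal
        truth = random_seq(rng, 80)
        noisy = mutate_one(truth, 40, "A" if truth[40] != "A" else "C")
        seqs = [(f"r{i:02d}", truth) for i in range(9)] + [("zz", noisy)]
        g1 = build_window_graph(seqs)
        paths1 = dict(g1.paths)
        paths2 = dict(paths1)
        for rid, rec in paths1.items():
            paths2["dup_" + rid] = rec
        s1 = compute_stats(g1, paths1)
        s2 = compute_stats(g1, paths2)
        assert s2.coverage(80) == pytest.approx(2 * s1.coverage(80))
        cfg = PruneConfig(L=80)
        C1, C2 = s1.coverage(80), s2.coverage(80)
        for (u, v), i in s1.edge_index.items():
            j = s2.edge_index[(u, v)]
            assert s2.w_edge[j] == pytest.approx(2 * s1.w_edge[i])
            d1 = s1.w_edge[i] < 0.2 * C1 or max(s1.conf_fwd[i], s1.conf_bwd[i]) < 0.2
            d2 = s2.w_edge[j] < 0.2 * C2 or max(s2.conf_fwd[j], s2.conf_bwd[j]) < 0.2
            assert d1 == d2


class TestPruneIterative:
    def test_clean_window_converges_immediately(self, rng):
        truth = random_seq(rng, 100)
        seqs = [(f"r{i}", truth, None, 0) for i in range(8)]
        g = poa_build(seqs, S)
        log = prune_iterative(g, seqs, S, PruneConfig(L=100))
        assert log == [0]

    def test_round_count_bounded(self, rng):
        truth = random_seq(rng, 150)
        seqs = []
        for i in range(12):
            noisy = truth
            for pos in rng.integers(5, 145, size=8):
                noisy = mutate_one(noisy, int(pos),
                                   "A" if noisy[pos] != "A" else "G")
            seqs.append((f"r{i:02d}", noisy, None, 0))
        g = poa_build(seqs, S)
        cfg = PruneConfig(L=150, iterations=3)
        log = prune_iterative(g, seqs, S, cfg)
        assert 1 <= len(log) <= 3

    def test_dag_and_paths_valid_after_pruning(self, rng):
        truth = random_seq(rng, 120)
        seqs = []
        for i in range(15):
            noisy = truth
            for pos in rng.integers(5, 115, size=5):
                noisy = mutate_one(noisy, int(pos),
                                   "A" if noisy[pos] != "A" else "G")
            seqs.append((f"r{i:02d}", noisy, None, 0))
        g = poa_build(seqs, S)
        prune_iterative(g, seqs, S, PruneConfig(L=120))
        assert g.is_dag()


class TestCorrectSubread:
    def _noisy_window(self, rng, truth, n_reads=30, n_err=6):
        seqs = []
        for i in range(n_reads):
            noisy = truth
            for pos in sorted(rng.integers(2, len(truth) - 2, size=n_err),
                              reverse=True):
                kind = rng.integers(0, 3)
                if kind == 0:
                    noisy = mutate_one(noisy, int(pos),
                                       "A" if noisy[pos] != "A" else "G")
                elif kind == 1:
                    noisy = noisy[:pos] + noisy[pos + 1:]
                else:
                    noisy = noisy[:pos] + "ACGT"[rng.integers(0, 4)] + noisy[pos:]
            seqs.append((f"r{i:02d}", noisy, None, 0))
        return seqs

    def test_clean_target_on_retained_path_unchanged(self, rng):
        truth = random_seq(rng, 100)
        seqs = [("__target__", truth, None, 0)] + \
               [(f"r{i}", truth, None, 0) for i in range(8)]
        g = poa_build(seqs, S)
        prune_iterative(g, seqs, S, PruneConfig(L=100))
        out, ok = correct_subread(g, truth, None, S)
        assert ok and out == truth

    def test_substitution_corrected_against_clean_window(self, rng):
        truth = random_seq(rng, 200)
        noisy = mutate_one(truth, 100, "A" if truth[100] != "A" else "C")
        seqs = [("__target__", noisy, None, 0)] + \
               [(f"r{i:02d}", truth, None, 0) for i in range(30)]
        g = poa_build(seqs, S)
        prune_iterative(g, seqs, S, PruneConfig(L=200))
        out, ok = correct_subread(g, noisy, None, S)
        assert ok and out == truth

    def test_noisy_window_corrects_target(self, rng):
        from conftest import edit_distance_dp
        truth = random_seq(rng, 200)
        seqs = self._noisy_window(rng, truth)
        target = seqs[0]
        seqs = [("__target__", target[1], None, 0)] + seqs[1:]
        g = poa_build(seqs, S)
        prune_iterative(g, seqs, S, PruneConfig(L=200))
        out, ok = correct_subread(g, target[1], None, S)
        assert ok
        assert edit_distance_dp(out, truth) < edit_distance_dp(target[1], truth)

    def test_diploid_window_preserves_target_allele(self, rng):
        # balanced SNP bubble: the target keeps its own haplotype's allele
        truth_a = random_seq(rng, 150)
        truth_b = mutate_one(truth_a, 75, "A" if truth_a[75] != "A" else "C")
        seqs = [("__target__", truth_a, None, 0)]
        seqs += [(f"a{i:02d}", truth_a, None, 0) for i in range(14)]
        seqs += [(f"b{i:02d}", truth_b, None, 0) for i in range(15)]
        g = poa_build(seqs, S)
        prune_iterative(g, seqs, S, PruneConfig(L=150))
        out, ok = correct_subread(g, truth_a, None, S)
        assert ok and out[75] == truth_a[75]
        out_b, ok_b = correct_subread(g, truth_b, None, S)
        assert ok_b and out_b[75] == truth_b[75]

    def test_empty_graph_passthrough(self):
        from hapcorrect.graph import VariationGraph
        g = VariationGraph()
        out, ok = correct_subread(g, "ACGT", None, S)
        assert (out, ok) == ("ACGT", False)
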