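"""Graph construction, alignment threading, and merge semantics."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import gapped_m5, perfect_m5
from sparsecons.io_formats import SequenceRecord
from sparsecons.kmer_graph import (
    NodeKey,
    add_alignment,
    average_backbone_multiplicity,
    build_backbone_graph,
    to_dot,
)

backbones = st.text(alphabet="ACGT", min_size=3, max_size=60)


def reconstruct_backbone_path(graph) -> str:
    """Emit the source k-mer, then follow backbone edges, then the tail."""
    seq = graph.backbone[: graph.k]
    for i in range(1, graph.n_anchors):
        seq += graph.backbone_label(i)
    return seq + graph.tail


class TestBuild:
    def test_dense_anchors_and_unit_weights(self):
        graph = build_backbone_graph(SequenceRecord("b", "ACGT"), k=2, g=1)
        assert graph.n_anchors == 3
        assert [graph.backbone_kmer(i) for i in range(3)] == ["AC", "CG", "GT"]
        edges = graph.backbone_edges()
        assert [e.label for e in edges] == ["G", "T"]
        assert all(e.weight == 1.0 for e in edges)
        assert graph.tail == ""

    def test_sparse_anchors_with_tail(self):
        graph = build_backbone_graph(SequenceRecord("b", "ACGTA"), k=2, g=2)
        assert graph.anchors == [0, 2]
        assert [graph.backbone_kmer(i) for i in range(2)] == ["AC", "GT"]
        (edge,) = graph.backbone_edges()
        assert edge.label == "GT" and edge.weight == 1.0
        assert graph.tail == "A"

    def test_too_short_backbone_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            build_backbone_graph(SequenceRecord("b", "AC"), k=3, g=1)

    @settings(max_examples=80, deadline=None)
    @given(backbones, st.integers(1, 3), st.integers(1, 5))
    def test_backbone_path_reconstructs_sequence(self, seq, k, g):
        if len(seq) < k:
            return
        graph = build_backbone_graph(SequenceRecord("b", seq), k=k, g=g)
        assert reconstruct_backbone_path(graph) == seq

    def test_periodic_backbone_keeps_positions_independent(self):
        graph = build_backbone_graph(SequenceRecord("b", "ACACACAC"), k=2, g=1)
        kmers = [graph.backbone_node(i) for i in range(graph.n_anchors)]
        # same k-mer string, all distinct nodes
        assert len(set(kmers)) == graph.n_anchors
        assert len({n.kmer for n in kmers}) == 2


class TestThreading:
    def test_perfect_query_increments_without_new_nodes(self, small_backbone):
        graph = build_backbone_graph(small_backbone, k=1, g=1)
        n_nodes = len(graph.nodes)
        add_alignment(graph, perfect_m5("r", small_backbone, 2, 9))
        assert len(graph.nodes) == n_nodes
        for i, edge in enumerate(graph.backbone_edges(), start=1):
            covered = 2 <= i - 1 and i <= 8  # steps fully inside [2, 9)
            assert edge.weight == (2.0 if covered else 1.0)

    def test_backbone_as_query_doubles_every_edge(self, small_backbone):
        graph = build_backbone_graph(small_backbone, k=1, g=1)
        n_nodes = len(graph.nodes)
        add_alignment(graph, perfect_m5("self", small_backbone, 0, 12))
        assert len(graph.nodes) == n_nodes
        assert all(e.weight == 2.0 for e in graph.backbone_edges())

    def test_insertion_allocates_branch_chain(self, small_backbone):
        # backbone ACGTACGGTACT; query inserts GG between positions 3 and 4
        graph = build_backbone_graph(small_backbone, k=1, g=1)
        rec = gapped_m5("ins", small_backbone, 0, "ACGTGGACGGTACT", "ACGT--ACGGTACT")
        add_alignment(graph, rec)
        branch_nodes = sorted(n for n in graph.nodes if n.offset >= 1)
        assert branch_nodes == [NodeKey(3, 1, "G"), NodeKey(3, 2, "G")]
        labels = {
            (e.src.offset, e.dst.offset): e.label
            for e in graph.edges()
            if e.src.offset >= 1 or e.dst.offset >= 1
        }
        assert labels == {(0, 1): "G", (1, 2): "G", (2, 0): "A"}

    def test_identical_variant_from_two_queries_merges(self, small_backbone):
        graph = build_backbone_graph(small_backbone, k=1, g=1)
        rec1 = gapped_m5("a", small_backbone, 0, "ACGTGGACGGTACT", "ACGT--ACGGTACT")
        rec2 = gapped_m5("b", small_backbone, 0, "ACGTGGACGGTACT", "ACGT--ACGGTACT")
        add_alignment(graph, rec1)
        nodes_after_first = set(graph.nodes)
        add_alignment(graph, rec2)
        assert set(graph.nodes) == nodes_after_first
        branch_edges = [
            e for e in graph.edges() if e.src.offset >= 1 or e.dst.offset >= 1
        ]
        assert all(e.weight == 2.0 for e in branch_edges)

    def test_duplicate_alignment_doubles_its_contribution(self, small_backbone):
        graph1 = build_backbone_graph(small_backbone, k=1, g=1)
        rec = gapped_m5("v", small_backbone, 0, "ACGTACAGTACT", "ACGTACGGTACT")
        add_alignment(graph1, rec)
        single = {
            (e.src, e.dst, e.label): e.weight for e in graph1.edges()
        }
        graph2 = build_backbone_graph(small_backbone, k=1, g=1)
        add_alignment(graph2, rec)
        add_alignment(graph2, rec)
        double = {
            (e.src, e.dst, e.label): e.weight for e in graph2.edges()
        }
        assert set(single) == set(double)
        for key, w in double.items():
            base = 1.0 if key in {  # backbone edges started at 1
                (e.src, e.dst, e.label) for e in graph2.backbone_edges()
            } or key[0].anchor == -1 else 0.0
            assert w - base == pytest.approx(2 * (single[key] - base))

    def test_mismatch_at_anchor_creates_branch_node(self, small_backbone):
        graph = build_backbone_graph(small_backbone, k=1, g=1)
        rec = gapped_m5("m", small_backbone, 0, "ACGTACAGTACT", "ACGTACGGTACT")
        add_alignment(graph, rec)
        assert NodeKey(6, 1, "A") in graph.nodes

    def test_full_deletion_jumps_anchor_with_short_label(self, small_backbone):
        # query deletes backbone positions 4-5 entirely (k=1: two anchors)
        graph = build_backbone_graph(small_backbone, k=1, g=1)
        rec = gapped_m5("d", small_backbone, 0, "ACGT--GGTACT", "ACGTACGGTACT")
        add_alignment(graph, rec)
        jump = [
            e for e in graph.edges()
            if e.src == graph.backbone_node(3) and e.dst == graph.backbone_node(6)
        ]
        assert len(jump) == 1 and jump[0].label == "G" and jump[0].weight == 1.0

    def test_acyclic_rank_order_preserved(self, small_backbone):
        rng = random.Random(7)
        graph = build_backbone_graph(small_backbone, k=1, g=1)
        variants = [
            gapped_m5("a", small_backbone, 0, "ACGTGGACGGTACT", "ACGT--ACGGTACT"),
            gapped_m5("b", small_backbone, 0, "ACGT--GGTACT", "ACGTACGGTACT"),
            gapped_m5("c", small_backbone, 0, "ACGTACAGTACT", "ACGTACGGTACT"),
        ]
        for rec in rng.sample(variants, len(variants)):
            add_alignment(graph, rec)
        for edge in graph.edges():
            assert (edge.src.anchor, edge.src.offset) < (
                edge.dst.anchor,
                edge.dst.offset,
            )

    def test_error_free_queries_cut_weight(self, small_backbone):
        rng = random.Random(3)
        graph = build_backbone_graph(small_backbone, k=1, g=1)
        spans = []
        for i in range(25):
            start = rng.randrange(0, 9)
            end = rng.randrange(start + 2, 13)
            spans.append((start, end))
            add_alignment(graph, perfect_m5(f"q{i}", small_backbone, start, end))
        for i, edge in enumerate(graph.backbone_edges(), start=1):
            spanning = sum(1 for s, e in spans if s <= i - 1 and i <= e - 1)
            assert edge.weight == 1.0 + spanning

    def test_short_overhang_alignment_counts_as_skipped(self, small_backbone):
        graph = build_backbone_graph(small_backbone, k=1, g=1)
        add_alignment(graph, perfect_m5("tiny", small_backbone, 5, 6))
        assert graph.skipped_alignments == 1

    def test_wrong_target_name_rejected(self, small_backbone):
        graph = build_backbone_graph(small_backbone, k=1, g=1)
        other = SequenceRecord("other", small_backbone.sequence)
        with pytest.raises(ValueError, match="targets"):
            add_alignment(graph, perfect_m5("r", other, 0, 12))


class TestMultiplicity:
    def test_fresh_graph_is_one(self, small_backbone):
        graph = build_backbone_graph(small_backbone, k=1, g=1)
        assert average_backbone_multiplicity(graph) == 1.0

    def test_arithmetic_mean_of_backbone_edges(self, small_backbone):
        graph = build_backbone_graph(SequenceRecord("b", "ACG"), k=1, g=1)
        edges = graph.backbone_edges()
        edges[0].weight = 3.0
        edges[1].weight = 5.0
        assert average_backbone_multiplicity(graph) == 4.0

    def test_full_span_queries_raise_mean_to_n_plus_one(self, small_backbone):
        graph = build_backbone_graph(small_backbone, k=1, g=1)
        n = 7
        for i in range(n):
            add_alignment(graph, perfect_m5(f"q{i}", small_backbone, 0, 12))
        assert average_backbone_multiplicity(graph) == pytest.approx(n + 1)


def test_dot_dump_mentions_every_edge(small_backbone):
    graph = build_backbone_graph(small_backbone, k=1, g=1)
    dot = to_dot(graph)
    assert dot.count("->") == graph.n_edges()
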