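"""Scoring and search: sparsity penalty, heaviest path, polishing rounds.

The path with the largest sum of edge weights approximates the most
likely underlying sequence, but a direct search favours long
single-read insertion errors (many edges, each with weight 1).  A soft
threshold — subtracting a penalty from every edge weight, an l1 penalty
on the weights — makes weakly supported paths lose to well-supported
ones.  The penalty is the larger of a fixed floor ``c`` and an adaptive
fraction ``t`` of the average backbone multiplicity, so it scales with
sequencing coverage.  Defaults are ``c = 2``, ``t = 0.2``.

With high-quality (NGS) queries available, edges they support receive an
extra boost ``b`` per supporting alignment, steering the path search
toward the accurate data (the hybrid mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .io_formats import M5Record, SequenceRecord, best_hit_filter
from .kmer_graph import (
    ConsensusGraph,
    NodeKey,
    add_alignment,
    average_backbone_multiplicity,
    build_backbone_graph,
)

__all__ = [
    "PenaltyParams",
    "ConsensusParams",
    "RoundStats",
    "compute_penalty",
    "adjust_weights",
    "heaviest_path",
    "consensus_round",
    "iterate_consensus",
]

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")


@dataclass
class PenaltyParams:
    """Soft-threshold parameters: fixed floor ``c``, adaptive fraction ``t``."""

    c: float = 2.0
    t: float = 0.2

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be >= 0")
        if not (0.0 <= self.t <= 1.0):
            raise ValueError("t must be in [0, 1]")


@dataclass
class ConsensusParams:
    """Parameters of one polishing run.

    Working ranges: ``k`` 1-3, ``g`` 1-5 (``k=1, g=1`` for ~15% error
    data, ``k=2, g=2`` for ~40%), boost ``b`` 5-15 for hybrid inputs.
    """

    k: int = 1
    g: int = 1
    penalty: PenaltyParams = field(default_factory=PenaltyParams)
    boost_b: float = 0.0
    hq_prefix: str = "hq"
    rounds: int = 2

    def __post_init__(self) -> None:
        if self.boost_b < 0:
            raise ValueError("boost_b must be >= 0")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class RoundStats:
    """Per-round diagnostics reported by :func:`consensus_round`."""

    contig: str
    n_alignments: int
    n_skipped: int
    n_nodes: int
    n_edges: int
    mean_backbone_multiplicity: float
    penalty: float
    consensus_length: int


def compute_penalty(graph: ConsensusGraph, params: PenaltyParams) -> float:
    """max(c, t * average backbone multiplicity)."""
    return max(params.c, params.t * average_backbone_multiplicity(graph))


def adjust_weights(graph: ConsensusGraph, penalty: float) -> None:
    """Soft-threshold every edge: adjusted = weight - penalty.

    Negative adjusted weights are kept (never clamped or deleted); the
    path search simply disfavours them.  Raw weights are preserved.
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    for edge in graph.edges():
        edge.adjusted_weight = edge.weight - penalty


def search_scores(
    graph: ConsensusGraph,
) -> Tuple[Dict[NodeKey, float], Dict[NodeKey, Tuple[NodeKey, object]]]:
    """Single-pass relaxation in topological order.

    Nodes are visited in (anchor, branch_offset) rank order, so every
    edge into a node is relaxed before its out-edges.  Each node keeps
    its best accumulated adjusted score and predecessor.  Only the
    virtual source starts at 0; everything else starts at -inf, so every
    reported path begins at the backbone start.  Score ties prefer a
    backbone predecessor, then the lexicographically smaller incoming
    label, for determinism.
    """
    order = sorted(graph.nodes)
    score: Dict[NodeKey, float] = {graph.source: 0.0}
    pred: Dict[NodeKey, Tuple[NodeKey, object]] = {}
    tie: Dict[NodeKey, Tuple[int, str]] = {}
    for node in order:
        acc = score.get(node)
        if acc is None:
            continue  # unreachable from the source
        for edge in graph.out_edges(node):
            cand = acc + edge.adjusted_weight
            dst = edge.dst
            tkey = (0 if node.offset == 0 else 1, edge.label)
            cur = score.get(dst)
            if cur is None or cand > cur or (cand == cur and tkey < tie[dst]):
                score[dst] = cand
                pred[dst] = (node, edge)
                tie[dst] = tkey
    return score, pred


def heaviest_path(graph: ConsensusGraph) -> SequenceRecord:
    """Backtrack from the highest-scored backbone node; emit the path.

    The returned sequence is the source k-mer emission plus the
    concatenated edge labels along the back-tracked path; the backbone
    tail (bases after the last anchor's k-mer) is appended only when the
    terminal is the final backbone anchor.  Terminal ties prefer the
    larger anchor index (the longer consensus).
    """
    score, pred = search_scores(graph)
    best_key: Optional[Tuple[float, int]] = None
    terminal: Optional[NodeKey] = None
    for node, acc in score.items():
        if node.anchor >= 0 and node.offset == 0:
            key = (acc, node.anchor)
            if best_key is None or key > best_key:
                best_key = key
                terminal = node
    assert terminal is not None  # the backbone path always exists
    labels: List[str] = []
    node = terminal
    while node != graph.source:
        node, edge = pred[node]
        labels.append(edge.label)
    sequence = "".join(reversed(labels))
    if terminal.anchor == graph.n_anchors - 1:
        sequence += graph.tail
    return SequenceRecord(name=graph.name, sequence=sequence)


def consensus_round(
    backbone: SequenceRecord,
    alignments: Sequence[M5Record],
    params: ConsensusParams,
    stats_out: Optional[List[RoundStats]] = None,
) -> SequenceRecord:
    """One polishing round: filter, build, thread, penalize, search.

    High-quality queries (names starting with ``params.hq_prefix``) use
    increment ``1 + boost_b`` per edge they support; ordinary queries use
    1.  With no surviving alignments the backbone is returned unchanged.
    """
    routed = [a for a in alignments if a.tName == backbone.name]
    filtered = best_hit_filter(routed)
    if not filtered:
        logger.warning(
            "no alignments for contig %s; returning backbone unchanged",
            backbone.name,
        )
        if stats_out is not None:
            stats_out.append(
                RoundStats(backbone.name, 0, 0, 0, 0, 0.0, 0.0, len(backbone))
            )
        return backbone
    graph = build_backbone_graph(backbone, params.k, params.g)
    for aln in filtered:
        increment = 1.0
        if params.boost_b > 0 and aln.qName.startswith(params.hq_prefix):
            increment += params.boost_b
        add_alignment(graph, aln, increment)
    penalty = compute_penalty(graph, params.penalty)
    adjust_weights(graph, penalty)
    result = heaviest_path(graph)
    stats = RoundStats(
        contig=backbone.name,
        n_alignments=len(filtered),
        n_skipped=graph.skipped_alignments,
        n_nodes=len(graph.nodes),
        n_edges=graph.n_edges(),
        mean_backbone_multiplicity=average_backbone_multiplicity(graph),
        penalty=penalty,
        consensus_length=len(result),
    )
    logger.info(
        "contig %s: %d alignments (%d skipped), %d nodes, %d edges, "
        "mean multiplicity %.2f, penalty %.2f, consensus %d bp",
        stats.contig,
        stats.n_alignments,
        stats.n_skipped,
        stats.n_nodes,
        stats.n_edges,
        stats.mean_backbone_multiplicity,
        stats.penalty,
        stats.consensus_length,
    )
    if stats_out is not None:
        stats_out.append(stats)
    return result


AlignerFn = Callable[[Sequence[SequenceRecord], SequenceRecord], List[M5Record]]


def iterate_consensus(
    backbone: SequenceRecord,
    reads: Sequence[SequenceRecord],
    params: ConsensusParams,
    aligner: AlignerFn,
    stats_out: Optional[List[RoundStats]] = None,
) -> List[SequenceRecord]:
    """Iterative polishing: each round's consensus seeds the next round.

    Reads are re-aligned to the current consensus every round; all
    intermediate consensuses are returned so round-series error curves
    can be computed.
    """
    current = backbone
    results: List[SequenceRecord] = []
    for round_idx in range(1, params.rounds + 1):
        try:
            alignments = aligner(reads, current)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"aligner failed in round {round_idx}") from exc
        current = consensus_round(current, alignments, params, stats_out)
        results.append(current)
    return results
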