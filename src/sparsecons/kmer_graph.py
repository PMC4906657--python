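"""The position-specific sparse k-mer graph.

Unlike a de Bruijn graph, identical k-mer strings at different backbone
positions are *distinct* nodes: the graph is anchored to the draft
sequence being polished.  An anchor k-mer is stored only every ``g``
bases (the "sparse" part), and edges carry the intervening bases as
their label, so traversing an edge appends its label to the growing
consensus.  Edge weights count the alignments supporting each link and
are the algorithm's proxy for confidence.

Node identity (and therefore the implicit merge rule) is the triple
``(anchor, branch_offset, kmer)``:

* ``(i, 0, K)`` is the backbone node at anchor ``i`` (k-mer ``K`` drawn
  from the backbone itself);
* ``(i, 1, Q)`` is a query k-mer ``Q`` that disagrees with the backbone
  at anchor ``i``;
* ``(i, o >= src.offset+1, Q)`` are successive nodes along an inserted
  branch hanging off anchor ``i``.

Two queries proposing the same variant in the same place thread through
the same nodes and simply add weight; the same variant one anchor over
does not merge.  The virtual source node ``(-1, 0, "")`` precedes anchor
0 and its single out-edge emits the first anchor's full k-mer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, NamedTuple, Optional, Tuple

from .io_formats import M5Record, SequenceRecord

__all__ = [
    "NodeKey",
    "WeightedEdge",
    "ConsensusGraph",
    "build_backbone_graph",
    "add_alignment",
    "average_backbone_multiplicity",
    "to_dot",
]


class NodeKey(NamedTuple):
    anchor: int
    offset: int
    kmer: str


@dataclass
class WeightedEdge:
    src: NodeKey
    dst: NodeKey
    label: str
    weight: float
    adjusted_weight: float


SOURCE = NodeKey(-1, 0, "")


class ConsensusGraph:
    """DAG over which the heaviest consensus path is searched."""

    def __init__(self, backbone: SequenceRecord, k: int, g: int) -> None:
        if k < 1 or g < 1:
            raise ValueError("k and g must be >= 1")
        if len(backbone.sequence) < k:
            raise ValueError(
                f"backbone {backbone.name!r} is shorter than k={k}"
            )
        self.k = k
        self.g = g
        self.name = backbone.name
        self.backbone = backbone.sequence
        self.n_anchors = (len(self.backbone) - k) // g + 1
        self.anchors = [i * g for i in range(self.n_anchors)]
        # bases after the last anchor's k-mer, carried outside the graph
        self.tail = self.backbone[(self.n_anchors - 1) * g + k :]
        self.source = SOURCE
        self.nodes: set = {SOURCE}
        self._adj: Dict[NodeKey, Dict[Tuple[NodeKey, str], WeightedEdge]] = {}
        self.skipped_alignments = 0

        self.add_edge(SOURCE, self.backbone_node(0), self.backbone[:k], 1.0)
        for i in range(1, self.n_anchors):
            self.add_edge(
                self.backbone_node(i - 1),
                self.backbone_node(i),
                self.backbone_label(i),
                1.0,
            )

    # -- structure ---------------------------------------------------------

    def backbone_kmer(self, i: int) -> str:
        pos = i * self.g
        return self.backbone[pos : pos + self.k]

    def backbone_node(self, i: int) -> NodeKey:
        return NodeKey(i, 0, self.backbone_kmer(i))

    def backbone_label(self, i: int) -> str:
        """Label of the backbone edge *into* anchor ``i`` (i >= 1)."""
        return self.backbone[(i - 1) * self.g + self.k : i * self.g + self.k]

    def add_edge(
        self, src: NodeKey, dst: NodeKey, label: str, increment: float
    ) -> WeightedEdge:
        """Create the edge or add ``increment`` to its weight.

        ``(src, dst, label)`` uniquely identifies an edge; re-adding it
        never duplicates.
        """
        self.nodes.add(src)
        self.nodes.add(dst)
        out = self._adj.setdefault(src, {})
        edge = out.get((dst, label))
        if edge is None:
            edge = WeightedEdge(src, dst, label, increment, increment)
            out[(dst, label)] = edge
        else:
            edge.weight += increment
            edge.adjusted_weight = edge.weight
        return edge

    def out_edges(self, node: NodeKey) -> Iterable[WeightedEdge]:
        return self._adj.get(node, {}).values()

    def edges(self) -> Iterable[WeightedEdge]:
        for out in self._adj.values():
            yield from out.values()

    def n_edges(self) -> int:
        return sum(len(out) for out in self._adj.values())

    def backbone_edges(self) -> List[WeightedEdge]:
        """The anchor-to-anchor edges, excluding the virtual-source edge."""
        result = []
        for i in range(1, self.n_anchors):
            edge = self._adj[self.backbone_node(i - 1)][
                (self.backbone_node(i), self.backbone_label(i))
            ]
            result.append(edge)
        return result


def build_backbone_graph(backbone: SequenceRecord, k: int, g: int) -> ConsensusGraph:
    """Initial linear graph: one node per g-spaced anchor, all weights 1."""
    return ConsensusGraph(backbone, k, g)


def average_backbone_multiplicity(graph: ConsensusGraph) -> float:
    """Mean weight over backbone-path edges (branch edges excluded).

    With a single anchor there are no backbone edges and the initial
    multiplicity 1.0 is returned.
    """
    edges = graph.backbone_edges()
    if not edges:
        return 1.0
    return sum(e.weight for e in edges) / len(edges)


def add_alignment(
    graph: ConsensusGraph, aln: M5Record, increment: float = 1.0
) -> int:
    """Thread one alignment through the graph, adding ``increment`` of weight.

    The alignment columns are scanned once.  The query is "at" anchor
    ``i`` when the column consuming backbone position ``i*g + k - 1`` is
    reached; the query bases consumed between consecutive anchor visits
    define that step's path.  A step that retraces the backbone (or an
    existing branch) increments weights; a novel step allocates branch
    nodes every ``g`` emitted bases.  Anchors whose k-mer window is
    entirely deleted in the query are jumped, producing a deletion edge
    whose label may be shorter than ``g`` (possibly empty).  Partial
    first/last steps (overhangs) are discarded.

    Returns the number of anchor-to-anchor steps credited; an alignment
    crediting none is counted in ``graph.skipped_alignments``.
    """
    if aln.tName != graph.name:
        raise ValueError(
            f"alignment targets {aln.tName!r}, graph is for {graph.name!r}"
        )
    k, g = graph.k, graph.g
    q = aln.qAlignedSeq
    t = aln.tAlignedSeq

    # pass 1: per-anchor count of query bases aligned within the anchor's
    # k-mer window [i*g, i*g+k); zero coverage means the window was deleted
    cov: Dict[int, int] = {}
    tpos = aln.tStart
    for qc, tc in zip(q, t):
        if tc != "-":
            if qc != "-":
                i_lo = max(0, -(-(tpos - k + 1) // g))
                i_hi = tpos // g
                for i in range(i_lo, i_hi + 1):
                    cov[i] = cov.get(i, 0) + 1
            tpos += 1

    # pass 2: thread anchor to anchor
    u: Optional[NodeKey] = None
    prev_tail = ""
    step_bases: List[str] = []
    tailbuf = ""  # rolling last <=k emitted query bases
    emitted = 0
    steps = 0
    tpos = aln.tStart
    for qc, tc in zip(q, t):
        if qc != "-":
            if u is not None:
                step_bases.append(qc)
            tailbuf = (tailbuf + qc)[-k:]
            emitted += 1
        if tc != "-":
            p = tpos
            tpos += 1
            if p + 1 >= k and (p + 1 - k) % g == 0:
                i = (p + 1 - k) // g
                if not (0 <= i < graph.n_anchors):
                    continue
                if i * g < aln.tStart or p >= aln.tEnd:
                    continue  # window not fully inside the alignment span
                if emitted < k or cov.get(i, 0) == 0:
                    continue  # leading partial, or window deleted: jump anchor
                qk = tailbuf
                bnode = graph.backbone_node(i)
                if qk == bnode.kmer and "N" not in qk:
                    v = bnode
                else:
                    v = NodeKey(i, 1, qk)
                if u is not None:
                    _emit_step(graph, u, v, "".join(step_bases), prev_tail, increment)
                    steps += 1
                u = v
                step_bases = []
                prev_tail = tailbuf
    if steps == 0:
        graph.skipped_alignments += 1
    return steps


def _emit_step(
    graph: ConsensusGraph,
    u: NodeKey,
    v: NodeKey,
    s: str,
    context: str,
    increment: float,
) -> None:
    """Credit one anchor-to-anchor step carrying query bases ``s``.

    ``context`` is the rolling k-mer just before the step started; it
    seeds the k-mers of any intermediate branch nodes so that identical
    variants from different queries land on identical node keys.
    """
    if (
        u.offset == 0
        and v.offset == 0
        and v.anchor == u.anchor + 1
        and s == graph.backbone_label(v.anchor)
    ):
        graph.add_edge(u, v, s, increment)
        return
    if not s:
        # the whole step was deleted in the query: a single (possibly
        # empty-labelled) jump edge
        graph.add_edge(u, v, "", increment)
        return
    g, k = graph.g, graph.k
    pieces = [s[j : j + g] for j in range(0, len(s), g)]
    cur = u
    rolled = context
    for idx, piece in enumerate(pieces):
        if idx == len(pieces) - 1:
            nxt = v
        else:
            rolled = (rolled + piece)[-k:]
            nxt = NodeKey(u.anchor, u.offset + idx + 1, rolled)
        graph.add_edge(cur, nxt, piece, increment)
        cur = nxt


def to_dot(graph: ConsensusGraph) -> str:
    """GraphViz DOT dump for debugging and documentation."""
    def name(n: NodeKey) -> str:
        return f"\"{n.anchor}:{n.offset}:{n.kmer or 'src'}\""

    lines = ["digraph consensus {", "  rankdir=LR;"]
    for edge in graph.edges():
        label = edge.label or "-"
        lines.append(
            f"  {name(edge.src)} -> {name(edge.dst)} "
            f"[label=\"{label}/{edge.weight:g}\"];"
        )
    lines.append("}")
    return "\n".join(lines)
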