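"""Re-alignment of a read to the variant graph.

Every path through the graph is a potential new alignment.  All paths whose
first node lies within ``w`` reference positions of the start of the read's
existing alignment are explored with a heap-ordered breadth-first traversal:
the heap sorts partial paths by the canonical node order, then path length,
then score, so the traversal is a dynamic program over the DAG the graph
forms in the read's strand direction.  Extending a path by a node whose base
matches the next read base costs nothing; a mismatch costs the base's Phred
quality (capped).  Because scores only decrease, the score of the read's
*original* alignment (recomputed against the reference) bounds the search:
any partial path scoring below it can never win and is dropped.  Paths are
additionally pruned by the coverage filters (``c``/``p``) so that only
well-supported nodes and edges are traversed.

If no surviving complete path scores at least as well as the original
alignment, the original alignment is returned unchanged.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

from .colorspace import ColorRead, complement, _CODE
from .variant_graph import (
    FilterTable,
    GraphNode,
    NodeType,
    VariantGraph,
    cigar_reference_span,
    node_sort_key,
    parse_cigar,
)

#: Maximum per-base mismatch penalty; qualities above this are capped.
QUALITY_CAP = 40


@dataclass
class RealignConfig:
    """Tunable re-alignment parameters.

    w:
        Start-window size in reference positions; paths may begin at any
        node within ``w`` of the original alignment start (the 5' end in
        the read's strand direction).
    c:
        Minimum node/edge coverage (absolute filter).
    p:
        Minimum binomial edge probability (depth-relative filter); combined
        with ``c`` by logical OR.
    max_heap:
        Safety valve — if the heap outgrows this, the read keeps its
        original alignment and is flagged as skipped.
    max_node_visits:
        Optional cap on distinct path lengths retained per node (0 =
        unlimited).  Left unlimited by default: traversal cost is already
        bounded by the score bound, the coverage filters and the heap
        valve, and any positive cap can prune an optimal path when start
        offsets or deletions give a node more than that many lengths.
    shortcut_perfect:
        When the original alignment already scores 0 (no penalised
        mismatch) nothing can strictly beat it and ties prefer the
        original, so the search can be skipped entirely.
    """

    w: int = 20
    c: int = 2
    p: float = 0.1
    max_heap: int = 8192
    max_node_visits: int = 0
    shortcut_perfect: bool = True


@dataclass
class ReadRecord:
    """A read with its bases, qualities and original alignment."""

    name: str
    bases: str
    base_qualities: Sequence[int]
    strand: str  # '+' or '-'
    position: int  # 1-based original alignment start
    cigar: str
    color: Optional[ColorRead] = None

    def __post_init__(self):
        if len(self.bases) != len(self.base_qualities):
            raise ValueError("bases and base_qualities lengths differ")


class HeapEntry(NamedTuple):
    """One partial path in the traversal heap."""

    node: GraphNode
    path_length: int
    score: float
    predecessor: Optional["HeapEntry"]


@dataclass
class AlignmentPath:
    """A scored complete path, convertible to position + CIGAR."""

    nodes: tuple
    score: float
    position: int
    cigar: str
    realigned: bool
    skipped: bool = False
    original_score: float = 0.0
    expansions: int = 0


# --------------------------------------------------------------------- #
# scoring primitives


def score_extension(
    previous_score: float, read_base: str, node_base: str, quality: int
) -> float:
    """Extend a path score by one base comparison.

    Match: unchanged.  Mismatch: subtract the base quality, capped at
    :data:`QUALITY_CAP`.
    """
    if read_base == node_base:
        return previous_score
    return previous_score - min(quality, QUALITY_CAP)


def prune_heap(
    entries: Sequence[HeapEntry], original_score: float = float("-inf")
) -> Optional[HeapEntry]:
    """Dominance pruning for entries sharing ``(node, path_length)``.

    Only the maximum-score entry survives; any entry scoring below the
    original alignment's score is dropped outright (the score is monotone
    non-increasing, so such a path can never win).
    """
    best = None
    for e in entries:
        if e.score < original_score:
            continue
        if best is None or e.score > best.score:
            best = e
    return best


def collect_start_nodes(
    graph: VariantGraph, original_start: int, w: int, strand: str = "+"
) -> list[GraphNode]:
    """All nodes within ``w`` positions of the original alignment start.

    Ordered canonically; for reverse-strand reads the traversal runs
    backwards along the reference, so the order is reversed.
    """
    out: list[GraphNode] = []
    for pos in range(original_start - w, original_start + w + 1):
        out.extend(graph.pos_nodes.get(pos, ()))
    out.sort(key=node_sort_key)
    if strand == "-":
        out.reverse()
    return out


# --------------------------------------------------------------------- #
# original alignment scoring


def _split_clips(ops):
    """Strip hard clips, return (lead_soft, core_ops, tail_soft)."""
    ops = [(op, ln) for op, ln in ops if op != "H"]
    lead = tail = 0
    if ops and ops[0][0] == "S":
        lead = ops[0][1]
        ops = ops[1:]
    if ops and ops[-1][0] == "S":
        tail = ops[-1][1]
        ops = ops[:-1]
    return lead, ops, tail


def _reference_path_nodes(
    graph: VariantGraph, core_bases: str, position: int, core_ops
) -> list[GraphNode]:
    """Node sequence of the alignment's *claimed* target sequence.

    Aligned (M) columns map to REFERENCE nodes regardless of the read base,
    insertions to INSERTION nodes carrying the read's bases.  Scoring the
    read against this sequence gives the conventional alignment score of
    the original alignment.
    """
    path: list[GraphNode] = []
    ref_pos = position
    read_i = 0
    for op, ln in core_ops:
        if op in ("M", "=", "X"):
            for _ in range(ln):
                path.append(
                    GraphNode(ref_pos, graph.ref_base(ref_pos), NodeType.REFERENCE, 0)
                )
                ref_pos += 1
                read_i += 1
        elif op == "I":
            for k in range(ln):
                path.append(
                    GraphNode(ref_pos, core_bases[read_i], NodeType.INSERTION, k + 1)
                )
                read_i += 1
        elif op in ("D", "N"):
            ref_pos += ln
        else:  # pragma: no cover
            raise ValueError(f"unexpected CIGAR op {op!r} in core")
    return path


def _normalize_cigar(cigar) -> str:
    """Canonical CIGAR string: =/X collapsed to M, adjacent runs merged."""
    out: list[list] = []
    for op, ln in parse_cigar(cigar):
        if op in ("=", "X"):
            op = "M"
        if out and out[-1][0] == op:
            out[-1][1] += ln
        else:
            out.append([op, ln])
    return "".join(f"{ln}{op}" for op, ln in out)


def path_to_alignment(
    nodes: Sequence[GraphNode], lead_clip: int = 0, tail_clip: int = 0
) -> tuple[int, str]:
    """Convert a genome-ordered node path to ``(position, CIGAR)``.

    Zero-offset nodes become M, insertion nodes I, and positional jumps
    greater than one between zero-offset nodes become D of the intervening
    length.  Soft-clip lengths are re-attached verbatim.  The start position
    is the first zero-offset node's position (the anchor, for paths that
    lead with insertion nodes).
    """
    ops: list[list] = []

    def emit(op, ln=1):
        if ops and ops[-1][0] == op:
            ops[-1][1] += ln
        else:
            ops.append([op, ln])

    pos = None
    prev0 = None
    for n in nodes:
        if n.offset > 0:
            emit("I")
        else:
            if prev0 is not None and n.position > prev0 + 1:
                emit("D", n.position - prev0 - 1)
            emit("M")
            if pos is None:
                pos = n.position
            prev0 = n.position
    if pos is None:
        raise ValueError("path contains no zero-offset node")
    if lead_clip:
        ops.insert(0, ["S", lead_clip])
    if tail_clip:
        emit("S", tail_clip)
    return pos, "".join(f"{ln}{op}" for op, ln in ops)


def _path_indel_ops(nodes) -> int:
    count = 0
    prev0 = None
    in_ins = False
    for n in nodes:
        if n.offset > 0:
            if not in_ins:
                count += 1
                in_ins = True
        else:
            in_ins = False
            if prev0 is not None and n.position > prev0 + 1:
                count += 1
            prev0 = n.position
    return count


# --------------------------------------------------------------------- #
# the traversal


def _score_node_sequence(nodes, reverse, t_bases, t_quals, color_ctx):
    """Score a fixed node sequence in traversal order (used for the bound)."""
    seq = nodes[::-1] if reverse else nodes
    score = 0.0
    prev = None
    for i, node in enumerate(seq):
        score += _step_delta(i, prev, node, t_bases, t_quals, color_ctx)
        prev = node
    return score


def _step_delta(i, prev_node, node, t_bases, t_quals, color_ctx):
    """Penalty for consuming traversal-order base ``i`` at ``node``."""
    if color_ctx is None:
        if t_bases[i] == node.base:
            return 0
        q = t_quals[i]
        return -(q if q < QUALITY_CAP else QUALITY_CAP)
    t_colors, t_cquals, start_code = color_ctx
    prev_code = start_code if prev_node is None else _CODE.get(prev_node.base)
    cur_code = _CODE.get(node.base)
    obs = t_colors[i]
    if prev_code is None or cur_code is None or obs > 3:
        return 0
    if prev_code ^ cur_code == obs:
        return 0
    q = t_cquals[i]
    return -(q if q < QUALITY_CAP else QUALITY_CAP)


def _original_result(read, orig_score, expansions=0, skipped=False):
    return AlignmentPath(
        nodes=(),
        score=orig_score,
        position=read.position,
        cigar=_normalize_cigar(read.cigar),
        realigned=False,
        skipped=skipped,
        original_score=orig_score,
        expansions=expansions,
    )


def realign_read(
    graph: VariantGraph,
    read: ReadRecord,
    config: Optional[RealignConfig] = None,
    filters: Optional[FilterTable] = None,
) -> AlignmentPath:
    """Re-align one read to the variant graph.

    Returns the maximum-score complete path among paths surviving the
    coverage filters and the original-score bound, converted to a new
    position/CIGAR; ties prefer the original alignment, then fewer indel
    operations, then the leftmost start, then canonical node order.  If no
    surviving path scores at least the original alignment's score, the
    original alignment is returned with ``realigned=False``.
    """
    cfg = config or RealignConfig()
    ft = filters if filters is not None else FilterTable(cfg.c, cfg.p)

    ops = parse_cigar(read.cigar)
    lead, core_ops, tail = _split_clips(ops)
    nb = len(read.bases)
    core = read.bases[lead : nb - tail] if tail else read.bases[lead:]
    core_quals = (
        list(read.base_qualities[lead : nb - tail])
        if tail
        else list(read.base_qualities[lead:])
    )
    L = len(core)
    if L == 0 or not core_ops:
        return _original_result(read, 0.0)

    reverse = read.strand == "-"
    ref_span = cigar_reference_span(core_ops)
    anchor = read.position + ref_span - 1 if reverse else read.position

    # traversal-order read arrays (reverse reads are walked 3'->5' along the
    # reference, i.e. in their sequencing order)
    t_bases = core[::-1] if reverse else core
    t_quals = core_quals[::-1] if reverse else core_quals

    color_ctx = None
    if read.color is not None:
        cr = read.color
        if len(cr.colors) != nb:
            raise ValueError("color read must carry one color per base")
        # sequencing-order index of the first core base
        off = tail if reverse else lead
        t_colors = cr.colors[off : off + L]
        t_cquals = cr.color_qualities[off : off + L]
        if off > 0:
            # transition into the core's first base starts from the adjacent
            # clipped base rather than the adapter
            if reverse:
                prev_base = read.bases[nb - tail]
            else:
                prev_base = read.bases[lead - 1]
        else:
            prev_base = complement(cr.adapter) if reverse else cr.adapter
        color_ctx = (t_colors, t_cquals, _CODE.get(prev_base))

    # original alignment score, recomputed against the reference
    orig_ref_nodes = _reference_path_nodes(graph, core, read.position, core_ops)
    orig_score = _score_node_sequence(orig_ref_nodes, reverse, t_bases, t_quals, color_ctx)

    if cfg.shortcut_perfect and orig_score == 0:
        # nothing can strictly beat a penalty-free alignment and ties keep
        # the original, so skip the search
        return _original_result(read, orig_score)

    starts = collect_start_nodes(graph, anchor, cfg.w, read.strand)
    if not starts:
        return _original_result(read, orig_score)

    # the graph path the original alignment takes (for tie preference)
    try:
        orig_path = graph.alignment_path(core, read.position, core_ops, core_quals)
    except (IndexError, ValueError):
        orig_path = None
    # traversal-order view of the original path: lets the dominance step
    # keep the original-path prefix on score ties, so the "prefer the
    # original alignment" tie-break survives DP state merging
    orig_traversal = None
    if orig_path is not None and len(orig_path) == L:
        orig_traversal = orig_path[::-1] if reverse else orig_path

    if reverse:
        keyf = _reverse_key
        direction = -1
    else:
        keyf = node_sort_key
        direction = 1

    node_cov = graph.nodes
    adj = graph.adj
    pos_n = graph.position_n
    passes = ft.passes
    visit_limit = cfg.max_node_visits  # 0 = unlimited
    max_heap = cfg.max_heap

    heap: list = []
    push = heapq.heappush
    pop = heapq.heappop
    best_state: dict = {}
    node_lengths: dict = {}
    serial = 0
    for sn in starts:
        if not passes(node_cov[sn], pos_n.get(sn.position, 0)):
            continue
        sc = _step_delta(0, None, sn, t_bases, t_quals, color_ctx)
        if sc < orig_score:
            continue
        on_orig = orig_traversal is not None and orig_traversal[0] == sn
        st = (sn, 1)
        prev_best = best_state.get(st)
        if prev_best is not None and prev_best >= (sc, on_orig):
            continue
        if prev_best is None and visit_limit:
            cnt = node_lengths.get(sn, 0)
            if cnt >= visit_limit:
                continue
            node_lengths[sn] = cnt + 1
        best_state[st] = (sc, on_orig)
        serial += 1
        push(heap, (keyf(sn), 1, -sc, serial, sn, None, on_orig))

    best_score = None
    best_tie = None
    best_nodes = None
    expansions = 0

    while heap:
        if len(heap) > max_heap:
            return _original_result(read, orig_score, expansions, skipped=True)
        entry = pop(heap)
        _, length, negsc, _, node, parent, on_orig = entry
        sc = -negsc
        if best_state.get((node, length), (sc, on_orig)) > (sc, on_orig):
            continue  # dominated by a later, better push
        expansions += 1
        if length == L:
            if best_score is None or sc >= best_score:
                nodes = _reconstruct(entry, reverse)
                tie = (
                    0 if (orig_path is not None and nodes == orig_path) else 1,
                    _path_indel_ops(nodes),
                    _first_anchor(nodes),
                    tuple(node_sort_key(n) for n in nodes),
                )
                if best_score is None or sc > best_score or tie < best_tie:
                    best_score, best_tie, best_nodes = sc, tie, nodes
            continue
        i = length  # traversal index of the next read base
        node_adj = adj[node]
        for child in graph.successors(node, direction):
            n_child = pos_n.get(child.position, 0)
            if not passes(node_cov[child], n_child):
                continue
            # the edge filter is anchored on the genome-later endpoint, so
            # filtering is independent of traversal direction
            n_edge = n_child if direction > 0 else pos_n.get(node.position, 0)
            if not passes(node_adj[child], n_edge):
                continue
            delta = _step_delta(i, node, child, t_bases, t_quals, color_ctx)
            nsc = sc + delta
            if nsc < orig_score:
                continue
            child_on_orig = (
                on_orig
                and orig_traversal is not None
                and orig_traversal[length] == child
            )
            st = (child, length + 1)
            prev_best = best_state.get(st)
            if prev_best is not None and prev_best >= (nsc, child_on_orig):
                continue
            if prev_best is None and visit_limit:
                cnt = node_lengths.get(child, 0)
                if cnt >= visit_limit:
                    continue
                node_lengths[child] = cnt + 1
            best_state[st] = (nsc, child_on_orig)
            serial += 1
            push(
                heap,
                (keyf(child), length + 1, -nsc, serial, child, entry, child_on_orig),
            )

    if best_nodes is None or best_score < orig_score:
        return _original_result(read, orig_score, expansions)

    new_pos, new_cigar = path_to_alignment(best_nodes, lead, tail)
    changed = (new_pos != read.position) or (
        _normalize_cigar(new_cigar) != _normalize_cigar(read.cigar)
    )
    return AlignmentPath(
        nodes=tuple(best_nodes),
        score=best_score,
        position=new_pos,
        cigar=new_cigar,
        realigned=changed,
        original_score=orig_score,
        expansions=expansions,
    )


def _reverse_key(node: GraphNode) -> tuple:
    k = node_sort_key(node)
    return (-k[0], -k[1], -k[2], -k[3], tuple(-ord(c) for c in k[4]))


def _reconstruct(entry, reverse: bool) -> list[GraphNode]:
    nodes = []
    while entry is not None:
        nodes.append(entry[4])
        entry = entry[5]
    if not reverse:
        nodes.reverse()
    return nodes


def _first_anchor(nodes) -> int:
    for n in nodes:
        if n.offset == 0:
            return n.position
    return nodes[0].position
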