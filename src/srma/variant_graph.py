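"""Variant graph built from overlapping short-read alignments.

The graph is a compact representation of every local alignment in a genomic
window.  Each node is a single DNA base anchored to a 1-based forward-strand
reference coordinate and is one of three types:

* ``REFERENCE``    — the base matches the reference at that position;
* ``SUBSTITUTION`` — a non-reference base observed at that position;
* ``INSERTION``    — a base inserted relative to the reference, anchored to
  the position of the next non-inserted reference base, with ``offset`` giving
  its 1-based index within the inserted run.

Two nodes share an (undirected) edge when they are adjacent read bases in at
least one alignment; a deletion is therefore an edge between two zero-offset
nodes whose positions differ by more than one.  Nodes carry the number of
alignments passing through them (coverage) and edges carry the number of
alignments containing that adjacency.  Every alignment added to the graph is
a connected path through it.

Coverage filtering uses two parameters combined with logical OR: a path may
pass through a node/edge if it was observed at least ``c`` times, or if its
observation count ``n`` is plausible given the total zero-offset depth ``N``
at that position under a balanced binomial model, ``Pr(x <= n | N) >= p``.
"""

from __future__ import annotations

import re
from enum import IntEnum
from typing import Iterable, NamedTuple, Optional

import pandas as pd
from scipy.stats import binom

BASES = "ACGT"
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR operation groups: which consume read bases / reference positions
_CONSUMES_READ = frozenset("MIS=X")
_CONSUMES_REF = frozenset("MDN=X")


class NodeType(IntEnum):
    """Kind of base a graph node represents relative to the reference."""

    REFERENCE = 0
    SUBSTITUTION = 1
    INSERTION = 2


class GraphNode(NamedTuple):
    """A single base in the variant graph.

    ``(position, base, node_type, offset)`` is the canonical node key and is
    unique within a graph.  ``offset`` is non-zero only for insertion nodes.
    """

    position: int
    base: str
    node_type: int
    offset: int


def node_sort_key(node: GraphNode) -> tuple:
    """Canonical total order over nodes, consistent with read-base order.

    Insertion nodes anchored at position ``q`` sort *between* the zero-offset
    nodes at ``q - 1`` and the zero-offset nodes at ``q`` (inserted bases
    precede the next non-inserted base), by increasing offset.  Remaining
    precedence: node type (REFERENCE < SUBSTITUTION < INSERTION), then base.
    """
    return (
        node.position,
        0 if node.node_type == NodeType.INSERTION else 1,
        node.offset,
        int(node.node_type),
        node.base,
    )


def node_key_order(a: GraphNode, b: GraphNode) -> int:
    """Three-way comparison (-1/0/+1) under the canonical node order."""
    ka, kb = node_sort_key(a), node_sort_key(b)
    if ka < kb:
        return -1
    if ka > kb:
        return 1
    return 0


def parse_cigar(cigar) -> list[tuple[str, int]]:
    """Parse a CIGAR string into ``(op, length)`` tuples.

    Already-parsed sequences are passed through (normalised to tuples).
    """
    if not isinstance(cigar, str):
        return [(op, int(ln)) for op, ln in cigar]
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if not ops or "".join(f"{ln}{op}" for op, ln in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return ops


def cigar_read_length(ops: Iterable[tuple[str, int]]) -> int:
    return sum(ln for op, ln in ops if op in _CONSUMES_READ)


def cigar_reference_span(ops: Iterable[tuple[str, int]]) -> int:
    return sum(ln for op, ln in ops if op in _CONSUMES_REF)


def binomial_cdf(n: int, total: int) -> float:
    """``Pr(x <= n | N)`` for x ~ Binomial(N, 1/2).

    Models the chance of observing an allele at most ``n`` times out of ``N``
    balanced draws; used to keep plausible low-frequency alleles in
    low-coverage regions while pruning rare observations at high coverage.
    """
    if n < 0 or total < 0 or n > total:
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={total}")
    return float(binom.cdf(n, total, 0.5))


def passes_filters(coverage_count: int, position_n: int, c: int, p: float) -> bool:
    """OR-combined coverage filters for a node or edge.

    True iff the observation count reaches the absolute minimum ``c``, or the
    binomial CDF of the count given the zero-offset depth ``position_n`` at
    that position is at least ``p``.
    """
    if coverage_count >= c:
        return True
    n_at = min(coverage_count, position_n)
    return binomial_cdf(n_at, position_n) >= p


class FilterTable:
    """Pre-computed pass/fail coverage filter for fixed ``(c, p)``.

    For each depth N, caches the minimum count passing the binomial filter,
    so the per-expansion check during re-alignment is O(1).
    """

    def __init__(self, c: int, p: float):
        self.c = c
        self.p = p
        self._min_pass: dict[int, int] = {}

    def _min_passing(self, total: int) -> int:
        got = self._min_pass.get(total)
        if got is None:
            # smallest n with CDF >= p (CDF is monotone in n)
            lo, hi = 0, total
            while lo < hi:
                mid = (lo + hi) // 2
                if binomial_cdf(mid, total) >= self.p:
                    hi = mid
                else:
                    lo = mid + 1
            got = lo if binomial_cdf(lo, total) >= self.p else total + 1
            self._min_pass[total] = got
        return got

    def passes(self, coverage_count: int, position_n: int) -> bool:
        if coverage_count >= self.c:
            return True
        n_at = min(coverage_count, position_n)
        return n_at >= self._min_passing(position_n)


class VariantGraph:
    """Rolling-window variant graph over one reference contig.

    Parameters
    ----------
    reference:
        Reference sequence (or the slice of it covering the working window).
    ref_start:
        1-based reference coordinate of ``reference[0]``.
    contig:
        Contig name, carried through for bookkeeping only.
    """

    def __init__(self, reference: str, ref_start: int = 1, contig: str = "ref"):
        self.reference = reference.upper()
        self.ref_start = ref_start
        self.contig = contig
        self.nodes: dict[GraphNode, int] = {}
        self.adj: dict[GraphNode, dict[GraphNode, int]] = {}
        self.position_n: dict[int, int] = {}
        self.pos_nodes: dict[int, list[GraphNode]] = {}
        self.low: Optional[int] = None  # window lower bound after pruning
        self.high: Optional[int] = None
        self._min_pos: Optional[int] = None
        self._nbr_cache: dict[GraphNode, tuple] = {}

    # ------------------------------------------------------------------ #
    # construction

    def ref_base(self, position: int) -> str:
        i = position - self.ref_start
        if i < 0 or i >= len(self.reference):
            raise IndexError(f"position {position} outside reference window")
        return self.reference[i]

    def alignment_path(
        self,
        bases: str,
        position: int,
        cigar,
        qualities: Optional[Iterable[int]] = None,
    ) -> list[GraphNode]:
        """Node path an alignment takes through the graph (no mutation).

        Soft-clipped bases contribute no nodes; hard clips are ignored.  A
        read base of 'N' (or any non-ACGT base) or with quality 0 that does
        not match the reference is routed through the REFERENCE node at that
        position rather than creating a spurious substitution node.
        Ambiguous bases inside an insertion are dropped from the inserted
        run.
        """
        ops = parse_cigar(cigar)
        if cigar_read_length(ops) != len(bases):
            raise ValueError(
                f"CIGAR consumes {cigar_read_length(ops)} bases but read has "
                f"{len(bases)}"
            )
        bases = bases.upper()
        quals = list(qualities) if qualities is not None else None
        path: list[GraphNode] = []
        ref_pos = position
        read_i = 0
        for op, ln in ops:
            if op in ("M", "=", "X"):
                for _ in range(ln):
                    rb = bases[read_i]
                    ref = self.ref_base(ref_pos)
                    q = quals[read_i] if quals is not None else 40
                    if rb == ref:
                        node = GraphNode(ref_pos, ref, NodeType.REFERENCE, 0)
                    elif rb not in BASES or q == 0:
                        node = GraphNode(ref_pos, ref, NodeType.REFERENCE, 0)
                    else:
                        node = GraphNode(ref_pos, rb, NodeType.SUBSTITUTION, 0)
                    path.append(node)
                    ref_pos += 1
                    read_i += 1
            elif op == "I":
                offset = 0
                for _ in range(ln):
                    rb = bases[read_i]
                    read_i += 1
                    if rb not in BASES:
                        continue
                    offset += 1
                    path.append(GraphNode(ref_pos, rb, NodeType.INSERTION, offset))
            elif op in ("D", "N"):
                ref_pos += ln
            elif op == "S":
                read_i += ln
            elif op in ("H", "P"):
                continue
            else:  # pragma: no cover - parse_cigar restricts ops
                raise ValueError(f"unsupported CIGAR op {op!r}")
        return path

    def add_alignment(
        self,
        bases: str,
        position: int,
        cigar,
        qualities: Optional[Iterable[int]] = None,
    ) -> list[GraphNode]:
        """Incorporate one alignment; returns the node path it follows.

        Alignments must arrive in non-decreasing start order relative to any
        pruning already performed.
        """
        if self.low is not None and position < self.low:
            raise ValueError(
                f"alignment start {position} precedes window low bound {self.low}"
            )
        path = self.alignment_path(bases, position, cigar, qualities)
        prev: Optional[GraphNode] = None
        for node in path:
            cov = self.nodes.get(node)
            if cov is None:
                self.nodes[node] = 1
                self.adj[node] = {}
                self.pos_nodes.setdefault(node.position, []).append(node)
            else:
                self.nodes[node] = cov + 1
            if node.offset == 0:
                self.position_n[node.position] = (
                    self.position_n.get(node.position, 0) + 1
                )
            if prev is not None:
                a_n = self.adj[prev]
                cnt = a_n.get(node)
                if cnt is None:
                    a_n[node] = 1
                    self.adj[node][prev] = 1
                    self._nbr_cache.pop(prev, None)
                    self._nbr_cache.pop(node, None)
                else:
                    a_n[node] = cnt + 1
                    self.adj[node][prev] = cnt + 1
            prev = node
        if path:
            lo = path[0].position
            hi = path[-1].position
            self._min_pos = lo if self._min_pos is None else min(self._min_pos, lo)
            self.high = hi if self.high is None else max(self.high, hi)
        return path

    # ------------------------------------------------------------------ #
    # queries

    def coverage(self, node: GraphNode) -> int:
        return self.nodes.get(node, 0)

    def edge_count(self, a: GraphNode, b: GraphNode) -> int:
        return self.adj.get(a, {}).get(b, 0)

    def depth_at(self, position: int) -> int:
        """Total zero-offset observations N at a reference position."""
        return self.position_n.get(position, 0)

    def nodes_at(self, position: int) -> list[GraphNode]:
        return sorted(self.pos_nodes.get(position, ()), key=node_sort_key)

    def _ordered_neighbors(self, node: GraphNode) -> tuple:
        got = self._nbr_cache.get(node)
        if got is None:
            key = node_sort_key(node)
            nbrs = sorted(self.adj.get(node, ()), key=node_sort_key)
            preds = tuple(n for n in nbrs if node_sort_key(n) < key)
            succs = tuple(n for n in nbrs if node_sort_key(n) > key)
            got = (preds, succs)
            self._nbr_cache[node] = got
        return got

    def successors(self, node: GraphNode, direction: int = 1) -> tuple:
        """Neighbors after ``node`` in traversal direction (+1 forward along
        the reference, -1 backward), in traversal order."""
        preds, succs = self._ordered_neighbors(node)
        return succs if direction > 0 else preds[::-1]

    # ------------------------------------------------------------------ #
    # window management

    def prune_window(self, low: int) -> None:
        """Drop every node with position < ``low`` (and incident edges).

        ``low`` must be non-decreasing across calls; the surviving graph is
        identical to one built only from the alignments overlapping
        ``[low, inf)`` restricted to positions >= low.
        """
        if self.low is not None and low < self.low:
            raise ValueError("prune_window low bound must be non-decreasing")
        start = self._min_pos
        if start is not None and start < low:
            for pos in range(start, low):
                for node in self.pos_nodes.pop(pos, ()):
                    del self.nodes[node]
                    for nbr in self.adj.pop(node):
                        nbr_adj = self.adj.get(nbr)
                        if nbr_adj is not None:
                            del nbr_adj[node]
                            self._nbr_cache.pop(nbr, None)
                    self._nbr_cache.pop(node, None)
                self.position_n.pop(pos, None)
            self._min_pos = low
        self.low = low if self.low is None else max(self.low, low)

    # ------------------------------------------------------------------ #
    # debug dump

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Node and edge tables (tab-separated friendly) for inspection."""
        nrows = [
            {
                "position": n.position,
                "offset": n.offset,
                "type": NodeType(n.node_type).name,
                "base": n.base,
                "coverage": cov,
            }
            for n, cov in sorted(self.nodes.items(), key=lambda kv: node_sort_key(kv[0]))
        ]
        erows = []
        for a in sorted(self.adj, key=node_sort_key):
            for b, cnt in self.adj[a].items():
                if node_sort_key(a) < node_sort_key(b):
                    erows.append({"from": tuple(a), "to": tuple(b), "count": cnt})
        return pd.DataFrame(nrows), pd.DataFrame(erows)
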