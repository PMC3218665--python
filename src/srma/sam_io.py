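"""Streaming SAM/BAM re-alignment over a rolling genomic window.

The input must be coordinate-sorted.  Records are added to the variant graph
as they arrive and re-aligned once the stream has advanced far enough past
their end that every alignment overlapping their reachable window is already
in the graph; the graph is pruned behind the earliest pending read, so peak
memory holds only the reads overlapping one window rather than the whole
file.  Output is re-sorted by (possibly shifted) coordinate on the fly.
Re-aligned records keep all fields except POS/CIGAR (NM is recomputed, a
custom tag marks the change) and the header gains a program-group line.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass
from typing import NamedTuple, Optional, Union

import pysam

from . import __version__ as _version
from .colorspace import parse_cs_cq
from .realign import ReadRecord, RealignConfig, realign_read
from .variant_graph import FilterTable, VariantGraph, parse_cigar

#: SAM tag marking a record whose alignment was changed by re-alignment
REALIGNED_TAG = "ZR"


class RegionSpec(NamedTuple):
    """A samtools-style target region, 1-based inclusive."""

    contig: str
    start: int
    end: int


def parse_region(text: str, contig_lengths: Optional[dict] = None) -> RegionSpec:
    """Parse ``chr``, ``chr:start-end`` (commas allowed in numbers)."""
    if ":" in text:
        contig, _, rng = text.partition(":")
        try:
            s, _, e = rng.partition("-")
            start = int(s.replace(",", ""))
            end = int(e.replace(",", "")) if e else None
        except ValueError as exc:
            raise ValueError(f"malformed region {text!r}") from exc
    else:
        contig, start, end = text, 1, None
    if not contig:
        raise ValueError(f"malformed region {text!r}")
    if end is None:
        if contig_lengths and contig in contig_lengths:
            end = contig_lengths[contig]
        else:
            end = 2**31 - 1
    if start < 1 or start > end:
        raise ValueError(f"invalid region bounds in {text!r}")
    return RegionSpec(contig, start, end)


def compute_nm(bases: str, position: int, cigar, reference: str) -> int:
    """SAM NM: mismatches plus inserted and deleted bases."""
    nm = 0
    ref_pos = position
    read_i = 0
    for op, ln in parse_cigar(cigar):
        if op in ("M", "=", "X"):
            for _ in range(ln):
                if bases[read_i].upper() != reference[ref_pos - 1].upper():
                    nm += 1
                read_i += 1
                ref_pos += 1
        elif op == "I":
            nm += ln
            read_i += ln
        elif op in ("D", "N"):
            nm += ln
            ref_pos += ln
        elif op == "S":
            read_i += ln
    return nm


def _record_to_read(rec: pysam.AlignedSegment) -> ReadRecord:
    quals = rec.query_qualities
    color = None
    if rec.has_tag("CS") and rec.has_tag("CQ"):
        color = parse_cs_cq(rec.get_tag("CS"), rec.get_tag("CQ"))
    return ReadRecord(
        name=rec.query_name,
        bases=rec.query_sequence,
        base_qualities=list(quals) if quals is not None else [30] * rec.query_length,
        strand="-" if rec.is_reverse else "+",
        position=rec.reference_start + 1,
        cigar=rec.cigarstring,
        color=color,
    )


@dataclass
class StreamStats:
    total: int = 0
    realigned: int = 0
    skipped: int = 0
    unmapped: int = 0


def stream_realign(
    in_path,
    reference: Union[str, dict],
    out_path,
    config: Optional[RealignConfig] = None,
    regions: Optional[list] = None,
    max_indel: int = 100,
) -> StreamStats:
    """Re-align a coordinate-sorted SAM/BAM file against its reference.

    ``reference`` is a FASTA path or a ``{contig: sequence}`` dict.  Every
    input record appears exactly once in the output (unmapped reads pass
    through untouched); output is coordinate-sorted.  ``max_indel`` bounds
    how far a re-alignment can shift, fixing the graph look-ahead margin.
    With ``regions``, only reads starting inside a region are re-aligned
    and emitted, while alignments within the margin around it still feed
    the graph.
    """
    cfg = config or RealignConfig()
    filters = FilterTable(cfg.c, cfg.p)
    margin = cfg.w + max_indel

    fasta = None
    if not isinstance(reference, dict):
        fasta = pysam.FastaFile(str(reference))
        ref_seqs: dict = {}
    else:
        ref_seqs = dict(reference)

    region_list = None
    if regions:
        region_list = [
            parse_region(r) if isinstance(r, str) else RegionSpec(*r) for r in regions
        ]

    infile = pysam.AlignmentFile(str(in_path), check_sq=False)
    header = infile.header.to_dict()
    for sq in header.get("SQ", []):
        name = sq["SN"]
        if fasta is not None:
            if name not in fasta.references:
                raise ValueError(f"contig {name!r} missing from reference FASTA")
        elif name not in ref_seqs:
            raise ValueError(f"contig {name!r} missing from reference")
    header.setdefault("PG", []).append(
        {"ID": "srma", "PN": "srma", "VN": _version, "CL": "srma realign"}
    )
    out_mode = "wb" if str(out_path).endswith(".bam") else "wh"
    outfile = pysam.AlignmentFile(str(out_path), out_mode, header=header)

    stats = StreamStats()
    out_heap: list = []
    out_serial = 0
    unmapped_tail: list = []

    def get_ref(contig: str) -> str:
        seq = ref_seqs.get(contig)
        if seq is None:
            seq = fasta.fetch(contig).upper()
            ref_seqs[contig] = seq
        return seq

    def in_region(contig, pos, end) -> tuple[bool, bool]:
        """(feeds graph, gets output) for a record on contig at [pos, end]."""
        if region_list is None:
            return True, True
        feed = out = False
        for r in region_list:
            if r.contig != contig:
                continue
            if pos <= r.end + margin and end >= r.start - margin:
                feed = True
            if r.start <= pos <= r.end:
                out = True
        return feed, out

    def emit(rec, pos_key):
        nonlocal out_serial
        out_serial += 1
        heapq.heappush(out_heap, (pos_key, out_serial, rec))

    def flush_output(bound: Optional[int]):
        while out_heap and (bound is None or out_heap[0][0] < bound):
            outfile.write(heapq.heappop(out_heap)[2])

    def finish_contig(graph, pending):
        while pending:
            realign_one(graph, pending, final=True)
        flush_output(None)

    def realign_one(graph, pending, final=False):
        rec, end = pending.popleft()
        read = _record_to_read(rec)
        result = realign_read(graph, read, cfg, filters)
        stats.total += 1
        if result.skipped:
            stats.skipped += 1
        if result.realigned:
            stats.realigned += 1
            rec.reference_start = result.position - 1
            rec.cigarstring = result.cigar
            rec.set_tag(REALIGNED_TAG, 1, value_type="i")
            rec.set_tag(
                "NM",
                compute_nm(
                    read.bases, result.position, result.cigar, graph.reference
                ),
                value_type="i",
            )
        emit(rec, rec.reference_start)
        if pending:
            graph.prune_window(max(1, pending[0][0].reference_start + 1 - margin))
        return rec

    graph = None
    pending: deque = deque()
    cur_tid = -1
    last_pos = -1
    for rec in infile:
        if rec.is_unmapped or rec.reference_id < 0:
            unmapped_tail.append(rec)
            stats.unmapped += 1
            stats.total += 1
            continue
        if rec.reference_id != cur_tid:
            if graph is not None:
                finish_contig(graph, pending)
            cur_tid = rec.reference_id
            contig = infile.get_reference_name(cur_tid)
            graph = VariantGraph(get_ref(contig), 1, contig)
            pending = deque()
            last_pos = -1
        pos = rec.reference_start  # 0-based
        if pos < last_pos:
            raise ValueError(
                f"input is not coordinate-sorted at {rec.query_name} "
                f"({pos + 1} after {last_pos + 1})"
            )
        last_pos = pos
        end = rec.reference_end or (pos + 1)
        feed, out = in_region(graph.contig, pos + 1, end)
        if not feed:
            continue
        while pending and pending[0][1] + margin < pos:
            realign_one(graph, pending)
            flush_output(min(pending[0][0].reference_start, pos) - margin if pending else pos - margin)
        try:
            graph.add_alignment(
                rec.query_sequence,
                pos + 1,
                rec.cigarstring,
                rec.query_qualities,
            )
        except (ValueError, IndexError):
            # unparseable record feeds nothing but still passes through
            pass
        if out:
            pending.append((rec, end))
        else:
            stats.total += 1
    if graph is not None:
        finish_contig(graph, pending)
    flush_output(None)
    for rec in unmapped_tail:
        outfile.write(rec)
    outfile.close()
    infile.close()
    return stats


def write_initial_alignments(
    path, alignments, contig: str, contig_length: int
) -> None:
    """Write stand-in initial alignments as a coordinate-sorted SAM/BAM.

    ``alignments`` is an iterable of :class:`srma.simulate.InitialAlignment`
    already sorted by position (as :func:`srma.simulate.naive_initial_align`
    returns them).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig, "LN": contig_length}],
    }
    mode = "wb" if str(path).endswith(".bam") else "wh"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for a in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = a.name
            rec.query_sequence = a.bases
            rec.query_qualities = pysam.qualitystring_to_array(
                chr(a.quality + 33) * len(a.bases)
            )
            rec.reference_id = 0
            rec.reference_start = a.position - 1
            rec.cigarstring = a.cigar
            rec.mapping_quality = 60
            flag = 0x1 | 0x2
            flag |= 0x40 if a.mate == 1 else 0x80
            if a.strand == "-":
                flag |= 0x10
            else:
                flag |= 0x20
            rec.flag = flag
            if a.cs is not None:
                rec.set_tag("CS", a.cs, value_type="Z")
                rec.set_tag("CQ", a.cq, value_type="Z")
            out.write(rec)


def iter_alignments(path):
    """Yield ``(position, cigar, bases)`` for mapped records of a SAM/BAM."""
    with pysam.AlignmentFile(str(path), check_sq=False) as f:
        for rec in f:
            if rec.is_unmapped or rec.cigarstring is None:
                continue
            yield rec.reference_start + 1, rec.cigarstring, rec.query_sequence
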