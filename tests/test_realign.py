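"""Heap-based re-alignment: scoring, pruning, oracle equivalence."""

import numpy as np
from _oracles import enumerate_best_score
from srma.realign import (
    HeapEntry,
    ReadRecord,
    RealignConfig,
    collect_start_nodes,
    path_to_alignment,
    prune_heap,
    realign_read,
    score_extension,
)
from srma.simulate import affine_glocal_align, random_reference, _to_codes
from srma.variant_graph import GraphNode, NodeType, VariantGraph


def make_read(bases, pos, cigar, strand="+", q=30):
    return ReadRecord("r", bases, [q] * len(bases), strand, pos, cigar)


def random_case(seed, n_reads=4, read_len=8, with_variants=True):
    """A small graph from randomly mutated reads, plus one member read."""
    rng = np.random.default_rng(seed)
    ref = random_reference(40, seed + 1)
    g = VariantGraph(ref)
    members = []
    for _ in range(n_reads):
        s = int(rng.integers(0, len(ref) - read_len - 6))
        hap = list(ref[s : s + read_len + 4])
        if with_variants and rng.random() < 0.7:
            k = int(rng.integers(0, len(hap)))
            r = rng.random()
            if r < 0.5:
                hap[k] = "ACGT"[("ACGT".index(hap[k]) + 1 + int(rng.integers(3))) % 4]
            elif r < 0.75:
                del hap[k]
            else:
                hap.insert(k, "ACGT"[int(rng.integers(4))])
        seq = "".join(hap)[:read_len]
        start, ops = affine_glocal_align(_to_codes(seq), _to_codes(ref[s : s + read_len + 8]))
        if any(op == "S" for op, _ in ops):
            continue
        cigar = "".join(f"{ln}{op}" for op, ln in ops)
        pos = s + start + 1
        strand = "+" if rng.random() < 0.5 else "-"
        g.add_alignment(seq, pos, cigar, [30] * read_len)
        members.append(make_read(seq, pos, cigar, strand))
    return g, members


class TestScoreExtension:
    def test_match_adds_no_penalty(self):
        assert score_extension(0, "A", "A", 30) == 0

    def test_mismatch_costs_base_quality(self):
        assert score_extension(0, "A", "C", 30) == -30

    def test_zero_quality_mismatch_is_free(self):
        assert score_extension(-10, "A", "C", 0) == -10

    def test_quality_capped(self):
        assert score_extension(0, "A", "C", 93) == -40


class TestPruneHeap:
    def test_dominated_entry_dropped(self):
        n = GraphNode(5, "A", NodeType.REFERENCE, 0)
        a = HeapEntry(n, 5, -10, None)
        b = HeapEntry(n, 5, -40, None)
        assert prune_heap([a, b]) is a

    def test_entries_below_original_score_dropped(self):
        n = GraphNode(5, "A", NodeType.REFERENCE, 0)
        assert prune_heap([HeapEntry(n, 5, -50, None)], original_score=-20) is None

    def test_different_path_lengths_are_independent(self):
        n = GraphNode(5, "A", NodeType.REFERENCE, 0)
        a = HeapEntry(n, 5, -10, None)
        b = HeapEntry(n, 6, -40, None)
        # pruning applies within one (node, length) group only
        assert prune_heap([a]) is a and prune_heap([b]) is b


class TestStartNodes:
    def test_degenerate_window_only_exact_start(self, linear_graph):
        nodes = collect_start_nodes(linear_graph, 5, 0)
        assert [n.position for n in nodes] == [5]

    def test_window_two_gives_five_positions(self, linear_graph):
        nodes = collect_start_nodes(linear_graph, 5, 2)
        assert [n.position for n in nodes] == [3, 4, 5, 6, 7]

    def test_substitution_node_is_start_candidate(self):
        g = VariantGraph("ACGTA")
        g.add_alignment("ACGTA", 1, "5M")
        g.add_alignment("TCGTA", 1, "5M")
        starts = collect_start_nodes(g, 1, 0)
        assert {n.node_type for n in starts} == {
            NodeType.REFERENCE,
            NodeType.SUBSTITUTION,
        }

    def test_reverse_strand_reverses_order(self, linear_graph):
        fwd = collect_start_nodes(linear_graph, 5, 2, "+")
        rev = collect_start_nodes(linear_graph, 5, 2, "-")
        assert rev == fwd[::-1]


class TestPathToAlignment:
    def test_plain_match_run(self):
        nodes = [GraphNode(p, "A", NodeType.REFERENCE, 0) for p in range(1, 51)]
        assert path_to_alignment(nodes) == (1, "50M")

    def test_long_deletion_jump(self):
        nodes = [GraphNode(p, "A", NodeType.REFERENCE, 0) for p in range(1, 11)]
        nodes += [GraphNode(p, "A", NodeType.REFERENCE, 0) for p in range(26, 66)]
        assert path_to_alignment(nodes) == (1, "10M15D40M")

    def test_insertion_run(self):
        nodes = [GraphNode(p, "A", NodeType.REFERENCE, 0) for p in range(1, 6)]
        nodes += [GraphNode(6, "C", NodeType.INSERTION, k) for k in (1, 2)]
        nodes += [GraphNode(p, "A", NodeType.REFERENCE, 0) for p in range(6, 9)]
        assert path_to_alignment(nodes) == (1, "5M2I3M")

    def test_soft_clips_reattached(self):
        nodes = [GraphNode(p, "A", NodeType.REFERENCE, 0) for p in range(4, 10)]
        assert path_to_alignment(nodes, 2, 3) == (4, "2S6M3S")


class TestRealignRead:
    def test_single_read_graph_returns_identical_alignment(self):
        ref = random_reference(60, 0)
        g = VariantGraph(ref)
        seq = ref[9:29]
        g.add_alignment(seq, 10, "20M")
        out = realign_read(g, make_read(seq, 10, "20M"))
        assert (out.position, out.cigar) == (10, "20M")
        assert not out.realigned
        assert out.score == out.original_score

    def test_read_with_private_mismatch_keeps_position(self):
        ref = random_reference(60, 1)
        g = VariantGraph(ref)
        seq = list(ref[9:29])
        seq[10] = "ACGT"[("ACGT".index(seq[10]) + 1) % 4]
        seq = "".join(seq)
        g.add_alignment(ref[9:29], 10, "20M")
        g.add_alignment(seq, 10, "20M")
        out = realign_read(g, make_read(seq, 10, "20M"))
        assert (out.position, out.cigar) == (10, "20M")
        assert not out.realigned

    def test_shared_variant_path_rescues_misplaced_read(self):
        # several reads observe a 5-bp deletion; another, aligned across it
        # with mismatches, should be re-routed through the deletion edge
        # (depth is high enough that its private mismatch nodes fail both
        # coverage filters)
        ref = random_reference(120, 2)
        hap = ref[:50] + ref[55:]
        g = VariantGraph(ref)
        for s in (26, 28, 30, 32, 34, 36, 38):
            g.add_alignment(hap[s : s + 50], s + 1, f"{50 - s}M5D{s}M")
        victim = hap[40:70]  # 10 bases before junction, 20 after
        g.add_alignment(victim, 41, "30M")  # misplaced: no deletion
        out = realign_read(g, make_read(victim, 41, "30M"))
        assert out.realigned
        assert out.cigar == "10M5D20M"
        assert out.position == 41
        assert out.score > out.original_score

    def test_never_worse_and_oracle_equivalence_on_random_graphs(self):
        checked = 0
        for seed in range(120):
            g, members = random_case(seed)
            for read in members:
                cfg = RealignConfig(w=int(seed % 4), c=1 + seed % 2, p=0.1)
                out = realign_read(g, read, cfg)
                assert out.score >= out.original_score
                best = enumerate_best_score(g, read, cfg)
                expected = max(
                    best if best is not None else float("-inf"), out.original_score
                )
                assert out.score == expected, f"seed={seed}"
                checked += 1
        assert checked > 150

    def test_filter_monotonicity_never_raises_score(self):
        for seed in range(40):
            g, members = random_case(seed + 500)
            for read in members:
                loose = realign_read(g, read, RealignConfig(w=3, c=1, p=0.0))
                tight = realign_read(g, read, RealignConfig(w=3, c=3, p=0.5))
                assert tight.score <= loose.score

    def test_idempotent_on_clean_data(self):
        ref = random_reference(200, 5)
        hap = ref[:100] + ref[103:]  # 3-bp deletion
        g = VariantGraph(ref)
        reads = []
        for s in range(60, 120, 5):
            seq = hap[s : s + 40]
            start, ops = affine_glocal_align(
                _to_codes(seq), _to_codes(ref[s : s + 60])
            )
            cigar = "".join(f"{ln}{op}" for op, ln in ops)
            g.add_alignment(seq, s + start + 1, cigar)
            reads.append(make_read(seq, s + start + 1, cigar))
        first = [realign_read(g, r) for r in reads]
        g2 = VariantGraph(ref)
        reads2 = []
        for r, out in sorted(zip(reads, first), key=lambda t: t[1].position):
            g2.add_alignment(r.bases, out.position, out.cigar)
            reads2.append(make_read(r.bases, out.position, out.cigar))
        second = [realign_read(g2, r) for r in reads2]
        assert all(not o.realigned for o in second)

    def test_heap_valve_returns_original_flagged_skipped(self):
        g, members = random_case(7)
        read = members[0]
        out = realign_read(g, read, RealignConfig(w=3, c=1, p=0.0, max_heap=0,
                                                  shortcut_perfect=False))
        assert out.skipped
        assert (out.position, out.cigar) == (read.position, out.cigar)

    def test_empty_window_returns_original(self):
        g = VariantGraph("ACGTACGTACGT")
        g.add_alignment("ACGT", 1, "4M")
        read = make_read("ACGT", 9, "4M")
        read.bases = "AAAA"  # force nonzero original score
        out = realign_read(g, read, RealignConfig(w=1))
        assert not out.realigned and not out.skipped

    def test_reverse_strand_equivalent_result(self):
        # strand only changes traversal direction; for base-space scoring the
        # best path must coincide
        ref = random_reference(120, 9)
        hap = ref[:60] + ref[64:]
        g = VariantGraph(ref)
        g.add_alignment(hap[40:90], 41, "20M4D30M")
        g.add_alignment(hap[38:88], 39, "22M4D28M")
        victim = hap[45:75]
        g.add_alignment(victim, 46, "30M")
        fwd = realign_read(g, make_read(victim, 46, "30M", "+"))
        rev = realign_read(g, make_read(victim, 46, "30M", "-"))
        assert (fwd.position, fwd.cigar) == (rev.position, rev.cigar)

    def test_majority_supports_deletion_and_snp_after_realignment(self):
        # a 15-bp deletion with a SNP eight bases downstream, covered by 30
        # reads at 1% error: after re-alignment the majority of overlapping
        # reads support both variants
        rng = np.random.default_rng(42)
        ref = random_reference(400, 1)
        snp_ref_pos = 222
        alt = "A" if ref[snp_ref_pos - 1] != "A" else "C"
        hap = ref[:199] + ref[214:]
        i = 199 + (snp_ref_pos - 215)
        hap = hap[:i] + alt + hap[i + 1 :]
        recs = []
        starts = list(range(150, 199, 2))
        for s in starts:
            seq = list(hap[s : s + 50])
            for k in range(50):  # 1% error
                if rng.random() < 0.01:
                    seq[k] = "ACGT"[("ACGT".index(seq[k]) + 1 + int(rng.integers(3))) % 4]
            seq = "".join(seq)
            ws = max(0, s - 30)
            start, ops = affine_glocal_align(_to_codes(seq), _to_codes(ref[ws : s + 95]))
            cigar = "".join(f"{ln}{op}" for op, ln in ops)
            recs.append((seq, ws + start + 1, cigar))
        g = VariantGraph(ref)
        for (seq, pos, cig), _s in sorted(zip(recs, starts), key=lambda r: r[0][1]):
            g.add_alignment(seq, pos, cig, [20] * len(seq))
        support = 0
        overlapping = 0
        before = after = 0
        for (seq, pos, cig), s in zip(recs, starts):
            out = realign_read(g, make_read(seq, pos, cig, q=20))
            before += "15D" in cig
            after += "15D" in out.cigar
            if 170 <= s <= 179:  # >=20-base anchors on both sides
                overlapping += 1
                if "15D" in out.cigar:
                    support += 1
        assert overlapping >= 4
        assert support / overlapping > 0.5
        assert after >= before
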