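"""Independent brute-force oracles used by the test suite.

These deliberately avoid the heap/dynamic-programming machinery they check:
path scoring is exhaustive DFS enumeration, truth matching is an all-pairs
scan, and genotype likelihoods are enumerated over every diploid genotype.
"""

import math
from itertools import combinations_with_replacement

from srma.realign import QUALITY_CAP, collect_start_nodes
from srma.variant_graph import FilterTable, parse_cigar


def enumerate_best_score(graph, read, cfg):
    """Maximum score over *all* complete filtered paths, by exhaustive DFS.

    Returns None when no complete path survives the coverage filters.
    Ignores the original-score bound and heap pruning entirely.
    """
    ft = FilterTable(cfg.c, cfg.p)
    ops = parse_cigar(read.cigar)
    assert not any(op in "SH" for op, _ in ops), "oracle expects unclipped reads"
    reverse = read.strand == "-"
    t_bases = read.bases[::-1] if reverse else read.bases
    t_quals = list(read.base_qualities)[::-1] if reverse else list(read.base_qualities)
    L = len(t_bases)
    span = sum(ln for op, ln in ops if op in "MDN=X")
    anchor = read.position + span - 1 if reverse else read.position
    direction = -1 if reverse else 1

    def delta(i, node):
        if t_bases[i] == node.base:
            return 0
        return -min(t_quals[i], QUALITY_CAP)

    best = [None]

    def dfs(node, consumed, score):
        if consumed == L:
            if best[0] is None or score > best[0]:
                best[0] = score
            return
        for child in graph.successors(node, direction):
            n_child = graph.depth_at(child.position)
            if not ft.passes(graph.coverage(child), n_child):
                continue
            later = child if direction > 0 else node
            if not ft.passes(graph.edge_count(node, child), graph.depth_at(later.position)):
                continue
            dfs(child, consumed + 1, score + delta(consumed, child))

    for start in collect_start_nodes(graph, anchor, cfg.w, read.strand):
        if not ft.passes(graph.coverage(start), graph.depth_at(start.position)):
            continue
        dfs(start, 1, delta(0, start))
    return best[0]


def brute_force_roc_counts(calls, truth, vtype, threshold, wiggle):
    """(tp_truth_sites, fp_calls) by all-pairs position matching."""
    tol = 0 if vtype == "SNP" else wiggle
    tpos = [int(p) for p in truth.loc[truth.vtype == vtype, "position"]]
    sub = calls[(calls.vtype == vtype) & (calls.quality >= threshold)]
    hit = set()
    fp = 0
    for _, row in sub.iterrows():
        matched = [i for i, tp in enumerate(tpos) if abs(tp - int(row.position)) <= tol]
        if matched:
            hit.update(matched)
        else:
            fp += 1
    return len(hit), fp


def brute_force_concordance(calls_pos_len, catalog_pos_len, wiggle):
    """Fraction of calls with a same-length catalog entry within wiggle."""
    if not calls_pos_len:
        return float("nan")
    n = 0
    for cp, cl in calls_pos_len:
        if any(abs(cp - kp) <= wiggle and cl == kl for kp, kl in catalog_pos_len):
            n += 1
    return n / len(calls_pos_len)


def brute_force_diploid_genotype(base_counts, ref_base, error):
    """Maximum-likelihood diploid genotype over all 10 unordered pairs."""
    def p_base(b, genotype):
        p = 0.0
        for g in genotype:
            p += 0.5 * ((1 - error) if b == g else error / 3.0)
        return p

    best, best_ll = None, -math.inf
    for genotype in combinations_with_replacement("ACGT", 2):
        ll = sum(
            count * math.log(p_base(b, genotype))
            for b, count in base_counts.items()
            if count
        )
        if ll > best_ll:
            best, best_ll = genotype, ll
    return best
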