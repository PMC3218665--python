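"""Diploid re-sequencing simulation: mutated genomes, reads, truth tables.

The generator emulates a whole-genome re-sequencing experiment at small
scale.  A reference sequence is mutated into two haplotypes: each base is
independently polymorphic at rate 1/1000, a variant is homozygous with
probability 1/3 (otherwise it lands on one random haplotype), insertions and
deletions each make up 5% of variants, and indel length extends beyond one
base with probability 0.3 per extra base (mean length 1/0.7).  Paired 50-base
reads are drawn uniformly from the haplotypes with insert sizes from
N(500, 50); base-space reads carry a uniform 1% per-base substitution error,
color-space reads a uniform 5% per-color error.  Every introduced variant and
every read's true origin are recorded so downstream calls can be scored
against a known truth.

A stand-in initial aligner (:func:`naive_initial_align`) maps each read
within a window around its recorded origin using unit-cost semi-global
alignment (edlib).  Like any per-read aligner it trades indels near read
ends for mismatches and places indels arbitrarily within repeats — exactly
the local misplacement that re-alignment is meant to repair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import edlib
import numpy as np
import pandas as pd


_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODES[_b] = _i
_CODE_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_codes(seq: str) -> np.ndarray:
    return _BASE_CODES[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _to_str(codes: np.ndarray) -> str:
    return _CODE_BASES[codes].tobytes().decode()


def phred_from_rate(rate: float, cap: int = 40) -> int:
    """Phred quality corresponding to an error rate (capped)."""
    if rate <= 0:
        return cap
    return min(cap, int(round(-10.0 * math.log10(rate))))


@dataclass
class SimParams:
    """Study conditions for the simulation (defaults are the experiment's).

    Rates are per base / per event; ``haploid_coverage`` is the expected
    depth contributed by *each* haplotype, so total depth is about twice it.
    """

    polymorphism_rate: float = 1e-3
    homozygous_prob: float = 1.0 / 3.0
    indel_fraction_each: float = 0.05
    indel_extension_prob: float = 0.3
    read_length: int = 50
    haploid_coverage: float = 15.0
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    base_error_rate: float = 0.01
    color_error_rate: float = 0.05
    adapter: str = "T"

    def __post_init__(self):
        for name in (
            "polymorphism_rate",
            "homozygous_prob",
            "indel_fraction_each",
            "indel_extension_prob",
            "base_error_rate",
            "color_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.haploid_coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.insert_mean <= self.read_length:
            raise ValueError("insert_mean must exceed read_length")


class Haplotype(NamedTuple):
    """One mutated chromosome copy.

    ``ref_positions[i]`` is the 1-based reference coordinate of haplotype
    base ``i``; inserted bases carry the position of the next non-inserted
    reference base.
    """

    sequence: str
    ref_positions: np.ndarray


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_reference(length: int, seed=0) -> str:
    """Uniform random A/C/G/T reference sequence."""
    rng = _rng(seed)
    return _to_str(rng.integers(0, 4, length).astype(np.uint8))


# --------------------------------------------------------------------- #
# genome mutation


def _indel_length(rng, extension_prob: float) -> int:
    ln = 1
    while rng.random() < extension_prob:
        ln += 1
    return ln


def mutate_diploid(
    reference: str, params: Optional[SimParams] = None, seed=0
) -> tuple[Haplotype, Haplotype, pd.DataFrame]:
    """Introduce variants into two haplotype copies of ``reference``.

    Returns both haplotypes plus the truth table: one row per introduced
    variant with 1-based ``position``, ``vtype`` (SNP/INS/DEL), alleles,
    ``zygosity`` (HET/HOM) and the haplotypes carrying it.  INS rows insert
    ``alt_allele`` immediately *before* reference base ``position`` (the
    anchor convention the variant graph uses); DEL rows delete
    ``position .. position + len - 1``.  Deletions never overlap each other
    (colliding deletions are re-placed uniformly); other overlaps are
    permitted.
    """
    params = params or SimParams()
    rng = _rng(seed)
    L = len(reference)
    ref_codes = _to_codes(reference)

    site_mask = rng.random(L) < params.polymorphism_rate
    sites = np.flatnonzero(site_mask) + 1  # 1-based

    f = params.indel_fraction_each
    rows = []
    # deletions already placed, per haplotype: list of (start, end) inclusive
    del_spans: list[list[tuple[int, int]]] = [[], []]

    def overlaps(haps, start, end) -> bool:
        for h in haps:
            for s, e in del_spans[h]:
                if start <= e and s <= end:
                    return True
        return False

    for pos in sites:
        pos = int(pos)
        zyg = "HOM" if rng.random() < params.homozygous_prob else "HET"
        haps = (0, 1) if zyg == "HOM" else (int(rng.integers(0, 2)),)
        u = rng.random()
        if u < f:
            vtype = "DEL"
        elif u < 2 * f:
            vtype = "INS"
        else:
            vtype = "SNP"
        if vtype == "SNP":
            ref_b = reference[pos - 1]
            alt = "ACGT"[(int(ref_codes[pos - 1]) + 1 + int(rng.integers(0, 3))) % 4]
            rows.append((pos, "SNP", ref_b, alt, zyg, haps))
        elif vtype == "INS":
            ln = _indel_length(rng, params.indel_extension_prob)
            alt = _to_str(rng.integers(0, 4, ln).astype(np.uint8))
            rows.append((pos, "INS", "-", alt, zyg, haps))
        else:
            ln = _indel_length(rng, params.indel_extension_prob)
            # re-place until the deletion fits and overlaps no other deletion
            dpos = pos
            for _ in range(1000):
                if dpos + ln - 1 <= L and not overlaps(haps, dpos, dpos + ln - 1):
                    break
                dpos = int(rng.integers(1, L - ln + 2))
            else:  # pragma: no cover - practically unreachable
                continue
            for h in haps:
                del_spans[h].append((dpos, dpos + ln - 1))
            rows.append((dpos, "DEL", reference[dpos - 1 : dpos - 1 + ln], "-", zyg, haps))

    rows.sort(key=lambda r: (r[0], r[1]))
    truth = pd.DataFrame(
        [
            {
                "position": r[0],
                "vtype": r[1],
                "ref_allele": r[2],
                "alt_allele": r[3],
                "zygosity": r[4],
                "haplotypes": "".join("AB"[h] for h in sorted(set(r[5]))),
            }
            for r in rows
        ],
        columns=["position", "vtype", "ref_allele", "alt_allele", "zygosity", "haplotypes"],
    )

    haplotypes = tuple(
        _materialize(reference, rows, h) for h in (0, 1)
    )
    return haplotypes[0], haplotypes[1], truth


def _materialize(reference: str, rows, hap: int) -> Haplotype:
    """Apply one haplotype's edits; returns sequence plus position map."""
    pieces: list[str] = []
    pos_pieces: list[np.ndarray] = []
    cursor = 1  # next reference base to copy
    # at equal positions: INS applies before the base, DEL consumes it, SNP
    # replaces it (a SNP inside a deletion is invisible)
    rank = {"INS": 0, "DEL": 1, "SNP": 2}
    for pos, vtype, ref_allele, alt_allele, _zyg, haps in sorted(
        rows, key=lambda r: (r[0], rank[r[1]])
    ):
        if hap not in haps:
            continue
        if vtype == "INS":
            if pos < cursor:
                continue
            pieces.append(reference[cursor - 1 : pos - 1])
            pos_pieces.append(np.arange(cursor, pos, dtype=np.int64))
            pieces.append(alt_allele)
            pos_pieces.append(np.full(len(alt_allele), pos, dtype=np.int64))
            cursor = pos
        elif vtype == "DEL":
            if pos < cursor:
                continue
            pieces.append(reference[cursor - 1 : pos - 1])
            pos_pieces.append(np.arange(cursor, pos, dtype=np.int64))
            cursor = pos + len(ref_allele)
        else:  # SNP
            if pos < cursor:
                continue
            pieces.append(reference[cursor - 1 : pos - 1])
            pos_pieces.append(np.arange(cursor, pos, dtype=np.int64))
            pieces.append(alt_allele)
            pos_pieces.append(np.array([pos], dtype=np.int64))
            cursor = pos + 1
    pieces.append(reference[cursor - 1 :])
    pos_pieces.append(np.arange(cursor, len(reference) + 1, dtype=np.int64))
    return Haplotype("".join(pieces), np.concatenate(pos_pieces))


# --------------------------------------------------------------------- #
# read generation


@dataclass
class SimulatedReads:
    """Paired-end reads plus their true origins (vectorised storage).

    ``bases`` are in *genome* orientation (as a SAM SEQ field would store
    them); reverse-strand reads were sequenced as the reverse complement.
    Color arrays, when present, are in sequencing orientation.
    """

    read_length: int
    bases: np.ndarray  # (n, read_length) uint8 base codes
    quality: int  # uniform per-base Phred quality
    haplotype: np.ndarray  # (n,) 0/1
    hap_start: np.ndarray  # (n,) 0-based start on the haplotype
    strand: np.ndarray  # (n,) '+'/'-' as '+' == 0
    mate: np.ndarray  # (n,) 1 or 2
    pair_id: np.ndarray  # (n,)
    ref_start: np.ndarray  # (n,) 1-based anchor of first base
    ref_end: np.ndarray  # (n,)
    insert_size: np.ndarray  # (n,) per pair, duplicated on both mates
    colors: Optional[np.ndarray] = None  # (n, read_length) uint8
    color_quality: int = 0
    adapter: str = "T"

    def __len__(self):
        return self.bases.shape[0]

    def sequence(self, i: int) -> str:
        return _to_str(self.bases[i])

    def name(self, i: int) -> str:
        return f"pair{self.pair_id[i]}"

    def origins(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [self.name(i) for i in range(len(self))],
                "mate": self.mate,
                "haplotype": self.haplotype,
                "hap_start": self.hap_start,
                "strand": np.where(self.strand == 0, "+", "-"),
                "ref_start": self.ref_start,
                "ref_end": self.ref_end,
                "insert_size": self.insert_size,
            }
        )

    def to_fastq(self, handle) -> None:
        """Write reads (sequencing orientation) as FASTQ."""
        qual = chr(self.quality + 33) * self.read_length
        comp = np.array([3, 2, 1, 0], dtype=np.uint8)
        for i in range(len(self)):
            codes = self.bases[i]
            if self.strand[i]:
                codes = comp[codes[::-1]]
            handle.write(
                f"@{self.name(i)}/{self.mate[i]}\n{_to_str(codes)}\n+\n{qual}\n"
            )


def generate_read_pairs(
    haplotypes: tuple[Haplotype, Haplotype],
    params: Optional[SimParams] = None,
    seed=0,
    n_pairs: Optional[int] = None,
    space: str = "base",
) -> SimulatedReads:
    """Draw uniformly-placed paired-end reads from the two haplotypes.

    The number of pairs defaults to ``haploid_coverage * genome_length /
    read_length`` so total depth is ~2x the haploid coverage.  Insert sizes
    (outer distance between the two ends) are normal, rounded, and
    re-sampled if the fragment does not fit the chromosome.  ``space`` is
    ``"base"`` (substitution errors on bases) or ``"color"`` (errors on the
    two-base-encoded colors; the stored bases are then the naive decode of
    the corrupted colors, as an alignment-free base caller would emit).
    """
    params = params or SimParams()
    rng = _rng(seed)
    rl = params.read_length
    hap_codes = [_to_codes(h.sequence) for h in haplotypes]
    hap_lens = np.array([len(c) for c in hap_codes])
    ref_len = int(max(h.ref_positions[-1] for h in haplotypes))
    if n_pairs is None:
        n_pairs = int(round(params.haploid_coverage * ref_len / rl))

    hap = rng.integers(0, 2, n_pairs)
    min_insert = rl + 1
    inserts = np.rint(rng.normal(params.insert_mean, params.insert_sd, n_pairs)).astype(
        np.int64
    )
    for _ in range(100):
        bad = (inserts < min_insert) | (inserts > hap_lens[hap])
        if not bad.any():
            break
        inserts[bad] = np.rint(
            rng.normal(params.insert_mean, params.insert_sd, int(bad.sum()))
        ).astype(np.int64)
    inserts = np.clip(inserts, min_insert, hap_lens[hap])
    span = hap_lens[hap] - inserts
    starts = (rng.random(n_pairs) * (span + 1)).astype(np.int64)  # 0-based

    # first mate: forward at fragment start; second: reverse at the far end
    start1 = starts
    start2 = starts + inserts - rl
    col = np.arange(rl)

    def gather(hsel, st):
        out = np.empty((len(st), rl), dtype=np.uint8)
        for h in (0, 1):
            m = hsel == h
            if m.any():
                out[m] = hap_codes[h][st[m][:, None] + col]
        return out

    b1 = gather(hap, start1)
    b2 = gather(hap, start2)

    n = 2 * n_pairs
    bases = np.empty((n, rl), dtype=np.uint8)
    bases[0::2] = b1
    bases[1::2] = b2
    strand = np.zeros(n, dtype=np.uint8)
    strand[1::2] = 1
    mate = np.ones(n, dtype=np.int64)
    mate[1::2] = 2
    pair_id = np.repeat(np.arange(n_pairs), 2)
    hap_all = np.repeat(hap, 2)
    hs = np.empty(n, dtype=np.int64)
    hs[0::2] = start1
    hs[1::2] = start2
    insert_all = np.repeat(inserts, 2)

    colors = None
    color_quality = 0
    if space == "color":
        # colors in sequencing orientation; complementation leaves the color
        # of a dibase unchanged, so only orientation matters
        seq_codes = bases.copy()
        rev = strand == 1
        seq_codes[rev] = (3 - seq_codes[rev])[:, ::-1]
        adapter_code = int(_BASE_CODES[ord(params.adapter)])
        colors = np.empty_like(seq_codes)
        colors[:, 0] = seq_codes[:, 0] ^ adapter_code
        colors[:, 1:] = seq_codes[:, 1:] ^ seq_codes[:, :-1]
        err = rng.random(colors.shape) < params.color_error_rate
        shift = rng.integers(1, 4, colors.shape).astype(np.uint8)
        colors[err] = (colors[err] + shift[err]) % 4
        color_quality = phred_from_rate(params.color_error_rate)
        # stored bases = naive cumulative decode of the (corrupted) colors
        decoded = np.bitwise_xor.accumulate(colors, axis=1) ^ adapter_code
        decoded[rev] = (3 - decoded[rev])[:, ::-1]
        bases = decoded
        quality = phred_from_rate(params.color_error_rate)
    else:
        err = rng.random(bases.shape) < params.base_error_rate
        shift = rng.integers(1, 4, bases.shape).astype(np.uint8)
        bases[err] = (bases[err] + shift[err]) % 4
        quality = phred_from_rate(params.base_error_rate)

    # true origin anchors in reference coordinates
    ref_start = np.empty(n, dtype=np.int64)
    ref_end = np.empty(n, dtype=np.int64)
    for h in (0, 1):
        m = hap_all == h
        pm = haplotypes[h].ref_positions
        ref_start[m] = pm[hs[m]]
        ref_end[m] = pm[hs[m] + rl - 1]

    return SimulatedReads(
        read_length=rl,
        bases=bases,
        quality=quality,
        haplotype=hap_all,
        hap_start=hs,
        strand=strand,
        mate=mate,
        pair_id=pair_id,
        ref_start=ref_start,
        ref_end=ref_end,
        insert_size=insert_all,
        colors=colors,
        color_quality=color_quality,
        adapter=params.adapter,
    )


# --------------------------------------------------------------------- #
# stand-in initial aligner

#: Affine-gap costs for the fallback aligner (minimised): match 0,
#: mismatch 3, gap open 6 + 1 per base.  Gap-friendly, like the
#: indel-sensitive mappers the method expects upstream: a long deletion
#: spanned with decent anchors is cheaper than scattering mismatches, while
#: an indel within a few bases of a read end still tends to be traded for
#: mismatches or clipped — the local misplacement re-alignment repairs.
MISMATCH_COST = 3.0
GAP_OPEN = 10.0
GAP_EXTEND = 1.0

_INF = 1e30


def affine_glocal_align(query_codes: np.ndarray, target_codes: np.ndarray):
    """Query-global, target-free-ends affine-gap alignment (Gotoh).

    Returns ``(start, ops)`` with ``start`` the 0-based target offset of
    the first aligned query base and ``ops`` SAM-style ``[op, length]``
    pairs.  Row-wise vectorised; the within-row deletion recurrence is an
    exact prefix-scan because any maximal run of D in an optimal affine
    path opens from a non-D state.
    """
    L = len(query_codes)
    W = len(target_codes)
    H = np.empty((L + 1, W + 1), dtype=np.float64)
    E = np.full((L + 1, W + 1), _INF)  # gap in query (D), horizontal
    F = np.full((L + 1, W + 1), _INF)  # gap in target (I), vertical
    HT = np.empty_like(H)  # min(diag, F): D-gap anchors
    H[0] = 0.0  # free target prefix
    HT[0] = 0.0
    H[1:, 0] = GAP_OPEN + GAP_EXTEND * np.arange(1, L + 1)
    F[1:, 0] = H[1:, 0]
    HT[1:, 0] = H[1:, 0]
    jext = GAP_EXTEND * np.arange(1, W + 1)
    for i in range(1, L + 1):
        sub = np.where(target_codes == query_codes[i - 1], 0.0, MISMATCH_COST)
        diag = H[i - 1, :-1] + sub
        F[i, 1:] = np.minimum(F[i - 1, 1:] + GAP_EXTEND, H[i - 1, 1:] + GAP_OPEN + GAP_EXTEND)
        ht = np.minimum(diag, F[i, 1:])
        HT[i, 1:] = ht
        # E[i][j] = min_{k<j} HT[i][k] + open + (j-k)*ext, via running min
        anchors = np.concatenate(([HT[i, 0]], ht[:-1]))
        run = np.minimum.accumulate(anchors + GAP_OPEN - GAP_EXTEND * np.arange(W))
        E[i, 1:] = run + jext
        H[i, 1:] = np.minimum(ht, E[i, 1:])

    # rightmost optimum: on ties prefer consuming more reference, so a
    # spanned deletion beats an equal-cost read insertion
    j = W - int(np.argmin(H[L][::-1]))
    ops: list[list] = []

    def emit(op):
        if ops and ops[-1][0] == op:
            ops[-1][1] += 1
        else:
            ops.append([op, 1])

    i = L
    state = "H"
    while i > 0:
        if state == "H":
            if j > 0 and H[i, j] == E[i, j] and HT[i, j] > E[i, j]:
                state = "E"
                continue
            state = "HT"
            continue
        if state == "HT":
            if j > 0 and HT[i, j] == H[i - 1, j - 1] + (
                0.0 if target_codes[j - 1] == query_codes[i - 1] else MISMATCH_COST
            ):
                emit("M")
                i -= 1
                j -= 1
                state = "H"
            else:
                state = "F"
            continue
        if state == "E":
            emit("D")
            if HT[i, j - 1] + GAP_OPEN + GAP_EXTEND == E[i, j]:
                j -= 1
                state = "HT"
            else:
                j -= 1
            continue
        # state == "F"
        emit("I")
        if j == 0 or H[i - 1, j] + GAP_OPEN + GAP_EXTEND == F[i, j]:
            i -= 1
            state = "H"
        else:
            i -= 1
    ops.reverse()
    if ops and ops[0][0] == "I":
        ops[0][0] = "S"
    if ops and ops[-1][0] == "I":
        ops[-1][0] = "S"
    return j, ops


def _edlib_is_clean(ops, distance: int) -> bool:
    """Accept a unit-cost alignment only when it looks like a real mapper's
    output: at most one contiguous indel block and few total edits."""
    indel_blocks = sum(1 for op, _ in ops if op in ("I", "D", "S"))
    indel_len = sum(ln for op, ln in ops if op in ("I", "D", "S"))
    if indel_blocks == 0:
        return distance <= 5
    return indel_blocks == 1 and distance - indel_len <= 5


class InitialAlignment(NamedTuple):
    """One read's initial alignment (genome-orientation SEQ, SAM-style)."""

    name: str
    position: int  # 1-based
    cigar: str
    strand: str
    bases: str
    quality: int
    mate: int
    cs: Optional[str] = None
    cq: Optional[str] = None


def _edlib_to_sam_cigar(cigar: str) -> list[list]:
    """Normalise an edlib path to SAM ops; end insertions become soft clips."""
    import re as _re

    ops = [[m.group(2), int(m.group(1))] for m in _re.finditer(r"(\d+)([=XIDM])", cigar)]
    out: list[list] = []
    for op, ln in ops:
        if op in ("=", "X"):
            op = "M"
        if out and out[-1][0] == op:
            out[-1][1] += ln
        else:
            out.append([op, ln])
    if out and out[0][0] == "I":
        out[0][0] = "S"
    if out and out[-1][0] == "I":
        out[-1][0] = "S"
    return out


def naive_initial_align(
    reads: SimulatedReads,
    reference: str,
    pad: int = 35,
) -> list[InitialAlignment]:
    """Align each read near its true origin with unit-cost edit distance.

    The search window is the read's true reference span padded by ``pad``
    bases (covering the largest simulated indels), so mapping location is
    essentially always right while *local* placement — indels near read
    ends, indel position within repeats — is left to the edit-distance
    optimum, reproducing the artifacts a production aligner leaves behind.
    Output is sorted by position.
    """
    L = len(reference)
    out = []
    qual = reads.quality
    cqual = reads.color_quality
    ref_codes_full = _to_codes(reference)
    for i in range(len(reads)):
        seq = reads.sequence(i)
        ws = max(1, int(reads.ref_start[i]) - pad)
        we = min(L, int(reads.ref_end[i]) + pad)
        res = edlib.align(seq, reference[ws - 1 : we], mode="HW", task="path")
        loc = res["locations"][0]
        ops = _edlib_to_sam_cigar(res["cigar"])
        pos = ws + loc[0]
        if not _edlib_is_clean(ops, res["editDistance"]):
            start, a_ops = affine_glocal_align(
                reads.bases[i], ref_codes_full[ws - 1 : we]
            )
            if a_ops:
                ops = a_ops
                pos = ws + start
        cigar = "".join(f"{ln}{op}" for op, ln in ops)
        cs = cq = None
        if reads.colors is not None:
            cs = reads.adapter + "".join(str(c) for c in reads.colors[i])
            cq = chr(cqual + 33) * reads.read_length
        out.append(
            InitialAlignment(
                name=reads.name(i),
                position=pos,
                cigar=cigar,
                strand="-" if reads.strand[i] else "+",
                bases=seq,
                quality=qual,
                mate=int(reads.mate[i]),
                cs=cs,
                cq=cq,
            )
        )
    out.sort(key=lambda a: a.position)
    return out


def write_truth_table(truth: pd.DataFrame, path) -> None:
    """Truth table as a VCF-like tab-separated file."""
    truth.to_csv(path, sep="\t", index=False)
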