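"""Variant calling and accuracy evaluation for simulated experiments.

:func:`pileup_call` is a deliberately simple *stand-in* caller — a
quality-agnostic diploid genotype likelihood per reference column (and per
indel allele), with a Phred-scaled variant quality — used identically on the
alignments before and after re-alignment so that caller bias cancels in
every comparison.  It is not a re-implementation of any production consensus
model.

The evaluation metrics mirror the standard simulation readouts: ROC curves
of sensitivity versus false-positive rate under an increasing variant
quality threshold, the non-reference allele-frequency spectrum split by
zygosity (heterozygous sites should centre on 0.5, homozygous on 1.0), and
concordance of called indels against a catalog with a +/-5 base positional
wiggle and exact length match.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .variant_graph import parse_cigar

_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODES[_b] = _i

#: Phred cap on reported variant qualities.
MAX_QUALITY = 4000.0


def _log10sumexp(cols: list[np.ndarray]) -> np.ndarray:
    m = np.maximum.reduce(cols)
    s = np.zeros_like(m)
    for c in cols:
        s += np.power(10.0, c - m)
    return m + np.log10(s)


def pileup_call(
    alignments: Iterable,
    reference: str,
    min_depth: int = 4,
    min_alt: int = 2,
    base_error: float = 0.01,
    indel_error: float = 1e-3,
) -> pd.DataFrame:
    """Call variants from aligned reads over one contig (stand-in caller).

    ``alignments`` yields ``(position, cigar, bases)`` tuples (1-based
    position, SAM CIGAR, genome-orientation sequence).  Each reference
    column with at least ``min_alt`` copies of the same non-reference base
    is genotyped under a three-genotype diploid model with a flat prior and
    symmetric per-base error ``base_error``; indel alleles are grouped from
    CIGAR I/D operations by position and allele string and genotyped the
    same way with error ``indel_error``.  The variant quality is the
    Phred-scaled posterior probability that the site is homozygous
    reference.  Output columns: position, vtype, ref_allele, alt_allele,
    zygosity, quality, consensus_quality, depth, alt_count.
    """
    L = len(reference)
    ref_codes = _BASE_CODES[np.frombuffer(reference.encode(), dtype=np.uint8)]

    # --- accumulate base counts per column (vectorised over reads) ------- #
    counts = np.zeros((L + 2) * 4, dtype=np.int64)
    simple_pos: list[int] = []
    simple_codes: list[np.ndarray] = []
    indel_obs: dict[tuple, int] = {}
    # deletion spanning coverage per position (reads whose D covers the column)
    del_span: dict[int, int] = {}

    batch_pos: list[np.ndarray] = []
    batch_codes: list[np.ndarray] = []

    def flush_simple():
        if not simple_pos:
            return
        starts = np.asarray(simple_pos, dtype=np.int64)
        codes = np.vstack(simple_codes)
        rl = codes.shape[1]
        pos = starts[:, None] + np.arange(rl)
        idx = (pos * 4 + codes).ravel()
        ok = codes.ravel() < 4
        np.add.at(counts, idx[ok], 1)
        simple_pos.clear()
        simple_codes.clear()

    cigar_cache: dict[str, list] = {}
    n_simple_len = None
    for position, cigar, bases in alignments:
        ops = cigar_cache.get(cigar)
        if ops is None:
            ops = parse_cigar(cigar)
            cigar_cache[cigar] = ops
        codes = _BASE_CODES[np.frombuffer(bases.encode(), dtype=np.uint8)]
        if len(ops) == 1 and ops[0][0] == "M":
            if n_simple_len is None:
                n_simple_len = len(codes)
            if len(codes) == n_simple_len:
                simple_pos.append(position)
                simple_codes.append(codes)
                if len(simple_pos) >= 200000:
                    flush_simple()
                continue
        ref_pos = position
        read_i = 0
        for op, ln in ops:
            if op in ("M", "=", "X"):
                batch_pos.append(np.arange(ref_pos, ref_pos + ln, dtype=np.int64))
                batch_codes.append(codes[read_i : read_i + ln])
                ref_pos += ln
                read_i += ln
            elif op == "I":
                allele = bases[read_i : read_i + ln]
                key = (ref_pos, "INS", allele)
                indel_obs[key] = indel_obs.get(key, 0) + 1
                read_i += ln
            elif op in ("D", "N"):
                key = (ref_pos, "DEL", ln)
                indel_obs[key] = indel_obs.get(key, 0) + 1
                for q in range(ref_pos, ref_pos + ln):
                    del_span[q] = del_span.get(q, 0) + 1
                ref_pos += ln
            elif op == "S":
                read_i += ln
        if len(batch_pos) > 100000:
            p = np.concatenate(batch_pos)
            c = np.concatenate(batch_codes)
            ok = c < 4
            np.add.at(counts, (p[ok] * 4 + c[ok]), 1)
            batch_pos.clear()
            batch_codes.clear()
    flush_simple()
    if batch_pos:
        p = np.concatenate(batch_pos)
        c = np.concatenate(batch_codes)
        ok = c < 4
        np.add.at(counts, (p[ok] * 4 + c[ok]), 1)

    counts = counts.reshape(-1, 4)[1 : L + 1]  # row i -> position i+1
    depth = counts.sum(axis=1)

    # --- SNP genotyping (vectorised) ------------------------------------- #
    rows = []
    valid = ref_codes < 4
    pos_index = np.arange(L)
    r = np.where(valid, counts[pos_index, np.where(valid, ref_codes, 0)], 0)
    alt_counts = counts.copy()
    alt_counts[pos_index[valid], ref_codes[valid]] = -1
    alt_code = alt_counts.argmax(axis=1)
    a = alt_counts[pos_index, alt_code]
    cand = valid & (a >= min_alt) & (depth >= min_depth)
    if cand.any():
        idx = np.flatnonzero(cand)
        rr, aa = r[idx].astype(float), a[idx].astype(float)
        e = base_error
        lg_match = math.log10(1 - e)
        lg_err = math.log10(e / 3.0)
        lg_het = math.log10((1 - e) / 2.0 + e / 6.0)
        l_rr = rr * lg_match + aa * lg_err
        l_ra = (rr + aa) * lg_het
        l_aa = aa * lg_match + rr * lg_err
        tot = _log10sumexp([l_rr, l_ra, l_aa])
        best = np.maximum(l_ra, l_aa)
        is_var = best > l_rr
        qual = np.minimum(-10.0 * (l_rr - tot), MAX_QUALITY)
        post_best = np.power(10.0, np.maximum.reduce([l_rr, l_ra, l_aa]) - tot)
        cons_q = np.minimum(
            -10.0 * np.log10(np.maximum(1.0 - post_best, 1e-300)), MAX_QUALITY
        )
        for k, i in enumerate(idx):
            if not is_var[k]:
                continue
            rows.append(
                {
                    "position": int(i + 1),
                    "vtype": "SNP",
                    "ref_allele": reference[i],
                    "alt_allele": "ACGT"[int(alt_code[i])],
                    "zygosity": "HET" if l_ra[k] >= l_aa[k] else "HOM",
                    "quality": float(qual[k]),
                    "consensus_quality": float(cons_q[k]),
                    "depth": int(depth[i]),
                    "alt_count": int(a[i]),
                }
            )

    # --- indel genotyping ------------------------------------------------ #
    by_site: dict[tuple, dict] = {}
    for (pos, vtype, allele), cnt in indel_obs.items():
        site = by_site.setdefault((pos, vtype), {})
        site[allele] = site.get(allele, 0) + cnt
    e = indel_error
    lg_match = math.log10(1 - e)
    lg_err = math.log10(e)
    lg_het = math.log10(0.5)
    for (pos, vtype), alleles in sorted(by_site.items()):
        allele, cnt = max(alleles.items(), key=lambda kv: (kv[1], str(kv[0])))
        if pos < 1 or pos > L:
            continue
        col_depth = int(depth[pos - 1])
        if vtype == "DEL":
            site_depth = col_depth + del_span.get(pos, 0)
        else:
            site_depth = col_depth
        ref_n = max(site_depth - cnt, 0)
        if cnt < min_alt or site_depth < min_depth:
            continue
        l_rr = ref_n * lg_match + cnt * lg_err
        l_ra = (ref_n + cnt) * lg_het
        l_aa = cnt * lg_match + ref_n * lg_err
        tot = _log10sumexp(
            [np.array([l_rr]), np.array([l_ra]), np.array([l_aa])]
        )[0]
        if max(l_ra, l_aa) <= l_rr:
            continue
        qual = min(-10.0 * (l_rr - tot), MAX_QUALITY)
        post_best = 10.0 ** (max(l_rr, l_ra, l_aa) - tot)
        cons_q = min(-10.0 * math.log10(max(1.0 - post_best, 1e-300)), MAX_QUALITY)
        if vtype == "DEL":
            ref_allele = reference[pos - 1 : pos - 1 + int(allele)]
            alt_allele = "-"
        else:
            ref_allele = "-"
            alt_allele = allele
        rows.append(
            {
                "position": int(pos),
                "vtype": vtype,
                "ref_allele": ref_allele,
                "alt_allele": alt_allele,
                "zygosity": "HET" if l_ra >= l_aa else "HOM",
                "quality": float(qual),
                "consensus_quality": float(cons_q),
                "depth": int(site_depth),
                "alt_count": int(cnt),
            }
        )

    calls = pd.DataFrame(
        rows,
        columns=[
            "position",
            "vtype",
            "ref_allele",
            "alt_allele",
            "zygosity",
            "quality",
            "consensus_quality",
            "depth",
            "alt_count",
        ],
    )
    return calls.sort_values(["position", "vtype"]).reset_index(drop=True)


# --------------------------------------------------------------------- #
# accuracy metrics


def _match_calls_to_truth(
    calls: pd.DataFrame, truth: pd.DataFrame, vtype: str, wiggle: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-call matched truth index (-1 if none), plus truth positions."""
    tpos = np.sort(truth.loc[truth.vtype == vtype, "position"].to_numpy())
    sub = calls[calls.vtype == vtype]
    cpos = sub["position"].to_numpy()
    matched = np.full(len(sub), -1, dtype=np.int64)
    if len(tpos) and len(cpos):
        tol = 0 if vtype == "SNP" else wiggle
        j = np.searchsorted(tpos, cpos)
        for k in range(len(cpos)):
            best = -1
            for jj in (j[k] - 1, j[k]):
                if 0 <= jj < len(tpos) and abs(int(tpos[jj]) - int(cpos[k])) <= tol:
                    best = jj
            matched[k] = best
    return matched, tpos


def roc_curve(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    genome_length: int,
    thresholds: Optional[Sequence[float]] = None,
    wiggle: int = 5,
) -> pd.DataFrame:
    """Sensitivity / false-positive rate per variant type and threshold.

    A call is a true positive if a truth row of the same type exists at the
    same position (indels within ``wiggle`` bases, since equivalent
    placements shift).  Sensitivity is the fraction of truth sites hit by a
    call at or above the threshold; the false-positive rate divides
    unmatched calls by the callable reference positions (genome length minus
    truth sites).
    """
    callable_n = genome_length - len(truth)
    if thresholds is None:
        qs = calls["quality"].to_numpy() if len(calls) else np.array([0.0])
        thresholds = np.unique(np.concatenate([[0.0], qs]))
    out = []
    for vtype in ("SNP", "INS", "DEL"):
        matched, tpos = _match_calls_to_truth(calls, truth, vtype, wiggle)
        sub = calls[calls.vtype == vtype]
        quals = sub["quality"].to_numpy()
        n_truth = len(tpos)
        # best call quality per truth site
        best_q = np.full(n_truth, -np.inf)
        for k in range(len(sub)):
            m = matched[k]
            if m >= 0 and quals[k] > best_q[m]:
                best_q[m] = quals[k]
        fp_quals = np.sort(quals[matched < 0])
        for t in thresholds:
            tp = int((best_q >= t).sum()) if n_truth else 0
            fp = int(len(fp_quals) - np.searchsorted(fp_quals, t, side="left"))
            out.append(
                {
                    "threshold": float(t),
                    "vtype": vtype,
                    "tp": tp,
                    "fp": fp,
                    "n_truth": n_truth,
                    "sensitivity": tp / n_truth if n_truth else float("nan"),
                    "fpr": fp / callable_n if callable_n > 0 else float("nan"),
                }
            )
    return pd.DataFrame(out)


def allele_frequency_spectrum(
    calls: pd.DataFrame, bins: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-reference allele frequency per call, split by zygosity and type.

    Returns the per-site table (with a ``frequency`` column; zero-depth
    sites are excluded) and a summary with the median frequency and
    histogram counts per (zygosity, vtype) group.
    """
    df = calls[calls["depth"] > 0].copy()
    df["frequency"] = df["alt_count"] / df["depth"]
    edges = np.linspace(0.0, 1.0, bins + 1)
    rows = []
    for (zyg, vtype), grp in df.groupby(["zygosity", "vtype"]):
        hist, _ = np.histogram(grp["frequency"], bins=edges)
        rows.append(
            {
                "zygosity": zyg,
                "vtype": vtype,
                "n": len(grp),
                "median_frequency": float(grp["frequency"].median()),
                "histogram": hist.tolist(),
            }
        )
    return df, pd.DataFrame(rows)


def catalog_concordance(
    indel_calls: pd.DataFrame,
    catalog: pd.DataFrame,
    wiggle: int = 5,
    thresholds: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Fraction of called indels matching a catalog entry, by threshold.

    A call is concordant if some catalog indel within ``wiggle`` positions
    has exactly the same length.  ``catalog`` needs ``position`` and
    ``length`` columns.  Reports concordance and discordance (= 1 -
    concordance) across increasing quality thresholds.
    """
    sub = indel_calls[indel_calls.vtype.isin(("INS", "DEL"))].copy()
    lengths = np.where(
        sub["vtype"] == "DEL",
        sub["ref_allele"].str.len(),
        sub["alt_allele"].str.len(),
    )
    cat = catalog.sort_values("position")
    cpos = cat["position"].to_numpy()
    clen = cat["length"].to_numpy()
    conc = np.zeros(len(sub), dtype=bool)
    pos_arr = sub["position"].to_numpy()
    for k in range(len(sub)):
        lo = np.searchsorted(cpos, pos_arr[k] - wiggle, side="left")
        hi = np.searchsorted(cpos, pos_arr[k] + wiggle, side="right")
        conc[k] = bool(np.any(clen[lo:hi] == lengths[k]))
    quals = sub["quality"].to_numpy()
    if thresholds is None:
        thresholds = np.unique(np.concatenate([[0.0], quals])) if len(sub) else [0.0]
    rows = []
    for t in thresholds:
        m = quals >= t
        n = int(m.sum())
        c = float(conc[m].mean()) if n else float("nan")
        rows.append(
            {
                "threshold": float(t),
                "n_calls": n,
                "concordance": c,
                "discordance": 1.0 - c if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def sensitivity_at_fpr(
    roc: pd.DataFrame, max_fpr: float = 1e-6
) -> dict[str, float]:
    """Per-type sensitivity at the smallest threshold with FPR <= max_fpr.

    Returns NaN for a type whose curve never reaches the FPR bound.
    """
    out = {}
    for vtype, grp in roc.groupby("vtype"):
        grp = grp.sort_values("threshold")
        ok = grp[grp["fpr"] <= max_fpr]
        out[vtype] = float(ok.iloc[0]["sensitivity"]) if len(ok) else float("nan")
    return out


def write_vcf(
    calls: pd.DataFrame,
    reference: str,
    path,
    contig: str = "ref",
    sample: str = "sample",
) -> None:
    """Write calls as minimal VCF 4.2 (CHROM POS REF ALT QUAL GT:DP:AD).

    Indels use the standard anchor-base representation: a deletion at
    position p is reported at p-1 with the deleted bases appended to REF,
    an insertion before p at p-1 with the inserted bases appended to ALT.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(reference)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample}\n"
        )
        for row in calls.sort_values("position").itertuples():
            pos = int(row.position)
            if row.vtype == "SNP":
                vpos, ref, alt = pos, row.ref_allele, row.alt_allele
            elif row.vtype == "DEL":
                if pos < 2:
                    continue
                anchor = reference[pos - 2]
                vpos, ref, alt = pos - 1, anchor + row.ref_allele, anchor
            else:  # INS before `pos`
                if pos < 2:
                    continue
                anchor = reference[pos - 2]
                vpos, ref, alt = pos - 1, anchor, anchor + row.alt_allele
            gt = "0/1" if row.zygosity == "HET" else "1/1"
            ad = f"{int(row.depth) - int(row.alt_count)},{int(row.alt_count)}"
            fh.write(
                f"{contig}\t{vpos}\t.\t{ref}\t{alt}\t{row.quality:.0f}\t.\t.\t"
                f"GT:DP:AD\t{gt}:{int(row.depth)}:{ad}\n"
            )
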