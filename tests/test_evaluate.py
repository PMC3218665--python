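"""Stand-in caller and evaluation metrics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from _oracles import (
    brute_force_concordance,
    brute_force_diploid_genotype,
    brute_force_roc_counts,
)
from srma.evaluate import (
    allele_frequency_spectrum,
    catalog_concordance,
    pileup_call,
    roc_curve,
    sensitivity_at_fpr,
)
from srma.simulate import random_reference


def reads_at(reference, rows):
    """Expand (position, cigar, bases, n_copies) into alignment tuples."""
    out = []
    for pos, cigar, bases, n in rows:
        out.extend([(pos, cigar, bases)] * n)
    return out


class TestPileupCall:
    def test_reference_matching_reads_produce_no_call(self):
        ref = random_reference(100, 1)
        calls = pileup_call(reads_at(ref, [(1, "50M", ref[:50], 10)]), ref)
        assert len(calls) == 0

    def test_balanced_column_called_heterozygous(self):
        ref = random_reference(100, 2)
        k = 25  # 0-based
        alt = "C" if ref[k] != "C" else "T"
        mutated = ref[:k] + alt + ref[k + 1 : 50]
        calls = pileup_call(
            reads_at(ref, [(1, "50M", ref[:50], 5), (1, "50M", mutated, 5)]), ref
        )
        assert len(calls) == 1
        row = calls.iloc[0]
        assert (row.position, row.vtype, row.zygosity) == (k + 1, "SNP", "HET")
        assert row.alt_allele == alt
        # ML genotype agrees with exhaustive enumeration over all 10 genotypes
        counts = {b: 0 for b in "ACGT"}
        counts[ref[k]] = 5
        counts[alt] = 5
        expected = brute_force_diploid_genotype(counts, ref[k], 0.01)
        assert set(expected) == {ref[k], alt}

    def test_near_unanimous_column_called_homozygous(self):
        ref = random_reference(100, 3)
        k = 10
        alt = "G" if ref[k] != "G" else "A"
        mutated = ref[:k] + alt + ref[k + 1 : 40]
        calls = pileup_call(
            reads_at(ref, [(1, "40M", mutated, 9), (1, "40M", ref[:40], 1)]), ref
        )
        row = calls[calls.position == k + 1].iloc[0]
        assert row.zygosity == "HOM"
        counts = {b: 0 for b in "ACGT"}
        counts[ref[k]] = 1
        counts[alt] = 9
        assert brute_force_diploid_genotype(counts, ref[k], 0.01) == (alt, alt)

    def test_dominant_deletion_called_homozygous(self):
        ref = random_reference(100, 4)
        with_del = ref[:20] + ref[22:50]
        calls = pileup_call(
            reads_at(
                ref,
                [(1, "20M2D28M", with_del, 9), (1, "50M", ref[:50], 1)],
            ),
            ref,
        )
        row = calls[calls.vtype == "DEL"].iloc[0]
        assert (row.position, row.zygosity) == (21, "HOM")
        assert row.ref_allele == ref[20:22]
        assert row.alt_count == 9 and row.depth == 10

    def test_insertion_allele_grouped_by_string(self):
        ref = random_reference(100, 5)
        with_ins = ref[:20] + "ACA" + ref[20:47]
        calls = pileup_call(
            reads_at(
                ref,
                [(1, "20M3I27M", with_ins, 6), (1, "50M", ref[:50], 6)],
            ),
            ref,
        )
        row = calls[calls.vtype == "INS"].iloc[0]
        assert (row.position, row.alt_allele, row.zygosity) == (21, "ACA", "HET")

    def test_min_depth_respected(self):
        ref = random_reference(100, 6)
        alt = "C" if ref[0] != "C" else "T"
        calls = pileup_call(
            reads_at(ref, [(1, "10M", alt + ref[1:10], 3)]), ref, min_depth=4
        )
        assert len(calls) == 0


def truth_frame(rows):
    return pd.DataFrame(rows, columns=["position", "vtype"]).assign(
        ref_allele="N", alt_allele="N", zygosity="HET", haplotypes="A"
    )


def calls_frame(rows):
    return pd.DataFrame(
        rows, columns=["position", "vtype", "quality"]
    ).assign(
        ref_allele="AA",
        alt_allele="AA",
        zygosity="HET",
        consensus_quality=10.0,
        depth=10,
        alt_count=5,
    )


class TestRocCurve:
    def test_perfect_calls_reach_full_sensitivity_zero_fpr(self):
        truth = truth_frame([(10, "SNP"), (20, "INS"), (30, "DEL")])
        calls = calls_frame([(10, "SNP", 50), (20, "INS", 50), (30, "DEL", 50)])
        roc = roc_curve(calls, truth, 1000, thresholds=[0.0])
        assert (roc.sensitivity == 1.0).all()
        assert (roc.fpr == 0.0).all()

    def test_threshold_above_all_quals_zeroes_curve(self):
        truth = truth_frame([(10, "SNP")])
        calls = calls_frame([(10, "SNP", 50), (40, "SNP", 30)])
        roc = roc_curve(calls, truth, 1000, thresholds=[100.0])
        snp = roc[roc.vtype == "SNP"].iloc[0]
        assert snp.sensitivity == 0.0 and snp.fpr == 0.0

    def test_counts_match_brute_force_matcher(self, rng):
        truth = truth_frame(
            [(int(p), v) for p, v in zip(rng.integers(1, 500, 25),
                                         rng.choice(["SNP", "INS", "DEL"], 25))]
        )
        calls = calls_frame(
            [
                (int(p), v, float(q))
                for p, v, q in zip(
                    rng.integers(1, 500, 40),
                    rng.choice(["SNP", "INS", "DEL"], 40),
                    rng.integers(0, 100, 40),
                )
            ]
        )
        thresholds = [0.0, 25.0, 50.0, 75.0]
        roc = roc_curve(calls, truth, 10_000, thresholds=thresholds)
        for vtype in ("SNP", "INS", "DEL"):
            for t in thresholds:
                tp, fp = brute_force_roc_counts(calls, truth, vtype, t, 5)
                row = roc[(roc.vtype == vtype) & (roc.threshold == t)].iloc[0]
                assert row.tp == tp, (vtype, t)
                assert row.fp == fp, (vtype, t)

    def test_monotone_in_threshold(self, rng):
        calls = calls_frame(
            [
                (int(p), "SNP", float(q))
                for p, q in zip(rng.integers(1, 300, 30), rng.integers(0, 60, 30))
            ]
        )
        truth = truth_frame([(int(p), "SNP") for p in rng.integers(1, 300, 10)])
        roc = roc_curve(calls, truth, 5000)
        snp = roc[roc.vtype == "SNP"].sort_values("threshold")
        assert (np.diff(snp.sensitivity) <= 1e-12).all()
        assert (np.diff(snp.fpr) <= 1e-12).all()

    def test_sensitivity_at_fpr_picks_smallest_qualifying_threshold(self):
        truth = truth_frame([(10, "SNP"), (20, "SNP")])
        calls = calls_frame(
            [(10, "SNP", 90), (20, "SNP", 40), (500, "SNP", 10)]
        )
        roc = roc_curve(calls, truth, 2_000_000, thresholds=[0.0, 20.0, 50.0])
        # at t=0 one FP (fpr 5e-7 <= 1e-6) so sensitivity 1.0 qualifies
        assert sensitivity_at_fpr(roc, 1e-6)["SNP"] == 1.0


class TestSpectrum:
    def test_frequency_is_alt_over_depth(self):
        calls = calls_frame([(10, "SNP", 50)])
        spec, summary = allele_frequency_spectrum(calls)
        assert spec.frequency.iloc[0] == 0.5
        het = summary[(summary.zygosity == "HET") & (summary.vtype == "SNP")]
        assert het.median_frequency.iloc[0] == 0.5

    def test_zero_depth_sites_excluded(self):
        calls = calls_frame([(10, "SNP", 50), (20, "SNP", 50)])
        calls.loc[calls.position == 20, "depth"] = 0
        spec, _ = allele_frequency_spectrum(calls)
        assert list(spec.position) == [10]


class TestCatalogConcordance:
    def catalog(self):
        return pd.DataFrame({"position": [100, 300], "length": [2, 3]})

    def indel_calls(self, rows):
        out = []
        for pos, vtype, length, q in rows:
            out.append(
                {
                    "position": pos,
                    "vtype": vtype,
                    "ref_allele": "A" * length if vtype == "DEL" else "-",
                    "alt_allele": "-" if vtype == "DEL" else "A" * length,
                    "zygosity": "HET",
                    "quality": q,
                    "consensus_quality": q,
                    "depth": 10,
                    "alt_count": 5,
                }
            )
        return pd.DataFrame(out)

    def test_exact_match_concordant_at_zero_wiggle(self):
        calls = self.indel_calls([(100, "DEL", 2, 50)])
        conc = catalog_concordance(calls, self.catalog(), wiggle=0)
        assert conc.concordance.iloc[0] == 1.0

    def test_wiggle_window_is_inclusive_five(self):
        near = self.indel_calls([(105, "DEL", 2, 50)])
        far = self.indel_calls([(106, "DEL", 2, 50)])
        assert catalog_concordance(near, self.catalog()).concordance.iloc[0] == 1.0
        assert catalog_concordance(far, self.catalog()).concordance.iloc[0] == 0.0

    def test_length_must_match_exactly(self):
        calls = self.indel_calls([(100, "DEL", 3, 50)])
        assert catalog_concordance(calls, self.catalog()).concordance.iloc[0] == 0.0

    def test_random_sets_match_brute_force(self, rng):
        calls = self.indel_calls(
            [
                (int(p), "DEL", int(l), 50)
                for p, l in zip(rng.integers(1, 400, 30), rng.integers(1, 5, 30))
            ]
        )
        catalog = pd.DataFrame(
            {
                "position": rng.integers(1, 400, 20),
                "length": rng.integers(1, 5, 20),
            }
        )
        got = catalog_concordance(calls, catalog, thresholds=[0.0]).concordance.iloc[0]
        expected = brute_force_concordance(
            [(int(r.position), len(r.ref_allele)) for r in calls.itertuples()],
            list(zip(catalog.position, catalog.length)),
            5,
        )
        assert got == pytest.approx(expected)


def test_write_vcf_anchors_indels(tmp_path):
    from srma.evaluate import write_vcf

    ref = "ACGTACGTAC"
    calls = pd.DataFrame(
        [
            {"position": 3, "vtype": "SNP", "ref_allele": "G", "alt_allele": "T",
             "zygosity": "HET", "quality": 40.0, "consensus_quality": 40.0,
             "depth": 10, "alt_count": 5},
            {"position": 5, "vtype": "DEL", "ref_allele": "AC", "alt_allele": "-",
             "zygosity": "HOM", "quality": 50.0, "consensus_quality": 50.0,
             "depth": 12, "alt_count": 11},
            {"position": 8, "vtype": "INS", "ref_allele": "-", "alt_allele": "TT",
             "zygosity": "HET", "quality": 30.0, "consensus_quality": 30.0,
             "depth": 9, "alt_count": 4},
        ]
    )
    path = tmp_path / "calls.vcf"
    write_vcf(calls, ref, path, contig="ctg")
    lines = [l.split("\t") for l in path.read_text().splitlines() if not l.startswith("#")]
    assert [l[1] for l in lines] == ["3", "4", "7"]
    assert lines[0][3:5] == ["G", "T"]
    assert lines[1][3:5] == ["TAC", "T"]  # anchor + deleted bases
    assert lines[2][3:5] == ["G", "GTT"]  # anchor + inserted bases
    assert lines[1][9].startswith("1/1:12:1,11")
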