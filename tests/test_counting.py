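"""Counting rules, TPM, replicate QC, intron retention."""

import numpy as np
import pandas as pd
import pytest

from hetsilence.counting import (
    AlignmentRecord,
    CountTable,
    CountingError,
    ReplicateQCError,
    count_reads,
    intron_retention,
    read_sam,
    replicate_qc,
    tpm_normalize,
)
from hetsilence.genome import GeneModel, GenomeAnnotation

from oracles import brute_force_count, brute_force_tpm, random_instance


def rec(rid, chrom, start, end, strand="+", n=1):
    return AlignmentRecord(rid, [(chrom, start, end, strand)] * n)


def multi(rid, locs):
    return AlignmentRecord(rid, locs)


def counts_of(table: CountTable) -> dict:
    return table.counts.iloc[:, 0].to_dict()


class TestUniqueReadAssignment:
    def test_read_inside_gene_matching_strand_counts(self, mini_ann):
        t = count_reads([rec("r1", "chr1", 200, 250, "+")], mini_ann, "rip")
        assert counts_of(t)["gA"] == 1
        assert t.drop_stats["counted"].iloc[0] == 1

    def test_antisense_read_dropped_for_rna_assay(self, mini_ann):
        t = count_reads([rec("r1", "chr1", 200, 250, "-")], mini_ann, "rip")
        assert sum(counts_of(t).values()) == 0
        assert t.drop_stats["strand"].iloc[0] == 1

    def test_chip_ignores_strand(self, mini_ann):
        t = count_reads([rec("r1", "chr1", 200, 250, "-")], mini_ann, "chip")
        assert counts_of(t)["gA"] == 1

    def test_read_straddling_gene_edge_not_counted(self, mini_ann):
        t = count_reads([rec("r1", "chr1", 1080, 1130, "+")], mini_ann, "chip")
        assert sum(counts_of(t).values()) == 0
        assert t.drop_stats["no_feature"].iloc[0] == 1

    def test_read_contained_in_two_genes_is_ambiguous(self):
        genes = [
            GeneModel("outer", "c", 0, 1000, "+", "protein_coding"),
            GeneModel("inner", "c", 200, 600, "+", "protein_coding"),
        ]
        ann = GenomeAnnotation(genes, {"c": 2000})
        t = count_reads([rec("r1", "c", 300, 350, "+")], ann, "chip")
        assert t.drop_stats["ambiguous"].iloc[0] == 1

    def test_rrna_overlap_removed_first(self, mini_ann):
        # read half inside the rRNA gene: removed, not no_feature
        t = count_reads([rec("r1", "chr1", 7980, 8030, "+")], mini_ann, "rip")
        assert t.drop_stats["rRNA"].iloc[0] == 1


class TestMultiMappers:
    def test_family_multimapper_counts_once_at_representative(self, mini_ann):
        r = multi("m1", [("chr1", 5100, 5150, "+"), ("chr1", 6100, 6150, "+")])
        t = count_reads([r], mini_ann, "rip")
        c = counts_of(t)
        assert c["rep1"] == 1 and c["rep2"] == 0

    def test_nh_at_cutoff_dropped(self, mini_ann):
        locs = [("chr1", 5100, 5150, "+")] * 16
        t = count_reads([multi("m1", locs)], mini_ann, "rip")
        assert t.drop_stats["multimapper"].iloc[0] == 1

    def test_nh_below_cutoff_within_family_counted(self, mini_ann):
        locs = [("chr1", 5100, 5150, "+")] * 15
        t = count_reads([multi("m1", locs)], mini_ann, "rip")
        assert counts_of(t)["rep1"] == 1

    def test_multimapper_with_euchromatic_location_dropped_by_default(self, mini_ann):
        locs = [("chr1", 5100, 5150, "+"), ("chr1", 200, 250, "+")]
        t = count_reads([multi("m1", locs)], mini_ann, "rip")
        assert t.drop_stats["multimapper"].iloc[0] == 1
        # relaxed mode: non-heterochromatic locations are ignored instead
        t2 = count_reads([multi("m1", locs)], mini_ann, "rip",
                         require_all_het=False)
        assert counts_of(t2)["rep1"] == 1

    def test_unknown_chromosome_is_an_error(self, mini_ann):
        with pytest.raises(CountingError, match="unknown chromosome"):
            count_reads([rec("r1", "chrX", 0, 50)], mini_ann, "chip")


def test_mixed_toy_sample_matches_brute_force(mini_ann):
    """20-read sample with ambiguous, antisense, rRNA and family reads."""
    reads = (
        [rec(f"u{i}", "chr1", 200 + 10 * i, 250 + 10 * i, "+") for i in range(8)]
        + [rec("anti", "chr1", 300, 350, "-")]
        + [rec("edge", "chr1", 1090, 1140, "+")]
        + [rec("rib", "chr1", 8100, 8150, "+")]
        + [rec("bminus", "chr1", 1600, 1650, "-")]
        + [
            multi(f"m{i}", [("chr1", 5050 + i, 5100 + i, "+"),
                            ("chr1", 6050 + i, 6100 + i, "+")])
            for i in range(6)
        ]
        + [multi("m16", [("chr1", 5050, 5100, "+")] * 16)]
        + [rec("inter", "chr1", 4500, 4550, "+")]
    )
    assert len(reads) == 20
    for assay in ("chip", "rip"):
        t = count_reads(reads, mini_ann, assay)
        exp_counts, exp_drops = brute_force_count(reads, mini_ann, assay)
        assert counts_of(t) == exp_counts
        assert t.drop_stats.iloc[0][list(exp_drops)].to_dict() == exp_drops


def test_count_conservation_and_oracle_equivalence_random(rng):
    """Engine == per-base enumeration oracle on random instances, and every
    read lands in exactly one bucket."""
    for _ in range(40):
        records, ann, assay = random_instance(rng, max_genes=20, max_reads=120,
                                              chrom_len=2000)
        t = count_reads(records, ann, assay)
        exp_counts, exp_drops = brute_force_count(records, ann, assay)
        assert counts_of(t) == exp_counts
        assert t.drop_stats.iloc[0][list(exp_drops)].to_dict() == exp_drops
        assert t.drop_stats["total"].iloc[0] == len(records)
        assert (
            t.drop_stats.iloc[0][
                ["counted", "rRNA", "no_feature", "ambiguous", "strand",
                 "multimapper"]
            ].sum()
            == len(records)
        )


class TestTPM:
    @staticmethod
    def table_from(counts: dict, ann) -> CountTable:
        df = pd.DataFrame({"s1": pd.Series(counts)})
        meta = pd.DataFrame(
            {"assay": ["rip"], "genotype": [""], "replicate": [1]},
            index=pd.Index(["s1"], name="sample_id"),
        )
        return CountTable(counts=df, meta=meta, drop_stats=pd.DataFrame(index=meta.index))

    def test_single_gene_gets_the_whole_million(self):
        ann = GenomeAnnotation(
            [GeneModel("g", "c", 0, 500, "+", "protein_coding")], {"c": 1000}
        )
        t = tpm_normalize(self.table_from({"g": 7}, ann), ann)
        assert t.tpm.loc["g", "s1"] == pytest.approx(1e6)

    def test_two_gene_closed_form(self):
        ann = GenomeAnnotation(
            [
                GeneModel("a", "c", 0, 1000, "+", "protein_coding"),
                GeneModel("b", "c", 2000, 4000, "+", "protein_coding"),
            ],
            {"c": 5000},
        )
        t = tpm_normalize(self.table_from({"a": 10, "b": 10}, ann), ann)
        assert t.tpm.loc["a", "s1"] == pytest.approx(1e6 * 10 / 15)
        assert t.tpm.loc["b", "s1"] == pytest.approx(1e6 * 5 / 15)

    def test_random_table_matches_independent_arithmetic(self, rng):
        genes = []
        pos = 0
        for i in range(50):
            length = int(rng.integers(200, 3000))
            genes.append(
                GeneModel(f"g{i}", "c", pos, pos + length, "+", "protein_coding")
            )
            pos += length + 100
        ann = GenomeAnnotation(genes, {"c": pos + 1000})
        counts = {f"g{i}": int(rng.integers(0, 500)) for i in range(50)}
        t = tpm_normalize(self.table_from(counts, ann), ann)
        expected = brute_force_tpm(counts, {g.gene_id: g.length for g in genes})
        for gid, v in expected.items():
            assert t.tpm.loc[gid, "s1"] == pytest.approx(v, rel=1e-12)
        assert t.tpm["s1"].sum() == pytest.approx(1e6, abs=1e-3)

    def test_tpm_invariant_under_count_scaling(self, rng, mini_ann):
        counts = {gid: int(rng.integers(1, 100))
                  for gid in mini_ann.counted_gene_ids()}
        t1 = tpm_normalize(self.table_from(counts, mini_ann), mini_ann)
        t2 = tpm_normalize(
            self.table_from({g: 13 * c for g, c in counts.items()}, mini_ann),
            mini_ann,
        )
        pd.testing.assert_frame_equal(t1.tpm, t2.tpm)

    def test_all_zero_sample_flagged_na(self, mini_ann):
        counts = {gid: 0 for gid in mini_ann.counted_gene_ids()}
        t = tpm_normalize(self.table_from(counts, mini_ann), mini_ann)
        assert t.tpm["s1"].isna().all()


class TestReplicateQC:
    @staticmethod
    def table_from_tpm(tpm: pd.DataFrame) -> CountTable:
        meta = pd.DataFrame(
            {"assay": "rip", "genotype": "", "replicate": range(1, tpm.shape[1] + 1)},
            index=pd.Index(tpm.columns, name="sample_id"),
        )
        return CountTable(counts=tpm, tpm=tpm, meta=meta,
                          drop_stats=pd.DataFrame(index=meta.index))

    def test_identical_replicates_fully_retained(self, rng):
        base = pd.Series(rng.gamma(2, 50, 100), index=[f"g{i}" for i in range(100)])
        tpm = pd.DataFrame({"r1": base, "r2": base})
        qc = replicate_qc(self.table_from_tpm(tpm))
        assert qc.retained == ["r1", "r2"]
        assert np.allclose(qc.correlation.to_numpy(), 1.0)
        pd.testing.assert_series_equal(qc.theta, base, check_names=False)

    def test_discordant_third_replicate_excluded(self, rng):
        base = pd.Series(rng.gamma(2, 50, 200), index=[f"g{i}" for i in range(200)])
        noisy = base * np.exp(rng.normal(0, 0.05, 200))
        shuffled = pd.Series(rng.permutation(base.to_numpy()), index=base.index)
        tpm = pd.DataFrame({"r1": base, "r2": noisy, "r3": shuffled})
        qc = replicate_qc(self.table_from_tpm(tpm))
        assert qc.excluded == ["r3"]
        assert set(qc.retained) == {"r1", "r2"}
        # theta averages only the retained replicates
        assert qc.theta.between(
            tpm[["r1", "r2"]].min(axis=1) - 1e-9,
            tpm[["r1", "r2"]].max(axis=1) + 1e-9,
        ).all()

    def test_no_concordant_pair_is_an_error_listing_matrix(self, rng):
        base = pd.Series(rng.gamma(2, 50, 200), index=[f"g{i}" for i in range(200)])
        shuffled = pd.Series(rng.permutation(base.to_numpy()), index=base.index)
        tpm = pd.DataFrame({"r1": base, "r2": shuffled})
        with pytest.raises(ReplicateQCError) as err:
            replicate_qc(self.table_from_tpm(tpm))
        assert err.value.correlation.shape == (2, 2)

    def test_threshold_is_inclusive_at_point_eight(self):
        # synthetic pair engineered to a Spearman of exactly 0.8 is retained
        n = 5
        a = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=[f"g{i}" for i in range(n)])
        # two adjacent rank swaps: rho = 1 - 6*4/(5*24) = 0.8 exactly
        b = pd.Series([2.0, 1.0, 3.0, 5.0, 4.0], index=a.index)
        from scipy.stats import spearmanr

        assert spearmanr(np.log2(a + 1), np.log2(b + 1)).statistic == pytest.approx(0.8)
        tpm = pd.DataFrame({"r1": a, "r2": b})
        qc = replicate_qc(self.table_from_tpm(tpm))
        assert qc.retained == ["r1", "r2"]


class TestIntronRetention:
    def test_relative_intronic_count_closed_form(self, mini_ann):
        # gB: span 1000 bp, intron (1900, 2100) of 200 bp, strand '-'
        reads = [rec(f"e{i}", "chr1", 1550 + 6 * i, 1590 + 6 * i, "-")
                 for i in range(30)]
        reads += [rec(f"i{i}", "chr1", 1950, 1990, "-") for i in range(20)]
        out = intron_retention(reads, mini_ann, "rip")
        row = out[out.gene_id == "gB"].iloc[0]
        assert row.gene_reads == 50 and row.intron_reads == 20
        assert row.relative_intronic_count == pytest.approx(
            (20 / 200) / (50 / 1000)
        )

    def test_zero_intron_reads_give_zero(self, mini_ann):
        reads = [rec(f"e{i}", "chr1", 1550, 1590, "-") for i in range(10)]
        out = intron_retention(reads, mini_ann, "rip")
        assert out[out.gene_id == "gB"].relative_intronic_count.iloc[0] == 0.0

    def test_unexpressed_gene_gives_na(self, mini_ann):
        out = intron_retention([], mini_ann, "rip")
        assert out[out.gene_id == "gB"].relative_intronic_count.isna().all()


def test_read_sam_infers_nh_and_groups(tmp_path, mini_ann):
    sam = tmp_path / "t.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"
        "rA\t0\tchr1\t201\t255\t50M\t*\t0\t0\t*\t*\tNH:i:1\n"
        "rB\t0\tchr1\t5101\t255\t50M\t*\t0\t0\t*\t*\n"
        "rB\t256\tchr1\t6101\t255\t50M\t*\t0\t0\t*\t*\n"
    )
    recs = list(read_sam(sam))
    assert [r.read_id for r in recs] == ["rA", "rB"]
    assert recs[0].nh == 1 and recs[1].nh == 2
    assert recs[1].locations[0] == ("chr1", 5100, 5150, "+")
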