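"""Silencing ratios, decomposition shares, SEM, region aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hetsilence as hs
from hetsilence.counting import ExpressionSummary
from hetsilence.metrics import (
    MetricsError,
    aggregate_region,
    delta_polII,
    pathway_decomposition,
    ratio_sem,
    residual_contributions,
    rna_output,
    rna_stability,
    transcription_efficiency,
)


def summary(genotype="wt", **cols) -> ExpressionSummary:
    theta = pd.DataFrame({k: pd.Series(v) for k, v in cols.items()})
    return ExpressionSummary(genotype=genotype, theta=theta)


class TestRatios:
    def test_transcription_efficiency_definition(self):
        s = summary(chip={"g": 100.0}, rip={"g": 50.0}, pa_rna={"g": 30.0})
        assert transcription_efficiency(s)["g"] == 0.5

    def test_te_na_below_floor(self):
        s = summary(chip={"g": 0.0}, rip={"g": 50.0}, pa_rna={"g": 30.0})
        assert np.isnan(transcription_efficiency(s)["g"])

    def test_stability_definition(self):
        s = summary(chip={"g": 100.0}, rip={"g": 60.0}, pa_rna={"g": 30.0})
        assert rna_stability(s)["g"] == 0.5
        s2 = summary(chip={"g": 100.0}, rip={"g": 60.0}, pa_rna={"g": 60.0})
        assert rna_stability(s2)["g"] == 1.0

    def test_delta_polII_log2(self):
        wt = summary("wt", chip={"g": 20.0}, rip={"g": 1.0}, pa_rna={"g": 1.0})
        mu = summary("mu", chip={"g": 80.0}, rip={"g": 1.0}, pa_rna={"g": 1.0})
        assert delta_polII(mu, wt)["g"] == pytest.approx(2.0)
        assert delta_polII(wt, wt)["g"] == pytest.approx(0.0)
        low = summary("lo", chip={"g": 0.5}, rip={"g": 1.0}, pa_rna={"g": 1.0})
        assert np.isnan(delta_polII(low, wt)["g"])

    def test_rna_output_telescopes_to_pa(self):
        s = summary(chip={"g": 100.0}, rip={"g": 50.0}, pa_rna={"g": 30.0})
        assert rna_output(s)["g"] == pytest.approx(30.0, rel=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        chip=st.floats(1.0, 1e6), rip=st.floats(1.0, 1e6),
        pa=st.floats(1.0, 1e6),
    )
    def test_output_identity_holds_on_arbitrary_theta(self, chip, rip, pa):
        s = summary(chip={"g": chip}, rip={"g": rip}, pa_rna={"g": pa})
        assert rna_output(s)["g"] == pytest.approx(pa, rel=1e-12)


def region_pair(fc_occ, fc_te, fc_stab):
    """wt/ref summary pair for one single-gene region with given FCs."""
    chip_w, rip_w, pa_w = 100.0, 50.0, 40.0
    chip_r = chip_w * fc_occ
    rip_r = rip_w * fc_occ * fc_te
    pa_r = pa_w * fc_occ * fc_te * fc_stab
    wt = summary("wt", chip={"m": chip_w}, rip={"m": rip_w}, pa_rna={"m": pa_w})
    ref = summary("clr4", chip={"m": chip_r}, rip={"m": rip_r}, pa_rna={"m": pa_r})
    return wt, ref


@pytest.fixture()
def one_gene_ann():
    from hetsilence.genome import GeneModel, GenomeAnnotation

    return GenomeAnnotation(
        [GeneModel("m", "c", 0, 1000, "+", "mat")], {"c": 2000}
    )


REGIONS = {"mat": {"categories": ["mat"]}}


class TestDecomposition:
    def test_symmetric_folds_share_equally(self, one_gene_ann):
        wt, ref = region_pair(4.0, 4.0, 4.0)
        dec = pathway_decomposition(wt, ref, REGIONS, one_gene_ann)
        row = dec.table.iloc[0]
        assert row[["share_occupancy", "share_efficiency", "share_stability"]] \
            .to_numpy() == pytest.approx([1 / 3] * 3)
        assert row["fc_output"] == pytest.approx(64.0)

    def test_log2_share_closed_form(self, one_gene_ann):
        wt, ref = region_pair(4.0, 2.0, 1.0)
        dec = pathway_decomposition(wt, ref, REGIONS, one_gene_ann)
        row = dec.table.iloc[0]
        assert row["share_occupancy"] == pytest.approx(2 / 3)
        assert row["share_efficiency"] == pytest.approx(1 / 3)
        assert row["share_stability"] == pytest.approx(0.0, abs=1e-12)

    def test_shares_sum_to_one_on_random_folds(self, rng, one_gene_ann):
        for _ in range(50):
            fcs = np.exp(rng.normal(0.5, 0.7, 3))
            if np.any(np.abs(np.log2(fcs)) < 1e-3):
                continue
            wt, ref = region_pair(*fcs)
            dec = pathway_decomposition(wt, ref, REGIONS, one_gene_ann)
            row = dec.table.iloc[0]
            assert (
                row[["share_occupancy", "share_efficiency", "share_stability"]].sum()
                == pytest.approx(1.0, abs=1e-9)
            )
            assert row["fc_output"] == pytest.approx(np.prod(fcs), rel=1e-9)

    def test_anti_silencing_pathway_reported_negative_and_flagged(self, one_gene_ann):
        wt, ref = region_pair(4.0, 2.0, 0.5)
        dec = pathway_decomposition(wt, ref, REGIONS, one_gene_ann)
        row = dec.table.iloc[0]
        assert row["share_stability"] < 0
        assert "anti_silencing_stability" in row["flags"]
        assert row[["share_occupancy", "share_efficiency", "share_stability"]] \
            .sum() == pytest.approx(1.0)

    def test_nonpositive_measure_warns_and_yields_na(self, one_gene_ann):
        wt = summary("wt", chip={"m": 0.0}, rip={"m": 1.0}, pa_rna={"m": 1.0})
        ref = summary("clr4", chip={"m": 4.0}, rip={"m": 4.0}, pa_rna={"m": 4.0})
        with pytest.warns(UserWarning, match="non-positive"):
            dec = pathway_decomposition(wt, ref, REGIONS, one_gene_ann)
        assert np.isnan(dec.table.iloc[0]["fc_occupancy"])


class TestResiduals:
    def test_reference_mutant_has_zero_residuals(self, one_gene_ann):
        wt, ref = region_pair(4.0, 2.0, 3.0)
        res = residual_contributions(ref, ref, REGIONS, one_gene_ann)
        assert np.allclose(res.iloc[0].to_numpy(), 0.0)

    def test_wild_type_residuals_equal_decomposition_numerators(self, one_gene_ann):
        wt, ref = region_pair(4.0, 2.0, 3.0)
        res = residual_contributions(wt, ref, REGIONS, one_gene_ann,
                                     summary_wt=wt)
        row = res.iloc[0]
        assert row["residual_occupancy"] == pytest.approx(2.0)
        assert row["residual_efficiency"] == pytest.approx(1.0)
        assert row["residual_stability"] == pytest.approx(np.log2(3.0))
        assert row["bar_height"] == pytest.approx(0.0)

    def test_caf1_style_mutant_te_restored(self, toy_ann):
        """Efficiency restored to the heterochromatin-independent level:
        TE residual ~ 0 while the occupancy residual stays at wt level."""
        ref = hs.expected_summary(hs.make_truth("clr4", toy_ann, 5), toy_ann)
        caf1 = hs.expected_summary(hs.make_truth("caf1", toy_ann, 5), toy_ann)
        wt = hs.expected_summary(hs.make_truth("wt", toy_ann, 5), toy_ann)
        regions = {"repeats": {"categories": ["dg", "dh"]}}
        res_caf1 = residual_contributions(caf1, ref, regions, toy_ann)
        res_wt = residual_contributions(wt, ref, regions, toy_ann)
        assert abs(res_caf1.iloc[0]["residual_efficiency"]) < 0.1
        assert res_caf1.iloc[0]["residual_occupancy"] == pytest.approx(
            res_wt.iloc[0]["residual_occupancy"], abs=0.1
        )


class TestRatioSEM:
    def test_worked_pairwise_example(self):
        ratios, sem = ratio_sem([2.0, 4.0], [1.0, 2.0])
        assert sorted(ratios) == [1.0, 2.0, 2.0, 4.0]
        assert sem == pytest.approx(np.std([2.0, 1.0, 4.0, 2.0], ddof=1) / 2.0)

    def test_constant_replicates_zero_sem(self):
        ratios, sem = ratio_sem([3.0, 3.0, 3.0], [1.5, 1.5])
        assert sem == 0.0

    def test_zero_denominator_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            ratios, sem = ratio_sem([2.0, 4.0], [0.0, 2.0])
        assert sorted(ratios) == [1.0, 2.0]

    def test_empty_lists_rejected(self):
        with pytest.raises(MetricsError):
            ratio_sem([], [1.0])


class TestAggregateRegion:
    def test_single_gene_region_equals_gene(self, one_gene_ann):
        s = summary(chip={"m": 10.0}, rip={"m": 5.0}, pa_rna={"m": 2.0})
        agg = aggregate_region(s, one_gene_ann, "mat")
        assert agg.loc["mat"].to_dict() == {"chip": 10.0, "rip": 5.0, "pa_rna": 2.0}

    def test_duplicating_a_gene_doubles_theta_but_not_ratios(self):
        from hetsilence.genome import GeneModel, GenomeAnnotation

        ann = GenomeAnnotation(
            [
                GeneModel("m1", "c", 0, 1000, "+", "mat"),
                GeneModel("m2", "c", 2000, 3000, "+", "mat"),
            ],
            {"c": 4000},
        )
        s = summary(chip={"m1": 10.0, "m2": 10.0},
                    rip={"m1": 5.0, "m2": 5.0},
                    pa_rna={"m1": 2.0, "m2": 2.0})
        agg = aggregate_region(s, ann, "mat")
        assert agg.loc["mat", "chip"] == 20.0
        assert agg.loc["mat", "rip"] / agg.loc["mat", "chip"] == pytest.approx(0.5)

    def test_by_strand_mode_separates_dh_strands(self, toy_ann):
        wt = hs.expected_summary(hs.make_truth("wt", toy_ann, 5), toy_ann)
        by = aggregate_region(wt, toy_ann, "dh", strand_mode="by_strand")
        assert set(by.index) == {"dh(+)", "dh(-)"}
        stab = by["pa_rna"] / by["rip"]
        assert stab["dh(+)"] / stab["dh(-)"] == pytest.approx(1.2 / 0.8, rel=0.02)
        combined = aggregate_region(wt, toy_ann, "dh", strand_mode="combined")
        assert combined.loc["dh", "chip"] == pytest.approx(by["chip"].sum())

    def test_empty_category_is_error(self, one_gene_ann):
        s = summary(chip={"m": 1.0}, rip={"m": 1.0}, pa_rna={"m": 1.0})
        with pytest.raises(MetricsError):
            aggregate_region(s, one_gene_ann, "dg")


def test_stability_monotonicity_on_expectations(toy_ann):
    """Doubling simulated stability of dg doubles the estimated region
    stability and leaves expected efficiency unchanged."""
    base = hs.make_truth("wt", toy_ann, 3)
    boosted = hs.make_truth(
        {"dg": {"s_mul": 2.0}}, toy_ann, 3, genotype="boosted"
    )
    s0 = hs.expected_summary(base, toy_ann)
    s1 = hs.expected_summary(boosted, toy_ann)
    r0 = aggregate_region(s0, toy_ann, "dg")
    r1 = aggregate_region(s1, toy_ann, "dg")
    stab0 = r0.loc["dg", "pa_rna"] / r0.loc["dg", "rip"]
    stab1 = r1.loc["dg", "pa_rna"] / r1.loc["dg", "rip"]
    # pA TPM renormalization over all genes shifts the ratio slightly below 2
    assert stab1 / stab0 == pytest.approx(2.0, rel=0.05)
    te0 = r0.loc["dg", "rip"] / r0.loc["dg", "chip"]
    te1 = r1.loc["dg", "rip"] / r1.loc["dg", "chip"]
    assert te1 == pytest.approx(te0, rel=1e-9)
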