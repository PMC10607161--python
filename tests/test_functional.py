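import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from iggseq.exceptions import ValidationError
from iggseq.functional import (
    GeneFamilyTable,
    apply_threshold_families,
    clr_transform,
    gene_family_prob_ratio,
    pca,
    prevalence_filter,
    read_gene_family_table,
    renormalise,
    zero_families_absent_in_all,
)
from iggseq.tables import FlowSummary


def _two_participant_table():
    """Two participants x three fractions, two families; fam2 absent from
    participant B's 'all' fraction."""
    cols = {
        "A_all": [10.0, 5.0],
        "A_igg_pos": [8.0, 2.0],
        "A_igg_neg": [6.0, 4.0],
        "B_all": [10.0, 0.0],
        "B_igg_pos": [8.0, 3.0],
        "B_igg_neg": [6.0, 1.0],
    }
    return GeneFamilyTable(pd.DataFrame(cols, index=["fam1", "fam2"]), unit="rpk")


def _flow(samples):
    return FlowSummary(
        pd.DataFrame(
            {
                "igg_pos_size": 0.4,
                "igg_neg_size": 0.5,
                "isotype_pct": 0.0,
                "microbial_load": 1e11,
            },
            index=samples,
        )
    )


class TestZeroFamiliesAbsentInAll:
    def test_zeroed_only_for_affected_participant(self):
        out = zero_families_absent_in_all(_two_participant_table())
        assert out.values.loc["fam2", "B_igg_pos"] == 0.0
        assert out.values.loc["fam2", "B_igg_neg"] == 0.0
        assert out.values.loc["fam2", "A_igg_pos"] == 2.0  # untouched

    def test_identity_when_present_everywhere(self):
        table = _two_participant_table()
        table.values.loc["fam2", "B_all"] = 1.0
        out = zero_families_absent_in_all(table)
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_missing_fraction_error_names_participant(self):
        table = _two_participant_table()
        broken = GeneFamilyTable(
            table.values.drop(columns=["B_igg_neg"]), unit="rpk"
        )
        with pytest.raises(ValidationError, match="'B'"):
            zero_families_absent_in_all(broken)


class TestPrevalenceFilter:
    def _table(self, n_below, n_samples=10, threshold=1e-6):
        values = {
            f"s{i}_all": [threshold / 2 if i < n_below else threshold * 10, 0.5]
            for i in range(n_samples)
        }
        return GeneFamilyTable(
            pd.DataFrame(values, index=["marginal", "common"]), unit="relab"
        )

    def test_family_below_in_eight_of_ten_discarded(self):
        out = prevalence_filter(self._table(8))
        assert list(out.values.index) == ["common"]

    def test_family_below_in_six_of_ten_retained(self):
        out = prevalence_filter(self._table(6))
        assert list(out.values.index) == ["marginal", "common"]

    def test_filter_disabled_by_large_max_below(self):
        table = self._table(10)
        out = prevalence_filter(table, max_below=11)
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_sample_permutation_does_not_change_survivors(self):
        table = self._table(8)
        permuted = GeneFamilyTable(
            table.values[list(table.values.columns)[::-1]], unit="relab"
        )
        a = prevalence_filter(table)
        b = prevalence_filter(permuted)
        assert list(a.values.index) == list(b.values.index)


class TestClr:
    def test_uniform_vector_maps_to_zero(self):
        df = pd.DataFrame({"s": [0.25, 0.25, 0.25, 0.25]})
        out = clr_transform(df, pseudocount=0)
        assert np.allclose(out["s"], 0.0)

    def test_columns_sum_to_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((20, 5)) + 0.01)
        out = clr_transform(df, pseudocount=0)
        assert np.allclose(out.sum(axis=0), 0.0, atol=1e-10)

    def test_hand_computed_example(self):
        # x ∝ (1, e^2, 1): logs are (0, 2, 0) minus mean 2/3
        z = 2.0 + math.e**2
        df = pd.DataFrame({"s": [1 / z, math.e**2 / z, 1 / z]})
        out = clr_transform(df, pseudocount=0)
        assert np.allclose(out["s"], [-2 / 3, 4 / 3, -2 / 3])

    def test_invariant_to_sample_rescaling(self):
        df = pd.DataFrame({"s": [0.1, 0.3, 0.6]})
        scaled = df * 40.0
        a = clr_transform(df, pseudocount=0)
        b = clr_transform(scaled, pseudocount=0)
        assert np.allclose(a["s"], b["s"])

    def test_zero_values_need_pseudocount(self):
        df = pd.DataFrame({"s": [0.0, 1.0]})
        with pytest.raises(ValidationError, match="pseudocount"):
            clr_transform(df, pseudocount=0)
        out = clr_transform(df)  # default: half the smallest positive value
        assert np.isfinite(out.to_numpy()).all()


class TestPca:
    def test_perfectly_correlated_variables_give_single_component(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=10)
        df = pd.DataFrame(
            [x, 2 * x], index=["f1", "f2"], columns=[f"s{i}" for i in range(10)]
        )
        out = pca(df, n_components=2)
        assert out.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(12, 8)))
        out = pca(df)
        assert (np.diff(out.explained_variance_ratio) <= 1e-12).all()

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(4, 400)))  # 4 features, 400 samples
        out = pca(df, n_components=4)
        assert np.allclose(out.explained_variance_ratio, 0.25, atol=0.1)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="variance"):
            pca(df)

    def test_excess_components_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValidationError):
            pca(df, n_components=4)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(6, 9)))
        a, b = pca(df), pca(df)
        assert np.array_equal(a.scores.to_numpy(), b.scores.to_numpy())
        # largest-magnitude loading of each component is positive
        load = a.loadings.to_numpy()
        top = load[np.abs(load).argmax(axis=0), np.arange(load.shape[1])]
        assert (top > 0).all()


class TestGeneFamilyProbRatio:
    def test_identical_fraction_behaviour_scores_zero(self):
        cols = {
            "A_all": [0.5, 0.5],
            "A_igg_pos": [0.5, 0.5],
            "A_igg_neg": [0.5, 0.5],
        }
        table = GeneFamilyTable(
            pd.DataFrame(cols, index=["f1", "f2"]), unit="relab"
        )
        flow = FlowSummary(
            pd.DataFrame(
                {
                    "igg_pos_size": [0.4],
                    "igg_neg_size": [0.4],
                    "isotype_pct": [0.0],
                    "microbial_load": [1e11],
                },
                index=["A"],
            )
        )
        out = gene_family_prob_ratio(table, flow)
        assert np.allclose(out.ratio.to_numpy(), 0.0)

    def test_bound_only_family_scores_positive_everywhere(self):
        cols = {
            "A_all": [0.6, 0.4],
            "A_igg_pos": [0.9, 0.1],
            "A_igg_neg": [0.1, 0.9],
            "B_all": [0.6, 0.4],
            "B_igg_pos": [0.8, 0.2],
            "B_igg_neg": [0.2, 0.8],
        }
        table = GeneFamilyTable(
            pd.DataFrame(cols, index=["coated", "uncoated"]), unit="relab"
        )
        out = gene_family_prob_ratio(table, _flow(["A", "B"]))
        assert (out.ratio.loc["coated"] > 0).all()
        assert (out.ratio.loc["uncoated"] < 0).all()

    def test_family_undetected_somewhere_is_dropped(self):
        cols = {
            "A_all": [0.5, 0.5],
            "A_igg_pos": [1.0, 0.0],
            "A_igg_neg": [1.0, 0.0],
            "B_all": [0.5, 0.5],
            "B_igg_pos": [0.6, 0.4],
            "B_igg_neg": [0.6, 0.4],
        }
        table = GeneFamilyTable(
            pd.DataFrame(cols, index=["kept", "patchy"]), unit="relab"
        )
        out = gene_family_prob_ratio(table, _flow(["A", "B"]))
        assert list(out.ratio.index) == ["kept"]

    def test_carrier_taxon_signal_propagates_from_simulation(self, small_bundle):
        """In a simulated cohort, gene families carried mostly by heavily
        coated taxa score higher than families carried by uncoated taxa."""
        from iggseq.pipeline import _isotype_normalised_flow

        gf = renormalise(zero_families_absent_in_all(small_bundle.gene_families))
        out = gene_family_prob_ratio(
            gf, _isotype_normalised_flow(small_bundle.flow), pseudocount=6e-10
        )
        # per-sample mean coating of each family's carriers, abundance-weighted
        truth = small_bundle.ground_truth
        sample = small_bundle.metadata.sample_ids[0]
        com = truth[sample]
        inc = com.gene_incidence.to_numpy(dtype=float)
        weights = (com.rel_abundance[:, None] * inc)
        carrier_theta = (weights * com.coating_prob[:, None]).sum(0) / weights.sum(0)
        theta_series = pd.Series(
            carrier_theta, index=com.gene_incidence.columns
        ).reindex(out.ratio.index)
        r = np.corrcoef(theta_series.to_numpy(), out.ratio[sample].to_numpy())[0, 1]
        assert r > 0.5


class TestReadGeneFamilyTable:
    def test_stratified_rows_dropped(self, tmp_path):
        text = (
            "# Gene Family\tA_all\tA_igg_pos\tA_igg_neg\n"
            "UniRef90_X\t10\t4\t6\n"
            "UniRef90_X|g__Bacteroides.s__dorei\t7\t2\t5\n"
            "UniRef90_Y\t1\t1\t0\n"
        )
        path = tmp_path / "genefamilies.tsv"
        path.write_text(text)
        table = read_gene_family_table(path)
        assert list(table.values.index) == ["UniRef90_X", "UniRef90_Y"]
        assert table.community_level

    def test_renormalise_makes_columns_sum_to_one(self):
        table = _two_participant_table()
        out = renormalise(table)
        assert out.unit == "relab"
        assert np.allclose(out.values.sum(axis=0), 1.0)

    def test_threshold_requires_relative_abundance(self):
        with pytest.raises(ValidationError):
            apply_threshold_families(_two_participant_table())
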