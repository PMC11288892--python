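import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import meltshift as ms
from meltshift import stats as mst
from meltshift.data import TemperatureGrid, dataset_from_table


class TestBHAdjust:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            ms.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert ms.bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_never_decreases_and_capped(self, rng):
        p = rng.random(50)
        adj = ms.bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        # monotone in rank
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            ms.bh_adjust([0.5, 1.5])


class TestModeratedT:
    def test_zero_prior_df_reproduces_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 6)
        prior = mst.VariancePrior(d0=0.0, s0_sq=1.0)
        t_mod, _ = ms.moderated_t(a, b, prior)
        t_ref, _ = sps.ttest_ind(a, b, equal_var=True)
        assert t_mod == pytest.approx(t_ref)

    def test_infinite_prior_uses_prior_variance_only(self, rng):
        a, b = rng.normal(0, 1, 4), rng.normal(0, 1, 4)
        prior = mst.VariancePrior(d0=np.inf, s0_sq=2.0)
        t_mod, _ = ms.moderated_t(a, b, prior)
        expected = (a.mean() - b.mean()) / np.sqrt(2.0 * (1 / 4 + 1 / 4))
        assert t_mod == pytest.approx(expected)

    def test_degenerate_equal_groups_give_p_one(self):
        prior = mst.VariancePrior(d0=0.0, s0_sq=0.0)
        t, p = ms.moderated_t([1.0, 1.0], [1.0, 1.0], prior)
        assert (t, p) == (0.0, 1.0)

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(42)
        units = [(rng.normal(0, 1, 3), rng.normal(0, 1, 3)) for _ in range(1000)]
        variances = [
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
            for a, b in units
        ]
        prior = mst.estimate_variance_prior(variances, df=4)
        pvals = [ms.moderated_t(a, b, prior)[1] for a, b in units]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


def _diff_dataset(effect_peptide_fc=1.0, n_peptides=12, seed=0):
    """Two-condition dataset at the two lowest gradient temperatures with
    one optionally spiked peptide."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_peptides):
        fc = effect_peptide_fc if i == 0 else 1.0
        for cond, mult in (("control", 1.0), ("osmolyte", fc)):
            for rep in (1, 2, 3):
                for t in (37.0, 40.5, 54.1):
                    base = 1000.0 * 2 ** rng.normal(0, 0.1)
                    rows.append({
                        "protein_id": f"P{i}", "peptide": f"pep{i}",
                        "start": 1, "end": 10, "tryptic_type": "FT",
                        "condition": cond, "replicate": rep,
                        "temperature_C": t, "intensity": base * mult,
                    })
    return dataset_from_table(pd.DataFrame(rows), grid=TemperatureGrid())


class TestDifferentialAbundance:
    def test_identical_conditions_give_no_hits(self):
        ds = _diff_dataset(effect_peptide_fc=1.0)
        out = ms.differential_abundance(ds, mode="binding")
        assert not out["hit"].any()

    def test_single_spiked_peptide_is_the_only_hit(self):
        ds = _diff_dataset(effect_peptide_fc=4.0)
        out = ms.differential_abundance(ds, mode="binding")
        assert out.loc[out["hit"], "peptide"].tolist() == ["pep0"]
        assert out.loc[out["peptide"] == "pep0", "protein_hit"].iloc[0]

    def test_exact_cutoff_is_not_a_hit(self):
        # two exact deterministic groups with |log2FC| == 1.5 exactly
        rows = []
        for i, fc in enumerate([2 ** 1.5, 1.0, 1.0, 1.0]):
            for cond, mult in (("control", 1.0), ("osmolyte", fc)):
                for rep, jitter in ((1, 1.0), (2, 1.0000001)):
                    for t in (37.0, 40.5):
                        rows.append({
                            "protein_id": f"P{i}", "peptide": f"pep{i}",
                            "start": 1, "end": 10, "tryptic_type": "FT",
                            "condition": cond, "replicate": rep,
                            "temperature_C": t, "intensity": 1000.0 * mult * jitter,
                        })
        ds = dataset_from_table(pd.DataFrame(rows), grid=TemperatureGrid())
        out = ms.differential_abundance(ds, mode="binding")
        row = out[out["peptide"] == "pep0"].iloc[0]
        assert row["log2_fc"] == pytest.approx(1.5, abs=1e-6)
        assert not row["hit"]

    def test_moderated_mode_runs(self):
        ds = _diff_dataset(effect_peptide_fc=4.0)
        out = ms.differential_abundance(ds, mode="binding", test="moderated")
        assert out.loc[out["peptide"] == "pep0", "hit"].iloc[0]


class TestNullFdrMachinery:
    def test_noise_free_null_has_zero_fdr(self):
        specs = ms.make_protein_specs(4, seed=1)
        null = ms.simulate_null_experiment(specs, ms.SimNoiseModel(sigma=0.0),
                                           seed=2)
        est, _ = ms.estimate_null_fdr(null, level="peptide", seed=0)
        assert est.fdr == 0.0
        assert est.n_tested == 32

    def test_sweep_returns_quantile_in_range(self):
        specs = ms.make_protein_specs(4, seed=1)
        null = ms.simulate_null_experiment(specs, ms.SimNoiseModel(sigma=0.05),
                                           seed=2)
        q, table = ms.sweep_quantile(null, target=1.0, seed=0)
        assert q == 0.5  # any pair meets a target of 1.0
        assert ((table["q"] >= 0.5) & (table["q"] <= 1.0)).all()


class TestTpp:
    def test_identical_conditions_score_zero_and_preserve_normalization(self):
        specs = ms.make_protein_specs(4, seed=3)
        tpp = ms.simulate_tpp_experiment(specs, ms.SimNoiseModel(sigma=0.0),
                                         seed=4)
        out = ms.tpp_analysis(tpp, seed=0)
        assert (out["score"] == 0.0).all()

    def test_shifted_midpoint_scores_positive(self):
        specs = [ms.SimProteinSpec(f"P{i}", archetype="unfolder",
                                   Tm_control=52.0 + i, delta_Tm=4.0)
                 for i in range(4)]
        tpp = ms.simulate_tpp_experiment(specs, ms.SimNoiseModel(sigma=0.02),
                                         seed=5)
        out = ms.tpp_analysis(tpp, seed=0)
        assert (out["score"] > 0).all()

    @pytest.mark.parametrize("value,expected", [(0.6, False), (0.5, True),
                                                (0.1, True)])
    def test_precipitator_rule(self, value, expected):
        grid = TemperatureGrid()
        rows = [
            {"protein_id": "P1", "condition": "control", "replicate": 1,
             "temperature_C": t,
             "rel_abundance": 1.0 if t == 37.0 else value}
            for t in grid
        ]
        ds = ms.ProteinSolubilityDataset(table=pd.DataFrame(rows), grid=grid)
        assert ms.classify_precipitator(ds, "P1") is expected


class TestLipTppAgreement:
    def test_identical_call_sets(self):
        calls = {"P1": True, "P2": False, "P3": True}
        out = ms.lip_tpp_agreement(calls, dict(calls))
        assert out["both"] + out["none"] == pytest.approx(1.0)
        assert out["only_lip"] == out["only_tpp"] == 0.0

    def test_disjoint_call_sets(self):
        lip = {"P1": True, "P2": False}
        tpp = {"P1": False, "P2": True}
        out = ms.lip_tpp_agreement(lip, tpp)
        assert out["both"] == 0.0

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            ms.lip_tpp_agreement({"P1": True}, {"P2": True})

    def test_restriction_to_precipitators(self):
        lip = {"P1": True, "P2": True}
        tpp = {"P1": True, "P2": True}
        out = ms.lip_tpp_agreement(lip, tpp, precipitators={"P1"})
        assert out["n"] == 1


class TestSpearmanRandomization:
    def _matrix(self, rng):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        X = np.vstack([base * k + rng.normal(0, 0.01, 5) for k in (1, 2, 3)])
        return pd.DataFrame(X, index=["P1", "P2", "P3"],
                            columns=list("abcde"))

    def test_proportional_vector_has_r_one(self, rng):
        obs, _ = ms.spearman_randomization(self._matrix(rng), n_rep=10, seed=0)
        assert obs["P1"] == pytest.approx(1.0)

    def test_constant_vector_excluded(self, rng):
        m = self._matrix(rng)
        m.loc["P3"] = 2.0
        obs, _ = ms.spearman_randomization(m, n_rep=10, seed=0)
        assert np.isnan(obs["P3"])

    def test_null_distribution_centred_near_zero(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 6)))
        _, null = ms.spearman_randomization(X, n_rep=200, seed=0)
        assert abs(np.nanmean(null)) < 0.05

    def test_needs_three_conditions(self):
        with pytest.raises(ValueError):
            ms.spearman_randomization(pd.DataFrame(np.ones((3, 2))), seed=0)


class TestSequenceFeatures:
    def test_polylysine_is_basic(self):
        f = ms.sequence_features("KKKK")
        assert f["charge_ph7.5"] > 0
        assert f["pct_K"] == 100.0
        assert f["pI"] > 9

    def test_polyaspartate_is_acidic(self):
        assert ms.sequence_features("DDDD")["pI"] < 7

    def test_gravy_matches_kyte_doolittle_mean(self):
        f = ms.sequence_features("AILV")
        assert f["gravy"] == pytest.approx((1.8 + 4.5 + 3.8 + 4.2) / 4)

    def test_aliphatic_index_formula(self):
        f = ms.sequence_features("AVIL")
        assert f["aliphatic_index"] == pytest.approx(
            25 + 2.9 * 25 + 3.9 * (25 + 25)
        )

    def test_nonstandard_residues_warn_and_are_excluded(self):
        with pytest.warns(UserWarning):
            f = ms.sequence_features("KKXK")
        assert f["length"] == 3


class TestCompareFeatureGroups:
    def _features(self, rng, shift=0.0):
        a = pd.DataFrame({
            "f1": rng.normal(0, 1, 10), "f2": rng.normal(0, 1, 10),
        })
        b = pd.DataFrame({
            "f1": rng.normal(shift, 1, 10), "f2": rng.normal(0, 1, 10),
        })
        X = pd.concat([a, b], ignore_index=True)
        labels = ["control"] * 10 + ["test"] * 10
        return X, labels

    def test_identical_groups_nothing_significant(self, rng):
        X, labels = self._features(rng, shift=0.0)
        out = mst.compare_feature_groups(X, labels, control_label="control")
        assert not out["significant"].any()

    def test_shifted_feature_detected_with_sign(self, rng):
        X, labels = self._features(rng, shift=3.0)
        out = mst.compare_feature_groups(X, labels, control_label="control")
        row = out[out["feature"] == "f1"].iloc[0]
        assert row["significant"] and row["delta_mean"] > 0

    def test_swapping_labels_negates_deltas(self, rng):
        X, labels = self._features(rng, shift=2.0)
        a = mst.compare_feature_groups(X, labels, control_label="control")
        b = mst.compare_feature_groups(X, labels, control_label="test")
        np.testing.assert_allclose(a["delta_mean"], -b["delta_mean"])
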