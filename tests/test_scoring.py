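import numpy as np
import pandas as pd
import pytest

from meltshift import scoring as sc
from meltshift.data import DomainAnnotation
from meltshift.gp import ProfileCurve, scoring_grid
from meltshift.simulate import folded_fraction


def curve(mean, sd=1e-4, grid=None):
    grid = scoring_grid() if grid is None else grid
    mean = np.asarray(mean, float)
    sd = np.full_like(mean, sd) if np.isscalar(sd) else np.asarray(sd)
    return ProfileCurve(grid=grid, mean=mean, sd=sd)


def sigmoid_curve(shift=0.0, sd=1e-4, grid=None):
    grid = scoring_grid() if grid is None else grid
    return curve(folded_fraction(grid - shift, 55.0), sd, grid)


class TestNonOverlapIntervals:
    def test_identical_curves_give_empty_list(self):
        a = sigmoid_curve()
        assert sc.nonoverlap_intervals(a, sigmoid_curve()) == []

    def test_constant_separation_gives_full_grid_interval(self):
        g = scoring_grid()
        a = curve(np.full(g.size, 0.2), sd=0.05)
        b = curve(np.full(g.size, 0.7), sd=0.05)
        ivs = sc.nonoverlap_intervals(a, b)
        assert len(ivs) == 1
        iv = ivs[0]
        assert (iv.t_start, iv.t_end) == (37.0, 76.0)
        # Riemann-sum area ~ 0.5 x gradient span
        assert iv.area == pytest.approx(0.5 * (76 - 37), rel=0.02)

    def test_wide_bands_suppress_everything(self):
        a = sigmoid_curve(0.0, sd=0.5)
        b = sigmoid_curve(4.0, sd=0.5)
        assert sc.nonoverlap_intervals(a, b) == []

    def test_mismatched_grids_rejected(self):
        a = sigmoid_curve()
        b = sigmoid_curve(grid=scoring_grid(step=1.0))
        with pytest.raises(ValueError):
            sc.nonoverlap_intervals(a, b)


class TestClassifyInterval:
    @pytest.mark.parametrize("t0,t1,expected", [
        (37.0, 40.5, "binding"),
        (72.5, 76.0, "aggregation"),
        (50.0, 60.0, "stabilization"),
    ])
    def test_midpoint_rule(self, t0, t1, expected):
        assert sc.classify_interval(t0, t1) == expected


class TestPeptideScore:
    def test_right_shift_scores_the_shift(self):
        ctl, osm = sigmoid_curve(0.0), sigmoid_curve(4.0)
        ps = sc.peptide_score("p", ctl, osm, "decreasing", 0.01, 0.01)
        assert ps.score == pytest.approx(4.0, rel=0.05)

    def test_increasing_profile_sign_corrected(self):
        g = scoring_grid()
        ctl = curve(1 - folded_fraction(g, 55.0))
        osm = curve(1 - folded_fraction(g - 4.0, 55.0))
        ps = sc.peptide_score("p", ctl, osm, "increasing", 0.01, 0.01)
        assert ps.score == pytest.approx(4.0, rel=0.05)

    def test_left_shift_scores_negative(self):
        ctl, osm = sigmoid_curve(0.0), sigmoid_curve(-4.0)
        ps = sc.peptide_score("p", ctl, osm, "decreasing", 0.01, 0.01)
        assert ps.score == pytest.approx(-4.0, rel=0.05)

    def test_swap_of_conditions_negates_score(self):
        ctl, osm = sigmoid_curve(0.0), sigmoid_curve(3.0)
        fwd = sc.peptide_score("p", ctl, osm, "decreasing", 0.01, 0.02)
        rev = sc.peptide_score("p", osm, ctl, "decreasing", 0.02, 0.01)
        assert fwd.score == pytest.approx(-rev.score)
        assert fwd.fit_weight == rev.fit_weight

    def test_no_stabilization_interval_scores_zero(self):
        ctl = sigmoid_curve(0.0, sd=0.5)
        ps = sc.peptide_score("p", ctl, sigmoid_curve(4.0, sd=0.5),
                              "decreasing", 0.01, 0.01)
        assert ps.score == 0.0 and ps.interval is None

    def test_grid_refinement_changes_score_below_two_percent(self):
        coarse = scoring_grid(step=0.5)
        fine = scoring_grid(step=0.25)
        s = {}
        for name, g in (("coarse", coarse), ("fine", fine)):
            ctl = curve(folded_fraction(g, 55.0), 1e-4, g)
            osm = curve(folded_fraction(g - 3.0, 55.0), 1e-4, g)
            s[name] = sc.peptide_score("p", ctl, osm, "decreasing", 0.01, 0.01).score
        assert abs(s["fine"] - s["coarse"]) / abs(s["coarse"]) < 0.02


class TestFitWeight:
    def test_rss_mode_weights_by_summed_rss(self):
        assert sc.fit_weight(0.02, 0.03) == pytest.approx(1e-3 + 0.05)

    def test_inverse_mode(self):
        assert sc.fit_weight(0.02, 0.03, mode="inverse_rss") == pytest.approx(
            1 / (1e-3 + 0.05)
        )


class TestWeightedQuantile:
    def test_all_equal_values(self):
        for q in (0.0, 0.25, 0.75, 1.0):
            assert sc.weighted_quantile([3.0, 3.0, 3.0], [1, 2, 5], q) == 3.0

    def test_equal_weight_example_matches_expansion(self):
        v = [1.0, 2.0, 3.0, 4.0]
        w = [1.0] * 4
        for method in ("inverse_cdf", "interpolated"):
            direct = sc.weighted_quantile(v, w, 0.75, method)
            expanded = sc.weighted_quantile(v, w, 0.75, method)  # already unit
            assert direct == expanded

    def test_doubling_weights_changes_nothing(self, rng):
        v = rng.normal(size=9)
        w = rng.uniform(0.1, 2.0, 9)
        for method in ("inverse_cdf", "interpolated"):
            a = sc.weighted_quantile(v, w, 0.3, method)
            b = sc.weighted_quantile(v, 2 * w, 0.3, method)
            assert a == b

    def test_repetition_expansion_invariance(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 8))
            v = rng.normal(size=n)
            w = rng.integers(1, 6, size=n).astype(float)
            q = float(rng.random())
            expanded = np.repeat(v, w.astype(int))
            for method in ("inverse_cdf", "interpolated"):
                a = sc.weighted_quantile(v, w, q, method)
                b = sc.weighted_quantile(expanded, np.ones(expanded.size), q,
                                         method)
                assert a == pytest.approx(b, abs=1e-12)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            sc.weighted_quantile([1.0, 2.0], [1.0, 0.0], 0.5)


def _ps(pid, score, weight=1.0):
    return sc.PeptideScore(pid, score, None, weight, "decreasing")


class TestResidueScores:
    def test_single_covering_peptide_passes_through(self):
        coords = {"a": ("P", 5, 8)}
        out = sc.residue_scores([_ps("a", 2.5)], coords)
        assert {r.position for r in out} == {5, 6, 7, 8}
        assert all(r.score == 2.5 for r in out)

    def test_positive_positions_use_upper_quantile(self):
        coords = {"a": ("P", 1, 3), "b": ("P", 1, 3), "c": ("P", 1, 3)}
        out = sc.residue_scores(
            [_ps("a", 1.0), _ps("b", 2.0), _ps("c", 3.0)], coords
        )
        expected = sc.weighted_quantile([1.0, 2.0, 3.0], [1.0] * 3, 0.75)
        assert all(r.score == expected for r in out)

    def test_negative_positions_use_lower_quantile(self):
        coords = {"a": ("P", 1, 2), "b": ("P", 1, 2)}
        out = sc.residue_scores([_ps("a", -1.0), _ps("b", -2.0)], coords)
        expected = sc.weighted_quantile([-1.0, -2.0], [1.0, 1.0], 0.25)
        assert all(r.score == expected for r in out)


class TestProteinScore:
    def test_all_zero_residues_give_none_direction(self):
        residues = [sc.ResidueScore("P", i, 0.0, 1.0) for i in range(1, 6)]
        prot = sc.protein_score(residues)
        assert prot.score == 0.0 and prot.direction == "none"

    def test_constant_positive_residues(self):
        residues = [sc.ResidueScore("P", i, 1.5, 1.0) for i in range(1, 6)]
        prot = sc.protein_score(residues)
        assert prot.score == 1.5 and prot.direction == "stabilized"

    def test_matches_two_stage_brute_force(self, rng):
        # independent rollup oracle: recompute residue and protein scores from
        # the raw peptide table with plain loops and the quantile definition
        for _ in range(20):
            n = int(rng.integers(3, 9))
            peptides = []
            coords = {}
            for i in range(n):
                start = int(rng.integers(1, 40))
                end = start + int(rng.integers(5, 20))
                score = float(rng.choice([0.0, rng.normal()], p=[0.5, 0.5]))
                w = float(rng.uniform(0.5, 3.0))
                pid = f"p{i}"
                peptides.append(_ps(pid, score, w))
                coords[pid] = ("P", start, end)
            residues = sc.residue_scores(peptides, coords)
            prot = sc.protein_score(residues)

            # brute force
            cover = {}
            for p in peptides:
                _, s, e = coords[p.peptide_id]
                for pos in range(s, e + 1):
                    cover.setdefault(pos, []).append(p)
            res_expected = {}
            wt_expected = {}
            for pos, plist in cover.items():
                vals = [p.score for p in plist]
                ws = [p.fit_weight for p in plist]
                mean = float(np.mean(vals))
                if mean > 0:
                    r = sc.weighted_quantile(vals, ws, 0.75)
                elif mean < 0:
                    r = sc.weighted_quantile(vals, ws, 0.25)
                else:
                    r = 0.0
                res_expected[pos] = r
                wt_expected[pos] = float(np.mean(ws))
            assert {r.position: r.score for r in residues} == res_expected
            rvals = list(res_expected.values())
            rws = [wt_expected[p] for p in res_expected]
            mean = float(np.mean(rvals))
            if mean > 0:
                expected = sc.weighted_quantile(rvals, rws, 0.75)
            elif mean < 0:
                expected = sc.weighted_quantile(rvals, rws, 0.25)
            else:
                expected = 0.0
            assert prot.score == expected


class TestBinderScaling:
    def test_median_peptide_maps_to_zero(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        scaled = sc.scaled_binder_score(s)
        assert scaled[2] == 0.0

    def test_formula_on_known_quantiles(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        scaled = sc.scaled_binder_score(s)
        denom = np.quantile(s, 0.7) - np.quantile(s, 0.25)
        assert scaled[-1] == pytest.approx((5.0 - 3.0) / denom)

    def test_translation_moves_only_the_centering(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        np.testing.assert_allclose(
            sc.scaled_binder_score(s + 10.0), sc.scaled_binder_score(s)
        )

    def test_needs_at_least_four_scores(self):
        with pytest.raises(ValueError):
            sc.scaled_binder_score(np.array([1.0, 2.0, 3.0]))

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ZeroDivisionError):
            sc.scaled_binder_score(np.array([2.0, 2.0, 2.0, 2.0]))


class TestDomainDifferential:
    def _coords(self, scores_by_domain):
        peptides, coords = [], {}
        i = 0
        for (start, end), scores in scores_by_domain.items():
            for s in scores:
                pid = f"p{i}"
                peptides.append(_ps(pid, s))
                coords[pid] = ("P", start, end)
                i += 1
        return peptides, coords

    def test_single_shared_residue_counts_as_member(self, rng):
        peptides, coords = self._coords({
            (10, 20): [5.0, 5.1, 4.9],    # overlaps domain 20-80 by residue 20
            (30, 40): [0.0, 0.1, -0.1],
        })
        domains = [DomainAnnotation("P", "d1", 20, 80),
                   DomainAnnotation("P", "d2", 81, 120)]
        # only d1 has members; protein fails the >=2 domain rule -> excluded
        out = sc.domain_differential(peptides, coords, domains)
        assert len(out) == 0

    def test_identical_domains_not_significant(self, rng):
        peptides, coords = self._coords({
            (1, 10): list(rng.normal(0, 1, 5)),
            (20, 30): list(rng.normal(0, 1, 5)),
        })
        domains = [DomainAnnotation("P", "d1", 1, 15),
                   DomainAnnotation("P", "d2", 16, 40)]
        out = sc.domain_differential(peptides, coords, domains)
        assert len(out) == 1
        assert not out["significant"].iloc[0]

    def test_separated_domains_significant(self, rng):
        peptides, coords = self._coords({
            (1, 10): list(rng.normal(5, 0.1, 5)),
            (20, 30): list(rng.normal(0, 0.1, 5)),
        })
        domains = [DomainAnnotation("P", "d1", 1, 15),
                   DomainAnnotation("P", "d2", 16, 40)]
        out = sc.domain_differential(peptides, coords, domains)
        assert out["significant"].iloc[0]

    def test_three_domains_use_anova(self, rng):
        peptides, coords = self._coords({
            (1, 10): list(rng.normal(5, 0.1, 4)),
            (20, 30): list(rng.normal(0, 0.1, 4)),
            (40, 50): list(rng.normal(0, 0.1, 4)),
        })
        domains = [DomainAnnotation("P", "d1", 1, 15),
                   DomainAnnotation("P", "d2", 16, 35),
                   DomainAnnotation("P", "d3", 36, 60)]
        out = sc.domain_differential(peptides, coords, domains)
        assert out["n_domains"].iloc[0] == 3
        assert out["significant"].iloc[0]
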