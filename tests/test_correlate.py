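"""Correlation primitives, count/distance correlations, and the gene screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heteroscope import heterosis
from heteroscope.correlate import (CorrelationError, bh_adjust, classify_correlated_genes,
                                   correlation_screen, deg_count_correlation,
                                   distance_correlation, filter_pathway_records,
                                   gene_correlation_screen, parental_expression_values,
                                   pearson_test, round_half_away, significance_stars)
from heteroscope.design import complete_design
from heteroscope.distance import pairwise_distances
from oracles import bh_stepup, pearson_closed_form


class TestPearson:
    @pytest.mark.parametrize("x,y,expected_r", [
        ((1, 2, 3), (1, 2, 3), 1.0),
        ((1, 2, 3), (3, 2, 1), -1.0),
        ((1, 2, 3), (2, 1, 3), 0.5),
    ])
    def test_hand_computed_examples(self, x, y, expected_r):
        r, p = pearson_test(x, y)
        assert r == pytest.approx(expected_r)

    @given(data=st.data(), n=st.integers(3, 25))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_closed_form(self, data, n):
        vals = st.floats(-100, 100)
        x = data.draw(st.lists(vals, min_size=n, max_size=n))
        y = data.draw(st.lists(vals, min_size=n, max_size=n))
        if np.std(x) == 0 or np.std(y) == 0:
            return
        r, p = pearson_test(x, y)
        r0, p0 = pearson_closed_form(x, y)
        assert r == pytest.approx(r0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(CorrelationError, match="variance"):
            pearson_test([1, 1, 1], [1, 2, 3])

    def test_short_series_rejected(self):
        with pytest.raises(CorrelationError):
            pearson_test([1, 2], [3, 4])


class TestBenjaminiHochberg:
    def test_stepup_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.5]),
                                   [0.04, 0.04, 0.04, 0.5])

    def test_single_and_tied_values(self):
        assert bh_adjust([0.07])[0] == pytest.approx(0.07)
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(CorrelationError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_oracle_for_all_short_permutations(self):
        base_sets = [(0.001, 0.01, 0.04, 0.2, 0.5, 0.9),
                     (0.05, 0.05, 0.1, 0.3), (0.5, 0.02, 0.9),
                     (1.0, 0.0, 0.25, 0.25, 0.8)]
        for base in base_sets:
            for m in range(1, len(base) + 1):
                for perm in itertools.permutations(base[:m]):
                    np.testing.assert_allclose(bh_adjust(list(perm)), bh_stepup(perm),
                                               atol=1e-12)

    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=6))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_stepup_oracle_random(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_stepup(p), atol=1e-12)


def test_significance_stars_thresholds():
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.05) == ""


def test_round_half_away_from_zero():
    assert round_half_away(0.425) == 0.43
    assert round_half_away(-0.425) == -0.43
    assert round_half_away(0.7465) == 0.75


class TestCountAndDistanceCorrelations:
    def setup_method(self):
        self.design = complete_design(["A", "B", "C"],
                                      missing=[("B", "A"), ("C", "A"), ("C", "B")])
        # hybrids AB, AC, BC

    def responses(self, values):
        return pd.DataFrame({"MPH": values}, index=["AB", "AC", "BC"])

    def test_perfect_linear_relation(self):
        counts = pd.DataFrame({"female": ["A", "A", "B"], "male": ["B", "C", "C"],
                               "UP": [2, 1, 3], "DOWN": [3, 0, 3], "ALL": [5, 1, 3]})
        out = deg_count_correlation(self.design, counts, self.responses([10, 2, 6]), "PGW")
        all_row = out[out.predictor == "ALL"].iloc[0]
        assert all_row.r == pytest.approx(1.0)   # responses = 2 × ALL counts
        assert all_row.n == 3

    def test_constant_response_flagged(self):
        counts = pd.DataFrame({"female": ["A", "A", "B"], "male": ["B", "C", "C"],
                               "UP": [1, 2, 3], "DOWN": [1, 2, 3], "ALL": [2, 4, 6]})
        out = deg_count_correlation(self.design, counts, self.responses([5, 5, 5]), "PGW")
        assert out["flag"].str.contains("variance").all()
        assert out["r"].isna().all()

    def test_hybrid_without_pair_dropped(self, caplog):
        counts = pd.DataFrame({"female": ["A", "A"], "male": ["B", "C"],
                               "UP": [1, 2], "DOWN": [0, 0], "ALL": [1, 2]})
        with caplog.at_level("WARNING"):
            out = deg_count_correlation(self.design, counts,
                                        self.responses([1.0, 2.0, 3.0]), "PGW")
        assert "BC" in caplog.text

    def test_reciprocal_hybrids_share_distance_predictor(self, tiny_dataset,
                                                         tiny_profiles, tiny_heterosis):
        distances = pairwise_distances(tiny_profiles)
        responses = heterosis.heterosis_responses(tiny_heterosis, "PGW")
        out = distance_correlation(distances, tiny_dataset.design, responses, "PGW")
        assert set(out["predictor"]) == {"euclidean", "binary"}
        assert (out["n"] == 53).all()

    def test_planted_distance_effect_recovered(self, tiny_dataset, tiny_profiles,
                                               tiny_heterosis):
        """Non-target traits carry a planted Euclidean-distance coefficient."""
        distances = pairwise_distances(tiny_profiles)
        rs = []
        for trait in ("LOL", "LHH", "HW", "PH"):
            responses = heterosis.heterosis_responses(tiny_heterosis, trait)
            out = distance_correlation(distances, tiny_dataset.design, responses, trait)
            rs.append(out[(out.predictor == "euclidean")
                          & (out.response == "MPH")].iloc[0].r)
        assert np.mean(rs) > 0.15


class TestParentalExpressionValues:
    def test_max_mean_min(self):
        profiles = pd.DataFrame({"A": [4.0, 6.0, 0.0], "B": [10.0, 6.0, 8.0]},
                                index=["g1", "g2", "g3"])
        out = parental_expression_values(profiles, "A", "B")
        np.testing.assert_allclose(out.loc["g1"], [10, 7, 4])
        np.testing.assert_allclose(out.loc["g2"], [6, 6, 6])
        np.testing.assert_allclose(out.loc["g3"], [8, 4, 0])

    def test_missing_parent_rejected(self):
        profiles = pd.DataFrame({"A": [1.0]}, index=["g1"])
        with pytest.raises(CorrelationError, match="parent"):
            parental_expression_values(profiles, "A", "X")


class TestScreen:
    def test_perfectly_tracking_gene_leads_its_family(self):
        design = complete_design("ABCD")
        rng = np.random.default_rng(5)
        profiles = pd.DataFrame(rng.uniform(1, 9, (6, 4)),
                                index=[f"g{i}" for i in range(6)], columns=list("ABCD"))
        pair_of = {c.hybrid: c.ordered_pair for c in design.crosses}
        hybrids = list(design.hybrids)
        mpv0 = [(profiles.loc["g0", pair_of[h][0]] + profiles.loc["g0", pair_of[h][1]]) / 2
                for h in hybrids]
        responses = pd.DataFrame({"observed": mpv0, "MPH": mpv0}, index=hybrids)
        screen = gene_correlation_screen(profiles, design, responses, alpha_fdr=0.05)
        family = screen[(screen.basis == "MPV") & (screen.response == "MPH")]
        top = family.sort_values("q").iloc[0]
        assert top.gene == "g0"
        assert top.r == pytest.approx(1.0)
        assert top.q == family["q"].min()

    def test_constant_gene_excluded_from_bh_universe(self):
        design = complete_design("ABC")
        profiles = pd.DataFrame({"A": [5.0, 1.0], "B": [5.0, 2.0], "C": [5.0, 4.0]},
                                index=["flat", "varies"])
        responses = pd.DataFrame({"observed": [1, 2, 3, 4, 5, 6.0],
                                  "MPH": [2, 1, 4, 3, 6, 5.0]}, index=design.hybrids)
        screen = gene_correlation_screen(profiles, design, responses)
        flat = screen[screen.gene == "flat"]
        assert flat["r"].isna().all() and flat["q"].isna().all()
        assert screen.attrs["n_constant"] == 6

    def test_q_never_below_p(self, tiny_dataset, tiny_profiles, tiny_heterosis):
        responses = heterosis.heterosis_responses(tiny_heterosis, "PGW")
        screen = gene_correlation_screen(tiny_profiles, tiny_dataset.design, responses)
        ok = screen.dropna(subset=["q"])
        assert (ok["q"] >= ok["p"] - 1e-12).all()


class TestClassify:
    @staticmethod
    def records(rows):
        df = pd.DataFrame(rows, columns=["gene", "basis", "response", "r", "q",
                                         "significant"])
        df["n"] = 10
        df["p"] = df["q"]
        return df

    def test_one_sided_gene_not_in_both(self):
        rec = self.records([("g1", "MPV", "observed", 0.9, 0.001, True),
                            ("g1", "MPV", "MPH", 0.1, 0.9, False)])
        sets = classify_correlated_genes(rec)
        assert sets["both"] == set()
        assert sets["observed_significant"] == {"g1"}

    def test_consistent_positive_gene(self):
        rec = self.records([("g1", "MPV", "observed", 0.8, 0.001, True),
                            ("g1", "HPV", "MPH", 0.7, 0.002, True)])
        sets = classify_correlated_genes(rec)
        assert sets["both_positive"] == {"g1"}
        assert sets["conflicting"] == set()

    def test_sign_conflict_reported_separately(self):
        rec = self.records([("g1", "MPV", "observed", 0.8, 0.001, True),
                            ("g1", "MPV", "MPH", -0.7, 0.002, True)])
        sets = classify_correlated_genes(rec)
        assert sets["both"] == {"g1"}
        assert sets["conflicting"] == {"g1"}
        assert sets["both_positive"] == sets["both_negative"] == set()

    def test_planted_truth_recovered_up_to_fdr(self, tiny_dataset, tiny_profiles,
                                               tiny_heterosis):
        """MPH-significant discoveries are dominated by planted genes with the
        planted signs; the diallel's parent-sharing bounds attainable purity."""
        responses = heterosis.heterosis_responses(tiny_heterosis, "PGW")
        screen = gene_correlation_screen(tiny_profiles, tiny_dataset.design, responses,
                                         alpha_fdr=0.01)
        truth = tiny_dataset.truth.planted
        pos = set(truth[truth.sign > 0].gene)
        neg = set(truth[truth.sign < 0].gene)
        mph_family = screen[(screen.response == "MPH") & (screen.basis == "MPV")
                            & screen.significant]
        hits = set(mph_family.gene)
        assert len(hits & (pos | neg)) >= 0.6 * len(pos | neg)
        sets = classify_correlated_genes(screen)
        assert not (sets["both_positive"] & neg)
        assert not (sets["both_negative"] & pos)


class TestPathwayFilter:
    def test_reference_ribosome_records(self):
        from heteroscope.fixtures import load_ribosome_records
        table = load_ribosome_records()
        rows, extrema = filter_pathway_records(table, table["gene"], q_max=0.05)
        assert len(rows) == 17
        assert extrema["max_r_observed"] == pytest.approx(0.43)
        assert extrema["max_r_mph"] == pytest.approx(0.75)

    def test_reference_terpenoid_records(self):
        from heteroscope.fixtures import load_terpenoid_records
        table = load_terpenoid_records()
        rows, extrema = filter_pathway_records(table, table["gene"], q_max=0.05)
        assert len(rows) == 8
        assert extrema["min_r_observed"] == pytest.approx(-0.42)

    def test_q_filter_excludes_rows(self):
        from heteroscope.fixtures import load_ribosome_records
        table = load_ribosome_records()
        rows, _ = filter_pathway_records(table, table["gene"], q_max=0.01)
        assert len(rows) == (table[["q_observed", "q_mph"]].max(axis=1) <= 0.01).sum()

    def test_empty_subset_gives_no_rows(self):
        from heteroscope.fixtures import load_ribosome_records
        rows, extrema = filter_pathway_records(load_ribosome_records(), [], q_max=0.05)
        assert len(rows) == 0 and extrema == {}


def test_correlation_screen_family_fdr_calibration():
    """Exchangeable global null: discovery fraction per family stays at or
    below the nominal q over seeded repetitions."""
    from heteroscope.simulate import simulate_planted_series
    fractions = []
    for seed in range(30):
        X, Y, _ = simulate_planted_series(1000, 0, 0.0, 53, seed=seed + 100)
        screen = correlation_screen(X, Y, alpha_fdr=0.01)
        fractions.append(screen["significant"].mean())
    assert np.mean(fractions) <= 0.01
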