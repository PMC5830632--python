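import numpy as np
import pandas as pd
import pytest

from batjsdm.model import PosteriorSamples
from batjsdm.prediction import (PredictionSet, build_prediction_grid,
                                change_summary, design_row,
                                expected_individuals, expected_richness,
                                predict_expected_count, predict_occurrence,
                                predict_set)


def make_samples(B1, B2, Lambda1=None, Lambda2=None, sigma2=None,
                 species=("s1",)):
    """Hand-built posterior archive (d draws, p=9, S species)."""
    d, p, S = B1.shape
    z = np.zeros((d, S, 2))
    draws = {
        "B1": B1, "B2": B2,
        "Gamma1": np.zeros((d, p, 2)), "Gamma2": np.zeros((d, p, 2)),
        "V1": np.tile(np.eye(p), (d, 1, 1)), "V2": np.tile(np.eye(p), (d, 1, 1)),
        "rho1": np.zeros(d), "rho2": np.zeros(d),
        "Lambda1": Lambda1 if Lambda1 is not None else z.copy(),
        "Lambda2": Lambda2 if Lambda2 is not None else z.copy(),
        "Eta1": np.zeros((d, 1, 2)), "Eta2": np.zeros((d, 1, 2)),
        "sigma2": sigma2 if sigma2 is not None else np.zeros((d, S)),
    }
    from batjsdm.core_data import DESIGN_COLUMNS
    return PosteriorSamples(draws=draws, species_ids=list(species),
                            site_ids=["x"],
                            design_columns=list(DESIGN_COLUMNS),
                            seed=0, spec_hash="test", spec={})


ROW0 = {"habitat": "continuous", "period": 1, "sec_cover": 0.0,
        "log_effort": 0.0}


class TestGrid:
    def test_effort_pooled_across_periods(self, toy_covariates):
        sessions = pd.DataFrame({
            "session_id": ["a", "b", "c", "d", "e", "f"],
            "site_id": ["CF01", "CF01", "FR01", "FR01", "SF01", "SF01"],
            "period": [1, 2, 1, 2, 1, 2],
            "effort_mnh": [10.0, 30.0, 10.0, 10.0, 5.0, 5.0]})
        grid = build_prediction_grid(toy_covariates, sessions)
        row = grid.row("continuous", 1)
        assert row["log_effort"] == pytest.approx(np.log(20.0))
        assert len(grid.table) == 6

    def test_single_site_habitat_cover(self, toy_covariates):
        sessions = pd.DataFrame({
            "session_id": list("abcdef"),
            "site_id": ["CF01", "CF01", "FR01", "FR01", "SF01", "SF01"],
            "period": [1, 2, 1, 2, 1, 2],
            "effort_mnh": [10.0] * 6})
        grid = build_prediction_grid(toy_covariates, sessions)
        assert grid.row("secondary", 2)["sec_cover"] == pytest.approx(0.85)

    def test_empty_cell_rejected(self, toy_covariates):
        sessions = pd.DataFrame({
            "session_id": ["a"], "site_id": ["CF01"], "period": [1],
            "effort_mnh": [10.0]})
        with pytest.raises(ValueError):
            build_prediction_grid(toy_covariates, sessions)


class TestOccurrence:
    def test_zero_coefficients_give_half(self):
        s = make_samples(np.zeros((3, 9, 1)), np.zeros((3, 9, 1)))
        occ = predict_occurrence(s, ROW0)
        assert np.allclose(occ, 0.5)

    def test_standard_normal_quantile(self):
        B1 = np.zeros((1, 9, 1))
        B1[0, 0, 0] = 1.2816  # x'b = 90th percentile
        s = make_samples(B1, np.zeros((1, 9, 1)))
        assert predict_occurrence(s, ROW0)[0, 0] == pytest.approx(0.90,
                                                                  abs=1e-3)

    def test_loadings_pull_toward_half(self):
        B1 = np.zeros((1, 9, 1))
        B1[0, 0, 0] = 1.0
        lam = np.zeros((1, 1, 2))
        lam[0, 0, 0] = 2.0
        s0 = make_samples(B1, np.zeros((1, 9, 1)))
        s1 = make_samples(B1, np.zeros((1, 9, 1)), Lambda1=lam)
        p0 = predict_occurrence(s0, ROW0)[0, 0]
        p1 = predict_occurrence(s1, ROW0)[0, 0]
        assert abs(p1 - 0.5) < abs(p0 - 0.5)


class TestExpectedCount:
    def test_hurdle_product_zero(self):
        B1 = np.full((1, 9, 1), 0.0)
        B1[0, 0, 0] = -40.0
        s = make_samples(B1, np.zeros((1, 9, 1)))
        cnt = predict_expected_count(s, ROW0)
        assert cnt[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_two(self):
        B1 = np.zeros((1, 9, 1))
        B1[0, 0, 0] = 40.0  # occ prob 1
        s = make_samples(B1, np.zeros((1, 9, 1)))
        assert predict_expected_count(s, ROW0)[0, 0] == pytest.approx(2.0)

    def test_count_never_below_occurrence(self):
        rng = np.random.default_rng(3)
        d, S = 200, 12
        B1 = rng.normal(0, 1, (d, 9, S))
        B2 = rng.normal(0, 1, (d, 9, S))
        lam1 = rng.normal(0, 0.5, (d, S, 2))
        lam2 = rng.normal(0, 0.5, (d, S, 2))
        sig = rng.uniform(0.1, 1.0, (d, S))
        s = make_samples(B1, B2, lam1, lam2, sig,
                         species=[f"s{i}" for i in range(S)])
        pred = predict_set(s, ROW0)
        assert np.all(pred.expected_count >= pred.occ_prob)

    def test_overflow_reported(self):
        B2 = np.zeros((1, 9, 1))
        B2[0, 0, 0] = 800.0
        s = make_samples(np.zeros((1, 9, 1)), B2)
        with pytest.raises(OverflowError):
            predict_expected_count(s, ROW0)


class TestRichness:
    def _pred(self, occ):
        occ = np.asarray(occ, float)
        d, S = occ.shape
        return PredictionSet(occ_prob=occ, expected_count=occ + 1.0,
                             species_ids=[f"s{i}" for i in range(S)])

    def test_sum_of_probabilities(self):
        pred = self._pred([[0.5, 0.5]] * 4)
        mean, sd = expected_richness(pred)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_zero_probabilities(self):
        pred = self._pred(np.zeros((3, 2)))
        assert expected_richness(pred)[0] == 0.0

    def test_additive_over_disjoint_subsets(self):
        rng = np.random.default_rng(5)
        pred = self._pred(rng.uniform(0, 1, (50, 6)))
        all_m, _ = expected_richness(pred)
        a, _ = expected_richness(pred, ["s0", "s1", "s2"])
        bcd, _ = expected_richness(pred, ["s3", "s4", "s5"])
        assert all_m == pytest.approx(a + bcd)
        assert 0.0 <= all_m <= 6.0

    def test_unknown_species_rejected(self):
        pred = self._pred(np.zeros((3, 2)))
        with pytest.raises(KeyError):
            expected_richness(pred, ["nope"])

    def test_individuals_at_least_richness(self):
        rng = np.random.default_rng(6)
        pred = self._pred(rng.uniform(0, 1, (20, 5)))
        assert expected_individuals(pred)[0] >= expected_richness(pred)[0]


class TestChangeSummary:
    def _pair(self, occ1, occ2):
        mk = lambda o: PredictionSet(
            occ_prob=np.asarray(o, float),
            expected_count=np.asarray(o, float) + 1.0,
            species_ids=["sA"])
        return mk(occ1), mk(occ2)

    def test_forced_increase_fully_supported(self):
        p1, p2 = self._pair([[0.2]] * 10, [[0.9]] * 10)
        tab = change_summary(p1, p2)
        occ = tab[tab.statistic == "occupancy"].iloc[0]
        assert occ["support"] == 1.0
        assert occ["high_support"]
        assert occ["direction"] == "increase"

    def test_ties_support_nothing(self):
        p1, p2 = self._pair([[0.4]] * 10, [[0.4]] * 10)
        tab = change_summary(p1, p2)
        occ = tab[tab.statistic == "occupancy"].iloc[0]
        assert occ["frac_positive"] == 0.0
        assert occ["frac_negative"] == 0.0
        assert not occ["high_support"]
        assert occ["delta_mean"] == 0.0

    def test_mismatched_draws_rejected(self):
        p1, p2 = self._pair([[0.4]] * 10, [[0.4]] * 9)
        with pytest.raises(ValueError):
            change_summary(p1, p2)


class TestMonotonicity:
    def test_occurrence_monotone_in_positive_coefficient_covariate(self):
        """Raising a covariate whose coefficient is positive (cover, with
        everything else fixed) can only raise the occurrence
        probability."""
        rng = np.random.default_rng(9)
        B1 = rng.normal(0, 0.5, (50, 9, 4))
        B1[:, 4, :] = np.abs(B1[:, 4, :])       # positive cover coefficient
        s = make_samples(B1, np.zeros((50, 9, 4)),
                         species=[f"s{i}" for i in range(4)])
        covers = np.linspace(0.0, 1.0, 6)
        probs = np.stack([predict_occurrence(
            s, dict(ROW0, sec_cover=c)) for c in covers])
        assert np.all(np.diff(probs, axis=0) >= 0)


class TestRecountOracle:
    def test_high_support_count_matches_independent_recount(self):
        """The number of high-support species equals a direct recount on
        the same draw arrays."""
        rng = np.random.default_rng(10)
        d, S = 400, 30
        occ1 = rng.uniform(0.05, 0.9, (d, S))
        occ2 = np.clip(occ1 + rng.normal(0.05, 0.1, (d, S)), 0.001, 0.999)
        ids = [f"s{i}" for i in range(S)]
        p1 = PredictionSet(occ_prob=occ1, expected_count=occ1 + 1,
                           species_ids=ids)
        p2 = PredictionSet(occ_prob=occ2, expected_count=occ2 + 1,
                           species_ids=ids)
        tab = change_summary(p1, p2)
        occ_tab = tab[tab.statistic == "occupancy"]
        # independent recount, straight from the definition
        diff = occ2 - occ1
        recount = sum(
            max((diff[:, i] > 0).sum(), (diff[:, i] < 0).sum()) / d > 0.95
            for i in range(S))
        assert int(occ_tab["high_support"].sum()) == recount


class TestDesignRow:
    def test_matches_design_matrix_coding(self):
        row = design_row("secondary", 2, 0.8, 0.0)
        assert np.allclose(row, [1, 0, 1, 1, 0.8, 0, 0, 1, 0.8])
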