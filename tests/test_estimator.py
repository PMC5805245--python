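"""Transference-rate estimation: matrix algebra, objective, optimiser."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nutristage as ns
from nutristage.core import SESGroup
from nutristage.estimate import (
    TransitionRateModel,
    estimate_all,
    estimate_trs,
    five_year_project,
    grid_search,
    objective,
    one_year_matrix,
)

feasible_tau = st.tuples(
    st.floats(0.0, 1.0),
    st.floats(0.0, 1.0),
    st.floats(0.0, 1.0),
    st.floats(0.0, 1.0),
).filter(lambda t: t[1] + t[3] <= 1.0)


class TestOneYearMatrix:
    def test_zero_rates_identity(self):
        assert np.array_equal(one_year_matrix((0, 0, 0, 0)), np.eye(3))

    def test_single_active_flow(self):
        A = one_year_matrix((0.1, 0, 0, 0))
        assert np.allclose(A, [[0.9, 0, 0], [0.1, 1, 0], [0, 0, 1]])

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            one_year_matrix((0.0, 0.7, 0.0, 0.5))
        with pytest.raises(ValueError):
            one_year_matrix((-0.1, 0, 0, 0))

    @settings(derandomize=True, max_examples=100)
    @given(feasible_tau)
    def test_stochastic_closure(self, tau):
        A = one_year_matrix(tau)
        assert np.allclose(A.sum(axis=0), 1.0, atol=1e-12)
        assert np.all((A >= 0) & (A <= 1))
        B = np.linalg.matrix_power(A, 5)
        assert np.allclose(B.sum(axis=0), 1.0, atol=1e-12)


class TestFiveYearProject:
    def test_identity(self):
        P = np.array([0.2, 0.5, 0.3])
        assert np.allclose(five_year_project(np.eye(3), P), P)

    def test_scalar_power(self):
        # tau1=0.1 only: not-overweight retention over 5 years is 0.9^5
        A = one_year_matrix((0.1, 0, 0, 0))
        out = five_year_project(A, np.array([1.0, 0.0, 0.0]))
        assert out[0] == pytest.approx(0.9**5)  # 0.59049

    def test_stays_on_simplex(self):
        rng = np.random.default_rng(2)
        A = one_year_matrix((0.3, 0.2, 0.1, 0.4))
        P = rng.dirichlet(np.ones(3), size=5).T
        out = five_year_project(A, P)
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-12)

    def test_rejects_non_simplex(self):
        with pytest.raises(ValueError):
            five_year_project(np.eye(3), np.array([0.5, 0.5, 0.5]))


class TestObjective:
    def test_exact_fit_is_zero(self):
        rng = np.random.default_rng(0)
        tau = (0.03, 0.01, 0.0, 0.0)
        P1 = rng.dirichlet(np.ones(3), size=5).T
        P2 = five_year_project(one_year_matrix(tau), P1)
        assert objective(tau, P1, P2) == pytest.approx(0.0, abs=1e-28)

    def test_hand_evaluated_single_column(self):
        # identity dynamics; observed differs by +0.1 in overweight,
        # -0.1 in not overweight: CD = 0.01 + 0.01 = 0.02
        P1 = np.array([[0.5], [0.3], [0.2]])
        P2 = np.array([[0.4], [0.4], [0.2]])
        assert objective((0, 0, 0, 0), P1, P2) == pytest.approx(0.02)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(1)
        P1 = rng.dirichlet(np.ones(3), size=5).T
        P2 = rng.dirichlet(np.ones(3), size=5).T
        tau = (0.05, 0.02, 0.01, 0.03)
        perm = [4, 2, 0, 3, 1]
        assert objective(tau, P1, P2) == pytest.approx(
            objective(tau, P1[:, perm], P2[:, perm])
        )

    def test_mismatched_columns_rejected(self):
        with pytest.raises(ValueError):
            objective((0, 0, 0, 0), np.ones((3, 5)) / 3, np.ones((3, 4)) / 3)


class TestEstimateTrs:
    def _forward(self, tau, seed=0):
        rng = np.random.default_rng(seed)
        P1 = rng.dirichlet(np.full(3, 8.0), size=5).T
        P2 = five_year_project(one_year_matrix(tau), P1)
        return P1, P2

    def test_noiseless_recovery(self):
        truth = np.array([0.03, 0.01, 0.0, 0.0])
        P1, P2 = self._forward(truth)
        res = estimate_trs(P1, P2, restarts=8, seed=0)
        assert np.abs(res.tau - truth).max() < 1e-4
        assert res.cd < 1e-10
        assert res.converged

    def test_boundary_truth_stays_feasible(self):
        truth = np.array([0.02, 0.015, 0.0, 0.0])  # tau3 = tau4 = 0 boundary
        P1, P2 = self._forward(truth, seed=3)
        res = estimate_trs(P1, P2, restarts=8, seed=1)
        assert np.all(res.tau >= 0.0) and np.all(res.tau <= 1.0)
        assert res.tau[1] + res.tau[3] <= 1.0 + 1e-12

    def test_deterministic_across_seeds(self):
        truth = np.array([0.025, 0.008, 0.001, 0.002])
        P1, P2 = self._forward(truth, seed=5)
        r1 = estimate_trs(P1, P2, restarts=16, seed=11)
        r2 = estimate_trs(P1, P2, restarts=16, seed=99)
        assert np.abs(r1.tau - r2.tau).max() < 1e-6

    def test_grid_search_oracle(self):
        # truth deliberately off the 0.001 lattice
        truth = np.array([0.0304, 0.0117, 0.0, 0.0023])
        P1, P2 = self._forward(truth, seed=7)
        res = estimate_trs(P1, P2, restarts=8, seed=0)
        grids = [np.arange(0.0, 0.05001, 0.001)] * 4
        tau_grid, cd_grid = grid_search(P1, P2, grids)
        assert res.cd <= cd_grid + 1e-12
        assert np.abs(tau_grid - truth).max() < 1e-3 + 1e-12


class TestEstimateAll:
    def test_round_trip_full_table(self, paper_like_waves):
        scn, w1, w2 = paper_like_waves
        table, results = estimate_all(w1, w2, restarts=8, seed=4)
        truth = scn.truth[SESGroup.ALL].tau
        assert np.abs(table.tau - truth).max() < 1e-4
        assert all(r.cd < 1e-10 for r in results)

    def test_null_signal_gives_zero_rates(self):
        """Wave 2 built as the age-shifted copy of wave 1 (tau = 0)."""
        scn = ns.generate_truth(3, "paper_like")
        zero = {SESGroup.ALL: ns.TransferenceRateTable.zeros()}
        scn = ns.SyntheticScenario(
            seed=3, profile="paper_like", truth=zero,
            demography=scn.demography, populations=scn.populations,
        )
        w1, w2 = ns.generate_waves(scn)[SESGroup.ALL]
        assert np.allclose(w2.P[:, 5:], w1.P[:, :60])
        table, _ = estimate_all(w1, w2, restarts=8, seed=0)
        assert np.abs(table.tau).max() < 1e-6

    def test_mismatched_strata_rejected(self):
        scn = ns.generate_truth(1, "paper_like", strata=("lower", "higher"))
        waves = ns.generate_waves(scn)
        w1_low, _ = waves[SESGroup.LOWER]
        _, w2_high = waves[SESGroup.HIGHER]
        with pytest.raises(ValueError, match="strata"):
            estimate_all(w1_low, w2_high)


class TestModelResults:
    def test_fit_matches_function_api(self, paper_like_waves):
        scn, w1, w2 = paper_like_waves
        res = TransitionRateModel(w1, w2).fit(restarts=8, seed=4)
        table, _ = estimate_all(w1, w2, restarts=8, seed=4)
        assert np.allclose(res.rates.tau, table.tau)
        assert res.converged
        assert res.cd.shape == (12,)

    def test_wave_gap_enforced(self, paper_like_waves):
        _, w1, w2 = paper_like_waves
        w2_bad = ns.SurveyPrevalence(wave=w1.wave + 3, P=w2.P, ses=w2.ses)
        with pytest.raises(ValueError, match="5 years apart"):
            TransitionRateModel(w1, w2_bad)

    def test_summary_and_means(self, paper_like_waves):
        scn, w1, w2 = paper_like_waves
        res = TransitionRateModel(w1, w2).fit(restarts=4, seed=0)
        text = res.summary()
        assert "tau1" in text and "55-59" in text
        assert res.mean_rate(1) == pytest.approx(res.rates.tau[:, 0].mean())
        preds = res.predict()
        assert set(preds) == set(range(12))
        # predictions replicate the observed wave-2 columns at zero noise
        worst = max(
            np.abs(preds[i] - w2.group_columns(i + 1)).max() for i in range(12)
        )
        assert worst < 1e-5
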