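"""Stock-and-flow engine: births, exits, derivatives, integration."""

import numpy as np
import pytest
from scipy.linalg import expm

import nutristage as ns
from nutristage.core import DemographicParams, PopulationState, TransferenceRateTable
from nutristage.simulate import (
    IntegrationConfig,
    births,
    evaluate_flows,
    exit_rates,
    net_derivative,
    run_projection,
    transfer_flows,
)


def _demo(mortality=0.0, fertility=0.0, theta=(1.0, 0.0, 0.0), mu=0.5):
    return DemographicParams(
        mortality=np.full(12, mortality),
        fertility={y: fertility for y in range(2000, 2161)},
        mu=mu,
        theta=np.asarray(theta, dtype=float),
    )


def _tau(**cols):
    tau = np.zeros((12, 4))
    for name, val in cols.items():
        tau[:, int(name[-1]) - 1] = val
    return TransferenceRateTable(tau)


class TestBirths:
    def test_hand_arithmetic(self):
        # mu=0.5, f=2, childbearing pool 3500 -> 0.5*3500*2/35 = 100/yr
        stocks = np.zeros((12, 3))
        stocks[3:10, 0] = 500.0  # groups 3..9 cover ages 15-49
        B = births(stocks, _demo(fertility=2.0, mu=0.5), 2005.0)
        assert B.sum() == pytest.approx(100.0)

    def test_theta_routes_births(self):
        stocks = np.ones((12, 3)) * 100
        B = births(stocks, _demo(fertility=2.0, theta=(1, 0, 0)), 2005.0)
        assert B[1] == 0.0 and B[2] == 0.0 and B[0] > 0

    def test_only_childbearing_groups_count(self):
        stocks = np.zeros((12, 3))
        stocks[0, 0] = 1e6  # ages 0-4 produce no births
        stocks[11, 0] = 1e6
        B = births(stocks, _demo(fertility=2.0), 2005.0)
        assert B.sum() == 0.0


class TestExitRates:
    def test_stock_outflow_definitional(self):
        stocks = np.zeros((12, 3))
        stocks[4, 1] = 500.0
        E = exit_rates(stocks, _tau(), _demo(), np.zeros(3), "stock_outflow")
        assert E[4, 1] == pytest.approx(100.0)  # 500 / Y, Y=5
        assert E.sum() == pytest.approx(100.0)

    def test_literal_form_is_degenerate(self):
        # no births, no transfers: the literal exit is zero whatever the stock
        stocks = np.zeros((12, 3))
        stocks[0, 0] = 1e6
        E = exit_rates(stocks, _tau(), _demo(), np.zeros(3), "literal_paper")
        assert np.all(E == 0.0)

    def test_zero_stocks_zero_exits(self):
        for form in ("stock_outflow", "literal_paper"):
            E = exit_rates(np.zeros((12, 3)), _tau(), _demo(), np.zeros(3), form)
            assert np.all(E == 0.0)

    def test_unknown_formulation(self):
        with pytest.raises(ValueError):
            exit_rates(np.zeros((12, 3)), _tau(), _demo(), np.zeros(3), "bogus")


class TestDerivative:
    def test_single_group_transfer(self):
        stocks = np.zeros((12, 3))
        stocks[5, 0] = 100.0
        d = transfer_flows(stocks, _tau(tau1=0.1))
        assert d[5] == pytest.approx([-10.0, 10.0, 0.0])
        assert np.allclose(d.sum(axis=1), 0.0)

    def test_rejects_negative_stock(self):
        state = PopulationState(t=2005.0, stocks=np.zeros((12, 3)))
        state.stocks[0, 0] = -1.0  # bypass constructor check deliberately
        with pytest.raises(ValueError):
            net_derivative(state, _tau(), _demo(), 2005.0)

    def test_conservation_without_demography(self):
        # S=1 (no deaths), no births: derivative only shuffles people except
        # the final group's maturation out of the system
        stocks = np.abs(np.random.default_rng(3).normal(1e3, 100, (12, 3)))
        state = PopulationState(t=2005.0, stocks=stocks)
        d = net_derivative(state, _tau(tau1=0.05, tau2=0.02), _demo(), 2005.0)
        top_exit = stocks[11].sum() / 5.0
        assert d.sum() == pytest.approx(-top_exit, rel=1e-12)

    def test_matrix_exponential_oracle_two_group_chain(self):
        """One year of integration matches expm on the equivalent linear
        6-compartment system (two age groups, three categories)."""
        rng = np.random.default_rng(5)
        tau = np.zeros((12, 4))
        tau[0] = [0.08, 0.03, 0.01, 0.02]
        tau[1] = [0.05, 0.04, 0.00, 0.01]
        rates = TransferenceRateTable(tau)
        demo = _demo(mortality=0.01)  # S_i = exp(-0.05)
        stocks0 = np.zeros((12, 3))
        stocks0[0] = [400.0, 150.0, 50.0]
        stocks0[1] = [380.0, 160.0, 60.0]

        def gen(t1, t2, t3, t4):
            return np.array(
                [[-t1, t4, 0.0], [t1, -(t2 + t4), t3], [0.0, t2, -t3]]
            )

        Y = 5.0
        S0 = np.exp(-0.01 * Y)
        M = np.zeros((6, 6))
        M[:3, :3] = gen(*tau[0]) - np.eye(3) / Y
        M[3:, 3:] = gen(*tau[1]) - np.eye(3) / Y
        M[3:, :3] = np.eye(3) * S0 / Y
        expected = expm(M * 1.0) @ stocks0[:2].ravel()

        cfg = IntegrationConfig(t0=2005.0, t1=2006.0, dt=0.05, method="rk4")
        run = run_projection(
            PopulationState(t=2005.0, stocks=stocks0), rates, demo, cfg
        )
        got = run.stocks_at(2006)[:2].ravel()
        assert np.allclose(got, expected, rtol=1e-8)


class TestRunProjection:
    def test_population_ledger_closes_each_step(self, uniform_initial):
        """Euler step change in total population equals dt * (births -
        deaths - final-group maturation)."""
        initial, _ = uniform_initial
        demo = _demo(mortality=0.004, fertility=2.0, theta=(0.8, 0.15, 0.05))
        rates = _tau(tau1=0.03, tau2=0.01)
        dt = 0.25
        stocks = initial.stocks.copy()
        S = demo.survival
        for k in range(200):
            t = 2005.0 + k * dt
            flows = evaluate_flows(stocks, rates, demo, t, "stock_outflow")
            deaths = (flows.exits * (1.0 - S[:, None])).sum()
            top = flows.exits[11].sum() * S[11]
            expected_change = dt * (flows.births.sum() - deaths - top)
            state = PopulationState(t=t, stocks=stocks)
            stocks = stocks + dt * net_derivative(state, rates, demo, t)
            assert stocks.sum() - state.total == pytest.approx(
                expected_change, rel=1e-6
            )

    def test_extreme_conditions_drain(self, uniform_initial):
        """Zero fertility, mortality and TRs: the chain drains only through
        the 55-59 exit and the total is strictly decreasing."""
        initial, _ = uniform_initial
        demo = _demo()
        cfg = IntegrationConfig(t0=2005.0, t1=2030.0)
        run = run_projection(initial, _tau(), demo, cfg)
        totals = [run.total_population(y) for y in run.years]
        assert all(b < a for a, b in zip(totals, totals[1:]))
        assert run.clamp_events == 0
        # after a long horizon most of the population has flowed out
        assert totals[-1] < totals[0]

    def test_linearity_in_population_scale(self, uniform_initial):
        initial, _ = uniform_initial
        demo = _demo(mortality=0.002, fertility=1.8, theta=(0.8, 0.15, 0.05))
        rates = _tau(tau1=0.02, tau2=0.01)
        cfg = IntegrationConfig(t0=2005.0, t1=2015.0)
        run1 = run_projection(initial, rates, demo, cfg)
        scaled = PopulationState(t=initial.t, stocks=initial.stocks * 7.0)
        run2 = run_projection(scaled, rates, demo, cfg)
        for y in run1.years:
            assert np.allclose(run2.stocks_at(y), 7.0 * run1.stocks_at(y), rtol=1e-12)

    def test_category_shares_converge_to_birth_fractions(self):
        """With tau=0 and steady demography, every age group's category mix
        relaxes to the birth fractions theta (the chain's slowest mode decays
        like a 12-stage gamma tail, so a long horizon is needed)."""
        theta = (0.7, 0.2, 0.1)
        demo = _demo(mortality=0.001, fertility=2.2, theta=theta)
        stocks = np.tile([900.0, 80.0, 20.0], (12, 1))
        cfg = IntegrationConfig(t0=2000.0, t1=2160.0)
        run = run_projection(
            PopulationState(t=2000.0, stocks=stocks), _tau(), demo, cfg
        )
        final = run.stocks_at(2160)
        shares = final / final.sum(axis=1, keepdims=True)
        assert np.allclose(shares, np.tile(theta, (12, 1)), atol=1e-4)

    def test_dt_halving_changes_little(self, uniform_initial):
        initial, demo = uniform_initial
        rates = _tau(tau1=0.03, tau2=0.008)
        runs = {}
        for dt in (0.25, 0.125):
            cfg = IntegrationConfig(t0=2005.0, t1=2030.0, dt=dt)
            runs[dt] = run_projection(initial, rates, demo, cfg)
        for y in runs[0.25].years:
            p1 = runs[0.25].stocks_at(y)
            p2 = runs[0.125].stocks_at(y)
            prev1 = p1 / p1.sum(axis=1, keepdims=True)
            prev2 = p2 / p2.sum(axis=1, keepdims=True)
            assert np.abs(prev1 - prev2).max() < 1e-3

    def test_euler_rk4_agreement(self, uniform_initial):
        initial, demo = uniform_initial
        rates = _tau(tau1=0.03, tau2=0.008)
        run_e = run_projection(
            initial, rates, demo, IntegrationConfig(t0=2005, t1=2020, dt=0.01)
        )
        run_r = run_projection(
            initial, rates, demo,
            IntegrationConfig(t0=2005, t1=2020, dt=0.25, method="rk4"),
        )
        for y in run_e.years:
            pe = run_e.stocks_at(y)
            pr = run_r.stocks_at(y)
            assert np.abs(
                pe / pe.sum(1, keepdims=True) - pr / pr.sum(1, keepdims=True)
            ).max() < 1e-3

    def test_projection_frame_invariants(self, uniform_initial):
        initial, demo = uniform_initial
        run = run_projection(
            initial, _tau(tau1=0.02), demo, IntegrationConfig(t0=2005, t1=2010)
        )
        frame = run.frame
        sums = frame.groupby(["year", "age_group"])["prevalence"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
        counts = frame.groupby(["year", "age_group"])["count"].sum()
        for (y, g), total in counts.items():
            i = list(ns.core.AGE_GROUP_LABELS).index(g)
            assert total == pytest.approx(run.stocks_at(y)[i].sum(), rel=1e-12)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            IntegrationConfig(dt=-0.1)
        with pytest.raises(ValueError):
            IntegrationConfig(t0=2010, t1=2005)
        with pytest.raises(ValueError):
            IntegrationConfig(method="dormand")
        with pytest.raises(ValueError):
            IntegrationConfig(exit_formulation="bogus")
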