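"""Unit and property tests for the forward magnetization model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypermet import (
    AcquisitionScheme,
    CapacityError,
    ConversionSet,
    Pool,
    SchemaError,
    closed_form_product,
    decay_budget,
    effective_decay_rate,
    propagate_pulsed,
    rf_loss_rate,
    simulate_magnetization,
    time_of_maximum,
)

# effective decay rate of [1-13C]pyruvate under the 5 deg / 3 s sampling,
# computed term by term: 1/51.4 + 2.92e-3 - ln(cos 5 deg)/3
RHO_S_NA = 1 / 51.4 + 2.92e-3 - math.log(math.cos(math.radians(5.0))) / 3.0
RHO_P_NA = 1 / 35.4 - math.log(math.cos(math.radians(5.0))) / 3.0


class TestEffectiveDecayRate:
    @pytest.mark.parametrize(
        "T1, k_total, flip, tr, expected",
        [
            (50.0, 0.0, 0.0, None, 0.02),
            (10.0, 0.0, 0.0, 3.0, 0.1),
            (51.4, 2.92e-3, 5.0, 3.0, 0.0236461),
        ],
    )
    def test_values(self, T1, k_total, flip, tr, expected):
        assert effective_decay_rate(T1, k_total, flip, tr) == pytest.approx(
            expected, rel=1e-5
        )

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            effective_decay_rate(-1.0)
        with pytest.raises(ValueError):
            effective_decay_rate(50.0, 0.0, 5.0, -3.0)
        with pytest.raises(ValueError):
            effective_decay_rate(50.0, 0.0, 5.0, None)
        with pytest.raises(ValueError):
            rf_loss_rate(90.0, 3.0)

    @given(
        T1=st.floats(5.0, 100.0),
        k=st.floats(0.0, 0.01),
        flip=st.floats(0.5, 30.0),
        tr=st.floats(0.5, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_at_least_relaxation(self, T1, k, flip, tr):
        assert effective_decay_rate(T1, k, flip, tr) >= 1.0 / T1


class TestClosedFormProduct:
    def test_starts_empty(self):
        assert closed_form_product(1.0, 1e-3, 0.02, 0.04, 0.0) == 0.0

    def test_equal_rate_limit(self):
        rho = 0.03
        t = 25.0
        expected = 1e-3 * 1.0 * t * math.exp(-rho * t)
        assert closed_form_product(1.0, 1e-3, rho, rho, t) == pytest.approx(expected)
        # formula at nearly-equal rates approaches the same limit
        assert closed_form_product(1.0, 1e-3, rho, rho * (1 + 1e-9), t) == pytest.approx(
            expected, rel=1e-6
        )

    def test_value_at_maximum_against_stationarity(self):
        # at the maximum dP/dt = 0, so P = k * S / rho_p — an independent
        # relation not using the closed-form difference quotient
        t_star = time_of_maximum(RHO_S_NA, RHO_P_NA)
        p_max = closed_form_product(1.0, 2.92e-3, RHO_S_NA, RHO_P_NA, t_star)
        s_at = math.exp(-RHO_S_NA * t_star)
        assert p_max == pytest.approx(2.92e-3 * s_at / RHO_P_NA, rel=1e-10)
        assert p_max == pytest.approx(0.040493, rel=1e-4)


class TestTimeOfMaximum:
    def test_degenerate_equal_rates(self):
        assert time_of_maximum(0.05, 0.05) == pytest.approx(20.0)

    def test_na_pyruvate_rates(self):
        assert time_of_maximum(RHO_S_NA, RHO_P_NA) == pytest.approx(37.77, abs=0.01)

    def test_independent_of_k_and_matches_grid_search(self):
        t_star = time_of_maximum(RHO_S_NA, RHO_P_NA)
        grid = np.linspace(0.0, 300.0, 300_001)
        for k in (1e-4, 2.92e-3):
            curve = closed_form_product(1.0, k, RHO_S_NA, RHO_P_NA, grid)
            assert grid[np.argmax(curve)] == pytest.approx(t_star, abs=2e-3)

    def test_invalid(self):
        with pytest.raises(ValueError):
            time_of_maximum(-0.01, 0.02)


class TestSimulateMagnetization:
    def _pools(self, T1_s=50.0, T1_p=30.0, k=3e-3):
        sub = Pool("sub", T1=T1_s, role="substrate", s0=1.0)
        prod = Pool("prod", T1=T1_p)
        return sub, (prod,), ConversionSet({"prod": k})

    def test_decoupled_exponentials_without_conversion(self):
        sub = Pool("sub", T1=40.0, role="substrate", s0=2.0)
        prod = Pool("prod", T1=25.0, s0=0.5)
        scheme = AcquisitionScheme(flip_angle=0.0, repetition_time=3.0, n_acquisitions=10)
        grid = np.linspace(0.0, 120.0, 41)
        sim = simulate_magnetization(sub, (prod,), ConversionSet({}), scheme, grid)
        np.testing.assert_allclose(
            sim.magnetization["sub"], 2.0 * np.exp(-grid / 40.0), rtol=1e-8
        )
        np.testing.assert_allclose(
            sim.magnetization["prod"], 0.5 * np.exp(-grid / 25.0), rtol=1e-8
        )

    def test_matches_closed_form_two_pool(self):
        sub, prods, conv = self._pools()
        scheme = AcquisitionScheme(flip_angle=0.0, repetition_time=3.0, n_acquisitions=10)
        grid = np.linspace(0.0, 300.0, 101)
        sim = simulate_magnetization(sub, prods, conv, scheme, grid)
        expected = closed_form_product(1.0, 3e-3, 1 / 50.0 + 3e-3, 1 / 30.0, grid)
        np.testing.assert_allclose(
            sim.magnetization["prod"].to_numpy()[1:], expected[1:], rtol=1e-8
        )

    def test_conservation_without_relaxation_or_pulses(self):
        sub = Pool("sub", T1=math.inf, role="substrate", s0=1.0)
        prods = (Pool("a", T1=math.inf), Pool("b", T1=math.inf))
        conv = ConversionSet({"a": 3e-3, "b": 1e-3})
        scheme = AcquisitionScheme(flip_angle=0.0, repetition_time=3.0, n_acquisitions=10)
        grid = np.linspace(0.0, 400.0, 81)
        sim = simulate_magnetization(sub, prods, conv, scheme, grid)
        total = sim.magnetization.sum(axis=1).to_numpy()
        assert np.max(np.abs(total - 1.0)) < 1e-9

    def test_per_pulse_depletion_is_exactly_cos_alpha(self):
        sub = Pool("sub", T1=math.inf, role="substrate", s0=1.0)
        scheme = AcquisitionScheme(flip_angle=10.0, repetition_time=2.0, n_acquisitions=8)
        grid = scheme.acquisition_times()
        sim = simulate_magnetization(sub, (), ConversionSet({}), scheme, grid)
        mz = sim.magnetization["sub"].to_numpy()
        expected = np.cos(math.radians(10.0)) ** np.arange(8)
        np.testing.assert_allclose(mz, expected, rtol=1e-10)
        np.testing.assert_allclose(
            sim.observed["sub"], mz * math.sin(math.radians(10.0)), rtol=1e-12
        )

    def test_capacity_and_schema_errors(self):
        sub = Pool("sub", T1=50.0, role="substrate", s0=1.0)
        five = tuple(Pool(f"p{i}", T1=30.0) for i in range(5))
        scheme = AcquisitionScheme(flip_angle=5.0, repetition_time=3.0, n_acquisitions=5)
        with pytest.raises(CapacityError):
            simulate_magnetization(sub, five, ConversionSet({}), scheme, [0.0, 3.0])
        with pytest.raises(SchemaError):
            simulate_magnetization(
                sub, (Pool("p", T1=30.0),), ConversionSet({"absent": 1e-3}),
                scheme, [0.0, 3.0],
            )
        with pytest.raises(CapacityError):
            ConversionSet({f"p{i}": 1e-3 for i in range(5)})

    def test_non_monotone_grid_rejected(self):
        sub, prods, conv = self._pools()
        scheme = AcquisitionScheme(flip_angle=5.0, repetition_time=3.0, n_acquisitions=5)
        with pytest.raises(ValueError):
            simulate_magnetization(sub, prods, conv, scheme, [0.0, 3.0, 3.0])

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=10, deadline=None)
    def test_trajectories_non_negative_and_product_unimodal(self, seed):
        rng = np.random.default_rng(seed)
        T1_s, T1_p = rng.uniform(10, 80), rng.uniform(5, 60)
        k = rng.uniform(1e-4, 8e-3)
        sub = Pool("sub", T1=T1_s, role="substrate", s0=1.0)
        scheme = AcquisitionScheme(flip_angle=0.0, repetition_time=3.0, n_acquisitions=5)
        grid = np.linspace(0.0, 300.0, 2001)
        sim = simulate_magnetization(
            sub, (Pool("p", T1=T1_p),), ConversionSet({"p": k}), scheme, grid
        )
        p = sim.magnetization["p"].to_numpy()
        assert np.all(sim.magnetization.to_numpy() >= -1e-12)
        t_star = time_of_maximum(1 / T1_s + k, 1 / T1_p)
        i_max = np.argmax(p)
        if t_star < 300.0:
            assert abs(grid[i_max] - t_star) <= 0.3  # within two grid steps
        # unimodal: rises before the max, falls after
        assert np.all(np.diff(p[: i_max + 1]) >= -1e-12)
        assert np.all(np.diff(p[i_max:]) <= 1e-12)


class TestPropagatePulsed:
    def test_matches_ode_with_pulses(self):
        scheme = AcquisitionScheme(flip_angle=5.0, repetition_time=3.0, n_acquisitions=60)
        sub = Pool("sub", T1=51.4, role="substrate", s0=1.0)
        prods = (Pool("a", T1=35.4), Pool("b", T1=11.2))
        conv = ConversionSet({"a": 2.92e-3, "b": 2.15e-3})
        times = scheme.acquisition_times()
        sim = simulate_magnetization(sub, prods, conv, scheme, times)
        S, P = propagate_pulsed(
            1.0, 51.4, np.array([2.92e-3, 2.15e-3]), np.array([35.4, 11.2]), times, 5.0
        )
        np.testing.assert_allclose(S, sim.magnetization["sub"], rtol=1e-8)
        np.testing.assert_allclose(P[:, 0], sim.magnetization["a"], rtol=1e-7, atol=1e-12)
        np.testing.assert_allclose(P[:, 1], sim.magnetization["b"], rtol=1e-7, atol=1e-12)

    def test_discrete_vs_continuous_rf_loss_small_angle(self):
        # the -ln(cos a)/TR continuous rate reproduces the pulsed substrate
        # envelope to <0.1% at 5 deg / 3 s over the full acquisition
        times = np.arange(60) * 3.0
        S, _ = propagate_pulsed(1.0, 51.4, np.array([]), np.array([]), times, 5.0)
        rho = effective_decay_rate(51.4, 0.0, 5.0, 3.0)
        cont = np.exp(-rho * times) / math.cos(math.radians(5.0))  # pre-pulse envelope
        # compare shapes normalized at the first point
        np.testing.assert_allclose(S / S[0], cont / cont[0], rtol=1e-3)


def test_decay_budget_decomposition():
    sub = Pool("sub", T1=50.0, role="substrate", s0=1.0)
    prod = Pool("p", T1=25.0)
    conv = ConversionSet({"p": 2e-3})
    scheme = AcquisitionScheme(flip_angle=5.0, repetition_time=3.0, n_acquisitions=10)
    budgets = decay_budget(sub, (prod,), conv, scheme)
    assert budgets["sub"].total == pytest.approx(
        effective_decay_rate(50.0, 2e-3, 5.0, 3.0)
    )
    assert budgets["p"].conversion == 0.0
    # substrate and product rho differ by exactly sum(k) when RF terms match
    diff = budgets["sub"].total - budgets["p"].total
    assert diff == pytest.approx(2e-3 + (1 / 50.0 - 1 / 25.0))
    for b in budgets.values():
        assert b.total >= b.relaxation


def test_pool_and_scheme_validation():
    with pytest.raises(ValueError):
        Pool("x", T1=-1.0)
    with pytest.raises(ValueError):
        Pool("x", T1=10.0, s0=-0.1)
    with pytest.raises(ValueError):
        AcquisitionScheme(flip_angle=100.0, repetition_time=3.0, n_acquisitions=5)
    with pytest.raises(ValueError):
        AcquisitionScheme(flip_angle=5.0, repetition_time=0.0, n_acquisitions=5)
    with pytest.raises(ValueError):
        ConversionSet({"p": -1e-3})
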