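"""Closed-form daily update: exactness, limits and invariants.

The independent oracles are scipy's matrix exponential (the exact flow of
the linear system) and the forward-Euler integrator; neither shares code
with the hand-derived propagator.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from csckinetics.euler import EulerConfig, euler_integrate
from csckinetics.kinetics import (
    CompartmentState,
    InvalidStateError,
    advance_one_day,
    analytic_state,
    day_propagator,
    rate_matrix,
    total_cells,
)
from csckinetics.params import KineticParameters

LN2 = math.log(2.0)


def make_params(**overrides):
    base = dict(
        delta=0.05, p=0.3, t_u=6.2, t_v=6.2, t_a=6.2, t_h=1.0,
        sf_u=0.95, sf_v=0.85,
    )
    base.update(overrides)
    return KineticParameters(**base)


# delta is either exactly zero or physiologically sized; extreme denormals
# (1e-100-scale) make the scipy expm reference itself misbehave
valid_params = st.builds(
    make_params,
    delta=st.one_of(st.just(0.0), st.floats(1e-6, 1.0)),
    t_u=st.floats(0.5, 60.0),
    t_v=st.floats(0.5, 60.0),
    t_a=st.floats(0.5, 60.0),
    t_h=st.floats(0.1, 20.0),
    sf_u=st.floats(0.05, 1.0),
    sf_v=st.floats(0.05, 1.0),
)


class TestTotalCells:
    @pytest.mark.parametrize(
        "state,expected",
        [((0, 0, 0), 0.0), ((0.3, 0.7, 0), 1.0), ((1, 2, 3), 6.0)],
    )
    def test_sums_compartments(self, state, expected):
        assert total_cells(CompartmentState(*state)) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidStateError):
            CompartmentState(-0.1, 0.0, 0.0)


class TestAdvanceOneDay:
    def test_pure_clearance_halves_dead_pool(self):
        params = make_params(t_h=1.0)
        state = advance_one_day(CompartmentState(0, 0, 8.0), params, treated=False)
        assert state.u == 0 and state.v == 0
        assert state.w == pytest.approx(4.0, rel=1e-12)

    def test_symmetric_growth_doubles_over_one_doubling_time(self):
        # delta=1, no kill: pure exponential CSC growth at rate ln2/T_u
        params = make_params(delta=1.0, t_u=4.0, sf_u=1.0)
        state = CompartmentState(1.0, 0, 0)
        for _ in range(4):
            state = advance_one_day(state, params, treated=False)
        assert state.u == pytest.approx(2.0, rel=1e-9)

    def test_kill_without_division_moves_mass_to_dead_pool(self):
        # negligible division: surviving fraction applies directly to U and
        # the killed mass appears in W (minus one day of clearance)
        params = make_params(delta=0.5, t_u=1e9, t_v=1e9, t_a=1e9, sf_u=0.5,
                             sf_v=1.0, t_h=5.0)
        state = advance_one_day(CompartmentState(1.0, 0, 0), params, treated=True)
        assert state.u == pytest.approx(0.5, rel=1e-6)
        assert state.w > 0.25  # killed half, partially cleared
        euler = euler_integrate(
            CompartmentState(1.0, 0, 0), params, [True], EulerConfig(10_000)
        )[0]
        assert state.w == pytest.approx(euler.w, rel=1e-3)

    def test_conservation_without_clearance_or_growth(self):
        # no division, no programmed death, no clearance: a treated day only
        # shuffles mass between live and dead compartments
        params = make_params(delta=0.0, t_u=1e12, t_v=1e12, t_a=1e12,
                             t_h=1e12, sf_u=0.7, sf_v=0.6)
        state0 = CompartmentState(0.4, 0.6, 0.0)
        state1 = advance_one_day(state0, params, treated=True)
        assert state1.total == pytest.approx(1.0, abs=1e-10)

    def test_growth_monotone_in_delta_and_survival(self):
        base = make_params(delta=0.2, sf_u=0.9)
        state = CompartmentState(1.0, 0, 0)
        u_base = advance_one_day(state, base, True).u
        assert advance_one_day(state, make_params(delta=0.4, sf_u=0.9), True).u > u_base
        assert advance_one_day(state, make_params(delta=0.2, sf_u=0.95), True).u > u_base


class TestAnalyticState:
    def test_identity_at_t_zero(self):
        state = CompartmentState(0.2, 0.5, 0.3)
        out = analytic_state(state, make_params(), True, t=0.0)
        assert (out.u, out.v, out.w) == (state.u, state.v, state.w)

    def test_stationary_when_all_rates_vanish(self):
        params = make_params(delta=0.0, t_u=1e12, t_v=1e12, t_a=1e12,
                             t_h=1e12, sf_u=1.0, sf_v=1.0)
        out = analytic_state(CompartmentState(0.5, 0.4, 0.1), params, True, t=3.0)
        assert out.u == pytest.approx(0.5, abs=1e-10)
        assert out.v == pytest.approx(0.4, abs=1e-10)
        assert out.w == pytest.approx(0.1, abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            analytic_state(CompartmentState(1, 0, 0), make_params(), True, t=-1.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(params=valid_params, treated=st.booleans())
    def test_semigroup_two_unit_steps_equal_t_two(self, params, treated):
        state0 = CompartmentState(0.3, 0.6, 0.1)
        stepped = advance_one_day(
            advance_one_day(state0, params, treated), params, treated
        )
        direct = analytic_state(state0, params, treated, t=2.0)
        for a, b in zip(
            (stepped.u, stepped.v, stepped.w), (direct.u, direct.v, direct.w)
        ):
            assert a == pytest.approx(b, rel=1e-12, abs=1e-15)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(params=valid_params, treated=st.booleans())
    def test_propagator_matches_matrix_exponential(self, params, treated):
        prop = day_propagator(params, treated)
        exact = expm(rate_matrix(params, treated))
        assert np.allclose(prop, exact, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize(
        "overrides",
        [
            # A == C exactly: delta=0 untreated with T_v = T_a
            dict(delta=0.0, t_v=3.0, t_a=3.0, sf_u=1.0, sf_v=1.0),
            # A == -gamma_w resonance (delta*m_u = -ln SF_u - ln2/T_h)
            dict(delta=0.0, sf_u=0.5, t_h=1.0, sf_v=0.9),
            # C == -gamma_w resonance under shared doubling time
            dict(delta=0.1, sf_v=0.5, t_h=1.0, sf_u=0.9),
        ],
    )
    def test_resonant_denominators_match_matrix_exponential(self, overrides):
        params = make_params(**overrides)
        prop = day_propagator(params, treated=True)
        exact = expm(rate_matrix(params, treated=True))
        assert np.allclose(prop, exact, rtol=1e-9, atol=1e-12)
        assert np.all(prop >= 0)

    def test_composition_over_a_week_matches_single_flow(self):
        params = make_params()
        state = CompartmentState(0.3, 0.7, 0.0)
        iterated = state
        for _ in range(7):
            iterated = advance_one_day(iterated, params, treated=False)
        direct = analytic_state(state, params, treated=False, t=7.0)
        assert iterated.total == pytest.approx(direct.total, rel=1e-10)


class TestEulerOracleEquivalence:
    def test_one_day_update_matches_euler_on_random_parameters(self):
        rng = np.random.default_rng(42)
        config = EulerConfig(substeps_per_day=10_000)
        for _ in range(100):
            params = make_params(
                delta=rng.uniform(0, 1),
                t_u=rng.uniform(0.5, 30),
                t_v=rng.uniform(0.5, 30),
                t_a=rng.uniform(0.5, 30),
                t_h=rng.uniform(0.1, 10),
                sf_u=rng.uniform(0.3, 1.0),
                sf_v=rng.uniform(0.3, 1.0),
            )
            treated = bool(rng.integers(2))
            state0 = CompartmentState(0.3, 0.7, 0.05)
            exact = advance_one_day(state0, params, treated)
            approx = euler_integrate(state0, params, [treated], config)[0]
            for a, b in zip(
                (exact.u, exact.v, exact.w), (approx.u, approx.v, approx.w)
            ):
                assert b == pytest.approx(a, rel=1e-3, abs=1e-9)
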