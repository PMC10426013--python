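"""Unit and property tests for the decision and attitude-update rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from coevo.core import (
    Authority,
    NoiseSpec,
    ParameterError,
    PsychParams,
    action_utility_gap,
    choose_binary,
    update_attitude,
    update_attitude_detailed,
    utility,
)

unit = st.floats(0.0, 1.0, allow_nan=False)
weight = st.floats(0.0, 2.0, allow_nan=False)


def _random_setting(rng):
    params = PsychParams(*rng.random(7) * 2.0)
    auth = Authority(G=rng.random(), F=2.0 * rng.random())
    return params, auth


class TestUtility:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            # perfect alignment with no payoff: every term vanishes
            (dict(x=0.7, y=0.7, xbar=0.7, pi_x=0.0, norm_x=0.0,
                  params=PsychParams(v=1, k1=1, k2=1, k3=1),
                  auth=Authority(G=0.7, F=1.0)), 0.0),
            # three unit mismatches at unit weights
            (dict(x=1.0, y=0.0, xbar=0.0, pi_x=0.0, norm_x=0.0,
                  params=PsychParams(v=0, k1=1, k2=1, k3=1),
                  auth=Authority(G=0.0, F=1.0)), -3.0),
            # psychology switched off: pure material + normative value
            (dict(x=1.0, y=0.3, xbar=0.9, pi_x=2.5, norm_x=0.4,
                  params=PsychParams(v=2.0),
                  auth=Authority(G=0.0, F=5.0)), 2.5 + 0.8),
        ],
    )
    def test_examples(self, kwargs, expected):
        assert utility(**kwargs) == pytest.approx(expected, abs=1e-12)

    def test_matches_term_by_term_oracle(self, rng):
        """The vectorised form equals a literal per-term recomputation."""
        for _ in range(1000):
            params, auth = _random_setting(rng)
            x, y, xbar = rng.random(3)
            pi_x, norm_x = rng.normal(size=2)
            expected = (
                pi_x
                + params.v * norm_x
                - params.k1 * (x - y) ** 2
                - params.k2 * (x - xbar) ** 2
                - params.k3 * auth.F * (x - auth.G) ** 2
            )
            got = utility(x, y, xbar, pi_x, norm_x, params, auth)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_negative_sensitivity_rejected(self):
        with pytest.raises(ParameterError):
            PsychParams(k1=-0.1)


class TestActionUtilityGap:
    def test_worked_example(self):
        params = PsychParams(v=1, k1=0.5, k2=0.5, k3=0.5)
        got = action_utility_gap(0.8, 0.6, 1.0, params, Authority(G=1, F=1))
        assert got == pytest.approx(0.7, abs=1e-12)

    def test_zero_at_exact_cost_balance(self):
        """At the all-share corner the gap is v + k1 + k2 + k3 F - c."""
        params = PsychParams(v=0.4, k1=0.3, k2=0.2, k3=0.1)
        c = 0.4 + 0.3 + 0.2 + 0.1 * 1.0
        got = action_utility_gap(1.0, 1.0, c, params, Authority(G=1, F=1))
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_pure_material_cost(self):
        got = action_utility_gap(0.3, 0.9, 1.7, PsychParams(), Authority())
        assert got == pytest.approx(-1.7, abs=1e-15)

    def test_equals_utility_difference(self, rng):
        """Gap identity: du == u(x=1) - u(x=0) with pi(1)=-c, V(1)=y."""
        for _ in range(1000):
            params, auth = _random_setting(rng)
            y, xbar = rng.random(2)
            c = rng.normal()
            u1 = utility(1.0, y, xbar, -c, y, params, auth)
            u0 = utility(0.0, y, xbar, 0.0, 0.0, params, auth)
            got = action_utility_gap(y, xbar, c, params, auth)
            assert got == pytest.approx(u1 - u0, abs=1e-12)

    @given(y=unit, xbar=unit, G=unit, c=st.floats(-2, 2),
           k1=weight, k2=weight, k3=weight, F=weight)
    @settings(max_examples=200, derandomize=True)
    def test_antisymmetry_without_normative_value(self, y, xbar, G, c, k1, k2, k3, F):
        """With v = 0, relabelling the two actions flips the gap's sign."""
        params = PsychParams(k1=k1, k2=k2, k3=k3)
        fwd = action_utility_gap(y, xbar, c, params, Authority(G=G, F=F))
        rev = action_utility_gap(1 - y, 1 - xbar, -c, params,
                                 Authority(G=1 - G, F=F))
        assert fwd == pytest.approx(-rev, abs=1e-10)


class TestChooseBinary:
    @pytest.mark.parametrize("lam", [0.0, 1.0, 10.0])
    @pytest.mark.parametrize("du", [-0.5, 0.0, 0.1])
    def test_empirical_frequency_matches_logistic(self, rng, lam, du):
        n = 100_000
        noise = NoiseSpec(lam=lam, sigma=0.0, u_y=1.0)
        draws = choose_binary(np.full(n, du), noise, rng)
        p = expit(lam * du)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(draws.mean() - p) < 3 * max(se, 1e-12)

    def test_deterministic_limit(self, rng):
        noise = NoiseSpec(lam=np.inf, sigma=0.0, u_y=1.0)
        assert choose_binary(np.full(100, -0.5), noise, rng).sum() == 0
        assert choose_binary(np.full(100, 0.5), noise, rng).sum() == 100

    def test_tie_at_zero_gap_is_fair_coin(self, rng):
        noise = NoiseSpec(lam=np.inf, sigma=0.0, u_y=1.0)
        freq = choose_binary(np.zeros(100_000), noise, rng).mean()
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / 100_000)

    def test_scalar_input_gives_python_int(self, rng):
        out = choose_binary(0.3, NoiseSpec(lam=5, sigma=0, u_y=1), rng)
        assert out in (0, 1)


class TestUpdateAttitude:
    def _det_noise(self):
        return NoiseSpec(lam=np.inf, sigma=0.0, u_y=1.0)

    def test_worked_example(self, rng):
        params = PsychParams(alpha=0.1, beta=0.1, gamma=0.1)
        got = update_attitude(0.5, 1.0, 0.5, params, Authority(G=1, F=1),
                              self._det_noise(), rng)
        assert got == pytest.approx(0.6, abs=1e-12)

    def test_constant_attitude_limit(self, rng):
        """alpha = beta = gamma = 0 freezes attitudes (classic reduction)."""
        params = PsychParams()
        for y in (0.0, 0.37, 1.0):
            got = update_attitude(y, 1.0, 0.2, params, Authority(),
                                  self._det_noise(), rng)
            assert got == y

    def test_clipping_contract(self):
        """A forced positive perturbation cannot push y above 1."""

        class ForcedRng:
            def random(self, size=None):
                return np.zeros(size)  # gate always fires

            def normal(self, loc, scale, size=None):
                return np.full(size, 0.5)  # +0.5 perturbation before sigma

        params = PsychParams(alpha=1, beta=1, gamma=1)
        noise = NoiseSpec(lam=np.inf, sigma=1.0, u_y=1.0)
        got = update_attitude(0.99, 1.0, 1.0, params, Authority(G=1, F=1),
                              noise, ForcedRng())
        assert got == 1.0

    def test_no_action_omits_dissonance_pull(self, rng):
        """x=None applies only the peer and authority pulls."""
        params = PsychParams(alpha=0.5, beta=0.2, gamma=0.1)
        auth = Authority(G=1.0, F=1.0)
        y = 0.4
        got = update_attitude(y, None, 0.8, params, auth, self._det_noise(), rng)
        expected = y + 0.2 * (0.8 - y) + 0.1 * (1.0 - y)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_acted_mask(self, rng):
        params = PsychParams(alpha=0.5, beta=0.0, gamma=0.0)
        y = np.array([0.4, 0.4])
        got = update_attitude(y, np.array([1.0, 1.0]), 0.0, params, Authority(),
                              self._det_noise(), rng,
                              acted=np.array([True, False]))
        assert got[0] == pytest.approx(0.7)
        assert got[1] == pytest.approx(0.4)

    def test_gate_probability(self, rng):
        """The update fires with probability u_y per round."""
        n = 50_000
        params = PsychParams(alpha=1.0)
        noise = NoiseSpec(lam=np.inf, sigma=0.0, u_y=0.3)
        y = np.full(n, 0.5)
        y2, updated, _ = update_attitude_detailed(
            y, np.ones(n), 0.5, params, Authority(G=0.5, F=0), noise, rng
        )
        assert abs(updated.mean() - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)
        assert np.all(y2[~updated] == 0.5)

    def test_contraction_fixed_point(self, rng):
        """Iterating with constant x, xbar converges to the weighted target."""
        for _ in range(50):
            a, b, g = rng.random(3) * 0.6
            F = rng.random() * 1.5
            params = PsychParams(alpha=a, beta=b, gamma=g)
            auth = Authority(G=rng.random(), F=F)
            x, xbar = rng.random(2)
            y = rng.random()
            noise = self._det_noise()
            for _ in range(2000):
                y = update_attitude(y, x, xbar, params, auth, noise, rng)
            denom = a + b + g * F
            expected = (a * x + b * xbar + g * F * auth.G) / denom
            assert y == pytest.approx(expected, abs=1e-9)

    @given(y=unit, x=unit, xbar=unit, a=weight, b=weight, g=weight,
           G=unit, F=weight, sigma=st.floats(0, 0.5))
    @settings(max_examples=200, derandomize=True)
    def test_result_always_in_unit_interval(self, y, x, xbar, a, b, g, G, F, sigma):
        params = PsychParams(alpha=a, beta=b, gamma=g)
        noise = NoiseSpec(lam=1.0, sigma=sigma, u_y=1.0)
        got = update_attitude(y, x, xbar, params, Authority(G=G, F=F),
                              noise, np.random.default_rng(0))
        assert 0.0 <= got <= 1.0
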