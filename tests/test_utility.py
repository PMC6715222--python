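import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smokesim as ss
from smokesim.population import AgentProfile, SmokingState
from smokesim.utility import SCENARIO_RANGE


def agent(state=SmokingState.NONE, o_cc=0.2, o_ec=0.2, freq_cc=0.0, freq_ec=0.0):
    return AgentProfile(0, 15.0, state, 0, o_cc, o_ec, freq_cc, freq_ec)


def params(**kw):
    base = dict(
        muCC=0.0, muEC=0.0, eta=0.0, phi=0.0, wPeer=0.0, wSoc=0.0,
        alphaPeerMix=0.5, gammaOpen=0.0, thetaCC=0.0, thetaEC=0.0,
        crossover=0.0, kappaDual=0.0, tasteScale=1.0,
    )
    base.update(kw)
    return ss.UtilityParameters(**base)


class TestPeerAndPopulationPrevalence:
    def test_mixed_close_friends(self, small_population):
        profiles, network, states = small_population
        network.closeFriends[0] = [1, 2, 3, 4]
        states.update({1: SmokingState.DUAL, 2: SmokingState.DUAL,
                       3: SmokingState.EC_ONLY, 4: SmokingState.NONE})
        assert ss.peer_prevalence(0, network, states) == (0.5, 0.75)

    def test_agent_without_close_friends(self, small_population):
        _, network, states = small_population
        network.closeFriends[0] = []
        assert ss.peer_prevalence(0, network, states) == (0.0, 0.0)

    def test_all_conventional_smoker_friends(self, small_population):
        _, network, states = small_population
        network.closeFriends[0] = [1, 2, 3, 4]
        states.update({i: SmokingState.CC_ONLY for i in (1, 2, 3, 4)})
        assert ss.peer_prevalence(0, network, states) == (1.0, 0.0)

    def test_unknown_agent_rejected(self, small_population):
        _, network, states = small_population
        with pytest.raises(KeyError):
            ss.peer_prevalence(10_000, network, states)

    def test_population_prevalence_counts_dual_in_both(self):
        states = dict(enumerate(
            [SmokingState.CC_ONLY] + [SmokingState.EC_ONLY] * 2
            + [SmokingState.DUAL] + [SmokingState.NONE] * 6
        ))
        pop_cc, pop_ec, frac = ss.population_prevalence(states)
        assert pop_cc == pytest.approx(0.2)
        assert pop_ec == pytest.approx(0.3)
        assert frac == pytest.approx([0.6, 0.1, 0.2, 0.1])

    def test_all_nonusers(self):
        pop_cc, pop_ec, frac = ss.population_prevalence({0: SmokingState.NONE})
        assert (pop_cc, pop_ec) == (0.0, 0.0)
        assert frac == pytest.approx([1, 0, 0, 0])

    def test_fractions_conserved_for_random_states(self):
        rng = np.random.default_rng(0)
        _, _, frac = ss.population_prevalence(rng.integers(0, 4, size=999))
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_state_map_rejected(self):
        with pytest.raises(ValueError):
            ss.population_prevalence({})


class TestDynamicOpenness:
    def test_zero_exposure_returns_base_openness(self):
        signals = ss.SocialSignals(0, 0, 0, 0)
        p = params(gammaOpen=0.5, crossover=0.1)
        assert ss.dynamic_openness(agent(o_cc=0.3, o_ec=0.4), signals, p) == (0.3, 0.4)

    def test_clamped_at_one(self):
        signals = ss.SocialSignals(0.5, 0.5, 0.5, 0.5)
        p = params(thetaCC=0.3, gammaOpen=1.0)
        o_cc, _ = ss.dynamic_openness(agent(o_cc=0.9), signals, p)
        assert o_cc == 1.0

    def test_crossover_raises_cc_openness_one_way(self):
        # exposure blends peer and population equally; EC exposure 0.3
        signals = ss.SocialSignals(peerCC=0.0, peerEC=0.4, popCC=0.0, popEC=0.2)
        p = params(alphaPeerMix=0.5, gammaOpen=0.5, crossover=0.3)
        o_cc, o_ec = ss.dynamic_openness(agent(o_cc=0.2, o_ec=0.2), signals, p)
        assert o_cc == pytest.approx(0.29)
        assert o_ec == pytest.approx(0.35)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        base=st.floats(0, 1), peer=st.floats(0, 1), pop=st.floats(0, 1),
        gamma=st.floats(0, 5), theta=st.floats(0, 0.3), chi=st.floats(0, 0.3),
    )
    def test_openness_always_in_unit_interval(self, base, peer, pop, gamma, theta, chi):
        signals = ss.SocialSignals(peer, peer, pop, pop)
        p = params(gammaOpen=gamma, thetaCC=theta, thetaEC=theta, crossover=chi)
        o_cc, o_ec = ss.dynamic_openness(agent(o_cc=base, o_ec=base), signals, p)
        assert 0.0 <= o_cc <= 1.0 and 0.0 <= o_ec <= 1.0


class TestAlternativeUtilities:
    def test_null_model_gives_zero_utilities(self):
        u = ss.alternative_utilities(agent(), ss.SocialSignals(0, 0, 0, 0), params())
        assert u == pytest.approx([0, 0, 0, 0])

    def test_single_taste_term_with_dual_cost(self):
        p = params(muCC=1.0, kappaDual=0.5)
        u = ss.alternative_utilities(agent(), ss.SocialSignals(0, 0, 0, 0), p,
                                     openness=(0.0, 0.0))
        assert u == pytest.approx([0.0, 1.0, 0.0, 0.5])

    def test_full_worked_example(self):
        # EC user under peer/societal EC prevalence with one-way crossover
        p = params(muCC=-1.0, muEC=-0.5, eta=0.8, wPeer=2.0, wSoc=1.0,
                   crossover=0.3, kappaDual=0.5)
        signals = ss.SocialSignals(peerCC=0.0, peerEC=0.4, popCC=0.0, popEC=0.2)
        u = ss.alternative_utilities(
            agent(state=SmokingState.EC_ONLY), signals, p, openness=(0.29, 0.35)
        )
        assert u == pytest.approx([0.0, -0.7, 1.65, 0.45])

    def test_no_crossover_decouples_cc_from_ec_prevalence(self):
        p = params(muCC=-1.0, wPeer=2.0, wSoc=1.0, crossover=0.0, gammaOpen=0.0)
        lo = ss.SocialSignals(0.1, 0.0, 0.1, 0.0)
        hi = ss.SocialSignals(0.1, 0.9, 0.1, 0.9)
        u_lo = ss.alternative_utilities(agent(), lo, p)
        u_hi = ss.alternative_utilities(agent(), hi, p)
        assert u_lo[1] == pytest.approx(u_hi[1])  # CC utility unchanged

    def test_negative_kappa_acts_as_complementarity(self):
        p = params(muCC=1.0, muEC=1.0, kappaDual=-0.5)
        u = ss.alternative_utilities(agent(), ss.SocialSignals(0, 0, 0, 0), p,
                                     openness=(0, 0))
        assert u[3] == pytest.approx(u[1] + u[2] + 0.5)


class TestChooseState:
    def test_equal_utilities_uniform_choice(self):
        rng = np.random.default_rng(0)
        draws = [ss.choose_state(np.zeros(4), 1.0, rng) for _ in range(20_000)]
        freq = np.bincount([int(d) for d in draws], minlength=4) / 20_000
        assert np.all(np.abs(freq - 0.25) < 3 * math.sqrt(0.25 * 0.75 / 20_000))

    def test_logit_closed_form_probability(self):
        # P(NONE) = e / (e + 3) for utilities (1, 0, 0, 0)
        rng = np.random.default_rng(1)
        n = 100_000
        u = np.array([1.0, 0.0, 0.0, 0.0])
        chosen = sum(ss.choose_state(u, 1.0, rng) == ss.SmokingState.NONE
                     for _ in range(n))
        p = math.e / (math.e + 3)
        assert abs(chosen / n - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_deterministic_argmax_with_tie_break_order(self):
        rng = np.random.default_rng(0)
        state = ss.choose_state(np.array([0.2, 0.2, 0.1, 0.0]), 0.0, rng)
        assert state == ss.SmokingState.NONE

    def test_nonfinite_utilities_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            ss.choose_state(np.array([np.nan, 0, 0, 0]), 1.0, rng)

    def test_monotonicity_in_utility(self):
        rng = np.random.default_rng(2)
        n = 30_000
        base = np.array([0.0, 0.5, -0.5, 0.2])
        p_low = sum(ss.choose_state(base, 1.0, rng) == ss.SmokingState.EC_ONLY
                    for _ in range(n)) / n
        boosted = base.copy()
        boosted[2] += 1.0
        p_high = sum(ss.choose_state(boosted, 1.0, rng) == ss.SmokingState.EC_ONLY
                     for _ in range(n)) / n
        assert p_high > p_low


def test_scenario_values_outside_study_range_warn():
    with pytest.warns(UserWarning, match="crossover"):
        params(crossover=0.5)
    with pytest.warns(UserWarning, match="thetaEC"):
        params(thetaEC=0.4)
    assert SCENARIO_RANGE == (0.0, 0.3)


def test_parameters_serialise_with_exact_field_names(default_params):
    d = default_params.to_dict()
    for key in ("muCC", "muEC", "eta", "phi", "wPeer", "wSoc", "alphaPeerMix",
                "gammaOpen", "thetaCC", "thetaEC", "crossover", "kappaDual",
                "tasteScale"):
        assert key in d
    assert ss.UtilityParameters.from_dict(d) == default_params
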