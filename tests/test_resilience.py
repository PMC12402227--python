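"""Weighted degrees, beta_eff, zone classification and the scalar R."""

import numpy as np
import pytest

from conftest import make_web, random_weighted_web
from ecotraits.errors import ConfigError, DegenerateNetworkError
from ecotraits.foodweb import Species, WebSeries
from ecotraits.resilience import (
    CONSERVATIVE_SCHEME,
    ResilienceThresholds,
    assess,
    beta_eff,
    classify_zone,
    resilience_scalar,
    resilience_trajectory,
    trajectory_frame,
    weighted_degrees,
)
from oracles import beta_eff_by_hand


class TestWeightedDegrees:
    def test_chain_flows(self, chain_web):
        s_in, s_out = weighted_degrees(chain_web)
        assert dict(s_in) == {"A": 1.0, "B": 2.0, "C": 0.0}
        assert dict(s_out) == {"A": 0.0, "B": 1.0, "C": 2.0}

    def test_totals_balance(self, rng):
        for _ in range(10):
            s_in, s_out = weighted_degrees(random_weighted_web(rng))
            assert s_in.sum() == pytest.approx(s_out.sum(), rel=1e-12)

    def test_linear_in_flows(self, chain_web):
        s_in, _ = weighted_degrees(chain_web)
        scaled = make_web([("A", "B", 10.0), ("B", "C", 20.0)])
        s_in10, _ = weighted_degrees(scaled)
        assert np.allclose(s_in10, 10 * s_in)

    def test_all_zero_flows_degenerate(self):
        with pytest.raises(DegenerateNetworkError):
            weighted_degrees(make_web([("A", "B", 0.0)]))


class TestBetaEff:
    def test_regular_web_beta_equals_mean_s(self):
        # 3-cycle with equal flows: every s_in = s_out = c, zero spread
        web = make_web([("A", "B", 2.0), ("B", "C", 2.0), ("C", "A", 2.0)])
        state = beta_eff(web)
        assert state.H == 0.0
        assert state.beta_eff == state.mean_s == 2.0

    def test_symmetric_two_values_closed_form(self):
        # per-node s_in = s_out with values {1, 3}:
        # <s> = 2, S = 1, H = 0.5, beta = <s^2>/<s> = 2.5
        web = make_web([("A", "B", 1.0), ("B", "A", 1.0), ("B", "B", 2.0)])
        state = beta_eff(web)
        assert state.mean_s == pytest.approx(2.0)
        assert state.S == pytest.approx(1.0)
        assert state.H == pytest.approx(0.5)
        assert state.beta_eff == pytest.approx(2.5)

    def test_matches_term_by_term_oracle(self, rng):
        for _ in range(50):
            web = random_weighted_web(rng, n=20)
            state = beta_eff(web)
            assert state.beta_eff == pytest.approx(
                beta_eff_by_hand(web), rel=1e-9
            )

    def test_symmetric_webs_hit_undirected_limit(self, rng):
        # when s_in = s_out for every node, beta = <s^2>/<s> exactly;
        # realised with pure cannibal loops, which make in = out by design
        for _ in range(5):
            flows = rng.lognormal(0.0, 1.0, 6)
            web = make_web([(f"s{i}", f"s{i}", float(f)) for i, f in enumerate(flows)])
            s_in, s_out = weighted_degrees(web)
            assert np.allclose(s_in, s_out)
            s = s_in.to_numpy()
            assert beta_eff(web).beta_eff == pytest.approx(
                (s**2).mean() / s.mean(), rel=1e-12
            )

    def test_scaling_linearity_and_s_invariance(self, rng):
        web = random_weighted_web(rng, n=15)
        scaled = make_web(
            [(l.predator, l.prey, 3.0 * l.consumption) for l in web.links],
            species=web.species,
        )
        a, b = beta_eff(web), beta_eff(scaled)
        assert b.beta_eff == pytest.approx(3 * a.beta_eff, rel=1e-9)
        assert b.mean_s == pytest.approx(3 * a.mean_s, rel=1e-12)
        assert b.H == pytest.approx(3 * a.H, rel=1e-9)
        assert b.S == pytest.approx(a.S, rel=1e-9)

    def test_symmetry_is_bounded(self, rng):
        for _ in range(20):
            state = beta_eff(random_weighted_web(rng))
            assert -1.0 - 1e-12 <= state.S <= 1.0 + 1e-12

    def test_exact_identity_beta_eq_mean_plus_sh(self, rng):
        for _ in range(20):
            state = beta_eff(random_weighted_web(rng))
            assert state.beta_eff == pytest.approx(
                state.mean_s + state.S * state.H, rel=1e-12, abs=1e-12
            )

    def test_too_small_web_degenerate(self):
        with pytest.raises(DegenerateNetworkError):
            beta_eff(make_web([("A", "A", 1.0)]))


class TestZones:
    thresholds = ResilienceThresholds(s_crit=1.0, h_crit=1.0, beta_crit=1.0)

    def _state(self, mean_s, H, beta):
        import pandas as pd

        from ecotraits.resilience import ResilienceState

        return ResilienceState(
            s_in=pd.Series(dtype=float),
            s_out=pd.Series(dtype=float),
            mean_s=mean_s,
            S=0.0,
            H=H,
            beta_eff=beta,
        )

    def test_above_both_axes_is_resilient(self):
        assert classify_zone(self._state(2.0, 2.0, 4.0), self.thresholds) == "resilient"

    def test_one_axis_below_is_partial(self):
        assert (
            classify_zone(self._state(0.5, 3.0, 2.0), self.thresholds)
            == "partially_resilient"
        )

    def test_below_frontier_is_non_resilient(self):
        assert (
            classify_zone(self._state(0.3, 0.3, 0.5), self.thresholds)
            == "non_resilient"
        )

    def test_frontier_wins_over_axis_test(self):
        # negative symmetry can push beta below the frontier even when both
        # axis thresholds are cleared; the frontier verdict dominates
        assert (
            classify_zone(self._state(1.5, 1.5, 0.8), self.thresholds)
            == "non_resilient"
        )

    def test_scaling_up_never_worsens_zone(self, rng):
        order = {"non_resilient": 0, "partially_resilient": 1, "resilient": 2}
        for _ in range(10):
            web = random_weighted_web(rng, n=10)
            scaled = make_web(
                [(l.predator, l.prey, 7.0 * l.consumption) for l in web.links],
                species=web.species,
            )
            z1 = classify_zone(beta_eff(web), self.thresholds)
            z2 = classify_zone(beta_eff(scaled), self.thresholds)
            assert order[z2] >= order[z1]

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            ResilienceThresholds(s_crit=-1.0)
        with pytest.raises(ConfigError):
            ResilienceThresholds(scheme={"resilient": 0.5, "partially_resilient": 0.8, "non_resilient": 1.0})


class TestScalar:
    def test_default_scheme(self):
        assert resilience_scalar("resilient") == 1.0
        assert resilience_scalar("partially_resilient") == 0.8
        assert resilience_scalar("non_resilient") == 0.5

    def test_conservative_scheme(self):
        assert resilience_scalar("resilient", CONSERVATIVE_SCHEME) == 1.0
        assert resilience_scalar("partially_resilient", CONSERVATIVE_SCHEME) == 0.5
        assert resilience_scalar("non_resilient", CONSERVATIVE_SCHEME) == 0.25

    def test_unknown_zone_raises(self):
        with pytest.raises(ConfigError):
            resilience_scalar("resilient", {"other": 1.0})


class TestTrajectory:
    def test_constant_series_constant_states(self):
        webs = [
            make_web([("A", "B", 2.0), ("B", "C", 1.0)], timestamp=t) for t in (1, 2, 3)
        ]
        states = resilience_trajectory(WebSeries(webs))
        betas = {s.beta_eff for s in states}
        assert len(betas) == 1
        assert [s.timestamp for s in states] == [1, 2, 3]

    def test_halving_flows_halves_density_until_non_resilient(self):
        thresholds = ResilienceThresholds(s_crit=1.0, h_crit=1.0, beta_crit=1.0)
        webs = [
            make_web(
                [("A", "B", 8.0 * 0.5**t), ("B", "C", 2.0 * 0.5**t)], timestamp=t
            )
            for t in range(8)
        ]
        states = resilience_trajectory(WebSeries(webs), thresholds)
        for earlier, later in zip(states, states[1:]):
            assert later.mean_s == pytest.approx(earlier.mean_s / 2)
        assert states[-1].zone == "non_resilient"

    def test_frame_has_one_row_per_snapshot(self):
        webs = [make_web([("A", "B", 1.0)], timestamp=t) for t in (1, 2)]
        frame = trajectory_frame(resilience_trajectory(WebSeries(webs)))
        assert list(frame.columns) == ["timestamp", "mean_s", "S", "H", "beta_eff", "zone", "R"]
        assert len(frame) == 2
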