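"""ODE construction, simulation, steady-state detection."""

import numpy as np
import pytest
from scipy.linalg import expm

from bayesmmi.model_space import (
    CandidateModel,
    InitiationScheme,
    RuleSpec,
    Topology,
)
from bayesmmi.popdyn import (
    SteadyStateCriteria,
    build_odes,
    check_steady_state,
    effective_rate,
    simulate,
    trajectory_frame,
)
from tests.conftest import make_candidate


class TestEffectiveRate:
    def test_saturated_effect_reaches_full_multiplier(self):
        # division at 0.469/day with a 5% supportive effect saturates at 0.493
        r = effective_rate(0.469, 1.05, effector_count=1e12, K=1000.0)
        assert r == pytest.approx(0.469 * 1.05, rel=1e-6)
        assert round(r, 3) == 0.492  # 0.49245/day at full saturation

    def test_no_effector_leaves_baseline(self):
        assert effective_rate(0.469, 1.05, 0.0, 1000.0) == 0.469

    def test_half_saturation(self):
        # at w = K the multiplier acts at half strength
        assert effective_rate(0.469, 1.05, 1000.0, 1000.0) == pytest.approx(
            0.469 * 1.025, abs=1e-12
        )

    @pytest.mark.parametrize("m", [0.5, 0.95, 1.0, 1.05, 3.0])
    def test_bounded_between_base_and_asymptote(self, m):
        base, K = 0.3, 500.0
        w = np.geomspace(1e-3, 1e9, 40)
        vals = np.array([effective_rate(base, m, wi, K) for wi in w])
        lo, hi = sorted((base, base * m))
        assert np.all(vals >= lo - 1e-12) and np.all(vals <= hi + 1e-12)
        assert np.all(np.diff(vals) >= -1e-12) if m >= 1 else np.all(np.diff(vals) <= 1e-12)


class TestBuildOdes:
    def test_single_division_rule_is_exponential_growth(self):
        cand = CandidateModel(
            topology=Topology(subtypes=("A",)),
            a2_class="not_present",
            rules=(RuleSpec(kind="division", subject="A"),),
            initiation=InitiationScheme(initiators=("A",)),
        )
        system = build_odes(cand, {"k_div_A": 0.469})
        dx = system.derivative(np.array([10.0]), {"k_div_A": 0.469})
        assert dx[0] == pytest.approx(0.469 * 10.0)

    def test_no_rules_is_stationary(self):
        cand = CandidateModel(
            topology=Topology(subtypes=("A", "Y")),
            a2_class="not_present",
            rules=(),
            initiation=InitiationScheme(initiators=("A", "Y")),
        )
        system = build_odes(cand, {})
        assert np.allclose(system.derivative(np.array([3.0, 7.0]), {}), 0.0)

    def test_transition_and_division_bookkeeping(self):
        # dA/dt = -t*A ; dY/dt = t*A + g*Y  (hand-derived mass action)
        rules = (
            RuleSpec(kind="transition", subject="A", target="Y", hierarchy="non_hierarchical"),
            RuleSpec(kind="division", subject="Y"),
        )
        cand = CandidateModel(
            topology=Topology(subtypes=("A", "Y")),
            a2_class="not_present",
            rules=rules,
            initiation=InitiationScheme(initiators=("A",)),
        )
        p = {"k_tr_A_Y": 0.2, "k_div_Y": 0.5}
        system = build_odes(cand, p)
        dx = system.derivative(np.array([10.0, 4.0]), p)
        assert dx[0] == pytest.approx(-0.2 * 10.0)
        assert dx[1] == pytest.approx(0.2 * 10.0 + 0.5 * 4.0)

    def test_missing_parameter_raises(self, ay_candidate):
        with pytest.raises(KeyError):
            build_odes(ay_candidate, {"k_div_A": 0.4})

    def test_transition_only_system_conserves_total(self, rng):
        cand = make_candidate(("A", "N", "Y"), transitions=[("A", "N"), ("N", "Y"), ("Y", "A")])
        # zero out division/death: transitions only
        p = {name: 0.0 for name in cand.parameter_names}
        for t in ("k_tr_A_N", "k_tr_N_Y", "k_tr_Y_A"):
            p[t] = rng.uniform(0.05, 0.5)
        system = build_odes(cand, p)
        for _ in range(5):
            x = rng.uniform(0, 100, size=3)
            assert system.derivative(x, p).sum() == pytest.approx(0.0, abs=1e-9)


class TestSimulate:
    def test_single_compartment_proportion_is_one(self):
        cand = CandidateModel(
            topology=Topology(subtypes=("A",)),
            a2_class="not_present",
            rules=(RuleSpec(kind="division", subject="A"),),
            initiation=InitiationScheme(initiators=("A",)),
        )
        p = {"k_div_A": 0.05}
        res = simulate(build_odes(cand, p), cand.initiation, SteadyStateCriteria(), p)
        assert res.steady_state_reached and res.valid
        assert np.allclose(res.proportions, 1.0)

    def test_symmetric_two_subtype_split(self):
        cand = make_candidate(("A", "Y"))
        p = {"k_div_A": 0.3, "k_die_A": 0.1, "k_div_Y": 0.3, "k_die_Y": 0.1}
        res = simulate(build_odes(cand, p), cand.initiation, SteadyStateCriteria(), p)
        assert res.steady_state_reached
        assert np.allclose(res.proportions, 0.5, atol=1e-9)

    def test_linear_final_proportions_match_dominant_eigenvector(self, rng):
        # eigen-decomposition oracle on random 3-subtype linear systems
        crit = SteadyStateCriteria()
        for _ in range(10):
            cand = make_candidate(
                ("A", "N", "Y"), transitions=[("A", "N"), ("N", "Y")], initiators=("A",)
            )
            p = {
                "k_div_A": rng.uniform(0.3, 0.45),
                "k_die_A": rng.uniform(0.01, 0.05),
                "k_div_N": rng.uniform(0.1, 0.2),
                "k_die_N": rng.uniform(0.01, 0.05),
                "k_div_Y": rng.uniform(0.01, 0.08),
                "k_die_Y": rng.uniform(0.005, 0.01),
                "k_tr_A_N": rng.uniform(0.02, 0.08),
                "k_tr_N_Y": rng.uniform(0.02, 0.08),
            }
            system = build_odes(cand, p)
            res = simulate(system, cand.initiation, crit, p)
            if not res.steady_state_reached:
                continue
            R = system.rate_matrix(p)
            lam, V = np.linalg.eig(R)
            v = np.real(V[:, np.argmax(np.real(lam))])
            v = np.abs(v) / np.abs(v).sum()
            final = res.proportions[:, -1]
            assert np.max(np.abs(final - v)) < 1e-3

    def test_matches_matrix_exponential(self, ay_candidate, ay_params, rng):
        system = build_odes(ay_candidate, ay_params)
        crit = SteadyStateCriteria(horizon_days=20.0, n_points=201)
        res = simulate(system, ay_candidate.initiation, crit, ay_params)
        R = system.rate_matrix(ay_params)
        x0 = np.array([100.0, 0.0])
        for i in (50, 120, 200):
            expected = expm(R * res.times[i]) @ x0
            assert np.allclose(res.counts[:, i], expected, rtol=1e-4)

    def test_nonlinear_path_agrees_with_linear_at_neutral_multiplier(self, ay_params):
        rules = (
            RuleSpec(kind="division", subject="A", effect_scheme="Y_only"),
            RuleSpec(kind="death", subject="A"),
            RuleSpec(kind="division", subject="Y"),
            RuleSpec(kind="death", subject="Y"),
            RuleSpec(kind="transition", subject="A", target="Y", hierarchy="non_hierarchical"),
        )
        cand = CandidateModel(
            topology=Topology(subtypes=("A", "Y")),
            a2_class="not_present",
            rules=rules,
            initiation=InitiationScheme(initiators=("A",)),
        )
        p = dict(ay_params)
        p["m_div_A"] = 1.0  # neutral multiplier: system is effectively linear
        p["K_div_A"] = 1000.0
        system_nl = build_odes(cand, p)
        assert system_nl.rate_matrix is None  # the effect forces the ODE path
        res_nl = simulate(system_nl, cand.initiation, SteadyStateCriteria(), p)
        lin = make_candidate(("A", "Y"), transitions=[("A", "Y")], initiators=("A",))
        res_lin = simulate(
            build_odes(lin, ay_params), lin.initiation, SteadyStateCriteria(), ay_params
        )
        assert np.allclose(res_nl.counts, res_lin.counts, rtol=1e-4)

    def test_proportions_sum_to_one(self, ay_candidate, ay_params):
        res = simulate(
            build_odes(ay_candidate, ay_params),
            ay_candidate.initiation,
            SteadyStateCriteria(),
            ay_params,
        )
        assert np.max(np.abs(res.proportions.sum(axis=0) - 1.0)) < 1e-8

    def test_overflow_guard_marks_failure(self):
        cand = CandidateModel(
            topology=Topology(subtypes=("A",)),
            a2_class="not_present",
            rules=(RuleSpec(kind="division", subject="A"),),
            initiation=InitiationScheme(initiators=("A",)),
        )
        p = {"k_div_A": 2.0}  # 100 * e^120 cells: far past the guard
        res = simulate(build_odes(cand, p), cand.initiation, SteadyStateCriteria(), p)
        assert res.failed and not res.valid

    def test_shrinking_tumor_is_invalid_but_not_failed(self):
        cand = make_candidate(("A", "Y"))
        p = {"k_div_A": 0.05, "k_die_A": 0.2, "k_div_Y": 0.05, "k_die_Y": 0.2}
        res = simulate(build_odes(cand, p), cand.initiation, SteadyStateCriteria(), p)
        assert not res.failed
        assert not res.valid  # fewer than 100 cells at the horizon

    def test_trajectory_frame_is_tidy(self, ay_candidate, ay_params):
        res = simulate(
            build_odes(ay_candidate, ay_params),
            ay_candidate.initiation,
            SteadyStateCriteria(n_points=11),
            ay_params,
        )
        df = trajectory_frame(res)
        assert set(df.columns) == {"time", "subtype", "count", "proportion"}
        assert len(df) == 2 * 11


class TestCheckSteadyState:
    def setup_method(self):
        self.crit = SteadyStateCriteria()
        self.times = self.crit.time_grid()

    def test_constant_trajectory_is_steady(self):
        props = np.vstack([np.full_like(self.times, 0.4), np.full_like(self.times, 0.6)])
        assert check_steady_state(self.times, props, self.crit)

    def test_ramp_in_final_window_is_not_steady(self):
        props = np.vstack([0.2 + 0.01 * self.times, 0.8 - 0.01 * self.times])
        assert not check_steady_state(self.times, props, self.crit)

    def test_slope_within_bound_is_steady(self):
        # final-window slope of 5e-5/day sits inside the +/-1e-4 bound
        props = np.vstack([0.3 + 5e-5 * self.times, 0.7 - 5e-5 * self.times])
        assert check_steady_state(self.times, props, self.crit)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            check_steady_state(self.times, np.ones((1, 10)), self.crit)
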