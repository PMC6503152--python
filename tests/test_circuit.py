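"""Circuit definition: populations, connectivity, state equations."""

import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from tcdcm.circuit import (
    ARCHITECTURE_TARGETS,
    CORTICAL_EDGES,
    Architecture,
    CircuitParameters,
    ModulationConfig,
    Population,
    build_connectivity,
    dynamics,
    make_spec,
    sigmoid,
    sigmoid_slope,
    POPULATIONS,
    POP_INDEX,
)


class TestPopulations:
    def test_exactly_six_with_fixed_polarity(self):
        assert len(POPULATIONS) == 6
        for name in ("SP", "MP", "DP", "REL"):
            assert Population(name).polarity == "excitatory"
        for name in ("II", "RET"):
            assert Population(name).polarity == "inhibitory"

    def test_structure_split(self):
        assert Population("REL").structure == "thalamus"
        assert Population("SP").structure == "cortex"
        with pytest.raises(ValueError):
            Population("XX")


class TestSigmoid:
    def test_zero_crossing_and_saturation(self):
        assert sigmoid(0.0, 2 / 3) == 0.0
        assert sigmoid(1e6, 2 / 3) == pytest.approx(0.5)
        assert sigmoid(-1e6, 2 / 3) == pytest.approx(-0.5)

    def test_matches_logistic_formula(self):
        # independent evaluation of the centred logistic at v=1, R=2/3
        expected = 1.0 / (1.0 + math.exp(-2.0 / 3.0)) - 0.5
        assert sigmoid(1.0, 2 / 3) == pytest.approx(expected, rel=1e-12)

    @given(
        v=st.floats(-50, 50),
        R=st.floats(0.05, 5.0),
    )
    def test_bounded_odd_monotone(self, v, R):
        s = sigmoid(v, R)
        assert -0.5 <= s <= 0.5
        assert sigmoid(-v, R) == pytest.approx(-s, abs=1e-12)
        if abs(R * v) < 30:  # away from floating-point saturation
            assert abs(s) < 0.5
            assert sigmoid(v + 0.5, R) > s

    def test_slope_is_derivative(self):
        v, R = 0.7, 1.2
        fd = (sigmoid(v + 1e-6, R) - sigmoid(v - 1e-6, R)) / 2e-6
        assert sigmoid_slope(v, R) == pytest.approx(fd, rel=1e-6)
        assert sigmoid_slope(0.0, R) == pytest.approx(R / 4)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            sigmoid(np.nan, 1.0)
        with pytest.raises(ValueError):
            sigmoid(1.0, 0.0)


class TestModelSpace:
    def test_nine_architectures(self):
        seen = [Architecture(a).tc_targets for a in range(1, 10)]
        assert len(seen) == 9
        assert set(seen[8]) == {"DP", "II"}
        assert ARCHITECTURE_TARGETS[6] == ("SP", "DP")
        with pytest.raises(ValueError):
            Architecture(10)

    @pytest.mark.parametrize(
        "mid,n_intrinsic,extrinsic",
        [(1, 2, True), (2, 2, True), (3, 1, True), (7, 3, True),
         (8, 0, True), (9, 2, False), (15, 3, False), (16, 0, False)],
    )
    def test_modulation_configs(self, mid, n_intrinsic, extrinsic):
        cfg = ModulationConfig(mid)
        assert len(cfg.intrinsic_motif) == n_intrinsic
        assert cfg.includes_extrinsic == extrinsic

    def test_modulated_edges_respect_architecture(self):
        # extrinsic modulation only includes thalamocortical edges that exist
        single = ModulationConfig(8).modulated_edges(Architecture(1))
        assert set(single) == {("DP", "REL"), ("DP", "RET"), ("REL", "SP")}
        null = ModulationConfig(16).modulated_edges(Architecture(9))
        assert null == ()

    def test_winning_configuration_has_eight_effects(self):
        spec = make_spec(9, 6)
        edges = set(spec.modulated_edges)
        assert len(edges) == 8
        assert {("SP", "MP"), ("MP", "SP"), ("REL", "RET"), ("RET", "REL")} <= edges
        assert {("DP", "REL"), ("DP", "RET"), ("REL", "DP"), ("REL", "II")} <= edges


class TestConnectivity:
    def test_fourteen_cortical_couplings(self, params):
        C, D, inp = build_connectivity(make_spec(1, 16), params)
        cort = [POP_INDEX[p] for p in ("SP", "MP", "DP", "II")]
        block = C[np.ix_(cort, cort)]
        assert np.count_nonzero(block) == 14

    def test_architecture9_thalamocortical_targets(self, params):
        C, _, _ = build_connectivity(make_spec(9, 16), params)
        rel = POP_INDEX["REL"]
        assert C[POP_INDEX["DP"], rel] > 0
        assert C[POP_INDEX["II"], rel] > 0
        assert C[POP_INDEX["SP"], rel] == 0

    def test_signs(self, params):
        C, _, _ = build_connectivity(make_spec(9, 16), params)
        ret, ii = POP_INDEX["RET"], POP_INDEX["II"]
        assert C[ret, ret] < 0  # reticular self-inhibition
        # edges out of inhibitory populations are negative
        for src in (ii, ret):
            col = C[:, src]
            assert np.all(col[col != 0] < 0)
        # all self-edges model local inhibition
        assert np.all(np.diag(C)[np.diag(C) != 0] < 0)

    def test_sign_pattern_invariant_under_rescaling(self, params, rng):
        spec = make_spec(9, 16)
        C1, _, _ = build_connectivity(spec, params)
        p2 = params.copy()
        p2.gamma_mmc = p2.gamma_mmc * np.exp(rng.normal(0, 0.5, 14))
        p2.gamma_tcr = p2.gamma_tcr * np.exp(rng.normal(0, 0.5, 3))
        p2.lam = p2.lam * np.exp(rng.normal(0, 0.5, 4))
        C2, _, _ = build_connectivity(spec, p2)
        assert np.array_equal(np.sign(C1), np.sign(C2))

    def test_delays_and_input_map(self, params):
        C, D, inp = build_connectivity(make_spec(9, 16), params)
        rel, dp = POP_INDEX["REL"], POP_INDEX["DP"]
        assert D[rel, dp] == pytest.approx(8e-3)  # corticothalamic
        assert D[dp, rel] == pytest.approx(8e-3)  # thalamocortical
        assert D[POP_INDEX["MP"], POP_INDEX["SP"]] == pytest.approx(1e-3)
        assert inp[POP_INDEX["MP"]] == 1 and inp[rel] == 1
        assert inp.sum() == 2

    def test_condition_effect_scales_multiplicatively(self, params):
        spec = make_spec(9, 6)
        p = params.copy()
        p.B = {("MP", "SP"): 0.5}
        CL, _, _ = build_connectivity(spec, p, "LB")
        CH, _, _ = build_connectivity(spec, p, "HB")
        i, j = POP_INDEX["SP"], POP_INDEX["MP"]
        assert CH[i, j] == pytest.approx(CL[i, j] * np.exp(0.5))
        # only the modulated edge moved (others have B=0 -> unchanged)
        CH[i, j] = CL[i, j]
        assert np.array_equal(CL, CH)

    def test_unmodulated_b_entry_rejected(self, params):
        p = params.copy()
        p.B = {("SP", "DP"): 0.3}  # not in configuration 6
        with pytest.raises(ValueError, match="not part of"):
            build_connectivity(make_spec(9, 6), p)


class TestDynamics:
    def test_origin_is_fixed_point_for_every_architecture(self, params):
        for a in range(1, 10):
            dx = dynamics(np.zeros(12), 0.0, make_spec(a, 16), params)
            assert np.all(dx == 0.0)

    def test_state_layout_voltage_then_velocity(self, params):
        # first six derivatives are the velocity block
        state = np.zeros(12)
        state[6:] = 1.0
        dx = dynamics(state, 0.0, make_spec(9, 16), params)
        assert np.allclose(dx[:6], 1.0)

    def test_impulse_response_peaks_at_time_constant(self):
        # nearly uncoupled mass: response to a brief kick is t e^{-t/T}
        p = CircuitParameters.defaults()
        p.gamma_mmc = np.full(14, 1e-9)
        p.gamma_tcr = np.full(3, 1e-9)
        p.lam = np.full(4, 1e-9)
        spec = make_spec(9, 16)
        T = p.time_constants[POP_INDEX["MP"]]

        x0 = np.zeros(12)
        x0[6 + POP_INDEX["MP"]] = 1.0  # impulse: unit initial velocity
        sol = solve_ivp(
            lambda t, x: dynamics(x, 0.0, spec, p),
            (0, 6 * T),
            x0,
            max_step=T / 50,
            dense_output=True,
        )
        t = np.linspace(0, 6 * T, 2000)
        v = sol.sol(t)[POP_INDEX["MP"]]
        assert t[np.argmax(v)] == pytest.approx(T, rel=0.02)

    def test_matches_independent_scalar_implementation(self, params, rng):
        spec = make_spec(9, 6)
        p = params.copy()
        p.B = {e: rng.normal(0, 0.2) for e in spec.modulated_edges}

        def oracle(state, drive, condition):
            # plain scalar re-implementation of the state equations
            C, D, inp = build_connectivity(spec, p, condition)
            T = p.time_constants
            R = p.slopes
            out = np.zeros(12)
            for j in range(6):
                out[j] = state[6 + j]
                syn = sum(
                    C[j, k] * (1 / (1 + np.exp(-R[k] * state[k])) - 0.5)
                    for k in range(6)
                )
                out[6 + j] = (
                    syn + inp[j] * drive - 2 * state[6 + j] - state[j] / T[j]
                ) / T[j]
            return out

        for cond in ("LB", "HB"):
            for _ in range(5):
                state = rng.normal(0, 0.5, 12)
                got = dynamics(state, 1.3, spec, p, condition=cond)
                assert np.allclose(got, oracle(state, 1.3, cond), rtol=1e-12)

    def test_contract_errors(self, params):
        spec = make_spec(1, 16)
        with pytest.raises(ValueError):
            dynamics(np.full(12, np.nan), 0.0, spec, params)
        bad = params.copy()
        bad.T_mmc[0] = -1.0
        with pytest.raises(ValueError):
            dynamics(np.zeros(12), 0.0, spec, bad)


class TestParameters:
    def test_defaults_match_published_priors(self, params):
        assert sorted(params.gamma_mmc) == sorted(
            [800.0] * 9 + [400.0] * 4 + [200.0]
        )
        assert np.all(params.gamma_tcr == 800.0)
        assert np.all(params.lam == 800.0)
        assert np.all(params.T_mmc == 8e-3) and np.all(params.T_tcr == 8e-3)
        assert params.R_mmc == pytest.approx(2 / 3)
        assert params.J.tolist() == [0.6, 0.2, 0.2]
        assert params.L == 1.0 and params.hE == 12.0
        assert params.d_intrinsic == 1e-3 and params.D_extrinsic == 8e-3

    def test_validation(self):
        with pytest.raises(ValueError):
            CircuitParameters(
                gamma_mmc=np.full(14, -1.0),
                gamma_tcr=np.full(3, 800.0),
                lam=np.full(4, 800.0),
                T_mmc=np.full(4, 8e-3),
                T_tcr=np.full(2, 8e-3),
            )

    def test_json_round_trip_preserves_units(self, params, tmp_path):
        p = params.copy()
        p.B = {("MP", "SP"): 0.25}
        d = p.to_dict()
        assert d["T_mmc_ms"] == [8.0, 8.0, 8.0, 8.0]  # milliseconds on disk
        assert d["D_extrinsic_ms"] == 8.0
        path = tmp_path / "params.json"
        p.to_json(path)
        q = CircuitParameters.from_json(path)
        assert np.array_equal(q.gamma_mmc, p.gamma_mmc)
        assert np.array_equal(q.T_mmc, p.T_mmc)  # back in seconds
        assert q.B == p.B
        # the file is plain JSON mirroring the prior table's names
        raw = json.loads(path.read_text())
        assert set(raw) >= {"gamma_mmc", "gamma_tcr", "lambda", "B", "J", "hE"}
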