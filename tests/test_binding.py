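import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camdecode.binding import (
    ACTIVE_INDEX,
    CAMTA_INDEX,
    IDX,
    BaseParameters,
    BindingModel,
    ReactionSpec,
    conservation_residual,
    derive_parameters,
    enumerate_species,
    equilibrium_oracle,
    simulate,
    steady_state,
    wegscheider_check,
)
from camdecode.signatures import CalciumTrace, PiecewiseSpec, make_piecewise


class TestEnumeration:
    def test_nineteen_species_apo_first_camta_last(self):
        names = enumerate_species()
        assert len(names) == 19
        assert names[0] == "M00"
        assert names[-1] == "X"
        assert len(set(names)) == 19

    def test_exactly_one_active_species(self):
        assert enumerate_species().count("M22X") == 1

    def test_ordering_is_stable(self):
        assert enumerate_species() == enumerate_species()


class TestDeriveParameters:
    def test_reaction_counts_by_kind(self, model):
        rx = model.reactions
        assert len(rx) == 33
        ca_free = [r for r in rx if r.ligand == "Ca" and not r.reactant.endswith("X")]
        ca_bound = [r for r in rx if r.ligand == "Ca" and r.reactant.endswith("X")]
        binding_rx = [r for r in rx if r.ligand == "CAMTA"]
        assert (len(ca_free), len(ca_bound), len(binding_rx)) == (12, 12, 9)

    def test_kd_is_koff_over_kon(self, model):
        for r in model.reactions:
            assert r.kd == pytest.approx(r.k_off / r.k_on, rel=1e-12)

    def test_apo_camta_binding_weakened_by_p(self, model):
        r15 = next(r for r in model.reactions if r.reaction_id == "R15")
        assert r15.kd == pytest.approx(1.2e-2, rel=1e-12)     # Kd(R14)/P
        assert r15.k_off == pytest.approx(1.2e-2, rel=1e-12)  # koff(R14)/(P*Q)

    def test_first_n_lobe_site_tightened_on_apo_camta(self, model):
        # the bound-layer counterpart of the first N-lobe site: Kd * P
        r23 = next(r for r in model.reactions
                   if r.reactant == "M00X" and r.product == "M10X")
        assert r23.reaction_id == "R23"
        assert r23.kd == pytest.approx(25.0 * 0.1, rel=1e-12)
        assert r23.k_on == pytest.approx(100.0)  # on-rate shared with free layer

    def test_second_c_lobe_site_equal_across_layers(self, model):
        r22 = next(r for r in model.reactions
                   if r.reactant == "M01X" and r.product == "M02X")
        assert r22.kd == pytest.approx(0.925, rel=1e-12)

    def test_first_c_lobe_site_on_apo_camta_from_cycle_closure(self, model):
        """Kd(M00X + Ca -> M01X) is forced by the detailed-balance loop
        apo <-> apo.X <-> 1C.X <-> 1C: brute-force product around the loop."""
        rmap = {(r.reactant, r.product): r for r in model.reactions}
        kd_loop = (
            rmap[("M00", "M00X")].kd          # apo binds CAMTA
            * rmap[("M00X", "M01X")].kd       # Ca onto apo.X (the derived edge)
            / (rmap[("M00", "M01")].kd * rmap[("M01", "M01X")].kd)
        )
        assert kd_loop == pytest.approx(1.0, rel=1e-12)
        assert rmap[("M00X", "M01X")].kd == pytest.approx(1.0, rel=1e-12)  # 10 * 0.1

    def test_all_nine_binding_reactions_share_loaded_affinity(self, model):
        kds = {r.reaction_id: r.kd for r in model.reactions if r.ligand == "CAMTA"}
        loaded = {k: v for k, v in kds.items() if k != "R15"}
        assert len(loaded) == 8
        assert all(v == pytest.approx(1.2e-3, rel=1e-12) for v in loaded.values())

    @pytest.mark.parametrize("bad", [
        dict(p=0.0), dict(p=1.5), dict(kc1=-1.0), dict(cam_total=0.0), dict(q=0.0),
    ])
    def test_invalid_base_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            BaseParameters(**bad)


class TestWegscheider:
    def test_default_network_thermodynamically_consistent(self, model):
        reports = wegscheider_check(model.reactions)
        assert len(reports) == 20  # 12 Ca x CAMTA squares + 8 lobe squares
        assert all(r.ok for r in reports)

    def test_injected_violation_detected(self, model):
        rx = [
            ReactionSpec(r.reaction_id, r.reactant, r.product, r.ligand,
                         r.kd * (2.0 if r.reaction_id == "R23" else 1.0), r.k_on)
            for r in model.reactions
        ]
        reports = wegscheider_check(rx)
        bad = [r for r in reports if not r.ok]
        assert bad and any("R23" in r.description for r in bad)

    def test_free_layer_lobe_squares_pass_by_hand_product(self, model):
        # lobe independence: e.g. Kd(R3)*Kd(R9) == Kd(R1)*Kd(R5) = 250
        rmap = {(r.reactant, r.product): r.kd for r in model.reactions}
        prod_nc = rmap[("M00", "M10")] * rmap[("M10", "M11")]
        prod_cn = rmap[("M00", "M01")] * rmap[("M01", "M11")]
        assert prod_nc == pytest.approx(prod_cn, rel=1e-12)
        assert prod_nc == pytest.approx(250.0, rel=1e-12)

    def test_dangling_species_reported(self, model):
        rx = list(model.reactions)
        rx[0] = ReactionSpec("R1", "M00", "M99", "Ca", 10.0, 4.0)
        with pytest.raises(ValueError, match="dangling|missing edge"):
            wegscheider_check(rx)


class TestRhs:
    def test_single_flux_hand_computation(self, model):
        """Apo-CaM 1 uM + free CAMTA 1 uM at 1 uM Ca: the only flux into M10
        is the first N-lobe on-step, kon * ca * [M00] = 100 uM/s."""
        y = np.zeros(19)
        y[IDX["M00"]] = 1.0
        y[CAMTA_INDEX] = 1.0
        dy = model.rhs(y, ca=1.0)
        assert dy[IDX["M10"]] == pytest.approx(100.0, rel=1e-12)

    def test_rhs_vanishes_at_equilibrium(self, model, control_state):
        dy = model.rhs(control_state, model.control_ca)
        assert np.max(np.abs(dy)) < 1e-9 * max(model.base.cam_total, 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_conservation_is_algebraic(self, seed):
        """CaM and CAMTA derivative sums vanish for arbitrary states."""
        rng = np.random.default_rng(seed)
        model = BindingModel()
        y = rng.uniform(0.0, 5.0, 19)
        ca = rng.uniform(0.0, 10.0)
        dy = model.rhs(y, ca)
        assert abs(dy[:18].sum()) < 1e-10
        assert abs(dy[9:18].sum() + dy[CAMTA_INDEX]) < 1e-10

    def test_jacobian_matches_finite_differences(self, model):
        rng = np.random.default_rng(0)
        y = rng.uniform(0.1, 2.0, 19)
        ca = 0.5
        J = model.jacobian(y, ca)
        eps = 1e-7
        for j in range(19):
            yp = y.copy(); yp[j] += eps
            ym = y.copy(); ym[j] -= eps
            col = (model.rhs(yp, ca) - model.rhs(ym, ca)) / (2 * eps)
            np.testing.assert_allclose(J[:, j], col, rtol=1e-5, atol=1e-4)


class TestSteadyState:
    def test_zero_calcium_limit_is_single_site_quadratic(self, model):
        """At ca = 0 only apo species remain and the apo-CaM / CAMTA partition
        solves the one-site binding quadratic at Kd(R15)."""
        y = steady_state(model, 0.0)
        loaded = [i for i, n in enumerate(enumerate_species())
                  if n not in ("M00", "M00X", "X")]
        assert np.max(y[loaded]) < 1e-12
        kd = model.base.kd_cam_camta / model.base.p
        cam_t, x_t = model.base.cam_total, model.base.camta_total
        # complex concentration from the quadratic for A + B <-> AB
        b = cam_t + x_t + kd
        complex_expected = (b - np.sqrt(b * b - 4 * cam_t * x_t)) / 2
        assert y[IDX["M00X"]] == pytest.approx(complex_expected, rel=1e-8)

    def test_matches_equilibrium_oracle(self, model):
        y_ode = steady_state(model, 0.1)
        y_or = equilibrium_oracle(model, 0.1)
        np.testing.assert_allclose(y_ode, y_or, rtol=1e-6, atol=1e-30)

    def test_active_complex_monotone_in_calcium(self, model):
        levels = [0.1 * 2**k for k in range(7)]  # 0.1 .. 6.4 uM
        m22x = [equilibrium_oracle(model, ca)[ACTIVE_INDEX] for ca in levels]
        assert np.all(np.diff(m22x) > 0)

    def test_oracle_zero_cam_limit(self):
        model = BindingModel(BaseParameters(cam_total=1e-12))
        y = equilibrium_oracle(model, 0.5)
        assert y[:18].sum() < 1e-11
        assert y[CAMTA_INDEX] == pytest.approx(model.base.camta_total, rel=1e-9)

    def test_low_occupancy_fourth_power_law(self, model):
        """For Ca far below every site Kd the ladder is unsaturated and a
        Ca fold f amplifies the active complex by ~f^4."""
        base_ca = 0.02
        y0 = equilibrium_oracle(model, base_ca)[ACTIVE_INDEX]
        for f in (1.5, 2.0):
            y1 = equilibrium_oracle(model, base_ca * f)[ACTIVE_INDEX]
            assert y1 / y0 == pytest.approx(f**4, rel=0.25)

    def test_negative_calcium_rejected(self, model):
        with pytest.raises(ValueError):
            steady_state(model, -0.1)
        with pytest.raises(ValueError):
            equilibrium_oracle(model, -0.1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("draw", range(8))
    def test_random_parameter_draws(self, draw):
        """ODE relaxation and partition-function equilibrium agree on random
        parameter/Ca draws (the module's central cross-check)."""
        rng = np.random.default_rng(1000 + draw)
        base = BaseParameters(
            kc1=rng.uniform(5, 20), kc2=rng.uniform(0.5, 2),
            kn1=rng.uniform(10, 50), kn2=rng.uniform(2, 10),
            kd_cam_camta=10 ** rng.uniform(-4, -2),
            p=rng.uniform(0.05, 1.0), q=10 ** rng.uniform(-1, 1),
            cam_total=rng.uniform(1, 50), camta_total=rng.uniform(1, 50),
        )
        model = BindingModel(base)
        ca = 10 ** rng.uniform(-2, 1)
        y_ode = steady_state(model, ca)
        y_or = equilibrium_oracle(model, ca)
        np.testing.assert_allclose(y_ode, y_or, rtol=1e-6,
                                   atol=1e-12 * base.cam_total)


class TestSimulate:
    def test_constant_control_trace_stays_flat(self, model, control_state):
        tr = CalciumTrace(np.array([0.0, 500.0]), np.array([0.1, 0.1]))
        t, Y = simulate(model, tr, t_out=np.linspace(0, 500, 51))
        np.testing.assert_allclose(
            Y, np.broadcast_to(control_state, Y.shape), rtol=1e-5, atol=1e-10
        )

    def test_step_trace_converges_to_new_steady_state(self, model):
        tr = CalciumTrace(np.array([0.0, 0.0, 4000.0]),
                          np.array([0.1, 0.52, 0.52]))
        t, Y = simulate(model, tr, t_out=np.linspace(0, 4000, 101))
        target = equilibrium_oracle(model, 0.52)
        np.testing.assert_allclose(Y[-1], target, rtol=1e-3, atol=1e-12)

    def test_conservation_along_square_wave(self, model, short_trace):
        t, Y = simulate(model, short_trace)
        assert conservation_residual(model, Y) < 1e-6

    def test_periodic_response_after_transient(self, model):
        spec = PiecewiseSpec(period=40.0, duration=400.0)
        tr = make_piecewise(spec)
        t_out = np.arange(0.0, 400.0, 0.5)
        t, Y = simulate(model, tr, t_out=t_out)
        m22x = Y[:, ACTIVE_INDEX]
        # compare the last two full cycles sample-by-sample
        per = int(40.0 / 0.5)
        a, b = m22x[-2 * per:-per], m22x[-per:]
        assert np.max(np.abs(a - b)) / np.max(m22x) < 0.02
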