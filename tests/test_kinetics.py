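"""Pointwise kinetics: flux laws, buffering, RyR gating."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from spinesim import kinetics as kin
from spinesim.kinetics import RyRGatingState
from spinesim.parameters import InfluxSpec, ModelParameters


@pytest.fixture(scope="module")
def p():
    return ModelParameters()


class TestBuffering:
    def test_equilibrium_free_buffer_closed_form(self, p):
        # 40 * 19 / (19 + 27 * 0.05)
        assert kin.equilibrium_free_buffer(p) == pytest.approx(37.34643734643734)

    def test_no_binding_limit(self, p):
        assert kin.equilibrium_free_buffer(p.replace(kb_plus=0.0)) == p.b_tot

    def test_saturation_limit(self, p):
        b0 = kin.equilibrium_free_buffer(p.replace(c_c0=1e9))
        assert b0 < 1e-5

    def test_rate_zero_at_equilibrium(self, p):
        b0 = kin.equilibrium_free_buffer(p)
        assert kin.buffer_reaction_rate(p.c_c0, b0, p) == pytest.approx(0.0, abs=1e-12)

    def test_pure_forward_binding(self, p):
        rate = kin.buffer_reaction_rate(0.5, p.b_tot, p)
        assert rate == pytest.approx(-p.kb_plus * p.b_tot * 0.5)

    def test_pure_release(self, p):
        assert kin.buffer_reaction_rate(0.0, 0.0, p) == pytest.approx(
            p.kb_minus * p.b_tot)

    def test_overfull_buffer_rejected(self, p):
        with pytest.raises(ValueError):
            kin.buffer_reaction_rate(0.05, p.b_tot * 1.01, p)


class TestMembraneFluxes:
    @pytest.mark.parametrize("c,expected", [
        (0.0, 0.0),
        (0.06, 4.25e-21),            # half-saturation: rho_p * I_p / 2
        (0.05, 3.4836065573770495e-21),
    ])
    def test_pmca(self, p, c, expected):
        assert kin.pmca_flux_density(c, p) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("c,expected", [
        (0.0, 0.0),
        (1.8, 1.875e-20),            # half-saturation: rho_N * I_N / 2
        (0.05, 1.0135135135135137e-21),
    ])
    def test_ncx(self, p, c, expected):
        assert kin.ncx_flux_density(c, p) == pytest.approx(expected, rel=1e-9)

    def test_fluxes_bounded_by_density_times_current(self, p):
        c = np.logspace(-3, 4, 50)
        assert np.all(kin.pmca_flux_density(c, p) < p.rho_p * p.I_p)
        assert np.all(kin.ncx_flux_density(c, p) < p.rho_N * p.I_N)

    def test_leaks(self, p):
        erm, pm = kin.leak_flux_densities(0.05, 250.0, p)
        assert erm == pytest.approx(38e-3 * 249.95e-21, rel=1e-9)
        # 4.5 nm/s * (2 mM - 50 nM) ~ 9.0e-21 mol s^-1 um^-2
        assert pm == pytest.approx(8.99977e-21, rel=1e-4)
        assert kin.leak_flux_densities(0.3, 0.3, p)[0] == 0.0
        assert kin.leak_flux_densities(p.c_o, 250.0, p)[1] == 0.0

    def test_calibrated_pm_leak_balances_pumps(self, p):
        v = kin.calibrate_pm_leak(p)
        # (3.4836e-21 + 1.0135e-21) / 2e-18 mol/um^3 = 2.2486e-3 um/s
        assert v == pytest.approx(2.2486e-3, rel=1e-3)
        extr = kin.pmca_flux_density(p.c_c0, p) + kin.ncx_flux_density(p.c_c0, p)
        leak = v * (p.c_o - p.c_c0) * 1e-21
        assert leak == pytest.approx(extr, rel=1e-12)

    def test_calibrated_leak_linearity_and_limit(self, p):
        v = kin.calibrate_pm_leak(p)
        doubled = kin.calibrate_pm_leak(p.replace(rho_p=2 * p.rho_p,
                                                  rho_N=2 * p.rho_N))
        assert doubled == pytest.approx(2 * v, rel=1e-12)
        assert kin.calibrate_pm_leak(p.replace(c_o=1e9)) < v / 1000


class TestRyR:
    def test_single_channel_reference(self, p):
        assert kin.ryr_single_channel_current(0.05, 250.05, p) == pytest.approx(
            p.IR_ref)
        assert kin.ryr_single_channel_current(1.0, 1.0, p) == 0.0
        assert kin.ryr_single_channel_current(0.05, 250.0, p) == pytest.approx(
            3.4993e-18, rel=1e-6)

    def test_fully_closed_state_dynamics(self, p):
        """With all occupancy in c1 (o1 = 0), the o2 and c2 channels are
        frozen; c1 itself drains at the calcium-driven activation rate and
        is stationary only at zero calcium."""
        st8 = RyRGatingState(c1=1.0, o2=0.0, c2=0.0)
        dc1, do2, dc2 = kin.ryr_gating_rhs(st8, 7.3, p)
        assert do2 == pytest.approx(0.0, abs=1e-15)
        assert dc2 == pytest.approx(0.0, abs=1e-15)
        assert dc1 == pytest.approx(-p.ka_plus * 7.3**4, rel=1e-12)
        dc1_0, _, _ = kin.ryr_gating_rhs(st8, 0.0, p)
        assert dc1_0 == 0.0

    def test_zero_calcium_o2_decay(self, p):
        st8 = RyRGatingState(c1=0.2, o2=0.3, c2=0.1)
        _, do2, _ = kin.ryr_gating_rhs(st8, 0.0, p)
        assert do2 == pytest.approx(-p.kb_minus_ryr * 0.3)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
           st.floats(1e-3, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_probability_conservation(self, c1, o2, c2, c):
        tot = c1 + o2 + c2
        if tot > 1:
            c1, o2, c2 = c1 / tot, o2 / tot, c2 / tot
        p = ModelParameters()
        dc1, do2, dc2 = kin.ryr_gating_rhs(RyRGatingState(c1, o2, c2), c, p)
        do1 = -dc1 - do2 - dc2  # derivative of o1 via the constraint
        assert dc1 + do2 + dc2 + do1 == pytest.approx(0.0, abs=1e-9)

    def test_steady_state_is_rhs_root(self, p):
        for c in (0.01, 0.05, 1.0, 50.0):
            ss = kin.ryr_steady_state(c, p)
            scale = 1.0 + p.ka_plus * c**4  # fastest rate in the system
            for d in kin.ryr_gating_rhs(ss, c, p):
                assert abs(float(d)) < 1e-12 * scale

    def test_steady_state_against_ode_relaxation(self, p):
        """Brute-force: integrate the gating ODEs at fixed calcium until
        stationary and compare with the closed-form steady state."""
        c = 0.05

        def rhs(_, y):
            return kin.ryr_gating_rhs(RyRGatingState(*y), c, p)

        sol = solve_ivp(rhs, (0, 2000.0), [0.4, 0.1, 0.1], method="BDF",
                        rtol=1e-10, atol=1e-14)
        ss = kin.ryr_steady_state(c, p)
        assert sol.y[0, -1] == pytest.approx(float(ss.c1), rel=1e-5)
        assert sol.y[1, -1] == pytest.approx(float(ss.o2), rel=1e-3, abs=1e-12)
        assert sol.y[2, -1] == pytest.approx(float(ss.c2), rel=1e-5)

    def test_closed_at_zero_calcium_limit(self, p):
        ss = kin.ryr_steady_state(1e-6, p)
        assert float(ss.c1) > 0.999
        assert float(ss.open_probability) < 1e-3

    def test_open_probability_nondecreasing_in_calcium(self, p):
        c = np.logspace(-2, 2, 200)
        po = np.array([float(kin.ryr_steady_state(x, p).open_probability)
                       for x in c])
        assert np.all(np.diff(po) >= -1e-12)
        assert po[-1] > 0.9

    def test_flux_density_composition(self, p):
        ss = RyRGatingState(c1=0.0, o2=1.0, c2=0.0)  # fully open
        j = kin.ryr_flux_density(ss, 0.05, 250.0, 2.0, p)
        assert j == pytest.approx(2.0 * 3.4993e-18, rel=1e-6)
        assert kin.ryr_flux_density(ss, 0.05, 250.0, 0.0, p) == 0.0
        assert kin.ryr_flux_density(ss, 300.0, 250.0, 2.0, p) < 0


class TestSynapticInflux:
    def test_triangle_pulse(self, p):
        spec = InfluxSpec(j_peak=8.6e-18, tau=0.010)
        assert kin.synaptic_influx_density(0.0, spec, 1.0) == pytest.approx(8.6e-18)
        assert kin.synaptic_influx_density(0.005, spec, 1.0) == pytest.approx(4.3e-18)
        assert kin.synaptic_influx_density(0.010, spec, 1.0) == pytest.approx(0.0)
        assert kin.synaptic_influx_density(0.02, spec, 1.0) == 0.0

    def test_total_ions_closed_form(self):
        spec = InfluxSpec(j_peak=8.6e-18, tau=0.010)
        # 0.5 * 8.6e-18 * 0.01 * 1.0 * N_A
        assert kin.total_influx_ions(spec, 1.0) == pytest.approx(
            25895.2, rel=1e-4)
        assert kin.total_influx_ions(
            InfluxSpec(j_peak=8.6e-18, tau=1e-12), 1.0) < 1e-5

    def test_psd_adjusted_total_invariant(self):
        spec = InfluxSpec(mode="psd_adjusted", j_peak=8.6e-18, tau=0.010,
                          reference_psd_area=0.09)
        ref = kin.total_influx_ions(spec, 0.09)
        for area in (0.01, 0.09, 0.5, 3.0):
            assert kin.total_influx_ions(spec, area) == pytest.approx(ref)

    def test_psd_adjusted_rejects_bad_area(self):
        spec = InfluxSpec(mode="psd_adjusted", j_peak=1e-18, tau=0.01,
                          reference_psd_area=0.09)
        with pytest.raises(ValueError):
            spec.effective_peak(0.0)


def test_table_defaults_roundtrip_serialization(p):
    q = ModelParameters.from_json(p.to_json())
    assert q == p
    q = ModelParameters.from_yaml(p.to_yaml())
    assert q == p
    assert q.content_hash() == p.content_hash()
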