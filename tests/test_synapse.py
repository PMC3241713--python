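"""Short-term plasticity recursion, Mg block and conductance kernels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mgbsim import (PlasticityState, SynapseParams, event_scale_update,
                    event_scales, nmda_mg_block, synaptic_conductance,
                    synaptic_current)
from mgbsim.synapse import kernel_peak_norm


def scales_for_train(times, mode, component, params=None):
    params = (params or SynapseParams()).replace(plasticity_mode=mode)
    sa, sn = event_scales(np.asarray(times, float), params)
    return sa if component == "AMPA" else sn


class TestPlasticityRecursion:
    def test_mode_none_always_unity(self):
        s = scales_for_train([0, 10, 20, 500], "None", "AMPA")
        assert np.allclose(s, 1.0)

    def test_ppd_recovers_at_long_interval(self):
        st_ = PlasticityState()
        event_scale_update(st_, 1.0, "PPD", "AMPA")  # first event
        st_.t_last = 0.0
        scale = event_scale_update(st_, math.inf, "PPD", "AMPA")
        assert scale == pytest.approx(1.0)

    def test_paired_pulse_ratios_match_hand_recursion(self):
        p = SynapseParams()
        # second-pulse amplitude: 1 + (f - 1) * exp(-isi / tau)
        for isi in (25.0, 50.0):
            ppd = scales_for_train([0.0, isi], "PPD", "AMPA")
            expected = 1.0 + (p.f_dep - 1.0) * math.exp(-isi / p.tau_rec_dep)
            assert ppd[1] == pytest.approx(expected)
            assert ppd[1] < 1.0
            ppf = scales_for_train([0.0, isi], "PPF", "AMPA")
            expected_f = 1.0 + (p.f_fac - 1.0) * math.exp(-isi / p.tau_rec_fac)
            assert ppf[1] == pytest.approx(expected_f)
            assert ppf[1] > 1.0
        ppf25 = scales_for_train([0.0, 25.0], "PPF", "AMPA")[1]
        ppf50 = scales_for_train([0.0, 50.0], "PPF", "AMPA")[1]
        assert ppf25 > ppf50

    def test_depression_persists_100_200_ms(self):
        # a single conditioning pulse still depresses the response at
        # 100-200 ms but has mostly recovered by 500 ms
        at100 = scales_for_train([0.0, 100.0], "PPD", "AMPA")[1]
        at200 = scales_for_train([0.0, 200.0], "PPD", "AMPA")[1]
        at500 = scales_for_train([0.0, 500.0], "PPD", "AMPA")[1]
        assert at100 < 0.8
        assert at200 < 0.9
        assert at500 > 0.95

    def test_mixed_dispatches_by_component(self):
        sa = scales_for_train([0.0, 25.0], "Mixed", "AMPA")
        sn = scales_for_train([0.0, 25.0], "Mixed", "NMDA")
        assert sa[1] < 1.0 < sn[1]

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError, match="PPD"):
            event_scale_update(PlasticityState(), 10.0, "bogus", "AMPA")

    @settings(deadline=None, max_examples=40)
    @given(isi=st.floats(min_value=1.0, max_value=200.0))
    def test_constant_train_converges_monotonically(self, isi):
        """PPD non-increasing to a fixed point, PPF non-decreasing; the
        fixed point depends only on the interval, not the initial state."""
        times = np.arange(60) * isi
        dep = scales_for_train(times, "PPD", "AMPA")
        fac = scales_for_train(times, "PPF", "AMPA")
        assert np.all(np.diff(dep) <= 1e-12)
        assert np.all(np.diff(fac) >= -1e-12)
        assert np.all(dep > 0) and np.all(dep <= 1.0)
        assert np.all(fac >= 1.0)
        assert np.all(fac <= SynapseParams().fac_cap + 1e-12)
        # restart from the tail: same fixed point
        assert dep[-1] == pytest.approx(dep[-2], rel=1e-6)

    def test_shorter_isi_stronger_steady_state_effect(self):
        def fp(mode, isi):
            return scales_for_train(np.arange(200) * isi, mode, "AMPA")[-1]
        assert fp("PPD", 5.0) < fp("PPD", 20.0) < fp("PPD", 100.0)
        assert fp("PPF", 5.0) >= fp("PPF", 20.0) >= fp("PPF", 100.0)


class TestMgBlock:
    def test_hyperpolarized_block(self):
        assert nmda_mg_block(-100.0) < 0.1

    def test_monotone_increasing(self):
        assert nmda_mg_block(-40.0) > nmda_mg_block(-70.0)
        v = np.linspace(-120, 40, 500)
        assert np.all(np.diff(nmda_mg_block(v)) > 0)

    def test_half_block_voltage(self):
        v_half = -math.log(3.57) / 0.062
        assert nmda_mg_block(v_half) == pytest.approx(0.5, rel=1e-12)

    def test_limits(self):
        assert nmda_mg_block(-300.0) < 1e-6
        assert nmda_mg_block(300.0) > 1 - 1e-6


class TestConductanceKernels:
    def test_no_events(self):
        g_a, g_n = synaptic_conductance([0.0, 10.0], [], SynapseParams())
        assert np.all(g_a == 0) and np.all(g_n == 0)

    def test_kernel_decays_to_zero(self):
        p = SynapseParams()
        g_a, g_n = synaptic_conductance(500.0, [(0.0, 1.0, 1.0)], p)
        assert g_a[0] < 1e-6 and g_n[0] < 1e-3

    def test_single_event_peaks(self):
        p = SynapseParams(g_ampa_max=16.0, nmda_ampa_ratio=0.5,
                          nmda_scale=1.5)
        t = np.linspace(0, 300, 60001)
        g_a, g_n = synaptic_conductance(t, [(0.0, 1.0, 1.0)], p)
        assert g_a.max() == pytest.approx(16.0, rel=1e-4)
        assert g_n.max() == pytest.approx(16.0 * 0.5 * 1.5, rel=1e-4)

    def test_two_event_superposition_matches_closed_form(self):
        """Below receptor saturation the response to two pulses equals the
        sum of shifted single-pulse kernels."""
        p = SynapseParams(g_ampa_max=2.0, nmda_ampa_ratio=0.5,
                          plasticity_mode="None")
        t = np.linspace(0.0, 300.0, 6001)
        # AMPA superposes exactly at any spacing
        g_a, _ = synaptic_conductance(t, [(0.0, 1.0, 1.0),
                                          (25.0, 1.0, 1.0)], p)
        a1, _ = synaptic_conductance(t, [(0.0, 1.0, 1.0)], p)
        a2, _ = synaptic_conductance(t, [(25.0, 1.0, 1.0)], p)
        assert np.allclose(g_a, a1 + a2, atol=1e-12)
        # NMDA superposes exactly below the receptor-saturation bound
        _, g_n = synaptic_conductance(t, [(0.0, 1.0, 1.0),
                                          (80.0, 1.0, 1.0)], p)
        _, n1 = synaptic_conductance(t, [(0.0, 1.0, 1.0)], p)
        _, n2 = synaptic_conductance(t, [(80.0, 1.0, 1.0)], p)
        assert np.allclose(g_n, n1 + n2, atol=1e-12)

    def test_nmda_receptor_saturation_bounds_accumulation(self):
        p = SynapseParams(g_ampa_max=2.0, nmda_ampa_ratio=2.0,
                          plasticity_mode="None")
        cap = p.nmda_sat_mult * p.g_ampa_max * p.nmda_ampa_ratio
        events = [(k * 5.0, 1.0, 1.0) for k in range(100)]
        _, g_n = synaptic_conductance(np.linspace(0, 500, 2000), events, p)
        assert g_n.max() <= cap + 1e-12

    def test_unsorted_events_raise(self):
        with pytest.raises(ValueError):
            synaptic_conductance(0.0, [(10.0, 1, 1), (0.0, 1, 1)],
                                 SynapseParams())

    def test_peak_normalization_is_exact(self):
        rise, decay = 0.6, 2.0
        tp = rise * decay / (decay - rise) * math.log(decay / rise)
        peak = math.exp(-tp / decay) - math.exp(-tp / rise)
        assert kernel_peak_norm(rise, decay) == pytest.approx(1.0 / peak)


class TestSynapticCurrent:
    def test_reversal(self):
        assert synaptic_current(0.0, 5.0, 5.0) == 0.0

    def test_zero_conductance(self):
        assert synaptic_current(-60.0, 0.0, 0.0) == 0.0

    def test_ohmic_value(self):
        # 1 nS * -60 mV = -0.06 nA
        assert synaptic_current(-60.0, 1.0, 0.0) == pytest.approx(-0.06)

    def test_inward_below_reversal_and_mg_blocked(self):
        i_with_nmda = synaptic_current(-60.0, 1.0, 10.0)
        assert i_with_nmda < synaptic_current(-60.0, 1.0, 0.0) < 0
        # at -60 mV the NMDA contribution is mostly blocked
        assert abs(i_with_nmda) < abs(synaptic_current(-60.0, 11.0, 0.0))

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            synaptic_current(-60.0, -1.0, 0.0)
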