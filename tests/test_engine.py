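"""Integration engine: calibration, firing modes, determinism, refinement."""

import numpy as np
import pytest

from mgbsim import (CalibrationError, MembraneParams, Protocol, StimulusSpec,
                    SynapseParams, calibrate_bias, find_rest,
                    measure_input_resistance, run_trials, simulate)
from mgbsim.ic_inputs import InputStream


class TestRestingState:
    def test_rest_is_stable_for_one_second(self, mp):
        res = simulate(mp, t_stop=1500.0, v0=-70.0)
        dt = res.dt
        tail = res.v[int(500.0 / dt):]
        rest = tail[-1]
        assert np.all(np.abs(tail - rest) < 0.5)
        assert res.spike_times.size == 0

    def test_dt_refinement_of_resting_potential(self, mp):
        v1 = find_rest(mp, dt=0.02)
        v2 = find_rest(mp, dt=0.01)
        assert abs(v1 - v2) < 0.01

    def test_gates_stay_bounded_during_strong_drive(self, mp, stim100):
        syn = SynapseParams(g_ampa_max=20.0, nmda_ampa_ratio=3.0,
                            plasticity_mode="None")
        streams = [InputStream(0, np.arange(250.0, 600.0, 5.0), stim100)]
        res = simulate(mp, t_stop=700.0, v0=-60.0,
                       bias=calibrate_bias(mp, -60.0),
                       streams=streams, synapses=[syn])
        assert np.all(np.isfinite(res.v))
        assert res.v.max() < 80.0 and res.v.min() > -150.0

    def test_subthreshold_iv_relation_monotone(self, mp):
        """Steady-state voltage grows monotonically with bias current in
        the subthreshold range."""
        vs = []
        for bias in (-0.1, -0.05, 0.0, 0.05):
            res = simulate(mp, t_stop=600.0, v0=-68.0, bias=bias)
            vs.append(np.nanmean(res.v[-2500:]))
        assert np.all(np.diff(vs) > 0)


class TestBiasCalibration:
    def test_rest_needs_no_bias(self, mp):
        rest = find_rest(mp)
        bias = calibrate_bias(mp, round(rest, 2))
        assert abs(bias) < 0.01

    def test_sign_of_bias(self, mp):
        rest = find_rest(mp)
        assert calibrate_bias(mp, -55.0) > 0
        assert calibrate_bias(mp, -75.0) < 0
        assert rest > -75.0

    @pytest.mark.parametrize("target", [-55.0, -65.0, -75.0])
    def test_holding_potentials_achievable(self, mp, target):
        bias = calibrate_bias(mp, target)
        res = simulate(mp, t_stop=400.0, v0=target, bias=bias)
        assert abs(np.nanmean(res.v[-2500:]) - target) < 0.5

    def test_unreachable_target_raises(self, mp):
        with pytest.raises(CalibrationError):
            calibrate_bias(mp, -20.0)


class TestFiringModes:
    def test_depolarizing_step_gives_tonic_train(self, mp):
        rest = find_rest(mp)
        res = simulate(mp, t_stop=900.0, v0=rest, pulse=(0.3, 200.0, 500.0))
        in_pulse = res.spike_times[(res.spike_times >= 200)
                                   & (res.spike_times <= 700)]
        assert in_pulse.size >= 4
        # sustained, not onset-only: spikes span most of the pulse
        assert in_pulse.max() - in_pulse.min() > 250.0

    def test_hyperpolarizing_release_gives_offset_burst(self, mp):
        rest = find_rest(mp)
        res = simulate(mp, t_stop=1100.0, v0=rest,
                       pulse=(-0.3, 200.0, 500.0))
        burst = res.spike_times[(res.spike_times >= 700)
                                & (res.spike_times <= 750)]
        assert burst.size >= 2
        # the doublet is complete within ~15 ms of its first spike
        assert burst[-1] - burst[0] < 30.0
        # no spiking while hyperpolarized
        assert np.sum((res.spike_times > 250) & (res.spike_times < 700)) == 0


class TestInputResistance:
    def test_input_resistance_near_75_mohm(self, mp):
        r = measure_input_resistance(mp)
        assert r == pytest.approx(75.0, rel=0.15)

    def test_resistance_scales_inversely_with_area(self, mp):
        r0 = measure_input_resistance(mp)
        r2 = measure_input_resistance(mp.replace(area=2 * mp.area))
        assert r2 == pytest.approx(r0 / 2, rel=0.02)


class TestTrials:
    def protocol(self, mp, **kw):
        kw.setdefault("stimulus", StimulusSpec(ici=25.0, duration=500.0))
        kw.setdefault("preset", "Large")
        kw.setdefault("n_trials", 3)
        kw.setdefault("seed", 9)
        return Protocol(kind="synaptic", membrane=mp, **kw)

    def test_reproducible_spike_sets(self, mp):
        a = run_trials(self.protocol(mp))
        b = run_trials(self.protocol(mp))
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.spike_times, rb.spike_times)

    def test_trials_have_distinct_inputs(self, mp):
        results = run_trials(self.protocol(mp))
        t0 = tuple(results[0].input_streams[0].spike_times)
        t1 = tuple(results[1].input_streams[0].spike_times)
        assert t0 != t1

    def test_fifty_trials_supported(self, mp):
        prot = self.protocol(mp, n_trials=50,
                             stimulus=StimulusSpec(ici=100.0, duration=500.0))
        results = run_trials(prot)
        assert len(results) == 50
        seeds = {r.seed for r in results}
        assert len(seeds) == 50

    def test_traces_dropped_unless_requested(self, mp):
        res = run_trials(self.protocol(mp))[0]
        assert res.v is None
        res = run_trials(self.protocol(mp, save_traces=True))[0]
        assert res.v is not None

    def test_protocol_validation(self, mp):
        with pytest.raises(ValueError):
            Protocol(kind="synaptic", membrane=mp, stimulus=None)
        with pytest.raises(ValueError):
            Protocol(kind="synaptic", membrane=mp,
                     stimulus=StimulusSpec(ici=10.0), settle_time=50.0)


class TestDtRefinement:
    def test_spike_times_shift_under_0p1_ms_when_dt_halved(self, mp):
        """Halving the step from the default 0.02 ms moves every spike by
        less than 0.1 ms (step-size convergence oracle)."""
        spec = StimulusSpec(ici=50.0, duration=300.0, onset=200.0, seed=2)
        syn = SynapseParams(g_ampa_max=16.0, nmda_ampa_ratio=0.5,
                            plasticity_mode="None")
        from mgbsim.ic_inputs import generate_stream
        streams = [generate_stream(spec, 0, 0)]
        bias = calibrate_bias(mp, -60.0)
        r1 = simulate(mp, t_stop=520.0, dt=0.02, v0=-60.0, bias=bias,
                      streams=streams, synapses=[syn])
        r2 = simulate(mp, t_stop=520.0, dt=0.01, v0=-60.0, bias=bias,
                      streams=streams, synapses=[syn])
        assert r1.spike_times.size == r2.spike_times.size > 0
        assert np.max(np.abs(r1.spike_times - r2.spike_times)) < 0.1

    def test_rk4_reference_agrees_on_resting_potential(self, mp):
        r_euler = simulate(mp, t_stop=400.0, v0=-70.0, method="euler")
        r_rk4 = simulate(mp, t_stop=400.0, v0=-70.0, method="rk4")
        assert abs(r_euler.v[-1] - r_rk4.v[-1]) < 0.05
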