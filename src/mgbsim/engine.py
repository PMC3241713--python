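"""Simulation protocols: integration, calibration and multi-trial runs.

Unit conventions across the package: mV, ms, nA, nS, uF/cm2; the membrane
``area`` (cm2) converts conductance densities to absolute conductances.
Integration uses a fixed step (default dt = 0.02 ms) with a semi-implicit
update for V and exponential Euler for the gates; an RK4 reference path
is available through ``method="rk4"`` for refinement checks.

A bias current holds the membrane at a requested pre-stimulus potential
(found by bisection and cached per parameter set); the bias is applied
from t = 0, at least 200 ms before any synaptic stimulation, so the
intrinsic conductances reach steady state first.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import _core
from .ic_inputs import (InputStream, StimulusSpec, generate_stream,
                        make_population)
from .membrane import MembraneParams, steady_gates
from .metrics import detect_spikes
from .synapse import SynapseParams, event_scales, kernel_peak_norm

__all__ = [
    "Protocol",
    "TrialResult",
    "CalibrationError",
    "simulate",
    "find_rest",
    "measure_input_resistance",
    "calibrate_bias",
    "calibrate_area",
    "run_trials",
]

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """Raised when no stable bias holds the membrane at the target."""


def pack_params(mp: MembraneParams) -> np.ndarray:
    p = np.empty(_core.N_PARAMS)
    p[_core.P_GNA] = mp.g_na
    p[_core.P_GKDR] = mp.g_kdr
    p[_core.P_GA] = mp.g_a
    p[_core.P_GK2] = mp.g_k2
    p[_core.P_GNAP] = mp.g_nap
    p[_core.P_GH] = mp.g_h
    p[_core.P_GLEAK] = mp.g_leak
    p[_core.P_PCAT] = mp.p_cat
    p[_core.P_PCAL] = mp.p_cal
    p[_core.P_ENA] = mp.e_na
    p[_core.P_EK] = mp.e_k
    p[_core.P_ELEAK] = mp.e_leak
    p[_core.P_EH] = mp.e_h
    p[_core.P_CM] = mp.c_m
    p[_core.P_AREA] = mp.area
    p[_core.P_CAI] = mp.ca_i
    p[_core.P_CAO] = mp.ca_o
    p[_core.P_TEMP] = mp.temperature
    p[_core.P_VSHIFT] = mp.vshift
    return p


@dataclass
class Protocol:
    """One simulation protocol (current clamp or synaptic drive)."""

    kind: str = "synaptic"              # "synaptic" | "current_clamp"
    dt: float = 0.02
    settle_time: float = 200.0
    stimulus: StimulusSpec | None = None
    preset: str | None = None
    plasticity_mode: str | None = None
    nmda_scale: float = 1.0
    synapse: SynapseParams | None = None  # explicit single-stream synapse
    target_vm: float | None = -60.0
    bias_current: float | None = None
    pulse_amp: float = 0.0              # nA (current_clamp)
    pulse_dur: float = 500.0
    tail: float = 30.0
    n_trials: int = 10
    seed: int = 0
    save_traces: bool = False
    membrane: MembraneParams = field(default_factory=MembraneParams)

    def __post_init__(self) -> None:
        if self.kind not in ("synaptic", "current_clamp"):
            raise ValueError("kind must be 'synaptic' or 'current_clamp'")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.target_vm is not None and self.settle_time < 200.0:
            raise ValueError("settle_time must be >= 200 ms when holding a "
                             "target membrane potential")
        if self.kind == "synaptic" and self.stimulus is None:
            raise ValueError("synaptic protocols need a StimulusSpec")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def onset(self) -> float:
        return self.settle_time

    @property
    def total_duration(self) -> float:
        if self.kind == "synaptic":
            return self.settle_time + self.stimulus.duration + self.tail
        return self.settle_time + self.pulse_dur + 200.0

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class TrialResult:
    """Output of one integrated trial."""

    dt: float
    n_steps: int
    onset: float
    spike_times: np.ndarray           # absolute ms
    input_streams: list = field(default_factory=list)
    v: np.ndarray | None = None
    seed: tuple = ()
    status: int = 0
    protocol_hash: str = ""

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt

    @property
    def input_spike_times(self) -> list[np.ndarray]:
        return [s.spike_times for s in self.input_streams]


def _build_events(streams: list[InputStream], synapses: list[SynapseParams],
                  dt: float):
    """Snap stream events to the grid and attach plasticity weights (nS).

    Returns (grid steps, stream index, AMPA weight, NMDA weight, per-stream
    NMDA saturation caps).
    """
    steps, sidx, wa, wn, caps = [], [], [], [], []
    for i, (stream, syn) in enumerate(zip(streams, synapses)):
        times = stream.spike_times
        sa, sn = event_scales(times, syn)
        steps.append(np.rint(times / dt).astype(np.int64))
        sidx.append(np.full(times.size, i, dtype=np.int64))
        wa.append(syn.g_ampa_max * sa)
        wn.append(syn.g_ampa_max * syn.nmda_ampa_ratio * syn.nmda_scale * sn)
        caps.append(syn.nmda_sat_mult * syn.g_ampa_max
                    * syn.nmda_ampa_ratio * syn.nmda_scale)
    if not steps:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                np.empty(0), np.empty(0), np.ones(1))
    steps = np.concatenate(steps)
    sidx = np.concatenate(sidx)
    wa = np.concatenate(wa)
    wn = np.concatenate(wn)
    order = np.argsort(steps, kind="stable")
    return steps[order], sidx[order], wa[order], wn[order], np.asarray(caps)


def simulate(mp: MembraneParams, *, t_stop: float, dt: float = 0.02,
             v0: float | None = None, bias: float = 0.0,
             pulse: tuple[float, float, float] | None = None,
             streams: list[InputStream] | None = None,
             synapses: list[SynapseParams] | None = None,
             method: str = "euler", record: bool = True) -> TrialResult:
    """Integrate one trial and detect output spikes.

    ``pulse`` is ``(amplitude_nA, start_ms, duration_ms)``; ``streams``
    and ``synapses`` are parallel lists of input trains and their synapse
    parameters.  ``v0`` defaults to the leak reversal; gates start at
    steady state for ``v0``.
    """
    streams = streams or []
    synapses = synapses or []
    if len(streams) != len(synapses):
        raise ValueError("streams and synapses must pair up")
    v0 = mp.e_leak if v0 is None else v0
    gates0 = steady_gates(v0, mp).values
    n_steps = int(round(t_stop / dt))
    evt_step, evt_stream, evt_wa, evt_wn, caps = _build_events(
        streams, synapses, dt)
    syn = synapses[0] if synapses else SynapseParams()
    if pulse is not None:
        amp, start, dur = pulse
        p_start = int(round(start / dt))
        p_end = int(round((start + dur) / dt))
    else:
        amp, p_start, p_end = 0.0, 0, 0
    v_out, gates, status, n_done = _core.run_trial(
        float(v0), gates0, pack_params(mp), float(dt), n_steps,
        evt_step, evt_stream, evt_wa, evt_wn, caps,
        syn.ampa_rise, syn.ampa_decay, syn.nmda_rise, syn.nmda_decay,
        kernel_peak_norm(syn.ampa_rise, syn.ampa_decay),
        kernel_peak_norm(syn.nmda_rise, syn.nmda_decay),
        syn.mg_mM, float(bias), float(amp), p_start, p_end,
        0 if method == "euler" else 1)
    if status != _core.STATUS_OK:
        logger.warning("integration left voltage rails at t = %.2f ms",
                       n_done * dt)
    t = np.arange(n_steps + 1) * dt
    spikes = detect_spikes(t, v_out)
    return TrialResult(dt=dt, n_steps=n_steps, onset=0.0,
                       spike_times=spikes, input_streams=streams,
                       v=v_out if record else None, status=status)


def find_rest(mp: MembraneParams, t_settle: float = 1000.0,
              dt: float = 0.02, v0: float = -70.0) -> float:
    """Free resting potential: no input, no bias, settled for ``t_settle``."""
    res = simulate(mp, t_stop=t_settle, dt=dt, v0=v0)
    return float(np.nanmean(res.v[-int(50.0 / dt):]))


_bias_cache: dict = {}


def _mp_key(mp: MembraneParams) -> tuple:
    return tuple(dataclasses.astuple(mp))


def calibrate_bias(mp: MembraneParams, target_vm: float, *,
                   dt: float = 0.02, settle: float = 400.0,
                   tol_nA: float = 0.001) -> float:
    """Bias current (nA) holding the membrane at ``target_vm``.

    Found by bisection; results are cached per (parameters, target).
    Raises :class:`CalibrationError` if the settled potential spikes or
    will not converge to the target (no stable fixed point there).
    """
    key = (_mp_key(mp), round(target_vm, 6), dt)
    if key in _bias_cache:
        return _bias_cache[key]

    def settled(bias: float):
        res = simulate(mp, t_stop=settle, dt=dt, v0=target_vm, bias=bias)
        if res.status != _core.STATUS_OK:
            # ran off the voltage rails: report the rail it hit so the
            # bisection still sees a monotone response
            finite = res.v[np.isfinite(res.v)]
            return float(finite[-1]), res
        tail = res.v[-int(50.0 / dt):]
        return float(np.nanmean(tail)), res

    lo, hi = -0.5, 0.5
    v_lo, _ = settled(lo)
    v_hi, _ = settled(hi)
    for _ in range(4):
        if v_lo > target_vm:
            lo *= 2.0
            v_lo, _ = settled(lo)
        if v_hi < target_vm:
            hi *= 2.0
            v_hi, _ = settled(hi)
    if not (v_lo <= target_vm <= v_hi):
        raise CalibrationError(
            f"target {target_vm} mV outside achievable range "
            f"[{v_lo:.1f}, {v_hi:.1f}] mV")
    while hi - lo > tol_nA:
        mid = 0.5 * (lo + hi)
        v_mid, _ = settled(mid)
        if v_mid < target_vm:
            lo = mid
        else:
            hi = mid
    bias = 0.5 * (lo + hi)
    v_fin, res = settled(bias)
    if res.spike_times.size:
        raise CalibrationError(
            f"membrane spikes spontaneously near {target_vm} mV; "
            "no stable holding point")
    if abs(v_fin - target_vm) > 0.5:
        raise CalibrationError(
            f"bias calibration settled at {v_fin:.2f} mV, "
            f"> 0.5 mV from target {target_vm} mV")
    _bias_cache[key] = bias
    return bias


def measure_input_resistance(mp: MembraneParams, v_hold: float = -60.0,
                             step_nA: float = -0.02, dt: float = 0.02
                             ) -> float:
    """Input resistance (MOhm) from small current steps at ``v_hold``."""
    bias = calibrate_bias(mp, v_hold, dt=dt)
    settle, dur = 400.0, 400.0
    res = simulate(mp, t_stop=settle + dur, dt=dt, v0=v_hold, bias=bias,
                   pulse=(step_nA, settle, dur))
    i0 = int((settle - 50.0) / dt)
    i1 = int(settle / dt)
    base = float(np.nanmean(res.v[i0:i1]))
    tail = float(np.nanmean(res.v[-int(50.0 / dt):]))
    return (tail - base) / step_nA  # mV / nA = MOhm


def calibrate_area(mp: MembraneParams, target_mohm: float = 75.0,
                   v_hold: float = -60.0) -> MembraneParams:
    """Rescale the membrane area so R_in(v_hold) hits ``target_mohm``.

    With uniform densities the input resistance is exactly inversely
    proportional to area, so a single measurement suffices.
    """
    r = measure_input_resistance(mp, v_hold=v_hold)
    return mp.replace(area=mp.area * r / target_mohm)


def run_trials(protocol: Protocol) -> list[TrialResult]:
    """Run all trials of a protocol; trial k is individually reproducible.

    Input streams for trial k derive from the (protocol seed, k, stream)
    counter, so results do not depend on execution order.
    """
    mp = protocol.membrane
    if protocol.bias_current is not None:
        bias = protocol.bias_current
    elif protocol.target_vm is not None:
        bias = calibrate_bias(mp, protocol.target_vm, dt=protocol.dt)
    else:
        bias = 0.0
    v0 = protocol.target_vm if protocol.target_vm is not None else mp.e_leak
    results = []
    phash = protocol.hash()
    for k in range(protocol.n_trials):
        if protocol.kind == "current_clamp":
            res = simulate(mp, t_stop=protocol.total_duration,
                           dt=protocol.dt, v0=v0, bias=bias,
                           pulse=(protocol.pulse_amp, protocol.settle_time,
                                  protocol.pulse_dur),
                           record=True)
        else:
            spec = protocol.stimulus.replace(onset=protocol.settle_time,
                                             seed=protocol.seed)
            if protocol.preset is not None:
                streams, synapses = make_population(
                    protocol.preset, spec, trial_index=k,
                    plasticity_mode=protocol.plasticity_mode,
                    nmda_scale=protocol.nmda_scale)
            else:
                syn = protocol.synapse or SynapseParams()
                if protocol.plasticity_mode is not None:
                    syn = syn.replace(plasticity_mode=protocol.plasticity_mode)
                syn = syn.replace(nmda_scale=protocol.nmda_scale)
                streams = [generate_stream(spec, stream_index=i,
                                           trial_index=k)
                           for i in range(spec.n_streams)]
                synapses = [syn] * len(streams)
            res = simulate(mp, t_stop=protocol.total_duration,
                           dt=protocol.dt, v0=v0, bias=bias,
                           streams=streams, synapses=synapses,
                           record=protocol.save_traces)
        res.onset = protocol.settle_time
        res.seed = (protocol.seed, k)
        res.protocol_hash = phash
        if not protocol.save_traces:
            res.v = None
        results.append(res)
    return results
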