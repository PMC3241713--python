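"""AMPA + NMDA synaptic conductances with short-term plasticity.

Each input stream drives one synapse consisting of an AMPA and an NMDA
component.  Both components are difference-of-exponential conductance
kernels normalized to unit peak, so the peak conductance of a single
naive event is ``g_ampa_max`` for AMPA and
``g_ampa_max * nmda_ampa_ratio * nmda_scale`` for NMDA (before the
voltage-dependent Mg2+ block).

Short-term plasticity is a multiplicative resource model in the style of
Varela et al.: each presynaptic event multiplies a running amplitude
scale by a factor ``f`` (f < 1 depression, f > 1 facilitation) and the
scale relaxes exponentially back toward 1 between events.  Four regimes
are supported:

* ``None``  : both components always at scale 1,
* ``PPD``   : both components depress,
* ``PPF``   : both components facilitate,
* ``Mixed`` : AMPA depresses while NMDA facilitates (the regime observed
  for small-terminal IC inputs).

The plasticity state of every stream is independent: it depends only on
the event times of that stream.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLASTICITY_MODES",
    "SynapseParams",
    "PlasticityState",
    "event_scale_update",
    "event_scales",
    "nmda_mg_block",
    "kernel_peak_norm",
    "synaptic_conductance",
    "synaptic_current",
]

PLASTICITY_MODES = ("None", "PPD", "PPF", "Mixed")


@dataclass
class SynapseParams:
    """Kinetic and plasticity constants of one synaptic input stream.

    Conductances in nS, time constants in ms.  ``plasticity_mode`` is one
    of ``PLASTICITY_MODES``; in ``Mixed`` mode the AMPA component uses the
    depression constants and the NMDA component the facilitation
    constants.
    """

    g_ampa_max: float = 16.0
    nmda_ampa_ratio: float = 0.5
    ampa_rise: float = 0.6
    ampa_decay: float = 2.0
    nmda_rise: float = 8.0
    nmda_decay: float = 40.0
    e_syn: float = 0.0
    plasticity_mode: str = "None"
    # per-event multiplicative factor and recovery time constant
    f_dep: float = 0.45
    tau_rec_dep: float = 150.0
    f_fac: float = 1.2
    tau_rec_fac: float = 150.0
    fac_cap: float = 2.0
    nmda_scale: float = 1.0
    mg_mM: float = 1.0
    # NMDA receptor-pool saturation: the summed NMDA conductance of one
    # stream cannot exceed this multiple of its single-event peak
    # (math.inf disables saturation).
    nmda_sat_mult: float = 1.4

    def __post_init__(self) -> None:
        if self.g_ampa_max < 0 or self.nmda_ampa_ratio < 0:
            raise ValueError("conductances and ratios must be non-negative")
        if self.plasticity_mode not in PLASTICITY_MODES:
            raise ValueError(
                f"unknown plasticity mode {self.plasticity_mode!r}; "
                f"valid modes: {PLASTICITY_MODES}")
        if not (0 < self.f_dep <= 1):
            raise ValueError("f_dep must lie in (0, 1]")
        if self.f_fac < 1:
            raise ValueError("f_fac must be >= 1")
        for name in ("ampa_rise", "ampa_decay", "nmda_rise", "nmda_decay",
                     "tau_rec_dep", "tau_rec_fac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ampa_rise >= self.ampa_decay or self.nmda_rise >= self.nmda_decay:
            raise ValueError("rise time constants must be shorter than decay")

    def replace(self, **kw) -> "SynapseParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynapseParams":
        return cls(**d)

    def component_constants(self, component: str) -> tuple[float, float]:
        """(f, tau_rec) governing ``component`` under the current mode."""
        mode = self.plasticity_mode
        if component not in ("AMPA", "NMDA"):
            raise ValueError("component must be 'AMPA' or 'NMDA'")
        if mode == "None":
            return 1.0, self.tau_rec_dep
        if mode == "PPD":
            return self.f_dep, self.tau_rec_dep
        if mode == "PPF":
            return self.f_fac, self.tau_rec_fac
        # Mixed: AMPA depresses, NMDA facilitates
        if component == "AMPA":
            return self.f_dep, self.tau_rec_dep
        return self.f_fac, self.tau_rec_fac


@dataclass
class PlasticityState:
    """Running amplitude scale of one component of one stream."""

    scale: float = 1.0
    t_last: float | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("amplitude scale must be positive")


def event_scale_update(state: PlasticityState, isi: float, mode: str,
                       component: str, params: SynapseParams | None = None
                       ) -> float:
    """Amplitude scale applied to an event arriving ``isi`` ms after the last.

    The state first recovers exponentially toward 1 over ``isi``; the
    recovered value is the scale applied to the incoming event; the event
    then multiplies the stored scale by the per-event factor ``f``
    (bounded above by ``fac_cap`` for facilitation).  ``isi = inf`` (or a
    state with no previous event) yields a fully recovered scale of 1.
    """
    if isi <= 0:
        raise ValueError("inter-spike interval must be positive")
    params = params or SynapseParams(plasticity_mode=mode if mode in
                                     PLASTICITY_MODES else "None")
    if mode not in PLASTICITY_MODES:
        raise ValueError(f"unknown plasticity mode {mode!r}; valid modes: "
                         f"{PLASTICITY_MODES}")
    params = params.replace(plasticity_mode=mode)
    f, tau = params.component_constants(component)
    if state.t_last is None or math.isinf(isi):
        recovered = 1.0
    else:
        recovered = 1.0 + (state.scale - 1.0) * math.exp(-isi / tau)
    state.scale = min(recovered * f, params.fac_cap)
    return recovered


def event_scales(times: np.ndarray, params: SynapseParams
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-event amplitude scales for both components of one stream.

    ``times`` must be sorted.  Returns ``(ampa_scales, nmda_scales)``
    aligned with ``times``; the first event of a naive stream has scale 1.
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("event times must be sorted")
    out = []
    for component in ("AMPA", "NMDA"):
        f, tau = params.component_constants(component)
        scales = np.empty_like(times)
        a = 1.0
        for i, t in enumerate(times):
            if i > 0:
                a = 1.0 + (a - 1.0) * math.exp(-(t - times[i - 1]) / tau)
            scales[i] = a
            a = min(a * f, params.fac_cap)
        out.append(scales)
    return out[0], out[1]


def nmda_mg_block(v, mg_mM: float = 1.0):
    """Voltage-dependent Mg2+ block of the NMDA conductance, in (0, 1).

    Jahr & Stevens sigmoid: ``1 / (1 + [Mg] * exp(-0.062 V) / 3.57)``.
    Monotonically increasing in V; the half-block voltage at 1 mM Mg2+ is
    ``-ln(3.57)/0.062`` (about -20.5 mV).
    """
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + mg_mM * np.exp(-0.062 * v) / 3.57)
    return float(out) if out.ndim == 0 else out


def kernel_peak_norm(rise: float, decay: float) -> float:
    """Normalization so a unit-weight dual-exponential kernel peaks at 1."""
    tp = rise * decay / (decay - rise) * math.log(decay / rise)
    return 1.0 / (math.exp(-tp / decay) - math.exp(-tp / rise))


def _kernel(t, rise: float, decay: float):
    """Unit-peak dual-exponential kernel evaluated at times >= 0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0,
                   np.exp(-np.maximum(t, 0) / decay)
                   - np.exp(-np.maximum(t, 0) / rise), 0.0)
    return out * kernel_peak_norm(rise, decay)


def synaptic_conductance(t, events, params: SynapseParams
                         ) -> tuple[np.ndarray, np.ndarray]:
    """(g_AMPA, g_NMDA) in nS at time(s) ``t`` by superposition over events.

    ``events`` is a sequence of ``(event_time, ampa_scale, nmda_scale)``
    sorted by time.  The NMDA conductance is returned before Mg2+ block;
    it superposes linearly up to the receptor-saturation bound
    ``nmda_sat_mult`` times the single-event peak, above which it clips.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    g_a = np.zeros_like(t)
    g_n = np.zeros_like(t)
    last = -np.inf
    for (te, sa, sn) in events:
        if te < last:
            raise ValueError("events must be sorted by time")
        last = te
        g_a += params.g_ampa_max * sa * _kernel(t - te, params.ampa_rise,
                                                params.ampa_decay)
        g_n += (params.g_ampa_max * params.nmda_ampa_ratio
                * params.nmda_scale * sn
                * _kernel(t - te, params.nmda_rise, params.nmda_decay))
    cap = (params.nmda_sat_mult * params.g_ampa_max
           * params.nmda_ampa_ratio * params.nmda_scale)
    g_n = np.minimum(g_n, cap)
    return g_a, g_n


def synaptic_current(v, g_ampa, g_nmda, e_syn: float = 0.0,
                     mg_mM: float = 1.0):
    """Total synaptic current in nA: ``(gA + gN * B(V)) * (V - E_syn)``.

    Conductances in nS, voltage in mV; negative (inward) for V < E_syn.
    """
    g_ampa = np.asarray(g_ampa, dtype=float)
    g_nmda = np.asarray(g_nmda, dtype=float)
    if np.any(g_ampa < 0) or np.any(g_nmda < 0):
        raise ValueError("conductances must be non-negative")
    i = (g_ampa + g_nmda * nmda_mg_block(v, mg_mM)) * (np.asarray(v) - e_syn)
    i = i * 1e-3  # nS * mV = pA -> nA
    return float(i) if np.ndim(i) == 0 else i
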