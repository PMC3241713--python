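"""Single-compartment membrane model of an MGB thalamocortical relay neuron.

The compartment carries nine intrinsic currents: fast transient Na+ (INa),
delayed-rectifier K+ (IKdr), persistent Na+ (INap), low-threshold T-type
Ca2+ (IT), high-threshold L-type Ca2+ (IL), transient A-type K+ (IA),
slowly-inactivating K+ (IK2), the hyperpolarization-activated cation
current (Ih) and an ohmic leak.  Ca2+ currents use the constant-field
(GHK) flux equation with fixed intra/extracellular concentrations; there
is no Ca2+-activated K+ current, so no Ca2+ pool dynamics are required.

Conductances are specified as densities (S/cm2) and permeabilities (cm/s);
the membrane ``area`` converts them to absolute values.  The default area
was calibrated once so that the input resistance measured from -60 mV is
approximately 75 MOhm, and the leak conductance sits at the value that
puts the free resting potential near -68 mV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._kinetics import GATE_NAMES, N_GATES, gate_tables, ghk_flux, temp_factors

__all__ = [
    "MembraneParams",
    "GateState",
    "NeuronState",
    "CHANNEL_GATES",
    "gate_steady_state_and_tau",
    "ghk_current",
    "ionic_currents",
    "total_ionic_current",
    "steady_gates",
]

#: map from channel-id to the gates it owns (activation first)
CHANNEL_GATES = {
    "na": ("na_m", "na_h"),
    "kdr": ("kdr_n",),
    "t": ("t_m", "t_h"),
    "l": ("l_m",),
    "a": ("a_m", "a_h"),
    "k2": ("k2_m", "k2_h"),
    "nap": ("nap_m",),
    "h": ("h_m",),
}

_GATE_INDEX = {name: i for i, name in enumerate(GATE_NAMES)}


@dataclass
class MembraneParams:
    """Biophysical parameters of the model compartment.

    Conductance densities in S/cm2, permeabilities in cm/s, potentials in
    mV, capacitance in uF/cm2, area in cm2, concentrations in mM,
    temperature in deg C.
    """

    g_na: float = 0.01
    g_kdr: float = 0.01
    g_a: float = 0.0008
    g_k2: float = 0.000134
    g_nap: float = 0.00001
    g_h: float = 0.00005
    # Leak density is the tunable that sets the free resting potential
    # near -68 mV (see docs/methods.md).
    g_leak: float = 0.000065
    p_cat: float = 0.00008
    p_cal: float = 0.00001
    e_na: float = 50.0
    e_k: float = -100.0
    e_leak: float = -73.0
    # Reversal of Ih; standard thalamocortical value (no direct
    # measurement in the source data for this model).
    e_h: float = -43.0
    c_m: float = 1.0
    # Calibrated once so that R_in from -60 mV ~ 75 MOhm, then frozen.
    area: float = 9.207e-5
    ca_i: float = 0.00024
    ca_o: float = 2.0
    temperature: float = 36.0
    # Threshold shift of the Traub Na/Kdr rate functions (mV); sets the
    # spike threshold of the cell (see docs/methods.md).
    vshift: float = -52.0

    def __post_init__(self) -> None:
        for name in ("g_na", "g_kdr", "g_a", "g_k2", "g_nap", "g_h",
                     "g_leak", "p_cat", "p_cal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.ca_i <= 0 or self.ca_o <= 0:
            raise ValueError("Ca2+ concentrations must be positive")

    def replace(self, **kw) -> "MembraneParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MembraneParams":
        return cls(**d)


@dataclass
class GateState:
    """All activation/inactivation variables, each in [0, 1]."""

    values: np.ndarray = field(
        default_factory=lambda: np.zeros(N_GATES))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_GATES,):
            raise ValueError(f"expected {N_GATES} gate variables")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("gate variables must lie in [0, 1]")

    def __getitem__(self, name: str) -> float:
        return float(self.values[_GATE_INDEX[name]])


@dataclass
class NeuronState:
    """Membrane potential, gating state and time of one snapshot."""

    v: float
    gates: GateState
    t: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.v) or not (-150.0 < self.v < 80.0):
            raise ValueError(f"membrane potential {self.v} mV outside "
                             "valid range (-150, 80)")


def gate_steady_state_and_tau(channel: str, v, params: MembraneParams | None = None):
    """Steady-state value(s) and time constant(s) of a channel's gates.

    Parameters
    ----------
    channel : channel id, one of ``CHANNEL_GATES`` keys, or a gate name
        from ``GATE_NAMES`` to address a single gate.
    v : voltage (mV), scalar or array.
    params : optional; supplies temperature and the Na/Kdr voltage shift.

    Returns
    -------
    For a gate name: ``(x_inf, tau)`` with the same shape as ``v``.
    For a channel id: dict mapping gate name to ``(x_inf, tau)``.
    """
    params = params or MembraneParams()
    tf = temp_factors(params.temperature)

    def tables(vv: float):
        return gate_tables(float(vv), params.vshift, tf)

    if channel in _GATE_INDEX:
        idx = _GATE_INDEX[channel]
        v_arr = np.atleast_1d(np.asarray(v, dtype=float))
        inf = np.empty_like(v_arr)
        tau = np.empty_like(v_arr)
        for i, vv in enumerate(v_arr):
            gi, gt = tables(vv)
            inf[i], tau[i] = gi[idx], gt[idx]
        if np.isscalar(v) or np.asarray(v).ndim == 0:
            return float(inf[0]), float(tau[0])
        return inf, tau
    if channel in CHANNEL_GATES:
        return {g: gate_steady_state_and_tau(g, v, params)
                for g in CHANNEL_GATES[channel]}
    valid = sorted(CHANNEL_GATES) + list(GATE_NAMES)
    raise KeyError(f"unknown channel {channel!r}; valid ids: {valid}")


def steady_gates(v: float, params: MembraneParams | None = None) -> GateState:
    """GateState with every variable at its steady state for voltage ``v``."""
    params = params or MembraneParams()
    inf, _ = gate_tables(float(v), params.vshift, temp_factors(params.temperature))
    return GateState(inf.copy())


def ghk_current(p: float, v: float, ca_i: float, ca_o: float,
                temperature: float = 36.0) -> float:
    """GHK (constant-field) Ca2+ current density in mA/cm2.

    ``p`` in cm/s, ``v`` in mV, concentrations in mM.  Negative values are
    inward by convention.
    """
    if p < 0:
        raise ValueError("permeability must be non-negative")
    if ca_i <= 0 or ca_o <= 0:
        raise ValueError("concentrations must be positive")
    return float(ghk_flux(p, float(v), ca_i, ca_o, temperature))


def ionic_currents(state: NeuronState, params: MembraneParams) -> dict:
    """Each intrinsic current density (mA/cm2) by name, at the given state."""
    v = state.v
    g = state.gates
    m_na, h_na = g["na_m"], g["na_h"]
    n = g["kdr_n"]
    out = {
        "na": params.g_na * m_na ** 3 * h_na * (v - params.e_na),
        "kdr": params.g_kdr * n ** 4 * (v - params.e_k),
        "t": ghk_flux(params.p_cat * g["t_m"] ** 2 * g["t_h"], v,
                      params.ca_i, params.ca_o, params.temperature),
        "l": ghk_flux(params.p_cal * g["l_m"] ** 2, v,
                      params.ca_i, params.ca_o, params.temperature),
        "a": params.g_a * g["a_m"] ** 4 * g["a_h"] * (v - params.e_k),
        "k2": params.g_k2 * g["k2_m"] * g["k2_h"] * (v - params.e_k),
        "nap": params.g_nap * g["nap_m"] * (v - params.e_na),
        "h": params.g_h * g["h_m"] * (v - params.e_h),
        "leak": params.g_leak * (v - params.e_leak),
    }
    return out


def total_ionic_current(state: NeuronState, params: MembraneParams) -> float:
    """Sum of all intrinsic current densities (mA/cm2)."""
    return float(sum(ionic_currents(state, params).values()))
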