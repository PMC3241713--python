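"""Voltage-gated channel kinetics for the thalamocortical relay neuron.

Rate functions follow the classic thalamocortical relay formulations of
McCormick & Huguenard (1992) and Destexhe and colleagues:

* fast Na+ / delayed-rectifier K+ : Traub-style rate functions with a
  threshold-shift parameter ``vshift`` (the spike threshold of the cell is
  set by this shift; see docs/methods.md for its calibration),
* low-threshold Ca2+ (T) : Destexhe et al. relay-cell kinetics, GHK flux,
* high-threshold Ca2+ (L), transient K+ (A), slow K+ (K2), persistent Na+
  (Nap) : McCormick & Huguenard rate functions,
* hyperpolarization-activated cation current (h) : Huguenard & McCormick.

All voltages in mV, times in ms.  Temperature scaling uses per-family Q10
factors relative to the temperature at which each formulation was fitted;
the factors multiply the rates (divide the time constants).

Gate indexing used throughout the package (module constant ``GATE_NAMES``):

    0 na_m   1 na_h   2 kdr_n  3 t_m   4 t_h   5 l_m
    6 a_m    7 a_h    8 k2_m   9 k2_h  10 nap_m  11 h_m
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

GATE_NAMES = (
    "na_m", "na_h", "kdr_n", "t_m", "t_h", "l_m",
    "a_m", "a_h", "k2_m", "k2_h", "nap_m", "h_m",
)
N_GATES = len(GATE_NAMES)

# Reference temperatures (deg C) of the source formulations.
_T_HH = 36.0      # Traub-style Na/K rates
_T_IT = 24.0      # Destexhe T-current
_T_MC = 23.5      # McCormick & Huguenard voltage-clamp data


@njit(cache=True)
def _vtrap(x: float, y: float) -> float:
    """x / (exp(x / y) - 1) with the removable singularity at x = 0 filled."""
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / (2.0 * y))
    return x / math.expm1(x / y)


@njit(cache=True)
def temp_factors(temperature: float) -> np.ndarray:
    """Q10 rate multipliers: [hh, t_act, t_inact, mccormick]."""
    out = np.empty(4)
    out[0] = 3.0 ** ((temperature - _T_HH) / 10.0)
    out[1] = 3.55 ** ((temperature - _T_IT) / 10.0)
    out[2] = 3.0 ** ((temperature - _T_IT) / 10.0)
    out[3] = 3.0 ** ((temperature - _T_MC) / 10.0)
    return out


@njit(cache=True)
def gate_tables(v: float, vshift: float, tf: np.ndarray):
    """Steady states and time constants of all 12 gates at voltage ``v``.

    Parameters
    ----------
    v : membrane potential (mV)
    vshift : threshold shift of the Traub Na/K rate functions (mV); the
        rates are evaluated at ``v - vshift``.
    tf : temperature factors from :func:`temp_factors`.

    Returns
    -------
    (inf, tau) : two length-12 float arrays; tau in ms, strictly positive.
    """
    inf = np.empty(N_GATES)
    tau = np.empty(N_GATES)

    # --- fast Na+ and delayed rectifier (Traub rates, shifted) ---
    v2 = v - vshift
    a = 0.32 * _vtrap(13.0 - v2, 4.0)
    b = 0.28 * _vtrap(v2 - 40.0, 5.0)
    inf[0] = a / (a + b)
    tau[0] = 1.0 / ((a + b) * tf[0])

    a = 0.128 * math.exp((17.0 - v2) / 18.0)
    b = 4.0 / (1.0 + math.exp((40.0 - v2) / 5.0))
    inf[1] = a / (a + b)
    tau[1] = 1.0 / ((a + b) * tf[0])

    a = 0.032 * _vtrap(15.0 - v2, 5.0)
    b = 0.5 * math.exp((10.0 - v2) / 40.0)
    inf[2] = a / (a + b)
    tau[2] = 1.0 / ((a + b) * tf[0])

    # --- low-threshold Ca2+ (T) ---
    inf[3] = 1.0 / (1.0 + math.exp(-(v + 57.0) / 6.2))
    inf[4] = 1.0 / (1.0 + math.exp((v + 81.0) / 4.0))
    tau[3] = (0.612 + 1.0 / (math.exp(-(v + 132.0) / 16.7)
                             + math.exp((v + 16.8) / 18.2))) / tf[1]
    if v < -80.0:
        tau[4] = math.exp((v + 467.0) / 66.6) / tf[2]
    else:
        tau[4] = (28.0 + math.exp(-(v + 22.0) / 10.5)) / tf[2]

    # --- high-threshold Ca2+ (L) ---
    a = 1.6 / (1.0 + math.exp(-0.072 * (v - 5.0)))
    b = 0.02 * _vtrap(v - 1.31, 5.36)
    inf[5] = a / (a + b)
    tau[5] = 1.0 / ((a + b) * tf[3])

    # --- transient K+ (A) ---
    inf[6] = 1.0 / (1.0 + math.exp(-(v + 60.0) / 8.5))
    tau[6] = (1.0 / (math.exp((v + 35.82) / 19.69)
                     + math.exp(-(v + 79.69) / 12.7)) + 0.37) / tf[3]
    inf[7] = 1.0 / (1.0 + math.exp((v + 78.0) / 6.0))
    if v < -63.0:
        tau[7] = (1.0 / (math.exp((v + 46.05) / 5.0)
                         + math.exp(-(v + 238.4) / 37.45))) / tf[3]
    else:
        tau[7] = 19.0 / tf[3]

    # --- slowly inactivating K+ (K2) ---
    inf[8] = 1.0 / (1.0 + math.exp(-(v + 43.0) / 17.0))
    tau[8] = (1.0 / (math.exp((v - 81.0) / 25.6)
                     + math.exp(-(v + 132.0) / 18.0)) + 9.9) / tf[3]
    inf[9] = 1.0 / (1.0 + math.exp((v + 58.0) / 10.6))
    tau[9] = (1.0 / (math.exp((v - 1329.0) / 200.0)
                     + math.exp(-(v + 130.0) / 7.1)) + 120.0) / tf[3]

    # --- persistent Na+ ---
    inf[10] = 1.0 / (1.0 + math.exp(-(v + 34.0) / 5.0))
    tau[10] = 1.0 / tf[3]

    # --- hyperpolarization-activated cation (h) ---
    # steady state: Destexhe relay-cell fit (half-activation -68.9 mV);
    # time constant: Huguenard-McCormick form (slow, ~700 ms near rest)
    inf[11] = 1.0 / (1.0 + math.exp((v + 68.9) / 6.5))
    tau[11] = 1.0 / (math.exp(-14.59 - 0.086 * v)
                     + math.exp(-1.87 + 0.0701 * v))

    return inf, tau


# Faraday constant (C/mol) and gas constant (J/(mol K)); values match
# scipy.constants to the digits used here.
_FARADAY = 96485.33212
_RGAS = 8.314462618


@njit(cache=True)
def ghk_flux(p: float, v: float, ca_i: float, ca_o: float,
             temperature: float) -> float:
    """Constant-field (GHK) Ca2+ current density.

    Parameters: permeability ``p`` in cm/s, ``v`` in mV, concentrations in
    mM, temperature in deg C.  Returns mA/cm2 (negative = inward).
    """
    z = 2.0
    t_kelvin = temperature + 273.15
    u = z * _FARADAY * (v * 1e-3) / (_RGAS * t_kelvin)
    # concentrations mM -> mol/cm3
    ci = ca_i * 1e-6
    co = ca_o * 1e-6
    if abs(u) < 1e-6:
        # first-order expansion around the u = 0 removable singularity
        flux = z * _FARADAY * ((ci - co) + 0.5 * u * (ci + co))
    else:
        flux = z * _FARADAY * u * (ci - co * math.exp(-u)) / (-math.expm1(-u))
    return p * flux * 1e3  # A/cm2 -> mA/cm2
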