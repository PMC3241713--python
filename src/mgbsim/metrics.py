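"""Spike detection and response statistics.

Synchrony is quantified with the vector strength

    VS = (1/n) * sqrt((sum cos phi_i)^2 + (sum sin phi_i)^2),

where phi_i = 2*pi*(t_i mod ICI)/ICI is the phase of spike i relative to
the click period, and its statistical significance with the
spike-count-corrected Rayleigh statistic R = 2*n*VS^2; R > 13.8
corresponds to P < 0.001.  VS and R are computed over spikes pooled
across trials inside the sustained-response analysis window, which runs
from 50 ms after stimulus onset to the end of the stimulus; firing rates
are computed over the entire stimulus duration unless a window is given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RAYLEIGH_THRESHOLD",
    "SynchronyMetrics",
    "detect_spikes",
    "vector_strength",
    "rayleigh",
    "analysis_window",
    "first_spike_latency",
    "rate_gain",
    "sync_boundary",
    "condition_metrics",
]

#: Rayleigh statistic above which a response is called synchronized (P < 0.001)
RAYLEIGH_THRESHOLD = 13.8

#: spike detection: threshold crossing level (mV) and refractory merge (ms)
SPIKE_LEVEL = 0.0
REFRACTORY = 1.0


@dataclass
class SynchronyMetrics:
    """All response statistics for one (condition, ICI) cell."""

    ici: float
    n_spikes: int
    rate: float                 # spikes/s over the full stimulus
    spikes_per_cycle: float
    rate_gain: float            # output rate / mean input stream rate (NaN if undefined)
    vs: float                   # NaN when no spikes in the window
    rayleigh_r: float
    is_synchronized: bool
    fsl: float                  # ms, NaN when no trial spiked
    fsl_fraction: float         # fraction of trials with >= 1 spike
    window: tuple
    n_trials: int = 0

    def as_row(self) -> dict:
        d = dict(self.__dict__)
        d["window_start"], d["window_end"] = self.window
        del d["window"]
        return d


def detect_spikes(t: np.ndarray, v: np.ndarray,
                  level: float = SPIKE_LEVEL,
                  refractory: float = REFRACTORY) -> np.ndarray:
    """Spike times from a voltage trace: upward crossings of ``level``.

    Crossings closer than ``refractory`` ms are merged into one event.
    NaN samples (e.g. past an aborted integration) are ignored.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    ok = np.isfinite(v)
    above = ok & (v >= level)
    idx = np.nonzero(~above[:-1] & above[1:])[0] + 1
    if idx.size == 0:
        return np.empty(0)
    times = t[idx]
    kept = [times[0]]
    for tt in times[1:]:
        if tt - kept[-1] >= refractory:
            kept.append(tt)
    return np.asarray(kept)


def vector_strength(spikes, ici: float, window: tuple[float, float],
                    onset: float = 0.0) -> tuple[float, int]:
    """Pooled vector strength of the spikes inside ``window``.

    Phases are taken relative to ``onset`` modulo ``ici``.  Returns
    ``(VS, n)``; with no spikes in the window VS is NaN (undefined, not
    zero) and n = 0.
    """
    if ici <= 0:
        raise ValueError("ici must be positive")
    spikes = np.asarray(spikes, dtype=float)
    lo, hi = window
    inside = spikes[(spikes >= lo) & (spikes <= hi)]
    n = inside.size
    if n == 0:
        return float("nan"), 0
    phi = 2.0 * np.pi * np.mod(inside - onset, ici) / ici
    vs = math.hypot(np.cos(phi).sum(), np.sin(phi).sum()) / n
    return float(vs), int(n)


def rayleigh(vs: float, n_spikes: int,
             threshold: float = RAYLEIGH_THRESHOLD) -> tuple[float, bool]:
    """Rayleigh statistic ``R = 2 n VS^2`` and the synchrony decision."""
    if n_spikes < 0:
        raise ValueError("spike count must be non-negative")
    if n_spikes == 0 or not np.isfinite(vs):
        return 0.0, False
    r = 2.0 * n_spikes * vs ** 2
    return float(r), bool(r > threshold)


def analysis_window(onset: float, duration: float) -> tuple[float, float]:
    """Sustained-response window: 50 ms after onset to stimulus end."""
    if duration <= 50.0:
        raise ValueError("stimulus must be longer than the 50 ms onset "
                         "exclusion")
    return (onset + 50.0, onset + duration)


def first_spike_latency(trial_spikes: list[np.ndarray], onset: float = 0.0,
                        aggregate: str = "mean") -> tuple[float, float]:
    """First-spike latency relative to stimulus onset, aggregated over trials.

    Returns ``(latency, fraction)`` where fraction is the share of trials
    with at least one spike after onset; latency is NaN when no trial
    spiked.  ``aggregate`` is ``"mean"`` (default) or ``"median"``.
    """
    if not trial_spikes:
        raise ValueError("at least one trial required")
    firsts = []
    for spikes in trial_spikes:
        spikes = np.asarray(spikes, dtype=float)
        after = spikes[spikes >= onset]
        if after.size:
            firsts.append(after[0] - onset)
    frac = len(firsts) / len(trial_spikes)
    if not firsts:
        return float("nan"), 0.0
    agg = np.median if aggregate == "median" else np.mean
    return float(agg(firsts)), frac


def rate_gain(output_spikes, input_streams: list[np.ndarray],
              window: tuple[float, float]) -> float:
    """Output rate divided by the mean per-stream input rate in ``window``.

    NaN when there are no input spikes in the window.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty window")
    span = (hi - lo) / 1000.0
    out = np.asarray(output_spikes, dtype=float)
    out_rate = np.sum((out >= lo) & (out <= hi)) / span
    in_rates = []
    for s in input_streams:
        s = np.asarray(s, dtype=float)
        in_rates.append(np.sum((s >= lo) & (s <= hi)) / span)
    mean_in = float(np.mean(in_rates)) if in_rates else 0.0
    if mean_in == 0.0:
        return float("nan")
    return float(out_rate / mean_in)


def sync_boundary(icis, flags) -> float:
    """Smallest ICI whose monotone closure is synchronized.

    The boundary is the smallest tested ICI such that every tested ICI at
    or above it is synchronized; isolated stochastic flips below the
    boundary are ignored.  NaN when even the largest ICI is
    unsynchronized.
    """
    order = np.argsort(icis)
    icis = np.asarray(icis, dtype=float)[order]
    flags = np.asarray(flags, dtype=bool)[order]
    boundary = float("nan")
    for ici, flag in zip(icis[::-1], flags[::-1]):
        if flag:
            boundary = float(ici)
        else:
            break
    return boundary


def condition_metrics(trial_output_spikes: list[np.ndarray],
                      trial_input_streams: list[list[np.ndarray]],
                      ici: float, onset: float, duration: float,
                      ) -> SynchronyMetrics:
    """Pool trials of one condition into a single metrics record.

    ``trial_output_spikes``: detected spike times per trial (absolute ms);
    ``trial_input_streams``: per trial, the list of input spike-time
    arrays that drove it.
    """
    window = analysis_window(onset, duration)
    full = (onset, onset + duration)
    pooled = (np.concatenate(trial_output_spikes)
              if trial_output_spikes else np.empty(0))
    n_trials = max(len(trial_output_spikes), 1)
    span = duration / 1000.0
    counts = [np.sum((s >= full[0]) & (s <= full[1]))
              for s in trial_output_spikes]
    rate = float(np.mean(counts)) / span if counts else 0.0
    vs, n_win = vector_strength(pooled, ici, window, onset=onset)
    r, sync = rayleigh(vs, n_win)
    fsl, frac = first_spike_latency(trial_output_spikes, onset=onset)
    gains = []
    for out, streams in zip(trial_output_spikes, trial_input_streams):
        g = rate_gain(out, streams, window)
        if np.isfinite(g):
            gains.append(g)
    gain = float(np.mean(gains)) if gains else float("nan")
    return SynchronyMetrics(
        ici=ici,
        n_spikes=int(n_win),
        rate=rate,
        spikes_per_cycle=rate * ici / 1000.0,
        rate_gain=gain,
        vs=vs,
        rayleigh_r=r,
        is_synchronized=sync,
        fsl=fsl,
        fsl_fraction=frac,
        window=window,
        n_trials=n_trials,
    )


def metrics_table(records: list[SynchronyMetrics], **extra) -> pd.DataFrame:
    """Tidy DataFrame from metric records, with constant annotation columns."""
    rows = []
    for m in records:
        row = m.as_row()
        row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)
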