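"""Synthetic inferior-colliculus (IC) afferent spike trains for click stimuli.

An IC input stream responding to a periodic click train is modeled as the
nominal click grid thinned by a period-dependent spike probability and
perturbed by Gaussian timing jitter.  The probability curve is a logistic
in log-period calibrated so that p = 0.95 at a 25 ms inter-click interval
(ICI) and p ~ 0.1 at 3 ms, consistent with IC responses to rapid periodic
stimuli: probabilities are close to 1 for ICIs above 25 ms and fall off
steeply below, approaching the synchronization limit of IC neurons near
300 Hz.  The curve is a parametric stand-in (the empirical curves exist
only as figures in the physiology literature) and both parameters are
exposed.

Randomness is counter-based: every (master seed, trial, stream) triple
maps to an independent, reproducible generator, so any trial can be
regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synapse import SynapseParams

__all__ = [
    "StimulusSpec",
    "InputStream",
    "PopulationPreset",
    "PRESETS",
    "spike_probability",
    "generate_stream",
    "make_population",
    "streams_to_frame",
    "streams_from_frame",
]

logger = logging.getLogger(__name__)

#: minimum separation below which two jittered spikes merge (ms)
MERGE_WINDOW = 0.1

# logistic-in-log-ICI defaults: midpoint 7.23 ms, slope such that
# p(25) = 0.95 and p(3) ~ 0.1
_P_MIDPOINT = 7.234
_P_SLOPE = math.log(25.0 / 7.234) / math.log(0.95 / 0.05)


@dataclass
class StimulusSpec:
    """Click-train stimulus and input-stream statistics.

    ``jitter_mode`` is ``"absolute_ms"`` (sigma = ``jitter_value`` ms) or
    ``"fraction_of_ici"`` (sigma = ``jitter_value * ici``).
    """

    ici: float
    duration: float = 500.0
    onset: float = 0.0
    n_streams: int = 1
    jitter_mode: str = "absolute_ms"
    jitter_value: float = 1.0
    seed: int = 0
    p_midpoint: float = _P_MIDPOINT
    p_slope: float = _P_SLOPE
    force_probability: float | None = None

    def __post_init__(self) -> None:
        if self.ici <= 0:
            raise ValueError("ici must be positive")
        if self.duration <= self.ici:
            raise ValueError("duration must exceed one inter-click interval")
        if self.jitter_mode not in ("absolute_ms", "fraction_of_ici"):
            raise ValueError("jitter_mode must be 'absolute_ms' or "
                             "'fraction_of_ici'")
        if not (3.0 <= self.ici <= 150.0):
            logger.warning("ICI %.3g ms outside the calibrated 3-150 ms "
                           "range", self.ici)

    @property
    def sigma(self) -> float:
        """Jitter standard deviation in ms."""
        if self.jitter_mode == "absolute_ms":
            return self.jitter_value
        return self.jitter_value * self.ici

    def replace(self, **kw) -> "StimulusSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class InputStream:
    """One IC afferent's spike times for one trial."""

    stream_id: int
    spike_times: np.ndarray
    source_spec: StimulusSpec
    realized_seed: tuple = ()
    n_merged: int = 0

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")


def spike_probability(ici, midpoint: float = _P_MIDPOINT,
                      slope: float = _P_SLOPE):
    """IC spike probability per click as a function of ICI (ms).

    Logistic in log-ICI: monotonically non-decreasing, ~1 above 25 ms,
    0.5 at ``midpoint`` (default 7.23 ms).
    """
    ici = np.asarray(ici, dtype=float)
    if np.any(ici <= 0):
        raise ValueError("ici must be positive")
    p = 1.0 / (1.0 + np.exp(-np.log(ici / midpoint) / slope))
    return float(p) if p.ndim == 0 else p


def _rng_for(seed: int, trial_index: int, stream_index: int
             ) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(int(trial_index), int(stream_index))))


def generate_stream(spec: StimulusSpec, stream_index: int = 0,
                    trial_index: int = 0) -> InputStream:
    """One jittered, thinned IC spike train for (trial, stream).

    Each nominal click time ``onset + k * ici`` is kept with probability
    ``p(ici)`` and perturbed by N(0, sigma^2).  Times are re-sorted after
    jitter, clipped to the stimulus window, and spikes closer than
    ``MERGE_WINDOW`` are merged (count logged on the stream).
    """
    rng = _rng_for(spec.seed, trial_index, stream_index)
    # click grid is half-open: clicks at onset + k*ici for k*ici < duration
    n_clicks = int(math.ceil(spec.duration / spec.ici))
    nominal = spec.onset + np.arange(n_clicks) * spec.ici
    nominal = nominal[nominal < spec.onset + spec.duration]
    p = (spec.force_probability if spec.force_probability is not None
         else spike_probability(spec.ici, spec.p_midpoint, spec.p_slope))
    keep = rng.random(nominal.size) < p
    times = nominal[keep]
    if spec.sigma > 0:
        times = times + rng.normal(0.0, spec.sigma, times.size)
    times = np.sort(times)
    times = np.clip(times, spec.onset, spec.onset + spec.duration)
    merged = 0
    if times.size > 1:
        keep_mask = np.ones(times.size, dtype=bool)
        last = times[0]
        for i in range(1, times.size):
            if times[i] - last < MERGE_WINDOW:
                keep_mask[i] = False
                merged += 1
            else:
                last = times[i]
        times = times[keep_mask]
    if merged:
        logger.debug("stream %d trial %d: merged %d coincident spikes",
                     stream_index, trial_index, merged)
    return InputStream(stream_id=stream_index, spike_times=times,
                       source_spec=spec,
                       realized_seed=(spec.seed, trial_index, stream_index),
                       n_merged=merged)


@dataclass(frozen=True)
class PopulationPreset:
    """Afferent population archetype: stream count + synapse template."""

    name: str
    n_streams: int
    g_ampa_max: float
    nmda_ampa_ratio: float
    plasticity_mode: str


#: Large-terminal (MGV-like) and small-terminal (MGD-like) IC afferents.
PRESETS = {
    "Large": PopulationPreset("Large", n_streams=2, g_ampa_max=16.0,
                              nmda_ampa_ratio=0.5, plasticity_mode="PPD"),
    "Small": PopulationPreset("Small", n_streams=4, g_ampa_max=2.0,
                              nmda_ampa_ratio=2.0, plasticity_mode="Mixed"),
}


def make_population(preset: str, spec: StimulusSpec, trial_index: int = 0,
                    plasticity_mode: str | None = None,
                    nmda_scale: float = 1.0,
                    synapse_overrides: dict | None = None,
                    ) -> tuple[list[InputStream], list[SynapseParams]]:
    """Independent input streams plus synapse parameters for a preset.

    ``Large`` = 2 strong depressing streams (16 nS AMPA, NMDA/AMPA 0.5);
    ``Small`` = 4 weak streams with a high NMDA/AMPA ratio (2 nS, ratio 2)
    and Mixed plasticity by default.  ``plasticity_mode`` overrides the
    preset default; ``nmda_scale`` globally scales the NMDA component.
    """
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; valid: "
                       f"{sorted(PRESETS)}")
    p = PRESETS[preset]
    mode = plasticity_mode if plasticity_mode is not None else p.plasticity_mode
    overrides = synapse_overrides or {}
    syn = SynapseParams(g_ampa_max=p.g_ampa_max,
                        nmda_ampa_ratio=p.nmda_ampa_ratio,
                        plasticity_mode=mode, nmda_scale=nmda_scale,
                        **overrides)
    spec = spec.replace(n_streams=p.n_streams)
    streams = [generate_stream(spec, stream_index=i, trial_index=trial_index)
               for i in range(p.n_streams)]
    return streams, [syn] * p.n_streams


def streams_to_frame(streams_by_trial: dict[int, list[InputStream]]
                     ) -> pd.DataFrame:
    """Tidy (trial, stream, time_ms) table of input spike times."""
    rows = []
    for trial, streams in streams_by_trial.items():
        for s in streams:
            for t in s.spike_times:
                rows.append((trial, s.stream_id, t))
    return pd.DataFrame(rows, columns=["trial", "stream", "time_ms"])


def streams_from_frame(frame: pd.DataFrame, spec: StimulusSpec
                       ) -> dict[int, list[InputStream]]:
    """Rebuild per-trial stream lists from a (trial, stream, time_ms) table."""
    out: dict[int, list[InputStream]] = {}
    for (trial, stream), grp in frame.groupby(["trial", "stream"]):
        out.setdefault(int(trial), []).append(
            InputStream(stream_id=int(stream),
                        spike_times=np.sort(grp["time_ms"].to_numpy()),
                        source_spec=spec))
    for trial in out:
        out[trial].sort(key=lambda s: s.stream_id)
    return out
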