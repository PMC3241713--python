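"""Parameter sweeps over the model: the response-classification experiments.

Each sweep runs multi-trial protocols over a set of conditions and
returns (and optionally persists) a tidy table with one row per
(condition, ICI): firing rate, spikes/cycle, rate gain, vector strength,
Rayleigh statistic, synchrony flag and first-spike latency.

Sweeps are resumable: when an output directory is given, completed
condition rows (identified by a configuration hash) are loaded from
``results.csv`` and skipped on re-run.

The standard sweeps:

* conductance grid  : AMPA peak conductance x NMDA/AMPA ratio, single
  afferent, per plasticity mode and ICI;
* ICI curves        : rate / synchrony / latency vs inter-click interval
  for the Large and Small afferent presets;
* jitter sweep      : synchrony vs ICI with jitter scaled as a fraction
  of the ICI;
* NMDA scaling      : ICI curves at 0-200 % of the default NMDA
  conductance;
* membrane potential: ICI curves at holding potentials of -55 to -75 mV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import CalibrationError, Protocol, run_trials
from .ic_inputs import StimulusSpec
from .membrane import MembraneParams
from .metrics import condition_metrics, sync_boundary

__all__ = [
    "SweepSpec",
    "DEFAULT_ICIS",
    "GRID_G_AMPA",
    "GRID_RATIOS",
    "run_condition",
    "run_conductance_grid",
    "run_ici_curves",
    "run_jitter_sweep",
    "run_nmda_scale_sweep",
    "run_vmem_sweep",
]

logger = logging.getLogger(__name__)

#: default ICI grid: superset of the intervals used across the response
#: classification figures (ms)
DEFAULT_ICIS = (3.0, 5.0, 7.5, 8.5, 10.0, 12.5, 15.0, 20.0, 25.0,
                50.0, 100.0, 150.0)

#: conductance-grid axes: 10 linear AMPA steps over [0, 20] nS and the
#: canonical NMDA/AMPA ratio list
GRID_G_AMPA = tuple(np.linspace(0.0, 20.0, 10))
GRID_RATIOS = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass
class SweepSpec:
    """Axes and base protocol of one sweep."""

    kind: str                       # conductance_grid | ici_curve | jitter | nmda_scale | vmem
    icis: tuple = DEFAULT_ICIS
    presets: tuple = ("Large", "Small")
    modes: tuple = ("None", "PPD", "PPF", "Mixed")
    g_ampa_values: tuple = GRID_G_AMPA
    ratio_values: tuple = GRID_RATIOS
    jitter_fractions: tuple = (0.1, 0.2, 0.5)
    nmda_scales: tuple = (0.0, 0.5, 1.0, 1.5, 2.0)
    vmems: tuple = (-55.0, -65.0, -75.0)
    target_vm: float = -60.0
    jitter_ms: float = 1.0
    duration: float = 500.0
    n_trials: int = 10
    seed: int = 0
    membrane: MembraneParams = field(default_factory=MembraneParams)
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items()
                   if k not in ("out_dir", "membrane")}
        payload["membrane"] = self.membrane.to_dict()
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


class _Store:
    """Append-only CSV result store keyed by (config hash, condition key)."""

    def __init__(self, out_dir: str | None, config_hash: str):
        self.path = None
        self.done: set = set()
        self.config_hash = config_hash
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            self.path = Path(out_dir) / "results.csv"
            if self.path.exists():
                prev = pd.read_csv(self.path)
                prev = prev[prev["config_hash"] == config_hash]
                self.done = set(prev["condition_key"])
                self.cached = prev
            else:
                self.cached = pd.DataFrame()

    def has(self, key: str) -> bool:
        return key in self.done

    def fetch(self, key: str) -> dict:
        row = self.cached[self.cached["condition_key"] == key].iloc[-1]
        return row.to_dict()

    def append(self, key: str, row: dict) -> None:
        if self.path is None:
            return
        row = dict(row)
        row["condition_key"] = key
        row["config_hash"] = self.config_hash
        header = not self.path.exists()
        pd.DataFrame([row]).to_csv(self.path, mode="a", header=header,
                                   index=False)


def run_condition(membrane: MembraneParams, stimulus: StimulusSpec, *,
                  preset: str | None = None, mode: str | None = None,
                  synapse=None, nmda_scale: float = 1.0,
                  target_vm: float = -60.0, n_trials: int = 10,
                  seed: int = 0, dt: float = 0.02):
    """Run one (stimulus, synapse) condition and pool its trials.

    Returns a :class:`~mgbsim.metrics.SynchronyMetrics` for the pooled
    response.
    """
    prot = Protocol(kind="synaptic", dt=dt, stimulus=stimulus,
                    preset=preset, plasticity_mode=mode, synapse=synapse,
                    nmda_scale=nmda_scale, target_vm=target_vm,
                    n_trials=n_trials, seed=seed, membrane=membrane)
    results = run_trials(prot)
    return condition_metrics(
        [r.spike_times for r in results],
        [[s.spike_times for s in r.input_streams] for r in results],
        stimulus.ici, prot.onset, stimulus.duration)


def _metrics_row(m, **extra) -> dict:
    row = m.as_row()
    row.update(extra)
    return row


def run_conductance_grid(spec: SweepSpec,
                         icis: tuple = (100.0, 25.0, 10.0),
                         modes: tuple | None = None) -> pd.DataFrame:
    """Firing rate and synchrony over the AMPA x NMDA/AMPA grid.

    Uses a single afferent input per condition.  Returns one row per
    (mode, ici, g_ampa, ratio).
    """
    from .synapse import SynapseParams

    modes = modes or spec.modes
    store = _Store(spec.out_dir, spec.config_hash())
    rows = []
    for mode in modes:
        for ici in icis:
            for g in spec.g_ampa_values:
                for ratio in spec.ratio_values:
                    key = f"grid|{mode}|{ici}|{g:.3f}|{ratio:.2f}"
                    if store.has(key):
                        rows.append(store.fetch(key))
                        continue
                    stim = StimulusSpec(ici=ici, duration=spec.duration,
                                        n_streams=1,
                                        jitter_value=spec.jitter_ms,
                                        seed=spec.seed)
                    syn = SynapseParams(g_ampa_max=max(g, 1e-9),
                                        nmda_ampa_ratio=ratio,
                                        plasticity_mode=mode)
                    m = run_condition(spec.membrane, stim, synapse=syn,
                                      target_vm=spec.target_vm,
                                      n_trials=spec.n_trials,
                                      seed=spec.seed)
                    row = _metrics_row(m, mode=mode, g_ampa=g, ratio=ratio)
                    store.append(key, row)
                    rows.append(row)
    return pd.DataFrame(rows)


def run_ici_curves(spec: SweepSpec, nmda_scale: float = 1.0) -> pd.DataFrame:
    """Rate / synchrony / latency vs ICI for each preset and mode."""
    store = _Store(spec.out_dir, spec.config_hash())
    rows = []
    for preset in spec.presets:
        for mode in spec.modes:
            for ici in spec.icis:
                key = f"ici|{preset}|{mode}|{ici}|{nmda_scale}"
                if store.has(key):
                    rows.append(store.fetch(key))
                    continue
                stim = StimulusSpec(ici=ici, duration=spec.duration,
                                    jitter_value=spec.jitter_ms,
                                    seed=spec.seed)
                m = run_condition(spec.membrane, stim, preset=preset,
                                  mode=mode, nmda_scale=nmda_scale,
                                  target_vm=spec.target_vm,
                                  n_trials=spec.n_trials, seed=spec.seed)
                row = _metrics_row(m, preset=preset, mode=mode,
                                   nmda_scale=nmda_scale)
                store.append(key, row)
                rows.append(row)
    return pd.DataFrame(rows)


def run_jitter_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Synchrony and rate vs ICI with jitter as a fraction of the ICI."""
    store = _Store(spec.out_dir, spec.config_hash())
    rows = []
    conditions = [("Small", m) for m in ("Mixed", "PPF")] + \
                 [("Large", m) for m in ("None", "PPD")]
    for preset, mode in conditions:
        if preset not in spec.presets:
            continue
        for frac in spec.jitter_fractions:
            for ici in spec.icis:
                key = f"jitter|{preset}|{mode}|{frac}|{ici}"
                if store.has(key):
                    rows.append(store.fetch(key))
                    continue
                stim = StimulusSpec(ici=ici, duration=spec.duration,
                                    jitter_mode="fraction_of_ici",
                                    jitter_value=frac, seed=spec.seed)
                m = run_condition(spec.membrane, stim, preset=preset,
                                  mode=mode, target_vm=spec.target_vm,
                                  n_trials=spec.n_trials, seed=spec.seed)
                row = _metrics_row(m, preset=preset, mode=mode,
                                   jitter_fraction=frac)
                store.append(key, row)
                rows.append(row)
    return pd.DataFrame(rows)


def run_nmda_scale_sweep(spec: SweepSpec) -> pd.DataFrame:
    """ICI curves at several multiples of the default NMDA conductance."""
    store = _Store(spec.out_dir, spec.config_hash())
    rows = []
    conditions = [("Large", "PPD"), ("Small", "Mixed"), ("Small", "PPF")]
    for preset, mode in conditions:
        if preset not in spec.presets:
            continue
        for scale in spec.nmda_scales:
            for ici in spec.icis:
                key = f"nmda|{preset}|{mode}|{scale}|{ici}"
                if store.has(key):
                    rows.append(store.fetch(key))
                    continue
                stim = StimulusSpec(ici=ici, duration=spec.duration,
                                    jitter_value=spec.jitter_ms,
                                    seed=spec.seed)
                m = run_condition(spec.membrane, stim, preset=preset,
                                  mode=mode, nmda_scale=scale,
                                  target_vm=spec.target_vm,
                                  n_trials=spec.n_trials, seed=spec.seed)
                row = _metrics_row(m, preset=preset, mode=mode,
                                   nmda_scale=scale)
                store.append(key, row)
                rows.append(row)
    return pd.DataFrame(rows)


def run_vmem_sweep(spec: SweepSpec) -> pd.DataFrame:
    """ICI curves at holding potentials of (by default) -55/-65/-75 mV.

    Conditions whose bias calibration fails (no stable holding point)
    are skipped with a logged warning.
    """
    store = _Store(spec.out_dir, spec.config_hash())
    rows = []
    conditions = [("Large", "None"), ("Large", "PPD"),
                  ("Small", "Mixed"), ("Small", "PPF")]
    for preset, mode in conditions:
        if preset not in spec.presets or mode not in spec.modes:
            continue
        for vmem in spec.vmems:
            for ici in spec.icis:
                key = f"vmem|{preset}|{mode}|{vmem}|{ici}"
                if store.has(key):
                    rows.append(store.fetch(key))
                    continue
                stim = StimulusSpec(ici=ici, duration=spec.duration,
                                    jitter_value=spec.jitter_ms,
                                    seed=spec.seed)
                try:
                    m = run_condition(spec.membrane, stim, preset=preset,
                                      mode=mode, target_vm=vmem,
                                      n_trials=spec.n_trials,
                                      seed=spec.seed)
                except CalibrationError as exc:
                    logger.warning("skipping %s/%s at %g mV: %s",
                                   preset, mode, vmem, exc)
                    continue
                row = _metrics_row(m, preset=preset, mode=mode, vmem=vmem)
                store.append(key, row)
                rows.append(row)
    return pd.DataFrame(rows)


def boundary_from_table(table: pd.DataFrame, **filters) -> float:
    """Synchronization boundary (monotone closure) from a sweep table."""
    sub = table
    for col, val in filters.items():
        sub = sub[sub[col] == val]
    sub = sub.sort_values("ici")
    return sync_boundary(sub["ici"].to_numpy(),
                        sub["is_synchronized"].to_numpy())
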