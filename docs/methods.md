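# Model and methods

## Scope

`mgbsim` is a single-compartment, conductance-based model of a
thalamocortical relay neuron of the medial geniculate body (MGB), the
auditory thalamus. Its purpose is to study how two classes of ascending
inferior-colliculus (IC) afferents transform a phase-locked (temporal)
representation of periodic click trains into either a *Synchronized*
response (spikes phase-locked to the clicks) or a *Non-synchronized*
rate response, as a function of synaptic strength, NMDA content,
short-term plasticity, input timing jitter, and membrane potential.
Inhibition (GABA_A/GABA_B, reticular or interneuronal), Ca²⁺-activated
K⁺ currents, and multicompartment morphology are deliberately out of
scope: the model isolates the transformations available to the
excitatory afferents alone.

## Membrane model

One isopotential compartment with nine currents:

| current | gating | kinetics source family |
|---|---|---|
| I_Na (fast transient Na⁺) | m³h | Traub-type rate functions with a threshold shift |
| I_Kdr (delayed rectifier) | n⁴ | Traub-type, same shift |
| I_T (low-threshold Ca²⁺) | m²h, GHK flux | Destexhe relay-cell fits |
| I_L (high-threshold Ca²⁺) | m², GHK flux | McCormick–Huguenard |
| I_A (transient K⁺) | m⁴h | McCormick–Huguenard |
| I_K2 (slowly inactivating K⁺) | m·h | McCormick–Huguenard |
| I_NaP (persistent Na⁺) | m | sigmoid activation, midpoint −34 mV |
| I_h (anomalous rectifier) | m | Destexhe relay-cell steady state (V½ = −68.9 mV), Huguenard–McCormick time constant |
| leak | — | ohmic, E = −73 mV |

Conductances are densities (S/cm²) at the values of the published
default-parameter table; the two Ca²⁺ currents are specified as GHK
permeabilities (cm/s) with fixed Ca_i = 2.4×10⁻⁴ mM and Ca_o = 2 mM (no
Ca²⁺ pool: nothing reads Ca_i, since there is no Ca²⁺-activated
current). Temperature is 36 °C; the McCormick–Huguenard time constants
are scaled with Q10 = 3 from 23.5 °C, the T-current with the standard
φ-factors from 24 °C, and the Traub rates are used at 36 °C natively.

Three quantities were calibrated once, against measurements the model is
documented to reproduce, and then frozen:

* **Leak conductance** 6.5×10⁻⁵ S/cm² places the free resting potential
  at −69.2 mV (target ≈ −68 mV); no adjustment from the published value
  was needed once I_h used the −68.9 mV half-activation fit.
* **Membrane area** 9.207×10⁻⁵ cm² sets the input resistance measured
  from −60 mV with −20 pA steps to 75 MΩ at steady state. Because all
  intrinsic conductances are densities, R_in is exactly inversely
  proportional to area, so one measurement suffices. With the slow I_h
  time constant (~700 ms near rest), 400 ms steps report an apparent
  R_in of ~82 MΩ because I_h has not finished settling; both values sit
  inside the documented 75 ± 15% band.
* **Na/Kdr voltage shift** (−52 mV) positions the spike threshold. It was
  chosen against the qualitative facts that define the two afferent
  classes: a single 16 nS "Large" input fires the cell from −60 mV; four
  coincident 2 nS "Small" inputs do not (nor do they fire it anywhere in
  a 500 ms train at ICI ≥ 100 ms); +300 pA from rest yields a sustained
  tonic train; release from −300 pA yields a low-threshold burst doublet
  (complete within ~15 ms of its first spike, which follows release by
  ~22 ms). The persistent-Na midpoint (−34 mV) was
  chosen jointly with this shift: with more hyperpolarized midpoints,
  subthreshold EPSP plateaus near −47 mV regenerate through I_NaP and
  slow K2 inactivation, and the Small-input class loses its defining
  subthreshold character.

The (−150, +80) mV limits are sanity rails: crossing them aborts the
trial with a diagnostic, it never clamps.

## Synapses

Each afferent stream drives one synapse with an AMPA and an NMDA
component, both difference-of-exponentials normalized to unit peak:
AMPA rise 0.6 ms / decay 2.0 ms; NMDA rise 8 ms / decay 40 ms. A single
naive event therefore peaks at exactly `g_ampa_max` (AMPA) and
`g_ampa_max × nmda_ampa_ratio × nmda_scale` (NMDA, before Mg²⁺ block).
The NMDA decay is the room-temperature "≈100 ms" class scaled to 36 °C
with Q10 ≈ 2.3; with an unscaled 100 ms decay, linear summation at
ICI ≤ 10 ms accumulates several hundred nS of NMDA conductance and
drives the cell into depolarization block, which is incompatible with
the sustained non-synchronized firing the model exists to produce.

The NMDA voltage dependence is the Jahr–Stevens sigmoid
`B(V) = 1/(1 + [Mg]·e^(−0.062V)/3.57)` at [Mg²⁺] = 1 mM (half-block
≈ −20.5 mV).

**Receptor saturation.** The summed NMDA conductance of one stream is
clipped at `nmda_sat_mult` (default 1.4) times its single-event peak —
a receptor-pool bound in the spirit of kinetic (saturating) receptor
models. Below the bound, superposition of events is exact; the bound
only engages for rapid trains. AMPA sums linearly (its fast decay never
approaches saturation at the intervals modeled).

**Short-term plasticity** is a multiplicative resource model: each event
is scaled by a running amplitude A; after the event A ← A·f, and between
events A relaxes to 1 with time constant τ_rec. Defaults: depression
f = 0.45, τ_rec = 150 ms — paired-pulse ratio ≈ 0.54 at 25 ms, with
depression still visible at 100–200 ms; facilitation f = 1.2,
τ_rec = 150 ms, capped at A ≤ 2 ("weak" facilitation; the cap prevents
runaway at short intervals). The four regimes are None, PPD (both
components depress), PPF (both facilitate) and Mixed (AMPA depresses,
NMDA facilitates). Plasticity state is strictly per-stream.

**Afferent presets.** `Large` = 2 streams, 16 nS AMPA, NMDA/AMPA 0.5,
PPD (the sparse, strong, depressing "driver" terminals of the ventral
MGB); `Small` = 4 streams, 2 nS AMPA, NMDA/AMPA 2, Mixed by default
(the convergent, weak, facilitating terminals of the dorsal MGB).

## IC input streams

A click train of inter-click interval ICI and duration 500 ms defines a
half-open nominal grid (clicks at onset + k·ICI, k·ICI < duration). Each
stream keeps each click with probability p(ICI) and jitters kept spikes
by N(0, σ²); σ is either absolute (default 1 ms) or a fraction of the
ICI. Times are re-sorted, clipped to the stimulus window, and spikes
closer than 0.1 ms are merged (count logged).

p(ICI) is a logistic in log-ICI with p(25 ms) = 0.95 and p(3 ms) ≈ 0.1
(midpoint 7.23 ms). The anchor at 25 ms follows the described IC
behavior (probability near 1 above 25 ms); the low-ICI tail was set so
that the model's first-spike-latency minimum for Small facilitating
inputs falls at ICI ≈ 10 ms, the documented behavior, which is
attributed precisely to the drop in input probability below 10 ms. The
curve is a parametric stand-in for a figure-only empirical curve; both
parameters are exposed in `StimulusSpec`.

Randomness is counter-based: generator seeded by (master seed, trial,
stream), so any trial is reproducible in isolation and trials are
order-independent.

## Numerics

Fixed-step integration at dt = 0.02 ms: exponential Euler for the twelve
gating variables against their voltage-dependent steady states, and a
semi-implicit (backward-Euler on the ohmic part) voltage update; GHK
currents enter explicitly. Synaptic kernels are advanced exactly
(per-step decay factors) with event deposits snapped to the nearest grid
point (≤ 0.01 ms error). A classical RK4 path over the full state vector
serves as an independent reference; halving dt from the default moves
spike times by < 0.1 ms and the resting potential by < 0.01 mV.

Bias current for a target holding potential is found by bisection
(tolerance 1 pA, cached per parameter set); calibration fails loudly if
the settled membrane spikes or misses the target by > 0.5 mV.

## Analysis conventions

* Spikes: upward crossings of 0 mV, 1 ms refractory merge.
* Firing rate and spike counts: entire stimulus duration.
* Vector strength VS = (1/n)·√((Σcos φ)² + (Σsin φ)²) with
  φ = 2π·((t − onset) mod ICI)/ICI, computed over spikes pooled across
  trials within the sustained-response window (onset + 50 ms → stimulus
  end). Zero spikes → VS undefined (NaN), never 0.
* Rayleigh statistic R = 2nVS², synchronized iff R > 13.8 (P < 0.001).
* First-spike latency: per-trial first spike after onset, averaged over
  spiking trials (median available); undefined if no trial spikes.
* Rate gain: output rate / mean per-stream input rate, same window.
* Synchronization boundary: the smallest tested ICI such that every
  tested ICI at or above it is synchronized (monotone closure), which
  tolerates isolated stochastic flips below the boundary.

## What the synthetic inputs do and do not emulate

The generator reproduces the first-order statistics the protocol
specifies — period-dependent thinning, Gaussian timing jitter,
independent streams — and nothing more: no adaptation of IC rate across
the train, no across-stream correlation, no stimulus-level envelope
(clicks only, no SAM tones), and no systematic latency differences
between streams unless a per-stream latency is configured. Passing
tests therefore certify the transformation from idealized IC spike
statistics to MGB response classes, not the realism of IC coding itself.

## Known limitations

* Detected firing rates under very strong NMDA drive (conductance-grid
  cells with NMDA/AMPA ratio ≥ 2 at 10 ms ICI) reach 150–190 spikes/s,
  roughly twice the ceiling reported for the original model. With
  peak-normalized kernels and the 1 mM Jahr–Stevens block, those cells
  sustain a pedestal-driven tonic mode; damping it enough to cap rates
  at ~90 spikes/s (e.g. stronger Mg²⁺ block) abolishes the defining
  suprathreshold behavior of Large inputs. The original supplementary
  synaptic equations (unavailable) most likely used saturating kinetic
  receptor models with lower effective NMDA efficacy.
* First-spike latency of Large inputs plateaus at 3–5 ms here versus
  ≈ 7 ms reported; the latency is set by the fast AMPA kernel and spike
  threshold, and lengthening it by slowing the kernel breaks the
  sub/suprathreshold dichotomies that define the input classes.
* At 100% NMDA the Small presets emit sparse late-train spikes at
  ICI = 100 ms (none at 150 ms). This matches the reported
  NMDA-scaling series (maximum spiking ICI 150/100/50 ms at
  150/100/50% NMDA) but not the separate statement that Small inputs
  are strictly subthreshold at ICI ≥ 100 ms; the two published
  statements are mutually inconsistent at the 100 ms point.
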