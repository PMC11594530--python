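# Methods

`blafear` simulates a minimal biophysical circuit of the basolateral
amygdala (BLA) in which three interneuron classes orchestrate the
spike-timing-dependent plasticity (STDP) that binds a sensory (CS) pathway
to a fear-output (F) neuron, and in which the signature of successful
learning is an increase of low-theta (2.5–4 Hz) power in a local-field-
potential (LFP) proxy.

## Cell models

All cells are single-compartment Hodgkin–Huxley models,

    cm dV/dt = −ΣI_membrane − ΣI_synaptic + I_app + I_noise,

with `cm = 1 µF/cm²` (so with mV/ms/µA-per-cm² units the voltage derivative
equals the current sum), voltages in mV, time in ms.  Gates obey
`dx/dt = (x∞(V) − x)/τx(V)`; channels specified through opening/closing
rates use `x∞ = α/(α+β)`, `τx = 1/(α+β)`.

* **VIP** — fast Na⁺ (instantaneous `m∞³h`, ḡNa = 112.5), delayed-rectifier
  K⁺ with *two* activation gates (`n²`, ḡK = 225), leak (0.25, EL = −70),
  and a D-type potassium current `ḡD a³b (V−EK)` with ḡD = 3, τa = 2 ms,
  τb = 150 ms.  The slowly inactivating D-current makes the cell a
  burster: short gamma bursts (intra-burst ≈ 40 Hz) recurring at low theta
  (≈ 3.5 Hz) at the 4 µA/cm² baseline drive.
* **SOM** — O-LM-like: fast Na⁺ (`m³h`, ḡNa = 52), K⁺ (`n⁴`, ḡK = 11), leak
  (0.62, EL = −65), H-current `ḡH (0.65hf + 0.35hs)(V−EH)` (ḡH = 1.45,
  EH = −20) and persistent Na⁺ `ḡP p (V−ENa)` (ḡP = 0.5, τp = 0.15 ms).
  H- and NaP-currents pace it at ≈ 12 Hz (upper high-theta) at
  0.1 µA/cm².
* **PV** — fast-spiking `m³h`/`n⁴` cell (ḡNa = 100, ḡK = 80, leak 0.1,
  EL = −67).  No applied current: silent unless excited.
* **E** (ECS, F, stimulus relays) — the classic reduced fast-spiking
  pyramidal model with instantaneous `m∞³h` sodium, `n⁴` potassium and the
  φ = 5 temperature factor on the h/n kinetics of its source model (the
  printed rate functions without φ put the F natural frequency at 18 Hz
  instead of its stated ≈ 11 Hz at 0.35 µA/cm²; with φ = 5 it is 11.0 Hz).

Three printed SOM time-constant expressions are typographically corrupted
in the source description; the package uses the standard published O-LM
forms (`τhf = 0.51/(e^{(V−1.7)/10} + e^{−(V+340)/52}) + 1`,
`τhs = 5.6/(e^{(V−1.7)/14} + e^{−(V+260)/43}) + 1`,
`h∞s = σ(−(V+2.83)/15.9)^58`), validated by the ≈ 12 Hz natural frequency.
Removable singularities of α/β ratios of the form `c·u/(1 − e^{−u/s})` are
series-guarded within |u| < 10⁻⁶.

## Synapses and connectivity

GABA_A and AMPA synapses carry one gate each,
`ds/dt = g_open(V_pre)(1 − s) − s/τ`, with presynaptic-type-specific open
rates (VIP `2(1+tanh(V/4))`, PV `7.5(1+tanh(V/0.1))`, SOM
`2.5(1+tanh(V/0.1))`, AMPA `5(1+tanh(V/4))`) and decay constants (10, 8.3,
20, 2 ms).  Currents are `ḡ s (V_post − E_rev)` with E_rev = −80 mV
(GABA_A) / 0 mV (AMPA).  The graph has exactly nine projection types —
VIP→PV, VIP→SOM, PV→F, PV→ECS, SOM→F, SOM→ECS (inhibitory) and ECS→F,
F→PV, F→VIP (excitatory) — all-to-all between populations, with inhibitory
conductances scaled 1/N as published.  The published VIP→SOM scaling uses
the *postsynaptic* count (1/N_SOM); it is kept verbatim, with a
`scale_by="pre"` switch for the symmetric alternative.  PV→SOM, PV→VIP,
SOM→PV and SOM→VIP connections are deliberately absent (reported weak).
ECS→F starts at zero and is plastic up to 0.18 mS/cm²; feedback inhibition
PV→F (0.5/N_PV) is stronger than lateral PV→ECS (0.4/N_PV), which biases
ECS to fire just before F inside each gamma cycle.

## Plasticity

The ECS→F conductance follows a pair-based trace STDP rule over the whole
spike history: a potentiation trace P (+A₊ per ECS spike, τ₊ = 14 ms) and a
depression trace M (−A₋ per F spike, τ₋ = 28 ms).  An ECS spike weakens
ḡ by the current M (floor 0); an F spike strengthens ḡ by the current P
(ceiling ḡmax = 0.18).  With A₊ = A₋ = 0.005 and τ₊ < τ₋ the rule is
depression-dominated: random co-activity drains the synapse
(E[dḡ/dt] ∝ A₊τ₊ − A₋τ₋ < 0) and only gamma-locked pre-before-post timing
*plus* periodic pauses (which let M relax) can net-potentiate.  Within one
spike event, traces are first decayed to the spike time, the conductance
update uses the pre-update trace, then the trace increment is applied; a
coincident pre and post spike in the same integration step is processed
pre-first (the description is silent; the fixed choice is documented here
and covered by the event-driven equivalence test).  A classical-Hebbian
configuration (A₊τ₊ > A₋τ₋) and a weak non-depression-dominated F→VIP rule
(A₊ = 0.00065, A₋ = 0.0003, ḡmax = 0.04) are available as variants.

## Stimuli

CS and US are homogeneous Poisson event trains (λ = 800 events/s,
independent streams) driving two auxiliary excitatory relay neurons.  Each
event depolarizes a virtual presynaptic unit for 1 ms; its gate follows the
standard AMPA kinetics and drives the relay with a conductance of
0.03 mS/cm², calibrated once so that the relay (fan-out conductance
0.2 mS/cm²) makes ECS and PV fire at ≈ 50 Hz in isolation — the only
normative number for this coupling.  The relays carry no applied current so
they are silent when their stream is off.  The US additionally raises the
VIP applied current 4 → 5 µA/cm² and the F current 0.35 → 0.5 µA/cm².  A
routing variant feeds PV from the US relay instead of the CS relay.
Shipped paradigms: `baseline`, `cs_probe`, `pairing_2s` (1 s CS + 1 s
CS+US), `conditioning_40s` (CS+US effects on for 40 s), and
`conditioning_15_30` (15 s CS+US, then 30 s CS alone).

## Integration

Classical RK4 at dt = 0.05 ms on the full coupled system.  Gaussian noise
(mean 0, sd 1) enters as an additive current of amplitude `k·dt` per step
(k = 5 for VIP, 4 otherwise), drawn once per cell per step and held
constant across the four stages; this follows the published recipe
literally, and a `noise_scaling="sqrt_dt"` option provides the
dt-invariant Euler–Maruyama alternative for convergence studies.  Gates are
clamped to [0, 1] after each step.  Initial voltages are drawn uniformly
from [−70, −60] mV with gates at steady state (realizations differ only in
initial state and noise).  Heterogeneous networks (3 VIP, 3 SOM, 3 PV,
10 ECS, 10 F; 5 CS-responsive ECS and 5 US-responsive F, the rest included
as unresponsive contributors to the LFP) jitter each cell's applied current
by ±5% (uniform, config-exposed) — the published description requires
"independent noise and cellular parameters" without a distribution.
Spikes are upward 0 mV crossings with a 2 ms refractory. The inner loop is
numba-compiled; plasticity updates are clock-driven at integration steps
and verified against an exact event-driven oracle (< 10⁻⁹ relative error
for grid-aligned spikes).

Under dt halving a noise-free network run preserves every spike count with
spike-time shifts < 2 ms; pointwise voltage comparison is not meaningful
for spiking trajectories because a sub-0.1 ms spike shift produces tens of
mV of instantaneous difference on the upstroke.

## LFP and spectra

The LFP proxy is the linear sum of all AMPA, GABA, D-, NaP- and H-currents
(the model has no spatial extension); a rectified variant sums absolute
values per current.  Currents are recorded at 1 kHz with boxcar averaging
over the 20-step window (all analysis bands are < 70 Hz).  Spectra are
Thomson multitaper estimates — DPSS tapers, NW = 4, 2·NW−1 = 7 tapers,
eigenvalue-weighted, signal demeaned — on 0.1–70 Hz, after discarding the
first 2000 ms of every run as transient.  Band power is the trapezoidal
integral with edges interpolated onto the grid (adjacent bands partition
exactly); the band peak density is also reported since "power" can denote
either.  Population spike spectra use 5 ms binned, mean-subtracted counts.

A realization is a *learner* when its (population-mean) ECS→F conductance
ends above 0.12 mS/cm² after 40 s of conditioning; crossing
0.037 mS/cm² at 15 s predicts learner status in the 15 s + 30 s paradigm.
Pre/post comparisons use a two-sided Wilcoxon rank-sum test (exact null for
n ≤ 25 without ties, tie-corrected normal approximation otherwise).

## Biomarker protocol

*Pre* is a baseline probe (no CS/US) of the naive network; *post* is a
CS-only probe with the learned ECS→F conductances installed (10 s analyzed
after the 2 s transient).  Non-learners are harvested as published: 10 s
conditioning runs whose conductance stays below 0.037 mS/cm².  The
alternative "pre = CS probe of the naive network" was examined and rejected
as default: it erases the high-theta invariance (CS drive roughly doubles
12–14 Hz power) while the baseline definition reproduces all three
contrasts — learner low-theta increase, high-theta unchanged, no
non-learner change.  The biomarker is expressed by the multi-cell network,
where ten F cells project onto three PV cells and the learned pathway paces
their summed AMPA currents at low theta; the single-cell network's lone
F→PV stream is too weak against the intrinsic currents to move the total
LFP, so spectral comparisons default to the heterogeneous configuration.

## Problem sizes and defaults

Defaults used by the shipped experiments and tests: natural-frequency scans
10 s (30 s for the VIP burst-repetition spectrum); conditioning 40 s (or
15 s + 30 s); ablation suites 5 realizations per variant; biomarker
comparisons 4 learners + 3 harvested non-learners with 12 s probes.  These
are the package's CI-scale presets; the CLI exposes the full-size
equivalents (e.g. 20–40 realizations) for overnight replication.

## Known limitations

* No neuromodulator dynamics: the sustained CS/US effects are scheduled by
  hand, as in the source description.
* No synaptic delays, gap junctions, multi-compartment morphology, or NMDA
  biophysics (the STDP rule stands in for receptor-level plasticity).
* The noise amplitude recipe (`k·dt`) ties noise strength to the step size;
  it is kept for fidelity, with the variance-preserving option available.
* Learner/non-learner proportions are seed-dependent; the heterogeneous
  network here learns somewhat faster than the published mean trajectory,
  so non-learner harvesting discards ~90% of candidate runs.
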