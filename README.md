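# blafear

A biophysical simulator of fear learning in the basolateral amygdala (BLA),
for computational neuroscientists studying how interneuron-generated
rhythms gate synaptic plasticity.

The model is a Hodgkin–Huxley network of three interneuron classes — VIP
cells (D-current bursters, low theta ~3–6 Hz), SOM cells (H- and
persistent-sodium currents, high theta ~12 Hz) and PV cells (fast spikers
that form a PING gamma rhythm with the excitatory cells) — plus excitatory
projection neurons encoding the conditioned stimulus (ECS) and the fear
response (F).  During conditioning, Poisson CS/US drives and applied-current
changes co-activate ECS and F, and a depression-dominated trace STDP rule

    dP/dt = −P/τ₊,  P ← P + A₊ at each ECS spike
    dM/dt = −M/τ₋,  M ← M − A₋ at each F spike
    ECS spike:  ḡ ← max(0, ḡ + M)      (weakening)
    F spike:    ḡ ← min(ḡmax, ḡ + P)   (strengthening)

with A₊ = A₋ = 0.005, τ₊ = 14 ms < τ₋ = 28 ms, ḡmax = 0.18 mS/cm², grows
the ECS→F conductance only when the interneurons provide both gamma-locked
pre-before-post timing (PING) and periodic pauses (VIP low-theta bursting
through SOM/PV).  Removing any interneuron class abolishes learning.  After
learning, the new pathway paces AMPA currents at low theta and the LFP
proxy (linear sum of all AMPA, GABA, D-, NaP- and H-currents) shows a
low-theta (2.5–4 Hz) power increase — a spectral biomarker of successful
conditioning.

## Worked example

```python
import blafear as bf
from blafear.experiments import mean_plastic_g, run_ablation

net = bf.assemble(bf.NetworkConfig())          # 1 VIP, 1 SOM, 1 PV, 1 ECS, 1 F
res = bf.run(net, "conditioning_40s", seed=1)  # 40 s paired CS+US
g = mean_plastic_g(res)
print(f"g(15 s) = {g[15000]:.3f}, g(40 s) = {g[-1]:.3f} mS/cm^2")

abl = run_ablation("noVIP", n_realizations=5, base_seed=0)
print(f"noVIP learners: {abl.learner_count}/{abl.n}")
```

prints

```
g(15 s) = 0.137, g(40 s) = 0.180 mS/cm^2
noVIP learners: 0/5
```

The full network crosses the 0.12 mS/cm² learner criterion before the 15 s
mark and saturates at ḡmax = 0.18; without VIP cells the conductance
never leaves zero.  The same interfaces are exposed on the command line:

```
blafear scan-frequencies --cell VIP --cell SOM --cell F
blafear condition --paradigm conditioning_15_30 --n 20 --seed 0
blafear ablate --variant noPV --quick
blafear biomarker --quick --out biomarker.csv
```

## Layout

| module | contents |
| --- | --- |
| `blafear.cellmodels` | HH currents and gating kinetics of VIP/SOM/PV/E cells, shipped parameter table |
| `blafear.synapses` | GABA_A/AMPA kinetics, the 9-projection connectivity graph, 1/N scaling |
| `blafear.plasticity` | depression-dominated trace STDP, event- and clock-driven forms |
| `blafear.stimuli` | Poisson CS/US drives, relay neurons, applied-current schedules, paradigms |
| `blafear.simulator` | network assembly, numba RK4 kernel (dt = 0.05 ms), spike detection |
| `blafear.analysis` | LFP proxy, multitaper spectra, band power, learner stats, rank-sum tests |
| `blafear.experiments` | frequency scans, conditioning, ablations, biomarker comparison |
| `blafear.cli` | `blafear` command-line entry point |

Model details, parameter provenance and design decisions are documented in
[docs/methods.md](docs/methods.md).
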