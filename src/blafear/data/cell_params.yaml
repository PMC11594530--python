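# Biophysical parameter table, version 1.
# Conductances in mS/cm^2, reversal potentials in mV, capacitance uF/cm^2.
# Iapp here is the cell class's intrinsic baseline; role-specific applied
# currents (F vs ECS vs auxiliary relay, US modulation) live in the stimulus
# schedule, not in this table.
# noise_amp_per_dt is the per-step noise recipe: I_noise = k * dt * N(0,1).
version: 1
VIP:
  gNa: 112.5
  ENa: 50.0
  gK: 225.0
  EK: -90.0
  gL: 0.25
  EL: -70.0
  gD: 3.0
  cm: 1.0
  Iapp: 4.0
  noise_amp_per_dt: 5.0
SOM:
  gNa: 52.0
  ENa: 55.0
  gK: 11.0
  EK: -90.0
  gL: 0.62
  EL: -65.0
  gH: 1.45
  EH: -20.0
  gP: 0.5
  cm: 1.0
  Iapp: 0.1
  noise_amp_per_dt: 4.0
PV:
  gNa: 100.0
  ENa: 50.0
  gK: 80.0
  EK: -100.0
  gL: 0.1
  EL: -67.0
  cm: 1.0
  Iapp: 0.0
  noise_amp_per_dt: 4.0
E:
  gNa: 100.0
  ENa: 50.0
  gK: 80.0
  EK: -100.0
  gL: 0.1
  EL: -67.0
  cm: 1.0
  Iapp: 0.35
  noise_amp_per_dt: 4.0
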