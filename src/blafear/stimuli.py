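"""Conditioned/unconditioned stimulus machinery and paradigm scheduling.

The conditioned stimulus (CS) is a homogeneous Poisson event train
(lambda = 800 events/s) driving an auxiliary excitatory relay neuron that
projects with AMPA conductance 0.2 mS/cm^2 onto the CS-encoding projection
cells (ECS) and onto PV, calibrated so both fire at ~50 Hz in isolation.
The unconditioned stimulus (US) is an independent Poisson train driving a
second relay that excites the fear cell F the same way; the US additionally
raises the VIP applied current from 4 to 5 uA/cm^2 and the F applied
current from 0.35 to 0.5 uA/cm^2.  A routing variant feeds PV from the US
relay instead of the CS relay.

Poisson events reach the relay as 1-ms depolarized pulses of a virtual
presynaptic unit whose gate follows the standard AMPA kinetics; only the
~50 Hz downstream rate is normative, and the virtual-unit drive conductance
is the single calibrated constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .cellmodels import ConfigurationError
from .synapses import SynapseSpec, _ampa

#: baseline applied current per cell role (uA/cm^2)
BASELINE_IAPP: Dict[str, float] = {
    "VIP": 4.0, "SOM": 0.1, "PV": 0.0, "ECS": 0.45, "F": 0.35, "AUX": 0.0,
}
#: overrides while the US is on
US_IAPP: Dict[str, float] = {"VIP": 5.0, "F": 0.5}

POISSON_RATE = 800.0  # events/s
G_AUX = 0.2  # relay -> target AMPA conductance, mS/cm^2
#: virtual Poisson unit -> relay drive conductance (mS/cm^2), calibrated so
#: the relay makes ECS and PV fire at ~50 Hz in isolation.
G_DRIVE = 0.03
PULSE_WIDTH = 1.0  # ms the virtual unit stays depolarized after an event
PULSE_V_ON = 30.0  # mV
PULSE_V_OFF = -70.0  # mV


@dataclass(frozen=True)
class PhaseSpec:
    t_start: float  # ms
    t_end: float
    cs_on: bool = False
    us_on: bool = False

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ConfigurationError("phase requires t_start < t_end")


def validate_phases(phases: Sequence[PhaseSpec]) -> None:
    for a, b in zip(phases, phases[1:]):
        if b.t_start < a.t_end:
            raise ConfigurationError("phases must be ordered and non-overlapping")


@dataclass(frozen=True)
class StimulusConfig:
    rate: float = POISSON_RATE  # events/s
    g_aux: float = G_AUX
    g_drive: float = G_DRIVE
    routing: str = "US->VIP"  # standard; "US->PV" is the appendix variant
    pulse_width: float = PULSE_WIDTH

    def __post_init__(self) -> None:
        if self.rate < 0 or self.g_aux < 0 or self.g_drive < 0:
            raise ConfigurationError("rate and conductances must be >= 0")
        if self.routing not in ("US->VIP", "US->PV"):
            raise ConfigurationError("routing must be 'US->VIP' or 'US->PV'")


def poisson_train(rate: float, t0: float, t1: float, rng: np.random.Generator) -> np.ndarray:
    """Ordered homogeneous Poisson event times (ms) on [t0, t1).

    ``rate`` is in events per second.  Reproducible given the generator
    state; CS and US use independently spawned streams.
    """
    if t1 < t0:
        raise ValueError("need t0 <= t1")
    if rate == 0 or t1 == t0:
        return np.empty(0)
    rate_ms = rate / 1000.0
    n_guess = int((t1 - t0) * rate_ms + 6.0 * np.sqrt((t1 - t0) * rate_ms) + 16)
    times: List[np.ndarray] = []
    t = t0
    while t < t1:
        gaps = rng.exponential(1.0 / rate_ms, size=n_guess)
        ts = t + np.cumsum(gaps)
        times.append(ts)
        t = ts[-1]
    all_ts = np.concatenate(times)
    return all_ts[all_ts < t1]


def phase_train(
    rate: float, phases: Sequence[PhaseSpec], flag: str, rng: np.random.Generator
) -> np.ndarray:
    """Poisson events restricted to the phases where ``flag`` (cs/us) is on."""
    validate_phases(phases)
    parts = [
        poisson_train(rate, p.t_start, p.t_end, rng)
        for p in phases
        if getattr(p, f"{flag}_on")
    ]
    return np.concatenate(parts) if parts else np.empty(0)


def applied_current(cell_role: str, phases: Sequence[PhaseSpec], t: float) -> float:
    """Applied current (uA/cm^2) of a cell role at time t under a schedule."""
    role = cell_role.rstrip("0123456789")
    if role.startswith("AUX"):
        role = "AUX"
    if role not in BASELINE_IAPP:
        raise ConfigurationError(f"unknown cell role {cell_role!r}")
    for p in phases:
        if p.t_start <= t < p.t_end or (p is phases[-1] and t == p.t_end):
            if p.us_on and role in US_IAPP:
                return US_IAPP[role]
            return BASELINE_IAPP[role]
    raise ValueError(f"t={t} ms lies outside the stimulus schedule")


@dataclass
class DriveSpec:
    """A virtual Poisson unit driving one relay cell through an AMPA gate."""

    target: str  # cell id (an AUX relay)
    source: str  # "CS" | "US" -- selects the event stream
    g: float


def build_stimulus_network(
    config: StimulusConfig,
    ecs_targets: Sequence[str],
    pv_targets: Sequence[str],
    f_targets: Sequence[str],
) -> Tuple[List[str], List[SynapseSpec], List[DriveSpec]]:
    """Auxiliary relay cells, their AMPA fan-out, and the Poisson drives.

    Standard routing: the CS relay excites ECS and PV, the US relay excites
    F.  In the ``US->PV`` variant PV is driven by the US relay instead.
    """
    aux = ["AUXCS", "AUXUS"]
    syns: List[SynapseSpec] = []
    for t in ecs_targets:
        syns.append(_ampa("AUXCS", t, config.g_aux))
    pv_src = "AUXCS" if config.routing == "US->VIP" else "AUXUS"
    for t in pv_targets:
        syns.append(_ampa(pv_src, t, config.g_aux))
    for t in f_targets:
        syns.append(_ampa("AUXUS", t, config.g_aux))
    drives = [
        DriveSpec("AUXCS", "CS", config.g_drive),
        DriveSpec("AUXUS", "US", config.g_drive),
    ]
    return aux, syns, drives


def export_train(path, times: np.ndarray, source_id: str) -> None:
    """Write a spike/event train as two-column delimited text
    (time_ms, source_id)."""
    with open(path, "w") as f:
        f.write("time_ms\tsource_id\n")
        for t in np.asarray(times, float):
            f.write(f"{t:.3f}\t{source_id}\n")


# ---------------------------------------------------------------------------
# Paradigm presets
# ---------------------------------------------------------------------------

def paradigm(name: str, duration: float | None = None) -> List[PhaseSpec]:
    """Shipped stimulus paradigms.

    * ``baseline``          -- no CS/US (pre-conditioning probe), default 12 s
    * ``cs_probe``          -- CS only (post-conditioning probe), default 12 s
    * ``pairing_2s``        -- 2 s CS with US during the second half
    * ``conditioning_40s``  -- CS+US effects continuously on for 40 s
    * ``conditioning_15_30``-- 15 s CS+US effects, then 30 s CS alone
    """
    if name == "baseline":
        T = duration or 12000.0
        return [PhaseSpec(0.0, T, False, False)]
    if name == "cs_probe":
        T = duration or 12000.0
        return [PhaseSpec(0.0, T, True, False)]
    if name == "pairing_2s":
        return [PhaseSpec(0.0, 1000.0, True, False), PhaseSpec(1000.0, 2000.0, True, True)]
    if name == "conditioning_40s":
        T = duration or 40000.0
        return [PhaseSpec(0.0, T, True, True)]
    if name == "conditioning_15_30":
        return [PhaseSpec(0.0, 15000.0, True, True), PhaseSpec(15000.0, 45000.0, True, False)]
    raise ConfigurationError(f"unknown paradigm {name!r}")


PARADIGMS = ("baseline", "cs_probe", "pairing_2s", "conditioning_40s", "conditioning_15_30")
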