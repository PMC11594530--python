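"""Network assembly and RK4 integration of the coupled BLA circuit.

The full model is a system of coupled ODEs: per cell a voltage plus up to
six gating variables, per synapse one gate, plus the AMPA gates of the two
virtual Poisson drive units.  It is integrated with the classical
fourth-order Runge-Kutta scheme at dt = 0.05 ms.  Additive Gaussian noise
(zero mean, unit sd, amplitude ``k*dt`` with k = 5 for VIP and 4 otherwise)
is drawn once per cell per step and held constant across the four stages.
Gates are clamped to [0, 1] after each step.

Spikes are detected as upward crossings of 0 mV separated by at least 2 ms;
each detected spike of a plastic synapse's pre/post cell triggers the
clock-driven STDP update (traces decayed each step, conductance updated
with the pre-update trace, pre events before post events within a step).

The inner loop is numba-compiled; a full 40 s single-realization run takes
seconds rather than hours.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from . import cellmodels as cm
from . import stimuli as st
from .cellmodels import ConfigurationError, _NJIT
from .plasticity import ECS_F_RULE, F_VIP_RULE, STDPRule
from .synapses import SynapseSpec, _open_rate, build_connectivity

DT_DEFAULT = 0.05  # ms
SPIKE_THRESHOLD = 0.0  # mV
REFRACTORY = 2.0  # ms
TRANSIENT_MS = 2000.0  # discarded by spectral analysis downstream

_TYPE_CODE = {"VIP": 0, "SOM": 1, "PV": 2, "E": 3}

# parameter-matrix columns
_PC = dict(gNa=0, ENa=1, gK=2, EK=3, gL=4, EL=5, gD=6, gH=7, gP=8, EH=9, cm=10, namp=11)


# ---------------------------------------------------------------------------
# Configuration / assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    """Composition and variant switches of one network instance."""

    sizes: Dict[str, int] = field(
        default_factory=lambda: {"VIP": 1, "SOM": 1, "PV": 1, "ECS": 1, "F": 1}
    )
    ablate: Tuple[str, ...] = ()
    connect: bool = True  # False drops all recurrent synapses (calibration)
    attach_stimulus: bool = True
    stimulus: st.StimulusConfig = field(default_factory=st.StimulusConfig)
    rule: STDPRule = ECS_F_RULE
    plastic_f_vip: bool = False
    rule_f_vip: STDPRule = F_VIP_RULE
    scale_by: str = "printed"
    n_cs_ecs: Optional[int] = None  # ECS cells receiving CS (default: all)
    n_us_f: Optional[int] = None  # F cells receiving US (default: all)
    iapp_jitter: float = 0.0  # multiplicative U(1-j, 1+j) heterogeneity
    iapp_overrides: Dict[str, float] = field(default_factory=dict)
    noise_scaling: str = "printed"  # "printed": k*dt; "sqrt_dt": k*sqrt(dt)
    noise_off: bool = False

    def __post_init__(self) -> None:
        for pop in self.ablate:
            if pop not in ("VIP", "SOM", "PV"):
                raise ConfigurationError(f"cannot ablate population {pop!r}")
        if self.noise_scaling not in ("printed", "sqrt_dt"):
            raise ConfigurationError("noise_scaling must be 'printed' or 'sqrt_dt'")


def heterogeneous_config(**kwargs) -> NetworkConfig:
    """The multi-cell network: 3 of each interneuron class, 10 of each
    projection class, 5 CS-responsive ECS and 5 US-responsive F cells,
    +/-5% applied-current jitter."""
    defaults = dict(
        sizes={"VIP": 3, "SOM": 3, "PV": 3, "ECS": 10, "F": 10},
        n_cs_ecs=5, n_us_f=5, iapp_jitter=0.05,
    )
    defaults.update(kwargs)
    return NetworkConfig(**defaults)


@dataclass
class Network:
    """Assembled network: cell labels, parameter matrix, synapse arrays."""

    config: NetworkConfig
    cells: List[str]
    roles: List[str]  # VIP/SOM/PV/ECS/F/AUX per cell
    type_code: np.ndarray
    params: np.ndarray  # (n, 12) parameter matrix
    synapses: List[SynapseSpec]
    syn_pre: np.ndarray
    syn_post: np.ndarray
    syn_kind: np.ndarray
    syn_g: np.ndarray
    syn_E: np.ndarray
    syn_tau: np.ndarray
    plastic_mask: np.ndarray
    plastic_rule: np.ndarray  # -1 not plastic, 0 ECS->F rule, 1 F->VIP rule
    drives: List[st.DriveSpec]
    cs_targets: List[str]
    us_targets: List[str]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def plastic_labels(self) -> List[str]:
        return [
            f"{s.pre}->{s.post}"
            for s, pl in zip(self.synapses, self.plastic_mask)
            if pl
        ]

    def index(self, cell: str) -> int:
        return self.cells.index(cell)

    def set_plastic_g(self, values: np.ndarray | float) -> None:
        """Install learned conductances (e.g. for a post-conditioning probe)."""
        idx = np.flatnonzero(self.plastic_mask)
        self.syn_g[idx] = values


def assemble(config: NetworkConfig) -> Network:
    """Build the network described by ``config``.

    Populations are laid out in the order VIP, SOM, PV, ECS, F, AUX.  The
    ablation set removes whole interneuron populations together with every
    synapse touching them.
    """
    cell_db = cm.load_cell_params()
    sizes = dict(config.sizes)
    for pop in config.ablate:
        sizes[pop] = 0
    for pop, n in sizes.items():
        if n < 0:
            raise ConfigurationError(f"sizes[{pop}] must be >= 0")

    ids = {p: [f"{p}{i}" for i in range(sizes.get(p, 0))] for p in ("VIP", "SOM", "PV", "ECS", "F")}
    n_cs = config.n_cs_ecs if config.n_cs_ecs is not None else len(ids["ECS"])
    n_us = config.n_us_f if config.n_us_f is not None else len(ids["F"])
    cs_targets = ids["ECS"][:n_cs]
    us_targets = ids["F"][:n_us]

    if config.connect:
        syns = build_connectivity(
            sizes, scale_by=config.scale_by, plastic_f_vip=config.plastic_f_vip,
            ecs_plastic=cs_targets, f_plastic=us_targets,
        )
    else:
        syns = []

    cells: List[str] = []
    roles: List[str] = []
    for p in ("VIP", "SOM", "PV", "ECS", "F"):
        cells.extend(ids[p])
        roles.extend([p] * len(ids[p]))

    drives: List[st.DriveSpec] = []
    if config.attach_stimulus:
        aux, aux_syns, drives = st.build_stimulus_network(
            config.stimulus, cs_targets, ids["PV"], us_targets
        )
        cells.extend(aux)
        roles.extend(["AUX"] * len(aux))
        syns = syns + aux_syns

    n = len(cells)
    if n == 0:
        raise ConfigurationError("network has no cells")
    type_code = np.empty(n, dtype=np.int8)
    params = np.zeros((n, 12))
    for i, role in enumerate(roles):
        ctype = role if role in ("VIP", "SOM", "PV") else "E"
        p = cell_db[ctype]
        type_code[i] = _TYPE_CODE[ctype]
        params[i, _PC["gNa"]] = p.gNa
        params[i, _PC["ENa"]] = p.ENa
        params[i, _PC["gK"]] = p.gK
        params[i, _PC["EK"]] = p.EK
        params[i, _PC["gL"]] = p.gL
        params[i, _PC["EL"]] = p.EL
        params[i, _PC["gD"]] = p.gD or 0.0
        params[i, _PC["gH"]] = p.gH or 0.0
        params[i, _PC["gP"]] = p.gP or 0.0
        params[i, _PC["EH"]] = p.EH or 0.0
        params[i, _PC["cm"]] = p.cm
        params[i, _PC["namp"]] = 0.0 if config.noise_off else p.noise_amp_per_dt

    index = {c: i for i, c in enumerate(cells)}
    ns = len(syns)
    syn_pre = np.array([index[s.pre] for s in syns], dtype=np.int64) if ns else np.empty(0, np.int64)
    syn_post = np.array([index[s.post] for s in syns], dtype=np.int64) if ns else np.empty(0, np.int64)
    syn_kind = np.array([s.kind_code for s in syns], dtype=np.int8) if ns else np.empty(0, np.int8)
    syn_g = np.array([s.g for s in syns]) if ns else np.empty(0)
    syn_E = np.array([s.E_rev for s in syns]) if ns else np.empty(0)
    syn_tau = np.array([s.tau_decay for s in syns]) if ns else np.empty(0)
    plastic_mask = np.array([s.plastic for s in syns], dtype=bool) if ns else np.empty(0, bool)
    plastic_rule = np.full(ns, -1, dtype=np.int8)
    for j, s in enumerate(syns):
        if s.plastic:
            plastic_rule[j] = 1 if s.post.startswith("VIP") else 0

    return Network(
        config=config, cells=cells, roles=roles, type_code=type_code,
        params=params, synapses=syns, syn_pre=syn_pre, syn_post=syn_post,
        syn_kind=syn_kind, syn_g=syn_g, syn_E=syn_E, syn_tau=syn_tau,
        plastic_mask=plastic_mask, plastic_rule=plastic_rule, drives=drives,
        cs_targets=cs_targets, us_targets=us_targets,
    )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

COMPONENTS = ("AMPA", "GABA", "D", "H", "NaP", "ABS")


@dataclass
class SimulationResult:
    t: np.ndarray  # recorded time grid (ms)
    V: np.ndarray  # (n_rec, n_cells)
    cells: List[str]
    roles: List[str]
    spikes: List[np.ndarray]  # per cell, strictly increasing times
    comp_t: np.ndarray
    comp: Dict[str, np.ndarray]  # LFP current components, boxcar-decimated
    g_t: np.ndarray
    g_traj: np.ndarray  # (n_g_rec, n_plastic)
    plastic_labels: List[str]
    final_plastic_g: np.ndarray
    dt: float
    seed: int
    config_hash: str
    transient_ms: float = TRANSIENT_MS

    def spike_times(self, cell: str) -> np.ndarray:
        return self.spikes[self.cells.index(cell)]

    def rate(self, cell: str, t0: float = 0.0, t1: Optional[float] = None) -> float:
        """Mean firing rate (Hz) of one cell over [t0, t1] ms."""
        t1 = t1 if t1 is not None else float(self.t[-1]) if self.t.size else 0.0
        if t1 <= t0:
            return 0.0
        s = self.spike_times(cell)
        return float(np.sum((s >= t0) & (s <= t1)) / ((t1 - t0) / 1000.0))

    def plastic_g_at(self, t_ms: float) -> np.ndarray:
        """Plastic conductances at (the recorded sample nearest to) t_ms."""
        if self.g_t.size == 0:
            return self.final_plastic_g
        k = int(np.argmin(np.abs(self.g_t - t_ms)))
        return self.g_traj[k]


def config_hash(config: NetworkConfig, phases: Sequence[st.PhaseSpec], dt: float) -> str:
    payload = json.dumps(
        {
            "sizes": config.sizes, "ablate": list(config.ablate),
            "connect": config.connect,
            "stimulus": config.stimulus.__dict__, "rule": config.rule.__dict__,
            "plastic_f_vip": config.plastic_f_vip, "scale_by": config.scale_by,
            "n_cs_ecs": config.n_cs_ecs, "n_us_f": config.n_us_f,
            "iapp_jitter": config.iapp_jitter,
            "iapp_overrides": config.iapp_overrides,
            "noise_scaling": config.noise_scaling, "noise_off": config.noise_off,
            "phases": [(p.t_start, p.t_end, p.cs_on, p.us_on) for p in phases],
            "dt": dt,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Generic RK4 step (used for oracle tests; the kernel applies the same scheme)
# ---------------------------------------------------------------------------

def rk4_step(f: Callable, y: np.ndarray, t: float, dt: float) -> np.ndarray:
    """One classical fourth-order Runge-Kutta step of dy/dt = f(t, y)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    k1 = f(t, y)
    k2 = f(t + dt / 2.0, y + dt / 2.0 * k1)
    k3 = f(t + dt / 2.0, y + dt / 2.0 * k2)
    k4 = f(t + dt, y + dt * k3)
    return y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(**_NJIT)
def _rhs(type_code, params, V, G, S, sD, drive_V, drive_g, drive_target,
         syn_pre, syn_post, syn_kind, syn_g, syn_E, syn_tau,
         iapp, inoise, dV, dG, dS, dsD, isyn):
    n = V.shape[0]
    ns = syn_g.shape[0]
    nd = drive_g.shape[0]
    for i in range(n):
        isyn[i] = 0.0
    for j in range(ns):
        vp = V[syn_pre[j]]
        rate = _open_rate(syn_kind[j], vp)
        s = S[j]
        dS[j] = rate * (1.0 - s) - s / syn_tau[j]
        po = syn_post[j]
        isyn[po] += syn_g[j] * s * (V[po] - syn_E[j])
    for d in range(nd):
        rate = _open_rate(3, drive_V[d])
        s = sD[d]
        dsD[d] = rate * (1.0 - s) - s / 2.0
        tgt = drive_target[d]
        isyn[tgt] += drive_g[d] * s * V[tgt]  # E_AMPA = 0
    for i in range(n):
        v = V[i]
        tc = type_code[i]
        gNa = params[i, 0]; ENa = params[i, 1]
        gK = params[i, 2]; EK = params[i, 3]
        gL = params[i, 4]; EL = params[i, 5]
        imem = gL * (v - EL)
        if tc == 0:  # VIP
            h = G[i, 0]; nn = G[i, 1]; a = G[i, 2]; b = G[i, 3]
            m = cm.vip_m_inf(v)
            imem += gNa * m * m * m * h * (v - ENa)
            imem += gK * nn * nn * (v - EK)
            imem += params[i, 6] * a * a * a * b * (v - EK)  # D-current
            hinf, tauh = cm.vip_h_inf_tau(v)
            ninf, taun = cm.vip_n_inf_tau(v)
            ainf, taua = cm.vip_a_inf_tau(v)
            binf, taub = cm.vip_b_inf_tau(v)
            dG[i, 0] = (hinf - h) / tauh
            dG[i, 1] = (ninf - nn) / taun
            dG[i, 2] = (ainf - a) / taua
            dG[i, 3] = (binf - b) / taub
            dG[i, 4] = 0.0; dG[i, 5] = 0.0
        elif tc == 1:  # SOM
            m = G[i, 0]; h = G[i, 1]; nn = G[i, 2]
            hf = G[i, 3]; hs = G[i, 4]; p = G[i, 5]
            imem += gNa * m * m * m * h * (v - ENa)
            imem += gK * nn ** 4 * (v - EK)
            imem += params[i, 7] * (0.65 * hf + 0.35 * hs) * (v - params[i, 9])
            imem += params[i, 8] * p * (v - ENa)
            minf, taum = cm.som_m_inf_tau(v)
            hinf, tauh = cm.som_h_inf_tau(v)
            ninf, taun = cm.som_n_inf_tau(v)
            hfinf, tauhf = cm.som_hf_inf_tau(v)
            hsinf, tauhs = cm.som_hs_inf_tau(v)
            pinf, taup = cm.som_p_inf_tau(v)
            dG[i, 0] = (minf - m) / taum
            dG[i, 1] = (hinf - h) / tauh
            dG[i, 2] = (ninf - nn) / taun
            dG[i, 3] = (hfinf - hf) / tauhf
            dG[i, 4] = (hsinf - hs) / tauhs
            dG[i, 5] = (pinf - p) / taup
        elif tc == 2:  # PV
            m = G[i, 0]; h = G[i, 1]; nn = G[i, 2]
            imem += gNa * m * m * m * h * (v - ENa)
            imem += gK * nn ** 4 * (v - EK)
            minf, taum = cm.pv_m_inf_tau(v)
            hinf, tauh = cm.pv_h_inf_tau(v)
            ninf, taun = cm.pv_n_inf_tau(v)
            dG[i, 0] = (minf - m) / taum
            dG[i, 1] = (hinf - h) / tauh
            dG[i, 2] = (ninf - nn) / taun
            dG[i, 3] = 0.0; dG[i, 4] = 0.0; dG[i, 5] = 0.0
        else:  # E
            h = G[i, 0]; nn = G[i, 1]
            m = cm.e_m_inf(v)
            imem += gNa * m * m * m * h * (v - ENa)
            imem += gK * nn ** 4 * (v - EK)
            hinf, tauh = cm.e_h_inf_tau(v)
            ninf, taun = cm.e_n_inf_tau(v)
            dG[i, 0] = (hinf - h) / tauh
            dG[i, 1] = (ninf - nn) / taun
            dG[i, 2] = 0.0; dG[i, 3] = 0.0; dG[i, 4] = 0.0; dG[i, 5] = 0.0
        dV[i] = (-imem - isyn[i] + iapp[i] + inoise[i]) / params[i, 10]


@njit(**_NJIT)
def _drive_voltage(tau, ev_times, e0, e1, ptr, last_ev, pulse_width):
    # advance the event pointer to tau (monotone across stages/steps)
    p = ptr
    last = last_ev
    while p < e1 and ev_times[p] <= tau:
        last = ev_times[p]
        p += 1
    if tau - last < pulse_width:
        return 30.0, p, last
    return -70.0, p, last


@njit(**_NJIT)
def _integrate(type_code, params, noise_amp,
               phase_edges, iapp_phase,
               syn_pre, syn_post, syn_kind, syn_g, syn_E, syn_tau,
               plastic_rule, rules,
               drive_target, drive_g, ev_times, ev_off, pulse_width,
               V0, G0, n_steps, dt, seed,
               rec_every, g_rec_every, spike_thresh, refractory, max_spikes):
    n = V0.shape[0]
    ns = syn_g.shape[0]
    nd = drive_g.shape[0]
    np.random.seed(seed)

    V = V0.copy()
    G = G0.copy()
    S = np.zeros(ns)
    sD = np.zeros(nd)

    # plastic bookkeeping
    n_plast = 0
    for j in range(ns):
        if plastic_rule[j] >= 0:
            n_plast += 1
    plast_idx = np.empty(n_plast, np.int64)
    k = 0
    for j in range(ns):
        if plastic_rule[j] >= 0:
            plast_idx[k] = j
            k += 1
    P = np.zeros(n_plast)
    M = np.zeros(n_plast)
    nrules = rules.shape[0]
    dec_p = np.empty(nrules)
    dec_m = np.empty(nrules)
    for r in range(nrules):
        dec_p[r] = math.exp(-dt / rules[r, 2])
        dec_m[r] = math.exp(-dt / rules[r, 3])

    # recording buffers
    n_rec = n_steps // rec_every + 1
    t_rec = np.empty(n_rec)
    V_rec = np.empty((n_rec, n))
    comp_rec = np.zeros((n_rec, 6))
    n_grec = n_steps // g_rec_every + 1
    g_t = np.empty(n_grec)
    g_rec = np.empty((n_grec, n_plast))

    spike_cell = np.empty(max_spikes, np.int64)
    spike_t = np.empty(max_spikes)
    n_spk = 0
    last_spike = np.full(n, -1e9)

    # work arrays
    dV1 = np.empty(n); dV2 = np.empty(n); dV3 = np.empty(n); dV4 = np.empty(n)
    dG1 = np.empty((n, 6)); dG2 = np.empty((n, 6)); dG3 = np.empty((n, 6)); dG4 = np.empty((n, 6))
    dS1 = np.empty(ns); dS2 = np.empty(ns); dS3 = np.empty(ns); dS4 = np.empty(ns)
    dD1 = np.empty(nd); dD2 = np.empty(nd); dD3 = np.empty(nd); dD4 = np.empty(nd)
    Vw = np.empty(n); Gw = np.empty((n, 6)); Sw = np.empty(ns); Dw = np.empty(nd)
    isyn = np.empty(n)
    inoise = np.zeros(n)
    drv_V = np.empty(nd)
    ev_ptr = np.empty(nd, np.int64)
    ev_last = np.empty(nd)
    for d in range(nd):
        ev_ptr[d] = ev_off[d]
        ev_last[d] = -1e9
    spiked = np.empty(n, np.uint8)
    comp_acc = np.zeros(6)

    # initial recording
    t_rec[0] = 0.0
    for i in range(n):
        V_rec[0, i] = V[i]
    g_t[0] = 0.0
    for q in range(n_plast):
        g_rec[0, q] = syn_g[plast_idx[q]]

    phase_i = 0
    n_phase = phase_edges.shape[0] - 1
    status = 0
    t_last_valid = 0.0

    for step in range(n_steps):
        t = step * dt
        while phase_i < n_phase - 1 and t >= phase_edges[phase_i + 1]:
            phase_i += 1
        iapp = iapp_phase[phase_i]

        for i in range(n):
            if noise_amp[i] > 0.0:
                inoise[i] = noise_amp[i] * np.random.normal(0.0, 1.0)
            else:
                inoise[i] = 0.0

        # stage 1 at t
        for d in range(nd):
            v, p, last = _drive_voltage(t, ev_times, ev_off[d], ev_off[d + 1],
                                        ev_ptr[d], ev_last[d], pulse_width)
            drv_V[d] = v; ev_ptr[d] = p; ev_last[d] = last
        _rhs(type_code, params, V, G, S, sD, drv_V, drive_g, drive_target,
             syn_pre, syn_post, syn_kind, syn_g, syn_E, syn_tau,
             iapp, inoise, dV1, dG1, dS1, dD1, isyn)

        # stages 2/3 at t + dt/2
        tm = t + 0.5 * dt
        for d in range(nd):
            v, p, last = _drive_voltage(tm, ev_times, ev_off[d], ev_off[d + 1],
                                        ev_ptr[d], ev_last[d], pulse_width)
            drv_V[d] = v; ev_ptr[d] = p; ev_last[d] = last
        for i in range(n):
            Vw[i] = V[i] + 0.5 * dt * dV1[i]
            for g in range(6):
                Gw[i, g] = G[i, g] + 0.5 * dt * dG1[i, g]
        for j in range(ns):
            Sw[j] = S[j] + 0.5 * dt * dS1[j]
        for d in range(nd):
            Dw[d] = sD[d] + 0.5 * dt * dD1[d]
        _rhs(type_code, params, Vw, Gw, Sw, Dw, drv_V, drive_g, drive_target,
             syn_pre, syn_post, syn_kind, syn_g, syn_E, syn_tau,
             iapp, inoise, dV2, dG2, dS2, dD2, isyn)

        for i in range(n):
            Vw[i] = V[i] + 0.5 * dt * dV2[i]
            for g in range(6):
                Gw[i, g] = G[i, g] + 0.5 * dt * dG2[i, g]
        for j in range(ns):
            Sw[j] = S[j] + 0.5 * dt * dS2[j]
        for d in range(nd):
            Dw[d] = sD[d] + 0.5 * dt * dD2[d]
        _rhs(type_code, params, Vw, Gw, Sw, Dw, drv_V, drive_g, drive_target,
             syn_pre, syn_post, syn_kind, syn_g, syn_E, syn_tau,
             iapp, inoise, dV3, dG3, dS3, dD3, isyn)

        # stage 4 at t + dt
        tp = t + dt
        for d in range(nd):
            v, p, last = _drive_voltage(tp, ev_times, ev_off[d], ev_off[d + 1],
                                        ev_ptr[d], ev_last[d], pulse_width)
            drv_V[d] = v; ev_ptr[d] = p; ev_last[d] = last
        for i in range(n):
            Vw[i] = V[i] + dt * dV3[i]
            for g in range(6):
                Gw[i, g] = G[i, g] + dt * dG3[i, g]
        for j in range(ns):
            Sw[j] = S[j] + dt * dS3[j]
        for d in range(nd):
            Dw[d] = sD[d] + dt * dD3[d]
        _rhs(type_code, params, Vw, Gw, Sw, Dw, drv_V, drive_g, drive_target,
             syn_pre, syn_post, syn_kind, syn_g, syn_E, syn_tau,
             iapp, inoise, dV4, dG4, dS4, dD4, isyn)

        # combine and clamp
        for i in range(n):
            v_old = V[i]
            V[i] = v_old + dt / 6.0 * (dV1[i] + 2.0 * dV2[i] + 2.0 * dV3[i] + dV4[i])
            for g in range(6):
                x = G[i, g] + dt / 6.0 * (dG1[i, g] + 2.0 * dG2[i, g] + 2.0 * dG3[i, g] + dG4[i, g])
                if x < 0.0:
                    x = 0.0
                elif x > 1.0:
                    x = 1.0
                G[i, g] = x
            spiked[i] = 0
            if v_old < spike_thresh and V[i] >= spike_thresh and tp - last_spike[i] >= refractory:
                if n_spk < max_spikes:
                    spike_cell[n_spk] = i
                    spike_t[n_spk] = tp
                    n_spk += 1
                last_spike[i] = tp
                spiked[i] = 1
            if not math.isfinite(V[i]) or abs(V[i]) > 500.0:
                status = 1
        for j in range(ns):
            x = S[j] + dt / 6.0 * (dS1[j] + 2.0 * dS2[j] + 2.0 * dS3[j] + dS4[j])
            if x < 0.0:
                x = 0.0
            elif x > 1.0:
                x = 1.0
            S[j] = x
        for d in range(nd):
            x = sD[d] + dt / 6.0 * (dD1[d] + 2.0 * dD2[d] + 2.0 * dD3[d] + dD4[d])
            if x < 0.0:
                x = 0.0
            elif x > 1.0:
                x = 1.0
            sD[d] = x

        if status != 0:
            t_last_valid = t
            break
        t_last_valid = tp

        # clock-driven STDP: decay traces, then pre updates, then post updates
        if n_plast > 0:
            for q in range(n_plast):
                r = plastic_rule[plast_idx[q]]
                P[q] *= dec_p[r]
                M[q] *= dec_m[r]
            for q in range(n_plast):
                j = plast_idx[q]
                if spiked[syn_pre[j]] == 1:
                    r = plastic_rule[j]
                    g_new = syn_g[j] + M[q]
                    syn_g[j] = g_new if g_new > 0.0 else 0.0
                    P[q] += rules[r, 0]
            for q in range(n_plast):
                j = plast_idx[q]
                if spiked[syn_post[j]] == 1:
                    r = plastic_rule[j]
                    g_new = syn_g[j] + P[q]
                    gmax = rules[r, 4]
                    syn_g[j] = g_new if g_new < gmax else gmax
                    M[q] -= rules[r, 1]

        # LFP current components (instantaneous, boxcar-averaged on output)
        for j in range(ns):
            po = syn_post[j]
            cur = syn_g[j] * S[j] * (V[po] - syn_E[j])
            if syn_kind[j] == 3:
                comp_acc[0] += cur
            else:
                comp_acc[1] += cur
            comp_acc[5] += abs(cur)
        for d in range(nd):
            tgt = drive_target[d]
            cur = drive_g[d] * sD[d] * V[tgt]
            comp_acc[0] += cur
            comp_acc[5] += abs(cur)
        for i in range(n):
            if type_code[i] == 0:
                a = G[i, 2]; b = G[i, 3]
                cur = params[i, 6] * a * a * a * b * (V[i] - params[i, 3])
                comp_acc[2] += cur
                comp_acc[5] += abs(cur)
            elif type_code[i] == 1:
                cur = params[i, 7] * (0.65 * G[i, 3] + 0.35 * G[i, 4]) * (V[i] - params[i, 9])
                comp_acc[3] += cur
                comp_acc[5] += abs(cur)
                cur = params[i, 8] * G[i, 5] * (V[i] - params[i, 1])
                comp_acc[4] += cur
                comp_acc[5] += abs(cur)

        if (step + 1) % rec_every == 0:
            idx = (step + 1) // rec_every
            t_rec[idx] = tp
            for i in range(n):
                V_rec[idx, i] = V[i]
            for c in range(6):
                comp_rec[idx, c] = comp_acc[c] / rec_every
                comp_acc[c] = 0.0
        if (step + 1) % g_rec_every == 0:
            idx = (step + 1) // g_rec_every
            g_t[idx] = tp
            for q in range(n_plast):
                g_rec[idx, q] = syn_g[plast_idx[q]]

    final_g = np.empty(n_plast)
    for q in range(n_plast):
        final_g[q] = syn_g[plast_idx[q]]
    return (t_rec, V_rec, comp_rec, spike_cell[:n_spk], spike_t[:n_spk],
            g_t, g_rec, final_g, V, G, status, t_last_valid)


# ---------------------------------------------------------------------------
# run()
# ---------------------------------------------------------------------------

def _initial_state(network: Network, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    n = network.n_cells
    V0 = rng.uniform(-70.0, -60.0, size=n)
    G0 = np.zeros((n, 6))
    code_to_type = {v: k for k, v in _TYPE_CODE.items()}
    for i in range(n):
        ctype = code_to_type[int(network.type_code[i])]
        gates = cm.steady_gating(ctype, V0[i])
        for g, name in enumerate(cm.GATES[ctype]):
            G0[i, g] = gates[name]
    return V0, G0


def _iapp_schedule(
    network: Network, phases: Sequence[st.PhaseSpec], jitter: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    edges = np.array([phases[0].t_start] + [p.t_end for p in phases])
    iapp = np.zeros((len(phases), network.n_cells))
    ov = network.config.iapp_overrides
    for pi, p in enumerate(phases):
        for i, role in enumerate(network.roles):
            cell = network.cells[i]
            base = ov.get(cell, ov.get(role, st.BASELINE_IAPP[role]))
            if p.us_on and role in st.US_IAPP and role not in ov and cell not in ov:
                base = st.US_IAPP[role]
            iapp[pi, i] = base * jitter[i]
    return edges, iapp


def run(
    network: Network,
    phases: Sequence[st.PhaseSpec] | str,
    seed: int = 0,
    dt: float = DT_DEFAULT,
    rec_every: Optional[int] = None,
    g_rec_every: Optional[int] = None,
    spike_threshold: float = SPIKE_THRESHOLD,
    refractory: float = REFRACTORY,
) -> SimulationResult:
    """Simulate ``network`` under a stimulus schedule.

    ``phases`` is a list of :class:`~blafear.stimuli.PhaseSpec` or a shipped
    paradigm name.  The run is bit-reproducible for a fixed (network config,
    phases, seed, dt).  Voltages and LFP current components are recorded at
    1 kHz (boxcar-averaged for the currents), plastic conductances every ms.
    """
    if isinstance(phases, str):
        phases = st.paradigm(phases)
    st.validate_phases(phases)
    duration = phases[-1].t_end - phases[0].t_start
    if phases[0].t_start != 0.0:
        raise ConfigurationError("schedules must start at t = 0")
    n_steps = int(round(duration / dt))
    rec_every = rec_every or max(1, int(round(1.0 / dt)))
    g_rec_every = g_rec_every or max(1, int(round(1.0 / dt)))

    ss = np.random.SeedSequence(seed)
    init_ss, cs_ss, us_ss, noise_ss = ss.spawn(4)
    init_rng = np.random.default_rng(init_ss)
    noise_seed = int(noise_ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)

    V0, G0 = _initial_state(network, init_rng)
    jitter = np.ones(network.n_cells)
    if network.config.iapp_jitter > 0:
        j = network.config.iapp_jitter
        jitter = init_rng.uniform(1.0 - j, 1.0 + j, size=network.n_cells)
        for i, role in enumerate(network.roles):
            if role == "AUX":
                jitter[i] = 1.0
    edges, iapp = _iapp_schedule(network, phases, jitter)

    # stimulus event streams
    ev_list = []
    for d in network.drives:
        rng = np.random.default_rng(cs_ss if d.source == "CS" else us_ss)
        ev_list.append(st.phase_train(network.config.stimulus.rate, list(phases),
                                      d.source.lower(), rng))
    ev_off = np.zeros(len(ev_list) + 1, dtype=np.int64)
    for i, ev in enumerate(ev_list):
        ev_off[i + 1] = ev_off[i] + len(ev)
    ev_times = np.concatenate(ev_list) if ev_list else np.empty(0)
    drive_target = np.array(
        [network.index(d.target) for d in network.drives], dtype=np.int64
    ) if network.drives else np.empty(0, np.int64)
    drive_g = np.array([d.g for d in network.drives]) if network.drives else np.empty(0)

    noise_amp = network.params[:, _PC["namp"]].copy()
    if network.config.noise_scaling == "printed":
        noise_amp *= dt
    else:
        noise_amp *= math.sqrt(dt)

    rules = np.array(
        [
            [network.config.rule.A_plus, network.config.rule.A_minus,
             network.config.rule.tau_plus, network.config.rule.tau_minus,
             network.config.rule.g_max],
            [network.config.rule_f_vip.A_plus, network.config.rule_f_vip.A_minus,
             network.config.rule_f_vip.tau_plus, network.config.rule_f_vip.tau_minus,
             network.config.rule_f_vip.g_max],
        ]
    )

    syn_g = network.syn_g.copy()
    max_spikes = int(network.n_cells * duration * 0.25) + 1024

    chash = config_hash(network.config, phases, dt)

    if n_steps == 0:
        n_plast = int(network.plastic_mask.sum())
        return SimulationResult(
            t=np.zeros(1), V=V0[None, :], cells=list(network.cells),
            roles=list(network.roles),
            spikes=[np.empty(0) for _ in range(network.n_cells)],
            comp_t=np.zeros(1), comp={c: np.zeros(1) for c in COMPONENTS},
            g_t=np.zeros(1), g_traj=syn_g[network.plastic_mask][None, :],
            plastic_labels=network.plastic_labels,
            final_plastic_g=syn_g[network.plastic_mask],
            dt=dt, seed=seed, config_hash=chash,
        )

    (t_rec, V_rec, comp_rec, spike_cell, spike_t, g_t, g_rec, final_g,
     V_end, G_end, status, t_last) = _integrate(
        network.type_code, network.params, noise_amp,
        edges, iapp,
        network.syn_pre, network.syn_post, network.syn_kind, syn_g,
        network.syn_E, network.syn_tau,
        network.plastic_rule, rules,
        drive_target, drive_g, ev_times, ev_off,
        network.config.stimulus.pulse_width,
        V0, G0, n_steps, dt, noise_seed,
        rec_every, g_rec_every, spike_threshold, refractory, max_spikes,
    )
    if status != 0:
        raise FloatingPointError(
            f"simulation diverged; last valid time {t_last:.2f} ms"
        )

    spikes = [spike_t[spike_cell == i] for i in range(network.n_cells)]
    comp = {name: comp_rec[:, c] for c, name in enumerate(COMPONENTS)}
    return SimulationResult(
        t=t_rec, V=V_rec, cells=list(network.cells), roles=list(network.roles),
        spikes=spikes, comp_t=t_rec, comp=comp, g_t=g_t, g_traj=g_rec,
        plastic_labels=network.plastic_labels, final_plastic_g=final_g,
        dt=dt, seed=seed, config_hash=chash,
    )


def detect_spikes(
    V: np.ndarray, t: np.ndarray, threshold: float = SPIKE_THRESHOLD,
    refractory: float = REFRACTORY,
) -> np.ndarray:
    """Upward threshold crossings of a voltage trace, >= refractory apart."""
    V = np.asarray(V, float)
    t = np.asarray(t, float)
    cross = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold)) + 1
    out = []
    last = -np.inf
    for k in cross:
        if t[k] - last >= refractory:
            out.append(t[k])
            last = t[k]
    return np.array(out)


def single_cell_network(
    role: str,
    iapp: Optional[float] = None,
    noise_off: bool = False,
    attach_stimulus: bool = False,
) -> Network:
    """An isolated cell of one role (VIP/SOM/PV/ECS/F), no synapses."""
    sizes = {p: 0 for p in ("VIP", "SOM", "PV", "ECS", "F")}
    pop = role if role in ("VIP", "SOM", "PV") else role
    sizes[pop] = 1
    overrides = {} if iapp is None else {pop: iapp}
    config = NetworkConfig(
        sizes=sizes, attach_stimulus=attach_stimulus,
        iapp_overrides=overrides, noise_off=noise_off,
    )
    return assemble(config)
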