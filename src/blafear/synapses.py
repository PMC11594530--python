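"""GABAa/AMPA synaptic kinetics and the BLA connectivity graph.

Each directed synapse carries one gating variable ``s`` obeying

    ds/dt = g_open(V_pre) * (1 - s) - s / tau_decay

where the open-rate function ``g_open`` and the decay constant depend on the
presynaptic cell type (VIP: tau 10 ms, PV: 8.3 ms, SOM: 20 ms, excitatory
AMPA: 2 ms).  The postsynaptic current is ``gbar * s * (V_post - E_rev)``
(E_rev = -80 mV for GABAa, 0 mV for AMPA) and enters the membrane equation
with a minus sign.

The circuit has exactly nine projection types: six inhibitory (VIP->PV,
VIP->SOM, PV->F, PV->ECS, SOM->F, SOM->ECS) and three excitatory (ECS->F,
F->PV, F->VIP).  Inhibitory conductances are scaled by population size as
printed in the parameter set (VIP->PV: 1/N_VIP, VIP->SOM: 1/N_SOM, PV->*:
0.5 or 0.4 / N_PV, SOM->*: 0.4/N_SOM); the ECS->F synapse starts at zero
and is plastic up to 0.18 mS/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import pandas as pd
from numba import njit

from .cellmodels import ConfigurationError, _NJIT

E_GABA = -80.0
E_AMPA = 0.0
TAU_GABA = {"VIP": 10.0, "PV": 8.3, "SOM": 20.0}
TAU_AMPA = 2.0

#: presynaptic-kind codes used by the integration kernel
KIND_VIP, KIND_PV, KIND_SOM, KIND_AMPA = 0, 1, 2, 3

GMAX_ECS_F = 0.18
GMAX_F_VIP = 0.04


@dataclass
class SynapseSpec:
    """One directed connection (cell ids refer to an assembled network)."""

    pre: str
    post: str
    kind: str  # "GABAa" | "AMPA"
    g: float  # maximal conductance, mS/cm^2
    E_rev: float
    tau_decay: float
    pre_type: str  # VIP | PV | SOM | E -- selects the open-rate form
    plastic: bool = False
    g_max: float = 0.0

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ConfigurationError("synaptic conductance must be >= 0")

    @property
    def kind_code(self) -> int:
        if self.kind == "AMPA":
            return KIND_AMPA
        return {"VIP": KIND_VIP, "PV": KIND_PV, "SOM": KIND_SOM}[self.pre_type]


@njit(**_NJIT)
def _open_rate(kind_code, V_pre):
    if kind_code == 0:  # VIP GABAa
        return 2.0 * (1.0 + math.tanh(V_pre / 4.0))
    elif kind_code == 1:  # PV GABAa
        return 7.5 * (1.0 + math.tanh(V_pre / 0.1))
    elif kind_code == 2:  # SOM GABAa
        return 2.5 * (1.0 + math.tanh(V_pre / 0.1))
    else:  # AMPA
        return 5.0 * (1.0 + math.tanh(V_pre / 4.0))


def presynaptic_open_rate(pre_type: str, V_pre: float) -> float:
    """Open rate (1/ms) of the receptor gated by a presynaptic cell type.

    ``pre_type`` in {VIP, PV, SOM} selects the GABAa forms, ``E`` (or
    ``AMPA``) the AMPA form.
    """
    codes = {"VIP": KIND_VIP, "PV": KIND_PV, "SOM": KIND_SOM,
             "E": KIND_AMPA, "AMPA": KIND_AMPA}
    try:
        code = codes[pre_type]
    except KeyError:
        raise ConfigurationError(f"unknown presynaptic type {pre_type!r}") from None
    return _open_rate(code, float(V_pre))


def gate_derivative(spec: SynapseSpec, s: float, V_pre: float) -> float:
    """``ds/dt`` of the synaptic gate for a given presynaptic voltage."""
    rate = _open_rate(spec.kind_code, float(V_pre))
    return rate * (1.0 - s) - s / spec.tau_decay


def synaptic_current(spec: SynapseSpec, s: float, V_post: float) -> float:
    """Postsynaptic current ``gbar*s*(V_post - E_rev)`` (uA/cm^2).

    The membrane equation subtracts this term, so a positive value is an
    outward (hyperpolarizing) contribution.
    """
    return spec.g * s * (V_post - spec.E_rev)


def _gaba(pre: str, post: str, pre_type: str, g: float) -> SynapseSpec:
    return SynapseSpec(pre, post, "GABAa", g, E_GABA, TAU_GABA[pre_type], pre_type)


def _ampa(pre: str, post: str, g: float, plastic: bool = False, g_max: float = 0.0) -> SynapseSpec:
    return SynapseSpec(pre, post, "AMPA", g, E_AMPA, TAU_AMPA, "E",
                       plastic=plastic, g_max=g_max)


def build_connectivity(
    sizes: Dict[str, int],
    scale_by: str = "printed",
    plastic_f_vip: bool = False,
    ecs_plastic: Sequence[str] | None = None,
    f_plastic: Sequence[str] | None = None,
) -> List[SynapseSpec]:
    """All-to-all connectivity between the five principal populations.

    ``sizes`` maps population name (VIP/SOM/PV/ECS/F) to its cell count;
    zero removes the population (ablation).  Cell ids are ``"VIP0"``,
    ``"ECS3"`` etc.  ``scale_by`` selects the VIP->SOM scaling: ``printed``
    uses 1/N_SOM exactly as published, ``pre`` uses 1/N_VIP for symmetry
    with VIP->PV.  ``ecs_plastic``/``f_plastic`` restrict which ECS/F cells
    carry plastic ECS->F synapses (default: all); used by the heterogeneous
    network where only stimulus-responsive cells form the fear pathway.
    """
    for pop, n in sizes.items():
        if n < 0:
            raise ConfigurationError(f"population size {pop} must be >= 0")
    n = {p: int(sizes.get(p, 0)) for p in ("VIP", "SOM", "PV", "ECS", "F")}
    ids = {p: [f"{p}{i}" for i in range(n[p])] for p in n}
    if scale_by not in ("printed", "pre"):
        raise ConfigurationError("scale_by must be 'printed' or 'pre'")

    syns: List[SynapseSpec] = []

    def add_gaba(pre_pop, post_pop, g_each):
        for a in ids[pre_pop]:
            for b in ids[post_pop]:
                syns.append(_gaba(a, b, pre_pop, g_each))

    # inhibitory projections with the printed 1/N scalings
    if n["VIP"] and n["PV"]:
        add_gaba("VIP", "PV", 1.0 / n["VIP"])
    if n["VIP"] and n["SOM"]:
        denom = n["SOM"] if scale_by == "printed" else n["VIP"]
        add_gaba("VIP", "SOM", 1.0 / denom)
    if n["PV"] and n["F"]:
        add_gaba("PV", "F", 0.5 / n["PV"])
    if n["PV"] and n["ECS"]:
        add_gaba("PV", "ECS", 0.4 / n["PV"])
    if n["SOM"] and n["F"]:
        add_gaba("SOM", "F", 0.4 / n["SOM"])
    if n["SOM"] and n["ECS"]:
        add_gaba("SOM", "ECS", 0.4 / n["SOM"])

    # excitatory projections
    ecs_pl = set(ecs_plastic) if ecs_plastic is not None else set(ids["ECS"])
    f_pl = set(f_plastic) if f_plastic is not None else set(ids["F"])
    for a in ids["ECS"]:
        for b in ids["F"]:
            if a in ecs_pl and b in f_pl:
                syns.append(_ampa(a, b, 0.0, plastic=True, g_max=GMAX_ECS_F))
    for a in ids["F"]:
        for b in ids["PV"]:
            syns.append(_ampa(a, b, 0.5))
    for a in ids["F"]:
        for b in ids["VIP"]:
            if plastic_f_vip:
                syns.append(_ampa(a, b, 0.01, plastic=True, g_max=GMAX_F_VIP))
            else:
                syns.append(_ampa(a, b, 0.01))
    return syns


def edge_table(syns: Sequence[SynapseSpec]) -> pd.DataFrame:
    """Delimited-text-friendly edge list of a connectivity graph."""
    return pd.DataFrame(
        [
            dict(pre=s.pre, post=s.post, kind=s.kind, g=s.g, tau=s.tau_decay,
                 E_rev=s.E_rev, plastic=s.plastic)
            for s in syns
        ]
    )
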