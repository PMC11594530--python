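"""Trace-based spike-timing-dependent plasticity for the fear pathway.

The ECS->F AMPA conductance is shaped by a pair-based STDP rule that keeps
two exponentially decaying traces of the *entire* spike history:

* ``P`` (potentiation trace, >= 0): incremented by ``A_plus`` at every
  presynaptic (ECS) spike, decays with ``tau_plus``;
* ``M`` (depression trace, <= 0): decremented by ``A_minus`` at every
  postsynaptic (F) spike, decays with ``tau_minus``.

At a presynaptic spike the conductance is weakened, ``g <- g + M`` (clipped
at 0); at a postsynaptic spike it is strengthened, ``g <- g + P`` (clipped
at ``g_max``).  Within one spike event the traces are first decayed to the
spike time, the conductance update uses the trace value *excluding* the
current spike's own increment, and the increment is applied last.  When a
pre and a post spike land on the same instant, the pre update runs first.

With ``A_plus == A_minus`` and ``tau_plus < tau_minus`` (the defaults,
0.005 and 14/28 ms) the rule is depression-dominated: for independent
Poisson pre/post trains the expected drift per pre-post spike-pair rate is
``A_plus*tau_plus - A_minus*tau_minus < 0``, so net potentiation requires
fine pre-before-post timing plus pauses that let ``M`` relax.  The plastic
F->VIP variant (``A_plus = 0.00065``, ``A_minus = 0.0003``) is not
depression-dominated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Tuple

import numpy as np


@dataclass(frozen=True)
class STDPRule:
    A_plus: float = 0.005
    A_minus: float = 0.005
    tau_plus: float = 14.0  # ms
    tau_minus: float = 28.0  # ms
    g_max: float = 0.18  # mS/cm^2

    def __post_init__(self) -> None:
        for name in ("A_plus", "A_minus", "tau_plus", "tau_minus", "g_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def depression_dominated(self) -> bool:
        return self.A_plus * self.tau_plus < self.A_minus * self.tau_minus


#: depression-dominated default for the ECS->F fear synapse
ECS_F_RULE = STDPRule()
#: non-depression-dominated variant for the plastic F->VIP synapse
F_VIP_RULE = STDPRule(A_plus=0.00065, A_minus=0.0003, g_max=0.04)
#: classical Hebbian configuration (potentiation-dominated at equal taus)
CLASSICAL_HEBBIAN_RULE = STDPRule(A_plus=0.005, A_minus=0.005 * 14.0 / 28.0 * 0.5,
                                  tau_plus=14.0, tau_minus=28.0)


@dataclass(frozen=True)
class PlasticityState:
    P: float = 0.0
    M: float = 0.0
    g: float = 0.0

    def __post_init__(self) -> None:
        if self.P < 0 or self.M > 0:
            raise ValueError("require P >= 0 and M <= 0")


def decay_traces(state: PlasticityState, dt: float, rule: STDPRule) -> PlasticityState:
    """Relax both traces toward zero over ``dt`` ms; ``g`` is untouched."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return replace(
        state,
        P=state.P * math.exp(-dt / rule.tau_plus),
        M=state.M * math.exp(-dt / rule.tau_minus),
    )


def on_pre_spike(state: PlasticityState, rule: STDPRule) -> PlasticityState:
    """Presynaptic (ECS) spike: weaken by the current M, then bump P."""
    g = max(0.0, state.g + state.M)
    return PlasticityState(P=state.P + rule.A_plus, M=state.M, g=g)


def on_post_spike(state: PlasticityState, rule: STDPRule) -> PlasticityState:
    """Postsynaptic (F) spike: strengthen by the current P, then dip M."""
    g = min(rule.g_max, state.g + state.P)
    return PlasticityState(P=state.P, M=state.M - rule.A_minus, g=g)


def run_event_driven(
    pre_times: Iterable[float],
    post_times: Iterable[float],
    rule: STDPRule,
    g0: float = 0.0,
) -> PlasticityState:
    """Exact event-driven evolution over two sorted spike-time lists (ms).

    Traces decay analytically between events; coincident pre/post spikes are
    processed pre-first.  This is the reference semantics the clock-driven
    simulator update must reproduce when spikes fall on grid points.
    """
    events = sorted(
        [(float(t), 0) for t in pre_times] + [(float(t), 1) for t in post_times]
    )
    state = PlasticityState(g=g0)
    t_last = events[0][0] if events else 0.0
    for t, which in events:
        state = decay_traces(state, t - t_last, rule)
        state = on_pre_spike(state, rule) if which == 0 else on_post_spike(state, rule)
        t_last = t
    return state


def run_clock_driven(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    rule: STDPRule,
    t_end: float,
    dt: float,
    g0: float = 0.0,
) -> PlasticityState:
    """Clock-driven evolution exactly as the integration kernel applies it.

    Per step the traces are multiplied by the precomputed per-step decay
    factors; spikes whose grid-rounded time falls at the end of the step are
    then applied, all pre updates before all post updates.
    """
    n_steps = int(round(t_end / dt))
    pre_idx = np.unique(np.round(np.asarray(pre_times, float) / dt).astype(np.int64))
    post_idx = np.unique(np.round(np.asarray(post_times, float) / dt).astype(np.int64))
    dec_p = math.exp(-dt / rule.tau_plus)
    dec_m = math.exp(-dt / rule.tau_minus)
    P, M, g = 0.0, 0.0, g0
    ip = ipo = 0
    for k in range(n_steps + 1):
        if k > 0:
            P *= dec_p
            M *= dec_m
        if ip < pre_idx.size and pre_idx[ip] == k:
            g = max(0.0, g + M)
            P += rule.A_plus
            ip += 1
        if ipo < post_idx.size and post_idx[ipo] == k:
            g = min(rule.g_max, g + P)
            M -= rule.A_minus
            ipo += 1
    return PlasticityState(P=P, M=M, g=g)


def expected_drift(rule: STDPRule, rate_pre: float, rate_post: float) -> float:
    """Expected conductance drift (mS/cm^2 per second) for independent
    stationary Poisson pre/post trains, ignoring the clip bounds.

    Each post spike collects the mean potentiation trace
    ``A_plus*tau_plus*rate_pre/1000`` and each pre spike the mean depression
    trace, giving ``rate_pre*rate_post*(A_plus*tau_plus -
    A_minus*tau_minus)`` with rates in Hz and taus in ms.
    """
    return rate_pre * rate_post * (
        rule.A_plus * rule.tau_plus - rule.A_minus * rule.tau_minus
    ) * 1e-3
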