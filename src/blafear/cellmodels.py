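"""Hodgkin-Huxley single-compartment models of the four BLA cell classes.

The circuit contains three interneuron classes and one excitatory class:

* ``VIP`` -- bursting interneurons whose D-type potassium current produces
  gamma bursts nested in a low-theta envelope,
* ``SOM`` -- O-LM-like interneurons whose H-current and persistent sodium
  current pace firing in the high-theta range (~12 Hz),
* ``PV``  -- fast-spiking interneurons, silent without input, that form a
  PING gamma rhythm with the excitatory cells,
* ``E``   -- excitatory projection neurons (used for the CS-encoding cell
  ECS, the fear cell F, and the auxiliary stimulus relays).

Every cell obeys ``cm dV/dt = -sum(I_membrane) - sum(I_synaptic) + I_app +
I_noise`` with currents in uA/cm^2, voltages in mV and time in ms.  Gating
variables follow first-order kinetics ``dx/dt = (x_inf(V) - x)/tau_x(V)``;
channels specified through opening/closing rates use ``x_inf = a/(a+b)``,
``tau_x = 1/(a+b)``.  The sodium activation gate of VIP and E cells is
algebraic (``m = m_inf(V)``, never integrated); SOM and PV integrate ``m``.

All rate functions are numba-jitted scalar functions so that the same code
is used by the Python-facing API and by the network integration kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Tuple

import yaml
from numba import njit

CELL_TYPES = ("VIP", "SOM", "PV", "E")

#: integrated gating variables per cell type (order fixed; the kernel relies
#: on it).  ``m`` of VIP and E is algebraic and therefore not listed.
GATES: Dict[str, Tuple[str, ...]] = {
    "VIP": ("h", "n", "a", "b"),
    "SOM": ("m", "h", "n", "hf", "hs", "p"),
    "PV": ("m", "h", "n"),
    "E": ("h", "n"),
}

#: algebraic gates, valid in ``steady_state_and_tau`` but never integrated.
ALGEBRAIC_GATES: Dict[str, Tuple[str, ...]] = {"VIP": ("m",), "E": ("m",)}


class ConfigurationError(ValueError):
    """Raised for invalid cell/channel pairings or malformed parameters."""


@dataclass(frozen=True)
class CellParams:
    """Biophysical constants of one cell (conductances mS/cm^2, E's in mV).

    ``noise_amp_per_dt`` is the printed noise recipe: the additive noise
    current each integration step is ``noise_amp_per_dt * dt * N(0, 1)``
    uA/cm^2 (dt in ms).
    """

    cell_type: str
    gNa: float
    ENa: float
    gK: float
    EK: float
    gL: float
    EL: float
    cm: float = 1.0
    Iapp: float = 0.0
    noise_amp_per_dt: float = 4.0
    gD: Optional[float] = None  # VIP only
    gH: Optional[float] = None  # SOM only
    gP: Optional[float] = None  # SOM only
    EH: Optional[float] = None  # SOM only

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ConfigurationError(f"unknown cell type {self.cell_type!r}")
        for name in ("gNa", "gK", "gL"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.cm <= 0:
            raise ConfigurationError("cm must be > 0")
        if self.cell_type == "VIP":
            if self.gD is None:
                raise ConfigurationError("VIP cells require gD")
        elif self.gD is not None:
            raise ConfigurationError("gD is only valid for VIP cells")
        if self.cell_type == "SOM":
            if self.gH is None or self.gP is None or self.EH is None:
                raise ConfigurationError("SOM cells require gH, gP and EH")
        elif any(v is not None for v in (self.gH, self.gP, self.EH)):
            raise ConfigurationError("gH/gP/EH are only valid for SOM cells")

    def replace(self, **kwargs) -> "CellParams":
        data = {**self.__dict__, **kwargs}
        return CellParams(**data)


def load_cell_params() -> Dict[str, CellParams]:
    """Load the shipped per-type parameter table (versioned YAML)."""
    text = resources.files("blafear").joinpath("data/cell_params.yaml").read_text()
    raw = yaml.safe_load(text)
    if raw.get("version") != 1:
        raise ConfigurationError("unsupported cell parameter table version")
    out = {}
    for cell_type in CELL_TYPES:
        if cell_type not in raw:
            raise ConfigurationError(f"parameter table misses {cell_type}")
        out[cell_type] = CellParams(cell_type=cell_type, **raw[cell_type])
    return out


# --------------------------------------------------------------------------
# numba scalar helpers.  The removable singularities of the alpha/beta forms
# c*u/(1 - exp(-u/s)) and c*u/(exp(u/s) - 1) are guarded by their limits.
# --------------------------------------------------------------------------

_NJIT = dict(cache=False, fastmath=False, error_model="numpy")


@njit(**_NJIT)
def _lin_over_one_minus_exp(c, u, s):
    # c*u / (1 - exp(-u/s)), -> c*s as u -> 0
    if abs(u) < 1e-6:
        return c * s * (1.0 + u / (2.0 * s))
    return c * u / (-math.expm1(-u / s))


@njit(**_NJIT)
def _lin_over_expm1(c, u, s):
    # c*u / (exp(u/s) - 1), -> c*s as u -> 0
    if abs(u) < 1e-6:
        return c * s * (1.0 - u / (2.0 * s))
    return c * u / math.expm1(u / s)


@njit(**_NJIT)
def _sig(v):
    return 1.0 / (1.0 + math.exp(-v))


# ----------------------------- VIP --------------------------------------- #

@njit(**_NJIT)
def vip_m_inf(V):
    return _sig((V + 24.0) / 11.5)


@njit(**_NJIT)
def vip_h_inf_tau(V):
    hinf = _sig(-(V + 58.3) / 6.7)
    tau = 0.5 + 14.0 / (1.0 + math.exp((V + 60.0) / 12.0))
    return hinf, tau


@njit(**_NJIT)
def vip_n_inf_tau(V):
    ninf = _sig((V + 12.4) / 6.8)
    tau = (0.087 + 11.4 / (1.0 + math.exp((V + 14.6) / 8.6))) * (
        0.087 + 11.4 / (1.0 + math.exp(-(V - 1.3) / 18.7))
    )
    return ninf, tau


@njit(**_NJIT)
def vip_a_inf_tau(V):
    return _sig((V + 50.0) / 20.0), 2.0


@njit(**_NJIT)
def vip_b_inf_tau(V):
    return _sig(-(V + 70.0) / 6.0), 150.0


# ----------------------------- SOM --------------------------------------- #

@njit(**_NJIT)
def som_m_inf_tau(V):
    a = _lin_over_one_minus_exp(0.1, V + 23.0, 10.0)
    b = 4.0 * math.exp(-(V + 48.0) / 18.0)
    return a / (a + b), 1.0 / (a + b)


@njit(**_NJIT)
def som_h_inf_tau(V):
    a = 0.07 * math.exp(-(V + 37.0) / 20.0)
    b = 1.0 / (math.exp(-0.1 * (V + 7.0)) + 1.0)
    return a / (a + b), 1.0 / (a + b)


@njit(**_NJIT)
def som_n_inf_tau(V):
    a = _lin_over_one_minus_exp(0.01, V + 27.0, 10.0)
    b = 0.125 * math.exp(-(V + 37.0) / 80.0)
    return a / (a + b), 1.0 / (a + b)


@njit(**_NJIT)
def som_hf_inf_tau(V):
    hinf = _sig(-(V + 79.2) / 9.78)
    tau = 0.51 / (math.exp((V - 1.7) / 10.0) + math.exp(-(V + 340.0) / 52.0)) + 1.0
    return hinf, tau


@njit(**_NJIT)
def som_hs_inf_tau(V):
    hinf = _sig(-(V + 2.83) / 15.9) ** 58
    tau = 5.6 / (math.exp((V - 1.7) / 14.0) + math.exp(-(V + 260.0) / 43.0)) + 1.0
    return hinf, tau


@njit(**_NJIT)
def som_p_inf_tau(V):
    return _sig((V + 38.0) / 6.5), 0.15


# ----------------------------- PV ---------------------------------------- #

@njit(**_NJIT)
def pv_m_inf_tau(V):
    a = _lin_over_one_minus_exp(0.32, V + 54.0, 4.0)
    b = _lin_over_expm1(0.28, V + 27.0, 5.0)
    return a / (a + b), 1.0 / (a + b)


@njit(**_NJIT)
def pv_h_inf_tau(V):
    a = 0.128 * math.exp(-(V + 50.0) / 18.0)
    b = 4.0 / (1.0 + math.exp(-(V + 27.0) / 5.0))
    return a / (a + b), 1.0 / (a + b)


@njit(**_NJIT)
def pv_n_inf_tau(V):
    a = _lin_over_one_minus_exp(0.032, V + 52.0, 5.0)
    b = 0.5 * math.exp(-(V + 57.0) / 40.0)
    return a / (a + b), 1.0 / (a + b)


# ----------------------------- E ------------------------------------------ #
# The excitatory projection cell is the classic fast-spiking reduced model
# whose h/n kinetics carry a phi = 5 temperature factor (alpha, beta both
# scaled; x_inf unchanged, tau divided by 5).  With it the F cell fires at
# its ~11 Hz natural frequency at the 0.35 uA/cm^2 baseline current.

PHI_E = 5.0


@njit(**_NJIT)
def e_m_inf(V):
    a = _lin_over_one_minus_exp(0.1, V + 35.0, 10.0)
    b = 4.0 * math.exp(-(V + 60.0) / 18.0)
    return a / (a + b)


@njit(**_NJIT)
def e_h_inf_tau(V):
    a = 0.07 * math.exp(-(V + 58.0) / 20.0)
    b = 1.0 / (math.exp(-0.1 * (V + 28.0)) + 1.0)
    return a / (a + b), 1.0 / (5.0 * (a + b))


@njit(**_NJIT)
def e_n_inf_tau(V):
    a = _lin_over_one_minus_exp(0.01, V + 34.0, 10.0)
    b = 0.125 * math.exp(-(V + 44.0) / 80.0)
    return a / (a + b), 1.0 / (5.0 * (a + b))


# --------------------------------------------------------------------------
# Python-facing API
# --------------------------------------------------------------------------

_RATE_TABLE = {
    ("VIP", "m"): lambda V: (vip_m_inf(V), 0.0),  # algebraic gate
    ("VIP", "h"): vip_h_inf_tau,
    ("VIP", "n"): vip_n_inf_tau,
    ("VIP", "a"): vip_a_inf_tau,
    ("VIP", "b"): vip_b_inf_tau,
    ("SOM", "m"): som_m_inf_tau,
    ("SOM", "h"): som_h_inf_tau,
    ("SOM", "n"): som_n_inf_tau,
    ("SOM", "hf"): som_hf_inf_tau,
    ("SOM", "hs"): som_hs_inf_tau,
    ("SOM", "p"): som_p_inf_tau,
    ("PV", "m"): pv_m_inf_tau,
    ("PV", "h"): pv_h_inf_tau,
    ("PV", "n"): pv_n_inf_tau,
    ("E", "m"): lambda V: (e_m_inf(V), 0.0),  # algebraic gate
    ("E", "h"): e_h_inf_tau,
    ("E", "n"): e_n_inf_tau,
}


def steady_state_and_tau(cell_type: str, channel: str, V: float) -> Tuple[float, float]:
    """Return ``(x_inf(V), tau_x(V))`` for one gating variable.

    For the algebraic sodium activation of VIP and E cells the returned tau
    is 0.0, flagging that the gate is evaluated instantaneously and never
    integrated.
    """
    if not math.isfinite(V):
        raise ValueError("V must be finite")
    try:
        fn = _RATE_TABLE[(cell_type, channel)]
    except KeyError:
        raise ConfigurationError(
            f"channel {channel!r} is not defined for cell type {cell_type!r}"
        ) from None
    return fn(float(V))


def steady_gating(cell_type: str, V: float) -> Dict[str, float]:
    """All integrated gates of a cell type at their voltage fixed point."""
    return {g: steady_state_and_tau(cell_type, g, V)[0] for g in GATES[cell_type]}


def gating_derivatives(cell_type: str, V: float, gating: Dict[str, float]) -> Dict[str, float]:
    """``dx/dt = (x_inf(V) - x)/tau_x(V)`` for every integrated gate."""
    out = {}
    for g in GATES[cell_type]:
        xinf, tau = steady_state_and_tau(cell_type, g, V)
        out[g] = (xinf - gating[g]) / tau
    return out


def membrane_currents(
    cell_type: str, V: float, gating: Dict[str, float], params: CellParams
) -> Dict[str, float]:
    """All intrinsic membrane currents (uA/cm^2) of one cell.

    Sodium uses the instantaneous ``m_inf^3`` form for VIP and E, the
    integrated ``m^3`` form for SOM and PV.  The potassium exponent is 2 for
    VIP (two activation gates) and 4 otherwise.
    """
    if params.cell_type != cell_type:
        raise ConfigurationError("params do not match cell_type")
    V = float(V)
    out: Dict[str, float] = {}
    if cell_type == "VIP":
        m = vip_m_inf(V)
        out["Na"] = params.gNa * m**3 * gating["h"] * (V - params.ENa)
        out["K"] = params.gK * gating["n"] ** 2 * (V - params.EK)
        out["L"] = params.gL * (V - params.EL)
        out["D"] = params.gD * gating["a"] ** 3 * gating["b"] * (V - params.EK)
    elif cell_type == "SOM":
        out["Na"] = params.gNa * gating["m"] ** 3 * gating["h"] * (V - params.ENa)
        out["K"] = params.gK * gating["n"] ** 4 * (V - params.EK)
        out["L"] = params.gL * (V - params.EL)
        out["H"] = params.gH * (0.65 * gating["hf"] + 0.35 * gating["hs"]) * (V - params.EH)
        out["P"] = params.gP * gating["p"] * (V - params.ENa)
    elif cell_type == "PV":
        out["Na"] = params.gNa * gating["m"] ** 3 * gating["h"] * (V - params.ENa)
        out["K"] = params.gK * gating["n"] ** 4 * (V - params.EK)
        out["L"] = params.gL * (V - params.EL)
    elif cell_type == "E":
        m = e_m_inf(V)
        out["Na"] = params.gNa * m**3 * gating["h"] * (V - params.ENa)
        out["K"] = params.gK * gating["n"] ** 4 * (V - params.EK)
        out["L"] = params.gL * (V - params.EL)
    else:  # pragma: no cover - guarded by CellParams
        raise ConfigurationError(f"unknown cell type {cell_type!r}")
    return out
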