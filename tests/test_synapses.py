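"""Unit tests for synaptic kinetics and the connectivity graph."""

import math

import numpy as np
import pytest

from blafear.cellmodels import ConfigurationError
from blafear.synapses import (
    SynapseSpec,
    build_connectivity,
    edge_table,
    gate_derivative,
    presynaptic_open_rate,
    synaptic_current,
)


@pytest.mark.parametrize(
    "pre,V,expected",
    [
        ("PV", 0.0, 7.5),
        ("SOM", 0.0, 2.5),
        ("VIP", 0.0, 2.0),
        ("E", 0.0, 5.0),
        ("VIP", 1000.0, 4.0),  # tanh saturation
        ("E", 1000.0, 10.0),
    ],
)
def test_open_rates(pre, V, expected):
    assert presynaptic_open_rate(pre, V) == pytest.approx(expected, rel=1e-9)


def test_open_rates_nonnegative_bounded():
    for pre, cap in (("VIP", 4.0), ("PV", 15.0), ("SOM", 5.0), ("E", 10.0)):
        for V in np.linspace(-120, 60, 37):
            r = presynaptic_open_rate(pre, V)
            assert 0.0 <= r <= cap + 1e-12


def _pv_synapse(g=0.5):
    return SynapseSpec("PV0", "F0", "GABAa", g, -80.0, 8.3, "PV")


def test_gate_derivative_limits():
    spec = _pv_synapse()
    assert gate_derivative(spec, 1.0, -100.0) == pytest.approx(-1.0 / 8.3, rel=1e-6)
    assert gate_derivative(spec, 0.0, -100.0) == pytest.approx(0.0, abs=1e-9)
    assert gate_derivative(spec, 0.0, 0.0) == pytest.approx(7.5, rel=1e-9)


def test_gate_decays_when_presynaptic_cell_silent():
    spec = _pv_synapse()
    s, dt = 1.0, 0.05
    for _ in range(int(10 * spec.tau_decay / dt)):
        s += dt * gate_derivative(spec, s, -70.0)
    assert s < 1e-3


def test_synaptic_current_values():
    assert synaptic_current(_pv_synapse(), 1.0, -80.0) == pytest.approx(0.0)
    ampa = SynapseSpec("F0", "PV0", "AMPA", 0.5, 0.0, 2.0, "E")
    assert synaptic_current(ampa, 0.7, 0.0) == pytest.approx(0.0)
    # PV->F at g=0.5, s=1, V=-60: 0.5*(-60+80) = 10 uA/cm^2 outward
    assert synaptic_current(_pv_synapse(), 1.0, -60.0) == pytest.approx(10.0)


def test_single_cell_connectivity_has_nine_projections():
    syns = build_connectivity({p: 1 for p in ("VIP", "SOM", "PV", "ECS", "F")})
    assert len(syns) == 9
    pairs = {(s.pre, s.post) for s in syns}
    assert pairs == {
        ("VIP0", "PV0"), ("VIP0", "SOM0"), ("PV0", "F0"), ("PV0", "ECS0"),
        ("SOM0", "F0"), ("SOM0", "ECS0"), ("ECS0", "F0"), ("F0", "PV0"),
        ("F0", "VIP0"),
    }


def test_population_scalings_and_plastic_flags():
    sizes = {"VIP": 3, "SOM": 2, "PV": 4, "ECS": 1, "F": 1}
    syns = build_connectivity(sizes)
    by_pair = {}
    for s in syns:
        by_pair.setdefault((s.pre[:-1], s.post[:-1]), []).append(s)
    assert all(s.g == pytest.approx(1 / 3) for s in by_pair[("VIP", "PV")])
    # printed scaling uses the postsynaptic SOM count
    assert all(s.g == pytest.approx(1 / 2) for s in by_pair[("VIP", "SOM")])
    assert all(s.g == pytest.approx(0.5 / 4) for s in by_pair[("PV", "F")])
    assert all(s.g == pytest.approx(0.4 / 4) for s in by_pair[("PV", "ECS")])
    assert all(s.g == pytest.approx(0.4 / 2) for s in by_pair[("SOM", "F")])
    ecs_f = by_pair[("ECS", "F")]
    assert all(s.plastic and s.g == 0.0 and s.g_max == 0.18 for s in ecs_f)
    assert all(s.g == 0.5 for s in by_pair[("F", "PV")])
    assert all(s.g == 0.01 and not s.plastic for s in by_pair[("F", "VIP")])
    # the 'pre' variant scales VIP->SOM by the VIP count instead
    syns_pre = build_connectivity(sizes, scale_by="pre")
    vip_som = [s for s in syns_pre if s.pre.startswith("VIP") and s.post.startswith("SOM")]
    assert all(s.g == pytest.approx(1 / 3) for s in vip_som)


def test_excluded_projections_absent():
    syns = build_connectivity({"VIP": 2, "SOM": 2, "PV": 2, "ECS": 2, "F": 2})
    pairs = {(s.pre[:-1], s.post[:-1]) for s in syns}
    for forbidden in (("PV", "SOM"), ("PV", "VIP"), ("SOM", "PV"), ("SOM", "VIP"),
                      ("ECS", "PV"), ("ECS", "VIP"), ("ECS", "SOM"), ("F", "SOM"),
                      ("F", "ECS")):
        assert forbidden not in pairs


def test_kinetic_constants_per_presynaptic_type():
    syns = build_connectivity({"VIP": 1, "SOM": 1, "PV": 1, "ECS": 1, "F": 1})
    taus = {(s.pre[:-1], s.kind): s.tau_decay for s in syns}
    assert taus[("VIP", "GABAa")] == 10.0
    assert taus[("PV", "GABAa")] == 8.3
    assert taus[("SOM", "GABAa")] == 20.0
    assert taus[("F", "AMPA")] == 2.0
    assert all(s.E_rev == -80.0 for s in syns if s.kind == "GABAa")
    assert all(s.E_rev == 0.0 for s in syns if s.kind == "AMPA")


def test_invalid_inputs_raise():
    with pytest.raises(ConfigurationError):
        build_connectivity({"VIP": -1, "SOM": 1, "PV": 1, "ECS": 1, "F": 1})
    with pytest.raises(ConfigurationError):
        build_connectivity({"VIP": 1, "SOM": 1, "PV": 1, "ECS": 1, "F": 1},
                           scale_by="post")
    with pytest.raises(ConfigurationError):
        presynaptic_open_rate("granule", 0.0)


def test_edge_table_roundtrip():
    syns = build_connectivity({p: 1 for p in ("VIP", "SOM", "PV", "ECS", "F")})
    df = edge_table(syns)
    assert len(df) == 9
    assert set(df.columns) == {"pre", "post", "kind", "g", "tau", "E_rev", "plastic"}
    assert df.plastic.sum() == 1
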