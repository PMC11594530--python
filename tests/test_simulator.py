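"""Integration-kernel tests: assembly, RK4 accuracy, determinism, spikes."""

import numpy as np
import pytest

import blafear as bf
from blafear.cellmodels import ConfigurationError
from blafear.simulator import detect_spikes, rk4_step


def test_rk4_matches_linear_ode_closed_form():
    """dV/dt = -V/tau integrated at dt=0.05 ms matches exp(-t/tau) to
    better than 1e-8 relative error after 10 ms."""
    tau = 10.0
    f = lambda t, y: -y / tau
    y = np.array([1.0])
    dt = 0.05
    for k in range(200):
        y = rk4_step(f, y, k * dt, dt)
    exact = np.exp(-10.0 / tau)
    assert abs(y[0] - exact) / exact < 1e-8


def test_rk4_zero_field_is_identity():
    y = np.array([1.2, -3.4])
    out = rk4_step(lambda t, y: np.zeros_like(y), y, 0.0, 0.1)
    np.testing.assert_array_equal(out, y)
    with pytest.raises(ValueError):
        rk4_step(lambda t, y: y, y, 0.0, 0.0)


def test_assemble_single_cell_full_network():
    net = bf.assemble(bf.NetworkConfig())
    assert len(net.cells) == 7  # 5 principals + 2 auxiliary relays
    assert sum(r != "AUX" for r in net.roles) == 5
    assert len(net.synapses) == 12  # 9 internal projections + 3 relay fan-outs
    assert net.plastic_mask.sum() == 1
    assert net.plastic_labels == ["ECS0->F0"]


def test_assemble_heterogeneous_network():
    net = bf.assemble(bf.heterogeneous_config())
    assert len(net.cells) == 31  # 3+3+3+10+10 + 2 relays
    assert net.plastic_mask.sum() == 25  # 5 CS-responsive ECS x 5 US-responsive F
    assert len(net.cs_targets) == 5 and len(net.us_targets) == 5


def test_ablation_removes_cells_and_synapses():
    net = bf.assemble(bf.NetworkConfig(ablate=("VIP",)))
    assert not any(c.startswith("VIP") for c in net.cells)
    for s in net.synapses:
        assert "VIP" not in s.pre and "VIP" not in s.post
    with pytest.raises(ConfigurationError):
        bf.NetworkConfig(ablate=("F",))


def test_zero_duration_returns_initial_state():
    net = bf.assemble(bf.NetworkConfig())
    res = bf.run(net, [bf.PhaseSpec(0.0, 1e-9)], seed=0)
    assert res.V.shape[0] == 1
    assert all(s.size == 0 for s in res.spikes)


def test_run_is_bit_reproducible(short_full_run):
    net, res = short_full_run
    res2 = bf.run(net, [bf.PhaseSpec(0.0, 4000.0, cs_on=True, us_on=True)], seed=17)
    np.testing.assert_array_equal(res.V, res2.V)
    for a, b in zip(res.spikes, res2.spikes):
        np.testing.assert_array_equal(a, b)
    np.testing.assert_array_equal(res.g_traj, res2.g_traj)
    assert res.config_hash == res2.config_hash


def test_different_seeds_differ(short_full_run):
    net, res = short_full_run
    res2 = bf.run(net, [bf.PhaseSpec(0.0, 4000.0, cs_on=True, us_on=True)], seed=18)
    assert not np.array_equal(res.V, res2.V)


def test_voltages_bounded_and_spikes_ordered(short_full_run):
    net, res = short_full_run
    assert res.V.min() > -120.0 and res.V.max() < 60.0
    for s in res.spikes:
        if s.size > 1:
            assert np.all(np.diff(s) >= bf.simulator.REFRACTORY - 1e-9)


def test_noise_off_run_is_deterministic_vector_field():
    cfg = bf.NetworkConfig(noise_off=True)
    net = bf.assemble(cfg)
    r1 = bf.run(net, [bf.PhaseSpec(0.0, 1000.0, cs_on=True)], seed=5)
    r2 = bf.run(net, [bf.PhaseSpec(0.0, 1000.0, cs_on=True)], seed=5)
    np.testing.assert_array_equal(r1.V, r2.V)


def test_dt_halving_preserves_spike_structure():
    """Halving dt on a 500 ms noise-free full-network run leaves every
    cell's spike count unchanged and shifts spike times by < 2 ms."""
    cfg = bf.NetworkConfig(noise_off=True)
    net = bf.assemble(cfg)
    r1 = bf.run(net, [bf.PhaseSpec(0.0, 500.0, True, True)], seed=4)
    r2 = bf.run(net, [bf.PhaseSpec(0.0, 500.0, True, True)], seed=4, dt=0.025)
    for a, b in zip(r1.spikes, r2.spikes):
        assert a.size == b.size
        if a.size:
            assert np.abs(a - b).max() < 2.0


def test_detect_spikes():
    t = np.arange(0.0, 1000.0, 0.05)
    assert detect_spikes(np.full(t.size, -70.0), t).size == 0
    one = -70 + 90 * np.exp(-((t - 500) / 2.0) ** 2)
    assert detect_spikes(one, t).size == 1
    train = -70 + 90 * (np.sin(2 * np.pi * 40 * t / 1000.0) > 0.99)
    det = detect_spikes(train, t)
    assert det.size == 40  # 40 Hz for 1 s


def test_ping_motif_gamma_with_f_leading():
    """Reciprocal F-PV pair with F driven: gamma-band 1:1 locking with the
    excitatory cell leading within each cycle."""
    cfg = bf.NetworkConfig(sizes={"VIP": 0, "SOM": 0, "PV": 1, "ECS": 0, "F": 1},
                           attach_stimulus=False, iapp_overrides={"F": 1.5})
    net = bf.assemble(cfg)
    res = bf.run(net, [bf.PhaseSpec(0.0, 4000.0)], seed=2)
    f = res.spike_times("F0")
    p = res.spike_times("PV0")
    f, p = f[f > 1000], p[p > 1000]
    assert f.size / 3.0 > 30.0 and p.size / 3.0 > 30.0  # gamma band
    lags = [p[p > t][0] - t for t in f if np.any(p > t)]
    assert 0.0 < np.median(lags) < 5.0  # F fires first in each cycle


def test_divergence_aborts_with_diagnostic():
    cfg = bf.NetworkConfig(sizes={"VIP": 0, "SOM": 0, "PV": 0, "ECS": 0, "F": 1},
                           attach_stimulus=False, iapp_overrides={"F": 1e7},
                           noise_off=True)
    net = bf.assemble(cfg)
    with pytest.raises(FloatingPointError, match="last valid time"):
        bf.run(net, [bf.PhaseSpec(0.0, 100.0)], seed=0)
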