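"""Orchestration of the in-silico fear-conditioning experiments.

Wraps the simulator into the study's figure-level protocols: isolated-cell
natural-frequency scans, conditioning runs with learner statistics,
interneuron ablations, and the pre/post spectral biomarker comparison.
Every experiment is reproducible from (config, base seed); realization r
uses seed ``base_seed + r``.

Pre/post spectral probes follow the conditioning protocol: the *pre* probe
is a baseline run (no CS/US) of the naive network, the *post* probe is a
CS-only run with the learned ECS->F conductances installed.  Non-learners
are harvested the way the study did: short (10 s) conditioning runs whose
conductance stays below the 0.037 mS/cm^2 predictor threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import analysis as an
from . import simulator as sim
from . import stimuli as st
from .simulator import Network, NetworkConfig, SimulationResult, assemble, run

ABLATION_VARIANTS: Dict[str, Tuple[str, ...]] = {
    "full": (),
    "noVIP": ("VIP",),
    "noSOM": ("SOM",),
    "noPV": ("PV",),
    "noSOM+PV": ("SOM", "PV"),
}


@dataclass
class ExperimentSummary:
    name: str
    n: int
    seeds: List[int]
    learner_count: int
    g_t: np.ndarray
    g_mean: np.ndarray
    g_sd: np.ndarray
    reports: List[an.LearnerReport]
    config_hash: str
    band_powers: Optional[pd.DataFrame] = None
    stats: Dict[str, float] = field(default_factory=dict)

    @property
    def learner_fraction(self) -> float:
        return self.learner_count / self.n if self.n else float("nan")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(realization=r.realization, g_mid=r.g_mid, g_end=r.g_end,
                     learner=r.learner, predicted_learner=r.predicted_learner)
                for r in self.reports
            ]
        )


# ---------------------------------------------------------------------------
# Natural frequencies (isolated cells)
# ---------------------------------------------------------------------------

def intra_burst_frequency(spikes: np.ndarray, isi_gap: float = 50.0) -> float:
    """Inverse mean within-burst inter-spike interval (Hz).

    Bursts are segmented wherever the inter-spike interval exceeds
    ``isi_gap`` ms (default 50 ms, between the ~25 ms intra-burst gamma
    interval and the ~300 ms inter-burst gap); single-spike bursts
    contribute no intervals.
    """
    s = np.asarray(spikes, float)
    if s.size < 2:
        return 0.0
    isis = np.diff(s)
    within = isis[isis <= isi_gap]
    if within.size == 0:
        return 0.0
    return 1000.0 / float(within.mean())


def burst_rate_peak(
    spikes: np.ndarray, duration: float, f_hi: float = 6.0, bin_ms: float = 5.0
) -> float:
    """Location (Hz) of the spectral peak of the binned spike signal below
    ``f_hi`` -- the burst-repetition (low theta) frequency of a VIP cell."""
    sig, fs = an.spike_rate_signal([spikes], bin_ms=bin_ms, t0=0.0, t1=duration)
    psd = an.multitaper_psd(sig, fs, source="spike-rate")
    sel = (psd.freq >= 0.5) & (psd.freq <= f_hi)
    return float(psd.freq[sel][np.argmax(psd.power[sel])])


def natural_frequency_scan(
    cell_role: str,
    duration: float = 10000.0,
    n_seeds: int = 3,
    base_seed: int = 0,
    iapp: Optional[float] = None,
) -> Dict[str, float]:
    """Baseline firing statistics of one isolated cell class.

    Returns the mean firing rate across seeds; for VIP additionally the
    intra-burst (gamma) frequency and the burst-repetition spectral peak.
    """
    rates, burst_f, burst_peak = [], [], []
    for s in range(n_seeds):
        net = sim.single_cell_network(cell_role, iapp=iapp)
        res = run(net, [st.PhaseSpec(0.0, duration)], seed=base_seed + s)
        cell = net.cells[0]
        rates.append(res.rate(cell))
        if cell_role == "VIP":
            spk = res.spike_times(cell)
            burst_f.append(intra_burst_frequency(spk))
            burst_peak.append(burst_rate_peak(spk, duration))
    out = {"rate": float(np.mean(rates))}
    if cell_role == "VIP":
        out["intra_burst_freq"] = float(np.mean(burst_f))
        out["burst_rate_peak"] = float(np.mean(burst_peak))
    return out


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def _network_config(network_kind: str, **kwargs) -> NetworkConfig:
    if network_kind == "single":
        return NetworkConfig(**kwargs)
    if network_kind == "heterogeneous":
        return sim.heterogeneous_config(**kwargs)
    raise ValueError("network_kind must be 'single' or 'heterogeneous'")


def mean_plastic_g(res: SimulationResult) -> np.ndarray:
    """Population-mean ECS->F conductance trajectory of one realization."""
    return res.g_traj.mean(axis=1)


def run_conditioning(
    paradigm: str = "conditioning_40s",
    network_kind: str = "single",
    n_realizations: int = 5,
    base_seed: int = 0,
    config: Optional[NetworkConfig] = None,
    collect_results: bool = False,
) -> ExperimentSummary:
    """Repeated conditioning runs with learner classification."""
    cfg = config if config is not None else _network_config(network_kind)
    seeds = [base_seed + r for r in range(n_realizations)]
    reports, trajs, results = [], [], []
    chash = ""
    for r, seed in enumerate(seeds):
        net = assemble(cfg)
        res = run(net, paradigm, seed=seed)
        chash = res.config_hash
        g = mean_plastic_g(res)
        trajs.append(g)
        reports.append(an.classify_learner(res.g_t, g, paradigm, realization=r))
        if collect_results:
            results.append(res)
        g_t = res.g_t
    traj = np.vstack(trajs)
    summary = ExperimentSummary(
        name=f"conditioning[{paradigm},{network_kind}]",
        n=n_realizations, seeds=seeds,
        learner_count=sum(r.learner for r in reports),
        g_t=g_t, g_mean=traj.mean(axis=0), g_sd=traj.std(axis=0),
        reports=reports, config_hash=chash,
    )
    if collect_results:
        summary.stats["results"] = results  # type: ignore[assignment]
    return summary


def run_ablation(
    variant: str,
    paradigm: str = "conditioning_40s",
    n_realizations: int = 5,
    base_seed: int = 0,
    network_kind: str = "single",
) -> ExperimentSummary:
    """Conditioning with an interneuron population removed."""
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"variant must be one of {sorted(ABLATION_VARIANTS)}")
    cfg = _network_config(network_kind, ablate=ABLATION_VARIANTS[variant])
    summary = run_conditioning(
        paradigm, network_kind, n_realizations, base_seed, config=cfg
    )
    summary.name = f"ablation[{variant},{paradigm},{network_kind}]"
    return summary


# ---------------------------------------------------------------------------
# Pre/post spectral biomarker
# ---------------------------------------------------------------------------

def _probe_pair(
    cfg: NetworkConfig, learned_g: np.ndarray, seed: int, probe_duration: float
) -> Tuple[SimulationResult, SimulationResult]:
    """Baseline (pre) and CS-only (post, learned conductance) probe runs."""
    net_pre = assemble(cfg)
    pre = run(net_pre, [st.PhaseSpec(0.0, probe_duration)], seed=seed)
    net_post = assemble(cfg)
    net_post.set_plastic_g(learned_g)
    post = run(net_post, [st.PhaseSpec(0.0, probe_duration, cs_on=True)], seed=seed + 1)
    return pre, post


def harvest_nonlearners(
    cfg: NetworkConfig,
    n_wanted: int,
    base_seed: int = 0,
    max_tries: int = 60,
    harvest_duration: float = 10000.0,
) -> List[Tuple[int, SimulationResult]]:
    """Short conditioning runs whose ECS->F conductance stays below the
    0.037 mS/cm^2 predictor threshold (the non-learner harvesting rule)."""
    out = []
    for k in range(max_tries):
        seed = base_seed + 1000 + k
        net = assemble(cfg)
        res = run(net, [st.PhaseSpec(0.0, harvest_duration, True, True)], seed=seed)
        if mean_plastic_g(res)[-1] < an.PREDICTED_THRESHOLD:
            out.append((seed, res))
        if len(out) >= n_wanted:
            break
    return out


def biomarker_analysis(
    pre_results: Sequence[SimulationResult],
    post_results: Sequence[SimulationResult],
    learner_flags: Sequence[bool],
    bands: Dict[str, Tuple[float, float]] | None = None,
) -> Dict[str, object]:
    """Band-power tables and rank-sum comparisons for matched pre/post runs.

    Returns the long-format power table, the learner low/high-theta and
    non-learner low-theta p-values, and the post/pre power ratios of the
    AMPA-only and GABA-only LFP components (learners, low theta).
    """
    if len(pre_results) != len(post_results) or len(pre_results) != len(learner_flags):
        raise ValueError("pre/post/flags must have matching lengths")
    bands = bands or {"low_theta": an.LOW_THETA, "high_theta": an.HIGH_THETA}
    rows = []
    comp_ratios: Dict[str, List[float]] = {"AMPA": [], "GABA": [], "intrinsic": []}
    for rid, (pre, post, flag) in enumerate(zip(pre_results, post_results, learner_flags)):
        for phase, res in (("pre", pre), ("post", post)):
            fs = 1000.0 / float(np.median(np.diff(res.comp_t)))
            lfp = an.discard_transient(res.comp_t, an.lfp_proxy(res), res.transient_ms)
            psd = an.multitaper_psd(lfp, fs)
            for bname, (lo, hi) in bands.items():
                rows.append(dict(realization=rid, learner=bool(flag), phase=phase,
                                 band=bname, power=an.band_power(psd, lo, hi)))
        if flag:
            for comp in comp_ratios:
                fs = 1000.0 / float(np.median(np.diff(pre.comp_t)))
                p_pre = an.multitaper_psd(
                    an.discard_transient(pre.comp_t, an.component_lfp(pre, comp),
                                         pre.transient_ms), fs)
                p_post = an.multitaper_psd(
                    an.discard_transient(post.comp_t, an.component_lfp(post, comp),
                                         post.transient_ms), fs)
                lo, hi = bands.get("low_theta", an.LOW_THETA)
                comp_ratios[comp].append(
                    an.band_power(p_post, lo, hi) / an.band_power(p_pre, lo, hi)
                )
    table = pd.DataFrame(rows)

    def _pick(learner: bool, phase: str, band: str) -> np.ndarray:
        sel = table[(table.learner == learner) & (table.phase == phase) & (table.band == band)]
        return sel.power.to_numpy()

    stats: Dict[str, object] = {"table": table}
    if any(learner_flags):
        _, stats["p_low_theta_learners"] = an.ranksum_compare(
            _pick(True, "pre", "low_theta"), _pick(True, "post", "low_theta"))
        _, stats["p_high_theta_learners"] = an.ranksum_compare(
            _pick(True, "pre", "high_theta"), _pick(True, "post", "high_theta"))
        for comp, vals in comp_ratios.items():
            stats[f"{comp.lower()}_power_ratio"] = float(np.mean(vals)) if vals else float("nan")
    if not all(learner_flags):
        _, stats["p_low_theta_nonlearners"] = an.ranksum_compare(
            _pick(False, "pre", "low_theta"), _pick(False, "post", "low_theta"))
    return stats


def run_biomarker_experiment(
    network_kind: str = "heterogeneous",
    n_learners: int = 5,
    n_nonlearners: int = 5,
    base_seed: int = 0,
    conditioning_duration: float = 40000.0,
    probe_duration: float = 12000.0,
) -> Dict[str, object]:
    """Full biomarker protocol: condition learners, harvest non-learners,
    run matched pre/post probes, compare band powers."""
    cfg = _network_config(network_kind)
    pre_results: List[SimulationResult] = []
    post_results: List[SimulationResult] = []
    flags: List[bool] = []

    got = 0
    k = 0
    while got < n_learners and k < 3 * n_learners:
        seed = base_seed + k
        k += 1
        net = assemble(cfg)
        res = run(net, [st.PhaseSpec(0.0, conditioning_duration, True, True)], seed=seed)
        g_end = mean_plastic_g(res)[-1]
        if g_end <= an.LEARNER_THRESHOLD:
            continue
        pre, post = _probe_pair(cfg, res.final_plastic_g, seed * 7 + 1, probe_duration)
        pre_results.append(pre)
        post_results.append(post)
        flags.append(True)
        got += 1

    for seed, res in harvest_nonlearners(cfg, n_nonlearners, base_seed):
        pre, post = _probe_pair(cfg, res.final_plastic_g, seed * 7 + 1, probe_duration)
        pre_results.append(pre)
        post_results.append(post)
        flags.append(False)

    out = biomarker_analysis(pre_results, post_results, flags)
    out["n_learners"] = sum(flags)
    out["n_nonlearners"] = len(flags) - sum(flags)
    return out
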