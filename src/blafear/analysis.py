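"""LFP proxy, multitaper spectra, band power and learner statistics.

The model has no spatial extension, so the local field potential is proxied
by the linear sum of all AMPA, GABA, D-, NaP- and H-currents in the network
(a rectified variant sums absolute values instead).  Spectra are Thomson
multitaper estimates (DPSS tapers, time-half-bandwidth NW = 4, 2*NW - 1
tapers, eigenvalue-weighted) evaluated on 0.1-70 Hz after discarding the
first 2 s of signal.  The learning biomarker is the band-integrated power
in the low-theta range (2.5-4 Hz); the high-theta control band is 12-14 Hz.

A network realization is a *learner* when its ECS->F AMPA conductance ends
above 0.12 mS/cm^2 after the 40 s conditioning interval; in the 15 s + 30 s
paradigm a realization whose conductance exceeds 0.037 mS/cm^2 at 15 s is
predicted to become a learner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal.windows import dpss
from scipy.stats import mannwhitneyu

from .cellmodels import ConfigurationError
from .simulator import SimulationResult

LOW_THETA = (2.5, 4.0)  # Hz, where the low-theta power peaks live
HIGH_THETA = (12.0, 14.0)
FREQ_RANGE = (0.1, 70.0)
LEARNER_THRESHOLD = 0.12  # mS/cm^2 at the end of 40 s conditioning
PREDICTED_THRESHOLD = 0.037  # mS/cm^2 at 15 s (or the 10 s harvesting runs)


# ---------------------------------------------------------------------------
# LFP proxy
# ---------------------------------------------------------------------------

def lfp_proxy(result: SimulationResult, mode: str = "linear") -> np.ndarray:
    """LFP time series on ``result.comp_t`` (1 kHz).

    ``linear`` sums the signed AMPA/GABA/D/NaP/H currents; ``rectified``
    sums their absolute values (computed per current at integration time).
    """
    if mode == "linear":
        needed = ("AMPA", "GABA", "D", "H", "NaP")
        for name in needed:
            if name not in result.comp:
                raise ConfigurationError(f"current trace {name!r} was not recorded")
        return sum(result.comp[name] for name in needed)
    if mode == "rectified":
        if "ABS" not in result.comp:
            raise ConfigurationError("current trace 'ABS' was not recorded")
        return result.comp["ABS"]
    raise ConfigurationError("mode must be 'linear' or 'rectified'")


def component_lfp(result: SimulationResult, component: str) -> np.ndarray:
    """Single-component LFP (``AMPA``, ``GABA`` or one intrinsic current)."""
    if component == "intrinsic":
        return result.comp["D"] + result.comp["H"] + result.comp["NaP"]
    if component not in result.comp:
        raise ConfigurationError(f"current trace {component!r} was not recorded")
    return result.comp[component]


def discard_transient(
    t: np.ndarray, x: np.ndarray, transient_ms: float = 2000.0
) -> np.ndarray:
    return np.asarray(x)[np.asarray(t) >= transient_ms]


# ---------------------------------------------------------------------------
# Multitaper PSD
# ---------------------------------------------------------------------------

@dataclass
class PSD:
    freq: np.ndarray  # Hz, strictly increasing within FREQ_RANGE
    power: np.ndarray  # density, >= 0
    nw: float
    n_tapers: int
    source: str = "LFP"


def multitaper_psd(
    signal: np.ndarray,
    fs: float,
    nw: float = 4.0,
    n_tapers: Optional[int] = None,
    freq_range: Tuple[float, float] = FREQ_RANGE,
    source: str = "LFP",
    demean: bool = True,
) -> PSD:
    """Thomson multitaper power spectral density estimate.

    DPSS tapers with time-half-bandwidth product ``nw`` (default 4, with
    ``2*nw - 1`` tapers), eigenvalue-weighted average of the per-taper
    periodograms, one-sided density in units^2/Hz.  Requires at least 2 s
    of signal (after any transient removal done by the caller).
    """
    x = np.asarray(signal, float)
    if x.size < 2 * fs:
        raise ValueError("signal shorter than 2 s; too short for a stable PSD")
    if demean:
        x = x - x.mean()
    K = int(n_tapers) if n_tapers is not None else int(2 * nw - 1)
    tapers, eigvals = dpss(x.size, nw, Kmax=K, return_ratios=True)
    spec = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    weights = eigvals / eigvals.sum()
    pxx = (weights[:, None] * spec).sum(axis=0) / fs
    # one-sided scaling (DC and Nyquist excluded from doubling)
    pxx[1:] *= 2.0
    if x.size % 2 == 0:
        pxx[-1] /= 2.0
    freq = np.fft.rfftfreq(x.size, d=1.0 / fs)
    sel = (freq >= freq_range[0]) & (freq <= freq_range[1])
    return PSD(freq=freq[sel], power=pxx[sel], nw=nw, n_tapers=K, source=source)


def band_power(psd: PSD, f_lo: float, f_hi: float) -> float:
    """Trapezoidal band-integrated power over [f_lo, f_hi].

    Band edges are linearly interpolated onto the PSD grid so that adjacent
    bands partition exactly.
    """
    if not f_lo < f_hi:
        raise ValueError("need f_lo < f_hi")
    if f_lo < psd.freq[0] or f_hi > psd.freq[-1]:
        raise ValueError("band outside the PSD frequency grid")
    inner = psd.freq[(psd.freq > f_lo) & (psd.freq < f_hi)]
    grid = np.concatenate(([f_lo], inner, [f_hi]))
    vals = np.interp(grid, psd.freq, psd.power)
    return float(np.trapezoid(vals, grid))


def band_peak(psd: PSD, f_lo: float, f_hi: float) -> Tuple[float, float]:
    """(frequency, density) of the PSD maximum inside [f_lo, f_hi]."""
    sel = (psd.freq >= f_lo) & (psd.freq <= f_hi)
    if not sel.any():
        raise ValueError("band outside the PSD frequency grid")
    k = int(np.argmax(psd.power[sel]))
    return float(psd.freq[sel][k]), float(psd.power[sel][k])


def spike_rate_signal(
    spikes: Sequence[np.ndarray],
    bin_ms: float = 5.0,
    t0: float = 0.0,
    t1: Optional[float] = None,
) -> Tuple[np.ndarray, float]:
    """Mean-subtracted binned population spike counts, ready for the PSD.

    Returns ``(signal, fs)`` with ``fs`` in Hz.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    all_t = np.concatenate([np.asarray(s) for s in spikes]) if len(spikes) else np.empty(0)
    if t1 is None:
        t1 = float(all_t.max()) if all_t.size else t0 + bin_ms
    edges = np.arange(t0, t1 + bin_ms, bin_ms)
    counts, _ = np.histogram(all_t, bins=edges)
    sig = counts.astype(float)
    return sig - sig.mean(), 1000.0 / bin_ms


# ---------------------------------------------------------------------------
# Learner classification
# ---------------------------------------------------------------------------

@dataclass
class LearnerReport:
    realization: int
    g_mid: float  # conductance at the 15 s checkpoint (or 10 s harvest)
    g_end: float
    learner: bool
    predicted_learner: bool
    threshold: float = LEARNER_THRESHOLD
    predicted_threshold: float = PREDICTED_THRESHOLD


def classify_learner(
    g_t: np.ndarray,
    g: np.ndarray,
    paradigm: str = "conditioning_40s",
    realization: int = 0,
) -> LearnerReport:
    """Classify one realization from its plastic-conductance trajectory.

    ``g`` is the (population-mean) ECS->F conductance on the ``g_t`` grid.
    The 40 s paradigm uses the end-of-run learner criterion (> 0.12); the
    15 s + 30 s paradigm additionally evaluates the 15 s predictor
    (> 0.037).
    """
    g_t = np.asarray(g_t, float)
    g = np.asarray(g, float)
    if paradigm == "conditioning_40s":
        t_mid, t_req = 15000.0, 40000.0
    elif paradigm == "conditioning_15_30":
        t_mid, t_req = 15000.0, 45000.0
    else:
        t_mid, t_req = min(15000.0, g_t[-1]), g_t[-1]
    if g_t[-1] + 1e-6 < t_req:
        raise ValueError("trajectory does not cover the paradigm")
    g_mid = float(np.interp(min(t_mid, g_t[-1]), g_t, g))
    g_end = float(g[-1])
    return LearnerReport(
        realization=realization, g_mid=g_mid, g_end=g_end,
        learner=g_end > LEARNER_THRESHOLD,
        predicted_learner=g_mid > PREDICTED_THRESHOLD,
    )


# ---------------------------------------------------------------------------
# Nonparametric comparison
# ---------------------------------------------------------------------------

def ranksum_compare(group_a: Sequence[float], group_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact small-sample null when both groups have <= 25 observations and no
    ties; normal approximation with tie correction otherwise.  Returns
    ``(U statistic, p value)``.
    """
    a = np.asarray(list(group_a), float)
    b = np.asarray(list(group_b), float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 25 and b.size <= 25 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def band_power_table(
    results: Iterable[Tuple[int, str, SimulationResult]],
    bands: Dict[str, Tuple[float, float]] | None = None,
    mode: str = "linear",
):
    """Long-format band-power table: (realization, phase, band, power).

    ``results`` yields ``(realization id, phase label, SimulationResult)``.
    The transient is discarded before the PSD.
    """
    import pandas as pd

    bands = bands or {"low_theta": LOW_THETA, "high_theta": HIGH_THETA}
    rows = []
    for rid, phase, res in results:
        lfp = discard_transient(res.comp_t, lfp_proxy(res, mode), res.transient_ms)
        fs = 1000.0 / float(np.median(np.diff(res.comp_t)))
        psd = multitaper_psd(lfp, fs)
        for bname, (lo, hi) in bands.items():
            rows.append(
                dict(realization=rid, phase=phase, band=bname,
                     power=band_power(psd, lo, hi))
            )
    return pd.DataFrame(rows)
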