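"""Miniature IPSC detection and per-cell event statistics.

mIPSCs are recorded at a +10 mV holding potential with glutamatergic
transmission and spikes blocked, so events are outward (positive) deflections.
Detection runs a sliding least-squares fit of a unit-peak biexponential
template (scale-only, after baseline subtraction), which yields a "scale
trace" whose value at the correct lag equals the event amplitude; peaks of
that trace above ``threshold_sd`` robust (MAD-based) noise SDs, separated by
at least ``min_interval_ms``, are events. Amplitude is then re-measured on
the raw trace as baseline-to-peak. A plain amplitude-threshold mode is
available as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import Config, SweepSet

__all__ = ["EventTrain", "MiniStats", "detect_minis", "mini_stats"]


@dataclass
class EventTrain:
    """Detected (or ground-truth) event times and amplitudes for one trace."""

    times_ms: np.ndarray
    amplitudes_pa: np.ndarray
    duration_s: float
    noise_sd_pa: float = 0.0

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.amplitudes_pa = np.asarray(self.amplitudes_pa, dtype=float)
        if self.times_ms.size and (np.diff(self.times_ms) <= 0).any():
            raise ValueError("event times must be strictly increasing")
        if (self.amplitudes_pa <= 0).any():
            raise ValueError("amplitudes must be positive")

    @property
    def n_events(self) -> int:
        return self.times_ms.size


@dataclass
class MiniStats:
    mean_iei_s: float | None
    mean_amplitude_pa: float
    n_events: int
    iei_defined: bool


def _robust_sd(x: np.ndarray) -> float:
    """MAD-based noise SD, insensitive to the sparse event peaks."""
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def detect_minis(trace: SweepSet, cfg: Config | None = None,
                 threshold_sd: float | None = None,
                 min_interval_ms: float | None = None,
                 mode: str = "template", polarity: int = +1) -> EventTrain:
    """Detect miniature events on the first sweep of ``trace``.

    mode="template" (default): Clements-Bekkers-style sliding template scale
    estimate; mode="amplitude": threshold the raw (polarity-corrected) trace.
    Events closer than ``min_interval_ms`` merge into the larger one.
    """
    cfg = cfg or Config()
    thr_sd = cfg.mini_threshold_sd if threshold_sd is None else threshold_sd
    min_int = cfg.mini_min_interval_ms if min_interval_ms is None else min_interval_ms
    x = polarity * trace.sweeps[0].astype(float)
    fs = trace.sampling_rate_hz
    dt = 1000.0 / fs
    kernel = _unit_kernel(dt, cfg.mini_tau_rise_ms, cfg.mini_tau_decay_ms)
    if x.size < kernel.size:
        raise ValueError("trace shorter than the event template")
    x = x - np.median(x)
    distance = max(1, int(round(min_int / dt)))
    if mode == "template":
        idx, amps = _matching_pursuit(x, kernel, thr_sd, distance)
    elif mode == "amplitude":
        sd = _robust_sd(x)
        floor = 1e-12 * (np.max(np.abs(x)) + 1.0)
        peaks, _ = signal.find_peaks(x, height=max(thr_sd * sd, floor),
                                     distance=distance)
        base_win = max(1, int(round(2.0 / dt)))
        idx, amps = [], []
        for i in peaks:
            base = float(np.mean(x[max(0, i - base_win):i])) if i > 0 else 0.0
            if x[i] - base > 0:
                idx.append(i)
                amps.append(float(x[i]) - base)
        idx, amps = np.asarray(idx, dtype=int), np.asarray(amps)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EventTrain(np.asarray(idx) * dt, np.asarray(amps),
                      duration_s=trace.n_samples / fs,
                      noise_sd_pa=_robust_sd(x))


def _matching_pursuit(x: np.ndarray, kernel: np.ndarray, thr_sd: float,
                      distance: int) -> tuple[np.ndarray, np.ndarray]:
    """Greedy template decomposition of the trace.

    The sliding least-squares scale of the unit-peak template,
    corr(x, k)/sum(k^2), equals the event amplitude at the event-onset lag.
    The largest scale peak is accepted, its template autocorrelation is
    subtracted, and the scan repeats until the residual drops below
    ``thr_sd`` robust SDs — so the slow tail of one event cannot spawn
    spurious detections, and overlapping events separate cleanly. Accepted
    onsets closer than ``distance`` samples merge into the larger event, and
    the amplitudes of the accepted onsets are re-fit jointly (Gram system of
    template overlaps), which makes noiseless recovery exact even for
    overlapping events.
    """
    energy = float(np.sum(kernel ** 2))
    scale = signal.fftconvolve(x, kernel[::-1], mode="valid") / energy
    acorr = np.correlate(kernel, kernel, mode="full") / energy
    half = kernel.size - 1
    # noise SD of the scale trace: for white noise of SD s the matched-filter
    # output has SD s/sqrt(sum k^2); take the larger of that and the direct
    # MAD so the estimate stays sane when events dominate the trace. The
    # relative floor keeps sub-resolution template-truncation residue from
    # registering on noise-free traces.
    sd = max(_robust_sd(scale), _robust_sd(x) / np.sqrt(energy))
    floor = max(5e-3 * float(scale.max(initial=0.0)), 1e-12)
    height = max(thr_sd * sd, floor)
    # candidate onsets are local maxima of the ORIGINAL scale trace: a pair
    # of events closer than the template resolution shows a single maximum
    # (the merging rule), and subtraction lobes can never become candidates
    candidates, _ = signal.find_peaks(scale)
    cand_mask = np.zeros(scale.size, dtype=bool)
    cand_mask[candidates] = True
    work = scale.copy()
    accepted: list[int] = []
    max_events = x.size // max(distance, 1) + 1
    open_sites = cand_mask.copy()
    while len(accepted) < max_events and open_sites.any():
        masked = np.where(open_sites, work, -np.inf)
        i = int(np.argmax(masked))
        amp = work[i]
        if not np.isfinite(amp) or amp < height:
            break
        accepted.append(i)
        lo, hi = max(0, i - half), min(work.size, i + half + 1)
        work[lo:hi] -= amp * acorr[lo - i + half:hi - i + half]
        open_sites[max(0, i - distance + 1):i + distance] = False
    if not accepted:
        return np.asarray([], dtype=int), np.asarray([])
    onsets = np.sort(np.asarray(accepted))
    # joint least-squares amplitude refit on the accepted onsets
    n = onsets.size
    gram = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            lag = onsets[b] - onsets[a]
            if lag <= half:
                gram[a, b] = gram[b, a] = acorr[half + lag]
    amps = np.linalg.solve(gram, scale[onsets])
    keep = amps > 0
    return onsets[keep], amps[keep]


def _unit_kernel(dt_ms: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    t = np.arange(0.0, 8.0 * tau_decay, dt_ms)
    g = (1.0 - np.exp(-t / tau_rise)) * np.exp(-t / tau_decay)
    return g / g.max()


def mini_stats(train: EventTrain) -> MiniStats:
    """Mean interevent interval (s) and mean amplitude (pA) of one train.

    The IEI is undefined (flagged) for fewer than two events.
    """
    n = train.n_events
    mean_amp = float(np.mean(train.amplitudes_pa)) if n else float("nan")
    if n < 2:
        return MiniStats(None, mean_amp, n, iei_defined=False)
    iei = float(np.mean(np.diff(train.times_ms)) / 1000.0)
    return MiniStats(iei, mean_amp, n, iei_defined=True)
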