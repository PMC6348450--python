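"""Cellular two-photon Ca²⁺ analysis.

Cells are classified from the fluorophore pair: SR-101-positive somata are
astrocytes (excluded from response analysis), Venus-positive/SR-101-negative
somata are GABAergic inhibitory neurons, double-negative somata are
glutamatergic excitatory neurons. Trial-averaged ΔF/F traces are extracted
per soma after a 9x9 spatial and a 3x3x3 spatiotemporal mean filter; a cell
responds when the suprathreshold run (> 2 x baseline SD) containing the
post-stimulus maximum lasts at least 100 ms. Kinetic metrics (time to peak,
latency, 20-80% rise time, duration above 2 SD) are measured on responding
cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core_io import Config, ImageStack

__all__ = [
    "Cell",
    "CellMap",
    "CaResponse",
    "classify_cells",
    "extract_dff_traces",
    "detect_ca_response",
    "ca_kinetics",
    "responding_fraction",
]


@dataclass
class Cell:
    id: int
    center_px: tuple[float, float]    # (row, col)
    radius_px: float
    venus_positive: bool = False
    sr101_positive: bool = False
    cls: str = "excitatory"
    excluded: bool = False
    exclusion_reason: str | None = None


@dataclass
class CellMap:
    cells: list[Cell]

    def active(self) -> list[Cell]:
        return [c for c in self.cells if not c.excluded]

    def by_id(self, cid: int) -> Cell:
        for c in self.cells:
            if c.id == cid:
                return c
        raise KeyError(cid)


@dataclass
class CaResponse:
    responding: bool
    peak_amplitude: float | None = None
    time_to_peak_ms: float | None = None
    latency_ms: float | None = None
    rise_time_20_80_ms: float | None = None
    duration_above_2sd_ms: float | None = None
    baseline_sd: float | None = None


def _classify_flags(venus: bool, sr101: bool) -> str:
    # classification is a pure function of the two fluorophore flags
    if sr101:
        return "astrocyte"
    return "inhibitory" if venus else "excitatory"


def _soma_mean(img: np.ndarray, center: tuple[float, float], radius: float) -> float:
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
    return float(img[mask].mean())


def _positivity_threshold(img: np.ndarray) -> float:
    """Threshold separating labelled somata from background: Otsu on the
    image, guarded against a label-free image by a robust background floor."""
    try:
        otsu = float(threshold_otsu(img))
    except ValueError:
        otsu = float(np.inf)
    med = float(np.median(img))
    mad = float(1.4826 * np.median(np.abs(img - med)))
    return max(otsu, med + 5.0 * mad)


def classify_cells(venus_stack: ImageStack, green: ImageStack,
                   red: ImageStack, somata: list[dict],
                   fiber_mask: np.ndarray | None = None,
                   cfg: Config | None = None,
                   venus_threshold: float | None = None,
                   red_threshold: float | None = None) -> CellMap:
    """Assign excitatory / inhibitory / astrocyte labels to soma ROIs.

    ``somata`` entries carry ``id``, ``center_px`` (row, col) and
    ``radius_px``. Per-soma mean intensities in the Venus and red (SR-101)
    images are thresholded (Otsu with a robust floor by default; manual
    overrides supported). Astrocytes are excluded from response analysis;
    somata intersecting ``fiber_mask`` are excluded as neuropil overlap.
    """
    venus_img = venus_stack.frames.max(axis=0)
    red_img = red.frames.max(axis=0)
    h, w = venus_img.shape
    thr_v = _positivity_threshold(venus_img) if venus_threshold is None else venus_threshold
    thr_r = _positivity_threshold(red_img) if red_threshold is None else red_threshold
    cells: list[Cell] = []
    for s in somata:
        center = tuple(s["center_px"])
        radius = float(s["radius_px"])
        if not (0 <= center[0] < h and 0 <= center[1] < w):
            raise ValueError(f"soma {s['id']} outside field")
        venus_pos = _soma_mean(venus_img, center, radius) > thr_v
        sr_pos = _soma_mean(red_img, center, radius) > thr_r
        cls = _classify_flags(venus_pos, sr_pos)
        cell = Cell(int(s["id"]), center, radius, venus_pos, sr_pos, cls)
        if cls == "astrocyte":
            cell.excluded = True
            cell.exclusion_reason = "astrocyte"
        if fiber_mask is not None:
            yy, xx = np.mgrid[0:h, 0:w]
            soma = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
            if (soma & fiber_mask).any():
                cell.excluded = True
                cell.exclusion_reason = "neuropil overlap"
        cells.append(cell)
    return CellMap(cells)


def extract_dff_traces(movie: ImageStack | list[ImageStack], cellmap: CellMap,
                       cfg: Config | None = None,
                       include_excluded: bool = False) -> dict[int, np.ndarray]:
    """Per-cell ΔF/F traces from the (trial-averaged) green-channel movie.

    A list of trial movies is averaged first. ΔF/F is computed per pixel
    against the pre-stimulus mean, smoothed with the 9x9 spatial and 3x3x3
    spatiotemporal mean filters, then averaged over each soma disk. Traces
    keep the native 10-ms sampling.
    """
    cfg = cfg or Config()
    if isinstance(movie, list):
        if not movie:
            raise ValueError("empty trial list")
        shape = movie[0].shape
        for m in movie:
            if m.shape != shape:
                raise ValueError("trial geometry mismatch")
        frames = np.mean([m.frames for m in movie], axis=0)
        ref = movie[0]
    else:
        frames = movie.frames.astype(float)
        ref = movie
    onset = ref.stim_onset_frame
    if onset < 1:
        raise ValueError("no pre-stimulus frames")
    cells = cellmap.cells if include_excluded else cellmap.active()
    if not cells:
        raise ValueError("no non-excluded cells")
    f0 = frames[:onset].mean(axis=0)
    if (f0 <= 0).any():
        raise ValueError("non-positive baseline fluorescence")
    dff = (frames - f0[None]) / f0[None]
    k = cfg.spatial_filter_px
    dff = ndimage.uniform_filter(dff, size=(1, k, k), mode="nearest")
    kt, ky, kx = cfg.ca_cubic_filter
    dff = ndimage.uniform_filter(dff, size=(kt, ky, kx), mode="nearest")
    h, w = dff.shape[1:]
    yy, xx = np.mgrid[0:h, 0:w]
    traces: dict[int, np.ndarray] = {}
    for c in cells:
        mask = (yy - c.center_px[0]) ** 2 + (xx - c.center_px[1]) ** 2 <= c.radius_px ** 2
        traces[c.id] = dff[:, mask].mean(axis=1)
    return traces


def _suprathreshold_run(trace: np.ndarray, onset: int, threshold: float
                        ) -> tuple[int, int, int] | None:
    """(run_start, run_end_exclusive, peak_index) of the suprathreshold run
    containing the post-stimulus maximum, or None if the peak is below
    threshold. Indices are absolute; the run may begin before the stimulus."""
    post = trace[onset:]
    peak = onset + int(np.argmax(post))
    if trace[peak] <= threshold:
        return None
    above = trace > threshold
    start = peak
    while start > 0 and above[start - 1]:
        start -= 1
    end = peak + 1
    while end < trace.size and above[end]:
        end += 1
    return start, end, peak


def detect_ca_response(trace: np.ndarray, stim_onset_frame: int,
                       cfg: Config | None = None,
                       sd_factor: float | None = None,
                       min_duration_ms: float | None = None) -> bool:
    """Response criterion: the run of consecutive samples above
    ``sd_factor`` x baseline SD that contains the post-stimulus maximum must
    last at least ``min_duration_ms`` (2 x SD for >= 100 ms by default)."""
    cfg = cfg or Config()
    factor = cfg.ca_sd_factor if sd_factor is None else sd_factor
    min_dur = cfg.ca_min_duration_ms if min_duration_ms is None else min_duration_ms
    trace = np.asarray(trace, dtype=float)
    if stim_onset_frame < 10:
        raise ValueError("need at least 10 baseline samples")
    sd = float(trace[:stim_onset_frame].std(ddof=0))
    run = _suprathreshold_run(trace, stim_onset_frame, factor * sd)
    if run is None:
        return False
    start, end, _ = run
    return (end - start) * cfg.ca_frame_interval_ms >= min_dur


def _interp_crossing(t: np.ndarray, y: np.ndarray, i: int, level: float) -> float:
    """Linear-interpolated time at which y crosses ``level`` between samples
    i-1 and i (y[i-1] < level <= y[i])."""
    if i == 0 or y[i] == y[i - 1]:
        return float(t[i])
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def ca_kinetics(trace: np.ndarray, stim_onset_frame: int,
                cfg: Config | None = None,
                sd_factor: float | None = None,
                min_duration_ms: float | None = None) -> CaResponse:
    """Kinetic metrics of one responding trace (all in ms from stimulus).

    time to peak: stimulus onset to the post-stimulus maximum. latency: the
    backward search from the peak finds the last sub-threshold sample; the
    sample after it is the response onset. rise time: interpolated interval
    between the 20% and 80% peak-amplitude crossings on the rising phase
    (a linear ramp of 100 ms rises 20->80% in 60 ms; a saturating exponential
    in tau*ln4). duration: length of the suprathreshold run containing the
    peak. Non-responders come back flagged with undefined metrics.
    """
    cfg = cfg or Config()
    factor = cfg.ca_sd_factor if sd_factor is None else sd_factor
    trace = np.asarray(trace, dtype=float)
    dt = cfg.ca_frame_interval_ms
    if not detect_ca_response(trace, stim_onset_frame, cfg, factor,
                              min_duration_ms):
        sd = float(trace[:stim_onset_frame].std(ddof=0))
        return CaResponse(responding=False, baseline_sd=sd)
    sd = float(trace[:stim_onset_frame].std(ddof=0))
    start, end, peak = _suprathreshold_run(trace, stim_onset_frame,
                                           factor * sd)
    t_ms = (np.arange(trace.size) - stim_onset_frame) * dt
    peak_amp = float(trace[peak])
    latency = float(t_ms[max(start, 0)])
    # 20-80% crossings on the rising phase, interpolated between samples
    t20 = t80 = None
    for i in range(start, peak + 1):
        if t20 is None and trace[i] >= 0.2 * peak_amp:
            t20 = _interp_crossing(t_ms, trace, i, 0.2 * peak_amp)
        if t80 is None and trace[i] >= 0.8 * peak_amp:
            t80 = _interp_crossing(t_ms, trace, i, 0.8 * peak_amp)
    rise = None if t20 is None or t80 is None else float(t80 - t20)
    return CaResponse(
        responding=True,
        peak_amplitude=peak_amp,
        time_to_peak_ms=float(t_ms[peak]),
        latency_ms=latency,
        rise_time_20_80_ms=rise,
        duration_above_2sd_ms=float((end - start) * dt),
        baseline_sd=sd,
    )


def responding_fraction(cellmap: CellMap, responses: dict[int, bool | CaResponse]
                        ) -> dict[str, dict]:
    """Per-class responder counts and percentage (to 0.1%).

    Every non-excluded cell must be scored. Returns
    ``{class: {"responding": r, "total": n, "percent": 100 r/n}}``; two
    conditions' counts feed a 2x2 contingency table for the chi-square test
    (e.g. 220 of 830 -> 26.5%).
    """
    out: dict[str, dict] = {}
    for c in cellmap.active():
        if c.id not in responses:
            raise ValueError(f"cell {c.id} not scored")
        r = responses[c.id]
        flag = r.responding if isinstance(r, CaResponse) else bool(r)
        entry = out.setdefault(c.cls, {"responding": 0, "total": 0})
        entry["total"] += 1
        entry["responding"] += int(flag)
    for cls, entry in out.items():
        if entry["total"] == 0:
            raise ValueError(f"empty class {cls}")
        entry["percent"] = round(100.0 * entry["responding"] / entry["total"], 1)
    return out
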