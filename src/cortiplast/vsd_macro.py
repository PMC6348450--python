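"""Macroscopic wide-field VSD analysis.

Pipeline: average stimulated and blank (no-stimulus) trials, subtract the
blank average frame-wise to cancel dye bleaching, divide by the pre-stimulus
baseline fluorescence F to get ΔF/F, smooth each frame with a 9x9 mean
filter, then threshold at ``sd_factor`` (default 7) times the per-pixel
baseline SD. Temporal metrics (peak amplitude, latency, time to peak) are
read off the mean ΔF/F trace of a circular ROI centred on the initial
response; the response area is the suprathreshold pixel count in the peak
frame times the pixel area. Maps from multiple animals are superimposed
after a rigid landmark alignment (rhinal-fissure direction + MCA point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy import ndimage
from skimage import measure, transform

from .core_io import Config, ImageStack

__all__ = [
    "DffMovie",
    "SignificanceMasks",
    "RoiMetrics",
    "ResponseMap",
    "AlignedMaps",
    "compute_dff_movie",
    "detect_significant_pixels",
    "find_initial_response",
    "roi_metrics",
    "peak_area",
    "align_and_superimpose",
]


@dataclass
class DffMovie:
    """ΔF/F movie plus the per-pixel baseline SD used for significance."""

    dff: np.ndarray                   # (t, h, w), dimensionless
    baseline_sd: np.ndarray           # (h, w)
    stim_onset_frame: int
    frame_interval_ms: float
    pixel_size_um: tuple[float, float]

    def __post_init__(self) -> None:
        if not np.isfinite(self.dff).all():
            raise ValueError("dff contains non-finite values")

    def times_ms(self) -> np.ndarray:
        idx = np.arange(self.dff.shape[0]) - self.stim_onset_frame
        return idx * self.frame_interval_ms


@dataclass
class SignificanceMasks:
    masks: np.ndarray                 # (t, h, w) bool
    sd_factor: float


@dataclass
class RoiMetrics:
    defined: bool
    peak_amplitude: float | None = None
    latency_ms: float | None = None
    time_to_peak_ms: float | None = None
    peak_frame: int | None = None
    roi_center: tuple[float, float] | None = None
    roi_radius_px: float | None = None
    trace: np.ndarray | None = None
    roi_baseline_sd: float | None = None


@dataclass
class ResponseMap:
    mask: np.ndarray                  # (h, w) bool, suprathreshold at peak
    area_mm2: float
    pixel_size_um: tuple[float, float]
    landmarks: dict = field(default_factory=dict)
    # landmarks: {"mca": (row, col), "fissure": ((r1, c1), (r2, c2))}


@dataclass
class AlignedMaps:
    overlap: np.ndarray               # (h, w) int, animals suprathreshold
    contour_mask: np.ndarray          # overlap >= ceil(n/2)
    threshold: int
    n_maps: int
    contours: list = field(default_factory=list)


def _spatial_filter(frames: np.ndarray, size: int) -> np.ndarray:
    """9x9 (by default) uniform mean filter applied frame-wise."""
    return ndimage.uniform_filter(frames, size=(1, size, size), mode="nearest")


def compute_dff_movie(stim_trials: list[ImageStack],
                      blank_trials: list[ImageStack],
                      cfg: Config | None = None) -> DffMovie:
    """Trial-average, blank-subtract, normalise and spatially filter.

    F (the normaliser) is the per-pixel mean of the raw stimulated average
    over the pre-stimulus window; the baseline SD is computed from the
    filtered ΔF/F over the same window.
    """
    cfg = cfg or Config()
    if not stim_trials or not blank_trials:
        raise ValueError("need at least one stimulated and one blank trial")
    shape = stim_trials[0].shape
    ref = stim_trials[0]
    for s in stim_trials + blank_trials:
        if s.shape != shape:
            raise ValueError("trial geometry mismatch")
    onset = ref.stim_onset_frame
    if onset < 1:
        raise ValueError("empty baseline window (stim_onset_frame == 0)")
    stim_avg = np.mean([s.frames for s in stim_trials], axis=0)
    blank_avg = np.mean([b.frames for b in blank_trials], axis=0)
    f0 = stim_avg[:onset].mean(axis=0)
    if (f0 <= 0).any():
        raise ValueError("non-positive baseline fluorescence")
    dff = (stim_avg - blank_avg) / f0[None]
    dff = _spatial_filter(dff, cfg.spatial_filter_px)
    baseline_sd = dff[:onset].std(axis=0, ddof=0)
    return DffMovie(dff, baseline_sd, onset, ref.frame_interval_ms,
                    ref.pixel_size_um)


def detect_significant_pixels(movie: DffMovie,
                              sd_factor: float | None = None,
                              cfg: Config | None = None) -> SignificanceMasks:
    """Per-pixel significance: ΔF/F exceeding ``sd_factor`` x baseline SD."""
    cfg = cfg or Config()
    factor = cfg.vsd_sd_factor if sd_factor is None else sd_factor
    if factor <= 0:
        raise ValueError("sd_factor must be > 0")
    masks = movie.dff > factor * movie.baseline_sd[None]
    return SignificanceMasks(masks, factor)


def find_initial_response(masks: SignificanceMasks,
                          movie: DffMovie | None = None,
                          region_polygon: np.ndarray | None = None,
                          ) -> tuple[int, tuple[float, float]] | None:
    """Earliest post-stimulus frame with any suprathreshold pixel, and the
    centroid of its suprathreshold pixels.

    ``region_polygon`` ((row, col) vertices) restricts the centroid to a
    cortical region of interest: when initial responses appear in several
    areas simultaneously, the ROI is placed in the designated region. Returns
    None when no frame is significant (a valid no-response outcome).
    """
    m = masks.masks
    start = movie.stim_onset_frame if movie is not None else 0
    region_mask = None
    if region_polygon is not None:
        from skimage.draw import polygon2mask
        region_mask = polygon2mask(m.shape[1:], np.asarray(region_polygon))
    for t in range(start, m.shape[0]):
        frame = m[t]
        if not frame.any():
            continue
        sel = frame & region_mask if region_mask is not None else frame
        if not sel.any():
            sel = frame  # nothing inside the region: fall back to the full frame
        ys, xs = np.nonzero(sel)
        return t, (float(ys.mean()), float(xs.mean()))
    return None


def _roi_mask(shape: tuple[int, int], center: tuple[float, float],
              radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def roi_metrics(movie: DffMovie, roi_center: tuple[float, float],
                roi_radius_px: float | None = None,
                cfg: Config | None = None,
                sd_factor: float | None = None) -> RoiMetrics:
    """Temporal metrics of the circular-ROI mean ΔF/F trace.

    Latency = first post-stimulus frame whose ROI trace exceeds
    ``sd_factor`` x the ROI-trace baseline SD, in ms from stimulus onset;
    time to peak = time of the post-stimulus maximum. Cases with no
    significant trace are flagged undefined rather than reported.
    """
    cfg = cfg or Config()
    radius = cfg.vsd_roi_radius_px if roi_radius_px is None else roi_radius_px
    if radius <= 0:
        raise ValueError("roi radius must be > 0")
    factor = cfg.vsd_sd_factor if sd_factor is None else sd_factor
    h, w = movie.dff.shape[1:]
    if not (0 <= roi_center[0] < h and 0 <= roi_center[1] < w):
        raise ValueError("ROI centre outside the field")
    mask = _roi_mask((h, w), roi_center, radius)
    trace = movie.dff[:, mask].mean(axis=1)
    onset = movie.stim_onset_frame
    base_sd = float(trace[:onset].std(ddof=0))
    post = trace[onset:]
    sig = post > factor * base_sd
    if not sig.any():
        return RoiMetrics(defined=False, roi_center=roi_center,
                          roi_radius_px=radius, trace=trace,
                          roi_baseline_sd=base_sd)
    first = int(np.argmax(sig))
    peak_rel = int(np.argmax(post))
    dt = movie.frame_interval_ms
    return RoiMetrics(
        defined=True,
        peak_amplitude=float(post[peak_rel]),
        latency_ms=first * dt,
        time_to_peak_ms=peak_rel * dt,
        peak_frame=onset + peak_rel,
        roi_center=roi_center,
        roi_radius_px=radius,
        trace=trace,
        roi_baseline_sd=base_sd,
    )


def peak_area(movie: DffMovie, masks: SignificanceMasks,
              metrics: RoiMetrics, landmarks: dict | None = None,
              largest_component_only: bool = False) -> ResponseMap:
    """Suprathreshold outline in the peak-amplitude frame and its area.

    Area = pixel count x pixel area; for the wide-field sensor one pixel is
    (6.4/184) x (4.8/124) mm, so 1000 pixels is about 1.35 mm^2. An undefined
    peak yields an empty map of area 0.
    """
    h, w = movie.dff.shape[1:]
    if not metrics.defined:
        return ResponseMap(np.zeros((h, w), dtype=bool), 0.0,
                           movie.pixel_size_um, landmarks or {})
    mask = masks.masks[metrics.peak_frame].copy()
    if largest_component_only and mask.any():
        labels = measure.label(mask, connectivity=2)
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        mask = labels == largest
    py, px = movie.pixel_size_um
    area_mm2 = float(mask.sum()) * (py / 1000.0) * (px / 1000.0)
    return ResponseMap(mask, area_mm2, movie.pixel_size_um, landmarks or {})


def _fissure_angle(landmarks: dict) -> float:
    (r1, c1), (r2, c2) = landmarks["fissure"]
    return float(np.arctan2(r2 - r1, c2 - c1))


def align_and_superimpose(maps: list[ResponseMap],
                          reference: int = 0) -> AlignedMaps:
    """Rigidly align response maps on their landmarks and count overlap.

    Each animal's map is rotated so its rhinal-fissure direction matches the
    reference and translated so its MCA point lands on the reference MCA
    point (two landmarks determine translation + rotation only). The overlap
    image counts animals suprathreshold per pixel; the contour encloses
    pixels responding in at least half (ceil(n/2)) of the animals. Maps
    lacking either landmark are excluded with a warning.
    """
    usable: list[ResponseMap] = []
    for i, m in enumerate(maps):
        if "mca" not in m.landmarks or "fissure" not in m.landmarks:
            warnings.warn(f"map {i} lacks landmarks and was excluded")
            continue
        usable.append(m)
    if not usable:
        raise ValueError("no maps with complete landmarks")
    ref = usable[reference if reference < len(usable) else 0]
    ref_angle = _fissure_angle(ref.landmarks)
    ref_mca = np.asarray(ref.landmarks["mca"], dtype=float)
    h, w = ref.mask.shape
    overlap = np.zeros((h, w), dtype=int)
    for m in usable:
        d_theta = ref_angle - _fissure_angle(m.landmarks)
        mca = np.asarray(m.landmarks["mca"], dtype=float)
        # transforms work in (x, y) = (col, row)
        rot = transform.EuclideanTransform(rotation=d_theta)
        src_xy = mca[::-1]
        dst_xy = ref_mca[::-1]
        shift = dst_xy - rot(src_xy[None])[0]
        tform = transform.EuclideanTransform(rotation=d_theta, translation=shift)
        warped = transform.warp(m.mask.astype(float), inverse_map=tform.inverse,
                                order=0, output_shape=(h, w), cval=0.0,
                                preserve_range=True)
        overlap += warped > 0.5
    threshold = ceil(len(usable) / 2)
    contour_mask = overlap >= threshold
    contours = measure.find_contours(contour_mask.astype(float), 0.5)
    return AlignedMaps(overlap, contour_mask, threshold, len(usable), contours)
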