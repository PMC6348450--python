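"""Ground-truthed synthetic recordings for all four modalities.

Each generator emulates the statistical structure the corresponding analysis
stage assumes — not the optics or biophysics of the preparation:

* wide-field VSD trials: a concentric, radially spreading Gaussian response
  riding on a linearly bleaching baseline, plus per-pixel Gaussian noise;
  blank (no-stimulus) trials carry the bleach and noise only, which is what
  the blank-subtraction step corrects;
* two-photon sessions: a Venus snapshot, a green Ca-indicator movie and a red
  astrocyte-marker snapshot with disk somata; responder neurons follow a
  difference-of-exponentials transient;
* photostimulation sessions: one voltage-clamp sweep per grid site whose
  windowed charge equals the planted input map; sites in the direct zone also
  carry a short-latency, slow-decay direct component;
* mIPSC traces: Poisson event trains with biexponential outward events at a
  +10 mV holding potential.

All generators are deterministic in their seed, and every ground truth is
rich enough to score the downstream detector (hit/miss/false-alarm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import Config, ImageStack, SweepSet
from .mini_events import EventTrain

__all__ = [
    "VsdGroundTruth",
    "CaCellTruth",
    "CaGroundTruth",
    "CaSession",
    "LspsGroundTruth",
    "MiniGroundTruth",
    "generate_vsd_trial_set",
    "generate_ca_session",
    "generate_lsps_session",
    "generate_mini_trace",
    "make_ca_truth",
    "make_lsps_truth",
    "vsd_response_movie",
    "ca_transient",
    "biexp_kernel",
]


# ---------------------------------------------------------------------------
# shared waveforms

def _alpha_profile(u_ms: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Normalised (peak = 1) rise-and-decay profile, zero for u < 0."""
    u = np.maximum(u_ms, 0.0)
    g = (1.0 - np.exp(-u / tau_rise)) * np.exp(-u / tau_decay)
    t_peak = tau_rise * np.log1p(tau_decay / tau_rise)
    g_max = (1.0 - np.exp(-t_peak / tau_rise)) * np.exp(-t_peak / tau_decay)
    out = np.where(u_ms >= 0.0, g / g_max, 0.0)
    return out


def ca_transient(t_ms: np.ndarray, amplitude: float, onset_ms: float,
                 tau_rise_ms: float, tau_decay_ms: float) -> np.ndarray:
    """Difference-of-exponentials Ca transient, peak = ``amplitude``.

    ``t_ms`` is time relative to stimulus onset; the transient starts at
    ``onset_ms`` after the stimulus.
    """
    return amplitude * _alpha_profile(np.asarray(t_ms, dtype=float) - onset_ms,
                                      tau_rise_ms, tau_decay_ms)


def biexp_kernel(dt_ms: float, tau_rise_ms: float, tau_decay_ms: float,
                 n_tau: float = 8.0) -> np.ndarray:
    """Unit-peak biexponential event kernel sampled at ``dt_ms``."""
    t = np.arange(0.0, n_tau * tau_decay_ms, dt_ms)
    return _alpha_profile(t, tau_rise_ms, tau_decay_ms)


# ---------------------------------------------------------------------------
# wide-field VSD

@dataclass
class VsdGroundTruth:
    """Parameters of one planted wide-field response.

    Scales follow the study's printed group means: peak ΔF/F ~0.23 for the
    control response, onset latency near 16 ms (4 frames at 250 Hz).
    """

    peak_dff: float = 0.229
    onset_latency_ms: float = 16.0
    response_center_px: tuple[float, float] | None = None  # (row, col)
    sigma0_um: float = 500.0          # spatial SD at onset
    spread_rate_um_per_ms: float = 10.0
    bleach_slope_per_frame: float = 5e-4
    noise_sd: float = 0.05            # per-pixel, per-trial, units of F0
    tau_rise_ms: float = 8.0
    tau_decay_ms: float = 80.0
    f0: float = 1000.0
    field_px: tuple[int, int] = (124, 184)
    n_frames: int = 75
    stim_onset_frame: int = 25        # 100-ms pre-stimulus baseline epoch

    def __post_init__(self) -> None:
        if self.peak_dff < 0:
            raise ValueError("peak_dff must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def center(self) -> tuple[float, float]:
        if self.response_center_px is not None:
            return self.response_center_px
        return ((self.field_px[0] - 1) / 2.0, (self.field_px[1] - 1) / 2.0)


def vsd_response_movie(truth: VsdGroundTruth, cfg: Config | None = None) -> np.ndarray:
    """Noiseless ΔF/F movie of the planted response (the closed-form model).

    dff(t, r) = A * g(t - onset) * exp(-r^2 / (2 sigma(t)^2)) with sigma
    growing linearly from onset — the simplest shape consistent with
    concentric propagation. Used both by the trial generator and as the
    analytic oracle in tests.
    """
    cfg = cfg or Config()
    h, w = truth.field_px
    py, px = cfg.vsd_pixel_size_um
    cy, cx = truth.center()
    t_ms = (np.arange(truth.n_frames) - truth.stim_onset_frame) * cfg.vsd_frame_interval_ms
    u = t_ms - truth.onset_latency_ms
    g = truth.peak_dff * _alpha_profile(u, truth.tau_rise_ms, truth.tau_decay_ms)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - cy) * py) ** 2 + ((xx - cx) * px) ** 2
    sigma = truth.sigma0_um + truth.spread_rate_um_per_ms * np.maximum(u, 0.0)
    dff = g[:, None, None] * np.exp(-r2[None] / (2.0 * sigma[:, None, None] ** 2))
    return dff


def generate_vsd_trial_set(
    truth: VsdGroundTruth, n_trials: int, seed: int, cfg: Config | None = None,
) -> tuple[list[ImageStack], list[ImageStack], VsdGroundTruth]:
    """Simulate ``n_trials`` stimulated and ``n_trials`` blank trials.

    Blank trials contain the bleaching drift and noise only; stimulated
    trials add the planted response. Identical seeds give identical stacks.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cfg = cfg or Config()
    h, w = truth.field_px
    py, px = cfg.vsd_pixel_size_um
    # response footprint (4 sigma across) must fit in the field
    if truth.peak_dff > 0 and 4.0 * truth.sigma0_um > min(h * py, w * px):
        raise ValueError("field smaller than the response footprint")
    rng = np.random.default_rng(seed)
    dff = vsd_response_movie(truth, cfg)
    frames_t = np.arange(truth.n_frames)
    bleach = (1.0 - truth.bleach_slope_per_frame * frames_t)[:, None, None]
    base = truth.f0 * bleach
    stim_clean = base * (1.0 + dff)
    noise_scale = truth.noise_sd * truth.f0

    def _make(clean: np.ndarray) -> ImageStack:
        frames = clean + rng.normal(0.0, noise_scale, size=clean.shape) \
            if noise_scale > 0 else clean.copy()
        return ImageStack(frames, cfg.vsd_frame_interval_ms,
                          cfg.vsd_pixel_size_um, channel="vsd",
                          stim_onset_frame=truth.stim_onset_frame)

    stim = [_make(stim_clean) for _ in range(n_trials)]
    blank = [_make(base * np.ones_like(dff)) for _ in range(n_trials)]
    return stim, blank, truth


# ---------------------------------------------------------------------------
# two-photon Ca sessions

@dataclass
class CaCellTruth:
    id: int
    center_px: tuple[float, float]  # (row, col)
    radius_px: float
    cls: str                        # excitatory | inhibitory | astrocyte
    responder: bool = False
    amplitude: float = 2.2
    onset_ms: float = 170.0
    tau_rise_ms: float = 50.0
    tau_decay_ms: float = 300.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius must be > 0")
        if self.cls == "astrocyte" and self.responder:
            raise ValueError("astrocytes are never responders")


@dataclass
class CaGroundTruth:
    cells: list[CaCellTruth]
    field_px: tuple[int, int] = (144, 512)
    n_frames: int = 120
    stim_onset_frame: int = 30
    n_trials: int = 20
    f0_cell: float = 800.0
    f0_background: float = 100.0
    noise_sd_frac: float = 0.10       # per-pixel per-trial, units of f0_cell
    venus_intensity: float = 1000.0
    red_intensity: float = 800.0
    overlap_warning: bool = False

    def __post_init__(self) -> None:
        h, w = self.field_px
        for c in self.cells:
            if not (0 <= c.center_px[0] < h and 0 <= c.center_px[1] < w):
                raise ValueError(f"soma {c.id} outside field")


@dataclass
class CaSession:
    venus: ImageStack
    green: ImageStack
    red: ImageStack
    truth: CaGroundTruth


def make_ca_truth(
    n_cells: int,
    responder_fraction: float,
    seed: int,
    field_px: tuple[int, int] = (144, 512),
    radius_px: float = 8.0,
    inhibitory_fraction: float = 0.17,
    astrocyte_fraction: float = 0.10,
    amplitude: float = 2.2,
    onset_ms: float = 170.0,
    tau_rise_ms: float = 50.0,
    tau_decay_ms: float = 300.0,
    min_gap_px: float = 8.0,
    **kwargs,
) -> CaGroundTruth:
    """Place non-overlapping somata and draw classes and responder flags.

    Responder flags are Bernoulli(``responder_fraction``) for neurons;
    astrocytes never respond. ``min_gap_px`` keeps somata separated beyond
    the reach of the 9x9 + 3x3 smoothing so one soma's transient cannot
    bleed into a neighbour's ROI (the in-vivo analogue — somata contaminated
    by overlapping structures — is excluded from analysis, not simulated).
    Raises if the requested count cannot be packed into the field.
    """
    rng = np.random.default_rng(seed)
    h, w = field_px
    margin = radius_px + 1
    min_d2 = (2.0 * radius_px + min_gap_px) ** 2
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > 200 * n_cells:
            raise ValueError("cannot pack requested somata into the field")
        cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all((cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= min_d2 for c in centers):
            centers.append(cand)
    cells = []
    for i, c in enumerate(centers):
        u = rng.uniform()
        if u < astrocyte_fraction:
            cls = "astrocyte"
        elif u < astrocyte_fraction + inhibitory_fraction:
            cls = "inhibitory"
        else:
            cls = "excitatory"
        responder = cls != "astrocyte" and rng.uniform() < responder_fraction
        cells.append(CaCellTruth(i, c, radius_px, cls, responder,
                                 amplitude=amplitude, onset_ms=onset_ms,
                                 tau_rise_ms=tau_rise_ms,
                                 tau_decay_ms=tau_decay_ms))
    return CaGroundTruth(cells, field_px=field_px, **kwargs)


def _disk_indices(center: tuple[float, float], radius: float,
                  shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    cy, cx = center
    y0, y1 = max(0, int(cy - radius) - 1), min(shape[0], int(cy + radius) + 2)
    x0, x1 = max(0, int(cx - radius) - 1), min(shape[1], int(cx + radius) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    return yy[inside], xx[inside]


def generate_ca_session(truth: CaGroundTruth, seed: int,
                        cfg: Config | None = None,
                        max_overlap_fraction: float = 0.0) -> CaSession:
    """Render one trial-averaged two-photon session.

    The green movie carries the Ca transients (responders only); the Venus
    snapshot labels inhibitory somata; the red snapshot labels astrocytes.
    Pixel noise is scaled by 1/sqrt(n_trials) to stand for the trial average.
    Somata overlapping beyond ``max_overlap_fraction`` of pairs set a warning
    flag on the returned truth rather than raising.
    """
    if not truth.cells:
        raise ValueError("need at least one cell")
    cfg = cfg or Config()
    rng = np.random.default_rng(seed)
    h, w = truth.field_px
    n_overlap = 0
    for i, a in enumerate(truth.cells):
        for b in truth.cells[i + 1:]:
            d2 = (a.center_px[0] - b.center_px[0]) ** 2 + \
                 (a.center_px[1] - b.center_px[1]) ** 2
            if d2 < (a.radius_px + b.radius_px) ** 2:
                n_overlap += 1
    n_pairs = max(1, len(truth.cells) * (len(truth.cells) - 1) // 2)
    if n_overlap / n_pairs > max_overlap_fraction:
        if n_overlap:
            warnings.warn("overlapping somata beyond configured fraction")
            truth.overlap_warning = True

    static = np.full((h, w), truth.f0_background)
    venus_img = np.full((h, w), truth.f0_background)
    red_img = np.full((h, w), truth.f0_background)
    disks = {c.id: _disk_indices(c.center_px, c.radius_px, (h, w))
             for c in truth.cells}
    for c in truth.cells:
        ys, xs = disks[c.id]
        static[ys, xs] = truth.f0_cell
        if c.cls == "inhibitory":
            venus_img[ys, xs] = truth.venus_intensity
        if c.cls == "astrocyte":
            red_img[ys, xs] = truth.red_intensity

    noise_sd = truth.noise_sd_frac * truth.f0_cell / np.sqrt(truth.n_trials)
    movie = rng.normal(0.0, noise_sd, size=(truth.n_frames, h, w)) + static[None]
    t_ms = (np.arange(truth.n_frames) - truth.stim_onset_frame) * cfg.ca_frame_interval_ms
    for c in truth.cells:
        if not c.responder:
            continue
        trace = ca_transient(t_ms, c.amplitude, c.onset_ms,
                             c.tau_rise_ms, c.tau_decay_ms)
        ys, xs = disks[c.id]
        movie[:, ys, xs] += truth.f0_cell * trace[:, None]

    img_noise = truth.noise_sd_frac * truth.f0_cell / 4.0  # stack projections
    venus_img = venus_img + rng.normal(0.0, img_noise, size=(h, w))
    red_img = red_img + rng.normal(0.0, img_noise, size=(h, w))

    pix = cfg.ca_pixel_size_um
    dt = cfg.ca_frame_interval_ms
    return CaSession(
        venus=ImageStack(venus_img[None], dt, pix, channel="venus"),
        green=ImageStack(movie, dt, pix, channel="green",
                         stim_onset_frame=truth.stim_onset_frame),
        red=ImageStack(red_img[None], dt, pix, channel="red"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# photostimulation (uncaging) sessions

@dataclass
class LspsGroundTruth:
    """Planted per-site synaptic charge (fC) plus direct-response zone."""

    input_map: np.ndarray             # fC per grid site, >= 0
    direct_zone: frozenset = frozenset()
    latency_range_ms: tuple[float, float] = (7.0, 30.0)
    tau_rise_ms: float = 2.0
    tau_decay_ms: float = 8.0
    noise_sd_pa: float = 2.0
    direct_amplitude_pa: float = 200.0
    direct_latency_range_ms: tuple[float, float] = (1.0, 3.0)
    direct_tau_decay_ms: float = 100.0
    sweep_duration_ms: float = 300.0  # long enough to expose direct decays
    stim_onset_ms: float = 50.0

    def __post_init__(self) -> None:
        self.input_map = np.asarray(self.input_map, dtype=float)
        if (self.input_map < 0).any():
            raise ValueError("charges must be >= 0")


def make_lsps_truth(grid, hot_band_um: tuple[float, float] = (500.0, 750.0),
                    hot_charge_fc: float = 250.0, base_charge_fc: float = 100.0,
                    soma_site: int | None = None, direct_radius_um: float = 100.0,
                    **kwargs) -> LspsGroundTruth:
    """Depth-profiled input map: ``hot_charge_fc`` inside the depth band,
    ``base_charge_fc`` elsewhere; sites within ``direct_radius_um`` of the
    soma site form the direct zone."""
    depths = grid.sites[:, 1]
    charges = np.where((depths >= hot_band_um[0]) & (depths < hot_band_um[1]),
                       hot_charge_fc, base_charge_fc)
    direct: frozenset = frozenset()
    if soma_site is not None:
        soma_xy = grid.sites[soma_site]
        d = np.hypot(*(grid.sites - soma_xy).T)
        direct = frozenset(np.nonzero(d <= direct_radius_um)[0].tolist())
    return LspsGroundTruth(charges, direct_zone=direct, **kwargs)


def generate_lsps_session(
    truth: LspsGroundTruth, grid, seed: int, cfg: Config | None = None,
) -> tuple[SweepSet, LspsGroundTruth]:
    """One voltage-clamp sweep per grid site (inward events are negative).

    Synaptic event amplitudes are scaled so that the trapezoidal integral of
    the noiseless sweep over the 5-70 ms analysis window equals the planted
    charge, making noiseless charge recovery exact by construction.
    """
    cfg = cfg or Config()
    n_sites = grid.n_sites
    if truth.input_map.shape != (n_sites,):
        raise ValueError("input_map length must equal the number of grid sites")
    if not set(truth.direct_zone) <= set(range(n_sites)):
        raise ValueError("direct_zone must be a subset of the grid")
    rng = np.random.default_rng(seed)
    fs = cfg.ephys_sampling_hz
    dt = 1000.0 / fs
    n = int(round(truth.sweep_duration_ms / dt))
    onset_idx = int(round(truth.stim_onset_ms / dt))
    t_rel = (np.arange(n) - onset_idx) * dt  # ms from photostimulus
    w0, w1 = cfg.synaptic_window_ms
    in_win = (t_rel >= w0) & (t_rel <= w1)
    sweeps = np.zeros((n_sites, n))
    for i in range(n_sites):
        c = truth.input_map[i]
        if c > 0:
            lat = rng.uniform(*truth.latency_range_ms)
            shape = _alpha_profile(t_rel - lat, truth.tau_rise_ms,
                                   truth.tau_decay_ms)
            unit_charge = np.trapezoid(shape[in_win], dx=dt)  # pA*ms = fC
            if unit_charge <= 0:
                raise ValueError("event lies outside the analysis window")
            sweeps[i] -= (c / unit_charge) * shape
        if i in truth.direct_zone:
            dlat = rng.uniform(*truth.direct_latency_range_ms)
            dshape = _alpha_profile(t_rel - dlat, 0.5, truth.direct_tau_decay_ms)
            sweeps[i] -= truth.direct_amplitude_pa * dshape
    if truth.noise_sd_pa > 0:
        sweeps += rng.normal(0.0, truth.noise_sd_pa, size=sweeps.shape)
    sweep_set = SweepSet(sweeps, fs, stim_onset_ms=truth.stim_onset_ms,
                         holding_potential_mv=-60.0)
    return sweep_set, truth


# ---------------------------------------------------------------------------
# mIPSC traces

@dataclass
class MiniGroundTruth:
    """Poisson mIPSC train parameters (control scale: ~5.9 Hz, 14.6 pA)."""

    rate_hz: float = 1.0 / 0.17
    amplitude_mean_pa: float = 14.6
    amplitude_sd_pa: float = 3.0
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 10.0
    noise_sd_pa: float = 2.0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate must be > 0")
        if self.amplitude_mean_pa <= 0:
            raise ValueError("amplitude_mean must be > 0")


def generate_mini_trace(
    truth: MiniGroundTruth, duration_s: float, seed: int,
    cfg: Config | None = None,
) -> tuple[SweepSet, EventTrain]:
    """Continuous voltage-clamp trace of Poisson mIPSCs (outward-positive at
    the +10 mV holding potential) plus the true event train.

    Event onsets are snapped to the sample grid so a noiseless trace can be
    recovered exactly. Warns when rate*duration < 5 (unstable statistics).
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    cfg = cfg or Config()
    if truth.rate_hz * duration_s < 5:
        warnings.warn("fewer than ~5 expected events: unstable statistics")
    rng = np.random.default_rng(seed)
    fs = cfg.ephys_sampling_hz
    dt = 1000.0 / fs
    n = int(round(duration_s * fs))
    # Poisson process via exponential gaps
    times = []
    t = rng.exponential(1.0 / truth.rate_hz)
    kernel = biexp_kernel(dt, truth.tau_rise_ms, truth.tau_decay_ms)
    while t < duration_s - len(kernel) / fs:
        times.append(t)
        t += rng.exponential(1.0 / truth.rate_hz)
    idx = np.unique(np.round(np.asarray(times) * fs).astype(int))
    amps = np.maximum(
        rng.normal(truth.amplitude_mean_pa, truth.amplitude_sd_pa, size=idx.size),
        0.1)
    trace = np.zeros(n)
    for i, a in zip(idx, amps):
        seg = min(len(kernel), n - i)
        trace[i:i + seg] += a * kernel[:seg]
    if truth.noise_sd_pa > 0:
        trace += rng.normal(0.0, truth.noise_sd_pa, size=n)
    sweep = SweepSet(trace[None], fs, stim_onset_ms=0.0,
                     holding_potential_mv=10.0)
    train = EventTrain(times_ms=idx * dt, amplitudes_pa=amps,
                       duration_s=duration_s, noise_sd_pa=truth.noise_sd_pa)
    return sweep, train
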