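"""Readers, writers and configuration shared by every pipeline stage.

Conventions used throughout the package:

* all times are milliseconds relative to stimulus onset unless a field name
  says otherwise (``duration_s`` etc.);
* pixel coordinates are 0-based, row-major, origin at the top-left;
* cortical depths are micrometres from the pial surface line;
* image interchange is multi-page TIFF, sweep interchange is CSV with a time
  column followed by one column per sweep, configuration is JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "SweepSet",
    "Config",
    "read_image_stack",
    "write_image_stack",
    "read_sweeps",
    "write_sweeps",
    "load_config",
]


@dataclass
class ImageStack:
    """Time-ordered fluorescence frames plus acquisition geometry.

    frames : (n_frames, height, width) array, intensity in arbitrary units.
    frame_interval_ms : time between frames (4 ms for the 250-Hz wide-field
        camera, 10 ms for the 100-Hz two-photon movies).
    pixel_size_um : (row, col) micrometres per pixel.
    channel : one of ``vsd | venus | green | red``.
    stim_onset_frame : index of the first frame at/after stimulus onset.
    """

    frames: np.ndarray
    frame_interval_ms: float
    pixel_size_um: tuple[float, float]
    channel: str = "vsd"
    stim_onset_frame: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, height, width) array")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be > 0")
        if min(self.pixel_size_um) <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if not (0 <= self.stim_onset_frame < self.frames.shape[0]):
            raise ValueError("stim_onset_frame outside stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def times_ms(self) -> np.ndarray:
        """Frame times in ms relative to stimulus onset."""
        idx = np.arange(self.n_frames) - self.stim_onset_frame
        return idx * self.frame_interval_ms


@dataclass
class SweepSet:
    """A block of equal-length electrophysiology sweeps.

    sweeps : (n_sweeps, n_samples); pA under voltage clamp, mV under current
        clamp.
    sampling_rate_hz : samples per second.
    stim_onset_ms : stimulus time from sweep start, scalar applied to every
        sweep or one value per sweep.
    holding_potential_mv : command potential (−60 mV for the uncaging maps,
        +10 mV for the mIPSC recordings); informational.
    """

    sweeps: np.ndarray
    sampling_rate_hz: float
    stim_onset_ms: float | np.ndarray = 0.0
    holding_potential_mv: float | None = None

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        onset = np.asarray(self.stim_onset_ms, dtype=float)
        if onset.ndim == 1 and onset.size != self.sweeps.shape[0]:
            raise ValueError("per-sweep stim_onset_ms length mismatch")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def onset_of(self, i: int) -> float:
        onset = np.asarray(self.stim_onset_ms, dtype=float)
        return float(onset) if onset.ndim == 0 else float(onset[i])

    def times_ms(self, i: int = 0) -> np.ndarray:
        """Sample times of sweep ``i`` in ms relative to its stimulus."""
        return np.arange(self.n_samples) * self.dt_ms - self.onset_of(i)


# Printed acquisition/analysis constants are collected here so every stage
# reads them from one place.
@dataclass
class Config:
    # significance thresholds
    vsd_sd_factor: float = 7.0          # wide-field: 7 x baseline SD
    ca_sd_factor: float = 2.0           # two-photon: 2 x baseline SD ...
    ca_min_duration_ms: float = 100.0   # ... sustained for >= 100 ms
    # acquisition timing
    vsd_frame_interval_ms: float = 4.0  # 250 Hz
    ca_frame_interval_ms: float = 10.0  # 100 Hz
    ephys_sampling_hz: float = 10000.0  # not stated for the rig; free default
    # filters
    spatial_filter_px: int = 9          # 9 x 9 mean filter, both imaging modes
    ca_cubic_filter: tuple[int, int, int] = (3, 3, 3)  # (t, y, x) mean filter
    # sensor geometry
    vsd_field_px: tuple[int, int] = (124, 184)      # rows, cols
    vsd_field_mm: tuple[float, float] = (4.8, 6.4)  # rows, cols
    ca_field_px: tuple[int, int] = (144, 512)
    ca_field_um: tuple[float, float] = (72.0, 254.0)
    # ROI
    vsd_roi_radius_px: float = 3.0
    # photostimulation map geometry and response windows
    grid_spacing_um: float = 62.5
    grid_width_um: float = 750.0
    grid_length_um: float = 1750.0
    min_separation_um: float = 120.0
    synaptic_window_ms: tuple[float, float] = (5.0, 70.0)
    direct_latency_ms: float = 5.0
    direct_decay_fraction: float = 0.5  # suprathreshold mass beyond 70 ms
    onset_sd_factor: float = 3.0        # evoked-response onset detection
    onset_min_run_ms: float = 0.5       # consecutive time above threshold
    # mIPSC detection
    mini_threshold_sd: float = 4.0
    mini_min_interval_ms: float = 5.0
    mini_tau_rise_ms: float = 1.0
    mini_tau_decay_ms: float = 10.0
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vsd_sd_factor", "ca_sd_factor", "ca_min_duration_ms",
                     "vsd_frame_interval_ms", "ca_frame_interval_ms",
                     "ephys_sampling_hz", "grid_spacing_um",
                     "mini_threshold_sd", "onset_sd_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.direct_latency_ms > self.synaptic_window_ms[0]:
            raise ValueError("direct window must end at or before the "
                             "synaptic window starts")

    @property
    def vsd_pixel_size_um(self) -> tuple[float, float]:
        return (self.vsd_field_mm[0] * 1000.0 / self.vsd_field_px[0],
                self.vsd_field_mm[1] * 1000.0 / self.vsd_field_px[1])

    @property
    def ca_pixel_size_um(self) -> tuple[float, float]:
        return (self.ca_field_um[0] / self.ca_field_px[0],
                self.ca_field_um[1] / self.ca_field_px[1])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_TUPLE_FIELDS = {"ca_cubic_filter", "vsd_field_px", "vsd_field_mm",
                 "ca_field_px", "ca_field_um", "synaptic_window_ms"}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> Config:
    """Build a :class:`Config`, filling unspecified keys with the defaults.

    ``path`` is a JSON object file (an empty file counts as ``{}``); unknown
    keys raise. ``load_config`` is idempotent: re-loading a dumped config
    returns an equal config.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text().strip()
        data = json.loads(text) if text else {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a JSON object")
    if overrides:
        data.update(overrides)
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(data):
        data[key] = tuple(data[key])
    return Config(**data)


# ---------------------------------------------------------------------------
# TIFF image stacks

_META_KEYS = ("frame_interval_ms", "pixel_size_um", "channel", "stim_onset_frame")


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF with JSON metadata in the description."""
    path = Path(path)
    meta = {
        "frame_interval_ms": stack.frame_interval_ms,
        "pixel_size_um": list(stack.pixel_size_um),
        "channel": stack.channel,
        "stim_onset_frame": int(stack.stim_onset_frame),
    }
    tifffile.imwrite(path, stack.frames, description=json.dumps(meta),
                     photometric="minisblack")
    return path


def read_image_stack(path: str | Path, meta: Config | None = None,
                     channel: str = "vsd") -> ImageStack:
    """Read a multi-page TIFF; metadata comes from embedded tags when present,
    otherwise from ``meta`` (VSD defaults: 4-ms frames from the 250-Hz camera).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent page shapes in {path}: {shapes}")
        frames = tif.asarray()
        desc = tif.pages[0].description or ""
    if frames.ndim == 2:
        frames = frames[None]
    tags: dict = {}
    try:
        parsed = json.loads(desc)
        if isinstance(parsed, dict):
            tags = {k: parsed[k] for k in _META_KEYS if k in parsed}
    except (json.JSONDecodeError, TypeError):
        pass
    cfg = meta if meta is not None else Config()
    if channel in ("venus", "green", "red"):
        default_interval = cfg.ca_frame_interval_ms
        default_pixel = cfg.ca_pixel_size_um
    else:
        default_interval = cfg.vsd_frame_interval_ms
        default_pixel = cfg.vsd_pixel_size_um
    return ImageStack(
        frames=frames,
        frame_interval_ms=float(tags.get("frame_interval_ms", default_interval)),
        pixel_size_um=tuple(tags.get("pixel_size_um", default_pixel)),
        channel=str(tags.get("channel", channel)),
        stim_onset_frame=int(tags.get("stim_onset_frame", 0)),
    )


# ---------------------------------------------------------------------------
# CSV sweep tables

def write_sweeps(sweeps: SweepSet, path: str | Path) -> Path:
    """Write a sweep set as CSV: header comments with metadata, a time column
    (ms from sweep start) and one column per sweep."""
    path = Path(path)
    t = np.arange(sweeps.n_samples) * sweeps.dt_ms
    cols = {"time_ms": t}
    cols.update({f"sweep_{i:03d}": sweeps.sweeps[i]
                 for i in range(sweeps.n_sweeps)})
    df = pd.DataFrame(cols)
    onset = np.asarray(sweeps.stim_onset_ms, dtype=float).ravel().tolist()
    header = [
        f"# sampling_rate_hz={sweeps.sampling_rate_hz!r}",
        f"# stim_onset_ms={json.dumps(onset)}",
        f"# holding_potential_mv={json.dumps(sweeps.holding_potential_mv)}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_sweeps(path: str | Path) -> SweepSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, value = line[1:].strip().partition("=")
        meta[key.strip()] = value
        n_header += 1
    import io

    df = pd.read_csv(io.StringIO("\n".join(lines[n_header:])))
    cols = [c for c in df.columns if c.startswith("sweep_")]
    if not cols:
        raise ValueError("sweep table contains no sweep columns")
    if df[cols].isna().any().any():
        raise ValueError("ragged sweep columns (missing values)")
    rate = float(meta.get("sampling_rate_hz", 10000.0))
    onset = json.loads(meta.get("stim_onset_ms", "[0.0]"))
    onset_arr: float | np.ndarray
    onset_arr = onset[0] if len(onset) == 1 else np.asarray(onset, dtype=float)
    holding = json.loads(meta.get("holding_potential_mv", "null"))
    return SweepSet(
        sweeps=df[cols].to_numpy(dtype=float).T,
        sampling_rate_hz=rate,
        stim_onset_ms=onset_arr,
        holding_potential_mv=holding,
    )
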