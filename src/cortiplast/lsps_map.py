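"""Laser-scanning photostimulation (glutamate uncaging) input mapping.

A UV spot walks a regular grid (62.5-µm spacing over 750 x 1750 µm = 336
sites by default) while the postsynaptic cell is held in voltage clamp.
Evoked currents are classified by onset latency: responses starting within
5 ms of the flash that also decay slowly are direct (glutamate on the
recorded cell itself) and are excluded; responses with onsets in the
5-70 ms window are synaptic and are integrated into a charge transfer (fC).
Charges tile an excitation map aligned to the pial surface and the soma's
vertical axis; cohort maps are averaged per grid cell and profiled in
250-µm depth bins within a 500-µm-wide strip centred on the soma axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import Config, SweepSet

__all__ = [
    "StimGrid",
    "EvokedResponse",
    "ExcitationMap",
    "make_grid",
    "stimulation_order",
    "detect_action_potentials",
    "threshold_intensity",
    "classify_evoked_response",
    "charge_transfer",
    "build_excitation_map",
    "average_maps",
    "depth_bin_charge",
]


@dataclass
class StimGrid:
    """Regular photostimulation lattice; sites are (x µm mediolateral,
    y µm depth), row-major, 0-based."""

    sites: np.ndarray                 # (n, 2)
    spacing_um: float
    n_cols: int
    n_rows: int

    @property
    def n_sites(self) -> int:
        return self.sites.shape[0]


@dataclass
class EvokedResponse:
    kind: str                         # direct | synaptic | none
    latency_ms: float | None
    charge_fc: float
    site: int

    def __post_init__(self) -> None:
        if self.kind == "direct" and not (self.latency_ms is not None
                                          and self.latency_ms < 5.0 + 1e-9):
            raise ValueError("direct responses must have latency < 5 ms")
        if self.charge_fc < 0:
            raise ValueError("charge magnitude must be >= 0")


@dataclass
class ExcitationMap:
    """Per-site charge in soma/pia-aligned coordinates.

    ``sites`` columns are (lateral µm from the soma axis, depth µm from the
    pial line); excluded (direct) sites carry NaN charge plus a marker.
    """

    sites: np.ndarray                 # (n, 2) aligned coordinates
    charge_fc: np.ndarray             # (n,), NaN where excluded
    excluded: np.ndarray              # (n,) bool
    soma_um: tuple[float, float]
    cell_class: str = "pyramidal"


def make_grid(spacing_um: float = 62.5, width_um: float = 750.0,
              length_um: float = 1750.0) -> StimGrid:
    """Regular lattice of site centres covering width x length.

    The study triple (62.5, 750, 1750) gives 12 x 28 = 336 sites. Extents
    that do not divide evenly are floored with a warning.
    """
    if spacing_um <= 0:
        raise ValueError("spacing must be > 0")
    n_cols = int(width_um / spacing_um + 1e-9)
    n_rows = int(length_um / spacing_um + 1e-9)
    if abs(n_cols * spacing_um - width_um) > 1e-6 * spacing_um or \
       abs(n_rows * spacing_um - length_um) > 1e-6 * spacing_um:
        warnings.warn("grid extent not divisible by spacing; flooring")
    if n_cols < 1 or n_rows < 1:
        raise ValueError("grid extent smaller than one spacing")
    xs = (np.arange(n_cols) + 0.5) * spacing_um
    ys = (np.arange(n_rows) + 0.5) * spacing_um
    yy, xx = np.meshgrid(ys, xs, indexing="ij")  # row-major over rows (depth)
    sites = np.column_stack([xx.ravel(), yy.ravel()])
    return StimGrid(sites, spacing_um, n_cols, n_rows)


def stimulation_order(grid: StimGrid, seed: int,
                      min_separation_um: float = 120.0,
                      max_restarts: int = 200) -> np.ndarray:
    """Random site permutation with consecutive sites >= ``min_separation_um``
    apart (prevents local receptor desensitisation between flashes).

    Greedy randomised construction with restarts; raises when no order can
    be found (e.g. two sites closer than the separation).
    """
    if grid.n_sites < 2:
        raise ValueError("need at least two sites")
    rng = np.random.default_rng(seed)
    sites = grid.sites
    for _ in range(max_restarts):
        remaining = list(rng.permutation(grid.n_sites))
        order = [remaining.pop()]
        ok = True
        while remaining:
            last = sites[order[-1]]
            dists = np.hypot(*(sites[remaining] - last).T)
            valid = np.nonzero(dists >= min_separation_um)[0]
            if valid.size == 0:
                ok = False
                break
            pick = valid[rng.integers(valid.size)]
            order.append(remaining.pop(pick))
        if ok:
            return np.asarray(order)
    raise ValueError("no stimulation order satisfies the separation constraint")


def detect_action_potentials(voltage: np.ndarray, sampling_rate_hz: float,
                             stim_onset_ms: float = 0.0,
                             threshold_mv: float = 0.0,
                             min_slope_mv_per_ms: float = 10.0) -> np.ndarray:
    """Spike times (ms from the photostimulus) on a current-clamp sweep.

    A spike is an upward crossing of ``threshold_mv`` with local dV/dt above
    ``min_slope_mv_per_ms``.
    """
    v = np.asarray(voltage, dtype=float)
    dt = 1000.0 / sampling_rate_hz
    crossings = np.nonzero((v[:-1] < threshold_mv) & (v[1:] >= threshold_mv))[0] + 1
    times = []
    for i in crossings:
        slope = (v[i] - v[i - 1]) / dt
        if slope > min_slope_mv_per_ms:
            times.append(i * dt - stim_onset_ms)
    return np.asarray(times)


def threshold_intensity(outcomes: dict[float, bool]) -> float | None:
    """Smallest tested laser intensity that evoked at least one spike.

    ``outcomes`` maps intensity (mW) to whether any spike occurred. Returns
    None when no intensity spiked (undefined threshold).
    """
    if not outcomes:
        raise ValueError("empty intensity series")
    spiking = [i for i, spiked in outcomes.items() if spiked]
    return min(spiking) if spiking else None


def _onset_index(sweep: np.ndarray, onset_idx: int, threshold: float,
                 min_run: int = 1) -> int | None:
    """First post-stimulus sample opening a run of >= ``min_run`` consecutive
    suprathreshold samples (single-sample noise spikes are not onsets)."""
    above = np.abs(sweep[onset_idx:]) > threshold
    if min_run > 1:
        kernel = np.ones(min_run, dtype=int)
        runs = np.convolve(above.astype(int), kernel, mode="valid") == min_run
        starts = np.nonzero(runs)[0]
    else:
        starts = np.nonzero(above)[0]
    return None if starts.size == 0 else int(starts[0])


def classify_evoked_response(sweeps: SweepSet, site: int = 0,
                             cfg: Config | None = None) -> EvokedResponse:
    """Classify one site's sweep as direct, synaptic or none.

    Onset = first post-stimulus sample beyond ``onset_sd_factor`` x baseline
    SD. Latency < 5 ms AND a long decay (more than ``direct_decay_fraction``
    of the suprathreshold samples falling beyond 70 ms) -> direct, excluded
    from maps. Onset in [5, 70) ms -> synaptic, integrated to charge.
    Anything else -> none.
    """
    cfg = cfg or Config()
    x = sweeps.sweeps[site]
    dt = sweeps.dt_ms
    onset_ms = sweeps.onset_of(site)
    onset_idx = int(round(onset_ms / dt))
    if onset_idx < 2:
        raise ValueError("no pre-stimulus baseline in sweep")
    base = x[:onset_idx]
    centred = x - base.mean()
    sd = base.std(ddof=0)
    thr = max(cfg.onset_sd_factor * sd, 1e-9 * (np.abs(centred).max() + 1.0))
    min_run = max(1, int(round(cfg.onset_min_run_ms / dt)))
    rel = _onset_index(centred, onset_idx, thr, min_run)
    if rel is None:
        return EvokedResponse("none", None, 0.0, site)
    latency = rel * dt
    w0, w1 = cfg.synaptic_window_ms
    if latency < cfg.direct_latency_ms:
        above = np.abs(centred[onset_idx:]) > thr
        t_rel = np.arange(above.size) * dt
        n_above = above.sum()
        late = (above & (t_rel > w1)).sum()
        if n_above > 0 and late / n_above > cfg.direct_decay_fraction:
            return EvokedResponse("direct", latency, 0.0, site)
        return EvokedResponse("none", latency, 0.0, site)
    if w0 <= latency < w1:
        charge = charge_transfer(sweeps, site=site, cfg=cfg)
        return EvokedResponse("synaptic", latency, charge, site)
    return EvokedResponse("none", latency, 0.0, site)


def charge_transfer(sweeps: SweepSet, site: int = 0,
                    window_ms: tuple[float, float] | None = None,
                    cfg: Config | None = None) -> float:
    """|∫(I − baseline) dt| over the synaptic window, in fC (pA·ms).

    Trapezoidal integration of the baseline-subtracted current between 5 and
    70 ms after the photostimulus (a −100 pA rectangle spanning 20 ms inside
    the window integrates to 2000 fC).
    """
    cfg = cfg or Config()
    w0, w1 = cfg.synaptic_window_ms if window_ms is None else window_ms
    x = sweeps.sweeps[site]
    dt = sweeps.dt_ms
    onset_ms = sweeps.onset_of(site)
    t_rel = np.arange(x.size) * dt - onset_ms
    if w1 > t_rel[-1] + 1e-9 or w0 < t_rel[0] - 1e-9:
        raise ValueError("analysis window outside the sweep")
    onset_idx = int(round(onset_ms / dt))
    baseline = x[:onset_idx].mean() if onset_idx > 0 else 0.0
    sel = (t_rel >= w0) & (t_rel <= w1)
    return float(abs(np.trapezoid(x[sel] - baseline, dx=dt)))


def _pial_frame(pial_line: tuple[tuple[float, float], tuple[float, float]]
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Origin, unit tangent (along the pia) and unit inward normal (depth)."""
    p1 = np.asarray(pial_line[0], dtype=float)
    p2 = np.asarray(pial_line[1], dtype=float)
    tangent = p2 - p1
    norm = np.linalg.norm(tangent)
    if norm == 0:
        raise ValueError("degenerate pial line")
    tangent /= norm
    normal = np.array([-tangent[1], tangent[0]])
    return p1, tangent, normal


def build_excitation_map(grid: StimGrid, responses: list[EvokedResponse],
                         soma_um: tuple[float, float],
                         pial_line: tuple[tuple[float, float], tuple[float, float]],
                         cell_class: str = "pyramidal") -> ExcitationMap:
    """Tile per-site charges into soma/pia-aligned coordinates.

    The rigid change of frame puts the pial line at depth 0 (depth = signed
    perpendicular distance to the line, positive into the tissue) and the
    soma on the vertical axis (lateral = along-pia distance from the soma's
    foot point). Direct sites are excluded markers, not charges.
    """
    if len(responses) != grid.n_sites:
        raise ValueError("one response per grid site required")
    origin, tangent, normal = _pial_frame(pial_line)
    soma = np.asarray(soma_um, dtype=float)
    mn = grid.sites.min(axis=0) - grid.spacing_um
    mx = grid.sites.max(axis=0) + grid.spacing_um
    if not ((mn <= soma).all() and (soma <= mx).all()):
        raise ValueError("soma lies off the stimulation grid")
    soma_depth = float((soma - origin) @ normal)
    if soma_depth < 0:  # flip the normal so depth grows into the tissue
        normal = -normal
        soma_depth = -soma_depth
    soma_lat = float((soma - origin) @ tangent)
    rel = grid.sites - origin
    lateral = rel @ tangent - soma_lat
    depth = rel @ normal
    charge = np.full(grid.n_sites, np.nan)
    excluded = np.zeros(grid.n_sites, dtype=bool)
    by_site = {r.site: r for r in responses}
    for i in range(grid.n_sites):
        r = by_site[i]
        if r.kind == "direct":
            excluded[i] = True
        elif r.kind == "synaptic":
            charge[i] = r.charge_fc
        else:
            charge[i] = 0.0
    sites = np.column_stack([lateral, depth])
    return ExcitationMap(sites, charge, excluded,
                         (soma_lat, soma_depth), cell_class)


def average_maps(maps: list[ExcitationMap],
                 spacing_um: float = 62.5) -> ExcitationMap:
    """Cohort mean map: site charges are snapped to a common lattice of
    ``spacing_um`` and averaged per grid cell, omitting excluded sites from
    their cell's mean."""
    if not maps:
        raise ValueError("no maps to average")
    cells: dict[tuple[int, int], list[float]] = {}
    for m in maps:
        for (lat, dep), q, ex in zip(m.sites, m.charge_fc, m.excluded):
            if ex or np.isnan(q):
                continue
            key = (round(lat / spacing_um), round(dep / spacing_um))
            cells.setdefault(key, []).append(float(q))
    if not cells:
        raise ValueError("no overlapping non-excluded sites after alignment")
    keys = sorted(cells)
    sites = np.array([[k[0] * spacing_um, k[1] * spacing_um] for k in keys])
    charge = np.array([np.mean(cells[k]) for k in keys])
    soma = (0.0, float(np.mean([m.soma_um[1] for m in maps])))
    return ExcitationMap(sites, charge, np.zeros(len(keys), dtype=bool),
                         soma, maps[0].cell_class)


def depth_bin_charge(emap: ExcitationMap, strip_width_um: float = 500.0,
                     bin_um: float = 250.0,
                     max_depth_um: float | None = None) -> dict[tuple[float, float], float]:
    """Mean charge per 250-µm depth slab within a 500-µm-wide strip centred
    on the soma axis (the laminar input profile; e.g. the 500-750 µm bin
    captures Layer IV/upper-V input)."""
    lat = emap.sites[:, 0]
    dep = emap.sites[:, 1]
    in_strip = np.abs(lat) <= strip_width_um / 2.0
    top = 0.0
    bottom = max_depth_um if max_depth_um is not None else float(np.nanmax(dep)) + 1e-9
    edges = np.arange(top, bottom + bin_um, bin_um)
    out: dict[tuple[float, float], float] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = in_strip & (dep >= lo) & (dep < hi) & ~emap.excluded
        vals = emap.charge_fc[sel]
        vals = vals[~np.isnan(vals)]
        out[(float(lo), float(hi))] = float(vals.mean()) if vals.size else float("nan")
    return out
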