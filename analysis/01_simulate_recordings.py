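#!/usr/bin/env python
"""Generate one ground-truthed example of each recording modality.

Writes a wide-field VSD trial set, a two-photon session, a photostimulation
sweep set and a mIPSC trace under scratch/synthetic/ (they are tens of
megabytes), in the interchange formats (TIFF/CSV) the pipeline consumes,
plus the ground truth as JSON.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np

from cortiplast import synthetic_data as syn
from cortiplast.core_io import write_image_stack, write_sweeps
from cortiplast.lsps_map import make_grid

OUT = Path(__file__).resolve().parents[1] / "scratch" / "synthetic"
SEED = 7


def _json_default(o):
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, frozenset):
        return sorted(o)
    return str(o)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    vsd_truth = syn.VsdGroundTruth()
    stim, blank, _ = syn.generate_vsd_trial_set(vsd_truth, 4, seed=SEED)
    write_image_stack(stim[0], OUT / "vsd_stim_trial0.tif")
    write_image_stack(blank[0], OUT / "vsd_blank_trial0.tif")
    (OUT / "vsd_truth.json").write_text(
        json.dumps(dataclasses.asdict(vsd_truth), default=_json_default, indent=2))

    ca_truth = syn.make_ca_truth(25, 0.363, seed=SEED, field_px=(144, 256))
    ses = syn.generate_ca_session(ca_truth, seed=SEED)
    write_image_stack(ses.venus, OUT / "ca_venus.tif")
    write_image_stack(ses.red, OUT / "ca_red.tif")
    (OUT / "ca_truth.json").write_text(
        json.dumps(dataclasses.asdict(ca_truth), default=_json_default, indent=2))

    grid = make_grid()
    lsps_truth = syn.make_lsps_truth(grid, soma_site=100)
    sweeps, _ = syn.generate_lsps_session(lsps_truth, grid, seed=SEED)
    write_sweeps(sweeps, OUT / "lsps_sweeps.csv")
    (OUT / "lsps_truth.json").write_text(
        json.dumps(dataclasses.asdict(lsps_truth), default=_json_default, indent=2))

    mini_truth = syn.MiniGroundTruth()
    trace, events = syn.generate_mini_trace(mini_truth, 60.0, seed=SEED)
    write_sweeps(trace, OUT / "mini_trace.csv")
    (OUT / "mini_truth.json").write_text(json.dumps(
        {"params": dataclasses.asdict(mini_truth),
         "event_times_ms": events.times_ms.tolist(),
         "event_amplitudes_pa": events.amplitudes_pa.tolist()},
        default=_json_default, indent=2))

    print(f"wrote example recordings for all four modalities to {OUT}")
    print(f"  VSD: {len(stim)} stim + {len(blank)} blank trials, "
          f"{vsd_truth.field_px} px at 4 ms/frame")
    print(f"  Ca:  {len(ca_truth.cells)} cells, field {ca_truth.field_px} px")
    print(f"  LSPS: {grid.n_sites} sites, sweeps {sweeps.sweeps.shape}")
    print(f"  mIPSC: {events.n_events} events over 60 s")


if __name__ == "__main__":
    main()
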