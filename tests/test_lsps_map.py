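"""Photostimulation mapping: grid arithmetic, sequence constraint, spike and
response classification, charge integration, map geometry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cortiplast import synthetic_data as syn
from cortiplast.core_io import Config, SweepSet
from cortiplast.lsps_map import (
    EvokedResponse,
    average_maps,
    build_excitation_map,
    charge_transfer,
    classify_evoked_response,
    depth_bin_charge,
    detect_action_potentials,
    make_grid,
    stimulation_order,
    threshold_intensity,
)


class TestGrid:
    @pytest.mark.parametrize("spacing, width, length, expected", [
        (62.5, 750.0, 1750.0, 336),   # the study's 12 x 28 grid
        (100.0, 100.0, 100.0, 1),
        (62.5, 125.0, 125.0, 4),
    ])
    def test_site_counts(self, spacing, width, length, expected):
        grid = make_grid(spacing, width, length)
        assert grid.n_sites == expected
        assert grid.n_sites == grid.n_cols * grid.n_rows

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValueError):
            make_grid(0.0, 100.0, 100.0)

    def test_indivisible_extent_floors_with_warning(self):
        with pytest.warns(UserWarning, match="floor"):
            grid = make_grid(62.5, 700.0, 125.0)
        assert grid.n_cols == 11


class TestStimulationOrder:
    def test_full_grid_order_satisfies_separation(self):
        grid = make_grid()
        order = stimulation_order(grid, seed=5)
        assert sorted(order) == list(range(336))
        gaps = np.hypot(*np.diff(grid.sites[order], axis=0).T)
        assert (gaps >= 120.0).all()

    def test_same_seed_same_order(self):
        grid = make_grid()
        np.testing.assert_array_equal(stimulation_order(grid, seed=9),
                                      stimulation_order(grid, seed=9))

    def test_unsatisfiable_grid_rejected(self):
        grid = make_grid(62.5, 125.0, 62.5)  # two sites 62.5 um apart
        with pytest.raises(ValueError, match="separation"):
            stimulation_order(grid, seed=0, max_restarts=5)


def _ap_waveform(fs=10000.0, spike_times_ms=(5.0,), duration_ms=100.0,
                 peak_mv=30.0, rest_mv=-65.0):
    n = int(duration_ms * fs / 1000)
    v = np.full(n, rest_mv)
    for t0 in spike_times_ms:
        i = int(t0 * fs / 1000)
        v[i - 3:i] = np.linspace(rest_mv, peak_mv, 3)  # fast upstroke
        v[i:i + 10] = np.linspace(peak_mv, rest_mv, 10)
    return v


class TestSpikeDetection:
    def test_single_ap_at_5ms(self):
        times = detect_action_potentials(_ap_waveform(), 10000.0)
        assert times.size == 1
        assert times[0] == pytest.approx(5.0, abs=0.3)

    def test_subthreshold_epsp_ignored(self):
        v = _ap_waveform(peak_mv=-40.0)  # never crosses 0 mV
        assert detect_action_potentials(v, 10000.0).size == 0

    def test_train_of_three_strictly_increasing(self):
        v = _ap_waveform(spike_times_ms=(10.0, 30.0, 55.0))
        times = detect_action_potentials(v, 10000.0)
        assert times.size == 3
        assert (np.diff(times) > 0).all()


class TestThresholdIntensity:
    def test_minimal_spiking_intensity(self):
        assert threshold_intensity({1.0: False, 2.3: False, 4.6: True}) == 4.6

    def test_no_spikes_undefined(self):
        assert threshold_intensity({1.0: False, 5.2: False}) is None

    def test_all_spiking_returns_lowest(self):
        assert threshold_intensity({4.6: True, 5.1: True, 5.2: True}) == 4.6

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            threshold_intensity({})


def _sweep_with_event(onset_ms, tau_decay_ms, amp_pa=-50.0, fs=10000.0,
                      duration_ms=300.0, stim_ms=50.0, noise_sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration_ms * fs / 1000)
    t = np.arange(n) / fs * 1000 - stim_ms
    x = rng.normal(0, noise_sd, n)
    u = np.maximum(t - onset_ms, 0.0)
    shape = (1 - np.exp(-u / 0.5)) * np.exp(-u / tau_decay_ms)
    x += np.where(t >= onset_ms, amp_pa * shape, 0.0)
    return SweepSet(x[None], fs, stim_onset_ms=stim_ms)


class TestResponseClassification:
    def test_short_latency_long_decay_is_direct(self):
        sw = _sweep_with_event(3.0, 200.0, amp_pa=-200.0)
        assert classify_evoked_response(sw).kind == "direct"

    def test_window_onset_is_synaptic(self):
        sw = _sweep_with_event(20.0, 8.0, amp_pa=-80.0)
        res = classify_evoked_response(sw)
        assert res.kind == "synaptic"
        assert res.latency_ms == pytest.approx(20.0, abs=1.0)
        assert res.charge_fc > 0

    def test_flat_sweep_is_none(self):
        sw = SweepSet(np.random.default_rng(0).normal(0, 1, 3000)[None],
                      10000.0, stim_onset_ms=50.0)
        assert classify_evoked_response(sw).kind == "none"

    def test_exact_5ms_onset_counts_synaptic(self):
        # the direct window is strictly < 5 ms
        sw = _sweep_with_event(5.0, 8.0, amp_pa=-80.0, noise_sd=0.0)
        assert classify_evoked_response(sw).kind == "synaptic"

    def test_direct_invariant_enforced(self):
        with pytest.raises(ValueError):
            EvokedResponse("direct", 20.0, 0.0, 0)


class TestChargeTransfer:
    def _rect_sweep(self, start_ms, stop_ms, amp_pa, fs=10000.0,
                    stim_ms=50.0, duration_ms=300.0):
        n = int(duration_ms * fs / 1000)
        t = np.arange(n) / fs * 1000 - stim_ms
        x = np.where((t >= start_ms) & (t < stop_ms), amp_pa, 0.0)
        return SweepSet(x[None], fs, stim_onset_ms=stim_ms)

    def test_rectangle_area(self):
        # -100 pA over 10-30 ms inside the 5-70 ms window -> 2000 fC
        sw = self._rect_sweep(10.0, 30.0, -100.0)
        assert charge_transfer(sw) == pytest.approx(2000.0, rel=1e-3)

    def test_flat_sweep_zero(self):
        sw = self._rect_sweep(10.0, 30.0, 0.0)
        assert charge_transfer(sw) == 0.0

    @given(st.floats(0.1, 8.0))
    def test_linearity(self, gain):
        sw = self._rect_sweep(10.0, 30.0, -100.0)
        scaled = SweepSet(sw.sweeps * gain, sw.sampling_rate_hz,
                          stim_onset_ms=50.0)
        assert charge_transfer(scaled) == pytest.approx(
            gain * charge_transfer(sw), rel=1e-9)

    def test_window_outside_sweep_rejected(self):
        sw = SweepSet(np.zeros(100)[None], 10000.0, stim_onset_ms=5.0)
        with pytest.raises(ValueError, match="window"):
            charge_transfer(sw)


class TestExcitationMap:
    def test_identity_geometry_keeps_coordinates(self):
        grid = make_grid(62.5, 125.0, 125.0)
        responses = [EvokedResponse("synaptic", 10.0, float(i), i)
                     for i in range(4)]
        em = build_excitation_map(grid, responses, tuple(grid.sites[0]),
                                  ((0.0, 0.0), (125.0, 0.0)))
        # pial line along x at depth 0: depths are the grid y coordinates
        np.testing.assert_allclose(np.sort(np.unique(em.sites[:, 1])),
                                   [31.25, 93.75])
        np.testing.assert_allclose(em.charge_fc, [0, 1, 2, 3])

    def test_single_hot_site(self):
        grid = make_grid(62.5, 125.0, 125.0)
        responses = [EvokedResponse("none", None, 0.0, i) for i in range(4)]
        responses[2] = EvokedResponse("synaptic", 12.0, 500.0, 2)
        em = build_excitation_map(grid, responses, tuple(grid.sites[0]),
                                  ((0.0, 0.0), (125.0, 0.0)))
        assert em.charge_fc[2] == 500.0
        assert em.charge_fc[[0, 1, 3]].sum() == 0.0

    def test_rotated_pial_line_depths_are_perpendicular_distances(self):
        # analytic geometry oracle: depths equal point-line distances
        grid = make_grid(62.5, 250.0, 250.0)
        responses = [EvokedResponse("synaptic", 10.0, 1.0, i)
                     for i in range(grid.n_sites)]
        p1, p2 = (0.0, -50.0), (250.0, 50.0)  # rotated line
        em = build_excitation_map(grid, responses, tuple(grid.sites[5]),
                                  (p1, p2))
        p1a, p2a = np.array(p1), np.array(p2)
        direction = (p2a - p1a) / np.linalg.norm(p2a - p1a)
        for site, (lat, dep) in zip(grid.sites, em.sites):
            vec = site - p1a
            perp = vec - (vec @ direction) * direction
            assert abs(dep) == pytest.approx(np.linalg.norm(perp), abs=1e-9)

    def test_alignment_is_rigid(self):
        grid = make_grid(62.5, 250.0, 250.0)
        responses = [EvokedResponse("none", None, 0.0, i)
                     for i in range(grid.n_sites)]
        em = build_excitation_map(grid, responses, tuple(grid.sites[0]),
                                  ((0.0, -20.0), (250.0, 30.0)))
        d_before = np.linalg.norm(grid.sites[3] - grid.sites[11])
        d_after = np.linalg.norm(em.sites[3] - em.sites[11])
        assert d_after == pytest.approx(d_before, rel=1e-12)

    def test_soma_off_grid_rejected(self):
        grid = make_grid(62.5, 125.0, 125.0)
        responses = [EvokedResponse("none", None, 0.0, i) for i in range(4)]
        with pytest.raises(ValueError, match="soma"):
            build_excitation_map(grid, responses, (5000.0, 5000.0),
                                 ((0.0, 0.0), (125.0, 0.0)))

    def test_direct_sites_are_markers_not_charges(self):
        grid = make_grid(62.5, 125.0, 125.0)
        responses = [EvokedResponse("synaptic", 10.0, 100.0, i)
                     for i in range(4)]
        responses[1] = EvokedResponse("direct", 2.0, 0.0, 1)
        em = build_excitation_map(grid, responses, tuple(grid.sites[0]),
                                  ((0.0, 0.0), (125.0, 0.0)))
        assert em.excluded[1] and np.isnan(em.charge_fc[1])


class TestAveragingAndDepthBins:
    def _map(self, grid, charges):
        responses = [EvokedResponse("synaptic", 10.0, float(q), i)
                     for i, q in enumerate(charges)]
        soma = (grid.sites[:, 0].mean(), 0.0)
        return build_excitation_map(grid, responses, soma,
                                    ((0.0, 0.0), (1.0, 0.0)))

    def test_mean_of_copies_is_the_map(self):
        grid = make_grid(62.5, 250.0, 500.0)
        em = self._map(grid, np.arange(grid.n_sites, dtype=float))
        one = average_maps([em])
        many = average_maps([em] * 5)
        np.testing.assert_allclose(many.charge_fc, one.charge_fc)
        np.testing.assert_allclose(many.sites, one.sites)

    def test_averaging_commutes_with_scaling(self):
        grid = make_grid(62.5, 250.0, 500.0)
        rng = np.random.default_rng(0)
        charges = rng.uniform(0, 300, size=(3, grid.n_sites))
        base = average_maps([self._map(grid, c) for c in charges])
        scaled = average_maps([self._map(grid, 3.0 * c) for c in charges])
        np.testing.assert_allclose(scaled.charge_fc, 3.0 * base.charge_fc)

    def test_all_zero_maps_give_zero_bins(self):
        grid = make_grid(62.5, 500.0, 1000.0)
        em = self._map(grid, np.zeros(grid.n_sites))
        bins = depth_bin_charge(average_maps([em]))
        assert all(v == 0.0 for v in bins.values())

    def test_planted_hot_band_maximal_in_its_bin(self):
        # cohort recovery: 250 fC band at 500-750 um depth over 100 fC base
        grid = make_grid()
        vals = []
        for seed in range(6):
            truth = syn.make_lsps_truth(grid, soma_site=100)
            sw, _ = syn.generate_lsps_session(truth, grid, seed=seed)
            responses = [classify_evoked_response(sw, i)
                         for i in range(grid.n_sites)]
            em = build_excitation_map(grid, responses, tuple(grid.sites[100]),
                                      ((0.0, 0.0), (750.0, 0.0)))
            vals.append(depth_bin_charge(em))
        mean_bins = {k: np.mean([v[k] for v in vals]) for k in vals[0]}
        hot = mean_bins[(500.0, 750.0)]
        assert hot == max(mean_bins.values())
        assert hot == pytest.approx(250.0, rel=0.15)
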