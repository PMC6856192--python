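"""Generator properties: determinism, rate calibration, rendering."""

import numpy as np
import pandas as pd
import pytest

from zgcalcium import (
    BurstParams,
    PerfusionProtocol,
    SimConfig,
    default_phenotype_effects,
    detect_spikes_trace,
    DetectionParams,
    extract_roi_traces,
    render_image_stack,
    render_traces,
    segment_bursts,
    simulate_phenotypes,
    simulate_spike_trains,
)
from zgcalcium.synthetic import SpikesPerBurstLaw, ground_truth_tables


def one_epoch_protocol(duration=10_000.0, potassium=3.0, atii=1000.0):
    return PerfusionProtocol(
        pd.DataFrame({"start_s": [0.0], "end_s": [duration],
                      "potassium_mM": [potassium], "atii_pM": [atii]})
    )


def single_cell_config(iso_rate, burst_rate, duration=10_000.0, seed=0, **kw):
    cond = (3.0, 1000.0)
    return SimConfig(
        n_animals_per_genotype=1,
        slices_per_animal=1,
        cells_per_slice=1,
        protocol=one_epoch_protocol(duration),
        isolated_spike_rate_per_s={cond: iso_rate},
        burst_initiation_rate_per_s={cond: burst_rate},
        animal_random_effect_sd=0.0,
        genotype_rate_multiplier=1.0,
        seed=seed,
        **kw,
    )


class TestSimulateSpikeTrains:
    def test_zero_rates_give_empty_trains(self):
        config = single_cell_config(0.0, 0.0, duration=1000.0)
        trains, truth = simulate_spike_trains(config)
        assert all(t.n_spikes == 0 for t in trains)
        assert truth.total_bursts() == 0

    def test_seeded_determinism(self):
        config = SimConfig(n_animals_per_genotype=2, cells_per_slice=4, seed=9)
        t1, truth1 = simulate_spike_trains(config)
        t2, truth2 = simulate_spike_trains(config)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.spike_times_s, b.spike_times_s)
        assert truth1.bursts == truth2.bursts
        assert truth1.animal_effects == truth2.animal_effects

    def test_burst_count_calibration_poisson(self):
        # 0.01 bursts/s over 10^4 s -> ~100 bursts per cell, 3*sqrt(100) band
        config = single_cell_config(0.0, 0.01)
        _, truth = simulate_spike_trains(config)
        for cell_id in truth.hierarchy.index:  # one WT and one MUT cell
            count = len(truth.bursts[cell_id])
            assert abs(count - 100) <= 3 * np.sqrt(100)

    def test_spike_times_sorted_and_strictly_increasing(self, small_cohort):
        _, trains, truth = small_cohort
        for times in truth.spike_times.values():
            assert np.all(np.diff(times) > 0)

    def test_true_bursts_recovered_exactly_by_segmentation(self, small_cohort):
        config, trains, truth = small_cohort
        for train in trains:
            bs = segment_bursts(train, BurstParams())
            expected = truth.bursts[train.cell_id]
            got = [(b.start_s, b.end_s, b.n_spikes) for b in bs.bursts]
            assert got == pytest.approx(expected)

    def test_genotype_multiplier_raises_mutant_rates(self):
        config = SimConfig(
            n_animals_per_genotype=6, cells_per_slice=10,
            genotype_rate_multiplier=3.0, animal_random_effect_sd=0.0, seed=3,
        )
        trains, _ = simulate_spike_trains(config)
        wt = sum(t.n_spikes for t in trains if t.genotype == "WT")
        mut = sum(t.n_spikes for t in trains if t.genotype == "MUT")
        assert mut > 1.5 * wt

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError):
            PerfusionProtocol(
                pd.DataFrame({"start_s": [0.0, 50.0], "end_s": [100.0, 150.0],
                              "potassium_mM": [3.0, 3.0], "atii_pM": [0.0, 20.0]})
            )

    def test_burst_size_law_support(self):
        with pytest.raises(ValueError):
            SpikesPerBurstLaw(minimum=2)

    def test_intra_burst_isi_must_undercut_gap(self):
        with pytest.raises(ValueError):
            single_cell_config(0.0, 0.01, intra_burst_isi_s=5.0)


class TestRenderTraces:
    def test_no_spikes_no_noise_no_bleach_is_constant(self):
        config = single_cell_config(0.0, 0.0, duration=100.0,
                                    noise_sd=0.0, bleach_tau_s=np.inf)
        _, truth = simulate_spike_trains(config)
        tm = render_traces(truth, config)
        np.testing.assert_allclose(tm.values, config.baseline_f0)

    def test_no_spikes_no_noise_is_pure_exponential(self):
        config = single_cell_config(0.0, 0.0, duration=100.0, noise_sd=0.0)
        _, truth = simulate_spike_trains(config)
        tm = render_traces(truth, config)
        t = tm.times()
        np.testing.assert_allclose(
            tm.values[0], config.baseline_f0 * np.exp(-t / config.bleach_tau_s)
        )

    def test_planted_spikes_recovered_downstream(self):
        # 20 well-separated spikes, amplitude/noise = 10
        config = single_cell_config(0.0, 0.0, duration=100.0, noise_sd=5.0)
        _, truth = simulate_spike_trains(config)
        cid = list(truth.spike_times)[0]
        planted = np.arange(5.0, 5.0 + 20 * 4.5, 4.5)
        truth.spike_times[cid] = planted
        tm = render_traces(truth, config)
        train = detect_spikes_trace(tm.values[0], config.frame_interval_s,
                                    DetectionParams())
        tol = config.frame_interval_s + 1e-9
        matched = sum(np.any(np.abs(train.spike_times_s - ts) <= tol) for ts in planted)
        assert matched / len(planted) >= 0.95

    def test_rendering_is_seeded(self):
        config = single_cell_config(0.02, 0.01, duration=200.0)
        _, truth = simulate_spike_trains(config)
        a = render_traces(truth, config)
        b = render_traces(truth, config)
        np.testing.assert_array_equal(a.values, b.values)


class TestRenderImageStack:
    # configs hold one cell per genotype -> two disks
    DISKS = [(10.0, 10.0, 4.0), (22.0, 22.0, 4.0)]

    def _setup(self, duration=20.0, **kw):
        config = single_cell_config(0.05, 0.02, duration=duration,
                                    noise_sd=0.0, **kw)
        _, truth = simulate_spike_trains(config)
        return config, truth

    def test_constant_cell_yields_constant_trace(self):
        config, truth = self._setup(bleach_tau_s=np.inf)
        for cid in truth.spike_times:
            truth.spike_times[cid] = np.empty(0)
        stack, mask = render_image_stack(truth, config, self.DISKS,
                                         frame_shape=(32, 32))
        tm = extract_roi_traces(stack, mask, config.frame_interval_s)
        np.testing.assert_allclose(tm.values, config.baseline_f0)

    def test_zero_cells_gives_background_mask_and_empty_traces(self):
        config, truth = self._setup()
        truth.hierarchy = truth.hierarchy.iloc[:0]
        stack, mask = render_image_stack(truth, config, [], frame_shape=(16, 16))
        assert (mask == 0).all()
        tm = extract_roi_traces(stack, mask, config.frame_interval_s)
        assert tm.n_cells == 0

    def test_roundtrip_matches_noiseless_traces(self):
        config, truth = self._setup()
        stack, mask = render_image_stack(truth, config, self.DISKS,
                                         frame_shape=(32, 32))
        tm = extract_roi_traces(stack, mask, config.frame_interval_s)
        clean = render_traces(truth, config)  # noise_sd == 0 here
        np.testing.assert_allclose(tm.values, clean.values, rtol=1e-12)

    def test_overlapping_disks_rejected(self):
        config, truth = self._setup()
        with pytest.raises(ValueError):
            render_image_stack(truth, config, [(10, 10, 5), (12, 12, 5)],
                               frame_shape=(32, 32))

    def test_disk_outside_frame_rejected(self):
        config, truth = self._setup()
        with pytest.raises(ValueError):
            render_image_stack(truth, config, [(2.0, 2.0, 6.0), (22.0, 22.0, 4.0)],
                               frame_shape=(32, 32))


class TestSimulatePhenotypes:
    def test_zero_sd_collapses_to_group_means(self):
        effects = default_phenotype_effects()
        for e in effects.values():
            for k in list(e):
                if k.endswith("_sd"):
                    e[k] = 0.0
        df = simulate_phenotypes(5, effects, seed=1)
        wt = df[df["genotype"] == "WT"]
        assert wt["ct_target"].nunique() == 1
        assert wt["aldosterone"].nunique() == 1

    def test_seeded_determinism(self):
        a = simulate_phenotypes(8, seed=4)
        b = simulate_phenotypes(8, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_group_size_rejected(self):
        with pytest.raises(ValueError):
            simulate_phenotypes(0)

    def test_ground_truth_tables_row_counts(self, small_cohort):
        _, _, truth = small_cohort
        spikes, bursts = ground_truth_tables(truth)
        assert len(spikes) == truth.total_spikes()
        assert len(bursts) == truth.total_bursts()
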