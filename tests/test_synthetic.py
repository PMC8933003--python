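"""Synthetic generators: determinism, trivial limits, and statistical calibration."""

import dataclasses

import numpy as np
import pytest

import polycolo as pc
from polycolo.synthetic import expected_frame


class TestSimulateLocalizations:
    def test_empty_field_when_densities_zero(self):
        cfg = pc.SimulationConfig(density_ch1=0.0, density_ch2=0.0, background_density=0.0)
        t1, t2, truth = pc.simulate_localizations(cfg)
        assert len(t1) == 0 and len(t2) == 0
        assert len(truth.clusters) == 0

    def test_full_colocalization_pairs_every_possible_ch2_cluster(self):
        cfg = pc.SimulationConfig(
            coloc_fraction=1.0, background_density=0.0, seed=3,
            roi_width_nm=5000.0, roi_height_nm=5000.0,
        )
        _, _, truth = pc.simulate_localizations(cfg)
        ch1, ch2 = truth.channel("ch1"), truth.channel("ch2")
        n_paired = int((ch2["partner_id"] >= 0).sum())
        assert n_paired == min(len(ch1), len(ch2))
        # paired ch2 clusters sit exactly on their ch1 partner centroid
        paired = ch2[ch2["partner_id"] >= 0]
        partners = ch1.set_index("id").loc[paired["partner_id"].to_numpy()]
        np.testing.assert_allclose(paired["x_nm"].to_numpy(), partners["x_nm"].to_numpy())
        np.testing.assert_allclose(paired["y_nm"].to_numpy(), partners["y_nm"].to_numpy())

    def test_partner_relation_is_symmetric_and_cross_channel(self):
        cfg = pc.SimulationConfig(seed=4, roi_width_nm=5000.0, roi_height_nm=5000.0)
        _, _, truth = pc.simulate_localizations(cfg)
        ch1 = truth.channel("ch1").set_index("id")
        ch2 = truth.channel("ch2").set_index("id")
        for i, rec in ch2[ch2["partner_id"] >= 0].iterrows():
            assert ch1.loc[rec["partner_id"], "partner_id"] == i

    def test_poisson_cluster_counts_calibrated(self):
        # density 2 per um^2 on 100 um^2: mean realized count over 100 seeds
        # within 3 standard errors of 200 (sigma = sqrt(200))
        counts = []
        for seed in range(100):
            cfg = pc.SimulationConfig(seed=seed, locs_per_cluster=1, background_density=0.0)
            _, _, truth = pc.simulate_localizations(cfg)
            counts.append(len(truth.channel("ch1")))
        assert abs(np.mean(counts) - 200.0) <= 3.0 * np.sqrt(200.0) / np.sqrt(len(counts))

    def test_same_seed_bit_identical(self, small_sim_config):
        a1, a2, ta = pc.simulate_localizations(small_sim_config)
        b1, b2, tb = pc.simulate_localizations(small_sim_config)
        assert a1 == b1 and a2 == b2
        assert ta.clusters.equals(tb.clusters)

    def test_nonpositive_roi_rejected(self):
        with pytest.raises(ValueError):
            pc.SimulationConfig(roi_width_nm=0.0)

    def test_ground_truth_serialization_round_trip(self, small_sim_config):
        _, _, truth = pc.simulate_localizations(small_sim_config)
        back = pc.GroundTruth.from_json(truth.to_json())
        assert back.n_background == truth.n_background
        np.testing.assert_allclose(
            back.clusters.select_dtypes("number").to_numpy(),
            truth.clusters.select_dtypes("number").to_numpy(),
        )

    def test_localization_csv_round_trip(self, tmp_path, small_sim_config):
        t1, _, _ = pc.simulate_localizations(small_sim_config)
        t1.to_csv(tmp_path / "locs.csv")
        assert pc.LocalizationTable.from_csv(tmp_path / "locs.csv") == t1
        header = (tmp_path / "locs.csv").read_text().splitlines()[0]
        assert header == "frame,x_nm,y_nm,photons,sigma_nm,background,precision_nm"


class TestSimulateFrames:
    def test_no_photons_no_background_gives_zero_stack(self):
        cfg = pc.FrameSimConfig(n_photons=0.0, b_noise=0.0, n_frames=5)
        stack = pc.simulate_frames(cfg)
        assert np.all(stack.frames == 0)

    def test_per_frame_photon_sum_poisson_with_mean_n(self):
        cfg = pc.FrameSimConfig(
            n_photons=400.0, b_noise=0.0, n_frames=300, duty_cycle=1.0,
            positions_nm=((1000.0, 1000.0),), fov_width_nm=2000.0, fov_height_nm=2000.0,
            seed=2,
        )
        stack = pc.simulate_frames(cfg)
        sums = stack.frames.sum(axis=(1, 2))
        # mean within 4 standard errors; variance ~ mean (Poisson)
        assert abs(sums.mean() - 400.0) <= 4.0 * np.sqrt(400.0 / len(sums))
        assert sums.var() == pytest.approx(400.0, rel=0.35)

    def test_duty_cycle_thins_on_frames(self):
        cfg = pc.FrameSimConfig(n_photons=300.0, b_noise=0.0, n_frames=400, duty_cycle=0.3, seed=6)
        sums = pc.simulate_frames(cfg).frames.sum(axis=(1, 2))
        on_fraction = np.mean(sums > 50)
        assert on_fraction == pytest.approx(0.3, abs=0.08)

    def test_doubling_pixel_size_halves_grid(self):
        cfg1 = pc.FrameSimConfig(q_nm=100.0, n_frames=1)
        cfg2 = dataclasses.replace(cfg1, q_nm=200.0)
        s1 = pc.simulate_frames(cfg1).shape
        s2 = pc.simulate_frames(cfg2).shape
        assert s1[0] == 2 * s2[0] and s1[1] == 2 * s2[1]

    def test_emitter_outside_field_rejected(self):
        with pytest.raises(ValueError):
            pc.FrameSimConfig(positions_nm=((5000.0, 100.0),), fov_width_nm=2000.0)

    def test_expected_frame_total_is_n_for_interior_emitter(self):
        cfg = pc.FrameSimConfig(n_photons=500.0, positions_nm=((1000.0, 1000.0),))
        assert expected_frame(cfg).sum() == pytest.approx(500.0, rel=1e-6)


class TestSimulateFret:
    def test_zero_efficiency_noiseless_is_pure_bleedthrough(self):
        cfg = pc.FretSimConfig(
            efficiency=0.0, noise_sd=0.0, offsets={"dd": 0.0, "aa": 0.0, "da": 7.0}
        )
        s = pc.simulate_fret_images(cfg)
        np.testing.assert_allclose(s.i_da, cfg.a * s.i_aa + cfg.d * s.i_dd + 7.0, rtol=1e-12)

    def test_zero_abundance_leaves_only_offsets(self):
        cfg = pc.FretSimConfig(
            donor_abundance=0.0, acceptor_abundance=0.0, noise_sd=0.0,
            offsets={"dd": 3.0, "aa": 4.0, "da": 5.0},
        )
        s = pc.simulate_fret_images(cfg)
        assert np.all(s.i_dd == 3.0) and np.all(s.i_aa == 4.0) and np.all(s.i_da == 5.0)

    def test_efficiency_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pc.FretSimConfig(efficiency=1.2)

    def test_map_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pc.FretSimConfig(shape=(8, 8), efficiency=np.zeros((4, 4)))


class TestSimulateCurrentTrace:
    def test_flat_trace_when_no_response_no_noise(self):
        cfg = pc.TraceSimConfig(
            transient_amplitude_pa_pf=0.0, sustained_shift_pa_pf=0.0, noise_sd_pa_pf=0.0
        )
        tr = pc.simulate_current_trace(cfg)
        np.testing.assert_allclose(pc.current_density(tr), cfg.baseline_pa_pf)

    def test_transient_amplitude_exact_without_noise(self):
        cfg = pc.TraceSimConfig(noise_sd_pa_pf=0.0)
        tr = pc.simulate_current_trace(cfg)
        dens = pc.current_density(tr)
        assert dens.min() - cfg.baseline_pa_pf == pytest.approx(-1.3, abs=1e-12)

    def test_sustained_shift_reached_before_flow_off(self):
        cfg = pc.TraceSimConfig(noise_sd_pa_pf=0.0, sustained_shift_pa_pf=4.5)
        tr = pc.simulate_current_trace(cfg)
        dens = pc.current_density(tr)
        late = dens[(tr.time_s >= 150.0) & (tr.time_s < 200.0)]
        assert late.mean() - cfg.baseline_pa_pf == pytest.approx(4.5, abs=1e-6)

    def test_markers_recorded(self):
        tr = pc.simulate_current_trace(pc.TraceSimConfig())
        assert tr.markers == {"flow_on": 60.0, "flow_off": 200.0}

    def test_invalid_event_order_rejected(self):
        with pytest.raises(ValueError):
            pc.TraceSimConfig(flow_on_s=100.0, flow_off_s=50.0)
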