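"""Generators: determinism, ground-truth consistency, closed-form checks."""

import numpy as np
import pytest

from transcyt import (FluorSimConfig, TirfSimConfig, compute_msd,
                      fit_msd_exponent, simulate_aorta_tile,
                      simulate_binding_curve, simulate_cell_fluorescence,
                      simulate_tirf_movie, summarize)
from transcyt.track import Track
from transcyt.detect import SpotDetection


def _truth_alpha(vesicle):
    """Anomalous exponent computed directly from ground-truth positions."""
    dets = [SpotDetection(t, x, y, 1, 100.0, 1.0, 1.0, 1.0)
            for t, (x, y) in enumerate(vesicle.positions)]
    track = Track(0, dets)
    return fit_msd_exponent(compute_msd(track, 20), fit_lags=5)


class TestTirfMovie:
    def test_no_exocytosing_class_means_no_true_events(self):
        cfg = TirfSimConfig(n_exocytosing=0, frame_count=30,
                            event_frame_range=(10, 20), seed=1)
        _, truth = simulate_tirf_movie(cfg)
        assert truth.total_true_events == 0

    def test_same_seed_is_bit_identical(self):
        cfg = TirfSimConfig(seed=5, frame_count=30, event_frame_range=(10, 20))
        s1, t1 = simulate_tirf_movie(cfg)
        s2, t2 = simulate_tirf_movie(cfg)
        assert np.array_equal(s1.data, s2.data)
        for a, b in zip(t1.vesicles, t2.vesicles):
            assert a.label == b.label and a.event_frame == b.event_frame
            assert np.array_equal(a.positions, b.positions)

    def test_docked_ground_truth_is_subdiffusive(self):
        cfg = TirfSimConfig(n_diffusing=0, n_docked=3, n_exocytosing=0,
                            noise_sigma=0.0, seed=2)
        _, truth = simulate_tirf_movie(cfg)
        assert len(truth.vesicles) == 3
        for v in truth.vesicles:
            assert _truth_alpha(v) < 1

    def test_class_separation_of_msd_exponents(self):
        """alpha(docked) < 1 <= alpha(diffusing) on ground-truth trajectories
        (diffusing as the per-movie mean; single-track alpha at 150 frames
        carries ~0.1 sampling spread)."""
        for seed in range(3):
            cfg = TirfSimConfig(noise_sigma=0.0, seed=seed)
            _, truth = simulate_tirf_movie(cfg)
            diff = [_truth_alpha(v) for v in truth.vesicles if v.label == "diffusing"]
            dock = [_truth_alpha(v) for v in truth.vesicles if v.label != "diffusing"]
            assert 0.85 <= np.mean(diff) <= 1.15
            assert all(a < 1 for a in dock)

    def test_flux_conservation_noise_free(self):
        """Sum of a background-free frame equals active amplitudes times the
        Gaussian mass 2*pi*sigma^2, within rendering truncation."""
        cfg = TirfSimConfig(background_level=0.0, noise_sigma=0.0,
                            frame_count=30, event_frame_range=(10, 20), seed=3)
        stack, truth = simulate_tirf_movie(cfg)
        for t in (0, 15, 29):
            active = sum(v.amplitudes[t] for v in truth.vesicles)
            expected = active * 2 * np.pi * cfg.psf_sigma ** 2
            assert stack.data[t].sum() == pytest.approx(expected, rel=0.01)

    def test_exocytosis_amplitude_drops_to_zero_and_stays(self):
        cfg = TirfSimConfig(seed=4)
        _, truth = simulate_tirf_movie(cfg)
        for v in truth.vesicles:
            if v.event_frame is None:
                continue
            assert v.amplitudes[v.event_frame - 1] == cfg.spot_amplitude
            assert np.all(v.amplitudes[v.event_frame + 1:] == 0.0)
            # the drop completes within two frames of the event
            assert v.amplitudes[v.event_frame] < cfg.spot_amplitude

    @pytest.mark.parametrize("bad_range", [(2, 20), (10, 146), (30, 20)])
    def test_rejects_event_frames_violating_margins(self, bad_range):
        with pytest.raises(ValueError):
            simulate_tirf_movie(TirfSimConfig(event_frame_range=bad_range))

    def test_trajectories_stay_inside_the_image(self):
        cfg = TirfSimConfig(seed=6, diffusion_coeff=0.3)
        _, truth = simulate_tirf_movie(cfg)
        for v in truth.vesicles:
            assert np.all(v.positions >= 0)
            assert np.all(v.positions <= cfg.image_size)


class TestCellFluorescence:
    def test_same_seed_identical(self):
        cfg = FluorSimConfig(seed=9, n_replicates=2, cells_per_group=5)
        a = simulate_cell_fluorescence(cfg).to_frame()
        b = simulate_cell_fluorescence(cfg).to_frame()
        assert a.equals(b)

    def test_values_positive_and_replicates_recorded(self):
        ds = simulate_cell_fluorescence(FluorSimConfig(seed=1, n_replicates=3,
                                                       cells_per_group=7))
        df = ds.to_frame()
        assert (df["value"] > 0).all()
        assert sorted(df["replicate_id"].unique()) == [0, 1, 2]
        assert set(df["group"]) == {"blank", "ctrl", "cond"}

    def test_null_effect_gives_unit_median_fold_change(self):
        ds = simulate_cell_fluorescence(FluorSimConfig(true_effect=1.0, seed=21))
        s = summarize(ds, "cond", cap=10 ** 5, rng=0)
        assert s.median == pytest.approx(1.0, abs=0.1)

    def test_half_effect_recovered_at_large_n(self):
        cfg = FluorSimConfig(true_effect=0.5, n_replicates=3,
                             cells_per_group=400, seed=22)
        s = summarize(simulate_cell_fluorescence(cfg), "cond", cap=10 ** 5, rng=0)
        assert s.median == pytest.approx(0.5, rel=0.05)

    @pytest.mark.parametrize("kw", [{"true_effect": 0.0}, {"true_effect": -1.0},
                                    {"cells_per_group": 0}])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            simulate_cell_fluorescence(FluorSimConfig(**kw))


class TestBindingCurve:
    def test_half_saturation_at_kd(self):
        kd = 2e-6
        # geometric series symmetric about kd: the middle point sits at kd
        curve = simulate_binding_curve(kd, noise_sd=0.0, baseline=0.3,
                                       amplitude=2.0,
                                       conc_range=(kd / 4, 4 * kd), n_points=5)
        assert curve.concentrations[2] == pytest.approx(kd)
        assert curve.responses[2] == pytest.approx(0.3 + 1.0)

    def test_saturation_limit(self):
        kd = 1e-8
        curve = simulate_binding_curve(kd, noise_sd=0.0, baseline=0.1,
                                       amplitude=1.5, conc_range=(1e-3, 1e-2),
                                       n_points=4)
        assert np.allclose(curve.responses, 1.6, atol=1e-4)

    def test_deterministic_and_geometric_series(self):
        c1 = simulate_binding_curve(1e-6, seed=3)
        c2 = simulate_binding_curve(1e-6, seed=3)
        assert np.array_equal(c1.responses, c2.responses)
        ratios = c1.concentrations[1:] / c1.concentrations[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            simulate_binding_curve(-1e-6)
        with pytest.raises(ValueError):
            simulate_binding_curve(1e-6, amplitude=0.0)
        with pytest.raises(ValueError):
            simulate_binding_curve(1e-6, n_points=3)


class TestAortaTile:
    def test_no_spots_no_signal(self):
        _, signal, _ = simulate_aorta_tile(n_ldl_spots=0, seed=1)
        assert signal == 0.0

    def test_signal_linear_in_amplitude(self):
        _, s1, _ = simulate_aorta_tile(spot_amplitude=100.0, seed=5)
        _, s2, _ = simulate_aorta_tile(spot_amplitude=200.0, seed=5)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_deterministic(self):
        a, sa, ma = simulate_aorta_tile(seed=7)
        b, sb, mb = simulate_aorta_tile(seed=7)
        assert np.array_equal(a.data, b.data) and sa == sb
        assert np.array_equal(ma, mb)

    def test_rejects_empty_marker_fraction(self):
        with pytest.raises(ValueError):
            simulate_aorta_tile(marker_mask_fraction=0.0)
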