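"""Measurement procedures on ground-truthed synthetic inputs."""

import numpy as np
import pytest
from skimage.draw import disk

import mtlength as mt
from mtlength.imaging import (classify_contact_fates, estimate_mt_count,
                              measure_cell_length, measure_pattern_width,
                              orientation_distribution)


class TestPatternWidth:
    def test_perfect_stripe(self):
        mask = np.zeros((60, 40), dtype=bool)
        mask[:, 10:23] = True
        assert measure_pattern_width(mask, 1.0) == 13.0

    def test_narrowest_pattern(self):
        mask = np.zeros((60, 40), dtype=bool)
        mask[:, 10:13] = True
        assert measure_pattern_width(mask, 1.0) == 3.0

    def test_edge_jitter_averages_out(self):
        mask = np.zeros((60, 40), dtype=bool)
        mask[:, 10:23] = True
        mask[::2, 9] = True     # +1 px on even rows
        mask[1::2, 22] = False  # -1 px on odd rows
        assert abs(measure_pattern_width(mask, 1.0) - 13.0) <= 0.5

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            measure_pattern_width(np.zeros((5, 5), dtype=bool))


class TestCellLength:
    def test_patterned_rectangle(self):
        mask = np.zeros((80, 40), dtype=bool)
        mask[10:54, 5:18] = True
        m = measure_cell_length(mask, None, mode="patterned")
        assert m.length_um == 44.0

    def test_translation_invariance_along_the_line(self):
        a = np.zeros((100, 40), dtype=bool)
        b = np.zeros((100, 40), dtype=bool)
        a[10:54, 5:18] = True
        b[40:84, 5:18] = True
        la = measure_cell_length(a, None).length_um
        lb = measure_cell_length(b, None).length_um
        assert la == lb

    def test_feret_diameter_of_a_circle(self):
        mask = np.zeros((60, 60), dtype=bool)
        rr, cc = disk((30, 30), 20)
        mask[rr, cc] = True
        m = measure_cell_length(mask, None, mode="nonpatterned")
        assert m.length_um == pytest.approx(40.0, abs=1.0)

    def test_feret_rotation_invariance(self):
        from skimage.transform import rotate

        rect = np.zeros((120, 120), dtype=bool)
        rect[40:81, 30:91] = True   # 61 x 41 rectangle, diag ~73.5
        rot = rotate(rect.astype(float), 30, order=0) > 0.5
        f0 = measure_cell_length(rect, None, mode="nonpatterned").length_um
        f30 = measure_cell_length(rot, None, mode="nonpatterned").length_um
        assert abs(f0 - f30) <= 1.5

    def test_binucleate_cells_rejected(self):
        img = mt.render_patterned_cell(44, 13, 1.0, 0, seed=0,
                                       nucleus_count=2)
        m = measure_cell_length(img.cell_mask, img.nucleus_mask)
        assert not m.accepted
        assert "mononucleate" in m.rejected_reason
        assert m.length_um is None

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            measure_cell_length(np.zeros((5, 5), dtype=bool), None)


class TestOrientationDistribution:
    def test_point_mass_recovers_axis_bin(self):
        img = mt.render_patterned_cell(120, 40, 1.0, 12,
                                       angle_model=("point", 0.0),
                                       noise_sd=2.0, seed=1,
                                       filament_length=(8, 15))
        d = orientation_distribution(img.filament, img.cell_mask)
        assert d.mass_at(0.0) >= 0.9
        assert d.masses.sum() == pytest.approx(1.0, abs=1e-9)

    def test_off_axis_point_mass(self):
        img = mt.render_patterned_cell(120, 60, 1.0, 12,
                                       angle_model=("point", 30.0),
                                       noise_sd=2.0, seed=2,
                                       filament_length=(8, 15))
        d = orientation_distribution(img.filament, img.cell_mask)
        # mass concentrates within one bin of the true angle
        near = d.mass_at(30.0) + d.mass_at(25.0) + d.mass_at(35.0)
        assert near >= 0.8

    def test_von_mises_circular_variance_recovered(self):
        img = mt.render_patterned_cell(200, 70, 1.0, 60,
                                       angle_model=("vonmises", 4.0),
                                       noise_sd=2.0, seed=2,
                                       filament_length=(8, 15))
        d = orientation_distribution(img.filament, img.cell_mask)
        ang = np.radians(img.ground_truth.angles_deg)
        gt_var = 1 - abs(np.mean(np.exp(2j * ang)))
        assert abs(d.circular_variance() - gt_var) / gt_var < 0.15

    def test_uniform_angles_give_a_flat_distribution(self):
        img = mt.render_patterned_cell(200, 70, 1.0, 60,
                                       angle_model=("uniform",),
                                       noise_sd=2.0, seed=3,
                                       filament_length=(8, 15))
        d = orientation_distribution(img.filament, img.cell_mask)
        assert d.masses.max() < 3 * d.masses.mean()

    def test_blank_image_flags_empty(self):
        img = mt.render_patterned_cell(44, 13, 1.0, 0, seed=0)
        d = orientation_distribution(img.filament, img.cell_mask)
        assert d.empty
        assert d.masses.sum() == 0


class TestFateClassification:
    def test_deterministic_bands_agree_perfectly(self):
        ts = mt.simulate_comet_tracks(44, 13, mt.FateRule(), 2000,
                                      ("uniform", 0.0, 90.0), seed=1)
        fc = classify_contact_fates(ts)
        assert fc.agreement == 1.0
        # ambiguous-band events are recorded as such, at about 7/90 of events
        frac_amb = fc.ambiguous.mean()
        assert frac_amb == pytest.approx(7 / 90, abs=0.02)

    def test_measured_angles_match_ground_truth(self):
        ts = mt.simulate_comet_tracks(44, 13, mt.FateRule(), 200,
                                      ("uniform", -90.0, 90.0), seed=2)
        fc = classify_contact_fates(ts)
        truth = np.array([a for a, _ in ts.contact_events])
        assert np.allclose(np.sort(fc.measured_angles), np.sort(truth),
                           atol=1e-9)

    def test_noise_on_steep_angles_rarely_flips_the_label(self):
        ts = mt.simulate_comet_tracks(44, 13, mt.FateRule(), 2000,
                                      ("uniform", 45.0, 90.0), seed=3)
        fc = classify_contact_fates(ts, angle_noise_sd=3.0, seed=4)
        assert fc.agreement >= 0.99

    def test_axial_tracks_are_skipped(self):
        ts = mt.simulate_comet_tracks(44, 13, mt.FateRule(), 50,
                                      ("point", 0.0), seed=5)
        fc = classify_contact_fates(ts)
        assert fc.n_skipped == 50
        assert len(fc.predicted) == 0


class TestMTCount:
    def test_exact_count_without_noise(self):
        img = mt.render_patterned_cell(60, 20, 1.0, 5,
                                       angle_model=("point", 0.0),
                                       noise_sd=0.0, seed=4,
                                       filament_length=10.0)
        est = estimate_mt_count(img.filament, img.cell_mask, 100.0,
                                img.ground_truth.mean_segment_length_px())
        assert est.count == 5

    def test_empty_region_counts_zero(self):
        channel = np.random.default_rng(0).normal(0, 2.0, (50, 50))
        region = np.zeros((50, 50), dtype=bool)
        region[10:40, 10:40] = True
        est = estimate_mt_count(channel, region, 100.0, 10.0)
        assert est.count == 0

    def test_edge_band_count_with_noise(self):
        """Eleven filaments rendered in a lateral edge band are recovered
        within +/-2 despite additive noise."""
        img = mt.render_patterned_cell(60, 20, 1.0, 11,
                                       angle_model=("point", 5.0),
                                       noise_sd=3.0, seed=5,
                                       filament_length=10.0,
                                       placement_box=(15, 65, 12, 18))
        est = estimate_mt_count(img.filament, img.cell_mask, 100.0,
                                img.ground_truth.mean_segment_length_px())
        assert abs(est.count - 11) <= 2

    def test_region_shape_mismatch(self):
        with pytest.raises(ValueError):
            estimate_mt_count(np.zeros((5, 5)), np.zeros((4, 4), dtype=bool),
                              100.0, 10.0)
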