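"""Synthetic panel / beam / acquisition generator."""

import numpy as np
import pytest

from epidpsm.geometry import PanelGeometry, PixelSensitivityMap
from epidpsm.simulate import (
    AcquisitionNoise,
    BeamModel,
    COUNTS_PER_MU,
    NO_NOISE,
    PanelDefectModel,
    beam_fluence,
    beam_response_grid,
    generate_ground_truth_psm,
    render_raw_image,
    simulate_abdf_sequence,
    subseed,
)

GEOM = PanelGeometry(238, 238, 40.0 / 238)


class TestGroundTruth:
    def test_featureless_model_gives_ones(self):
        defects = PanelDefectModel(smooth_gain_amplitude=0.0, pixel_noise_sd=0.0)
        psm = generate_ground_truth_psm(defects, GEOM)
        assert np.allclose(psm.values, 1.0, atol=1e-12)

    def test_pixel_noise_sd_matches_request(self):
        defects = PanelDefectModel(smooth_gain_amplitude=0.0, pixel_noise_sd=0.02, seed=4)
        psm = generate_ground_truth_psm(defects, GEOM)
        sd = psm.values.std()
        # n ~ 57 000 pixels: the empirical sd pins down the parameter tightly
        assert 0.018 < sd < 0.022

    def test_dead_column_zeroed_and_masked(self):
        defects = PanelDefectModel(
            smooth_gain_amplitude=0.0, pixel_noise_sd=0.0, dead_columns=(30,)
        )
        psm = generate_ground_truth_psm(defects, GEOM)
        assert np.all(psm.values[:, 30] == 0.0)
        assert not psm.valid_mask[:, 30].any()
        assert psm.valid_mask[:, 31].all()

    def test_deterministic_per_seed(self):
        d = PanelDefectModel(seed=9)
        a = generate_ground_truth_psm(d, GEOM)
        b = generate_ground_truth_psm(d, GEOM)
        assert np.array_equal(a.values, b.values)


class TestBeamFluence:
    def test_unity_on_axis_for_symmetric_model(self):
        model = BeamModel()
        assert beam_fluence(model, 0.0, 0.0, 40, 40) == pytest.approx(1.0, abs=1e-15)

    def test_mirror_symmetry_exact(self):
        model = BeamModel()
        x = np.linspace(0.3, 19, 40)
        y = np.linspace(-17, 17, 40)
        xx, yy = np.meshgrid(x, y)
        assert np.array_equal(
            beam_fluence(model, xx, yy, 40, 40), beam_fluence(model, -xx, yy, 40, 40)
        )

    def test_horns_raise_off_axis_response(self):
        model = BeamModel()  # horns at 16 cm
        assert beam_fluence(model, 15.0, 0.0, 40, 40) > beam_fluence(model, 5.0, 0.0, 40, 40)

    def test_asymmetry_tilts_profile(self):
        model = BeamModel(asym_x=0.005)
        assert beam_fluence(model, 10.0, 0.0, 40, 40) > beam_fluence(model, -10.0, 0.0, 40, 40)


class TestRender:
    def test_unit_panel_noiseless_equals_beam_grid(self):
        ones = PixelSensitivityMap(values=np.ones(GEOM.shape))
        img = render_raw_image(ones, BeamModel(), GEOM, mu=2.0, noise=NO_NOISE)
        br = beam_response_grid(BeamModel(), GEOM, 40, 40)
        assert np.array_equal(img.pixels, 2.0 * COUNTS_PER_MU * br.values)

    def test_dead_column_propagates_to_raw(self):
        defects = PanelDefectModel(dead_columns=(50,))
        psm = generate_ground_truth_psm(defects, GEOM)
        img = render_raw_image(psm, BeamModel(), GEOM, mu=1.0)
        assert np.all(img.pixels[:, 50] == 0.0)

    def test_same_seed_bitwise_identical(self):
        psm = generate_ground_truth_psm(PanelDefectModel(seed=2), GEOM)
        noise = AcquisitionNoise(0.001, 0.002, 10.0, 0.01)
        a = render_raw_image(psm, BeamModel(), GEOM, mu=5.0, noise=noise, seed=42)
        b = render_raw_image(psm, BeamModel(), GEOM, mu=5.0, noise=noise, seed=42)
        assert np.array_equal(a.pixels, b.pixels)

    def test_negative_mu_rejected(self):
        psm = PixelSensitivityMap(values=np.ones(GEOM.shape))
        with pytest.raises(ValueError):
            render_raw_image(psm, BeamModel(), GEOM, mu=-1.0)

    def test_inverse_square_and_magnification(self):
        ones = PixelSensitivityMap(values=np.ones(GEOM.shape))
        model = BeamModel()
        near = render_raw_image(ones, model, GEOM.with_sid(100.0), mu=1.0)
        far = render_raw_image(ones, model, GEOM.with_sid(200.0), mu=1.0)
        c = GEOM.n_rows // 2
        central_near = near.pixels[c - 1 : c + 1, c - 1 : c + 1].mean()
        central_far = far.pixels[c - 1 : c + 1, c - 1 : c + 1].mean()
        # the beam shape is magnified too, so the central 2x2 samples the
        # dome at slightly different radii: agreement to ~1e-5
        assert central_far / central_near == pytest.approx(0.25, rel=1e-4)
        # a 20x20 field ends at |x|=10 at reference SID, |x|=20 at doubled SID
        small_near = render_raw_image(ones, model, GEOM.with_sid(100.0), mu=1.0,
                                      field_x=20.0, field_y=20.0)
        small_far = render_raw_image(ones, model, GEOM.with_sid(200.0), mu=1.0,
                                     field_x=20.0, field_y=20.0)
        row = small_near.pixels[c]
        row_far = small_far.pixels[c]
        x = (np.arange(GEOM.n_cols) - (GEOM.n_cols - 1) / 2) * GEOM.pitch_iso
        half_near = x[row > 0.5 * row.max()][-1]
        half_far = x[row_far > 0.5 * row_far.max()][-1]
        assert half_far / half_near == pytest.approx(2.0, rel=0.02)

    def test_output_fluctuation_is_global_scale(self):
        psm = generate_ground_truth_psm(PanelDefectModel(seed=2), GEOM)
        noise = AcquisitionNoise(0.01, 0.0, 0.0, 0.0)  # output only
        a = render_raw_image(psm, BeamModel(), GEOM, mu=5.0, noise=noise, seed=1)
        b = render_raw_image(psm, BeamModel(), GEOM, mu=5.0, noise=noise, seed=2)
        good = (a.pixels > 1) & (b.pixels > 1)
        ratio = a.pixels[good] / b.pixels[good]
        assert np.ptp(ratio) < 1e-9 * ratio.mean()


class TestAbdf:
    def test_lag_free_darks_are_pure_offset(self):
        ones = PixelSensitivityMap(values=np.ones(GEOM.shape))
        noise = AcquisitionNoise(0.0, 0.0, 10.0, 0.0)
        pairs = simulate_abdf_sequence(ones, BeamModel(), GEOM, 5, 2.0, noise)
        for _, dark in pairs:
            assert np.allclose(dark.pixels, 10.0)

    def test_first_dark_carries_lag_of_first_beam(self):
        ones = PixelSensitivityMap(values=np.ones(GEOM.shape))
        noise = AcquisitionNoise(0.0, 0.0, 10.0, 0.05)
        pairs = simulate_abdf_sequence(ones, BeamModel(), GEOM, 3, 2.0, noise)
        beam0, dark0 = pairs[0]
        assert np.allclose(dark0.pixels, 10.0 + 0.05 * beam0.pixels)

    def test_sequence_equilibrates_after_initial_pairs(self):
        ones = PixelSensitivityMap(values=np.ones(GEOM.shape))
        noise = AcquisitionNoise(0.0, 0.0005, 10.0, 0.05)
        pairs = simulate_abdf_sequence(ones, BeamModel(), GEOM, 60, 2.0, noise, seed=3)
        nets = [b.pixels.mean() - d.pixels.mean() for b, d in pairs]
        early = np.mean(nets[10:30])
        late = np.mean(nets[40:60])
        assert abs(early - late) / late < 1e-3
        # ... but the very first pair is contaminated by the primed lag
        assert abs(nets[0] - late) / late > 1e-3

    def test_deterministic_per_seed(self):
        ones = PixelSensitivityMap(values=np.ones((32, 32)))
        g = PanelGeometry(32, 32, 1.0)
        noise = AcquisitionNoise(0.001, 0.001, 5.0, 0.02)
        a = simulate_abdf_sequence(ones, BeamModel(), g, 4, 2.0, noise, seed=11)
        b = simulate_abdf_sequence(ones, BeamModel(), g, 4, 2.0, noise, seed=11)
        assert all(np.array_equal(x[0].pixels, y[0].pixels) for x, y in zip(a, b))


def test_subseed_is_stable_and_bounded():
    assert subseed(123, 5) == subseed(123, 5)
    assert subseed(123, 5) != subseed(123, 6)
    assert 0 <= subseed(2**20, 999) < 2**31
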