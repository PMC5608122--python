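import math

import numpy as np
import pytest
from scipy import stats as sps

from vesselrep import (
    CardiacModel,
    T1W_GATED,
    T1W_UNGATED,
    TissueProperties,
    central_chi_sd_factor,
    default_scene,
    dir_signal,
    null_inversion_time,
    render_scene,
    sample_effective_tr,
)
from vesselrep.exceptions import GeometryError, InvalidParameterError
from vesselrep.phantom import (
    PhantomScene,
    calibrated_tissues,
    raster_fraction_circle,
    sum_of_squares_noise,
)


class TestDirSignal:
    def test_long_t1_limit_is_zero(self):
        tissue = TissueProperties("wall", t1_ms=1e9, m0=1.0)
        assert dir_signal(tissue, 500.0, 2000.0) == pytest.approx(0.0, abs=1e-6)

    def test_null_point_gives_zero(self):
        t1 = 1300.0
        ti = null_inversion_time(t1, 2000.0)
        tissue = TissueProperties("wall", t1_ms=t1, m0=2.5)
        assert dir_signal(tissue, ti, 2000.0) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_value(self):
        # |1 - 2 e^{-0.5} + e^{-2}| evaluated directly
        expected = abs(1 - 2 * math.exp(-0.5) + math.exp(-2))
        tissue = TissueProperties("wall", t1_ms=1000.0, m0=1.0)
        assert dir_signal(tissue, 500.0, 2000.0) == pytest.approx(expected, rel=1e-12)

    def test_invalid_timing_raises(self):
        tissue = TissueProperties("wall", t1_ms=1000.0, m0=1.0)
        with pytest.raises(InvalidParameterError):
            dir_signal(tissue, -1.0, 2000.0)
        with pytest.raises(InvalidParameterError):
            dir_signal(tissue, 500.0, 400.0)  # TI >= TR


class TestEffectiveTr:
    def test_ungated_is_fixed(self):
        trs = sample_effective_tr(T1W_UNGATED, CardiacModel(sd_rr_ms=200.0), 50)
        assert np.all(trs == T1W_UNGATED.tr_ms)

    def test_gated_degenerate_hrv(self):
        card = CardiacModel(mean_rr_ms=900.0, sd_rr_ms=0.0)
        trs = sample_effective_tr(T1W_GATED, card, 20, rng=np.random.default_rng(0))
        assert np.all(trs == T1W_GATED.rr_multiple * 900.0)

    def test_gated_sample_mean(self):
        card = CardiacModel(mean_rr_ms=1000.0, sd_rr_ms=100.0)
        trs = sample_effective_tr(T1W_GATED, card, 1000, rng=np.random.default_rng(7))
        se = 100.0 / math.sqrt(1000)
        assert abs(trs.mean() - 1000.0) < 3 * se

    def test_reproducible(self):
        card = CardiacModel(mean_rr_ms=1000.0, sd_rr_ms=80.0, seed=5)
        assert np.array_equal(
            sample_effective_tr(T1W_GATED, card, 64),
            sample_effective_tr(T1W_GATED, card, 64),
        )


class TestRenderScene:
    def test_noise_free_limit_is_piecewise_constant(self, small_scene):
        acq = render_scene(
            small_scene, T1W_UNGATED, CardiacModel(), 1, seed=0, per_channel_sigma=0.0
        )
        assert np.all(acq.noise_image == 0)
        amps = acq.truth["amplitudes"]
        values = set(np.round(np.unique(acq.signal_image), 9))
        # interior pixels carry exact tissue amplitudes (plus blends at edges)
        for amp in (0.0, *amps.values()):
            assert round(amp, 9) in values

    def test_black_blood_contrast(self, small_scene):
        acq = render_scene(
            small_scene, T1W_UNGATED, CardiacModel(), 1, seed=0, per_channel_sigma=0.0
        )
        amps = acq.truth["amplitudes"]
        assert amps["wall"] > amps["lumen"]

    def test_determinism(self, small_scene):
        a = render_scene(small_scene, T1W_GATED, CardiacModel(), 1, seed=42)
        b = render_scene(small_scene, T1W_GATED, CardiacModel(), 1, seed=42)
        assert np.array_equal(a.signal_image, b.signal_image)
        assert np.array_equal(a.noise_image, b.noise_image)

    def test_zero_signal_scene_matches_noise_law(self, small_scene):
        """With no tissue signal, signal and noise images share one chi law."""
        tissues = {
            k: TissueProperties(k, t1_ms=v.t1_ms, m0=0.0)
            for k, v in small_scene.tissues.items()
        }
        scene = PhantomScene(
            pixel_spacing_mm=small_scene.pixel_spacing_mm,
            matrix=small_scene.matrix,
            lumen_center_mm=small_scene.lumen_center_mm,
            lumen_radius_mm=small_scene.lumen_radius_mm,
            outer_radius_mm=small_scene.outer_radius_mm,
            muscle_region=small_scene.muscle_region,
            tissues=tissues,
        )
        for seed in (1, 2, 3, 4):
            acq = render_scene(scene, T1W_UNGATED, CardiacModel(), 1, seed=seed)
            p = sps.mannwhitneyu(
                acq.signal_image.ravel(), acq.noise_image.ravel()
            ).pvalue
            assert p > 0.01

    def test_geometry_conservation(self, gated_acquisition, small_scene):
        """Pixel-count areas agree with the true circle areas within a ring."""
        sp = small_scene.pixel_spacing_mm
        truth = gated_acquisition.truth
        r = truth["lumen_radius_mm"]
        frac = raster_fraction_circle(small_scene.matrix, sp, truth["lumen_center_mm"], r)
        measured = (frac >= 0.5).sum() * sp**2
        ring = 2 * math.pi * r * sp
        assert abs(measured - math.pi * r**2) < ring

    def test_out_of_fov_geometry_raises(self):
        with pytest.raises(GeometryError):
            PhantomScene(matrix=(32, 32), lumen_center_mm=(1.0, 1.0))


class TestNoisePhysics:
    def test_sum_of_squares_sd_factor(self):
        """Empirical 4-channel background SD approaches the central-chi value."""
        rng = np.random.default_rng(0)
        img = sum_of_squares_noise((250, 250), 1.0, 4, rng)
        assert img.std(ddof=1) == pytest.approx(central_chi_sd_factor(4), rel=0.02)

    def test_sd_factor_closed_form(self):
        # single channel: Rayleigh SD = sqrt(2 - pi/2)
        assert central_chi_sd_factor(1) == pytest.approx(math.sqrt(2 - math.pi / 2), rel=1e-12)


def test_gating_variance_monotone_in_hrv(small_scene):
    """Repeat-difference variance of wall intensity rises with R-R spread."""
    sp = small_scene.pixel_spacing_mm
    f_lumen = raster_fraction_circle(
        small_scene.matrix, sp, small_scene.lumen_center_mm, small_scene.lumen_radius_mm
    )
    f_outer = raster_fraction_circle(
        small_scene.matrix, sp, small_scene.lumen_center_mm, small_scene.outer_radius_mm
    )
    wall = (f_outer >= 1.0) & (f_lumen <= 0.0)
    variances = []
    for sd_rr in (0.0, 40.0, 80.0):
        card = CardiacModel(mean_rr_ms=1000.0, sd_rr_ms=sd_rr)
        diffs = []
        for i in range(100):
            a = render_scene(small_scene, T1W_GATED, card, 1, seed=2 * i)
            b = render_scene(small_scene, T1W_GATED, card, 2, seed=2 * i + 1)
            diffs.append(a.signal_image[wall].mean() - b.signal_image[wall].mean())
        variances.append(np.var(diffs, ddof=1))
    assert variances[0] < variances[1] < variances[2]


def test_calibrated_tissues_hit_targets():
    tissues = calibrated_tissues(T1W_GATED, "T1W")
    for label, tissue in tissues.items():
        amp = dir_signal(tissue, T1W_GATED.ti_ms, 1000.0)
        from vesselrep.phantom import AMPLITUDE_TARGETS

        assert amp == pytest.approx(AMPLITUDE_TARGETS["T1W"][label], rel=1e-9)
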