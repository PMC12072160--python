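"""2D-FFT fiber metrics: ROI placement, spectra, amplitude, eccentricity."""
import numpy as np
import pytest

from secretofft import (
    FFTConfig,
    FiberImage,
    FiberSimParams,
    ROI,
    amplitude_metric,
    angular_power_profile,
    power_spectrum,
    roi_metrics,
    select_rois,
    simulate_fiber_image,
    spectral_eccentricity,
)
from secretofft.fiberfft import aggregate_metrics, metrics_to_frame


def blank_image(h=256, w=256, value=10.0):
    return FiberImage(pixels=np.full((h, w), value))


class TestSelectROIs:
    def test_exact_fit_single_roi(self):
        img = FiberImage(pixels=np.zeros((100, 100)) + 1)
        rois = select_rois(img, 1, strategy="grid")
        assert rois == [ROI(0, 0, 100)]

    def test_too_small_image_raises(self):
        img = FiberImage(pixels=np.ones((99, 200)))
        with pytest.raises(ValueError, match="smaller"):
            select_rois(img, 1)

    def test_grid_9_disjoint(self):
        img = FiberImage(pixels=np.ones((512, 512)))
        rois = select_rois(img, 9, strategy="grid")
        assert len(rois) == 9
        for i, a in enumerate(rois):
            for b in rois[i + 1 :]:
                assert abs(a.row - b.row) >= 100 or abs(a.col - b.col) >= 100

    def test_infeasible_n_reports_max(self):
        img = FiberImage(pixels=np.ones((256, 256)))
        with pytest.raises(ValueError, match="max feasible is 4"):
            select_rois(img, 5, strategy="grid")

    def test_random_deterministic_and_disjoint(self):
        img = FiberImage(pixels=np.ones((512, 512)))
        a = select_rois(img, 6, strategy="random", seed=3)
        b = select_rois(img, 6, strategy="random", seed=3)
        assert a == b
        for i, r1 in enumerate(a):
            for r2 in a[i + 1 :]:
                assert abs(r1.row - r2.row) >= 100 or abs(r1.col - r2.col) >= 100

    def test_mask_strategy(self):
        img = FiberImage(pixels=np.ones((400, 400)))
        mask = np.zeros((400, 400), bool)
        mask[:200, :200] = True
        rois = select_rois(img, 1, strategy="mask", mask=mask, seed=0)
        r = rois[0]
        assert mask[r.slices()].mean() >= 0.9

    def test_mask_strategy_requires_mask(self):
        img = FiberImage(pixels=np.ones((256, 256)))
        with pytest.raises(ValueError, match="mask"):
            select_rois(img, 1, strategy="mask")


class TestPowerSpectrum:
    def test_constant_roi_zero_power(self):
        spec = power_spectrum(np.full((100, 100), 7.0), window="none")
        assert np.all(spec.power == 0)

    def test_parseval_identity(self):
        rng = np.random.default_rng(5)
        x = rng.random((100, 100))
        spec = power_spectrum(x, window="none")
        total = spec.power.sum()
        expected = x.size * x.var()
        assert total == pytest.approx(expected, rel=1e-8)

    def test_cosine_grating_localizes(self):
        """cos(2*pi*f*y) puts all power in the two bins at +/-f on the row-frequency axis."""
        n, k = 100, 10
        y = np.arange(n)[:, None]
        x = np.cos(2 * np.pi * k / n * y) * np.ones((1, n))
        spec = power_spectrum(x, window="none")
        dc_r, dc_c = spec.dc_index
        power = spec.power / spec.power.sum()
        assert power[dc_r - k, dc_c] == pytest.approx(0.5, abs=1e-10)
        assert power[dc_r + k, dc_c] == pytest.approx(0.5, abs=1e-10)

    def test_point_symmetry_real_input(self):
        rng = np.random.default_rng(6)
        spec = power_spectrum(rng.random((100, 100)))
        p = spec.power
        # real input: power symmetric under point reflection through DC
        flipped = p[::-1, ::-1]
        # fftshift leaves the negative-most row/col unpaired on even sizes
        assert np.allclose(p[1:, 1:], flipped[:-1, :-1], rtol=1e-9, atol=1e-12)


class TestAngularProfile:
    def test_isotropic_ring_uniform(self):
        n = 101
        f = np.fft.fftshift(np.fft.fftfreq(n))
        from secretofft.fiberfft import Spectrum

        r = np.hypot(f[:, None], f[None, :])
        power = ((r > 0.15) & (r < 0.25)).astype(float)
        spec = Spectrum(power=power, freq_row=f, freq_col=f)
        p = angular_power_profile(spec, band=(0.1, 0.3), n_bins=18)
        assert p.sum() == pytest.approx(1.0)
        assert p.std() < 0.2 * p.mean()

    def test_delta_pair_profile(self):
        n = 100
        f = np.fft.fftshift(np.fft.fftfreq(n))
        from secretofft.fiberfft import Spectrum

        power = np.zeros((n, n))
        dc = n // 2
        power[dc + 10, dc] = 1.0  # pure row-frequency pair
        power[dc - 10, dc] = 1.0
        spec = Spectrum(power=power, freq_row=f, freq_col=f)
        p = angular_power_profile(spec, n_bins=36)
        theta = (np.argmax(p) + 0.5) * np.pi / 36
        assert abs(theta - np.pi / 2) < np.pi / 36
        assert p.max() == pytest.approx(1.0)

    def test_rotation_by_90_shifts_profile(self):
        """Rotating the ROI by 90 deg circularly shifts the profile by pi/2."""
        img = simulate_fiber_image(FiberSimParams(kappa=8.0, seed=1))
        roi = img.pixels[78:178, 78:178]
        p0 = angular_power_profile(power_spectrum(roi), n_bins=36)
        p90 = angular_power_profile(power_spectrum(np.rot90(roi)), n_bins=36)
        shifted = np.roll(p0, 18)
        assert np.corrcoef(shifted, p90)[0, 1] > 0.9

    def test_empty_annulus_raises(self):
        spec = power_spectrum(np.random.default_rng(0).random((100, 100)))
        with pytest.raises(ValueError, match="annulus"):
            # below the lowest nonzero frequency bin (0.01 for a 100-px ROI)
            angular_power_profile(spec, band=(0.0001, 0.005))


class TestAmplitudeMetric:
    def test_uniform_profile_zero(self):
        amp, _ = amplitude_metric(np.full(36, 1 / 36))
        assert amp == pytest.approx(0.0, abs=1e-12)

    def test_delta_profile_one(self):
        p = np.zeros(36)
        p[7] = 1.0
        amp, orient = amplitude_metric(p)
        assert amp == pytest.approx(1.0)
        assert orient == pytest.approx((7 + 0.5) * np.pi / 36)

    def test_orthogonal_deltas_cancel(self):
        p = np.zeros(36)
        p[0] = 0.5
        p[18] = 0.5  # pi/2 away: 2-theta phasors are opposite
        amp, _ = amplitude_metric(p)
        assert amp == pytest.approx(0.0, abs=1e-12)

    def test_zero_profile_missing(self):
        amp, orient = amplitude_metric(np.zeros(36))
        assert np.isnan(amp) and np.isnan(orient)


class TestEccentricity:
    def test_circularly_symmetric_zero(self):
        n = 101
        f = np.fft.fftshift(np.fft.fftfreq(n))
        from secretofft.fiberfft import Spectrum

        r = np.hypot(f[:, None], f[None, :])
        power = np.exp(-((r - 0.2) ** 2) / 1e-4)
        spec = Spectrum(power=power, freq_row=f, freq_col=f)
        assert spectral_eccentricity(spec, power_quantile=0.0) == pytest.approx(0.0, abs=0.05)

    def test_line_through_dc_approaches_one(self):
        n = 101
        f = np.fft.fftshift(np.fft.fftfreq(n))
        from secretofft.fiberfft import Spectrum

        power = np.zeros((n, n))
        power[:, n // 2] = 1.0  # vertical line through DC
        spec = Spectrum(power=power, freq_row=f, freq_col=f)
        assert spectral_eccentricity(spec, power_quantile=0.0) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_small_vs_aligned(self):
        """Noise-only eccentricity (simulation oracle, 20 seeds) stays far below
        the aligned-fiber regime."""
        noise_eccs, aligned_eccs = [], []
        for seed in range(20):
            img = simulate_fiber_image(FiberSimParams(n_fibers=0, noise_sd=5.0, seed=seed))
            noise_eccs.append(roi_metrics(img, ROI(50, 50)).eccentricity)
        for seed in range(5):
            img = simulate_fiber_image(FiberSimParams(kappa=8.0, n_fibers=200, seed=seed))
            aligned_eccs.append(roi_metrics(img, ROI(50, 50)).eccentricity)
        assert np.mean(noise_eccs) < 0.35
        assert np.mean(aligned_eccs) > 0.9
        assert np.mean(noise_eccs) < np.mean(aligned_eccs) - 0.5


class TestROIMetrics:
    def test_blank_roi(self):
        img = blank_image(value=10.0)
        m = roi_metrics(img, ROI(0, 0))
        assert m.intensity == pytest.approx(10.0)
        assert np.isnan(m.amplitude) and np.isnan(m.eccentricity) and np.isnan(m.orientation)

    def test_aligned_beats_isotropic(self, aligned_image, isotropic_image):
        rois = select_rois(aligned_image, 4)
        amp8 = np.mean([roi_metrics(aligned_image, r).amplitude for r in rois])
        amp0 = np.mean([roi_metrics(isotropic_image, r).amplitude for r in rois])
        assert amp8 > amp0 + 0.3

    def test_orientation_recovers_fiber_axis(self):
        img = simulate_fiber_image(
            FiberSimParams(kappa=50.0, mean_orientation=np.pi / 3, n_fibers=200, seed=7)
        )
        m = roi_metrics(img, ROI(78, 78))
        d = abs(((m.orientation - np.pi / 3) + np.pi / 2) % np.pi - np.pi / 2)
        assert d < np.pi / 18  # within 10 degrees

    def test_intensity_scale_invariance(self, aligned_image):
        m1 = roi_metrics(aligned_image, ROI(78, 78))
        scaled = FiberImage(pixels=aligned_image.pixels * 2.0)
        m2 = roi_metrics(scaled, ROI(78, 78))
        assert abs(m1.amplitude - m2.amplitude) < 0.02
        assert abs(m1.eccentricity - m2.eccentricity) < 0.02
        assert m2.intensity == pytest.approx(2 * m1.intensity)

    def test_roi_outside_image_raises(self, aligned_image):
        with pytest.raises(ValueError):
            roi_metrics(aligned_image, ROI(200, 200))


class TestMonotonicityAndRotation:
    def test_amplitude_monotone_in_kappa(self):
        """Mean amplitude strictly increases across kappa in {0, 2, 8} (20 seeds)."""
        means = []
        for kappa in (0.0, 2.0, 8.0):
            amps = [
                roi_metrics(
                    simulate_fiber_image(FiberSimParams(kappa=kappa, n_fibers=200, seed=s)),
                    ROI(78, 78),
                ).amplitude
                for s in range(20)
            ]
            means.append(np.mean(amps))
        assert means[0] < means[1] < means[2]

    def test_rotation_equivariance(self):
        """45 deg rotation shifts orientation by 45 +/- 5 deg, amplitude within 0.05."""
        from skimage.transform import rotate

        img = simulate_fiber_image(FiberSimParams(kappa=8.0, n_fibers=200, seed=13))
        rotated = FiberImage(
            pixels=np.clip(rotate(img.pixels, 45.0, resize=False, preserve_range=True), 0, None)
        )
        m0 = roi_metrics(img, ROI(78, 78))
        m45 = roi_metrics(rotated, ROI(78, 78))
        shift = (m45.orientation - m0.orientation) % np.pi
        # skimage rotates counterclockwise in display coords = -45 deg on the fiber axis
        d = min(abs(shift - np.pi / 4), abs(shift - 3 * np.pi / 4))
        assert d < np.deg2rad(5)
        assert abs(m45.amplitude - m0.amplitude) < 0.05


class TestAggregate:
    def test_single_value_flagged(self):
        import pandas as pd

        df = pd.DataFrame({"amplitude": [0.5], "condition": ["CTR"]})
        out = aggregate_metrics(df)
        assert out.loc[0, "median"] == pytest.approx(0.5)
        assert out.loc[0, "ci_flag"] is not None

    def test_median_of_1_to_5(self):
        import pandas as pd

        df = pd.DataFrame({"amplitude": [1.0, 2, 3, 4, 5], "condition": ["g"] * 5})
        out = aggregate_metrics(df)
        assert out.loc[0, "median"] == pytest.approx(3.0)

    def test_missing_excluded_and_counted(self):
        import pandas as pd

        df = pd.DataFrame({"amplitude": [1.0, np.nan, 3.0], "condition": ["g"] * 3})
        out = aggregate_metrics(df)
        assert out.loc[0, "n"] == 2 and out.loc[0, "n_missing"] == 1

    def test_metrics_frame_columns(self, aligned_image):
        ms = [roi_metrics(aligned_image, r) for r in select_rois(aligned_image, 2)]
        df = metrics_to_frame(ms, image_id="img0", condition="FSH")
        assert set(df.columns) >= {
            "image", "roi_row", "roi_col", "intensity", "amplitude",
            "eccentricity", "orientation", "condition",
        }
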