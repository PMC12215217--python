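"""Spectral decomposition: area averaging, PSD, IRASA, slope fitting."""

import numpy as np
import pytest

from remaperiodic.simulate import synth_aperiodic_signal
from remaperiodic.spectral import (
    AreaSignal,
    IrasaConfig,
    SpectralDecomposition,
    average_area_signal,
    compute_psd,
    epoch_slopes,
    fit_aperiodic_slope,
    irasa_decompose,
)


class TestAreaAveraging:
    def test_sample_wise_mean(self, rng):
        chans = {lb: rng.standard_normal(100) for lb in ("Fz", "F3", "F4")}
        out = average_area_signal(chans, 250.0, {"frontal": ("Fz", "F3", "F4")})
        expected = (chans["Fz"] + chans["F3"] + chans["F4"]) / 3
        np.testing.assert_allclose(out[0].samples, expected)

    def test_single_channel_identity(self, rng):
        x = rng.standard_normal(50)
        out = average_area_signal({"O1": x}, 250.0, {"occipital": ("O1",)})
        np.testing.assert_array_equal(out[0].samples, x)

    def test_missing_channel_named_in_error(self, rng):
        with pytest.raises(KeyError, match="O2"):
            average_area_signal({"O1": rng.standard_normal(10)}, 250.0,
                                {"occipital": ("O1", "O2")})

    def test_duplicate_channel_rejected(self, rng):
        with pytest.raises(ValueError, match="duplicate"):
            average_area_signal({"Fz": rng.standard_normal(10)}, 250.0,
                                {"frontal": ("Fz", "Fz")})


class TestPsd:
    def test_sinusoid_line_spectrum(self):
        t = np.arange(4 * 256) / 256.0
        f, p = compute_psd(np.sin(2 * np.pi * 10 * t), 256.0)
        band = (f >= 9.75) & (f <= 10.25)
        assert p[band].sum() / p.sum() > 0.99

    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(150_000) * 2.0  # variance 4
        f, p = compute_psd(x, 250.0)
        total = p.sum() * (f[1] - f[0])
        assert total == pytest.approx(x.var(), rel=0.01)

    def test_zero_signal_gives_zero_power(self):
        f, p = compute_psd(np.zeros(1000), 250.0)
        assert np.all(p == 0)

    def test_nonfinite_rejected(self):
        x = np.ones(1000)
        x[5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            compute_psd(x, 250.0)


class TestIrasa:
    def test_additivity_bin_exact(self):
        x = synth_aperiodic_signal(-2.0, 250.0, 4.0, seed=0)
        dec = irasa_decompose(x, 250.0)
        np.testing.assert_allclose(
            dec.total_power, dec.fractal_power + dec.oscillatory_power
        )

    def test_pure_power_law_fractal_matches_total(self):
        """For shaped noise with no oscillation the fractal estimate tracks
        the total spectrum (unit median ratio) and recovers the exponent;
        individual bins still fluctuate with periodogram noise."""
        x = synth_aperiodic_signal(-2.0, 250.0, 60.0, seed=1)
        dec = irasa_decompose(x, 250.0)
        band = (dec.freqs >= 2) & (dec.freqs <= 30)
        ratio = np.median(dec.fractal_power[band] / dec.total_power[band])
        assert ratio == pytest.approx(1.0, abs=0.1)
        assert fit_aperiodic_slope(dec, (2, 30)).slope == pytest.approx(-2.0, abs=0.1)

    def test_oscillation_isolated_in_residual(self):
        x = synth_aperiodic_signal(-2.0, 250.0, 60.0, seed=2)
        t = np.arange(x.size) / 250.0
        x_osc = x + 10.0 * np.sin(2 * np.pi * 10.0 * t)
        dec = irasa_decompose(x_osc, 250.0)
        band = dec.freqs >= 2.0  # below the fitted range the residual is noise
        peak_f = dec.freqs[band][np.argmax(dec.oscillatory_power[band])]
        assert peak_f == pytest.approx(10.0, abs=0.5)
        # fractal fit barely moves relative to the oscillation-free fit
        ref = fit_aperiodic_slope(irasa_decompose(x, 250.0), (2, 30)).slope
        osc = fit_aperiodic_slope(dec, (2, 30)).slope
        assert abs(osc - ref) < 0.1

    def test_nyquist_precondition(self):
        cfg = IrasaConfig()
        x = np.random.default_rng(0).standard_normal(600)
        with pytest.raises(ValueError, match="Nyquist"):
            irasa_decompose(x, 150.0, cfg)


class TestSlopeFit:
    def _dec(self, power):
        f = np.arange(1, 201) * 0.25
        return SpectralDecomposition(freqs=f, total_power=power(f),
                                     fractal_power=power(f))

    def test_exact_power_law(self):
        fit = fit_aperiodic_slope(self._dec(lambda f: 3.0 * f**-2.0), (2, 30))
        assert fit.slope == pytest.approx(-2.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_spectrum(self):
        fit = fit_aperiodic_slope(self._dec(lambda f: np.full(f.size, 2.0)), (2, 30))
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_band_edges_inclusive(self):
        fit = fit_aperiodic_slope(self._dec(lambda f: f**-1.0), (2, 30))
        assert fit.band == (2, 30)

    def test_nonpositive_power_rejected(self):
        f = np.arange(1, 201) * 0.25
        dec = SpectralDecomposition(freqs=f, total_power=np.ones(f.size),
                                    fractal_power=np.zeros(f.size))
        with pytest.raises(ValueError, match="non-positive"):
            fit_aperiodic_slope(dec, (2, 30))

    def test_too_few_bins_rejected(self):
        dec = self._dec(lambda f: f**-1.0)
        with pytest.raises(ValueError, match="bins"):
            fit_aperiodic_slope(dec, (10.0, 10.3))


class TestEpochSlopes:
    def test_row_count(self):
        x = synth_aperiodic_signal(-2.0, 250.0, 60.0, seed=3)
        df = epoch_slopes([AreaSignal("frontal", x, 250.0)])
        assert len(df) == 15 * 2  # 15 epochs x 2 bands
        assert set(df.band) == {"low", "high"}

    def test_unimodal_around_truth(self):
        x = synth_aperiodic_signal(-2.5, 250.0, 120.0, seed=4)
        df = epoch_slopes([AreaSignal("central", x, 250.0)])
        low = df[df.band == "low"].slope
        assert low.median() == pytest.approx(-2.5, abs=0.1)
        assert low.std() < 0.5

    def test_nonfinite_epoch_marked_missing(self):
        x = synth_aperiodic_signal(-2.0, 250.0, 12.0, seed=5)
        x[1100] = np.nan  # second epoch
        df = epoch_slopes([AreaSignal("frontal", x, 250.0)])
        second = df[df.epoch_index == 1]
        assert second.slope.isna().all()
        rest = df[df.epoch_index != 1]
        assert rest.slope.notna().all()

    def test_epoch_subset(self):
        x = synth_aperiodic_signal(-2.0, 250.0, 40.0, seed=6)
        df = epoch_slopes([AreaSignal("frontal", x, 250.0)], epoch_indices=[0, 3])
        assert sorted(df.epoch_index.unique()) == [0, 3]


def test_monotonicity_of_generative_exponent():
    """Steepening the generative exponent strictly decreases the fitted slope."""
    medians = []
    for alpha in (-1.0, -2.0, -3.0):
        x = synth_aperiodic_signal(alpha, 250.0, 60.0, seed=7)
        df = epoch_slopes([AreaSignal("frontal", x, 250.0)], bands={"low": (2, 30)})
        medians.append(df.slope.median())
    assert medians[0] > medians[1] > medians[2]
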