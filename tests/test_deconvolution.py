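import numpy as np
import pytest

from adcbiotx.deconvolution import (
    DeconvConfig,
    PreprocessConfig,
    RTWindow,
    Spectrum,
    deconvolve,
    deconvolve_run,
    export_peaks,
    preprocess,
    read_peaks,
    read_run,
    sum_window,
    write_csv_run,
)
from adcbiotx.simulate import SpectrumSimConfig, simulate_spectrum, write_mzml

CLEAN = SpectrumSimConfig(snr=0, baseline_level=0.0)  # snr=0 disables noise


def gaussian_spectrum(center=2000.0, sigma=0.2, height=100.0, rt=1.0):
    mz = np.arange(1900.0, 2100.0, 0.02)
    return Spectrum(rt=rt, mz=mz, intensity=height * np.exp(-0.5 * ((mz - center) / sigma) ** 2))


class TestSpectrumType:
    def test_rejects_unsorted_mz(self):
        with pytest.raises(ValueError, match="increasing"):
            Spectrum(rt=0, mz=np.array([2.0, 1.0]), intensity=np.array([1.0, 1.0]))

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError):
            Spectrum(rt=0, mz=np.array([1.0, 2.0]), intensity=np.array([1.0, -1.0]))

    def test_window_requires_start_before_end(self):
        with pytest.raises(ValueError):
            RTWindow("LC", 2.0, 1.0)


class TestReadRun:
    def test_csv_round_trip(self, tmp_path):
        spectra = [gaussian_spectrum(rt=0.5), gaussian_spectrum(rt=1.5)]
        path = write_csv_run(spectra, tmp_path / "run.csv")
        back = read_run(path)
        assert [s.rt for s in back] == [0.5, 1.5]
        assert np.allclose(back[0].intensity, spectra[0].intensity, atol=1e-5)

    def test_mzml_round_trip(self, tmp_path):
        spectra = [
            simulate_spectrum([30000.0], [1.0], CLEAN, seed=i, rt=0.5 * (i + 1))
            for i in range(3)
        ]
        path = write_mzml(spectra, tmp_path / "run.mzml")
        back = read_run(path)
        assert len(back) == 3
        assert [s.rt for s in back] == pytest.approx([0.5, 1.0, 1.5])
        assert all(s.mode == "profile" for s in back)
        for orig, re in zip(spectra, back):
            assert np.array_equal(orig.mz, re.mz)
            assert np.array_equal(orig.intensity, re.intensity)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("rt,mz,intensity\n")
        with pytest.raises(ValueError):
            read_run(p)


class TestPreprocess:
    def test_flat_baseline_invariance(self):
        clean = gaussian_spectrum()
        raised = Spectrum(rt=clean.rt, mz=clean.mz, intensity=clean.intensity + 50.0)
        out = preprocess(raised)
        ref = preprocess(clean)
        assert np.allclose(out.intensity, ref.intensity, atol=1e-6)

    def test_pure_noise_mostly_removed(self, rng):
        mz = np.arange(1000.0, 1400.0, 0.02)
        noise = np.abs(rng.normal(0, 1.0, mz.size))
        sp = Spectrum(rt=0, mz=mz, intensity=noise)
        out = preprocess(sp, PreprocessConfig(noise_k=5.0))
        assert out.intensity.sum() <= 0.01 * sp.intensity.sum()

    def test_clean_peak_area_preserved(self):
        sp = gaussian_spectrum()
        out = preprocess(sp)
        assert out.intensity.sum() == pytest.approx(sp.intensity.sum(), rel=0.01)

    def test_output_non_negative(self, rng):
        mz = np.arange(1000.0, 1100.0, 0.02)
        sp = Spectrum(rt=0, mz=mz, intensity=np.abs(rng.normal(5, 1, mz.size)))
        assert np.all(preprocess(sp).intensity >= 0)


class TestSumWindow:
    def test_linearity(self):
        s = gaussian_spectrum(rt=1.9)
        double = sum_window([s, s], RTWindow("LC", 1.7, 2.2))
        assert np.allclose(double.intensity, 2 * s.intensity)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="no scans"):
            sum_window([gaussian_spectrum(rt=5.0)], RTWindow("LC", 1.7, 2.2))

    def test_window_selects_only_contained_scans(self):
        lc = gaussian_spectrum(center=1980.0, rt=1.9)
        hc = gaussian_spectrum(center=2050.0, rt=4.5)
        comp = sum_window([lc, hc], RTWindow("LC", 1.7, 2.2))
        assert comp.intensity[np.argmin(np.abs(comp.mz - 2050.0))] < 1e-6
        assert comp.rt == pytest.approx(1.9)


class TestDeconvolve:
    def test_single_species_no_noise(self):
        sp = simulate_spectrum([23710.0], [1.0], CLEAN, seed=1)
        peaks = deconvolve(sp)
        assert len(peaks) == 1
        assert peaks[0].neutral_mass == pytest.approx(23710.0, abs=0.5)
        assert peaks[0].n_charges_supporting >= 3

    def test_two_equal_species_equal_intensity(self):
        sp = simulate_spectrum([50000.0, 55000.0], [1.0, 1.0], CLEAN, seed=2)
        peaks = sorted(deconvolve(sp), key=lambda p: p.neutral_mass)
        assert len(peaks) == 2
        assert peaks[0].neutral_mass == pytest.approx(50000.0, abs=0.5)
        assert peaks[1].neutral_mass == pytest.approx(55000.0, abs=0.5)
        ratio = peaks[0].intensity / peaks[1].intensity
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_empty_spectrum_gives_no_peaks(self):
        mz = np.arange(1000.0, 5000.0, 0.5)
        sp = Spectrum(rt=0, mz=mz, intensity=np.zeros_like(mz))
        assert deconvolve(sp) == []

    def test_mass_range_respected(self):
        sp = simulate_spectrum([30000.0, 52000.0], [1.0, 1.0], CLEAN, seed=3)
        cfg = DeconvConfig(mass_range=(45000.0, 60000.0))
        peaks = deconvolve(sp, cfg)
        assert all(45000.0 <= p.neutral_mass <= 60000.0 for p in peaks)
        assert any(abs(p.neutral_mass - 52000.0) < 0.5 for p in peaks)

    def test_no_harmonic_artifacts(self):
        # M/2 and 2M of a clean species must not be reported
        sp = simulate_spectrum([48000.0], [1.0], CLEAN, seed=4)
        peaks = deconvolve(sp)
        assert len(peaks) == 1
        assert peaks[0].neutral_mass == pytest.approx(48000.0, abs=0.5)

    def test_intensity_monotone_in_abundance(self):
        cfg = SpectrumSimConfig(snr=0, baseline_level=0.0)
        lo = deconvolve(simulate_spectrum([40000.0, 52000.0], [0.5, 1.0], cfg, seed=5))
        hi = deconvolve(simulate_spectrum([40000.0, 52000.0], [1.0, 1.0], cfg, seed=5))
        get = lambda peaks: next(
            p.intensity for p in peaks if abs(p.neutral_mass - 40000.0) < 1
        )
        assert get(hi) > get(lo)

    def test_hydrolysis_ladder_resolved(self):
        # 18 Da apart at 55 kDa: the resolution regime of the HC ladder
        masses = [55455.2, 55473.2, 55491.3, 55509.3]
        ab = [0.3, 1.0, 0.9, 0.35]
        sp = simulate_spectrum(masses, ab, SpectrumSimConfig(snr=20), seed=6)
        peaks = sorted(deconvolve(preprocess(sp)), key=lambda p: p.neutral_mass)
        found = [p.neutral_mass for p in peaks]
        assert len(found) == 4
        for m, f in zip(masses, found):
            assert f == pytest.approx(m, abs=0.5)


class TestRunPipeline:
    def test_deconvolve_run_labels_windows(self):
        lc_scans = [
            simulate_spectrum([24749.4], [1.0], CLEAN, seed=7, rt=rt)
            for rt in (1.8, 1.9, 2.0)
        ]
        hc_scans = [
            simulate_spectrum([55473.2], [1.0], CLEAN, seed=8, rt=rt)
            for rt in (4.4, 4.5, 4.6)
        ]
        windows = [RTWindow("LC", 1.7, 2.2), RTWindow("HC", 4.0, 5.0)]
        peaks = deconvolve_run(lc_scans + hc_scans, windows)
        by_window = {p.rt_window: p.neutral_mass for p in peaks}
        assert by_window["LC"] == pytest.approx(24749.4, abs=0.5)
        assert by_window["HC"] == pytest.approx(55473.2, abs=0.5)

    def test_peaks_csv_round_trip(self, tmp_path):
        sp = simulate_spectrum([30000.0], [1.0], CLEAN, seed=9)
        peaks = deconvolve(sp, rt_window_label="LC")
        path = export_peaks(peaks, tmp_path / "peaks.csv")
        back = read_peaks(path)
        assert back[0].neutral_mass == pytest.approx(peaks[0].neutral_mass, abs=1e-3)
        assert back[0].rt_window == "LC"
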