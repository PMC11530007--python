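"""Generator contracts: species libraries, event statistics, waveform physics, archive IO."""

import dataclasses
import math

import h5py
import numpy as np
import pytest

from polaridar import spectra, synthdata
from polaridar.synthdata import (
    ArchiveFormatError,
    ObservationTruth,
    SpeciesProfile,
    make_species_library,
    read_archive,
    render_raw_stream,
    sample_events,
    synth_waveform,
    write_archive,
)


class TestSpeciesLibrary:
    def test_empty_and_errors(self):
        assert make_species_library(0, seed=0) == []
        with pytest.raises(ValueError):
            make_species_library(-1, seed=0)

    def test_default_within_species_spread_is_25_percent(self):
        lib = make_species_library(8, seed=1)
        assert all(p.wbf_rel_spread == 0.25 for p in lib)

    def test_deterministic_given_seed(self):
        a = make_species_library(6, seed=42)
        b = make_species_library(6, seed=42)
        assert a == b

    def test_parameter_ranges_and_dolp_stratification(self):
        lib = make_species_library(12, seed=3)
        wbf = np.array([p.wbf_mean for p in lib])
        dolp = np.array([p.dolp_target for p in lib])
        assert np.all((wbf >= 10.0) & (wbf <= 1000.0))
        # glossy, randomized and diffuse regimes all represented
        assert dolp.min() <= 0.1 and dolp.max() >= 0.9
        assert np.any(np.abs(dolp - 0.5) < 0.15)

    def test_overrides(self):
        lib = make_species_library(3, seed=0, overrides={"dolp_target": [0.9, 0.5, 0.1]})
        assert [p.dolp_target for p in lib] == [0.9, 0.5, 0.1]

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpeciesProfile(species_id="x", wbf_mean=5.0)
        with pytest.raises(ValueError):
            SpeciesProfile(species_id="x", wbf_mean=100.0, dolp_target=1.5)


class TestSampleEvents:
    def test_empty_and_errors(self, small_library):
        assert sample_events(small_library, 0, seed=0) == []
        with pytest.raises(ValueError):
            sample_events([], 5, seed=0)

    def test_transit_filter_mass(self, small_library):
        """The fraction below 40 ms matches the configured log-normal mass (binomial 3 sigma)."""
        events = sample_events(small_library, 10000, seed=7)
        below = sum(e.transit_ms < 40.0 for e in events)
        p = synthdata.TRANSIT_SUB40_MASS
        sigma = math.sqrt(10000 * p * (1 - p))
        assert abs(below - 10000 * p) < 3 * sigma

    def test_range_density_decays(self):
        """Per-bin event mass tracks the truncated-exponential oracle and decays."""
        lib = make_species_library(1, seed=5, overrides={"range_scale": 30.0})
        events = sample_events(lib, 10000, seed=8)
        edges = np.geomspace(48.0, 427.0, 21)
        counts, _ = np.histogram([e.range_m for e in events], bins=edges)
        s = 30.0
        cdf = lambda r: math.exp(-48.0 / s) - math.exp(-r / s)
        masses = np.diff([cdf(r) for r in edges]) / cdf(427.0)
        assert np.all(np.diff(masses) <= 0)  # oracle is monotone for this scale
        assert np.max(np.abs(counts / 10000 - masses)) < 0.02
        empirical = counts / 10000
        assert np.all(np.diff(empirical) <= 0.01)  # sampling slack

    def test_wbf_spread_convention(self):
        """Realized per-species CV matches the +-12.5% uniform band, within 20%."""
        lib = make_species_library(1, seed=2, overrides={"wbf_mean": 200.0})
        events = sample_events(lib, 2000, seed=3)
        wbf = np.array([e.wbf for e in events])
        cv = wbf.std() / wbf.mean()
        expected = 0.25 / (2.0 * math.sqrt(3.0))
        assert abs(cv - expected) / expected < 0.2
        assert wbf.min() >= 200.0 * 0.875 - 1e-9 and wbf.max() <= 200.0 * 1.125 + 1e-9

    def test_diel_minimum_near_noon(self, small_library):
        events = sample_events(small_library, 20000, seed=9)
        hours = np.array([e.solar_time for e in events]) / 3600.0
        counts, _ = np.histogram(hours, bins=24, range=(0, 24))
        assert 11 <= int(np.argmin(counts)) < 13

    def test_deterministic(self, small_library):
        assert sample_events(small_library, 50, seed=4) == sample_events(
            small_library, 50, seed=4
        )


class TestSynthWaveform:
    def test_no_wings_is_pure_envelope(self):
        prof = SpeciesProfile(species_id="x", wbf_mean=250.0, wing_contrast=0.0)
        truth = ObservationTruth("o", "x", 250.0, 3600.0, 100.0, 200.0, 0.5)
        obs = synth_waveform(prof, truth, noise_sd=0.0, seed=0)
        env = np.hanning(obs.waveform_co.size + 2)[1:-1]
        assert np.allclose(obs.waveform_co, env, atol=1e-6)
        assert np.allclose(obs.waveform_de, env, atol=1e-6)
        # no wingbeat peak: the band above 100 Hz carries almost no mass
        p = spectra.welch_psd(obs.waveform_co)
        high = p[spectra.FREQS_HZ > 100.0].sum()
        assert high < 0.01 * p.sum()

    def test_dolp_calibration_grid(self):
        """Realized co-fraction within +-0.05 of target over a DoLP grid and transits."""
        for transit in (60.0, 100.0, 400.0):
            for i, target in enumerate(np.linspace(0.05, 0.95, 10)):
                prof = SpeciesProfile(
                    species_id=f"g{i}", wbf_mean=200.0, dolp_target=float(target)
                )
                truth = ObservationTruth(
                    "o", prof.species_id, 200.0, 3600.0, 100.0, transit, float(target)
                )
                obs = synth_waveform(prof, truth, noise_sd=0.0, seed=i)
                pair = spectra.spectrum_pair(obs.waveform_co, obs.waveform_de)
                assert abs(spectra.observation_dolp(pair) - target) <= 0.05

    def test_wingbeat_peak_recovered(self):
        prof = SpeciesProfile(species_id="x", wbf_mean=250.0, dolp_target=0.5)
        truth = ObservationTruth("o", "x", 250.0, 3600.0, 100.0, 200.0, 0.5)
        obs = synth_waveform(prof, truth, noise_sd=0.0, seed=1)
        pair = spectra.spectrum_pair(obs.waveform_co, obs.waveform_de)
        unpol, _, _ = spectra.build_datasets(pair)
        nearest = spectra.FREQS_HZ[np.argmin(np.abs(spectra.FREQS_HZ - 250.0))]
        assert spectra.FREQS_HZ[np.argmax(unpol)] == nearest

    def test_nonnegative_and_deterministic(self, small_library):
        truth = ObservationTruth("o", "sp000", 120.0, 3600.0, 100.0, 90.0, 0.5)
        a = synth_waveform(small_library[0], truth, noise_sd=0.3, seed=5)
        b = synth_waveform(small_library[0], truth, noise_sd=0.3, seed=5)
        assert np.array_equal(a.waveform_co, b.waveform_co)
        assert np.array_equal(a.waveform_de, b.waveform_de)
        assert a.waveform_co.min() >= 0.0 and a.waveform_de.min() >= 0.0
        assert a.waveform_co.size == round(90.0 * 2)


class TestRawStream:
    def test_no_events_zero_noise_is_constant(self):
        stream = render_raw_stream([], 1.0, 0.0, seed=0, n_samples=2000)
        assert np.all(stream.intensity_co == 1.0)
        from polaridar.extraction import detect_events

        assert detect_events(stream) == []

    def test_injection_recorded_and_deterministic(self, small_library):
        truth = ObservationTruth("o", "sp000", 120.0, 2.0, 100.0, 90.0, 0.5)
        obs = synth_waveform(small_library[0], truth, noise_sd=0.0, seed=1)
        s1 = render_raw_stream([(obs, 400, 3)], 1.0, 0.05, seed=2, n_samples=2000)
        s2 = render_raw_stream([(obs, 400, 3)], 1.0, 0.05, seed=2, n_samples=2000)
        assert np.array_equal(s1.intensity_co, s2.intensity_co)
        assert len(s1.injected_events) == 1
        assert s1.injected_events[0][1:] == (400, 3)
        assert np.all(s1.intensity_co > 0)

    def test_event_must_fit(self, small_library):
        truth = ObservationTruth("o", "sp000", 120.0, 2.0, 100.0, 90.0, 0.5)
        obs = synth_waveform(small_library[0], truth, noise_sd=0.0, seed=1)
        with pytest.raises(ValueError):
            render_raw_stream([(obs, 1950, 0)], 1.0, 0.05, seed=2, n_samples=2000)


class TestArchive:
    def test_roundtrip_lossless(self, tmp_path, small_observations):
        obs = small_observations[:30]
        write_archive(obs, tmp_path / "arch")
        back = read_archive(tmp_path / "arch")
        assert len(back) == len(obs)
        for a, b in zip(obs, back):
            assert a.obs_id == b.obs_id
            assert np.array_equal(a.waveform_co, b.waveform_co)
            assert np.array_equal(a.waveform_de, b.waveform_de)
            assert a.solar_time == b.solar_time
            assert a.range_m == b.range_m
            assert a.transit_ms == b.transit_ms
            assert dataclasses.asdict(a.truth) == dataclasses.asdict(b.truth)

    def test_empty_archive(self, tmp_path):
        write_archive([], tmp_path / "arch")
        assert read_archive(tmp_path / "arch") == []

    def test_missing_waveform_is_format_error(self, tmp_path, small_observations):
        obs = small_observations[:3]
        write_archive(obs, tmp_path / "arch")
        with h5py.File(tmp_path / "arch" / "waveforms.h5", "a") as f:
            del f[obs[1].obs_id]
        with pytest.raises(ArchiveFormatError, match=obs[1].obs_id):
            read_archive(tmp_path / "arch")

    def test_not_an_archive(self, tmp_path):
        with pytest.raises(ArchiveFormatError):
            read_archive(tmp_path / "nope")
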