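"""Chromatogram I/O, noise estimation, peak detection/integration, matching."""
import numpy as np
import pytest

from cordyqc import synthgen
from cordyqc.chromio import (Chromatogram, FormatError, Peak, detect_peaks,
                             estimate_noise, integrate_peak,
                             match_common_peaks, read_chromatogram,
                             write_chromatogram)
from cordyqc.synthgen import (PeakSpec, default_config, generate_standard_mixture,
                              simulate_chromatogram)


def quiet_config(seed=0, **kw):
    defaults = dict(noise_sd=0.0, baseline_amplitude=0.0,
                    rt_warp_sd=0.0, rt_peak_jitter_sd=0.0)
    defaults.update(kw)
    return default_config(seed=seed, **defaults)


def gaussian_chrom(height=100.0, sigma=0.05, rt=15.0, baseline=0.0, noise=0.0,
                   seed=0):
    cfg = quiet_config(noise_sd=noise)
    spec = PeakSpec("x", rt, sigma, 1.0)
    amount = height * sigma * np.sqrt(2 * np.pi)
    chrom = simulate_chromatogram([(spec, amount)], cfg, seed=seed)
    if baseline:
        chrom.intensity = chrom.intensity + baseline
    return chrom


class TestIO:
    def test_read_three_row_file(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("time_min\tintensity\n0.0\t1.0\n0.5\t2.0\n1.0\t1.5\n")
        chrom = read_chromatogram(p)
        assert chrom.n_points == 3
        assert chrom.sample_id == "c"

    def test_decreasing_time_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("0.0\t1.0\n0.5\t2.0\n0.4\t1.5\n")
        with pytest.raises(FormatError, match="increasing"):
            read_chromatogram(p)

    def test_non_numeric_cell_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("0.0\t1.0\n0.5\toops\n1.0\t1.5\n")
        with pytest.raises(FormatError, match="line 2"):
            read_chromatogram(p)

    def test_round_trip_preserves_values(self, tmp_path):
        chrom = gaussian_chrom(noise=1.0, seed=5)
        path = tmp_path / "rt.tsv"
        write_chromatogram(chrom, path)
        back = read_chromatogram(path)
        assert np.array_equal(back.time, chrom.time)
        assert np.array_equal(back.intensity, chrom.intensity)

    def test_constructor_invariants(self):
        with pytest.raises(ValueError):
            Chromatogram("x", [0.0, 1.0], [1.0])
        with pytest.raises(ValueError):
            Chromatogram("x", [0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            Chromatogram("x", [0.0, 1.0], [1.0, np.nan])


class TestNoise:
    def test_constant_trace_has_zero_noise(self):
        chrom = Chromatogram("c", np.linspace(0, 10, 500), np.full(500, 7.0))
        assert estimate_noise(chrom, (1.0, 5.0)) == 0.0

    def test_recovers_generator_sd_within_ten_percent(self):
        rng = np.random.default_rng(2024)
        t = np.linspace(0, 10, 2000)
        y = rng.normal(0, 0.5, t.size)
        chrom = Chromatogram("n", t, y)
        est = estimate_noise(chrom, (0.0, 10.0))
        assert est == pytest.approx(0.5, rel=0.10)

    def test_window_overlapping_peak_region_rejected(self):
        chrom = gaussian_chrom()
        with pytest.raises(ValueError, match="overlaps"):
            estimate_noise(chrom, (14.0, 16.0), exclude=[(14.5, 15.5)])

    def test_window_outside_grid_rejected(self):
        chrom = gaussian_chrom()
        with pytest.raises(ValueError, match="outside"):
            estimate_noise(chrom, (25.0, 35.0))

    def test_detrends_linear_baseline(self):
        t = np.linspace(0, 10, 2000)
        rng = np.random.default_rng(3)
        chrom = Chromatogram("d", t, 5.0 * t + rng.normal(0, 0.5, t.size))
        assert estimate_noise(chrom, (0.0, 10.0)) == pytest.approx(0.5, rel=0.10)


class TestDetect:
    def test_flat_trace_yields_no_peaks(self):
        chrom = Chromatogram("f", np.linspace(0, 30, 1000), np.zeros(1000))
        assert detect_peaks(chrom, noise=1.0) == []

    def test_standard_mixture_yields_exactly_five_peaks(self):
        cfg = quiet_config(noise_sd=1.0)
        chrom = generate_standard_mixture(cfg, seed=9)
        noise = estimate_noise(chrom, (0.5, 2.0))
        peaks = detect_peaks(chrom, noise)
        assert len(peaks) == 5
        expected = sorted(
            p.retention_time for p in cfg.peak_specs
            if p.analyte_name in synthgen.NAMED_ANALYTES)
        dt = chrom.sampling_interval
        for peak, rt in zip(peaks, expected):
            assert abs(peak.apex_time - rt) <= 2 * dt + 0.05

    def test_peak_below_snr_threshold_ignored(self):
        noise = 1.0
        chrom = gaussian_chrom(height=0.5 * 10 * noise, noise=noise, seed=11)
        assert detect_peaks(chrom, noise, min_snr=10.0) == []

    def test_apexes_sorted_by_time(self, study, study_tables):
        samples, _ = study
        noise, _tables = study_tables
        peaks = detect_peaks(samples[0], noise)
        times = [p.apex_time for p in peaks]
        assert times == sorted(times)

    def test_empty_like_trace_rejected(self):
        chrom = Chromatogram("t", [0.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            detect_peaks(chrom, noise=1.0)


class TestIntegrate:
    def test_closed_form_gaussian_area(self):
        chrom = gaussian_chrom(height=100.0, sigma=0.05)
        area = integrate_peak(chrom, (13.0, 17.0))
        assert area == pytest.approx(100 * 0.05 * np.sqrt(2 * np.pi), rel=5e-3)

    def test_constant_baseline_subtracted(self):
        clean = integrate_peak(gaussian_chrom(), (13.0, 17.0))
        raised = integrate_peak(gaussian_chrom(baseline=50.0), (13.0, 17.0))
        assert raised == pytest.approx(clean, rel=5e-3)

    def test_zero_width_bounds_give_zero(self):
        assert integrate_peak(gaussian_chrom(), (15.0, 15.0)) == 0.0

    def test_reversed_bounds_rejected(self):
        with pytest.raises(ValueError, match="reversed"):
            integrate_peak(gaussian_chrom(), (17.0, 13.0))

    def test_bounds_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            integrate_peak(gaussian_chrom(), (29.0, 31.0))

    def test_area_monotone_in_amount_noiseless(self):
        cfg = quiet_config()
        spec = cfg.peak_specs[3]
        areas = []
        for amount in np.linspace(0.5, 30, 8):
            chrom = simulate_chromatogram([(spec, amount)], cfg, seed=0)
            noise = 0.0
            peaks = detect_peaks(chrom, noise)
            areas.append(peaks[0].area)
        assert np.all(np.diff(areas) > 0)


class TestAreaRecovery:
    def test_within_two_percent_at_snr_50(self):
        """100 isolated peaks at SNR 50-500: every integrated area within 2%
        of the generator truth."""
        cfg = quiet_config(noise_sd=1.0, baseline_amplitude=2.0)
        rng = np.random.default_rng(77)
        errors = []
        for i in range(100):
            rt = rng.uniform(5.0, 25.0)
            sigma = rng.uniform(0.05, 0.15)
            snr = rng.uniform(50.0, 500.0)
            height = snr * cfg.noise_sd
            spec = PeakSpec("p", rt, sigma, 1.0)
            amount = height * sigma * np.sqrt(2 * np.pi)
            chrom = simulate_chromatogram([(spec, amount)], cfg,
                                          seed=int(rng.integers(2**31)))
            peaks = detect_peaks(chrom, cfg.noise_sd)
            assert len(peaks) == 1, f"peak {i} at snr {snr:.0f} not isolated"
            errors.append(abs(peaks[0].area / amount - 1.0))
        assert max(errors) < 0.02


class TestMatching:
    def test_jitter_free_sample_matches_all_ten(self, default_config):
        cfg = quiet_config()
        profile = cfg.class_profiles[0]
        pairs = [(s, synthgen.content_to_concentration(
            profile.mean_contents[s.analyte_name])) for s in cfg.peak_specs]
        chrom = simulate_chromatogram(pairs, cfg, seed=0, sample_id="J")
        peaks = detect_peaks(chrom, 0.0)
        (table,) = match_common_peaks([("J", peaks)],
                                      synthgen.reference_times(cfg))
        assert sorted(table.assignments) == list(range(1, 11))
        assert table.rrt[10] == pytest.approx(1.0)
        assert table.rpa[10] == pytest.approx(1.0)

    def test_suppressed_peak_absent_from_assignments(self, study_tables, study):
        _noise, tables = study_tables
        _samples, truth = study
        c_tables = [t for t in tables
                    if truth.classes[t.sample_id] == "capsule_C"]
        for t in c_tables:
            assert sorted(t.assignments) == [1, 2, 4, 7, 8, 9, 10]

    def test_peaks_outside_tolerance_left_unmatched(self):
        mk = lambda rt: Peak(rt, 10.0, 1.0, rt - 0.2, rt + 0.2)
        (table,) = match_common_peaks(
            [("s", [mk(10.0), mk(11.5), mk(20.0)])],
            [10.0, 13.0, 20.0], rel_tolerance=0.02)
        assert sorted(table.assignments) == [1, 3]
        assert len(table.unmatched) == 1

    def test_missing_reference_peak_flags_sample(self):
        mk = lambda rt: Peak(rt, 10.0, 1.0, rt - 0.2, rt + 0.2)
        (table,) = match_common_peaks([("s", [mk(10.0)])], [10.0, 20.0])
        assert table.flagged and table.rrt is None

    def test_closest_candidate_wins(self):
        near = Peak(10.02, 5.0, 1.0, 9.8, 10.2)
        far = Peak(10.15, 50.0, 10.0, 9.95, 10.35)
        (table,) = match_common_peaks([("s", [near, far])], [10.0, 20.0],
                                      reference_index=1)
        assert table.assignments[1] is near

    def test_matching_invariant_to_sample_order(self, study_tables):
        _noise, tables = study_tables
        reversed_tables = match_common_peaks(
            [(t.sample_id, list(t.assignments.values()) + t.unmatched)
             for t in reversed(tables)],
            synthgen.reference_times(synthgen.default_config()))
        by_id = {t.sample_id: t for t in reversed_tables}
        for t in tables:
            assert sorted(by_id[t.sample_id].assignments) == sorted(t.assignments)
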