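"""Synthetic-chromatogram generator: determinism, closed-form areas, study design."""
import numpy as np
import pytest

from cordyqc import synthgen
from cordyqc.synthgen import (ClassProfile, ConfigurationError, PeakSpec,
                              SimulationConfig, content_to_concentration,
                              default_config, generate_calibration_series,
                              generate_study, simulate_chromatogram)


def quiet_config(seed=0, **kw):
    defaults = dict(noise_sd=0.0, baseline_amplitude=0.0,
                    rt_warp_sd=0.0, rt_peak_jitter_sd=0.0)
    defaults.update(kw)
    return default_config(seed=seed, **defaults)


class TestSimulateChromatogram:
    def test_zero_amount_noiseless_trace_is_flat(self):
        cfg = quiet_config()
        spec = cfg.peak_specs[0]
        chrom = simulate_chromatogram([(spec, 0.0)], cfg, seed=0)
        assert np.allclose(chrom.intensity, 0.0)

    def test_gaussian_area_matches_closed_form(self):
        """A height-100, sigma-0.05 Gaussian integrates to 100*0.05*sqrt(2pi)."""
        cfg = quiet_config()
        spec = PeakSpec("x", 15.0, 0.05, 1.0)
        height = 100.0
        amount = height * 0.05 * np.sqrt(2 * np.pi)  # area = amount * rf(=1)
        chrom = simulate_chromatogram([(spec, amount)], cfg, seed=0)
        area = np.trapezoid(chrom.intensity, chrom.time)
        assert area == pytest.approx(12.533, rel=1e-3)
        assert np.max(chrom.intensity) == pytest.approx(height, rel=1e-4)

    def test_same_seed_identical_different_seed_differs(self):
        cfg = default_config(seed=7)
        spec = cfg.peak_specs[0]
        a = simulate_chromatogram([(spec, 5.0)], cfg, seed=42)
        b = simulate_chromatogram([(spec, 5.0)], cfg, seed=42)
        c = simulate_chromatogram([(spec, 5.0)], cfg, seed=43)
        assert np.array_equal(a.intensity, b.intensity)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_negative_amount_rejected(self):
        cfg = quiet_config()
        with pytest.raises(ValueError):
            simulate_chromatogram([(cfg.peak_specs[0], -1.0)], cfg, seed=0)

    def test_nonpositive_sampling_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(peak_specs=[], class_profiles=[], sampling_interval=0.0)

    def test_noiseless_area_linear_in_amount(self):
        """Integrated area is proportional to amount to within 0.1%."""
        cfg = quiet_config()
        spec = cfg.peak_specs[3]  # uracil
        areas = []
        for amount in (1.0, 5.0, 20.0):
            chrom = simulate_chromatogram([(spec, amount)], cfg, seed=0)
            areas.append(np.trapezoid(chrom.intensity, chrom.time))
        ratios = np.array(areas) / np.array([1.0, 5.0, 20.0])
        assert np.ptp(ratios) / ratios.mean() < 1e-3


class TestCalibrationSeries:
    def test_true_area_follows_reference_uracil_line(self):
        """Level 33.8 ug/mL on Y = 41.219X + 5.2065 gives area 1398.41."""
        cfg = quiet_config()
        spec = next(p for p in cfg.peak_specs if p.analyte_name == "uracil")
        _chroms, truth = generate_calibration_series(
            spec, [0.338, 33.8], slope=41.219, intercept=5.2065, config=cfg)
        assert truth["true_area"].iloc[-1] == pytest.approx(1398.41, abs=0.005)

    def test_zero_level_zero_intercept_gives_zero_area(self):
        cfg = quiet_config()
        spec = cfg.peak_specs[3]
        _chroms, truth = generate_calibration_series(spec, [0.0, 10.0], config=cfg)
        assert truth["true_area"].iloc[0] == 0.0

    def test_negative_level_rejected(self):
        cfg = quiet_config()
        with pytest.raises(ValueError):
            generate_calibration_series(cfg.peak_specs[0], [-1.0, 1.0], config=cfg)

    def test_noiseless_truth_identifies_line_exactly(self):
        from cordyqc.calibration import fit_calibration
        cfg = quiet_config()
        spec = cfg.peak_specs[3]
        levels = [0.338, 1.0, 3.38, 10.0, 20.0, 33.8]
        _c, truth = generate_calibration_series(
            spec, levels, slope=41.219, intercept=5.2065, config=cfg)
        curve = fit_calibration(truth["concentration_ug_ml"], truth["true_area"])
        assert curve.slope == pytest.approx(41.219, rel=1e-9)
        assert curve.intercept == pytest.approx(5.2065, rel=1e-9)


class TestGenerateStudy:
    def test_counts_and_classes(self, study, default_config):
        samples, truth = study
        assert len(samples) == 30
        assert truth.classes.value_counts().to_dict() == {
            "capsule_A": 10, "tablet_B": 10, "capsule_C": 10}

    def test_determinism_full_study(self, default_config, study):
        samples, truth = study
        samples2, truth2 = generate_study(default_config)
        assert all(np.array_equal(a.intensity, b.intensity)
                   for a, b in zip(samples, samples2))
        assert truth.contents.equals(truth2.contents)

    def test_zero_cv_gives_identical_contents_within_class(self):
        cfg = quiet_config(seed=3)
        for p in cfg.class_profiles:
            p.content_cv = 0.0
        _samples, truth = generate_study(cfg)
        for cls, ids in truth.classes.groupby(truth.classes).groups.items():
            block = truth.contents.loc[list(ids)]
            assert (block.nunique() <= 1).all(), cls

    def test_capsule_c_content_ordering_holds_per_sample(self, study):
        """The Bailing-like class keeps adenosine > guanosine > uridine >
        uracil > adenine in every sample."""
        _samples, truth = study
        c_ids = truth.classes[truth.classes == "capsule_C"].index
        block = truth.contents.loc[c_ids]
        order = ["adenosine", "guanosine", "uridine", "uracil", "adenine"]
        for hi, lo in zip(order, order[1:]):
            assert (block[hi] > block[lo]).all(), (hi, lo)

    def test_suppressed_peaks_are_zero(self, study, default_config):
        _samples, truth = study
        names = synthgen.analyte_names(default_config)
        c_ids = truth.classes[truth.classes == "capsule_C"].index
        for idx in (3, 5, 6):
            assert (truth.contents.loc[c_ids, names[idx]] == 0).all()

    def test_empty_class_profiles_rejected(self):
        cfg = quiet_config()
        cfg.class_profiles = []
        with pytest.raises(ConfigurationError):
            generate_study(cfg)

    def test_between_class_cosine_distance_exceeds_within(self):
        """At content_cv = 0.1 every between-class pair of true content
        vectors is farther (cosine distance) than any within-class pair."""
        cfg = quiet_config(seed=2024, noise_sd=1.0)
        for p in cfg.class_profiles:
            p.content_cv = 0.1
        _samples, truth = generate_study(cfg)
        X = truth.contents.to_numpy()
        X = X / np.linalg.norm(X, axis=1, keepdims=True)
        cos = X @ X.T
        labels = truth.classes.to_numpy()
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        within = 1 - cos[same & off]
        between = 1 - cos[~same]
        assert within.mean() < between.mean()
        assert within.max() < between.min()


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = default_config(seed=11)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()

    def test_grid_must_cover_retention_times(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(
                peak_specs=[PeakSpec("x", 40.0, 0.1, 1.0)], class_profiles=[])

    def test_profile_validation(self):
        with pytest.raises(ConfigurationError):
            ClassProfile("bad", {"x": -1.0})
        with pytest.raises(ConfigurationError):
            ClassProfile("bad", {"x": 1.0}, content_cv=1.5)


def test_content_to_concentration_default_preparation():
    """1.00 g in 50 mL: 2.7 mg/g -> 54 ug/mL."""
    assert content_to_concentration(2.7) == pytest.approx(54.0)
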