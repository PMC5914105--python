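"""Synthetic HPLC chromatogram generator with known ground truth.

Emulates a 30-sample study of three fermented *Cordyceps sinensis* product
classes (Jinshuibao-capsule-like, Jinshuibao-tablet-like, Bailing-capsule-like)
carrying 10 common peaks, five of which are the named nucleosides uracil,
uridine, adenine, guanosine and adenosine.  Peaks are Gaussian; the generator
adds detector noise, a small baseline drift and run-to-run retention-time
jitter (a shared multiplicative warp plus per-peak noise), and returns the
true contents, areas and retention times alongside the traces so every
downstream stage is testable against known truth.

Unit conventions: retention times and widths in minutes, contents in mg/g of
product, solution concentrations in ug/mL.  A 1.00 g sample extracted into a
50 mL flask gives C (ug/mL) = content (mg/g) * 1000 / 50.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .chromio import Chromatogram

__all__ = [
    "PeakSpec",
    "ClassProfile",
    "SimulationConfig",
    "GroundTruth",
    "ConfigurationError",
    "default_peak_specs",
    "default_class_profiles",
    "default_config",
    "reference_times",
    "analyte_names",
    "content_to_concentration",
    "simulate_chromatogram",
    "generate_calibration_series",
    "generate_study",
    "generate_standard_mixture",
    "STANDARD_MIXTURE_UG_ML",
    "NAMED_ANALYTES",
]

#: Working standard-mixture concentrations (ug/mL) of the five nucleosides.
STANDARD_MIXTURE_UG_ML: dict[str, float] = {
    "uracil": 33.8,
    "uridine": 93.6,
    "adenine": 30.1,
    "guanosine": 120.8,
    "adenosine": 93.6,
}

#: The five identified common peaks, in elution order.
NAMED_ANALYTES = ("uracil", "uridine", "adenine", "guanosine", "adenosine")

#: mg/g -> ug/mL for the default 1.00 g / 50 mL extraction.
DEFAULT_EXTRACT_VOLUME_ML = 50.0
DEFAULT_SAMPLE_MASS_G = 1.0


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def content_to_concentration(content_mg_g: float,
                             extract_volume_ml: float = DEFAULT_EXTRACT_VOLUME_ML,
                             sample_mass_g: float = DEFAULT_SAMPLE_MASS_G) -> float:
    """Convert product content (mg/g) to extract concentration (ug/mL)."""
    return content_mg_g * sample_mass_g * 1000.0 / extract_volume_ml


@dataclass
class PeakSpec:
    """One common peak: name, position, width and detector response.

    ``response_factor`` is the peak area produced per ug/mL of analyte in the
    injected solution; for the five named nucleosides the defaults are the
    slopes of their area calibration lines.
    """

    analyte_name: str
    retention_time: float  # minutes
    width_sigma: float  # minutes (Gaussian SD)
    response_factor: float  # area units per (ug/mL)

    def __post_init__(self) -> None:
        if self.retention_time <= 0 or self.width_sigma <= 0 or self.response_factor <= 0:
            raise ConfigurationError("PeakSpec fields must be positive")


@dataclass
class ClassProfile:
    """Per-class mean contents (mg/g) and between-sample variability.

    ``content_cv`` is the total between-sample coefficient of variation.  It is
    realized as a dominant shared batch-potency factor plus a small independent
    per-analyte factor (fraction ``analyte_cv_fraction`` of the total), so
    content *orderings* between analytes are stable from sample to sample while
    overall potency varies — the pattern seen in commercial batches.
    ``missing_peaks`` lists 1-based common-peak indices suppressed to zero
    amplitude (e.g. the Bailing-like class lacks three of the unknown peaks).
    """

    class_name: str
    mean_contents: dict[str, float]
    content_cv: float = 0.15
    analyte_cv_fraction: float = 0.312
    missing_peaks: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.mean_contents.values()):
            raise ConfigurationError("mean contents must be non-negative")
        if not (0 <= self.content_cv < 1):
            raise ConfigurationError("content_cv must lie in [0, 1)")
        self.missing_peaks = frozenset(int(i) for i in self.missing_peaks)


@dataclass
class SimulationConfig:
    """Full study design: peaks, classes, grid, noise and jitter levels."""

    peak_specs: list[PeakSpec]
    class_profiles: list[ClassProfile]
    samples_per_class: int = 10
    time_start: float = 0.0
    time_end: float = 30.0
    sampling_interval: float = 0.005  # minutes
    noise_sd: float = 1.0  # detector units
    baseline_amplitude: float = 2.0  # detector units
    baseline_period: float = 40.0  # minutes (slow sine)
    rt_warp_sd: float = 0.003  # shared multiplicative warp SD
    rt_peak_jitter_sd: float = 0.01  # minutes, per peak
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ConfigurationError("sampling interval must be positive")
        if self.samples_per_class < 1:
            raise ConfigurationError("samples_per_class must be >= 1")
        if self.peak_specs:
            rts = [p.retention_time for p in self.peak_specs]
            if min(rts) < self.time_start or max(rts) > self.time_end:
                raise ConfigurationError("time span must cover all retention times")

    def time_grid(self) -> np.ndarray:
        n = int(round((self.time_end - self.time_start) / self.sampling_interval)) + 1
        return self.time_start + self.sampling_interval * np.arange(n)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for p in d["class_profiles"]:
            p["missing_peaks"] = sorted(p["missing_peaks"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["peak_specs"] = [PeakSpec(**p) for p in d["peak_specs"]]
        d["class_profiles"] = [
            ClassProfile(**{**p, "missing_peaks": frozenset(p.get("missing_peaks", ()))})
            for p in d["class_profiles"]
        ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """True per-sample quantities behind a generated study."""

    contents: pd.DataFrame  # sample_id x analyte, mg/g
    areas: pd.DataFrame  # sample_id x analyte, detector area units
    retention_times: pd.DataFrame  # sample_id x analyte, minutes (after jitter)
    classes: pd.Series  # sample_id -> class_name


# ---------------------------------------------------------------------------
# Defaults (the study conditions)
# ---------------------------------------------------------------------------

def _width_at(rt: float) -> float:
    # Peak width grows mildly with retention time, as on an isocratic-to-shallow
    # gradient separation.
    return 0.045 + 0.0035 * rt


def default_peak_specs() -> list[PeakSpec]:
    """Ten common peaks on a 0-30 min window; peaks 4/7/8/9/10 are the named
    nucleosides, whose response factors are their calibration-line slopes."""
    layout = [
        ("unknown_1", 3.0, 30.0),
        ("unknown_2", 4.2, 25.0),
        ("unknown_3", 5.3, 28.0),
        ("uracil", 8.0, 41.219),
        ("unknown_5", 13.5, 26.0),
        ("unknown_6", 20.0, 24.0),
        ("uridine", 22.0, 23.568),
        ("adenine", 23.5, 62.462),
        ("guanosine", 25.5, 22.077),
        ("adenosine", 27.5, 28.112),
    ]
    return [PeakSpec(name, rt, _width_at(rt), rf) for name, rt, rf in layout]


def default_class_profiles() -> list[ClassProfile]:
    """Three product classes with the reported per-class content orderings.

    capsule_A / tablet_B: adenosine > uridine > guanosine > adenine > uracil.
    capsule_C: adenosine > guanosine > uridine > uracil > adenine, with the
    three unknown peaks at 5.3, 13.5 and 20.0 min suppressed.  tablet_B has
    the lowest content of the 3.0 min peak.
    """
    return [
        ClassProfile(
            "capsule_A",
            {
                "unknown_1": 0.45, "unknown_2": 0.35, "unknown_3": 0.50,
                "uracil": 0.155, "unknown_5": 0.40, "unknown_6": 0.55,
                "uridine": 2.50, "adenine": 0.295, "guanosine": 2.25,
                "adenosine": 2.70,
            },
        ),
        ClassProfile(
            "tablet_B",
            {
                "unknown_1": 0.04, "unknown_2": 0.30, "unknown_3": 0.45,
                "uracil": 0.125, "unknown_5": 0.35, "unknown_6": 0.50,
                "uridine": 1.80, "adenine": 0.215, "guanosine": 1.55,
                "adenosine": 1.95,
            },
        ),
        ClassProfile(
            "capsule_C",
            {
                "unknown_1": 0.40, "unknown_2": 0.28, "unknown_3": 0.45,
                "uracil": 0.105, "unknown_5": 0.35, "unknown_6": 0.50,
                "uridine": 1.10, "adenine": 0.072, "guanosine": 1.90,
                "adenosine": 2.35,
            },
            missing_peaks=frozenset({3, 5, 6}),
        ),
    ]


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(
        peak_specs=default_peak_specs(),
        class_profiles=default_class_profiles(),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def reference_times(config: SimulationConfig) -> list[float]:
    """Expected common-peak retention times, sorted (matching anchors)."""
    return sorted(p.retention_time for p in config.peak_specs)


def analyte_names(config: SimulationConfig) -> dict[int, str]:
    """1-based common-peak index -> analyte name, in elution order."""
    specs = sorted(config.peak_specs, key=lambda p: p.retention_time)
    return {i + 1: p.analyte_name for i, p in enumerate(specs)}


# ---------------------------------------------------------------------------
# Simulation primitives
# ---------------------------------------------------------------------------

def _gaussian(t: np.ndarray, rt: float, sigma: float, area: float) -> np.ndarray:
    h = area / (sigma * np.sqrt(2.0 * np.pi))
    return h * np.exp(-0.5 * ((t - rt) / sigma) ** 2)


def _baseline(t: np.ndarray, config: SimulationConfig) -> np.ndarray:
    if config.baseline_amplitude == 0:
        return np.zeros_like(t)
    span = max(config.time_end - config.time_start, 1e-9)
    lin = 0.5 * (t - config.time_start) / span
    sine = 0.5 * np.sin(2.0 * np.pi * t / config.baseline_period)
    return config.baseline_amplitude * (lin + sine)


def simulate_chromatogram(
    peaks: Sequence[tuple[PeakSpec, float]],
    config: SimulationConfig,
    seed: int | None = None,
    sample_id: str = "sample",
    metadata: dict | None = None,
    return_truth: bool = False,
):
    """Simulate one trace from (PeakSpec, amount ug/mL) pairs.

    The trace is the sum of Gaussians (area = amount x response_factor, apex
    jittered by the shared warp and per-peak noise) plus baseline drift and
    white detector noise.  Deterministic given the seed.  With
    ``return_truth=True`` also returns ``(true_rts, true_areas)`` dicts.
    """
    for spec, amount in peaks:
        if amount < 0:
            raise ValueError(f"negative amount for {spec.analyte_name}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = config.time_grid()
    warp = 1.0 + rng.normal(0.0, config.rt_warp_sd)
    y = _baseline(t, config)
    true_rts: dict[str, float] = {}
    true_areas: dict[str, float] = {}
    for spec, amount in peaks:
        rt = spec.retention_time * warp + rng.normal(0.0, config.rt_peak_jitter_sd)
        area = amount * spec.response_factor
        if area > 0:
            y = y + _gaussian(t, rt, spec.width_sigma, area)
        true_rts[spec.analyte_name] = rt
        true_areas[spec.analyte_name] = area
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=t.size)
    chrom = Chromatogram(sample_id, t, y, metadata or {})
    if return_truth:
        return chrom, true_rts, true_areas
    return chrom


def generate_calibration_series(
    peak_spec: PeakSpec,
    levels: Sequence[float],
    *,
    slope: float | None = None,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[list[Chromatogram], pd.DataFrame]:
    """Simulate a standard series for one analyte at the given levels (ug/mL).

    Each standard's true peak area follows the calibration line
    ``slope * level + intercept`` (``slope`` defaults to the spec's response
    factor); the returned truth table holds level and true area per standard.
    """
    levels = [float(c) for c in levels]
    if len(levels) < 2:
        raise ValueError("need at least two calibration levels")
    if any(c < 0 for c in levels):
        raise ValueError("calibration concentrations must be non-negative")
    if slope is None:
        slope = peak_spec.response_factor
    if config is None:
        config = default_config(seed=seed)
    rng = np.random.default_rng(seed)
    chroms: list[Chromatogram] = []
    rows = []
    for i, level in enumerate(levels):
        true_area = slope * level + intercept
        amount = true_area / peak_spec.response_factor
        sub = int(rng.integers(0, 2**31 - 1))
        cfg = _with_noise(config, noise_sd)
        chrom = simulate_chromatogram(
            [(peak_spec, amount)], cfg, seed=sub,
            sample_id=f"{peak_spec.analyte_name}_std{i + 1}",
            metadata={"level_ug_ml": level, "role": "standard"},
        )
        chroms.append(chrom)
        rows.append({"standard": i + 1, "concentration_ug_ml": level,
                     "true_area": true_area})
    return chroms, pd.DataFrame(rows)


def _with_noise(config: SimulationConfig, noise_sd: float) -> SimulationConfig:
    if noise_sd == config.noise_sd:
        return config
    d = config.to_dict()
    d["noise_sd"] = noise_sd
    return SimulationConfig.from_dict(d)


def generate_standard_mixture(
    config: SimulationConfig,
    concentrations: dict[str, float] | None = None,
    *,
    seed: int = 0,
    amount_scale: float = 1.0,
    response_scale: dict[str, float] | None = None,
    sample_id: str = "standard_mixture",
    metadata: dict | None = None,
) -> Chromatogram:
    """Simulate the five-nucleoside standard mixture.

    ``amount_scale`` jointly scales injected amounts (an injection-volume
    change); ``response_scale`` multiplies per-analyte response factors (an
    instrument/column/flow/temperature effect on detector response).
    """
    conc = dict(STANDARD_MIXTURE_UG_ML if concentrations is None else concentrations)
    specs = {p.analyte_name: p for p in config.peak_specs}
    pairs = []
    for name, c in conc.items():
        if name not in specs:
            raise ConfigurationError(f"no PeakSpec for analyte {name!r}")
        spec = specs[name]
        scale = (response_scale or {}).get(name, 1.0)
        eff = PeakSpec(spec.analyte_name, spec.retention_time, spec.width_sigma,
                       spec.response_factor * scale)
        pairs.append((eff, c * amount_scale))
    return simulate_chromatogram(pairs, config, seed=seed, sample_id=sample_id,
                                 metadata=metadata or {"role": "standard_mixture"})


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------

_CLASS_DEFAULT_METADATA = {
    "instrument": "Agilent 1260",
    "column": "Agilent",
    "flow_rate_ml_min": 1.0,
    "temperature_c": 30.0,
    "injection_volume_ul": 10.0,
}


def generate_study(config: SimulationConfig) -> tuple[list[Chromatogram], GroundTruth]:
    """Generate the full multi-class study with ground truth.

    Returns ``3 x samples_per_class`` chromatograms (for the default three
    class profiles) plus a :class:`GroundTruth` with true contents (mg/g),
    areas and jittered retention times per sample.  Contents are drawn per
    class profile: shared batch factor x per-analyte factor, both lognormal,
    suppressed peaks set to zero.  Fully determined by ``config.seed``.
    """
    if not config.class_profiles:
        raise ConfigurationError("class_profiles must not be empty")
    master = np.random.default_rng(config.seed)
    name_by_index = analyte_names(config)
    chroms: list[Chromatogram] = []
    contents_rows, areas_rows, rt_rows, classes = {}, {}, {}, {}
    for profile in config.class_profiles:
        label = profile.class_name.split("_")[-1].upper() or profile.class_name
        cv_total = profile.content_cv
        cv_analyte = cv_total * profile.analyte_cv_fraction
        cv_shared = float(np.sqrt(max(cv_total**2 - cv_analyte**2, 0.0)))
        for s in range(config.samples_per_class):
            sample_id = f"{label}{s + 1}"
            shared = float(np.exp(master.normal(0.0, cv_shared))) if cv_shared else 1.0
            contents: dict[str, float] = {}
            for spec in config.peak_specs:
                base = profile.mean_contents.get(spec.analyte_name, 0.0)
                factor = (
                    float(np.exp(master.normal(0.0, cv_analyte))) if cv_analyte else 1.0
                )
                contents[spec.analyte_name] = base * shared * factor
            for idx in profile.missing_peaks:
                contents[name_by_index[idx]] = 0.0
            pairs = [
                (spec, content_to_concentration(contents[spec.analyte_name]))
                for spec in config.peak_specs
            ]
            sub = int(master.integers(0, 2**31 - 1))
            chrom, true_rts, true_areas = simulate_chromatogram(
                pairs, config, seed=sub, sample_id=sample_id,
                metadata={"class": profile.class_name, "batch": sample_id,
                          **_CLASS_DEFAULT_METADATA},
                return_truth=True,
            )
            chroms.append(chrom)
            contents_rows[sample_id] = contents
            areas_rows[sample_id] = true_areas
            rt_rows[sample_id] = true_rts
            classes[sample_id] = profile.class_name
    order = [name_by_index[i] for i in sorted(name_by_index)]
    truth = GroundTruth(
        contents=pd.DataFrame.from_dict(contents_rows, orient="index")[order],
        areas=pd.DataFrame.from_dict(areas_rows, orient="index")[order],
        retention_times=pd.DataFrame.from_dict(rt_rows, orient="index")[order],
        classes=pd.Series(classes, name="class"),
    )
    return chroms, truth
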