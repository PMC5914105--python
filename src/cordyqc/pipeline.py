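"""End-to-end pipeline: simulate -> peaks -> calibrate -> fingerprint ->
cluster -> QAMS/ESM -> report.

Every stage is a plain function over the library types so the CLI (and tests)
can run stages independently; :func:`run_pipeline` wires them together and,
given an output directory, writes the delimited-text report bundle plus a JSON
run manifest.  All randomness derives from the single configuration seed via
named substreams, so a config+seed pair reproduces the bundle byte for byte.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationCurve, fit_calibration, lod_loq, esm_quantify
from .chromio import (Chromatogram, detect_peaks, estimate_noise,
                      match_common_peaks, peak_tables_frame, read_chromatogram,
                      write_chromatogram, PeakTable)
from .cluster import (cosine_distance_matrix, cut_groups, hca_between_groups,
                      to_newick, to_scipy_linkage, LinkageTree)
from .fingerprint import (build_reference, normalize_retention, peak_vector,
                          similarity_report, class_mean_similarity, trace_vector)
from .qams import (DEFAULT_INTERNAL_STANDARD, RCFEntry, compute_rcf,
                   method_agreement, qams_quantify, rcf_robustness)
from .synthgen import (GroundTruth, SimulationConfig, analyte_names,
                       default_config, generate_calibration_series,
                       generate_standard_mixture, generate_study,
                       reference_times, NAMED_ANALYTES, STANDARD_MIXTURE_UG_ML)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_study", "read_study"]

#: Robustness axes mirroring the standard mixed-condition design:
#: seven injection volumes, three instruments x two columns, three flow rates,
#: three column temperatures.
ROBUSTNESS_AXES: dict[str, list] = {
    "injection_volume": [2, 4, 6, 8, 10, 12, 15],
    "instrument_column": [
        ("Agilent 1100", "Phenomenex"), ("Agilent 1100", "Agilent"),
        ("Agilent 1260", "Phenomenex"), ("Agilent 1260", "Agilent"),
        ("Waters 2695", "Phenomenex"), ("Waters 2695", "Agilent"),
    ],
    "flow_rate": [0.9, 1.0, 1.1],
    "temperature": [25, 30, 35],
}

#: Systematic per-analyte response perturbation (CV) per robustness axis.
#: Injection volume only rescales the injected amount, so its conditions carry
#: a smaller residual perturbation than a change of instrument, column, flow
#: rate or temperature.
_AXIS_RESPONSE_CV = {
    "injection_volume": 0.005,
    "instrument_column": 0.01,
    "flow_rate": 0.01,
    "temperature": 0.01,
}
_RUN_RESPONSE_CV = 0.003  # run-to-run detector fluctuation within a condition
_ROBUSTNESS_REPLICATES = 3


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    simulation: SimulationConfig = field(default_factory=default_config)
    input_dir: str | None = None  # read chromatograms instead of simulating
    outdir: str | None = None
    min_snr: float = 10.0
    match_tolerance: float = 0.02
    internal_standard: str = DEFAULT_INTERNAL_STANDARD
    extract_volume_ml: float = 50.0
    sample_mass_g: float = 1.0
    noise_window: tuple[float, float] = (0.5, 2.0)
    calibration_fractions: tuple[float, ...] = (0.01, 0.02, 0.05, 0.1, 0.5, 1.0)
    do_fingerprint: bool = True
    do_cluster: bool = True
    do_qams: bool = True
    k_groups: int = 2
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["noise_window"] = list(self.noise_window)
        d["calibration_fractions"] = list(self.calibration_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "noise_window" in d:
            d["noise_window"] = tuple(d["noise_window"])
        if "calibration_fractions" in d:
            d["calibration_fractions"] = tuple(d["calibration_fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    """Everything one run produced, as dataframes plus the raw objects."""

    samples: list[Chromatogram]
    truth: GroundTruth | None
    noise: float
    peak_tables: list[PeakTable]
    peak_table_frame: pd.DataFrame
    curves: dict[str, CalibrationCurve]
    calibration_frame: pd.DataFrame
    similarity: pd.DataFrame | None
    class_similarity: pd.DataFrame | None
    tree: LinkageTree | None
    groups: dict[str, int] | None
    rcf_summaries: pd.DataFrame | None
    rcf_grand_means: dict[str, float] | None
    contents: pd.DataFrame | None
    agreement: pd.DataFrame | None
    manifest: dict


def _substream(seed: int, key: int) -> int:
    """Deterministic named substream seed below 2**31."""
    return int(np.random.SeedSequence((seed, key)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def peaks_stage(samples: list[Chromatogram], config: RunConfig):
    """Noise estimate, peak detection and common-peak matching for all samples."""
    ref_times = reference_times(config.simulation)
    noise = estimate_noise(samples[0], config.noise_window)
    detected = [
        (c.sample_id, detect_peaks(c, noise, min_snr=config.min_snr)) for c in samples
    ]
    names = analyte_names(config.simulation)
    ref_index = next(i for i, n in names.items() if n == config.internal_standard)
    tables = match_common_peaks(detected, ref_times, reference_index=ref_index,
                                rel_tolerance=config.match_tolerance)
    return noise, tables


def calibration_stage(config: RunConfig, seed: int) -> tuple[dict[str, CalibrationCurve], pd.DataFrame]:
    """Fit per-analyte area and height calibrations from simulated standard
    series, and derive S/N-based LOD/LOQ from the measured noise."""
    sim = config.simulation
    specs = {p.analyte_name: p for p in sim.peak_specs}
    curves: dict[str, CalibrationCurve] = {}
    rows = []
    for k, analyte in enumerate(NAMED_ANALYTES):
        spec = specs[analyte]
        stock = STANDARD_MIXTURE_UG_ML[analyte]
        levels = [f * stock for f in config.calibration_fractions]
        chroms, _truth = generate_calibration_series(
            spec, levels, noise_sd=sim.noise_sd, config=sim,
            seed=_substream(seed, 100 + k),
        )
        noise = estimate_noise(chroms[-1], config.noise_window)
        areas, heights = [], []
        for chrom in chroms:
            peaks = detect_peaks(chrom, noise, min_snr=3.0)
            if not peaks:
                raise RuntimeError(f"calibration standard for {analyte} lost its peak")
            peak = max(peaks, key=lambda p: p.area)
            areas.append(peak.area)
            heights.append(peak.height)
        curve = fit_calibration(levels, areas, analyte=analyte)
        height_fit = fit_calibration(levels, heights, analyte=analyte)
        curve.height_slope = height_fit.slope
        curve.lod, curve.loq = lod_loq(noise, height_fit.slope)
        curves[analyte] = curve
        rows.append({
            "analyte": analyte, "slope": curve.slope, "intercept": curve.intercept,
            "r_squared": curve.r_squared,
            "range_low_ug_ml": curve.linear_range[0],
            "range_high_ug_ml": curve.linear_range[1],
            "lod_ug_ml": curve.lod, "loq_ug_ml": curve.loq,
        })
    return curves, pd.DataFrame(rows)


def fingerprint_stage(samples: list[Chromatogram], tables: list[PeakTable],
                      config: RunConfig):
    """Retention-normalized trace fingerprints and similarity vs the mean
    chromatogram of the whole study."""
    ref_times = reference_times(config.simulation)
    by_id = {t.sample_id: t for t in tables}
    vectors = []
    for chrom in samples:
        table = by_id[chrom.sample_id]
        if table.flagged or len(table.assignments) < 2:
            logger.warning("sample %s skipped in fingerprinting", chrom.sample_id)
            continue
        normalized = normalize_retention(chrom, table, ref_times)
        vectors.append(trace_vector(normalized))
    reference = build_reference(vectors)
    report = similarity_report(vectors, reference)
    return vectors, reference, report, class_mean_similarity(report)


def cluster_stage(tables: list[PeakTable], config: RunConfig,
                  classes: pd.Series | None = None):
    """HCA of the common-peak-area fingerprints (cosine distance, UPGMA)."""
    n_common = len(config.simulation.peak_specs)
    vectors = [
        peak_vector(t, n_common,
                    class_label=None if classes is None else classes.get(t.sample_id))
        for t in tables
    ]
    dm = cosine_distance_matrix(vectors)
    tree = hca_between_groups(dm)
    groups = cut_groups(tree, config.k_groups)
    return dm, tree, groups


def rcf_stage(config: RunConfig, seed: int):
    """Relative correction factors under the four robustness axes.

    Each condition is measured on ``n=3`` replicate standard-mixture runs;
    the per-condition F is the replicate mean, and per-axis summaries report
    the mean and sample-SD RSD across conditions.  The grand mean F per
    analyte (across all conditions of all axes) is what batch quantification
    uses.
    """
    sim = config.simulation
    istd = config.internal_standard
    entries: list[RCFEntry] = []
    summaries = []
    for a, (axis, levels) in enumerate(ROBUSTNESS_AXES.items()):
        axis_rng = np.random.default_rng(_substream(seed, 200 + a))
        axis_entries: list[RCFEntry] = []
        for level in levels:
            response_scale = {
                name: float(np.exp(axis_rng.normal(0.0, _AXIS_RESPONSE_CV[axis])))
                for name in NAMED_ANALYTES
            }
            amount_scale = (level / 10.0) if axis == "injection_volume" else 1.0
            f_reps: dict[str, list[float]] = {n: [] for n in NAMED_ANALYTES if n != istd}
            for rep in range(_ROBUSTNESS_REPLICATES):
                run_scale = {
                    name: response_scale[name]
                    * float(np.exp(axis_rng.normal(0.0, _RUN_RESPONSE_CV)))
                    for name in NAMED_ANALYTES
                }
                chrom = generate_standard_mixture(
                    sim, seed=int(axis_rng.integers(0, 2**31 - 1)),
                    amount_scale=amount_scale, response_scale=run_scale,
                    sample_id=f"std_{axis}_{level}_{rep + 1}",
                )
                noise = estimate_noise(chrom, config.noise_window)
                detected = detect_peaks(chrom, noise, min_snr=config.min_snr)
                ref_times = [p.retention_time for p in sim.peak_specs
                             if p.analyte_name in NAMED_ANALYTES]
                names = {i + 1: n for i, n in enumerate(
                    sorted(NAMED_ANALYTES,
                           key=lambda n: next(p.retention_time for p in sim.peak_specs
                                              if p.analyte_name == n)))}
                (table,) = match_common_peaks(
                    [(chrom.sample_id, detected)], sorted(ref_times),
                    reference_index=next(i for i, n in names.items() if n == istd),
                    rel_tolerance=config.match_tolerance,
                )
                area = {names[i]: p.area for i, p in table.assignments.items()}
                for name in f_reps:
                    f_reps[name].append(compute_rcf(
                        STANDARD_MIXTURE_UG_ML[name], STANDARD_MIXTURE_UG_ML[istd],
                        area[name], area[istd],
                    ))
            for name, reps in f_reps.items():
                axis_entries.append(RCFEntry(
                    analyte=name, f_value=float(np.mean(reps)),
                    internal_standard=istd, condition={axis: level},
                ))
        entries.extend(axis_entries)
        summaries.append(rcf_robustness(axis_entries, condition_axis=axis))
    summary = pd.concat(summaries, ignore_index=True)
    grand = {
        name: float(np.mean([e.f_value for e in entries if e.analyte == name]))
        for name in NAMED_ANALYTES if name != istd
    }
    return summary, grand


def quant_stage(tables: list[PeakTable], curves: dict[str, CalibrationCurve],
                grand_f: dict[str, float], config: RunConfig):
    """ESM and QAMS contents per sample/analyte plus the agreement report.

    The internal standard is always ESM-quantified; its QAMS record equals the
    ESM one by construction.
    """
    sim = config.simulation
    names = analyte_names(sim)
    index_of = {n: i for i, n in names.items()}
    istd = config.internal_standard
    rows = []
    for table in tables:
        if table.flagged:
            logger.warning("sample %s: internal standard missing, skipped",
                           table.sample_id)
            continue
        a_s = table.assignments[index_of[istd]].area
        c_s = curves[istd].invert(a_s)
        for analyte in NAMED_ANALYTES:
            peak = table.assignments.get(index_of[analyte])
            if peak is None:
                continue
            esm_content = esm_quantify(
                peak.area, curves[analyte],
                extract_volume_ml=config.extract_volume_ml,
                sample_mass_g=config.sample_mass_g,
            )
            rows.append({"sample_id": table.sample_id, "analyte": analyte,
                         "method": "ESM", "content_mg_g": esm_content})
            if analyte == istd:
                if grand_f:
                    rows.append({"sample_id": table.sample_id, "analyte": analyte,
                                 "method": "QAMS", "content_mg_g": esm_content})
            elif analyte in grand_f:
                rec = qams_quantify(
                    peak.area, a_s, c_s, grand_f[analyte],
                    extract_volume_ml=config.extract_volume_ml,
                    sample_mass_g=config.sample_mass_g,
                    sample_id=table.sample_id, analyte=analyte,
                )
                rows.append({"sample_id": table.sample_id, "analyte": analyte,
                             "method": "QAMS", "content_mg_g": rec.content_mg_g})
    contents = pd.DataFrame(rows)
    agreements = []
    for analyte in NAMED_ANALYTES:
        if analyte == istd:
            continue
        sub = contents[contents["analyte"] == analyte]
        q = sub[sub["method"] == "QAMS"].set_index("sample_id")["content_mg_g"]
        e = sub[sub["method"] == "ESM"].set_index("sample_id")["content_mg_g"]
        common = q.index.intersection(e.index)
        if len(common) < 2:
            continue
        rep = method_agreement(q.loc[common], e.loc[common], analyte=analyte)
        agreements.append({"analyte": analyte, "cosine": rep.cosine,
                           "correlation": rep.correlation})
    return contents, pd.DataFrame(agreements)


# ---------------------------------------------------------------------------
# Study I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = ["sample_id", "class", "batch", "instrument", "column",
                 "flow_rate_ml_min", "temperature_c", "injection_volume_ul"]


def write_study(samples: list[Chromatogram], outdir: str | Path) -> None:
    """Write chromatograms as two-column text plus a metadata sidecar table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for chrom in samples:
        write_chromatogram(chrom, outdir / f"{chrom.sample_id}.tsv")
        rows.append({"sample_id": chrom.sample_id,
                     **{k: chrom.metadata.get(k, "") for k in _META_COLUMNS[1:]}})
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(
        outdir / "metadata.tsv", sep="\t", index=False)


def read_study(indir: str | Path) -> list[Chromatogram]:
    """Read a directory written by :func:`write_study`."""
    indir = Path(indir)
    meta_path = indir / "metadata.tsv"
    meta = {}
    if meta_path.exists():
        df = pd.read_csv(meta_path, sep="\t")
        meta = {str(r["sample_id"]): r.drop("sample_id").to_dict()
                for _, r in df.iterrows()}
    reserved = {"metadata.tsv", "ground_truth_contents.tsv"}
    samples = []
    for path in sorted(indir.glob("*.tsv")):
        if path.name in reserved:
            continue
        if meta and path.stem not in meta:
            continue  # sidecar tables are not chromatograms
        samples.append(read_chromatogram(path, metadata=meta.get(path.stem, {})))
    if not samples:
        raise FileNotFoundError(f"no chromatograms found under {indir}")
    return samples


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every enabled stage and (if ``config.outdir`` is set) write the
    report bundle."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    sim = config.simulation
    seed = sim.seed
    truth: GroundTruth | None = None
    if config.input_dir:
        logger.info("stage=load reading chromatograms from %s", config.input_dir)
        samples = read_study(config.input_dir)
    else:
        logger.info("stage=simulate seed=%d", seed)
        samples, truth = generate_study(sim)

    logger.info("stage=peaks detecting and matching common peaks")
    noise, tables = peaks_stage(samples, config)
    names = analyte_names(sim)
    pt_frame = peak_tables_frame(tables, names)

    logger.info("stage=calibrate fitting calibration curves")
    curves, cal_frame = calibration_stage(config, seed)

    sim_report = class_sim = None
    if config.do_fingerprint:
        logger.info("stage=fingerprint similarity analysis")
        _vecs, _ref, sim_report, class_sim = fingerprint_stage(samples, tables, config)

    tree = groups = None
    if config.do_cluster:
        logger.info("stage=cluster HCA with cosine distance / average linkage")
        classes = truth.classes if truth is not None else None
        _dm, tree, groups = cluster_stage(tables, config, classes)

    rcf_summary = grand_f = None
    contents = agreement = None
    if config.do_qams:
        logger.info("stage=qams RCF robustness and single-marker quantification")
        rcf_summary, grand_f = rcf_stage(config, seed)
        contents, agreement = quant_stage(tables, curves, grand_f, config)
    else:
        contents, _ = quant_stage(tables, curves, {}, config)

    parameters = config.to_dict()
    parameters.pop("outdir", None)  # paths vary per run; keep manifests comparable
    parameters.pop("input_dir", None)
    manifest = {
        "cordyqc_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "n_samples": len(samples),
        "noise_estimate": noise,
        "parameters": parameters,
    }
    result = PipelineResult(
        samples=samples, truth=truth, noise=noise, peak_tables=tables,
        peak_table_frame=pt_frame, curves=curves, calibration_frame=cal_frame,
        similarity=sim_report, class_similarity=class_sim, tree=tree,
        groups=groups, rcf_summaries=rcf_summary, rcf_grand_means=grand_f,
        contents=contents, agreement=agreement, manifest=manifest,
    )
    if config.outdir:
        write_artifacts(result, config.outdir)
    return result


def write_artifacts(result: PipelineResult, outdir: str | Path) -> None:
    """Write the delimited-text report bundle and the JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")

    _tsv(result.peak_table_frame, "peak_table.tsv")
    _tsv(result.calibration_frame, "calibration.tsv")
    if result.similarity is not None:
        _tsv(result.similarity, "similarity.tsv")
        _tsv(result.class_similarity, "class_similarity.tsv")
    if result.tree is not None:
        Z = to_scipy_linkage(result.tree)
        _tsv(pd.DataFrame(Z, columns=["cluster_a", "cluster_b", "height", "size"]),
             "linkage.tsv")
        (outdir / "dendrogram.nwk").write_text(to_newick(result.tree) + "\n")
        _tsv(pd.DataFrame(sorted(result.groups.items()),
                          columns=["sample_id", "group"]), "groups.tsv")
    if result.rcf_summaries is not None:
        _tsv(result.rcf_summaries, "rcf_summary.tsv")
    if result.contents is not None:
        _tsv(result.contents, "contents.tsv")
    if result.agreement is not None:
        _tsv(result.agreement, "agreement.tsv")
    if result.truth is not None:
        truth = result.truth.contents.copy()
        truth.insert(0, "sample_id", truth.index)
        _tsv(truth.reset_index(drop=True), "ground_truth_contents.tsv")
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True, default=str) + "\n")
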