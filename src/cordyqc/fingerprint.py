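"""Fingerprint construction and similarity analysis.

A sample's fingerprint is either its full standardized trace (retention-time
normalized, baseline-subtracted) or the vector of its common-peak areas.  The
reference fingerprint is the pointwise arithmetic mean ("mean chromatogram");
each sample is scored against it with the cosine of the vector angle and the
Pearson correlation coefficient.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chromio import Chromatogram, PeakTable

__all__ = [
    "FingerprintVector",
    "normalize_retention",
    "trace_vector",
    "peak_vector",
    "build_reference",
    "similarity",
    "similarity_report",
]


@dataclass
class FingerprintVector:
    """A sample's fingerprint: a trace or common-peak-area vector."""

    sample_id: str
    values: np.ndarray
    mode: str = "trace"  # "trace" | "peaks"
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("fingerprint values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fingerprint values must be finite")
        if self.mode not in ("trace", "peaks"):
            raise ValueError("mode must be 'trace' or 'peaks'")


def _interp_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation, extrapolating with the edge slopes."""
    y = np.interp(x, xp, fp)
    if xp.size >= 2:
        left = x < xp[0]
        if left.any():
            slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
            y[left] = fp[0] + slope * (x[left] - xp[0])
        right = x > xp[-1]
        if right.any():
            slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
            y[right] = fp[-1] + slope * (x[right] - xp[-1])
    return y


def normalize_retention(
    chrom: Chromatogram,
    matched: PeakTable,
    reference_times: Sequence[float],
) -> Chromatogram:
    """Warp a trace so matched peak apexes land on the expected retention times.

    The warp is piecewise linear through the (observed apex, expected time)
    anchors, extrapolated with the nearest segment's slope, and the intensity
    is resampled back onto the original grid by linear interpolation.  At
    least two matched anchors are required.
    """
    rt = np.asarray(reference_times, dtype=float)
    anchors = [
        (matched.assignments[idx].apex_time, rt[idx - 1])
        for idx in sorted(matched.assignments)
        if 1 <= idx <= rt.size
    ]
    if len(anchors) < 2:
        raise ValueError("retention normalization needs at least two matched anchors")
    obs = np.array([a[0] for a in anchors])
    exp = np.array([a[1] for a in anchors])
    order = np.argsort(exp)
    obs, exp = obs[order], exp[order]
    if np.any(np.diff(obs) <= 0):
        raise ValueError("anchor apex times must be strictly increasing")
    # inverse warp: for each target grid time, the source time to sample from
    src = _interp_extrap(chrom.time, exp, obs)
    values = np.interp(src, chrom.time, chrom.intensity)
    return Chromatogram(chrom.sample_id, chrom.time.copy(), values,
                        dict(chrom.metadata))


def trace_vector(chrom: Chromatogram, baseline: str = "median") -> FingerprintVector:
    """Full-trace fingerprint, optionally baseline-subtracted.

    ``baseline='median'`` subtracts the trace median — a cheap but effective
    background removal when most of the grid is baseline, as in a
    well-separated fingerprint; ``baseline='none'`` keeps the raw trace.
    """
    y = chrom.intensity
    if baseline == "median":
        y = y - np.median(y)
    elif baseline != "none":
        raise ValueError("baseline must be 'median' or 'none'")
    return FingerprintVector(chrom.sample_id, y,
                             mode="trace",
                             class_label=chrom.metadata.get("class"))


def peak_vector(table: PeakTable, n_common: int,
                class_label: str | None = None) -> FingerprintVector:
    """Common-peak-area fingerprint (missing peaks contribute zero)."""
    v = np.zeros(n_common)
    for idx, peak in table.assignments.items():
        if 1 <= idx <= n_common:
            v[idx - 1] = peak.area
    return FingerprintVector(table.sample_id, v, mode="peaks",
                             class_label=class_label)


def build_reference(vectors: Sequence[FingerprintVector],
                    method: str = "mean") -> FingerprintVector:
    """Reference fingerprint: the pointwise mean (or median) of the samples."""
    if not vectors:
        raise ValueError("need at least one fingerprint")
    mode = vectors[0].mode
    dim = vectors[0].values.size
    for v in vectors:
        if v.mode != mode or v.values.size != dim:
            raise ValueError("all fingerprints must share mode and dimension")
    stack = np.vstack([v.values for v in vectors])
    if method == "mean":
        ref = stack.mean(axis=0)
    elif method == "median":
        ref = np.median(stack, axis=0)
    else:
        raise ValueError("method must be 'mean' or 'median'")
    return FingerprintVector("reference", ref, mode=mode)


def similarity(sample: FingerprintVector,
               reference: FingerprintVector) -> tuple[float, float]:
    """Cosine similarity and Pearson correlation of a sample vs the reference.

    A zero-norm sample is flagged with a warning and scored as NaN.
    """
    x, y = sample.values, reference.values
    if x.size != y.size:
        raise ValueError("sample and reference must share dimension")
    ny = np.linalg.norm(y)
    if ny == 0:
        raise ValueError("reference fingerprint must not be all-zero")
    nx = np.linalg.norm(x)
    if nx == 0:
        warnings.warn(f"sample {sample.sample_id}: zero-norm fingerprint, "
                      "similarity undefined", stacklevel=2)
        return float("nan"), float("nan")
    cosine = float(np.dot(x, y) / (nx * ny))
    if np.std(x) == 0 or np.std(y) == 0:
        correlation = float("nan")
    else:
        correlation = float(np.corrcoef(x, y)[0, 1])
    return cosine, correlation


def similarity_report(vectors: Sequence[FingerprintVector],
                      reference: FingerprintVector) -> pd.DataFrame:
    """Per-sample cosine/correlation vs the reference, with class labels."""
    rows = []
    for v in vectors:
        cos, corr = similarity(v, reference)
        rows.append({"sample_id": v.sample_id, "class": v.class_label or "",
                     "cosine": cos, "correlation": corr})
    return pd.DataFrame(rows)


def class_mean_similarity(report: pd.DataFrame) -> pd.DataFrame:
    """Class-level similarity values: mean per-sample cosine by class."""
    return (report.groupby("class", as_index=False)
            .agg(mean_cosine=("cosine", "mean"),
                 mean_correlation=("correlation", "mean"),
                 n=("sample_id", "count")))
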