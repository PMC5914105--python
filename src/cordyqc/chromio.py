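"""Chromatogram I/O, noise estimation, peak detection, integration and common-peak matching.

A :class:`Chromatogram` is a strictly increasing time grid (minutes) with a
detector-response trace and free-form acquisition metadata.  Detected peaks are
integrated with a chord baseline anchored on robust local baseline estimates,
then matched to the study's expected common-peak retention times, yielding
:class:`PeakTable` objects with relative retention times (RRT) and relative
peak areas (RPA) against the internal reference peak (adenosine by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "Chromatogram",
    "Peak",
    "PeakTable",
    "FormatError",
    "read_chromatogram",
    "write_chromatogram",
    "estimate_noise",
    "detect_peaks",
    "integrate_peak",
    "match_common_peaks",
]


class FormatError(ValueError):
    """A chromatogram file violates the two-column time/intensity format."""


@dataclass
class Chromatogram:
    """Time–intensity trace of one HPLC run.

    Parameters
    ----------
    sample_id : str
        Identifier of the run (e.g. ``"A3"`` for the third capsule-A sample).
    time : array-like
        Retention-time grid in minutes, strictly increasing.
    intensity : array-like
        Detector response (arbitrary units, e.g. mAU at 260 nm), same length
        as ``time``.
    metadata : dict
        Acquisition context: product class, batch, instrument, column,
        flow rate (mL/min), column temperature (deg C), injection volume (uL).
    """

    sample_id: str
    time: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise ValueError("a chromatogram needs at least two points")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.intensity))):
            raise ValueError("time and intensity must be finite")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.time.size)

    @property
    def sampling_interval(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass
class Peak:
    """One integrated chromatographic peak (times in minutes)."""

    apex_time: float
    height: float
    area: float
    left_bound: float
    right_bound: float

    def __post_init__(self) -> None:
        if not (self.left_bound < self.apex_time < self.right_bound):
            raise ValueError("peak bounds must bracket the apex")
        if self.height <= 0 or self.area <= 0:
            raise ValueError("peak height and area must be positive")


@dataclass
class PeakTable:
    """Common-peak assignments for one sample.

    ``assignments`` maps 1-based common-peak indices to the detected
    :class:`Peak`; ``rrt``/``rpa`` hold relative retention times and relative
    peak areas against the reference peak, or ``None`` when the reference peak
    was not found (then ``flagged`` is set).
    """

    sample_id: str
    assignments: dict[int, Peak]
    unmatched: list[Peak]
    reference_index: int
    rrt: dict[int, float] | None
    rpa: dict[int, float] | None
    flagged: bool = False

    def to_frame(self, analyte_names: dict[int, str] | None = None) -> pd.DataFrame:
        rows = []
        for idx in sorted(self.assignments):
            p = self.assignments[idx]
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "common_index": idx,
                    "analyte": (analyte_names or {}).get(idx, ""),
                    "rt_min": p.apex_time,
                    "rrt": self.rrt.get(idx) if self.rrt else np.nan,
                    "height": p.height,
                    "area": p.area,
                    "rpa": self.rpa.get(idx) if self.rpa else np.nan,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chromatogram(
    source: str | Path, sample_id: str | None = None, metadata: dict | None = None
) -> Chromatogram:
    """Read a two-column delimited text file (time_min, intensity).

    A single header line is allowed.  Raises :class:`FormatError` with the
    offending line number for non-numeric cells and for non-monotone time.
    """
    path = Path(source)
    try:
        # dtype=str + explicit float(): pandas' sniffing python engine parses
        # floats lossily, which would break full-precision round trips
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         comment="#", skip_blank_lines=True, dtype=str)
    except Exception as exc:  # pragma: no cover - delegated parsing failures
        raise FormatError(f"{path}: cannot parse as delimited text ({exc})") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns, found {df.shape[1]}")
    try:
        float(df.iat[0, 0]), float(df.iat[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:]  # header line
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    cols = []
    for c in (0, 1):
        vals = np.empty(len(df), dtype=float)
        for pos, (idx, raw) in enumerate(df[c].items()):
            try:
                vals[pos] = float(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric value in column {c + 1}, "
                    f"line {int(idx) + 1}"
                ) from None
        cols.append(vals)
    try:
        return Chromatogram(sample_id or path.stem, cols[0], cols[1], metadata or {})
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_chromatogram(chrom: Chromatogram, destination: str | Path) -> None:
    """Write ``chrom`` as tab-separated text with full float precision."""
    arr = np.column_stack([chrom.time, chrom.intensity])
    np.savetxt(destination, arr, delimiter="\t", header="time_min\tintensity",
               comments="", fmt="%.17g")


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def estimate_noise(
    chrom: Chromatogram,
    window: tuple[float, float],
    exclude: Iterable[tuple[float, float]] = (),
) -> float:
    """Robust noise amplitude in a peak-free time window.

    The window is linearly detrended (tolerates slow baseline drift) and the
    spread of the residual is estimated as the median absolute deviation
    scaled to the standard deviation of a normal distribution.  ``exclude``
    lists known peak regions; a window overlapping any of them is rejected.
    """
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValueError("noise window must have positive width")
    if t0 < chrom.time[0] - 1e-9 or t1 > chrom.time[-1] + 1e-9:
        raise ValueError("noise window lies outside the time grid")
    for a, b in exclude:
        if t0 < b and a < t1:
            raise ValueError(f"noise window overlaps peak region ({a:g}, {b:g})")
    mask = (chrom.time >= t0) & (chrom.time <= t1)
    if int(mask.sum()) < 20:
        raise ValueError("noise window must contain at least 20 grid points")
    t, y = chrom.time[mask], chrom.intensity[mask]
    if np.ptp(y) == 0:
        return 0.0
    resid = y - np.polyval(np.polyfit(t, y, 1), t)
    mad = float(np.median(np.abs(resid - np.median(resid))))
    return 1.4826 * mad


# ---------------------------------------------------------------------------
# Detection & integration
# ---------------------------------------------------------------------------

def _smooth(y: np.ndarray, points: int) -> np.ndarray:
    """Centred moving average with reflective edges (odd window)."""
    if points <= 1:
        return y.astype(float)
    if points % 2 == 0:
        points += 1
    pad = points // 2
    yp = np.pad(y, pad, mode="reflect")
    return np.convolve(yp, np.full(points, 1.0 / points), mode="valid")


def _local_baseline(t: np.ndarray, y: np.ndarray, bound: float, halfwidth: float,
                    side: int) -> tuple[float, float]:
    """Robust local baseline anchor for one peak bound.

    The window extends *outward* (away from the apex) so it stays clear of the
    peak itself; the anchor is (window centre, median intensity), which keeps
    the estimate unbiased under a locally linear drift when the chord is drawn
    through the two anchors.
    """
    if side < 0:
        lo, hi = bound - halfwidth, bound
    else:
        lo, hi = bound, bound + halfwidth
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        return bound, float(np.interp(bound, t, y))
    return float(t[mask].mean()), float(np.median(y[mask]))


def _chord(tt: np.ndarray, anchor_l: tuple[float, float],
           anchor_r: tuple[float, float]) -> np.ndarray:
    (tl, yl), (tr, yr) = anchor_l, anchor_r
    if tr == tl:
        return np.full_like(tt, 0.5 * (yl + yr))
    slope = (yr - yl) / (tr - tl)
    return yl + slope * (tt - tl)


def _integrate(chrom: Chromatogram, left: float, right: float,
               baseline_halfwidth: float) -> tuple[float, float, float]:
    t, y = chrom.time, chrom.intensity
    if right < left:
        raise ValueError("integration bounds are reversed")
    if left < t[0] - 1e-9 or right > t[-1] + 1e-9:
        raise ValueError("integration bounds lie outside the time grid")
    if right == left:
        base = float(np.interp(left, t, y))
        return 0.0, base, base
    anchor_l = _local_baseline(t, y, left, baseline_halfwidth, side=-1)
    anchor_r = _local_baseline(t, y, right, baseline_halfwidth, side=+1)
    mask = (t >= left) & (t <= right)
    tt, yy = t[mask], y[mask]
    bl = float(_chord(np.array([left]), anchor_l, anchor_r)[0])
    br = float(_chord(np.array([right]), anchor_l, anchor_r)[0])
    if tt.size < 2:
        return 0.0, bl, br
    area = float(np.trapezoid(yy - _chord(tt, anchor_l, anchor_r), tt))
    return area, bl, br


def integrate_peak(
    chrom: Chromatogram,
    peak: "Peak | tuple[float, float]",
    baseline_halfwidth: float = 0.5,
) -> float:
    """Trapezoidal area above a chord baseline between the peak bounds.

    The chord endpoints are robust (outward-median) baseline estimates at the
    bounds, which makes the integral insensitive to a constant or slowly
    varying baseline offset.  ``peak`` may be a :class:`Peak` or a
    ``(left, right)`` pair of times in minutes.
    """
    if isinstance(peak, Peak):
        left, right = peak.left_bound, peak.right_bound
    else:
        left, right = float(peak[0]), float(peak[1])
    area, _, _ = _integrate(chrom, left, right, baseline_halfwidth)
    return area


def detect_peaks(
    chrom: Chromatogram,
    noise: float,
    min_snr: float = 10.0,
    smooth_points: int = 11,
    sigma_cap: float = 4.0,
    baseline_halfwidth: float = 0.5,
) -> list[Peak]:
    """Detect and integrate peaks with height >= ``min_snr`` x ``noise``.

    Local maxima are located on a lightly smoothed trace (prominence filter),
    apexes are refined on the raw trace, and bounds are placed at the flanking
    valleys, capped at ``sigma_cap`` estimated Gaussian widths from the apex.
    Peaks are returned sorted by retention time.
    """
    if min_snr <= 0:
        raise ValueError("min_snr must be positive")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    t, y = chrom.time, chrom.intensity
    if t.size < 3:
        raise ValueError("trace too short for peak detection")
    ys = _smooth(y, smooth_points)
    threshold = min_snr * noise
    prominence = threshold if threshold > 0 else 1e-9 * max(1.0, float(np.max(np.abs(ys))))
    idx, props = find_peaks(ys, prominence=prominence)
    if idx.size == 0:
        return []
    dt = chrom.sampling_interval
    peaks: list[Peak] = []
    for k, i in enumerate(idx):
        lo = int(idx[k - 1]) if k > 0 else 0
        hi = int(idx[k + 1]) if k + 1 < idx.size else t.size - 1
        # Gaussian width from the half-prominence crossing on the smoothed trace
        half = ys[i] - props["prominences"][k] / 2.0
        l = i
        while l > lo and ys[l] > half:
            l -= 1
        r = i
        while r < hi and ys[r] > half:
            r += 1
        sigma = max(t[r] - t[l], 2 * dt) / 2.3548
        # bounds: flanking valleys, capped at +- sigma_cap * sigma
        vl = lo + int(np.argmin(ys[lo:i + 1]))
        vr = i + int(np.argmin(ys[i:hi + 1]))
        left = max(t[vl], t[i] - sigma_cap * sigma)
        right = min(t[vr], t[i] + sigma_cap * sigma)
        # refine the apex on the raw trace within the smoothing window
        w = smooth_points // 2 + 1
        j0 = max(i - w, 0)
        j = j0 + int(np.argmax(y[j0:i + w + 1]))
        apex = t[j]
        left = min(left, apex - dt)
        right = max(right, apex + dt)
        area, bl, br = _integrate(chrom, left, right, baseline_halfwidth)
        height = float(y[j] - np.interp(apex, [left, right], [bl, br]))
        if height < threshold or height <= 0 or area <= 0:
            continue
        peaks.append(Peak(float(apex), height, area, float(left), float(right)))
    return peaks


# ---------------------------------------------------------------------------
# Common-peak matching
# ---------------------------------------------------------------------------

def match_common_peaks(
    samples: Sequence[tuple[str, Sequence[Peak]]],
    reference_times: Sequence[float],
    reference_index: int | None = None,
    rel_tolerance: float = 0.02,
) -> list[PeakTable]:
    """Assign detected peaks to expected common-peak retention times.

    Each peak goes to the nearest expected time if the relative deviation is
    within ``rel_tolerance``; at most one peak per common index is kept per
    sample (closest wins; exact ties go to the larger area, logged).  RRT and
    RPA are computed against the reference peak (``reference_index``, 1-based;
    defaults to the last expected peak, adenosine in the default study).  A
    sample whose reference peak is missing is flagged and excluded from
    RRT/RPA with a logged warning.
    """
    rt = np.asarray(reference_times, dtype=float)
    if rt.ndim != 1 or rt.size < 1:
        raise ValueError("reference_times must be a non-empty 1-D sequence")
    if np.any(np.diff(rt) <= 0):
        raise ValueError("reference_times must be strictly increasing")
    if not (0 < rel_tolerance <= 0.1):
        raise ValueError("rel_tolerance must lie in (0, 0.1]")
    if reference_index is None:
        reference_index = rt.size
    if not (1 <= reference_index <= rt.size):
        raise ValueError("reference_index out of range")

    tables: list[PeakTable] = []
    for sample_id, peaks in samples:
        best: dict[int, tuple[Peak, float]] = {}
        unmatched: list[Peak] = []
        for p in peaks:
            j = int(np.argmin(np.abs(rt - p.apex_time)))
            dev = abs(p.apex_time - rt[j]) / rt[j]
            if dev > rel_tolerance:
                unmatched.append(p)
                continue
            idx = j + 1
            held = best.get(idx)
            if held is None:
                best[idx] = (p, dev)
            else:
                keep_new = dev < held[1] - 1e-12 or (
                    abs(dev - held[1]) <= 1e-12 and p.area > held[0].area
                )
                if abs(dev - held[1]) <= 1e-12:
                    logger.info(
                        "sample %s: tie at common peak %d resolved toward larger area",
                        sample_id, idx,
                    )
                if keep_new:
                    unmatched.append(held[0])
                    best[idx] = (p, dev)
                else:
                    unmatched.append(p)
        assignments = {idx: pd_[0] for idx, pd_ in best.items()}
        ref = assignments.get(reference_index)
        if ref is None:
            logger.warning(
                "sample %s: reference peak %d absent; RRT/RPA not computed",
                sample_id, reference_index,
            )
            tables.append(PeakTable(sample_id, assignments, unmatched,
                                    reference_index, None, None, flagged=True))
        else:
            rrt = {i: p.apex_time / ref.apex_time for i, p in assignments.items()}
            rpa = {i: p.area / ref.area for i, p in assignments.items()}
            tables.append(PeakTable(sample_id, assignments, unmatched,
                                    reference_index, rrt, rpa))
    return tables


def peak_tables_frame(tables: Sequence[PeakTable],
                      analyte_names: dict[int, str] | None = None) -> pd.DataFrame:
    """Concatenate per-sample peak tables into one long table."""
    frames = [t.to_frame(analyte_names) for t in tables]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=["sample_id", "common_index", "analyte",
                                     "rt_min", "rrt", "height", "area", "rpa"])
    return pd.concat(frames, ignore_index=True)
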