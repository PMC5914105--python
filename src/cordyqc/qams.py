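"""Single-marker quantification (QAMS).

An analyte *i* is quantified against one calibrated internal reference *s*
(adenosine by default) through its relative correction factor

    F_i/s = (C_i / C_s) * (A_s / A_i)

measured on standard solutions.  Sample contents then follow from

    C_i = F_i/s * (A_i / A_s) * C_s,      m_i = C_i * V_i,

with the same volume/mass unit path as the external-standard method (ESM).
Robustness of F across conditions (injection volume, instrument x column,
flow rate, column temperature) is summarized as mean and RSD per analyte, and
QAMS/ESM agreement across samples is scored by the cosine of the vector angle.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_INTERNAL_STANDARD",
    "RCFEntry",
    "ContentRecord",
    "AgreementReport",
    "compute_rcf",
    "rcf_robustness",
    "summarize_rcf_table",
    "qams_quantify",
    "method_agreement",
]

logger = logging.getLogger(__name__)

DEFAULT_INTERNAL_STANDARD = "adenosine"


@dataclass
class RCFEntry:
    """One relative correction factor measurement under a labeled condition."""

    analyte: str
    f_value: float
    internal_standard: str = DEFAULT_INTERNAL_STANDARD
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.f_value <= 0:
            raise ValueError("RCF must be positive")


@dataclass
class ContentRecord:
    """Per-sample, per-analyte content with its method tag."""

    sample_id: str
    analyte: str
    method: str  # "QAMS" | "ESM"
    content_mg_g: float
    concentration_ug_ml: float
    mass_ug: float

    def __post_init__(self) -> None:
        if self.content_mg_g < 0:
            raise ValueError("content must be non-negative")
        if self.method not in ("QAMS", "ESM"):
            raise ValueError("method must be 'QAMS' or 'ESM'")


@dataclass
class AgreementReport:
    """Cosine (and Pearson correlation) between QAMS and ESM content vectors."""

    analyte: str
    cosine: float
    correlation: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.cosine <= 1.0 + 1e-12):
            raise ValueError("cosine out of [-1, 1]")


def compute_rcf(c_i: float, c_s: float, a_i: float, a_s: float) -> float:
    """Relative correction factor F_i/s = (C_i/C_s) * (A_s/A_i).

    All four inputs (concentrations in ug/mL, areas in detector units) must be
    positive.
    """
    for name, v in (("c_i", c_i), ("c_s", c_s), ("a_i", a_i), ("a_s", a_s)):
        if v <= 0:
            raise ValueError(f"{name} must be positive (got {v!r})")
    return (c_i / c_s) * (a_s / a_i)


def rcf_robustness(entries: Sequence[RCFEntry],
                   condition_axis: str = "") -> pd.DataFrame:
    """Mean and sample-SD RSD of F per analyte over a robustness axis.

    Analytes with fewer than two entries are skipped with a warning.  Rows are
    ordered by first appearance of the analyte, mirroring the standard
    report layout.
    """
    order: list[str] = []
    values: dict[str, list[float]] = {}
    for e in entries:
        if e.analyte not in values:
            order.append(e.analyte)
            values[e.analyte] = []
        values[e.analyte].append(e.f_value)
    rows = []
    for analyte in order:
        v = np.asarray(values[analyte], dtype=float)
        if v.size < 2:
            logger.warning("analyte %s: fewer than two RCF entries, skipped", analyte)
            continue
        mean = float(v.mean())
        rows.append({
            "analyte": analyte,
            "condition_axis": condition_axis,
            "n": int(v.size),
            "mean": mean,
            "rsd_percent": float(100.0 * v.std(ddof=1) / mean),
        })
    return pd.DataFrame(rows)


def summarize_rcf_table(table: pd.DataFrame, condition_axis: str = "") -> pd.DataFrame:
    """Summarize a wide condition-by-analyte RCF table (one column per analyte)."""
    entries = [
        RCFEntry(analyte=col, f_value=float(v), condition={"axis": condition_axis})
        for col in table.columns
        for v in table[col].to_numpy()
    ]
    return rcf_robustness(entries, condition_axis=condition_axis)


def qams_quantify(
    a_i: float,
    a_s: float,
    c_s: float,
    f: float,
    extract_volume_ml: float = 50.0,
    sample_mass_g: float = 1.0,
    sample_id: str = "",
    analyte: str = "",
) -> ContentRecord:
    """Quantify one analyte from the internal-standard peak.

    C_i = f * (A_i/A_s) * C_s; m_i = C_i * V; content = m_i / mass / 1000,
    the same unit path as ESM so the two methods are directly comparable.
    """
    if a_s <= 0:
        raise ValueError("internal standard peak area must be positive")
    if c_s <= 0 or f <= 0:
        raise ValueError("internal standard concentration and RCF must be positive")
    if a_i < 0:
        raise ValueError("analyte area must be non-negative")
    if sample_mass_g <= 0 or extract_volume_ml <= 0:
        raise ValueError("sample mass and extract volume must be positive")
    conc = f * (a_i / a_s) * c_s
    mass_ug = conc * extract_volume_ml
    return ContentRecord(
        sample_id=sample_id,
        analyte=analyte,
        method="QAMS",
        content_mg_g=mass_ug / sample_mass_g / 1000.0,
        concentration_ug_ml=conc,
        mass_ug=mass_ug,
    )


def method_agreement(qams_vec: Sequence[float], esm_vec: Sequence[float],
                     analyte: str = "") -> AgreementReport:
    """Cosine of the angle (and Pearson correlation) between the QAMS and ESM
    content vectors across samples."""
    q = np.asarray(qams_vec, dtype=float)
    e = np.asarray(esm_vec, dtype=float)
    if q.shape != e.shape or q.ndim != 1 or q.size < 2:
        raise ValueError("content vectors must be equal-length 1-D with >= 2 samples")
    nq, ne = np.linalg.norm(q), np.linalg.norm(e)
    if nq == 0 or ne == 0:
        raise ValueError("cosine undefined for a zero-norm content vector")
    cosine = float(np.dot(q, e) / (nq * ne))
    with np.errstate(invalid="ignore"):
        correlation = float(np.corrcoef(q, e)[0, 1])
    return AgreementReport(analyte=analyte, cosine=cosine, correlation=correlation)
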