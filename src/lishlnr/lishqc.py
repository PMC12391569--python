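"""Absolute quantification for the qPCR-based LISH-QC pre-qualification assay.

A standard curve Cq = intercept + slope * log10(copies/uL) is fitted to a
synthetic dilution series of a housekeeping gene; sample Cq values are
inverted through the curve, scaled by the elution volume, and normalized
to the tissue area to report molecules per mm^2.  Configurable thresholds
turn the quantity into a pass/caution/fail qualification of the specimen
for downstream spatial transcriptomics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "QCResult",
    "ExtrapolationWarning",
    "fit_standard_curve",
    "quantify",
    "qualify",
]


class ExtrapolationWarning(UserWarning):
    """Sample Cq lies outside the calibrated dilution range."""


@dataclass
class StandardCurve:
    """Fitted qPCR standard curve for one gene.

    ``efficiency`` is the per-cycle amplification gain minus one:
    10**(-1/slope) - 1, so a perfect doubling per cycle
    (slope = -1/log10(2) ~ -3.3219) gives efficiency 1.0.
    """

    gene: str
    points: pd.DataFrame  # log10_copies, cq
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10 ** (-1.0 / self.slope) - 1.0

    @property
    def cq_range(self) -> tuple[float, float]:
        cq = self.points["cq"]
        return float(cq.min()), float(cq.max())

    def copies_at(self, cq: float) -> float:
        """Invert the curve: copies/uL at the given Cq."""
        return float(10 ** ((cq - self.intercept) / self.slope))


@dataclass
class QCResult:
    gene: str
    sample_id: str
    cq: float
    copies_per_uL: float
    total_copies: float
    tissue_area_mm2: float
    molecules_per_mm2: float
    qualification: str = ""


def fit_standard_curve(points: pd.DataFrame, gene: str = "") -> StandardCurve:
    """Least-squares line through (log10_copies, Cq) dilution points.

    A valid amplification gives slope < 0 (higher input -> earlier Cq);
    a non-negative slope raises.
    """
    x = points["log10_copies"].to_numpy(dtype=float)
    y = points["cq"].to_numpy(dtype=float)
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 dilution points with distinct log10_copies")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(f"non-negative slope {fit.slope:.3f}: not a valid curve")
    return StandardCurve(gene=gene, points=points.copy(), slope=float(fit.slope),
                         intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue**2))


def quantify(
    curve: StandardCurve,
    sample_cq: float,
    tissue_area_mm2: float,
    elution_volume_uL: float = 100.0,
    sample_id: str = "",
) -> QCResult:
    """Convert a sample Cq to molecules per mm^2 of tissue.

    copies/uL from the inverted curve, times the elution volume, divided
    by the tissue area.  A Cq outside the calibrated dilution range emits
    an :class:`ExtrapolationWarning`.
    """
    if tissue_area_mm2 <= 0:
        raise ValueError("tissue area must be positive")
    if elution_volume_uL <= 0:
        raise ValueError("elution volume must be positive")
    lo, hi = curve.cq_range
    if not lo <= sample_cq <= hi:
        warnings.warn(
            f"Cq {sample_cq:.2f} outside calibrated range [{lo:.2f}, {hi:.2f}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    copies = curve.copies_at(sample_cq)
    total = copies * elution_volume_uL
    return QCResult(
        gene=curve.gene,
        sample_id=sample_id,
        cq=float(sample_cq),
        copies_per_uL=copies,
        total_copies=total,
        tissue_area_mm2=float(tissue_area_mm2),
        molecules_per_mm2=total / tissue_area_mm2,
    )


def qualify(
    results: Sequence[QCResult],
    thresholds: Mapping[str, tuple[float, float]],
) -> pd.DataFrame:
    """Categorize each result as pass / caution / fail.

    ``thresholds`` maps gene -> (fail_below, pass_at_or_above) in
    molecules/mm^2: below the first cut is "fail", at or above the second
    is "pass", in between is "caution".  Thresholds are configuration —
    they encode an instrument/tissue-specific calibration, not constants
    of the assay.
    """
    rows = []
    for r in results:
        if r.gene not in thresholds:
            raise ValueError(f"no thresholds configured for gene {r.gene!r}")
        fail_below, pass_above = thresholds[r.gene]
        if not 0 <= fail_below <= pass_above:
            raise ValueError(f"bad thresholds for {r.gene!r}")
        if r.molecules_per_mm2 < fail_below or r.molecules_per_mm2 <= 0:
            q = "fail"
        elif r.molecules_per_mm2 >= pass_above:
            q = "pass"
        else:
            q = "caution"
        r.qualification = q
        rows.append({
            "sample_id": r.sample_id,
            "gene": r.gene,
            "molecules_per_mm2": r.molecules_per_mm2,
            "qualification": q,
        })
    return pd.DataFrame(rows)
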