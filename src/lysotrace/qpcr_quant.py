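"""qPCR absolute quantification and contamination-corrected phage counts.

Virion concentrations in filtered culture supernatants or macrophage lysates
are measured by qPCR against a genomic-DNA standard curve. Because virome
preparations always carry residual bacterial DNA, every phage measurement is
compared against its expected contamination level: for an integrated
prophage that is the host-genome concentration itself (1 prophage copy per
chromosome); for a multi-copy episome it is host concentration × copy
number. Replicates below their contamination level are flagged and excluded
from means. Virions that are unstable in a given matrix (e.g. a macrophage
lysate held before processing) are corrected by a measured per-phage
instability factor.

Core relations
--------------
standard curve      Cq = intercept + slope · log10(copies),  slope < 0
efficiency          E = 10^(−1/slope) − 1          (1.0 ⇔ perfect doubling)
relative copies     ratio = (1 + E)^(Cq_ref − Cq_target)     (ΔΔCt)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    UndefinedRatioError,
    ValidationError,
)

__all__ = [
    "QpcrMeasurement",
    "StandardCurve",
    "QuantResult",
    "fit_standard_curve",
    "absolute_quantify",
    "copy_number_ratio",
    "contamination_estimate",
    "flag_above_contamination",
    "phage_per_bacterium",
    "fold_induction",
    "format_fold",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One well: sample, target (phage or host reference gene), Cq."""

    sample_id: str
    target: str
    cq: float
    dilution_factor: float = 1.0
    replicate: int = 1
    context: str = "in_vitro"

    def __post_init__(self) -> None:
        if not math.isfinite(self.cq) or self.cq <= 0:
            raise ValidationError(f"invalid Cq {self.cq}")
        if self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear dilution-series calibration of one qPCR assay."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValidationError("standard-curve slope must be negative")

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency; 1.0 is perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def efficiency_in_range(self) -> bool:
        """True when efficiency is within the conventional 0.9–1.1 band."""
        return 0.9 <= self.efficiency <= 1.1


@dataclass
class QuantResult:
    """One target's concentration with its contamination bookkeeping."""

    target: str
    copies_per_mL: float
    contamination_copies_per_mL: float = 0.0
    instability_factor: float = 1.0
    context: str = "in_vitro"

    @property
    def above_contamination(self) -> bool:
        return self.copies_per_mL > self.contamination_copies_per_mL

    @property
    def fold_over_contamination(self) -> float:
        if self.contamination_copies_per_mL == 0:
            return float("inf") if self.copies_per_mL > 0 else 0.0
        return self.copies_per_mL / self.contamination_copies_per_mL

    @property
    def corrected_copies_per_mL(self) -> float:
        return self.copies_per_mL * self.instability_factor


def fit_standard_curve(
    copies: Sequence[float], cq: Sequence[float]
) -> StandardCurve:
    """Least-squares fit of Cq against log10(copies) for a dilution series."""
    copies = np.asarray(copies, dtype=float)
    cq = np.asarray(cq, dtype=float)
    if copies.shape != cq.shape:
        raise InvalidParameterError("copies and cq must have equal length")
    if np.any(copies <= 0):
        raise InvalidParameterError("all copy numbers must be > 0")
    if np.unique(copies).size < 3:
        raise InsufficientDataError("need >= 3 distinct copy levels")
    res = stats.linregress(np.log10(copies), cq)
    if res.slope >= 0:
        raise ValidationError("positive slope: Cq must decrease with copies")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def absolute_quantify(
    curve: StandardCurve,
    cq: float,
    dilution_factor: float = 1.0,
    volume_scale: float = 1.0,
) -> float:
    """Copies/mL from one Cq via the standard curve.

    ``volume_scale`` converts per-reaction copies to per-mL of the original
    sample (e.g. 1000/6 for a 6 µL template input).
    """
    copies = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return copies * dilution_factor * volume_scale


def copy_number_ratio(
    cq_target: Sequence[float],
    cq_reference: Sequence[float],
    efficiency: float = 1.0,
) -> float:
    """Target/reference copy ratio by the ΔΔCt method.

    ``cq_target`` and ``cq_reference`` are paired (same dilution, same run)
    Cq values; the per-pair ratio (1+E)^(Cq_ref − Cq_target) is averaged
    across pairs. With efficiency 1 a ΔCq of −1 cycle halves the ratio.
    """
    t = np.asarray(cq_target, dtype=float)
    r = np.asarray(cq_reference, dtype=float)
    if t.shape != r.shape or t.size == 0:
        raise InvalidParameterError("target and reference Cq lists must pair up")
    if efficiency <= 0:
        raise InvalidParameterError("efficiency must be > 0")
    ratios = (1.0 + efficiency) ** (r - t)
    return float(np.mean(ratios))


def contamination_estimate(
    host_copies_per_mL: float, copy_number: float = 1.0
) -> float:
    """Expected prophage signal from contaminating bacterial DNA alone.

    Host genomic contamination measured on a single-copy reference gene,
    multiplied by the prophage's per-cell copy number (1 for integrated
    prophages, >1 for multi-copy episomes).
    """
    if host_copies_per_mL < 0 or copy_number < 0:
        raise InvalidParameterError("inputs must be >= 0")
    return host_copies_per_mL * copy_number


def flag_above_contamination(
    measured_copies: float, contamination_copies: float
) -> tuple[bool, float]:
    """Is a measurement explained by contamination? Returns (above, fold)."""
    if measured_copies < 0 or contamination_copies < 0:
        raise InvalidParameterError("inputs must be >= 0")
    if contamination_copies == 0:
        return (measured_copies > 0, float("inf") if measured_copies > 0 else 0.0)
    fold = measured_copies / contamination_copies
    return (fold > 1.0, fold)


def phage_per_bacterium(
    copies_per_mL: float,
    cfu_per_mL: float,
    instability_factor: float = 1.0,
) -> float:
    """Virions per bacterium, with optional instability correction.

    The instability factor compensates measured losses of virions in the
    sample matrix between lysis and qPCR (a per-phage, per-matrix constant;
    it must only be applied in the context where the loss was measured).
    """
    if cfu_per_mL <= 0:
        raise UndefinedRatioError("cfu_per_mL must be > 0")
    if instability_factor <= 0:
        raise InvalidParameterError("instability_factor must be > 0")
    return copies_per_mL * instability_factor / cfu_per_mL


def _arm_values(arm: Sequence[QuantResult | float], use_corrected: bool) -> np.ndarray:
    vals = []
    for r in arm:
        if isinstance(r, QuantResult):
            if r.above_contamination:
                vals.append(r.corrected_copies_per_mL if use_corrected else r.copies_per_mL)
        else:
            vals.append(float(r))
    return np.asarray(vals, dtype=float)


def fold_induction(
    treated: Sequence[QuantResult | float],
    untreated: Sequence[QuantResult | float],
    test: str = "t",
    use_corrected: bool = False,
) -> tuple[float, float]:
    """Fold change of phage production between two conditions.

    Replicates below their contamination level are excluded before the
    fold of arithmetic means is formed; the remaining replicate values are
    compared with a two-sided Welch t-test (``test="t"``) or Mann-Whitney U
    (``test="mann_whitney"``). Returns (fold, p_value).
    """
    if test not in ("t", "mann_whitney"):
        raise InvalidParameterError(f"unknown test {test!r}")
    x = _arm_values(treated, use_corrected)
    y = _arm_values(untreated, use_corrected)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError(
            "need >= 2 above-contamination replicates per arm"
        )
    if y.mean() == 0:
        raise UndefinedRatioError("untreated arm has zero mean")
    fold = float(x.mean() / y.mean())
    if np.var(x) == 0 and np.var(y) == 0:
        p = 1.0 if x.mean() == y.mean() else 0.0
    elif test == "t":
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return fold, p


def significance_stars(p_value: float) -> str:
    """Figure-legend star annotation: * <0.05, ** <0.01, *** <0.005."""
    if p_value < 0.005:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "NS"


def format_fold(fold: float) -> str:
    """Display convention: integers for folds >= 10, one decimal below."""
    if not math.isfinite(fold):
        return "inf"
    if fold >= 10:
        return str(int(round(fold)))
    return f"{fold:.1f}"
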