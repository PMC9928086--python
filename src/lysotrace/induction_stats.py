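"""Frequencies and comparisons from count data.

Induction frequencies (fraction of cells entering the lytic cycle, scored by
a fluorescent capsid-fusion reporter), conditional lysis fractions,
lysogenization frequencies from resistant-colony counts, and CFU survival
ratios. Binomial proportions carry Wilson 95% confidence intervals, which
behave well for the very small proportions typical of induction assays
(e.g. 1 event in a few thousand cells), unlike the Wald interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InsufficientDataError, UndefinedRatioError, ValidationError

__all__ = [
    "CellCounts",
    "FrequencyEstimate",
    "induction_frequency",
    "conditional_lysis_fraction",
    "lysogenization_frequency",
    "survival_ratio",
    "format_percent",
]


@dataclass(frozen=True)
class CellCounts:
    """Microscopy counts: induced cells (intact + recently lysed) / total."""

    n_induced: int
    n_total: int
    context: str = ""

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValidationError("n_total must be >= 1")
        if not 0 <= self.n_induced <= self.n_total:
            raise ValidationError("need 0 <= n_induced <= n_total")


@dataclass(frozen=True)
class FrequencyEstimate:
    """A binomial proportion with its Wilson 95% interval."""

    frequency: float
    ci_low: float
    ci_high: float
    n_total: int

    @property
    def percent_display(self) -> str:
        return format_percent(self.frequency)


def _wilson(k: int, n: int) -> FrequencyEstimate:
    low, high = proportion_confint(k, n, alpha=0.05, method="wilson")
    return FrequencyEstimate(
        frequency=k / n, ci_low=float(low), ci_high=float(high), n_total=n
    )


def format_percent(proportion: float) -> str:
    """Percent display: two decimals below 1%, integers at or above 1%."""
    pct = proportion * 100.0
    if pct < 1.0:
        return f"{pct:.2f}"
    return str(int(round(pct)))


def induction_frequency(counts: CellCounts) -> FrequencyEstimate:
    """Fraction of observed cells that entered the lytic cycle."""
    return _wilson(counts.n_induced, counts.n_total)


def conditional_lysis_fraction(
    n_lysed_given_induced: int, n_induced: int
) -> FrequencyEstimate:
    """Fraction of induced cells that went on to lyse."""
    if n_induced < 1:
        raise UndefinedRatioError("n_induced must be >= 1")
    if not 0 <= n_lysed_given_induced <= n_induced:
        raise ValidationError("need 0 <= n_lysed <= n_induced")
    return _wilson(n_lysed_given_induced, n_induced)


def lysogenization_frequency(
    n_resistant: int, n_viable: int, background_rate: float = 7e-9
) -> tuple[float, bool]:
    """Lysogens per infected bacterium from marker-resistance counts.

    Returns (frequency, above_background); the flag is strict — a frequency
    exactly at the spontaneous-resistance background is not called above it.
    """
    if n_viable < 1:
        raise UndefinedRatioError("n_viable must be >= 1")
    if n_resistant < 0:
        raise ValidationError("n_resistant must be >= 0")
    freq = n_resistant / n_viable
    return freq, freq > background_rate


def survival_ratio(
    cfu_timepoint: Sequence[float],
    cfu_reference: Sequence[float],
    test: str = "t",
) -> tuple[float, float]:
    """Ratio of mean CFU counts plus a two-sided Welch t-test p-value.

    Used e.g. to compare intramacrophage survival of two strains against
    their initial endocytosed inoculum. Zero variance on both arms returns
    p = 1 for equal means (degenerate convention).
    """
    if test != "t":
        raise ValidationError(f"unknown test {test!r}")
    x = np.asarray(cfu_timepoint, dtype=float)
    y = np.asarray(cfu_reference, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("need >= 2 replicates per arm")
    if y.mean() == 0:
        raise UndefinedRatioError("reference arm has zero mean")
    ratio = float(x.mean() / y.mean())
    if np.var(x) == 0 and np.var(y) == 0:
        p = 1.0 if x.mean() == y.mean() else 0.0
    else:
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    return ratio, p
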