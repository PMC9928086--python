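"""Moron detection from prophage expression tables.

Morons are prophage genes expressed autonomously during lysogeny — outside
the control of the lysogeny master repressor — that typically benefit the
bacterial host. In a lysogen's transcriptome the distribution of expression
over a prophage region is bimodal: most phage genes are silent (a high peak
of low read counts) while a handful stand well above them. The calling rule:

1. For each prophage, the *local background* is the median of the
   replicate-averaged normalized expression (fpkm) over **all** genes of the
   region, silent and expressed alike.
2. A candidate gene (i.e. not curated as a core phage-cycle gene such as the
   master repressor) is called a moron when its mean fpkm is at least
   ``threshold`` (default 5) times the local background.
3. *Operon rescue*: an uncalled candidate that shares an operon with a
   called gene is added to the call set — a co-transcribed gene just under
   the cut is still part of the expressed unit.

Folds are computed on the linear fpkm scale; the log2(fpkm + 5) transform
used for storage/plotting is provided for interoperability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "ExpressionRecord",
    "MoronCall",
    "compute_fpkm",
    "log2p5",
    "inverse_log2p5",
    "local_background",
    "call_morons",
    "bimodality_gap",
]

CORE_PHAGE = "core_phage"
CANDIDATE = "candidate"


@dataclass
class ExpressionRecord:
    """Normalized expression of one prophage gene across replicates."""

    gene_id: str
    prophage: str
    category: str = CANDIDATE
    operon_id: str | None = None
    fpkm_per_replicate: list[float] = field(default_factory=list)
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.category not in (CORE_PHAGE, CANDIDATE):
            raise InvalidParameterError(
                f"{self.gene_id}: unknown category {self.category!r}"
            )
        if any(v < 0 for v in self.fpkm_per_replicate):
            raise InvalidParameterError(f"{self.gene_id}: negative fpkm")

    @property
    def mean_fpkm(self) -> float:
        if not self.fpkm_per_replicate:
            return 0.0
        return float(np.mean(self.fpkm_per_replicate))


@dataclass(frozen=True)
class MoronCall:
    """One called moron with its fold over the prophage-local background."""

    gene_id: str
    prophage: str
    fold_above_background: float
    called_by: str  # "threshold" | "operon_rescue"

    @property
    def fold_display(self) -> int:
        """Integer fold as printed in result tables."""
        return int(round(self.fold_above_background))


def compute_fpkm(
    fragment_count: float, gene_length: int, library_size: float
) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if gene_length <= 0:
        raise InvalidParameterError("gene_length must be > 0")
    if library_size <= 0:
        raise InvalidParameterError("library_size must be > 0")
    return fragment_count / (gene_length / 1e3) / (library_size / 1e6)


def log2p5(fpkm: float) -> float:
    """Storage/plotting transform log2(fpkm + 5)."""
    return math.log2(fpkm + 5.0)


def inverse_log2p5(value: float) -> float:
    """Invert :func:`log2p5`, clipping tiny negative round-off to 0."""
    return max(0.0, 2.0**value - 5.0)


def local_background(prophage_records: list[ExpressionRecord]) -> float:
    """Median replicate-averaged fpkm over all genes of one prophage region."""
    if not prophage_records:
        raise InsufficientDataError("no records for this prophage")
    return float(np.median([r.mean_fpkm for r in prophage_records]))


def call_morons(
    records: list[ExpressionRecord],
    threshold: float = 5.0,
    operon_rescue: bool = True,
) -> list[MoronCall]:
    """Apply the fold-over-local-background moron rule to all prophages.

    Records may mix several prophages; the background is computed per
    prophage. Core phage-cycle genes are never called regardless of their
    expression (the master repressor is typically well above background).
    """
    if threshold <= 0:
        raise InvalidParameterError("threshold must be > 0")
    by_prophage: dict[str, list[ExpressionRecord]] = {}
    for r in records:
        by_prophage.setdefault(r.prophage, []).append(r)

    calls: list[MoronCall] = []
    for prophage, recs in by_prophage.items():
        background = local_background(recs)
        if background <= 0:
            continue
        called_ids: set[str] = set()
        called_operons: set[str] = set()
        for r in recs:
            if r.category != CANDIDATE:
                continue
            fold = r.mean_fpkm / background
            if fold >= threshold:
                calls.append(MoronCall(r.gene_id, prophage, fold, "threshold"))
                called_ids.add(r.gene_id)
                if r.operon_id:
                    called_operons.add(r.operon_id)
        if operon_rescue:
            for r in recs:
                if (
                    r.category == CANDIDATE
                    and r.gene_id not in called_ids
                    and r.operon_id
                    and r.operon_id in called_operons
                    and r.mean_fpkm > 0
                ):
                    calls.append(
                        MoronCall(
                            r.gene_id,
                            prophage,
                            r.mean_fpkm / background,
                            "operon_rescue",
                        )
                    )
    return calls


def bimodality_gap(
    prophage_records: list[ExpressionRecord],
) -> tuple[float, int]:
    """Largest expression gap in the upper half of the sorted fpkm values.

    A diagnostic for the silent-genes/expressed-genes bimodality the calling
    rule relies on: returns (gap_ratio, split_index) where ``split_index``
    is the index (into the ascending-sorted values) of the first gene above
    the widest gap. Uniform tables return ratio 1.
    """
    if len(prophage_records) < 4:
        raise InsufficientDataError("need >= 4 genes for a bimodality diagnostic")
    values = np.sort([r.mean_fpkm for r in prophage_records])
    n = values.size
    best_ratio, best_idx = 1.0, n
    for i in range(n - 1):
        if i + 1 < n // 2:
            continue  # only gaps in the upper half
        lo, hi = values[i], values[i + 1]
        ratio = float("inf") if lo == 0 and hi > 0 else (hi / lo if lo > 0 else 1.0)
        if ratio > best_ratio:
            best_ratio, best_idx = ratio, i + 1
    return best_ratio, best_idx
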