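"""Genomic data model for prophages of a poly-lysogenic bacterium.

Coordinates are 1-based and inclusive everywhere in this package (the
convention under which an interval [start, end] has length end - start + 1,
and which reproduces published prophage sizes from their boundaries).
0-based half-open inputs such as bedGraph are converted at the I/O boundary.

Besides the annotation containers this module provides small pieces of
phage biology arithmetic:

* headful (pac-type) packaging capacity — a terminase that packages a fixed
  "headful" slightly larger than one genome (e.g. ~103.8% for P22-like
  phages) sets the length of each lateral-transduction coverage step;
* siphovirus tail-length prediction from the tape measure protein (TMP),
  using the canonical ~0.15 nm per residue ratio;
* in-silico reconstruction of the bacterial attachment site (attB) after
  prophage excision, with an ORF-restoration check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import (
    InvalidParameterError,
    MissingDataError,
    UnsupportedModeError,
    ValidationError,
)

__all__ = [
    "ProphageAnnotation",
    "RepliconMap",
    "OrfHit",
    "prophage_length",
    "headful_capacity",
    "headful_capacity_kb",
    "predict_tail_length",
    "find_orfs",
    "reconstruct_attB",
]

INTEGRATED = "integrated"
EPISOME = "episome"

#: P22-like headful packaging fraction (fraction of genome length per capsid).
DEFAULT_PACKAGING_FRACTION = 1.038

#: Tail length contributed per tape-measure-protein residue, in nm.
TMP_NM_PER_AA = 0.15

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class ProphageAnnotation:
    """One prophage: coordinates, integration mode and packaging metadata.

    Parameters
    ----------
    name : unique prophage name.
    replicon_id : replicon (chromosome or plasmid) carrying it.
    start, end : 1-based inclusive boundaries on the replicon.
    mode : ``"integrated"`` or ``"episome"``. Episomes (phage-plasmids)
        have no flanking host DNA, so transduction-flank analyses do not
        apply to them.
    pac_position : headful packaging initiation site, if known.
    att_core_length : length of the att core repeat, if known.
    copy_number : copies per bacterium (1 for integrated prophages;
        >1 for multi-copy episomes), used by contamination correction.
    """

    name: str
    replicon_id: str
    start: int
    end: int
    mode: str = INTEGRATED
    pac_position: int | None = None
    att_core_length: int | None = None
    copy_number: float = 1.0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"{self.name}: invalid interval [{self.start}, {self.end}] "
                "(need 1 <= start <= end)"
            )
        if self.mode not in (INTEGRATED, EPISOME):
            raise ValidationError(f"{self.name}: unknown mode {self.mode!r}")
        if self.pac_position is not None and not (
            self.start <= self.pac_position <= self.end
        ):
            raise ValidationError(
                f"{self.name}: pac_position {self.pac_position} outside "
                f"[{self.start}, {self.end}]"
            )
        if self.copy_number < 0:
            raise ValidationError(f"{self.name}: negative copy_number")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_episome(self) -> bool:
        return self.mode == EPISOME


@dataclass
class RepliconMap:
    """A replicon with its prophage annotations and optional sequence."""

    replicon_id: str
    length: int
    prophages: list[ProphageAnnotation] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError("replicon length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"sequence length {len(self.sequence)} != declared length "
                f"{self.length}"
            )
        seen: set[str] = set()
        for p in self.prophages:
            if p.name in seen:
                raise ValidationError(f"duplicate prophage name {p.name!r}")
            seen.add(p.name)
            if p.replicon_id == self.replicon_id and p.end > self.length:
                raise ValidationError(
                    f"{p.name} extends past replicon end ({p.end} > {self.length})"
                )

    def get(self, name: str) -> ProphageAnnotation:
        for p in self.prophages:
            if p.name == name:
                return p
        raise KeyError(name)


def prophage_length(annotation: ProphageAnnotation) -> int:
    """Prophage length in bp under the 1-based inclusive convention."""
    return annotation.length


def headful_capacity(
    prophage_len: int, packaging_fraction: float = DEFAULT_PACKAGING_FRACTION
) -> int:
    """DNA content of one capsid, in bp, for a headful-packaging phage.

    ``round(prophage_len * packaging_fraction)`` with Python's round-half-even
    rule. For a 38,682 bp P22-like prophage at 103.8% this is 40,152 bp.
    """
    if prophage_len < 1:
        raise InvalidParameterError("prophage_len must be >= 1")
    if packaging_fraction <= 0:
        raise InvalidParameterError("packaging_fraction must be > 0")
    return round(prophage_len * packaging_fraction)


def headful_capacity_kb(
    prophage_len: int, packaging_fraction: float = DEFAULT_PACKAGING_FRACTION
) -> float:
    """Headful capacity in kb, truncated (not rounded) to one decimal.

    Truncation matches the convention used to report e.g. 40,152 bp as 40.1 kb.
    """
    bp = headful_capacity(prophage_len, packaging_fraction)
    return math.floor(bp / 100.0) / 10.0


def predict_tail_length(tmp_length_aa: int, ratio: float = TMP_NM_PER_AA) -> float:
    """Predicted siphovirus tail length in nm from its TMP length in residues."""
    if tmp_length_aa < 0:
        raise InvalidParameterError("tmp_length_aa must be >= 0")
    return tmp_length_aa * ratio


def predict_tail_length_rounded(
    tmp_length_aa: int, ratio: float = TMP_NM_PER_AA
) -> int:
    """Tail length rounded to the nearest 10 nm (convenience display value)."""
    return int(round(predict_tail_length(tmp_length_aa, ratio) / 10.0) * 10)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfHit:
    """One ORF on a linear sequence; 1-based inclusive, strand +/-."""

    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_orfs(sequence: str, min_length: int = 300) -> list[OrfHit]:
    """ATG-initiated ORFs with an in-frame stop, on both strands.

    An ORF runs from an ATG to the first in-frame stop codon (stop included
    in the reported interval); nested ATGs within an already-reported ORF of
    the same frame are skipped, so each (frame, stop) pair yields at most the
    longest ORF. Only ORFs of at least ``min_length`` bp are returned.
    """
    seq = sequence.upper()
    n = len(seq)
    hits: list[OrfHit] = []
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        for frame in range(3):
            i = frame
            claimed_until = -1
            while i + 3 <= n:
                if s[i : i + 3] == "ATG" and i > claimed_until:
                    j = i
                    while j + 3 <= n:
                        if s[j : j + 3] in _STOPS:
                            length = j + 3 - i
                            if length >= min_length:
                                if strand == "+":
                                    hits.append(OrfHit(i + 1, j + 3, "+"))
                                else:
                                    hits.append(OrfHit(n - (j + 3) + 1, n - i, "-"))
                            claimed_until = j
                            break
                        j += 3
                i += 3
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def reconstruct_attB(
    replicon: RepliconMap, prophage_name: str, min_orf_length: int = 300
) -> tuple[str, list[OrfHit]]:
    """Excise an integrated prophage in silico and scan the new junction.

    Returns the host sequence with [start, end] removed and the flanks
    joined, plus the list of ORFs (>= ``min_orf_length`` bp, both strands)
    that span the new attB junction and are not already intact within either
    unexcised flank — i.e. reading frames restored by excision.
    """
    prophage = replicon.get(prophage_name)
    if prophage.is_episome:
        raise UnsupportedModeError(
            f"{prophage_name} is an episome: attB reconstruction undefined"
        )
    if replicon.sequence is None:
        raise MissingDataError(f"replicon {replicon.replicon_id} carries no sequence")
    left = replicon.sequence[: prophage.start - 1]
    right = replicon.sequence[prophage.end :]
    joined = left + right
    if not joined:
        raise ValidationError(
            f"{prophage_name} spans the whole replicon: nothing left after excision"
        )
    junction = len(left)  # 0-based index of first base after the junction
    restored: list[OrfHit] = []
    flank_orfs = {
        (h.length, h.strand) for h in find_orfs(left, min_orf_length)
    } | {(h.length, h.strand) for h in find_orfs(right, min_orf_length)}
    for hit in find_orfs(joined, min_orf_length):
        if hit.start <= junction < hit.end:  # spans the junction
            if (hit.length, hit.strand) not in flank_orfs:
                restored.append(hit)
    return joined, restored
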