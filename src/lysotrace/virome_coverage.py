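"""Coverage-based inference of prophage activity and lateral transduction.

A virome library (encapsidated, nuclease-protected DNA) mapped back onto the
host genome leaves three diagnostic footprints that this module quantifies:

1. **Spontaneous induction.** An active prophage is covered far above the
   residual bacterial-DNA contamination. Activity is tested with one-sided
   Welch t-tests on non-overlapping window means (prophage windows vs a
   background region around the integration site).

2. **Headful packaging and lateral transduction.** A pac-type prophage shows
   a sharp coverage jump at the pac site, and its downstream flank shows
   successive coverage steps of roughly one headful (~103.8% of the genome)
   each, decreasing two-to-three-fold per step — packaged host DNA. Steps are
   recovered by binary-segmentation changepoint search on log2(depth + 1)
   with a BIC-style penalty.

3. **In-situ replication.** Bidirectional replication of the prophage before
   excision inflates coverage of the upstream flank, decaying smoothly with
   distance from attL; quantified by least-squares on the log2 scale.

All coordinates are 1-based inclusive; intervals are ``(start, end)`` tuples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    NoBackgroundError,
    ValidationError,
)
from .prophage_model import ProphageAnnotation, RepliconMap

__all__ = [
    "CoverageTrack",
    "ActivityTestResult",
    "TransductionProfile",
    "ClipEvidence",
    "estimate_background",
    "window_means",
    "test_activity",
    "detect_pac",
    "segment_transduction",
    "estimate_insitu_replication",
    "detect_boundaries",
    "summarize_virome",
]

Interval = tuple[int, int]


@dataclass
class CoverageTrack:
    """Per-base read depth over one replicon (1-based positions)."""

    replicon_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size < 1:
            raise ValidationError("depth must be a non-empty 1-D array")
        if np.any(self.depth < 0):
            raise ValidationError("negative depth values")

    @property
    def length(self) -> int:
        return int(self.depth.size)

    def slice(self, start: int, end: int) -> np.ndarray:
        """Depth over the 1-based inclusive interval [start, end]."""
        if start < 1 or end > self.length or start > end:
            raise ValidationError(
                f"interval [{start}, {end}] outside track of length {self.length}"
            )
        return self.depth[start - 1 : end]


@dataclass
class ActivityTestResult:
    """Outcome of one prophage-vs-background coverage comparison."""

    prophage: str
    window_size: int
    n_prophage_windows: int
    n_background_windows: int
    mean_prophage: float
    mean_background: float
    p_value: float
    active: bool


@dataclass
class TransductionProfile:
    """Headful-step structure of a transduction flank.

    ``step_breakpoints`` are the 1-based positions of the first base of each
    new segment (strictly increasing). ``step_levels`` are linear-scale mean
    depths per segment (one more than breakpoints). ``monotone_violations``
    counts adjacent segment pairs whose level increases (diagnostic only;
    monotone decrease is expected but not enforced).
    """

    pac_position: int | None
    step_breakpoints: list[int]
    step_levels: list[float]
    step_fold_decreases: list[float]
    headful_size_estimate: float | None
    extent_bp: int
    first_segment_fold_over_background: float | None = None
    monotone_violations: int = 0


@dataclass(frozen=True)
class ClipEvidence:
    """Soft-clip support for a prophage junction at one position."""

    position: int
    side: str  # "left_clip" | "right_clip"
    support: int

    def __post_init__(self) -> None:
        if self.side not in ("left_clip", "right_clip"):
            raise ValidationError(f"unknown clip side {self.side!r}")
        if self.support < 0 or self.position < 1:
            raise ValidationError("invalid clip evidence")


def estimate_background(
    track: CoverageTrack,
    masked_regions: list[Interval] | None = None,
    statistic: str = "mean",
) -> float:
    """Contamination depth over all positions outside the masked regions.

    Masked regions should include the prophages themselves and any flank
    affected by lateral transduction, so only genuinely contaminating
    bacterial DNA contributes.
    """
    if statistic not in ("mean", "median"):
        raise InvalidParameterError(f"unknown statistic {statistic!r}")
    mask = np.zeros(track.length, dtype=bool)
    for start, end in masked_regions or []:
        start = max(1, start)
        end = min(track.length, end)
        if start <= end:
            mask[start - 1 : end] = True
    unmasked = track.depth[~mask]
    if unmasked.size == 0:
        raise NoBackgroundError("all positions masked: no background available")
    return float(np.mean(unmasked) if statistic == "mean" else np.median(unmasked))


def window_means(
    track: CoverageTrack, region: Interval, window: int = 5000
) -> list[float]:
    """Mean depth over consecutive non-overlapping windows of a region.

    Windows run left to right; a trailing partial window is kept when it is
    at least half a window long, otherwise dropped.
    """
    if window < 1:
        raise InvalidParameterError("window must be >= 1")
    start, end = region
    if start > end:
        return []
    values = track.slice(start, end)
    out: list[float] = []
    for i in range(0, values.size, window):
        chunk = values[i : i + window]
        if chunk.size < window and chunk.size < window / 2:
            break
        out.append(float(chunk.mean()))
    return out


def _welch_greater(x: np.ndarray, y: np.ndarray, pooled: bool = False) -> float:
    """One-sided two-sample t-test p-value for mean(x) > mean(y).

    Degenerate zero-variance-both-sides comparisons return p = 1 when the
    means are equal, 0/1 by sign otherwise (a fixed convention so pipelines
    never see NaN).
    """
    scale = max(1.0, abs(float(np.mean(x))), abs(float(np.mean(y))))
    if np.ptp(x) <= 1e-9 * scale and np.ptp(y) <= 1e-9 * scale:
        diff = float(np.mean(x) - np.mean(y))
        return 1.0 if diff <= 1e-9 * scale else 0.0
    res = stats.ttest_ind(x, y, equal_var=pooled, alternative="greater")
    return float(res.pvalue)


def test_activity(
    track: CoverageTrack,
    prophage: ProphageAnnotation,
    background_region: Interval,
    window: int = 5000,
    alpha: float = 0.05,
    pooled: bool = False,
) -> ActivityTestResult:
    """Is the prophage covered above the bacterial-DNA contamination?

    Both the prophage and the background region are cut into ``window``-bp
    windows, and the window means are compared with a one-sided (greater)
    Welch t-test (set ``pooled=True`` for the equal-variance variant).
    """
    pw = np.array(window_means(track, (prophage.start, prophage.end), window))
    bw = np.array(window_means(track, background_region, window))
    if pw.size < 2 or bw.size < 2:
        raise InsufficientDataError(
            f"{prophage.name}: need >= 2 windows per side "
            f"(got {pw.size} prophage, {bw.size} background)"
        )
    p = _welch_greater(pw, bw, pooled=pooled)
    mean_p, mean_b = float(pw.mean()), float(bw.mean())
    return ActivityTestResult(
        prophage=prophage.name,
        window_size=window,
        n_prophage_windows=int(pw.size),
        n_background_windows=int(bw.size),
        mean_prophage=mean_p,
        mean_background=mean_b,
        p_value=p,
        active=bool(p <= alpha and mean_p > mean_b),
    )


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (same length as input)."""
    if width <= 1:
        return x.astype(float)
    kernel = np.ones(width) / width
    smoothed = np.convolve(x, kernel, mode="same")
    # correct the shrunken edges (convolve pads with zeros)
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return smoothed / norm


def detect_pac(
    track: CoverageTrack,
    prophage: ProphageAnnotation,
    smooth_window: int = 200,
) -> int | None:
    """Locate the headful packaging initiation (pac) site inside a prophage.

    The pac site shows as a sharp upward coverage jump. The depth is smoothed
    with a centered ``smooth_window``-bp moving average and the position of
    the maximal positive forward difference is returned (ties broken toward
    the smaller coordinate). Returns None — "no pac detected" — when no jump
    exceeds twice the robust noise scale of the differences.
    """
    values = track.slice(prophage.start, prophage.end)
    if values.size < max(smooth_window, 2) + 1:
        return None
    smoothed = _moving_average(values, smooth_window)
    diffs = np.diff(smoothed)
    if diffs.size == 0:
        return None
    # robust noise scale of the differences (MAD); exact-flat tracks give 0
    sigma = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs))))
    # absolute floor keeps float round-off on constant tracks from faking a jump
    threshold = max(2.0 * sigma, 1e-8 * (1.0 + float(np.max(smoothed))))
    best = int(np.argmax(diffs))  # argmax returns the first (smallest) index
    if diffs[best] <= threshold:
        return None
    return prophage.start + best


def _binary_segmentation(
    signal: np.ndarray, min_size: int, penalty: float
) -> list[int]:
    """Changepoints (0-based start-of-new-segment indices) of a 1-D signal.

    Recursive binary segmentation minimising within-segment squared error;
    a split is accepted when it reduces the cost by more than ``penalty``.
    """
    n = signal.size
    cum = np.concatenate([[0.0], np.cumsum(signal)])
    cum2 = np.concatenate([[0.0], np.cumsum(signal**2)])

    def sse(a: int, b: int) -> float:  # [a, b) segment cost
        m = b - a
        s = cum[b] - cum[a]
        return float(cum2[b] - cum2[a] - s * s / m)

    breaks: list[int] = []
    stack = [(0, n)]
    while stack:
        a, b = stack.pop()
        if b - a < 2 * min_size:
            continue
        total = sse(a, b)
        cuts = np.arange(a + min_size, b - min_size + 1)
        if cuts.size == 0:
            continue
        m_l = cuts - a
        m_r = b - cuts
        s_l = cum[cuts] - cum[a]
        s_r = cum[b] - cum[cuts]
        costs = (cum2[cuts] - cum2[a] - s_l**2 / m_l) + (
            cum2[b] - cum2[cuts] - s_r**2 / m_r
        )
        k = int(np.argmin(costs))
        if total - costs[k] > penalty:
            cut = int(cuts[k])
            breaks.append(cut)
            stack.append((a, cut))
            stack.append((cut, b))
    return sorted(breaks)


def segment_transduction(
    track: CoverageTrack,
    prophage: ProphageAnnotation,
    background: float,
    direction: str = "downstream_of_attR",
    max_extent: int = 300_000,
    expected_step: int | None = None,
    extent_factor: float = 2.0,
    bin_size: int = 200,
    penalty_scale: float = 3.0,
) -> TransductionProfile:
    """Segment a transduction flank into headful coverage steps.

    The flank (``max_extent`` bp downstream of attR, or upstream of attL) is
    binned to ``bin_size`` bp, log2(depth + 1)-transformed, and segmented by
    binary segmentation with penalty ``penalty_scale * sigma^2 * log(n)``
    (sigma estimated robustly from first differences). Minimum segment length
    is ``expected_step / 4`` when an expected headful size is given, else
    10 kb. Reported per profile:

    * breakpoints (first base of each new segment, genome coordinates),
    * linear-scale mean depth per segment and adjacent fold decreases,
    * headful-size estimate = median spacing between segment boundaries
      (flank start included as a boundary),
    * extent = distance from the flank start to the last base of the
      farthest segment whose level exceeds ``background * extent_factor``.

    A flank entirely at or below ``background * extent_factor`` yields an
    empty profile (no breakpoints, extent 0).
    """
    if direction not in ("downstream_of_attR", "upstream_of_attL"):
        raise InvalidParameterError(f"unknown direction {direction!r}")
    if prophage.is_episome:
        raise InvalidParameterError(
            f"{prophage.name} is an episome: it has no transduction flank"
        )
    if direction == "downstream_of_attR":
        flank_start = prophage.end + 1
        flank_end = min(track.length, prophage.end + max_extent)
    else:
        flank_start = max(1, prophage.start - max_extent)
        flank_end = prophage.start - 1
    if flank_start > flank_end:
        raise InvalidParameterError("no flank exists in the requested direction")

    values = track.slice(flank_start, flank_end)
    if direction == "upstream_of_attL":
        values = values[::-1]  # analyse outward from the att site

    # bin, then segment on the log scale
    n_bins = values.size // bin_size
    if n_bins < 2:
        raise InsufficientDataError("flank too short to segment")
    binned = values[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    log_sig = np.log2(binned + 1.0)

    min_seg_bp = (expected_step // 4) if expected_step else 10_000
    min_size = max(2, min_seg_bp // bin_size)
    d = np.diff(log_sig)
    sigma = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)
    sigma = max(sigma, 1e-3)
    penalty = penalty_scale * sigma**2 * np.log(n_bins) * min_size
    cuts = _binary_segmentation(log_sig, min_size, penalty)

    bounds = [0] + cuts + [n_bins]
    levels = [float(binned[a:b].mean()) for a, b in zip(bounds[:-1], bounds[1:])]
    threshold = background * extent_factor

    if all(lv <= threshold for lv in levels):
        return TransductionProfile(
            pac_position=prophage.pac_position,
            step_breakpoints=[],
            step_levels=[],
            step_fold_decreases=[],
            headful_size_estimate=None,
            extent_bp=0,
            first_segment_fold_over_background=None,
        )

    def to_genome(offset_bp: float) -> int:
        # offset in bp from the flank start, outward from the att site
        if direction == "downstream_of_attR":
            return int(flank_start + offset_bp)
        return int(flank_end - offset_bp)

    breakpoints = [to_genome(c * bin_size) for c in cuts]
    folds = [
        levels[i] / levels[i + 1] if levels[i + 1] > 0 else float("inf")
        for i in range(len(levels) - 1)
    ]
    violations = sum(1 for f in folds if f < 1.0)

    # headful size: median spacing between boundaries, flank start included
    boundary_bp = [0] + [c * bin_size for c in cuts]
    spacings = np.diff(boundary_bp)
    headful = float(np.median(spacings)) if spacings.size else None

    last_active = max(i for i, lv in enumerate(levels) if lv > threshold)
    extent = bounds[last_active + 1] * bin_size
    if bounds[last_active + 1] == n_bins:
        extent = values.size  # ragged tail bin counted fully

    return TransductionProfile(
        pac_position=prophage.pac_position,
        step_breakpoints=breakpoints,
        step_levels=levels,
        step_fold_decreases=folds,
        headful_size_estimate=headful,
        extent_bp=int(extent),
        first_segment_fold_over_background=(
            levels[0] / background if background > 0 else float("inf")
        ),
        monotone_violations=violations,
    )


def estimate_insitu_replication(
    track: CoverageTrack,
    prophage: ProphageAnnotation,
    background: float,
    flank: int = 100_000,
) -> tuple[float, float]:
    """Fold coverage at the att site and its decay rate, upstream of attL.

    In-situ bidirectional replication of an induced prophage before excision
    inflates flank coverage, decaying with distance. We fit
    ``log2(depth + 1) = a + b * distance`` by least squares over ``flank`` bp
    upstream of attL and report ``fold_at_att = (2^a - 1) / background`` and
    ``decay_rate = |b|`` (log2 units per bp). A flank with no signal above
    background reports (1.0, 0.0).
    """
    if prophage.is_episome:
        raise InvalidParameterError(f"{prophage.name} is an episome")
    start = max(1, prophage.start - flank)
    end = prophage.start - 1
    if start > end:
        raise InsufficientDataError("no upstream flank")
    values = track.slice(start, end)[::-1]  # index 0 adjacent to attL
    dist = np.arange(values.size, dtype=float)
    slope, intercept = np.polyfit(dist, np.log2(values + 1.0), 1)
    fold = (2.0**intercept - 1.0) / background if background > 0 else float("inf")
    if fold <= 1.0 + 1e-9:
        return 1.0, 0.0
    return float(fold), float(abs(slope))


def detect_boundaries(
    clips: list[ClipEvidence], min_support: int = 3
) -> tuple[int, int]:
    """Prophage boundaries from soft-clipped read evidence.

    Reads clipped at the prophage junctions pile up at attL/attR. The start
    is the modal position among right-clipped evidence and the end the modal
    position among left-clipped evidence, each requiring summed support of at
    least ``min_support``. Ties are broken by higher support, then by the
    smaller coordinate.
    """
    if not clips:
        raise InsufficientDataError("no clip evidence supplied")

    def modal(side: str) -> int:
        support: dict[int, int] = {}
        for c in clips:
            if c.side == side:
                support[c.position] = support.get(c.position, 0) + c.support
        if not support:
            raise InsufficientDataError(f"no {side} evidence")
        pos, best = min(support.items(), key=lambda kv: (-kv[1], kv[0]))
        if best < min_support:
            raise InsufficientDataError(
                f"best {side} position has support {best} < {min_support}"
            )
        return pos

    return modal("right_clip"), modal("left_clip")


def summarize_virome(
    tracks: CoverageTrack | dict[str, CoverageTrack],
    annotations: RepliconMap | list[RepliconMap],
    background: float | None = None,
) -> pd.DataFrame:
    """Per-feature mean coverage and share of total mapped read-bases.

    One row per prophage plus one ``<replicon>|host`` row per replicon for
    the non-prophage remainder (omitted when a replicon is fully covered by
    prophages). Fractions are shares of the summed depth over all supplied
    tracks and sum to 1.
    """
    if isinstance(tracks, CoverageTrack):
        tracks = {tracks.replicon_id: tracks}
    if isinstance(annotations, RepliconMap):
        annotations = [annotations]

    total = sum(float(t.depth.sum()) for t in tracks.values())
    rows: list[dict] = []
    for rep in annotations:
        track = tracks.get(rep.replicon_id)
        if track is None:
            continue
        covered = np.zeros(track.length, dtype=bool)
        for p in rep.prophages:
            if p.replicon_id != rep.replicon_id:
                continue
            sub = track.slice(p.start, p.end)
            covered[p.start - 1 : p.end] = True
            rows.append(
                {
                    "feature": p.name,
                    "replicon": rep.replicon_id,
                    "length_bp": p.length,
                    "mean_depth": float(sub.mean()),
                    "fraction_of_mapped_bases": float(sub.sum()) / total
                    if total > 0
                    else 0.0,
                }
            )
        rest = track.depth[~covered]
        if rest.size:
            rows.append(
                {
                    "feature": f"{rep.replicon_id}|host",
                    "replicon": rep.replicon_id,
                    "length_bp": int(rest.size),
                    "mean_depth": float(rest.mean()),
                    "fraction_of_mapped_bases": float(rest.sum()) / total
                    if total > 0
                    else 0.0,
                }
            )
    df = pd.DataFrame(rows)
    if background is not None and not df.empty:
        df["fold_over_background"] = df["mean_depth"] / background
    return df
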