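"""Seeded generators with the statistical structure the analyses assume.

Every stage of the pipeline can be exercised without any sequencing data:

* :func:`simulate_virome_coverage` builds per-base Poisson coverage tracks
  with the canonical footprint of an induced pac-type prophage — uniform
  bacterial-DNA contamination, a coverage jump at the pac site, headful
  steps of geometrically decreasing level downstream of attR, a smooth
  in-situ-replication gradient upstream of attL, and copy-number-inflated
  episome replicons. Defaults mirror the study conditions of a strongly
  induced P22-like prophage: 7.6 reads/bp contamination, ~35,000 reads/bp
  prophage plateau, first transduction step ~500 reads/bp (≈65-fold over
  background), 40,152 bp headfuls decaying 2.5-fold per step.
* :func:`simulate_qpcr` draws Cq values from a log-linear standard curve
  with Gaussian cycle noise.
* :func:`simulate_expression_table` builds bimodal prophage expression
  tables with planted morons at known folds.
* :func:`simulate_cell_counts` draws binomial induction counts.

All generators are pure functions of (config, seed): the same seed gives
bit-identical output. Depth is Poisson per base with no read-length
autocorrelation — adequate for windowed statistics, see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .moron_caller import CANDIDATE, CORE_PHAGE, ExpressionRecord
from .induction_stats import CellCounts
from .prophage_model import ProphageAnnotation
from .qpcr_quant import QpcrMeasurement
from .virome_coverage import CoverageTrack

__all__ = [
    "ProphageSimSpec",
    "ViromeSimConfig",
    "QpcrSimConfig",
    "ViromeGroundTruth",
    "simulate_virome_coverage",
    "simulate_qpcr",
    "simulate_expression_table",
    "simulate_cell_counts",
]


@dataclass(frozen=True)
class ProphageSimSpec:
    """One prophage to plant in a simulated track."""

    annotation: ProphageAnnotation
    induction_depth: float = 35_000.0  # intra-prophage plateau, reads/bp
    pac_offset: int | None = 20_270  # pac position relative to start, bp
    pre_pac_fraction: float = 0.6  # plateau level left of pac, as a fraction


@dataclass
class ViromeSimConfig:
    """Forward model of a virome coverage track over one host replicon.

    Parameters
    ----------
    replicon_length : host replicon size in bp.
    prophages : prophages to plant, with their induction depths.
    background_lambda : contaminating bacterial DNA, reads/bp (default 7.6).
    first_step_level : mean depth of the first headful step downstream of
        attR (default 500 reads/bp, ≈65-fold over the default background).
    headful_size : length of each transduction step (default 40,152 bp,
        i.e. 103.8% of a 38,682 bp prophage).
    step_decay : fold decrease per successive headful (default 2.5).
    n_steps : number of headful steps to plant.
    insitu_fold_at_att : coverage fold over background immediately upstream
        of attL (default 6.6, i.e. ~50 reads/bp over 7.6).
    insitu_decay_span : distance over which the in-situ gradient relaxes to
        background (default 100 kb).
    episome_copy_number : depth multiplier for episome replicons.
    """

    replicon_length: int = 1_000_000
    prophages: list[ProphageSimSpec] = field(default_factory=list)
    background_lambda: float = 7.6
    first_step_level: float = 500.0
    headful_size: int = 40_152
    step_decay: float = 2.5
    n_steps: int = 5
    insitu_fold_at_att: float = 6.6
    insitu_decay_span: int = 100_000
    episome_copy_number: float = 5.5

    def validate(self) -> None:
        if self.replicon_length < 1:
            raise InvalidParameterError("replicon_length must be >= 1")
        if self.background_lambda < 0 or self.first_step_level < 0:
            raise InvalidParameterError("rates must be >= 0")
        if self.step_decay <= 1:
            raise InvalidParameterError("step_decay must be > 1")
        if self.headful_size < 1 or self.n_steps < 0:
            raise InvalidParameterError("invalid headful configuration")


@dataclass
class ViromeGroundTruth:
    """Everything the generator planted, for recovery tests."""

    pac_positions: dict[str, int]
    step_boundaries: dict[str, list[int]]
    step_levels: dict[str, list[float]]
    insitu_fold_at_att: float
    background_lambda: float


def simulate_virome_coverage(
    config: ViromeSimConfig, seed: int
) -> tuple[CoverageTrack, ViromeGroundTruth]:
    """Draw one Poisson coverage track plus its generating ground truth."""
    config.validate()
    rng = np.random.default_rng(seed)
    mu = np.full(config.replicon_length, config.background_lambda, dtype=float)

    pac_positions: dict[str, int] = {}
    boundaries: dict[str, list[int]] = {}
    levels: dict[str, list[float]] = {}

    for spec in config.prophages:
        ann = spec.annotation
        if ann.end > config.replicon_length:
            raise InvalidParameterError(
                f"{ann.name} extends past the simulated replicon"
            )
        s, e = ann.start - 1, ann.end  # 0-based half-open
        if spec.pac_offset is not None:
            pac = ann.start + spec.pac_offset
            if not ann.start <= pac <= ann.end:
                raise InvalidParameterError(f"{ann.name}: pac_offset outside prophage")
            pac_positions[ann.name] = pac
            mu[s : pac - 1] = (
                config.background_lambda
                + spec.induction_depth * spec.pre_pac_fraction
            )
            mu[pac - 1 : e] = config.background_lambda + spec.induction_depth
        else:
            mu[s:e] = config.background_lambda + spec.induction_depth

        # headful steps downstream of attR
        step_bounds: list[int] = []
        step_levels: list[float] = []
        pos = ann.end  # 0-based index of first flank base
        for k in range(config.n_steps):
            level = config.first_step_level / config.step_decay**k
            nxt = min(pos + config.headful_size, config.replicon_length)
            if pos >= nxt:
                break
            mu[pos:nxt] = config.background_lambda + level
            step_bounds.append(pos + 1)  # 1-based first base of the step
            step_levels.append(level)
            pos = nxt
        boundaries[ann.name] = step_bounds
        levels[ann.name] = step_levels

        # in-situ replication gradient upstream of attL: log-linear relaxation
        span = min(config.insitu_decay_span, ann.start - 1)
        if span > 0 and config.insitu_fold_at_att > 1:
            d = np.arange(span, dtype=float)
            top = np.log2(config.insitu_fold_at_att * config.background_lambda + 1)
            bot = np.log2(config.background_lambda + 1)
            log_mu = top + (bot - top) * d / config.insitu_decay_span
            grad = 2.0**log_mu - 1.0
            # index 0 of grad sits immediately left of attL
            mu[ann.start - 1 - span : ann.start - 1] = np.maximum(
                grad[::-1], config.background_lambda
            )

    depth = rng.poisson(mu).astype(float)
    truth = ViromeGroundTruth(
        pac_positions=pac_positions,
        step_boundaries=boundaries,
        step_levels=levels,
        insitu_fold_at_att=config.insitu_fold_at_att,
        background_lambda=config.background_lambda,
    )
    return CoverageTrack(replicon_id="sim", depth=depth), truth


def simulate_episome_track(
    config: ViromeSimConfig, length: int, seed: int, replicon_id: str = "episome"
) -> CoverageTrack:
    """Episome replicon at background × copy number (contamination only)."""
    rng = np.random.default_rng(seed)
    lam = config.background_lambda * config.episome_copy_number
    return CoverageTrack(
        replicon_id=replicon_id, depth=rng.poisson(lam, size=length).astype(float)
    )


@dataclass
class QpcrSimConfig:
    """Cq draws from a known log-linear curve with Gaussian cycle noise."""

    true_copies: dict[str, float] = field(
        default_factory=lambda: {"target": 1e5}
    )
    slope: float = -3.3219  # perfect doubling
    intercept: float = 37.0
    cq_noise_sd: float = 0.2
    dilutions: tuple[float, ...] = (50.0, 100.0, 200.0, 400.0, 800.0)
    replicates: int = 3

    def validate(self) -> None:
        if self.slope >= 0:
            raise InvalidParameterError("slope must be negative")
        if self.cq_noise_sd < 0:
            raise InvalidParameterError("cq_noise_sd must be >= 0")
        if any(c <= 0 for c in self.true_copies.values()):
            raise InvalidParameterError("true copies must be > 0")


def simulate_qpcr(config: QpcrSimConfig, seed: int) -> list[QpcrMeasurement]:
    """Measurements for every (target, dilution, replicate) combination."""
    config.validate()
    rng = np.random.default_rng(seed)
    out: list[QpcrMeasurement] = []
    for target, copies in sorted(config.true_copies.items()):
        for dil in config.dilutions:
            for rep in range(1, config.replicates + 1):
                cq = (
                    config.intercept
                    + config.slope * np.log10(copies / dil)
                    + rng.normal(0.0, config.cq_noise_sd)
                )
                out.append(
                    QpcrMeasurement(
                        sample_id=f"sim_d{dil:g}",
                        target=target,
                        cq=float(cq),
                        dilution_factor=dil,
                        replicate=rep,
                    )
                )
    return out


def simulate_expression_table(
    n_core: int = 50,
    n_morons: int = 5,
    background_level: float = 10.0,
    moron_folds: list[float] | None = None,
    noise_cv: float = 0.2,
    n_replicates: int = 2,
    seed: int = 0,
    prophage: str = "sim_prophage",
    with_operon: bool = False,
) -> list[ExpressionRecord]:
    """Bimodal prophage expression table with planted morons.

    Core genes are lognormal around ``background_level`` (CV ``noise_cv``);
    moron k sits at ``background_level * moron_folds[k]``. With
    ``with_operon`` all morons share one operon id. ``noise_cv = 0`` gives
    exact folds.
    """
    if n_core < 1 or n_morons < 0:
        raise InvalidParameterError("need n_core >= 1 and n_morons >= 0")
    folds = list(moron_folds) if moron_folds is not None else [20.0] * n_morons
    if len(folds) != n_morons:
        raise InvalidParameterError("moron_folds length must equal n_morons")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))

    def draw(mean: float) -> list[float]:
        if sigma == 0:
            return [float(mean)] * n_replicates
        return list(
            mean * rng.lognormal(-(sigma**2) / 2.0, sigma, size=n_replicates)
        )

    records = [
        ExpressionRecord(
            gene_id=f"core_{i:03d}",
            prophage=prophage,
            category=CORE_PHAGE,
            fpkm_per_replicate=draw(background_level),
        )
        for i in range(n_core)
    ]
    for k, fold in enumerate(folds):
        records.append(
            ExpressionRecord(
                gene_id=f"moron_{k:03d}",
                prophage=prophage,
                category=CANDIDATE,
                operon_id="sim_operon" if with_operon else None,
                fpkm_per_replicate=draw(background_level * fold),
            )
        )
    return records


def simulate_cell_counts(
    p_induction: float, n_cells: int, seed: int, context: str = "sim"
) -> CellCounts:
    """Binomial draw of induced cells among ``n_cells`` observed."""
    if not 0.0 <= p_induction <= 1.0:
        raise InvalidParameterError("p_induction must lie in [0, 1]")
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    return CellCounts(
        n_induced=int(rng.binomial(n_cells, p_induction)),
        n_total=n_cells,
        context=context,
    )
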