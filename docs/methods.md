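# Methods

## Coordinate conventions

All genomic coordinates are 1-based and inclusive, so an interval
[start, end] has length end − start + 1; this is the convention under which
published prophage boundary tables reproduce their printed sizes exactly
(e.g. 998,954–1,037,635 → 38,682 bp). bedGraph input (0-based half-open) is
converted at the I/O boundary and nowhere else.

## Virome coverage model

The virome — filtered, nuclease-protected DNA from a culture supernatant —
is mapped to the host genome and summarised as per-base depth. Three
signals are modelled:

**Contamination background.** Residual bacterial DNA covers the genome
roughly uniformly. `estimate_background` summarises depth over all
positions outside a mask (prophages plus any transduction-affected flank:
the headful-step region beyond *attR* and the in-situ replication gradient
upstream of *attL*). The default statistic is the mean, matching how such
contamination levels are conventionally reported; the median is available
for robustness against unmasked hotspots.

**Prophage activity.** Depth over a prophage and over a background region
(by default 50 kb on each side of the integration site; for prophages whose
flanks are transduction-affected, a distal region upstream) is cut into
non-overlapping 5 kb windows and the window means compared with a
one-sided, unequal-variance (Welch) two-sample *t*-test, alternative
"greater". Welch is the default because it is the reference behaviour of
the standard R `t.test`; a pooled-variance variant is available by flag.
Windowing rule: a trailing partial window at least half a window long is
kept, shorter ones are dropped (the rule is our choice; only "5 kb
portions" is conventional). Degenerate comparisons where both sides have
zero variance return p = 1 (and never "active") rather than NaN.

**pac site.** Headful packaging initiates at *pac*, producing a sharp
upward coverage jump inside the prophage. The depth is smoothed with a
centered 200 bp moving average (width our choice; the real signal is a
near-discontinuity) and the position of the maximal positive forward
difference is reported, ties broken toward the smaller coordinate. If no
jump exceeds twice the robust (MAD-based) noise scale of the differences,
"no pac detected" is returned — a signal distinct from an error.

**Headful steps (lateral transduction).** Downstream of *attR*, each
packaging series continues into host DNA, one headful (~103.8% of the
prophage length) per capsid, so successively fewer capsids cover
successively more distal DNA: piecewise-constant coverage steps. The flank
(300 kb by default) is binned to 200 bp, log2(depth + 1)-transformed, and
segmented by binary segmentation minimising within-segment squared error; a
split is accepted when it reduces the cost by more than a BIC-style penalty
`3 · σ² · log(n_bins) · min_size`, with σ estimated robustly from first
differences of the binned signal. The log scale makes Poisson noise
approximately level-independent, which is what lets a single penalty serve
steps spanning two orders of magnitude. Minimum segment length is a quarter
of the expected step when one is supplied (e.g. from the headful capacity),
else 10 kb. Reported quantities: breakpoints; linear-scale segment means;
adjacent fold decreases (expected 2–3× for high steps — note the additive
background compresses the fold between the lowest steps); headful size =
median spacing between segment boundaries (flank start included); and the
transduction extent, the distance to the end of the farthest segment whose
level exceeds `background × extent_factor` (factor 2 by default). Levels
are not forced to decrease; increases are counted as diagnostics.

**In-situ replication.** Bidirectional replication of the induced prophage
before excision inflates the *attL*-side flank smoothly. We fit
log2(depth + 1) against distance from *attL* by least squares over 100 kb
and report the fold at the att site, `(2^intercept − 1) / background`
(subtracting the 1 that the log transform added, so a flank exactly at
background gives fold 1.0), and the decay rate |slope|. Flanks with no
signal above background report (1, 0).

**Boundaries from clipped reads.** Reads soft-clipped at the prophage
junctions pile up at *attL*/*attR*; boundaries are the modal positions of
right- and left-clipped evidence with summed support ≥ 3, ties broken by
higher support then smaller coordinate.

## qPCR quantification

Standard curves are least-squares fits Cq = intercept + slope·log10(copies)
over a dilution series (≥ 3 distinct levels required); efficiency is
10^(−1/slope) − 1, with curves outside [0.9, 1.1] flagged. Copy-number
ratios use ΔΔCt, ratio = (1+E)^(Cq_ref − Cq_target), averaged across
dilution pairs; E defaults to 1.0 (perfect doubling) unless per-target
curves are supplied. Contamination logic: a prophage's expected signal from
bacterial-DNA carry-over is the host concentration measured on a
single-copy reference gene times the prophage copy number (1 for integrated
prophages; e.g. 5.5 for a multi-copy phage-plasmid). Replicates at or below
that level are flagged and excluded from means and fold-induction
computations. Instability factors (measured virion losses in a given
matrix, e.g. 20× for an unstable phage in stored macrophage lysate, 3× for
a hardier one) are per-target, per-context constants applied only in the
context where the loss was measured — applying them globally would corrupt
in-vitro ratios. Fold display follows the reporting convention of integers
at ≥ 10 and one decimal below; significance stars are * < 0.05, ** < 0.01,
*** < 0.005.

## Moron calling

The expression of a prophage region in a lysogen is bimodal: a large group
of silent phage-cycle genes and a small group of autonomously expressed
genes. Per prophage, the local background is the median replicate-averaged
fpkm over **all** genes of the region; candidate genes (everything not
curated as core phage machinery — the curation is an input annotation, not
inferred) at ≥ 5× background are called, and uncalled candidates sharing an
operon with a called gene are rescued with any positive expression (the
rescue has no lower fold bound; the canonical rescued example sits at
4-fold). Folds are computed on the linear fpkm scale; log2(fpkm + 5) is
supported as a storage/plotting transform only. Replicates are combined by
arithmetic mean before the median. A gap diagnostic (`bimodality_gap`)
reports the largest consecutive ratio in the upper half of the sorted
values as a check that the bimodality assumption holds.

The packaged LF82 table encodes the published per-gene folds directly
(background ≡ 1.0); the silent bulk of each prophage is represented by
synthetic filler genes placed so each region's median is exactly 1.0, as
stated in the file header. The fixture therefore reproduces the published
call set (29 morons: 0/7/7/2/13 across Gally, Perceval, Tritos, Cartapus,
Cyrano) but carries no information about absolute expression levels.

## Induction statistics

Proportions (induction frequency, conditional lysis, lysogenization) use
Wilson 95% intervals — chosen over Wald because the assays routinely
produce counts like 1/2,232 where Wald degenerates. "Induced" pools intact
and recently lysed reporter-positive cells. Percent display: two decimals
below 1%, integers at ≥ 1% (0.37 / 44 / 0.04). Lysogenization calls
"above background" strictly (a ratio exactly at the spontaneous-resistance
rate is not above it). Survival ratios use two-sided Welch *t*-tests.

## Synthetic data

Generators are pure functions of (config, seed) via `numpy`'s PCG64.
Coverage is Poisson per base around a deterministic mean profile:
background 7.6 reads/bp; intra-prophage plateau 35,000 reads/bp with a
0.6× shoulder left of *pac*; headful steps of 40,152 bp starting at 500
reads/bp and decaying 2.5× per step (five steps); an in-situ gradient
relaxing log-linearly from 6.6× background to background over 100 kb;
episome replicons at background × copy number. These defaults are the
study conditions of a strongly induced P22-like prophage and are what the
validation suite runs at. qPCR draws add Gaussian noise (sd 0.2 cycles by
default) to curve-predicted Cq values; expression tables are lognormal
around the background with planted morons at fixed folds; cell counts are
binomial.

Fidelity limits: per-base Poisson depth has no read-length autocorrelation,
no GC or mappability bias, and no duplicate structure, so passing recovery
tests demonstrate correctness of the estimators under the assumed
statistical structure, not robustness to mapping artefacts of real
libraries. Real per-prophage p-values from a sequencing run are
dataset-specific and are not reproduced here.

## Problem sizes used in the validation suite

Calibration and recovery checks run at sizes chosen to make their
uncertainty much smaller than the tested tolerance: 1,000 null simulations
of 20-window tracks for type-I error (band 0.03–0.07 at α = 0.05); 100
seeded tracks of 450 kb for pac (±200 bp) and headful (±5%) recovery at
first-step depth 500; 100 qPCR round trips at Cq noise 0.2 (median error
< 10%); 25 dilution-series simulations for copy-number recovery
(5.5 ± 0.5); 100 expression tables for planted-moron recovery (≥ 95 exact);
2,000 binomial draws per condition for Wilson coverage (93–97%).

## Known limitations

* Segmentation validates on simulations only; whether published step
  boundaries were fitted or drawn by eye is not stated in the sources the
  defaults mirror, so no claim of boundary-level agreement is made.
* The attB ORF check uses ATG-initiated ORFs (≥ 300 bp, both strands);
  alternative starts (GTG/TTG) are off by default.
* The episome length in the packaged annotation fixture is nominal; only
  its mode and copy number feed the analyses.
* Boundary-base assignment at a duplicated att core (a prophage annotated
  to carry only its attR copy) is not modelled; boundaries are taken as
  given by the annotation.
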