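# Methods

This note documents the models behind `longtemplate`: what the simulator
emulates, how each pipeline stage works, which parameters matter and why
their defaults were chosen, and what the package's passing tests do and do
not establish about real sequencer data.

## Tile simulator (`flowcell_sim`)

One sequencing-by-synthesis cycle produces four single-channel images of a
tile; each cluster appears as a spot in the channel of the base it
incorporated. The simulator draws ground-truth clusters and renders these
images.

**Placement.** Homogeneous Poisson: the cluster count is Poisson with mean
`optimal_density × density_fraction × tile_area` and positions are uniform.
An optional hard-core exclusion radius thins pairs closer than a minimum
spacing (clusters are physical colonies of roughly 1 px at our scale and
cannot grow concentrically); it is off by default and switched on where a
particular experiment warrants it (see *Multiplexed lanes* below).

**Sequences.** A `lowdiv_fraction` share of clusters carries one of the
configured 5′ prefixes (default: the two 11-nt BLESS barcodes
`TCGAGGTAGTA`/`TCGAGACGACG`) followed by i.i.d. uniform bases; the rest are
fully random. Amplitudes are log-normal with mean 4000 counts and CV 0.3.

**Optics and noise.** Isotropic Gaussian PSF, σ = 1.2 px, truncated at 4σ
(≥ 99.9 % of flux); each spot integrates to its amplitude. Channels can be
mixed by a row-stochastic 4×4 crosstalk matrix (identity by default).
Constant background (100 counts) plus Gaussian read noise (SD 10) are
added; Poisson shot noise is available but off by default so that analytic
oracles (linearity, flux integrals, composition shares) hold exactly.
In-memory images are float64 clipped to [0, 65535]; quantisation to uint16
happens only at TIFF export, keeping noiseless renders exactly linear in
amplitude.

**Geometry and drift.** Default tile 512×512 px. Cycle 1 is imaged at
offset (0, 0); later cycles are translated by independent uniform offsets
in ±2 px (stage drift), the only inter-cycle misregistration modelled.

**Cluster density.** The reference "optimal" density is 0.02 clusters/px²
(~5200 clusters per default tile, mean nearest-neighbour spacing ≈ 3.5 px
at σ = 1.2 px). This value defines what "100 % density" means in this
package and was chosen to reproduce the semantics optimal density has on a
real flowcell: a fully diverse library still resolves well (neighbours
usually occupy different channels), while a library sharing a 5′ prefix
puts every neighbour into one channel and merges a large fraction of
clusters. Densities meaningfully above this degrade even diverse libraries;
fractions of 0.65–0.75 measurably mitigate the low-diversity failure.

## Template engine (`template_engine`)

**Spot detection.** Each channel image is searched separately: local maxima
(3×3 neighbourhood) exceeding background + 4 robust SDs (median/MAD), with
sub-pixel refinement by the centre of mass of the background-subtracted 3×3
patch; within-channel peaks closer than `merge_radius_px` (1.5) collapse to
an intensity-weighted centroid. The four per-channel lists are then
combined, collapsing coincidences within `cross_channel_merge_px` (0.75),
which removes crosstalk ghosts of a single physical cluster without merging
genuinely distinct neighbours that happen to occupy different channels.
Two clusters sharing a base and sitting within ~2σ of each other produce a
single summed-Gaussian maximum and are irreversibly reported as one spot —
the failure mode a low-diversity cycle suffers tile-wide. Detection is
per-channel rather than on the max-over-channels composite because the
composite is resolution-limited by the pixel grid for *different*-channel
neighbours as well, which blurs the distinction between diverse and
non-diverse cycles that the whole method turns on.

**Golden/silver and the union rule.** Spot counts are computed for each of
the `template_cycle_count` cycles; the cycle with the most spots is golden,
the runner-up silver (ties to the earlier cycle). The silver cycle is
registered to the golden frame, and the template is the union of the two
spot lists under a *one-to-one* dedup: each golden spot absorbs at most its
single nearest silver spot within `dedup_radius_px` (1.5). One-to-one
matters: when the golden cycle merged a close pair into one centroid, the
silver cycle (with different bases) often resolves both members; plain
radius-dedup would discard both silver spots against the one centroid,
while one-to-one keeps the second as a rescue. The final union is collapsed
at the 0.75-px minimum position separation. The template is immutable
afterwards.

**Registration.** Translation-only, as on the instrument: a synthetic image
of unit Gaussians at the template positions is FFT-cross-correlated with
the cycle's max-channel image; the integer argmax within ±8 px is refined
per axis by a three-point quadratic fit. Accuracy on simulated drift is
≤ 0.25 px; integer shifts are recovered exactly at integer resolution.

**Recovery metric.** `template_recovery` matches template positions to true
cluster positions one-to-one (greedy nearest pair) within 1.5 px, so a
merged centroid can account for only one of the clusters behind it. At the
default density, 100 % low-diversity with a 5-nt prefix: 4-cycle templates
recover ~0.75–0.77 of true clusters; (prefix+2)-cycle templates recover
~0.95–0.98; recovery is non-decreasing in template length between the two.

**Memory model.** Bytes per template cycle = channels × width × height ×
bytes/pixel; totals scale exactly linearly in template length. Decimal GB
(10⁹ bytes) throughout, matching the instrument-scale arithmetic
(2.62 GB/cycle for four 16-bit 2048×160000 images; 10.49 GB for 4 cycles;
52.4 GB for 20). `max_template_length` is `⌊RAM / GB-per-cycle⌋`.

## Base caller (`base_caller`)

**Extraction.** Two modes share one interface.

* *Aperture* (default): background-subtracted Gaussian-weighted sum in a
  3σ window, with the weighting kernel at **half** the PSF sigma. A matched
  filter (kernel = PSF) would maximize SNR for an isolated spot but pulls
  in 50–70 % of a neighbour's flux at 1.5–2 px separation; the narrow
  aperture trades a little SNR for much better isolation. SNR is not
  limiting at the simulated noise levels.
* *Joint* (`method="joint"`): the image is modelled as a sum of unit
  Gaussians at all template positions and per-position amplitudes are
  obtained by solving the sparse normal equations (Gram entries
  exp(−d²/4σ²), one LU factorization reused across all cycles and channels
  since a whole-image translation preserves pairwise distances; ridge
  1e−3). Resolved overlapping neighbours are thereby unmixed almost
  exactly; a *merged* template position — two clusters behind one
  coordinate — remains an irreversible mixture. This is the extraction
  used for demultiplexing, where contamination of the 6-cycle index read
  cannot be caught by any chastity history.

**Calling and chastity.** Base = argmax channel; chastity =
I₁/(I₁+I₂) over the two largest channel intensities; an all-zero cycle
calls N with chastity 0.25. The purity filter passes a read iff at most one
of its first 25 cycles has chastity < 0.6 (the conventional values; the
source material names the filter without specifying them, so both are
parameters).

**Quality model.** Monotone piecewise-linear map from chastity to Phred:
0.5 → Q2, 0.6 → Q21, 0.75 → Q30, 1.0 → Q40 (cap). The Q21 knot sits at the
chastity-filter threshold so that calls the purity filter deems usable also
clear per-base Q20 — without it, the 34-consecutive-Q20 read filter would
silently re-apply a much stricter chastity cut than the purity filter
itself. This is a deliberately simple desk-scale model, not a recalibrated
quality table; absolute %Q30-style figures produced under it are not
comparable to instrument values.

## Read QC (`read_qc`)

The quality filter keeps reads with ≥ 34 consecutive bases **strictly
above** Q20 (the boundary reading "above" as > is documented and
configurable). Barcode matching is exact-prefix by default ("intact"
barcode, 0 mismatches); N calls never match. `normalized_barcode_pct`
divides the raw %-barcoded by the low-diversity share of the library, so a
sample that is 10 % barcoded material with 10 % barcoded reads normalizes
to 100 %. The AasI redesign returns the four primers
(`GACNNNNNNGTC`-patterned, variable dinucleotides reverse-complement
paired) and their 5-mer barcodes {ACGTC, CTGTC, TGGTC, GAGTC}, which cover
all four bases at cycle 1; per-position balance is quantified as Shannon
entropy over base frequencies divided by 2 bits (a package-defined metric).

## Bleeding statistics (`bleeding_stats`)

**Null model.** `index_morph_prob` in `any_errors` mode is the upper
binomial tail P(X ≥ d), X ~ Binomial(n, p) — at least d sequencing errors
in an n-nt index, the loosest condition under which one valid index can
morph into another at distance d. A `specific_substitutions` mode,
(p/3)^d (1−p)^(n−d), is provided for sensitivity analysis (each error must
hit one specific alternative base). The `any_errors` mode reproduces the
published figures (9.3×10⁻⁹ at n=6, d=4, p=0.5 %; <2×10⁻⁸ and <2×10⁻¹¹ at
d=3 for p=10⁻³ and 10⁻⁴; 4.3×10⁻⁶ at n=7, d=3, p=0.5 % — the 7-nt reading
of that figure is adopted because the 6-nt computation gives 2.5×10⁻⁶).

**Mapping.** "Maps with 0 mismatches" is implemented as exact substring
search (forward or reverse complement) against small synthetic references
(~20 kb), preserving the 0-mismatch criterion at desk scale; there is no
gapped or mismatch-tolerant alignment.

**Multiplexed lanes.** `simulate_multiplexed_lane` renders a two-sample
lane in which both samples' reads share one 5-nt 5′ barcode followed by a
45-nt exact substring of their own reference, plus a separate 6-cycle index
read (TruSeq-style indices at Hamming distance 6) rendered from the same
positions. Two modelling choices define the bleeding mechanism:

* each cluster's index-read amplitude equals its insert-read amplitude
  times a log-normal re-priming jitter (CV 0.35) — the index read follows
  its own priming step whose efficiency varies per cluster but is strongly
  correlated with cluster brightness;
* placement uses a 1-px hard-core exclusion, so fully coincident pairs
  (which no template of any length could separate, and which would only
  add a template-independent noise floor) do not occur.

A merged cross-sample cluster pair can then pass the chastity and quality
filters dominated by one member's insert while the jitter hands the index
read to the other member — a clean read demultiplexed into the wrong
sample. With joint extraction, *resolved* neighbours are unmixed and do not
bleed; what a merged template position cannot unmix is precisely the
bleeding risk, which is why template length controls the rate. On the
default lane (384² px, 50/50 mix, normal density), 4-cycle templates show
median observed bleeding of a few 10⁻³ while (prefix+2)-cycle templates
show a median at or near zero — the direction and at least the 2× magnitude
of the published comparison, at desk-scale counts.

The expected rate attached to a lane estimate uses the binomial null with
the lane's actual index length and pairwise distance at p = 0.5 %
(Phred 23); observed/expected ratios are rounded half-away-from-zero for
table-style output.

## Orchestration (`report`, `cli`)

`run_cell`/`run_experiment` run simulate → template → call → qc for each
grid cell and emit `RunReport` rows: purity-pass read count, %Q30 (fraction
of called bases with Q ≥ 30 among purity-pass reads — the base-level
reading of the ambiguous "reads with Phred > 30" phrasing; switchable),
raw and normalized %-barcoded (computed among purity-pass reads that also
pass the quality filter), and the one-to-one template recovery. The CLI
(`simulate`, `template`, `call`, `qc`, `bleed`, `report`, `memory`) is a
thin layer over these functions; images travel as single-page 16-bit
little-endian TIFFs (`C{cycle}_{base}.tif`) with a YAML run manifest and a
TSV ground-truth table.

## Problem sizes

Simulation-based tests run at 256–512 px tiles (≈ 1 300–5 200 clusters),
8–25 cycles, 3–10 seeds per claim; multiplexed-lane experiments use 384 px
tiles (≈ 2 900 clusters) over 10 seeds. These sizes give stable medians for
every directional claim while keeping the full suite in a few minutes.

## What the simulations do and do not show

The generator reproduces the *structure* of the problem — per-cycle
channel images, PSF-limited spot merging, template immutability, chastity
statistics of mixed clusters, index misassignment at merged positions — and
the package's tests demonstrate the mechanisms on that synthetic ground
truth. It does not model bridge-amplification chemistry, phasing/
pre-phasing, quality decay along the read, optical aberrations or tile
stitching, real genomic sequence composition, or instrument-scale read
counts; absolute yields, %Q30 values and bleeding rates are therefore not
comparable to instrument data — only the analytic quantities (binomial
tails, rate ratios, memory arithmetic, normalization folds) and the
directions and orderings of the mechanism experiments are.

## Known limitations

* The spot detector and extraction models stand in for undisclosed
  instrument internals; parameters are exposed and defaults documented, but
  no claim is made that they match the vendor's implementation.
* Joint extraction assumes the PSF is known exactly and identical for all
  clusters; it degrades gracefully (ridge) but is not robust to strong PSF
  mismatch.
* The bleeding model attributes index/insert disagreement entirely to
  re-priming efficiency jitter; other real sources (library cross-
  contamination, oligo synthesis errors, free-adapter exchange) are out of
  scope.
* Demultiplexing requires an exact index match; mismatch-tolerant demux
  would raise observed bleeding for both protocols roughly equally.
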