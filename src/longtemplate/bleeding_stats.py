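"""Sample bleeding: observed rates, the binomial index-morphing null, and
an end-to-end measurement on simulated multiplexed lanes.

*Sample bleeding* is the misassignment of reads between samples
multiplexed in one lane.  Under the classical explanation — sequencing
errors corrupting one valid index into another — the rate is bounded by an
upper-tail binomial probability and is astronomically small for indices
with pairwise Hamming distance >= 3 at realistic per-base error rates.
Observed bleeding exceeds that bound by orders of magnitude because the
dominant mechanism is merged clusters: two clusters behind one template
position, where the insert read can follow one sample and the index read
the other.  Longer templates resolve more clusters and therefore reduce
bleeding.

"Mapping" here is exact substring search (forward or reverse complement)
against small synthetic references, which preserves the 0-mismatch
cross-mapping criterion at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from longtemplate.flowcell_sim import (
    BASES,
    ClusterGroundTruth,
    CycleImageSet,
    SimConfig,
    draw_positions,
    render_cycle,
    _lognormal_params,
)
from longtemplate.template_engine import Template, TemplateConfig, build_template
from longtemplate.base_caller import ReadRecord, call_run, extract_intensities, call_bases
from longtemplate.read_qc import BarcodeSet, hamming_distance, match_barcode, quality_filter


def phred_to_error(q: float) -> float:
    """Phred score -> per-base error probability, 10**(-q/10)."""
    if q < 0:
        raise ValueError("Phred score must be nonnegative")
    return 10.0 ** (-q / 10.0)


@dataclass(frozen=True)
class BinomialIndexModel:
    """Null model for one valid index morphing into another by errors.

    ``n`` is the index length, ``d`` the Hamming distance to the other
    valid index, ``p`` the per-base error probability.  In ``any_errors``
    mode the morph probability is the upper binomial tail P(X >= d) with
    X ~ Binomial(n, p): the chance of at least d sequencing errors, i.e.
    the loosest bound under which a morph is possible at all.  In
    ``specific_substitutions`` mode each of the d errors must additionally
    hit one specific alternative base: (p/3)^d (1-p)^(n-d).
    """

    n: int = 6
    d: int = 3
    p: float = 0.005
    mode: str = "any_errors"

    def __post_init__(self) -> None:
        if not 1 <= self.d <= self.n:
            raise ValueError("need 1 <= d <= n")
        if not 0 < self.p < 1:
            raise ValueError("need 0 < p < 1")
        if self.mode not in ("any_errors", "specific_substitutions"):
            raise ValueError(f"unknown mode {self.mode!r}")


def index_morph_prob(model: BinomialIndexModel) -> float:
    """Probability of an index morphing into another valid one under the null."""
    if model.mode == "any_errors":
        return float(stats.binom.sf(model.d - 1, model.n, model.p))
    return (model.p / 3.0) ** model.d * (1.0 - model.p) ** (model.n - model.d)


@dataclass
class BleedingEstimate:
    """Observed vs expected bleeding, with the counts it came from."""

    n_cross: int
    n_total: int
    expected: float
    observed: float = field(init=False)
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        self.observed = observed_bleeding(self.n_cross, self.n_total)
        self.ratio = self.observed / self.expected if self.expected > 0 else math.inf


def observed_bleeding(n_cross: int, n_total: int) -> float:
    """Fraction of reads in one sample's bin that cross-map to the other."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_cross <= n_total:
        raise ValueError("need 0 <= n_cross <= n_total")
    return n_cross / n_total


def obs_exp_ratio(observed: float, expected: float) -> int:
    """Observed/expected ratio rounded half-away-from-zero to an integer."""
    if expected <= 0:
        raise ValueError("expected must be positive")
    r = observed / expected
    return int(math.floor(r + 0.5)) if r >= 0 else -int(math.floor(-r + 0.5))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def maps_to(seq: str, ref: str) -> bool:
    """Exact-substring 'alignment': seq or its reverse complement in ref."""
    return seq in ref or _revcomp(seq) in ref


def cross_map(
    reads: Sequence[str],
    ref_own: str,
    ref_other: str,
    model: BinomialIndexModel | None = None,
) -> BleedingEstimate:
    """Count reads that map only to the *other* sample's reference.

    A read is cross-mapped iff it (or its reverse complement) occurs
    exactly in ``ref_other`` and does not occur in ``ref_own`` — the
    0-mismatch criterion.  ``expected`` comes from the binomial null.
    """
    if not ref_own or not ref_other:
        raise ValueError("references must be non-empty")
    model = model or BinomialIndexModel(n=6, d=4, p=0.005)
    n_cross = sum(
        1 for r in reads if maps_to(r, ref_other) and not maps_to(r, ref_own)
    )
    return BleedingEstimate(
        n_cross=n_cross, n_total=len(reads), expected=index_morph_prob(model)
    )


# ---------------------------------------------------------------------------
# end-to-end multiplexed lane simulation


#: TruSeq-style 6 nt indices for the two lane samples (Hamming distance 6).
DEFAULT_INDICES = {"human": "ATCACG", "yeast": "CGATGT"}


@dataclass
class MultiplexedLane:
    """A rendered two-sample lane: insert cycles, index cycles, truth."""

    config: SimConfig
    clusters: list[ClusterGroundTruth]
    image_sets: list[CycleImageSet]
    index_image_sets: list[CycleImageSet]
    references: dict[str, str]
    indices: dict[str, str]
    barcode: str
    insert_length: int


def _random_reference(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, size=length))


def simulate_multiplexed_lane(
    seed: int,
    tile_px: int = 384,
    density_fraction: float = 1.0,
    barcode: str = "TCGAG",
    insert_length: int = 45,
    ref_length: int = 20000,
    sample_fractions: dict[str, float] | None = None,
    indices: dict[str, str] | None = None,
    drift_px: float = 2.0,
    index_jitter_cv: float = 0.35,
    exclusion_radius_px: float = 1.0,
) -> MultiplexedLane:
    """Simulate one two-sample multiplexed lane sharing a 5' barcode.

    Both samples' reads start with the same low-diversity ``barcode``
    followed by an exact substring of their own synthetic reference, so a
    short (4-cycle) template sits entirely inside the shared prefix.  The
    index read is rendered from the same cluster positions, with each
    cluster's index amplitude equal to its read amplitude times a
    log-normal re-priming jitter of CV ``index_jitter_cv`` (the index read
    follows a separate priming step whose efficiency varies per cluster).
    For a merged cluster pair, the jitter lets the insert read and the
    index read each follow a *different* member — the bleeding mechanism.

    Cluster placement uses a hard-core exclusion radius of one pixel:
    colonies are physical objects of roughly that size and cannot grow
    concentrically, so fully coincident cluster pairs (which no template,
    however long, could ever separate) do not occur.
    """
    sample_fractions = sample_fractions or {"human": 0.5, "yeast": 0.5}
    indices = indices or dict(DEFAULT_INDICES)
    rng = np.random.default_rng([seed, 555])
    n_cycles = len(barcode) + insert_length
    config = SimConfig(
        tile_width_px=tile_px,
        tile_height_px=tile_px,
        density_fraction=density_fraction,
        n_cycles=n_cycles,
        lowdiv_fraction=1.0,
        prefix_sequences=(barcode,),
        drift_px=drift_px,
        exclusion_radius_px=exclusion_radius_px,
        seed=seed,
    )
    references = {s: _random_reference(rng, ref_length) for s in sample_fractions}
    xy = draw_positions(rng, config)
    n = len(xy)
    labels = list(sample_fractions)
    probs = np.array([sample_fractions[s] for s in labels], dtype=float)
    probs /= probs.sum()
    which = rng.choice(len(labels), size=n, p=probs)
    mu, sig = _lognormal_params(config.amplitude_mean, config.amplitude_cv)
    amps = rng.lognormal(mu, sig, size=n)
    mu_j, sig_j = _lognormal_params(1.0, index_jitter_cv)
    index_amps = amps * rng.lognormal(mu_j, sig_j, size=n)
    clusters = []
    for i in range(n):
        label = labels[which[i]]
        ref = references[label]
        start = rng.integers(0, len(ref) - insert_length + 1)
        clusters.append(
            ClusterGroundTruth(
                id=i,
                x_px=float(xy[i, 0]),
                y_px=float(xy[i, 1]),
                sequence=barcode + ref[start : start + insert_length],
                amplitude=float(amps[i]),
                sample_label=label,
                index_sequence=indices[label],
                index_amplitude=float(index_amps[i]),
            )
        )
    # insert read cycles
    offsets = [(0.0, 0.0)] + [
        tuple(rng.uniform(-drift_px, drift_px, 2)) for _ in range(n_cycles - 1)
    ]
    image_sets = [
        render_cycle(clusters, c, config, offsets[c - 1]) for c in range(1, n_cycles + 1)
    ]
    # index read: same positions, independent amplitudes, own drift
    index_len = len(next(iter(indices.values())))
    index_clusters = [
        ClusterGroundTruth(
            id=c.id,
            x_px=c.x_px,
            y_px=c.y_px,
            sequence=c.index_sequence,
            amplitude=c.index_amplitude,
            sample_label=c.sample_label,
        )
        for c in clusters
    ]
    index_config = SimConfig(
        tile_width_px=tile_px,
        tile_height_px=tile_px,
        density_fraction=density_fraction,
        n_cycles=index_len,
        drift_px=drift_px,
        seed=seed + 1,
    )
    index_offsets = [
        tuple(rng.uniform(-drift_px, drift_px, 2)) for _ in range(index_len)
    ]
    index_image_sets = [
        render_cycle(index_clusters, c, index_config, index_offsets[c - 1])
        for c in range(1, index_len + 1)
    ]
    return MultiplexedLane(
        config=config,
        clusters=clusters,
        image_sets=image_sets,
        index_image_sets=index_image_sets,
        references=references,
        indices=indices,
        barcode=barcode,
        insert_length=insert_length,
    )


def measure_lane_bleeding(
    lane: MultiplexedLane,
    template_cycle_count: int = 4,
    focal_sample: str = "human",
    template_cfg: TemplateConfig | None = None,
    model: BinomialIndexModel | None = None,
    extraction: str = "joint",
) -> BleedingEstimate:
    """Run the full pipeline on a lane and measure bleeding into one bin.

    Template -> registration -> base calls (insert and index reads) ->
    chastity filter -> demultiplex by exact index match -> quality filter
    -> trim the shared 5' barcode -> map each read in the focal sample's
    bin against both references.  Bleeding = fraction of the focal bin
    that maps, with 0 mismatches, only to the other sample's reference.
    """
    cfg = template_cfg or TemplateConfig(template_cycle_count=template_cycle_count)
    if cfg.template_cycle_count != template_cycle_count:
        cfg = TemplateConfig(
            template_cycle_count=template_cycle_count,
            first_template_cycle=cfg.first_template_cycle,
            detection_threshold_sd=cfg.detection_threshold_sd,
            merge_radius_px=cfg.merge_radius_px,
            dedup_radius_px=cfg.dedup_radius_px,
            psf_sigma_px=cfg.psf_sigma_px,
        )
    template = build_template(lane.image_sets, cfg)
    # joint extraction unmixes resolved neighbours for both reads; what a
    # merged template position cannot unmix is exactly the bleeding risk
    reads = call_run(template, lane.image_sets, cfg=cfg, method=extraction)
    index_iv = extract_intensities(
        template, lane.index_image_sets, None, cfg.psf_sigma_px, cfg, method=extraction
    )
    index_reads = call_bases(index_iv)
    if model is None:
        labels = list(lane.indices)
        d = (
            hamming_distance(lane.indices[labels[0]], lane.indices[labels[1]])
            if len(labels) == 2
            else 3
        )
        model = BinomialIndexModel(
            n=len(lane.indices[labels[0]]), d=d, p=phred_to_error(23.0)
        )
    bc_set = BarcodeSet(barcodes=(lane.barcode,), name="shared_prefix")
    other = [s for s in lane.references if s != focal_sample]
    ref_own = lane.references[focal_sample]
    ref_other = "".join(lane.references[s] for s in other)
    bin_reads = []
    for read, idx_read in zip(reads, index_reads):
        if not read.purity_pass or not quality_filter(read):
            continue
        sample = next(
            (s for s, idx in lane.indices.items() if idx_read.bases == idx), None
        )
        read.index_called = idx_read.bases
        if sample != focal_sample:
            continue
        bc, trimmed = match_barcode(read.bases, bc_set)
        if bc is None:
            continue
        bin_reads.append(trimmed)
    if not bin_reads:
        return BleedingEstimate(n_cross=0, n_total=1, expected=index_morph_prob(model))
    n_cross = sum(
        1 for r in bin_reads if maps_to(r, ref_other) and not maps_to(r, ref_own)
    )
    return BleedingEstimate(
        n_cross=n_cross, n_total=len(bin_reads), expected=index_morph_prob(model)
    )
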