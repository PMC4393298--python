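"""Synthetic flowcell tile simulator.

One sequencing cycle of sequencing-by-synthesis produces four single-channel
images of the same tile, one per nucleotide; every cluster shows up as a
diffraction-limited spot in the channel of the base it incorporated that
cycle.  This module generates ground-truth clusters (positions, sequences,
amplitudes) and renders per-cycle four-channel 16-bit tiles with a Gaussian
point-spread function, channel crosstalk, background and read noise, and a
per-cycle whole-image translation (stage drift).

A *low-diversity* library is one whose reads share a fixed 5' prefix (e.g.
an 11 nt BLESS barcode): in the prefix cycles every cluster lights up the
same channel, so spots crowd one image and neighbouring clusters merge —
the failure mode the rest of the package studies.

In-memory channel images are kept as float64 (clipped to the 16-bit range);
quantisation to uint16 happens only when writing TIFFs, so that noiseless
renders remain exactly linear in cluster amplitude.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Desk-scale stand-in for the manufacturer's optimal cluster density,
#: in clusters per pixel^2.  At 512x512 this gives ~5200 clusters per tile
#: (mean nearest-neighbour spacing ~3.5 px at a 1.2 px PSF sigma): the
#: working regime of a real flowcell, where a fully diverse library still
#: resolves well because neighbours usually occupy different channels,
#: while a shared 5' prefix puts every neighbour in one channel and merges
#: a large share of clusters.
DEFAULT_OPTIMAL_DENSITY = 0.02


@dataclass(frozen=True)
class SimConfig:
    """Geometry, library composition and optics of one simulated tile."""

    tile_width_px: int = 512
    tile_height_px: int = 512
    optimal_density: float = DEFAULT_OPTIMAL_DENSITY
    density_fraction: float = 1.0
    n_cycles: int = 12
    lowdiv_fraction: float = 0.0
    prefix_sequences: tuple[str, ...] = ("TCGAGGTAGTA", "TCGAGACGACG")
    psf_sigma_px: float = 1.2
    amplitude_mean: float = 4000.0
    amplitude_cv: float = 0.3
    background_level: float = 100.0
    read_noise_sd: float = 10.0
    shot_noise: bool = False
    crosstalk: tuple[tuple[float, ...], ...] | None = None
    drift_px: float = 2.0
    exclusion_radius_px: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_width_px <= 0 or self.tile_height_px <= 0:
            raise ValueError("tile dimensions must be positive")
        if self.optimal_density < 0:
            raise ValueError("optimal_density must be nonnegative")
        if not 0 <= self.density_fraction <= 1.5:
            raise ValueError("density_fraction must be in [0, 1.5]")
        if not 0 <= self.lowdiv_fraction <= 1:
            raise ValueError("lowdiv_fraction must be in [0, 1]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        for p in self.prefix_sequences:
            if not p or set(p) - set(BASES):
                raise ValueError(f"prefix {p!r} not over alphabet ACGT")
        if self.crosstalk is not None:
            m = np.asarray(self.crosstalk, dtype=float)
            if m.shape != (4, 4):
                raise ValueError("crosstalk must be 4x4")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("crosstalk rows must each sum to 1")

    @property
    def area_px2(self) -> float:
        return float(self.tile_width_px * self.tile_height_px)

    @property
    def expected_cluster_count(self) -> float:
        return self.optimal_density * self.density_fraction * self.area_px2

    def crosstalk_matrix(self) -> np.ndarray:
        if self.crosstalk is None:
            return np.eye(4)
        return np.asarray(self.crosstalk, dtype=float)


@dataclass
class ClusterGroundTruth:
    """The simulator's hidden truth for one clonal cluster."""

    id: int
    x_px: float
    y_px: float
    sequence: str
    amplitude: float
    sample_label: str = "diverse"
    index_sequence: str | None = None
    #: amplitude of the separately primed index read (None = no index read)
    index_amplitude: float | None = None


@dataclass
class CycleImageSet:
    """Four co-registered channel images for one tile and one cycle."""

    cycle: int
    channel_images: dict[str, np.ndarray]
    applied_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.channel_images.values()}
        if len(shapes) != 1:
            raise ValueError("channel images must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channel_images.values())).shape

    def max_channel(self) -> np.ndarray:
        """Per-pixel maximum over the four channels (spot-detection image)."""
        return np.maximum.reduce([self.channel_images[b] for b in BASES])


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def draw_positions(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Homogeneous-Poisson cluster placement; returns an (N, 2) x,y array.

    If ``exclusion_radius_px`` is set, clusters violating the minimum
    spacing are greedily thinned (earlier clusters win).
    """
    n = rng.poisson(config.expected_cluster_count)
    xy = np.column_stack(
        [
            rng.uniform(0.0, config.tile_width_px, size=n),
            rng.uniform(0.0, config.tile_height_px, size=n),
        ]
    )
    r = config.exclusion_radius_px
    if r is not None and n > 1:
        from scipy.spatial import cKDTree

        keep = np.ones(n, dtype=bool)
        tree = cKDTree(xy)
        for i, j in sorted(tree.query_pairs(r)):
            if keep[i]:
                keep[j] = False
        xy = xy[keep]
    return xy


def random_sequences(
    rng: np.random.Generator,
    n: int,
    length: int,
    lowdiv_fraction: float,
    prefixes: Sequence[str],
) -> tuple[list[str], np.ndarray]:
    """Draw read sequences; a ``lowdiv_fraction`` share gets a 5' prefix.

    Returns the sequences and a boolean mask of which clusters are
    low-diversity (prefixed).
    """
    is_lowdiv = rng.random(n) < lowdiv_fraction
    which_prefix = rng.integers(0, len(prefixes), size=n)
    base_draws = rng.integers(0, 4, size=(n, length))
    seqs: list[str] = []
    for i in range(n):
        suffix = "".join(BASES[b] for b in base_draws[i])
        if is_lowdiv[i]:
            p = prefixes[which_prefix[i]][:length]
            seqs.append((p + suffix)[:length])
        else:
            seqs.append(suffix)
    return seqs, is_lowdiv


def generate_clusters(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[ClusterGroundTruth]:
    """Draw ground-truth clusters for one tile.

    The number of clusters is Poisson with mean
    ``optimal_density * density_fraction * tile_area``; positions are
    uniform, amplitudes log-normal with the configured mean and CV, and a
    ``lowdiv_fraction`` share of sequences starts with one of the
    configured 5' prefixes (the rest are i.i.d. uniform over ACGT).
    """
    if config.expected_cluster_count < 0:
        raise ValueError("nonpositive expected cluster count")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    xy = draw_positions(rng, config)
    n = len(xy)
    mu, sig = _lognormal_params(config.amplitude_mean, config.amplitude_cv)
    amps = rng.lognormal(mu, sig, size=n)
    seqs, is_lowdiv = random_sequences(
        rng, n, config.n_cycles, config.lowdiv_fraction, config.prefix_sequences
    )
    return [
        ClusterGroundTruth(
            id=i,
            x_px=float(xy[i, 0]),
            y_px=float(xy[i, 1]),
            sequence=seqs[i],
            amplitude=float(amps[i]),
            sample_label="lowdiv" if is_lowdiv[i] else "diverse",
        )
        for i in range(n)
    ]


def _splat(
    shape: tuple[int, int],
    cx: np.ndarray,
    cy: np.ndarray,
    amp: np.ndarray,
    chan: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Accumulate Gaussian spots into a (4, H, W) stack.

    Each spot integrates to its amplitude; the kernel is truncated at 4
    sigma (>99.9% of the flux).
    """
    h, w = shape
    stack = np.zeros((4, h, w))
    if len(cx) == 0:
        return stack
    r = max(4, int(np.ceil(4.0 * sigma)))
    # pad enough that off-tile centers (drifted clusters) still index safely
    overhang = max(0.0, -cx.min(), cx.max() - (w - 1), -cy.min(), cy.max() - (h - 1))
    pad = r + 1 + int(np.ceil(overhang))
    padded = np.zeros((4, h + 2 * pad, w + 2 * pad))
    offs = np.arange(-r, r + 1)
    ix = np.round(cx).astype(int)
    iy = np.round(cy).astype(int)
    gx = ix[:, None] + offs[None, :]  # (N, K)
    gy = iy[:, None] + offs[None, :]
    norm = 1.0 / (2.0 * np.pi * sigma * sigma)
    wx = np.exp(-((gx - cx[:, None]) ** 2) / (2.0 * sigma * sigma))
    wy = np.exp(-((gy - cy[:, None]) ** 2) / (2.0 * sigma * sigma))
    patches = (amp[:, None, None] * norm) * wy[:, :, None] * wx[:, None, :]
    k = len(offs)
    rows = (gy + pad)[:, :, None].repeat(k, axis=2)
    cols = (gx + pad)[:, None, :].repeat(k, axis=1)
    for c in range(4):
        sel = chan == c
        if sel.any():
            np.add.at(padded[c], (rows[sel].ravel(), cols[sel].ravel()), patches[sel].ravel())
    stack = padded[:, pad : pad + h, pad : pad + w]
    return stack


def render_cycle(
    clusters: Sequence[ClusterGroundTruth],
    cycle: int,
    config: SimConfig,
    offset: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> CycleImageSet:
    """Render the four channel images for one cycle (1-based).

    Each cluster contributes an isotropic Gaussian spot of integrated
    intensity equal to its amplitude, into the channel of its base at this
    cycle, at position (x+dx, y+dy).  Channels are then mixed by the
    crosstalk matrix, and background plus Gaussian read noise (plus
    optional Poisson shot noise) are added.
    """
    if cycle < 1 or cycle > config.n_cycles:
        raise ValueError(f"cycle {cycle} outside 1..{config.n_cycles}")
    if rng is None:
        # decouple the noise stream from cluster generation and from other
        # cycles so renders are individually reproducible
        rng = np.random.default_rng([config.seed, 977, cycle])
    shape = (config.tile_height_px, config.tile_width_px)
    dx, dy = offset
    cx = np.array([c.x_px + dx for c in clusters])
    cy = np.array([c.y_px + dy for c in clusters])
    amp = np.array([c.amplitude for c in clusters])
    chan = np.array([_BASE_INDEX[c.sequence[cycle - 1]] for c in clusters], dtype=int)
    stack = _splat(shape, cx, cy, amp, chan, config.psf_sigma_px)
    m = config.crosstalk_matrix()
    if not np.allclose(m, np.eye(4)):
        stack = np.einsum("ij,ihw->jhw", m, stack)
    if config.shot_noise:
        stack = rng.poisson(np.maximum(stack, 0.0)).astype(float)
    stack = stack + config.background_level
    if config.read_noise_sd > 0:
        stack = stack + rng.normal(0.0, config.read_noise_sd, size=stack.shape)
    stack = np.clip(stack, 0.0, 65535.0)
    return CycleImageSet(
        cycle=cycle,
        channel_images={b: stack[i] for i, b in enumerate(BASES)},
        applied_offset=(float(dx), float(dy)),
    )


def simulate_run(
    config: SimConfig,
    clusters: Sequence[ClusterGroundTruth] | None = None,
) -> tuple[list[CycleImageSet], list[ClusterGroundTruth]]:
    """Simulate a full run: one CycleImageSet per cycle plus ground truth.

    Cycle 1 is imaged at offset (0, 0); later cycles drift independently,
    uniform in [-drift_px, drift_px] per axis.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 131])
    if clusters is None:
        clusters = generate_clusters(config, np.random.default_rng(config.seed))
    offsets = [(0.0, 0.0)]
    for _ in range(1, config.n_cycles):
        if config.drift_px > 0:
            offsets.append(tuple(rng.uniform(-config.drift_px, config.drift_px, 2)))
        else:
            offsets.append((0.0, 0.0))
    image_sets = [
        render_cycle(clusters, c, config, offsets[c - 1])
        for c in range(1, config.n_cycles + 1)
    ]
    return image_sets, list(clusters)


# ---------------------------------------------------------------------------
# on-disk formats: 16-bit single-page grayscale TIFF per channel, a YAML run
# manifest, and a TSV ground-truth table


def write_cycle_tiffs(image_set: CycleImageSet, out_dir: str | Path) -> list[Path]:
    """Write one 16-bit little-endian TIFF per channel: C{cycle}_{base}.tif."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for b in BASES:
        p = out_dir / f"C{image_set.cycle}_{b}.tif"
        tifffile.imwrite(
            p, np.round(image_set.channel_images[b]).astype("<u2"), photometric="minisblack"
        )
        paths.append(p)
    return paths


def read_cycle_tiffs(cycle: int, in_dir: str | Path) -> CycleImageSet:
    in_dir = Path(in_dir)
    images = {
        b: tifffile.imread(in_dir / f"C{cycle}_{b}.tif").astype(float) for b in BASES
    }
    return CycleImageSet(cycle=cycle, channel_images=images)


def write_run(
    image_sets: Sequence[CycleImageSet],
    clusters: Sequence[ClusterGroundTruth],
    config: SimConfig,
    out_dir: str | Path,
) -> Path:
    """Write all cycles, the ground-truth TSV and a YAML manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for ims in image_sets:
        write_cycle_tiffs(ims, out_dir)
    ground_truth_frame(clusters).to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    manifest = {
        "format_version": 1,
        "config": dataclasses.asdict(config),
        "n_clusters": len(clusters),
        "offsets": {ims.cycle: list(ims.applied_offset) for ims in image_sets},
    }
    path = out_dir / "run.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def ground_truth_frame(clusters: Sequence[ClusterGroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.id for c in clusters],
            "x": [c.x_px for c in clusters],
            "y": [c.y_px for c in clusters],
            "sequence": [c.sequence for c in clusters],
            "amplitude": [c.amplitude for c in clusters],
            "sample_label": [c.sample_label for c in clusters],
            "index_sequence": [c.index_sequence or "" for c in clusters],
        }
    )


def read_ground_truth(path: str | Path) -> list[ClusterGroundTruth]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        ClusterGroundTruth(
            id=int(r.id),
            x_px=float(r.x),
            y_px=float(r.y),
            sequence=str(r.sequence),
            amplitude=float(r.amplitude),
            sample_label=str(r.sample_label),
            index_sequence=str(r.index_sequence) or None,
        )
        for r in df.itertuples()
    ]
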