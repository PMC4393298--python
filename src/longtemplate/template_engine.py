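"""Template generation: the heart of Illumina-style cluster calling.

Cluster positions are estimated once, from the images of the first K
cycles (K = ``template_cycle_count``, historically 4).  Spots are detected
in each of those cycles separately; the cycle with the most spots is the
*golden* cycle, the runner-up the *silver* cycle, and the template is the
union of their (registered, de-duplicated) spot lists.  The template is
never corrected afterwards — every later cycle is only translated onto it.

When the first K cycles all fall inside a shared 5' prefix, every cluster
occupies the same channel and neighbouring spots merge, so the template
under-counts clusters.  Extending K at least two cycles past the prefix
lets golden and silver land on fully diverse cycles (the Long Template
Protocol).  The RAM cost of holding K cycles of images in memory is modeled
by :func:`estimate_template_memory` / :func:`max_template_length`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage
from scipy.spatial import cKDTree

from longtemplate.flowcell_sim import BASES, CycleImageSet


@dataclass(frozen=True)
class TemplateConfig:
    """Parameters of spot detection and template construction."""

    template_cycle_count: int = 4
    first_template_cycle: int = 1
    detection_threshold_sd: float = 4.0
    merge_radius_px: float = 1.5
    dedup_radius_px: float = 1.5
    #: minimum separation of distinct template positions: cross-channel
    #: coincidences within this radius (crosstalk ghosts, or two clusters
    #: too entangled for their reads to ever be distinct) collapse to one
    cross_channel_merge_px: float = 0.75
    psf_sigma_px: float = 1.2
    max_registration_shift_px: float = 8.0

    def __post_init__(self) -> None:
        if self.template_cycle_count < 2:
            raise ValueError("template_cycle_count must be >= 2 (golden and silver)")
        if self.first_template_cycle < 1:
            raise ValueError("first_template_cycle must be >= 1")
        if self.merge_radius_px <= 0 or self.dedup_radius_px <= 0:
            raise ValueError("radii must be positive")


@dataclass(frozen=True)
class Template:
    """Immutable table of cluster coordinates in the golden cycle's frame."""

    positions: tuple[tuple[float, float], ...]
    golden_cycle: int
    silver_cycle: int
    per_cycle_spot_counts: tuple[int, ...]
    source_cycles: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.positions)

    def as_array(self) -> np.ndarray:
        return np.array(self.positions, dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class MemoryModel:
    """Pixel bookkeeping behind the 'GB per template cycle' rule of thumb."""

    image_width_px: int = 2048
    image_height_px: int = 160000
    bytes_per_pixel: int = 2
    channels_per_cycle: int = 4

    def __post_init__(self) -> None:
        if min(
            self.image_width_px,
            self.image_height_px,
            self.bytes_per_pixel,
            self.channels_per_cycle,
        ) <= 0:
            raise ValueError("all MemoryModel fields must be positive")

    @property
    def bytes_per_cycle(self) -> int:
        return (
            self.channels_per_cycle
            * self.image_width_px
            * self.image_height_px
            * self.bytes_per_pixel
        )

    @property
    def gb_per_template_cycle(self) -> float:
        return self.bytes_per_cycle / 1e9


def _background_stats(image: np.ndarray) -> tuple[float, float]:
    """Robust background level and noise SD (median / scaled MAD)."""
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return med, 1.4826 * mad


def _channel_peaks(
    img: np.ndarray, threshold_sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima above background + k sigma in one channel image.

    Returns (positions, peak heights); positions are refined to sub-pixel
    precision by the centre of mass of the background-subtracted 3x3 patch.
    """
    bg, sd = _background_stats(img)
    if sd <= 0:
        sd = max(1e-6, float(img.std()))
    thresh = bg + threshold_sd * sd
    footprint = np.ones((3, 3), dtype=bool)
    local_max = (ndimage.maximum_filter(img, footprint=footprint) == img) & (img > thresh)
    ys, xs = np.nonzero(local_max)
    if len(xs) == 0:
        return np.empty((0, 2)), np.empty(0)
    peak_val = img[ys, xs] - bg
    h, w = img.shape
    sub = np.zeros((len(xs), 2))
    for k in range(len(xs)):
        x0, y0 = xs[k], ys[k]
        xlo, xhi = max(0, x0 - 1), min(w, x0 + 2)
        ylo, yhi = max(0, y0 - 1), min(h, y0 + 2)
        patch = np.maximum(img[ylo:yhi, xlo:xhi] - bg, 0.0)
        tot = patch.sum()
        if tot <= 0:
            sub[k] = (x0, y0)
        else:
            gy, gx = np.mgrid[ylo:yhi, xlo:xhi]
            sub[k] = ((gx * patch).sum() / tot, (gy * patch).sum() / tot)
    return sub, peak_val


def detect_spots(image_set: CycleImageSet, cfg: TemplateConfig) -> np.ndarray:
    """Detect cluster spots in one cycle; returns an (N, 2) x,y array.

    Each channel image is searched separately for local maxima exceeding
    background + ``detection_threshold_sd`` noise SDs; within a channel,
    maxima closer than ``merge_radius_px`` are collapsed to their
    intensity-weighted centroid.  Two clusters that share the same base at
    this cycle and sit within roughly two PSF sigmas of each other produce
    a single maximum and are therefore reported as one spot — the merging
    failure mode under study, which a cycle of low sequence diversity
    suffers tile-wide.  The four per-channel spot lists are finally
    combined, collapsing cross-channel coincidences within
    ``cross_channel_merge_px`` (crosstalk ghosts of one physical cluster).
    """
    all_xy = []
    all_w = []
    for b in BASES:
        xy, w = _channel_peaks(image_set.channel_images[b], cfg.detection_threshold_sd)
        if len(xy):
            merged = _merge_close(xy, w, cfg.merge_radius_px)
            all_xy.append(merged)
            all_w.append(np.ones(len(merged)))
    if not all_xy:
        return np.empty((0, 2))
    xy = np.vstack(all_xy)
    w = np.concatenate(all_w)
    return _merge_close(xy, w, cfg.cross_channel_merge_px)


def _merge_close(xy: np.ndarray, weight: np.ndarray, radius: float) -> np.ndarray:
    """Collapse points closer than ``radius`` into weighted centroids.

    Connected components of the proximity graph are merged, so chains of
    mutually close peaks become a single spot.
    """
    if len(xy) == 0:
        return xy
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    parent = np.arange(len(xy))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = np.array([find(i) for i in range(len(xy))])
    out = []
    for r in np.unique(roots):
        sel = roots == r
        w = weight[sel]
        out.append((xy[sel] * w[:, None]).sum(axis=0) / w.sum())
    return np.array(out)


def rank_cycles(per_cycle_counts: Sequence[int]) -> tuple[int, int]:
    """Pick the golden (most spots) and silver (second-most) cycles.

    Returns 1-based indices *within the supplied list*; ties go to the
    earlier cycle.
    """
    counts = np.asarray(per_cycle_counts)
    if counts.size < 2:
        raise ValueError("need at least 2 cycles to rank")
    golden = int(np.argmax(counts))
    rest = counts.copy().astype(float)
    rest[golden] = -np.inf
    silver = int(np.argmax(rest))
    return golden + 1, silver + 1


def _template_image(
    positions: np.ndarray, shape: tuple[int, int], sigma: float
) -> np.ndarray:
    """Render unit-amplitude Gaussians at template positions (for registration)."""
    img = np.zeros(shape)
    if len(positions) == 0:
        return img
    r = max(3, int(np.ceil(3 * sigma)))
    h, w = shape
    pad = r + 1
    padded = np.zeros((h + 2 * pad, w + 2 * pad))
    offs = np.arange(-r, r + 1)
    ix = np.round(positions[:, 0]).astype(int)
    iy = np.round(positions[:, 1]).astype(int)
    keep = (ix >= -pad) & (ix < w + pad) & (iy >= -pad) & (iy < h + pad)
    ix, iy = ix[keep], iy[keep]
    pos = positions[keep]
    gx = ix[:, None] + offs[None, :]
    gy = iy[:, None] + offs[None, :]
    wx = np.exp(-((gx - pos[:, 0:1]) ** 2) / (2 * sigma * sigma))
    wy = np.exp(-((gy - pos[:, 1:2]) ** 2) / (2 * sigma * sigma))
    k = len(offs)
    rows = np.clip((gy + pad)[:, :, None].repeat(k, axis=2), 0, h + 2 * pad - 1)
    cols = np.clip((gx + pad)[:, None, :].repeat(k, axis=1), 0, w + 2 * pad - 1)
    patches = wy[:, :, None] * wx[:, None, :]
    np.add.at(padded, (rows.ravel(), cols.ravel()), patches.ravel())
    return padded[pad : pad + h, pad : pad + w]


def register_offset(
    image_set: CycleImageSet,
    template: Template | np.ndarray,
    cfg: TemplateConfig | None = None,
) -> tuple[float, float]:
    """Estimate this cycle's (dx, dy) translation relative to the template.

    A synthetic image of unit Gaussians at the template positions is
    cross-correlated (FFT) with the cycle's max-channel image; the integer
    argmax within ``max_registration_shift_px`` is refined by a 1-D
    quadratic fit per axis.  The returned offset satisfies
    image_position ≈ template_position + (dx, dy).
    """
    cfg = cfg or TemplateConfig()
    positions = template.as_array() if isinstance(template, Template) else np.asarray(template)
    if len(positions) == 0:
        raise ValueError("cannot register against an empty template")
    img = image_set.max_channel()
    bg, _ = _background_stats(img)
    timg = _template_image(positions, img.shape, cfg.psf_sigma_px)
    a = np.fft.rfft2(img - bg)
    b = np.fft.rfft2(timg)
    corr = np.fft.irfft2(a * np.conj(b), s=img.shape)
    # corr[dy, dx] = sum_t template(p) * image(p + (dx,dy)), circularly
    h, w = img.shape
    m = int(np.ceil(cfg.max_registration_shift_px))
    shifts = np.r_[np.arange(0, m + 1), np.arange(-m, 0)]
    window = corr[np.ix_(shifts % h, shifts % w)]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    dy, dx = float(shifts[iy]), float(shifts[ix])

    def refine(center_idx: int, axis: int) -> float:
        lo = window.take(center_idx - 1, axis=axis, mode="wrap")
        mid = window.take(center_idx, axis=axis, mode="wrap")
        hi = window.take((center_idx + 1) % len(shifts), axis=axis, mode="wrap")
        other = ix if axis == 0 else iy
        c0, c1, c2 = lo[other], mid[other], hi[other]
        denom = c0 - 2 * c1 + c2
        if denom >= 0:
            return 0.0
        return float(np.clip(0.5 * (c0 - c2) / denom, -0.5, 0.5))

    dy += refine(iy, axis=0)
    dx += refine(ix, axis=1)
    return (dx, dy)


def build_template(
    image_sets: Sequence[CycleImageSet], cfg: TemplateConfig
) -> Template:
    """Build the cluster template from the first-K-cycle images.

    Spots are detected independently in each template cycle; the golden and
    silver cycles are chosen by spot count; the silver spot list is
    translated into the golden frame (registration between the two cycles)
    and unioned with the golden list, dropping silver spots within
    ``dedup_radius_px`` of a golden spot.  The result is frozen.
    """
    first = cfg.first_template_cycle
    last = first + cfg.template_cycle_count - 1
    by_cycle = {ims.cycle: ims for ims in image_sets}
    missing = [c for c in range(first, last + 1) if c not in by_cycle]
    if missing:
        raise ValueError(f"template range {first}..{last} missing cycles {missing}")
    cycles = list(range(first, last + 1))
    spots = {c: detect_spots(by_cycle[c], cfg) for c in cycles}
    counts = [len(spots[c]) for c in cycles]
    g_idx, s_idx = rank_cycles(counts)
    golden, silver = cycles[g_idx - 1], cycles[s_idx - 1]
    gspots = spots[golden]
    sspots = spots[silver]
    positions = gspots
    if len(sspots) and len(gspots):
        # silver -> golden frame: register the silver image against the
        # golden spot list, then subtract the estimated translation
        dx, dy = register_offset(by_cycle[silver], gspots, cfg)
        shifted = sspots - np.array([dx, dy])
        # one-to-one dedup: each golden spot absorbs at most its single
        # nearest silver spot within dedup_radius; remaining silver spots
        # are genuinely new positions (e.g. the second member of a pair
        # the golden cycle merged into one centroid)
        tree = cKDTree(gspots)
        d, j = tree.query(shifted, k=1)
        order = np.argsort(d)
        taken = np.zeros(len(gspots), dtype=bool)
        new = np.ones(len(shifted), dtype=bool)
        for i in order:
            if d[i] <= cfg.dedup_radius_px and not taken[j[i]]:
                taken[j[i]] = True
                new[i] = False
        positions = np.vstack([gspots, shifted[new]])
        # enforce the template's minimum position separation on the union
        positions = _merge_close(
            positions, np.ones(len(positions)), cfg.cross_channel_merge_px
        )
    elif len(sspots):
        positions = sspots
    return Template(
        positions=tuple(map(tuple, positions)),
        golden_cycle=golden,
        silver_cycle=silver,
        per_cycle_spot_counts=tuple(counts),
        source_cycles=tuple(cycles),
    )


def template_recovery(
    template: Template,
    true_xy: np.ndarray,
    match_radius_px: float = 1.5,
) -> float:
    """Fraction of true clusters with a template position within radius.

    ``true_xy`` is an (N, 2) array of ground-truth x,y positions in the
    same frame as the template (the golden cycle's frame).  Matching is
    one-to-one (greedy nearest-pair first), so a single merged template
    position can account for only one of the clusters behind it.
    """
    true_xy = np.asarray(true_xy, dtype=float).reshape(-1, 2)
    if len(true_xy) == 0:
        raise ValueError("no true clusters to match")
    if len(template) == 0:
        return 0.0
    pos = template.as_array()
    tree = cKDTree(pos)
    pairs = []  # (distance, template_idx, truth_idx)
    for j, p in enumerate(true_xy):
        for i in tree.query_ball_point(p, match_radius_px):
            pairs.append((np.hypot(*(pos[i] - p)), i, j))
    pairs.sort()
    used_t: set[int] = set()
    used_c: set[int] = set()
    for _, i, j in pairs:
        if i not in used_t and j not in used_c:
            used_t.add(i)
            used_c.add(j)
    return len(used_c) / len(true_xy)


def estimate_template_memory(
    model: MemoryModel, template_cycle_count: int
) -> tuple[int, float]:
    """RAM needed to hold ``template_cycle_count`` cycles of images.

    Returns (bytes, decimal GB).  Memory scales linearly in template
    length: per-cycle bytes = channels x width x height x bytes/pixel.
    """
    if template_cycle_count < 1:
        raise ValueError("template_cycle_count must be >= 1")
    total = model.bytes_per_cycle * template_cycle_count
    return total, total / 1e9


def max_template_length(ram_gb: float, gb_per_cycle: float = 4.0) -> int:
    """Longest template that fits in ``ram_gb`` at ``gb_per_cycle`` GB/cycle."""
    if ram_gb <= 0 or gb_per_cycle <= 0:
        raise ValueError("ram_gb and gb_per_cycle must be positive")
    return int(np.floor(ram_gb / gb_per_cycle))


def write_template(template: Template, cfg: TemplateConfig, out_dir: str | Path) -> Path:
    """Serialize a template: TSV of positions plus a YAML sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "template.tsv"
    with open(tsv, "w") as fh:
        fh.write("x\ty\n")
        for x, y in template.positions:
            fh.write(f"{x:.3f}\t{y:.3f}\n")
    sidecar = {
        "golden_cycle": template.golden_cycle,
        "silver_cycle": template.silver_cycle,
        "per_cycle_spot_counts": list(template.per_cycle_spot_counts),
        "source_cycles": list(template.source_cycles),
        "n_positions": len(template),
        "config": {
            "template_cycle_count": cfg.template_cycle_count,
            "first_template_cycle": cfg.first_template_cycle,
            "detection_threshold_sd": cfg.detection_threshold_sd,
            "merge_radius_px": cfg.merge_radius_px,
            "dedup_radius_px": cfg.dedup_radius_px,
        },
    }
    with open(out_dir / "template.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return tsv
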