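"""Tag preprocessing: deduplication, fragment size, shifting, binning,
and beta-based control correction."""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome_io import MINUS, PLUS, GenomeLayout, TagCollection

logger = logging.getLogger(__name__)

FALLBACK_FRAGMENT = 150
MIN_TAGS_PER_STRAND = 1000


@dataclass
class FragmentEstimate:
    fragment_size: int
    method: str  # cross_correlation | paired_end | user_fixed
    profile: Optional[np.ndarray] = None  # columns: shift (bp), correlation

    def __post_init__(self) -> None:
        if self.fragment_size < 0:
            raise ValueError("fragment_size must be >= 0")


@dataclass
class BinnedTrack:
    """Per-chromosome bin counts; chromosome order follows the layout."""

    counts: dict[str, np.ndarray]
    bin_size: int
    library_size: float

    def concat(self) -> np.ndarray:
        return np.concatenate([np.asarray(c, dtype=float) for c in self.counts.values()])

    @property
    def n_bins(self) -> int:
        return sum(len(c) for c in self.counts.values())


@dataclass
class ControlCorrection:
    beta: float
    control_scale: float
    corrected: BinnedTrack


def remove_duplicates(tags: TagCollection) -> TagCollection:
    """Keep one tag per (chrom, position, strand) — plus insert size when paired."""
    positions: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    inserts: dict[str, np.ndarray] = {}
    for chrom in tags.chroms():
        pos = tags.positions[chrom]
        strand = tags.strands[chrom].astype(np.int64)
        cols = [pos, strand]
        if tags.paired and tags.inserts is not None:
            cols.append(tags.inserts[chrom])
        key = np.stack(cols, axis=1)
        _, idx = np.unique(key, axis=0, return_index=True)
        idx.sort()
        positions[chrom] = pos[idx]
        strands[chrom] = tags.strands[chrom][idx]
        if tags.paired and tags.inserts is not None:
            inserts[chrom] = tags.inserts[chrom][idx]
    return TagCollection(
        positions,
        strands,
        paired=tags.paired,
        inserts=inserts if tags.paired and tags.inserts is not None else None,
        read_length=tags.read_length,
        n_dropped=tags.n_dropped,
    )


def _strand_coverage(tags: TagCollection, layout: GenomeLayout, micro_bin: int):
    """Micro-binned 5' coverage vectors per chromosome and strand."""
    out = {}
    for chrom in tags.chroms():
        nb = math.ceil(layout.length(chrom) / micro_bin)
        pos = tags.positions[chrom]
        strand = tags.strands[chrom]
        plus = np.bincount(pos[strand == PLUS] // micro_bin, minlength=nb).astype(float)
        minus = np.bincount(pos[strand == MINUS] // micro_bin, minlength=nb).astype(float)
        out[chrom] = (plus, minus)
    return out


def _pooled_pearson(pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    n = sx = sy = sxx = syy = sxy = 0.0
    for x, y in pairs:
        n += len(x)
        sx += x.sum()
        sy += y.sum()
        sxx += (x * x).sum()
        syy += (y * y).sum()
        sxy += (x * y).sum()
    if n == 0:
        return np.nan
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= 0 or vy <= 0:
        return np.nan
    return (n * sxy - sx * sy) / math.sqrt(vx * vy)


def estimate_fragment_size(
    tags: TagCollection,
    layout: GenomeLayout,
    max_shift: int = 500,
    read_length: Optional[int] = None,
    micro_bin: int = 5,
) -> FragmentEstimate:
    """Estimate library fragment size.

    Paired-end libraries use the median insert size.  Single-end libraries
    use strand cross-correlation: the Pearson correlation between plus- and
    minus-strand 5' coverage (micro-binned) is evaluated for every shift in
    ``[0, max_shift]`` and the argmax is taken, excluding a +-10 bp "phantom"
    window around the read length.  Degenerate inputs fall back to a fixed
    150 bp estimate.
    """
    if read_length is None:
        read_length = tags.read_length
    if tags.paired and tags.inserts is not None:
        all_ins = np.concatenate([v for v in tags.inserts.values()]) if tags.inserts else np.array([])
        all_ins = all_ins[all_ins > 0]
        if len(all_ins) > 0:
            return FragmentEstimate(int(np.median(all_ins)), "paired_end")

    n_plus = sum(int((s == PLUS).sum()) for s in tags.strands.values())
    n_minus = sum(int((s == MINUS).sum()) for s in tags.strands.values())
    if n_plus < MIN_TAGS_PER_STRAND or n_minus < MIN_TAGS_PER_STRAND:
        logger.warning(
            "too few tags per strand (+%d/-%d); falling back to fragment=%d",
            n_plus, n_minus, FALLBACK_FRAGMENT,
        )
        return FragmentEstimate(FALLBACK_FRAGMENT, "user_fixed")

    coverage = _strand_coverage(tags, layout, micro_bin)
    shifts = np.arange(0, max_shift // micro_bin + 1)
    profile = np.full(len(shifts), np.nan)
    for i, d in enumerate(shifts):
        pairs = []
        for plus, minus in coverage.values():
            if len(plus) > d + 1:
                pairs.append((plus[: len(plus) - d], minus[d:]))
        profile[i] = _pooled_pearson(pairs)

    shift_bp = shifts * micro_bin
    prof = np.column_stack([shift_bp, profile])
    usable = np.isfinite(profile)
    if read_length is not None:
        usable &= np.abs(shift_bp - read_length) > 10
    if not usable.any() or np.nanmax(profile[usable]) - np.nanmin(profile[usable]) < 1e-12:
        logger.warning("flat correlation profile; falling back to fragment=%d", FALLBACK_FRAGMENT)
        return FragmentEstimate(FALLBACK_FRAGMENT, "user_fixed", prof)
    masked = np.where(usable, profile, -np.inf)
    best = int(shift_bp[int(np.argmax(masked))])
    return FragmentEstimate(best, "cross_correlation", prof)


def shift_and_bin(
    tags: TagCollection,
    fragment: FragmentEstimate | int,
    layout: GenomeLayout,
) -> BinnedTrack:
    """Shift tags toward fragment centers and accumulate per-bin counts.

    Plus tags move to ``pos + fragment // 2``, minus tags to ``pos -
    fragment // 2``; shifted positions are clamped to the chromosome.  The
    total over all bins equals the tag count exactly.
    """
    if layout.bin_size is None:
        raise ValueError("layout has no bin grid")
    frag = fragment.fragment_size if isinstance(fragment, FragmentEstimate) else int(fragment)
    half = frag // 2
    bs = layout.bin_size
    counts: dict[str, np.ndarray] = {}
    total = 0
    for chrom in layout.names:
        nb = layout.n_bins(chrom)
        if chrom not in tags.positions:
            counts[chrom] = np.zeros(nb, dtype=np.int64)
            continue
        pos = tags.positions[chrom].astype(np.int64)
        strand = tags.strands[chrom]
        shifted = np.where(strand == PLUS, pos + half, pos - half)
        shifted = np.clip(shifted, 0, layout.length(chrom) - 1)
        counts[chrom] = np.bincount(shifted // bs, minlength=nb).astype(np.int64)
        total += len(pos)
    return BinnedTrack(counts=counts, bin_size=bs, library_size=float(total))


def _abs_corr(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson correlation| with zero-variance cases defined as 0."""
    xc = x - x.mean()
    yc = y - y.mean()
    dx = math.sqrt(float((xc * xc).sum()))
    dy = math.sqrt(float((yc * yc).sum()))
    if dx == 0.0 or dy == 0.0:
        return 0.0
    return abs(float((xc * yc).sum()) / (dx * dy))


def correct_with_control(
    signal: BinnedTrack,
    control: BinnedTrack,
    grid_step: float = 0.01,
) -> ControlCorrection:
    """Subtract a scaled control, choosing beta on a grid over [0, 1].

    The control is first scaled by the treatment/control library-size ratio.
    Beta minimizes ``|corr(signal - beta * scaled_control, scaled_control)|``
    over all genome bins; corrected counts are ``max(0, round(signal - beta *
    scaled_control))``.
    """
    if control.library_size == 0:
        raise ValueError("control track has library_size 0")
    if signal.bin_size != control.bin_size:
        raise ValueError("signal and control bin sizes differ")
    scale = signal.library_size / control.library_size
    sig = signal.concat()
    ctrl = control.concat() * scale
    betas = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    objective = np.array([_abs_corr(sig - b * ctrl, ctrl) for b in betas])
    beta = float(betas[int(np.argmin(objective))])
    corrected_counts: dict[str, np.ndarray] = {}
    total = 0.0
    for chrom, counts in signal.counts.items():
        resid = np.asarray(counts, dtype=float) - beta * scale * np.asarray(
            control.counts[chrom], dtype=float
        )
        vals = np.maximum(0, np.rint(resid)).astype(np.int64)
        corrected_counts[chrom] = vals
        total += float(vals.sum())
    corrected = BinnedTrack(corrected_counts, signal.bin_size, library_size=total)
    logger.info("control correction: beta=%.2f scale=%.4f", beta, scale)
    return ControlCorrection(beta=beta, control_scale=scale, corrected=corrected)


def scaled_control(signal: BinnedTrack, control: BinnedTrack) -> BinnedTrack:
    """Control counts scaled to the treatment library size (for scoring)."""
    if control.library_size == 0:
        raise ValueError("control track has library_size 0")
    scale = signal.library_size / control.library_size
    counts = {c: np.asarray(v, dtype=float) * scale for c, v in control.counts.items()}
    return BinnedTrack(counts, control.bin_size, library_size=control.library_size * scale)
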