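"""Synthetic tag-track generator with ground-truth peaks.

A lightweight surrogate for model-based ChIP-seq read simulators: peaks are
placed with a minimum inter-peak gap, lengths are log-normal around a
narrow (~1 kb) or broad (~20 kb) regime mean, and each read comes from a
peak (with probability ``quality``, triangular enrichment toward the peak
center) or from the uniform background.  Everything is bit-reproducible
from (spec, seed).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .genome_io import MINUS, PLUS, GenomeLayout, TagCollection

NARROW_MEAN = 1_000
BROAD_MEAN = 20_000
LENGTH_LOG_SD = 0.5
#: fraction of within-peak fragments drawn from the triangular center bump
#: (the rest are uniform across the peak, approximating real pileup shapes)
TRIANGULAR_WEIGHT = 0.5


@dataclass
class SimulationSpec:
    layout: GenomeLayout
    n_peaks: int = 500
    length_model: str = "narrow"  # narrow | broad | mixed
    n_narrow: int = 400  # used by the mixed model
    n_broad: int = 100
    min_gap: int = 5_000
    n_reads: int = 1_000_000
    quality: float = 1.0
    fragment: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.quality <= 1:
            raise ValueError("quality must be in (0, 1]")
        if self.length_model not in ("narrow", "broad", "mixed"):
            raise ValueError(f"unknown length model: {self.length_model}")
        if self.length_model == "mixed":
            self.n_peaks = self.n_narrow + self.n_broad

    @property
    def mean_length(self) -> float:
        if self.length_model == "narrow":
            return NARROW_MEAN
        if self.length_model == "broad":
            return BROAD_MEAN
        return (self.n_narrow * NARROW_MEAN + self.n_broad * BROAD_MEAN) / max(self.n_peaks, 1)

    def to_json(self, path: str) -> None:
        d = asdict(self)
        d["layout"] = {
            "chromosomes": list(self.layout.chromosomes),
            "bin_size": self.layout.bin_size,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def _length_means(spec: SimulationSpec) -> np.ndarray:
    if spec.length_model == "narrow":
        return np.full(spec.n_peaks, NARROW_MEAN, dtype=float)
    if spec.length_model == "broad":
        return np.full(spec.n_peaks, BROAD_MEAN, dtype=float)
    means = np.concatenate(
        [np.full(spec.n_narrow, NARROW_MEAN, float), np.full(spec.n_broad, BROAD_MEAN, float)]
    )
    return means


def sample_ground_truth(spec: SimulationSpec) -> list[tuple[str, int, int]]:
    """Sample ground-truth intervals with pairwise gaps >= ``min_gap``.

    Peaks are apportioned to chromosomes proportionally to length, lengths
    drawn log-normally (sd 0.5 in log space) around the regime mean, and
    placed left-to-right with random slack.  Deterministic given the seed.
    """
    if spec.n_peaks == 0:
        return []
    if spec.n_peaks * (spec.mean_length + spec.min_gap) >= spec.layout.total_length:
        raise ValueError("infeasible packing: peaks + gaps exceed genome length")
    rng = np.random.default_rng([spec.seed, 0])
    means = _length_means(spec)
    lengths = np.rint(np.exp(rng.normal(np.log(means), LENGTH_LOG_SD))).astype(np.int64)
    lengths = np.maximum(lengths, 50)
    # shuffle so mixed narrow/broad peaks interleave along the genome
    rng.shuffle(lengths)

    # proportional apportionment of peaks to chromosomes
    total = spec.layout.total_length
    alloc: dict[str, int] = {}
    assigned = 0
    for name, clen in spec.layout.chromosomes:
        k = int(round(spec.n_peaks * clen / total))
        alloc[name] = k
        assigned += k
    first = spec.layout.names[0]
    alloc[first] += spec.n_peaks - assigned

    truth: list[tuple[str, int, int]] = []
    offset = 0
    for name, clen in spec.layout.chromosomes:
        k = alloc[name]
        if k <= 0:
            continue
        ls = lengths[offset : offset + k]
        offset += k
        slack = clen - int(ls.sum()) - (k - 1) * spec.min_gap
        if slack < 0:
            raise ValueError(f"infeasible packing on chromosome {name}")
        # random split of the slack into k+1 gaps (ends included)
        w = rng.exponential(size=k + 1)
        extra = np.floor(slack * w / w.sum()).astype(np.int64)
        pos = int(extra[0])
        for i in range(k):
            truth.append((name, pos, pos + int(ls[i])))
            pos += int(ls[i]) + spec.min_gap + int(extra[i + 1])
    return truth


def _sample_midpoints(
    truth: list[tuple[str, int, int]], spec: SimulationSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment midpoints for all reads: (chrom_index, midpoint)."""
    n = spec.n_reads
    names = spec.layout.names
    chrom_index = {c: i for i, c in enumerate(names)}
    clens = np.array([l for _, l in spec.layout.chromosomes], dtype=float)

    from_peak = rng.random(n) < spec.quality
    n_peak = int(from_peak.sum())
    chroms = np.empty(n, dtype=np.int64)
    mids = np.empty(n, dtype=np.int64)

    if n_peak and truth:
        lens = np.array([e - s for _, s, e in truth], dtype=float)
        picks = rng.choice(len(truth), size=n_peak, p=lens / lens.sum())
        starts = np.array([truth[i][1] for i in range(len(truth))])[picks]
        ends = np.array([truth[i][2] for i in range(len(truth))])[picks]
        tchroms = np.array([chrom_index[truth[i][0]] for i in range(len(truth))])[picks]
        centers = (starts + ends) / 2.0
        # center-peaked enrichment: uniform base blended with a triangular bump
        tri = rng.random(n_peak) < TRIANGULAR_WEIGHT
        vals = np.where(
            tri,
            rng.triangular(starts, centers, ends),
            starts + rng.random(n_peak) * (ends - starts),
        )
        chroms[from_peak] = tchroms
        mids[from_peak] = np.minimum(np.floor(vals).astype(np.int64), ends - 1)
    elif n_peak:
        from_peak[:] = False  # no truth intervals: everything is background

    bg = ~from_peak
    n_bg = int(bg.sum())
    if n_bg:
        bchroms = rng.choice(len(names), size=n_bg, p=clens / clens.sum())
        positions = np.floor(rng.random(n_bg) * clens[bchroms]).astype(np.int64)
        chroms[bg] = bchroms
        mids[bg] = positions
    return chroms, mids


def _tags_from_midpoints(
    chroms: np.ndarray, mids: np.ndarray, spec: SimulationSpec, rng: np.random.Generator
) -> TagCollection:
    """Emit one single-end tag per fragment at a random fragment end."""
    names = spec.layout.names
    half = spec.fragment // 2
    strands = rng.integers(0, 2, size=len(mids)).astype(np.int8)
    pos = np.where(strands == PLUS, mids - half, mids + half - 1)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ci, name in enumerate(names):
        mask = chroms == ci
        if not mask.any():
            continue
        p = np.clip(pos[mask], 0, spec.layout.length(name) - 1)
        by_chrom[name] = (p, strands[mask])
    return TagCollection.from_arrays(by_chrom, chrom_order=names)


def generate_reads(truth: list[tuple[str, int, int]], spec: SimulationSpec) -> TagCollection:
    """Generate ``n_reads`` single-end tags from peaks + uniform background."""
    rng = np.random.default_rng([spec.seed, 1])
    chroms, mids = _sample_midpoints(truth, spec, rng)
    return _tags_from_midpoints(chroms, mids, spec, rng)


def generate_control(spec: SimulationSpec, n_reads: Optional[int] = None) -> TagCollection:
    """Uniform background control track from an independent seed stream."""
    rng = np.random.default_rng([spec.seed, 2])
    ctrl_spec = SimulationSpec(
        layout=spec.layout,
        n_peaks=0,
        length_model=spec.length_model,
        min_gap=spec.min_gap,
        n_reads=spec.n_reads if n_reads is None else n_reads,
        quality=1.0,
        fragment=spec.fragment,
        seed=spec.seed,
    )
    if ctrl_spec.n_reads == 0:
        return TagCollection.from_arrays({}, chrom_order=spec.layout.names)
    chroms, mids = _sample_midpoints([], ctrl_spec, rng)
    return _tags_from_midpoints(chroms, mids, ctrl_spec, rng)


def write_truth_bed(truth: list[tuple[str, int, int]], path: str) -> None:
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(truth, start=1):
            fh.write(f"{chrom}\t{s}\t{e}\ttruth_{i}\t0\t.\n")


def read_truth_bed(path: str) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.split("\t")
            if len(f) >= 3:
                out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_tags_bed(
    tags: TagCollection, layout: GenomeLayout, path: str, read_length: int = 50
) -> None:
    """Write tags as BED6 reads whose 5' ends reproduce the tag positions."""
    with open(path, "w") as fh:
        for chrom in tags.chroms():
            clen = layout.length(chrom)
            for pos, strand in zip(tags.positions[chrom], tags.strands[chrom]):
                if strand == PLUS:
                    s, e, sym = pos, min(pos + read_length, clen), "+"
                else:
                    s, e, sym = max(pos + 1 - read_length, 0), pos + 1, "-"
                fh.write(f"{chrom}\t{s}\t{e}\t.\t0\t{sym}\n")
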