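"""Reading chromosome layouts and aligned tags, writing peaks.

All coordinates are 0-based half-open, matching the BED convention.  A bin
index ``b`` maps to the interval ``[b * bin_size, min((b + 1) * bin_size,
chrom_length))``.
"""
from __future__ import annotations

import gzip
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

logger = logging.getLogger(__name__)

#: strand codes used in tag arrays
PLUS = 0
MINUS = 1

_ALIGNMENT_EXTS = {".bam": "bam", ".sam": "sam", ".cram": "cram"}


class EmptyTrackError(ValueError):
    """Raised when an input file yields zero usable reads."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names/lengths plus an optional bin grid."""

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("no chromosomes")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate chromosome name: {dup}")
        for name, length in self.chromosomes:
            if int(length) <= 0:
                raise ValueError(f"non-positive length for chromosome {name}")
        if self.bin_size is not None and self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def length(self, name: str) -> int:
        for n, l in self.chromosomes:
            if n == name:
                return l
        raise KeyError(name)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def n_bins(self, name: str) -> int:
        if self.bin_size is None:
            raise ValueError("layout has no bin grid")
        return math.ceil(self.length(name) / self.bin_size)

    def with_bin_size(self, bin_size: int) -> "GenomeLayout":
        return GenomeLayout(self.chromosomes, bin_size)

    def bin_to_interval(self, name: str, b: int) -> tuple[int, int]:
        """Coordinates of bin ``b``: half-open, clipped at the chromosome end."""
        bs = self.bin_size
        if bs is None:
            raise ValueError("layout has no bin grid")
        return b * bs, min((b + 1) * bs, self.length(name))


@dataclass
class TagCollection:
    """Deduplicatable, strand-aware read 5' positions per chromosome.

    ``positions[chrom]`` is sorted; ``strands[chrom]`` holds :data:`PLUS` /
    :data:`MINUS` codes aligned with it.  For paired-end data ``inserts``
    carries the absolute template length per tag (0 when unknown).
    """

    positions: dict[str, np.ndarray]
    strands: dict[str, np.ndarray]
    paired: bool = False
    inserts: Optional[dict[str, np.ndarray]] = None
    read_length: Optional[int] = None
    n_dropped: int = 0

    @property
    def n_tags(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def chroms(self) -> Iterator[str]:
        return iter(self.positions)

    @staticmethod
    def from_lists(
        by_chrom: dict[str, list[tuple[int, int, int]]],
        paired: bool = False,
        read_length: Optional[int] = None,
        n_dropped: int = 0,
        chrom_order: Optional[list[str]] = None,
    ) -> "TagCollection":
        """Build a sorted collection from ``chrom -> [(pos, strand, insert)]``."""
        positions: dict[str, np.ndarray] = {}
        strands: dict[str, np.ndarray] = {}
        inserts: dict[str, np.ndarray] = {}
        order = chrom_order if chrom_order is not None else list(by_chrom)
        for chrom in order:
            rows = by_chrom.get(chrom, [])
            if not rows:
                continue
            arr = np.asarray(rows, dtype=np.int64)
            idx = np.lexsort((arr[:, 2], arr[:, 1], arr[:, 0]))
            arr = arr[idx]
            positions[chrom] = arr[:, 0].copy()
            strands[chrom] = arr[:, 1].astype(np.int8)
            inserts[chrom] = arr[:, 2].copy()
        return TagCollection(
            positions,
            strands,
            paired=paired,
            inserts=inserts if paired else None,
            read_length=read_length,
            n_dropped=n_dropped,
        )

    @staticmethod
    def from_arrays(
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
        read_length: Optional[int] = None,
        chrom_order: Optional[list[str]] = None,
    ) -> "TagCollection":
        """Build a sorted single-end collection from ``chrom -> (pos, strand)``."""
        positions: dict[str, np.ndarray] = {}
        strands: dict[str, np.ndarray] = {}
        order = chrom_order if chrom_order is not None else list(by_chrom)
        for chrom in order:
            if chrom not in by_chrom:
                continue
            pos, strand = by_chrom[chrom]
            if len(pos) == 0:
                continue
            idx = np.lexsort((strand, pos))
            positions[chrom] = np.asarray(pos, dtype=np.int64)[idx]
            strands[chrom] = np.asarray(strand, dtype=np.int8)[idx]
        return TagCollection(positions, strands, read_length=read_length)


@dataclass
class PeakRecord:
    """One BED 6+3 row, coordinates 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str
    value: float
    neg_log10_p: float
    neg_log10_q: float
    summits: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if not 0 <= self.score <= 1000:
            raise ValueError(f"score out of range: {self.score}")


def q_to_score(neg_log10_q: float) -> int:
    """BED score column: ``min(1000, round(10 * -log10 q))``."""
    if not np.isfinite(neg_log10_q):
        return 1000
    return int(min(1000, round(10.0 * max(0.0, neg_log10_q))))


def read_chrom_sizes(path: str, bin_size: Optional[int] = None) -> GenomeLayout:
    """Parse a two-column ``name<TAB>length`` file into a :class:`GenomeLayout`."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from exc
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length for {name}")
            if name in seen:
                raise ValueError(f"duplicate chromosome name: {name}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise ValueError("no chromosomes")
    return GenomeLayout(tuple(chroms), bin_size)


def infer_format(path: str) -> str:
    low = path.lower()
    if low.endswith(".bed.gz"):
        return "bed.gz"
    ext = os.path.splitext(low)[1]
    if ext in _ALIGNMENT_EXTS:
        return _ALIGNMENT_EXTS[ext]
    if ext == ".bed":
        return "bed"
    if ext in (".bw", ".bigwig"):
        return "bigwig"
    raise ValueError(f"cannot infer format from {path!r}")


def load_tags(path, layout: GenomeLayout, fmt: Optional[str] = None, reference: Optional[str] = None):
    """Load aligned tags (or binned coverage for BigWig) from ``path``.

    Alignment formats yield a :class:`TagCollection` of 5' positions; a plus
    tag sits at the alignment start and a minus tag at ``end - 1``.  BigWig
    input bypasses tag preprocessing and is returned as a
    :class:`~hmmpeaks.preprocess.BinnedTrack` with per-bin value sums rounded
    to integers.
    """
    path = os.fspath(path)
    if fmt is None:
        fmt = infer_format(path)
    fmt = fmt.lower()
    if fmt in ("bed", "bed.gz"):
        return _load_bed(path, layout, gzipped=fmt == "bed.gz")
    if fmt in ("bam", "sam", "cram"):
        return _load_alignment(path, layout, reference=reference)
    if fmt == "bigwig":
        return _load_bigwig(path, layout)
    raise ValueError(f"unsupported format: {fmt}")


def _load_bed(path: str, layout: GenomeLayout, gzipped: bool) -> TagCollection:
    known = set(layout.names)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {n: [] for n in layout.names}
    dropped = 0
    lengths: list[int] = []
    opener = gzip.open if gzipped else open
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line in {path}: {line!r}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if chrom not in known:
                dropped += 1
                continue
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand == "-":
                pos, code = end - 1, MINUS
            else:
                pos, code = start, PLUS
            pos = min(max(pos, 0), layout.length(chrom) - 1)
            by_chrom[chrom].append((pos, code, 0))
            lengths.append(end - start)
    if dropped:
        logger.info("dropped %d reads on chromosomes absent from layout", dropped)
    if not lengths:
        raise EmptyTrackError(f"empty track: {path}")
    read_length = int(np.median(lengths))
    return TagCollection.from_lists(
        by_chrom, paired=False, read_length=read_length, n_dropped=dropped, chrom_order=layout.names
    )


def _load_alignment(path: str, layout: GenomeLayout, reference: Optional[str] = None) -> TagCollection:
    import pysam

    known = set(layout.names)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {n: [] for n in layout.names}
    dropped = 0
    lengths: list[int] = []
    any_paired = False
    kwargs = {}
    if reference is not None:
        kwargs["reference_filename"] = reference
    save = pysam.set_verbosity(0)  # silence missing-index warnings
    try:
        with pysam.AlignmentFile(path, **kwargs) as af:
            for read in af.fetch(until_eof=True):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                chrom = read.reference_name
                if chrom not in known:
                    dropped += 1
                    continue
                if read.is_reverse:
                    pos, code = read.reference_end - 1, MINUS
                else:
                    pos, code = read.reference_start, PLUS
                insert = 0
                if read.is_paired:
                    any_paired = True
                    insert = abs(read.template_length)
                pos = min(max(pos, 0), layout.length(chrom) - 1)
                by_chrom[chrom].append((pos, code, insert))
                if read.query_length:
                    lengths.append(read.query_length)
    finally:
        pysam.set_verbosity(save)
    if dropped:
        logger.info("dropped %d reads on chromosomes absent from layout", dropped)
    total = sum(len(v) for v in by_chrom.values())
    if total == 0:
        raise EmptyTrackError(f"empty track: {path}")
    read_length = int(np.median(lengths)) if lengths else None
    return TagCollection.from_lists(
        by_chrom, paired=any_paired, read_length=read_length, n_dropped=dropped, chrom_order=layout.names
    )


def _load_bigwig(path: str, layout: GenomeLayout):
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("BigWig input requires the optional pyBigWig dependency") from exc
    from .preprocess import BinnedTrack

    if layout.bin_size is None:
        raise ValueError("BigWig loading requires a layout with bin_size")
    bs = layout.bin_size
    counts: dict[str, np.ndarray] = {}
    bw = pyBigWig.open(path)
    try:
        bw_chroms = bw.chroms()
        for chrom in layout.names:
            nb = layout.n_bins(chrom)
            acc = np.zeros(nb, dtype=float)
            if chrom in bw_chroms:
                for start, end, val in bw.intervals(chrom) or []:
                    end = min(end, layout.length(chrom))
                    if end <= start:
                        continue
                    b0, b1 = start // bs, (end - 1) // bs
                    if b0 == b1:
                        acc[b0] += val * (end - start)
                    else:
                        acc[b0] += val * ((b0 + 1) * bs - start)
                        acc[b0 + 1 : b1] += val * bs
                        acc[b1] += val * (end - b1 * bs)
            counts[chrom] = np.rint(acc).astype(np.int64)
    finally:
        bw.close()
    total = float(sum(c.sum() for c in counts.values()))
    if total == 0:
        raise EmptyTrackError(f"empty track: {path}")
    return BinnedTrack(counts=counts, bin_size=bs, library_size=total)


def write_peaks_bed(peaks: list[PeakRecord], path: str) -> None:
    """Write peaks as 9-column BED 6+3; floats carry 5 decimal places."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score}\t{p.strand}\t"
                f"{p.value:.5f}\t{p.neg_log10_p:.5f}\t{p.neg_log10_q:.5f}\n"
            )


def write_summits_bed(peaks: list[PeakRecord], path: str) -> None:
    """Companion BED6 with one row per summit (score = peak score)."""
    with open(path, "w") as fh:
        for p in peaks:
            for i, off in enumerate(p.summits or []):
                pos = p.start + off
                fh.write(f"{p.chrom}\t{pos}\t{pos + 1}\t{p.name}_summit_{i + 1}\t{p.score}\t.\n")


def read_peaks_bed(path: str) -> list[PeakRecord]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"expected 9 columns, got {len(f)}")
            peaks.append(
                PeakRecord(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    name=f[3],
                    score=int(f[4]),
                    strand=f[5],
                    value=float(f[6]),
                    neg_log10_p=float(f[7]),
                    neg_log10_q=float(f[8]),
                )
            )
    return peaks
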