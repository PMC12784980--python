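"""From PEPs to peaks: threshold scan, pivotal points and saturation
threshold, candidate grouping, block-wise local-Poisson scoring,
multiple-testing adjustment, boundary refinement, and summits.

A bin "exceeds the threshold" when its PEP is <= the cutoff: PEP is an
error probability, so small means confident.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp
from scipy.stats import poisson

from .genome_io import GenomeLayout, PeakRecord, q_to_score
from .hmm import Constraints, HmmModel, PosteriorTrack
from .preprocess import BinnedTrack

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)

GRID_MIN = 1e-10
GRID_MAX = 0.5
SATURATION_FRACTION = 0.05
BLOWUP_FACTOR = 2.0
#: candidates must already exist at this PEP before the scan is trusted;
#: tracks whose first candidates only appear at lax thresholds carry no
#: confidently enriched bins at all
MIN_CONFIDENT_PEP = 0.05


class NoEnrichmentError(ValueError):
    """No candidate peaks at any threshold."""


@dataclass
class ThresholdScan:
    thresholds: np.ndarray  # ascending PEP (descending stringency)
    counts: np.ndarray  # candidates per threshold
    mean_lengths: np.ndarray  # mean candidate length (bp) per threshold


@dataclass
class CandidateSet:
    threshold: float
    candidates: list[tuple[str, int, int]]  # (chrom, start_bin, end_bin) end-exclusive


@dataclass
class SelectedThreshold:
    threshold: float
    index: int
    pivotal: tuple[int, int]


def candidates_at(pep: PosteriorTrack, threshold: float) -> CandidateSet:
    """Maximal runs of consecutive bins with PEP <= threshold (no gap merging)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    cands: list[tuple[str, int, int]] = []
    for chrom, peps in pep.pep.items():
        mask = peps <= threshold
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        cands.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return CandidateSet(threshold=threshold, candidates=cands)


def scan_thresholds(pep: PosteriorTrack, bin_size: int, grid_size: int = 40) -> ThresholdScan:
    """Candidate count and mean length per log-spaced PEP threshold."""
    thresholds = np.logspace(math.log10(GRID_MIN), math.log10(GRID_MAX), grid_size)
    counts = np.zeros(grid_size, dtype=np.int64)
    mean_lengths = np.zeros(grid_size)
    for i, thr in enumerate(thresholds):
        cs = candidates_at(pep, float(thr))
        counts[i] = len(cs.candidates)
        if cs.candidates:
            mean_lengths[i] = float(
                np.mean([(e - s) * bin_size for _, s, e in cs.candidates])
            )
    return ThresholdScan(thresholds=thresholds, counts=counts, mean_lengths=mean_lengths)


def select_threshold(scan: ThresholdScan) -> SelectedThreshold:
    """Saturation threshold between pivotal points of the candidate-count curve.

    The first pivotal point is the grid index where candidates appear; the
    last is the index just before the count gain "blows up" (a gain jump
    exceeding twice every previous gain, marking the noise regime).  Within
    the pivotal interval the threshold is the first grid point after the gain
    maximum where the gain drops to <= 5% of that maximum; if the gain never
    saturates the midpoint of the interval is used.
    """
    counts = np.asarray(scan.counts, dtype=np.int64)
    if counts.max() < 1:
        raise NoEnrichmentError("no enrichment detected")
    n = len(counts)
    gains = np.diff(counts, prepend=0)

    i0 = int(np.flatnonzero(counts > 0)[0])
    if scan.thresholds[i0] > MIN_CONFIDENT_PEP:
        raise NoEnrichmentError(
            "no enrichment detected: first candidates appear only at "
            f"PEP {scan.thresholds[i0]:.3g}"
        )
    i1 = n - 1
    prior_max = max(int(gains[i0]), 1)
    for j in range(i0 + 1, n):
        g = int(gains[j])
        if g > BLOWUP_FACTOR * prior_max and g >= 0.1 * counts[j]:
            i1 = j - 1
            break
        prior_max = max(prior_max, g, 1)
    i1 = max(i1, i0)

    window = gains[i0 : i1 + 1]
    gmax = int(window.max())
    im = i0 + int(np.argmax(window))
    selected: Optional[int] = None
    for j in range(im + 1, i1 + 1):
        if gains[j] <= SATURATION_FRACTION * gmax:
            selected = j
            break
    if selected is None:
        selected = (i0 + i1) // 2  # gain never saturates inside the interval
    selected = int(np.clip(selected, i0, i1))
    return SelectedThreshold(
        threshold=float(scan.thresholds[selected]), index=selected, pivotal=(i0, i1)
    )


def _log10_poisson_tail(k: int, lam: float) -> float:
    """log10 P(X >= k) for X ~ Poisson(lam), stable for extreme tails.

    scipy's logsf underflows to -inf once the survival probability drops
    below the float range; the far tail (k >> lam) is then summed as a
    log-space series of pmf terms instead.
    """
    ls = poisson.logsf(k - 1, lam)
    if np.isfinite(ls):
        return float(ls) / LN10
    terms = poisson.logpmf(k + np.arange(64), lam)
    return float(logsumexp(terms)) / LN10


def score_candidates(
    cands: CandidateSet,
    track: BinnedTrack,
    control: Optional[BinnedTrack],
    model: HmmModel,
    pep: PosteriorTrack,
    noise_min: float = 0.01,
) -> list[tuple[tuple[str, int, int], float]]:
    """Length-weighted block log10 p-value per candidate.

    Within a candidate, bins are ranked by PEP (ties to the leftmost bin);
    the most confident ceil(n/2) bins are kept and partitioned into maximal
    consecutive runs ("blocks").  Each block gets an upper-tail Poisson
    p-value of its treatment count sum against the scaled-control sum (or
    noise.mean * block length without control), floored at noise_min per
    bin; the candidate score is the block-length-weighted mean of block
    log10 p-values.
    """
    if not cands.candidates:
        raise ValueError("candidate set is empty")
    results = []
    for chrom, s, e in cands.candidates:
        nbins = e - s
        peps = pep.pep[chrom][s:e]
        order = np.argsort(peps, kind="stable")  # stable => leftmost wins ties
        keep = np.sort(order[: math.ceil(nbins / 2)])
        # maximal consecutive runs of kept bin offsets
        splits = np.flatnonzero(np.diff(keep) > 1) + 1
        blocks = np.split(keep, splits)
        num = 0.0
        den = 0
        tcounts = np.asarray(track.counts[chrom], dtype=float)
        ccounts = np.asarray(control.counts[chrom], dtype=float) if control is not None else None
        for block in blocks:
            blen = len(block)
            obs = float(tcounts[s + block].sum())
            if ccounts is not None:
                lam = float(ccounts[s + block].sum())
            else:
                lam = model.noise.mean * blen
            lam = max(lam, noise_min * blen)
            log10_p = _log10_poisson_tail(math.ceil(obs), lam)
            num += blen * log10_p
            den += blen
        results.append(((chrom, s, e), num / den))
    return results


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """BH step-up (with monotonicity enforcement) or Bonferroni q-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method != "bh":
        raise ValueError(f"unknown adjustment method: {method}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(1.0, q_sorted)
    return q


def adjust_log10_pvalues(log10_p, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment carried out entirely in log10 space.

    Equivalent to :func:`adjust_pvalues` on ``10**log10_p`` but immune to
    underflow for extremely small p-values.
    """
    lp = np.asarray(log10_p, dtype=float)
    m = len(lp)
    log_m = math.log10(m) if m else 0.0
    if method == "bonferroni":
        return np.minimum(0.0, lp + log_m)
    if method != "bh":
        raise ValueError(f"unknown adjustment method: {method}")
    order = np.argsort(lp, kind="stable")
    ranked = lp[order] + log_m - np.log10(np.arange(1, m + 1))
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(0.0, q_sorted)
    return q


def refine_boundaries(
    peak: tuple[str, int, int],
    coverage: BinnedTrack,
    clip_fraction: float = 0.25,
    max_clip: float = 0.25,
) -> tuple[str, int, int]:
    """Trim low-coverage edge bins.

    From each edge inward, bins with count < clip_fraction * max count inside
    the peak are dropped, removing at most ``max_clip`` of the original
    length per side; the peak is never emptied.
    """
    chrom, s, e = peak
    counts = np.asarray(coverage.counts[chrom][s:e], dtype=float)
    n = len(counts)
    if n == 0:
        raise ValueError("empty peak")
    thr = clip_fraction * counts.max()
    budget = int(max_clip * n)
    left = 0
    while left < budget and left < n - 1 and counts[left] < thr:
        left += 1
    right = 0
    while right < budget and (n - 1 - right) > left and counts[n - 1 - right] < thr:
        right += 1
    return (chrom, s + left, e - right)


def _smooth3(x: np.ndarray) -> np.ndarray:
    """3-bin moving average with shrinking windows at the edges."""
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        out[i] = x[max(0, i - 1) : min(n, i + 2)].mean()
    return out


def find_summits(
    peak: tuple[str, int, int],
    coverage: BinnedTrack,
    min_separation: int = 5,
    height_fraction: float = 0.5,
) -> list[int]:
    """Local maxima of smoothed in-peak coverage, greedily thinned.

    Maxima (leftmost bin of any plateau) with smoothed height >=
    ``height_fraction`` of the peak maximum are kept highest-first, subject
    to a ``min_separation`` spacing; ties break to the leftmost.  Returns
    absolute bin indices.
    """
    chrom, s, e = peak
    x = np.asarray(coverage.counts[chrom][s:e], dtype=float)
    sm = _smooth3(x)
    n = len(sm)
    maxima = []
    for i in range(n):
        left_ok = i == 0 or sm[i] > sm[i - 1]
        right_ok = i == n - 1 or sm[i] >= sm[i + 1]
        if left_ok and right_ok:
            maxima.append(i)
    peak_max = sm.max()
    maxima = [i for i in maxima if sm[i] >= height_fraction * peak_max]
    maxima.sort(key=lambda i: (-sm[i], i))
    kept: list[int] = []
    for i in maxima:
        if all(abs(i - j) >= min_separation for j in kept):
            kept.append(i)
    return sorted(s + i for i in kept)


def interval_jaccard(
    a: list[tuple[str, int, int]], b: list[tuple[str, int, int]]
) -> float:
    """Length-based Jaccard index of two interval sets (0-based half-open)."""

    def merged(intervals):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        out = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            acc = []
            for s, e in ivs:
                if acc and s <= acc[-1][1]:
                    acc[-1] = (acc[-1][0], max(acc[-1][1], e))
                else:
                    acc.append((s, e))
            out[chrom] = acc
        return out

    ma, mb = merged(a), merged(b)
    inter = 0
    len_a = sum(e - s for ivs in ma.values() for s, e in ivs)
    len_b = sum(e - s for ivs in mb.values() for s, e in ivs)
    for chrom in set(ma) & set(mb):
        ia, ib = ma[chrom], mb[chrom]
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if e > s:
                inter += e - s
            if ia[i][1] < ib[j][1]:
                i += 1
            else:
                j += 1
    union = len_a + len_b - inter
    return inter / union if union > 0 else 0.0


def call_peaks(
    pep: PosteriorTrack,
    track: BinnedTrack,
    control: Optional[BinnedTrack],
    model: HmmModel,
    layout: GenomeLayout,
    fdr: float = 0.05,
    method: str = "bh",
    summits: bool = False,
    noise_min: float = 0.01,
    clip_fraction: float = 0.25,
    max_clip: float = 0.25,
) -> tuple[list[PeakRecord], SelectedThreshold]:
    """Full PEP-to-peaks pipeline.

    select_threshold -> candidates_at -> score_candidates -> adjust ->
    filter q <= fdr -> refine_boundaries -> optional summits.  ``control``
    must already be scaled to the treatment library size.
    """
    scan = scan_thresholds(pep, track.bin_size)
    sel = select_threshold(scan)
    cands = candidates_at(pep, sel.threshold)
    if not cands.candidates:
        raise NoEnrichmentError("no enrichment detected")
    scored = score_candidates(cands, track, control, model, pep, noise_min=noise_min)
    log10_p = np.array([lp for _, lp in scored])
    log10_q = adjust_log10_pvalues(log10_p, method=method)
    keep = log10_q <= math.log10(fdr) if fdr < 1.0 else np.ones(len(scored), dtype=bool)

    bs = track.bin_size
    chrom_rank = {name: i for i, name in enumerate(layout.names)}
    rows = [
        (scored[i][0], log10_p[i], log10_q[i]) for i in range(len(scored)) if keep[i]
    ]
    rows.sort(key=lambda r: (chrom_rank[r[0][0]], r[0][1]))
    records: list[PeakRecord] = []
    for idx, ((chrom, s, e), lp, lq) in enumerate(rows, start=1):
        chrom_r, rs, re = refine_boundaries(
            (chrom, s, e), track, clip_fraction=clip_fraction, max_clip=max_clip
        )
        counts = np.asarray(track.counts[chrom][rs:re], dtype=float)
        if control is not None:
            lam = float(np.asarray(control.counts[chrom][rs:re], dtype=float).mean())
        else:
            lam = model.noise.mean
        lam = max(lam, noise_min)
        fold = float(counts.mean()) / lam
        neg_p = -lp
        neg_q = -lq
        summit_offsets = None
        if summits:
            summit_bins = find_summits((chrom, rs, re), track)
            summit_offsets = [
                b * bs + bs // 2 - rs * bs for b in summit_bins
            ]
        records.append(
            PeakRecord(
                chrom=chrom,
                start=rs * bs,
                end=min(re * bs, layout.length(chrom)),
                name=f"peak_{idx}",
                score=q_to_score(neg_q),
                strand=".",
                value=fold,
                neg_log10_p=neg_p,
                neg_log10_q=neg_q,
                summits=summit_offsets,
            )
        )
    logger.info(
        "called %d peaks at PEP threshold %.3g (fdr=%g, %s)",
        len(records), sel.threshold, fdr, method,
    )
    return records, sel
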