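import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

from hmmpeaks.genome_io import GenomeLayout
from hmmpeaks.hmm import HmmModel, NegBinParams, PosteriorTrack, compute_pep
from hmmpeaks.peaks import (
    CandidateSet,
    NoEnrichmentError,
    ThresholdScan,
    adjust_log10_pvalues,
    adjust_pvalues,
    call_peaks,
    candidates_at,
    find_summits,
    interval_jaccard,
    refine_boundaries,
    scan_thresholds,
    score_candidates,
    select_threshold,
)
from hmmpeaks.preprocess import BinnedTrack


def _pep_track(values, chrom="chrT"):
    values = np.asarray(values, dtype=float)
    gamma = np.column_stack([np.zeros_like(values), values, 1.0 - values])
    pt = PosteriorTrack({chrom: gamma})
    return compute_pep(pt)


def _track(values, bin_size=200):
    arr = np.asarray(values, dtype=float)
    return BinnedTrack({"chrT": arr}, bin_size, float(arr.sum()))


def _model(noise_mean=2.0):
    return HmmModel(
        initial=np.array([1 / 3] * 3),
        transitions=np.full((3, 3), 1 / 3),
        noise=NegBinParams(noise_mean, 4.0),
        signal=NegBinParams(40.0, 10.0),
    )


class TestCandidatesAt:
    def test_strict_threshold_two_singletons(self):
        pep = _pep_track([0.01, 0.2, 0.01])
        cs = candidates_at(pep, 0.05)
        assert cs.candidates == [("chrT", 0, 1), ("chrT", 2, 3)]

    def test_relaxed_threshold_merges(self):
        pep = _pep_track([0.01, 0.2, 0.01])
        cs = candidates_at(pep, 0.3)
        assert cs.candidates == [("chrT", 0, 3)]

    def test_all_one_empty(self):
        pep = _pep_track([1.0, 1.0, 1.0])
        assert candidates_at(pep, 0.5).candidates == []

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60), st.integers(1, 8))
    @settings(max_examples=60, deadline=None)
    def test_nesting_under_relaxation(self, peps, k):
        strict, loose = 0.05, 0.05 * (1 + k)
        pep = _pep_track(peps)
        cs_strict = candidates_at(pep, strict)
        cs_loose = candidates_at(pep, loose)
        for _, s, e in cs_strict.candidates:
            containers = [
                (ls, le) for _, ls, le in cs_loose.candidates if ls <= s and e <= le
            ]
            assert len(containers) == 1


class TestScanThresholds:
    def test_bimodal_plateau(self):
        peps = np.tile([1e-6, 0.9], 50)
        scan = scan_thresholds(_pep_track(peps), bin_size=200)
        past = scan.counts[scan.thresholds >= 1e-6]
        assert (past == 50).all()  # plateau persists: 0.9 > grid max 0.5

    def test_matches_per_threshold_recount(self, rng):
        peps = rng.random(500) ** 4
        pt = _pep_track(peps)
        scan = scan_thresholds(pt, bin_size=200)
        for i, thr in enumerate(scan.thresholds):
            cs = candidates_at(pt, float(thr))
            assert scan.counts[i] == len(cs.candidates)
            if cs.candidates:
                expected = np.mean([(e - s) * 200 for _, s, e in cs.candidates])
                assert scan.mean_lengths[i] == pytest.approx(expected)


def _scan(counts):
    counts = np.asarray(counts, dtype=np.int64)
    n = len(counts)
    thresholds = np.logspace(-10, math.log10(0.5), n)
    return ThresholdScan(thresholds, counts, np.ones(n))


class TestSelectThreshold:
    def test_step_function_selects_plateau(self):
        counts = [0, 0, 100] + [100] * 30 + [5000]
        sel = select_threshold(_scan(counts))
        assert _scan(counts).counts[sel.index] == 100
        assert sel.pivotal[0] == 2
        assert sel.index < len(counts) - 1

    def test_linear_counts_fallback_midpoint(self):
        counts = list(range(40))
        sel = select_threshold(_scan(counts))
        i0, i1 = sel.pivotal
        assert sel.index == (i0 + i1) // 2

    def test_degenerate_scan_raises(self):
        with pytest.raises(NoEnrichmentError, match="no enrichment"):
            select_threshold(_scan([0] * 40))

    def test_late_first_candidates_rejected(self):
        # candidates only at lax PEP -> nothing confidently enriched
        counts = [0] * 38 + [50, 400]
        with pytest.raises(NoEnrichmentError):
            select_threshold(_scan(counts))

    def test_simulated_track_count_near_truth(self, small_sim, small_result):
        spec, truth, _ = small_sim
        pep = small_result.pep
        scan = scan_thresholds(pep, bin_size=200)
        sel = select_threshold(scan)
        n_at_sel = len(candidates_at(pep, sel.threshold).candidates)
        assert abs(n_at_sel - len(truth)) <= 0.1 * len(truth)
        # oracle: the count at the selected threshold matches the sweep
        assert n_at_sel == scan.counts[sel.index]


class TestScoreCandidates:
    def test_single_bin_direct_tail_sum(self):
        pep = _pep_track([1e-8])
        cands = CandidateSet(0.5, [("chrT", 0, 1)])
        track = _track([10])
        scored = score_candidates(cands, track, None, _model(noise_mean=2.0), pep)
        # oracle: direct Poisson tail summation P(X >= 10 | lambda=2)
        tail = sum(math.exp(-2) * 2**k / math.factorial(k) for k in range(10, 60))
        assert scored[0][1] == pytest.approx(math.log10(tail), rel=1e-9)

    def test_equal_peps_tie_broken_leftmost(self):
        pep = _pep_track([0.01] * 4)
        cands = CandidateSet(0.5, [("chrT", 0, 4)])
        track = _track([7, 7, 7, 7])
        scored = score_candidates(cands, track, None, _model(noise_mean=2.0), pep)
        # top-2 most confident bins are the leftmost two -> one block of 2 bins
        expected = poisson.logsf(13, 4.0) / math.log(10)
        assert scored[0][1] == pytest.approx(expected, rel=1e-12)

    def test_unenriched_candidate_p_near_one(self):
        pep = _pep_track([0.01, 0.01])
        cands = CandidateSet(0.5, [("chrT", 0, 2)])
        track = _track([1, 1])
        scored = score_candidates(cands, track, None, _model(noise_mean=5.0), pep)
        assert scored[0][1] >= math.log10(0.25)

    def test_control_lambda_used(self):
        pep = _pep_track([1e-8])
        cands = CandidateSet(0.5, [("chrT", 0, 1)])
        track = _track([10])
        control = _track([8.0])
        scored = score_candidates(cands, track, control, _model(noise_mean=0.1), pep)
        expected = poisson.logsf(9, 8.0) / math.log(10)
        assert scored[0][1] == pytest.approx(expected, rel=1e-12)

    def test_lambda_floored_by_noise_min(self):
        pep = _pep_track([1e-8])
        cands = CandidateSet(0.5, [("chrT", 0, 1)])
        track = _track([3])
        scored = score_candidates(
            cands, track, None, _model(noise_mean=1e-9), pep, noise_min=0.01
        )
        expected = poisson.logsf(2, 0.01) / math.log(10)
        assert scored[0][1] == pytest.approx(expected, rel=1e-12)


class TestAdjustPvalues:
    def test_bh_closed_form(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "bh"), [0.03, 0.03, 0.03]
        )

    def test_bonferroni(self):
        p = [0.01] + [1.0] * 9
        assert adjust_pvalues(p, "bonferroni")[0] == pytest.approx(0.1)

    def test_single_test_identity(self):
        for method in ("bh", "bonferroni"):
            assert adjust_pvalues([0.2], method)[0] == pytest.approx(0.2)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        np.testing.assert_allclose(
            adjust_pvalues(p, "bh"), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )
        np.testing.assert_allclose(
            adjust_pvalues(p, "bonferroni"),
            multipletests(p, method="bonferroni")[1],
            atol=1e-12,
        )

    def test_log_space_agrees_with_linear(self, rng):
        p = rng.random(100) * 0.5 + 1e-6
        for method in ("bh", "bonferroni"):
            q_lin = adjust_pvalues(p, method)
            q_log = adjust_log10_pvalues(np.log10(p), method)
            np.testing.assert_allclose(10**q_log, q_lin, rtol=1e-9)

    def test_q_at_least_p(self, rng):
        lp = -rng.random(50) * 300
        for method in ("bh", "bonferroni"):
            assert (adjust_log10_pvalues(lp, method) >= lp - 1e-12).all()


class TestRefineBoundaries:
    def test_edges_trimmed(self):
        track = _track([0, 5, 9, 5, 0])
        assert refine_boundaries(("chrT", 0, 5), track) == ("chrT", 1, 4)

    def test_flat_unchanged(self):
        track = _track([4, 4, 4, 4])
        assert refine_boundaries(("chrT", 0, 4), track) == ("chrT", 0, 4)

    def test_clip_capped_per_side(self):
        track = _track([1, 1, 1, 1, 100])
        # oracle: threshold 25, bins 0-3 all fail, but cap = int(0.25*5) = 1
        assert refine_boundaries(("chrT", 0, 5), track) == ("chrT", 1, 5)

    @given(
        st.lists(st.integers(0, 50), min_size=1, max_size=30),
        st.integers(0, 5),
    )
    @settings(max_examples=80, deadline=None)
    def test_never_outward_never_empty(self, counts, pad):
        values = [0] * pad + counts + [0] * pad
        track = _track(values)
        n = len(values)
        chrom, s, e = refine_boundaries(("chrT", 0, n), track)
        assert 0 <= s < e <= n
        assert s <= int(0.25 * n) and (n - e) <= int(0.25 * n)


class TestFindSummits:
    def test_unimodal_single_summit(self):
        track = _track([0, 1, 5, 1, 0])
        assert find_summits(("chrT", 0, 5), track) == [2]

    def test_two_separated_maxima(self):
        values = np.zeros(15)
        values[1:4] = (1, 10, 1)
        values[11:14] = (1, 10, 1)
        track = _track(values)
        assert find_summits(("chrT", 0, 15), track, min_separation=5) == [2, 12]

    def test_close_maxima_thinned_leftmost(self):
        values = np.array([0.0, 8, 10, 2, 10, 8, 0])
        track = _track(values)
        got = find_summits(("chrT", 0, 7), track, min_separation=5)
        # oracle: brute-force maxima on the smoothed array, greedy thinning
        sm = np.array(
            [values[max(0, i - 1): i + 2].mean() for i in range(len(values))]
        )
        maxima = [
            i
            for i in range(len(sm))
            if (i == 0 or sm[i] > sm[i - 1]) and (i == len(sm) - 1 or sm[i] >= sm[i + 1])
            and sm[i] >= 0.5 * sm.max()
        ]
        maxima.sort(key=lambda i: (-sm[i], i))
        kept = []
        for i in maxima:
            if all(abs(i - j) >= 5 for j in kept):
                kept.append(i)
        assert got == sorted(kept)
        assert len(got) == 1


class TestIntervalJaccard:
    def test_identical_sets(self):
        a = [("c", 0, 100), ("c", 200, 300)]
        assert interval_jaccard(a, a) == 1.0

    def test_disjoint(self):
        assert interval_jaccard([("c", 0, 10)], [("c", 20, 30)]) == 0.0

    def test_half_overlap(self):
        assert interval_jaccard([("c", 0, 100)], [("c", 50, 150)]) == pytest.approx(50 / 150)

    def test_against_boolean_mask_oracle(self, rng):
        a = [("c", int(s), int(s) + int(l)) for s, l in
             zip(rng.integers(0, 9000, 20), rng.integers(1, 500, 20))]
        b = [("c", int(s), int(s) + int(l)) for s, l in
             zip(rng.integers(0, 9000, 20), rng.integers(1, 500, 20))]
        ma = np.zeros(10_000, bool)
        mb = np.zeros(10_000, bool)
        for _, s, e in a:
            ma[s:e] = True
        for _, s, e in b:
            mb[s:e] = True
        expected = (ma & mb).sum() / (ma | mb).sum()
        assert interval_jaccard(a, b) == pytest.approx(expected)


class TestCallPeaks:
    def test_quality_one_recovers_truth(self, small_sim, small_result):
        spec, truth, _ = small_sim
        called = [(p.chrom, p.start, p.end) for p in small_result.peaks]
        assert interval_jaccard(called, truth) >= 0.7

    def test_fdr_one_keeps_all_scored_candidates(self, small_sim, small_result):
        spec, truth, tags = small_sim
        pep, track, model = small_result.pep, small_result.track, small_result.model
        layout = spec.layout
        all_peaks, sel = call_peaks(pep, track, None, model, layout, fdr=1.0)
        n_candidates = len(candidates_at(pep, sel.threshold).candidates)
        assert len(all_peaks) == n_candidates

    def test_peak_count_non_increasing_in_stricter_fdr(self, small_sim, small_result):
        spec, _, _ = small_sim
        pep, track, model = small_result.pep, small_result.track, small_result.model
        prev = None
        for fdr in (1.0, 0.05, 1e-10, 1e-50):
            n = len(call_peaks(pep, track, None, model, spec.layout, fdr=fdr)[0])
            if prev is not None:
                assert n <= prev
            prev = n

    def test_records_well_formed(self, small_result):
        for p in small_result.peaks:
            assert p.start < p.end
            assert p.strand == "."
            assert p.neg_log10_q <= p.neg_log10_p + 1e-9
            assert p.score == min(1000, round(10 * p.neg_log10_q))

    def test_pure_background_no_enrichment(self, layout2m):
        from hmmpeaks.cli import analyze_tags
        from hmmpeaks.simulate import SimulationSpec, generate_reads

        spec = SimulationSpec(
            layout=layout2m, n_peaks=0, n_reads=100_000, quality=0.5, seed=3
        )
        tags = generate_reads([], spec)
        try:
            result = analyze_tags(tags, layout2m, seed=3)
            assert len(result.peaks) == 0
        except NoEnrichmentError:
            pass

    def test_summits_inside_peaks(self, small_sim):
        from hmmpeaks.cli import analyze_tags

        spec, truth, tags = small_sim
        result = analyze_tags(tags, spec.layout, summits=True, seed=7)
        assert any(p.summits for p in result.peaks)
        for p in result.peaks:
            for off in p.summits or []:
                assert 0 <= off < p.end - p.start
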