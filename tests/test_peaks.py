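"""Pileups, permutation-FDR peak calling, robust-site thresholds, CITS,
and k-mer enrichment."""

import numpy as np
import pytest
from scipy import stats

from clipshift.annotation import GeneModel, GenomicInterval
from clipshift.peaks import (
    ClipTag,
    Peak,
    _candidate_peaks,
    _dinucleotide_shuffle,
    _null_ph_counts,
    call_cits,
    call_peaks,
    define_robust_sites,
    kmer_enrichment,
    pileup,
    stratify_by_ph,
)


def _gene(length=10_000, downstream=0):
    return GeneModel.from_exons("g", "chr1", "+", [(0, length)],
                                (0, length), downstream=downstream)


def _tag(s, e, rep="r1", serum="A", strand="+"):
    return ClipTag(GenomicInterval("chr1", s, e, strand), rep, serum)


class TestPileup:
    def test_hand_pileup(self):
        gm = _gene(100)
        tags = [_tag(10, 20), _tag(15, 25), _tag(18, 22)]
        depth = pileup(tags, gm)
        assert depth[18] == 3
        assert depth.max() == 3
        assert depth[9] == 0 and depth[10] == 1

    def test_empty(self):
        assert pileup([], _gene(50)).sum() == 0

    def test_depth_sum_conservation(self, rng):
        gm = _gene(2_000)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            starts = rng.integers(0, 1_950, n)
            tags = [_tag(int(s), int(s) + int(rng.integers(1, 50))) for s in starts]
            depth = pileup(tags, gm)
            clipped = sum(min(t.interval.end, 2_000) - t.interval.start
                          for t in tags)
            assert depth.sum() == clipped

    def test_truncation_position_invariant(self):
        t_plus = _tag(10, 45)
        assert t_plus.truncation_pos == 10
        t_minus = _tag(10, 45, strand="-")
        assert t_minus.truncation_pos == 44


class TestCandidatesAndKernel:
    def test_kernel_matches_python_candidates(self, rng):
        """The numba null kernel counts exactly the candidates the observed
        path produces, over random tag configurations."""
        for _ in range(150):
            n = int(rng.integers(1, 40))
            starts = np.sort(rng.integers(0, 400, n)).astype(np.int64)
            ends = starts + int(rng.integers(5, 40))
            cands = _candidate_peaks(starts.copy(), ends.copy())
            max_ph = max(ph for *_, ph in cands)
            counts = _null_ph_counts(starts, ends, 0.5, max_ph)
            for h in range(1, max_ph + 1):
                assert counts[h] == sum(1 for *_, ph in cands if ph >= h)

    def test_valley_split(self):
        # two stacks bridged by one tag: depth 10/11 at the stacks (the
        # bridge overlaps both) with a depth-1 valley between -> split
        tags = [(0, 30)] * 10 + [(25, 65)] + [(60, 90)] * 10
        starts = np.array([s for s, _ in tags])
        ends = np.array([e for _, e in tags])
        cands = _candidate_peaks(starts, ends)
        assert len(cands) == 2
        assert sorted(ph for *_, ph in cands) == [11, 11]
        left, right = sorted(cands)
        assert 30 <= left[1] <= 60 and 30 <= right[0] <= 60


class TestCallPeaks:
    def test_strong_site_called(self):
        gm = _gene(10_000)
        rng = np.random.default_rng(5)
        tags = [_tag(5_000 + int(rng.integers(-3, 4)), 5_030) for _ in range(50)]
        tags += [_tag(int(s), int(s) + 30) for s in rng.integers(0, 9_900, 10)]
        peaks = call_peaks(tags, gm, alpha=0.01, n_perm=100, seed=1)
        assert len(peaks) == 1
        assert peaks[0].fdr < 0.01
        assert peaks[0].interval.start <= 5_000 < peaks[0].interval.end
        assert peaks[0].ph >= 45

    def test_single_tag_never_passes(self):
        peaks = call_peaks([_tag(100, 130)], _gene(10_000), n_perm=50, seed=0)
        assert peaks == []

    def test_low_n_perm_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            call_peaks([_tag(0, 10)], _gene(100), n_perm=10)

    def test_support_sets_recorded(self):
        gm = _gene(5_000)
        tags = [_tag(1_000, 1_030, rep=f"r{i%3}", serum="AB"[i % 2])
                for i in range(30)]
        peaks = call_peaks(tags, gm, n_perm=50, seed=2)
        assert len(peaks) == 1
        assert peaks[0].support_replicates == {"r0", "r1", "r2"}
        assert peaks[0].support_antisera == {"A", "B"}


def _peak(s, e, ph, reps, sera, gene="g", fdr=0.0):
    return Peak(GenomicInterval("chr1", s, e, "+"), gene, ph, max(ph, 20),
                fdr, frozenset(reps), frozenset(sera))


class TestRobustSites:
    def test_retained_at_thresholds(self):
        peaks = [
            _peak(10, 40, 6, {"r1"}, {"A"}),
            _peak(20, 50, 4, {"r2"}, {"A"}),
            _peak(30, 55, 3, {"r3"}, {"B"}),
        ]
        sites = define_robust_sites(peaks)
        assert len(sites) == 1
        s = sites[0]
        assert (s.interval.start, s.interval.end) == (10, 55)  # union
        assert s.ph == 6  # max constituent
        assert s.support_replicates == {"r1", "r2", "r3"}

    def test_ph_threshold_is_strict(self):
        peaks = [_peak(10, 40, 5, {f"r{i}"}, {"AB"[i % 2]}) for i in range(4)]
        assert define_robust_sites(peaks) == []

    def test_single_antiserum_rejected(self):
        peaks = [_peak(10, 40, 8, {f"r{i}"}, {"A"}) for i in range(4)]
        assert define_robust_sites(peaks) == []

    def test_pooled_mode_default_support(self):
        p6 = _peak(10, 40, 9, {f"r{i}" for i in range(6)}, {"A", "B"})
        p5 = _peak(10, 40, 9, {f"r{i}" for i in range(5)}, {"A", "B"})
        assert len(define_robust_sites([p6], merge_mode="pooled")) == 1
        assert define_robust_sites([p5], merge_mode="pooled") == []

    def test_support_monotonicity(self, rng):
        """Raising thresholds never increases the robust-site count."""
        peaks = []
        for i in range(60):
            s = int(rng.integers(0, 5_000))
            peaks.append(
                _peak(s, s + int(rng.integers(10, 80)),
                      int(rng.integers(1, 15)),
                      {f"r{j}" for j in rng.choice(6, rng.integers(1, 6),
                                                   replace=False)},
                      {"AB"[j] for j in rng.choice(2, rng.integers(1, 3) % 2 + 1,
                                                   replace=False)})
            )
        base = len(define_robust_sites(peaks, min_ph=3, min_replicates=2,
                                       min_antisera=1))
        for kwargs in ({"min_ph": 5}, {"min_replicates": 4},
                       {"min_antisera": 2}):
            stricter = len(define_robust_sites(
                peaks, **{"min_ph": 3, "min_replicates": 2,
                          "min_antisera": 1, **kwargs}))
            assert stricter <= base

    def test_missing_provenance_rejected(self):
        bad = _peak(0, 10, 6, set(), {"A"})
        with pytest.raises(ValueError, match="provenance"):
            define_robust_sites([bad])


class TestStratify:
    def _sites(self, phs):
        peaks = [_peak(100 * i, 100 * i + 50, ph,
                       {"r1", "r2", "r3"}, {"A", "B"}, gene=f"g{i}")
                 for i, ph in enumerate(phs)]
        return define_robust_sites(peaks, min_ph=0, min_replicates=1,
                                   min_antisera=1)

    def test_top_quintile_of_ten(self):
        sites = stratify_by_ph(self._sites(range(1, 11)), 0.20, scope="global")
        top = {s.ph for s in sites if s.tier == "top"}
        assert top == {9, 10}

    def test_all_top_when_fraction_one(self):
        sites = stratify_by_ph(self._sites(range(1, 11)), 1.0, scope="global")
        assert all(s.tier == "top" for s in sites)

    def test_deterministic_ties(self):
        a = stratify_by_ph(self._sites([7] * 10), 0.2, scope="global")
        b = stratify_by_ph(self._sites([7] * 10), 0.2, scope="global")
        assert [(s.site_id, s.tier) for s in a] == [(s.site_id, s.tier) for s in b]

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            stratify_by_ph(self._sites([1, 2]), 0.2)


class TestCits:
    def test_concentrated_truncations_called(self):
        peak = _peak(100, 120, 10, {"r1"}, {"A"})
        tags = [_tag(105, 140) for _ in range(9)] + [_tag(111, 140)]
        sites = call_cits(tags, [peak])
        assert len(sites) == 1
        assert sites[0].position == 105
        # exact upper tail: P(X >= 9 | n=10, p=1/20)
        oracle = sum(
            stats.binom.pmf(k, 10, 0.05) for k in range(9, 11)
        )
        assert sites[0].p_value == pytest.approx(oracle, rel=1e-9)
        assert oracle < 1e-9

    def test_uniform_truncations_not_called(self):
        peak = _peak(100, 120, 10, {"r1"}, {"A"})
        tags = [_tag(100 + i, 140 + i) for i in range(20)]
        assert call_cits(tags, [peak]) == []

    def test_no_truncations(self):
        peak = _peak(100, 120, 10, {"r1"}, {"A"})
        assert call_cits([], [peak]) == []


class TestKmerEnrichment:
    def _random_windows(self, rng, n=30, L=30):
        return ["".join(rng.choice(list("ACGU"), L)) for _ in range(n)]

    def test_planted_motif_ranks_first(self, rng):
        windows = []
        for w in self._random_windows(rng):
            windows.append(w[:11] + "UAUUUAUU" + w[19:])
        table = kmer_enrichment(windows, k=8, n_shuffles=100, seed=1)
        assert table.iloc[0]["kmer"] == "UAUUUAUU"
        assert table.iloc[0]["z"] > 5

    def test_null_windows_no_extreme_z(self, rng):
        windows = self._random_windows(rng)
        table = kmer_enrichment(windows, k=8, n_shuffles=100, seed=2)
        assert table["z"].abs().max() < 5.5

    def test_single_window_finite(self):
        table = kmer_enrichment(["ACGUACGUACGUACGU"], k=8, n_shuffles=50, seed=0)
        assert np.isfinite(table["z"]).all()

    def test_dinucleotide_counts_preserved(self, rng):
        def dinucs(s):
            from collections import Counter
            return Counter(s[i:i + 2] for i in range(len(s) - 1))

        for _ in range(20):
            s = "".join(rng.choice(list("ACGU"), 40))
            sh = _dinucleotide_shuffle(s, rng)
            assert dinucs(sh) == dinucs(s)
            assert sh[0] == s[0] and sh[-1] == s[-1]

    def test_short_windows_excluded(self):
        with pytest.raises(ValueError):
            kmer_enrichment(["ACGU"], k=8)
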