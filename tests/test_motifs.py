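"""PWM scanning, dinucleotide shuffling and the motif-evaluation procedures."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zfdiv.intervals import GenomicInterval, GenomicIntervalSet
from zfdiv.motifs import (
    PWM,
    central_enrichment_window,
    dinucleotide_counts,
    dinucleotide_shuffle,
    find_motif_hits,
    motif_auroc,
    optimize_affinity_cutoff,
    rank_auroc,
    reverse_complement,
    score_sequence,
)

TOY = PWM(
    name="toy",
    matrix=np.array(
        [
            [0.85, 0.05, 0.05, 0.05],
            [0.05, 0.85, 0.05, 0.05],
            [0.05, 0.05, 0.85, 0.05],
            [0.05, 0.05, 0.05, 0.85],
        ]
    ),
)


def _informative(name, consensus):
    mat = np.full((len(consensus), 4), 0.05)
    for i, c in enumerate(consensus):
        mat[i, "ACGT".index(c)] = 0.85
    return PWM(name=name, matrix=mat)


# long non-palindromic PWM for peak-level procedures (a 4-mer matches
# background too often to plant cleanly)
TOY10 = _informative("toy10", "AACGTGACTT")


def _brute_best(pwm, seq):
    """Enumerate every placement on both strands."""
    lo = pwm.log_odds()
    L = len(pwm)
    best = -np.inf
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for i in range(len(s) - L + 1):
            sc = 0.0
            for j, c in enumerate(s[i:i + L]):
                if c == "N":
                    sc = -np.inf
                    break
                sc += lo[j, "ACGT".index(c)]
            best = max(best, sc)
    return best


class TestScoreSequence:
    def test_consensus_attains_matrix_max(self):
        sc = score_sequence(TOY, "ACGT")
        assert sc.best_score == pytest.approx(TOY.max_score)
        assert sc.best_strand == "+"

    def test_all_n_has_no_finite_hit(self):
        sc = score_sequence(TOY, "NNNNNN")
        assert sc.best_score == -np.inf

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(6, 15)))
            sc = score_sequence(TOY, seq)
            assert sc.best_score == pytest.approx(_brute_best(TOY, seq))

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=20))
            a = score_sequence(TOY, seq)
            b = score_sequence(TOY, reverse_complement(seq))
            assert a.best_score == pytest.approx(b.best_score)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            score_sequence(TOY, "AC")


class TestPWM:
    def test_bad_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PWM(name="bad", matrix=np.full((4, 4), 0.3))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            PWM(name="bad", matrix=np.full((3, 4), 0.25))

    def test_reverse_complement_round_trip(self):
        rc = TOY.reverse_complement().reverse_complement()
        assert np.allclose(rc.matrix, TOY.matrix)


class TestDinucleotideShuffle:
    def test_monomorphic_sequence_fixed(self):
        assert dinucleotide_shuffle("AAAA", seed=0) == "AAAA"

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=2, max_size=60),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_dinucleotide_counts_conserved(self, seq, seed):
        out = dinucleotide_shuffle(seq, seed=seed)
        assert len(out) == len(seq)
        assert dinucleotide_counts(out) == dinucleotide_counts(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_covers_all_valid_arrangements(self):
        seq = "ACGCGT"
        target = dinucleotide_counts(seq)
        valid = {
            "".join(p)
            for p in itertools.permutations(seq)
            if "".join(p)[0] == seq[0]
            and "".join(p)[-1] == seq[-1]
            and dinucleotide_counts("".join(p)) == target
        }
        emitted = {dinucleotide_shuffle(seq, seed=s) for s in range(300)}
        assert emitted <= valid
        assert emitted == valid

    def test_n_runs_held_fixed(self):
        seq = "ACGTACGTNNNACGTACGT"
        out = dinucleotide_shuffle(seq, seed=3)
        assert out[8:11] == "NNN"
        assert len(out) == len(seq)

    def test_deterministic_given_seed(self):
        seq = "ACGTACGTAGCTTACG"
        assert dinucleotide_shuffle(seq, seed=9) == dinucleotide_shuffle(seq, seed=9)


class TestRankAuroc:
    def test_perfect_separation(self):
        assert rank_auroc(np.full(5, 10.0), np.zeros(5)) == 1.0

    def test_hand_counted_pairs(self):
        # pos=(3,2,1), neg=(2.5,0.5,0): 7 of 9 pairs won
        assert rank_auroc([3, 2, 1], [2.5, 0.5, 0]) == pytest.approx(7 / 9)

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for _ in range(20):
            pos = rng.integers(0, 6, size=rng.integers(5, 200)).astype(float)
            neg = rng.integers(0, 6, size=rng.integers(5, 200)).astype(float)
            wins = sum(
                1.0 if p > n else (0.5 if p == n else 0.0)
                for p in pos
                for n in neg
            )
            assert rank_auroc(pos, neg) == pytest.approx(wins / (len(pos) * len(neg)))


class TestMotifAuroc:
    def test_null_pwm_near_half(self, small_world):
        rng = np.random.default_rng(42)
        mat = np.full((16, 4), 0.05)
        mat[np.arange(16), rng.integers(0, 4, 16)] = 0.85
        random_pwm = PWM(name="mismatch", matrix=mat)
        truth = small_world.landscape.truth_sets["ZF001"]
        auc = motif_auroc(random_pwm, truth, small_world.genome, n_top=100, seed=7)
        assert 0.4 <= auc <= 0.6

    def test_planted_pwm_high(self, small_world):
        p = "ZF001"
        auc = motif_auroc(
            small_world.landscape.pwms[p],
            small_world.landscape.truth_sets[p],
            small_world.genome,
            n_top=100,
            seed=7,
        )
        assert auc > 0.9

    def test_too_few_peaks_refused(self, small_world):
        tiny = GenomicIntervalSet(
            list(small_world.landscape.truth_sets["ZF001"])[:5], label="tiny"
        )
        with pytest.raises(ValueError, match="at least 10"):
            motif_auroc(TOY, tiny, small_world.genome)


def _peakset_with_hits(rng, genome_len=200_000, n_peaks=300, offset_sd=None, pwm=TOY10):
    """Uniform-background chromosome with the PWM consensus planted at a
    configurable offset from each summit (None: uniform in the window)."""
    seq = rng.choice(list("ACGT"), size=genome_len)
    L = len(pwm)
    ivs = []
    for k in range(n_peaks):
        summit = 500 + k * ((genome_len - 1000) // n_peaks)
        if offset_sd is None:
            # uniform over the full feasible center range +/-(250 - L/2)
            off = int(rng.integers(-(250 - L // 2), 250 - L // 2 + 1))
        else:
            off = int(np.clip(round(rng.normal(0, offset_sd)), -240, 240))
        s = summit + off - L // 2
        seq[s:s + L] = list(pwm.consensus)
        ivs.append(GenomicInterval("chr1", summit - 100, summit + 100,
                                   summit=summit, score=float(n_peaks - k)))
    return {"chr1": "".join(seq)}, GenomicIntervalSet(ivs, label="T")


class TestCentralEnrichmentWindow:
    def test_hits_at_summits_select_minimal_window(self, rng):
        genome, peaks = _peakset_with_hits(rng, offset_sd=0.0)
        res = central_enrichment_window(TOY10, peaks, genome, n_top=300)
        assert res.significant
        assert res.halfwidth == 10

    def test_uniform_hits_not_significant(self, rng):
        genome, peaks = _peakset_with_hits(rng, offset_sd=None)
        res = central_enrichment_window(TOY10, peaks, genome, n_top=300)
        assert res.halfwidth == 250
        assert not res.significant

    def test_gaussian_offsets_calibrated_window(self):
        # offsets ~ Normal(0, 25 bp): the selected half-width should settle
        # in the 30-80 bp range for nearly all seeds
        ok = 0
        n_seeds = 10
        for s in range(n_seeds):
            rng = np.random.default_rng(1000 + s)
            genome, peaks = _peakset_with_hits(rng, n_peaks=300, offset_sd=25.0)
            res = central_enrichment_window(TOY10, peaks, genome, n_top=300)
            ok += res.significant and 30 <= res.halfwidth <= 80
        assert ok >= 0.9 * n_seeds


class TestOptimizeAffinityCutoff:
    def test_planted_threshold_recovery(self, rng):
        # consensus only in the top-score half of the peaks
        genome_len, n_peaks = 120_000, 200
        seq = rng.choice(list("ACGT"), size=genome_len)
        ivs = []
        L = len(TOY10)
        for k in range(n_peaks):
            summit = 500 + k * ((genome_len - 1000) // n_peaks)
            if k < n_peaks // 5:  # top 20% by score
                s = summit - L // 2
                seq[s:s + L] = list(TOY10.consensus)
            ivs.append(GenomicInterval("chr1", summit - 100, summit + 100,
                                       summit=summit, score=float(n_peaks - k)))
        genome = {"chr1": "".join(seq)}
        peaks = GenomicIntervalSet(ivs, label="T")
        res = optimize_affinity_cutoff(TOY10, peaks, genome, window=100)
        assert res.informative
        assert res.enrichment > 3
        # hits above the returned cutoff should be concentrated in top peaks
        hits = find_motif_hits(TOY10, peaks, genome, cutoff=res.cutoff, window=100)
        assert len(hits) >= n_peaks // 5

    def test_score_independent_hits_flagged_uninformative(self, rng):
        genome, peaks = _peakset_with_hits(rng, n_peaks=200, offset_sd=5.0)
        res = optimize_affinity_cutoff(TOY10, peaks, genome, window=100)
        assert res.enrichment == pytest.approx(1.0, abs=0.25)


class TestFindMotifHits:
    def test_cutoff_above_max_empty(self, rng):
        genome, peaks = _peakset_with_hits(rng, n_peaks=50, offset_sd=0.0)
        hits = find_motif_hits(TOY10, peaks, genome, cutoff=TOY10.max_score + 1, window=100)
        assert hits == []

    def test_one_hit_per_peak_at_consensus_cutoff(self, rng):
        genome, peaks = _peakset_with_hits(rng, n_peaks=50, offset_sd=0.0)
        hits = find_motif_hits(
            TOY10, peaks, genome, cutoff=TOY10.max_score - 1e-9, window=100
        )
        by_peak = {}
        for h in hits:
            by_peak.setdefault(h.peak_id, []).append(h)
        # consensus ACGT is its own reverse complement partner's score only on
        # the forward strand here; each peak yields exactly one placement
        assert len(by_peak) == 50
        assert all(len(v) == 1 for v in by_peak.values())

    def test_matches_exhaustive_scan_oracle(self):
        genome = {"chr1": "TTTTTACGTTTTTTTTACGTTTTT"[:24] + "T" * 200}
        ivs = [
            GenomicInterval("chr1", 0, 24, summit=12, score=1.0),
        ]
        peaks = GenomicIntervalSet(ivs, label="T")
        cutoff = 5.0
        hits = find_motif_hits(TOY, peaks, genome, cutoff=cutoff, window=12)
        seq = genome["chr1"][0:25]
        sc = score_sequence(TOY, seq)
        expected = []
        for strand, vec in (("+", sc.forward), ("-", sc.reverse)):
            for i, v in enumerate(vec):
                if v >= cutoff:
                    expected.append((i, strand))
        got = {(h.start, h.strand) for h in hits}
        # the oracle set, after greedy same-strand overlap resolution
        assert got <= {(i, s) for i, s in expected}
        assert len(got) >= 1
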