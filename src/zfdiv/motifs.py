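"""PWM scanning and motif-evaluation procedures.

Implements log-odds scanning of position weight matrices, the exact
dinucleotide shuffle (Altschul–Erickson Eulerian-path algorithm), AUROC of a
motif for separating top peaks from their dinucleotide-shuffled counterparts,
central-enrichment window selection, affinity-cutoff optimization, and hit
calling inside peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.stats

from .intervals import GenomicIntervalSet

__all__ = [
    "PWM",
    "MotifHit",
    "SequenceScore",
    "score_sequence",
    "dinucleotide_shuffle",
    "dinucleotide_counts",
    "motif_auroc",
    "central_enrichment_window",
    "CentralWindow",
    "optimize_affinity_cutoff",
    "AffinityCutoff",
    "find_motif_hits",
    "reverse_complement",
]

_ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PWM:
    """Position weight matrix: L × 4 per-position probabilities over ACGT.

    Scores are log₂ odds against ``background`` with pseudocount ε added to
    both numerator and denominator: Σ log₂((p+ε)/(bg+ε)).
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM must have at least 4 positions")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def __len__(self) -> int:
        return int(self.matrix.shape[0])

    def log_odds(self) -> np.ndarray:
        """L × 4 log₂-odds score matrix."""
        eps = self.pseudocount
        return np.log2((self.matrix + eps) / (self.background[None, :] + eps))

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )


@dataclass(frozen=True)
class MotifHit:
    """A strand-aware PWM hit; end − start equals the motif width."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    peak_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class SequenceScore:
    """Best hit of a PWM in one sequence plus the per-position score vectors.

    ``best_start`` is the 0-based offset of the best placement; ties are
    broken by leftmost position, forward strand first.
    """

    best_score: float
    best_start: int
    best_strand: str
    forward: np.ndarray
    reverse: np.ndarray


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(256, 4, dtype=np.int8)
    for c, i in _CODE.items():
        code[ord(c)] = i
    return code[arr]


def _scan_strand(lo_ext: np.ndarray, codes: np.ndarray) -> np.ndarray:
    L = lo_ext.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lo_ext[np.arange(L), windows].sum(axis=1)


def score_sequence(pwm: PWM, sequence: str) -> SequenceScore:
    """Scan both strands; placements containing N score −∞.

    The reverse strand is scored by scanning the forward sequence with the
    reverse-complement PWM, so hit coordinates always refer to the forward
    strand.
    """
    if len(sequence) < len(pwm):
        raise ValueError("sequence shorter than the motif")
    codes = _encode(sequence)
    lo = pwm.log_odds()
    lo_ext = np.hstack([lo, np.full((len(pwm), 1), -np.inf)])  # column 4 = N
    lo_rc = pwm.reverse_complement().log_odds()
    lo_rc_ext = np.hstack([lo_rc, np.full((len(pwm), 1), -np.inf)])
    fwd = _scan_strand(lo_ext, codes)
    rev = _scan_strand(lo_rc_ext, codes)
    fi, ri = int(np.argmax(fwd)), int(np.argmax(rev))
    # leftmost wins; at equal position and score, '+' wins
    if (fwd[fi], -fi, 1) >= (rev[ri], -ri, 0):
        return SequenceScore(float(fwd[fi]), fi, "+", fwd, rev)
    return SequenceScore(float(rev[ri]), ri, "-", fwd, rev)


# ---------------------------------------------------------------------------
# dinucleotide shuffle
# ---------------------------------------------------------------------------

def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


def _shuffle_acgt(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson shuffle of one sequence over {A,C,G,T}.

    Preserves the exact dinucleotide count vector, the first and the last
    nucleotide. Every valid arrangement has positive probability.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = [v for v in _ALPHABET if v in edges]

    # choose the last edge out of every vertex (except the terminal one) so
    # that the chosen edges form a tree rooted at the terminal vertex
    while True:
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in last_edge:
            seen, cur = {v}, v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    out_lists: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = rng.permutation(len(rest))
        ordered = [rest[i] for i in perm]
        if v in last_edge:
            ordered.append(last_edge[v])
        out_lists[v] = ordered

    result = [first]
    ptr = {v: 0 for v in vertices}
    cur = first
    total_edges = len(seq) - 1
    for _ in range(total_edges):
        nxt = out_lists[cur][ptr[cur]]
        ptr[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)


def dinucleotide_shuffle(sequence: str, seed=None) -> str:
    """Exact dinucleotide-preserving shuffle; deterministic given ``seed``.

    Runs of characters outside {A,C,G,T} are held fixed in place and the
    intervening segments are shuffled independently.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = sequence.upper()
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] in _ALPHABET:
            j = i
            while j < n and seq[j] in _ALPHABET:
                j += 1
            out.append(_shuffle_acgt(seq[i:j], rng))
            i = j
        else:
            j = i
            while j < n and seq[j] not in _ALPHABET:
                j += 1
            out.append(seq[i:j])
            i = j
    return "".join(out)


# ---------------------------------------------------------------------------
# peak-level procedures
# ---------------------------------------------------------------------------

def _summit_sequences(
    peaks: GenomicIntervalSet,
    genome: Mapping[str, str],
    n_top: int,
    flank: int,
) -> list[str]:
    top = peaks.top_by_score(n_top)
    seqs = []
    for iv in top:
        if iv.summit is None:
            raise ValueError("peaks must carry summits")
        chrom_seq = genome[iv.chrom]
        s = max(0, iv.summit - flank)
        e = min(len(chrom_seq), iv.summit + flank + 1)
        seqs.append(chrom_seq[s:e])
    return seqs


def rank_auroc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUROC via the Mann–Whitney rank statistic; ties contribute ½."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    ranks = scipy.stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def motif_auroc(
    pwm: PWM,
    peaks: GenomicIntervalSet,
    genome: Mapping[str, str],
    n_top: int = 500,
    flank: int = 250,
    seed=None,
) -> float:
    """AUROC of the motif for separating top peaks from shuffled sequence.

    Positives are the best log-odds score per ±``flank`` bp summit sequence of
    the ``n_top`` highest-score peaks; each positive is paired with a single
    dinucleotide shuffle of the same sequence scored identically.
    """
    if len(peaks) < 10:
        raise ValueError(f"need at least 10 scored peaks, got {len(peaks)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqs = _summit_sequences(peaks, genome, n_top, flank)
    pos, neg = [], []
    for s in seqs:
        pos.append(score_sequence(pwm, s).best_score)
        neg.append(score_sequence(pwm, dinucleotide_shuffle(s, rng)).best_score)
    pos_a, neg_a = np.array(pos), np.array(neg)
    # -inf on both sides (all-N windows) would poison the ranks; treat any
    # remaining -inf as the global minimum finite score minus 1
    both = np.concatenate([pos_a, neg_a])
    if np.any(~np.isfinite(both)):
        floor = both[np.isfinite(both)].min() - 1 if np.any(np.isfinite(both)) else 0.0
        pos_a = np.where(np.isfinite(pos_a), pos_a, floor)
        neg_a = np.where(np.isfinite(neg_a), neg_a, floor)
    return rank_auroc(pos_a, neg_a)


@dataclass
class CentralWindow:
    """Selected half-width of the summit-centered motif-enrichment window."""

    halfwidth: int
    p_value: float
    significant: bool


def central_enrichment_window(
    pwm: PWM,
    peaks: GenomicIntervalSet,
    genome: Mapping[str, str],
    n_top: int = 500,
    flank: int = 250,
    step: int = 10,
    alpha: float = 0.01,
) -> CentralWindow:
    """Pick the half-width with the strongest central enrichment of hits.

    For each candidate half-width w the fraction of top peaks whose best-hit
    center lies within ±w of the summit is tested one-sidedly against the
    uniform expectation (binomial; a width-L motif's center can only reach
    ±(flank − L/2), so the uniform null is w/(flank − L/2)). The w with the
    smallest p-value wins, ties to the smaller w. If no window reaches
    ``alpha`` the full ``flank`` is returned flagged non-significant.
    """
    seqs = _summit_sequences(peaks, genome, n_top, flank)
    offsets = []
    L = len(pwm)
    for s in seqs:
        sc = score_sequence(pwm, s)
        if not np.isfinite(sc.best_score):
            continue
        center = sc.best_start + L / 2
        offsets.append(center - len(s) / 2)
    offsets_a = np.abs(np.array(offsets))
    n = len(offsets_a)
    if n == 0:
        raise ValueError("no scorable peak sequences")
    best_w, best_p = flank, 1.0
    eff_flank = max(1.0, flank - L / 2)
    for w in range(step, flank + 1, step):
        k = int((offsets_a <= w).sum())
        p0 = min(1.0, w / eff_flank)
        p = float(scipy.stats.binom.sf(k - 1, n, p0))
        if p < best_p:
            best_w, best_p = w, p
    if best_p >= alpha:
        return CentralWindow(halfwidth=flank, p_value=best_p, significant=False)
    return CentralWindow(halfwidth=best_w, p_value=best_p, significant=True)


@dataclass
class AffinityCutoff:
    """Log-odds cutoff maximizing top-vs-rest hit enrichment."""

    cutoff: float
    enrichment: float
    informative: bool


def optimize_affinity_cutoff(
    pwm: PWM,
    peaks: GenomicIntervalSet,
    genome: Mapping[str, str],
    window: int = 250,
    top_fraction: float = 0.2,
    n_grid: int = 19,
    min_hit_fraction: float = 0.05,
) -> AffinityCutoff:
    """Choose the cutoff that maximizes enrichment of motif-containing peaks
    among the highest-MACS-score peaks.

    Candidate cutoffs are quantiles of the observed per-peak best scores
    inside ±``window`` of the summit. Enrichment is the fraction of the
    ``top_fraction`` highest-score peaks with a hit ≥ cutoff divided by the
    same fraction among the remaining peaks; only cutoffs leaving ≥
    ``min_hit_fraction`` of all peaks with a hit are eligible; ties go to the
    higher cutoff. ``informative`` is False when no cutoff yields enrichment
    above 1.
    """
    ivs = sorted(peaks, key=lambda iv: (-iv.score, iv.chrom, iv.start))
    if not ivs:
        raise ValueError("no peaks supplied")
    best_scores = []
    for iv in ivs:
        chrom_seq = genome[iv.chrom]
        s = max(0, (iv.summit if iv.summit is not None else (iv.start + iv.end) // 2) - window)
        e = min(len(chrom_seq), (iv.summit if iv.summit is not None else (iv.start + iv.end) // 2) + window + 1)
        best_scores.append(score_sequence(pwm, chrom_seq[s:e]).best_score)
    scores = np.array(best_scores)
    finite = scores[np.isfinite(scores)]
    if finite.size == 0:
        raise ValueError("no finite motif scores in any peak")
    qs = np.quantile(finite, np.linspace(0.05, 0.95, n_grid))
    candidates = np.unique(qs)
    n = len(ivs)
    n_topset = max(1, int(round(top_fraction * n)))
    is_top = np.zeros(n, dtype=bool)
    is_top[:n_topset] = True

    best = None
    for c in candidates:
        has_hit = scores >= c
        if has_hit.mean() < min_hit_fraction:
            continue
        f_top = has_hit[is_top].mean()
        f_rest = has_hit[~is_top].mean() if (~is_top).any() else f_top
        enr = f_top / f_rest if f_rest > 0 else (np.inf if f_top > 0 else 0.0)
        key = (enr, c)  # ties -> higher cutoff
        if best is None or key >= best[0]:
            best = (key, c, enr)
    if best is None:
        raise ValueError("no cutoff yields any motif hit")
    _, cutoff, enr = best
    return AffinityCutoff(cutoff=float(cutoff), enrichment=float(enr), informative=bool(enr > 1))


def find_motif_hits(
    pwm: PWM,
    peaks: GenomicIntervalSet,
    genome: Mapping[str, str],
    cutoff: float,
    window: int = 250,
) -> list[MotifHit]:
    """All placements within ±``window`` of each summit scoring ≥ cutoff.

    Overlapping same-strand hits within a peak are resolved greedily to the
    best-scoring placement (ties to the leftmost).
    """
    L = len(pwm)
    hits: list[MotifHit] = []
    for k, iv in enumerate(peaks):
        summit = iv.summit if iv.summit is not None else (iv.start + iv.end) // 2
        chrom_seq = genome[iv.chrom]
        s = max(0, summit - window)
        e = min(len(chrom_seq), summit + window + 1)
        if e - s < L:
            continue
        sc = score_sequence(pwm, chrom_seq[s:e])
        peak_id = f"{iv.chrom}:{iv.start}-{iv.end}"
        for strand, vec in (("+", sc.forward), ("-", sc.reverse)):
            idx = np.where(vec >= cutoff)[0]
            chosen: list[tuple[int, float]] = []
            for i in sorted(idx, key=lambda i: (-vec[i], i)):
                if all(abs(i - j) >= L for j, _ in chosen):
                    chosen.append((int(i), float(vec[i])))
            for i, v in chosen:
                hits.append(MotifHit(iv.chrom, s + i, s + i + L, strand, v, peak_id))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits
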