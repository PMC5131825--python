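"""Genomic-context statistics of binding sites.

Fold enrichment of binding sites around point features (DHS, TSS), histone
signal fold change over the genomic average, overlap of top peaks with
endogenous-retroelement (ERE) classes, ERE enrichment tests, and the common
SNP-depletion test inside motif hits versus their immediate flanks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, GenomicIntervalSet
from .motifs import MotifHit

__all__ = [
    "SignalTrack",
    "DepletionResult",
    "feature_fold_enrichment",
    "histone_fold_change",
    "ere_overlap_fraction",
    "ere_enrichment_test",
    "snp_depletion_test",
]


class SignalTrack:
    """Step-function signal with bedGraph semantics (uncovered bases = 0)."""

    def __init__(
        self,
        intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        chrom_lengths: Mapping[str, int],
    ) -> None:
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.chrom_lengths = dict(chrom_lengths)
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts)
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping signal intervals on {chrom}")
            if not np.all(np.isfinite(values)):
                raise ValueError("signal values must be finite")
            self._data[chrom] = (starts, ends, values)
        self._genome_mean: Optional[float] = None

    @property
    def genome_mean(self) -> float:
        """Signal mass divided by total genome length (uncovered bases are 0)."""
        if self._genome_mean is None:
            mass = sum(
                float(((e - s) * v).sum()) for s, e, v in self._data.values()
            )
            total = sum(self.chrom_lengths.values())
            self._genome_mean = mass / total if total else 0.0
        return self._genome_mean

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean signal over [start, end), clipped to the chromosome."""
        start = max(0, start)
        end = min(self.chrom_lengths.get(chrom, end), end)
        if end <= start:
            return 0.0
        if chrom not in self._data:
            return 0.0
        s, e, v = self._data[chrom]
        i0 = np.searchsorted(e, start, side="right")
        i1 = np.searchsorted(s, end, side="left")
        if i1 <= i0:
            return 0.0
        ov = np.minimum(e[i0:i1], end) - np.maximum(s[i0:i1], start)
        return float((ov * v[i0:i1]).sum() / (end - start))


def feature_fold_enrichment(
    sites: GenomicIntervalSet,
    feature_points: Mapping[str, np.ndarray],
    chrom_lengths: Mapping[str, int],
    max_dist: int = 5000,
    n_bins: int = 50,
    n_random: Optional[int] = None,
    seed=None,
) -> pd.DataFrame:
    """Fold enrichment of site summits around the nearest feature point.

    Signed summit-to-nearest-feature distances are histogrammed over
    [−max_dist, max_dist] and divided bin-wise by the same histogram for
    uniformly drawn random points with matched per-chromosome counts. Bins
    with zero random mass get NaN (undefined, not infinite).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    feats = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in feature_points.items()}

    def signed_dists(points_by_chrom: Mapping[str, np.ndarray]) -> np.ndarray:
        out = []
        for chrom, pts in points_by_chrom.items():
            f = feats.get(chrom)
            if f is None or f.size == 0:
                continue
            idx = np.clip(np.searchsorted(f, pts), 0, f.size - 1)
            idx_lo = np.clip(idx - 1, 0, f.size - 1)
            d_hi = pts - f[idx]
            d_lo = pts - f[idx_lo]
            d = np.where(np.abs(d_hi) <= np.abs(d_lo), d_hi, d_lo)
            out.append(d)
        return np.concatenate(out) if out else np.empty(0, dtype=np.int64)

    site_points: dict[str, np.ndarray] = {}
    for chrom in sites.chromosomes:
        pts = [
            iv.summit if iv.summit is not None else (iv.start + iv.end) // 2
            for iv in sites.per_chromosome(chrom)
        ]
        site_points[chrom] = np.asarray(pts, dtype=np.int64)

    scale = 1.0
    if n_random is not None:
        total = sum(len(p) for p in site_points.values())
        scale = n_random / total if total else 1.0
    rand_points = {
        chrom: rng.integers(0, chrom_lengths[chrom], size=max(1, int(round(len(p) * scale))))
        for chrom, p in site_points.items()
    }

    edges = np.linspace(-max_dist, max_dist, n_bins + 1)
    h_sites, _ = np.histogram(signed_dists(site_points), bins=edges)
    h_rand, _ = np.histogram(signed_dists(rand_points), bins=edges)
    p_sites = h_sites / h_sites.sum() if h_sites.sum() else np.full(n_bins, np.nan)
    p_rand = h_rand / h_rand.sum() if h_rand.sum() else np.full(n_bins, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(p_rand > 0, p_sites / p_rand, np.nan)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "fold_enrichment": fold}
    )


def histone_fold_change(
    track: SignalTrack, sites: GenomicIntervalSet, halfwidth: int = 1000
) -> float:
    """log₁₀ of mean signal in ±halfwidth windows around summits over the
    genome-wide mean. Windows straddling chromosome ends are truncated."""
    if track.genome_mean <= 0:
        raise ValueError("genome-wide mean signal is zero")
    num = 0.0
    denom = 0
    for iv in sites:
        summit = iv.summit if iv.summit is not None else (iv.start + iv.end) // 2
        start = max(0, summit - halfwidth)
        end = min(track.chrom_lengths.get(iv.chrom, summit + halfwidth), summit + halfwidth)
        if end <= start:
            continue
        num += track.window_mean(iv.chrom, start, end) * (end - start)
        denom += end - start
    if denom == 0:
        raise ValueError("no usable site windows")
    return float(np.log10((num / denom) / track.genome_mean))


def ere_overlap_fraction(
    peaks: GenomicIntervalSet,
    ere_by_class: Mapping[str, GenomicIntervalSet],
    n_top: int = 500,
) -> pd.Series:
    """Fraction of the top ``n_top`` peaks overlapping ≥1 bp of each ERE
    class. Classes are independent: one peak may count for several."""
    top = peaks.top_by_score(n_top)
    fractions = {}
    for cls, eres in ere_by_class.items():
        if len(top) == 0:
            fractions[cls] = 0.0
        else:
            fractions[cls] = float(top.overlaps_any(eres).mean())
    return pd.Series(fractions, name="overlap_fraction")


def ere_enrichment_test(
    motif_peaks: GenomicIntervalSet,
    ere_by_class: Mapping[str, GenomicIntervalSet],
    chrom_lengths: Mapping[str, int],
    fdr: float = 0.01,
    coverage_switch: float = 0.2,
    n_permutations: int = 1000,
    seed=None,
) -> tuple[pd.DataFrame, Optional[str]]:
    """Per-class enrichment of peak overlap against genomic background.

    The null probability that a random peak overlaps a class is approximated
    by the class's genomic coverage after dilating every instance by half the
    median peak width on each side; a one-sided binomial test is applied to
    the overlap count. For classes covering more than ``coverage_switch`` of
    the genome the binomial approximation is poor and a within-chromosome
    permutation test (peak positions re-drawn uniformly, lengths preserved)
    is used instead. BH correction across classes; returns the table and the
    smallest-p class among those with q < fdr (None if none).
    """
    if len(motif_peaks) == 0:
        raise ValueError("no peaks supplied")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(motif_peaks)
    genome_bp = sum(chrom_lengths.values())
    widths = np.array([iv.width for iv in motif_peaks])
    med_w = float(np.median(widths))

    rows = []
    for cls, eres in sorted(ere_by_class.items()):
        merged = eres.merged()
        k = int(motif_peaks.overlaps_any(merged).sum())
        cov = merged.total_bp() / genome_bp
        dilated = GenomicIntervalSet(
            [
                GenomicInterval(
                    iv.chrom,
                    max(0, iv.start - int(med_w // 2)),
                    min(chrom_lengths.get(iv.chrom, iv.end), iv.end + int(med_w // 2)),
                )
                for iv in merged
            ]
        ).merged()
        p0 = min(1.0, dilated.total_bp() / genome_bp)
        if cov > coverage_switch:
            exceed = 0
            for _ in range(n_permutations):
                shuf = _shuffle_peaks(motif_peaks, chrom_lengths, rng)
                if int(shuf.overlaps_any(merged).sum()) >= k:
                    exceed += 1
            p = (1 + exceed) / (1 + n_permutations)
            method = "permutation"
        else:
            p = float(scipy.stats.binom.sf(k - 1, n, p0))
            method = "binomial"
        rows.append({"ere_class": cls, "n_overlap": k, "n_peaks": n,
                     "coverage": cov, "null_p": p0, "p_value": p, "method": method})
    df = pd.DataFrame(rows)
    _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["q_value"] = q
    df["significant"] = df["q_value"] < fdr
    sig = df[df["significant"]]
    best = None
    if len(sig):
        best = str(sig.loc[sig["p_value"].idxmin(), "ere_class"])
    return df, best


def _shuffle_peaks(
    peaks: GenomicIntervalSet, chrom_lengths: Mapping[str, int], rng: np.random.Generator
) -> GenomicIntervalSet:
    out = []
    for iv in peaks:
        lo_max = max(1, chrom_lengths[iv.chrom] - iv.width)
        s = int(rng.integers(0, lo_max))
        out.append(GenomicInterval(iv.chrom, s, s + iv.width))
    return GenomicIntervalSet(out)


@dataclass
class DepletionResult:
    """SNP counts and depletion test for one protein (or the pooled set)."""

    label: str
    snps_in_motifs: int
    snps_in_flanks: int
    motif_bp: int
    flank_bp: int
    p_value: float
    q_value: float = float("nan")

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _territories(
    hits: Sequence[MotifHit], flank: int
) -> tuple[GenomicIntervalSet, GenomicIntervalSet]:
    motif = GenomicIntervalSet(
        [GenomicInterval(h.chrom, h.start, h.end) for h in hits]
    ).merged()
    flanks_raw = GenomicIntervalSet(
        [GenomicInterval(h.chrom, max(0, h.start - flank), h.end + flank) for h in hits]
    ).merged()
    # flank territory = dilated hits minus the motif territory itself
    out = []
    for chrom in flanks_raw.chromosomes:
        f_s, f_e = flanks_raw.arrays(chrom)
        m_s, m_e = motif.arrays(chrom)
        events = []
        for s, e in zip(f_s, f_e):
            events.append((s, e))
        cuts = list(zip(m_s, m_e))
        for s, e in events:
            cur = s
            for ms, me in cuts:
                if me <= cur or ms >= e:
                    continue
                if ms > cur:
                    out.append(GenomicInterval(chrom, int(cur), int(ms)))
                cur = max(cur, me)
            if cur < e:
                out.append(GenomicInterval(chrom, int(cur), int(e)))
    return motif, GenomicIntervalSet(out).merged()


def _count_points(points: Mapping[str, np.ndarray], region: GenomicIntervalSet) -> int:
    total = 0
    for chrom in region.chromosomes:
        pts = np.sort(np.asarray(points.get(chrom, ()), dtype=np.int64))
        if pts.size == 0:
            continue
        s, e = region.arrays(chrom)
        total += int((np.searchsorted(pts, e, side="left") - np.searchsorted(pts, s, side="left")).sum())
    return total


def snp_depletion_test(
    hits_by_protein: Mapping[str, Sequence[MotifHit]],
    snps: Mapping[str, np.ndarray],
    flank: int = 20,
    fdr: float = 0.025,
    alternative: str = "less",
) -> tuple[list[DepletionResult], DepletionResult]:
    """Binomial test of SNP depletion inside motif hits versus ±flank bp.

    Per protein, the motif territory is the union of its hit intervals and
    the flank territory the union of ±``flank`` bp beyond each hit minus the
    motif territory (no base is counted twice). Under the null the
    ``s_motif`` of ``s_motif + s_flank`` SNPs fall in the motif territory
    with probability motif_bp/(motif_bp+flank_bp); the one-sided (depletion)
    binomial p-value is BH-corrected across proteins. A pooled result
    aggregates counts over all proteins.
    """
    if alternative not in ("less", "two-sided"):
        raise ValueError("alternative must be 'less' or 'two-sided'")
    results = []
    pool = dict(s_m=0, s_f=0, bp_m=0, bp_f=0)
    for label in sorted(hits_by_protein):
        motif, flanks = _territories(hits_by_protein[label], flank)
        s_m = _count_points(snps, motif)
        s_f = _count_points(snps, flanks)
        bp_m, bp_f = motif.total_bp(), flanks.total_bp()
        p = _binom_p(s_m, s_f, bp_m, bp_f, alternative)
        results.append(DepletionResult(label, s_m, s_f, bp_m, bp_f, p))
        pool["s_m"] += s_m
        pool["s_f"] += s_f
        pool["bp_m"] += bp_m
        pool["bp_f"] += bp_f
    if results:
        _, qs, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, q in zip(results, qs):
            r.q_value = float(q)
    pooled_p = _binom_p(pool["s_m"], pool["s_f"], pool["bp_m"], pool["bp_f"], alternative)
    pooled = DepletionResult(
        "pooled", pool["s_m"], pool["s_f"], pool["bp_m"], pool["bp_f"], pooled_p, pooled_p
    )
    return results, pooled


def _binom_p(s_m: int, s_f: int, bp_m: int, bp_f: int, alternative: str) -> float:
    n = s_m + s_f
    if n == 0:
        warnings.warn("zero SNPs in motif+flank territory; p set to 1")
        return 1.0
    if bp_m + bp_f == 0:
        return 1.0
    p0 = bp_m / (bp_m + bp_f)
    if alternative == "less":
        return float(scipy.stats.binom.cdf(s_m, n, p0))
    return float(scipy.stats.binomtest(s_m, n, p0, alternative="two-sided").pvalue)
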