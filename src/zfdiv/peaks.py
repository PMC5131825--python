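"""Peak-set post-processing and binding-site diversity statistics.

Replicate summit merging (50 bp single linkage), non-negative least-squares
composite-background fitting, base-pair Jaccard similarity, the
max-over-replicates similarity matrix, and replicate specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .intervals import GenomicInterval, GenomicIntervalSet, SimilarityMatrix

__all__ = [
    "merge_replicate_peaks",
    "fit_nnls_background",
    "NNLSBackground",
    "interval_jaccard",
    "jaccard_matrix",
    "replicate_specificity",
    "filter_min_peaks",
]


def merge_replicate_peaks(
    replicate_sets: Sequence[GenomicIntervalSet], distance: int = 50
) -> GenomicIntervalSet:
    """Collapse replicate peaks whose summits lie within ``distance`` bp.

    Summits are clustered per chromosome by single linkage (adjacent summits
    ≤ ``distance`` apart chain into one cluster, so a chain can span more than
    ``distance`` bp end-to-end). Each cluster becomes one peak whose score is
    the sum of constituent scores and whose summit is the score-weighted mean
    of constituent summits, rounded to the nearest integer with ties toward
    the lower coordinate. The merged interval is re-centered on that summit
    using the widest constituent width.
    """
    labels = {s.label for s in replicate_sets}
    if len(labels) > 1:
        raise ValueError(f"replicate sets carry multiple labels: {sorted(map(str, labels))}")
    label = next(iter(labels)) if labels else None

    peaks: list[GenomicInterval] = []
    for s in replicate_sets:
        for iv in s:
            if iv.summit is None:
                raise ValueError(f"peak {iv.chrom}:{iv.start}-{iv.end} has no summit")
            peaks.append(iv)

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in peaks:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: iv.summit)  # type: ignore[arg-type]
        cluster: list[GenomicInterval] = []
        for iv in ivs:
            if cluster and iv.summit - cluster[-1].summit > distance:  # type: ignore[operator]
                merged.append(_collapse(chrom, cluster))
                cluster = []
            cluster.append(iv)
        if cluster:
            merged.append(_collapse(chrom, cluster))
    return GenomicIntervalSet(merged, label=label)


def _collapse(chrom: str, cluster: list[GenomicInterval]) -> GenomicInterval:
    scores = np.array([iv.score for iv in cluster], dtype=float)
    summits = np.array([iv.summit for iv in cluster], dtype=float)
    total = scores.sum()
    if total > 0:
        mean = float((scores * summits).sum() / total)
    else:  # all-zero scores: unweighted mean
        mean = float(summits.mean())
    # nearest integer, exact .5 rounds toward the lower coordinate
    summit = int(np.ceil(mean - 0.5))
    width = max(iv.width for iv in cluster)
    start = max(0, summit - width // 2)
    return GenomicInterval(chrom, start, start + width, summit=summit, score=float(total))


@dataclass
class NNLSBackground:
    """Composite-background fit: non-negative track weights and the weighted
    combination rescaled to the target library size."""

    weights: np.ndarray
    residual: float
    composite: np.ndarray


def fit_nnls_background(
    target_bin_counts: np.ndarray,
    input_bin_counts: np.ndarray,
    normalize: bool = True,
) -> NNLSBackground:
    """Fit w ≥ 0 minimizing ‖Aw − y‖₂ (Lawson–Hanson active-set NNLS).

    Columns of ``input_bin_counts`` are candidate input (control) tracks
    binned like the target. With ``normalize`` each track is first scaled to
    the target library size, so weights express mixture proportions. The
    composite background Aw is rescaled to the target's total count.
    """
    y = np.asarray(target_bin_counts, dtype=float)
    A = np.asarray(input_bin_counts, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if A.shape[0] != y.shape[0]:
        raise ValueError("target and input tracks must share the bin grid")
    if np.any(y < 0) or np.any(A < 0):
        raise ValueError("bin counts must be non-negative")
    col_sums = A.sum(axis=0)
    if np.any(col_sums == 0):
        raise ValueError("all-zero input track supplied")
    if normalize:
        A = A * (y.sum() / col_sums)
    w, rnorm = scipy.optimize.nnls(A, y)
    composite = A @ w
    if composite.sum() > 0:
        composite = composite * (y.sum() / composite.sum())
    return NNLSBackground(weights=w, residual=float(rnorm), composite=composite)


def interval_jaccard(a: GenomicIntervalSet, b: GenomicIntervalSet) -> float:
    """Base-pair Jaccard: |A ∩ B| / |A ∪ B| over covered base pairs (bedtools
    convention). Empty vs empty is defined as 0."""
    am, bm = a.merged(), b.merged()
    inter = am.intersect_bp(bm)
    union = am.total_bp() + bm.total_bp() - inter
    return inter / union if union > 0 else 0.0


def jaccard_matrix(experiments: Sequence[GenomicIntervalSet]) -> SimilarityMatrix:
    """Protein × protein Jaccard similarity.

    Experiments sharing a label are replicates; the entry for a protein pair
    is the maximum Jaccard over all replicate-pair combinations. Diagonal is 1.
    Use :meth:`SimilarityMatrix.fraction_above` for the fraction of
    distinct-protein pairs at or above a threshold (0.2 in typical use).
    """
    if not experiments:
        raise ValueError("no experiments supplied")
    labels: list[str] = []
    for s in experiments:
        if s.label is None:
            raise ValueError("every experiment needs a label")
        if s.label not in labels:
            labels.append(s.label)
    merged = [s.merged() for s in experiments]
    n_exp = len(experiments)
    pairwise = np.ones((n_exp, n_exp))
    for i in range(n_exp):
        for j in range(i + 1, n_exp):
            pairwise[i, j] = pairwise[j, i] = interval_jaccard(merged[i], merged[j])

    idx = {lab: [k for k, s in enumerate(experiments) if s.label == lab] for lab in labels}
    n = len(labels)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            block = pairwise[np.ix_(idx[labels[i]], idx[labels[j]])]
            values[i, j] = values[j, i] = float(block.max())
    return SimilarityMatrix(labels=labels, values=values, value_kind="jaccard")


def replicate_specificity(
    experiments: Sequence[GenomicIntervalSet],
) -> tuple[pd.Series, float]:
    """Are replicates more similar to each other than to any other protein?

    For each experiment whose protein has ≥2 replicates, all other experiments
    are ranked by Jaccard; the experiment is flagged specific iff the
    top-ranked one belongs to the same protein (a tie at similarity 0 is not
    counted as specific). Returns the per-experiment flags and the fraction
    flagged among eligible experiments.
    """
    if len(experiments) < 2:
        raise ValueError("need at least two experiments")
    keys = [(s.label, s.replicate_id) for s in experiments]
    n_reps = {lab: sum(1 for s in experiments if s.label == lab) for lab, _ in keys}
    if max(n_reps.values()) < 2:
        raise ValueError("no protein has two or more replicates")
    merged = [s.merged() for s in experiments]
    n = len(experiments)
    J = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            J[i, j] = J[j, i] = interval_jaccard(merged[i], merged[j])

    flags: dict[str, bool] = {}
    eligible = []
    for i, (lab, rep) in enumerate(keys):
        if n_reps[lab] < 2:
            continue
        same = [j for j in range(n) if j != i and keys[j][0] == lab]
        other = [j for j in range(n) if keys[j][0] != lab]
        same_best = max(J[i, same]) if same else -np.inf
        other_best = max(J[i, other]) if other else -np.inf
        flag = same_best > other_best or (same_best == other_best and same_best > 0)
        name = f"{lab}/{rep}" if rep is not None else str(lab)
        flags[name] = bool(flag)
        eligible.append(flag)
    frac = float(np.mean(eligible)) if eligible else float("nan")
    return pd.Series(flags, name="replicate_specific"), frac


def filter_min_peaks(
    experiments: Sequence[GenomicIntervalSet], min_peaks: int = 500
) -> list[GenomicIntervalSet]:
    """Generic QC filter: keep experiments with at least ``min_peaks`` peaks."""
    kept = [s for s in experiments if len(s) >= min_peaks]
    if len(kept) < len(experiments):
        dropped = [s.label for s in experiments if len(s) < min_peaks]
        warnings.warn(f"dropped {len(dropped)} experiments below {min_peaks} peaks: {dropped}")
    return kept
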