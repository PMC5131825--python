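"""The multiparameter diversity framework.

PAM (k-medoids, BUILD + SWAP) clustering of distance matrices, silhouette
profiling over a range of cluster counts, the 95%-of-maximum rule that turns
a silhouette profile into an estimate of the number of distinct functional
profiles, a PWM column-correlation distance, and Pearson correlation of
similarity measures across data types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .intervals import SimilarityMatrix
from .motifs import PWM

__all__ = [
    "DistanceMatrix",
    "ClusteringSummary",
    "pam_cluster",
    "mean_silhouette",
    "estimate_profile_count",
    "motif_distance",
    "cross_parameter_correlation",
    "hierarchical_cluster",
    "distance_from_similarity",
    "sequence_distance",
]

_SOURCE_KINDS = ("peaks", "motifs", "ppi", "expression", "sequence", "other")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    source_kind: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < -1e-12) or not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite and non-negative")
        self.values = np.clip(self.values, 0, None)
        if self.source_kind not in _SOURCE_KINDS:
            raise ValueError(f"source_kind must be one of {_SOURCE_KINDS}")

    def __len__(self) -> int:
        return len(self.labels)


def distance_from_similarity(sim: SimilarityMatrix, source_kind: str = "other") -> DistanceMatrix:
    """1 − similarity, with the diagonal forced to zero."""
    v = 1.0 - np.asarray(sim.values, dtype=float)
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(labels=list(sim.labels), values=v, source_kind=source_kind)


def pam_cluster(
    d: DistanceMatrix, k: int, seed=None
) -> tuple[list[int], np.ndarray]:
    """Classic PAM: greedy BUILD then steepest-descent SWAP to convergence.

    Returns (medoid indices, assignment array). Deterministic: all ties break
    to the lowest index, so ``seed`` only exists for interface symmetry.
    """
    D = d.values
    n = len(d)
    if not (2 <= k < n):
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")

    # BUILD: first medoid minimizes total distance, then greedy additions
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        gains = np.maximum(nearest[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    def cost(meds: Sequence[int]) -> float:
        return float(D[:, list(meds)].min(axis=1).sum())

    current = cost(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in med_set:
                    continue
                trial = list(medoids)
                trial[mi] = h
                delta = cost(trial) - current
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            medoids.sort()
            current = cost(medoids)
            improved = True

    assignment = np.argmin(D[:, medoids], axis=1)
    return medoids, assignment


def mean_silhouette(d: DistanceMatrix, assignment: np.ndarray) -> float:
    """Mean silhouette s(i) = (b−a)/max(a,b); singleton clusters score 0."""
    D = d.values
    labels = np.asarray(assignment)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        same = (labels == own) & (np.arange(n) != i)
        if not same.any():  # singleton
            s[i] = 0.0
            continue
        a = D[i, same].mean()
        b = min(D[i, labels == c].mean() for c in uniq if c != own)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


@dataclass
class ClusteringSummary:
    """Silhouette profile over k plus the 95%-of-max profile-count estimate."""

    k_values: list[int]
    mean_silhouettes: list[float]
    estimated_k: int
    max_silhouette: float
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k_values, "mean_silhouette": self.mean_silhouettes}
        )


def estimate_profile_count(
    d: DistanceMatrix, k_max: Optional[int] = None, seed=None
) -> ClusteringSummary:
    """PAM + silhouette for k in {2..k_max}; the estimate is the *largest* k
    whose silhouette is ≥ 95% of the maximum (the profile-count rule).

    All-zero distances give silhouettes of 0 for every k; the summary is then
    flagged degenerate and the estimate is k_max.
    """
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 entities")
    upper = min(n - 1, k_max if k_max is not None else 100)
    ks = list(range(2, upper + 1))
    sils = []
    for k in ks:
        _, assign = pam_cluster(d, k, seed=seed)
        if len(np.unique(assign)) < 2:  # tie-degenerate assignment
            sils.append(0.0)
        else:
            sils.append(mean_silhouette(d, assign))
    smax = max(sils)
    if smax <= 0:
        return ClusteringSummary(ks, sils, estimated_k=ks[-1], max_silhouette=smax, degenerate=True)
    est = max(k for k, s in zip(ks, sils) if s >= 0.95 * smax)
    return ClusteringSummary(ks, sils, estimated_k=est, max_silhouette=smax)


def hierarchical_cluster(d: DistanceMatrix, k: int) -> np.ndarray:
    """Average-linkage alternative used for clustering-robustness checks."""
    condensed = scipy.spatial.distance.squareform(d.values, checks=False)
    Z = scipy.cluster.hierarchy.linkage(condensed, method="average")
    return scipy.cluster.hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two probability 4-vectors; degenerate constant
    columns compare as 1 when equal, else 0."""
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def motif_distance(a: PWM, b: PWM, min_overlap: int = 4) -> float:
    """1 − best mean per-column Pearson correlation over all alignments.

    All relative offsets with at least ``min_overlap`` overlapping columns
    are tried for b in both orientations (forward and reverse complement);
    similarity is the maximum mean column correlation, so the distance lies
    in [0, 2] and is 0 for a PWM against itself or its reverse complement.
    """
    best = -np.inf
    for mat_b in (b.matrix, b.reverse_complement().matrix):
        la, lb = a.matrix.shape[0], mat_b.shape[0]
        for off in range(-(lb - min_overlap), la - min_overlap + 1):
            i0, i1 = max(0, off), min(la, off + lb)
            if i1 - i0 < min_overlap:
                continue
            cols = [
                _column_correlation(a.matrix[i], mat_b[i - off])
                for i in range(i0, i1)
            ]
            best = max(best, float(np.mean(cols)))
    if not np.isfinite(best):
        raise ValueError("no alignment with the required overlap")
    return 1.0 - best


def sequence_distance(a: str, b: str) -> float:
    """1 − fractional identity from pairwise global alignment.

    Used for protein-sequence similarity (zinc-finger-only or full-length
    minus zinc fingers); identity = matched positions / length of the longer
    sequence, under Needleman–Wunsch with simple scoring (match 1, mismatch
    0, gap open −1, gap extend −0.5).
    """
    from Bio import Align

    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    matches = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        matches += sum(x == y for x, y in zip(a[s1:e1], b[s2:e2]))
    return 1.0 - matches / max(len(a), len(b))


def cross_parameter_correlation(
    similarities: Mapping[str, SimilarityMatrix],
    pair_subset: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Pearson correlation between similarity measures across data types.

    Each similarity matrix is vectorized over the upper triangle of the
    shared entity set (optionally restricted to ``pair_subset``, e.g. paralog
    pairs); parameter pairs are correlated with listwise NaN dropping. Needs
    at least 3 usable entity pairs.
    """
    if not similarities:
        raise ValueError("no similarity matrices supplied")
    keys = list(similarities)
    common = set(similarities[keys[0]].labels)
    for k in keys[1:]:
        common &= set(similarities[k].labels)
    common_sorted = sorted(common)
    if pair_subset is not None:
        pairs = [tuple(sorted(p)) for p in pair_subset if p[0] in common and p[1] in common]
    else:
        pairs = [
            (common_sorted[i], common_sorted[j])
            for i in range(len(common_sorted))
            for j in range(i + 1, len(common_sorted))
        ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 usable entity pairs")
    data = {}
    for k in keys:
        sm = similarities[k]
        pos = {lab: i for i, lab in enumerate(sm.labels)}
        data[k] = [sm.values[pos[a], pos[b]] for a, b in pairs]
    df = pd.DataFrame(data, index=pd.MultiIndex.from_tuples(pairs))
    return df.corr(method="pearson")  # pairwise-complete over parameter pairs
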