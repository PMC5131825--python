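"""Genomic interval containers used throughout the pipeline.

Coordinates are 0-based, half-open everywhere. A peak may carry a summit
(absolute coordinate of maximal signal) and a non-negative score; annotation
tracks (EREs, DHS) usually carry neither.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GenomicIntervalSet",
    "SimilarityMatrix",
]


@dataclass(frozen=True)
class GenomicInterval:
    """One interval; ``summit`` is an absolute coordinate inside [start, end)."""

    chrom: str
    start: int
    end: int
    summit: Optional[int] = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside {self.chrom}:{self.start}-{self.end}"
            )
        if self.score < 0:
            raise ValueError("score must be non-negative")

    @property
    def width(self) -> int:
        return self.end - self.start


class GenomicIntervalSet:
    """Per-chromosome, start-sorted interval collection.

    Parameters
    ----------
    intervals
        Any iterable of :class:`GenomicInterval`.
    label
        Protein / experiment identifier.
    replicate_id
        Optional replicate tag; two sets with equal ``label`` but different
        ``replicate_id`` are replicates of the same protein.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        label: Optional[str] = None,
        replicate_id: Optional[str] = None,
    ) -> None:
        self.label = label
        self.replicate_id = replicate_id
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._by_chrom: dict[str, list[GenomicInterval]] = {
            chrom: sorted(ivs, key=lambda iv: (iv.start, iv.end))
            for chrom, ivs in sorted(by_chrom.items())
        }

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomicIntervalSet):
            return NotImplemented
        return list(self) == list(other)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def per_chromosome(self, chrom: str) -> list[GenomicInterval]:
        return self._by_chrom.get(chrom, [])

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) for one chromosome as int arrays."""
        ivs = self._by_chrom.get(chrom, [])
        if not ivs:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        starts = np.fromiter((iv.start for iv in ivs), dtype=np.int64, count=len(ivs))
        ends = np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs))
        return starts, ends

    # -- interval algebra --------------------------------------------------
    def merged(self) -> "GenomicIntervalSet":
        """Union of overlapping/adjacent-overlap intervals (summits and scores
        are dropped; merged sets are the substrate of base-pair Jaccard)."""
        out: list[GenomicInterval] = []
        for chrom, ivs in self._by_chrom.items():
            cur_s, cur_e = None, None
            for iv in ivs:
                if cur_s is None:
                    cur_s, cur_e = iv.start, iv.end
                elif iv.start < cur_e:
                    cur_e = max(cur_e, iv.end)
                else:
                    out.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            if cur_s is not None:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
        return GenomicIntervalSet(out, label=self.label, replicate_id=self.replicate_id)

    def total_bp(self) -> int:
        return sum(iv.width for iv in self)

    def is_merged(self) -> bool:
        for ivs in self._by_chrom.values():
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    return False
        return True

    def intersect_bp(self, other: "GenomicIntervalSet") -> int:
        """Total overlapping base pairs between the merged forms of two sets."""
        a = self if self.is_merged() else self.merged()
        b = other if other.is_merged() else other.merged()
        total = 0
        for chrom in a.chromosomes:
            a_s, a_e = a.arrays(chrom)
            b_s, b_e = b.arrays(chrom)
            if len(a_s) == 0 or len(b_s) == 0:
                continue
            total += _merged_overlap_bp(a_s, a_e, b_s, b_e)
        return int(total)

    def overlaps_any(self, other: "GenomicIntervalSet") -> np.ndarray:
        """Boolean per interval of *self* (iteration order): overlaps ≥1 bp of
        the merged *other*."""
        b = other if other.is_merged() else other.merged()
        flags: list[bool] = []
        for chrom in self._by_chrom:
            b_s, b_e = b.arrays(chrom)
            for iv in self._by_chrom[chrom]:
                if len(b_s) == 0:
                    flags.append(False)
                    continue
                i0 = int(np.searchsorted(b_e, iv.start, side="right"))
                flags.append(i0 < len(b_s) and b_s[i0] < iv.end)
        return np.asarray(flags, dtype=bool)

    def top_by_score(self, n: int) -> "GenomicIntervalSet":
        """The ``n`` highest-score intervals (ties broken by coordinate)."""
        ivs = sorted(self, key=lambda iv: (-iv.score, iv.chrom, iv.start))
        return GenomicIntervalSet(ivs[:n], label=self.label, replicate_id=self.replicate_id)

    # -- frames ------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self],
                "start": [iv.start for iv in self],
                "end": [iv.end for iv in self],
                "summit": [iv.summit for iv in self],
                "score": [iv.score for iv in self],
            }
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label: Optional[str] = None,
        replicate_id: Optional[str] = None,
    ) -> "GenomicIntervalSet":
        ivs = [
            GenomicInterval(
                str(r.chrom),
                int(r.start),
                int(r.end),
                None if pd.isna(r.summit) else int(r.summit),
                float(r.score) if not pd.isna(r.score) else 0.0,
            )
            for r in df.itertuples()
        ]
        return cls(ivs, label=label, replicate_id=replicate_id)


def _merged_overlap_bp(
    a_s: np.ndarray, a_e: np.ndarray, b_s: np.ndarray, b_e: np.ndarray
) -> int:
    """Overlap bp between two merged, sorted interval arrays on one chromosome."""
    cum = np.concatenate([[0], np.cumsum(b_e - b_s)])
    i0 = np.searchsorted(b_e, a_s, side="right")
    i1 = np.searchsorted(b_s, a_e, side="left")
    total = 0
    for s, e, lo, hi in zip(a_s, a_e, i0, i1):
        if hi <= lo:
            continue
        span = cum[hi] - cum[lo]
        span -= max(0, s - b_s[lo])
        span -= max(0, b_e[hi - 1] - e)
        total += span
    return int(total)


@dataclass
class SimilarityMatrix:
    """Symmetric entity × entity similarity (Jaccard, Pearson, motif)."""

    labels: list[str]
    values: np.ndarray
    value_kind: str = "jaccard"

    _KINDS = ("jaccard", "pearson", "motif_similarity")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")
        if self.value_kind not in self._KINDS:
            raise ValueError(f"value_kind must be one of {self._KINDS}")
        if self.value_kind == "jaccard":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1 + 1e-12):
                raise ValueError("jaccard values must lie in [0, 1]")

    def fraction_above(self, tau: float = 0.2) -> float:
        """Fraction of distinct-entity pairs with similarity ≥ tau."""
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        vals = self.values[iu]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return 0.0
        return float(np.mean(vals >= tau))

    def upper_triangle(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        n = len(self.labels)
        pairs = [
            (self.labels[i], self.labels[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        iu = np.triu_indices(n, k=1)
        return pairs, self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)
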