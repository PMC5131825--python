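"""Readers and writers for the exchange formats.

BED (column 5 = score, column 7 = summit offset from start, the MACS
convention), MEME minimal motif format, FASTA, bedGraph, and TSV helpers.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import os
import warnings
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .context import SignalTrack
from .intervals import GenomicInterval, GenomicIntervalSet, SimilarityMatrix
from .motifs import PWM, MotifHit

__all__ = [
    "read_bed",
    "write_bed",
    "read_meme_motifs",
    "write_meme_motifs",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "write_motif_hits_bed",
    "read_similarity_tsv",
    "write_similarity_tsv",
]

PathLike = Union[str, os.PathLike]


def read_bed(
    path: PathLike,
    label: Optional[str] = None,
    replicate_id: Optional[str] = None,
) -> GenomicIntervalSet:
    """BED3+ reader; honors column 5 (score) and column 7 (summit offset).

    Malformed lines (start ≥ end, negative coordinates, too few fields) are
    rejected with the offending line number. Unsorted input is accepted (the
    container sorts) — a warning is emitted.
    """
    intervals = []
    last: dict[str, int] = {}
    unsorted = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            score = 0.0
            if len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            summit = None
            if len(fields) >= 7 and fields[6] not in (".", ""):
                summit = start + int(fields[6])
            if chrom in last and start < last[chrom]:
                unsorted = True
            last[chrom] = start
            intervals.append(GenomicInterval(chrom, start, end, summit=summit, score=score))
    if unsorted:
        warnings.warn(f"{path}: input not sorted by start; sorting")
    return GenomicIntervalSet(intervals, label=label, replicate_id=replicate_id)


def write_bed(intervals: GenomicIntervalSet, path: PathLike) -> None:
    """BED6+1 writer: name column carries the set label, column 7 the summit
    offset (or '.' when absent)."""
    name = intervals.label or "."
    with open(path, "w") as fh:
        for iv in intervals:
            summit_off = "." if iv.summit is None else str(iv.summit - iv.start)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{iv.score:g}\t.\t{summit_off}\n"
            )


def write_motif_hits_bed(hits: Sequence[MotifHit], path: PathLike) -> None:
    """Hits as BED6 with score = log-odds."""
    with open(path, "w") as fh:
        for h in hits:
            name = h.peak_id or "."
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{name}\t{h.score:.4f}\t{h.strand}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme_motifs(path: PathLike, pseudocount: float = 0.01) -> list[PWM]:
    """Parse MEME minimal format (version, alphabet, optional background,
    letter-probability matrices). Rows off by ≤10⁻³ are renormalized; larger
    deviations are an error. A missing background line means uniform (with a
    warning)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    background = None
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            parts = lines[i + 1].split()
            freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freq.get(b, 0.25) for b in "ACGT"])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            j = i + 1
            while j < len(lines) and not lines[j].strip().lower().startswith("letter-probability"):
                j += 1
            if j == len(lines):
                raise ValueError(f"{path}: motif {name} has no letter-probability matrix")
            header = lines[j].strip()
            width = None
            if "w=" in header:
                width = int(header.split("w=")[1].split()[0])
            rows = []
            j += 1
            while j < len(lines):
                s = lines[j].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = [float(x) for x in s.split()]
                if len(vals) != 4:
                    break
                rows.append(vals)
                j += 1
            mat = np.array(rows)
            if width is not None and mat.shape[0] != width:
                raise ValueError(f"{path}: motif {name}: got {mat.shape[0]} rows, declared w={width}")
            sums = mat.sum(axis=1)
            if np.any(np.abs(sums - 1) > 1e-3):
                raise ValueError(f"{path}: motif {name}: probability rows do not sum to 1")
            mat = mat / sums[:, None]
            if background is None:
                warnings.warn(f"{path}: no background line; assuming uniform")
                bg = np.full(4, 0.25)
            else:
                bg = background
            pwms.append(PWM(name=name, matrix=mat, background=bg, pseudocount=pseudocount))
            i = j
            continue
        i += 1
    return pwms


def write_meme_motifs(pwms: Sequence[PWM], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write("Background letter frequencies\n")
            fh.write(f"A {bg[0]:.6f} C {bg[1]:.6f} G {bg[2]:.6f} T {bg[3]:.6f}\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(p)} nsites= 20 E= 0\n")
            for row in p.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA / bedGraph
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    """Whole-genome FASTA into a chrom → sequence dict (indexed access via
    pyfaidx is available for large files; synthetic genomes fit in memory)."""
    try:
        from pyfaidx import Fasta
        fa = Fasta(str(path), rebuild=True, build_index=True)
        out = {name: str(fa[name][:]) for name in fa.keys()}
        fa.close()
        return out
    except Exception:
        out: dict[str, list[str]] = {}
        name = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    out[name] = []
                elif name is not None:
                    out[name].append(line)
        return {k: "".join(v) for k, v in out.items()}


def write_fasta(genome: Mapping[str, str], path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_bedgraph(path: PathLike, chrom_lengths: Mapping[str, int]) -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    data = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        data[str(chrom)] = (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
            grp["value"].to_numpy(float),
        )
    return SignalTrack(data, chrom_lengths)


def write_bedgraph(track: SignalTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track._data):
            s, e, v = track._data[chrom]
            for a, b, val in zip(s, e, v):
                fh.write(f"{chrom}\t{a}\t{b}\t{val:g}\n")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_similarity_tsv(m: SimilarityMatrix, path: PathLike) -> None:
    m.to_dataframe().to_csv(path, sep="\t")


def read_similarity_tsv(path: PathLike, value_kind: str = "jaccard") -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(labels=list(df.index), values=df.to_numpy(), value_kind=value_kind)
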