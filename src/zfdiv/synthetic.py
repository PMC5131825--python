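"""Synthetic-world generator.

Builds genomes, annotation tracks, peak sets, AP-MS count matrices and
expression matrices carrying the statistical structure the downstream
analyses assume: planted protein clusters with controlled within/between
base-pair Jaccard, planted PWM occurrences at a configurable fraction of
peak summits, SNPs thinned inside motif hits by a configurable depletion
factor, planted bait–prey interaction modules plus low-variation contaminant
preys, and expression shifts at bound promoters. Every generator returns its
ground truth alongside the data, and identical config + seed yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, GenomicIntervalSet
from .motifs import PWM, MotifHit

__all__ = [
    "SyntheticWorldConfig",
    "AnnotationBundle",
    "BindingLandscape",
    "SyntheticWorld",
    "generate_genome",
    "plant_annotations",
    "plant_snps",
    "generate_binding_landscape",
    "generate_ppi_counts",
    "generate_expression",
    "generate_world",
    "uniform_dinucleotide_bias",
]

_BASES = "ACGT"


def uniform_dinucleotide_bias() -> np.ndarray:
    return np.full((4, 4), 0.25)


@dataclass
class SyntheticWorldConfig:
    """Study-scale conditions of the synthetic world.

    The defaults emulate, at desk scale, the structure of the real study:
    a multi-chromosome genome, a dozen proteins in a few binding-site
    clusters with duplicate ChIP experiments, long informative motifs
    planted in most peaks, several ERE classes, common SNPs depleted inside
    motif hits, planted AP-MS interaction modules over a contaminant
    background, and expression shifts at bound promoters.
    """

    genome_length: int = 5_000_000        # bp per chromosome
    n_chromosomes: int = 4
    dinucleotide_bias: np.ndarray = field(default_factory=uniform_dinucleotide_bias)
    n_proteins: int = 12
    n_clusters: int = 3
    peaks_per_protein: int = 300
    replicates_per_protein: int = 2
    within_cluster_jaccard: float = 0.5
    between_cluster_jaccard: float = 0.02
    peak_width: int = 200
    summit_jitter_sd: float = 10.0        # bp, replicate summit noise
    peak_dropout: float = 0.1             # replicate peak-loss probability
    motif_length: int = 16
    motif_fraction: float = 0.9           # fraction of peaks with a planted occurrence
    ere_classes: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("LINE", 200, 400), ("SINE", 500, 150), ("LTR", 120, 350)]
    )
    n_tss: int = 400
    n_dhs: int = 300
    dhs_width: int = 300
    snp_density: float = 0.01             # SNPs per bp
    snp_depletion_factor: float = 0.3     # keep probability inside motif hits
    ppi_modules: Optional[list[tuple[list[int], list[int], float]]] = None
    ppi_module_mean: float = 25.0
    ppi_preys_per_module: int = 10
    contaminant_prey_count: int = 15
    contaminant_mean: float = 10.0        # abundant, low-variation background
    ppi_baseline_mean: float = 0.2        # non-planted, non-contaminant pairs
    ppi_strength_sd: float = 0.6          # log-sd of per-pair interaction strength
    ppi_replicates: int = 2
    n_negative_control_baits: int = 3
    expression_effect: float = 1.0        # log-scale shift for bound-promoter genes
    expression_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.dinucleotide_bias = np.asarray(self.dinucleotide_bias, dtype=float)
        if self.dinucleotide_bias.shape != (4, 4):
            raise ValueError("dinucleotide_bias must be 4 x 4")
        if not np.allclose(self.dinucleotide_bias.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each dinucleotide_bias row must sum to 1")
        if np.any(self.dinucleotide_bias < 0):
            raise ValueError("dinucleotide_bias entries must be probabilities")
        for name, v in [
            ("genome_length", self.genome_length),
            ("n_chromosomes", self.n_chromosomes),
            ("n_proteins", self.n_proteins),
            ("n_clusters", self.n_clusters),
            ("peaks_per_protein", self.peaks_per_protein),
            ("replicates_per_protein", self.replicates_per_protein),
            ("motif_length", self.motif_length),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        for name, v in [
            ("within_cluster_jaccard", self.within_cluster_jaccard),
            ("between_cluster_jaccard", self.between_cluster_jaccard),
            ("peak_dropout", self.peak_dropout),
            ("motif_fraction", self.motif_fraction),
        ]:
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.snp_depletion_factor <= 1:
            raise ValueError("snp_depletion_factor must lie in (0, 1]")
        if self.within_cluster_jaccard <= self.between_cluster_jaccard:
            raise ValueError("within_cluster_jaccard must exceed between_cluster_jaccard")
        # normalize list-of-list forms (e.g. from YAML) to tuples
        self.ere_classes = [(str(c), int(n), int(w)) for c, n, w in self.ere_classes]
        if self.ppi_modules is not None:
            self.ppi_modules = [
                (list(b), list(p), float(m)) for b, p, m in self.ppi_modules
            ]
        if self.ppi_modules is None:
            # default: one interaction module per binding cluster, sharing the
            # round-robin protein-to-cluster assignment of the landscape
            self.ppi_modules = [
                (
                    [i for i in range(self.n_proteins) if i % self.n_clusters == c],
                    list(range(c * self.ppi_preys_per_module,
                               (c + 1) * self.ppi_preys_per_module)),
                    self.ppi_module_mean,
                )
                for c in range(self.n_clusters)
            ]
        for bait_idx, _, _ in self.ppi_modules:
            if any(b >= self.n_proteins or b < 0 for b in bait_idx):
                raise ValueError("ppi_modules bait index out of range")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.genome_length for c in self.chrom_names}

    def protein_names(self) -> list[str]:
        return [f"ZF{i + 1:03d}" for i in range(self.n_proteins)]


def _rng(seed: int, *path: int) -> np.random.Generator:
    """Named substream of the world seed (one per generator stage)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=path))


def generate_genome(config: SyntheticWorldConfig, rng: Optional[np.random.Generator] = None) -> dict[str, str]:
    """First-order Markov genome with the configured dinucleotide bias.

    A first-order chain is all the downstream dinucleotide-shuffle null
    needs; higher-order structure is deliberately absent.
    """
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be at least 10 kb")
    rng = rng if rng is not None else _rng(config.seed, 0)
    P = config.dinucleotide_bias
    genome = {}
    uniform = np.allclose(P, 0.25)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom in config.chrom_names:
        n = config.genome_length
        if uniform:  # i.i.d. fast path (identical marginal law)
            codes = rng.integers(0, 4, size=n)
        else:
            cum = P.cumsum(axis=1)
            codes = np.empty(n, dtype=np.int64)
            codes[0] = rng.integers(0, 4)
            u = rng.random(n)
            for i in range(1, n):
                codes[i] = np.searchsorted(cum[codes[i - 1]], u[i], side="right")
        genome[chrom] = lut[codes].tobytes().decode("ascii")
    return genome


@dataclass
class AnnotationBundle:
    """ERE instances per class, TSS points, DHS intervals and SNP positions."""

    ere_by_class: dict[str, GenomicIntervalSet]
    tss: dict[str, np.ndarray]
    dhs: GenomicIntervalSet
    snps: dict[str, np.ndarray]
    gene_names: dict[str, list[str]]


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    count: int,
    width: int,
    occupied: Optional[dict[str, list[tuple[int, int]]]] = None,
) -> list[GenomicInterval]:
    """Uniformly place ``count`` width-``width`` intervals without overlap
    (within this call and against ``occupied``), via rejection sampling."""
    chroms = sorted(chrom_lengths)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    if occupied:
        for c, ivs in occupied.items():
            placed.setdefault(c, []).extend(ivs)
    out = []
    attempts = 0
    max_attempts = 200 * count + 1000
    while len(out) < count:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("requested annotation mass exceeds genome capacity")
        chrom = chroms[rng.integers(len(chroms))]
        L = chrom_lengths[chrom]
        if L <= width:
            raise ValueError("interval width exceeds chromosome length")
        s = int(rng.integers(0, L - width))
        e = s + width
        if any(s < pe and ps < e for ps, pe in placed[chrom]):
            continue
        placed[chrom].append((s, e))
        out.append(GenomicInterval(chrom, s, e))
    return out


def plant_annotations(
    genome: dict[str, str],
    config: SyntheticWorldConfig,
    motif_intervals: Optional[GenomicIntervalSet] = None,
    rng: Optional[np.random.Generator] = None,
) -> AnnotationBundle:
    """EREs (non-overlapping within each class), TSS points, DHS intervals
    and SNPs at ``snp_density``, thinned by ``snp_depletion_factor`` inside
    the designated motif-occurrence intervals."""
    rng = rng if rng is not None else _rng(config.seed, 1)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    total_mass = sum(cnt * w for _, cnt, w in config.ere_classes)
    if total_mass > sum(chrom_lengths.values()):
        raise ValueError("requested ERE mass exceeds genome length")
    ere_by_class = {}
    for cls, count, width in config.ere_classes:
        ivs = _place_nonoverlapping(rng, chrom_lengths, count, width) if count else []
        ere_by_class[cls] = GenomicIntervalSet(ivs, label=cls)
    tss = {
        c: np.sort(rng.integers(0, chrom_lengths[c], size=config.n_tss // len(genome)))
        for c in sorted(genome)
    }
    gene_names = {}
    k = 0
    for c in sorted(genome):
        gene_names[c] = [f"gene{k + i:04d}" for i in range(len(tss[c]))]
        k += len(tss[c])
    dhs = GenomicIntervalSet(
        _place_nonoverlapping(rng, chrom_lengths, config.n_dhs, config.dhs_width),
        label="DHS",
    )
    snps = plant_snps(genome, config, motif_intervals, rng=rng)
    return AnnotationBundle(ere_by_class, tss, dhs, snps, gene_names)


def plant_snps(
    genome: dict[str, str],
    config: SyntheticWorldConfig,
    motif_intervals: Optional[GenomicIntervalSet] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, np.ndarray]:
    """Bernoulli(snp_density) per base, then keep each SNP falling inside a
    motif-occurrence interval with probability ``snp_depletion_factor``."""
    rng = rng if rng is not None else _rng(config.seed, 2)
    snps = {}
    for chrom in sorted(genome):
        L = len(genome[chrom])
        pos = np.where(rng.random(L) < config.snp_density)[0]
        if motif_intervals is not None and config.snp_depletion_factor < 1.0:
            m_s, m_e = motif_intervals.merged().arrays(chrom)
            if m_s.size:
                idx = np.searchsorted(m_s, pos, side="right") - 1
                inside = (idx >= 0) & (pos < m_e[np.clip(idx, 0, None)])
                keep = ~inside | (rng.random(pos.size) < config.snp_depletion_factor)
                pos = pos[keep]
        snps[chrom] = pos.astype(np.int64)
    return snps


@dataclass
class BindingLandscape:
    """Peak sets with replicates, planted PWMs and motif-hit ground truth."""

    genome: dict[str, str]                     # genome with motifs planted
    truth_sets: dict[str, GenomicIntervalSet]  # protein -> true site set
    replicate_sets: list[GenomicIntervalSet]   # jittered replicate peak sets
    pwms: dict[str, PWM]
    motif_hits: dict[str, list[MotifHit]]
    cluster_of: dict[str, int]


def _informative_pwm(rng: np.random.Generator, name: str, length: int) -> PWM:
    """Concentrated random PWM: one dominant base (~0.85) per column."""
    mat = np.full((length, 4), 0.05)
    dom = rng.integers(0, 4, size=length)
    mat[np.arange(length), dom] = 0.85
    return PWM(name=name, matrix=mat)


def _sample_from_pwm(rng: np.random.Generator, pwm: PWM) -> str:
    cum = pwm.matrix.cumsum(axis=1)
    u = rng.random(len(pwm))
    idx = [int(np.searchsorted(cum[i], u[i], side="right")) for i in range(len(pwm))]
    return "".join(_BASES[min(i, 3)] for i in idx)


def generate_binding_landscape(
    genome: dict[str, str],
    annotations: Optional[AnnotationBundle],
    config: SyntheticWorldConfig,
    rng: Optional[np.random.Generator] = None,
) -> BindingLandscape:
    """Plant clustered binding sites, motif occurrences and replicate noise.

    Proteins are assigned round-robin to ``n_clusters``. Each protein's true
    site set mixes three pools of fixed-width, genome-wide non-overlapping
    slots: a global pool shared by all proteins, a cluster pool shared within
    its cluster, and private sites. For two sets sharing a fraction f of
    identical fixed-width sites the base-pair Jaccard is f/(2−f), so pool
    sizes are chosen from the inverse map f = 2J/(1+J) to hit the configured
    within/between Jaccard targets in expectation. Replicates are jittered
    copies (summit noise, dropout) of the truth set; a PWM occurrence is
    written into the genome at a ``motif_fraction`` subset of true summits.
    """
    rng = rng if rng is not None else _rng(config.seed, 3)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    P = config.peaks_per_protein
    w = config.peak_width
    if P * w > sum(chrom_lengths.values()):
        raise ValueError("peaks_per_protein x peak width exceeds genome")

    f_between = 2 * config.between_cluster_jaccard / (1 + config.between_cluster_jaccard)
    f_within = 2 * config.within_cluster_jaccard / (1 + config.within_cluster_jaccard)
    n_global = int(round(f_between * P))
    n_cluster = max(0, int(round((f_within - f_between) * P)))
    n_private = P - n_global - n_cluster
    if n_private < 0:
        raise ValueError("jaccard targets leave no room for private sites")

    proteins = config.protein_names()
    cluster_of = {p: i % config.n_clusters for i, p in enumerate(proteins)}

    # carve a genome-wide slot grid so all sites are non-overlapping
    slot_w = w
    slots = []
    for chrom in sorted(chrom_lengths):
        n_slots = chrom_lengths[chrom] // slot_w
        slots.extend((chrom, i * slot_w) for i in range(1, n_slots - 1))
    needed = n_global + config.n_clusters * n_cluster + len(proteins) * n_private
    if needed > len(slots):
        raise ValueError("not enough genome for the requested site structure")
    chosen = rng.choice(len(slots), size=needed, replace=False)
    it = iter(chosen)

    def take(k: int) -> list[tuple[str, int]]:
        return [slots[next(it)] for _ in range(k)]

    global_pool = take(n_global)
    cluster_pools = {c: take(n_cluster) for c in range(config.n_clusters)}
    mutable = {c: np.frombuffer(genome[c].encode(), dtype=np.uint8).copy() for c in genome}
    # proteins sharing a site plant their motifs in distinct lanes around the
    # summit so co-bound sites carry every owner's motif (offsets 0, +L, -L,
    # +2L, ... relative to the summit)
    lane_count: dict[tuple[str, int], int] = {}

    truth_sets, pwms, motif_hits = {}, {}, {}
    replicate_sets: list[GenomicIntervalSet] = []
    L = config.motif_length
    for p in proteins:
        own = list(global_pool) + list(cluster_pools[cluster_of[p]]) + take(n_private)
        scores = 100.0 * (1.0 + rng.exponential(1.0, size=len(own)))
        ivs = []
        for (chrom, start), sc in zip(own, scores):
            summit = start + w // 2
            ivs.append(GenomicInterval(chrom, start, start + w, summit=summit, score=float(sc)))
        truth = GenomicIntervalSet(ivs, label=p)
        truth_sets[p] = truth

        pwm = _informative_pwm(rng, f"{p}_motif", L)
        pwms[p] = pwm
        hits = []
        n_with_motif = int(round(config.motif_fraction * len(ivs)))
        which = rng.choice(len(ivs), size=n_with_motif, replace=False)
        for qi in sorted(which):
            iv = ivs[qi]
            site = _sample_from_pwm(rng, pwm)
            strand = "+" if rng.random() < 0.5 else "-"
            planted = site if strand == "+" else _revcomp(site)
            lane = lane_count.get((iv.chrom, iv.start), 0)
            lane_count[(iv.chrom, iv.start)] = lane + 1
            # lane 0 at the summit, then alternating +L, -L, +2L, -2L, ...
            offset = ((lane + 1) // 2) * L * (1 if lane % 2 == 1 else -1) if lane else 0
            s = iv.summit + offset - L // 2
            arr = mutable[iv.chrom]
            if s < 0 or s + L > arr.size:
                continue
            arr[s:s + L] = np.frombuffer(planted.encode(), dtype=np.uint8)
            hits.append(MotifHit(iv.chrom, s, s + L, strand, pwm.max_score,
                                 peak_id=f"{iv.chrom}:{iv.start}-{iv.end}"))
        motif_hits[p] = hits

        for r in range(config.replicates_per_protein):
            rep = []
            for iv in ivs:
                if rng.random() < config.peak_dropout:
                    continue
                jitter = int(round(rng.normal(0, config.summit_jitter_sd))) if config.summit_jitter_sd > 0 else 0
                summit = int(np.clip(iv.summit + jitter, 1, chrom_lengths[iv.chrom] - 2))
                start = max(0, summit - w // 2)
                end = min(chrom_lengths[iv.chrom], start + w)
                score = float(iv.score * rng.lognormal(0, 0.1))
                rep.append(GenomicInterval(iv.chrom, start, end, summit=summit, score=score))
            replicate_sets.append(
                GenomicIntervalSet(rep, label=p, replicate_id=f"rep{r + 1}")
            )

    planted_genome = {c: mutable[c].tobytes().decode() for c in genome}
    return BindingLandscape(
        genome=planted_genome,
        truth_sets=truth_sets,
        replicate_sets=replicate_sets,
        pwms=pwms,
        motif_hits=motif_hits,
        cluster_of=cluster_of,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_ppi_counts(
    config: SyntheticWorldConfig, rng: Optional[np.random.Generator] = None
):
    """Spectral-count matrix with planted interaction modules.

    Planted bait–prey pairs draw Poisson(mean_count × s_ij) per replicate,
    where s_ij is a per-pair log-normal interaction strength (so every bait
    has a distinctive quantitative profile, as real AP-MS baits do); a set of
    contaminant preys draws Poisson(contaminant_mean) in every bait including
    the negative controls; everything else draws a small Poisson baseline.
    Returns (SpectralCountMatrix, truth DataFrame with per-pair planted flag
    and per-prey direction labels used by the classification demo).
    """
    from .ppi import SpectralCountMatrix  # local import avoids a cycle

    rng = rng if rng is not None else _rng(config.seed, 4)
    baits = config.protein_names() + [
        f"CTRL{i + 1}" for i in range(config.n_negative_control_baits)
    ]
    module_preys = sorted({j for _, preys, _ in config.ppi_modules for j in preys})
    prey_names = [f"prey{j:03d}" for j in module_preys] + [
        f"contam{j + 1:02d}" for j in range(config.contaminant_prey_count)
    ]
    n_b, n_p, n_r = len(baits), len(prey_names), config.ppi_replicates
    lam = np.full((n_b, n_p), config.ppi_baseline_mean)
    planted = np.zeros((n_b, n_p), dtype=bool)
    prey_pos = {j: i for i, j in enumerate(module_preys)}
    for bait_idx, preys, mean_count in config.ppi_modules:
        for b in bait_idx:
            for j in preys:
                strength = rng.lognormal(0.0, config.ppi_strength_sd) if mean_count > 0 else 0.0
                lam[b, prey_pos[j]] = mean_count * strength
                planted[b, prey_pos[j]] = mean_count > 0
    lam[:, len(module_preys):] = config.contaminant_mean
    counts = rng.poisson(lam[:, :, None], size=(n_b, n_p, n_r)).astype(np.int64)

    m = SpectralCountMatrix(
        baits, prey_names, counts,
        negative_control_baits=baits[config.n_proteins:],
    )
    directions = {}
    for i, name in enumerate(prey_names):
        if i < len(module_preys):
            directions[name] = ("activator", "repressor", "both")[i % 3]
        else:
            directions[name] = "unknown"
    truth = pd.DataFrame(
        [
            {"bait": baits[i], "prey": prey_names[j], "planted": bool(planted[i, j]),
             "direction": directions[prey_names[j]]}
            for i in range(n_b)
            for j in range(n_p)
        ]
    )
    return m, truth


def generate_expression(
    annotations: AnnotationBundle,
    bound_promoter_sets: dict[str, Sequence[str]],
    config: SyntheticWorldConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Gene × {control, induced_<protein>} log-scale expression matrix.

    Genes bound at the promoter by protein i shift by ``expression_effect``
    in induced_i relative to control; other genes are unshifted. Noise is
    i.i.d. Normal(0, expression_noise_sd) on the log scale (log-normal on
    the natural scale). Returns the matrix plus the bound sets used (truth).
    """
    rng = rng if rng is not None else _rng(config.seed, 5)
    genes = [g for c in sorted(annotations.gene_names) for g in annotations.gene_names[c]]
    base = rng.normal(5.0, 1.0, size=len(genes))
    data = {"control": base + rng.normal(0, config.expression_noise_sd, len(genes))}
    bound_used = {}
    gene_idx = {g: i for i, g in enumerate(genes)}
    for p in config.protein_names():
        bound = [g for g in bound_promoter_sets.get(p, ()) if g in gene_idx]
        bound_used[p] = bound
        shift = np.zeros(len(genes))
        for g in bound:
            shift[gene_idx[g]] = config.expression_effect
        data[f"induced_{p}"] = base + shift + rng.normal(0, config.expression_noise_sd, len(genes))
    return pd.DataFrame(data, index=pd.Index(genes, name="gene")), bound_used


def bound_promoter_genes(
    peaks: GenomicIntervalSet,
    annotations: AnnotationBundle,
    max_dist: int = 10_000,
) -> list[str]:
    """Genes whose TSS lies within ``max_dist`` of any peak summit."""
    out = []
    for chrom in sorted(annotations.tss):
        t = annotations.tss[chrom]
        names = annotations.gene_names[chrom]
        summits = np.array(
            [iv.summit if iv.summit is not None else (iv.start + iv.end) // 2
             for iv in peaks.per_chromosome(chrom)],
            dtype=np.int64,
        )
        if summits.size == 0:
            continue
        summits.sort()
        for pos, name in zip(t, names):
            i = np.searchsorted(summits, pos)
            near = []
            if i < summits.size:
                near.append(abs(int(summits[i]) - int(pos)))
            if i > 0:
                near.append(abs(int(summits[i - 1]) - int(pos)))
            if near and min(near) <= max_dist:
                out.append(name)
    return out


@dataclass
class SyntheticWorld:
    """Everything a full pipeline run needs, with ground truth."""

    config: SyntheticWorldConfig
    genome: dict[str, str]
    annotations: AnnotationBundle
    landscape: BindingLandscape
    ppi_matrix: "object"
    ppi_truth: pd.DataFrame
    expression: pd.DataFrame
    bound_genes: dict[str, list[str]]


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Deterministic end-to-end world build from one config + seed."""
    genome = generate_genome(config, rng=_rng(config.seed, 0))
    landscape = generate_binding_landscape(genome, None, config, rng=_rng(config.seed, 3))
    all_hits = GenomicIntervalSet(
        [GenomicInterval(h.chrom, h.start, h.end)
         for hits in landscape.motif_hits.values() for h in hits]
    )
    annotations = plant_annotations(
        landscape.genome, config, motif_intervals=all_hits, rng=_rng(config.seed, 1)
    )
    ppi_matrix, ppi_truth = generate_ppi_counts(config, rng=_rng(config.seed, 4))
    bound_sets = {
        p: bound_promoter_genes(landscape.truth_sets[p], annotations)
        for p in config.protein_names()
    }
    expression, bound_used = generate_expression(
        annotations, bound_sets, config, rng=_rng(config.seed, 5)
    )
    return SyntheticWorld(
        config=config,
        genome=landscape.genome,
        annotations=annotations,
        landscape=landscape,
        ppi_matrix=ppi_matrix,
        ppi_truth=ppi_truth,
        expression=expression,
        bound_genes=bound_used,
    )
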