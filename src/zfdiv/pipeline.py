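"""End-to-end pipeline: synthetic or supplied data through every stage.

Inputs either come from the synthetic-world generator (default: a run needs
only the seed) or from files on disk (FASTA genome, BED peak sets, MEME
motifs, BED annotation tracks, TSV count/expression matrices). Each stage
writes TSV/JSON outputs into the run directory and a manifest records
parameters, the seed, package versions and output checksums, so a fixed
seed reproduces the run byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .context import ere_overlap_fraction, feature_fold_enrichment, snp_depletion_test
from .diversity import (
    cross_parameter_correlation,
    distance_from_similarity,
    DistanceMatrix,
    estimate_profile_count,
    motif_distance,
)
from .intervals import GenomicIntervalSet, SimilarityMatrix
from .motifs import PWM, find_motif_hits, motif_auroc, optimize_affinity_cutoff
from .peaks import jaccard_matrix, merge_replicate_peaks, replicate_specificity
from .ppi import (
    SpectralCountMatrix,
    filter_low_variation_preys,
    replicate_profile_specificity,
    significance_calls,
    spectral_odds_ratios,
    expression_response_test,
)
from .synthetic import SyntheticWorldConfig, bound_promoter_genes, generate_world

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline inputs and stage parameters.

    With no input paths the pipeline runs on a generated synthetic world, so
    an end-to-end run needs only the seed. Supplying paths switches the
    corresponding stages to real data: ``peaks_beds`` are BED files named
    ``peaks_<protein>_<replicate>.bed`` (the layout ``zfdiv simulate``
    writes), ``motifs_meme`` holds one motif named ``<protein>_motif`` per
    protein, ``ere_beds`` are ``ere_<class>.bed`` files, ``snps_bed`` is a
    BED of 1-bp SNP intervals, ``counts_tsv`` is preys × ``bait_repN``
    spectral counts, and ``expression_tsv`` is genes × (control,
    induced_<protein>).
    """

    seed: int = 0
    output_dir: str = "zfdiv_run"
    world: SyntheticWorldConfig = None  # type: ignore[assignment]
    # real-data inputs (None -> synthetic)
    genome_fasta: Optional[str] = None
    peaks_beds: Optional[list[str]] = None
    motifs_meme: Optional[str] = None
    ere_beds: Optional[list[str]] = None
    snps_bed: Optional[str] = None
    tss_bed: Optional[str] = None
    counts_tsv: Optional[str] = None
    expression_tsv: Optional[str] = None
    # stage parameters
    n_top_peaks: int = 500
    motif_flank: int = 250
    jaccard_threshold: float = 0.2
    snp_flank: int = 20
    snp_fdr: float = 0.025
    expression_fdr: float = 0.01
    k_max: int = 10

    def __post_init__(self) -> None:
        if self.world is None:
            self.world = SyntheticWorldConfig(seed=self.seed)

    @property
    def real_mode(self) -> bool:
        return any(
            v is not None
            for v in (self.genome_fasta, self.peaks_beds, self.motifs_meme,
                      self.ere_beds, self.snps_bed, self.counts_tsv,
                      self.expression_tsv)
        )

    def validate(self) -> None:
        """Pre-flight checks; raises before any computation starts."""
        if not self.real_mode:
            return
        if self.peaks_beds is None:
            raise ValueError("real-data mode requires peaks_beds")
        if self.motifs_meme is not None and self.genome_fasta is None:
            raise ValueError("motif stage enabled but no genome path given")
        for name in ("genome_fasta", "motifs_meme", "snps_bed", "tss_bed",
                     "counts_tsv", "expression_tsv"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise ValueError(f"{name} does not exist: {p}")
        for p in (self.peaks_beds or []) + (self.ere_beds or []):
            if not os.path.exists(p):
                raise ValueError(f"input does not exist: {p}")

    def to_yaml(self, path: str) -> None:
        import yaml

        doc = dataclasses.asdict(self)
        doc["world"]["dinucleotide_bias"] = np.asarray(
            doc["world"]["dinucleotide_bias"]
        ).tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        world = doc.pop("world", None)
        if world is not None:
            world = SyntheticWorldConfig(**world)
        return cls(world=world, **doc)


@dataclass
class _Inputs:
    """Stage inputs, wherever they came from."""

    replicate_sets: list[GenomicIntervalSet]
    proteins: list[str]
    genome: Optional[Mapping[str, str]] = None
    pwms: Optional[Mapping[str, PWM]] = None
    ere_by_class: Optional[Mapping[str, GenomicIntervalSet]] = None
    snps: Optional[Mapping[str, np.ndarray]] = None
    tss: Optional[Mapping[str, np.ndarray]] = None
    ppi_matrix: Optional[SpectralCountMatrix] = None
    expression: Optional[pd.DataFrame] = None
    bound_genes: Optional[Mapping[str, Sequence[str]]] = None


def _load_synthetic(cfg: SyntheticWorldConfig) -> _Inputs:
    world = generate_world(cfg)
    return _Inputs(
        replicate_sets=world.landscape.replicate_sets,
        proteins=cfg.protein_names(),
        genome=world.genome,
        pwms=world.landscape.pwms,
        ere_by_class=world.annotations.ere_by_class,
        snps=world.annotations.snps,
        tss=world.annotations.tss,
        ppi_matrix=world.ppi_matrix,
        expression=world.expression,
        bound_genes=world.bound_genes,
    )


def _load_real(config: PipelineConfig) -> _Inputs:
    from . import io as zio

    replicate_sets = []
    proteins: list[str] = []
    pat = re.compile(r"peaks_(?P<label>.+)_(?P<rep>[^_]+)\.bed$")
    for path in config.peaks_beds or []:
        m = pat.search(os.path.basename(path))
        if m:
            label, rep = m.group("label"), m.group("rep")
        else:
            label, rep = os.path.splitext(os.path.basename(path))[0], "rep1"
        replicate_sets.append(zio.read_bed(path, label=label, replicate_id=rep))
        if label not in proteins:
            proteins.append(label)
    genome = zio.read_fasta(config.genome_fasta) if config.genome_fasta else None
    pwms = None
    if config.motifs_meme:
        pwms = {}
        for p in zio.read_meme_motifs(config.motifs_meme):
            pwms[p.name.removesuffix("_motif")] = p
    ere_by_class = None
    if config.ere_beds:
        ere_by_class = {}
        for path in config.ere_beds:
            cls = re.sub(r"^ere_|\.bed$", "", os.path.basename(path))
            ere_by_class[cls] = zio.read_bed(path, label=cls)
    snps = None
    if config.snps_bed:
        snp_set = zio.read_bed(config.snps_bed)
        snps = {
            c: np.array([iv.start for iv in snp_set.per_chromosome(c)], dtype=np.int64)
            for c in snp_set.chromosomes
        }
    tss = None
    if config.tss_bed:
        tss_set = zio.read_bed(config.tss_bed)
        tss = {
            c: np.array([iv.start for iv in tss_set.per_chromosome(c)], dtype=np.int64)
            for c in tss_set.chromosomes
        }
    ppi_matrix = None
    if config.counts_tsv:
        df = pd.read_csv(config.counts_tsv, sep="\t", index_col=0)
        ppi_matrix = SpectralCountMatrix.from_frame(df)
    expression = None
    if config.expression_tsv:
        expression = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
    return _Inputs(
        replicate_sets=replicate_sets,
        proteins=proteins,
        genome=genome,
        pwms=pwms,
        ere_by_class=ere_by_class,
        snps=snps,
        tss=tss,
        ppi_matrix=ppi_matrix,
        expression=expression,
        bound_genes=None,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run peaks → motifs → context → ppi → diversity.

    Stages whose inputs are unavailable (real-data mode without the
    corresponding files) are skipped and recorded as such. Returns the
    results bundle as a dict (also serialized under ``config.output_dir``).
    Any stage failure propagates as an exception naming the stage.
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    results: dict = {"seed": config.seed, "skipped_stages": []}
    expr_df = pd.DataFrame()
    table = None
    summaries: dict = {}

    stage = "load"
    try:
        inputs = _load_real(config) if config.real_mode else _load_synthetic(config.world)
        proteins = inputs.proteins

        stage = "peaks"
        merged = {}
        for p in proteins:
            reps = [s for s in inputs.replicate_sets if s.label == p]
            merged[p] = merge_replicate_peaks(reps)
        sim = jaccard_matrix([merged[p] for p in proteins])
        n_reps = {p: sum(1 for s in inputs.replicate_sets if s.label == p) for p in proteins}
        if max(n_reps.values()) >= 2:
            _, rep_frac = replicate_specificity(inputs.replicate_sets)
        else:
            rep_frac = float("nan")
        results["peaks"] = {
            "fraction_pairs_jaccard_ge_threshold": sim.fraction_above(config.jaccard_threshold),
            "replicate_specificity": rep_frac,
        }

        stage = "motifs"
        hits_by_protein: dict = {}
        if inputs.genome is not None and inputs.pwms is not None:
            aurocs = {}
            motif_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(10,))
            )
            for p in proteins:
                pwm = inputs.pwms[p]
                peaks = merged[p]
                aurocs[p] = motif_auroc(
                    pwm, peaks, inputs.genome,
                    n_top=min(config.n_top_peaks, len(peaks)),
                    flank=config.motif_flank, seed=motif_rng,
                )
                cut = optimize_affinity_cutoff(
                    pwm, peaks, inputs.genome, window=config.motif_flank
                )
                hits_by_protein[p] = find_motif_hits(
                    pwm, peaks, inputs.genome, cutoff=cut.cutoff,
                    window=config.motif_flank,
                )
            results["motifs"] = {
                "auroc": aurocs,
                "median_auroc": float(np.median(list(aurocs.values()))),
            }
        else:
            results["skipped_stages"].append("motifs")

        stage = "context"
        ctx: dict = {}
        chrom_lengths = (
            {c: len(s) for c, s in inputs.genome.items()} if inputs.genome else None
        )
        if inputs.tss is not None and chrom_lengths is not None:
            tss_fold = feature_fold_enrichment(
                merged[proteins[0]], inputs.tss, chrom_lengths,
                seed=np.random.default_rng(
                    np.random.SeedSequence(entropy=config.seed, spawn_key=(11,))
                ),
            )
            ctx["tss_central_fold"] = float(
                tss_fold["fold_enrichment"].iloc[len(tss_fold) // 2]
            )
        if inputs.ere_by_class is not None:
            ctx["ere_overlap_fractions"] = {
                p: ere_overlap_fraction(
                    merged[p], inputs.ere_by_class, n_top=config.n_top_peaks
                ).to_dict()
                for p in proteins
            }
        if inputs.snps is not None and hits_by_protein:
            dep_results, pooled = snp_depletion_test(
                hits_by_protein, inputs.snps,
                flank=config.snp_flank, fdr=config.snp_fdr,
            )
            ctx["snp_depletion_significant"] = sorted(
                r.label for r in dep_results if r.q_value < config.snp_fdr
            )
            ctx["snp_depletion_pooled_p"] = pooled.p_value
        if ctx:
            results["context"] = ctx
        else:
            results["skipped_stages"].append("context")

        stage = "ppi"
        ppi_sim = None
        if inputs.ppi_matrix is not None:
            m = inputs.ppi_matrix
            retained, dropped = filter_low_variation_preys(m)
            sub = m.subset_preys(retained)
            table = spectral_odds_ratios(sub, significance_calls(sub))
            _, ppi_frac = replicate_profile_specificity(m, preys=retained)
            results["ppi"] = {
                "n_preys_retained": len(retained),
                "n_preys_dropped": len(dropped),
                "replicate_specificity": ppi_frac,
            }
            bound = inputs.bound_genes
            if bound is not None and inputs.expression is not None:
                expr_df = expression_response_test(
                    inputs.expression, bound, fdr=config.expression_fdr
                )
                results["ppi"]["n_expression_responsive"] = (
                    int(expr_df["significant"].sum()) if len(expr_df) else 0
                )
            or_wide = table.pivot(index="bait", columns="prey", values="odds_ratio")
            or_wide = np.log1p(or_wide.loc[[p for p in proteins if p in or_wide.index]])
            ppi_corr = np.corrcoef(or_wide.to_numpy())
            v = np.clip((ppi_corr + ppi_corr.T) / 2, -1, 1)
            ppi_sim = SimilarityMatrix(
                labels=list(or_wide.index), values=v, value_kind="pearson"
            )
        else:
            results["skipped_stages"].append("ppi")

        stage = "diversity"
        sims: dict[str, SimilarityMatrix] = {"peaks": sim}
        dmats = {"peaks": distance_from_similarity(sim, source_kind="peaks")}
        if inputs.pwms is not None:
            n = len(proteins)
            md = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    md[i, j] = md[j, i] = motif_distance(
                        inputs.pwms[proteins[i]], inputs.pwms[proteins[j]]
                    )
            dmats["motifs"] = DistanceMatrix(labels=proteins, values=md,
                                             source_kind="motifs")
            sims["motifs"] = SimilarityMatrix(
                labels=proteins, values=np.clip(1 - md, -1, 1),
                value_kind="motif_similarity",
            )
        if ppi_sim is not None:
            v = 1 - ppi_sim.values
            np.fill_diagonal(v, 0)
            dmats["ppi"] = DistanceMatrix(labels=list(ppi_sim.labels), values=v,
                                          source_kind="ppi")
            sims["ppi"] = ppi_sim
        summaries = {
            k: estimate_profile_count(d, k_max=config.k_max) for k, d in dmats.items()
        }
        results["diversity"] = {
            "estimated_k": {k: s.estimated_k for k, s in summaries.items()},
        }
        if len(sims) >= 2:
            xcorr = cross_parameter_correlation(sims)
            results["diversity"]["cross_parameter_correlation"] = xcorr.to_dict()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- serialize ---------------------------------------------------------
    out = config.output_dir
    with open(os.path.join(out, "results.json"), "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    sim.to_dataframe().to_csv(os.path.join(out, "jaccard_matrix.tsv"), sep="\t")
    if table is not None:
        table.to_csv(os.path.join(out, "ppi_odds_ratios.tsv"), sep="\t", index=False)
    if len(expr_df):
        expr_df.to_csv(os.path.join(out, "expression_response.tsv"), sep="\t", index=False)
    if summaries:
        pd.DataFrame(
            [{"parameter": k, "estimated_k": s.estimated_k,
              "max_silhouette": s.max_silhouette}
             for k, s in summaries.items()]
        ).to_csv(os.path.join(out, "profile_counts.tsv"), sep="\t", index=False)

    world_params = dataclasses.asdict(config.world)
    world_params["dinucleotide_bias"] = np.asarray(
        world_params["dinucleotide_bias"]
    ).tolist()
    manifest = {
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "mode": "real" if config.real_mode else "synthetic",
        "world_parameters": None if config.real_mode else world_params,
        "outputs": {
            f: _sha256(os.path.join(out, f))
            for f in sorted(os.listdir(out))
            if f != "manifest.json" and os.path.isfile(os.path.join(out, f))
        },
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results
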