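"""AP-MS spectral-count post-processing and regulatory-direction analysis.

Low-variation prey filtering, background-probability odds-ratio scoring of
bait–prey interactions, replicate profile specificity, classification of
baits by the known direction (activator/repressor) of their significant
preys, and the Wilcoxon expression-response test for bound-promoter genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SpectralCountMatrix",
    "RegulatoryAnnotation",
    "filter_low_variation_preys",
    "significance_calls",
    "spectral_odds_ratios",
    "replicate_profile_specificity",
    "classify_regulatory_direction",
    "expression_response_test",
]


class SpectralCountMatrix:
    """bait × prey × replicate non-negative integer spectral counts.

    ``avgp`` optionally carries externally computed interaction confidence
    scores (bait × prey, in [0, 1]); they are consumed, never produced here.
    """

    def __init__(
        self,
        baits: Sequence[str],
        preys: Sequence[str],
        counts: np.ndarray,
        negative_control_baits: Sequence[str] = (),
        avgp: Optional[np.ndarray] = None,
    ) -> None:
        self.baits = list(baits)
        self.preys = list(preys)
        self.counts = np.asarray(counts)
        if self.counts.shape[:2] != (len(self.baits), len(self.preys)):
            raise ValueError("counts must be bait x prey x replicate")
        if self.counts.ndim == 2:
            self.counts = self.counts[:, :, None]
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        unknown = set(negative_control_baits) - set(self.baits)
        if unknown:
            raise ValueError(f"negative controls not among baits: {sorted(unknown)}")
        self.negative_control_baits = list(negative_control_baits)
        self.avgp = None if avgp is None else np.asarray(avgp, dtype=float)
        if self.avgp is not None and self.avgp.shape != (len(self.baits), len(self.preys)):
            raise ValueError("avgp must be bait x prey")

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[2]

    def summed(self) -> np.ndarray:
        """bait × prey counts summed over replicates."""
        return self.counts.sum(axis=2)

    def subset_preys(self, preys: Sequence[str]) -> "SpectralCountMatrix":
        idx = [self.preys.index(p) for p in preys]
        return SpectralCountMatrix(
            self.baits,
            list(preys),
            self.counts[:, idx, :],
            self.negative_control_baits,
            None if self.avgp is None else self.avgp[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Rows preys, columns ``bait_rep{r}`` (the TSV exchange layout)."""
        cols = {}
        for i, b in enumerate(self.baits):
            for r in range(self.n_replicates):
                cols[f"{b}_rep{r + 1}"] = self.counts[i, :, r]
        return pd.DataFrame(cols, index=pd.Index(self.preys, name="prey"))

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, negative_control_baits: Sequence[str] = ()
    ) -> "SpectralCountMatrix":
        baits: list[str] = []
        rep_cols: dict[str, list[str]] = {}
        for c in df.columns:
            bait, _, rep = c.rpartition("_rep")
            if not bait or not rep.isdigit():
                raise ValueError(f"column {c!r} is not of the form bait_repN")
            if bait not in baits:
                baits.append(bait)
            rep_cols.setdefault(bait, []).append(c)
        n_rep = {len(v) for v in rep_cols.values()}
        if len(n_rep) != 1:
            raise ValueError("all baits must have the same replicate count")
        counts = np.stack(
            [np.stack([df[c].to_numpy() for c in sorted(rep_cols[b])], axis=1) for b in baits]
        ).astype(np.int64)
        return cls(baits, list(df.index), counts, negative_control_baits)


@dataclass(frozen=True)
class RegulatoryAnnotation:
    """Curated direction of a prey's transcriptional role (input table)."""

    prey: str
    direction: str  # activator | repressor | both | unknown
    functional_tag: str = ""
    evidence_ids: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("activator", "repressor", "both", "unknown"):
            raise ValueError(f"bad direction {self.direction!r}")


def filter_low_variation_preys(
    m: SpectralCountMatrix, min_cv: float = 0.5
) -> tuple[list[str], list[str]]:
    """Drop preys whose coefficient of variation of summed counts across
    baits falls below ``min_cv`` (ubiquitous contaminants vary little).

    Returns (retained, dropped). CV uses the sample standard deviation; an
    all-zero prey has CV 0 and is dropped.
    """
    summed = m.summed().astype(float)
    mean = summed.mean(axis=0)
    sd = summed.std(axis=0, ddof=1) if summed.shape[0] > 1 else np.zeros(summed.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    retained = [p for p, c in zip(m.preys, cv) if c >= min_cv]
    dropped = [p for p, c in zip(m.preys, cv) if c < min_cv]
    return retained, dropped


def significance_calls(
    m: SpectralCountMatrix, avgp_cutoff: float = 1.0, min_count: int = 5
) -> np.ndarray:
    """bait × prey boolean interaction calls.

    Uses the externally computed confidence scores at ``avgp_cutoff`` when
    available; otherwise a count-threshold fallback: a pair is called when
    its summed count is ≥ ``min_count`` and ≥ 2× the expectation under
    proportional allocation of the prey's total across baits.
    """
    if m.avgp is not None:
        return m.avgp >= avgp_cutoff
    summed = m.summed().astype(float)
    total = summed.sum()
    if total == 0:
        return np.zeros(summed.shape, dtype=bool)
    expected = np.outer(summed.sum(axis=1), summed.sum(axis=0)) / total
    return (summed >= min_count) & (summed >= 2 * expected)


def spectral_odds_ratios(
    m: SpectralCountMatrix,
    significance: Optional[np.ndarray] = None,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Odds ratios of observing each prey in each bait versus background.

    For prey j the background probability is estimated from the baits whose
    (i, j) pair is *not* called significant:

        p_j = (Σ_{i not sig} c_ij + α) / (Σ_{i not sig} T_i + α·P)

    with T_i the bait's total summed count, P the number of preys and α a
    pseudocount. The bait-specific probability is q_ij = (c_ij+α)/(T_i+α·P)
    and OR_ij = [q_ij/(1−q_ij)] / [p_j/(1−p_j)]. A prey significant in every
    bait falls back to the negative-control baits for its background; if
    there are none, that prey is an error.
    """
    summed = m.summed().astype(float)
    n_baits, n_preys = summed.shape
    if significance is None:
        significance = significance_calls(m)
    significance = np.asarray(significance, dtype=bool)
    if significance.shape != summed.shape:
        raise ValueError("significance must be bait x prey")
    T = summed.sum(axis=1)
    P = n_preys
    ctrl_idx = [m.baits.index(b) for b in m.negative_control_baits]

    p_bg = np.empty(n_preys)
    for j in range(n_preys):
        nonsig = ~significance[:, j]
        if not nonsig.any():
            if not ctrl_idx:
                raise ValueError(
                    f"prey {m.preys[j]!r} significant in every bait and no negative controls"
                )
            idx = np.array(ctrl_idx)
        else:
            idx = np.where(nonsig)[0]
        p_bg[j] = (summed[idx, j].sum() + alpha) / (T[idx].sum() + alpha * P)

    q = (summed + alpha) / (T[:, None] + alpha * P)
    orr = (q / (1 - q)) / (p_bg[None, :] / (1 - p_bg[None, :]))
    rows = []
    for i, b in enumerate(m.baits):
        for j, p in enumerate(m.preys):
            rows.append(
                {
                    "bait": b,
                    "prey": p,
                    "summed_count": int(summed[i, j]),
                    "odds_ratio": float(orr[i, j]),
                    "significant": bool(significance[i, j]),
                }
            )
    return pd.DataFrame(rows)


def replicate_profile_specificity(
    m: SpectralCountMatrix, preys: Optional[Sequence[str]] = None
) -> tuple[pd.Series, float]:
    """Is each bait's replicate profile more self-similar than cross-similar?

    Pearson correlation between replicate count vectors (over the given prey
    subset, typically the variation-filtered preys). A bait is flagged when
    its best within-bait replicate correlation strictly exceeds its best
    correlation with any replicate of any other bait; exact ties resolve to
    False with a warning. Negative-control baits are excluded from the
    eligible set but still serve as comparison partners.
    """
    sub = m if preys is None else m.subset_preys(preys)
    if sub.n_replicates < 2:
        raise ValueError("need at least two replicates per bait")
    X = sub.counts.astype(float)  # bait x prey x rep
    n_baits, _, n_rep = X.shape
    vecs = X.transpose(0, 2, 1).reshape(n_baits * n_rep, -1)
    sd = vecs.std(axis=1)
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(vecs)
    C = np.nan_to_num(C, nan=0.0)
    owner = np.repeat(np.arange(n_baits), n_rep)

    flags = {}
    eligible = []
    controls = set(sub.negative_control_baits)
    for i, bait in enumerate(sub.baits):
        if bait in controls:
            continue
        rows = np.where(owner == i)[0]
        within = max(
            C[a, b] for ai, a in enumerate(rows) for b in rows[ai + 1:]
        )
        between = max(C[a, b] for a in rows for b in np.where(owner != i)[0])
        if np.isclose(within, between):
            warnings.warn(f"bait {bait}: within/between correlations tie; flagged False")
            flag = False
        else:
            flag = within > between
        flags[bait] = bool(flag)
        eligible.append(flag)
    frac = float(np.mean(eligible)) if eligible else float("nan")
    return pd.Series(flags, name="replicate_specific"), frac


def classify_regulatory_direction(
    interactions: pd.DataFrame, annotations: Sequence[RegulatoryAnnotation]
) -> pd.Series:
    """Label each bait by the union of known directions of its significant
    preys: activator-only, repressor-only, both, or none. Preys annotated
    "both" contribute to both sides."""
    direction = {a.prey: a.direction for a in annotations}
    labels = {}
    for bait, grp in interactions.groupby("bait", sort=True):
        acts = reps = False
        for prey in grp.loc[grp["significant"], "prey"]:
            d = direction.get(prey, "unknown")
            if d in ("activator", "both"):
                acts = True
            if d in ("repressor", "both"):
                reps = True
        if acts and reps:
            labels[bait] = "both"
        elif acts:
            labels[bait] = "activator-only"
        elif reps:
            labels[bait] = "repressor-only"
        else:
            labels[bait] = "none"
    return pd.Series(labels, name="regulatory_direction")


def expression_response_test(
    expr: pd.DataFrame,
    bound_genes: Mapping[str, Sequence[str]],
    control_col: str = "control",
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Per-bait Wilcoxon rank-sum test of expression change at bound promoters.

    ``expr`` is genes × samples with a control column and one ``induced_<bait>``
    column per bait (log scale). For each bait the induced-minus-control
    change of its bound-promoter genes is compared two-sidedly against the
    change of all other genes; BH across baits; direction is the sign of the
    median difference for significant baits. Baits with an empty bound set
    are skipped with a warning.
    """
    if control_col not in expr.columns:
        raise ValueError(f"missing control column {control_col!r}")
    rows = []
    for col in expr.columns:
        if not col.startswith("induced_"):
            continue
        bait = col[len("induced_"):]
        bound = [g for g in bound_genes.get(bait, ()) if g in expr.index]
        if not bound:
            warnings.warn(f"bait {bait}: empty bound-gene set, skipped")
            continue
        delta = expr[col] - expr[control_col]
        in_mask = expr.index.isin(bound)
        d_in, d_out = delta[in_mask], delta[~in_mask]
        if len(d_out) == 0:
            warnings.warn(f"bait {bait}: no unbound genes, skipped")
            continue
        stat = scipy.stats.mannwhitneyu(d_in, d_out, alternative="two-sided")
        med_diff = float(d_in.median() - d_out.median())
        rows.append(
            {"bait": bait, "n_bound": len(d_in), "median_shift": med_diff,
             "p_value": float(stat.pvalue)}
        )
    df = pd.DataFrame(rows)
    if len(df):
        _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
        df["q_value"] = q
        df["significant"] = df["q_value"] < fdr
        df["direction"] = np.where(
            ~df["significant"], "ns", np.where(df["median_shift"] > 0, "up", "down")
        )
    return df
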