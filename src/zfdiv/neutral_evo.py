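"""Monte-Carlo simulation of neutral coding-sequence evolution.

Quantifies how quickly unselected C2H2 zinc-finger domains decay: after a
span of neutral evolution at a given per-base substitution rate, what
fraction of amino-acid residues change identity, and what fraction of
domains acquire an in-frame stop codon? Each base accrues a Poisson number
of substitution events applied sequentially, each replacing the base with
one of the other three uniformly, which reproduces the closed-form per-site
saturation 1 − exp(−rt) in expectation of at least one event and
¾·(1 − exp(−4rt/3)) for a net base change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "NeutralEvoConfig",
    "NeutralEvoResult",
    "simulate_neutral_evolution",
    "domain_length_sensitivity",
]

_BASES = "ACGT"


def _codon_tables() -> tuple[np.ndarray, np.ndarray]:
    """(aa_index per codon 0..63, sense-codon index list). Stops get −1."""
    aa = np.empty(64, dtype=np.int16)
    for idx in range(64):
        codon = _BASES[idx >> 4] + _BASES[(idx >> 2) & 3] + _BASES[idx & 3]
        res = str(Seq(codon).translate())
        aa[idx] = -1 if res == "*" else ord(res)
    sense = np.where(aa >= 0)[0].astype(np.int64)
    return aa, sense


_AA_BY_CODON, _SENSE_CODONS = _codon_tables()


@dataclass
class NeutralEvoConfig:
    """Parameters of the neutral-decay simulation.

    rate
        Substitutions per base per year (default: the typical mammalian
        neutral rate, 2.2 × 10⁻⁹).
    years
        Elapsed time (default 20 million years).
    domain_codons
        Codons per domain; 23 is the canonical C2H2-ZF repeat span.
    n_domains
        Independent domains simulated.
    base_sequence
        Optional fixed codon sequence (string of length 3 × domain_codons);
        by default every domain starts from an independent uniform draw over
        the 61 sense codons.
    substitution_model
        Only "uniform-to-other-3" is implemented.
    """

    rate: float = 2.2e-9
    years: float = 2e7
    domain_codons: int = 23
    n_domains: int = 100_000
    base_sequence: Optional[str] = None
    substitution_model: str = "uniform-to-other-3"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rate < 0 or self.years < 0:
            raise ValueError("rate and years must be non-negative")
        if self.domain_codons < 1 or self.n_domains < 1:
            raise ValueError("domain_codons and n_domains must be positive")
        if self.substitution_model != "uniform-to-other-3":
            raise ValueError(f"unknown substitution model {self.substitution_model!r}")
        if self.base_sequence is not None:
            if len(self.base_sequence) != 3 * self.domain_codons:
                raise ValueError("base_sequence length must be 3 * domain_codons")
            if set(self.base_sequence.upper()) - set(_BASES):
                raise ValueError("base_sequence must be over ACGT")


@dataclass
class NeutralEvoResult:
    """Output fractions with their Monte-Carlo standard errors."""

    fraction_aa_changed: float
    fraction_domains_with_stop: float
    expected_subs_per_site: float
    se_aa_changed: float
    se_domains_with_stop: float
    fraction_sites_hit: float = float("nan")  # sites with >=1 substitution event

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def simulate_neutral_evolution(config: NeutralEvoConfig) -> NeutralEvoResult:
    """Evolve ``n_domains`` domains and measure amino-acid turnover and stop
    accrual.

    A codon whose translation differs from the original counts as changed;
    codons that became stops count as changed. A domain counts toward stop
    accrual when it contains at least one in-frame stop after evolution.
    """
    rng = np.random.default_rng(config.seed)
    n, L = config.n_domains, config.domain_codons
    n_bases = n * L * 3

    if config.base_sequence is not None:
        seq = config.base_sequence.upper()
        base0 = np.array([_BASES.index(c) for c in seq], dtype=np.int8)
        bases = np.tile(base0, n)
        codons0 = (
            (base0[0::3].astype(np.int64) << 4)
            | (base0[1::3].astype(np.int64) << 2)
            | base0[2::3]
        )
        codons0 = np.tile(codons0, n)
    else:
        codons0 = rng.choice(_SENSE_CODONS, size=n * L)
        bases = np.empty(n_bases, dtype=np.int8)
        bases[0::3] = codons0 >> 4
        bases[1::3] = (codons0 >> 2) & 3
        bases[2::3] = codons0 & 3

    rt = config.rate * config.years
    n_events = rng.poisson(rt, size=n_bases)
    pending = n_events.copy()
    while True:
        active = np.where(pending > 0)[0]
        if active.size == 0:
            break
        # replace with one of the other three bases, uniformly
        shift = rng.integers(1, 4, size=active.size).astype(np.int8)
        bases[active] = (bases[active] + shift) % 4
        pending[active] -= 1

    codons1 = (
        (bases[0::3].astype(np.int64) << 4)
        | (bases[1::3].astype(np.int64) << 2)
        | bases[2::3]
    )
    aa0, aa1 = _AA_BY_CODON[codons0], _AA_BY_CODON[codons1]
    changed = aa0 != aa1
    frac_aa = float(changed.mean())
    stops = (aa1 == -1).reshape(n, L).any(axis=1)
    frac_stop = float(stops.mean())
    return NeutralEvoResult(
        fraction_aa_changed=frac_aa,
        fraction_domains_with_stop=frac_stop,
        expected_subs_per_site=rt,
        se_aa_changed=float(np.sqrt(frac_aa * (1 - frac_aa) / (n * L))),
        se_domains_with_stop=float(np.sqrt(frac_stop * (1 - frac_stop) / n)),
        fraction_sites_hit=float((n_events > 0).mean()),
    )


def domain_length_sensitivity(
    config: NeutralEvoConfig, codon_range: tuple[int, int] = (21, 28)
) -> dict[int, NeutralEvoResult]:
    """Re-run the simulation across a range of domain lengths (inclusive)."""
    out = {}
    for L in range(codon_range[0], codon_range[1] + 1):
        cfg = NeutralEvoConfig(
            rate=config.rate,
            years=config.years,
            domain_codons=L,
            n_domains=config.n_domains,
            substitution_model=config.substitution_model,
            seed=config.seed,
        )
        out[L] = simulate_neutral_evolution(cfg)
    return out
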