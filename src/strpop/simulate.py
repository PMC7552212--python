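"""Synthetic STR genotype generator (Balding-Nichols model).

Emulates the sampling design of a six-sire-line conservation study: six
subpopulations of sizes 48/12/35/32/36/33 (196 diploid individuals), 17 STR
loci (16 autosomal + 1 X-linked) with 3-12 alleles each, weak differentiation
and negligible inbreeding.

The generative model:

1. ancestral allele frequencies per locus ~ Dirichlet(lambda_anc * 1_k), with
   the allele count k drawn uniformly from the configured range;
2. subpopulation frequencies ~ Dirichlet(p * (1 - F) / F) — the
   Balding-Nichols drift model, which makes F the expected Wright F_ST
   (Var(p_tilde) = F p (1 - p));
3. genotypes by the inbreeding law P(ii) = p_i^2 + F_IS p_i (1 - p_i),
   P(ij) = 2 p_i p_j (1 - F_IS); males at the X-linked locus receive a single
   allele copy, stored as a doubled code with a hemizygous flag.

Everything is reproducible bit-for-bit given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

from .genotype_io import AUTOSOMAL, X_LINKED, GenotypeTable, LocusMeta

#: Sire-line sizes of the emulated study design.
DEFAULT_POP_SIZES: tuple[int, ...] = (48, 12, 35, 32, 36, 33)
DEFAULT_POP_NAMES: tuple[str, ...] = (
    "Wicek", "Myszak", "GlejtI", "Goraj", "Chochlik", "Liliput",
)


@dataclass
class SimulationConfig:
    """Study-design parameters for the generator.

    ``fst`` is the Balding-Nichols differentiation parameter (the study's
    observed regime is ~0.03); ``fis`` the within-population inbreeding
    coefficient.  ``fis`` defaults to 0: the study's estimate (-0.013) is
    statistically indistinguishable from zero, and the genotype law requires
    ``fis >= -p/(1-p)`` for every allele, which a negative default would
    violate whenever the Dirichlet draw produces a rare allele.
    """

    pop_sizes: tuple[int, ...] = DEFAULT_POP_SIZES
    pop_names: tuple[str, ...] = DEFAULT_POP_NAMES
    n_loci: int = 17
    x_linked_index: int | None = 16     # last locus is X-linked; None disables
    min_alleles: int = 3
    max_alleles: int = 12
    lambda_anc: float = 1.0
    fst: float = 0.03
    fis: float = 0.0
    male_fraction: float = 0.5
    allele_code_base: int = 90          # emitted codes are base + 2k (fragment-size style)

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst={self.fst} outside (0, 1)")
        if not -1.0 <= self.fis <= 1.0:
            raise ValueError(f"fis={self.fis} outside [-1, 1]")
        if any(s <= 0 for s in self.pop_sizes):
            raise ValueError("population sizes must be positive")
        if len(self.pop_names) != len(self.pop_sizes):
            raise ValueError("pop_names and pop_sizes differ in length")
        if not 1 <= self.min_alleles <= self.max_alleles:
            raise ValueError("invalid allele count range")
        if self.lambda_anc <= 0:
            raise ValueError("lambda_anc must be positive")

    @property
    def n_pops(self) -> int:
        return len(self.pop_sizes)

    @property
    def n_individuals(self) -> int:
        return int(sum(self.pop_sizes))

    def locus_meta(self) -> list[LocusMeta]:
        metas = []
        for l in range(self.n_loci):
            mode = X_LINKED if l == self.x_linked_index else AUTOSOMAL
            name = "LEX3" if mode == X_LINKED else f"STR{l + 1:02d}"
            metas.append(LocusMeta(name, mode))
        return metas


def simulate_ancestral_freqs(
    config: SimulationConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per-locus ancestral frequency vectors (Dirichlet, random allele count)."""
    out = []
    for _ in range(config.n_loci):
        k = int(rng.integers(config.min_alleles, config.max_alleles + 1))
        out.append(rng.dirichlet(np.full(k, config.lambda_anc)))
    return out


def simulate_subpop_freqs(
    ancestral: list[np.ndarray],
    fst: float,
    n_pops: int,
    rng: np.random.Generator,
) -> list[list[np.ndarray]]:
    """Balding-Nichols subpopulation frequencies, ``[locus][pop] -> vector``."""
    if not 0.0 < fst < 1.0:
        raise ValueError(f"fst={fst} outside (0, 1)")
    scale = (1.0 - fst) / fst
    out = []
    for p in ancestral:
        alpha = np.maximum(p * scale, 1e-12)   # guard exact zeros
        out.append([rng.dirichlet(alpha) for _ in range(n_pops)])
    return out


def _genotype_distribution(p: np.ndarray, fis: float, locus: str) -> tuple[np.ndarray, np.ndarray]:
    """Unordered genotype index pairs and their probabilities under F_IS."""
    k = p.size
    pairs = np.asarray(list(combinations_with_replacement(range(k), 2)), dtype=np.int64)
    i, j = pairs[:, 0], pairs[:, 1]
    probs = np.where(
        i == j,
        p[i] ** 2 + fis * p[i] * (1 - p[i]),
        2 * p[i] * p[j] * (1 - fis),
    )
    if (probs < -1e-12).any():
        bad = int(i[np.argmin(probs)])
        raise ValueError(
            f"fis={fis} gives a negative homozygote probability at locus "
            f"{locus!r}, allele index {bad}"
        )
    probs = np.clip(probs, 0.0, None)
    return pairs, probs / probs.sum()


def sample_genotypes(
    subpop_freqs: list[list[np.ndarray]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GenotypeTable:
    """Draw a full genotype table from per-population allele frequencies."""
    metas = config.locus_meta()
    n = config.n_individuals
    calls = np.zeros((n, config.n_loci, 2), dtype=np.int64)
    hemi = np.zeros((n, config.n_loci), dtype=bool)
    individuals: list[str] = []
    populations: list[str] = []
    is_male = rng.random(n) < config.male_fraction

    row = 0
    for pop_idx, (name, size) in enumerate(zip(config.pop_names, config.pop_sizes)):
        for s in range(size):
            individuals.append(f"{name}_{s + 1:03d}")
            populations.append(name)
        for l, meta in enumerate(metas):
            p = subpop_freqs[l][pop_idx]
            codes = config.allele_code_base + 2 * np.arange(p.size)
            rows = np.arange(row, row + size)
            if meta.x_linked:
                males = is_male[rows]
                # hemizygous males: one copy, stored doubled
                single = codes[_categorical(rng, p, int(males.sum()))]
                calls[rows[males], l, 0] = single
                calls[rows[males], l, 1] = single
                hemi[rows[males], l] = True
                n_f = int((~males).sum())
                pairs, probs = _genotype_distribution(p, config.fis, meta.name)
                draws = pairs[_categorical(rng, probs, n_f)]
                calls[rows[~males], l, 0] = codes[draws[:, 0]]
                calls[rows[~males], l, 1] = codes[draws[:, 1]]
            else:
                pairs, probs = _genotype_distribution(p, config.fis, meta.name)
                draws = pairs[_categorical(rng, probs, size)]
                calls[rows, l, 0] = codes[draws[:, 0]]
                calls[rows, l, 1] = codes[draws[:, 1]]
        row += size
    return GenotypeTable(individuals, populations, metas, calls, hemi)


def _categorical(rng: np.random.Generator, probs: np.ndarray, size: int) -> np.ndarray:
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    return rng.choice(probs.size, size=size, p=probs)


def simulate_table(config: SimulationConfig | None = None, seed: int = 0) -> GenotypeTable:
    """End-to-end draw: ancestral -> subpopulation frequencies -> genotypes."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    ancestral = simulate_ancestral_freqs(config, rng)
    subpop = simulate_subpop_freqs(ancestral, config.fst, config.n_pops, rng)
    return sample_genotypes(subpop, config, rng)
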