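"""Allele frequencies and per-locus diversity statistics.

Implements the classical frequency functionals used to summarise codominant
STR panels: observed allele counts (Na), count of common alleles (frequency
>= 5%), effective allele number Ae = 1/sum(p^2), Shannon information index
I = -sum(p ln p), observed/expected/unbiased-expected heterozygosity,
polymorphism information content (PIC), private-allele counts, and rarefied
allelic richness by hypergeometric subsampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .genotype_io import MISSING, GenotypeTable

POOLED = "__pooled__"


@dataclass
class AlleleFrequencyTable:
    """Allele frequencies per locus x population.

    ``freqs[locus][pop]`` maps allele code -> relative frequency;
    ``gene_counts[locus][pop]`` is the number of allele copies observed (N).
    ``counts[locus][pop]`` holds the raw copy counts behind the frequencies.
    A (locus, pop) cell with no observed genotypes is simply absent and listed
    in ``empty_cells``.
    """

    loci: list[str]
    populations: list[str]
    freqs: dict[str, dict[str, dict[int, float]]]
    counts: dict[str, dict[str, dict[int, int]]]
    gene_counts: dict[str, dict[str, int]]
    empty_cells: list[tuple[str, str]] = field(default_factory=list)

    def alleles(self, locus: str) -> list[int]:
        """All allele codes seen at ``locus`` across populations, sorted."""
        codes: set[int] = set()
        for pop_map in self.counts[locus].values():
            codes.update(pop_map)
        return sorted(codes)

    def freq_vector(self, locus: str, pop: str) -> np.ndarray:
        """Frequency vector over the observed alleles of one cell."""
        cell = self.freqs[locus][pop]
        return np.asarray([cell[a] for a in sorted(cell)], dtype=float)


def allele_frequencies(
    table: GenotypeTable,
    pooled: bool = False,
    count_hemizygous_once: bool = False,
) -> AlleleFrequencyTable:
    """Estimate allele frequencies per population (or pooled).

    Missing genotypes are excluded from the gene count.  Hemizygous genotypes
    (doubled single-copy calls) contribute two copies by default, matching the
    convention under which the X-linked locus is tabulated alongside the
    autosomal ones; ``count_hemizygous_once=True`` counts one copy instead.
    """
    pops = [POOLED] if pooled else table.population_labels()
    freqs: dict[str, dict[str, dict[int, float]]] = {}
    counts: dict[str, dict[str, dict[int, int]]] = {}
    gene_counts: dict[str, dict[str, int]] = {}
    empty: list[tuple[str, str]] = []
    for l, meta in enumerate(table.loci):
        freqs[meta.name] = {}
        counts[meta.name] = {}
        gene_counts[meta.name] = {}
        for pop in pops:
            mask = (
                np.ones(table.n_individuals, dtype=bool)
                if pop == POOLED
                else table.population_mask(pop)
            )
            sub = table.calls[mask, l, :]
            hemi = table.hemizygous[mask, l]
            called = sub[:, 0] != MISSING
            tally: dict[int, int] = {}
            n_copies = 0
            for row, h in zip(sub[called], hemi[called]):
                copies = (int(row[0]),) if (h and count_hemizygous_once) else (
                    int(row[0]),
                    int(row[1]),
                )
                for a in copies:
                    tally[a] = tally.get(a, 0) + 1
                n_copies += len(copies)
            if n_copies == 0:
                empty.append((meta.name, pop))
                continue
            counts[meta.name][pop] = tally
            gene_counts[meta.name][pop] = n_copies
            freqs[meta.name][pop] = {a: c / n_copies for a, c in tally.items()}
    return AlleleFrequencyTable(
        loci=table.locus_names,
        populations=pops,
        freqs=freqs,
        counts=counts,
        gene_counts=gene_counts,
        empty_cells=empty,
    )


# ---------------------------------------------------------------------------
# scalar statistics

def effective_alleles(p: np.ndarray) -> float:
    return 1.0 / float(np.sum(np.square(p)))

def shannon_index(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))

def expected_heterozygosity(p: np.ndarray) -> float:
    return 1.0 - float(np.sum(np.square(p)))


def pic(p: np.ndarray) -> float:
    """Polymorphism information content (Botstein marker informativeness).

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.  Always <= He, with
    equality only for the monomorphic (zero) case.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    return 1.0 - s2 - (s2 * s2 - s4)


def allelic_richness(counts: dict[int, int] | np.ndarray, g: int) -> float:
    """Rarefied allelic richness: expected allele count in g gene copies.

    Hypergeometric rarefaction over the observed copy counts:
    ``AR_g = sum_a [1 - C(N - N_a, g) / C(N, g)]`` with N total copies and
    N_a copies of allele a.  ``AR_N`` equals the observed allele count.
    """
    if isinstance(counts, dict):
        n_a = np.asarray(list(counts.values()), dtype=np.int64)
    else:
        n_a = np.asarray(counts, dtype=np.int64)
    n_a = n_a[n_a > 0]
    n_total = int(n_a.sum())
    if not 1 <= g <= n_total:
        raise ValueError(f"rarefaction size g={g} outside [1, {n_total}]")
    # hypergeom.pmf(0, N, N_a, g) = C(N - N_a, g)/C(N, g)
    miss = hypergeom.pmf(0, n_total, n_a, g)
    return float(np.sum(1.0 - miss))


def observed_heterozygosity(table: GenotypeTable, locus: str, pop: str | None = None) -> float:
    """Fraction of non-missing genotypes carrying two distinct alleles."""
    l = table.locus_index(locus)
    mask = (
        np.ones(table.n_individuals, dtype=bool)
        if pop is None
        else table.population_mask(pop)
    )
    sub = table.calls[mask, l, :]
    called = sub[:, 0] != MISSING
    n = int(called.sum())
    if n == 0:
        return math.nan
    return float(np.sum(sub[called, 0] != sub[called, 1]) / n)


# ---------------------------------------------------------------------------
# per-locus records

@dataclass
class LocusDiversity:
    """Diversity summary for one locus in one population (or pooled)."""

    locus: str
    population: str
    n: int                 # non-missing genotypes
    na: int
    na_freq5: int
    ae: float
    shannon: float
    ho: float
    he: float
    uhe: float
    pic: float
    richness: float | None = None   # rarefied AR_g (None if not computed)
    private: int | None = None      # private alleles (None for pooled)


def locus_diversity(
    freqs: AlleleFrequencyTable,
    table: GenotypeTable,
    rarefaction_g: int | str | None = "auto",
) -> list[LocusDiversity]:
    """Per locus x population diversity records.

    ``rarefaction_g='auto'`` uses twice the smallest per-population genotype
    count at each locus (the smallest standardised sample all populations can
    supply); an integer fixes g globally; ``None`` skips richness.
    Cells with no observed genotypes are omitted.
    """
    records: list[LocusDiversity] = []
    privates = (
        private_alleles(freqs)[0] if len(freqs.populations) >= 2 else None
    )
    for locus in freqs.loci:
        cells = freqs.freqs.get(locus, {})
        if not cells:
            continue
        if rarefaction_g == "auto":
            g = 2 * min(_n_genotypes(table, locus, pop) for pop in cells)
        else:
            g = rarefaction_g
        for pop, cell in cells.items():
            p = np.asarray(list(cell.values()), dtype=float)
            n_copies = freqs.gene_counts[locus][pop]
            n_geno = _n_genotypes(table, locus, pop)
            he = expected_heterozygosity(p)
            uhe = he * (2 * n_geno) / (2 * n_geno - 1) if n_geno > 1 else math.nan
            ar = None
            if g is not None and 1 <= g <= n_copies:
                ar = allelic_richness(freqs.counts[locus][pop], int(g))
            records.append(
                LocusDiversity(
                    locus=locus,
                    population=pop,
                    n=n_geno,
                    na=len(cell),
                    na_freq5=int(sum(1 for f in cell.values() if f >= 0.05)),
                    ae=effective_alleles(p),
                    shannon=shannon_index(p),
                    ho=observed_heterozygosity(
                        table, locus, None if pop == POOLED else pop
                    ),
                    he=he,
                    uhe=uhe,
                    pic=pic(p),
                    richness=ar,
                    private=None if privates is None or pop == POOLED
                    else privates.get((locus, pop), 0),
                )
            )
    return records


def _n_genotypes(table: GenotypeTable, locus: str, pop: str) -> int:
    l = table.locus_index(locus)
    mask = (
        np.ones(table.n_individuals, dtype=bool)
        if pop == POOLED
        else table.population_mask(pop)
    )
    sub = table.calls[mask, l, 0]
    return int(np.sum(sub != MISSING))


def population_means(records: list[LocusDiversity]) -> dict[str, dict[str, float]]:
    """Arithmetic means over loci for each population (the per-lineage rows)."""
    by_pop: dict[str, list[LocusDiversity]] = {}
    for r in records:
        by_pop.setdefault(r.population, []).append(r)
    out: dict[str, dict[str, float]] = {}
    for pop, recs in by_pop.items():
        out[pop] = {
            "n": float(np.mean([r.n for r in recs])),
            "na": float(np.mean([r.na for r in recs])),
            "na_freq5": float(np.mean([r.na_freq5 for r in recs])),
            "ae": float(np.mean([r.ae for r in recs])),
            "shannon": float(np.mean([r.shannon for r in recs])),
            "ho": float(np.mean([r.ho for r in recs])),
            "he": float(np.mean([r.he for r in recs])),
            "uhe": float(np.mean([r.uhe for r in recs])),
            "pic": float(np.mean([r.pic for r in recs])),
        }
        rich = [r.richness for r in recs if r.richness is not None]
        if rich:
            out[pop]["richness"] = float(np.mean(rich))
        priv = [r.private for r in recs if r.private is not None]
        if priv:
            out[pop]["private"] = float(np.mean(priv))
    return out


def private_alleles(
    freqs: AlleleFrequencyTable,
) -> tuple[dict[tuple[str, str], int], dict[str, float]]:
    """Count alleles observed in exactly one population.

    Returns ``(per_cell, per_pop_mean)``: counts keyed by (locus, population)
    and, per population, the mean count across loci.
    """
    pops = [p for p in freqs.populations if p != POOLED]
    if len(pops) < 2:
        raise ValueError("private alleles are undefined for fewer than 2 populations")
    per_cell: dict[tuple[str, str], int] = {}
    for locus in freqs.loci:
        cells = freqs.counts.get(locus, {})
        incidence: dict[int, list[str]] = {}
        for pop in pops:
            for allele in cells.get(pop, {}):
                incidence.setdefault(allele, []).append(pop)
        for pop in pops:
            if pop in cells:
                per_cell[(locus, pop)] = sum(
                    1 for allele, where in incidence.items() if where == [pop]
                )
    per_pop_mean: dict[str, float] = {}
    for pop in pops:
        vals = [v for (loc, p), v in per_cell.items() if p == pop]
        per_pop_mean[pop] = float(np.mean(vals)) if vals else math.nan
    return per_cell, per_pop_mean
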