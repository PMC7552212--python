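"""Weir-Cockerham F-statistics for codominant multi-allelic loci.

Per locus, the among-population (a), among-individual-within-population (b)
and within-individual (c) variance components are estimated allele by allele
and summed before forming the ratios

    F_ST = a / (a + b + c)
    F_IT = 1 - c / (a + b + c)
    F_IS = 1 - c / (b + c)

Multi-locus summaries support two conventions: the arithmetic mean of
per-locus ratios (the convention behind typical published per-locus tables)
and the overall ratio of summed components (the weighted estimator FSTAT
reports).  Because X-linked loci violate the diploid sampling model when males
are scored, per-statistic exclusion sets let callers report means with and
without such loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeTable


@dataclass
class FStatRecord:
    """Variance components and fixation indices for one locus."""

    locus: str
    a: float
    b: float
    c: float
    fit: float
    fst: float
    fis: float
    n_pops: int
    monomorphic: bool = False

    @property
    def defined(self) -> bool:
        return not self.monomorphic and math.isfinite(self.fst)


@dataclass
class FStatSummary:
    records: list[FStatRecord]
    mean_fit: float
    mean_fst: float
    mean_fis: float
    excluded: dict[str, list[str]]
    # ratio-of-sums ("overall") variant over all defined loci
    overall_fit: float = math.nan
    overall_fst: float = math.nan
    overall_fis: float = math.nan


def wc_fstats(table: GenotypeTable, locus: str) -> FStatRecord:
    """Weir-Cockerham variance components for one locus.

    For each allele, with r populations of (genotype) sizes n_i, allele
    frequencies p_i and heterozygote fractions h_i:

        n_bar = sum n_i / r
        n_c   = (r n_bar - sum n_i^2 / (r n_bar)) / (r - 1)
        p_bar = sum n_i p_i / (r n_bar)
        s2    = sum n_i (p_i - p_bar)^2 / ((r - 1) n_bar)
        h_bar = sum n_i h_i / (r n_bar)
        a = (n_bar / n_c) [s2 - (p_bar(1-p_bar) - s2 (r-1)/r - h_bar/4)/(n_bar - 1)]
        b = (n_bar/(n_bar-1)) [p_bar(1-p_bar) - s2 (r-1)/r - h_bar (2 n_bar - 1)/(4 n_bar)]
        c = h_bar / 2

    Components are summed over alleles before forming ratios.  Missing
    genotypes are dropped per locus; populations left without genotypes are
    dropped from r.
    """
    l = table.locus_index(locus)
    pops = table.population_labels()
    sizes: list[int] = []
    pop_calls: list[np.ndarray] = []
    for pop in pops:
        sub = table.calls[table.population_mask(pop), l, :]
        sub = sub[sub[:, 0] != MISSING]
        if len(sub) > 0:
            sizes.append(len(sub))
            pop_calls.append(sub)
    r = len(sizes)
    if r < 2:
        raise ValueError(
            f"locus {locus!r}: need >=2 populations with data, found {r}"
        )
    n = np.asarray(sizes, dtype=float)
    n_bar = n.sum() / r
    n_c = (r * n_bar - np.sum(n**2) / (r * n_bar)) / (r - 1)

    alleles = sorted({int(a) for sub in pop_calls for a in sub.ravel()})
    if len(alleles) < 2:
        return FStatRecord(locus, 0.0, 0.0, 0.0, math.nan, math.nan, math.nan,
                           n_pops=r, monomorphic=True)

    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.asarray(
            [np.mean(sub == allele) for sub in pop_calls], dtype=float
        )
        h_i = np.asarray(
            [
                np.mean((sub[:, 0] != sub[:, 1]) & np.any(sub == allele, axis=1))
                for sub in pop_calls
            ],
            dtype=float,
        )
        p_bar = float(np.sum(n * p_i) / (r * n_bar))
        s2 = float(np.sum(n * (p_i - p_bar) ** 2) / ((r - 1) * n_bar))
        h_bar = float(np.sum(n * h_i) / (r * n_bar))
        a_comp = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
        )
        b_comp = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - s2 * (r - 1) / r
            - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c_comp = h_bar / 2
        a_sum += a_comp
        b_sum += b_comp
        c_sum += c_comp

    total = a_sum + b_sum + c_sum
    if total <= 0:
        return FStatRecord(locus, a_sum, b_sum, c_sum, math.nan, math.nan,
                           math.nan, n_pops=r, monomorphic=True)
    fst = a_sum / total
    fit = 1.0 - c_sum / total
    fis = 1.0 - c_sum / (b_sum + c_sum) if (b_sum + c_sum) > 0 else math.nan
    return FStatRecord(locus, a_sum, b_sum, c_sum, fit, fst, fis, n_pops=r)


def all_loci_fstats(table: GenotypeTable) -> list[FStatRecord]:
    return [wc_fstats(table, m.name) for m in table.loci]


def fstat_means(
    records: list[FStatRecord],
    exclude: dict[str, set[str] | list[str]] | None = None,
) -> FStatSummary:
    """Multi-locus summary with per-statistic locus exclusion sets.

    ``exclude`` maps statistic name ('fit' | 'fst' | 'fis') to locus names to
    drop from that statistic's arithmetic mean; undefined (monomorphic) loci
    are always dropped.  The ratio-of-sums overall estimate uses every defined
    locus regardless of the exclusion sets.
    """
    exclude = {k: set(v) for k, v in (exclude or {}).items()}
    means: dict[str, float] = {}
    excluded_report: dict[str, list[str]] = {}
    for stat in ("fit", "fst", "fis"):
        drop = exclude.get(stat, set())
        vals = [
            getattr(rec, stat)
            for rec in records
            if rec.defined and rec.locus not in drop
        ]
        if not vals:
            raise ValueError(f"no loci left to average for {stat}")
        means[stat] = float(np.mean(vals))
        excluded_report[stat] = sorted(
            {rec.locus for rec in records if not rec.defined} | drop
        )
    defined = [rec for rec in records if rec.defined]
    a = sum(rec.a for rec in defined)
    b = sum(rec.b for rec in defined)
    c = sum(rec.c for rec in defined)
    total = a + b + c
    return FStatSummary(
        records=records,
        mean_fit=means["fit"],
        mean_fst=means["fst"],
        mean_fis=means["fis"],
        excluded=excluded_report,
        overall_fit=1 - c / total if total > 0 else math.nan,
        overall_fst=a / total if total > 0 else math.nan,
        overall_fis=1 - c / (b + c) if (b + c) > 0 else math.nan,
    )


def x_linked_exclusion(table: GenotypeTable, which: str = "both") -> dict[str, list[str]]:
    """Exclusion sets dropping X-linked loci from means.

    ``which``: 'both' (drop from all three statistics), 'fis-only', or 'none'.
    """
    xl = [m.name for m in table.loci if m.x_linked]
    if which == "none":
        return {}
    if which == "fis-only":
        return {"fis": xl}
    if which == "both":
        return {"fit": xl, "fst": xl, "fis": xl}
    raise ValueError(f"unknown exclusion mode {which!r}")
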