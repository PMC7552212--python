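import math

import numpy as np
import pytest

from strpop import (
    FStatRecord,
    GenotypeTable,
    LocusMeta,
    SimulationConfig,
    all_loci_fstats,
    fstat_means,
    simulate_table,
    wc_fstats,
)
from strpop import published
from strpop.fstatistics import x_linked_exclusion


def reference_components(pop_calls):
    """Plain-loop evaluation of the Weir-Cockerham component formulas.

    Independent of the implementation: works from per-population genotype
    lists, iterating alleles with explicit arithmetic.
    """
    r = len(pop_calls)
    sizes = [len(calls) for calls in pop_calls]
    n_bar = sum(sizes) / r
    n_c = (r * n_bar - sum(s * s for s in sizes) / (r * n_bar)) / (r - 1)
    alleles = sorted({a for calls in pop_calls for g in calls for a in g})
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i, h_i = [], []
        for calls in pop_calls:
            copies = [a for g in calls for a in g]
            p_i.append(copies.count(allele) / len(copies))
            h_i.append(
                sum(1 for g in calls if g[0] != g[1] and allele in g) / len(calls)
            )
        p_bar = sum(s * p for s, p in zip(sizes, p_i)) / (r * n_bar)
        s2 = sum(s * (p - p_bar) ** 2 for s, p in zip(sizes, p_i)) / ((r - 1) * n_bar)
        h_bar = sum(s * h for s, h in zip(sizes, h_i)) / (r * n_bar)
        a_sum += (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b_sum += (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c_sum += h_bar / 2
    return a_sum, b_sum, c_sum


def _table(pop_genotypes):
    individuals, populations, rows = [], [], []
    for pop, genotypes in pop_genotypes.items():
        for i, g in enumerate(genotypes):
            individuals.append(f"{pop}{i}")
            populations.append(pop)
            rows.append([list(g)])
    return GenotypeTable(individuals, populations, [LocusMeta("L")], np.array(rows))


class TestWcFstats:
    def test_matches_independent_arithmetic(self):
        pops = {
            "A": [(1, 1), (1, 2), (2, 2), (1, 2)],
            "B": [(1, 2), (2, 2), (2, 2), (1, 1)],
        }
        rec = wc_fstats(_table(pops), "L")
        a, b, c = reference_components(list(pops.values()))
        assert rec.a == pytest.approx(a, abs=1e-12)
        assert rec.b == pytest.approx(b, abs=1e-12)
        assert rec.c == pytest.approx(c, abs=1e-12)
        assert rec.fst == pytest.approx(a / (a + b + c), abs=1e-12)
        assert rec.fis == pytest.approx(1 - c / (b + c), abs=1e-12)

    def test_multiallelic_matches_reference(self):
        rng = np.random.default_rng(4)
        pops = {
            pop: [tuple(rng.integers(1, 5, size=2)) for _ in range(12)]
            for pop in "ABC"
        }
        rec = wc_fstats(_table(pops), "L")
        a, b, c = reference_components(list(pops.values()))
        assert (rec.a, rec.b, rec.c) == pytest.approx((a, b, c), abs=1e-12)

    def test_identical_populations_fst_near_zero(self):
        rng = np.random.default_rng(8)
        p = np.array([0.4, 0.35, 0.25])
        geno = lambda n: [tuple(rng.choice(3, 2, p=p) + 1) for _ in range(n)]
        rec = wc_fstats(_table({"A": geno(500), "B": geno(500)}), "L")
        assert abs(rec.fst) < 0.01

    def test_heterozygote_excess_gives_negative_fis(self):
        pops = {"A": [(1, 2)] * 10, "B": [(1, 2)] * 10}
        rec = wc_fstats(_table(pops), "L")
        assert rec.fis < 0

    def test_identity_fit_fis_fst(self, study_table):
        for rec in all_loci_fstats(study_table):
            if rec.defined and math.isfinite(rec.fis):
                assert rec.fit == pytest.approx(
                    rec.fis + rec.fst - rec.fis * rec.fst, abs=1e-10
                )

    def test_monomorphic_locus_flagged(self):
        pops = {"A": [(1, 1)] * 5, "B": [(1, 1)] * 5}
        rec = wc_fstats(_table(pops), "L")
        assert rec.monomorphic and not rec.defined

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            wc_fstats(_table({"A": [(1, 2)] * 5}), "L")


def _records_from_published():
    recs = []
    for i, locus in enumerate(published.LOCI):
        recs.append(
            FStatRecord(
                locus=locus, a=0, b=0, c=0,
                fit=float(published.FIT[i]),
                fst=float(published.FST[i]),
                fis=float(published.FIS[i]),
                n_pops=6,
            )
        )
    return recs


class TestMeans:
    def test_published_fit_mean_all_loci(self):
        s = fstat_means(_records_from_published())
        assert round(s.mean_fit, 4) == 0.0741

    def test_published_fit_mean_excluding_x_linked(self):
        s = fstat_means(
            _records_from_published(),
            {"fit": {"LEX3"}, "fst": {"LEX3"}, "fis": {"LEX3"}},
        )
        assert round(s.mean_fit, 4) == 0.0189
        assert round(s.mean_fis, 4) == -0.0134

    def test_single_record_mean_is_identity(self):
        rec = FStatRecord("L", 1, 1, 1, fit=0.2, fst=0.1, fis=0.05, n_pops=2)
        s = fstat_means([rec])
        assert (s.mean_fit, s.mean_fst, s.mean_fis) == (0.2, 0.1, 0.05)

    def test_empty_inclusion_set_rejected(self):
        rec = FStatRecord("L", 1, 1, 1, fit=0.2, fst=0.1, fis=0.05, n_pops=2)
        with pytest.raises(ValueError):
            fstat_means([rec], {"fst": {"L"}})


class TestSimulationProperties:
    def test_permuting_labels_removes_differentiation(self, study_table):
        rng = np.random.default_rng(0)
        shuffled = list(study_table.populations)
        rng.shuffle(shuffled)
        permuted = GenotypeTable(
            study_table.individuals, shuffled, study_table.loci,
            study_table.calls.copy(), study_table.hemizygous.copy(),
        )
        orig = fstat_means(
            all_loci_fstats(study_table), x_linked_exclusion(study_table)
        ).mean_fst
        perm = fstat_means(
            all_loci_fstats(permuted), x_linked_exclusion(permuted)
        ).mean_fst
        assert abs(perm) < orig
        assert abs(perm) < 0.01

    def test_short_parameter_recovery(self):
        """Scaled-down recovery check; the full 20-seed version is in the
        acceptance suite."""
        fsts = []
        for seed in range(5):
            table = simulate_table(SimulationConfig(fst=0.05), seed=seed)
            s = fstat_means(all_loci_fstats(table), x_linked_exclusion(table))
            fsts.append(s.mean_fst)
        assert abs(np.mean(fsts) - 0.05) < 0.015
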