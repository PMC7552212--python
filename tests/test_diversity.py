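import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strpop import (
    SimulationConfig,
    allele_frequencies,
    allelic_richness,
    locus_diversity,
    pic,
    private_alleles,
    simulate_table,
)
from strpop.diversity import POOLED, expected_heterozygosity

simplexes = st.lists(
    st.floats(0.01, 1.0), min_size=2, max_size=8
).map(lambda xs: np.asarray(xs) / np.sum(xs))


class TestAlleleFrequencies:
    def test_direct_count(self, tiny_table):
        f = allele_frequencies(tiny_table)
        cell = f.freqs["L1"]["A"]  # genotypes (101,103), (101,101)
        assert cell == {101: 0.75, 103: 0.25}
        assert f.gene_counts["L1"]["A"] == 4

    def test_monomorphic(self, tiny_table):
        tiny_table.calls[:, 1, :] = 200
        f = allele_frequencies(tiny_table, pooled=True)
        assert f.freqs["L2"][POOLED] == {200: 1.0}

    def test_pooled_is_size_weighted_mean(self, study_table):
        per_pop = allele_frequencies(study_table)
        pooled = allele_frequencies(study_table, pooled=True)
        for locus in study_table.locus_names:
            weighted: dict[int, float] = {}
            total = 0
            for pop, cell in per_pop.freqs[locus].items():
                n = per_pop.gene_counts[locus][pop]
                total += n
                for a, freq in cell.items():
                    weighted[a] = weighted.get(a, 0.0) + freq * n
            for a, v in weighted.items():
                assert pooled.freqs[locus][POOLED][a] == pytest.approx(v / total)

    def test_frequencies_sum_to_one(self, study_table):
        f = allele_frequencies(study_table)
        for locus in f.loci:
            for cell in f.freqs[locus].values():
                assert sum(cell.values()) == pytest.approx(1.0, abs=1e-12)


class TestLocusStatistics:
    def test_symmetric_biallelic(self):
        p = np.array([0.5, 0.5])
        assert 1 / np.sum(p**2) == pytest.approx(2.0)
        assert expected_heterozygosity(p) == pytest.approx(0.5)
        assert -np.sum(p * np.log(p)) == pytest.approx(math.log(2))

    def test_three_allele_case(self):
        p = np.array([0.7, 0.2, 0.1])
        assert 1 / np.sum(p**2) == pytest.approx(1 / 0.54)
        assert -np.sum(p * np.log(p)) == pytest.approx(0.8018, abs=5e-5)

    def test_records_schema_and_bounds(self, study_table):
        f = allele_frequencies(study_table)
        records = locus_diversity(f, study_table)
        assert len(records) == 17 * 6
        for r in records:
            assert 1 <= r.ae <= r.na
            assert 0 <= r.ho <= 1 and 0 <= r.he <= 1
            assert r.na_freq5 <= r.na
            assert r.uhe >= r.he
            assert r.pic <= r.he + 1e-12
            if r.richness is not None:
                assert 1 <= r.richness <= r.na + 1e-9


class TestPic:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([1.0], 0.0),
            ([0.5, 0.5], 0.375),
            ([0.25, 0.25, 0.25, 0.25], 0.703125),
        ],
    )
    def test_known_values(self, p, expected):
        assert pic(np.asarray(p)) == pytest.approx(expected, abs=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            pic(np.array([]))

    @settings(max_examples=200, deadline=None)
    @given(p=simplexes)
    def test_pic_below_he(self, p):
        assert pic(p) <= expected_heterozygosity(p) + 1e-12


class TestAllelicRichness:
    def test_hand_computed_example(self):
        # (1 - C(1,2)/C(4,2)) + (1 - C(3,2)/C(4,2)) = 1 + 0.5
        assert allelic_richness({1: 3, 2: 1}, g=2) == pytest.approx(1.5)

    def test_full_sample_equals_allele_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 10, size=rng.integers(2, 7))
            assert allelic_richness(counts, g=int(counts.sum())) == pytest.approx(
                len(counts)
            )

    def test_monotone_in_g(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(1, 8, size=rng.integers(2, 6))
            n = int(counts.sum())
            values = [allelic_richness(counts, g) for g in range(1, n + 1)]
            assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
            assert values[0] == pytest.approx(1.0)

    def test_out_of_range_g(self):
        with pytest.raises(ValueError):
            allelic_richness({1: 2}, g=3)
        with pytest.raises(ValueError):
            allelic_richness({1: 2}, g=0)


class TestPrivateAlleles:
    def test_disjoint_alleles_all_private(self, tiny_table):
        # L1: pop A carries {101,103}, pop B carries {101,103}; make disjoint
        tiny_table.calls[2:, 0, :] = [[105, 107], [105, 105]]
        per_cell, _ = private_alleles(allele_frequencies(tiny_table))
        assert per_cell[("L1", "A")] == 2
        assert per_cell[("L1", "B")] == 2

    def test_identical_populations_zero(self, tiny_table):
        tiny_table.calls[2:] = tiny_table.calls[:2]
        per_cell, means = private_alleles(allele_frequencies(tiny_table))
        assert all(v == 0 for v in per_cell.values())
        assert all(v == 0 for v in means.values())

    def test_single_population_undefined(self, tiny_table):
        tiny_table.populations = ["A"] * 4
        with pytest.raises(ValueError):
            private_alleles(allele_frequencies(tiny_table))

    def test_matches_brute_force_scan(self, study_table):
        freqs = allele_frequencies(study_table)
        per_cell, _ = private_alleles(freqs)
        pops = study_table.population_labels()
        for locus in study_table.locus_names:
            for pop in pops:
                count = 0
                for allele in freqs.counts[locus][pop]:
                    seen_elsewhere = any(
                        allele in freqs.counts[locus].get(other, {})
                        for other in pops if other != pop
                    )
                    count += not seen_elsewhere
                assert per_cell[(locus, pop)] == count


class TestStructureProperties:
    def test_wahlund_pooled_he_exceeds_within(self):
        cfg = SimulationConfig(fst=0.15)
        table = simulate_table(cfg, seed=77)
        per_pop = allele_frequencies(table)
        pooled = allele_frequencies(table, pooled=True)
        margin = 0.0
        for locus in table.locus_names:
            he_pooled = expected_heterozygosity(pooled.freq_vector(locus, POOLED))
            he_within = np.mean([
                expected_heterozygosity(per_pop.freq_vector(locus, pop))
                for pop in per_pop.freqs[locus]
            ])
            margin += he_pooled - he_within
        assert margin > 0  # differentiation inflates pooled He on average
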