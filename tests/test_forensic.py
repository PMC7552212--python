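import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strpop import (
    combine_panel,
    cumulative_from_values,
    exclusion_prob_duo,
    exclusion_prob_trio,
    forensic_record,
    power_of_discrimination,
    power_of_exclusion,
    probability_of_identity,
    published,
)
from strpop.forensic import (
    exclusion_duo_enumeration,
    exclusion_trio_enumeration,
    hwe_genotype_freqs,
    pid_enumeration,
)

simplexes = st.lists(
    st.floats(0.01, 1.0), min_size=2, max_size=10
).map(lambda xs: np.asarray(xs) / np.sum(xs))


class TestPowerOfExclusion:
    @pytest.mark.parametrize(
        "locus, ho, expected",
        [("AHT4", 0.7602, 0.5274), ("AHT5", 0.7908, 0.5821), ("LEX3", 0.0357, 0.0012)],
    )
    def test_reproduces_reported_values(self, locus, ho, expected):
        """PE is a function of observed heterozygosity alone; the published
        per-locus PE values recompute from the published Ho values."""
        assert round(power_of_exclusion(ho), 4) == expected

    def test_no_heterozygotes_no_power(self):
        assert power_of_exclusion(0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            power_of_exclusion(1.2)


class TestPowerOfDiscrimination:
    def test_single_genotype(self):
        assert power_of_discrimination({(1, 1): 1.0}) == 0.0

    def test_two_equal_genotypes(self):
        assert power_of_discrimination({(1, 1): 0.5, (1, 2): 0.5}) == pytest.approx(0.5)

    def test_hwe_biallelic(self):
        gf = hwe_genotype_freqs(np.array([0.5, 0.5]))
        assert power_of_discrimination(gf) == pytest.approx(0.625)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            power_of_discrimination({})


class TestProbabilityOfIdentity:
    def test_monomorphic_is_one(self):
        assert probability_of_identity(np.array([1.0])) == pytest.approx(1.0)

    def test_biallelic_half(self):
        assert probability_of_identity(np.array([0.5, 0.5])) == pytest.approx(0.375)

    @settings(max_examples=100, deadline=None)
    @given(p=simplexes)
    def test_equals_genotype_enumeration(self, p):
        assert probability_of_identity(p) == pytest.approx(
            pid_enumeration(p), abs=1e-12
        )


class TestExclusionProbabilities:
    def test_monomorphic_never_excludes(self):
        p = np.array([1.0])
        assert exclusion_prob_duo(p) == pytest.approx(0.0, abs=1e-12)
        assert exclusion_prob_trio(p) == pytest.approx(0.0, abs=1e-12)

    def test_biallelic_against_enumeration(self):
        p = np.array([0.5, 0.5])
        assert exclusion_prob_duo(p) == pytest.approx(
            exclusion_duo_enumeration(p), abs=1e-12
        )
        assert exclusion_prob_trio(p) == pytest.approx(
            exclusion_trio_enumeration(p), abs=1e-12
        )

    def test_four_equifrequent_alleles(self):
        p = np.full(4, 0.25)
        assert exclusion_prob_duo(p) == pytest.approx(
            exclusion_duo_enumeration(p), abs=1e-12
        )
        assert exclusion_prob_trio(p) == pytest.approx(
            exclusion_trio_enumeration(p), abs=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(p=simplexes)
    def test_second_parent_knowledge_helps(self, p):
        assert exclusion_prob_trio(p) >= exclusion_prob_duo(p) - 1e-12

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            exclusion_prob_duo(np.array([]))


class TestPanelCombination:
    def test_reported_cumulative_exclusion_one_parent(self):
        cpe1 = cumulative_from_values(published.PE1, "power")
        assert round(100 * cpe1, 4) == 99.9269

    def test_reported_cumulative_identity(self):
        cpid = cumulative_from_values(published.PID, "identity")
        assert float(f"{cpid:.2e}") == pytest.approx(5.04e-17)

    def test_single_locus_panel(self):
        rec = forensic_record("L", np.array([0.5, 0.5]), ho=0.4)
        panel = combine_panel([rec])
        assert panel.cpe1 == pytest.approx(rec.pe1)
        assert panel.cpid == pytest.approx(rec.pid)

    def test_monomorphic_locus_is_neutral(self):
        rec = forensic_record("L", np.array([0.4, 0.3, 0.3]), ho=0.6)
        mono = forensic_record("M", np.array([1.0]), ho=0.0)
        with_mono = combine_panel([rec, mono])
        without = combine_panel([rec])
        assert with_mono.cpe1 == pytest.approx(without.cpe1)
        assert with_mono.cpe2 == pytest.approx(without.cpe2)
        assert with_mono.cpd == pytest.approx(without.cpd)
        assert with_mono.cpid == pytest.approx(without.cpid)

    def test_monotone_in_panel_size(self):
        rng = np.random.default_rng(2)
        records = [
            forensic_record(
                f"L{i}", rng.dirichlet(np.ones(rng.integers(2, 8))),
                ho=float(rng.uniform(0.2, 0.9)),
            )
            for i in range(8)
        ]
        prev = None
        for size in range(1, 9):
            panel = combine_panel(records[:size])
            if prev is not None:
                assert panel.cpe1 >= prev.cpe1 - 1e-15
                assert panel.cpe2 >= prev.cpe2 - 1e-15
                assert panel.cpd >= prev.cpd - 1e-15
                assert panel.cpid <= prev.cpid + 1e-15
            prev = panel

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            combine_panel([])
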