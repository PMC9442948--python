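import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirdesign import (
    ExperimentDesign,
    GenotypeCounts,
    GroupDesign,
    InvalidDesignError,
    canonical_design,
    genotype_effect,
    summarize_design,
)
from sirdesign.design import dump_design, largest_remainder_round, load_design

counts_st = st.builds(
    GenotypeCounts,
    n_AA=st.integers(0, 50),
    n_AB=st.integers(0, 50),
    n_BB=st.integers(0, 50),
).filter(lambda c: c.total > 0)


class TestGenotypeCounts:
    @given(counts_st)
    @settings(max_examples=200, deadline=None)
    def test_balance_bounded_by_homozygosity(self, counts):
        assert 0.0 <= counts.H <= 1.0
        assert abs(counts.chi) <= counts.H + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidDesignError):
            GenotypeCounts(-1, 0, 0)

    def test_empty_counts_have_no_composition(self):
        with pytest.raises(InvalidDesignError):
            GenotypeCounts(0, 0, 0).H


class TestGenotypeEffect:
    @pytest.mark.parametrize(
        "genotype, a, delta, expected",
        [
            ("AA", 0.4, 0.0, 0.4),
            ("AB", 0.4, 0.0, 0.0),
            ("AB", 0.4, -1.0, -0.4),  # complete dominance of B
            ("AB", 0.4, 1.0, 0.4),
            ("BB", 0.4, 0.5, -0.4),
        ],
    )
    def test_genotype_map(self, genotype, a, delta, expected):
        assert genotype_effect(genotype, a, delta) == pytest.approx(expected)

    def test_unknown_genotype(self):
        with pytest.raises(ValueError):
            genotype_effect("AC", 0.4)


class TestSummarize:
    def test_single_group_fig2a_composition(self):
        design = ExperimentDesign(
            (
                GroupDesign(
                    seeders=GenotypeCounts(0, 0, 15),
                    contacts=GenotypeCounts(90, 0, 10),
                ),
            )
        )
        s = summarize_design(design, 1.0)
        assert s.H_cont[0] == pytest.approx(1.0)
        assert s.chi_cont[0] == pytest.approx(0.8)
        assert s.chi_seed[0] == pytest.approx(-1.0)

    def test_symmetric_single_group(self):
        design = ExperimentDesign(
            (
                GroupDesign(
                    seeders=GenotypeCounts(5, 0, 5),
                    contacts=GenotypeCounts(50, 0, 50),
                ),
            )
        )
        s = summarize_design(design, 1.0)
        assert s.chi_cont[0] == 0.0
        assert s.mean_H_cont == 1.0
        assert s.var_chi_cont == 0.0

    def test_two_group_balance_variance(self):
        c = 1 / math.sqrt(2)
        # 100-contact groups realising chi = +-c approximately via floats
        design = ExperimentDesign(
            tuple(
                GroupDesign(
                    seeders=GenotypeCounts(3, 0, 0),
                    contacts=GenotypeCounts(50 * (1 + s * c), 0, 50 * (1 - s * c)),
                )
                for s in (+1, -1)
            )
        )
        s = summarize_design(design, 1.0)
        assert s.mean_chi_cont == pytest.approx(0.0)
        assert s.var_chi_cont == pytest.approx(0.5)  # population var of {+c,-c}

    def test_h_definition(self):
        design = canonical_design("single", g_size=100, exact=True)
        for phi in (0.25, 0.5, 1.0):
            s = summarize_design(design, phi)
            assert s.h == pytest.approx(15.0 / (15.0 + phi * 85.0))

    def test_replication_leaves_summaries_unchanged(self):
        base = canonical_design("mixed", g_size=60)
        rep = base.replicate(5)
        s1 = summarize_design(base, 0.8)
        s5 = summarize_design(rep, 0.8)
        assert s5.n_group == 5 * s1.n_group
        assert s5.mean_chi_cont == pytest.approx(s1.mean_chi_cont)
        assert s5.var_chi_cont == pytest.approx(s1.var_chi_cont)
        assert s5.H_bar == pytest.approx(s1.H_bar)

    def test_invalid_designs_signalled(self):
        with pytest.raises(InvalidDesignError):
            summarize_design(
                ExperimentDesign(
                    (
                        GroupDesign(
                            seeders=GenotypeCounts(0, 0, 0),
                            contacts=GenotypeCounts(10, 0, 0),
                        ),
                    )
                ),
                1.0,
            )
        with pytest.raises(ValueError):
            summarize_design(canonical_design("pure"), 1.2)


class TestCanonicalDesigns:
    def test_pure_blueprint(self):
        d = canonical_design("pure", g_size=100)
        assert len(d.groups) == 4
        assert all(g.n_seed == 47 and g.n_cont == 53 for g in d.groups)
        s = summarize_design(d, 1.0)
        assert set(abs(x) for x in s.chi_seed) == {1.0}
        assert s.mean_chi_cont == pytest.approx(0.0)

    def test_mixed_blueprint_integer_rounding(self):
        d = canonical_design("mixed", g_size=100)
        g1 = d.groups[0]
        assert g1.n_seed == 3
        assert (g1.contacts.n_AA, g1.contacts.n_BB) == (83, 14)
        s = summarize_design(d, 1.0)
        assert s.mean_chi_cont == pytest.approx(0.0)

    def test_single_blueprint_chi_near_target(self):
        d = canonical_design("single", g_size=100)
        g = d.groups[0]
        assert g.n_seed == 15 and g.seeders.n_BB == 15
        assert abs(g.contacts.chi - 0.8) < 0.02

    def test_dominance_blueprints(self):
        d9 = canonical_design("pure_dominance", g_size=100)
        assert len(d9.groups) == 9
        s = summarize_design(d9, 1.0)
        assert s.mean_H_cont == pytest.approx(2.0 / 3.0)
        d3 = canonical_design("mixed_dominance", g_size=100)
        assert len(d3.groups) == 3
        # largest-remainder: 0.8*97 = 77.6 floors to 77; the two 0.7
        # fractional parts of the minor classes win the spare units
        assert d3.groups[0].contacts.as_dict() == {"AA": 77, "AB": 10, "BB": 10}

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            canonical_design("fancy")

    def test_complete_dominance_recoding(self):
        from sirdesign import recode_complete_dominance

        d = canonical_design("pure_dominance", g_size=100)
        recoded = recode_complete_dominance(d, dominant="A")
        s = summarize_design(recoded, 1.0)
        assert s.mean_H_cont == 1.0  # AA and AB merged: everyone "homozygous"
        # AB contacts now count with AA in the balance
        assert set(s.chi_cont) == {1.0, -1.0}
        with pytest.raises(ValueError):
            recode_complete_dominance(d, dominant="C")


class TestRoundingAndIO:
    def test_largest_remainder_conserves_total(self):
        assert largest_remainder_round([0.8536, 0.1464], 97) == [83, 14]
        assert sum(largest_remainder_round([0.5, 0.3, 0.2], 7)) == 7

    def test_design_config_roundtrip(self, tmp_path):
        d = canonical_design("mixed_dominance", g_size=80, replicates=2)
        path = tmp_path / "design.json"
        dump_design(d, str(path))
        d2 = load_design(str(path))
        assert d2 == d
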