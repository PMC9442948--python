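import math
import warnings

import numpy as np
import pytest

from sirdesign import (
    DegenerateDesignError,
    ExperimentDesign,
    GenotypeCounts,
    GroupDesign,
    NonEstimableWarning,
    PrecisionInputs,
    canonical_design,
    compute_WY,
    fisher_gf,
    gwas_sd,
    sd_closed_form,
    sd_dominance,
    sd_snp_effects,
    summarize_design,
    table3_report,
)


def _sds(summary, inputs=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NonEstimableWarning)
        return sd_snp_effects(summary, inputs)


class TestWY:
    def test_single_group_W_vanishes(self, single_summary):
        W, Y = compute_WY(single_summary)
        assert W == pytest.approx(0.0, abs=1e-12)
        assert Y > 0

    def test_no_seeder_contact_contrast(self):
        # chi_seed = chi_cont in every group -> both intermediates vanish
        design = ExperimentDesign(
            tuple(
                GroupDesign(
                    seeders=GenotypeCounts(n_AA, 0, 10 - n_AA),
                    contacts=GenotypeCounts(5 * n_AA, 0, 5 * (10 - n_AA)),
                )
                for n_AA in (2, 8)
            )
        )
        W, Y = compute_WY(summarize_design(design, 0.7))
        assert W == pytest.approx(0.0, abs=1e-12)
        assert Y == pytest.approx(0.0, abs=1e-12)

    def test_pure_design_values(self, pure_summary):
        W, Y = compute_WY(pure_summary)
        assert W == pytest.approx(math.log(0.47), abs=1e-12)  # -log(h) * (-1)
        assert Y == pytest.approx(2 * 0.53, abs=1e-12)

    def test_zero_seeders_degenerate(self, mixed_summary_limit):
        with pytest.raises(DegenerateDesignError):
            compute_WY(mixed_summary_limit)


class TestFisher:
    def test_symmetry_and_contact_block(self, single_summary):
        info = fisher_gf(single_summary)
        assert np.allclose(info.M, info.M.T)
        # single group: M[a_g, a_g] = phi * N_cont * (<H_cont> - <chi_cont>^2)
        assert info.M[0, 0] == pytest.approx(85.0 * (1 - 0.8**2))
        assert info.M[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_pure_af_entry(self, pure_summary):
        info = fisher_gf(pure_summary)
        W, Y = compute_WY(pure_summary)
        expected = 4 * (53.0 * 1.0 + 47.0 * (2 * W + Y))
        assert info.M[1, 1] == pytest.approx(expected)

    def test_psd_on_canonical_designs(self, unit_inputs):
        for name in ("single", "pure", "pure_dominance", "mixed"):
            n_seed = 0.0 if name == "mixed" else None
            d = canonical_design(name, 100, exact=True, n_seed=n_seed)
            s = summarize_design(d, 1.0, allow_empty_seeders=True)
            eig = np.linalg.eigvalsh(fisher_gf(s).M)
            assert eig.min() >= -1e-9


class TestSnpEffectSDs:
    def test_pure_design_coefficients(self, pure_summary, unit_inputs):
        sd_ag, sd_af, sd_ar = _sds(pure_summary, unit_inputs)
        rtN = math.sqrt(pure_summary.n_total)
        assert sd_ag * rtN == pytest.approx(1.52, abs=0.005)
        assert sd_af * rtN == pytest.approx(1.96, abs=0.005)
        assert sd_ar * rtN == pytest.approx(1.0, abs=1e-9)

    def test_mixed_design_zero_seeder_coefficients(self, mixed_summary_limit):
        sd_ag, sd_af, _ = _sds(mixed_summary_limit)
        rtN = math.sqrt(mixed_summary_limit.n_total)
        assert sd_ag * rtN == pytest.approx(math.sqrt(2.0), rel=1e-9)
        assert sd_af * rtN == pytest.approx(2.0, rel=1e-9)

    def test_all_AA_design_has_no_recoverability_information(self):
        design = ExperimentDesign(
            (
                GroupDesign(
                    seeders=GenotypeCounts(10, 0, 0),
                    contacts=GenotypeCounts(90, 0, 0),
                ),
            )
        )
        with pytest.warns(NonEstimableWarning):
            *_, sd_ar = sd_snp_effects(summarize_design(design, 1.0))
        assert sd_ar == math.inf

    def test_phi_monotonicity(self, unit_inputs):
        d = canonical_design("pure", 100, exact=True)
        prev = (math.inf, math.inf, math.inf)
        for phi in (0.2, 0.4, 0.6, 0.8, 1.0):
            cur = _sds(summarize_design(d, phi), unit_inputs)
            assert all(c <= p + 1e-12 for c, p in zip(cur, prev))
            prev = cur

    def test_effect_size_independence(self, pure_summary):
        a = _sds(pure_summary, PrecisionInputs(1.0, 1.0, 0.1, 0.1, 0.1))
        b = _sds(pure_summary, PrecisionInputs(1.0, 1.0, 2.0, -1.0, 0.5))
        assert a == b

    def test_k_scaling_of_recoverability(self, pure_summary):
        _, _, sd1 = _sds(pure_summary, PrecisionInputs(k=1.0))
        _, _, sd4 = _sds(pure_summary, PrecisionInputs(k=4.0))
        assert sd4 == pytest.approx(sd1 / 2.0, rel=1e-12)


class TestDominanceSDs:
    def test_no_heterozygotes_dominance_diverges(self, pure_summary, unit_inputs):
        with pytest.warns(NonEstimableWarning):
            sd_dg, _, _ = sd_dominance(pure_summary, unit_inputs)
        assert sd_dg == math.inf

    def test_pure_dominance_coefficient(self, unit_inputs):
        d = canonical_design("pure_dominance", 100, exact=True)
        s = summarize_design(d, 1.0)
        sd_dg, sd_df, _ = sd_dominance(s, unit_inputs)
        rtN = math.sqrt(s.n_total)
        assert sd_dg * rtN == pytest.approx(3.0 / math.sqrt(1.06), rel=1e-9)
        assert sd_df * rtN == pytest.approx(3.76, abs=0.005)

    def test_inverse_effect_size_scaling(self, unit_inputs):
        d = canonical_design("pure_dominance", 100, exact=True)
        s = summarize_design(d, 1.0)
        one = sd_dominance(s, PrecisionInputs(1.0, 1.0, 1.0, 1.0, 1.0))
        two = sd_dominance(s, PrecisionInputs(1.0, 1.0, 2.0, 2.0, 2.0))
        for x, y in zip(one, two):
            assert y == pytest.approx(x / 2.0, rel=1e-12)

    def test_zero_effect_not_estimable(self, unit_inputs):
        d = canonical_design("pure_dominance", 100, exact=True)
        s = summarize_design(d, 1.0)
        with pytest.warns(NonEstimableWarning):
            sd_dg, _, _ = sd_dominance(s, PrecisionInputs(1.0, 1.0, 0.0, 1.0, 1.0))
        assert sd_dg == math.inf


class TestClosedForms:
    def test_single_group_value(self):
        assert sd_closed_form("single", 0.15, -1.0, 0.8, 1.0) == pytest.approx(
            3.09, abs=0.005
        )

    def test_single_no_contrast_diverges(self):
        with pytest.warns(NonEstimableWarning):
            assert sd_closed_form("single", 0.15, 0.5, 0.5) == math.inf

    def test_mixed_optimum(self):
        val = sd_closed_form("mixed", 0.0, chi_cont=1 / math.sqrt(2))
        assert val == pytest.approx(2.0, rel=1e-12)

    def test_pure_value(self):
        assert sd_closed_form("pure", 0.47) == pytest.approx(1.96, abs=0.005)


class TestGwas:
    def test_direct_substitution(self):
        sd_ag, sd_af, sd_ar = gwas_sd(p=0.5, n_total=1.0, n_group=1.0, g_size=10, k=1.0)
        assert sd_ag == pytest.approx(1 / math.sqrt(0.5))
        assert sd_ar == pytest.approx(sd_ag)
        assert sd_af == pytest.approx(1 / math.sqrt(0.5 * (2 - 1 / 9)))

    def test_g_size_two_bracket(self):
        _, sd_af, _ = gwas_sd(0.5, 1.0, 1.0, g_size=2)
        assert sd_af == pytest.approx(1 / math.sqrt(0.5 * 1.0))

    def test_boundary_frequency(self):
        with pytest.warns(NonEstimableWarning):
            assert gwas_sd(1.0, 100, 10, 10) == (math.inf,) * 3


class TestTable3:
    def test_report_matches_published_coefficients(self):
        table = table3_report()
        assert table.loc["single", "a_f"] == 3.09
        assert table.loc["pure", "a_g"] == 1.52
        assert table.loc["pure", "a_f"] == 1.96
        assert table.loc["pure", "a_r"] == 1.0
        assert table.loc["mixed", "a_g"] == 1.41
        assert table.loc["mixed", "a_f"] == 2.0
        assert table.loc["pure_dominance", "a_f"] == 2.40
        assert table.loc["pure_dominance", "Delta_g"] == 2.91
        assert math.isinf(table.loc["pure", "Delta_g"])
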