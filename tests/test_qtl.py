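"""Conditional QTL-genotype probabilities and generation adjustment."""

import numpy as np
import pytest

from preril import (
    ThreeLocusThetas,
    genotype_priors_selfing,
    interval_theta,
    marker_given_qtl,
    preril_qtl_inputs,
    qtl_posterior,
    write_posterior_table,
)


def posterior_row(table, a, b):
    row = table[(table.A == a) & (table.B == b)].iloc[0]
    return np.array([row.QQ, row.Qq, row.qq])


class TestIntervalTheta:
    def test_f2_worked_example_full_precision(self):
        got = interval_theta(0.05, 0.01)
        assert got == pytest.approx(0.04 / 0.98, abs=1e-15)
        assert round(got, 4) == 0.0408

    def test_f4_worked_example(self):
        assert round(interval_theta(0.08923, 0.01905), 5) == 0.07296

    def test_marker_coincident_with_qtl(self):
        assert interval_theta(0.3, 0.0) == pytest.approx(0.3)

    def test_qtl_outside_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_theta(0.05, 0.06)


class TestPriors:
    @pytest.mark.parametrize("t,expected", [
        (2, (0.25, 0.5, 0.25)),
        (3, (0.375, 0.25, 0.375)),
        (4, (0.4375, 0.125, 0.4375)),
    ])
    def test_selfing_generations(self, t, expected):
        assert np.allclose(genotype_priors_selfing(t), expected)

    def test_fully_inbred_limit(self):
        assert np.allclose(genotype_priors_selfing(60), [0.5, 0, 0.5], atol=1e-15)

    def test_pre_f2_rejected(self):
        with pytest.raises(ValueError):
            genotype_priors_selfing(1)


class TestMarkerGivenQtl:
    def test_complete_linkage_is_identity(self):
        assert np.allclose(marker_given_qtl(0.0), np.eye(3))

    def test_independence_at_half(self):
        T = marker_given_qtl(0.5)
        assert np.allclose(T, np.tile([0.25, 0.5, 0.25], (3, 1)))

    def test_rows_normalize(self):
        for th in np.linspace(0, 0.5, 21):
            assert np.allclose(marker_given_qtl(th).sum(axis=1), 1, atol=1e-14)


class TestPosteriorF2:
    @pytest.fixture
    def f2_table(self):
        th_qb = interval_theta(0.05, 0.01)
        return qtl_posterior(genotype_priors_selfing(2), 0.01, th_qb)

    def test_flanking_hom_het_cell(self, f2_table):
        got = posterior_row(f2_table, 1, 2)
        assert np.allclose(np.round(got, 7), [0.807816, 0.1921015, 0.0000824])

    def test_double_homozygote_cell(self, f2_table):
        got = posterior_row(f2_table, 1, 1)
        assert round(got[0], 7) == 0.9991409
        assert round(got[1], 7) == 0.0008589
        assert got[2] == pytest.approx(1.846e-7, rel=5e-4)

    def test_denominators_match_closed_forms(self):
        # marginal marker-pair probabilities collapse to functions of theta_AB
        th_ab, th_aq = 0.05, 0.01
        th_qb = interval_theta(th_ab, th_aq)
        priors = genotype_priors_selfing(2)
        T_aq, T_qb = marker_given_qtl(th_aq), marker_given_qtl(th_qb)
        denom_12 = sum(priors[k] * T_aq[k, 0] * T_qb[k, 1] for k in range(3))
        denom_11 = sum(priors[k] * T_aq[k, 0] * T_qb[k, 0] for k in range(3))
        assert denom_12 == pytest.approx(0.5 * th_ab * (1 - th_ab), abs=1e-12)
        assert denom_12 == pytest.approx(0.02375, abs=1e-12)
        assert denom_11 == pytest.approx(0.25 * (1 - th_ab) ** 2, abs=1e-12)

    def test_qtl_on_marker_gives_certainty(self):
        table = qtl_posterior(genotype_priors_selfing(2), 0.0, 0.05)
        for b in (1, 2, 3):
            assert posterior_row(table, 1, b)[0] == pytest.approx(1.0)


class TestPosteriorF4:
    @pytest.fixture
    def f4_table(self):
        thetas, priors = preril_qtl_inputs(0.05, 0.01, "self", 4, round_chain=5)
        return qtl_posterior(priors, thetas.theta_aq, thetas.theta_qb)

    def test_flanking_hom_het_cell(self, f4_table):
        got = posterior_row(f4_table, 1, 2)
        assert np.allclose(np.round(got, 7), [0.9653945, 0.0342414, 0.0003641])

    def test_double_homozygote_cell(self, f4_table):
        got = posterior_row(f4_table, 1, 1)
        assert round(got[0], 7) == 0.9995612
        assert round(got[1], 7) == 0.0004365
        assert got[2] == pytest.approx(2.3349e-6, rel=5e-4)

    def test_homozygote_posteriors_grow_with_inbreeding(self):
        f2 = qtl_posterior(genotype_priors_selfing(2), 0.01,
                           interval_theta(0.05, 0.01))
        thetas, priors = preril_qtl_inputs(0.05, 0.01, "self", 4)
        f4 = qtl_posterior(priors, thetas.theta_aq, thetas.theta_qb)
        assert posterior_row(f4, 1, 1)[1] < posterior_row(f2, 1, 1)[1]
        assert posterior_row(f4, 1, 1)[0] > posterior_row(f2, 1, 1)[0]


class TestPosteriorInvariants:
    @pytest.mark.parametrize("t_app", range(0, 9))
    def test_rows_sum_to_one_across_generations(self, t_app):
        for th_ab in (0.02, 0.05, 0.2, 0.4):
            thetas, priors = preril_qtl_inputs(th_ab, th_ab / 3, "self", t_app)
            table = qtl_posterior(priors, thetas.theta_aq, thetas.theta_qb)
            assert np.allclose(table[["QQ", "Qq", "qq"]].sum(axis=1), 1,
                               atol=1e-12)

    def test_marker_pair_marginals_sum_to_one(self):
        priors = genotype_priors_selfing(3)
        T_aq, T_qb = marker_given_qtl(0.07), marker_given_qtl(0.12)
        total = sum(priors[k] * T_aq[k, i] * T_qb[k, j]
                    for k in range(3) for i in range(3) for j in range(3))
        assert total == pytest.approx(1, abs=1e-12)


class TestGenerationAdjustment:
    def test_f4_adjusted_thetas(self):
        thetas, priors = preril_qtl_inputs(0.05, 0.01, "self", 4)
        assert round(thetas.theta_ab, 5) == 0.08923
        assert round(thetas.theta_aq, 5) == 0.01905
        assert round(thetas.theta_qb, 5) == 0.07296
        assert np.allclose(priors, [0.4375, 0.125, 0.4375])

    def test_zero_applications_leaves_inputs_unchanged(self):
        thetas, priors = preril_qtl_inputs(0.05, 0.01, "self", 0)
        assert thetas.theta_ab == 0.05 and thetas.theta_aq == 0.01
        assert np.allclose(priors, [0.25, 0.5, 0.25])

    def test_adjustment_is_monotone(self):
        for t_app in (1, 2, 5):
            thetas, _ = preril_qtl_inputs(0.1, 0.03, "self", t_app)
            assert thetas.theta_ab >= 0.1

    def test_sib_priors_follow_chain_heterozygosity(self):
        _, priors_sib = preril_qtl_inputs(0.05, 0.01, "sib", 4)
        # sib-line heterozygosity decays slower than selfing
        assert priors_sib[1] > genotype_priors_selfing(4)[1]
        assert priors_sib.sum() == pytest.approx(1)

    def test_composition_invariant_enforced(self):
        with pytest.raises(ValueError):
            ThreeLocusThetas(theta_aq=0.1, theta_qb=0.1, theta_ab=0.3)
        ThreeLocusThetas(theta_aq=0.1, theta_qb=0.1,
                         theta_ab=0.1 + 0.1 - 2 * 0.01)  # valid


def test_posterior_table_round_trips_through_csv(tmp_path):
    table = qtl_posterior(genotype_priors_selfing(2), 0.01,
                          interval_theta(0.05, 0.01))
    path = tmp_path / "posterior.csv"
    write_posterior_table(table, path)
    assert path.read_text().splitlines()[0] == "A,B,QQ,Qq,qq"
    import pandas as pd
    back = pd.read_csv(path)
    assert np.allclose(back[["QQ", "Qq", "qq"]], table[["QQ", "Qq", "qq"]])
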