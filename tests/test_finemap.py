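"""Fine mapping: priors, PIPs, credible sets, DENTIST-S/SLALOM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magwas.finemap import (
    FineMapLocus,
    credible_set_size_comparison,
    dentist_s,
    extract_locus,
    finemap_locus,
    finemap_locus_single,
    heterogeneity_prior,
    per_variant_meta_i2,
    posterior_pips,
    slalom_qc,
    summarize_set_sizes,
)
from magwas.meta import ivw_meta
from magwas.simulate import (
    AncestryConfig,
    CausalModel,
    simulate_ld_matrix,
    simulate_study,
)
from magwas.sumstats import Variant


def _locus(beta, se, r_to_lead=None, groups=None):
    """Build a FineMapLocus from (n_groups, n_members) arrays."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    se = np.atleast_2d(np.asarray(se, dtype=float))
    n = beta.shape[1]
    members = [Variant(f"m{j}", "1", 1_000_000 + j * 5_000, "A", "G")
               for j in range(n)]
    groups = groups or [f"g{i}" for i in range(beta.shape[0])]
    r = np.ones(n) if r_to_lead is None else np.asarray(r_to_lead, dtype=float)
    return FineMapLocus(lead=members[0], members=members, groups=list(groups),
                        beta=beta, se=se, r_to_lead=r)


def _sumstats_frame(ld, z, se=0.02):
    return pd.DataFrame({
        "SNP": [v.id for v in ld.variants],
        "CHR": [v.chrom for v in ld.variants],
        "BP": [v.pos for v in ld.variants],
        "BETA": np.asarray(z) * se, "SE": se,
    })


class TestExtractLocus:
    def test_r2_threshold_rule(self):
        # AR-1 rho=0.4: lag-1 r^2 = 0.16 > 0.1, lag-2 r^2 = 0.0256 < 0.1
        ld = simulate_ld_matrix([7], [0.4])
        frames = {"EUR": _sumstats_frame(ld, np.zeros(7))}
        locus = extract_locus("rs4", frames, ld)
        assert [v.id for v in locus.members] == ["rs3", "rs4", "rs5"]

    def test_isolated_lead_single_member(self):
        ld = simulate_ld_matrix([5], [0.0])
        frames = {"EUR": _sumstats_frame(ld, np.zeros(5))}
        locus = extract_locus("rs3", frames, ld)
        assert [v.id for v in locus.members] == ["rs3"]

    def test_members_ordered_by_position(self):
        ld = simulate_ld_matrix([9], [0.9])
        frames = {"EUR": _sumstats_frame(ld, np.zeros(9))}
        locus = extract_locus("rs5", frames, ld)
        pos = [v.pos for v in locus.members]
        assert pos == sorted(pos)

    def test_missing_group_data_is_nan(self):
        ld = simulate_ld_matrix([3], [0.9])
        full = _sumstats_frame(ld, np.zeros(3))
        partial = full.iloc[:2]
        locus = extract_locus("rs1", {"EUR": full, "AFR": partial}, ld)
        gi = locus.groups.index("AFR")
        assert np.isnan(locus.beta[gi, -1])

    def test_absent_lead_is_hard_error(self):
        ld = simulate_ld_matrix([3], [0.9])
        with pytest.raises(KeyError):
            extract_locus("rsX", {"EUR": _sumstats_frame(ld, np.zeros(3))}, ld)


class TestPerVariantMeta:
    def test_identical_groups_no_heterogeneity(self):
        locus = _locus([[0.2, 0.1], [0.2, 0.1]], [[0.05, 0.05], [0.05, 0.05]])
        chi2, i2, beta, se = per_variant_meta_i2(locus)
        assert np.allclose(i2, 0.0)
        assert np.allclose(beta, [0.2, 0.1])

    def test_opposite_effects_hand_values(self):
        locus = _locus([[0.2], [-0.2]], [[0.02], [0.02]])
        chi2, i2, _, _ = per_variant_meta_i2(locus)
        assert i2[0] == pytest.approx(0.995)
        # Q = sum w (b - bhat)^2 = 2 * (0.2/0.02)^2 = 200
        res = ivw_meta([0.2, -0.2], [0.02, 0.02])
        assert res.q == pytest.approx(200.0)

    def test_equivalence_with_meta_module(self, rng):
        beta = rng.normal(0, 0.1, (3, 6))
        se = rng.uniform(0.01, 0.1, (3, 6))
        locus = _locus(beta, se)
        chi2, i2, pooled, pooled_se = per_variant_meta_i2(locus)
        for j in range(6):
            ref = ivw_meta(beta[:, j], se[:, j])
            assert pooled[j] == pytest.approx(ref.beta)
            assert chi2[j] == pytest.approx(ref.chi2)
            assert i2[j] == pytest.approx(ref.i2)

    def test_single_group_member_i2_zero(self):
        beta = np.array([[0.1, 0.2], [np.nan, 0.1]])
        se = np.array([[0.05, 0.05], [np.nan, 0.05]])
        locus = _locus(beta, se)
        _, i2, _, _ = per_variant_meta_i2(locus)
        assert i2[0] == 0.0


class TestPrior:
    def test_homogeneous_uniform(self):
        prior = heterogeneity_prior(np.zeros(4))
        assert np.allclose(prior, 0.25)

    def test_hand_normalization(self):
        prior = heterogeneity_prior(np.array([0.0, 0.5]))
        assert prior == pytest.approx([2 / 3, 1 / 3])

    @given(st.lists(st.floats(0, 0.98), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one_and_monotone(self, i2s):
        prior = heterogeneity_prior(np.array(i2s))
        assert prior.sum() == pytest.approx(1.0)
        order = np.argsort(i2s)
        assert np.all(np.diff(prior[order]) <= 1e-12)

    def test_floor_keeps_heterogeneous_variants(self):
        prior = heterogeneity_prior(np.array([0.0, 1.0]), floor=0.01)
        assert prior[1] == pytest.approx(0.01 / 1.01)


class TestPosteriors:
    def test_uniform_prior_hand_values(self):
        locus = _locus([[1.0, 1.0]], [[1.0, 1.0]])
        ps = posterior_pips(locus, np.array([10.0, 5.0]),
                            np.array([0.5, 0.5]), "multi")
        assert ps.pip == pytest.approx([2 / 3, 1 / 3])

    def test_informative_prior_hand_values(self):
        locus = _locus([[1.0, 1.0]], [[1.0, 1.0]])
        ps = posterior_pips(locus, np.array([10.0, 5.0]),
                            np.array([0.8, 0.2]), "multi")
        assert ps.pip == pytest.approx([8 / 9, 1 / 9])

    def test_single_member_trivial(self):
        locus = _locus([[4.0]], [[1.0]])
        ps = posterior_pips(locus, np.array([16.0]), np.array([1.0]), "multi")
        assert ps.pip == pytest.approx([1.0])
        assert ps.credible_set == [0]

    def test_accumulation_rule_sizes(self):
        locus = _locus([np.ones(4)], [np.ones(4)])
        # weights proportional to the intended PIPs
        ps = posterior_pips(locus, np.array([0.6, 0.3, 0.08, 0.02]), None,
                            "single_ancestry")
        assert ps.credible_set_size == 4

    def test_accumulation_stops_at_coverage(self):
        locus = _locus([np.ones(3)], [np.ones(3)])
        ps = posterior_pips(locus, np.array([0.995, 0.004, 0.001]), None,
                            "single_ancestry")
        assert ps.credible_set_size == 1

    def test_all_zero_chi2_uniform(self):
        locus = _locus([np.ones(4)], [np.ones(4)])
        ps = posterior_pips(locus, np.zeros(4), None, "single_ancestry")
        assert ps.pip == pytest.approx([0.25] * 4)

    def test_pips_sum_to_one(self, rng):
        locus = _locus([np.ones(20)], [np.ones(20)])
        chi2 = rng.uniform(0, 30, 20)
        prior = heterogeneity_prior(rng.uniform(0, 1, 20))
        ps = posterior_pips(locus, chi2, prior, "multi")
        assert abs(ps.pip.sum() - 1.0) < 1e-9
        assert abs(ps.prior.sum() - 1.0) < 1e-9

    def test_one_group_multi_equals_single(self, rng):
        beta = rng.normal(0, 0.1, (1, 8))
        se = np.full((1, 8), 0.05)
        locus = _locus(beta, se)
        multi = finemap_locus(locus)
        single = finemap_locus_single(locus, locus.groups[0])
        np.testing.assert_allclose(multi.pip, single.pip, atol=1e-12)
        assert multi.credible_set == single.credible_set


class TestComparison:
    def test_identical_inputs_equal_sizes(self, rng):
        beta = rng.normal(0, 0.1, (1, 10))
        locus = _locus(beta, np.full((1, 10), 0.05))
        multi = finemap_locus(locus)
        single = finemap_locus_single(locus, locus.groups[0])
        cmp = credible_set_size_comparison(multi, single)
        assert cmp["multi_size"] == cmp["single_size"]
        assert not cmp["smaller_under_multi"]

    def test_summary_medians(self):
        comparisons = [
            {"multi_size": 2, "single_size": 5, "smaller_under_multi": True},
            {"multi_size": 4, "single_size": 4, "smaller_under_multi": False},
            {"multi_size": 1, "single_size": 9, "smaller_under_multi": True},
        ]
        s = summarize_set_sizes(comparisons)
        assert s["median_multi"] == 2 and s["median_single"] == 5
        assert s["fraction_smaller"] == pytest.approx(2 / 3)


class TestDentistS:
    def test_perfect_consistency(self):
        t, p = dentist_s(0.9 * 6.0, 6.0, 0.9)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_uncorrelated_reduces_to_z_squared(self):
        t, _ = dentist_s(2.0, 6.0, 0.0)
        assert t == pytest.approx(4.0)

    def test_inconsistent_variant_hand_value(self):
        t, p = dentist_s(1.0, 6.0, 0.9)
        assert t == pytest.approx((1 - 5.4) ** 2 / 0.19, rel=1e-9)
        assert t == pytest.approx(101.9, abs=0.1)
        assert p < 1e-4

    def test_perfect_ld_undefined(self):
        t, p = dentist_s(3.0, 3.0, 1.0)
        assert np.isnan(t)

    @given(z_i=st.floats(-8, 8), z_l=st.floats(-8, 8), r=st.floats(-0.99, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_sign_flip_invariance(self, z_i, z_l, r):
        t1, _ = dentist_s(z_i, z_l, r)
        t2, _ = dentist_s(-z_i, -z_l, r)
        t3, _ = dentist_s(z_i, -z_l, -r)
        assert t1 == pytest.approx(t2, rel=1e-9, abs=1e-12)
        assert t1 == pytest.approx(t3, rel=1e-9, abs=1e-12)


class TestSlalom:
    def _simulated_locus(self, seed, flip_index=None, beta=0.4):
        rng = np.random.default_rng(seed)
        ld = simulate_ld_matrix([21], [0.9])
        af = rng.uniform(0.2, 0.8, 21)
        anc = AncestryConfig("EUR", 10_000, 10_000, af, [(21, 0.9)])
        causal = CausalModel(np.array([10]), {"EUR": np.array([beta])})
        df = simulate_study(ld, causal, anc, rng)
        if flip_index is not None:
            df.loc[flip_index, "BETA"] *= -1
        locus = extract_locus("rs11", {"EUR": df}, ld)
        return ld, locus

    def test_low_pip_locus_not_applied(self):
        ld, locus = self._simulated_locus(0, beta=0.0)
        posterior = finemap_locus(locus)
        report = slalom_qc(locus, posterior, ld)
        if posterior.max_pip <= 0.1:
            assert not report.applied and report.robust

    def test_gate_forced_not_applied(self):
        ld, locus = self._simulated_locus(1)
        posterior = finemap_locus(locus)
        report = slalom_qc(locus, posterior, ld, pip_gate=1.1)
        assert not report.applied

    def test_consistent_locus_mostly_robust(self):
        robust = 0
        for seed in range(40):
            ld, locus = self._simulated_locus(seed)
            posterior = finemap_locus(locus)
            report = slalom_qc(locus, posterior, ld)
            assert report.applied
            robust += report.robust
        assert robust >= 38

    def test_planted_sign_flip_flagged(self):
        flagged = 0
        for seed in range(40):
            # flip a variant two steps from the causal site: r = 0.81,
            # r^2 ~= 0.66 > 0.6, expected |z| large
            ld, locus = self._simulated_locus(seed, flip_index=12)
            posterior = finemap_locus(locus)
            report = slalom_qc(locus, posterior, ld)
            mi = [v.id for v in locus.members].index("rs13")
            flagged += bool(report.outlier[mi])
        assert flagged >= 38
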