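"""Power-adjusted transferability: credible sets, thresholds, power, PAT."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from magwas.simulate import simulate_ld_matrix
from magwas.sumstats import Variant
from magwas.transfer import (
    PF_CONSTANTS,
    CredibleSetT,
    KnownLocus,
    TransferRecord,
    build_transfer_credible_set,
    call_nontransferable,
    call_transferable,
    estimate_penalization_factor,
    locus_power,
    pat_ratio,
    transfer_threshold,
)


def _frame(variants, p, beta=None, eaf=0.3):
    n = len(variants)
    return pd.DataFrame({
        "SNP": [v.id for v in variants],
        "CHR": [v.chrom for v in variants],
        "BP": [v.pos for v in variants],
        "EAF": eaf,
        "BETA": np.ones(n) * 0.1 if beta is None else beta,
        "SE": 0.02, "P": p,
    })


class TestCredibleSet:
    def _setup(self, rho=0.95, spacing=10_000):
        ld = simulate_ld_matrix([7], [rho], spacing_bp=spacing)
        lead = ld.variants[3]
        locus = KnownLocus(lead, beta_discovery=0.12, eaf_discovery=0.3,
                           p_discovery=1e-10)
        return ld, lead, locus

    def test_high_ld_near_neighbors_included(self):
        ld, lead, locus = self._setup()
        p = np.full(7, 1e-9)
        cs = build_transfer_credible_set(locus, _frame(ld.variants, p), ld)
        # lag-1 neighbours have r^2 = 0.9025, lag-2 r^2 = 0.8145 (both >= 0.8),
        # lag-3 r^2 = 0.735 falls below the threshold
        assert lead in cs.members
        assert cs.n == 5

    def test_low_ld_gives_singleton(self):
        ld, lead, locus = self._setup(rho=0.5)
        p = np.full(7, 1e-9)
        cs = build_transfer_credible_set(locus, _frame(ld.variants, p), ld)
        assert cs.n == 1

    def test_window_rule_excludes_distant_proxy(self):
        ld, lead, locus = self._setup(spacing=60_000)  # neighbours 60 kb away
        p = np.full(7, 1e-9)
        cs = build_transfer_credible_set(locus, _frame(ld.variants, p), ld)
        assert cs.n == 1

    def test_discovery_p_filter(self):
        ld, lead, locus = self._setup()
        p = np.full(7, 1e-9)
        p[2] = 5e-7  # > 100 x p_lead = 1e-8
        cs = build_transfer_credible_set(locus, _frame(ld.variants, p), ld)
        assert "rs3" not in [m.id for m in cs.members]
        assert cs.n == 4

    def test_lead_absent_from_panel_yields_singleton(self):
        ld, _, _ = self._setup()
        outside = KnownLocus(Variant("rsX", "1", 999, "A", "G"), 0.1, 0.3, 1e-9)
        cs = build_transfer_credible_set(outside, _frame(ld.variants, np.full(7, 0.5)), ld)
        assert cs.n == 1 and cs.lead.id == "rsX"


class TestThreshold:
    def test_singleton_threshold_is_alpha(self):
        for pf in (0.0, 0.003147, 0.123):
            assert transfer_threshold(1, pf) == pytest.approx(0.05)

    def test_printed_afr_slope_hand_value(self):
        assert transfer_threshold(11, PF_CONSTANTS["AFR"]) == pytest.approx(
            0.05 * 10 ** (-0.08341), rel=1e-6)
        assert transfer_threshold(11, PF_CONSTANTS["AFR"]) == pytest.approx(0.04126, abs=1e-4)

    def test_strictly_decreasing_in_set_size(self):
        th = [transfer_threshold(n, 0.007378) for n in range(1, 30)]
        assert all(a > b for a, b in zip(th, th[1:]))


class TestPenalizationFit:
    def _sets(self, sizes):
        out = []
        for i, n in enumerate(sizes):
            members = [Variant(f"l{i}m{j}", "1", 1000 + i * 100 + j, "A", "G")
                       for j in range(n)]
            out.append(CredibleSetT(members[0], members,
                                    np.full(n, 0.1), np.full(n, 1e-9)))
        return out

    def test_constant_response_gives_zero_slope(self):
        sets = self._sets([1, 2, 3, 5, 8, 1, 2, 3, 5, 8, 13, 21])
        rows = []
        for cs in sets:
            for m in cs.members:
                rows.append({"SNP": m.id, "P": 0.5})
        fit = estimate_penalization_factor(sets, pd.DataFrame(rows))
        assert fit.p_f == pytest.approx(0.0, abs=1e-12)

    def test_slope_matches_independent_regression_oracle(self):
        # null target p-values independent uniform; min over N members
        rng = np.random.default_rng(21)
        sizes = rng.integers(1, 25, size=400)
        sets = self._sets(sizes)
        rows = []
        for cs in sets:
            for m in cs.members:
                rows.append({"SNP": m.id, "P": rng.uniform()})
        tgt = pd.DataFrame(rows)
        fit = estimate_penalization_factor(sets, tgt)
        # oracle: same regression done directly on the raw data
        minp = [tgt.set_index("SNP").loc[[m.id for m in cs.members], "P"].min()
                for cs in sets]
        oracle = stats.linregress(sizes, -np.log10(minp))
        assert fit.p_f == pytest.approx(oracle.slope, rel=1e-9)
        assert fit.p_f > 0
        assert abs(fit.p_f - oracle.slope) < 2 * oracle.stderr + 1e-9

    def test_too_few_loci_rejected(self):
        sets = self._sets([1, 2, 3])
        with pytest.raises(ValueError):
            estimate_penalization_factor(sets, pd.DataFrame({"SNP": ["l0m0"], "P": [0.5]}))


class TestTransferCalls:
    def _cs(self, betas=(0.1, 0.1)):
        members = [Variant(f"m{j}", "1", 1000 + j * 10_000, "A", "G")
                   for j in range(len(betas))]
        return CredibleSetT(members[0], members, np.array(betas),
                            np.full(len(betas), 1e-9))

    def test_member_below_threshold_same_sign_transfers(self):
        cs = self._cs()
        target = _frame(cs.members, p=np.array([0.5, 0.03]), beta=np.array([0.0, 0.2]))
        flag, minp = call_transferable(cs, target, p_f=0.0)
        assert flag and minp == pytest.approx(0.03)

    def test_opposite_sign_does_not_transfer(self):
        cs = self._cs()
        target = _frame(cs.members, p=np.array([0.5, 0.03]), beta=np.array([0.0, -0.2]))
        flag, _ = call_transferable(cs, target, p_f=0.0)
        assert not flag

    def test_all_members_above_threshold(self):
        cs = self._cs()
        target = _frame(cs.members, p=np.array([0.2, 0.6]))
        assert not call_transferable(cs, target, p_f=0.0)[0]

    def test_no_member_in_target_unassessable(self):
        cs = self._cs()
        ghost = [Variant("x1", "1", 1, "A", "G")]
        flag, minp = call_transferable(cs, _frame(ghost, np.array([0.5])), p_f=0.0)
        assert not flag and math.isnan(minp)

    def test_penalization_tightens_call(self):
        betas = tuple([0.1] * 20)
        cs = self._cs(betas)
        p = np.full(20, 0.045)
        target = _frame(cs.members, p=p, beta=np.full(20, 0.1))
        assert call_transferable(cs, target, p_f=0.0)[0]
        assert not call_transferable(cs, target, p_f=0.008341)[0]


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        assert locus_power(0.0, 0.3, 5000, 5000) == pytest.approx(0.05, abs=1e-9)

    def test_power_against_allele_count_wald_oracle(self):
        # independent oracle: simulate case/control allele counts under the
        # logistic model and apply a Wald test on the log odds ratio
        beta, f, n = 0.15, 0.3, 5000
        rng = np.random.default_rng(3)
        n_rep = 20_000
        f_case = f * math.exp(beta) / (1 - f + f * math.exp(beta))
        ca = rng.binomial(2 * n, f_case, n_rep)
        co = rng.binomial(2 * n, f, n_rep)
        log_or = (np.log(ca / (2 * n - ca)) - np.log(co / (2 * n - co)))
        se = np.sqrt(1 / ca + 1 / (2 * n - ca) + 1 / co + 1 / (2 * n - co))
        mc_power = np.mean((log_or / se) ** 2 > stats.chi2.ppf(0.95, 1))
        analytic = locus_power(beta, f, n, n)
        assert analytic == pytest.approx(0.998, abs=0.002)
        assert abs(analytic - mc_power) < 0.005

    def test_monotone_in_effect_samples_and_frequency(self):
        base = locus_power(0.1, 0.2, 2000, 2000)
        assert locus_power(0.2, 0.2, 2000, 2000) > base
        assert locus_power(0.1, 0.2, 4000, 4000) > base
        assert locus_power(0.1, 0.4, 2000, 2000) > base

    def test_degenerate_frequency_zero_power(self):
        assert locus_power(0.5, 0.0, 1000, 1000) == 0.0


class TestNontransferable:
    def _cs(self, n=3):
        members = [Variant(f"m{j}", "1", 1_000_000 + j * 10_000, "A", "G")
                   for j in range(n)]
        return CredibleSetT(members[0], members, np.full(n, 0.1), np.full(n, 1e-9))

    def _target(self, cs, member_p, neighbor_p):
        near = Variant("nb", "1", cs.lead.pos + 40_000, "A", "G")
        variants = cs.members + [near]
        p = np.concatenate([member_p, [neighbor_p]])
        return _frame(variants, p)

    def test_neighbor_signal_blocks_call(self):
        cs = self._cs()
        target = self._target(cs, np.full(3, 0.2), neighbor_p=0.01 * 1e-2)
        assert not call_nontransferable(cs, target, [0.9, 0.2, 0.1])

    def test_well_powered_silent_locus_called(self):
        cs = self._cs()
        target = self._target(cs, np.full(3, 0.2), neighbor_p=0.002)
        assert call_nontransferable(cs, target, [0.9, 0.2, 0.1])

    def test_underpowered_locus_never_called(self):
        cs = self._cs()
        target = self._target(cs, np.full(3, 0.9), neighbor_p=0.9)
        assert not call_nontransferable(cs, target, [0.5, 0.2, 0.1])

    def test_member_signal_blocks_call(self):
        cs = self._cs()
        target = self._target(cs, np.array([0.2, 0.04, 0.3]), neighbor_p=0.5)
        assert not call_nontransferable(cs, target, [0.95, 0.2, 0.1])


class TestPATRatio:
    def _records(self, flags, powers):
        return [TransferRecord(f"l{i}", 1, p, 0.5, f, False)
                for i, (f, p) in enumerate(zip(flags, powers))]

    def test_all_transferable_full_power(self):
        res = pat_ratio(self._records([True] * 10, [1.0] * 10), seed=0)
        assert res.ratio == pytest.approx(1.0)
        assert (res.ci_low, res.ci_high) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_arithmetic(self):
        flags = [True] * 10 + [False] * 30
        res = pat_ratio(self._records(flags, [1.0] * 40), seed=0)
        assert res.observed == 10
        assert res.expected == pytest.approx(40.0)
        assert res.ratio == pytest.approx(0.25)

    def test_ci_contains_point_estimate(self, rng):
        flags = rng.random(50) < 0.4
        powers = rng.uniform(0.3, 1.0, 50)
        res = pat_ratio(self._records(flags, powers), seed=1)
        assert res.ci_low <= res.ratio <= res.ci_high

    def test_order_invariance(self, rng):
        flags = list(rng.random(30) < 0.5)
        powers = list(rng.uniform(0.2, 1.0, 30))
        a = pat_ratio(self._records(flags, powers), seed=3)
        b = pat_ratio(self._records(flags[::-1], powers[::-1]), seed=3)
        assert a.ratio == pytest.approx(b.ratio)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            pat_ratio(self._records([False], [0.0]))

    def test_unassessable_loci_excluded_from_both_sums(self):
        recs = self._records([True, False], [1.0, 1.0])
        recs.append(TransferRecord("ghost", 1, 0.0, math.nan, False, False,
                                   assessable=False))
        res = pat_ratio(recs, seed=0)
        assert res.expected == pytest.approx(2.0)
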