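"""Potential impact fraction: categorical, single, independent, general."""

import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from pifdpp import (
    CategoricalExposure,
    Stratum,
    TreatmentEffect,
    delta_dpp_combination,
    delta_dpp_from_pif,
    from_independent,
    from_joint_table,
    marginal_risk,
    mortality_reduction,
    percent_difference,
    pif_categorical,
    pif_general,
    pif_independent,
    pif_single,
    random_scenario,
    stratified_delta_dpp,
)

probs = st.floats(0, 1)


class TestCategorical:
    def test_no_shift_no_impact(self):
        e = CategoricalExposure(p=(0.5, 0.3, 0.2), p_prime=(0.5, 0.3, 0.2), rr=(1, 2, 4))
        assert pif_categorical(e) == 0.0

    def test_three_level_arithmetic(self):
        e = CategoricalExposure(p=(0.5, 0.3, 0.2), p_prime=(0.7, 0.2, 0.1), rr=(1, 2, 4))
        assert pif_categorical(e) == pytest.approx((1.9 - 1.5) / 1.9, abs=1e-12)

    @given(u_b=st.floats(0, 0.99), u_t=probs, rr=st.floats(0.01, 1))
    def test_two_level_protective_collapses_to_single(self, u_b, u_t, rr):
        """The binary protective-exposure substitution into the categorical
        formula yields the single-treatment PIF."""
        e = CategoricalExposure(p=(1 - u_b, u_b), p_prime=(1 - u_t, u_t), rr=(1.0, rr))
        assert pif_categorical(e) == pytest.approx(pif_single(u_b, u_t, rr), abs=1e-12)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            CategoricalExposure(p=(0.6, 0.6), p_prime=(0.5, 0.5), rr=(1, 2))
        with pytest.raises(ValueError, match="reference"):
            CategoricalExposure(p=(0.5, 0.5), p_prime=(0.5, 0.5), rr=(2, 1))


class TestSingle:
    def test_zero_baseline_reduces_to_attributable_form(self):
        assert pif_single(0.0, 0.7, 0.8) == pytest.approx(0.7 * 0.2)

    def test_no_change_no_impact(self):
        assert pif_single(0.4, 0.4, 0.8) == 0.0

    def test_worked_value(self):
        assert pif_single(0.5, 0.9, 0.8) == pytest.approx(0.08 / 0.9, abs=1e-12)

    @given(u_b=st.floats(0, 0.95), u_t=probs, rr=st.floats(0.01, 1), cf=st.floats(0.01, 1))
    def test_cf_cancels_from_weighted_risk_ratio(self, u_b, u_t, rr, cf):
        """Oracle: PIF is the proportional drop in marginal risk cf*(1-u*RRR),
        for any cf -- the fatality rate cancels."""
        rrr = 1 - rr
        risk_b = cf * (1 - u_b * rrr)
        risk_t = cf * (1 - u_t * rrr)
        assert pif_single(u_b, u_t, rr) == pytest.approx((risk_b - risk_t) / risk_b, abs=1e-12)

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError, match="undefined"):
            pif_single(1.0, 1.0, 0.0)

    @given(u_b=st.floats(0, 0.9), rr=st.floats(0.01, 0.99))
    def test_monotone_in_target_uptake(self, u_b, rr):
        vals = [pif_single(u_b, u_t, rr) for u_t in (0.2, 0.5, 0.8)]
        assert vals == sorted(vals)

    @given(u_b=st.floats(0, 0.9), u_t=probs)
    def test_monotone_decreasing_in_rr(self, u_b, u_t):
        assume(u_t > u_b)
        vals = [pif_single(u_b, u_t, rr) for rr in (0.9, 0.5, 0.1)]
        assert vals == sorted(vals)


class TestIndependent:
    def test_worked_example_value(self, worked_example):
        tr = [TreatmentEffect.from_rrr(f"t{i}", r) for i, r in enumerate(worked_example["rrr"])]
        got = pif_independent(worked_example["u_b"], worked_example["u_t"], tr)
        assert got == pytest.approx(0.04258, abs=5e-6)

    @given(u_b=st.floats(0, 0.95), u_t=probs, rr=st.floats(0.01, 1))
    def test_k1_reduces_to_single(self, u_b, u_t, rr):
        assert pif_independent([u_b], [u_t], [rr]) == pytest.approx(
            pif_single(u_b, u_t, rr), abs=1e-12
        )

    def test_no_shift_no_impact(self):
        assert pif_independent((0.5, 0.6), (0.5, 0.6), (0.93, 0.9)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            pif_independent((0.5,), (0.8, 0.8), (0.93, 0.9))

    @given(
        u_b=st.lists(st.floats(0, 0.9), min_size=2, max_size=4),
        bump=st.lists(st.floats(0, 1), min_size=4, max_size=4),
        rr=st.lists(st.floats(0.05, 0.95), min_size=4, max_size=4),
    )
    def test_range_and_sign(self, u_b, bump, rr):
        """PIF <= 1 always; PIF >= 0 when every target uptake >= baseline."""
        k = len(u_b)
        u_b = np.array(u_b)
        u_t = u_b + (1 - u_b) * np.array(bump[:k])
        val = pif_independent(u_b, u_t, rr[:k])
        assert -1e-12 <= val <= 1 + 1e-12

    def test_monotone_in_each_target_marginal(self):
        base = pif_independent((0.4, 0.4), (0.5, 0.5), (0.9, 0.8))
        assert pif_independent((0.4, 0.4), (0.7, 0.5), (0.9, 0.8)) > base
        assert pif_independent((0.4, 0.4), (0.5, 0.7), (0.9, 0.8)) > base


class TestGeneral:
    def test_comonotone_two_term_example(self):
        b = from_joint_table({"00": 0.5, "11": 0.5})
        t = from_joint_table({"00": 0.2, "11": 0.8})
        got = pif_general(b, t, (0.9, 0.8))
        assert got == pytest.approx((0.86 - 0.776) / 0.86, abs=1e-12)

    def test_same_table_no_impact(self):
        d = from_joint_table({"00": 0.5, "11": 0.5})
        assert pif_general(d, d, (0.9, 0.8)) == 0.0

    def test_reproduces_independent_form(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 5))
            u_b = rng.uniform(0, 0.95, size=k)
            u_t = rng.uniform(0, 1, size=k)
            rr = rng.uniform(0.05, 1, size=k)
            got = pif_general(from_independent(u_b), from_independent(u_t), rr)
            assert got == pytest.approx(pif_independent(u_b, u_t, rr), abs=1e-12)

    def test_cf_invariance(self, rng):
        """The defining advantage: PIF never consumes a fatality rate, and the
        classic-method ratio dDPP/(N*cf*PGF_b) agrees with it for every cf."""
        sc = random_scenario(7, k_max=3)
        p = pif_general(sc.baseline, sc.target, sc.treatments)
        for cf in (0.05, 0.2, 0.8):
            d = sc.strata[0].n * marginal_risk(cf, sc.treatments, sc.baseline)
            classic = delta_dpp_combination(
                cf, sc.treatments, sc.baseline, sc.target, sc.strata[0].n
            )
            assert classic / d == pytest.approx(p, abs=1e-12)

    def test_degenerate_baseline_rejected(self):
        b = from_joint_table({"1": 1.0})
        t = from_joint_table({"0": 1.0})
        with pytest.raises(ValueError, match="undefined"):
            pif_general(b, t, [0.0])


class TestDppConversion:
    def test_worked_example(self):
        assert delta_dpp_from_pif(0.04258, 750) == pytest.approx(31.935)

    def test_no_deaths_no_dpp(self):
        assert delta_dpp_from_pif(0.5, 0) == 0.0

    def test_full_pif_prevents_all_deaths(self):
        assert delta_dpp_from_pif(1.0, 321) == 321.0

    def test_negative_deaths_rejected(self):
        with pytest.raises(ValueError):
            delta_dpp_from_pif(0.1, -1)


class TestStratified:
    def _dists(self):
        return from_independent((0.5, 0.6)), from_independent((0.8, 0.8))

    def test_single_stratum_equals_scalar_form(self):
        b, t = self._dists()
        tr = (TreatmentEffect.from_rrr("a", 0.07), TreatmentEffect.from_rrr("b", 0.1))
        total, rows = stratified_delta_dpp(
            [Stratum(label="all", n=2500, deaths=750)], treatments=tr, baseline=b, target=t
        )
        assert total == pytest.approx(delta_dpp_from_pif(rows[0].pif, 750), abs=1e-12)

    def test_linearity_for_equal_pif(self):
        b, t = self._dists()
        tr = ((TreatmentEffect.from_rrr("a", 0.07)), TreatmentEffect.from_rrr("b", 0.1))
        strata = [
            Stratum(label="x", n=1000, deaths=100),
            Stratum(label="y", n=3000, deaths=250),
        ]
        total, rows = stratified_delta_dpp(strata, treatments=tr, baseline=b, target=t)
        assert rows[0].pif == pytest.approx(rows[1].pif)
        assert total == pytest.approx(rows[0].pif * 350, abs=1e-12)

    def test_three_strata_hand_sum_with_overrides(self):
        b, t = self._dists()
        tr = (TreatmentEffect.from_rrr("a", 0.07), TreatmentEffect.from_rrr("b", 0.1))
        strata = [
            Stratum(label="s1", n=1000, deaths=100),
            Stratum(label="s2", n=1000, deaths=200, baseline=from_independent((0.2, 0.3))),
            Stratum(label="s3", n=1000, deaths=50, target=from_independent((1.0, 1.0))),
        ]
        total, rows = stratified_delta_dpp(strata, treatments=tr, baseline=b, target=t)
        assert total == pytest.approx(sum(r.pif * r.deaths for r in rows), abs=1e-12)
        assert rows[1].pif != pytest.approx(rows[0].pif)

    def test_empty_strata_rejected(self):
        with pytest.raises(ValueError, match="stratum"):
            stratified_delta_dpp([])


class TestReporting:
    def test_mortality_reduction_examples(self):
        assert mortality_reduction(31.93, 750) == pytest.approx(4.2573, abs=1e-3)
        assert mortality_reduction(0, 750) == 0.0
        assert mortality_reduction(750, 750) == 100.0
        with pytest.raises(ValueError):
            mortality_reduction(1.0, 0)

    def test_percent_difference_convention(self):
        assert percent_difference(7.16, 8.29) == pytest.approx(15.78, abs=5e-3)
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)


class TestMethodComparison:
    @given(u_b=st.floats(0.05, 0.95), u_t=probs, rrr=st.floats(0.01, 0.99), cf=st.floats(0.05, 0.9))
    def test_classic_underestimates_with_observed_rate(self, u_b, u_t, rrr, cf):
        """With cf estimated from baseline deaths, classic dDPP <= PIF dDPP
        whenever baseline uptake > 0 and rrr in (0, 1)."""
        assume(u_t > u_b)
        n = 10_000
        rr = 1 - rrr
        d = n * cf * (1 - u_b * rrr)  # observed deaths under baseline
        classic_biased = (d / n) * (u_t - u_b) * rrr * n
        pif_based = pif_single(u_b, u_t, rr) * d
        assert classic_biased <= pif_based + 1e-9

    def test_equivalence_under_true_cf(self, rng):
        """dDPP via PIF*d with d = N*cf*PGF_b equals the classic dDPP computed
        with the true cf (the exact-equivalence identity)."""
        for seed in range(30):
            sc = random_scenario(seed, k_max=4)
            st_ = sc.strata[0]
            cf = st_.cf
            d = st_.n * marginal_risk(cf, sc.treatments, sc.baseline)
            via_pif = pif_general(sc.baseline, sc.target, sc.treatments) * d
            classic = delta_dpp_combination(cf, sc.treatments, sc.baseline, sc.target, st_.n)
            assert math.isclose(via_pif, classic, rel_tol=1e-12, abs_tol=1e-10)
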