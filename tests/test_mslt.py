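"""Multi-state life table: PIF quadrature, cohort recursion, DALYs, costs."""

import math

import numpy as np
import pytest

from ssbtax.bmi import fit_lognormal
from ssbtax.mslt import (
    DiseaseEpi,
    EconParams,
    LifeTableTrace,
    RRSchedule,
    costs_saved,
    dalys_averted,
    discount,
    life_table_matrix,
    pif,
    pif_vec,
    run_life_table,
)


class TestPIF:
    def test_no_shift_is_zero(self):
        d = fit_lognormal(27.0, 4.5)
        assert pif(1.1, d, d) == 0.0

    def test_unit_rr_is_zero(self):
        pre = fit_lognormal(27.0, 4.5)
        post = pre.shift(-0.5)
        assert pif(1.0, pre, post) == 0.0

    @pytest.mark.parametrize("method", ["fixed", "quad"])
    def test_point_mass_closed_form(self, method):
        """Degenerate distributions at 30 -> 29, rr 1.1: PIF = 1 - 1/1.1."""
        pre = fit_lognormal(30.0, 0.0)
        post = fit_lognormal(29.0, 0.0)
        assert pif(1.1, pre, post, method=method) == pytest.approx(
            1.0 - 1.0 / 1.1, abs=1e-12
        )

    def test_narrow_distribution_approaches_point_mass(self):
        """Quadrature PIF with sd=0.01 matches the closed form to 1e-6."""
        pre = fit_lognormal(30.0, 0.01)
        post = fit_lognormal(29.0, 0.01)
        assert pif(1.1, pre, post, method="quad") == pytest.approx(
            1.0 - 1.0 / 1.1, abs=1e-6
        )

    def test_fixed_rule_matches_adaptive_quadrature(self):
        pre = fit_lognormal(27.3, 4.4)
        post = pre.shift(-0.21)
        assert pif(1.19, pre, post, method="fixed") == pytest.approx(
            pif(1.19, pre, post, method="quad"), abs=1e-10
        )

    def test_invariant_to_reference_bmi(self):
        pre = fit_lognormal(27.0, 4.5)
        post = pre.shift(-0.189)
        vals = [
            pif_vec(
                np.array([1.18]),
                np.array([pre.mu]),
                np.array([pre.sigma]),
                np.array([post.mu]),
                np.array([post.sigma]),
                x_ref=x_ref,
            )[0]
            for x_ref in (0.0, 20.0, 25.0)
        ]
        assert max(vals) - min(vals) < 1e-8

    def test_monotone_in_shift_size(self):
        pre = fit_lognormal(27.0, 4.5)
        small = pif(1.18, pre, pre.shift(-0.1))
        large = pif(1.18, pre, pre.shift(-0.3))
        assert 0 < small < large < 1

    def test_risk_increase_gives_negative_pif(self):
        pre = fit_lognormal(27.0, 4.5)
        assert pif(1.18, pre, pre.shift(+0.2)) < 0


class TestLifeTable:
    def test_zero_pif_matches_base(self):
        inc = np.full(80, 0.01)
        acm = np.full(80, 0.02)
        exc = np.full(80, 0.05)
        a = run_life_table(1000.0, 0.05, 30, inc, acm, exc, pif_value=0.0)
        b = run_life_table(1000.0, 0.05, 30, inc, acm, exc, pif_value=0.0)
        np.testing.assert_array_equal(a.alive_without, b.alive_without)
        np.testing.assert_array_equal(a.alive_with, b.alive_with)

    def test_immortal_cohort_life_years(self):
        """No mortality, no disease: 1000 persons aged 20 live 80,000 years."""
        zeros = np.zeros(80)
        tr = run_life_table(1000.0, 0.0, 20, zeros, zeros, zeros)
        assert tr.life_years == pytest.approx(80_000.0, abs=1e-9)

    def test_three_cycle_hand_unrolled_recursion(self):
        """Constant rates i=0.01, m=0.02, excess=0.05: match hand arithmetic."""
        i, m, e = 0.01, 0.02, 0.05
        pop, prev0 = 1000.0, 0.10
        s, c = pop * (1 - prev0), pop * prev0
        expected_s, expected_c = [], []
        for _ in range(3):
            expected_s.append(s)
            expected_c.append(c)
            exits = s * (1 - math.exp(-(i + m)))
            new_cases = exits * i / (i + m)
            deaths_c = c * (1 - math.exp(-(m + e)))
            s = s - exits
            c = c - deaths_c + new_cases
        tr = run_life_table(
            pop, prev0, 97, np.full(80, i), np.full(80, m), np.full(80, e)
        )
        np.testing.assert_allclose(tr.alive_without, expected_s, atol=1e-12)
        np.testing.assert_allclose(tr.alive_with, expected_c, atol=1e-12)

    def test_constant_rate_survivorship_closed_form(self):
        """Disease-free survivorship equals exp(-(i+m)t) under constant rates."""
        i, m = 0.008, 0.015
        tr = run_life_table(
            1.0, 0.0, 20, np.full(80, i), np.full(80, m), np.zeros(80)
        )
        t = np.arange(80)
        np.testing.assert_allclose(
            tr.alive_without, np.exp(-(i + m) * t), rtol=0, atol=1e-10
        )

    def test_person_conservation_each_cycle(self, engine):
        """Every cohort conserves persons across the 3-state split, all cycles."""
        # conservation is asserted inside life_table_matrix at 1e-9 relative;
        # run both the base case and a strong intervention through it
        engine.base_traces
        inter = life_table_matrix(
            engine.pop,
            engine.prev0,
            engine.entry_col,
            engine.haz_inc,
            engine.haz_acm,
            engine.haz_exc,
            np.full(engine.n, 0.3),
            check_conservation=True,
        )
        assert np.all(inter["S"] >= 0) and np.all(inter["C"] >= 0)

    def test_negative_rates_rejected(self):
        bad = np.full(80, -0.01)
        with pytest.raises(ValueError, match="hazards"):
            run_life_table(1000.0, 0.0, 20, bad, np.zeros(80), np.zeros(80))

    def test_intervention_reduces_incidence(self):
        inc = np.full(80, 0.01)
        acm = np.full(80, 0.02)
        exc = np.full(80, 0.05)
        base = run_life_table(1000.0, 0.05, 40, inc, acm, exc, pif_value=0.0)
        inter = run_life_table(1000.0, 0.05, 40, inc, acm, exc, pif_value=0.25)
        assert inter.incident.sum() < base.incident.sum()
        assert inter.prevalent_years < base.prevalent_years
        assert inter.life_years > base.life_years  # less excess mortality


class TestDiscount:
    def test_reference_values(self):
        assert discount(np.array([100.0]), 0.0) == 100.0
        assert discount(np.array([0.0, 100.0]), 0.03) == pytest.approx(100 / 1.03)
        assert discount(np.array([100.0]), 0.03) == 100.0

    def test_zero_rate_is_plain_sum(self):
        v = np.array([1.0, 2.0, 3.0])
        assert discount(v, 0.0) == pytest.approx(6.0)

    def test_discounted_not_above_undiscounted(self):
        v = np.abs(np.sin(np.arange(50)))
        assert discount(v, 0.03) <= v.sum()


def _toy_trace(entry_age, alive_without, alive_with):
    aw = np.asarray(alive_without, dtype=float)
    return LifeTableTrace(
        entry_age=entry_age,
        ages=np.arange(entry_age, entry_age + len(aw)),
        alive_without=aw,
        alive_with=np.asarray(alive_with, dtype=float),
        incident=np.zeros_like(aw),
    )


class TestValuation:
    def test_identical_traces_are_zero(self):
        tr = _toy_trace(50, [900.0, 850.0], [100.0, 110.0])
        assert dalys_averted(tr, tr, np.zeros(2), 0.05) == 0.0
        assert costs_saved(tr, tr, EconParams(4900.0, 2500.0)) == 0.0

    def test_dalys_reduce_to_life_years(self):
        """With dw = 0 and no background pYLD, DALYs = discounted LY gained."""
        base = _toy_trace(50, [900.0, 800.0], [0.0, 0.0])
        inter = _toy_trace(50, [950.0, 900.0], [0.0, 0.0])
        out = dalys_averted(base, inter, np.zeros(2), 0.0, discount_rate=0.03)
        assert out == pytest.approx(50.0 + 100.0 / 1.03)

    def test_one_cycle_prevalence_toy(self):
        """100 fewer prevalent person-years at dw 0.05 in year 0: 5 DALYs."""
        base = _toy_trace(60, [900.0], [100.0])
        inter = _toy_trace(60, [1000.0], [0.0])
        assert dalys_averted(base, inter, np.zeros(1), 0.05, 0.03) == pytest.approx(5.0)

    def test_one_cycle_cost_toy(self):
        """1000 fewer prevalent years at excess cost 3000/year: 3M saved."""
        base = _toy_trace(60, [0.0], [1000.0])
        inter = _toy_trace(60, [1000.0], [0.0])
        econ = EconParams(cost_with_t2dm=5000.0, cost_without_t2dm=2000.0)
        assert costs_saved(base, inter, econ) == pytest.approx(3_000_000.0)

    def test_equal_costs_sign_of_survival(self):
        """cost_with == cost_without: extra survivors cost money (negative)."""
        base = _toy_trace(60, [1000.0], [0.0])
        inter = _toy_trace(60, [1100.0], [0.0])
        econ = EconParams(cost_with_t2dm=3000.0, cost_without_t2dm=3000.0)
        assert costs_saved(base, inter, econ) == pytest.approx(-100.0 * 3000.0)

    def test_mismatched_traces_rejected(self):
        a = _toy_trace(60, [1.0], [0.0])
        b = _toy_trace(61, [1.0], [0.0])
        with pytest.raises(ValueError):
            dalys_averted(a, b, np.zeros(1), 0.05)


class TestInputTypes:
    def test_rr_schedule_lookup(self):
        rr = RRSchedule(age_breaks=(20, 40, 60, 80), rr_per_bmi_unit=(1.3, 1.2, 1.1, 1.05))
        assert rr.rr_at(25) == 1.3
        assert rr.rr_at(40) == 1.2
        assert rr.rr_at(95) == 1.05  # constant above the oldest group

    def test_rr_schedule_validation(self):
        with pytest.raises(ValueError):
            RRSchedule(age_breaks=(20, 40), rr_per_bmi_unit=(1.2,))
        with pytest.raises(ValueError):
            RRSchedule(age_breaks=(20, 40), rr_per_bmi_unit=(1.2, -0.5))

    def test_epi_rejects_incomplete_ages(self, epi):
        df = epi.table[epi.table.age != 50]
        with pytest.raises(ValueError, match="single ages"):
            DiseaseEpi(table=df)

    def test_econ_validation(self):
        with pytest.raises(ValueError):
            EconParams(-1.0, 0.0)
        with pytest.raises(ValueError):
            EconParams(100.0, 50.0, discount_rate=-0.01)
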