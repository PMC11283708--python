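"""Demand response: price change, elasticity application, adjustments, presets."""

import numpy as np
import pytest
from helpers import make_stratum
from hypothesis import given
from hypothesis import strategies as st

from ssbtax.demand import (
    ElasticitySet,
    ScenarioConfig,
    TaxPolicy,
    adjust_cross_pe,
    adjust_own_pe,
    apply_underreporting,
    consumption_change,
    effective_price_change,
    scenario_volume_changes,
    solve_gamma,
)


class TestPriceChange:
    @pytest.mark.parametrize(
        "rate,pt,expected",
        [(0.20, 0.82, 0.164), (0.0, 0.82, 0.0), (0.30, 0.82, 0.246)],
    )
    def test_effective_price_change(self, rate, pt, expected):
        policy = TaxPolicy(rate=rate, pass_through=pt)
        assert effective_price_change(policy) == pytest.approx(expected, abs=1e-12)

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            TaxPolicy(rate=1.5)
        with pytest.raises(ValueError):
            TaxPolicy(rate=0.2, pass_through=-0.1)
        with pytest.raises(ValueError):
            TaxPolicy(rate=0.2, taxed_categories=frozenset({"fruit_juice"}))
        with pytest.raises(ValueError):
            TaxPolicy(rate=0.2, taxed_categories=frozenset({"ssb", "milk"}))


class TestConsumptionChange:
    def test_alternative_meta_relative_change(self):
        """A 20% tax at 82% pass-through with own-PE 0.674 cuts SSBs 11.05%."""
        delta = consumption_change(100.0, -0.674, 0.164)
        assert round(delta / 100.0 * 100, 2) == -11.05

    def test_zero_price_change(self):
        assert consumption_change(250.0, -1.299, 0.0) == 0.0

    def test_marginal_volume_change(self):
        assert consumption_change(300.0, -1.299, 0.164) == pytest.approx(-63.9108)

    def test_clamped_at_zero_consumption(self, caplog):
        delta = consumption_change(100.0, -9.0, 0.8)
        assert delta == -100.0

    @given(
        baseline=st.floats(0.0, 1000.0),
        pe=st.floats(-2.0, 0.0),
        dp=st.floats(0.0, 0.3),
        k=st.floats(0.1, 3.0),
    )
    def test_linearity(self, baseline, pe, dp, k):
        base = consumption_change(baseline, pe, dp, clamp=False)
        assert consumption_change(k * baseline, pe, dp, clamp=False) == pytest.approx(
            k * base, rel=1e-12, abs=1e-12
        )
        assert consumption_change(baseline, k * pe, dp, clamp=False) == pytest.approx(
            k * base, rel=1e-12, abs=1e-12
        )
        assert consumption_change(baseline, pe, k * dp, clamp=False) == pytest.approx(
            k * base, rel=1e-12, abs=1e-12
        )


class TestOwnPEAdjustment:
    def test_reference_ratios(self):
        # thetas [2, 4, 8, 2] have mean 4: ratios 2, 1, 0.5, 2
        out = adjust_own_pe([2.0, 4.0, 8.0, 2.0], -1.299, 0.5)
        assert out[1] == pytest.approx(-0.6495)  # theta == mean, halved
        assert out[2] == pytest.approx(-0.32475)  # double the mean
        assert out[0] == pytest.approx(-1.299)  # half the mean

    def test_zero_intake_names_stratum(self):
        with pytest.raises(ValueError, match="male 40-44"):
            adjust_own_pe(
                [300.0, 0.0], -1.299, 0.5, labels=["male 20-24", "male 40-44"]
            )

    @given(
        theta=st.lists(st.floats(10.0, 600.0), min_size=3, max_size=16),
    )
    def test_magnitude_decreases_with_consumption(self, theta):
        """|adjusted own-PE| is strictly smaller for heavier consumers."""
        theta = np.asarray(theta)
        out = adjust_own_pe(theta, -1.299, 0.5)
        order = np.argsort(theta)
        sorted_theta = theta[order]
        sorted_abs = np.abs(out[order])
        distinct = np.diff(sorted_theta) > 1e-9
        assert np.all(np.diff(sorted_abs)[distinct] < 0)

    @given(
        theta=st.lists(st.floats(10.0, 600.0), min_size=2, max_size=16),
        weighted=st.booleans(),
    )
    def test_solved_gamma_recovers_mean(self, theta, weighted):
        """With solved gamma the mean adjusted elasticity equals the input."""
        weights = np.linspace(1.0, 2.0, len(theta)) if weighted else None
        gamma = solve_gamma(theta, weights=weights)
        adjusted = adjust_own_pe(theta, -1.299, gamma, weights=weights)
        mean = np.average(adjusted, weights=weights)
        assert mean == pytest.approx(-1.299, abs=1e-12)

    def test_constant_consumption_gamma_is_one(self):
        assert solve_gamma([250.0, 250.0, 250.0]) == pytest.approx(1.0, abs=1e-14)


class TestCrossPEAdjustment:
    def test_reference_ratios(self):
        out = adjust_cross_pe([2.0, 4.0, 8.0, 0.0], 0.388)
        mean = 3.5
        assert out[1] == pytest.approx(0.388 * 4.0 / mean)
        assert out[3] == 0.0  # no SSB consumption, no substitution pull

    def test_at_mean_unchanged(self):
        out = adjust_cross_pe([300.0, 300.0], 0.388)
        np.testing.assert_allclose(out, 0.388)

    def test_double_mean_doubles(self):
        out = adjust_cross_pe([100.0, 300.0], 0.388)  # mean 200
        assert out[1] == pytest.approx(0.388 * 1.5)

    @given(theta=st.lists(st.floats(0.0, 600.0), min_size=2, max_size=16))
    def test_increases_with_consumption(self, theta):
        theta = np.asarray(theta)
        if theta.mean() <= 0:
            return
        out = adjust_cross_pe(theta, 0.388)
        order = np.argsort(theta)
        distinct = np.diff(theta[order]) > 1e-9
        assert np.all(np.diff(out[order])[distinct] > 0)


class TestUnderreporting:
    def test_scales_mean_and_se(self):
        s = make_stratum(ssb=400.0)
        out = apply_underreporting(s, 1.86)
        assert out.intake_ml_day["ssb"].mean == pytest.approx(744.0)
        assert out.intake_ml_day["ssb"].se == pytest.approx(400.0 * 0.07 * 1.86)
        # other categories and energy untouched
        assert out.intake_ml_day["fruit_juice"] == s.intake_ml_day["fruit_juice"]
        assert out.energy_kcal_day == s.energy_kcal_day

    def test_identity_factor(self):
        s = make_stratum()
        out = apply_underreporting(s, 1.0)
        assert out.intake_ml_day["ssb"] == s.intake_ml_day["ssb"]

    def test_absolute_change_scales_relative_unchanged(self):
        """Under marginal own-PE the volume change scales by the factor."""
        s = make_stratum(ssb=400.0)
        cfg_kw = dict(policy=TaxPolicy(rate=0.2))
        plain = ScenarioConfig(name="main", **cfg_kw)
        inflated = ScenarioConfig(name="M3", underreporting_factor=1.86, **cfg_kw)
        e = ElasticitySet()
        d0 = scenario_volume_changes(plain, s, e)["ssb"]
        d1 = scenario_volume_changes(inflated, s, e)["ssb"]
        assert d1 == pytest.approx(1.86 * d0, rel=1e-12)
        assert d1 / (400.0 * 1.86) == pytest.approx(d0 / 400.0, rel=1e-12)


class TestScenarioVolumeChanges:
    def test_no_substitution(self):
        cfg = ScenarioConfig(name="main", policy=TaxPolicy(rate=0.2))
        out = scenario_volume_changes(cfg, make_stratum(), ElasticitySet())
        assert out["fruit_juice"] == 0.0 and out["milk"] == 0.0
        assert out["ssb"] == pytest.approx(-1.299 * 0.164 * 300.0)

    def test_cross_pe_substitution(self):
        cfg = ScenarioConfig(
            name="M4a", policy=TaxPolicy(rate=0.2), substitution_mode="cross_pe"
        )
        out = scenario_volume_changes(cfg, make_stratum(juice=200.0), ElasticitySet())
        assert out["fruit_juice"] == pytest.approx(12.73, abs=0.005)
        assert out["milk"] == pytest.approx(0.129 * 0.164 * 150.0)

    def test_juice_taxed_with_ssb_own_pe(self):
        cfg = ScenarioConfig(
            name="S3",
            policy=TaxPolicy(rate=0.2, taxed_categories=frozenset({"ssb", "fruit_juice"})),
        )
        out = scenario_volume_changes(cfg, make_stratum(juice=200.0), ElasticitySet())
        assert out["fruit_juice"] == pytest.approx(-42.61, abs=0.005)
        assert out["milk"] == 0.0

    def test_juice_tax_with_cross_substitution_is_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            ScenarioConfig(
                name="bad",
                policy=TaxPolicy(
                    rate=0.2, taxed_categories=frozenset({"ssb", "fruit_juice"})
                ),
                substitution_mode="cross_pe",
            )

    def test_adjusted_mode_requires_precomputed_elasticity(self):
        cfg = ScenarioConfig(
            name="M1x",
            policy=TaxPolicy(rate=0.2),
            own_pe_mode="consumption_adjusted",
        )
        with pytest.raises(ValueError, match="consumption_adjusted"):
            scenario_volume_changes(cfg, make_stratum(), ElasticitySet())


class TestPresetFidelity:
    def test_the_ten_presets(self, presets):
        """Preset parameterization matches the published scenario table."""
        assert set(presets) == {
            "main", "M1", "M2", "M3", "M4a", "M4b", "M4c", "S1", "S2", "S3"
        }
        for name, cfg in presets.items():
            assert cfg.policy.pass_through == 0.82
        assert presets["main"].policy.rate == 0.20
        assert presets["main"].substitution_mode == "none"
        assert presets["main"].own_pe_mode == "marginal"
        assert presets["M1"].own_pe_mode == "consumption_adjusted"
        assert presets["M1"].gamma == 0.5
        assert presets["M2"].own_pe_mode == "alternative_meta"
        assert presets["M3"].underreporting_factor == 1.86
        assert presets["M4a"].substitution_mode == "cross_pe"
        assert presets["M4b"].substitution_mode == "adjusted_cross_pe"
        assert presets["M4c"].substitution_mode == "caloric_fraction"
        assert presets["M4c"].compensation_fraction == 0.61
        assert presets["S1"].policy.rate == 0.10
        assert presets["S2"].policy.rate == 0.30
        assert presets["S3"].policy.taxed_categories == frozenset(
            {"ssb", "fruit_juice"}
        )
        e = ElasticitySet()
        assert e.own_pe_ssb.mean == -1.299
        assert e.cross_pe_juice.mean == 0.388
        assert e.cross_pe_milk.mean == 0.129
        assert e.alt_own_pe_ssb.mean == -0.674
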