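"""Unit tests for the closed-form estimators."""

import math

import numpy as np
import pytest

from restamp import (
    BirthDeathParams,
    BottleneckLedger,
    CfuSeries,
    FounderEstimate,
    PlasmidObservation,
    ReferenceProfile,
    SensitivityQuery,
    TagFrequencyProfile,
    bd_frequency_variance,
    bottleneck_sensitivity,
    corrected_founder_population_size,
    death_emulation_scale,
    death_emulation_schedule,
    death_emulation_volume,
    doubling_time_from_rate,
    estimate_rates,
    expected_surviving_tags,
    founder_population_size,
    mean_founder_theoretical,
    net_growth_rate,
    plasmid_segregation_rates,
    rate_from_doubling_time,
    sensitivity_grid,
    volume_rescale,
)

from oracles import inverse_founder_of_multinomial


def make_profile(freqs, ids=None):
    ids = ids or tuple(f"t{i}" for i in range(len(freqs)))
    return TagFrequencyProfile(ids, np.asarray(freqs), total_count=1000)


def make_reference(freqs, ids=None):
    ids = ids or tuple(f"t{i}" for i in range(len(freqs)))
    return ReferenceProfile(ids, np.asarray(freqs))


class TestFounderPopulationSize:
    def test_two_tag_hand_evaluation(self):
        # (0.6-0.5)^2/0.25 = 0.04 per tag, mean 0.04 -> N_B = 25
        est = founder_population_size(
            make_profile([0.6, 0.4]), make_reference([0.5, 0.5])
        )
        assert est.value == pytest.approx(25.0, rel=1e-12)
        assert not est.negative_flag

    def test_identical_profiles_give_flagged_infinity(self):
        est = founder_population_size(
            make_profile([0.5, 0.5]), make_reference([0.5, 0.5])
        )
        assert math.isinf(est.value)
        assert est.negative_flag

    def test_mismatched_tag_sets_error(self):
        with pytest.raises(ValueError, match="tag set"):
            founder_population_size(
                make_profile([0.6, 0.4], ids=("a", "b")),
                make_reference([0.5, 0.5], ids=("a", "c")),
            )

    def test_reference_zero_tags_are_excluded(self):
        est = founder_population_size(
            make_profile([0.6, 0.4, 0.0]), make_reference([0.5, 0.5, 0.0])
        )
        assert est.n_tags_used == 2
        assert est.n_tags_excluded == 1
        assert est.value == pytest.approx(25.0, rel=1e-12)

    def test_too_few_informative_tags_error(self):
        with pytest.raises(ValueError, match="informative"):
            founder_population_size(
                make_profile([1.0, 0.0]), make_reference([1.0, 0.0])
            )

    def test_multinomial_sampling_interpretation(self, rng, uniform_reference):
        # a multinomial draw of size S has expected inverse founder size 1/S
        k, S, reps = 1000, 100, 200
        ids = uniform_reference.tag_ids
        inv = np.empty(reps)
        for i in range(reps):
            draw = rng.multinomial(S, np.full(k, 1 / k))
            prof = TagFrequencyProfile.from_counts(ids, draw)
            inv[i] = 1.0 / founder_population_size(prof, uniform_reference).value
        se = inv.std(ddof=1) / np.sqrt(reps)
        assert abs(inv.mean() - 1 / S) < 3 * se


class TestCorrectedFounder:
    def test_empty_ledger_identity(self):
        prof, ref = make_profile([0.6, 0.4]), make_reference([0.5, 0.5])
        raw = founder_population_size(prof, ref)
        cor = corrected_founder_population_size(prof, ref, BottleneckLedger())
        assert cor.value == pytest.approx(raw.value)
        assert cor.corrected

    def test_harmonic_subtraction_arithmetic(self):
        # choose drift so the raw value is 3.027e4, then subtract 1.3e-5
        raw = 3.027e4
        inv_corrections = 1e-5 + 1e-6 + 1e-6 + 1e-6
        f0 = 0.5
        drift = 1.0 / raw
        delta_f = math.sqrt(drift * f0 * (1 - f0))
        prof = make_profile([f0 + delta_f, f0 - delta_f])
        ledger = BottleneckLedger.from_sizes(
            inoculum_sizes=[1e6, 1e6], sample_sizes=[1e5, 1e6]
        )
        est = corrected_founder_population_size(prof, make_reference([f0, f0]), ledger)
        expected = 1.0 / (1.0 / raw - inv_corrections)
        assert est.value == pytest.approx(expected, rel=1e-9)
        assert est.value == pytest.approx(4.99e4, rel=0.01)

    def test_overcorrection_is_flagged_not_raised(self):
        prof, ref = make_profile([0.6, 0.4]), make_reference([0.5, 0.5])
        ledger = BottleneckLedger.from_sizes(sample_sizes=[2.0])  # 1/2 > 1/25
        est = corrected_founder_population_size(prof, ref, ledger)
        assert est.negative_flag
        assert est.value < 0

    def test_mean_of_inverses_not_inverse_of_mean(self):
        ledger = BottleneckLedger.from_sizes(sample_sizes=[[100.0, 300.0]])
        assert ledger.sample_inverse_means[0] == pytest.approx(
            (1 / 100 + 1 / 300) / 2
        )


class TestMeanFounderTheoretical:
    def test_dying_and_growing_closed_forms(self):
        dying = BirthDeathParams(beta=0.01, delta=0.03, t=120, n0=1e6)
        growing = BirthDeathParams(beta=0.03, delta=0.01, t=120, n0=1e6)
        assert mean_founder_theoretical(dying) == pytest.approx(4.99e4, rel=0.005)
        assert mean_founder_theoretical(growing) == pytest.approx(5.50e5, rel=0.005)

    def test_critical_case_uses_series_limit(self):
        crit = BirthDeathParams(beta=0.02, delta=0.02, t=100, n0=1e6)
        assert mean_founder_theoretical(crit) == pytest.approx(2.5e5, rel=1e-9)
        # continuity: r = ±1e-6 evaluations bracket the limit tightly
        for eps in (1e-6, -1e-6):
            near = BirthDeathParams(
                beta=0.02 + max(eps, 0), delta=0.02 + max(-eps, 0), t=100, n0=1e6
            )
            assert mean_founder_theoretical(near) == pytest.approx(2.5e5, rel=1e-4)

    def test_t_zero_is_undefined(self):
        with pytest.raises(ValueError):
            mean_founder_theoretical(BirthDeathParams(0.01, 0.03, 0.0, 1e6))


class TestEstimateRates:
    def test_dying_case_target_rates(self):
        nb = mean_founder_theoretical(BirthDeathParams(0.01, 0.03, 120, 1e6))
        est = estimate_rates(-0.02, 1e6, 1e6 * math.exp(-2.4), nb)
        assert est.delta_hat == pytest.approx(0.03, rel=1e-9)
        assert est.beta_hat == pytest.approx(0.01, rel=1e-9)

    def test_pure_birth_round_trip(self):
        nb = 1e6 / (1 - math.exp(-2.4))
        est = estimate_rates(0.02, 1e6, 1e6 * math.exp(2.4), nb)
        assert est.delta_hat == pytest.approx(0.0, abs=1e-12)
        assert est.beta_hat == pytest.approx(0.02, rel=1e-12)

    @pytest.mark.parametrize("beta", [0.005, 0.02, 0.046])
    @pytest.mark.parametrize("delta", [0.0, 0.01, 0.14])
    @pytest.mark.parametrize("t", [30.0, 120.0, 600.0])
    def test_inversion_identity_on_grid(self, beta, delta, t):
        # the rate estimator inverts the founder-size closed form exactly
        for n0 in (1e5, 1e6):
            p = BirthDeathParams(beta=beta, delta=delta, t=t, n0=n0)
            if p.beta + p.delta == 0:
                continue
            nb = mean_founder_theoretical(p)
            est = estimate_rates(p.r, n0, n0 * math.exp(p.r * t), nb, t=t)
            assert est.beta_hat == pytest.approx(beta, abs=1e-10)
            assert est.delta_hat == pytest.approx(delta, abs=1e-10)

    def test_r_zero_limit_requires_t(self):
        with pytest.raises(ValueError, match="elapsed time"):
            estimate_rates(0.0, 1e6, 1e6, 1e5)
        est = estimate_rates(0.0, 1e6, 1e6, 2.5e5, t=100.0)
        assert est.delta_hat == pytest.approx(0.02, rel=1e-9)

    def test_flagged_founder_size_rejected(self):
        bad = FounderEstimate(value=-100.0, negative_flag=True, corrected=True)
        with pytest.raises(ValueError, match="redesign"):
            estimate_rates(0.02, 1e6, 2e6, bad)

    def test_rate_identity_invariant(self):
        est = estimate_rates(-0.02, 1e6, 1e6 * math.exp(-2.4), 4.99e4)
        assert est.beta_hat - est.delta_hat == pytest.approx(est.r_hat, abs=1e-15)


class TestNetGrowthRate:
    def test_noiseless_exponential_recovery(self):
        t = np.arange(0, 100, 10.0)
        series = CfuSeries(times=t, cfu_per_ml=1e5 * np.exp(0.02 * t))
        fit = net_growth_rate(series)
        assert fit["r"] == pytest.approx(0.02, abs=1e-12)
        lo, hi = fit["r_ci"]
        assert lo <= fit["r"] <= hi

    def test_flat_series_gives_zero(self):
        series = CfuSeries(times=[0.0, 10, 20], cfu_per_ml=[1e5, 1e5, 1e5])
        assert net_growth_rate(series)["r"] == pytest.approx(0.0, abs=1e-15)

    def test_lb_growth_mean_points(self):
        # per-ml CFU from the printed per-200-µl means, scaled by 5
        series = CfuSeries(
            times=[0.0, 20, 40, 60, 80],
            cfu_per_ml=[1.95e5, 5 * 7.5e4, 5 * 9.7e4, 5 * 1.8e5, 5 * 3.2e5],
        )
        fit = net_growth_rate(series)
        assert fit["r"] == pytest.approx(0.02547, rel=0.02)

    def test_nonpositive_cfu_rejected(self):
        with pytest.raises(ValueError):
            CfuSeries(times=[0.0, 10], cfu_per_ml=[1e5, 0.0])


class TestFrequencyVariance:
    def test_zero_at_t_zero(self):
        p = BirthDeathParams(0.01, 0.03, 0.0, 1e6)
        assert bd_frequency_variance(p, 0.001) == 0.0

    def test_direct_evaluation(self):
        p = BirthDeathParams(0.01, 0.03, 120.0, 1e6)
        assert bd_frequency_variance(p, 0.001) == pytest.approx(2.003e-8, rel=0.005)

    def test_pure_death_reduces_to_binomial_survival_form(self):
        # beta=0: factor reduces to (e^{delta t} - 1)/N0
        delta, t, n0, f = 0.03, 50.0, 1e4, 0.05
        p = BirthDeathParams(0.0, delta, t, n0)
        expected = (math.exp(delta * t) - 1) / n0 * f * (1 - f)
        assert bd_frequency_variance(p, f) == pytest.approx(expected, rel=1e-12)

    def test_critical_limit_continuity(self):
        crit = BirthDeathParams(0.02, 0.02, 60.0, 1e6)
        v_lim = bd_frequency_variance(crit, 0.01)
        near = BirthDeathParams(0.02 + 1e-9, 0.02, 60.0, 1e6)
        assert bd_frequency_variance(near, 0.01) == pytest.approx(v_lim, rel=1e-6)


class TestBottleneckSensitivity:
    def fig5_query(self, t, nb):
        return SensitivityQuery(
            BirthDeathParams(beta=0.025, delta=0.0, t=t, n0=1.95e5), nb=nb
        )

    def test_printed_timepoint_values(self):
        assert bottleneck_sensitivity(self.fig5_query(20, 8.643e5)) == pytest.approx(
            0.573, rel=0.005
        )
        assert bottleneck_sensitivity(self.fig5_query(80, 1.3145e6)) == pytest.approx(
            0.1716, rel=0.005
        )

    def test_vanishes_at_infinite_depth(self):
        assert bottleneck_sensitivity(self.fig5_query(20, 1e30)) < 1e-20

    def test_positive_and_monotonic(self):
        # s_B > 0 for r != 0 (either sign) and strictly decreasing in t, N_B
        for beta, delta in [(0.025, 0.0), (0.0, 0.025)]:
            vals = [
                bottleneck_sensitivity(
                    SensitivityQuery(
                        BirthDeathParams(beta, delta, t, 1e5), nb=1e6
                    )
                )
                for t in (10, 20, 40, 80)
            ]
            assert all(v > 0 for v in vals)
            assert all(a > b for a, b in zip(vals, vals[1:]))
        s1 = bottleneck_sensitivity(self.fig5_query(20, 1e5))
        s2 = bottleneck_sensitivity(self.fig5_query(20, 1e6))
        assert s1 > s2

    def test_continuity_across_r_zero(self):
        lim = bottleneck_sensitivity(
            SensitivityQuery(BirthDeathParams(0.02, 0.02, 60, 1e5), nb=1e6)
        )
        for eps in (1e-8, -1e-8):
            q = SensitivityQuery(
                BirthDeathParams(0.02 + max(eps, 0), 0.02 + max(-eps, 0), 60, 1e5),
                nb=1e6,
            )
            assert bottleneck_sensitivity(q) == pytest.approx(lim, rel=1e-6)


class TestSensitivityGrid:
    def test_single_cell_reduces_to_pointwise(self):
        grid = sensitivity_grid((0.025, 0.025), (0.0, 0.0), 0.001, 20, 1.95e5, 8.643e5)
        assert len(grid) == 1
        assert grid["s_b"].iloc[0] == pytest.approx(0.573, rel=0.005)

    def test_design_guideline_scenario(self):
        grid = sensitivity_grid((0, 0.046), (0, 0.14), 0.001, t=60, n0=1e5, nb=1e6)
        below = grid[~grid["exceeds"]]
        # nearly the whole design space is safe ...
        assert len(below) / len(grid) > 0.95
        # ... but sensitivity rises sharply as both rates approach zero
        slow = grid[(grid.beta < 0.005) & (grid.delta < 0.005)]
        fast = grid[(grid.beta > 0.02) & (grid.delta > 0.02)]
        assert slow["s_b"].median() > 10 * fast["s_b"].median()

    def test_monotone_in_time(self):
        g1 = sensitivity_grid((0.01, 0.02), (0.0, 0.01), 0.01, 30, 1e5, 1e6)
        g2 = sensitivity_grid((0.01, 0.02), (0.0, 0.01), 0.01, 60, 1e5, 1e6)
        assert (g2["s_b"].values <= g1["s_b"].values).all()


class TestDeathEmulation:
    def test_low_death_rate_schedule(self):
        vols = death_emulation_schedule(100, 0.015, [0, 20, 25, 30, 35, 40])
        # one-decimal agreement (59.156 was truncated, not rounded, to 59.1)
        expected = [100.0, 74.1, 68.7, 63.8, 59.1, 54.9]
        assert vols == pytest.approx(expected, abs=0.1)

    def test_high_death_rate_schedule(self):
        vols = death_emulation_schedule(1000, 0.1, [0, 20, 25, 30, 35, 40])
        expected = [1000.0, 135.3, 82.1, 49.8, 30.2, 18.3]
        assert vols == pytest.approx(expected, abs=0.1)

    def test_identity_at_t_zero_and_monotone_decrease(self):
        assert death_emulation_volume(100, 0.05, 0) == 100
        vols = death_emulation_schedule(100, 0.05, np.linspace(0, 60, 20))
        assert all(a > b for a, b in zip(vols, vols[1:]))

    def test_scale_factor_arithmetic(self):
        nb = FounderEstimate(value=1000.0)
        scaled = death_emulation_scale(nb, delta=0.1, t=20)
        assert scaled.value == pytest.approx(1156.5, rel=1e-3)
        assert scaled.emulation_scale == pytest.approx(1 / (1 - math.exp(-2)))

    def test_scale_diverges_at_zero(self):
        with pytest.raises(ValueError):
            death_emulation_scale(FounderEstimate(value=1000.0), delta=0.0, t=20)

    def test_scale_factor_approaches_one(self):
        nb = FounderEstimate(value=1000.0)
        scaled = death_emulation_scale(nb, delta=1.0, t=1000)
        assert scaled.value == pytest.approx(1000.0, rel=1e-9)


class TestVolumeRescale:
    def test_200ul_to_1ml_is_factor_5(self):
        nb = FounderEstimate(value=1e4)
        scaled = volume_rescale(nb, measured_volume=200, reference_volume=1000)
        assert scaled.value == pytest.approx(5e4)
        assert scaled.volume_scale == pytest.approx(5.0)

    def test_identity_and_composition(self):
        nb = FounderEstimate(value=1e4)
        assert volume_rescale(nb, 1.0, 1.0).value == nb.value
        ab = volume_rescale(volume_rescale(nb, 1.0, 3.0), 3.0, 7.0)
        ac = volume_rescale(nb, 1.0, 7.0)
        assert ab.value == pytest.approx(ac.value)


class TestPlasmidSegregation:
    def test_constant_marker_and_census_give_zero_rates(self):
        obs = PlasmidObservation(f0=0.3, ft=0.3, n0=1e5, nt=1e5, t=30)
        est = plasmid_segregation_rates(obs)
        assert est.beta_hat == pytest.approx(0.0, abs=1e-15)
        assert est.delta_hat == pytest.approx(0.0, abs=1e-15)

    def test_marker_halving_census_doubling(self):
        obs = PlasmidObservation(f0=0.4, ft=0.2, n0=1e5, nt=2e5, t=28)
        est = plasmid_segregation_rates(obs)
        assert est.beta_hat == pytest.approx(math.log(2) / 28, rel=1e-12)
        assert est.delta_hat == pytest.approx(0.0, abs=1e-12)
        assert est.beta_hat == pytest.approx(0.025, rel=0.02)

    def test_pure_death_round_trip(self):
        delta, t = 0.05, 40.0
        obs = PlasmidObservation(
            f0=0.3, ft=0.3, n0=1e6, nt=1e6 * math.exp(-delta * t), t=t
        )
        est = plasmid_segregation_rates(obs)
        assert est.beta_hat == pytest.approx(0.0, abs=1e-12)
        assert est.delta_hat == pytest.approx(delta, rel=1e-12)

    def test_fully_diluted_marker_rejected(self):
        with pytest.raises(ValueError):
            PlasmidObservation(f0=0.3, ft=0.0, n0=1e5, nt=1e5, t=30)


class TestExpectedSurvivingTags:
    def test_no_death_all_tags_survive(self):
        frac, n = expected_surviving_tags(np.ones(100), beta=0.02, delta=0.0, t=500)
        assert frac == 1.0
        assert n == 100

    def test_pure_death_closed_form(self):
        frac, n = expected_surviving_tags(np.ones(1000), beta=0.0, delta=0.03, t=120)
        assert frac == pytest.approx(math.exp(-3.6), rel=1e-12)
        assert n == pytest.approx(1000 * math.exp(-3.6), rel=1e-12)

    def test_multicell_tags_survive_more(self):
        f1, _ = expected_surviving_tags(np.ones(50), 0.01, 0.03, 60)
        f3, _ = expected_surviving_tags(np.full(50, 3), 0.01, 0.03, 60)
        assert f3 > f1

    def test_critical_limit_form(self):
        delta, t = 0.02, 50.0
        frac, _ = expected_surviving_tags([1], beta=delta, delta=delta, t=t)
        assert frac == pytest.approx(1 - delta * t / (1 + delta * t), rel=1e-12)


def test_design_rate_helpers():
    assert rate_from_doubling_time(15) == pytest.approx(0.046, rel=0.02)
    assert rate_from_doubling_time(5) == pytest.approx(0.14, rel=0.02)
    assert doubling_time_from_rate(0.025) == pytest.approx(28, rel=0.02)
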