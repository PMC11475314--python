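"""Time-course simulation: the exponential-phase model, schedules, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxprop.reference_fba import ReferenceState
from fluxprop.simulate import (
    NoiseModel,
    SamplingSchedule,
    ideal_concentration,
    make_schedule,
    simulate_biomass,
    simulate_profiles,
)
from fluxprop.synthetic_data import CellLineDataset


def tiny_dataset(i0=2.0, dry=250.0):
    return CellLineDataset(
        name="tiny",
        rates={"glucose": -0.01},
        initial_concentrations={"glucose": i0},
        dry_mass_per_cell=dry,
        initial_cell_density=1.6e5,
    )


def tiny_reference(q=-0.01, mu=0.03):
    return ReferenceState(mu_ref=mu, rates_complete={"glucose": q})


class TestIdealConcentration:
    def test_starts_at_initial_concentration(self):
        assert ideal_concentration(2.0, -0.01, 0.03, 0.04, 0.0) == 2.0

    def test_zero_rate_stays_constant(self):
        t = np.linspace(0, 90, 10)
        assert np.all(ideal_concentration(5.0, 0.0, 0.03, 0.04, t) == 5.0)

    def test_hand_computed_value(self):
        # 2 + (-0.01)(0.04/0.03)(e^2.7 - 1) = 1.81493...
        assert ideal_concentration(2.0, -0.01, 0.03, 0.04, 90.0) == pytest.approx(1.8149, abs=1e-4)

    def test_nonpositive_growth_rejected(self):
        with pytest.raises(ValueError):
            ideal_concentration(2.0, -0.01, 0.0, 0.04, 10.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        i0=st.floats(0.1, 50), q=st.floats(-0.5, 0.5), mu=st.floats(0.01, 0.06),
        t=st.floats(0.0, 90.0),
    )
    def test_monotone_in_time_with_rate_sign(self, i0, q, mu, t):
        c_t = ideal_concentration(i0, q, mu, 0.04, t)
        c_later = ideal_concentration(i0, q, mu, 0.04, t + 1.0)
        assert (c_later - c_t) * np.sign(q) >= 0 or q == 0


class TestSchedules:
    @pytest.mark.parametrize("interval,n_expected", [(6.0, 16), (12.0, 8), (24.0, 4)])
    def test_regular_point_counts_over_90h(self, interval, n_expected):
        sched = make_schedule("regular", interval)
        assert sched.n_times == n_expected
        assert sched.times[0] == 0.0

    def test_daily_schedule_times(self):
        assert make_schedule("regular", 24.0).times.tolist() == [0.0, 24.0, 48.0, 72.0]

    def test_shift_gap_after_dense(self):
        sched = make_schedule("shift", 4.0, shift_variant="gap_after_dense")
        assert sched.times[:6].tolist() == [0.0, 4.0, 8.0, 12.0, 24.0, 28.0]

    def test_shift_gap_first(self):
        sched = make_schedule("shift", 4.0, shift_variant="gap_first")
        assert sched.times[:6].tolist() == [0.0, 12.0, 16.0, 20.0, 24.0, 36.0]

    def test_shift_dense_interval_2p5(self):
        sched = make_schedule("shift", 2.5, shift_variant="gap_after_dense")
        assert sched.times[:5].tolist() == [0.0, 2.5, 5.0, 7.5, 24.0]

    def test_shift_has_four_samples_per_full_day(self):
        sched = make_schedule("shift", 4.0, shift_variant="gap_after_dense")
        day2 = sched.times[(sched.times >= 24) & (sched.times < 48)]
        assert day2.size == 4

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            make_schedule("weekly")
        with pytest.raises(ValueError):
            make_schedule("shift", 4.0, shift_variant="nope")
        with pytest.raises(ValueError):
            make_schedule("regular", 60.0)
        with pytest.raises(ValueError):
            SamplingSchedule(times=np.array([0.0, 5.0]), n_replicates=0)
        with pytest.raises(ValueError):
            SamplingSchedule(times=np.array([5.0, 10.0]))


class TestNoise:
    def test_zero_rsd_reproduces_ideal_exactly(self):
        ds, ref = tiny_dataset(), tiny_reference()
        sched = make_schedule("regular", 6.0)
        prof = simulate_profiles(ref, ds, sched, NoiseModel(0.0), 5, seed=1)["glucose"]
        ideal = ideal_concentration(2.0, -0.01, 0.03, ds.bm0, sched.times)
        assert np.allclose(prof, ideal[None, None, :], atol=0)
        _, bm = simulate_biomass(ds, 0.03, sched, 0.0, 3, seed=1)
        assert np.allclose(bm, ds.bm0 * np.exp(0.03 * sched.times)[None, None, :], atol=0)

    def test_noise_sd_matches_requested_rsd(self):
        ds, ref = tiny_dataset(), tiny_reference()
        sched = make_schedule("regular", 24.0, n_replicates=1)
        prof = simulate_profiles(ref, ds, sched, NoiseModel(0.1), 10_000, seed=2)["glucose"]
        ideal = ideal_concentration(2.0, -0.01, 0.03, ds.bm0, sched.times)
        emp_rsd = prof[:, 0, :].std(axis=0) / ideal
        assert np.allclose(emp_rsd, 0.1, rtol=0.03)

    def test_noise_is_unbiased(self):
        ds, ref = tiny_dataset(), tiny_reference()
        sched = make_schedule("regular", 24.0, n_replicates=1)
        prof = simulate_profiles(ref, ds, sched, NoiseModel(0.1), 10_000, seed=3)["glucose"]
        ideal = ideal_concentration(2.0, -0.01, 0.03, ds.bm0, sched.times)
        se = 0.1 * ideal / np.sqrt(10_000)
        assert np.all(np.abs(prof[:, 0, :].mean(axis=0) - ideal) < 4 * se)

    def test_noise_sd_scales_with_ideal_value(self):
        """Heteroscedasticity: empirical SD regresses onto ideal with slope=rsd."""
        ds, ref = tiny_dataset(i0=30.0), tiny_reference(q=-0.3)
        sched = make_schedule("regular", 6.0, n_replicates=1)
        prof = simulate_profiles(ref, ds, sched, NoiseModel(0.1), 5000, seed=4)["glucose"]
        ideal = ideal_concentration(30.0, -0.3, 0.03, ds.bm0, sched.times)
        sd = prof[:, 0, :].std(axis=0)
        slope, intercept = np.polyfit(ideal, sd, 1)
        assert slope == pytest.approx(0.1, rel=0.05)
        assert abs(intercept) < 0.05 * sd.mean()

    def test_common_random_numbers_across_rsd_levels(self):
        """Same seed: deviations from ideal scale exactly with the RSD."""
        ds, ref = tiny_dataset(), tiny_reference()
        sched = make_schedule("regular", 12.0)
        a = simulate_profiles(ref, ds, sched, NoiseModel(0.05), 20, seed=7)["glucose"]
        b = simulate_profiles(ref, ds, sched, NoiseModel(0.10), 20, seed=7)["glucose"]
        ideal = ideal_concentration(2.0, -0.01, 0.03, ds.bm0, sched.times)
        np.testing.assert_allclose(b - ideal, 2.0 * (a - ideal), rtol=1e-12)

    def test_identical_seed_bit_identical(self):
        ds, ref = tiny_dataset(), tiny_reference()
        sched = make_schedule("regular", 12.0)
        a = simulate_profiles(ref, ds, sched, NoiseModel(0.1), 10, seed=9)["glucose"]
        b = simulate_profiles(ref, ds, sched, NoiseModel(0.1), 10, seed=9)["glucose"]
        assert np.array_equal(a, b)

    def test_negative_concentrations_not_clamped(self):
        ds = tiny_dataset(i0=0.05)
        ref = ReferenceState(mu_ref=0.03, rates_complete={"glucose": -0.0001})
        sched = make_schedule("regular", 6.0)
        prof = simulate_profiles(ref, ds, sched, NoiseModel(0.9), 200, seed=10)["glucose"]
        assert (prof < 0).any()

    def test_missing_initial_concentration_named(self):
        ds = tiny_dataset()
        ref = ReferenceState(mu_ref=0.03, rates_complete={"glucose": -0.01, "serine": -0.002})
        with pytest.raises(KeyError, match="serine"):
            simulate_profiles(ref, ds, make_schedule("regular", 12.0),
                              NoiseModel(0.1), n_draws=2, seed=1)

    def test_rsd_bounds_validated(self):
        with pytest.raises(ValueError):
            NoiseModel(concentration_rsd=1.5)
        with pytest.raises(ValueError):
            NoiseModel(biomass_rsd=-0.1)


def test_log_of_noiseless_biomass_is_linear_in_time():
    ds = tiny_dataset()
    sched = make_schedule("regular", 6.0)
    t, bm = simulate_biomass(ds, 0.042, sched, 0.0, 1, seed=1)
    slope = np.polyfit(t, np.log(bm[0, 0, :]), 1)[0]
    assert slope == pytest.approx(0.042, rel=1e-10)
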