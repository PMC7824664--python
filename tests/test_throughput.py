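import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnascale import throughput as tp
from rnascale.scenarios import Demand, ProcessParams, random_scenario


class TestBatchesPerYear:
    def test_anchor_1l(self):
        assert tp.batches_per_year(1.0) == 471.0

    def test_anchor_30l(self):
        assert tp.batches_per_year(30.0) == 444.0

    def test_midpoint(self):
        assert tp.batches_per_year(15.5) == pytest.approx(457.5)

    def test_clamped_above(self):
        assert tp.batches_per_year(50.0) == 444.0

    def test_nonpositive_volume(self):
        with pytest.raises(ValueError, match="volume"):
            tp.batches_per_year(0.0)


class TestBatchDuration:
    def test_anchors(self):
        assert tp.batch_duration(1.0) == 41.0
        assert tp.batch_duration(30.0) == 48.2

    def test_midpoint(self):
        assert tp.batch_duration(15.5) == pytest.approx(44.6)

    def test_monotone(self):
        vols = [1, 3, 7, 15, 22, 30, 40]
        durs = [tp.batch_duration(v) for v in vols]
        assert durs == sorted(durs)


class TestEffectiveRecovery:
    def test_calibrated_default(self):
        assert tp.effective_recovery(0.56, 0.05, 0.92521) == pytest.approx(0.4922, abs=5e-5)

    def test_no_extra_losses(self):
        assert tp.effective_recovery(0.56, 0.0, 1.0) == 0.56

    def test_all_batches_fail(self):
        assert tp.effective_recovery(0.7, 1.0, 0.9) == 0.0

    def test_out_of_range(self):
        with pytest.raises(ValueError, match="failure_rate"):
            tp.effective_recovery(0.5, 1.2, 1.0)


class TestAnnualOutput:
    def test_30l_nominal(self):
        annual, per_batch = tp.annual_output(30.0, 5.0, 0.56)
        assert per_batch == pytest.approx(84.0)
        assert annual == pytest.approx(37296.0)

    def test_7l_meets_demand_at_1ug(self):
        annual, _ = tp.annual_output(7.0, 5.0, 0.56)
        assert tp.annual_doses(annual, 1.0) > 8e9

    def test_zero_titre(self):
        annual, per_batch = tp.annual_output(10.0, 0.0, 0.5)
        assert annual == 0.0 and per_batch == 0.0


class TestAnnualDoses:
    def test_direct_division(self):
        assert tp.annual_doses(37296.0, 1.0) == pytest.approx(3.7296e10)

    def test_reciprocity(self):
        assert tp.annual_doses(100.0, 2.0) == pytest.approx(tp.annual_doses(100.0, 1.0) / 2)

    def test_zero_mass(self):
        assert tp.annual_doses(0.0, 5.0) == 0.0

    def test_domain_error(self):
        with pytest.raises(ValueError, match="rna_per_dose"):
            tp.annual_doses(10.0, 0.0)


class TestRequiredBatches:
    def test_100ug_low_titre(self, effective_recovery_default):
        b = tp.required_batches(8e9, 100.0, 30.0, 4.0, effective_recovery_default)
        assert round(b) == 13544

    def test_100ug_high_titre(self, effective_recovery_default):
        b = tp.required_batches(8e9, 100.0, 30.0, 6.0, effective_recovery_default)
        assert round(b) == 9030

    def test_next_gen_high_titre(self, effective_recovery_default):
        b = tp.required_batches(8e9, 0.1, 1.0, 6.0, effective_recovery_default)
        assert round(b) == 271

    def test_zero_demand(self, effective_recovery_default):
        assert tp.required_batches(0.0, 1.0, 30.0, 5.0, effective_recovery_default) == 0.0

    def test_strictly_decreasing_in_titre(self, effective_recovery_default):
        b = [tp.required_batches(8e9, 30.0, 30.0, t, effective_recovery_default)
             for t in (3.0, 4.0, 5.0, 6.0, 7.0)]
        assert all(x > y for x, y in zip(b, b[1:]))

    def test_strictly_decreasing_in_recovery(self):
        b = [tp.required_batches(8e9, 30.0, 30.0, 5.0, r) for r in (0.3, 0.45, 0.56, 0.7)]
        assert all(x > y for x, y in zip(b, b[1:]))


class TestRequiredTotalVolume:
    def test_100ug_low(self, effective_recovery_default):
        v = tp.required_total_volume(8e9, 100.0, 4.0, effective_recovery_default, 30.0)
        assert round(v) == 915

    def test_100ug_high(self, effective_recovery_default):
        v = tp.required_total_volume(8e9, 100.0, 6.0, effective_recovery_default, 30.0)
        assert round(v) == 610

    def test_next_gen_low(self, effective_recovery_default):
        v = tp.required_total_volume(8e9, 0.1, 4.0, effective_recovery_default, 1.0)
        assert round(v, 2) == 0.86

    def test_linearity_in_demand(self, effective_recovery_default):
        v1 = tp.required_total_volume(4e9, 50.0, 5.0, effective_recovery_default, 30.0)
        v2 = tp.required_total_volume(8e9, 50.0, 5.0, effective_recovery_default, 30.0)
        assert v2 == pytest.approx(2 * v1)

    def test_consistency_with_batches(self, effective_recovery_default):
        r = effective_recovery_default
        batches = tp.required_batches(8e9, 100.0, 30.0, 4.0, r)
        v = tp.required_total_volume(8e9, 100.0, 4.0, r, 30.0)
        assert v == pytest.approx(batches * 30.0 / tp.batches_per_year(30.0))


class TestFacilities:
    def test_low_titre_100ug(self):
        assert tp.facilities_required(13544, 30.0) == 31

    def test_exactly_one_year(self):
        assert tp.facilities_required(444, 30.0) == 1

    def test_ceiling_boundary(self):
        assert tp.facilities_required(445, 30.0) == 2

    def test_zero_batches(self):
        assert tp.facilities_required(0, 30.0) == 0

    def test_consistency_21_31(self, effective_recovery_default):
        r = effective_recovery_default
        low = tp.required_batches(8e9, 100.0, 30.0, 4.0, r)
        high = tp.required_batches(8e9, 100.0, 30.0, 6.0, r)
        assert tp.facilities_required(low, 30.0) == 31
        assert tp.facilities_required(high, 30.0) == 21


class TestTimeToDemand:
    def test_1ug_30l(self):
        years = tp.time_to_demand(8e9, 1.0, 30.0, 5.0, 0.56)
        assert round(years * 12, 1) == 2.6

    def test_next_gen_30l(self):
        years = tp.time_to_demand(8e9, 0.1, 30.0, 5.0, 0.56)
        assert years * 365 == pytest.approx(7.8, abs=0.05)
        assert round(years * 365) == 8

    def test_half_demand_half_time(self):
        t_full = tp.time_to_demand(8e9, 1.0, 30.0, 5.0, 0.56)
        t_half = tp.time_to_demand(4e9, 1.0, 30.0, 5.0, 0.56)
        assert t_half == pytest.approx(t_full / 2)

    def test_zero_rate_unbounded(self):
        assert tp.time_to_demand(8e9, 1.0, 30.0, 0.0, 0.56) == math.inf

    def test_strictly_decreasing_in_volume(self):
        times = [tp.time_to_demand(8e9, 1.0, v, 5.0, 0.56) for v in (1, 5, 10, 20, 30, 40)]
        assert all(x > y for x, y in zip(times, times[1:]))


class TestDemandFromPopulation:
    def test_global_demand(self):
        assert tp.demand_from_population(7.8e9, 2) == 15.6e9

    def test_identity(self):
        assert tp.demand_from_population(123.0, 1) == 123.0

    def test_zero(self):
        assert tp.demand_from_population(0.0, 2) == 0.0


class TestScheduleOracle:
    @pytest.mark.parametrize("volume", [1.0, 7.0, 30.0])
    @pytest.mark.parametrize("horizon", [90.0, 365.0, 730.0])
    def test_agrees_with_closed_form(self, volume, horizon):
        oracle = tp.schedule_oracle(volume, horizon)
        closed = tp.batches_per_year(volume) * horizon / 365.0
        assert abs(oracle - closed) <= 1.0

    def test_proportionality(self):
        tenth = tp.schedule_oracle(30.0, 36.5)
        assert abs(tenth - 44.4) <= 1.0

    def test_horizon_too_short(self):
        with pytest.raises(ValueError, match="horizon"):
            tp.schedule_oracle(30.0, 1.0)


class TestEvaluateCapacity:
    def test_mass_conservation_exact(self, presets, process, demand):
        for vac in presets:
            proc = process.model_copy(update={"volume_l": vac.feasible_scale_l})
            cap = tp.evaluate_capacity(vac, proc, demand)
            assert cap.annual_doses * vac.rna_per_dose_ug == pytest.approx(
                cap.annual_mass_g * 1e6, rel=1e-12
            )

    def test_facility_invariant(self, presets, process, demand):
        for vac in presets:
            proc = process.model_copy(update={"volume_l": vac.feasible_scale_l})
            cap = tp.evaluate_capacity(vac, proc, demand)
            assert cap.facilities == math.ceil(cap.required_batches / cap.batches_per_year)

    def test_time_unit_conversions(self, presets, process, demand):
        cap = tp.evaluate_capacity(presets[0], process, demand)
        assert cap.time_to_demand_months == pytest.approx(cap.time_to_demand_years * 12)
        assert cap.time_to_demand_days == pytest.approx(cap.time_to_demand_years * 365)


@settings(max_examples=150, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10**9))
def test_property_mass_conservation_and_reciprocity(seed):
    vac, proc, _ = random_scenario(seed)
    r = tp.process_recovery(proc)
    annual_mass, _ = tp.annual_output(proc.volume_l, proc.titre_g_per_l, r,
                                      proc.capacity_anchors)
    doses = tp.annual_doses(annual_mass, vac.rna_per_dose_ug)
    assert doses * vac.rna_per_dose_ug == pytest.approx(annual_mass * 1e6, rel=1e-9)
    # reciprocity: doses x dose is invariant to the dose mass
    doses2 = tp.annual_doses(annual_mass, 2 * vac.rna_per_dose_ug)
    assert doses2 * 2 * vac.rna_per_dose_ug == pytest.approx(
        doses * vac.rna_per_dose_ug, rel=1e-9
    )


@settings(max_examples=60, deadline=None)
@given(
    volume=st.floats(min_value=1.0, max_value=50.0),
    horizon=st.floats(min_value=30.0, max_value=1000.0),
)
def test_property_oracle_vs_closed_form(volume, horizon):
    oracle = tp.schedule_oracle(volume, horizon)
    closed = tp.batches_per_year(volume) * horizon / 365.0
    assert abs(oracle - closed) <= 1.0
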