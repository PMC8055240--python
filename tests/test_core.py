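"""BED engine: closed-form protraction terms, limits, and the grid evaluator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gkbed import (
    RepairParameters,
    VoxelExposure,
    bed_grid,
    bed_voxel,
    phi_cross,
    phi_numeric_oracle,
    phi_protocol,
    phi_self,
    repair_rate_from_half_time,
    voxel_exposure,
    build_timeline,
)
from conftest import random_exposure, random_plan

LN2 = math.log(2.0)
EPS = 1e-7  # acute segments: duration -> 0 at fixed dose


def acute(doses, intervals=()):
    """Protocol of near-instantaneous segments with the given doses (Gy)."""
    return VoxelExposure(
        rates=tuple(d / EPS for d in doses),
        durations=(EPS,) * len(doses),
        intervals=tuple(intervals),
    )


class TestRepairRate:
    def test_identity_and_forced_arithmetic(self):
        assert repair_rate_from_half_time(LN2) == pytest.approx(1.0)
        assert repair_rate_from_half_time(12.0) == pytest.approx(0.057762, abs=1e-6)

    def test_scaling_symmetry(self):
        assert repair_rate_from_half_time(6.0) == pytest.approx(
            2.0 * repair_rate_from_half_time(12.0)
        )

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            repair_rate_from_half_time(0.0)


class TestRepairParameters:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha_beta": -1.0},
            {"half_time_fast": 0.0},
            {"half_time_fast": 200.0},  # exceeds slow
            {"partition_fast": 1.5},
            {"partition_fast": -0.1},
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RepairParameters(**kwargs)

    def test_rates_ordered(self, params):
        assert params.mu_fast >= params.mu_slow


class TestPhiTerms:
    def test_phi_self_zero_rate(self):
        assert phi_self(0.0, 3.0, 1.0) == 0.0

    def test_phi_self_acute_limit_is_dose_squared(self):
        # mu t -> 0: the protraction term degenerates to d^2
        assert phi_self(2.0, 3.0, 1e-9) == pytest.approx(36.0, rel=1e-6)

    def test_phi_self_unit_case(self):
        # frozen from the 2D quadrature oracle over the exposure square
        assert phi_self(1.0, 1.0, 1.0) == pytest.approx(2.0 * math.exp(-1.0))

    def test_phi_cross_complete_repair(self):
        assert phi_cross(1.0, 1.0, 1.0, 1.0, 1e6, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_phi_cross_acute_no_repair_limit(self):
        # mu -> 0 with acute segments: 2 d_j d_k
        val = phi_cross(3.0 / EPS, EPS, 4.0 / EPS, EPS, 0.0, 1e-9)
        assert val == pytest.approx(24.0, rel=1e-5)

    def test_phi_cross_unit_interval_halves(self):
        # doses 1 and 1, one fast half-time apart: e^{-ln2} = 1/2, doubled
        val = phi_cross(1.0 / EPS, EPS, 1.0 / EPS, EPS, 1.0, LN2)
        assert val == pytest.approx(1.0, rel=1e-5)

    def test_phi_cross_strictly_decreasing_in_interval(self):
        vals = [phi_cross(2.0, 1.0, 3.0, 2.0, tau, 0.06) for tau in (0.0, 1.0, 5.0)]
        assert vals[0] > vals[1] > vals[2]

    @pytest.mark.parametrize("bad", [-1.0])
    def test_negative_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            phi_cross(1.0, 1.0, 1.0, 1.0, bad, 1.0)

    def test_non_positive_mu_rejected(self):
        with pytest.raises(ValueError):
            phi_self(1.0, 1.0, 0.0)


class TestPhiProtocol:
    def test_single_segment_equals_self_term(self):
        e = VoxelExposure(rates=(2.0,), durations=(3.0,))
        assert phi_protocol(e, 0.5) == phi_self(2.0, 3.0, 0.5)

    def test_two_acute_shots_worked_example(self):
        # two acute 6 Gy sub-fractions, 0.06 min apart, fast repair t1/2=12
        e = acute([6.0, 6.0], [0.06])
        assert phi_protocol(e, LN2 / 12.0) == pytest.approx(143.7509, abs=2e-3)

    def test_empty_protocol(self):
        assert phi_protocol(VoxelExposure((), ()), 1.0) == 0.0

    def test_time_reversal_invariance(self, rng):
        for _ in range(20):
            e = random_exposure(rng)
            for mu in (0.0608, 0.00535):
                assert phi_protocol(e.reversed(), mu) == pytest.approx(
                    phi_protocol(e, mu), rel=1e-12
                )

    def test_dropping_zero_rate_segments_leaves_phi_unchanged(self):
        e = VoxelExposure(
            rates=(1.5, 0.0, 2.5), durations=(2.0, 4.0, 1.0), intervals=(0.1, 0.2)
        )
        stripped = e.drop_zero_rate()
        assert len(stripped) == 2
        for mu in (0.0608, 0.00535):
            assert phi_protocol(stripped, mu) == pytest.approx(
                phi_protocol(e, mu), rel=1e-12
            )


class TestBedVoxel:
    def test_zero_dose(self, params):
        e = VoxelExposure(rates=(0.0,), durations=(1.0,))
        assert bed_voxel(e, params) == 0.0

    def test_single_acute_13gy(self, params):
        # acute limit closed form D (1 + D / (alpha/beta))
        assert bed_voxel(acute([13.0]), params) == pytest.approx(81.421, abs=1e-3)

    def test_two_acute_6gy_complete_repair(self, params):
        # intervals -> inf: per-sub-fraction BEDs add up
        e = acute([6.0, 6.0], [1e7])
        assert bed_voxel(e, params) == pytest.approx(12.0 + 2 * 36.0 / 2.47, abs=1e-3)

    def test_bracketed_by_total_dose_and_acute_limit(self, rng, params):
        for _ in range(20):
            e = random_exposure(rng)
            d = e.total_dose
            b = bed_voxel(e, params)
            assert d - 1e-9 <= b <= d * (1 + d / params.alpha_beta) + 1e-9

    def test_partition_one_is_mono_exponential(self):
        e = VoxelExposure(rates=(1.0, 2.0), durations=(3.0, 2.0), intervals=(5.0,))
        mono = RepairParameters(
            half_time_fast=11.4, half_time_slow=11.4, partition_fast=0.5
        )
        fast_only = RepairParameters(half_time_fast=11.4, partition_fast=1.0)
        assert bed_voxel(e, fast_only) == pytest.approx(bed_voxel(e, mono), rel=1e-12)

    def test_bi_exponential_bracketed_by_mono_models(self, rng):
        bi = RepairParameters()
        fast = RepairParameters(partition_fast=1.0)
        slow = RepairParameters(
            half_time_fast=bi.half_time_slow, partition_fast=1.0,
            half_time_slow=bi.half_time_slow,
        )
        for _ in range(20):
            e = random_exposure(rng)
            assert (
                bed_voxel(e, fast) - 1e-9
                <= bed_voxel(e, bi)
                <= bed_voxel(e, slow) + 1e-9
            )


class TestBedGrid:
    def test_matches_per_voxel_loop(self, rng, params):
        plan = random_plan(rng, n_shots=5, shape=(7, 7, 7))
        grid = bed_grid(plan, params)
        timeline = build_timeline(plan)
        for voxel in [(0, 0, 0), (3, 3, 3), (6, 2, 5), (1, 6, 4)]:
            e = voxel_exposure(plan, timeline, voxel)
            assert grid.values[voxel] == pytest.approx(bed_voxel(e, params), rel=1e-10)

    def test_zero_dose_voxels_map_to_zero(self, rng, params):
        plan = random_plan(rng, n_shots=3)
        for shot in plan.shots:
            shot.dose[0, 0, 0] = 0.0
        grid = bed_grid(plan, params)
        assert grid.values[0, 0, 0] == 0.0

    def test_constant_exposure_gives_constant_grid(self, params):
        from gkbed import IsoCentre, TreatmentPlan

        shots = tuple(
            IsoCentre(id=f"s{k}", beam_on=2.0, dose=np.full((4, 4, 4), 3.0))
            for k in range(3)
        )
        plan = TreatmentPlan(
            case_id="const", shots=shots, beam_off=(0.06, 0.06), prescription=9.0
        )
        grid = bed_grid(plan, params)
        assert np.allclose(grid.values, grid.values.flat[0])


class TestNumericOracle:
    def test_single_acute_segment(self):
        assert phi_numeric_oracle(acute([2.0]), 0.0608) == pytest.approx(4.0, rel=1e-5)

    def test_instantaneous_repair_limit(self):
        # Phi vanishes as mu -> inf, following the 2 sum(R^2 t) / mu asymptote
        e = VoxelExposure(rates=(2.0, 3.0), durations=(1.0, 1.0), intervals=(0.5,))
        mu = 1e4
        assert phi_numeric_oracle(e, mu) == pytest.approx(
            2.0 * (4.0 + 9.0) / mu, rel=1e-3
        )
        assert phi_numeric_oracle(e, 1e7) < 1e-5


@settings(max_examples=40, deadline=None, derandomize=True)
@given(data=st.data())
def test_phi_closed_form_agrees_with_quadrature(data):
    """Property: closed-form Phi equals the independent quadrature oracle."""
    n = data.draw(st.integers(1, 4))
    rates = data.draw(
        st.lists(st.floats(0.0, 5.0), min_size=n, max_size=n)
    )
    durations = data.draw(
        st.lists(st.floats(0.01, 10.0), min_size=n, max_size=n)
    )
    intervals = data.draw(
        st.lists(st.floats(0.0, 60.0), min_size=n - 1, max_size=n - 1)
    )
    e = VoxelExposure(tuple(rates), tuple(durations), tuple(intervals))
    for mu in (0.0608, 0.00535):
        a = phi_protocol(e, mu)
        b = phi_numeric_oracle(e, mu)
        assert abs(a - b) / max(abs(b), 1e-9) < 1e-6


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    gap=st.floats(0.0, 30.0),
    extra=st.floats(0.1, 30.0),
    mu=st.sampled_from([0.0608, 0.00535]),
)
def test_phi_strictly_decreases_as_any_interval_grows(gap, extra, mu):
    """Property: widening a beam-off interval can only lose interaction."""
    e1 = VoxelExposure((1.0, 2.0, 1.5), (2.0, 1.0, 3.0), (gap, 0.06))
    e2 = VoxelExposure((1.0, 2.0, 1.5), (2.0, 1.0, 3.0), (gap + extra, 0.06))
    assert phi_protocol(e2, mu) < phi_protocol(e1, mu)
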