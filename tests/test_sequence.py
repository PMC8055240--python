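"""Delivery-order search, heuristics and cohort statistics."""

import itertools

import numpy as np
import pytest

from gkbed import (
    CohortRow,
    apply_sequence,
    bed_grid,
    cohort_summary,
    delta_rel,
    exhaustive_search,
    extract_shell,
    heuristic_max_sequence,
    heuristic_min_sequence,
    paired_t_test,
    reference_cohort,
    shell_mean_bed,
)
from gkbed.sequence import ExhaustiveSearchRefused
from conftest import random_plan


class TestApplySequence:
    def test_identity(self, rng):
        plan = random_plan(rng, n_shots=4)
        same = apply_sequence(plan, (0, 1, 2, 3))
        assert [s.id for s in same.shots] == [s.id for s in plan.shots]

    def test_any_permutation_conserves_total_dose(self, rng):
        plan = random_plan(rng, n_shots=4)
        permuted = apply_sequence(plan, (3, 0, 2, 1))
        np.testing.assert_allclose(permuted.total_dose, plan.total_dose)

    def test_reversal_leaves_shell_mean_bed_unchanged(self, rng, params):
        # uniform slot gaps: time-reversal symmetry of the repair kernel
        plan = random_plan(rng, n_shots=4)
        plan = plan.with_beam_off((0.06,) * 3)
        pres = float(np.percentile(plan.total_dose, 80))
        shell = extract_shell(plan.total_dose, pres, tolerance=0.5)
        fwd = shell_mean_bed(bed_grid(plan, params), shell)
        rev = shell_mean_bed(
            bed_grid(apply_sequence(plan, (3, 2, 1, 0)), params), shell
        )
        assert rev == pytest.approx(fwd, rel=1e-12)

    def test_non_bijective_rejected(self, rng):
        plan = random_plan(rng, n_shots=3)
        with pytest.raises(ValueError, match="bijection"):
            apply_sequence(plan, (0, 0, 2))


class TestExhaustiveSearch:
    def test_matches_naive_grid_loop(self, rng, params):
        """Cached-moment search equals brute force through the full grid route."""
        plan = random_plan(rng, n_shots=3)
        pres = float(np.percentile(plan.total_dose, 80))
        shell = extract_shell(plan.total_dose, pres, tolerance=0.5)
        result = exhaustive_search(plan, params, shell=shell)
        assert result.n_evaluated == 6

        naive = {
            perm: shell_mean_bed(
                bed_grid(apply_sequence(plan, perm), params), shell
            )
            for perm in itertools.permutations(range(3))
        }
        assert result.minimum.mean_bed == pytest.approx(min(naive.values()), rel=1e-10)
        assert result.maximum.mean_bed == pytest.approx(max(naive.values()), rel=1e-10)
        assert naive[result.minimum.permutation] == pytest.approx(
            result.minimum.mean_bed, rel=1e-10
        )

    def test_refusal_names_sequence_count(self, rng, params):
        plan = random_plan(rng, n_shots=13, shape=(4, 4, 4))
        with pytest.raises(ExhaustiveSearchRefused, match="6.2270e"):
            exhaustive_search(plan, params)

    def test_extremes_contain_reversals(self, rng, params):
        # uniform gaps: every order ties its reversal, so the extreme BEDs
        # are attained by at least two permutations
        plan = random_plan(rng, n_shots=4).with_beam_off((0.06,) * 3)
        pres = float(np.percentile(plan.total_dose, 80))
        shell = extract_shell(plan.total_dose, pres, tolerance=0.5)
        result = exhaustive_search(plan, params, shell=shell)
        rev = tuple(reversed(result.minimum.permutation))
        from gkbed import ShellMeanBED

        ev = ShellMeanBED(plan, shell, params)
        assert ev.mean_bed(np.array(rev)) == pytest.approx(
            result.minimum.mean_bed, rel=1e-12
        )


class TestHeuristics:
    def test_pyramidal_max_rule(self):
        # ascending rates fill the schedule outside-in: peak mid-schedule
        assert heuristic_max_sequence([1, 2, 3, 4, 5]) == (0, 2, 4, 3, 1)

    def test_zigzag_min_rule(self):
        assert heuristic_min_sequence([1, 2, 3, 4, 5]) == (4, 0, 3, 1, 2)

    def test_all_equal_rates_keep_original_order(self):
        assert heuristic_max_sequence([2.0, 2.0, 2.0]) == (0, 1, 2)
        assert heuristic_min_sequence([2.0, 2.0, 2.0]) == (0, 1, 2)

    def test_two_shots_reversal_equivalent(self, rng, params):
        plan = random_plan(rng, n_shots=2).with_beam_off((0.06,))
        pres = float(np.percentile(plan.total_dose, 80))
        shell = extract_shell(plan.total_dose, pres, tolerance=0.5)
        from gkbed import heuristic_search

        result = heuristic_search(plan, params, shell=shell)
        assert result.minimum.mean_bed == pytest.approx(
            result.maximum.mean_bed, rel=1e-12
        )

    def test_permutations_are_bijections(self, rng):
        rates = rng.uniform(0.1, 3.0, 9)
        for perm in (heuristic_max_sequence(rates), heuristic_min_sequence(rates)):
            assert sorted(perm) == list(range(9))


class TestDeltaRel:
    def test_published_case_example(self):
        assert delta_rel(61.95, 60.67, 63.33) == pytest.approx(4.29, abs=0.005)

    def test_degenerate_and_simple(self):
        assert delta_rel(50.0, 45.0, 55.0) == pytest.approx(20.0)
        assert delta_rel(10.0, 7.0, 7.0) == 0.0
        with pytest.raises(ValueError):
            delta_rel(0.0, 1.0, 2.0)


class TestPairedTTest:
    def test_identical_vectors(self):
        t, df, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and df == 2 and p == 1.0

    def test_hand_computed_example(self):
        # d = (-1,-2,-3): mean -2, sd 1, t = -2/(1/sqrt(3)) = -3.464
        t, df, p = paired_t_test([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert t == pytest.approx(-3.4641, abs=1e-3)
        assert df == 2
        assert p == pytest.approx(0.0742, abs=5e-4)

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


class TestCohortSummary:
    def test_all_identical_rows_degenerate(self):
        rows = [
            CohortRow("a", 12.0, 30.0, 5, 60.0, 60.0, 60.0),
            CohortRow("b", 13.0, 30.0, 5, 60.0, 60.0, 60.0),
            CohortRow("c", 13.0, 30.0, 5, 60.0, 60.0, 60.0),
        ]
        summary = cohort_summary(rows)
        assert summary.groups[12.0].spread_pct == 0.0
        assert summary.group_bed_ratio_pct == pytest.approx(0.0)
        assert summary.mean_delta_rel == 0.0
        assert summary.overall_t_test[0] == 0.0

    def test_reference_cohort_group_sizes(self):
        rows = reference_cohort()
        assert sum(r.prescription == 12.0 for r in rows) == 6
        assert sum(r.prescription == 13.0 for r in rows) == 9
        summary = cohort_summary(rows)
        assert summary.groups[12.0].mean_n_shots == pytest.approx(15.0)
        assert summary.groups[13.0].mean_total_time == pytest.approx(40.69, abs=0.005)
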