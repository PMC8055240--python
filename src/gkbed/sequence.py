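"""Iso-centre delivery-order evaluation and optimization.

Because the repair terms of the BED couple every pair of sub-fractions
through ``exp(-mu * separation)``, the order in which a plan's iso-centres
are delivered changes the shell-mean BED even though the physical dose grid
is order-invariant.  This module provides:

* exhaustive evaluation of all ``n!`` delivery orders (practical for
  ``n <= 8``; 8! = 40,320 schedules),
* deterministic heuristics that group high dose-rate shots mid-schedule
  ("pyramidal", maximising BED) or interleave them with low-rate shots
  ("zig-zag", minimising BED),
* per-case and cohort-level statistics: the relative achievable range
  ``delta_rel`` and paired t-tests between min- and max-BED sequences.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import RepairParameters
from .plan import TreatmentPlan
from .shell import Shell, ShellMeanBED, extract_shell

__all__ = [
    "SequenceEvaluation",
    "SequenceSearchResult",
    "CohortRow",
    "CohortSummary",
    "EXHAUSTIVE_LIMIT",
    "apply_sequence",
    "exhaustive_search",
    "heuristic_max_sequence",
    "heuristic_min_sequence",
    "heuristic_search",
    "delta_rel",
    "paired_t_test",
    "cohort_summary",
]

#: Largest iso-centre count accepted for exhaustive permutation search
#: without an explicit override (8! = 40,320 schedules).
EXHAUSTIVE_LIMIT = 8

_PERMUTATION_CHUNK = 5040


class ExhaustiveSearchRefused(ValueError):
    """Exhaustive search over too many iso-centres was requested."""


@dataclass(frozen=True)
class SequenceEvaluation:
    """One delivery order and its shell-mean BED."""

    permutation: tuple[int, ...]
    mean_bed: float


@dataclass(frozen=True)
class SequenceSearchResult:
    """Extremal sequences of a search plus the number of schedules tried."""

    minimum: SequenceEvaluation
    maximum: SequenceEvaluation
    n_evaluated: int


def _validate_permutation(permutation, n: int) -> tuple[int, ...]:
    perm = tuple(int(p) for p in permutation)
    if sorted(perm) != list(range(n)):
        raise ValueError(
            f"permutation {perm!r} is not a bijection on 0..{n - 1}"
        )
    return perm


def apply_sequence(plan: TreatmentPlan, permutation) -> TreatmentPlan:
    """Re-order the plan's shots according to ``permutation``.

    ``permutation[p]`` is the original index of the shot delivered in slot
    ``p``.  Beam-on times travel with their shots; beam-off durations stay
    attached to schedule slots (inert when all gaps share the default
    0.06 min value).  The total dose grid is unchanged.
    """
    perm = _validate_permutation(permutation, plan.n_shots)
    return replace(plan, shots=tuple(plan.shots[p] for p in perm))


def exhaustive_search(
    plan: TreatmentPlan,
    params: RepairParameters,
    limit: int = EXHAUSTIVE_LIMIT,
    shell: Shell | None = None,
    override: bool = False,
) -> SequenceSearchResult:
    """Evaluate every delivery order and return the min/max BED sequences.

    Evaluation uses the shell-mean BED with cached pairwise rate moments,
    so each schedule costs O(n^2).  Plans with more than ``limit``
    iso-centres are refused (naming the sequence count the search would
    need) unless ``override`` is set.  Ties are broken by the
    lexicographically smallest permutation.
    """
    n = plan.n_shots
    if n > limit and not override:
        count = math.factorial(n)
        raise ExhaustiveSearchRefused(
            f"exhaustive search over {n} iso-centres would evaluate "
            f"{count:,} ≈ {count:.4e} sequences (limit {limit}); "
            "pass override=True to force"
        )
    if shell is None:
        shell = extract_shell(plan.total_dose, plan.prescription)
    evaluator = ShellMeanBED(plan, shell, params)

    best_min: SequenceEvaluation | None = None
    best_max: SequenceEvaluation | None = None
    n_evaluated = 0
    perm_iter = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perm_iter, _PERMUTATION_CHUNK))
        if not chunk:
            break
        orders = np.array(chunk)
        beds = evaluator.mean_bed_many(orders)
        n_evaluated += len(chunk)
        i_min = int(np.argmin(beds))
        i_max = int(np.argmax(beds))
        # itertools yields lexicographic order, strict comparison keeps the
        # lexicographically smallest permutation on exact ties
        if best_min is None or beds[i_min] < best_min.mean_bed:
            best_min = SequenceEvaluation(chunk[i_min], float(beds[i_min]))
        if best_max is None or beds[i_max] > best_max.mean_bed:
            best_max = SequenceEvaluation(chunk[i_max], float(beds[i_max]))
    assert best_min is not None and best_max is not None
    return SequenceSearchResult(best_min, best_max, n_evaluated)


# ---------------------------------------------------------------------------
# Dose-rate heuristics
# ---------------------------------------------------------------------------

def _rate_order(rates: np.ndarray, descending: bool = False) -> list[int]:
    """Stable sort of shot indices by rate, ties by original index."""
    idx = np.argsort(rates, kind="stable")
    return list(idx[::-1] if descending else idx)


def heuristic_max_sequence(rates) -> tuple[int, ...]:
    """Pyramidal BED-maximising order from per-shot mean shell dose-rates.

    Shots sorted ascending by rate fill the schedule outside-in,
    alternating left and right ends, so the highest-rate shots end up
    contiguous mid-schedule where their mutual separations are smallest.
    Ties are broken by original shot index; an all-tied rate vector keeps
    the original order (the rates carry no information to act on).
    """
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    if n == 0:
        return ()
    if np.all(rates == rates[0]):
        return tuple(range(n))
    ascending = _rate_order(rates)
    sequence = [-1] * n
    left, right = 0, n - 1
    for i, shot in enumerate(ascending):
        if i % 2 == 0:
            sequence[left] = shot
            left += 1
        else:
            sequence[right] = shot
            right -= 1
    return tuple(sequence)


def heuristic_min_sequence(rates) -> tuple[int, ...]:
    """Zig-zag BED-minimising order from per-shot mean shell dose-rates.

    Alternates the highest-remaining and lowest-remaining rate shots so
    that high-rate shots are spread out, separated by low-rate deliveries.
    Ties are broken by original shot index; an all-tied rate vector keeps
    the original order.
    """
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    if n == 0:
        return ()
    if np.all(rates == rates[0]):
        return tuple(range(n))
    ascending = _rate_order(rates)
    sequence = []
    lo, hi = 0, n - 1
    take_high = True
    while lo <= hi:
        if take_high:
            sequence.append(ascending[hi])
            hi -= 1
        else:
            sequence.append(ascending[lo])
            lo += 1
        take_high = not take_high
    return tuple(sequence)


def heuristic_search(
    plan: TreatmentPlan,
    params: RepairParameters,
    shell: Shell | None = None,
) -> SequenceSearchResult:
    """Evaluate the pyramidal-max and zig-zag-min heuristic sequences."""
    from .shell import shell_dose_rates

    if shell is None:
        shell = extract_shell(plan.total_dose, plan.prescription)
    rates = shell_dose_rates(plan, shell)
    evaluator = ShellMeanBED(plan, shell, params)
    perm_max = heuristic_max_sequence(rates)
    perm_min = heuristic_min_sequence(rates)
    bed_max = evaluator.mean_bed(np.array(perm_max))
    bed_min = evaluator.mean_bed(np.array(perm_min))
    return SequenceSearchResult(
        minimum=SequenceEvaluation(perm_min, bed_min),
        maximum=SequenceEvaluation(perm_max, bed_max),
        n_evaluated=2,
    )


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

def delta_rel(bed_orig: float, bed_min: float, bed_max: float) -> float:
    """Achievable mean-BED range relative to the original sequence (%).

    ``100 * (bed_max - bed_min) / bed_orig``.
    """
    if bed_orig <= 0:
        raise ValueError(f"original mean BED must be > 0, got {bed_orig!r}")
    return 100.0 * (bed_max - bed_min) / bed_orig


def paired_t_test(x, y) -> tuple[float, int, float]:
    """Classical paired t-test on the differences ``x - y``.

    Returns ``(t, df, p)`` with ``df = n - 1`` and a two-sided p-value.
    Raises on unequal lengths, fewer than two pairs, or zero-variance
    differences (degenerate t statistic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired t-test needs two equal-length 1D vectors")
    if x.size < 2:
        raise ValueError("paired t-test needs at least two pairs")
    diffs = x - y
    if np.allclose(diffs, diffs[0]) and not np.all(diffs == 0.0):
        # identical nonzero differences: sd = 0, t undefined
        raise ValueError("zero-variance differences: t statistic undefined")
    if np.all(diffs == 0.0):
        return 0.0, x.size - 1, 1.0
    result = stats.ttest_rel(x, y)
    return float(result.statistic), int(x.size - 1), float(result.pvalue)


@dataclass(frozen=True)
class CohortRow:
    """Per-case sequencing result: the printed-table row of one treatment."""

    case_id: str
    prescription: float
    total_time: float
    n_shots: int
    bed_orig: float
    bed_min: float
    bed_max: float

    @property
    def delta_rel(self) -> float:
        return delta_rel(self.bed_orig, self.bed_min, self.bed_max)


@dataclass(frozen=True)
class GroupSummary:
    """Averages and spreads of one prescription group."""

    prescription: float
    n_cases: int
    mean_total_time: float
    mean_n_shots: float
    mean_bed_orig: float
    mean_bed_min: float
    mean_bed_max: float
    mean_delta_rel: float
    spread_pct: float
    t_test: tuple[float, int, float]


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level sequencing statistics.

    ``spread_pct`` per group is the min-to-max envelope across cases,
    ``100 * (max bed_max - min bed_min) / mean bed_orig``; the heuristic
    increase/decrease are cohort means of the per-case relative gains and
    losses; ``group_bed_ratio_pct`` compares the two prescription groups'
    mean original BEDs.
    """

    groups: dict[float, GroupSummary]
    mean_delta_rel: float
    heuristic_increase_pct: float
    heuristic_decrease_pct: float
    group_bed_ratio_pct: float | None
    overall_t_test: tuple[float, int, float]


def cohort_rows_frame(rows: list[CohortRow]) -> pd.DataFrame:
    """Tabulate per-case rows (printed-table layout)."""
    return pd.DataFrame(
        {
            "case": [r.case_id for r in rows],
            "dose_gy": [r.prescription for r in rows],
            "T_min": [r.total_time for r in rows],
            "iso_centre_number": [r.n_shots for r in rows],
            "bed_orig": [r.bed_orig for r in rows],
            "bed_min": [r.bed_min for r in rows],
            "bed_max": [r.bed_max for r in rows],
            "delta_rel_pct": [r.delta_rel for r in rows],
        }
    )


def cohort_summary(rows: list[CohortRow]) -> CohortSummary:
    """Summarise per-case sequencing rows into cohort statistics.

    Produces per-prescription-group averages, the cross-case min/max BED
    spread per group, the cohort-mean achievable range and heuristic
    gain/loss, the between-group original-BED ratio (two groups only), and
    paired min-vs-max t-tests per group and overall.
    """
    if not rows:
        raise ValueError("cohort summary needs at least one row")
    groups: dict[float, GroupSummary] = {}
    for dose in sorted({r.prescription for r in rows}):
        members = [r for r in rows if r.prescription == dose]
        mean_orig = float(np.mean([r.bed_orig for r in members]))
        spread = (
            100.0
            * (max(r.bed_max for r in members) - min(r.bed_min for r in members))
            / mean_orig
        )
        groups[dose] = GroupSummary(
            prescription=dose,
            n_cases=len(members),
            mean_total_time=float(np.mean([r.total_time for r in members])),
            mean_n_shots=float(np.mean([r.n_shots for r in members])),
            mean_bed_orig=mean_orig,
            mean_bed_min=float(np.mean([r.bed_min for r in members])),
            mean_bed_max=float(np.mean([r.bed_max for r in members])),
            mean_delta_rel=float(np.mean([r.delta_rel for r in members])),
            spread_pct=spread,
            t_test=paired_t_test(
                [r.bed_min for r in members], [r.bed_max for r in members]
            )
            if len(members) >= 2
            else (math.nan, len(members) - 1, math.nan),
        )

    ratio = None
    if len(groups) == 2:
        lo, hi = sorted(groups)
        ratio = 100.0 * (groups[hi].mean_bed_orig / groups[lo].mean_bed_orig - 1.0)

    return CohortSummary(
        groups=groups,
        mean_delta_rel=float(np.mean([r.delta_rel for r in rows])),
        heuristic_increase_pct=float(
            np.mean([100.0 * (r.bed_max - r.bed_orig) / r.bed_orig for r in rows])
        ),
        heuristic_decrease_pct=float(
            np.mean([100.0 * (r.bed_orig - r.bed_min) / r.bed_orig for r in rows])
        ),
        group_bed_ratio_pct=ratio,
        overall_t_test=paired_t_test(
            [r.bed_min for r in rows], [r.bed_max for r in rows]
        ),
    )
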