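"""Impact of an unscheduled treatment interruption on the shell-mean BED.

A single unscheduled gap (nominally 15 min, about one fast repair
half-time) is simulated at every possible position between consecutive
iso-centres by lengthening that slot's scheduled beam-off period.  Dose
grids are untouched, so the prescription shell is unchanged; only the
protraction (repair) terms lose interaction across the gap, and the
shell-mean BED can only decrease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RepairParameters
from .plan import TreatmentPlan
from .shell import Shell, ShellMeanBED, extract_shell

__all__ = ["GapSweepResult", "DEFAULT_GAP_MIN", "insert_gap", "gap_sweep"]

#: Nominal unscheduled interruption duration (min) — about one fast
#: repair half-time.
DEFAULT_GAP_MIN = 15.0


@dataclass(frozen=True)
class GapSweepResult:
    """Shell-mean BED change from one gap at each inter-shot position.

    ``positions`` are 1-based slot indices (gap after shot ``i``);
    ``relative_change_pct`` entries are <= 0 for a positive gap.
    """

    case_id: str
    gap_min: float
    positions: tuple[int, ...]
    mean_bed_original: float
    mean_bed_gapped: tuple[float, ...]
    relative_change_pct: tuple[float, ...]

    @property
    def worst_position(self) -> int:
        """Position whose gap causes the largest BED reduction."""
        return self.positions[int(np.argmin(self.relative_change_pct))]

    @property
    def best_position(self) -> int:
        """Position whose gap causes the smallest BED reduction."""
        return self.positions[int(np.argmax(self.relative_change_pct))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case": self.case_id,
                "position": self.positions,
                "gap_min": self.gap_min,
                "mean_bed_original": self.mean_bed_original,
                "mean_bed_gapped": self.mean_bed_gapped,
                "relative_change_pct": self.relative_change_pct,
            }
        )


def insert_gap(
    plan: TreatmentPlan, position: int, duration: float = DEFAULT_GAP_MIN
) -> TreatmentPlan:
    """Lengthen the beam-off period after shot ``position`` by ``duration``.

    The gap is additive to the scheduled beam-off (it models an extra delay
    on top of the ~0.06 min repositioning pause), so the total treatment
    time increases by exactly ``duration``.  ``position`` is 1-based:
    ``1 <= position <= n_shots - 1``.
    """
    if duration < 0:
        raise ValueError(f"gap duration must be >= 0 min, got {duration!r}")
    if not 1 <= position <= plan.n_shots - 1:
        raise ValueError(
            f"gap position must be in [1, {plan.n_shots - 1}], got {position}"
        )
    beam_off = list(plan.beam_off)
    beam_off[position - 1] += duration
    return plan.with_beam_off(beam_off)


def gap_sweep(
    plan: TreatmentPlan,
    params: RepairParameters,
    duration: float = DEFAULT_GAP_MIN,
    shell: Shell | None = None,
) -> GapSweepResult:
    """Relative shell-mean BED change of one gap at every position.

    For each position ``i`` in ``1 .. n_shots - 1`` the change is
    ``100 * (mean_bed_gap - mean_bed_orig) / mean_bed_orig`` on the fixed
    prescription shell of the original plan.  A single-shot plan yields an
    empty result (there is no inter-shot position).
    """
    if shell is None:
        shell = extract_shell(plan.total_dose, plan.prescription)
    if plan.n_shots == 1:
        evaluator = ShellMeanBED(plan, shell, params)
        return GapSweepResult(
            case_id=plan.case_id,
            gap_min=duration,
            positions=(),
            mean_bed_original=evaluator.mean_bed(),
            mean_bed_gapped=(),
            relative_change_pct=(),
        )

    evaluator = ShellMeanBED(plan, shell, params)
    baseline = evaluator.mean_bed()
    gapped = []
    base_gaps = np.asarray(plan.beam_off, dtype=float)
    for i in range(plan.n_shots - 1):
        gaps = base_gaps.copy()
        gaps[i] += duration
        gapped.append(evaluator.mean_bed(beam_off=gaps))
    gapped_arr = np.array(gapped)
    rel = 100.0 * (gapped_arr - baseline) / baseline
    return GapSweepResult(
        case_id=plan.case_id,
        gap_min=duration,
        positions=tuple(range(1, plan.n_shots)),
        mean_bed_original=baseline,
        mean_bed_gapped=tuple(gapped_arr),
        relative_change_pct=tuple(rel),
    )
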