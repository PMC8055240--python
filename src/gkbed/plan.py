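"""Treatment-plan data model, absolute timeline, and plan-bundle I/O.

A multi-iso-centre Gamma Knife treatment is an ordered sequence of "shots"
(iso-centres), each contributing its own 3D dose grid (Gy) on a shared voxel
lattice and delivered over its own beam-on time (min), with short beam-off
periods between consecutive shots while the patient couch repositions
(0.06 min on average for the machine protocols this format emulates).

On disk a plan is a "bundle": a JSON manifest plus one NIfTI float32 dose
volume per shot — a plain stand-in for a planning-system research export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .core import VoxelExposure

__all__ = [
    "IsoCentre",
    "TreatmentPlan",
    "Timeline",
    "DEFAULT_BEAM_OFF_MIN",
    "build_timeline",
    "voxel_exposure",
    "read_plan_bundle",
    "write_plan_bundle",
]

#: Average scheduled beam-off period between consecutive iso-centres (min).
DEFAULT_BEAM_OFF_MIN = 0.06

MANIFEST_NAME = "plan.json"


class PlanValidationError(ValueError):
    """A plan bundle or plan construction violated an invariant."""


@dataclass(frozen=True)
class IsoCentre:
    """One shot: a 3D dose grid (Gy) delivered over ``beam_on`` minutes."""

    id: str
    beam_on: float
    dose: np.ndarray

    def __post_init__(self) -> None:
        if not self.beam_on > 0:
            raise PlanValidationError(
                f"shot {self.id!r}: beam_on must be > 0 min, got {self.beam_on!r}"
            )
        dose = np.asarray(self.dose, dtype=float)
        if dose.ndim != 3:
            raise PlanValidationError(
                f"shot {self.id!r}: dose grid must be 3D, got shape {dose.shape}"
            )
        if np.any(dose < 0):
            raise PlanValidationError(f"shot {self.id!r}: dose must be >= 0 Gy")
        object.__setattr__(self, "dose", dose)


@dataclass(frozen=True)
class TreatmentPlan:
    """Ordered shots with inter-shot beam-off durations and a prescription.

    Invariants: at least one shot; all shot grids share one lattice;
    ``len(beam_off) == n_shots - 1`` with every entry >= 0.
    """

    case_id: str
    shots: tuple[IsoCentre, ...]
    beam_off: tuple[float, ...]
    prescription: float
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shots", tuple(self.shots))
        object.__setattr__(self, "beam_off", tuple(float(g) for g in self.beam_off))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        if len(self.shots) < 1:
            raise PlanValidationError("plan needs at least one iso-centre")
        if len(self.beam_off) != len(self.shots) - 1:
            raise PlanValidationError(
                f"beam_off length must be n_shots - 1 = {len(self.shots) - 1}, "
                f"got {len(self.beam_off)}"
            )
        if any(g < 0 for g in self.beam_off):
            raise PlanValidationError("beam_off durations must be >= 0 min")
        if not self.prescription > 0:
            raise PlanValidationError("prescription dose must be > 0 Gy")
        shape = self.shots[0].dose.shape
        for shot in self.shots[1:]:
            if shot.dose.shape != shape:
                raise PlanValidationError(
                    f"shot {shot.id!r}: lattice mismatch "
                    f"({shot.dose.shape} vs {shape})"
                )

    @property
    def n_shots(self) -> int:
        return len(self.shots)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.shots[0].dose.shape

    @property
    def total_time(self) -> float:
        """Total treatment time (min): all beam-on plus all beam-off."""
        return float(sum(s.beam_on for s in self.shots) + sum(self.beam_off))

    @property
    def total_dose(self) -> np.ndarray:
        """Per-voxel total physical dose D_T (Gy): elementwise shot sum."""
        return np.sum([s.dose for s in self.shots], axis=0)

    def with_beam_off(self, beam_off: Sequence[float]) -> "TreatmentPlan":
        return replace(self, beam_off=tuple(beam_off))


@dataclass(frozen=True)
class Timeline:
    """Absolute (start, end) times (min) of each shot; first start at 0."""

    starts: tuple[float, ...]
    ends: tuple[float, ...]

    @property
    def total_time(self) -> float:
        return self.ends[-1]


def build_timeline(plan: TreatmentPlan) -> Timeline:
    """Lay the plan's shots on an absolute clock.

    ``start_1 = 0``; each shot ends after its beam-on time and the next one
    starts after the scheduled beam-off; the last end equals the plan's
    total treatment time.
    """
    starts, ends = [], []
    t = 0.0
    for k, shot in enumerate(plan.shots):
        starts.append(t)
        t += shot.beam_on
        ends.append(t)
        if k < len(plan.beam_off):
            t += plan.beam_off[k]
    return Timeline(starts=tuple(starts), ends=tuple(ends))


def voxel_exposure(
    plan: TreatmentPlan,
    timeline: Timeline,
    voxel: tuple[int, int, int],
    drop_zero: bool = False,
) -> VoxelExposure:
    """Exposure protocol of one voxel: (rate, duration) per shot plus gaps.

    Segment rates are ``dose_k(voxel) / beam_on_k``.  Zero-dose shots are
    kept as rate-0 segments by default, which is Phi-equivalent to dropping
    them (``drop_zero=True``) since zero-rate terms vanish and absolute
    timing is preserved.
    """
    rates = tuple(
        float(shot.dose[voxel]) / shot.beam_on for shot in plan.shots
    )
    durations = tuple(shot.beam_on for shot in plan.shots)
    exposure = VoxelExposure(
        rates=rates, durations=durations, intervals=plan.beam_off
    )
    return exposure.drop_zero_rate() if drop_zero else exposure


# ---------------------------------------------------------------------------
# Plan bundle I/O
# ---------------------------------------------------------------------------

def write_plan_bundle(plan: TreatmentPlan, path: str | Path) -> Path:
    """Write a plan as a JSON manifest plus one NIfTI dose volume per shot.

    Dose volumes are stored as float32 Gy; ``read_plan_bundle`` after
    ``write_plan_bundle`` is the identity up to float32 precision.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    affine = np.diag((*plan.spacing_mm, 1.0))
    shots_meta = []
    for shot in plan.shots:
        fname = f"dose_{shot.id}.nii.gz"
        img = nib.Nifti1Image(shot.dose.astype(np.float32), affine)
        nib.save(img, path / fname)
        shots_meta.append(
            {"id": shot.id, "beam_on_min": shot.beam_on, "dose_file": fname}
        )
    manifest = {
        "case_id": plan.case_id,
        "prescription_dose_gy": plan.prescription,
        "lattice": {"shape": list(plan.shape), "spacing_mm": list(plan.spacing_mm)},
        "shots": shots_meta,
        "beam_off_min": list(plan.beam_off),
    }
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    return path


def read_plan_bundle(path: str | Path) -> TreatmentPlan:
    """Read a plan bundle, validating manifest/volume consistency.

    A legacy manifest without ``beam_off_min`` is filled with the default
    0.06 min scheduled gap between every pair of consecutive shots.
    """
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise PlanValidationError(f"missing manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())

    try:
        shots_meta = manifest["shots"]
        prescription = float(manifest["prescription_dose_gy"])
        lattice = manifest["lattice"]
        shape = tuple(lattice["shape"])
        spacing = tuple(float(s) for s in lattice["spacing_mm"])
    except KeyError as exc:
        raise PlanValidationError(f"manifest missing field {exc.args[0]!r}") from exc

    if "beam_off_min" in manifest:
        beam_off = tuple(float(g) for g in manifest["beam_off_min"])
    else:
        beam_off = (DEFAULT_BEAM_OFF_MIN,) * (len(shots_meta) - 1)
    if len(beam_off) != len(shots_meta) - 1:
        raise PlanValidationError(
            f"beam_off_min length {len(beam_off)} != n_shots - 1 "
            f"= {len(shots_meta) - 1}"
        )

    shots = []
    for meta in shots_meta:
        dose_path = path / meta["dose_file"]
        if not dose_path.exists():
            raise PlanValidationError(f"missing dose volume {dose_path}")
        dose = np.asarray(nib.load(dose_path).get_fdata(), dtype=float)
        if dose.shape != shape:
            raise PlanValidationError(
                f"shot {meta['id']!r}: volume shape {dose.shape} does not "
                f"match manifest lattice {shape}"
            )
        beam_on = float(meta["beam_on_min"])
        if beam_on <= 0:
            raise PlanValidationError(
                f"shot {meta['id']!r}: beam_on_min must be > 0, got {beam_on}"
            )
        shots.append(IsoCentre(id=str(meta["id"]), beam_on=beam_on, dose=dose))

    return TreatmentPlan(
        case_id=str(manifest.get("case_id", path.name)),
        shots=tuple(shots),
        beam_off=beam_off,
        prescription=prescription,
        spacing_mm=spacing,
    )
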