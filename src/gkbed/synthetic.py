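"""Synthetic multi-iso-centre treatment plans and cohorts.

Emulates planning-system research exports (per-shot 3D dose grids and
beam-on times) for vestibular-schwannoma-like Gamma Knife treatments, so
the BED pipeline is testable without patient data.  Shots are anisotropic
Gaussian dose kernels centred inside an ellipsoidal target on a 31x31x31,
1 mm lattice; kernel widths emulate the 4/8/16 mm collimators, and
source-decay and blocking effects are collapsed into lognormal per-shot
amplitude heterogeneity (the BED model only sees rates and times).

Defaults mirror the emulated study's cohort: 6 cases at 12 Gy and 9 at
13 Gy, iso-centre counts 4-19, total treatment times 20.8-73.7 min, and a
0.06 min scheduled beam-off between shots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .plan import DEFAULT_BEAM_OFF_MIN, IsoCentre, TreatmentPlan
from .shell import extract_shell

__all__ = ["SyntheticConfig", "make_plan", "make_cohort"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Tunable knobs of the synthetic cohort generator.

    ``cases_per_group`` maps prescription dose (Gy) to case count;
    ``heterogeneity`` is the lognormal sigma of per-shot amplitude draws
    (larger -> fewer dominant shots carry more of the shell dose);
    ``collimators_mm`` are the kernel FWHMs emulating collimator sizes.
    """

    cases_per_group: dict[float, int] = field(
        default_factory=lambda: {12.0: 6, 13.0: 9}
    )
    n_shots_range: tuple[int, int] = (4, 19)
    total_time_range: tuple[float, float] = (20.8, 73.7)
    shape: tuple[int, int, int] = (31, 31, 31)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    collimators_mm: tuple[float, ...] = (4.0, 8.0, 16.0)
    penumbra_mm: float = 3.0
    axial_elongation: float = 1.5
    heterogeneity: float = 0.9
    beam_off_min: float = DEFAULT_BEAM_OFF_MIN
    shell_tolerance: float = 0.02
    min_shell_voxels: int = 30
    min_rate_span: float = 3.0
    max_retries: int = 60

    def __post_init__(self) -> None:
        if self.n_shots_range[0] < 1 or self.n_shots_range[0] > self.n_shots_range[1]:
            raise ValueError("n_shots_range must be ordered and >= 1")
        if not 0 < self.total_time_range[0] <= self.total_time_range[1]:
            raise ValueError("total_time_range must be positive and ordered")
        if any(c < 1 for c in self.cases_per_group.values()):
            raise ValueError("each prescription group needs >= 1 case")


def _gaussian_kernel(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    centre_mm: np.ndarray,
    sigmas_mm: np.ndarray,
) -> np.ndarray:
    axes = [
        (np.arange(n) * s - c) ** 2 / (2.0 * sig**2)
        for n, s, c, sig in zip(shape, spacing, centre_mm, sigmas_mm)
    ]
    expo = (
        axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    )
    return np.exp(-expo)


def _sphere_points(n: int) -> np.ndarray:
    """Fibonacci-lattice sample of the unit sphere, shape (n, 3)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _best_shell_level(
    dose: np.ndarray, prescription: float, tolerance: float
) -> tuple[float, int]:
    """Raw-dose level whose ±tolerance window (after rescaling the plan so
    that the level maps to the prescription) holds the most voxels.

    Candidate levels span 30-70% of the maximum dose, the range where a
    prescription iso-surface normally sits relative to the hottest spot.
    """
    flat = np.sort(dose.ravel())
    peak = flat[-1]
    levels = np.linspace(0.30, 0.70, 241) * peak
    widths = tolerance * levels / prescription
    counts = np.searchsorted(flat, levels + widths, side="right") - np.searchsorted(
        flat, levels - widths, side="left"
    )
    best = int(np.argmax(counts))
    return float(levels[best]), int(counts[best])


def make_plan(
    config: SyntheticConfig,
    seed: int | np.random.Generator,
    n_shots: int,
    prescription: float,
    total_time: float | None = None,
    case_id: str = "synthetic",
    elongated: bool = False,
) -> TreatmentPlan:
    """Generate one synthetic plan with a usable prescription shell.

    Shot kernels are placed inside an ellipsoidal target (one elongated
    preset stretches it along a single axis, emulating geometries where
    rate-based re-sequencing fails), amplitudes are rescaled so that the
    summed dose crosses the prescription on a shell of at least
    ``config.min_shell_voxels`` voxels, and beam-on times are drawn so the
    total treatment time lands on ``total_time`` (or uniformly inside the
    configured range).  Draws failing the shell-size or dose-rate-span
    self-checks are regenerated, with bounded retries.

    Deterministic for a fixed seed and arguments.
    """
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lo_t, hi_t = config.total_time_range
    if total_time is None:
        total_time = float(rng.uniform(lo_t, hi_t))
    beam_off_total = config.beam_off_min * (n_shots - 1)
    if total_time <= beam_off_total:
        raise ValueError(
            f"total_time {total_time} min cannot accommodate {n_shots - 1} "
            f"beam-off periods of {config.beam_off_min} min"
        )

    centre_mm = np.array(
        [(n - 1) * s / 2.0 for n, s in zip(config.shape, config.spacing_mm)]
    )
    last_error = "no attempt made"
    for _ in range(config.max_retries):
        if elongated:
            semi_axes = np.array(
                [rng.uniform(10.0, 13.0), rng.uniform(3.0, 4.5), rng.uniform(3.0, 4.5)]
            )
            semi_axes = rng.permutation(semi_axes)
        else:
            semi_axes = rng.uniform(6.0, 10.0, size=3)

        # shot positions: uniform draws inside the target ellipsoid
        unit_positions = []
        while len(unit_positions) < n_shots:
            p = rng.uniform(-1.0, 1.0, size=3)
            if (p**2).sum() <= 1.0:
                unit_positions.append(p)
        unit_positions = np.array(unit_positions)
        positions = centre_mm + unit_positions * semi_axes
        radial = np.sqrt((unit_positions**2).sum(axis=1))  # 0 centre, 1 surface

        # clinical packing: large collimators fill the core, small ones
        # shape the periphery
        sizes = np.asarray(config.collimators_mm, dtype=float)
        fwhm = np.empty(n_shots)
        for k, d in enumerate(radial):
            weights = np.exp(-(((sizes / sizes.max()) - (1.0 - d)) ** 2) / 0.08)
            fwhm[k] = rng.choice(sizes, p=weights / weights.sum())
        # delivered profile width = collimator size + penumbra; shots are
        # elongated along the device axis
        eff = (fwhm + config.penumbra_mm) / 2.355
        sigmas = np.column_stack(
            [eff, eff, eff * config.axial_elongation]
        ) * rng.lognormal(0.0, 0.10, size=(n_shots, 3))

        # amplitude fit: conform the summed dose to the prescription on the
        # target surface while preferring a lognormal per-shot contribution
        # profile (configured heterogeneity); every shot keeps a minimum
        # surface presence, as on measured per-shot dose-rate profiles
        surface_mm = centre_mm + _sphere_points(128) * semi_axes
        surface_a = np.stack(
            [
                np.exp(-(((surface_mm - c) ** 2 / (2.0 * s**2)).sum(axis=1)))
                for c, s in zip(positions, sigmas)
            ],
            axis=1,
        )
        preferred = rng.lognormal(0.0, config.heterogeneity, size=n_shots)
        preferred *= prescription / np.median(surface_a @ preferred)
        lam = 0.3
        design = np.vstack([surface_a, lam * np.eye(n_shots)])
        rhs = np.concatenate(
            [np.full(len(surface_mm), prescription), lam * preferred]
        )
        lower = 0.3 * prescription / (
            n_shots * np.maximum(surface_a.mean(axis=0), 1e-3)
        )
        amplitudes = lsq_linear(design, rhs, bounds=(lower, np.inf)).x

        doses = np.stack(
            [
                a * _gaussian_kernel(config.shape, config.spacing_mm, c, s)
                for a, c, s in zip(amplitudes, positions, sigmas)
            ]
        )
        total = doses.sum(axis=0)
        level, count = _best_shell_level(
            total, prescription, config.shell_tolerance
        )
        if count < config.min_shell_voxels:
            last_error = f"shell too small ({count} voxels)"
            continue
        doses *= prescription / level

        # delivery times: every shot's focal dose is comparable (each is
        # planned near the same multiple of the prescription), so beam-on
        # times spread only modestly across shots — independently of the
        # widely varying shell contribution, which is set by geometry
        budget = total_time - beam_off_total
        beam_on = rng.lognormal(0.0, 0.35, size=n_shots)
        beam_on *= budget / beam_on.sum()
        if beam_on.min() < 0.1:
            last_error = "degenerate beam-on split"
            continue

        shots = tuple(
            IsoCentre(id=f"s{k + 1:02d}", beam_on=float(beam_on[k]), dose=doses[k])
            for k in range(n_shots)
        )
        plan = TreatmentPlan(
            case_id=case_id,
            shots=shots,
            beam_off=(config.beam_off_min,) * (n_shots - 1),
            prescription=prescription,
            spacing_mm=config.spacing_mm,
        )

        shell = extract_shell(
            plan.total_dose, prescription, config.shell_tolerance
        )
        if shell.size < config.min_shell_voxels:
            last_error = f"shell too small after rescale ({shell.size} voxels)"
            continue
        if n_shots > 1:
            rates = np.array(
                [s.dose[shell.indices].mean() / s.beam_on for s in shots]
            )
            span = rates.max() / max(rates.min(), 1e-12)
            if span < config.min_rate_span:
                last_error = f"dose-rate span {span:.2f} below required"
                continue
        return plan
    raise RuntimeError(
        f"could not generate a feasible plan in {config.max_retries} draws "
        f"(last failure: {last_error})"
    )


def make_cohort(
    config: SyntheticConfig, seed: int
) -> list[TreatmentPlan]:
    """Generate a full synthetic cohort (default 6 cases at 12 Gy + 9 at 13 Gy).

    Iso-centre counts and total treatment times are sampled across the
    configured ranges; within each prescription group cases are ordered by
    increasing total treatment time, mirroring how such cohorts are
    presented.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    plans: list[TreatmentPlan] = []
    case_no = 0
    lo_n, hi_n = config.n_shots_range
    lo_t, hi_t = config.total_time_range
    for prescription in sorted(config.cases_per_group):
        n_cases = config.cases_per_group[prescription]
        group: list[TreatmentPlan] = []
        # cover the count and time spread across the group
        n_draws = rng.integers(lo_n, hi_n + 1, size=n_cases)
        t_draws = rng.uniform(lo_t, hi_t, size=n_cases)
        for n_shots, total_time in zip(n_draws, t_draws):
            case_no += 1
            group.append(
                make_plan(
                    config,
                    rng,
                    int(n_shots),
                    prescription,
                    total_time=float(total_time),
                    case_id=f"S{case_no:02d}",
                )
            )
        group.sort(key=lambda p: p.total_time)
        plans.extend(group)
    return plans
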