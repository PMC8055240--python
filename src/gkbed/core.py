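"""Bi-exponential incomplete-repair BED model.

Evaluates the biologically effective dose (BED) of a protracted,
piecewise-constant dose-rate exposure under the linear-quadratic model with
bi-exponential repair of sublethal damage.  Each iso-centre ("shot") of a
Gamma Knife treatment is one continuously-irradiated sub-fraction; beam-off
periods between sub-fractions act as incomplete-repair intervals during
which pairwise dose interaction decays as ``exp(-mu * gap)``.

For a voxel exposed to segments with dose-rates ``R_k`` over durations
``t_k``, the dose-protraction sum for repair rate ``mu`` is

    Phi(Xi, mu) = 2 * integral_{s < s'} R(s) R(s') exp(-mu (s' - s)) ds ds'

which expands, for piecewise-constant rates, into closed-form self and cross
terms (Millar-Canney style incomplete-repair algebra).  The BED combines the
fast and slow repair components with a partition coefficient ``c``:

    BED = D_T + [ c * Phi(mu_fast) + (1 - c) * Phi(mu_slow) ] / (alpha/beta)

Units are fixed throughout the package: minutes, Gy and Gy/min; BED carries
units Gy_{alpha/beta}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import integrate

if TYPE_CHECKING:  # pragma: no cover
    from .plan import TreatmentPlan

__all__ = [
    "RepairParameters",
    "VoxelExposure",
    "BEDGrid",
    "repair_rate_from_half_time",
    "phi_self",
    "phi_cross",
    "phi_protocol",
    "bed_voxel",
    "bed_grid",
    "phi_numeric_oracle",
]

LN2 = math.log(2.0)

#: Threshold below which ``x - 1 + exp(-x)`` and ``1 - exp(-x)`` switch to a
#: series expansion to avoid catastrophic cancellation.
_SERIES_CUTOFF = 1e-4


def repair_rate_from_half_time(half_time: float) -> float:
    """Convert a repair half-time (min) to a repair rate ``mu`` (1/min).

    ``mu = ln 2 / T_half``.

    Raises
    ------
    ValueError
        If ``half_time`` is not strictly positive.
    """
    if not half_time > 0:
        raise ValueError(f"repair half-time must be > 0 min, got {half_time!r}")
    return LN2 / half_time


@dataclass(frozen=True)
class RepairParameters:
    """Radiobiological constants of the bi-exponential repair model.

    Defaults are the collective rat-spinal-cord fit used throughout the
    Gamma Knife BED literature: ``alpha_beta = 2.47`` Gy and repair
    half-times 11.4 min (fast) and 129.6 min (slow).  The default partition
    coefficient 0.35 was calibrated against a published 15-case cohort's
    per-case shell-mean BED values (see the methods note): an idealized
    uniform-plan inversion of those printed values gives 0.32-0.40
    depending on the assumed voxel heterogeneity, and independently
    reproduces the published gap-impact range and re-sequencing ranges.

    Attributes
    ----------
    alpha_beta:
        Tissue alpha/beta ratio (Gy); sets the weight of the dose-squared
        (repair-sensitive) term.
    half_time_fast, half_time_slow:
        Repair half-times (min) of the two exponential components;
        ``half_time_fast <= half_time_slow``.
    partition_fast:
        Fraction ``c`` in [0, 1] of the quadratic damage repaired with the
        fast kinetics; ``c = 1`` reduces the model to mono-exponential
        repair at the fast rate.
    """

    alpha_beta: float = 2.47
    half_time_fast: float = 11.4
    half_time_slow: float = 129.6
    partition_fast: float = 0.35

    def __post_init__(self) -> None:
        if not self.alpha_beta > 0:
            raise ValueError(f"alpha_beta must be > 0 Gy, got {self.alpha_beta!r}")
        if not (0 < self.half_time_fast and 0 < self.half_time_slow):
            raise ValueError("repair half-times must be > 0 min")
        if self.half_time_fast > self.half_time_slow:
            raise ValueError(
                "half_time_fast must not exceed half_time_slow "
                f"({self.half_time_fast} > {self.half_time_slow})"
            )
        if not 0.0 <= self.partition_fast <= 1.0:
            raise ValueError(
                f"partition_fast must lie in [0, 1], got {self.partition_fast!r}"
            )

    @property
    def mu_fast(self) -> float:
        """Fast repair rate (1/min); ``mu_fast >= mu_slow``."""
        return repair_rate_from_half_time(self.half_time_fast)

    @property
    def mu_slow(self) -> float:
        """Slow repair rate (1/min)."""
        return repair_rate_from_half_time(self.half_time_slow)

    @property
    def bed_unit(self) -> str:
        """Unit label for BED values produced with these parameters."""
        return f"Gy_{self.alpha_beta:g}"


@dataclass(frozen=True)
class VoxelExposure:
    """The exposure protocol of a single voxel.

    An ordered sequence of continuous-irradiation segments (dose-rate in
    Gy/min, duration in min) separated by beam-off intervals (min).
    """

    rates: tuple[float, ...]
    durations: tuple[float, ...]
    intervals: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        object.__setattr__(self, "durations", tuple(float(t) for t in self.durations))
        object.__setattr__(self, "intervals", tuple(float(g) for g in self.intervals))
        n = len(self.rates)
        if len(self.durations) != n:
            raise ValueError("rates and durations must have equal length")
        if n and len(self.intervals) != n - 1:
            raise ValueError(
                f"need {n - 1} intervals for {n} segments, got {len(self.intervals)}"
            )
        if any(t <= 0 for t in self.durations):
            raise ValueError("segment durations must be > 0 min")
        if any(r < 0 for r in self.rates):
            raise ValueError("dose-rates must be >= 0 Gy/min")
        if any(g < 0 for g in self.intervals):
            raise ValueError("beam-off intervals must be >= 0 min")

    def __len__(self) -> int:
        return len(self.rates)

    @property
    def total_dose(self) -> float:
        """Total physical dose (Gy): sum of rate x duration over segments."""
        return float(
            sum(r * t for r, t in zip(self.rates, self.durations))
        )

    @property
    def start_times(self) -> tuple[float, ...]:
        """Absolute start time (min) of each segment, first segment at 0."""
        starts = []
        t = 0.0
        for k, dur in enumerate(self.durations):
            starts.append(t)
            t += dur
            if k < len(self.intervals):
                t += self.intervals[k]
        return tuple(starts)

    @property
    def end_times(self) -> tuple[float, ...]:
        return tuple(s + t for s, t in zip(self.start_times, self.durations))

    def reversed(self) -> "VoxelExposure":
        """Time-reversed protocol (segments and intervals both reversed)."""
        return VoxelExposure(
            rates=self.rates[::-1],
            durations=self.durations[::-1],
            intervals=self.intervals[::-1],
        )

    def drop_zero_rate(self) -> "VoxelExposure":
        """Remove zero-rate segments, merging their time into the gaps.

        Phi-equivalent to the original protocol (zero-rate terms vanish and
        absolute timing of the remaining segments is preserved).
        """
        keep = [k for k, r in enumerate(self.rates) if r > 0]
        if len(keep) == len(self.rates):
            return self
        starts, ends = self.start_times, self.end_times
        rates = tuple(self.rates[k] for k in keep)
        durations = tuple(self.durations[k] for k in keep)
        intervals = tuple(
            starts[b] - ends[a] for a, b in zip(keep[:-1], keep[1:])
        )
        return VoxelExposure(rates=rates, durations=durations, intervals=intervals)


@dataclass(frozen=True)
class BEDGrid:
    """Per-voxel BED values on a plan's voxel lattice.

    ``values`` is non-negative, zero exactly where the physical dose is zero,
    and bounded above by the acute limit ``D (1 + D / alpha_beta)``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    alpha_beta: float

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def unit(self) -> str:
        return f"Gy_{self.alpha_beta:g}"


# ---------------------------------------------------------------------------
# Stable elementary factors
# ---------------------------------------------------------------------------

def _g_self(x: np.ndarray | float) -> np.ndarray | float:
    """``x - 1 + exp(-x)``, series-protected for small x (-> x^2/2)."""
    x = np.asarray(x, dtype=float)
    small = x < _SERIES_CUTOFF
    safe = np.where(small, 1.0, x)
    out = np.where(
        small,
        x * x / 2.0 - x**3 / 6.0 + x**4 / 24.0,
        safe - 1.0 + np.exp(-safe),
    )
    return out if out.shape else float(out)


def _f_on(x: np.ndarray | float) -> np.ndarray | float:
    """``1 - exp(-x)`` via expm1 (stable for small x)."""
    out = -np.expm1(-np.asarray(x, dtype=float))
    return out if out.shape else float(out)


def _check_mu(mu: float) -> None:
    if not mu > 0:
        raise ValueError(f"repair rate mu must be > 0 (1/min), got {mu!r}")


# ---------------------------------------------------------------------------
# Closed-form protraction terms
# ---------------------------------------------------------------------------

def phi_self(rate: float, duration: float, mu: float) -> float:
    """Self-interaction protraction term of one segment (Gy^2).

    Closed form ``(2 R^2 / mu^2) (mu t - 1 + exp(-mu t))``; tends to the
    acute value ``(R t)^2 = d^2`` as ``mu t -> 0``.
    """
    _check_mu(mu)
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not duration > 0:
        raise ValueError("duration must be > 0 min")
    return 2.0 * rate * rate / (mu * mu) * float(_g_self(mu * duration))


def phi_cross(
    rate_j: float,
    dur_j: float,
    rate_k: float,
    dur_k: float,
    interval: float,
    mu: float,
) -> float:
    """Cross-interaction term of two segments separated by ``interval`` (Gy^2).

    ``interval`` is measured from the end of the earlier segment *j* to the
    start of the later segment *k*.  Closed form
    ``(2 R_j R_k / mu^2) (1 - exp(-mu t_j)) (1 - exp(-mu t_k)) exp(-mu tau)``;
    strictly decreasing in the interval and tending to the acute no-repair
    value ``2 d_j d_k`` as ``mu -> 0``.
    """
    _check_mu(mu)
    if interval < 0:
        raise ValueError(f"beam-off interval must be >= 0 min, got {interval!r}")
    if not (dur_j > 0 and dur_k > 0):
        raise ValueError("segment durations must be > 0 min")
    return (
        2.0
        * rate_j
        * rate_k
        / (mu * mu)
        * float(_f_on(mu * dur_j))
        * float(_f_on(mu * dur_k))
        * math.exp(-mu * interval)
    )


def phi_protocol(exposure: VoxelExposure, mu: float) -> float:
    """Total protraction sum Phi of a protocol at repair rate ``mu`` (Gy^2).

    Sum of per-segment self terms plus all pairwise cross terms, with each
    pair's separation taken from the absolute timeline so that gaps between
    non-adjacent segments accumulate the intermediate beam-on and beam-off
    periods.
    """
    _check_mu(mu)
    n = len(exposure)
    if n == 0:
        return 0.0
    starts = exposure.start_times
    ends = exposure.end_times
    total = 0.0
    for k in range(n):
        total += phi_self(exposure.rates[k], exposure.durations[k], mu)
    for j in range(n):
        if exposure.rates[j] == 0.0:
            continue
        for k in range(j + 1, n):
            if exposure.rates[k] == 0.0:
                continue
            tau = starts[k] - ends[j]
            total += phi_cross(
                exposure.rates[j],
                exposure.durations[j],
                exposure.rates[k],
                exposure.durations[k],
                tau,
                mu,
            )
    return total


def bed_voxel(exposure: VoxelExposure, params: RepairParameters) -> float:
    """BED (Gy_{alpha/beta}) of one voxel's exposure protocol.

    ``BED = D_T + [c Phi(mu_fast) + (1-c) Phi(mu_slow)] / (alpha/beta)``;
    bracketed between ``D_T`` (complete repair) and the acute limit
    ``D_T (1 + D_T / alpha_beta)``.
    """
    d_total = exposure.total_dose
    if d_total == 0.0:
        return 0.0
    c = params.partition_fast
    phi = 0.0
    if c > 0.0:
        phi += c * phi_protocol(exposure, params.mu_fast)
    if c < 1.0:
        phi += (1.0 - c) * phi_protocol(exposure, params.mu_slow)
    return d_total + phi / params.alpha_beta


# ---------------------------------------------------------------------------
# Vectorized grid evaluation
# ---------------------------------------------------------------------------

def _phi_weights(beam_on: np.ndarray, starts: np.ndarray, mu: float):
    """Permutation-independent per-shot and pairwise Phi weights.

    Returns ``(a, b)`` with ``a[k]`` the self-term weight multiplying
    ``R_k^2`` and ``b[j, k]`` (upper triangle) the cross-term weight
    multiplying ``R_j R_k``.
    """
    ends = starts + beam_on
    a = 2.0 / mu**2 * _g_self(mu * beam_on)
    f = _f_on(mu * beam_on)
    tau = starts[None, :] - ends[:, None]  # tau[j, k] = start_k - end_j
    b = 2.0 / mu**2 * np.outer(f, f) * np.exp(-mu * np.clip(tau, 0.0, None))
    b = np.triu(b, k=1)
    return a, b


def bed_grid(plan: "TreatmentPlan", params: RepairParameters) -> BEDGrid:
    """Evaluate the BED voxel-by-voxel over a treatment plan's dose lattice.

    Vectorized equivalent of applying :func:`bed_voxel` to every voxel of
    the plan; zero-dose voxels map to BED 0.  A 31x31x31 lattice with ~20
    shots evaluates in well under a second.
    """
    from .plan import build_timeline  # local import avoids a cycle

    doses = np.stack([shot.dose for shot in plan.shots])  # (N, *shape)
    beam_on = np.array([shot.beam_on for shot in plan.shots])
    timeline = build_timeline(plan)
    starts = np.array(timeline.starts)

    rates = doses / beam_on[:, None, None, None]
    d_total = doses.sum(axis=0)

    phi = np.zeros_like(d_total)
    c = params.partition_fast
    for weight, mu in ((c, params.mu_fast), (1.0 - c, params.mu_slow)):
        if weight == 0.0:
            continue
        a, b = _phi_weights(beam_on, starts, mu)
        term = np.einsum("k,k...->...", a, rates**2)
        jj, kk = np.nonzero(b)
        if jj.size:
            term = term + np.einsum(
                "p,p...->...", b[jj, kk], rates[jj] * rates[kk]
            )
        phi += weight * term

    values = d_total + phi / params.alpha_beta
    values[d_total == 0.0] = 0.0
    return BEDGrid(
        values=values,
        spacing_mm=plan.spacing_mm,
        alpha_beta=params.alpha_beta,
    )


# ---------------------------------------------------------------------------
# Independent numerical oracle
# ---------------------------------------------------------------------------

def phi_numeric_oracle(exposure: VoxelExposure, mu: float) -> float:
    """Brute-force Phi by adaptive quadrature (reference implementation).

    Evaluates ``2 * integral_{s < s'} R(s) R(s') exp(-mu (s' - s)) ds ds'``
    over the piecewise-constant rate function (rate 0 during beam-off) by
    adaptive quadrature on each segment-pair rectangle.  Deliberately avoids
    the closed forms used by :func:`phi_protocol`.
    """
    _check_mu(mu)
    n = len(exposure)
    if n == 0:
        return 0.0
    starts = exposure.start_times
    ends = exposure.end_times
    total = 0.0
    for j in range(n):
        rj = exposure.rates[j]
        if rj == 0.0:
            continue
        # self term: 2 * integral over the triangle s < s' within segment j
        def inner_self(s_prime: float, j: int = j) -> float:
            val, _ = integrate.quad(
                lambda s: math.exp(-mu * (s_prime - s)),
                starts[j],
                s_prime,
                epsabs=1e-13,
                epsrel=1e-10,
            )
            return val

        tri, _ = integrate.quad(
            inner_self, starts[j], ends[j], epsabs=1e-13, epsrel=1e-10, limit=200
        )
        total += 2.0 * rj * rj * tri
        for k in range(j + 1, n):
            rk = exposure.rates[k]
            if rk == 0.0:
                continue

            def inner_cross(s_prime: float, j: int = j) -> float:
                val, _ = integrate.quad(
                    lambda s: math.exp(-mu * (s_prime - s)),
                    starts[j],
                    ends[j],
                    epsabs=1e-13,
                    epsrel=1e-10,
                )
                return val

            rect, _ = integrate.quad(
                inner_cross, starts[k], ends[k], epsabs=1e-13, epsrel=1e-10,
                limit=200,
            )
            total += 2.0 * rj * rk * rect
    return total
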