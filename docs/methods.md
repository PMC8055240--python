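# Methods

## Model

The engine evaluates the linear-quadratic biologically effective dose of a
protracted, piecewise-constant dose-rate exposure with incomplete repair of
sublethal damage between and during sub-fractions.  Each iso-centre of a
Gamma Knife plan is one continuously irradiated segment; scheduled beam-off
pauses and unscheduled gaps separate segments on an absolute timeline.  For
one voxel,

    BED = D_T + [ c·Φ(μ_fast) + (1−c)·Φ(μ_slow) ] / (α/β),
    Φ(μ) = 2 ∬_{s<s'} R(s) R(s') e^{−μ(s'−s)} ds ds',

with the repair kernel a two-component exponential partitioned by `c`.
For piecewise-constant rates Φ expands into closed-form self terms
`(2R²/μ²)(μt − 1 + e^{−μt})` and cross terms
`(2R_jR_k/μ²)(1−e^{−μt_j})(1−e^{−μt_k})e^{−μτ}`, where τ is the end-to-start
separation of the pair taken from the absolute timeline, so non-adjacent
pairs automatically accumulate all intermediate beam-on and beam-off time.
The expansion is gated by a test against an independent adaptive-quadrature
oracle (1e-6 relative on randomized protocols at both repair rates) rather
than trusted; the factor-2 convention of the cross terms is thereby fixed
operationally.

Assumptions inherited from the model class: repair kinetics are
time-invariant and dose-independent; no repopulation or reoxygenation over
the ≤ 75 min horizon; dose grids are inputs (no transport physics); voxels
are independent (BED is evaluated per voxel).

## Parameters

| parameter | default | unit | origin |
|---|---|---|---|
| α/β | 2.47 | Gy | rat-spinal-cord collective fit (95% CI 1.50–3.95) |
| fast repair half-time | 11.4 | min | same fit (0.19 h) |
| slow repair half-time | 129.6 | min | same fit (2.16 h) |
| partition coefficient c | 0.35 | – | calibrated, see below |
| shell tolerance | ±0.02 (inclusive) | Gy | < 0.17% of a 12–13 Gy prescription |
| scheduled beam-off | 0.06 | min | average couch-repositioning pause |
| unscheduled gap | 15 | min | ≈ one fast repair half-time |
| exhaustive-search limit | 8 shots | – | 8! = 40,320 schedules |

All four radiobiological constants are plain fields of
`RepairParameters`; nothing is hard-coded.

**Calibration of `c`.**  The primary source for the partition coefficient
was not machine-readable in our working material, and the cited fit was
unreachable.  The default was therefore calibrated against the published
15-case cohort table (prescription, total time, shot count and original
shell-mean BED per case), inverting an idealized uniform-plan model:
least squares gives c ≈ 0.32 (RMSE 1.2 Gy over 15 cases), rising to
≈ 0.40 after correcting for the uniform model's downward bias (voxel-level
dose heterogeneity raises Φ by 1–2 Gy_2.47 on synthetic plans).  We froze
the midpoint c = 0.35.  Two further published statistics corroborate the
calibration independently: with c = 0.35 the synthetic pipeline produces
15 min-gap reductions and re-sequencing ranges on the scale the source
reports, whereas c near 1 overshoots both several-fold and underestimates
every printed BED.  Treat `c` as a calibrated, not transcribed, value.

## Shell statistics

The analysis metric is the arithmetic mean of per-voxel BED over the
prescription shell: all voxels whose **total** physical dose lies within
the inclusive ±0.02 Gy window (mean of BEDs, not BED of the mean dose).
The shell depends only on the summed dose grid, which is invariant under
re-ordering and gap edits, so one shell per case serves every downstream
evaluation.  An empty shell triggers a warning at extraction and an error
in any statistic computed on it.

## Gap analysis

A single unscheduled gap (default 15 min) is *added* to the scheduled
beam-off at one position, for every position in turn; dose grids are
untouched and the total treatment time grows by exactly the gap.  The
reported quantity is the relative change of shell-mean BED versus the
original plan, which is ≤ 0 for any positive gap and monotone
non-increasing in gap duration (both property-tested).  Multiple gaps
compose additively through the same interface but are outside the tested
envelope.

## Sequence search

The search objective is the shell-mean BED.  Its key computational
property: the shell mean is linear in the per-voxel protraction sums, so
it only needs the second-moment matrix `M[j,k] = ⟨R_j R_k⟩_shell`, which is
independent of delivery order and gap schedule.  `M` is cached once per
case; each candidate schedule then costs O(n²) exponential attenuation
factors, and the 8! sweep runs in seconds (evaluated in vectorized chunks
of 5040 permutations).  Exhaustive search refuses plans above the limit,
naming the factorial count, unless explicitly overridden.  Full grids are
recomputed only for winners (or via `bed_grid` on demand).

Because all scheduled gaps share the 0.06 min default, every schedule ties
its time-reversal; ties are broken by the lexicographically smallest
permutation (the enumeration order), making outputs deterministic.
Beam-off durations stay attached to schedule *slots* under re-ordering
(inert at uniform defaults; the alternative — gaps travelling with shots —
is not meaningful for the emulated cohort).

The heuristics are deterministic constructions from the per-shot mean
shell dose-rates:

* **pyramidal (max BED)** — shots sorted ascending by rate fill the
  schedule outside-in, alternating left/right ends, so the highest-rate
  shots end up contiguous mid-schedule;
* **zig-zag (min BED)** — alternate highest-remaining and lowest-remaining
  rate, spreading high-rate shots apart.

Ties break by original shot index; a fully tied rate vector returns the
original order (the rates then carry no information).  These concrete
rules are this package's determinization of the published qualitative
descriptions ("grouped in a pyramidal shape" / "spread out"); they are
validated by bracketing inside the exhaustive extremes on synthetic plans,
not asserted to be the source's exact rule.

Cohort statistics (group means, min-to-max spreads, achievable-range
`Δ_rel = 100·(BED_max − BED_min)/BED_orig`, heuristic mean gain/loss,
between-group BED ratio) are plain arithmetic on per-case rows; the paired
t-test on min- vs max-sequence BEDs uses the classical statistic with
`df = n − 1` (two-sided, via `scipy.stats.ttest_rel`), with zero-variance
differences rejected as degenerate.  A table-ingest path accepts printed
per-case values so the statistics are testable independently of the BED
engine; the published 15-case table ships as a reference fixture.

## Synthetic plan generator

The generator emulates the statistical structure of planning-system
research exports for vestibular-schwannoma-like targets:

* 31×31×31 lattice at 1 mm; ellipsoidal targets (semi-axes 6–10 mm; one
  elongated preset at ~11×4×4 mm for heuristic stress tests);
* shots are anisotropic Gaussian kernels at positions uniform in the
  target; profile FWHM = collimator size (4/8/16 mm) + 3 mm penumbra,
  elongated 1.5× axially, matching measured Gamma Knife profile widths;
  collimator choice is depth-dependent (large central, small peripheral),
  as in clinical packing;
* amplitudes solve a bounded least-squares fit: conform the summed dose to
  the prescription on the target surface while preferring a lognormal
  (σ = 0.9) per-shot contribution profile, every shot keeping a minimum
  surface presence — this reproduces per-shot mean shell dose-rate
  profiles with a few dominant shots and spans well above the 3× self-check
  floor;
* beam-on times spread modestly (lognormal σ = 0.35, 0.1 min floor) and
  independently of shell contribution, since every shot's focal dose is
  planned near the same multiple of the prescription; totals hit the
  requested treatment time exactly, inside the 20.8–73.7 min cohort range;
* default cohort: 6 cases at 12 Gy + 9 at 13 Gy, 4–19 shots, ordered by
  total time within group.

A ±0.02 Gy window on a 1 mm grid is intrinsically thin: the expected shell
is tens of voxels.  After fine-rescaling the plan so the prescription sits
at the densest candidate iso-level (30–70% of the maximum dose), draws
failing the ≥ 30-voxel shell or ≥ 3× rate-span self-checks are redrawn
(bounded retries, deterministic under seed).

**What a green synthetic test establishes** — that the pipeline reproduces
the *qualitative* published findings (BED falling with total time; gap
reductions of order 0.1–10%; pyramidal re-sequencing beating the original
order in most cases; significant min-vs-max separation) on plans with
realistic geometry, timing and rate heterogeneity.  It does not establish
per-case agreement with any real patient: the generator does not model
transport physics, skull attenuation, source decay within a session, or
the actual per-shot rate curves of the published figures (only their
shape class).

## Numerical choices

* `x − 1 + e^{−x}` switches to its series (`x²/2 − x³/6 + x⁴/24`) below
  `x = 1e-4`; `1 − e^{−x}` uses `expm1` throughout — both avoid
  catastrophic cancellation in the near-acute regime.
* `μ ≤ 0` is a domain error everywhere; the no-repair limit is reached
  stably by small μ (the series path), the instantaneous-repair limit by
  large μ (terms decay as `2ΣR_k²t_k/μ`).
* Zero-dose voxels map to BED 0 exactly; zero-rate segments may be kept
  (timeline clarity) or dropped — proven Φ-equivalent.
* Plan bundles store float32 Gy volumes (NIfTI); write∘read is identity to
  float32 precision, validated field-by-field with named errors; a
  manifest without beam-off data is filled with the 0.06 min default.
* Units are fixed package-wide: minutes, Gy, Gy/min; BED labels carry the
  α/β used (`Gy_2.47`).

## Known limitations

* The partition coefficient is calibrated, not transcribed (above); users
  with access to the primary fit should set all four constants explicitly.
* Shell means on ~30–70 voxels carry sampling noise of the shell
  definition itself; sub-voxel isosurface interpolation is out of scope.
* Exhaustive search beyond 8 shots is refused by default for cost reasons
  (13! ≈ 6.2e9 schedules); the heuristics are the intended tool there.
* Gap analysis models inter-shot interruptions only; intra-shot
  interruptions and multi-gap scenarios are untested territory.
* No DICOM-RT or planning-system connectivity; the bundle format is a
  neutral research stand-in.
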