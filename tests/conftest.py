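import numpy as np
import pytest

from gkbed import IsoCentre, RepairParameters, TreatmentPlan, VoxelExposure


@pytest.fixture
def params() -> RepairParameters:
    return RepairParameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_exposure(rng: np.random.Generator, max_segments: int = 5) -> VoxelExposure:
    """Random piecewise-constant protocol in the domain's realistic ranges."""
    n = int(rng.integers(1, max_segments + 1))
    return VoxelExposure(
        rates=tuple(rng.uniform(0.0, 5.0, n)),
        durations=tuple(rng.uniform(0.01, 10.0, n)),
        intervals=tuple(rng.uniform(0.0, 60.0, n - 1)),
    )


def random_plan(
    rng: np.random.Generator,
    n_shots: int = 5,
    shape: tuple[int, int, int] = (7, 7, 7),
    prescription: float = 12.0,
) -> TreatmentPlan:
    """Small random plan for engine-level tests (no shell realism needed)."""
    shots = tuple(
        IsoCentre(
            id=f"s{k}",
            beam_on=float(rng.uniform(0.5, 5.0)),
            dose=rng.uniform(0.0, 4.0, shape),
        )
        for k in range(n_shots)
    )
    return TreatmentPlan(
        case_id="toy",
        shots=shots,
        beam_off=tuple(rng.uniform(0.02, 0.5, n_shots - 1)),
        prescription=prescription,
    )


@pytest.fixture
def toy_plan(rng) -> TreatmentPlan:
    return random_plan(rng)
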