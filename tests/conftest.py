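import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amesbmd.plate_io import Design, DoseResponseArm, PlateRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


DESIGN = Design("NDMA", "plate_incorporation", "hamster", "dmso", "TA100")


def make_arm(
    treated,
    controls=(100, 100, 100, 100, 100, 100),
    design=DESIGN,
    toxicity_notes=None,
):
    """Arm from {dose: counts}; controls default to a flat 100."""
    doses = tuple(sorted(treated))
    return DoseResponseArm(
        design=design,
        doses=doses,
        treated_counts={d: tuple(treated[d]) for d in doses},
        control_counts=tuple(controls),
        toxicity_notes={
            d: frozenset(v) for d, v in (toxicity_notes or {}).items()
        },
    )


@pytest.fixture
def arm_factory():
    return make_arm


@pytest.fixture
def canonical_records():
    """One complete arm in the 3/6/2 scheme, plus positive controls."""
    d = DESIGN
    recs = [
        PlateRecord(*d, "vehicle_control", 0.0, 100 + i) for i in range(6)
    ]
    for j, dose in enumerate((50.0, 150.0, 500.0, 1500.0, 5000.0)):
        for i in range(3):
            recs.append(PlateRecord(*d, "treated", dose, 100 + 30 * j + i))
    recs += [PlateRecord(*d, "positive_control", 1.0, 900 + i) for i in range(2)]
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
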