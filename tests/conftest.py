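import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pamkit import amplicon_editing as ae
from pamkit import synthetic_data as sd

settings.register_profile(
    "pamkit",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pamkit")


@pytest.fixture(scope="session")
def default_model():
    return sd.default_activity_model()


@pytest.fixture(scope="session")
def small_library(default_model):
    """Read-level library pair at modest depth, error-free for exact bookkeeping."""
    cfg = sd.LibrarySimConfig(depth=20_000, error_rate=0.0, seed=7)
    return sd.simulate_library(default_model, cfg)


@pytest.fixture(scope="session")
def plus_site():
    return sd.make_test_site("plus_site", "+")


@pytest.fixture(scope="session")
def minus_site():
    return sd.make_test_site("minus_site", "-")


@pytest.fixture(scope="session")
def ct_position(plus_site):
    """A protospacer-strand C inside the default editing window."""
    return next(p for p in range(-21, -7) if plus_site.base_at(p) == "C")


@pytest.fixture(scope="session")
def amplicon_run(plus_site, ct_position):
    """One aligned edited/control replicate with planted truth, shared by tests."""
    artifact = ae.MutationKey("sub", 5, "G" if plus_site.reference[5] != "G" else "A")
    cfg = sd.AmpliconSimConfig(
        site=plus_site,
        indel_frequency=0.40,
        ct_truth={ct_position: 0.20},
        control_artifacts=[(artifact, 0.02)],
        depth=2000,
        seed=11,
    )
    sim = sd.simulate_amplicons(cfg)
    edited = ae.align_sample(sim.edited_reads, plus_site)
    control = ae.align_sample(sim.control_reads, plus_site)
    return {"sim": sim, "edited": edited, "control": control,
            "site": plus_site, "artifact": artifact, "ct_position": ct_position}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
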