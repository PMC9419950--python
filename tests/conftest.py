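import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from crispramp.oligo_design import GuideSpec
from crispramp.synthetic import (
    SimulationConfig,
    make_loci,
    make_samples,
)


@pytest.fixture(scope="session")
def guide() -> GuideSpec:
    return GuideSpec(spacer="GGGCACTAGCTTACGGATCC", pam="TGG")


@pytest.fixture(scope="session")
def loci():
    return make_loci(seed=11, n_off_targets=2, mismatches_per_off_target=2)


@pytest.fixture(scope="session")
def samples(loci):
    return make_samples(loci, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, loci, samples):
    """A small error-free simulated run shared across tests."""
    from crispramp.synthetic import write_run

    cfg = SimulationConfig(
        true_indel_rate=0.3,
        substitution_error_rate=0.0,
        n_reads=200,
        seed=11,
    )
    out = tmp_path_factory.mktemp("smallrun")
    manifest = write_run(loci, samples, cfg, out)
    return {"cfg": cfg, "manifest": manifest, "loci": loci, "samples": samples}
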