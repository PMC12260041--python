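import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from udil.synthetic import DomainSpec, StreamSpec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_stream_spec(master_seed: int = 0, n_domains: int = 3) -> StreamSpec:
    """Small, fast stream for trainer unit tests (not the study conditions)."""
    specs = []
    for k in range(n_domains):
        shift = np.zeros(6)
        shift[k % 6] = 1.2 * k
        specs.append(
            DomainSpec(
                name=f"d{k + 1}",
                n_positive=16,
                n_negative=32,
                dim=6,
                mean_shift=tuple(shift),
                class_separation=2.5,
            )
        )
    ood = DomainSpec(
        name="ood", n_positive=8, n_negative=24, dim=6,
        mean_shift=tuple([5.0] * 6), rotation_seed=3, scale=4.0, class_separation=2.5,
    )
    return StreamSpec(domains=tuple(specs), ood_domain=ood, test_fraction=0.25,
                      master_seed=master_seed)


@pytest.fixture
def tiny_stream():
    return tiny_stream_spec()
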