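import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FS = 173.61


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fs():
    return FS


@pytest.fixture
def tiny_tree(tmp_path):
    """A 2-records-per-class Bonn-dialect tree with small integer records."""
    from ictalnet.bonn import CLASS_LABELS

    gen = np.random.default_rng(7)
    for label in CLASS_LABELS:
        d = tmp_path / label
        d.mkdir()
        for i in range(2):
            vals = gen.integers(-100, 100, size=64)
            (d / f"{label}{i:03d}.txt").write_text(
                "\n".join(str(v) for v in vals) + "\n"
            )
    return tmp_path
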