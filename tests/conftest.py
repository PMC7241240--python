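import numpy as np
import pytest

from mota.blocks import GroupedStudy, OmicBlock
from mota.synthetic import FixtureSpec, generate


@pytest.fixture
def tiny_study():
    """Two-block study, 12 samples, small enough for exhaustive checks."""
    rng = np.random.default_rng(42)
    samples = [f"s{i}" for i in range(12)]
    b1 = OmicBlock("metab", samples, ["m1", "m2", "m3", "m4"],
                   rng.standard_normal((12, 4)))
    b2 = OmicBlock("prot", samples, ["p1", "p2", "p3"],
                   rng.standard_normal((12, 3)))
    groups = {s: (1 if i < 6 else 2) for i, s in enumerate(samples)}
    return GroupedStudy(blocks=[b1, b2], group_of=groups)


@pytest.fixture(scope="session")
def planted_study():
    """Fixture with one differential intra pair, cross links and a mean shift."""
    spec = FixtureSpec(
        n_per_group=100,
        blocks=[("metab", 10), ("prot", 6)],
        intra_edges=[(0, 1, 0.6, 0.0)],
        cross_links=[(0, "prot", i, 0.7, 0.0) for i in range(3)],
        mean_shifts={0: 1.0},
        seed=11,
    )
    return generate(spec)
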