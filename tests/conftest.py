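import pytest
from hypothesis import HealthCheck, settings

import ppimcl as pm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def triangle() -> pm.ProteinGraph:
    return pm.ProteinGraph.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3() -> pm.ProteinGraph:
    return pm.ProteinGraph.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def two_triangles() -> pm.ProteinGraph:
    return pm.ProteinGraph.from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
    )


@pytest.fixture(scope="session")
def synthetic_dataset():
    """The seeded planted-complex benchmark used by the heavier tests."""
    spec = pm.SyntheticSpec(seed=11)
    g, truth, expr = pm.simulate_dataset(spec)
    return spec, g, truth, expr


@pytest.fixture(scope="session")
def synthetic_model(synthetic_dataset):
    _, g, _, expr = synthetic_dataset
    return pm.CoexpressionModel.build(g, expr)
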