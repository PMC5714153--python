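import pytest
from hypothesis import HealthCheck, settings

from datamed_rank import build_index
from datamed_rank import synthetic

settings.register_profile(
    "default",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def collection():
    """Default synthetic study collection (seed 7), shared read-only."""
    return synthetic.generate(synthetic.SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def coll_index(collection):
    return build_index(collection.records)


@pytest.fixture(scope="session")
def coll_embeddings(collection):
    return synthetic.make_embeddings(
        synthetic.SyntheticSpec(seed=7), collection=collection
    )


@pytest.fixture(scope="session")
def coll_qrels(collection):
    return synthetic.make_qrels(collection.manifest, seed=7)
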