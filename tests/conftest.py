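import pytest
from hypothesis import HealthCheck, settings

from iterotu.align import SimilaritySpec
from iterotu.simulate import CommunitySpec, generate_community

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec097() -> SimilaritySpec:
    return SimilaritySpec(threshold=0.97)


@pytest.fixture(scope="session")
def small_community():
    """20 well-separated planted clusters (mass 10-60), 20% singletons."""
    spec = CommunitySpec(
        n_clusters=20,
        distribution="uniform",
        dist_params={"low": 10, "high": 60},
        similarity_threshold=0.97,
        seed=11,
    )
    ds, gt = generate_community(spec)
    return ds, gt, spec
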