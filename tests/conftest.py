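import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from dreamnet import SyntheticSpec, generate_corpora  # noqa: E402


#: Strong-separation regime: big corpora, most of the vocabulary shared and
#: equally prevalent, enriched conditions displaced far beyond the bottom of
#: the base ranking. Used wherever planted-class recovery is scored.
STRONG_SPEC = SyntheticSpec(
    n_conditions=250,
    zipf_exponent=1.1,
    n_mentions_waking=500_000,
    n_reports=40_000,
    report_size_mean=2.5,
    frac_shared=0.80,
    frac_waking_only=0.02,
    frac_dream_only=0.02,
    frac_waking_enriched=0.08,
    frac_dream_enriched=0.08,
    rank_shift=5000.0,
    seed=1,
)

#: Dense planted-cluster regime for co-occurrence recovery checks.
CLUSTER_SPEC = SyntheticSpec(
    n_conditions=100,
    zipf_exponent=1.0,
    n_mentions_waking=10_000,
    n_reports=4_000,
    report_size_mean=3.0,
    frac_shared=1.0,
    frac_waking_only=0.0,
    frac_dream_only=0.0,
    frac_waking_enriched=0.0,
    frac_dream_enriched=0.0,
    rank_shift=1.0,
    n_clusters=5,
    within_cluster_prob=0.9,
    seed=5,
)

#: Small fast corpus for end-to-end and I/O tests.
SMALL_SPEC = SyntheticSpec(
    n_conditions=80,
    n_mentions_waking=4_000,
    n_reports=600,
    report_size_mean=2.0,
    rank_shift=40.0,
    n_clusters=4,
    seed=11,
)


@pytest.fixture(scope="session")
def strong_corpora():
    return generate_corpora(STRONG_SPEC)


@pytest.fixture(scope="session")
def cluster_corpora():
    return generate_corpora(CLUSTER_SPEC)


@pytest.fixture(scope="session")
def small_corpora():
    return generate_corpora(SMALL_SPEC)
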