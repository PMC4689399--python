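"""Shared fixtures: tiny named graphs and session-scoped synthetic benchmarks.

The expensive artifacts (benchmark graphs plus their full feature matrices)
are computed once per session and shared; everything is generated from
fixed seeds so the suite is deterministic.
"""

import logging

import pytest

from netdrugg.pipeline import RunConfig, compute_features
from netdrugg.pu_model import PUEnsembleRegressor
from netdrugg.synthetic_benchmark import BenchmarkSpec, generate, small_fixtures

logging.getLogger("netdrugg").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fixtures():
    return small_fixtures()


@pytest.fixture(scope="session")
def validation_estimator():
    """Reduced-size ensemble used for validation runs (signal is strong enough
    that 100 trees/stages and 500 behave identically on the planted benchmarks)."""
    return PUEnsembleRegressor(n_trees=100, gbm_stages=100)


@pytest.fixture(scope="session")
def bench_small():
    """A small planted cancer-like benchmark with its full feature matrix."""
    spec = BenchmarkSpec(n_nodes=300, n_communities=5, n_positives=30,
                         p_intra=0.08, p_inter=0.004, seed=7)
    g, labels, manifest = generate(spec)
    config = RunConfig(seed=7, n_trees=60, gbm_stages=60)
    features, partitions = compute_features(g, config)
    return {"graph": g, "labels": labels, "manifest": manifest,
            "features": features, "partitions": partitions, "spec": spec}


@pytest.fixture(scope="session")
def bench_default():
    """The reference study conditions: n=2000, 10 communities, 100 positives."""
    spec = BenchmarkSpec(seed=101)
    g, labels, manifest = generate(spec)
    features, partitions = compute_features(g, RunConfig(seed=101))
    return {"graph": g, "labels": labels, "manifest": manifest,
            "features": features, "partitions": partitions, "spec": spec}
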