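import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spanflow import (
    BayesNet,
    BenefitSpec,
    GridSpec,
    NodeDef,
    RasterLayer,
    RouterSpec,
    SpanProblem,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def grid3():
    return GridSpec(3, 3, 10.0)


def make_layer(values, cell_size=10.0, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    spec = GridSpec(values.shape[0], values.shape[1], cell_size, nodata=nodata)
    return RasterLayer(spec, values)


def random_d8_problem(rng, n=5, rivalness="rival", benefit_type="provisioning"):
    """A random small downslope problem with a tilted noisy DEM."""
    cols = np.arange(n)
    dem_vals = rng.random((n, n)) * 2.0 + (n - 1 - cols)[None, :] * 1.5
    spec = GridSpec(n, n, 10.0)
    dem = RasterLayer(spec, dem_vals)
    source = RasterLayer(spec, rng.integers(0, 6, (n, n)).astype(float))
    sink = RasterLayer(spec, rng.integers(0, 3, (n, n)).astype(float))
    use = RasterLayer(spec, rng.integers(0, 4, (n, n)).astype(float))
    return SpanProblem(
        source, sink, use,
        BenefitSpec(benefit_type, rivalness, "water", "m3/yr"),
        RouterSpec("d8_downslope", dem=dem),
    )


def random_bayes_net(rng, max_nodes=6):
    """A random binary DAG with random CPTs (edges only forward)."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    nodes = {m: NodeDef(("s0", "s1"), midpoints=(0.0, 1.0)) for m in names}
    parents = {}
    for i, m in enumerate(names):
        pool = names[:i]
        k = int(rng.integers(0, min(len(pool), 2) + 1))
        chosen = sorted(rng.choice(len(pool), size=k, replace=False)) if k else []
        parents[m] = tuple(pool[c] for c in chosen)
    cpts = {}
    for m in names:
        shape = tuple(2 for _ in parents[m]) + (2,)
        raw = rng.random(shape) + 0.05
        cpts[m] = raw / raw.sum(axis=-1, keepdims=True)
    return BayesNet(nodes, parents, cpts)
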