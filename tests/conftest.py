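import numpy as np
import pytest

from hetpaths import (
    MetaPath,
    MetricContext,
    SchemaSpec,
    fixture_fix1,
    generate_kg,
    precompute_adjacency,
)

RDPF = MetaPath.of("drug", "disease", "protein", "function")
RDR = MetaPath.of("drug", "disease", "drug")


@pytest.fixture(scope="session")
def fix1():
    return fixture_fix1()


@pytest.fixture(scope="session")
def fix1_index(fix1):
    return precompute_adjacency(fix1)


@pytest.fixture()
def fix1_ctx(fix1_index):
    return MetricContext(fix1_index)


def random_schema(seed: int, n_per_type: int = 25) -> SchemaSpec:
    """A small random biokg-like schema; densities drawn per type pair."""
    rng = np.random.default_rng(seed)
    types = ["disease", "drug", "protein", "function", "side-effect"]
    counts = {t: int(rng.integers(n_per_type // 2, n_per_type + 1)) for t in types}
    pairs = [
        ("disease", "drug"), ("disease", "protein"), ("function", "protein"),
        ("drug", "protein"), ("drug", "side-effect"), ("protein", "protein"),
    ]
    density = {p: float(rng.uniform(0.01, 0.12)) for p in pairs}
    return SchemaSpec(type_counts=counts, edge_density=density, seed=seed)


def random_graph(seed: int, n_per_type: int = 25):
    return generate_kg(random_schema(seed, n_per_type))


def random_metapath(seed: int, max_types: int = 5) -> MetaPath:
    """A random admissible metapath walking the schema's nonzero type pairs."""
    rng = np.random.default_rng(seed)
    steps = {
        "disease": ["drug", "protein"],
        "drug": ["disease", "protein", "side-effect"],
        "protein": ["disease", "function", "drug", "protein"],
        "function": ["protein"],
        "side-effect": ["drug"],
    }
    length = int(rng.integers(2, max_types + 1))
    t = str(rng.choice(sorted(steps)))
    types = [t]
    while len(types) < length:
        t = str(rng.choice(steps[types[-1]]))
        types.append(t)
    return MetaPath(tuple(types))


def sample_typed_pair(graph, metapath, seed: int):
    """A random (origin, destination) with the metapath's endpoint types, or None."""
    rng = np.random.default_rng(seed)
    origins = sorted(n for n, t in graph.type_of.items() if t == metapath.types[0])
    dests = sorted(n for n, t in graph.type_of.items() if t == metapath.types[-1])
    if not origins or not dests:
        return None
    return str(rng.choice(origins)), str(rng.choice(dests))
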