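import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from crosstalk import PropagationParams, RunConfig, generate_fixture, run_pipeline
from crosstalk.config import SyntheticConfig
from crosstalk.propagation import null_ensemble, score_phenotype
from crosstalk.subnetwork import build_phenotype_network

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_path() -> nx.Graph:
    graph = nx.Graph()
    graph.add_edges_from([("A", "B"), ("B", "C")])
    return graph


@pytest.fixture(scope="session")
def headline_run():
    """The default synthetic fixture (n=1000, 2 CVD + 1 CD + 1 OS modules of
    40, 10 planted bridges) scored end to end — shared across tests because
    propagation with the full null ensemble is the expensive step."""
    graph, seed_sets, truth = generate_fixture(12345)
    params = PropagationParams(rng_seed=7)
    nulls = null_ensemble(graph, params)
    tables = {}
    components = {}
    for seed_set in seed_sets:
        combo, parts = score_phenotype(
            graph, seed_set, params, null_graphs=nulls, return_components=True
        )
        tables[seed_set.phenotype_id] = combo
        components[seed_set.phenotype_id] = parts
    networks = {
        s.phenotype_id: build_phenotype_network(graph, tables[s.phenotype_id], s)
        for s in seed_sets
    }
    return {
        "graph": graph,
        "seed_sets": seed_sets,
        "truth": truth,
        "params": params,
        "tables": tables,
        "components": components,
        "networks": networks,
    }


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A complete but scaled-down pipeline run (n=250, modules of 20)."""
    out_dir = tmp_path_factory.mktemp("small_run")
    config = RunConfig(
        rng_seed=123,
        out_dir=out_dir,
        synthetic=SyntheticConfig(
            n_nodes=250, module_size=20, n_bridges=6, n_decoy_sets=10
        ),
    )
    return config, run_pipeline(config)
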