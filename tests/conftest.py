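import numpy as np
import pytest

from wardflow import (
    ArrivalProfile,
    CarePathway,
    Ward,
    build_network,
    make_constant_service,
    make_spike_arrivals,
    make_toy_hospital,
)
from wardflow.network_model import SENTINEL_CAPACITY


def sentinel_ward(name):
    return Ward(name, SENTINEL_CAPACITY, SENTINEL_CAPACITY)


@pytest.fixture
def chain_network():
    """Source -> A -> Sink with A: 10 beds, 10 servers, queue capacity 5."""
    wards = [
        sentinel_ward("Source"),
        Ward("A", 10, 10, (5.0, 5.0, 5.0)),
        sentinel_ward("Sink"),
    ]
    edges = [
        CarePathway("Source", "A", 5.0, 1.0),
        CarePathway("A", "Sink", 5.0, 1.0),
    ]
    return build_network(wards, edges, "Source", "Sink")


@pytest.fixture
def three_chain_network():
    """Source -> A -> B -> Sink, distinct capacities for bottleneck tests."""
    wards = [
        sentinel_ward("Source"),
        Ward("A", 10, 10, (4.0,)),
        Ward("B", 8, 8, (6.0,)),
        sentinel_ward("Sink"),
    ]
    edges = [
        CarePathway("Source", "A", 5.0, 1.0),
        CarePathway("A", "B", 3.0, 1.0),
        CarePathway("B", "Sink", 7.0, 1.0),
    ]
    return build_network(wards, edges, "Source", "Sink")


@pytest.fixture
def toy_hospital():
    return make_toy_hospital(seed=1)


@pytest.fixture
def spike_profile():
    return make_spike_arrivals()


@pytest.fixture
def constant_5_01(toy_hospital):
    return make_constant_service(toy_hospital, 5.01)


@pytest.fixture
def flat_profile():
    return ArrivalProfile((1.0,) * 6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_tables(tmp_path, net, arrivals=None):
    """Write a network (and optionally an arrival profile) as CSV tables."""
    from wardflow.network_model import write_network_tables

    wards_p = tmp_path / "wards.csv"
    edges_p = tmp_path / "edges.csv"
    los_p = tmp_path / "los.csv"
    write_network_tables(net, wards_p, edges_p, los_p)
    paths = {"wards": wards_p, "edges": edges_p, "los": los_p}
    if arrivals is not None:
        arr_p = tmp_path / "arrivals.csv"
        with open(arr_p, "w") as fh:
            fh.write("hour,rate\n")
            for h, r in enumerate(arrivals.rates):
                fh.write(f"{h},{r}\n")
        paths["arrivals"] = arr_p
    return paths
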