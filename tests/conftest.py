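import pytest

from tcpin.mcl_clustering import MCLParams, mcl
from tcpin.synthetic_data import (
    SyntheticSpec,
    make_annotations,
    make_expression,
    make_network,
)


@pytest.fixture(scope="session")
def study_spec():
    """The planted-complex study conditions used across the suite."""
    return SyntheticSpec()


@pytest.fixture(scope="session")
def planted(study_spec):
    return make_network(study_spec)


@pytest.fixture(scope="session")
def planted_network(planted):
    return planted[0]


@pytest.fixture(scope="session")
def planted_complexes(planted):
    return planted[1]


@pytest.fixture(scope="session")
def planted_expression(study_spec, planted):
    return make_expression(study_spec, *planted)


@pytest.fixture(scope="session")
def planted_annotations(planted):
    network, complexes = planted
    return make_annotations(complexes, seed=0, all_genes=set(network.nodes()))


@pytest.fixture(scope="session")
def planted_modules(planted_network):
    """MCL modules (size >= 2) of the full planted network at inflation 2.0."""
    result = mcl(planted_network, MCLParams(inflation=2.0))
    return [c for c in result.clusters if len(c) >= 2]


@pytest.fixture(scope="session")
def tcpin_modules(planted_network, planted_expression):
    """Cleaned time-course modules from the full planted pipeline."""
    from tcpin.io_formats import Module, ModuleSet
    from tcpin.module_postprocess import clean_modules
    from tcpin.tcpin_builder import build_tcpins, filter_expression

    active = filter_expression(planted_expression)
    raw = []
    for t, net in enumerate(build_tcpins(planted_network, active)):
        if net.number_of_nodes() == 0:
            continue
        result = mcl(net, MCLParams(inflation=2.0))
        raw.extend(Module(c, t, i) for i, c in enumerate(result.clusters))
    return clean_modules(ModuleSet(raw)).protein_sets()
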