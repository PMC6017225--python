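import numpy as np
import pytest

from dendrisome.cgmap import assign_bonded_params, map_to_cg
from dendrisome.grammar import build_janus
from dendrisome.structures import get_fixture


@pytest.fixture(scope="session")
def janus_tree():
    return build_janus()


@pytest.fixture(scope="session")
def janus_topology(janus_tree):
    return map_to_cg(janus_tree)


@pytest.fixture(scope="session")
def parameterized_topology(janus_topology):
    return assign_bonded_params(janus_topology)


@pytest.fixture(scope="session")
def reference_patch():
    return get_fixture("reference_patch")


def brute_force_clusters(frame, cutoff, selection="hydrophobic_total"):
    """O(N^2) minimum-image single-linkage components (independent oracle)."""
    import networkx as nx

    mask = frame.select(selection)
    pos = frame.coords[mask]
    mols = frame.molecule_id[mask]
    g = nx.Graph()
    g.add_nodes_from(range(frame.n_molecules))
    for i in range(len(pos)):
        d = pos[i + 1:] - pos[i]
        d -= frame.box * np.round(d / frame.box)
        close = np.nonzero((d ** 2).sum(axis=1) < cutoff ** 2)[0]
        for j in close:
            g.add_edge(int(mols[i]), int(mols[i + 1 + j]))
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=len, reverse=True)
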