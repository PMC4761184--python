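import itertools
import random

import networkx as nx
import pytest

from unbio.combimol import ChemSpaceSpec, MoleculeSet, enumerate_space, sample_space
from unbio.molgraph import MolecularGraph, parse_structure


@pytest.fixture(scope="session")
def tri_metabolome() -> MoleculeSet:
    """Ethanol, acetic acid, glycine: 3-fragments {CCO, CC=O, O=CO, NCC}."""
    return MoleculeSet.from_smiles(["CCO", "CC(=O)O", "NCC(=O)O"])


@pytest.fixture(scope="session")
def chon_space() -> MoleculeSet:
    """Small acyclic CHON space used as a sampling pool in several suites."""
    spec = ChemSpaceSpec(
        elements=("C", "N", "O"),
        max_size=5,
        allowed_bond_orders=(1, 2),
        ring_policy="acyclic_only",
    )
    return enumerate_space(spec)


@pytest.fixture(scope="session")
def random_molecules(chon_space) -> list[MolecularGraph]:
    """A deterministic, diverse molecule list (sizes 1-5, CHON)."""
    rng = random.Random(7)
    mols = list(chon_space)
    return [mols[rng.randrange(len(mols))] for _ in range(60)]


def brute_force_mcs_size(a: MolecularGraph, b: MolecularGraph) -> int:
    """Independent maximum-common-subgraph size: exhaustive search over all
    connected subgraphs (atom subsets x bond subsets) of ``a``, tested
    against ``b`` by raw VF2 monomorphism on networkx graphs."""
    from networkx.algorithms import isomorphism as iso

    best = 0
    ga, gb = a.graph, b.graph
    nodes = list(ga.nodes)
    for r in range(len(nodes), 0, -1):
        if r <= best:
            break
        for atom_subset in itertools.combinations(nodes, r):
            induced = ga.subgraph(atom_subset)
            if not nx.is_connected(induced):
                continue
            edges = list(induced.edges)
            for m in range(len(edges), r - 2, -1):
                for bond_subset in itertools.combinations(edges, m):
                    cand = nx.Graph()
                    for n_ in atom_subset:
                        cand.add_node(n_, el=ga.nodes[n_]["el"])
                    for u, v in bond_subset:
                        cand.add_edge(u, v, order=ga.edges[u, v]["order"])
                    if not nx.is_connected(cand):
                        continue
                    gm = iso.GraphMatcher(
                        gb,
                        cand,
                        node_match=iso.categorical_node_match("el", None),
                        edge_match=iso.categorical_edge_match("order", None),
                    )
                    if gm.subgraph_is_monomorphic():
                        best = max(best, r)
                        break
                if best == r:
                    break
            if best == r:
                break
    return best
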